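"""Descriptive group comparisons: median-split labels, KS and Wilcoxon tests,
Bonferroni control over the 16 comparison cells, and topographic interpolation.

The 16 cells are the product of the four separation classes, the two
prefrontal sides, and the two task episodes; channels are the pairing unit
within a cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import griddata

from .constants import ALPHA_DEFAULT, K_DEFAULT, SEPARATION_CLASSES
from .features import ActivationMatrix
from .synthetic.layout import ChannelLayout


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class StatsConfig:
    alpha: float = ALPHA_DEFAULT
    k: int = K_DEFAULT

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise StatsError("alpha must lie in (0, 1)")
        if self.k < 1:
            raise StatsError("k must be >= 1")

    @property
    def threshold(self) -> float:
        return self.alpha / self.k


def median_split(scores: np.ndarray) -> np.ndarray:
    """Within-group high/low labels: score > median -> 'high', else 'low'."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise StatsError("cannot median-split an empty group")
    if scores.size < 2:
        warnings.warn("median split of a single score is degenerate; labelled low",
                      stacklevel=2)
    med = np.median(scores)
    return np.where(scores > med, "high", "low")


def ks_compare(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov D statistic and asymptotic p-value."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsError("KS test needs at least 2 values per sample")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def wilcoxon_paired(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired values; zeros dropped."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise StatsError("paired samples must have equal length")
    diffs = a - b
    if np.all(diffs == 0):
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 0.0, 1.0
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def bonferroni(p_values: np.ndarray, config: StatsConfig | None = None) -> np.ndarray:
    """Significance flags p_i < alpha / k."""
    config = config or StatsConfig()
    config.validate()
    p = np.asarray(p_values, dtype=float)
    if p.size > config.k:
        raise StatsError(f"{p.size} tests exceed the configured k={config.k}")
    return p < config.threshold


def compare_cells(
    matrix: ActivationMatrix,
    comparison: str,
    group: str | None = None,
    config: StatsConfig | None = None,
    test: str = "wilcoxon",
) -> pd.DataFrame:
    """Per-cell comparison over (separation class, hemisphere, task episode).

    ``comparison='skill'`` contrasts student v attending rows; ``'load'``
    contrasts high v low TLX rows within ``group``.  Channel-wise means over
    the relevant rows form the paired samples of each cell.
    """
    if comparison not in ("skill", "load"):
        raise StatsError("comparison must be 'skill' or 'load'")
    if comparison == "load" and group is None:
        raise StatsError("load comparison requires a group")
    config = config or StatsConfig()
    config.validate()

    episodes = sorted(matrix.row_meta["episode"].unique())
    rows = []
    for episode in episodes:
        if comparison == "skill":
            ra = matrix.rows_for(episode=episode, group="student")
            rb = matrix.rows_for(episode=episode, group="attending")
        else:
            r = matrix.rows_for(episode=episode, group=group)
            lab = matrix.row_meta.loc[r, "load_label"].to_numpy()
            ra, rb = r[lab == "high"], r[lab == "low"]
        for sep in SEPARATION_CLASSES:
            for hemi in ("L", "R"):
                cols = matrix.columns_for(separation_cm=sep, hemisphere=hemi)
                if cols.size == 0 or ra.size == 0 or rb.size == 0:
                    rows.append(
                        dict(comparison=comparison, episode=episode, class_cm=sep,
                             hemisphere=hemi, n_channels=int(cols.size),
                             statistic=np.nan, p=np.nan, median_diff=np.nan)
                    )
                    continue
                a = matrix.values[np.ix_(ra, cols)].mean(axis=0)
                b = matrix.values[np.ix_(rb, cols)].mean(axis=0)
                if test == "wilcoxon":
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        stat, p = wilcoxon_paired(a, b)
                else:
                    stat, p = ks_compare(a, b)
                rows.append(
                    dict(comparison=comparison, episode=episode, class_cm=sep,
                         hemisphere=hemi, n_channels=int(cols.size),
                         statistic=stat, p=p,
                         median_diff=float(np.median(a - b)))
                )
    out = pd.DataFrame(rows)
    with np.errstate(invalid="ignore"):
        out["significant"] = np.where(
            np.isfinite(out["p"]), out["p"] < config.threshold, False
        )
    return out


def topographic_map(
    activations: np.ndarray,
    layout: ChannelLayout,
    channel_index: np.ndarray | None = None,
    grid_resolution: int = 50,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linear interpolation of channel activations onto a regular grid.

    Returns (grid_x, grid_y, field); grid nodes outside the convex hull of
    the channel midpoints are NaN.
    """
    idx = np.arange(layout.n_channels) if channel_index is None else np.asarray(channel_index)
    pts = layout.midpoints[idx]
    vals = np.asarray(activations, dtype=float)
    if vals.shape[0] != idx.shape[0]:
        raise StatsError("activation vector does not match the channel subset")
    if pts.shape[0] < 3 or np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 2:
        raise StatsError("need at least 3 non-collinear channel midpoints")
    gx = np.linspace(pts[:, 0].min(), pts[:, 0].max(), grid_resolution)
    gy = np.linspace(pts[:, 1].min(), pts[:, 1].max(), grid_resolution)
    mx, my = np.meshgrid(gx, gy)
    field = griddata(pts, vals, (mx, my), method="linear", fill_value=np.nan)
    return mx, my, field
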