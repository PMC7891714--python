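"""Activation features: window statistics, episode averaging, superficial
signal regression, and assembly of the labelled feature matrix.

The activation measure is the SD of the (band-passed) oxyhemoglobin changes
in non-overlapping 10 s windows, averaged over the retained windows of a task
episode.  Rows of the feature matrix are (subject, task-episode) observations
and columns are channels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import kurtosis, skew

from .preprocess import HbSeries, window_length_samples
from .synthetic.layout import ChannelLayout
from .synthetic.simulate import ProtocolSchedule, TLXRecord

logger = logging.getLogger(__name__)

MIN_RETAINED_WINDOWS = 3

_STATISTICS = {
    "sd": lambda x: x.std(axis=1, ddof=1),
    "mean": lambda x: x.mean(axis=1),
    "skewness": lambda x: skew(x, axis=1),
    "kurtosis": lambda x: kurtosis(x, axis=1),
}


class FeatureError(ValueError):
    pass


def window_statistic(
    series: np.ndarray, fs: float, window_s: float, statistic: str = "sd"
) -> np.ndarray:
    """Per-window statistic over complete non-overlapping windows (axis 0)."""
    if statistic not in _STATISTICS:
        raise FeatureError(
            f"unknown statistic {statistic!r}; choose from {sorted(_STATISTICS)}"
        )
    arr = np.asarray(series, dtype=float)
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[:, None]
    w = window_length_samples(fs, window_s)
    n_win = arr.shape[0] // w
    if n_win < 1:
        raise FeatureError("series shorter than one window")
    trimmed = arr[: n_win * w].reshape(n_win, w, arr.shape[1])
    out = _STATISTICS[statistic](trimmed)
    return out[:, 0] if squeeze else out


def episode_window_index(
    schedule: ProtocolSchedule, episode: str, fs: float, window_s: float, n_windows: int
) -> np.ndarray:
    """Indices of complete windows lying fully inside the episode."""
    ep = schedule.episode(episode)  # raises KeyError naming the episode
    w = window_length_samples(fs, window_s)
    starts = np.arange(n_windows) * w / fs
    ends = starts + w / fs
    return np.nonzero((starts >= ep.start_s - 1e-9) & (ends <= ep.end_s + 1e-9))[0]


def episode_activation(
    window_values: np.ndarray,
    mask: np.ndarray,
    schedule: ProtocolSchedule,
    episode: str,
    fs: float,
    window_s: float,
) -> np.ndarray:
    """Mean of retained window statistics inside an episode, per channel.

    Channels with fewer than three retained windows are returned as NaN
    (missing) so that imputation downstream is explicit.
    """
    window_values = np.atleast_2d(np.asarray(window_values, dtype=float).T).T
    mask = np.atleast_2d(np.asarray(mask, dtype=bool).T).T
    if window_values.shape != mask.shape:
        raise FeatureError("window values and mask shapes differ")
    idx = episode_window_index(schedule, episode, fs, window_s,
                               window_values.shape[0])
    vals = window_values[idx]
    keep = mask[idx]
    counts = keep.sum(axis=0)
    with np.errstate(invalid="ignore"):
        sums = np.where(keep, vals, 0.0).sum(axis=0)
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    means = np.where(counts >= MIN_RETAINED_WINDOWS, means, np.nan)
    return means


def ssr(
    series: np.ndarray,
    layout: ChannelLayout,
    target_classes: tuple[float, ...] = (3.0, 3.35),
    short_class: float = 1.5,
) -> np.ndarray:
    """Superficial signal regression on long-separation channels.

    Each target channel is regressed on the short-separation channel with the
    nearest midpoint (ties break to the lowest channel id); the least-squares
    slope beta = <y, s> / <s, s> is fitted over the whole recording and the
    residual y - beta * s replaces the target channel.  A zero-variance
    regressor leaves the channel unchanged with a warning.
    """
    out = np.array(series, dtype=float, copy=True)
    targets = np.nonzero(
        np.any([np.isclose(layout.separations, c) for c in target_classes], axis=0)
    )[0]
    for i in targets:
        j = layout.nearest_short(int(i), short_class)
        s = series[:, j]
        denom = float(s @ s)
        if denom == 0.0:
            warnings.warn(
                f"zero-variance short regressor for channel {layout.ids[i]}; "
                "channel left unchanged",
                stacklevel=2,
            )
            continue
        beta = float(series[:, i] @ s) / denom
        out[:, i] = series[:, i] - beta * s
    return out


def subject_activations(
    hb: HbSeries,
    layout: ChannelLayout,
    use_ssr: bool = False,
    statistic: str = "sd",
) -> dict[str, np.ndarray]:
    """Per task episode, the per-channel episode-averaged window statistic."""
    series = hb.hbo
    if use_ssr:
        series = ssr(series, layout)
    wv = window_statistic(series, hb.fs, hb.window_s, statistic)
    return {
        task: episode_activation(wv, hb.window_mask, hb.schedule, task,
                                 hb.fs, hb.window_s)
        for task in hb.schedule.task_names()
    }


@dataclass
class ActivationMatrix:
    """Subject-episode x channel activation matrix with labels."""

    values: np.ndarray  # (R, C), imputed, uM
    row_meta: pd.DataFrame  # subject_id, group, episode, tlx_mean, load_label
    col_meta: pd.DataFrame  # channel_id, separation_cm, hemisphere, region
    missing: np.ndarray  # (R, C) bool, True where the value was imputed

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def rows_for(self, episode: str | None = None, group: str | None = None) -> np.ndarray:
        sel = np.ones(self.n_rows, dtype=bool)
        if episode is not None:
            sel &= (self.row_meta["episode"] == episode).to_numpy()
        if group is not None:
            sel &= (self.row_meta["group"] == group).to_numpy()
        return np.nonzero(sel)[0]

    def columns_for(self, separation_cm: float | None = None,
                    hemisphere: str | None = None) -> np.ndarray:
        sel = np.ones(self.values.shape[1], dtype=bool)
        if separation_cm is not None:
            sel &= np.isclose(self.col_meta["separation_cm"].to_numpy(), separation_cm)
        if hemisphere is not None:
            sel &= (self.col_meta["hemisphere"] == hemisphere).to_numpy()
        return np.nonzero(sel)[0]

    def to_frame(self) -> pd.DataFrame:
        df = self.row_meta.copy()
        for k, cid in enumerate(self.col_meta["channel_id"]):
            df[f"ch{int(cid)}"] = self.values[:, k]
        return df

    @classmethod
    def from_frames(cls, df: pd.DataFrame, col_meta: pd.DataFrame) -> "ActivationMatrix":
        meta_cols = ["subject_id", "group", "episode", "tlx_mean", "load_label"]
        ch_cols = [f"ch{int(c)}" for c in col_meta["channel_id"]]
        values = df[ch_cols].to_numpy(dtype=float)
        return cls(values, df[meta_cols].reset_index(drop=True),
                   col_meta.reset_index(drop=True),
                   np.zeros(values.shape, dtype=bool))


def build_feature_matrix(
    activations: dict[str, dict[str, np.ndarray]],
    tlx_records: list[TLXRecord],
    groups: dict[str, str],
    layout: ChannelLayout,
) -> ActivationMatrix:
    """Assemble the labelled feature matrix.

    ``activations`` maps subject_id -> episode -> per-channel activation.
    Rows lacking a TLX record are dropped with a warning; missing channel
    entries are imputed with the column median over non-missing rows.  Load
    labels are assigned by a within-group median split of the TLX means.
    """
    from .group_stats import median_split

    tlx_by_key = {(r.subject_id, r.episode): r for r in tlx_records}
    rows, meta = [], []
    for sid, by_episode in activations.items():
        for episode, vals in sorted(by_episode.items()):
            rec = tlx_by_key.get((sid, episode))
            if rec is None:
                warnings.warn(
                    f"subject {sid} lacks a TLX record for {episode}; row dropped",
                    stacklevel=2,
                )
                continue
            rows.append(np.asarray(vals, dtype=float))
            meta.append(
                {
                    "subject_id": sid,
                    "group": groups[sid],
                    "episode": episode,
                    "tlx_mean": rec.mean_score,
                }
            )
    if not rows:
        raise FeatureError("no rows could be assembled")
    values = np.vstack(rows)
    row_meta = pd.DataFrame(meta)

    missing = ~np.isfinite(values)
    if missing.any():
        logger.info("imputing %d missing entries with column medians",
                    int(missing.sum()))
    for j in np.nonzero(missing.any(axis=0))[0]:
        col = values[:, j]
        good = np.isfinite(col)
        fill = np.median(col[good]) if good.any() else 0.0
        col[~good] = fill

    labels = np.empty(len(row_meta), dtype=object)
    for group in row_meta["group"].unique():
        sel = (row_meta["group"] == group).to_numpy()
        labels[sel] = median_split(row_meta.loc[sel, "tlx_mean"].to_numpy())
    row_meta["load_label"] = labels

    col_meta = pd.DataFrame(
        {
            "channel_id": layout.ids,
            "separation_cm": layout.separations,
            "hemisphere": layout.hemispheres,
            "region": layout.regions,
        }
    )
    if values.shape[1] != len(col_meta):
        raise FeatureError("activation vectors do not match the layout")
    return ActivationMatrix(values, row_meta, col_meta, missing)


def cohort_feature_matrix(cohort, preprocess_config=None, use_ssr: bool = False,
                          statistic: str = "sd") -> ActivationMatrix:
    """Preprocess every recording of a cohort and assemble its feature matrix."""
    from .preprocess import preprocess_recording

    activations = {}
    for rec in cohort.recordings:
        hb = preprocess_recording(rec, preprocess_config)
        activations[rec.subject_id] = subject_activations(
            hb, cohort.layout, use_ssr=use_ssr, statistic=statistic
        )
    return build_feature_matrix(activations, cohort.tlx, cohort.groups, cohort.layout)
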