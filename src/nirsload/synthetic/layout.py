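"""Deterministic channel-layout fixture for the multi-distance prefrontal montage.

The true optode geometry is proprietary; downstream analysis only relies on
the separation class, the hemisphere, and midpoint proximity (for pairing long
channels with short regressor channels).  Midpoints are therefore laid out on
a deterministic grid spanning both hemispheres of a flattened forehead plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..constants import CLASS_COUNTS_DEFAULT, SEPARATION_CLASSES

N_SOURCES = 24
N_DETECTORS = 32


class LayoutError(ValueError):
    """Invalid layout configuration or violated layout invariant."""


@dataclass(frozen=True)
class Channel:
    channel_id: int
    source_id: int
    detector_id: int
    separation_cm: float
    x_cm: float
    y_cm: float
    hemisphere: str  # "L" or "R"
    region: str


@dataclass(frozen=True)
class LayoutConfig:
    """Per-class channel counts and the lateral/vertical extent of the montage."""

    class_counts: dict[float, int] = field(
        default_factory=lambda: dict(CLASS_COUNTS_DEFAULT)
    )
    x_extent_cm: float = 6.0
    y_extent_cm: float = 5.0

    def validate(self) -> None:
        if not self.class_counts:
            raise LayoutError("class_counts is empty")
        for sep, n in self.class_counts.items():
            if sep <= 0 or n < 0:
                raise LayoutError(f"invalid class count {n} for separation {sep}")
        if sum(self.class_counts.values()) <= 0:
            raise LayoutError("class counts must sum to a positive total")
        if self.x_extent_cm <= 0 or self.y_extent_cm <= 0:
            raise LayoutError("layout extents must be positive")


class ChannelLayout:
    """Immutable collection of channels with array views used downstream."""

    def __init__(self, channels: list[Channel]):
        if not channels:
            raise LayoutError("layout has no channels")
        self.channels = tuple(channels)
        self.ids = np.array([c.channel_id for c in channels], dtype=int)
        self.separations = np.array([c.separation_cm for c in channels])
        self.midpoints = np.array([[c.x_cm, c.y_cm] for c in channels])
        self.hemispheres = np.array([c.hemisphere for c in channels])
        self.regions = np.array([c.region for c in channels])

    def __len__(self) -> int:
        return len(self.channels)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def class_indices(self, separation_cm: float) -> np.ndarray:
        """Positional indices of channels in a separation class."""
        return np.nonzero(np.isclose(self.separations, separation_cm))[0]

    def nearest_short(self, index: int, short_class: float = 1.5) -> int:
        """Index of the nearest short-separation channel (ties -> lowest id)."""
        short = self.class_indices(short_class)
        if short.size == 0:
            raise LayoutError(f"no channels of class {short_class} cm for pairing")
        d = np.hypot(
            self.midpoints[short, 0] - self.midpoints[index, 0],
            self.midpoints[short, 1] - self.midpoints[index, 1],
        )
        # lexicographic: distance first, channel id second
        order = np.lexsort((self.ids[short], np.round(d, 9)))
        return int(short[order[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "source": [c.source_id for c in self.channels],
                "detector": [c.detector_id for c in self.channels],
                "class_cm": self.separations,
                "x_cm": self.midpoints[:, 0],
                "y_cm": self.midpoints[:, 1],
                "hemisphere": self.hemispheres,
                "region": self.regions,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ChannelLayout":
        channels = [
            Channel(
                channel_id=int(r.id),
                source_id=int(r.source),
                detector_id=int(r.detector),
                separation_cm=float(r.class_cm),
                x_cm=float(r.x_cm),
                y_cm=float(r.y_cm),
                hemisphere=str(r.hemisphere),
                region=str(r.region),
            )
            for r in df.itertuples()
        ]
        return cls(channels)


def _grid_positions(n: int, x0: float, x1: float, y0: float, y1: float) -> np.ndarray:
    """n deterministic grid points inside [x0, x1] x [y0, y1], row-major."""
    if n == 0:
        return np.empty((0, 2))
    nrows = max(1, int(math.ceil(math.sqrt(n / 2.0))))
    if n >= 3:
        nrows = max(nrows, 2)  # keep midpoints non-collinear
    ncols = math.ceil(n / nrows)
    xs = np.linspace(x0, x1, ncols) if ncols > 1 else np.array([(x0 + x1) / 2.0])
    ys = np.linspace(y0, y1, nrows) if nrows > 1 else np.array([(y0 + y1) / 2.0])
    pts = [(x, y) for y in ys for x in xs]
    return np.array(pts[:n])


def _region_for(x: float, y: float, y_extent: float, x_extent: float) -> str:
    if y >= 0.64 * y_extent:
        return "dorsolateral"
    if y <= 0.24 * y_extent:
        return "orbitofrontal"
    if abs(x) <= 0.27 * x_extent:
        return "medial"
    return "ventrolateral"


def build_layout(config: LayoutConfig | None = None) -> ChannelLayout:
    """Build the deterministic channel layout.

    Each separation class is split across hemispheres (extra channel goes
    left) and tiled over the same rectangle so that every long channel has a
    short channel nearby, which guarantees superficial-regression pairing.
    """
    config = config or LayoutConfig()
    config.validate()

    channels: list[Channel] = []
    cid = 1
    classes = sorted(config.class_counts, key=lambda s: SEPARATION_CLASSES.index(s)
                     if s in SEPARATION_CLASSES else len(SEPARATION_CLASSES) + s)
    for k, sep in enumerate(classes):
        n = config.class_counts[sep]
        n_left = (n + 1) // 2
        offset = 0.05 * k  # keep classes visually distinct, well under pairing radius
        xa = 0.1 * config.x_extent_cm + offset
        xb = 0.9 * config.x_extent_cm + offset
        y0 = 0.08 * config.y_extent_cm + 0.6 * offset
        y1 = 0.92 * config.y_extent_cm - 0.4 * offset
        for side, m in (("L", n_left), ("R", n - n_left)):
            pts = _grid_positions(m, xa, xb, y0, y1)
            sgn = -1.0 if side == "L" else 1.0
            for x, y in pts:
                channels.append(
                    Channel(
                        channel_id=cid,
                        source_id=(cid - 1) % N_SOURCES + 1,
                        detector_id=(cid - 1) % N_DETECTORS + 1,
                        separation_cm=float(sep),
                        x_cm=float(sgn * x),
                        y_cm=float(y),
                        hemisphere=side,
                        region=_region_for(sgn * x, y, config.y_extent_cm,
                                           config.x_extent_cm),
                    )
                )
                cid += 1

    layout = ChannelLayout(channels)
    _check_invariants(layout, config)
    return layout


def _check_invariants(layout: ChannelLayout, config: LayoutConfig) -> None:
    if np.any(layout.midpoints[:, 0] == 0):
        raise LayoutError("channel midpoint on the midline (x = 0) is forbidden")
    left = layout.midpoints[:, 0] < 0
    if not np.array_equal(np.where(left, "L", "R"), layout.hemispheres):
        raise LayoutError("hemisphere labels inconsistent with midpoint sign")
    # pairing feasibility for superficial regression
    has_short = any(np.isclose(s, 1.5) for s in config.class_counts if config.class_counts.get(s, 0) > 0)
    if not has_short:
        return
    for i in np.nonzero(layout.separations >= 2.5)[0]:
        j = layout.nearest_short(int(i))
        d = np.hypot(*(layout.midpoints[i] - layout.midpoints[j]))
        if d > 3.0:
            raise LayoutError(
                f"channel {layout.ids[i]} has no short channel within 3 cm "
                f"(nearest at {d:.2f} cm)"
            )
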