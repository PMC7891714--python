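"""Preprocessing: dOD -> hemoglobin, band-pass filtering, artifact windows.

Two-wavelength optical-density changes are inverted to oxy-/deoxy-hemoglobin
concentration changes through the modified Beer-Lambert law (DPF defaults
5.075 at 780 nm and 4.64 at 850 nm), band-pass filtered at 0.01-0.5 Hz with a
zero-phase Butterworth filter, and screened for motion artifacts with a
windowed-SD rule: any non-overlapping 10 s window whose SD exceeds the
channel's median window-SD by more than 4.5 MAD is rejected.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .constants import (
    BAND_DEFAULT,
    DPF_DEFAULT,
    EXTINCTION_DEFAULT,
    MAD_MULTIPLIER_DEFAULT,
    WAVELENGTHS,
    WINDOW_S_DEFAULT,
)
from .synthetic.simulate import ProtocolSchedule, RawRecording

logger = logging.getLogger(__name__)


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class PreprocessConfig:
    dpf: dict[float, float] = field(default_factory=lambda: dict(DPF_DEFAULT))
    extinction: np.ndarray = field(default_factory=lambda: EXTINCTION_DEFAULT.copy())
    band_hz: tuple[float, float] = BAND_DEFAULT
    window_s: float = WINDOW_S_DEFAULT
    mad_multiplier: float = MAD_MULTIPLIER_DEFAULT
    filter_order: int = 4
    mask_per_episode: bool = False

    def validate(self, fs: float) -> None:
        lo, hi = self.band_hz
        if not (0 < lo < hi < fs / 2):
            raise PreprocessError(f"band {self.band_hz} incompatible with fs={fs}")
        if self.window_s <= 0:
            raise PreprocessError("window_s must be positive")
        if self.mad_multiplier <= 0:
            raise PreprocessError("mad_multiplier must be positive")


@dataclass
class HbSeries:
    """Hemoglobin time series with the per-window artifact retention mask."""

    hbo: np.ndarray  # (T, C) uM
    hbr: np.ndarray  # (T, C) uM
    fs: float
    schedule: ProtocolSchedule | None
    window_mask: np.ndarray  # (W, C) bool, True = retained
    window_s: float = WINDOW_S_DEFAULT

    def validate(self) -> None:
        if not (np.all(np.isfinite(self.hbo)) and np.all(np.isfinite(self.hbr))):
            raise PreprocessError("hemoglobin series contain non-finite values")
        w = window_length_samples(self.fs, self.window_s)
        if self.window_mask.shape[0] != self.hbo.shape[0] // w:
            raise PreprocessError("window mask row count inconsistent with series")


def window_length_samples(fs: float, window_s: float) -> int:
    w = int(round(fs * window_s))
    if w < 1:
        raise PreprocessError("window shorter than one sample")
    return w


def mbll_invert(
    od: np.ndarray,
    separation_cm: float | np.ndarray,
    config: PreprocessConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the 2x2 Beer-Lambert system per sample: dOD -> (dHbO, dHbR) in uM.

    ``od`` has a trailing wavelength axis of length 2 (780, 850 nm);
    ``separation_cm`` is scalar or per-channel for (T, C, 2) input.
    """
    config = config or PreprocessConfig()
    od = np.asarray(od, dtype=float)
    if od.shape[-1] != len(WAVELENGTHS):
        raise PreprocessError("od must have a trailing wavelength axis of length 2")
    sep = np.asarray(separation_cm, dtype=float)
    if np.any(sep <= 0):
        raise PreprocessError("separation must be positive")

    dpf = np.array([config.dpf[lam] for lam in WAVELENGTHS])
    A = np.asarray(config.extinction, dtype=float) * dpf[:, None]
    det = np.linalg.det(A)
    if abs(det) < 1e-9 * float(np.abs(A).max()) ** 2:
        raise PreprocessError(
            f"singular extinction system for wavelength pair {WAVELENGTHS}"
        )
    Ainv = np.linalg.inv(A)
    # effective pathlength: per-channel separation scales both wavelengths
    scaled = od / sep[..., None] if sep.ndim else od / sep
    conc = scaled @ Ainv.T
    return conc[..., 0], conc[..., 1]


def bandpass(
    series: np.ndarray,
    fs: float,
    band_hz: tuple[float, float] = BAND_DEFAULT,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along axis 0."""
    lo, hi = band_hz
    if fs <= 2 * hi:
        raise PreprocessError(f"fs={fs} must exceed twice the upper band edge {hi}")
    series = np.asarray(series, dtype=float)
    sos = butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    # the low band edge dictates the transient length; pad accordingly
    padlen = int(round(3.0 * fs / lo))
    min_len = 3 * (2 * sos.shape[0] + 1)
    if series.shape[0] < 3 * min_len:
        raise PreprocessError(
            f"series of length {series.shape[0]} is too short to filter "
            f"(need >= {3 * min_len} samples)"
        )
    padlen = min(padlen, series.shape[0] - 1)
    return sosfiltfilt(sos, series, axis=0, padlen=padlen)


def window_sd(series: np.ndarray, fs: float, window_s: float) -> np.ndarray:
    """SD of each complete non-overlapping window; trailing partial dropped."""
    series = np.atleast_2d(np.asarray(series, dtype=float).T).T  # (T,) -> (T, 1)
    w = window_length_samples(fs, window_s)
    n_win = series.shape[0] // w
    if n_win < 1:
        raise PreprocessError("series shorter than one window")
    trimmed = series[: n_win * w].reshape(n_win, w, series.shape[1])
    return trimmed.std(axis=1, ddof=1)


def detect_artifact_windows(
    series: np.ndarray,
    fs: float,
    window_s: float = WINDOW_S_DEFAULT,
    mad_multiplier: float = MAD_MULTIPLIER_DEFAULT,
    schedule: ProtocolSchedule | None = None,
    per_episode: bool = False,
) -> np.ndarray:
    """Retention mask (True = keep) for non-overlapping windows of each channel.

    Per channel the SD of every complete window is computed; with m the median
    of those SDs and MAD their median absolute deviation, a window is rejected
    iff SD > m + mad_multiplier * MAD.  Only high-side excursions are flagged:
    low-variance windows are not severe artifacts.  A zero MAD (constant
    variance) flags nothing.  With ``per_episode`` the rule is applied
    separately to the windows of each scheduled episode.
    """
    sds = window_sd(series, fs, window_s)  # (W, C)
    n_win = sds.shape[0]
    if n_win < 3:
        raise PreprocessError("need at least 3 complete windows per channel")

    groups: list[np.ndarray]
    if per_episode:
        if schedule is None:
            raise PreprocessError("per_episode masking requires a schedule")
        w = window_length_samples(fs, window_s)
        starts = np.arange(n_win) * w / fs
        ends = starts + w / fs
        groups = []
        for ep in schedule.episodes:
            inside = np.nonzero((starts >= ep.start_s - 1e-9) & (ends <= ep.end_s + 1e-9))[0]
            if inside.size:
                groups.append(inside)
    else:
        groups = [np.arange(n_win)]

    mask = np.ones_like(sds, dtype=bool)
    for idx in groups:
        sub = sds[idx]
        med = np.median(sub, axis=0)
        mad = np.median(np.abs(sub - med), axis=0)
        degenerate = mad == 0
        if np.any(degenerate):
            warnings.warn(
                "zero MAD of window SDs in %d channel(s); no windows flagged there"
                % int(degenerate.sum()),
                stacklevel=2,
            )
        thresh = med + mad_multiplier * mad
        flagged = sub > thresh
        flagged[:, degenerate] = False
        mask[idx] &= ~flagged
    return mask


def preprocess_recording(
    rec: RawRecording, config: PreprocessConfig | None = None
) -> HbSeries:
    """Full preprocessing of a raw recording into a masked hemoglobin series."""
    config = config or PreprocessConfig()
    config.validate(rec.schedule.fs)
    hbo, hbr = mbll_invert(rec.od, rec.layout.separations, config)
    hbo = bandpass(hbo, rec.schedule.fs, config.band_hz, config.filter_order)
    hbr = bandpass(hbr, rec.schedule.fs, config.band_hz, config.filter_order)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-MAD warnings are per-channel noise
        mask = detect_artifact_windows(
            hbo,
            rec.schedule.fs,
            config.window_s,
            config.mad_multiplier,
            schedule=rec.schedule,
            per_episode=config.mask_per_episode,
        )
    series = HbSeries(
        hbo=hbo,
        hbr=hbr,
        fs=rec.schedule.fs,
        schedule=rec.schedule,
        window_mask=mask,
        window_s=config.window_s,
    )
    series.validate()
    return series
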