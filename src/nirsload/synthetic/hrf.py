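"""Canonical double-gamma hemodynamic response function."""

from __future__ import annotations

import numpy as np
from scipy.stats import gamma


def double_gamma_hrf(
    fs: float,
    duration_s: float = 30.0,
    peak_s: float = 6.0,
    undershoot_s: float = 16.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Sampled double-gamma HRF, normalized to unit peak."""
    if fs <= 0 or duration_s <= 0:
        raise ValueError("fs and duration_s must be positive")
    t = np.arange(0.0, duration_s, 1.0 / fs)
    h = gamma.pdf(t, peak_s) - undershoot_ratio * gamma.pdf(t, undershoot_s)
    peak = np.max(np.abs(h))
    if peak == 0:
        raise ValueError("degenerate HRF parameters")
    return h / peak
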