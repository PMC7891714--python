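"""Device and analysis constants shared across modules.

Defaults mirror the measurement setup: a 24-source / 32-detector prefrontal
montage with 204 channels in four source-detector separation classes, sampled
at 8.138 Hz at 780 and 850 nm.
"""

from __future__ import annotations

import numpy as np

#: Sampling rate of the headset (Hz).
FS_DEFAULT: float = 8.138

#: Measurement wavelengths (nm), order fixed for all (time, channel, wavelength) arrays.
WAVELENGTHS: tuple[float, float] = (780.0, 850.0)

#: Differential pathlength factors per wavelength.
DPF_DEFAULT: dict[float, float] = {780.0: 5.075, 850.0: 4.64}

#: Band-pass edges for hemoglobin series (Hz).
BAND_DEFAULT: tuple[float, float] = (0.01, 0.5)

#: Non-overlapping artifact / feature window length (s).
WINDOW_S_DEFAULT: float = 10.0

#: Robust outlier threshold: windows with SD > median + 4.5 * MAD are rejected.
MAD_MULTIPLIER_DEFAULT: float = 4.5

#: Family-wise error parameters: each of K tests must reach p < ALPHA / K.
ALPHA_DEFAULT: float = 0.05
K_DEFAULT: int = 16

#: Source-detector separation classes (cm) and default channel counts.
SEPARATION_CLASSES: tuple[float, ...] = (1.5, 2.12, 3.0, 3.35)
CLASS_COUNTS_DEFAULT: dict[float, int] = {1.5: 52, 2.12: 36, 3.0: 68, 3.35: 48}

# Molar extinction coefficients in (uM * cm)^-1, rows = wavelength (780, 850),
# columns = chromophore (HbO, HbR).  Values follow a standard compilation for
# hemoglobin in vivo; all correctness checks are round-trip based, so only
# invertibility of this matrix matters.
EXTINCTION_DEFAULT: np.ndarray = np.array(
    [
        [7.354e-4, 1.1006e-3],  # 780 nm
        [1.058e-3, 6.913e-4],  # 850 nm
    ]
)

#: Prefrontal region labels used by the layout fixture.
REGIONS: tuple[str, ...] = ("dorsolateral", "ventrolateral", "medial", "orbitofrontal")
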