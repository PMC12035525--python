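"""Common spectral grid conventions.

All spectra in the package live on (subsets of) a 1-nm integer wavelength grid
from 400 to 2500 nm inclusive (2101 points), the region of peak solar
irradiance used throughout the analysis.
"""

from __future__ import annotations

import numpy as np

WL_MIN = 400
WL_MAX = 2500

#: The full 1-nm working grid (2101 wavelengths, nm).
WAVELENGTHS = np.arange(WL_MIN, WL_MAX + 1, dtype=float)

#: Nominal region bounds (nm) used when summarising impacts per region.
REGIONS = {"VIS": (400.0, 700.0), "NIR": (700.0, 1300.0), "SWIR": (1300.0, 2500.0)}


def default_grid(step: int = 1) -> np.ndarray:
    """Return the working grid, optionally subsampled to a coarser step (nm)."""
    if step < 1:
        raise ValueError("step must be >= 1 nm")
    return np.arange(WL_MIN, WL_MAX + 1, step, dtype=float)


def check_grid(wl: np.ndarray) -> np.ndarray:
    """Validate a wavelength vector: 1-D, strictly increasing, inside [400, 2500]."""
    wl = np.asarray(wl, dtype=float)
    if wl.ndim != 1 or wl.size == 0:
        raise ValueError("wavelength grid must be a non-empty 1-D array")
    if np.any(np.diff(wl) <= 0):
        raise ValueError("wavelengths must be strictly increasing")
    if wl[0] < WL_MIN or wl[-1] > WL_MAX:
        raise ValueError(f"wavelengths must lie within [{WL_MIN}, {WL_MAX}] nm")
    return wl
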