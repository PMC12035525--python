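"""Diffuse-sky irradiance fraction S(lambda, theta_s).

The combined canopy-top reflectance mixes the bidirectional (direct-beam)
and hemispherical-directional (diffuse-incidence) terms by the fraction of
diffuse sky light.  The default table is the synthetic Rayleigh-plus-aerosol
curve from :mod:`lianaspec.coefficients` (one column per 10 degrees of solar
zenith, interpolated); any user table with the same layout can be supplied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._grid import check_grid
from .coefficients import diffuse_fraction_table

__all__ = ["diffuse_fraction"]

_DEFAULT_CACHE: dict = {}


def diffuse_fraction(
    wavelengths: np.ndarray,
    theta_s: float,
    table: pd.DataFrame | None = None,
) -> np.ndarray:
    """Per-wavelength diffuse-light fraction at solar zenith ``theta_s``.

    Linearly interpolates between the tabulated zenith columns and onto the
    requested wavelength grid.  Values are clipped to [0, 1].
    """
    wl = check_grid(np.asarray(wavelengths, dtype=float))
    if not (0.0 <= theta_s < 90.0):
        raise ValueError("theta_s must lie in [0, 90)")
    if table is None:
        key = (float(theta_s), wl.size, float(wl[0]), float(wl[-1]))
        cached = _DEFAULT_CACHE.get(key)
        if cached is not None and np.array_equal(cached[0], wl):
            return cached[1].copy()
        table = diffuse_fraction_table(wl)
        out = _interp_table(wl, theta_s, table)
        if len(_DEFAULT_CACHE) > 32:
            _DEFAULT_CACHE.clear()
        _DEFAULT_CACHE[key] = (wl.copy(), out)
        return out.copy()
    return _interp_table(wl, theta_s, table)


def _interp_table(wl: np.ndarray, theta_s: float, table: pd.DataFrame) -> np.ndarray:
    cols = [c for c in table.columns if c.startswith("theta_")]
    thetas = np.array(sorted(float(c.split("_")[1]) for c in cols))
    twl = table["wavelength_nm"].to_numpy(float)
    lo = thetas[np.searchsorted(thetas, theta_s, side="right") - 1]
    hi = thetas[min(np.searchsorted(thetas, theta_s, side="right"), thetas.size - 1)]
    s_lo = np.interp(wl, twl, table[f"theta_{int(lo)}"].to_numpy(float))
    s_hi = np.interp(wl, twl, table[f"theta_{int(hi)}"].to_numpy(float))
    frac = 0.0 if hi == lo else (theta_s - lo) / (hi - lo)
    return np.clip((1.0 - frac) * s_lo + frac * s_hi, 0.0, 1.0)
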