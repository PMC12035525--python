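"""Sensor spectral response functions and band convolution.

Built-in sensors are boxcar approximations constructed from published band
edges (Landsat 5 TM reflective bands, the WorldView-2 WV110 multispectral
bands, and a Hyperion-like ladder of 10-nm bands across the VNIR and SWIR).
Boxcars are adequate here because every sensor-level conclusion drawn in
this package is ordering-based.  Users may supply full SRF tables as
delimited text with columns ``wavelength_nm, band_id, weight``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._grid import WAVELENGTHS, check_grid

__all__ = ["Band", "SensorModel", "load_srf", "band_convolve", "BUILTIN_SENSORS"]


@dataclass(frozen=True)
class Band:
    """One sensor band: identifier, centre (nm) and normalised weights."""

    band_id: str
    center: float
    wavelengths: np.ndarray
    weights: np.ndarray  # >= 0, sum to 1


@dataclass(frozen=True)
class SensorModel:
    name: str
    bands: tuple

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    @property
    def centers(self) -> np.ndarray:
        return np.array([b.center for b in self.bands])


# Published reflective band edges (nm); thermal bands excluded.
_LANDSAT5_TM = [
    ("B1", 450, 520),
    ("B2", 520, 600),
    ("B3", 630, 690),
    ("B4", 760, 900),
    ("B5", 1550, 1750),
    ("B7", 2080, 2350),
]

_WORLDVIEW2 = [
    ("coastal", 400, 450),
    ("blue", 450, 510),
    ("green", 510, 580),
    ("yellow", 585, 625),
    ("red", 630, 690),
    ("red_edge", 705, 745),
    ("nir1", 770, 895),
    ("nir2", 860, 1040),
]


def _boxcar(band_id: str, lo: float, hi: float) -> Band:
    wl = np.arange(lo, hi + 1, dtype=float)
    w = np.ones_like(wl)
    w /= w.sum()
    return Band(band_id=band_id, center=0.5 * (lo + hi), wavelengths=wl, weights=w)


def _hyperion_like() -> tuple:
    """10-nm contiguous boxcar bands, 430-2400 nm (VNIR + SWIR)."""
    bands = []
    for i, lo in enumerate(np.arange(430.0, 2400.0, 10.0)):
        bands.append(_boxcar(f"b{i + 1:03d}", lo, lo + 10.0))
    return tuple(bands)


def _builtin(name: str) -> SensorModel:
    if name == "landsat5_tm":
        return SensorModel(name, tuple(_boxcar(*b) for b in _LANDSAT5_TM))
    if name == "worldview2":
        return SensorModel(name, tuple(_boxcar(*b) for b in _WORLDVIEW2))
    if name == "hyperion":
        return SensorModel(name, _hyperion_like())
    raise KeyError(name)


BUILTIN_SENSORS = ("landsat5_tm", "worldview2", "hyperion")


def load_srf(source) -> SensorModel:
    """Load a sensor model from a builtin name or an SRF table file.

    File format: delimited text with columns ``wavelength_nm, band_id,
    weight``; weights are renormalised to sum to 1 per band.
    """
    if isinstance(source, str) and source in BUILTIN_SENSORS:
        return _builtin(source)
    df = pd.read_csv(source, sep=None, engine="python", comment="#")
    needed = {"wavelength_nm", "band_id", "weight"}
    if not needed.issubset(df.columns):
        raise ValueError(f"SRF table must have columns {sorted(needed)}")
    bands = []
    for band_id, grp in df.groupby("band_id", sort=False):
        wl = check_grid(grp["wavelength_nm"].to_numpy(float))
        w = grp["weight"].to_numpy(float)
        if np.any(w < 0):
            raise ValueError(f"band {band_id!r} has negative weights")
        total = w.sum()
        if total <= 0:
            raise ValueError(f"band {band_id!r} has zero total weight")
        w = w / total
        bands.append(
            Band(band_id=str(band_id), center=float(np.sum(wl * w)), wavelengths=wl, weights=w)
        )
    return SensorModel(name=str(source), bands=tuple(bands))


def _band_weight_vector(band: Band, wavelengths: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(wavelengths, band.wavelengths)
    ok = (idx < wavelengths.size) & (
        wavelengths[np.minimum(idx, wavelengths.size - 1)] == band.wavelengths
    )
    if not np.any(ok):
        raise ValueError(
            f"band {band.band_id!r} does not overlap the spectrum grid"
        )
    v = np.zeros_like(wavelengths)
    np.add.at(v, idx[ok], band.weights[ok])
    s = v.sum()
    return v / s


def band_convolve(
    spectrum: np.ndarray,
    sensor: SensorModel,
    wavelengths: np.ndarray | None = None,
    variance: np.ndarray | None = None,
):
    """Convolve a spectrum (and optionally a variance) to sensor bands.

    Means convolve linearly with the normalised weights; variances convolve
    with squared weights, assuming independent per-wavelength errors (the
    same assumption as the inversion likelihood).  Returns the band means,
    or ``(means, variances)`` when ``variance`` is given.
    """
    wl = WAVELENGTHS if wavelengths is None else check_grid(np.asarray(wavelengths, float))
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.shape[-1] != wl.size:
        raise ValueError("spectrum grid mismatch")
    W = np.stack([_band_weight_vector(b, wl) for b in sensor.bands])
    means = spectrum @ W.T
    if variance is None:
        return means
    variance = np.asarray(variance, dtype=float)
    if variance.shape[-1] != wl.size:
        raise ValueError("variance grid mismatch")
    return means, variance @ (W**2).T
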