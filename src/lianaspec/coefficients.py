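"""Specific-absorption coefficients, refractive index, soil spectra and sky tables.

The leaf radiative-transfer model needs, per wavelength, a leaf refractive
index and one specific absorption coefficient (SAC) per biochemical
constituent.  The default tables produced here are SYNTHETIC: smooth
parametric curves (sums of Gaussian absorption features placed at the
well-known pigment, water and dry-matter band positions) rather than any
published empirical calibration.  They reproduce the qualitative optics of
real leaves -- strong chlorophyll absorption in the blue and red, carotenoids
in the blue, anthocyanins in the green, liquid-water bands near 1450 and
1940 nm, dry-matter absorption rising through the SWIR, and a near-infrared
plateau with almost no absorption -- which is what every ordering- and
invariant-based result in this package relies on.  Users with a preferred
empirical calibration can load it from a delimited text file with
:func:`load_coefficient_table`.

Model variants mirror the common leaf-model family tree: variant ``"5"``
uses chlorophyll, carotenoids, water and dry matter; ``"5b"`` adds brown
pigments; ``"D"`` adds anthocyanins.  All variants share identical columns
here, the variant label only selects which constituents contribute.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._grid import WAVELENGTHS, check_grid

__all__ = [
    "CoefficientTable",
    "default_table",
    "load_coefficient_table",
    "write_coefficient_table",
    "SACS_BY_VARIANT",
    "default_soil_spectra",
    "diffuse_fraction_table",
]

#: Column order of the delimited-text interface.
COLUMNS = [
    "wavelength_nm",
    "refractive_index",
    "k_cab",
    "k_car",
    "k_can",
    "k_brown",
    "k_cw",
    "k_cm",
]

#: Constituents contributing to absorption, per model variant.
SACS_BY_VARIANT = {
    "5": ("k_cab", "k_car", "k_cw", "k_cm"),
    "5b": ("k_cab", "k_car", "k_brown", "k_cw", "k_cm"),
    "D": ("k_cab", "k_car", "k_can", "k_brown", "k_cw", "k_cm"),
}

#: Maps SAC column -> LeafParams field carrying its concentration.
SAC_TO_PARAM = {
    "k_cab": "c_ab",
    "k_car": "c_ar",
    "k_can": "c_an",
    "k_brown": "c_br",
    "k_cw": "c_w",
    "k_cm": "c_m",
}


@dataclass(frozen=True)
class CoefficientTable:
    """Wavelength-indexed refractive index and specific absorption coefficients.

    Attributes
    ----------
    wavelengths : ndarray, nm
    refractive_index : ndarray, > 1
    sacs : dict of column name -> ndarray (>= 0), same grid
    variant : one of ``"5"``, ``"5b"``, ``"D"``
    """

    wavelengths: np.ndarray
    refractive_index: np.ndarray
    sacs: dict = field(default_factory=dict)
    variant: str = "D"

    def __post_init__(self):
        wl = check_grid(self.wavelengths)
        object.__setattr__(self, "wavelengths", wl)
        if self.variant not in SACS_BY_VARIANT:
            raise ValueError(f"unknown variant {self.variant!r}")
        n = np.asarray(self.refractive_index, dtype=float)
        if n.shape != wl.shape:
            raise ValueError("refractive index grid mismatch")
        if np.any(n <= 1.0):
            raise ValueError("refractive index must exceed 1 everywhere")
        object.__setattr__(self, "refractive_index", n)
        sacs = {}
        for name, k in self.sacs.items():
            k = np.asarray(k, dtype=float)
            if k.shape != wl.shape:
                raise ValueError(f"SAC column {name!r} grid mismatch")
            if np.any(k < 0):
                raise ValueError(f"SAC column {name!r} has negative values")
            sacs[name] = k
        object.__setattr__(self, "sacs", sacs)

    @property
    def active_sacs(self) -> tuple:
        """SAC columns contributing under this table's variant."""
        return SACS_BY_VARIANT[self.variant]

    def with_variant(self, variant: str) -> "CoefficientTable":
        return replace(self, variant=variant)

    def subset(self, wavelengths: np.ndarray) -> "CoefficientTable":
        """Restrict the table to a coarser wavelength grid (must be a subset)."""
        wl = check_grid(np.asarray(wavelengths, dtype=float))
        idx = np.searchsorted(self.wavelengths, wl)
        if np.any(idx >= self.wavelengths.size) or np.any(
            self.wavelengths[idx] != wl
        ):
            raise ValueError("requested wavelengths are not on the table grid")
        return CoefficientTable(
            wavelengths=wl,
            refractive_index=self.refractive_index[idx],
            sacs={k: v[idx] for k, v in self.sacs.items()},
            variant=self.variant,
        )

    def to_frame(self) -> pd.DataFrame:
        data = {"wavelength_nm": self.wavelengths, "refractive_index": self.refractive_index}
        for name in COLUMNS[2:]:
            data[name] = self.sacs.get(name, np.zeros_like(self.wavelengths))
        return pd.DataFrame(data)


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-(((wl - center) / width) ** 2))


def _sigmoid(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(wl - center) / width))


def default_table(variant: str = "D", wavelengths: np.ndarray | None = None) -> CoefficientTable:
    """Build the synthetic default coefficient table.

    Parametric idealisation of leaf constituent optics; see the module
    docstring.  Units follow the concentration conventions of the leaf model:
    pigments in cm^2/ug, water and dry matter in cm^2/g.
    """
    wl = WAVELENGTHS if wavelengths is None else check_grid(np.asarray(wavelengths, float))
    # Refractive index: ~1.53 in the blue declining smoothly to ~1.36 in the SWIR.
    n = 1.35 + 0.18 * np.exp(-(wl - 400.0) / 700.0)
    # Chlorophyll a+b: Soret band in the blue, red band near 675 nm, weak green.
    k_cab = (
        0.080 * _gauss(wl, 420.0, 35.0)
        + 0.060 * _gauss(wl, 675.0, 25.0)
        + 0.010 * _gauss(wl, 545.0, 80.0)
    )
    # Carotenoids: blue only.
    k_car = 0.045 * _gauss(wl, 450.0, 28.0) + 0.035 * _gauss(wl, 485.0, 25.0)
    # Anthocyanins: green absorption.
    k_can = 0.040 * _gauss(wl, 540.0, 35.0)
    # Brown pigments: featureless decay from the blue edge (arbitrary units).
    k_brown = 0.050 * np.exp(-(wl - 400.0) / 180.0)
    # Liquid water (per cm equivalent water thickness): overtone bands plus a
    # continuum rising beyond ~1350 nm.
    k_cw = (
        0.40 * _gauss(wl, 975.0, 45.0)
        + 1.10 * _gauss(wl, 1200.0, 70.0)
        + 28.0 * _gauss(wl, 1450.0, 65.0)
        + 125.0 * _gauss(wl, 1940.0, 90.0)
        + 45.0 * _gauss(wl, 2500.0, 160.0)
        + 3.0 * _sigmoid(wl, 1350.0, 120.0)
    )
    # Dry matter: weak in the VIS/NIR, rising in the SWIR with cellulose/lignin
    # features near 1720, 2100 and 2300 nm.
    k_cm = (
        6.0 * _sigmoid(wl, 900.0, 250.0)
        + 30.0 * _gauss(wl, 1720.0, 60.0)
        + 45.0 * _gauss(wl, 2100.0, 80.0)
        + 40.0 * _gauss(wl, 2300.0, 90.0)
        + 0.5 * np.exp(-(wl - 400.0) / 500.0)
    )
    sacs = {
        "k_cab": k_cab,
        "k_car": k_car,
        "k_can": k_can,
        "k_brown": k_brown,
        "k_cw": k_cw,
        "k_cm": k_cm,
    }
    return CoefficientTable(wavelengths=wl, refractive_index=n, sacs=sacs, variant=variant)


def load_coefficient_table(path, variant: str = "D") -> CoefficientTable:
    """Read a coefficient table from delimited text (columns as in COLUMNS)."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"coefficient table missing columns: {missing}")
    df = df.sort_values("wavelength_nm")
    return CoefficientTable(
        wavelengths=df["wavelength_nm"].to_numpy(float),
        refractive_index=df["refractive_index"].to_numpy(float),
        sacs={c: df[c].to_numpy(float) for c in COLUMNS[2:]},
        variant=variant,
    )


def write_coefficient_table(table: CoefficientTable, path) -> None:
    """Write a coefficient table as delimited text with a provenance header."""
    buf = io.StringIO()
    buf.write("# lianaspec coefficient table (synthetic parametric calibration)\n")
    buf.write(f"# variant: {table.variant}\n")
    table.to_frame().to_csv(buf, sep="\t", index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# Soil spectra
# ---------------------------------------------------------------------------

def default_soil_spectra(wavelengths: np.ndarray | None = None):
    """Synthetic dry and wet reference soil reflectance spectra.

    Dry soil brightens smoothly toward the SWIR; the wet spectrum is darker
    overall with deepened water bands at 1450 and 1940 nm.  Returns
    ``(dry, wet)`` arrays on the requested grid.
    """
    wl = WAVELENGTHS if wavelengths is None else check_grid(np.asarray(wavelengths, float))
    dry = 0.10 + 0.28 * (1.0 - np.exp(-(wl - 400.0) / 900.0))
    wet = 0.55 * dry * (1.0 - 0.35 * _gauss(wl, 1450.0, 100.0) - 0.50 * _gauss(wl, 1940.0, 120.0))
    return dry, np.clip(wet, 0.01, 1.0)


# ---------------------------------------------------------------------------
# Diffuse sky fraction
# ---------------------------------------------------------------------------

def diffuse_fraction_table(wavelengths: np.ndarray | None = None) -> pd.DataFrame:
    """Tabulated default diffuse-sky fraction S(lambda, theta_s).

    One column per solar zenith angle in 10-degree steps (0-80 deg); a
    Rayleigh-like power-law decline in wavelength on top of a small aerosol
    floor, with the overall level growing as the solar path length increases.
    A documented synthetic stand-in for an atmospheric irradiance model; fully
    overridable by a user table of the same layout.
    """
    wl = WAVELENGTHS if wavelengths is None else check_grid(np.asarray(wavelengths, float))
    out = {"wavelength_nm": wl}
    for theta in range(0, 90, 10):
        amp = min(0.22 / max(np.cos(np.deg2rad(theta)), 0.05), 0.85)
        s = amp * (400.0 / wl) ** 3 + 0.05
        out[f"theta_{theta}"] = np.clip(s, 0.0, 1.0)
    return pd.DataFrame(out)
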