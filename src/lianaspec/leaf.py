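"""Leaf radiative transfer: the generalized plate model.

A leaf is represented as one elementary plate with a rough top surface plus
N - 1 additional compact layers (N need not be an integer).  Light entering
the top interface does so within a 40-degree solid angle (the conventional
value for a rough epidermis); internal interfaces exchange light
isotropically.  Per-wavelength absorption is the concentration-weighted sum
of the constituent specific absorption coefficients divided by the layer
count N.  The N-layer system is solved in closed form (the Stokes solution
for a pile of identical plates, extended to real-valued N); an iterative
plate-stacking solver kept in the test-suite serves as the independent
oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy.special import exp1

from ._grid import check_grid
from .coefficients import SAC_TO_PARAM, CoefficientTable, default_table

__all__ = ["LeafParams", "LeafOptics", "total_absorption", "prospect_forward", "tav"]

#: Incidence solid angle (degrees) of the elementary plate's top interface.
PLATE_INCIDENCE_DEG = 40.0

#: Physical ranges used for validation and as default flat-prior bounds.
LEAF_BOUNDS = {
    "n_layers": (1.0, 4.0),
    "c_ab": (0.0, 120.0),
    "c_ar": (0.0, 40.0),
    "c_an": (0.0, 40.0),
    "c_br": (0.0, 4.0),
    "c_w": (0.0, 0.08),
    "c_m": (0.0, 0.05),
}


@dataclass(frozen=True)
class LeafParams:
    """Biochemical and structural traits of one leaf type.

    n_layers
        Mean number of air-cell wall interfaces in the mesophyll (>= 1).
    c_ab, c_ar, c_an
        Chlorophyll, carotenoid and anthocyanin content (ug/cm^2).
    c_br
        Brown pigment content (arbitrary units).
    c_w
        Equivalent water thickness (g/cm^2).
    c_m
        Leaf dry mass per area (g/cm^2).
    """

    n_layers: float = 1.5
    c_ab: float = 40.0
    c_ar: float = 8.0
    c_an: float = 0.0
    c_br: float = 0.0
    c_w: float = 0.01
    c_m: float = 0.009

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"{f.name} must be finite")
            if f.name == "n_layers":
                if v < 1.0:
                    raise ValueError("n_layers must be >= 1")
            elif v < 0.0:
                raise ValueError(f"{f.name} must be non-negative")

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "LeafParams":
        known = {f.name for f in fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass(frozen=True)
class LeafOptics:
    """Per-wavelength leaf reflectance, transmittance and absorption."""

    wavelengths: np.ndarray
    reflectance: np.ndarray
    transmittance: np.ndarray

    def __post_init__(self):
        wl = check_grid(self.wavelengths)
        object.__setattr__(self, "wavelengths", wl)
        for name in ("reflectance", "transmittance"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != wl.shape:
                raise ValueError(f"{name} grid mismatch")
            object.__setattr__(self, name, v)

    @property
    def absorption(self) -> np.ndarray:
        return 1.0 - self.reflectance - self.transmittance


def total_absorption(params: LeafParams, table: CoefficientTable) -> np.ndarray:
    """Per-layer absorption argument k(lambda) = sum_i c_i sac_i(lambda) / N.

    Only the constituents active under the table's variant contribute (the
    "D" variant adds anthocyanins to the "5b" set).
    """
    k = np.zeros_like(table.wavelengths)
    for sac_name in table.active_sacs:
        conc = getattr(params, SAC_TO_PARAM[sac_name])
        if conc:
            k = k + conc * table.sacs[sac_name]
    return k / params.n_layers


def tav(alpha_deg: float, n: np.ndarray) -> np.ndarray:
    """Transmissivity of a dielectric interface averaged over incidence.

    Average transmissivity of a plane interface of refractive index ``n``
    for radiation incident within a solid angle of half-angle ``alpha_deg``
    (Stern's classical integral in closed form).  ``alpha_deg = 90`` gives
    the isotropic value used for internal plate interfaces.
    """
    n = np.asarray(n, dtype=float)
    rd = np.deg2rad(alpha_deg)
    n2 = n**2
    npx = n2 + 1.0
    nm = n2 - 1.0
    a = (n + 1.0) ** 2 / 2.0
    k = -((n2 - 1.0) ** 2) / 4.0
    ds = np.sin(rd) ** 2

    if alpha_deg == 0:
        return 4.0 * n / (n + 1.0) ** 2

    if alpha_deg == 90:
        b1 = np.zeros_like(n)
    else:
        b1 = np.sqrt((ds - npx / 2.0) ** 2 + k)
    b2 = ds - npx / 2.0
    b = b1 - b2

    ts = (k**2 / (6.0 * b**3) + k / b - b / 2.0) - (
        k**2 / (6.0 * a**3) + k / a - a / 2.0
    )
    tp1 = -2.0 * n2 * (b - a) / (npx**2)
    tp2 = -2.0 * n2 * npx * np.log(b / a) / (nm**2)
    tp3 = n2 * (1.0 / b - 1.0 / a) / 2.0
    tp4 = (
        16.0
        * n2**2
        * (n2**2 + 1.0)
        * np.log((2.0 * npx * b - nm**2) / (2.0 * npx * a - nm**2))
        / (npx**3 * nm**2)
    )
    tp5 = (
        16.0
        * n2**3
        * (1.0 / (2.0 * npx * b - nm**2) - 1.0 / (2.0 * npx * a - nm**2))
        / (npx**3)
    )
    tp = tp1 + tp2 + tp3 + tp4 + tp5
    return (ts + tp) / (2.0 * ds)


def plate_transmissivity(k: np.ndarray) -> np.ndarray:
    """Fraction of radiation transmitted through one plate's interior.

    For isotropic radiation crossing an absorbing slab of optical depth k:
    theta(k) = (1 - k) e^{-k} + k^2 E1(k), with theta(0) = 1.
    """
    k = np.asarray(k, dtype=float)
    theta = np.ones_like(k)
    pos = k > 0
    kp = k[pos]
    theta[pos] = (1.0 - kp) * np.exp(-kp) + kp**2 * exp1(kp)
    return theta


def elementary_plate(n: np.ndarray, theta: np.ndarray, alpha_deg: float):
    """Reflectance/transmittance of a single plate.

    Returns ``(r_alpha, t_alpha, r90, t90)``: the plate response for top
    incidence within ``alpha_deg`` and for isotropic (90 deg) incidence.
    """
    talf = tav(alpha_deg, n)
    ralf = 1.0 - talf
    t12 = tav(90.0, n)
    r12 = 1.0 - t12
    t21 = t12 / n**2
    r21 = 1.0 - t21
    denom = 1.0 - r21**2 * theta**2
    Ta = talf * theta * t21 / denom
    Ra = ralf + r21 * theta * Ta
    t90 = t12 * theta * t21 / denom
    r90 = r12 + r21 * theta * t90
    return Ra, Ta, r90, t90


def stokes_stack(r: np.ndarray, t: np.ndarray, n_extra: float):
    """Closed-form reflectance/transmittance of ``n_extra`` identical layers.

    Stokes' solution for a pile of plates, valid for real-valued layer
    counts.  ``r`` and ``t`` are the single-layer (isotropic incidence)
    responses.
    """
    if n_extra <= 0:
        return np.zeros_like(r), np.ones_like(r)
    r = np.asarray(r, float)
    t = np.asarray(t, float)
    D = np.sqrt(
        np.maximum(
            (1.0 + r + t) * (1.0 + r - t) * (1.0 - r + t) * (1.0 - r - t), 0.0
        )
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        a = (1.0 + r**2 - t**2 + D) / (2.0 * r)
        b = (1.0 - r**2 + t**2 + D) / (2.0 * t)
        bn = b**n_extra
        a2 = a**2
        denom = a2 * bn**2 - 1.0
        Rsub = a * (bn**2 - 1.0) / denom
        Tsub = bn * (a2 - 1.0) / denom
    # Conservative limit r + t -> 1: the general form is 0/0 there.
    cons = (r + t) >= 1.0 - 1e-12
    if np.any(cons):
        Rsub = np.array(Rsub, copy=True)
        Tsub = np.array(Tsub, copy=True)
        tc = t[cons]
        Tsub[cons] = tc / (tc + (1.0 - tc) * n_extra)
        Rsub[cons] = 1.0 - Tsub[cons]
    return Rsub, Tsub


def prospect_forward(
    params: LeafParams, table: CoefficientTable | None = None
) -> LeafOptics:
    """Forward leaf model: traits -> reflectance, transmittance, absorption.

    One elementary plate (top incidence within 40 deg) over N - 1 compact
    layers solved with the Stokes closed form.
    """
    if table is None:
        table = default_table()
    k = total_absorption(params, table)
    theta = plate_transmissivity(k)
    n = table.refractive_index
    Ra, Ta, r90, t90 = elementary_plate(n, theta, PLATE_INCIDENCE_DEG)
    Rsub, Tsub = stokes_stack(r90, t90, params.n_layers - 1.0)
    denom = 1.0 - Rsub * r90
    tran = Ta * Tsub / denom
    refl = Ra + Ta * Rsub * t90 / denom
    return LeafOptics(
        wavelengths=table.wavelengths, reflectance=refl, transmittance=tran
    )
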