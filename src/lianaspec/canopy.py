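"""Two-layer canopy radiative transfer (four-stream, SAIL family).

The canopy is modelled as two vertically stacked, horizontally infinite
turbid layers above a Lambertian soil.  The top layer holds the liana
foliage, the bottom layer the host-tree foliage; each layer has its own leaf
optics and leaf inclination distribution.  Four radiation streams are
tracked: the direct solar beam, downward and upward hemispherical diffuse
flux, and radiance in the observer direction.  Each homogeneous layer is
solved in closed form; layers and soil are combined with the adding method.
The hotspot effect (enhanced bidirectional reflectance when the view
direction approaches the solar direction) is included through the
sun-view gap-correlation integral, evaluated per layer.

Layer partition: the top (liana) layer receives a fraction ``L * (1 - f2)``
of the total LAI, where ``f2`` is the tree share of leaf area in a fully
infested canopy and ``L`` in [0, 1] is the infestation index; at ``L = 0``
the canopy collapses to a single tree layer.  The dissociation factor ``D``
interpolates between that fully layered arrangement (D = 1) and a
homogeneous mixture of the two particle types in both layers (D = 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from ._grid import check_grid
from .coefficients import CoefficientTable, default_soil_spectra, default_table
from .leaf import LeafOptics, LeafParams, prospect_forward
from .sky import diffuse_fraction

__all__ = [
    "CanopyConfig",
    "ViewGeometry",
    "SoilModel",
    "CanopyReflectance",
    "campbell_lidf",
    "foursail2_forward",
    "couple_prosail2",
    "liana_lai_fraction",
]

#: Standard 13 leaf inclination classes (degrees): 8 coarse + 5 near-vertical.
LIDF_ANGLES = np.array(
    [5.0, 15.0, 25.0, 35.0, 45.0, 55.0, 65.0, 75.0, 81.0, 83.0, 85.0, 87.0, 89.0]
)
_LIDF_EDGES = np.array(
    [0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 82.0, 84.0, 86.0, 88.0, 90.0]
)

#: Physical parameter bounds (also the default flat-prior ranges).
CANOPY_BOUNDS = {
    "lai": (0.0, 20.0),
    "omega1": (5.0, 85.0),
    "omega2": (5.0, 85.0),
    "f2": (0.0, 1.0),
    "L": (0.0, 1.0),
    "D": (0.0, 1.0),
    "hotspot": (0.0, 1.0),
    "soil_moisture": (0.0, 1.0),
    "cv": (0.0, 1.0),
    "zeta": (0.0, 2.0),
}


@dataclass(frozen=True)
class CanopyConfig:
    """Structural parameters of the two-layer canopy.

    lai : total leaf area index (m^2/m^2)
    omega1, omega2 : mean leaf inclination (deg from zenith) of the liana
        (top) and tree (bottom) layers
    f2 : tree fraction of total LAI in a fully infested canopy
    L : liana infestation index in [0, 1]
    D : dissociation factor (1 = pure liana top layer)
    hotspot : hotspot parameter b/H (mean projected particle size over
        canopy height)
    soil_moisture : mixing weight between the dry and wet soil spectra
    cv : vertical crown cover (fixed at 1 for closed tropical canopies,
        which makes the crown-shape parameter zeta inert)
    zeta : crown shape Cd/H (inert when cv = 1)
    """

    lai: float = 6.0
    omega1: float = 27.9
    omega2: float = 37.1
    f2: float = 0.66
    L: float = 1.0
    D: float = 1.0
    hotspot: float = 0.05
    soil_moisture: float = 0.5
    cv: float = 1.0
    zeta: float = 0.5

    def __post_init__(self):
        for name, (lo, hi) in CANOPY_BOUNDS.items():
            v = getattr(self, name)
            if not np.isfinite(v) or v < lo or v > hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.cv != 1.0:
            raise NotImplementedError(
                "only closed canopies (cv = 1) are supported; zeta is then inert"
            )

    def replace(self, **kw) -> "CanopyConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class ViewGeometry:
    """Sun-sensor geometry: solar zenith, observer zenith, relative azimuth (deg)."""

    theta_s: float = 30.0
    theta_o: float = 0.0
    psi: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.theta_s < 90.0 and 0.0 <= self.theta_o < 90.0):
            raise ValueError("zenith angles must lie in [0, 90)")
        if not (0.0 <= self.psi < 360.0):
            raise ValueError("relative azimuth must lie in [0, 360)")


@dataclass(frozen=True)
class SoilModel:
    """Lambertian soil: linear mix of a dry and a wet reference spectrum."""

    wavelengths: np.ndarray
    dry: np.ndarray
    wet: np.ndarray

    def __post_init__(self):
        wl = check_grid(self.wavelengths)
        object.__setattr__(self, "wavelengths", wl)
        for name in ("dry", "wet"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != wl.shape:
                raise ValueError(f"soil {name} spectrum grid mismatch")
            if np.any((v < 0) | (v > 1)):
                raise ValueError(f"soil {name} spectrum outside [0, 1]")
            object.__setattr__(self, name, v)

    @classmethod
    def default(cls, wavelengths: np.ndarray | None = None) -> "SoilModel":
        dry, wet = default_soil_spectra(wavelengths)
        from ._grid import WAVELENGTHS

        wl = WAVELENGTHS if wavelengths is None else np.asarray(wavelengths, float)
        return cls(wavelengths=wl, dry=dry, wet=wet)

    def reflectance(self, soil_moisture: float) -> np.ndarray:
        return (1.0 - soil_moisture) * self.dry + soil_moisture * self.wet


@dataclass(frozen=True)
class CanopyReflectance:
    """Canopy-top reflectance: direct-beam, diffuse-incidence, and combined."""

    wavelengths: np.ndarray
    rho_s: np.ndarray  # bidirectional (direct-beam incidence)
    rho_d: np.ndarray  # hemispherical-directional (diffuse incidence)
    rho: np.ndarray | None = None  # combined surface reflectance (Eq. of mixing)


# ---------------------------------------------------------------------------
# Leaf inclination distribution
# ---------------------------------------------------------------------------

def _campbell_lidf_exact(mean_angle_deg: float) -> np.ndarray:
    ala = np.deg2rad(mean_angle_deg)
    # Campbell's relation: mean angle [rad] ~= 9.65 * (3 + chi)^(-1.65), inverted
    chi = (ala / 9.65) ** (-1.0 / 1.65) - 3.0
    chi = max(chi, 1e-6)
    theta = np.linspace(0.0, np.pi / 2.0, 2001)[1:-1]
    dens = (
        2.0
        * chi**3
        * np.sin(theta)
        / (np.cos(theta) ** 2 + chi**2 * np.sin(theta) ** 2) ** 2
    )
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1]) * np.diff(theta))])
    cdf /= cdf[-1]
    edges = np.deg2rad(_LIDF_EDGES)
    cdf_at = np.interp(edges, theta, cdf, left=0.0, right=1.0)
    w = np.diff(cdf_at)
    w = np.clip(w, 0.0, None)
    return w / w.sum()


_LIDF_TABLE = None


def campbell_lidf(mean_angle_deg: float) -> np.ndarray:
    """Ellipsoidal leaf-angle distribution discretised to the 13 SAIL classes.

    The one-parameter ellipsoidal family is parameterised by its mean
    inclination via Campbell's empirical relation chi(mean angle); class
    weights integrate the density over each class interval and sum to 1.
    Evaluated from a precomputed fine lookup over the mean angle (0.1-degree
    knots, linearly interpolated) for speed inside MCMC loops.
    """
    if not (5.0 <= mean_angle_deg <= 85.0):
        raise ValueError("mean leaf angle must lie in [5, 85] degrees")
    global _LIDF_TABLE
    if _LIDF_TABLE is None:
        knots = np.arange(5.0, 85.01, 0.1)
        _LIDF_TABLE = (knots, np.array([_campbell_lidf_exact(a) for a in knots]))
    knots, table = _LIDF_TABLE
    i = min(int((mean_angle_deg - 5.0) / 0.1), knots.size - 2)
    frac = (mean_angle_deg - knots[i]) / 0.1
    w = (1.0 - frac) * table[i] + frac * table[i + 1]
    return w / w.sum()


# ---------------------------------------------------------------------------
# Geometry kernels
# ---------------------------------------------------------------------------

def _volscatt(tts: float, tto: float, psi: float, ttl: float):
    """Scattering geometry factors for one leaf inclination class.

    Returns (chi_s, chi_o, frho, ftau): fractional projections toward sun and
    observer and the bidirectional scattering area fractions weighting leaf
    reflectance and transmittance.
    """
    rts, rto, rpsi, rtl = map(math.radians, (tts, tto, psi, ttl))
    costs, costo = math.cos(rts), math.cos(rto)
    sints, sinto = math.sin(rts), math.sin(rto)
    costl, sintl = math.cos(rtl), math.sin(rtl)
    cs = costl * costs
    co = costl * costo
    ss = sintl * sints
    so = sintl * sinto

    cosbts = 5.0 if abs(ss) <= 1e-6 else -cs / ss
    cosbto = 5.0 if abs(so) <= 1e-6 else -co / so

    if abs(cosbts) < 1.0:
        bts = math.acos(cosbts)
        ds = ss
    else:
        bts = math.pi
        ds = cs
    chi_s = 2.0 / math.pi * ((bts - math.pi * 0.5) * cs + math.sin(bts) * ss)

    if abs(cosbto) < 1.0:
        bto = math.acos(cosbto)
        do_ = so
    else:
        bto = math.pi if tto < 90.0 else 0.0
        do_ = co if tto < 90.0 else -co
    chi_o = 2.0 / math.pi * ((bto - math.pi * 0.5) * co + math.sin(bto) * so)

    btran1 = abs(bts - bto)
    btran2 = math.pi - abs(bts + bto - math.pi)
    if rpsi <= btran1:
        bt1, bt2, bt3 = rpsi, btran1, btran2
    else:
        bt1 = btran1
        if rpsi <= btran2:
            bt2, bt3 = rpsi, btran2
        else:
            bt2, bt3 = btran2, rpsi

    t1 = 2.0 * cs * co + ss * so * math.cos(rpsi)
    t2 = 0.0
    if bt2 > 0.0:
        t2 = math.sin(bt2) * (2.0 * ds * do_ + ss * so * math.cos(bt1) * math.cos(bt3))
    denom = 2.0 * math.pi**2
    frho = max(((math.pi - bt2) * t1 + t2) / denom, 0.0)
    ftau = max((-bt2 * t1 + t2) / denom, 0.0)
    return chi_s, chi_o, frho, ftau


_VOLSCATT_CACHE: dict = {}


def _volscatt_classes(theta_s: float, theta_o: float, psi: float):
    """Per-class geometry kernels for the 13 SAIL inclination classes, cached
    per sun-sensor geometry (they do not depend on the LIDF weights)."""
    key = (theta_s, theta_o, psi)
    hit = _VOLSCATT_CACHE.get(key)
    if hit is None:
        rows = np.array(
            [_volscatt(theta_s, theta_o, psi, ttl) for ttl in LIDF_ANGLES]
        )
        hit = (rows[:, 0], rows[:, 1], rows[:, 2], rows[:, 3])
        if len(_VOLSCATT_CACHE) > 64:
            _VOLSCATT_CACHE.clear()
        _VOLSCATT_CACHE[key] = hit
    return hit


_COS2_TTL = np.cos(np.deg2rad(LIDF_ANGLES)) ** 2


def _geom_factors(lidf: np.ndarray, geom: ViewGeometry) -> dict:
    """LIDF-weighted extinction/scattering geometry factors (scalars)."""
    cts = math.cos(math.radians(geom.theta_s))
    cto = math.cos(math.radians(geom.theta_o))
    chi_s, chi_o, frho, ftau = _volscatt_classes(geom.theta_s, geom.theta_o, geom.psi)
    return {
        "ks": float(lidf @ chi_s) / cts,
        "ko": float(lidf @ chi_o) / cto,
        "bf": float(lidf @ _COS2_TTL),
        "sob": float(lidf @ frho) * math.pi / (cts * cto),
        "sof": float(lidf @ ftau) * math.pi / (cts * cto),
    }


# ---------------------------------------------------------------------------
# Homogeneous-layer closed-form solution
# ---------------------------------------------------------------------------

def _j1(k: float, m: np.ndarray, t: float) -> np.ndarray:
    """(exp(-m t) - exp(-k t)) / (k - m), stable near k = m."""
    d = k - m
    out = np.empty_like(m)
    near = np.abs(d) < 1e-6
    out[~near] = (np.exp(-m[~near] * t) - np.exp(-k * t)) / d[~near]
    mm = m[near]
    out[near] = 0.5 * t * (np.exp(-k * t) + np.exp(-mm * t)) * (
        1.0 - (d[near] * t) ** 2 / 12.0
    )
    return out


def _j2(k: float, m: np.ndarray, t: float) -> np.ndarray:
    """(1 - exp(-(k + m) t)) / (k + m)."""
    s = k + m
    return (1.0 - np.exp(-s * t)) / s


@dataclass
class LayerOps:
    """Transfer operators of one homogeneous layer (or combined system).

    Scalars: tss, too, tsstoo (direct/directional gap fractions); arrays over
    wavelength: rdd, tdd, rsd, tsd, rdo, tdo, rso.
    """

    tss: float
    too: float
    tsstoo: float
    rdd: np.ndarray
    tdd: np.ndarray
    rsd: np.ndarray
    tsd: np.ndarray
    rdo: np.ndarray
    tdo: np.ndarray
    rso: np.ndarray


def _identity_ops(nwl: int) -> LayerOps:
    z = np.zeros(nwl)
    return LayerOps(1.0, 1.0, 1.0, z, np.ones(nwl), z, z.copy(), z.copy(), z.copy(), z.copy())


def _hotspot_integral(ks: float, ko: float, lai: float, hspot: float, dso: float):
    """Bidirectional gap fraction and single-scattering path integral.

    Returns (tsstoo, sumint) where ``sumint`` integrates the joint
    sun-view gap probability over depth (Kuusk's correlation kernel,
    20-point scheme).  With hspot = 0 the exact uncorrelated forms are used.
    """
    tss = math.exp(-ks * lai)
    too = math.exp(-ko * lai)
    if lai <= 0:
        return 1.0, 0.0
    if hspot <= 0:
        tsstoo = tss * too
        sumint = (1.0 - tsstoo) / ((ks + ko) * lai)
        return tsstoo, sumint
    alf = (dso / hspot) * 2.0 / (ks + ko)
    if alf == 0.0:
        # pure hotspot: sun and view paths coincide
        tsstoo = tss
        sumint = (1.0 - tss) / (ks * lai)
        return tsstoo, sumint
    # joint gap probability over relative depth x:
    #   P(x) = exp(-(ks+ko) lai x + sqrt(ks ko) lai (1 - exp(-alf x)) / alf)
    # integrated on a dense geometric grid resolving both the correlation
    # scale (1/alf) and the attenuation scale (1/((ks+ko) lai))
    fhot = lai * math.sqrt(ko * ks)
    rate = max(alf, (ks + ko) * lai, 1.0)
    x = np.concatenate([[0.0], np.geomspace(1e-6 / rate, 1.0, 240)])
    y = -(ko + ks) * lai * x + fhot * (1.0 - np.exp(-np.minimum(alf * x, 700.0))) / alf
    f = np.exp(y)
    sumint = float(np.trapezoid(f, x))
    tsstoo = float(f[-1])
    return tsstoo, sumint


def _layer_ops(
    rho: np.ndarray,
    tau: np.ndarray,
    lidf: np.ndarray,
    lai: float,
    hotspot: float,
    geom: ViewGeometry,
    dso: float,
) -> LayerOps:
    """Closed-form four-stream operators of one homogeneous layer."""
    nwl = rho.size
    if lai <= 0:
        return _identity_ops(nwl)
    g = _geom_factors(lidf, geom)
    ks, ko, bf, sob, sof = g["ks"], g["ko"], g["bf"], g["sob"], g["sof"]

    sdb = 0.5 * (ks + bf)
    sdf = 0.5 * (ks - bf)
    dob = 0.5 * (ko + bf)
    dof = 0.5 * (ko - bf)
    ddb = 0.5 * (1.0 + bf)
    ddf = 0.5 * (1.0 - bf)

    sigb = ddb * rho + ddf * tau
    sigf = ddf * rho + ddb * tau
    att = 1.0 - sigf
    m2 = (att + sigb) * (att - sigb)
    m = np.sqrt(np.maximum(m2, 1e-30))
    sb = sdb * rho + sdf * tau
    sf = sdf * rho + sdb * tau
    vb = dob * rho + dof * tau
    vf = dof * rho + dob * tau
    w = sob * rho + sof * tau

    tss = math.exp(-ks * lai)
    too = math.exp(-ko * lai)
    z = _j2(ks, np.full_like(m, ko), lai)

    e1 = np.exp(-m * lai)
    e2 = e1**2
    with np.errstate(divide="ignore", invalid="ignore"):
        rinf = np.where(sigb > 0, (att - m) / np.where(sigb > 0, sigb, 1.0), 0.0)
    rinf2 = rinf**2
    re = rinf * e1
    denom = 1.0 - rinf2 * e2

    J1ks = _j1(ks, m, lai)
    J2ks = _j2(ks, m, lai)
    J1ko = _j1(ko, m, lai)
    J2ko = _j2(ko, m, lai)

    Ps = (sf + sb * rinf) * J1ks
    Qs = (sf * rinf + sb) * J2ks
    Pv = (vf + vb * rinf) * J1ko
    Qv = (vf * rinf + vb) * J2ko

    tdd = (1.0 - rinf2) * e1 / denom
    rdd = rinf * (1.0 - e2) / denom
    tsd = (Ps - re * Qs) / denom
    rsd = (Qs - re * Ps) / denom
    tdo = (Pv - re * Qv) / denom
    rdo = (Qv - re * Pv) / denom

    g1 = (z - J1ks * too) / (ko + m)
    g2 = (z - J1ko * tss) / (ks + m)
    Tv1 = (vf * rinf + vb) * g1
    Tv2 = (vf + vb * rinf) * g2
    T1 = Tv1 * (sf + sb * rinf)
    T2 = Tv2 * (sf * rinf + sb)
    T3 = (rdo * Qs + tdo * Ps) * rinf
    rsod = (T1 + T2 - T3) / (1.0 - rinf2)

    tsstoo, sumint = _hotspot_integral(ks, ko, lai, hotspot, dso)
    rsos = w * lai * sumint
    rso = rsos + rsod

    return LayerOps(tss, too, tsstoo, rdd, tdd, rsd, tsd, rdo, tdo, rso)


@dataclass
class BottomOps:
    """Reflectance operators of everything below a layer (opaque system)."""

    rsd: np.ndarray
    rdd: np.ndarray
    rso: np.ndarray
    rdo: np.ndarray


def _soil_bottom(rs: np.ndarray) -> BottomOps:
    return BottomOps(rsd=rs, rdd=rs, rso=rs, rdo=rs)


def _add_layer(layer: LayerOps, below: BottomOps) -> BottomOps:
    """Adding method: stack a homogeneous layer on top of an opaque system."""
    dn = 1.0 - layer.rdd * below.rdd
    # direct-beam incidence
    Ds = (layer.tsd + layer.rdd * below.rsd * layer.tss) / dn
    Us = below.rsd * layer.tss + below.rdd * Ds
    rsd = layer.rsd + layer.tdd * Us
    rso = (
        layer.rso
        + layer.tsstoo * below.rso
        + layer.too * below.rdo * Ds
        + layer.tdo * Us
    )
    # diffuse incidence
    Dd = layer.tdd / dn
    Ud = below.rdd * Dd
    rdd = layer.rdd + layer.tdd * Ud
    rdo = layer.rdo + layer.too * below.rdo * Dd + layer.tdo * Ud
    return BottomOps(rsd=rsd, rdd=rdd, rso=rso, rdo=rdo)


# ---------------------------------------------------------------------------
# Public forward model
# ---------------------------------------------------------------------------

def liana_lai_fraction(L: float, f2: float) -> float:
    """Fraction of total LAI carried by the liana (top) layer: L * (1 - f2)."""
    if not (0.0 <= L <= 1.0) or not (0.0 <= f2 <= 1.0):
        raise ValueError("L and f2 must lie in [0, 1]")
    return L * (1.0 - f2)


def _mixed_layers(liana: LeafOptics, tree: LeafOptics, canopy: CanopyConfig):
    """Per-layer effective optics and mean angles under the dissociation factor.

    With D = 1 the top layer is pure liana foliage; with D = 0 both layers
    carry the canopy-wide liana/tree mixture.  Liana leaf area is conserved
    across the interpolation.
    """
    p_top = liana_lai_fraction(canopy.L, canopy.f2)
    lai_top = canopy.lai * p_top
    lai_bot = canopy.lai - lai_top
    q_global = p_top  # liana share of total leaf area
    q_top = canopy.D * 1.0 + (1.0 - canopy.D) * q_global
    if lai_bot > 0:
        q_bot = (canopy.lai * q_global - lai_top * q_top) / lai_bot
        q_bot = min(max(q_bot, 0.0), 1.0)
    else:
        q_bot = 0.0

    def mix(q):
        rho = q * liana.reflectance + (1.0 - q) * tree.reflectance
        tau = q * liana.transmittance + (1.0 - q) * tree.transmittance
        ang = q * canopy.omega1 + (1.0 - q) * canopy.omega2
        return rho, tau, ang

    return (lai_top, *mix(q_top)), (lai_bot, *mix(q_bot))


def foursail2_forward(
    liana_optics: LeafOptics,
    tree_optics: LeafOptics,
    canopy: CanopyConfig,
    geom: ViewGeometry,
    soil: SoilModel,
) -> CanopyReflectance:
    """Two-layer four-stream canopy reflectance (direct and diffuse terms).

    Returns a :class:`CanopyReflectance` with ``rho_s`` (bidirectional,
    direct-beam incidence) and ``rho_d`` (hemispherical-directional, diffuse
    incidence); the combined surface reflectance is left to the coupling
    step, which weighs the two by the diffuse-sky fraction.
    """
    wl = liana_optics.wavelengths
    if not np.array_equal(wl, tree_optics.wavelengths) or not np.array_equal(
        wl, soil.wavelengths
    ):
        raise ValueError("leaf optics and soil must share one wavelength grid")
    rs = soil.reflectance(canopy.soil_moisture)

    tants = math.tan(math.radians(geom.theta_s))
    tanto = math.tan(math.radians(geom.theta_o))
    dso = math.sqrt(
        max(
            tants**2
            + tanto**2
            - 2.0 * tants * tanto * math.cos(math.radians(geom.psi)),
            0.0,
        )
    )

    (lai1, rho1, tau1, ang1), (lai2, rho2, tau2, ang2) = _mixed_layers(
        liana_optics, tree_optics, canopy
    )

    bottom = _soil_bottom(rs)
    if lai2 > 0:
        ops2 = _layer_ops(rho2, tau2, campbell_lidf(ang2), lai2, canopy.hotspot, geom, dso)
        bottom = _add_layer(ops2, bottom)
    if lai1 > 0:
        ops1 = _layer_ops(rho1, tau1, campbell_lidf(ang1), lai1, canopy.hotspot, geom, dso)
        bottom = _add_layer(ops1, bottom)

    return CanopyReflectance(wavelengths=wl, rho_s=bottom.rso, rho_d=bottom.rdo)


def combine_reflectance(
    refl: CanopyReflectance, geom: ViewGeometry, diffuse: np.ndarray | float | None = None
) -> CanopyReflectance:
    """Mix direct and diffuse reflectance by the diffuse-sky fraction S.

    rho = S * rho_d + (1 - S) * rho_s.  ``diffuse`` may be a per-wavelength
    array, a scalar (e.g. 0 or 1 to force either term), or None to use the
    default sky table at the configured solar zenith.
    """
    if diffuse is None:
        S = diffuse_fraction(refl.wavelengths, geom.theta_s)
    else:
        S = np.broadcast_to(np.asarray(diffuse, dtype=float), refl.wavelengths.shape)
    rho = S * refl.rho_d + (1.0 - S) * refl.rho_s
    return CanopyReflectance(
        wavelengths=refl.wavelengths, rho_s=refl.rho_s, rho_d=refl.rho_d, rho=rho
    )


def couple_prosail2(
    liana_leaf: LeafParams,
    tree_leaf: LeafParams,
    canopy: CanopyConfig,
    geom: ViewGeometry,
    soil: SoilModel | None = None,
    table: CoefficientTable | None = None,
    diffuse: np.ndarray | float | None = None,
) -> CanopyReflectance:
    """Full coupled chain: leaf model (twice) -> two-layer canopy -> sky mixing."""
    if table is None:
        table = default_table()
    if soil is None:
        soil = SoilModel.default(table.wavelengths)
    liana_optics = prospect_forward(liana_leaf, table)
    tree_optics = prospect_forward(tree_leaf, table)
    refl = foursail2_forward(liana_optics, tree_optics, canopy, geom, soil)
    return combine_reflectance(refl, geom, diffuse)
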