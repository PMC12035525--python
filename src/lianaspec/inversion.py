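"""Bayesian inversion of leaf and canopy reflectance, and trait hierarchies.

Three model classes follow the familiar model/results pattern: construct the
model from data, call :meth:`fit`, inspect the returned results object.

* :class:`LeafInversion` -- estimate leaf traits from a single leaf
  reflectance spectrum (fast bounded MAP with multiple starts by default,
  full MCMC on request).
* :class:`CanopyInversion` -- estimate canopy structure and (optionally)
  leaf traits of both growth forms from a canopy/stand spectrum, sampled
  with differential-evolution MCMC; leaf-level posteriors enter as normal
  priors (see :func:`derive_priors`).
* :class:`TraitHierarchy` -- decompose trait variation into growth-form,
  species-within-study and study components with a conjugate Gibbs sampler,
  yielding the posterior of the liana-minus-tree contrast.

The likelihood everywhere is independent Gaussian per wavelength (or per
sensor band after SRF convolution) with a single residual standard
deviation ``sigma``, itself a free parameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from ._grid import check_grid
from .canopy import (
    CANOPY_BOUNDS,
    CanopyConfig,
    SoilModel,
    ViewGeometry,
    combine_reflectance,
    foursail2_forward,
)
from .coefficients import CoefficientTable, default_table
from .leaf import LEAF_BOUNDS, LeafParams, prospect_forward
from .priors import Fixed, Normal, PriorSet, Uniform
from .sampling import PosteriorSamples, gelman_rubin, run_demc
from .sensors import SensorModel, band_convolve

__all__ = [
    "log_posterior",
    "LeafInversion",
    "CanopyInversion",
    "TraitHierarchy",
    "InversionResults",
    "HierarchyResults",
    "invert_leaf",
    "derive_priors",
    "default_leaf_priors",
    "default_canopy_priors",
]

#: Minimum number of sensor bands accepted for inversion by default; sparser
#: multispectral sampling makes parameter uncertainty unreliable.
MIN_BANDS = 10


def log_posterior(
    theta: np.ndarray,
    observed: np.ndarray,
    priors: PriorSet,
    forward,
    sensor: SensorModel | None = None,
    wavelengths: np.ndarray | None = None,
) -> float:
    """Log posterior density of free parameters ``theta``.

    ``forward`` maps a full parameter dict (free + fixed) to a predicted
    spectrum on ``wavelengths``; when a ``sensor`` is given both prediction
    and data live in band space.  The residual standard deviation must be a
    parameter named ``"sigma"``.  Returns -inf outside the prior support.
    """
    observed = np.asarray(observed, dtype=float)
    if np.any(~np.isfinite(observed)):
        raise ValueError("observed spectrum contains NaN/inf")
    lp = priors.log_prior(theta)
    if not np.isfinite(lp):
        return -np.inf
    params = priors.to_dict(theta)
    sigma = params.get("sigma")
    if sigma is None or sigma <= 0:
        return -np.inf
    pred = forward(params)
    if sensor is not None:
        pred = band_convolve(pred, sensor, wavelengths)
    resid = observed - pred
    n = resid.size
    ll = -0.5 * n * np.log(2.0 * np.pi) - n * np.log(sigma) - 0.5 * np.sum(
        resid**2
    ) / sigma**2
    return float(lp + ll)


# ---------------------------------------------------------------------------
# Results containers
# ---------------------------------------------------------------------------

@dataclass
class InversionResults:
    """Estimates, uncertainties and diagnostics from a spectral inversion."""

    method: str
    param_names: list
    estimates: dict
    sd: dict
    ci_low: dict
    ci_high: dict
    samples: PosteriorSamples | None = None
    rhat: dict | None = None
    converged: bool = True
    flags: list = field(default_factory=list)
    residual_sd: float | None = None

    @property
    def params(self) -> dict:
        return self.estimates

    def ci(self, name: str):
        return (self.ci_low[name], self.ci_high[name])

    def leaf_params(self, prefix: str = "") -> LeafParams:
        """Assemble a LeafParams from (optionally prefixed) estimates."""
        vals = {
            k[len(prefix):]: v
            for k, v in self.estimates.items()
            if k.startswith(prefix) and k[len(prefix):] in LEAF_BOUNDS
        }
        return LeafParams(**vals)

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in self.param_names:
            rows.append(
                {
                    "parameter": name,
                    "estimate": self.estimates[name],
                    "sd": self.sd.get(name, np.nan),
                    "ci2.5": self.ci_low.get(name, np.nan),
                    "ci97.5": self.ci_high.get(name, np.nan),
                    "rhat": (self.rhat or {}).get(name, np.nan),
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def __repr__(self):
        state = "converged" if self.converged else "NOT converged"
        return (
            f"<InversionResults method={self.method} {state} "
            f"params={len(self.param_names)} flags={self.flags}>"
        )


# ---------------------------------------------------------------------------
# Base spectral inversion
# ---------------------------------------------------------------------------

class _SpectralInversion:
    """Shared fitting machinery; subclasses define the forward model."""

    def __init__(self, wavelengths, observed, priors: PriorSet, sensor=None,
                 allow_multispectral: bool = False):
        self.wavelengths = check_grid(np.asarray(wavelengths, dtype=float))
        self.observed = np.asarray(observed, dtype=float)
        if sensor is not None and sensor.n_bands < MIN_BANDS and not allow_multispectral:
            raise ValueError(
                f"sensor {sensor.name!r} has {sensor.n_bands} bands (< {MIN_BANDS}); "
                "parameter uncertainty is unreliable at coarse spectral resolution. "
                "Pass allow_multispectral=True to override."
            )
        self.sensor = sensor
        expected = sensor.n_bands if sensor is not None else self.wavelengths.size
        if self.observed.size != expected:
            raise ValueError("observed length does not match grid/bands")
        self.priors = priors

    # subclasses override
    def forward(self, params: dict) -> np.ndarray:
        raise NotImplementedError

    def log_posterior(self, theta: np.ndarray) -> float:
        return log_posterior(
            theta, self.observed, self.priors, self.forward,
            sensor=self.sensor, wavelengths=self.wavelengths,
        )

    def _fit_map(self, seed: int, n_starts: int) -> InversionResults:
        rng = np.random.default_rng(seed)
        bounds = self.priors.bounds()
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        span = hi - lo

        def neg(theta_unit):
            val = self.log_posterior(lo + theta_unit * span)
            return 1e12 if not np.isfinite(val) else -val

        best = None
        starts = self.priors.sample(rng, n_starts)
        for s in starts:
            u0 = np.clip((s - lo) / span, 1e-6, 1.0 - 1e-6)
            res = minimize(
                neg, u0, method="L-BFGS-B",
                bounds=[(0.0, 1.0)] * len(bounds),
                options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10},
            )
            if best is None or res.fun < best.fun:
                best = res
        theta = lo + best.x * span
        est = self.priors.to_dict(theta)
        flags = []
        if not best.success and best.fun > 0:
            flags.append("optimizer_not_converged")
        names = self.priors.free_names
        return InversionResults(
            method="map",
            param_names=names,
            estimates=est,
            sd={},
            ci_low={},
            ci_high={},
            converged=bool(best.success) or best.fun < 1e11,
            flags=flags,
            residual_sd=est.get("sigma"),
        )

    def _fit_demc(self, seed: int, n_iter: int, n_chains: int,
                  rhat_target: float = 1.1, max_restarts: int = 2) -> InversionResults:
        # convergence-targeted fitting: when the scale-reduction diagnostic
        # misses the target, refit with doubled chain length (fresh derived
        # seed); deterministic given the input seed
        samples = None
        for attempt in range(max_restarts + 1):
            samples = run_demc(
                self.log_posterior,
                lambda rng, n: self.priors.sample(rng, n),
                n_params=self.priors.n_free,
                n_iter=n_iter * 2**attempt,
                n_chains=n_chains,
                seed=(seed + 1_000_003 * attempt) % 2**31,
                names=self.priors.free_names,
                snooker_prob=0.3,
                gamma_unit_every=5,
            )
            if float(np.max(gelman_rubin(samples))) < rhat_target:
                break
        names = self.priors.free_names
        q = samples.quantiles((0.025, 0.5, 0.975))
        rhat = gelman_rubin(samples)
        est = self.priors.to_dict(q[1])
        sd = dict(zip(names, samples.flat.std(axis=0, ddof=1)))
        res = InversionResults(
            method="demc",
            param_names=names,
            estimates=est,
            sd=sd,
            ci_low=dict(zip(names, q[0])),
            ci_high=dict(zip(names, q[2])),
            samples=samples,
            rhat=dict(zip(names, rhat)),
            converged=bool(np.all(rhat < rhat_target)),
            residual_sd=est.get("sigma"),
        )
        return res

    def fit(
        self,
        method: str = "demc",
        seed: int = 0,
        n_iter: int = 4000,
        n_chains: int = 3,
        n_starts: int = 5,
    ) -> InversionResults:
        """Fit the model; ``method`` is ``"map"`` or ``"demc"``."""
        if method == "map":
            return self._fit_map(seed=seed, n_starts=n_starts)
        if method == "demc":
            return self._fit_demc(seed=seed, n_iter=n_iter, n_chains=n_chains)
        raise ValueError("method must be 'map' or 'demc'")


def default_leaf_priors(variant: str = "D", sigma_hi: float = 0.2) -> PriorSet:
    """Flat priors over the physical leaf-trait ranges, plus sigma."""
    priors = {k: Uniform(*LEAF_BOUNDS[k]) for k in LEAF_BOUNDS}
    if variant in ("5", "5b"):
        priors["c_an"] = Fixed(0.0)
    if variant == "5":
        priors["c_br"] = Fixed(0.0)
    priors["sigma"] = Uniform(1e-4, sigma_hi)
    return PriorSet(priors)


class LeafInversion(_SpectralInversion):
    """Estimate leaf traits from one reflectance spectrum.

    Parameters
    ----------
    wavelengths, observed : the measured reflectance spectrum.
    priors : optional PriorSet (defaults to flat physical ranges).
    table : coefficient table (selects the model variant).
    """

    def __init__(self, wavelengths, observed, priors: PriorSet | None = None,
                 table: CoefficientTable | None = None, sensor=None,
                 allow_multispectral: bool = False):
        base_table = default_table() if table is None else table
        wl = check_grid(np.asarray(wavelengths, dtype=float))
        # without a sensor the forward model runs directly on the observation grid
        self.table = base_table if sensor is not None else base_table.subset(wl)
        if priors is None:
            priors = default_leaf_priors(self.table.variant)
        super().__init__(wl, observed, priors, sensor, allow_multispectral)

    def forward(self, params: dict) -> np.ndarray:
        leaf = LeafParams.from_dict(params)
        return prospect_forward(leaf, self.table).reflectance

    def fit(self, method: str = "map", **kw) -> InversionResults:
        res = super().fit(method=method, **kw)
        if float(np.max(self.observed)) < 5e-3:
            res.flags.append("non_physical_spectrum")
            res.converged = False
        return res


def invert_leaf(wavelengths, spectrum, priors=None, mode: str = "map",
                table=None, seed: int = 0, **kw) -> InversionResults:
    """Convenience wrapper: fit a single leaf spectrum (MAP or MCMC)."""
    model = LeafInversion(wavelengths, spectrum, priors=priors, table=table)
    return model.fit(method="map" if mode == "map" else "demc", seed=seed, **kw)


# ---------------------------------------------------------------------------
# Canopy inversion
# ---------------------------------------------------------------------------

#: Leaf parameter names prefixed per growth form in canopy parameter dicts.
_LEAF_FIELDS = tuple(LEAF_BOUNDS)


def default_canopy_priors(
    free=("lai", "omega1", "omega2", "f2", "sigma"),
    leaf_defaults: dict | None = None,
    fixed: dict | None = None,
) -> PriorSet:
    """Flat priors over physical canopy ranges; leaf traits fixed by default.

    ``leaf_defaults`` maps "liana"/"tree" to LeafParams used as fixed values
    (or as centres when the caller upgrades them to normal priors via
    :func:`derive_priors`).
    """
    from .synthetic import DEFAULT_TRAITS, trait_means  # late import, no cycle

    if leaf_defaults is None:
        leaf_defaults = {
            gf: LeafParams.from_dict(trait_means(DEFAULT_TRAITS[gf]))
            for gf in ("liana", "tree")
        }
    priors: dict = {}
    defaults = CanopyConfig()
    for name in ("lai", "omega1", "omega2", "f2", "L", "D", "hotspot", "soil_moisture"):
        lo, hi = CANOPY_BOUNDS[name]
        if name in free:
            if name == "lai":
                # closed-canopy inversions: reflectance saturates well below the
                # physical ceiling, so the flat prior stops at LAI 12
                lo, hi = max(lo, 0.5), min(hi, 12.0)
            priors[name] = Uniform(lo, hi)
        else:
            priors[name] = Fixed((fixed or {}).get(name, getattr(defaults, name)))
    for gf in ("liana", "tree"):
        lp = leaf_defaults[gf]
        for f in _LEAF_FIELDS:
            key = f"{gf}_{f}"
            if key in free:
                priors[key] = Uniform(*LEAF_BOUNDS[f])
            else:
                priors[key] = Fixed((fixed or {}).get(key, getattr(lp, f)))
    priors["sigma"] = (
        Uniform(1e-4, 0.1) if "sigma" in free
        else Fixed((fixed or {}).get("sigma", 0.01))
    )
    if fixed:
        for k, v in fixed.items():
            if k in priors and not isinstance(priors[k], Fixed):
                priors[k] = Fixed(v)
    return PriorSet(priors)


class CanopyInversion(_SpectralInversion):
    """Estimate two-layer canopy parameters from a canopy/stand spectrum.

    The forward model is the full coupled chain (leaf model per growth form,
    two-layer canopy, diffuse-sky mixing).  Canopy parameter names follow
    :class:`CanopyConfig`; leaf traits are prefixed ``liana_``/``tree_``.
    """

    def __init__(self, wavelengths, observed, priors: PriorSet | None = None,
                 geometry: ViewGeometry | None = None,
                 soil: SoilModel | None = None,
                 table: CoefficientTable | None = None,
                 diffuse=None,
                 sensor=None, allow_multispectral: bool = False):
        wl = check_grid(np.asarray(wavelengths, float))
        self.geometry = geometry or ViewGeometry()
        base_table = default_table() if table is None else table
        self.table = base_table if sensor is not None else base_table.subset(wl)
        grid = self.table.wavelengths
        self.soil = soil or SoilModel.default(grid)
        self.diffuse = diffuse
        if priors is None:
            priors = default_canopy_priors()
        super().__init__(wl, observed, priors, sensor, allow_multispectral)
        self._leaf_cache: dict = {}

    def forward(self, params: dict) -> np.ndarray:
        liana = LeafParams(**{f: params[f"liana_{f}"] for f in _LEAF_FIELDS})
        tree = LeafParams(**{f: params[f"tree_{f}"] for f in _LEAF_FIELDS})
        cfg = CanopyConfig(
            lai=params["lai"], omega1=params["omega1"], omega2=params["omega2"],
            f2=params["f2"], L=params["L"], D=params["D"],
            hotspot=params["hotspot"], soil_moisture=params["soil_moisture"],
        )
        # leaf optics are costly and often fixed across proposals: memoise
        key_l = tuple(liana.as_dict().values())
        key_t = tuple(tree.as_dict().values())
        if key_l not in self._leaf_cache:
            if len(self._leaf_cache) > 64:
                self._leaf_cache.clear()
            self._leaf_cache[key_l] = prospect_forward(liana, self.table)
        if key_t not in self._leaf_cache:
            self._leaf_cache[key_t] = prospect_forward(tree, self.table)
        refl = foursail2_forward(
            self._leaf_cache[key_l], self._leaf_cache[key_t], cfg,
            self.geometry, self.soil,
        )
        return combine_reflectance(refl, self.geometry, self.diffuse).rho


# ---------------------------------------------------------------------------
# Prior derivation from leaf-stage output
# ---------------------------------------------------------------------------

def derive_priors(
    leaf_stats: dict,
    free=("lai", "omega1", "omega2", "f2", "sigma"),
    fixed: dict | None = None,
) -> PriorSet:
    """Build canopy-inversion priors from leaf-stage posterior summaries.

    ``leaf_stats`` maps growth form ("liana"/"tree") to {trait: (mean, sd)}.
    Leaf traits get normal priors truncated to physical ranges; canopy
    structure gets flat priors (or Fixed entries via ``fixed``, e.g. the
    infestation index L when known from data).  Missing traits fall back to
    package defaults with a warning.
    """
    from .synthetic import DEFAULT_TRAITS, trait_means

    base = default_canopy_priors(free=free, fixed=fixed)
    priors = dict(base.items())
    for gf in ("liana", "tree"):
        stats_gf = leaf_stats.get(gf, {})
        fallback = trait_means(DEFAULT_TRAITS[gf])
        for f in _LEAF_FIELDS:
            key = f"{gf}_{f}"
            if fixed and key in fixed:
                continue
            if f in stats_gf:
                mean, sd = stats_gf[f]
                lo, hi = LEAF_BOUNDS[f]
                priors[key] = Normal(float(mean), float(sd), lo, hi)
            else:
                warnings.warn(
                    f"no leaf-stage summary for {key}; using package default",
                    stacklevel=2,
                )
                priors[key] = Fixed(fallback[f])
    return PriorSet(priors)


# ---------------------------------------------------------------------------
# Hierarchical trait decomposition
# ---------------------------------------------------------------------------

@dataclass
class HierarchyResults:
    """Posterior decomposition of trait variation.

    ``contrast`` holds draws of the liana-minus-tree growth-form difference;
    ``zero_overlap`` is the two-sided fraction of contrast mass overlapping
    zero (2 * min(P(c > 0), P(c < 0))): ~0.5 for a null effect, ~0 for a
    decisive one.
    """

    trait: str
    group_means: dict
    contrast: np.ndarray
    variance_draws: dict
    seed: int

    @property
    def contrast_mean(self) -> float:
        return float(self.contrast.mean())

    @property
    def contrast_sd(self) -> float:
        return float(self.contrast.std(ddof=1))

    @property
    def zero_overlap(self) -> float:
        p = float(np.mean(self.contrast > 0))
        return 2.0 * min(p, 1.0 - p)

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "quantity": f"mean[{gf}]",
                "estimate": float(v.mean()),
                "sd": float(v.std(ddof=1)),
                "ci2.5": float(np.quantile(v, 0.025)),
                "ci97.5": float(np.quantile(v, 0.975)),
            }
            for gf, v in self.group_means.items()
        ]
        rows.append(
            {
                "quantity": "contrast (liana - tree)",
                "estimate": self.contrast_mean,
                "sd": self.contrast_sd,
                "ci2.5": float(np.quantile(self.contrast, 0.025)),
                "ci97.5": float(np.quantile(self.contrast, 0.975)),
            }
        )
        for name, v in self.variance_draws.items():
            rows.append(
                {
                    "quantity": f"sd[{name}]",
                    "estimate": float(np.sqrt(v).mean()),
                    "sd": float(np.sqrt(v).std(ddof=1)),
                    "ci2.5": float(np.quantile(np.sqrt(v), 0.025)),
                    "ci97.5": float(np.quantile(np.sqrt(v), 0.975)),
                }
            )
        return pd.DataFrame(rows).set_index("quantity")


class TraitHierarchy:
    """Hierarchical decomposition of a leaf trait across groupings.

    Model: T = mu_{growth form} + b_{species in study} + c_{study} + e, with
    b, c zero-mean normal random effects and conjugate inverse-gamma
    hyperpriors on all variances (weakly informative, scaled to the sample
    variance so the prior carries no unit information).
    Growth-form means carry flat priors; the quantity of interest is their
    liana-minus-tree contrast.
    """

    def __init__(self, values, growth_form, species, study, trait: str = "trait"):
        values = np.asarray(values, dtype=float)
        growth_form = np.asarray(growth_form)
        species = np.asarray(species)
        study = np.asarray(study)
        if not (values.size == growth_form.size == species.size == study.size):
            raise ValueError("all columns must have equal length")
        if np.any(~np.isfinite(values)):
            raise ValueError("trait values contain NaN/inf")
        self.trait = trait
        self.values = values
        self.gf_labels = sorted(set(growth_form.tolist()))
        self.gf_idx = np.searchsorted(self.gf_labels, growth_form)
        # species nested in study
        sp_keys = np.array([f"{st}::{sp}" for st, sp in zip(study, species)])
        self.sp_labels, self.sp_idx = np.unique(sp_keys, return_inverse=True)
        self.st_labels, self.st_idx = np.unique(study, return_inverse=True)
        self.use_study = self.st_labels.size >= 2
        if not self.use_study:
            warnings.warn(
                "single study: study effect dropped from the hierarchy",
                stacklevel=2,
            )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, value: str = "value", growth_form: str = "growth_form",
        species: str = "species", study: str = "study", trait: str | None = None,
    ) -> "TraitHierarchy":
        return cls(
            df[value], df[growth_form], df[species], df[study],
            trait=trait or value,
        )

    def fit(self, n_draws: int = 3000, burn: int = 1000, seed: int = 0) -> HierarchyResults:
        rng = np.random.default_rng(seed)
        y = self.values
        n = y.size
        n_gf = len(self.gf_labels)
        n_sp = self.sp_labels.size
        n_st = self.st_labels.size
        # weakly-informative conjugate hyperpriors, scaled to the data so they
        # stay uninformative regardless of the trait's units
        a0 = 0.01
        b0 = 0.01 * max(float(y.var()), 1e-12)

        mu = np.array([y[self.gf_idx == i].mean() for i in range(n_gf)])
        b = np.zeros(n_sp)
        c = np.zeros(n_st)
        se2 = max(y.var(), 1e-8)
        sb2 = sc2 = se2 / 2.0

        n_gf_obs = np.bincount(self.gf_idx, minlength=n_gf).astype(float)
        n_sp_obs = np.bincount(self.sp_idx, minlength=n_sp).astype(float)
        n_st_obs = np.bincount(self.st_idx, minlength=n_st).astype(float)

        keep_mu = np.empty((n_draws, n_gf))
        keep_var = {"residual": np.empty(n_draws), "species": np.empty(n_draws)}
        if self.use_study:
            keep_var["study"] = np.empty(n_draws)

        # species -> growth form map (species are nested in one growth form)
        sp_gf = np.zeros(n_sp, dtype=int)
        sp_gf[self.sp_idx] = self.gf_idx

        for it in range(burn + n_draws):
            # growth-form means, sampled with the species effects integrated
            # out (partially collapsed step: the centred parameterisation of
            # mu against the species-effect means mixes poorly otherwise).
            # Species means of (y - c) have marginal variance sb2 + se2/n_j.
            resid = y - (c[self.st_idx] if self.use_study else 0.0)
            sp_mean = np.bincount(self.sp_idx, weights=resid, minlength=n_sp) / n_sp_obs
            w = 1.0 / (sb2 + se2 / n_sp_obs)
            w_sum = np.bincount(sp_gf, weights=w, minlength=n_gf)
            w_mean = np.bincount(sp_gf, weights=w * sp_mean, minlength=n_gf) / w_sum
            mu = w_mean + rng.standard_normal(n_gf) / np.sqrt(w_sum)
            # species effects
            resid = y - mu[self.gf_idx] - (c[self.st_idx] if self.use_study else 0.0)
            sums = np.bincount(self.sp_idx, weights=resid, minlength=n_sp)
            prec = n_sp_obs / se2 + 1.0 / sb2
            b = sums / se2 / prec + rng.standard_normal(n_sp) / np.sqrt(prec)
            # study effects
            if self.use_study:
                resid = y - mu[self.gf_idx] - b[self.sp_idx]
                sums = np.bincount(self.st_idx, weights=resid, minlength=n_st)
                prec = n_st_obs / se2 + 1.0 / sc2
                c = sums / se2 / prec + rng.standard_normal(n_st) / np.sqrt(prec)
            # variances
            resid = y - mu[self.gf_idx] - b[self.sp_idx] - (
                c[self.st_idx] if self.use_study else 0.0
            )
            se2 = 1.0 / rng.gamma(a0 + n / 2.0, 1.0 / (b0 + 0.5 * np.sum(resid**2)))
            sb2 = 1.0 / rng.gamma(a0 + n_sp / 2.0, 1.0 / (b0 + 0.5 * np.sum(b**2)))
            if self.use_study:
                sc2 = 1.0 / rng.gamma(
                    a0 + n_st / 2.0, 1.0 / (b0 + 0.5 * np.sum(c**2))
                )
            j = it - burn
            if j >= 0:
                keep_mu[j] = mu
                keep_var["residual"][j] = se2
                keep_var["species"][j] = sb2
                if self.use_study:
                    keep_var["study"][j] = sc2

        group_means = {
            gf: keep_mu[:, i] for i, gf in enumerate(self.gf_labels)
        }
        if "liana" in group_means and "tree" in group_means:
            contrast = group_means["liana"] - group_means["tree"]
        else:
            contrast = keep_mu[:, 0] - keep_mu[:, -1]
        return HierarchyResults(
            trait=self.trait,
            group_means=group_means,
            contrast=contrast,
            variance_draws=keep_var,
            seed=seed,
        )
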