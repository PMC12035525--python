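"""Synthetic data generators emulating the study's statistical structure.

All generators are pure functions of (configuration, seed).  Default trait
distributions encode the observed liana/tree contrasts: lianas build
cheaper leaves on average (thinner, lower pigment, dry-mass and water
content per area) and hold them ~25% flatter (mean inclination 27.9 deg vs
37.1 deg for trees).  Magnitudes of the leaf-trait contrasts sit in the
10-30% relative range; draws are truncated normals within physical bounds.
The annotated defaults also ship as ``data/default_traits.yaml`` so a user
can adapt them to any site.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._grid import default_grid
from .canopy import CanopyConfig, SoilModel, ViewGeometry, couple_prosail2
from .coefficients import CoefficientTable, default_table
from .divergence import SpectralDistribution
from .leaf import LeafParams, prospect_forward

__all__ = [
    "DEFAULT_TRAITS",
    "trait_means",
    "sample_traits",
    "generate_leaf_spectra",
    "generate_canopy_spectra",
    "generate_trait_table",
    "default_endmembers",
]

def _load_default_traits() -> dict:
    import importlib.resources

    import yaml

    text = (
        importlib.resources.files("lianaspec") / "data" / "default_traits.yaml"
    ).read_text()
    raw = yaml.safe_load(text)
    return {gf: {k: tuple(v) for k, v in cfg.items()} for gf, cfg in raw.items()}


#: Per-growth-form trait distributions: (mean, sd, lower, upper), loaded from
#: the annotated ``data/default_traits.yaml``.  Leaf fields follow LeafParams;
#: "omega" is the mean leaf inclination (deg).
DEFAULT_TRAITS = _load_default_traits()

#: Default canopy/site configuration for synthetic canopy ensembles.
DEFAULT_SITE = {
    "lai": (6.0, 1.0, 2.0, 10.0),
    "f2": (0.66, 0.08, 0.3, 0.95),
    "soil_moisture": (0.5, 0.1, 0.0, 1.0),
    "hotspot": 0.05,
    "theta_s": 30.0,
    "theta_o": 0.0,
    "psi": 0.0,
}


def trait_means(config: dict) -> dict:
    """Collapse a trait config to its mean values."""
    return {k: v[0] for k, v in config.items()}


def _truncnorm(rng, mean, sd, lo, hi, n):
    if sd < 0:
        raise ValueError("trait sd must be non-negative")
    if sd == 0:
        return np.full(n, float(mean))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm(a, b, loc=mean, scale=sd).ppf(rng.uniform(size=n))


def sample_traits(
    growth_form: str, n: int, seed: int, config: dict | None = None
) -> pd.DataFrame:
    """Draw per-individual leaf traits (plus leaf angle) for one growth form."""
    if config is None:
        config = DEFAULT_TRAITS[growth_form]
    rng = np.random.default_rng(seed)
    out = {}
    for name, (mean, sd, lo, hi) in config.items():
        out[name] = _truncnorm(rng, mean, sd, lo, hi, n)
    df = pd.DataFrame(out)
    df.insert(0, "growth_form", growth_form)
    return df


def generate_leaf_spectra(
    n: int,
    growth_form: str,
    noise_sd: float = 0.005,
    seed: int = 0,
    config: dict | None = None,
    table: CoefficientTable | None = None,
    wavelengths: np.ndarray | None = None,
):
    """Simulate leaf reflectance spectra with known ground truth.

    Returns ``(wavelengths, spectra, truth)``: an (n, n_wl) array of noisy
    reflectance spectra (iid Gaussian noise, clipped to [0, 1]) and the
    trait table that generated them.
    """
    if table is None:
        table = default_table()
    if wavelengths is not None:
        table = table.subset(np.asarray(wavelengths, float))
    truth = sample_traits(growth_form, n, seed, config)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    spectra = np.empty((n, table.wavelengths.size))
    for i in range(n):
        leaf = LeafParams.from_dict(truth.iloc[i].to_dict())
        spectra[i] = prospect_forward(leaf, table).reflectance
    if noise_sd > 0:
        spectra = spectra + rng.normal(0.0, noise_sd, size=spectra.shape)
    return table.wavelengths, np.clip(spectra, 0.0, 1.0), truth


def _site_draw(rng, spec, n):
    if isinstance(spec, tuple):
        return _truncnorm(rng, *spec, n)
    return np.full(n, float(spec))


def generate_canopy_spectra(
    n_per_class: int = 50,
    L_levels=(1.0, 0.0),
    seed: int = 0,
    noise_sd: float = 0.01,
    site: dict | None = None,
    traits: dict | None = None,
    table: CoefficientTable | None = None,
    wavelengths: np.ndarray | None = None,
):
    """Simulate ensembles of canopy spectra per infestation level.

    Each canopy draws its own leaf traits (growth-form distributions) and
    structure (site distributions); ``L_levels`` sets the infestation index
    per class (e.g. heavy > 0.5 vs light < 0.5).  Returns
    ``(wavelengths, spectra, truth)`` where truth records every generating
    parameter and the class label.
    """
    if table is None:
        table = default_table()
    if wavelengths is not None:
        table = table.subset(np.asarray(wavelengths, float))
    site = dict(DEFAULT_SITE, **(site or {}))
    traits = traits or DEFAULT_TRAITS
    rng = np.random.default_rng(seed)
    soil = SoilModel.default(table.wavelengths)

    rows = []
    spectra = []
    for L in L_levels:
        liana_tr = sample_traits("liana", n_per_class, int(rng.integers(2**31)), traits.get("liana"))
        tree_tr = sample_traits("tree", n_per_class, int(rng.integers(2**31)), traits.get("tree"))
        lai = _site_draw(rng, site["lai"], n_per_class)
        f2 = _site_draw(rng, site["f2"], n_per_class)
        sm = _site_draw(rng, site["soil_moisture"], n_per_class)
        geom = ViewGeometry(site["theta_s"], site["theta_o"], site["psi"])
        for i in range(n_per_class):
            liana = LeafParams.from_dict(liana_tr.iloc[i].to_dict())
            tree = LeafParams.from_dict(tree_tr.iloc[i].to_dict())
            cfg = CanopyConfig(
                lai=float(lai[i]), omega1=float(liana_tr["omega"][i]),
                omega2=float(tree_tr["omega"][i]), f2=float(f2[i]), L=float(L),
                hotspot=site["hotspot"], soil_moisture=float(sm[i]),
            )
            rho = couple_prosail2(liana, tree, cfg, geom, soil, table).rho
            spectra.append(rho)
            row = {"L": L, "class": "infested" if L > 0.5 else "light",
                   "lai": cfg.lai, "f2": cfg.f2, "omega1": cfg.omega1,
                   "omega2": cfg.omega2, "soil_moisture": cfg.soil_moisture}
            row.update({f"liana_{k}": v for k, v in liana.as_dict().items()})
            row.update({f"tree_{k}": v for k, v in tree.as_dict().items()})
            rows.append(row)
    spectra = np.array(spectra)
    if noise_sd > 0:
        spectra = spectra + rng.normal(0.0, noise_sd, size=spectra.shape)
    return table.wavelengths, np.clip(spectra, 0.0, 1.0), pd.DataFrame(rows)


def generate_trait_table(
    n_studies: int = 3,
    n_species: int = 40,
    contrast: float = -0.002,
    intercept: float = 0.01,
    sd_species: float = 0.002,
    sd_study: float = 0.003,
    sd_resid: float = 0.001,
    n_per_species: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a hierarchical trait table T = b0 + b_gf + b_species + b_study + e.

    ``n_species`` species per growth form are split evenly across studies
    (species nested in study); ``contrast`` is the liana-minus-tree
    growth-form difference.  Returns columns value, growth_form, species,
    study and the true effects for recovery tests.
    """
    if n_studies < 1:
        raise ValueError("need at least one study")
    rng = np.random.default_rng(seed)
    study_eff = rng.normal(0.0, sd_study, n_studies) if n_studies > 1 else np.zeros(1)
    rows = []
    for gf, gf_eff in (("liana", contrast / 2.0), ("tree", -contrast / 2.0)):
        for s in range(n_species):
            study = s % n_studies
            sp_eff = rng.normal(0.0, sd_species)
            name = f"{gf}_sp{s:03d}"
            for _ in range(n_per_species):
                val = (
                    intercept + gf_eff + sp_eff + study_eff[study]
                    + rng.normal(0.0, sd_resid)
                )
                rows.append(
                    {"value": val, "growth_form": gf, "species": name,
                     "study": f"study{study}"}
                )
    return pd.DataFrame(rows)


def default_endmembers(
    L: float = 1.0,
    sigma: float = 0.01,
    wavelengths: np.ndarray | None = None,
    site: dict | None = None,
    traits: dict | None = None,
):
    """Liana-infested and liana-free canopy endmember spectral distributions.

    Runs the coupled chain at the growth-form mean traits with infestation
    ``L`` (feature) and 0 (background); the spread is the constant residual
    reflectance error ``sigma``.  Returns ``(infested, background)``.
    """
    wl = default_grid(10) if wavelengths is None else np.asarray(wavelengths, float)
    table = default_table().subset(wl)
    site = dict(DEFAULT_SITE, **(site or {}))
    traits = traits or DEFAULT_TRAITS
    liana = LeafParams.from_dict(trait_means(traits["liana"]))
    tree = LeafParams.from_dict(trait_means(traits["tree"]))
    geom = ViewGeometry(site["theta_s"], site["theta_o"], site["psi"])
    soil = SoilModel.default(wl)

    def run(Lval):
        cfg = CanopyConfig(
            lai=site["lai"][0] if isinstance(site["lai"], tuple) else site["lai"],
            omega1=traits["liana"]["omega"][0], omega2=traits["tree"]["omega"][0],
            f2=site["f2"][0] if isinstance(site["f2"], tuple) else site["f2"],
            L=Lval, hotspot=site["hotspot"],
            soil_moisture=site["soil_moisture"][0]
            if isinstance(site["soil_moisture"], tuple) else site["soil_moisture"],
        )
        rho = couple_prosail2(liana, tree, cfg, geom, soil, table).rho
        return SpectralDistribution(wavelengths=wl, mean=rho, sd=np.full_like(rho, sigma))

    return run(L), run(0.0)
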