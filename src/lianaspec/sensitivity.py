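"""Trait-swap sensitivity: which parameters create the liana spectral signal.

Starting from a canopy whose top layer carries tree traits, parameters are
replaced one at a time (or in pairs) by their liana values, and the KL
divergence to the fully liana-parameterised reference distribution is
recomputed.  A positive impact (reduction of divergence relative to the
all-tree baseline) means the swap moves the spectrum toward the liana
signal.  Each configuration defines a spectral distribution with the
predicted reflectance as its mean and the inversion residual error sigma as
a constant spread.

Swappable parameters: the seven leaf traits of the top layer plus the top
layer's mean leaf inclination ``omega``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._grid import REGIONS, default_grid
from .canopy import CanopyConfig, SoilModel, ViewGeometry, couple_prosail2
from .coefficients import CoefficientTable, default_table
from .divergence import SpectralDistribution, gaussian_kld, gaussian_kld_scalar
from .leaf import LEAF_BOUNDS, LeafParams

__all__ = [
    "trait_swap_experiment",
    "interaction_effect",
    "summarize_trait_contrast",
    "SWAPPABLE",
]

SWAPPABLE = tuple(LEAF_BOUNDS) + ("omega",)


def _top_layer_distribution(
    top_traits: dict,
    tree_traits: dict,
    canopy: CanopyConfig,
    geom: ViewGeometry,
    soil: SoilModel,
    table: CoefficientTable,
    sigma: float,
) -> SpectralDistribution:
    """Spectral distribution of a canopy whose top layer carries ``top_traits``."""
    top_leaf = LeafParams.from_dict(top_traits)
    tree_leaf = LeafParams.from_dict(tree_traits)
    cfg = canopy.replace(omega1=float(top_traits["omega"]))
    rho = couple_prosail2(top_leaf, tree_leaf, cfg, geom, soil, table).rho
    return SpectralDistribution(
        wavelengths=table.wavelengths, mean=rho, sd=np.full_like(rho, sigma)
    )


def trait_swap_experiment(
    tree_traits: dict,
    liana_traits: dict,
    sigma: float,
    swap_sets,
    canopy: CanopyConfig | None = None,
    geom: ViewGeometry | None = None,
    soil: SoilModel | None = None,
    table: CoefficientTable | None = None,
    wavelengths: np.ndarray | None = None,
) -> pd.DataFrame:
    """Compute the KLD impact of replacing top-layer tree traits by liana values.

    ``tree_traits`` / ``liana_traits`` map the swappable parameter names
    (leaf traits + "omega") to values; ``swap_sets`` is an iterable of
    parameter subsets (each a tuple/list of names; the empty set gives the
    baseline check).  Bottom-layer (host) traits stay tree throughout.

    Returns a tidy table with one row per swap set: the total impact
    (baseline KLD minus post-swap KLD, positive = toward the liana signal),
    per-region impacts (VIS/NIR/SWIR, trapezoid-integrated), and the raw
    post-swap divergence.  The per-wavelength impact curves are attached as
    ``DataFrame.attrs["per_wavelength"]``.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    for name in SWAPPABLE:
        if name not in tree_traits or name not in liana_traits:
            raise KeyError(f"parameter {name!r} missing from a trait config")
    if table is None:
        wl = default_grid(10) if wavelengths is None else np.asarray(wavelengths, float)
        table = default_table().subset(wl)
    canopy = canopy or CanopyConfig()
    geom = geom or ViewGeometry()
    soil = soil or SoilModel.default(table.wavelengths)

    reference = _top_layer_distribution(
        dict(liana_traits), tree_traits, canopy, geom, soil, table, sigma
    )

    def kld_curves(top):
        dist = _top_layer_distribution(top, tree_traits, canopy, geom, soil, table, sigma)
        curve = gaussian_kld_scalar(dist.mean, dist.sd, reference.mean, reference.sd)
        return gaussian_kld(dist, reference), curve

    d_base, base_curve = kld_curves(dict(tree_traits))

    wlg = table.wavelengths
    rows = []
    curves = {}
    for s in swap_sets:
        s = tuple(s)
        unknown = [p for p in s if p not in SWAPPABLE]
        if unknown:
            raise KeyError(f"unknown swap parameter(s): {unknown}")
        top = dict(tree_traits)
        for p in s:
            top[p] = liana_traits[p]
        d_swap, curve = kld_curves(top)
        impact_curve = base_curve - curve
        label = "+".join(s) if s else "(none)"
        row = {
            "swap": label,
            "n_params": len(s),
            "impact": d_base - d_swap,
            "kld_after_swap": d_swap,
            "kld_baseline": d_base,
        }
        for region, (lo, hi) in REGIONS.items():
            sel = (wlg >= lo) & (wlg <= hi)
            row[f"impact_{region}"] = float(np.trapezoid(impact_curve[sel], wlg[sel]))
        rows.append(row)
        curves[label] = impact_curve
    out = pd.DataFrame(rows)
    out.attrs["per_wavelength"] = {"wavelengths": wlg, "impact": curves,
                                   "baseline_kld": base_curve}
    return out


def interaction_effect(pair_impact: float, single_impacts) -> float:
    """Interactive component of a two-parameter swap.

    interactive(s1, s2) = impact({s1, s2}) - impact({s1}) - impact({s2});
    all impacts must share the same baseline.
    """
    single_impacts = list(single_impacts)
    if len(single_impacts) != 2:
        raise ValueError("exactly two single-swap impacts are required")
    return float(pair_impact - single_impacts[0] - single_impacts[1])


def pairwise_interactions(impacts: pd.DataFrame) -> pd.DataFrame:
    """Decompose all two-parameter rows of a swap table into additive and
    interactive components (both the raw pair impact and the interaction
    after subtracting single effects are reported)."""
    singles = {
        r["swap"]: r["impact"] for _, r in impacts.iterrows() if r["n_params"] == 1
    }
    rows = []
    for _, r in impacts.iterrows():
        if r["n_params"] != 2:
            continue
        p1, p2 = r["swap"].split("+")
        if p1 not in singles or p2 not in singles:
            raise ValueError(f"missing single-swap rows for pair {r['swap']}")
        inter = interaction_effect(r["impact"], (singles[p1], singles[p2]))
        rows.append(
            {"pair": r["swap"], "pair_impact": r["impact"],
             "additive": singles[p1] + singles[p2], "interactive": inter,
             "sign": int(np.sign(inter))}
        )
    return pd.DataFrame(rows)


def summarize_trait_contrast(liana_value: float, tree_value: float) -> float:
    """Signed percent difference (liana - tree) / tree * 100."""
    if tree_value == 0:
        raise ZeroDivisionError("tree value must be non-zero")
    return (liana_value - tree_value) / tree_value * 100.0
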