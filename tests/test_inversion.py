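"""Spectral inversion: posterior density, leaf MAP recovery, prior derivation."""

import numpy as np
import pytest
from scipy import stats

from lianaspec._grid import default_grid
from lianaspec.inversion import (
    CanopyInversion,
    LeafInversion,
    default_canopy_priors,
    derive_priors,
    invert_leaf,
    log_posterior,
)
from lianaspec.leaf import LeafParams
from lianaspec.priors import Fixed, Normal, PriorSet, Uniform
from lianaspec.synthetic import generate_leaf_spectra


class TestLogPosterior:
    def _toy(self):
        wl = np.array([500.0, 600.0, 700.0, 800.0, 900.0])
        priors = PriorSet({"a": Uniform(0.0, 1.0), "sigma": Uniform(1e-4, 0.5)})

        def forward(params):
            return np.full(5, params["a"])

        return wl, priors, forward

    def test_outside_uniform_support_is_minus_inf(self):
        wl, priors, forward = self._toy()
        obs = np.full(5, 0.4)
        assert log_posterior(np.array([1.5, 0.1]), obs, priors, forward,
                             wavelengths=wl) == -np.inf

    def test_perfect_fit_maximised_at_true_sigma_scale(self):
        wl, priors, forward = self._toy()
        rng = np.random.default_rng(0)
        true_sigma = 0.05
        obs = 0.4 + rng.normal(0, true_sigma, 500)
        priors2 = PriorSet({"a": Uniform(0.0, 1.0), "sigma": Uniform(1e-4, 0.5)})

        def fwd(params):
            return np.full(500, params["a"])

        grid = np.linspace(0.01, 0.3, 60)
        vals = [log_posterior(np.array([0.4, s]), obs, priors2, fwd,
                              wavelengths=np.linspace(400, 2500, 500)) for s in grid]
        best = grid[int(np.argmax(vals))]
        assert best == pytest.approx(true_sigma, rel=0.2)

    def test_matches_hand_computed_sum(self):
        wl, priors, forward = self._toy()
        obs = np.array([0.35, 0.42, 0.38, 0.40, 0.44])
        theta = np.array([0.4, 0.05])
        got = log_posterior(theta, obs, priors, forward, wavelengths=wl)
        expected = (
            np.log(1.0)  # uniform(0,1) density
            + np.log(1.0 / (0.5 - 1e-4))
            + np.sum(stats.norm(0.4, 0.05).logpdf(obs))
        )
        assert got == pytest.approx(expected, abs=1e-10)

    def test_nan_in_data_rejected(self):
        wl, priors, forward = self._toy()
        obs = np.array([0.3, np.nan, 0.3, 0.3, 0.3])
        with pytest.raises(ValueError, match="NaN"):
            log_posterior(np.array([0.4, 0.05]), obs, priors, forward, wavelengths=wl)


class TestLeafInversion:
    def test_noiseless_spectrum_recovered_within_one_percent(self, table):
        wl, spectra, truth = generate_leaf_spectra(
            1, "tree", noise_sd=0.0, seed=5, wavelengths=default_grid(10)
        )
        res = invert_leaf(wl, spectra[0], seed=0)
        assert res.converged
        for k in ("n_layers", "c_ab", "c_w", "c_m"):
            assert res.estimates[k] == pytest.approx(truth.iloc[0][k], rel=0.01)

    def test_noisy_spectrum_recovers_major_traits(self):
        wl, spectra, truth = generate_leaf_spectra(
            1, "liana", noise_sd=0.005, seed=9, wavelengths=default_grid(10)
        )
        res = invert_leaf(wl, spectra[0], seed=1)
        # N, water and dry matter remain well constrained under noise; the
        # two pigments are partially confounded and get looser tolerance
        for k, tol in (("n_layers", 0.10), ("c_w", 0.10), ("c_m", 0.25)):
            assert res.estimates[k] == pytest.approx(truth.iloc[0][k], rel=tol)
        assert res.estimates["c_ab"] == pytest.approx(truth.iloc[0]["c_ab"], rel=0.4)

    def test_all_zero_spectrum_flagged_not_raised(self):
        wl = default_grid(10)
        res = LeafInversion(wl, np.zeros(wl.size)).fit(method="map", seed=0,
                                                       n_starts=2)
        assert "non_physical_spectrum" in res.flags
        assert not res.converged

    def test_sparse_multispectral_sensor_refused(self):
        from lianaspec.sensors import load_srf

        wl = default_grid(10)
        sensor = load_srf("landsat5_tm")
        with pytest.raises(ValueError, match="bands"):
            LeafInversion(wl, np.zeros(sensor.n_bands), sensor=sensor)
        # explicit override allowed
        LeafInversion(wl, np.full(sensor.n_bands, 0.2), sensor=sensor,
                      allow_multispectral=True)


class TestDerivePriors:
    def test_leaf_summaries_pass_through_as_normal_priors(self):
        stats_in = {
            "liana": {f: (1.0, 0.1) for f in ("n_layers",)} | {
                "c_ab": (35.0, 8.0), "c_ar": (8.0, 2.0), "c_an": (1.0, 0.5),
                "c_br": (0.15, 0.1), "c_w": (0.009, 0.002), "c_m": (0.0075, 0.002)},
            "tree": {
                "n_layers": (1.8, 0.2), "c_ab": (40.0, 8.0), "c_ar": (10.0, 2.0),
                "c_an": (1.0, 0.5), "c_br": (0.15, 0.1), "c_w": (0.012, 0.002),
                "c_m": (0.010, 0.002)},
        }
        priors = derive_priors(stats_in)
        p = priors["tree_c_ab"]
        assert isinstance(p, Normal)
        assert p.mean == 40.0 and p.sd == 8.0

    def test_default_growth_form_priors_overlap_within_one_sd(self):
        from lianaspec.synthetic import DEFAULT_TRAITS

        stats_in = {
            gf: {k: (v[0], v[1]) for k, v in DEFAULT_TRAITS[gf].items() if k != "omega"}
            for gf in ("liana", "tree")
        }
        priors = derive_priors(stats_in)
        for f in ("n_layers", "c_ab", "c_ar", "c_w", "c_m"):
            a = priors[f"liana_{f}"]
            b = priors[f"tree_{f}"]
            assert abs(a.mean - b.mean) <= max(a.sd, b.sd) + 1e-12

    def test_fixed_parameter_excluded_from_sampled_dimensions(self):
        priors = default_canopy_priors(fixed={"L": 1.0})
        assert "L" not in priors.free_names
        assert priors.fixed["L"] == 1.0

    def test_missing_trait_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="default"):
            priors = derive_priors({"liana": {}, "tree": {}})
        assert isinstance(priors["liana_c_ab"], Fixed)


class TestLikelihoodConsistency:
    def test_more_wavelengths_shrink_posterior_sd(self, geom, soil10):
        """Doubling the informative wavelengths tightens identifiable
        parameters (LAI here) in the canopy posterior."""
        from lianaspec.canopy import CanopyConfig, SoilModel, couple_prosail2
        from lianaspec.coefficients import default_table
        from lianaspec.synthetic import DEFAULT_TRAITS, trait_means

        results = {}
        rng = np.random.default_rng(5)
        noise_full = rng.normal(0, 0.01, default_grid(10).size)
        for step in (20, 10):
            wl = default_grid(step)
            table = default_table().subset(wl)
            soil = SoilModel.default(wl)
            liana = LeafParams.from_dict(trait_means(DEFAULT_TRAITS["liana"]))
            tree = LeafParams.from_dict(trait_means(DEFAULT_TRAITS["tree"]))
            cfg = CanopyConfig(lai=4.0, omega1=28.0, omega2=42.0, f2=0.65,
                               hotspot=0.05, soil_moisture=0.5)
            spec = couple_prosail2(liana, tree, cfg, geom, soil, table).rho
            # same noise realisation at shared wavelengths: the coarse grid is
            # every other sample of the fine one
            noise = noise_full[:: step // 10]
            priors = default_canopy_priors(free=("lai", "omega1", "omega2", "f2"),
                                           fixed={"sigma": 0.01})
            model = CanopyInversion(wl, np.clip(spec + noise, 0, 1), priors=priors,
                                    geometry=geom, soil=soil, table=table)
            res = model.fit(method="demc", seed=3, n_iter=4000)
            results[step] = res.sd["lai"]
        assert results[10] < results[20]
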