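"""Two-layer canopy model: limits, symmetries, oracles and the coupled chain."""

import numpy as np
import pytest

from lianaspec.canopy import (
    CanopyConfig,
    SoilModel,
    ViewGeometry,
    _campbell_lidf_exact,
    _mixed_layers,
    campbell_lidf,
    combine_reflectance,
    couple_prosail2,
    foursail2_forward,
    liana_lai_fraction,
)
from lianaspec.leaf import prospect_forward
from lianaspec.sky import diffuse_fraction

from _oracles import slab_four_stream


@pytest.fixture(scope="module")
def optics(table10, liana_leaf, tree_leaf):
    return (
        prospect_forward(liana_leaf, table10),
        prospect_forward(tree_leaf, table10),
    )


class TestLimits:
    def test_bare_soil_limit(self, optics, geom, soil10):
        cfg = CanopyConfig(lai=0.0)
        r = foursail2_forward(*optics, cfg, geom, soil10)
        rs = soil10.reflectance(cfg.soil_moisture)
        np.testing.assert_array_equal(r.rho_s, rs)
        np.testing.assert_array_equal(r.rho_d, rs)

    def test_zero_infestation_is_independent_of_liana_optics(
        self, optics, geom, soil10, table10, rng
    ):
        from conftest import random_leaf_params

        cfg = CanopyConfig(L=0.0)
        ref = foursail2_forward(*optics, cfg, geom, soil10)
        for p in random_leaf_params(rng, 10):
            other = prospect_forward(p, table10)
            alt = foursail2_forward(other, optics[1], cfg, geom, soil10)
            np.testing.assert_array_equal(alt.rho_s, ref.rho_s)
            np.testing.assert_array_equal(alt.rho_d, ref.rho_d)

    def test_indistinguishable_particles_merge_to_single_layer(
        self, optics, geom, soil10
    ):
        """Same leaf type and angle in both layers == one layer of the full LAI
        (hotspot off: the gap-correlation kernel is not additive across layers)."""
        _, tree = optics
        cfg = CanopyConfig(lai=4.0, omega1=40.0, omega2=40.0, f2=0.5, L=1.0,
                           hotspot=0.0)
        two = foursail2_forward(tree, tree, cfg, geom, soil10)
        single = foursail2_forward(
            tree, tree, cfg.replace(L=0.0), geom, soil10
        )
        np.testing.assert_allclose(two.rho_s, single.rho_s, atol=1e-12)
        np.testing.assert_allclose(two.rho_d, single.rho_d, atol=1e-12)

    def test_reflectance_in_unit_interval_random_configs(
        self, optics, geom, soil10, rng
    ):
        for _ in range(200):
            cfg = CanopyConfig(
                lai=rng.uniform(0.0, 15.0),
                omega1=rng.uniform(5.0, 85.0),
                omega2=rng.uniform(5.0, 85.0),
                f2=rng.uniform(0.0, 1.0),
                L=rng.uniform(0.0, 1.0),
                D=rng.uniform(0.0, 1.0),
                hotspot=rng.uniform(0.0, 0.5),
                soil_moisture=rng.uniform(0.0, 1.0),
            )
            g = ViewGeometry(rng.uniform(0, 60), rng.uniform(0, 60), rng.uniform(0, 360))
            r = foursail2_forward(*optics, cfg, g, soil10)
            assert np.all((r.rho_s >= 0) & (r.rho_s <= 1))
            assert np.all((r.rho_d >= 0) & (r.rho_d <= 1))


class TestSymmetries:
    def test_bidirectional_reciprocity(self, optics, soil10):
        cfg = CanopyConfig()
        a = foursail2_forward(*optics, cfg, ViewGeometry(35, 12, 64), soil10)
        b = foursail2_forward(*optics, cfg, ViewGeometry(12, 35, 64), soil10)
        np.testing.assert_allclose(a.rho_s, b.rho_s, atol=1e-8)

    def test_hotspot_brightens_backscatter(self, optics, soil10):
        cfg = CanopyConfig(hotspot=0.1)
        hot = foursail2_forward(*optics, cfg, ViewGeometry(30, 30, 0), soil10)
        fwd = foursail2_forward(*optics, cfg, ViewGeometry(30, 30, 180), soil10)
        assert np.all(hot.rho_s >= fwd.rho_s)

    def test_dense_canopy_reflectance_saturates(self, optics, geom, soil10, wl10):
        """Radiative saturation with a black soil.  Hotspot off: the sun-view
        gap-correlation term approaches its own asymptote only slowly in LAI
        (its effective extinction reduction saturates as 1/LAI), which is a
        geometric, not radiative, effect."""
        black = SoilModel(wavelengths=wl10, dry=np.zeros_like(wl10), wet=np.zeros_like(wl10))
        r15 = foursail2_forward(*optics, CanopyConfig(lai=15, hotspot=0.0), geom, black)
        r20 = foursail2_forward(*optics, CanopyConfig(lai=20, hotspot=0.0), geom, black)
        for a, b in ((r15.rho_s, r20.rho_s), (r15.rho_d, r20.rho_d)):
            rel = np.abs(b - a) / np.maximum(a, 1e-9)
            assert np.max(rel) < 0.005

    def test_flatter_top_layer_brightens_nir(self, optics, geom, soil10, wl10):
        flat = foursail2_forward(*optics, CanopyConfig(omega1=20.0), geom, soil10)
        steep = foursail2_forward(*optics, CanopyConfig(omega1=60.0), geom, soil10)
        nir = (wl10 >= 800) & (wl10 <= 1200)
        assert np.all(flat.rho_s[nir] > steep.rho_s[nir])


class TestSlabOracle:
    def test_two_layer_solution_matches_slab_discretisation(
        self, optics, soil10, wl10, table10
    ):
        """Analytic four-stream vs 200-sublayer matrix-exponential slabs,
        black soil, dense canopy, hotspot off."""
        geom = ViewGeometry(30, 10, 47)
        cfg = CanopyConfig(lai=10.0, hotspot=0.0)
        black = SoilModel(wavelengths=wl10, dry=np.zeros_like(wl10), wet=np.zeros_like(wl10))
        res = foursail2_forward(*optics, cfg, geom, black)
        (l1, r1, t1, a1), (l2, r2, t2, a2) = _mixed_layers(*optics, cfg)
        lidf1, lidf2 = campbell_lidf(a1), campbell_lidf(a2)
        for iw in [15, 45, 80, 120, 170]:
            rso, rdo, rsd, rdd = slab_four_stream(
                [(r1[iw], t1[iw], lidf1, l1), (r2[iw], t2[iw], lidf2, l2)],
                0.0,
                geom,
                n_slab=200,
            )
            assert abs(res.rho_s[iw] - rso) / max(rso, 1e-9) < 0.01
            assert abs(res.rho_d[iw] - rdo) / max(rdo, 1e-9) < 0.01

    def test_single_layer_with_bright_soil_matches_slab(self, optics, soil10, wl10):
        geom = ViewGeometry(25, 0, 0)
        cfg = CanopyConfig(lai=3.0, L=0.0, hotspot=0.0, soil_moisture=0.3)
        res = foursail2_forward(*optics, cfg, geom, soil10)
        (l1, r1, t1, a1), (l2, r2, t2, a2) = _mixed_layers(*optics, cfg)
        rs = soil10.reflectance(0.3)
        for iw in [30, 100, 150]:
            rso, rdo, _, _ = slab_four_stream(
                [(r2[iw], t2[iw], campbell_lidf(a2), l2)], rs[iw], geom, n_slab=200
            )
            assert abs(res.rho_s[iw] - rso) / max(rso, 1e-9) < 0.01
            assert abs(res.rho_d[iw] - rdo) / max(rdo, 1e-9) < 0.01


class TestCoupling:
    def test_forcing_diffuse_fraction_selects_terms(self, optics, geom, soil10):
        r = foursail2_forward(*optics, CanopyConfig(), geom, soil10)
        only_s = combine_reflectance(r, geom, diffuse=0.0)
        only_d = combine_reflectance(r, geom, diffuse=1.0)
        np.testing.assert_array_equal(only_s.rho, r.rho_s)
        np.testing.assert_array_equal(only_d.rho, r.rho_d)

    def test_coupled_chain_equals_manual_composition(
        self, liana_leaf, tree_leaf, geom, soil10, table10
    ):
        cfg = CanopyConfig(lai=5.5, f2=0.7)
        full = couple_prosail2(liana_leaf, tree_leaf, cfg, geom, soil10, table10)
        lo = prospect_forward(liana_leaf, table10)
        to = prospect_forward(tree_leaf, table10)
        manual = foursail2_forward(lo, to, cfg, geom, soil10)
        S = diffuse_fraction(table10.wavelengths, geom.theta_s)
        np.testing.assert_allclose(full.rho, S * manual.rho_d + (1 - S) * manual.rho_s,
                                   atol=1e-12)

    def test_identical_leaves_and_angles_match_single_layer_chain(
        self, tree_leaf, geom, soil10, table10
    ):
        cfg = CanopyConfig(lai=4.0, omega1=40.0, omega2=40.0, f2=0.5, L=1.0,
                           hotspot=0.0)
        two = couple_prosail2(tree_leaf, tree_leaf, cfg, geom, soil10, table10)
        one = couple_prosail2(tree_leaf, tree_leaf, cfg.replace(L=0.0), geom,
                              soil10, table10)
        np.testing.assert_allclose(two.rho, one.rho, atol=1e-12)


class TestLianaLaiFraction:
    def test_printed_tree_share_gives_347_percent(self):
        assert liana_lai_fraction(1.0, 0.653) == pytest.approx(0.347, abs=1e-12)

    def test_model_average_gives_34_percent(self):
        assert liana_lai_fraction(1.0, 0.66) == pytest.approx(0.34, abs=1e-12)

    def test_zero_infestation(self):
        assert liana_lai_fraction(0.0, 0.2) == 0.0

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            liana_lai_fraction(1.2, 0.5)


class TestDiffuseFraction:
    def test_blue_sky_exceeds_nir(self, wl10):
        s = diffuse_fraction(wl10, 30.0)
        s450 = s[np.searchsorted(wl10, 450)]
        s850 = s[np.searchsorted(wl10, 850)]
        assert s450 > s850

    def test_monotone_nonincreasing_in_wavelength(self, wl10):
        s = diffuse_fraction(wl10, 45.0)
        sub = s[(wl10 >= 400) & (wl10 <= 1000)]
        assert np.all(np.diff(sub) <= 1e-12)

    def test_bounds(self, wl10):
        for theta in (0.0, 33.3, 75.0):
            s = diffuse_fraction(wl10, theta)
            assert np.all((s >= 0) & (s <= 1))


def test_lidf_lookup_matches_exact_integration():
    for ang in (7.3, 27.9, 37.1, 57.0, 84.2):
        np.testing.assert_allclose(
            campbell_lidf(ang), _campbell_lidf_exact(ang), atol=5e-5
        )
        assert campbell_lidf(ang).sum() == pytest.approx(1.0, abs=1e-12)


def test_lidf_mean_angle_tracks_parameter():
    centers = np.array([5, 15, 25, 35, 45, 55, 65, 75, 81, 83, 85, 87, 89], float)
    for ang in (20.0, 40.0, 60.0):
        mean = float(campbell_lidf(ang) @ centers)
        assert abs(mean - ang) < 6.0
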