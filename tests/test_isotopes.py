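"""Calibration, Monte-Carlo assignment and isoscape reclassification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from warblerstop.isotopes import (
    FeatherSample,
    classify_destination,
    feather_to_precip,
    hdr_thresholds,
    origin_density,
    precip_to_feather,
    reclassify_isoscape,
    region_probability,
    region_probability_analytic,
    IsoscapeGrid,
)


class TestCalibration:
    @pytest.mark.parametrize(
        "feather,precip",
        [(-65.07, -50.0), (-17.57, 0.0), (-112.57, -100.0)],
    )
    def test_printed_equation(self, feather, precip):
        assert feather_to_precip(feather) == pytest.approx(precip, abs=1e-9)
        assert precip_to_feather(precip) == pytest.approx(feather, abs=1e-9)

    @pytest.mark.parametrize("x", [-150.0, -60.0, 0.0])
    def test_round_trip(self, x):
        assert precip_to_feather(feather_to_precip(x)) == pytest.approx(x, abs=1e-9)

    @given(st.floats(-300, 100))
    @settings(deadline=None, max_examples=50)
    def test_round_trip_property(self, x):
        assert feather_to_precip(precip_to_feather(x)) == pytest.approx(x, abs=1e-9)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            feather_to_precip(float("nan"))

    def test_plausibility_warning(self):
        with pytest.warns(UserWarning):
            FeatherSample("b1", -300.0)


class TestRegionProbability:
    def test_monte_carlo_matches_analytic(self, regions, rng):
        for f in (-112.57, -84.07, -60.0, -40.0):
            mc = region_probability(f, regions, 5.5, n_draws=1000, rng=rng)
            an = region_probability_analytic(f, regions, 5.5)
            for label in regions:
                q = an[label]
                # 3-SE binomial band, with a small additive floor so the
                # check stays valid in the Poisson regime (q near 0 or 1)
                tol = 3 * np.sqrt(max(q * (1 - q), 1e-9) / 1000) + 3 / 1000
                assert abs(mc[label] - q) <= tol

    def test_boundary_gives_half(self, regions, rng):
        # feather-scale upper boreal boundary: 0.95*(-70) - 17.57
        probs = region_probability(-84.07, regions, 5.5, n_draws=4000, rng=rng)
        assert probs["boreal"] == pytest.approx(0.5, abs=0.03)

    def test_window_centre_certain(self, regions, rng):
        probs = region_probability(-112.57, regions, 5.5, n_draws=1000, rng=rng)
        assert probs["boreal"] == pytest.approx(1.0, abs=1e-6)

    def test_tiny_error_degenerate(self, regions, rng):
        # feather value inside the southeast feather window
        probs = region_probability(-46.07, regions, 1e-9, n_draws=100, rng=rng)
        assert probs["southeast"] == 1.0

    def test_invalid_inputs(self, regions):
        with pytest.raises(ValueError):
            region_probability(-80.0, regions, error_sd=0.0)
        with pytest.raises(ValueError):
            region_probability(-80.0, {"a": (-60, -10), "b": (-30, 0)})


class TestClassify:
    @pytest.mark.parametrize(
        "equiv,label",
        [(-100.0, "boreal"), (-60.0, "unassigned"), (-30.0, "southeast")],
    )
    def test_window_rule(self, regions, equiv, label):
        assert classify_destination(equiv, regions) == label

    def test_max_prob_rule(self, regions):
        probs = {"southeast": 0.7, "boreal": 0.1}
        assert (
            classify_destination(-30.0, regions, rule="max_prob", region_probs=probs)
            == "southeast"
        )
        weak = {"southeast": 0.4, "boreal": 0.3}
        assert (
            classify_destination(-30.0, regions, rule="max_prob", region_probs=weak)
            == "unassigned"
        )

    def test_recovery_inside_window(self, config, regions):
        """Classification recovery for birds drawn >=1 SD inside their window.

        Cross-window misassignment is essentially impossible (the 20 permil
        gap is ~3.5 SD wide), so <1% of such birds carry the *wrong*
        destination label; the exact-label recovery rate matches the
        closed-form expectation 1 - 2c/w (c = integral of Phi(-x) from 1 to
        inf = phi(1) - Phi(-1), w = interior window width in SD units),
        birds near a boundary occasionally falling into the unassigned gap.
        """
        from scipy.stats import norm
        from warblerstop.synth import gen_isotope_samples

        config.n_birds_per_group = 0
        samples = gen_isotope_samples(config, 4000)
        sd_p = 5.5 / 0.95
        c = norm.pdf(1.0) - norm.cdf(-1.0)
        correct = wrong = total = 0
        expected_correct = {}
        for label, (lo, hi) in regions.items():
            w_int = (hi - lo) / sd_p - 2.0
            expected_correct[label] = 1.0 - 2.0 * c / w_int
        expect_n = expect_sum = 0.0
        for row in samples.itertuples(index=False):
            lo, hi = regions[row.true_destination]
            if not (lo + sd_p <= row.true_d2h_p <= hi - sd_p):
                continue
            total += 1
            expect_sum += expected_correct[row.true_destination]
            label = classify_destination(feather_to_precip(row.d2h_feather), regions)
            correct += label == row.true_destination
            wrong += label not in (row.true_destination, "unassigned")
        assert total > 1000
        assert wrong / total < 0.01
        expected_rate = expect_sum / total
        se = np.sqrt(expected_rate * (1 - expected_rate) / total)
        assert abs(correct / total - expected_rate) <= 4 * se + 0.005


class TestReclassify:
    def _grid(self):
        lons = np.arange(-100, -59.5, 1.0)
        lats = np.arange(30, 60.5, 1.0)
        # smooth north-south depletion gradient spanning both windows
        values = np.tile((-10.0 - 4.5 * (lats - 30))[:, None], (1, lons.size))
        return IsoscapeGrid(lons=lons, lats=lats, values=values)

    def test_nested_categories(self):
        grid = self._grid()
        cats = reclassify_isoscape(grid, {"boreal": [-112.57]}, 5.5)
        cat = cats["boreal"]
        assert set(np.unique(cat)) <= {0, 50, 75, 90}
        # nesting: 50% cells subset of <=75% cells subset of <=90% cells
        n50 = (cat == 50).sum()
        n75 = ((cat == 50) | (cat == 75)).sum()
        n90 = (cat > 0).sum()
        assert 0 < n50 <= n75 <= n90 < cat.size

    def test_modal_grid_all_in_50(self):
        lons = lats = np.arange(3)
        mode = feather_to_precip(-112.57)
        grid = IsoscapeGrid(lons, lats, np.full((3, 3), mode))
        cats = reclassify_isoscape(grid, {"boreal": [-112.57]}, 5.5)
        assert np.all(cats["boreal"] == 50)

    def test_enclosed_mass_matches_level(self):
        """Quadrature oracle: HDR at level 0.9 encloses ~0.9 of the mass."""
        dens = origin_density([-112.57, -100.0, -120.0], 5.5)
        thr = hdr_thresholds(dens, (0.5, 0.75, 0.9))
        grid = np.linspace(-200, -50, 20001)
        f = dens(grid)
        dx = grid[1] - grid[0]
        for level, c in thr.items():
            mass = f[f >= c].sum() * dx
            assert mass == pytest.approx(level, abs=0.01)

    def test_empty_samples_error(self):
        grid = self._grid()
        with pytest.raises(ValueError):
            reclassify_isoscape(grid, {"boreal": []}, 5.5)

    def test_all_nodata_error(self):
        grid = IsoscapeGrid(np.arange(2), np.arange(2), np.full((2, 2), np.nan))
        with pytest.raises(ValueError):
            reclassify_isoscape(grid, {"boreal": [-110.0]}, 5.5)
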