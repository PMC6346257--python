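"""AROC, projection, target resolution and attainment probabilities."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cgfmap import targets as tg
from cgfmap.geostat import PosteriorCube
from cgfmap.util import expit, logit

YEARS16 = np.arange(2000, 2016)


class TestAroc:
    def test_constant_series_zero(self):
        p = np.full(16, 0.3)
        np.testing.assert_array_equal(tg.annual_logit_aroc(p), np.zeros(15))

    def test_single_step_closed_form(self):
        p = np.concatenate([[0.5, 0.45], np.full(14, 0.45)])
        aroc = tg.annual_logit_aroc(p)
        assert aroc[0] == pytest.approx(np.log(0.45 / 0.55), abs=1e-12)
        assert aroc[0] == pytest.approx(-0.2007, abs=5e-5)

    def test_length_contract(self):
        with pytest.raises(ValueError, match="length 16"):
            tg.annual_logit_aroc(np.full(10, 0.3))
        tg.annual_logit_aroc(np.full(10, 0.3), expected_length=None)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            tg.annual_logit_aroc(np.full(16, 1.5))


class TestWeights:
    def test_linear_weights_2015(self):
        w = tg.ProjectionConfig(gamma=1.0).weights(np.arange(2001, 2016))
        assert w[-1] == pytest.approx(15 / 120)
        assert w[-1] == pytest.approx(0.125)
        np.testing.assert_allclose(w, (np.arange(1, 16)) / 120)

    def test_gamma_zero_uniform(self):
        w = tg.ProjectionConfig(gamma=0.0).weights(np.arange(2001, 2016))
        np.testing.assert_allclose(w, 1 / 15)

    @given(st.floats(0.0, 4.0))
    @settings(max_examples=30, deadline=None)
    def test_weights_sum_to_one(self, gamma):
        w = tg.ProjectionConfig(gamma=gamma).weights(np.arange(2001, 2016))
        assert w.sum() == pytest.approx(1.0)
        assert (w >= 0).all()

    def test_constant_aroc_invariant_to_gamma(self):
        aroc = np.full(15, -0.05)
        for gamma in (0.0, 1.0, 2.5):
            got = tg.weighted_aroc(aroc, np.arange(2001, 2016),
                                   tg.ProjectionConfig(gamma=gamma))
            assert got == pytest.approx(-0.05)


class TestProjection:
    def test_zero_aroc_identity(self):
        assert tg.project_prevalence(0.31, 0.0) == pytest.approx(0.31)

    def test_closed_form_value(self):
        got = tg.project_prevalence(expit(-1.0), -0.05, horizon=10)
        assert got == pytest.approx(expit(-1.5), abs=1e-12)
        assert got == pytest.approx(0.1824, abs=5e-5)

    def test_constant_decline_equivalence(self):
        """Constant logit decline d: logit(p2025) = logit(p2015) + 10 d."""
        d = -0.04
        p = expit(-0.6 + d * np.arange(16))
        aroc = tg.annual_logit_aroc(p)
        mean_aroc = tg.weighted_aroc(aroc, YEARS16[1:])
        p2025 = tg.project_prevalence(p[-1], mean_aroc)
        assert logit(p2025) == pytest.approx(logit(p[-1]) + 10 * d, abs=1e-12)

    def test_result_in_unit_interval(self):
        p = tg.project_prevalence(np.array([0.01, 0.5, 0.99]),
                                  np.array([-2.0, 0.0, 2.0]))
        assert np.all((p > 0) & (p < 1))


class TestResolveTargets:
    def test_relative_arithmetic(self):
        series = pd.DataFrame({"country_id": [0], "year": [2010],
                               "prevalence": [0.50]})
        spec = tg.TargetSpec("stunting", "relative", reduction_fraction=0.40)
        out = tg.resolve_targets(spec, series)
        assert out.resolved_target == pytest.approx(0.30)

    def test_fixed_wasting_five_percent(self):
        out = tg.resolve_targets(tg.DEFAULT_TARGETS["wasting"])
        assert out.resolved_target == 0.05

    def test_population_weighting(self):
        series = pd.DataFrame({"country_id": [0, 1], "year": [2010, 2010],
                               "prevalence": [0.2, 0.6]})
        spec = tg.TargetSpec("stunting", "relative", reduction_fraction=0.40)
        out = tg.resolve_targets(spec, series, populations={0: 300, 1: 100})
        assert out.resolved_target == pytest.approx(0.6 * 0.3)

    def test_missing_reference_year_errors(self):
        series = pd.DataFrame({"country_id": [0], "year": [2000],
                               "prevalence": [0.5]})
        with pytest.raises(ValueError, match="2010"):
            tg.resolve_targets(
                tg.TargetSpec("stunting", "relative", reduction_fraction=0.4),
                series)


class TestPace:
    def test_ratio_and_acceleration(self):
        # constant decline 0.05/yr, target requiring 0.10/yr
        p = expit(logit(0.5) - 0.05 * np.arange(16))
        target = expit(logit(p[-1]) - 1.0)     # required = 1.0/10 = 0.10
        out = tg.pace_and_acceleration(p, YEARS16[1:], target)
        assert out["pace_ratio"].iloc[0] == pytest.approx(50.0, abs=1e-6)
        assert out["acceleration"].iloc[0] == pytest.approx(2.0, abs=1e-9)
        assert out["status"].iloc[0] == tg.STATUS_BEHIND

    def test_met_status(self):
        p = np.full(16, 0.10)
        out = tg.pace_and_acceleration(p, YEARS16[1:], target=0.2)
        assert out["status"].iloc[0] == tg.STATUS_MET

    def test_non_decreasing_class(self):
        p = expit(logit(0.3) + 0.02 * np.arange(16))
        out = tg.pace_and_acceleration(p, YEARS16[1:], target=0.05)
        assert out["status"].iloc[0] == tg.STATUS_NON_DECREASING

    def test_acceleration_capped_at_400_percent(self):
        p = expit(logit(0.5) - 0.001 * np.arange(16))
        target = expit(logit(p[-1]) - 1.0)
        out = tg.pace_and_acceleration(p, YEARS16[1:], target)
        assert out["acceleration"].iloc[0] == tg.ACCELERATION_CAP


class TestProbTargetMet:
    def _grid_cube(self, small_world, draws):
        grid, _ = small_world
        D = len(draws)
        vals = np.empty((D, grid.n_pixels, grid.n_years))
        vals[:] = np.asarray(draws)[:, None, None]
        return grid, PosteriorCube(vals, tuple(grid.years))

    def test_all_below(self, small_world):
        grid, cube = self._grid_cube(small_world, np.full(20, 0.20))
        prob = tg.prob_target_met(cube, 0.242, grid)
        np.testing.assert_array_equal(prob, 1.0)

    def test_direct_count(self, small_world):
        draws = np.concatenate([np.full(100, 0.1), np.full(150, 0.9)])
        grid, cube = self._grid_cube(small_world, draws)
        prob = tg.prob_target_met(cube, 0.5, grid)
        np.testing.assert_allclose(prob, 0.4)

    def test_monotone_in_target(self, small_world):
        rng = np.random.default_rng(5)
        grid, cube = self._grid_cube(small_world, rng.uniform(0, 1, 60))
        p_small = tg.prob_target_met(cube, 0.2, grid)
        p_big = tg.prob_target_met(cube, 0.4, grid)
        assert np.all(p_small <= p_big)

    def test_admin_level_from_aggregate_draws(self, small_world):
        grid, cube = self._grid_cube(small_world, np.full(10, 0.3))
        pix, admin = tg.prob_target_met(cube, 0.35, grid, level="admin1")
        assert set(admin["probability"]) == {1.0}
        assert len(admin) == len(np.unique(grid.admin1_id))
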