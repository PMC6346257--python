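"""Aggregation, raking, masking and population-weighted classes."""
import copy

import numpy as np
import pandas as pd
import pytest

from cgfmap import postestimation as pe
from cgfmap.geostat import PosteriorCube


def _cube(grid, values):
    """Wrap a (D, P, T) array as a cube on the grid's years."""
    return PosteriorCube(np.asarray(values, float), tuple(grid.years))


def _flat_cube(grid, p, n_draws=4):
    return _cube(grid, np.full((n_draws, grid.n_pixels, grid.n_years), p))


class TestAggregate:
    def test_weighted_mean_two_pixels(self, small_world):
        grid, _ = small_world
        g = copy.deepcopy(grid)
        g.mask[:] = True
        g.mask[:2] = False
        g.country_id[:] = 0
        g.population[0, :] = 100.0
        g.population[1, :] = 300.0
        vals = np.zeros((1, g.n_pixels, g.n_years))
        vals[0, 0, :], vals[0, 1, :] = 0.2, 0.4
        agg = pe.aggregate_admin(_cube(g, vals), g, "national")
        np.testing.assert_allclose(agg.draws, 0.35)

    def test_constant_field_identity(self, small_world):
        grid, _ = small_world
        agg = pe.aggregate_admin(_flat_cube(grid, 0.27), grid, "admin1")
        np.testing.assert_allclose(agg.draws, 0.27)

    def test_national_equals_weighted_admin1(self, small_world, small_truth):
        grid, _ = small_world
        rng = np.random.default_rng(0)
        vals = rng.uniform(0.05, 0.6, (3, grid.n_pixels, grid.n_years))
        cube = _cube(grid, vals)
        nat = pe.aggregate_admin(cube, grid, "national")
        a1 = pe.aggregate_admin(cube, grid, "admin1")
        for ci, c in enumerate(nat.unit_ids):
            members = [i for i, u in enumerate(a1.unit_ids)
                       if grid.country_id[grid.admin1_id == u][0] == c]
            pops = a1.population[members]             # (m, T)
            sub = a1.draws[members]                   # (m, D, T)
            recomposed = np.einsum("mdt,mt->dt", sub, pops) / pops.sum(axis=0)
            np.testing.assert_allclose(nat.draws[ci], recomposed, atol=1e-12)

    def test_linear_in_field(self, small_world):
        grid, _ = small_world
        rng = np.random.default_rng(1)
        vals = rng.uniform(0.1, 0.4, (2, grid.n_pixels, grid.n_years))
        a = pe.aggregate_admin(_cube(grid, vals), grid, "admin2")
        b = pe.aggregate_admin(_cube(grid, 2 * vals), grid, "admin2")
        np.testing.assert_allclose(2 * a.draws, b.draws, atol=1e-12)


def _series(countries, years, values):
    rows = [{"country_id": c, "indicator": "stunting", "year": y,
             "prevalence": v}
            for c in countries for y, v in zip(years, values)]
    return pd.DataFrame(rows)


class TestRaking:
    def test_simple_ratio(self, small_world):
        grid, _ = small_world
        cube = _flat_cube(grid, 0.25)
        nat = pe.aggregate_admin(cube, grid, "national")
        series = _series(nat.unit_ids, grid.years, [0.30] * grid.n_years)
        table = pe.compute_raking_factors(nat, series, anchors=grid.years)
        np.testing.assert_allclose(table.factors, 1.2, atol=1e-12)

    def test_factor_interpolation(self):
        years = tuple(range(2008, 2016))
        nat = pe.AdminAggregate("national", np.array([0]), years,
                                np.full((1, 2, len(years)), 0.5),
                                np.ones((1, len(years))))
        series = _series([0], [2010, 2015], [0.5, 0.55])
        table = pe.compute_raking_factors(nat, series, anchors=(2010, 2015))
        d = dict(zip(years, table.factors[0, 0]))
        assert d[2010] == pytest.approx(1.0)
        assert d[2015] == pytest.approx(1.1)
        assert d[2012] == pytest.approx(1.04)

    def test_2015_target_interpolated_between_2010_and_2016(self):
        years = tuple(range(2000, 2016))
        nat = pe.AdminAggregate("national", np.array([0]), years,
                                np.full((1, 1, len(years)), 0.25),
                                np.ones((1, len(years))))
        series = _series([0], [2000, 2005, 2010, 2016], [0.4, 0.35, 0.30, 0.24])
        table = pe.compute_raking_factors(nat, series)
        # target(2015) = 0.30 + 5/6 * (0.24 - 0.30) = 0.25
        assert table.factors[0, 0, -1] == pytest.approx(0.25 / 0.25)

    def test_identity_factor_leaves_cube(self, small_world):
        grid, _ = small_world
        cube = _flat_cube(grid, 0.3)
        nat = pe.aggregate_admin(cube, grid, "national")
        table = pe.RakingTable(nat.unit_ids, cube.years,
                               np.ones((len(nat.unit_ids), cube.n_draws,
                                        grid.n_years)))
        raked = pe.apply_raking(cube, table, grid)
        np.testing.assert_array_equal(raked.prevalence, cube.prevalence)
        assert raked.raked and raked.n_clipped == 0

    def test_clipping_counted(self, small_world):
        grid, _ = small_world
        cube = _flat_cube(grid, 0.3, n_draws=1)
        nat = pe.aggregate_admin(cube, grid, "national")
        table = pe.RakingTable(nat.unit_ids, cube.years,
                               np.full((len(nat.unit_ids), 1, grid.n_years), 4.0))
        raked = pe.apply_raking(cube, table, grid)
        assert np.all(raked.prevalence == 1.0)
        assert raked.n_clipped == grid.n_pixels * grid.n_years

    def test_exact_at_anchor_years_per_draw(self, small_world):
        """After raking, national aggregates equal the series to 1e-10."""
        grid, _ = small_world
        rng = np.random.default_rng(2)
        vals = rng.uniform(0.1, 0.5, (5, grid.n_pixels, grid.n_years))
        cube = _cube(grid, vals)
        nat = pe.aggregate_admin(cube, grid, "national")
        series = _series(nat.unit_ids, grid.years,
                         np.linspace(0.35, 0.25, grid.n_years))
        table = pe.compute_raking_factors(nat, series, anchors=grid.years)
        raked = pe.apply_raking(cube, table, grid)
        assert raked.n_clipped == 0
        renat = pe.aggregate_admin(raked, grid, "national")
        for ci, c in enumerate(renat.unit_ids):
            tgt = series[series["country_id"] == c].sort_values("year")[
                "prevalence"].to_numpy()
            np.testing.assert_allclose(
                renat.draws[ci], np.tile(tgt, (cube.n_draws, 1)), atol=1e-10)


class TestMask:
    def test_low_population_pixels_masked(self):
        from cgfmap import WorldConfig, make_world
        cfg = WorldConfig(n_rows=6, n_cols=6, years=(2000,), pop_median=5.0,
                          pop_log_sd=2.0, mask_pop_threshold=1.0)
        grid, _ = make_world(cfg, seed=3)
        assert grid.mask.any()
        assert (grid.population[grid.mask].mean(axis=1) < 1.0).all()

    def test_identity_and_idempotence(self, small_world):
        grid, _ = small_world
        field = np.arange(grid.n_pixels, dtype=float)
        once = pe.apply_mask(field, grid)
        twice = pe.apply_mask(once, grid)
        np.testing.assert_array_equal(once[~grid.mask], field[~grid.mask])
        np.testing.assert_array_equal(once, twice)
        assert np.isnan(once[grid.mask]).all()


class TestQuantileClasses:
    def test_equal_population_lowest_decile(self):
        vals = np.arange(10, dtype=float)
        pop = np.ones(10)
        classes = pe.pw_quantile_classes(vals, pop, fractions=(0.10,))
        low, high = classes[0.10]
        assert low.sum() == 1 and low[0]
        assert high.sum() == 1 and high[9]

    def test_all_equal_field_no_overlap(self):
        vals = np.full(10, 3.0)
        pop = np.ones(10)
        low, high = pe.pw_quantile_classes(vals, pop, fractions=(0.25,))[0.25]
        assert not np.any(low & high)
        # deterministic tie-break by pixel index
        assert low[0] and high[9]

    def test_cumulative_population_bound(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=40)
        pop = rng.uniform(1, 10, size=40)
        low, _ = pe.pw_quantile_classes(vals, pop, fractions=(0.10,))[0.10]
        tot = pop.sum()
        assert pop[low].sum() <= 0.10 * tot
        # adding the next pixel in value order would exceed the bound
        order = np.argsort(vals, kind="stable")
        nxt = [i for i in order if not low[i]][0]
        assert pop[low].sum() + pop[nxt] > 0.10 * tot

    def test_zero_population_errors(self):
        with pytest.raises(ValueError, match="population"):
            pe.pw_quantile_classes(np.ones(3), np.zeros(3))
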