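"""Covariance kernels and the Laplace inference engine."""
import numpy as np
import pandas as pd
import pytest

from cgfmap import geostat
from cgfmap.geostat import (GPHyperParams, ar1_corr, fit_geostat,
                            laplace_latent, matern_cov, predict_pixel_draws,
                            st_covariance)
from cgfmap.util import expit, logit


class TestMatern:
    def test_zero_distance_is_variance(self):
        assert matern_cov(0.0, 2.5, 4.0) == pytest.approx(2.5)

    def test_exponential_limit_nu_half(self):
        # at nu = 1/2 the kernel is var * exp(-2 d / range)
        d = np.array([0.0, 0.5, 1.0, 3.0])
        got = matern_cov(d, 1.0, 2.0, nu=0.5)
        np.testing.assert_allclose(got, np.exp(-2 * d / 2.0), rtol=1e-10)

    def test_correlation_at_range(self):
        # frozen from an independent Bessel-form evaluation at nu = 1
        assert matern_cov(4.0, 1.0, 4.0, nu=1.0) == pytest.approx(0.1396674740,
                                                                  abs=1e-8)

    def test_monotone_nonincreasing(self):
        d = np.linspace(0, 20, 200)
        c = matern_cov(d, 1.0, 3.0)
        assert np.all(np.diff(c) <= 1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            matern_cov(1.0, 1.0, -1.0)


class TestSpaceTimeCovariance:
    def _small(self):
        coords = np.array([[0.5, 0.5], [1.5, 0.5], [0.5, 1.5], [3.5, 3.5]])
        years = [2000, 2001, 2002]
        gp = GPHyperParams(2.0, 1.3, 0.6)
        return coords, years, gp

    def test_shape_symmetry_psd(self):
        coords, years, gp = self._small()
        K = st_covariance(coords, years, gp)
        assert K.shape == (12, 12)
        np.testing.assert_allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() >= -1e-8

    def test_same_pixel_lag_two(self):
        coords = np.array([[0.5, 0.5], [5.5, 0.5]])
        K = st_covariance(coords, [2000, 2001, 2002],
                          GPHyperParams(2.0, 1.0, 0.9))
        # year-major ordering: (t0, p0) vs (t2, p0)
        assert K[0, 4] == pytest.approx(0.81)

    def test_kronecker_eigenvalues(self):
        coords, years, gp = self._small()
        K = st_covariance(coords, years, gp)
        d = np.linalg.norm(coords[:, None] - coords[None], axis=-1)
        es = np.linalg.eigvalsh(matern_cov(d, gp.spatial_var, gp.spatial_range))
        et = np.linalg.eigvalsh(ar1_corr(years, gp.ar1_rho))
        products = np.sort(np.outer(et, es).ravel())
        np.testing.assert_allclose(np.sort(np.linalg.eigvalsh(K)), products,
                                   atol=1e-8)

    def test_memory_guard(self):
        coords = np.zeros((2001, 2))
        with pytest.raises(MemoryError):
            st_covariance(coords, range(2000, 2010), GPHyperParams(1, 1, 0.5))


def _point_obs(grid, pix, years, N, C):
    return pd.DataFrame({
        "cluster_id": range(len(pix)),
        "x": grid.pixel_centers[pix, 0], "y": grid.pixel_centers[pix, 1],
        "year": years, "N": N, "C": C, "weight": 1.0})


class TestFit:
    def test_refuses_tiny_datasets(self, small_world):
        grid, _ = small_world
        obs = _point_obs(grid, np.arange(5), [2000] * 5, 10, 2)
        with pytest.raises(ValueError, match="fewer than 10"):
            fit_geostat(obs, np.zeros((5, 1)), grid, constraint="linear")

    def test_simplex_constraint_holds(self, small_world):
        grid, _ = small_world
        rng = np.random.default_rng(0)
        pix = rng.integers(0, grid.n_pixels, 40)
        obs = _point_obs(grid, pix, rng.integers(2000, 2006, 40), 30,
                         rng.integers(0, 30, 40))
        F = rng.normal(0, 1, (40, 3))
        post = fit_geostat(obs, F, grid, n_draws=40, seed=1, maxfev=40)
        np.testing.assert_allclose(post.beta_draws.sum(axis=1), 1.0, atol=1e-10)
        assert (post.beta_draws >= -1e-12).all()

    def test_likelihood_domination_large_n(self, small_world):
        """A single huge observation pins the posterior at its pixel-year."""
        grid, _ = small_world
        pix = np.arange(12)
        N = np.full(12, 5); C = np.full(12, 2)
        N[0], C[0] = 1_000_000, 300_000
        obs = _point_obs(grid, pix, [2000] * 12, N, C)
        fixed = {"spatial_var": 0.5, "spatial_range": 3.0, "ar1_rho": 0.5,
                 "nugget_var": 1e-6}
        post = fit_geostat(obs, np.zeros((12, 0)), grid, constraint="linear",
                           fixed=fixed, n_draws=100, seed=2)
        F_pix = np.zeros((grid.n_pixels, grid.n_years, 0))
        cube = predict_pixel_draws(post, F_pix, grid, seed=2, years=grid.years)
        mean_at = cube.mean()[0, 0]
        assert 0.29 < mean_at < 0.31

    def test_half_weight_duplicates_equivalent(self, small_world):
        """Duplicating every observation at weight 0.5 leaves the fit alone."""
        grid, _ = small_world
        rng = np.random.default_rng(3)
        pix = rng.integers(0, grid.n_pixels, 30)
        obs = _point_obs(grid, pix, rng.integers(2000, 2006, 30), 40,
                         rng.integers(5, 35, 30))
        F = rng.normal(0, 1, (30, 2))
        dup = pd.concat([obs, obs], ignore_index=True)
        dup["weight"] = 0.5
        fixed = {"spatial_var": 0.3, "spatial_range": 3.0, "ar1_rho": 0.5,
                 "nugget_var": 0.1}
        p1 = fit_geostat(obs, F, grid, constraint="linear", fixed=fixed,
                         n_draws=200, seed=4)
        p2 = fit_geostat(dup, np.vstack([F, F]), grid, constraint="linear",
                         fixed=fixed, n_draws=200, seed=5)
        np.testing.assert_allclose(p1.beta_draws.mean(axis=0),
                                   p2.beta_draws.mean(axis=0), atol=0.05)

    def test_deterministic_given_seed(self, small_world):
        grid, _ = small_world
        rng = np.random.default_rng(6)
        pix = rng.integers(0, grid.n_pixels, 25)
        obs = _point_obs(grid, pix, rng.integers(2000, 2006, 25), 25,
                         rng.integers(0, 25, 25))
        F = rng.normal(0, 1, (25, 2))
        a = fit_geostat(obs, F, grid, n_draws=20, seed=7, maxfev=30)
        b = fit_geostat(obs, F, grid, n_draws=20, seed=7, maxfev=30)
        np.testing.assert_array_equal(a.beta_draws, b.beta_draws)
        np.testing.assert_array_equal(a.field_draws, b.field_draws)


class TestPredict:
    def test_bounds_and_shape(self, small_world):
        grid, _ = small_world
        rng = np.random.default_rng(8)
        pix = rng.integers(0, grid.n_pixels, 30)
        obs = _point_obs(grid, pix, rng.integers(2000, 2006, 30), 30,
                         rng.integers(0, 30, 30))
        F = rng.normal(0, 1, (30, 2))
        post = fit_geostat(obs, F, grid, n_draws=30, seed=9, maxfev=30)
        Fp = rng.normal(0, 1, (grid.n_pixels, grid.n_years, 2))
        cube = predict_pixel_draws(post, Fp, grid, seed=9, years=grid.years)
        assert cube.prevalence.shape == (30, grid.n_pixels, grid.n_years)
        assert cube.prevalence.min() >= 0 and cube.prevalence.max() <= 1

    def test_zero_residual_draws_vary_only_through_beta(self, small_world):
        grid, _ = small_world
        rng = np.random.default_rng(10)
        pix = rng.integers(0, grid.n_pixels, 20)
        obs = _point_obs(grid, pix, [2000] * 20, 30, rng.integers(0, 30, 20))
        F = rng.normal(0, 1, (20, 2))
        post = fit_geostat(obs, F, grid, constraint="linear", include_gp=False,
                           fixed={"nugget_var": 0.0}, n_draws=15, seed=11)
        Fp = np.tile(rng.normal(0, 1, (grid.n_pixels, 1, 2)), (1, 1, 1))
        cube = predict_pixel_draws(post, Fp, grid, seed=11, years=(2000,))
        eta = logit(cube.prevalence[:, :, 0])
        ones = np.column_stack([np.ones(grid.n_pixels), Fp[:, 0, :]])
        expect = expit(ones @ post.beta_draws.T).T
        np.testing.assert_allclose(cube.prevalence[:, :, 0], expect, atol=1e-9)


class TestLaplaceLatent:
    def test_large_counts_pin_the_field(self):
        n = 8
        K = 0.5 * np.eye(n) + 0.2
        C = np.array([300, 100, 200, 250, 150, 120, 280, 90], float)
        N = np.full(n, 1000.0)
        mean, cov = laplace_latent(C, N, np.ones(n), np.zeros(n), K)
        np.testing.assert_allclose(expit(mean), C / N, atol=0.02)
        assert np.all(np.diag(cov) < 0.05)
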