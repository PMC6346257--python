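"""Seasonality adjustment and polygon-to-point resampling."""
import numpy as np
import pandas as pd
import pytest

from cgfmap import preprocess
from cgfmap.preprocess import (cyclic_bspline_design, fit_seasonal_model,
                               adjust_seasonality, resample_polygon_obs)


def _whz_records(n=5000, amplitude=0.4, noise=0.1, seed=0, n_countries=2):
    rng = np.random.default_rng(seed)
    month = rng.integers(1, 13, n)
    year = rng.integers(2000, 2006, n)
    country = rng.integers(0, n_countries, n)
    whz = (amplitude * np.sin(2 * np.pi * (month - 1) / 12.0)
           + noise * rng.standard_normal(n))
    return pd.DataFrame({"region_id": 0, "country_id": country,
                         "interview_year": year, "interview_month": month,
                         "whz": whz})


def _fitted_amplitude(model):
    grid = np.arange(1, 13)
    f = model.f_periodic(grid)
    return (f.max() - f.min()) / 2


class TestSeasonalModel:
    def test_cyclic_basis_is_periodic(self):
        x = np.array([0.0, 3.7, 11.99])
        B1 = cyclic_bspline_design(x)
        B2 = cyclic_bspline_design(x + 12.0)
        np.testing.assert_allclose(B1, B2, atol=1e-9)
        np.testing.assert_allclose(B1.sum(axis=1), 1.0, atol=1e-9)

    def test_recovers_injected_sinusoid(self):
        rec = _whz_records(amplitude=0.4)
        model = fit_seasonal_model(rec)[0]
        assert 0.3 <= _fitted_amplitude(model) <= 0.5

    def test_constant_whz_gives_flat_periodic(self):
        rec = _whz_records(amplitude=0.0, noise=0.0)
        rec["whz"] = 1.3
        model = fit_seasonal_model(rec)[0]
        assert np.max(np.abs(model.f_periodic(np.arange(1, 13)))) < 1e-6

    def test_month_13_rejected(self):
        rec = _whz_records(n=100)
        rec.loc[0, "interview_month"] = 13
        with pytest.raises(ValueError, match="1..12"):
            fit_seasonal_model(rec)

    def test_single_month_region_errors(self):
        rec = _whz_records(n=50)
        rec["interview_month"] = 4
        with pytest.raises(ValueError, match="skip"):
            fit_seasonal_model(rec)


class TestAdjustment:
    def test_flat_model_is_identity(self):
        rec = _whz_records(amplitude=0.0, noise=0.0, n=200)
        rec["whz"] = 0.7
        models = fit_seasonal_model(rec)
        out = adjust_seasonality(rec, models)
        np.testing.assert_allclose(out["whz"], 0.7, atol=1e-6)

    def test_shift_by_periodic_value(self):
        rec = _whz_records(n=3000, amplitude=0.4, noise=0.05, seed=1)
        models = fit_seasonal_model(rec)
        out = adjust_seasonality(rec, models)
        shift = rec["whz"].to_numpy() - out["whz"].to_numpy()
        expect = models[0].f_periodic(rec["interview_month"].to_numpy())
        np.testing.assert_allclose(shift, expect, atol=1e-12)

    def test_residual_seasonality_attenuated(self):
        """Refitting on adjusted data recovers <= 20% of the amplitude."""
        rec = _whz_records(n=6000, amplitude=0.4, seed=2)
        models = fit_seasonal_model(rec)
        adjusted = adjust_seasonality(rec, models)
        refit = fit_seasonal_model(adjusted)[0]
        assert _fitted_amplitude(refit) <= 0.2 * 0.4

    def test_missing_region_model_errors(self):
        rec = _whz_records(n=100)
        with pytest.raises(KeyError):
            adjust_seasonality(rec, {3: None})

    def test_missing_dates_dropped(self):
        rec = _whz_records(n=100)
        rec.loc[:4, "interview_month"] = np.nan
        models = fit_seasonal_model(rec.dropna(subset=["interview_month"]))
        out = adjust_seasonality(rec, models)
        assert len(out) == 95

    def test_annual_mean_preserved_under_uniform_months(self):
        rec = _whz_records(n=12 * 400, seed=3, noise=0.0)
        rec["interview_month"] = np.tile(np.arange(1, 13), 400)
        rec["whz"] = 0.4 * np.sin(2 * np.pi * (rec["interview_month"] - 1) / 12.0)
        models = fit_seasonal_model(rec)
        out = adjust_seasonality(rec, models)
        assert abs(out["whz"].mean() - rec["whz"].mean()) < 1e-6


def _poly_row(cluster_id=0, admin_ref=0, year=2000, N=50, C=10):
    return pd.Series({"cluster_id": cluster_id, "admin_ref": admin_ref,
                      "year": year, "N": N, "C": C, "weight": 1.0,
                      "month": 6, "indicator": "stunting",
                      "geometry_type": "polygon"})


class TestResampling:
    def test_uniform_square_k1_centroid_at_center(self, small_world):
        grid, _ = small_world
        grid2 = _uniform_pop(grid)
        unit = 0
        pix = grid2.pixels_of_unit("admin2", unit)
        center = grid2.pixel_centers[pix].mean(axis=0)
        out = resample_polygon_obs(_poly_row(admin_ref=unit), grid2,
                                   n_samples=4000, k=1, seed=0)
        assert len(out) == 1
        assert out.iloc[0]["weight"] == pytest.approx(1.0)
        dist = np.hypot(out.iloc[0]["x"] - center[0], out.iloc[0]["y"] - center[1])
        assert dist < 0.5 * grid2.pixel_size

    def test_weights_sum_to_one(self, small_world):
        grid, _ = small_world
        out = resample_polygon_obs(_poly_row(admin_ref=1), grid,
                                   n_samples=2000, k=5, seed=1)
        assert out["weight"].sum() == pytest.approx(1.0, abs=1e-12)
        assert (out["weight"] > 0).all()

    def test_concentrated_population(self, small_world):
        grid, _ = small_world
        import copy
        g = copy.deepcopy(grid)
        pix = g.pixels_of_unit("admin2", 0)
        g.population[pix] = 0.0
        g.population[pix[0]] = 100.0
        g.mask[:] = False
        out = resample_polygon_obs(_poly_row(admin_ref=0), g,
                                   n_samples=1000, k=3, seed=2)
        cx, cy = g.pixel_centers[pix[0]]
        assert np.all(np.abs(out["x"] - cx) <= 0.5 * g.pixel_size)
        assert out["weight"].sum() == pytest.approx(1.0)

    def test_two_pixel_equal_population_weights(self, small_world):
        grid, _ = small_world
        import copy
        g = copy.deepcopy(grid)
        pix = g.pixels_of_unit("admin2", 0)
        g.population[pix] = 0.0
        g.population[pix[0]] = 50.0
        g.population[pix[-1]] = 50.0
        out = resample_polygon_obs(_poly_row(admin_ref=0), g,
                                   n_samples=10_000, k=2, seed=3)
        assert sorted(out["weight"]) == pytest.approx([0.5, 0.5], abs=0.02)

    def test_zero_population_polygon_errors(self, small_world):
        grid, _ = small_world
        import copy
        g = copy.deepcopy(grid)
        g.population[g.pixels_of_unit("admin2", 0)] = 0.0
        with pytest.raises(ValueError, match="no populated"):
            resample_polygon_obs(_poly_row(admin_ref=0), g, seed=0)

    def test_k_greater_than_samples_errors(self, small_world):
        grid, _ = small_world
        with pytest.raises(ValueError, match="exceed"):
            resample_polygon_obs(_poly_row(), grid, n_samples=5, k=10)

    def test_seeded_reproducibility(self, small_world):
        grid, _ = small_world
        a = resample_polygon_obs(_poly_row(), grid, n_samples=500, k=4, seed=7)
        b = resample_polygon_obs(_poly_row(), grid, n_samples=500, k=4, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_mass_conservation_in_expansion(self, small_world, small_surveys):
        grid, _ = small_world
        obs = small_surveys.head(40)
        out = preprocess.expand_polygon_observations(obs, grid, n_samples=500,
                                                     seed=4)
        eff = out.groupby(out["cluster_id"].astype(str).str.split("_k").str[0])[
            "weight"].sum()
        np.testing.assert_allclose(eff, 1.0, atol=1e-9)


def _uniform_pop(grid):
    import copy
    g = copy.deepcopy(grid)
    g.population = np.ones_like(g.population)
    g.mask[:] = False
    return g
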