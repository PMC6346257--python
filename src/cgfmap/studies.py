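"""Seeded simulation studies: the package's own validation experiments.

Each study builds a synthetic world with known truth, runs the relevant part
of the pipeline and measures how well the method recovers the truth. They
are used both by the test suite and by the reproduction script. Problem
sizes default to desk-scale settings (a 16x16-pixel decade-long world with
60 clusters per year for the recovery study; smaller worlds for the
formulation comparison) chosen so a full study runs in minutes on one CPU;
the generative hyperparameters (rho = 0.8, spatial range = 6 pixels,
sigma^2 = 0.5) are the standard study conditions.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from . import anthro, geostat, postestimation, preprocess, stacking, validation
from .geostat import GPHyperParams
from .synthetic_world import (SurveyDesign, WorldConfig, make_world,
                              simulate_national_series, simulate_surveys,
                              simulate_truth)
from .util import expit, logit, rng_from_seed

RECOVERY_TRUTH = GPHyperParams(spatial_range=6.0, spatial_var=0.5,
                               ar1_rho=0.8, nugget_var=0.0)


def _raw_features(obs, covs, grid):
    pix = grid.nearest_pixel(obs["x"].to_numpy(float), obs["y"].to_numpy(float))
    t = np.array([grid.year_index(y) for y in obs["year"]])
    return covs.values[pix, t, :]


def recovery_replicate(seed: int, n_rows: int = 16, n_cols: int = 16,
                       n_years: int = 10, clusters_per_year: int = 60,
                       gp_true: GPHyperParams = RECOVERY_TRUTH,
                       n_draws: int = 150, maxfev: int = 150) -> dict:
    """Simulate from the model, refit it, and score recovery + calibration.

    The world is simulated exactly from the fitted model's generative form
    (covariate linear predictor + Matern x AR1 field; binomial cluster
    counts at population-weighted point locations), the model is refitted
    with all hyperparameters free, and the posterior is summarised: median
    hyperparameters, and 95%-interval coverage of the true prevalence over
    all pixel-years.
    """
    years = tuple(range(2000, 2000 + n_years))
    cfg = WorldConfig(n_rows=n_rows, n_cols=n_cols, years=years)
    grid, covs = make_world(cfg, seed)
    rng = rng_from_seed(seed, "recovery-beta")
    beta = rng.normal(0.0, 0.3, covs.values.shape[2])
    truth = simulate_truth(grid, covs, gp_true, beta, seed)
    design = SurveyDesign(clusters_per_year=clusters_per_year,
                          point_fraction=1.0, microdata=False)
    obs, _ = simulate_surveys(truth, grid, design, seed,
                              indicator="stunting")
    F = _raw_features(obs, covs, grid)
    post = geostat.fit_geostat(obs, F, grid, constraint="linear",
                               n_draws=n_draws, seed=seed, maxfev=maxfev)
    F_pix = covs.values[:, [grid.year_index(y) for y in years], :]
    cube = geostat.predict_pixel_draws(post, F_pix, grid, seed=seed,
                                       years=years)
    lo, hi = cube.interval(0.95)
    tp = truth.prevalence
    covered = (tp >= lo) & (tp <= hi)
    return {
        "seed": seed,
        "rho_median": float(np.median([h.ar1_rho for h in post.hyper_draws])),
        "range_median": float(np.median([h.spatial_range
                                         for h in post.hyper_draws])),
        "sigma2_median": float(np.median([h.spatial_var
                                          for h in post.hyper_draws])),
        "coverage": float(covered.mean()),
        "n_covered": int(covered.sum()),
        "n_cells": int(covered.size),
        "mean_abs_error": float(np.abs(cube.mean() - tp).mean()),
        "n_obs": len(obs),
    }


def recovery_study(n_replicates: int = 10, base_seed: int = 0, **kw) -> pd.DataFrame:
    rows = [recovery_replicate(base_seed * 1000 + r, **kw)
            for r in range(n_replicates)]
    return pd.DataFrame(rows)


def raking_consistency_run(seed: int, n_rows: int = 10, n_cols: int = 10,
                           n_years: int = 6, clusters_per_year: int = 40,
                           perturbation_sd: float = 0.0, n_draws: int = 80,
                           maxfev: int = 120) -> dict:
    """Fit a well-specified model and rake to an (unperturbed) national series.

    With zero series noise the median raking factor should sit near 1: the
    model's national aggregates already track the truth the series reports.
    """
    years = tuple(range(2000, 2000 + n_years))
    grid, covs = make_world(WorldConfig(n_rows=n_rows, n_cols=n_cols,
                                        years=years), seed)
    rng = rng_from_seed(seed, "rake-beta")
    beta = rng.normal(0.0, 0.3, covs.values.shape[2])
    gp = GPHyperParams(4.0, 0.3, 0.7, 0.0)
    truth = simulate_truth(grid, covs, gp, beta, seed)
    obs, _ = simulate_surveys(
        truth, grid, SurveyDesign(clusters_per_year=clusters_per_year,
                                  point_fraction=1.0, microdata=False), seed)
    anchors = (years[0], years[len(years) // 2], years[-1])
    series = simulate_national_series(truth, grid, perturbation_sd, seed,
                                      years=anchors)
    F = _raw_features(obs, covs, grid)
    post = geostat.fit_geostat(obs, F, grid, constraint="linear",
                               n_draws=n_draws, seed=seed, maxfev=maxfev)
    F_pix = covs.values[:, [grid.year_index(y) for y in years], :]
    cube = geostat.predict_pixel_draws(post, F_pix, grid, seed=seed, years=years)
    national = postestimation.aggregate_admin(cube, grid, "national")
    table = postestimation.compute_raking_factors(national, series,
                                                  anchors=anchors)
    raked = postestimation.apply_raking(cube, table, grid)
    return {"seed": seed, "median_factor": table.median_factor(),
            "n_clipped": raked.n_clipped}


def formulation_study(seed: int, n_rows: int = 12, n_cols: int = 12,
                      n_years: int = 6, clusters_per_year: int = 60,
                      mean_children: float = 40.0,
                      n_draws: int = 60, maxfev: int = 60) -> pd.DataFrame:
    """Five-formulation out-of-sample comparison on one synthetic world.

    The world realises the conditions the ensemble covariates exist for: a
    strong *nonlinear* covariate signal (saturating, folded and periodic
    transforms of moderately rough covariate fields — structure a linear
    model cannot represent and the residual GP cannot interpolate across
    held-out admin blocks) plus a genuine Matern x AR1 residual field. Under
    these conditions the stacked ensemble + GP formulation should attain the
    lowest out-of-sample RMSE.
    """
    years = tuple(range(2000, 2000 + n_years))
    grid, covs = make_world(WorldConfig(n_rows=n_rows, n_cols=n_cols,
                                        n_admin1_per_country=3, years=years,
                                        covariate_smoothness=1.5),
                            seed)
    rng = rng_from_seed(seed, "formulation-beta")
    beta = rng.normal(0.0, 0.3, covs.values.shape[2])
    gp = GPHyperParams(4.0, 0.5, 0.8, 0.0)
    truth = simulate_truth(grid, covs, gp, beta, seed)
    v = covs.values
    truth.logit_prev = (truth.logit_prev
                        + 1.2 * np.tanh(1.5 * v[:, :, 0])
                        + 1.0 * np.abs(v[:, :, 1])
                        + 0.9 * np.sin(1.8 * v[:, :, 2]) - 0.9)
    obs, _ = simulate_surveys(
        truth, grid, SurveyDesign(clusters_per_year=clusters_per_year,
                                  mean_children=mean_children,
                                  point_fraction=1.0, microdata=False), seed)
    return validation.compare_formulations(obs, covs, grid, seed=seed,
                                           n_draws=n_draws, maxfev=maxfev,
                                           include_learners=True)


def oracle_weight_run(seed: int, n_obs: int = 1500, noise_sd: float = 1.0) -> dict:
    """Simplex-weight recovery when one learner's feature IS the truth.

    With the residual field and nugget pinned at zero, the posterior mean
    weight on the oracle learner should approach 1 at large n.
    """
    grid, covs = make_world(WorldConfig(n_rows=12, n_cols=12,
                                        years=tuple(range(2000, 2004))), seed)
    rng = rng_from_seed(seed, "oracle")
    pix = rng.integers(0, grid.n_pixels, n_obs)
    yrs = rng.integers(2000, 2004, n_obs)
    eta_true = rng.normal(0.0, 1.0, n_obs)
    N = np.full(n_obs, 50)
    C = rng.binomial(N, expit(eta_true))
    obs = pd.DataFrame({"cluster_id": range(n_obs),
                        "x": grid.pixel_centers[pix, 0],
                        "y": grid.pixel_centers[pix, 1],
                        "year": yrs, "N": N, "C": C, "weight": 1.0})
    F = np.column_stack([
        eta_true,                                       # the oracle learner
        eta_true + noise_sd * rng.normal(size=n_obs),   # noisy competitors
        eta_true + noise_sd * rng.normal(size=n_obs)])
    post = geostat.fit_geostat(
        obs, F, grid, constraint="simplex",
        fixed={"spatial_var": 0.0, "nugget_var": 0.0, "spatial_range": 1.0,
               "ar1_rho": 0.0},
        include_gp=False, n_draws=200, seed=seed)
    w = post.beta_draws.mean(axis=0)
    return {"oracle_weight": float(w[0]), "weights": w}


def seasonality_attenuation_run(seed: int, amplitude: float = 0.4,
                                clusters_per_year: int = 25) -> dict:
    """Inject a 12-month WHZ sinusoid, adjust it away, measure the residual."""
    years = tuple(range(2000, 2006))
    grid, covs = make_world(WorldConfig(n_rows=10, n_cols=10, years=years), seed)
    gp = GPHyperParams(4.0, 0.2, 0.7, 0.0)
    rng = rng_from_seed(seed, "season-beta")
    beta = rng.normal(0.0, 0.2, covs.values.shape[2])
    truth = simulate_truth(grid, covs, gp, beta, seed)
    design = SurveyDesign(clusters_per_year=clusters_per_year,
                          point_fraction=1.0,
                          seasonal_amplitude_whz=amplitude, microdata=True)
    obs, children = simulate_surveys(truth, grid, design, seed,
                                     indicator="wasting")
    lms = anthro.make_synthetic_lms_tables()
    children = children.copy()
    children["whz"] = anthro._score_records(children, lms, "wasting")
    coords = obs.set_index("cluster_id")[["x", "y"]]
    pix = grid.nearest_pixel(
        coords["x"].reindex(children["cluster_id"]).to_numpy(),
        coords["y"].reindex(children["cluster_id"]).to_numpy())
    children["region_id"] = grid.region_id[pix]
    children["country_id"] = grid.country_id[pix]

    def amp(rec):
        model = preprocess.fit_seasonal_model(rec)[0]
        f = model.f_periodic(np.arange(1, 13))
        return (f.max() - f.min()) / 2

    before = amp(children)
    models = preprocess.fit_seasonal_model(children)
    adjusted = preprocess.adjust_seasonality(children, models)
    after = amp(adjusted)
    return {"amplitude_before": float(before), "amplitude_after": float(after),
            "attenuation": float(1.0 - after / before)}
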