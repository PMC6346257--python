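"""End-to-end orchestration: simulate -> score -> adjust -> stack -> fit ->
predict -> aggregate -> rake -> mask -> project -> targets -> validate.

`run_pipeline` drives every stage from a single seeded RunConfig and writes
standard-format products plus a manifest of stage checksums, so a rerun with
the same config is bit-identical for the deterministic stages.
"""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import anthro, geostat, io, postestimation, preprocess, stacking, targets, validation
from .synthetic_world import (SurveyDesign, WorldConfig, make_world,
                              simulate_national_series, simulate_surveys,
                              simulate_truth)
from .util import rng_from_seed

log = logging.getLogger("cgfmap")

STAGES = ("simulate", "prep", "stack", "fit", "rake", "project", "validate", "report")


@dataclass
class RunConfig:
    """Everything one pipeline run needs; the seed is mandatory."""
    seed: int
    output_dir: str = "cgfmap_run"
    indicator: str = "stunting"
    n_draws: int = 100
    world: WorldConfig = field(default_factory=WorldConfig)
    # desk-scale default survey: the dense-covariance engine targets runs of
    # a few thousand (pseudo-)observations at most
    survey: SurveyDesign = field(default_factory=lambda: SurveyDesign(
        clusters_per_year=25))
    resample_k: int = 4             # k-means centroids per polygon observation
    truth_gp: geostat.GPHyperParams = field(default_factory=lambda: geostat.GPHyperParams(
        spatial_range=6.0, spatial_var=0.5, ar1_rho=0.8, nugget_var=0.05))
    truth_beta: tuple | None = None
    truth_intercept: float = -1.0
    national_perturbation_sd: float = 0.0
    maxfev: int = 150
    n_folds_validation: int = 0       # 0 skips the CV harness
    projection: targets.ProjectionConfig = field(default_factory=targets.ProjectionConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError("config must set a seed")
        kw = dict(raw)
        if "world" in kw:
            w = dict(kw["world"])
            if "years" in w:
                w["years"] = tuple(w["years"])
            kw["world"] = WorldConfig(**w)
        if "survey" in kw:
            kw["survey"] = SurveyDesign(**kw["survey"])
        if "truth_gp" in kw:
            kw["truth_gp"] = geostat.GPHyperParams(**kw["truth_gp"])
        if "projection" in kw:
            kw["projection"] = targets.ProjectionConfig(**kw["projection"])
        return cls(**kw)


def run_pipeline(config: RunConfig, stop_after: str | None = None) -> dict:
    """Execute the pipeline; returns the run manifest (also written to disk).

    ``stop_after`` names a stage from STAGES to halt at (inclusive).
    """
    if stop_after is not None and stop_after not in STAGES:
        raise ValueError(f"unknown stage {stop_after!r}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "indicator": config.indicator,
                      "stages": {}, "files": {}}
    t0 = time.time()

    def done(stage, **hashes):
        manifest["stages"][stage] = {"elapsed_s": round(time.time() - t0, 2), **hashes}
        log.info("stage %s done (%.1fs)", stage, time.time() - t0)
        return stop_after == stage

    # --- simulate ---------------------------------------------------------
    grid, covs = make_world(config.world, config.seed)
    rng = rng_from_seed(config.seed, "pipeline-beta")
    beta = (np.asarray(config.truth_beta, float) if config.truth_beta is not None
            else rng.normal(0, 0.4, covs.values.shape[2]))
    truth = simulate_truth(grid, covs, config.truth_gp, beta, config.seed,
                           config.truth_intercept)
    obs_raw, children = simulate_surveys(truth, grid, config.survey, config.seed,
                                         indicator=config.indicator)
    anchors = tuple(y for y in postestimation.ANCHOR_YEARS if y in grid.years)
    if len(anchors) < 2:        # short test worlds: anchor on the span ends
        anchors = (grid.years[0], grid.years[-1])
    series = simulate_national_series(truth, grid, config.national_perturbation_sd,
                                      config.seed, years=anchors,
                                      indicator=config.indicator)
    if done("simulate", truth=io.array_checksum(truth.logit_prev),
            obs=io.array_checksum(obs_raw[["N", "C"]].to_numpy())):
        return _finish(manifest, out)

    # --- prep: score microdata, seasonal adjustment, polygon resampling ---
    lms = anthro.make_synthetic_lms_tables()
    geometry = dict(zip(obs_raw["cluster_id"], obs_raw["geometry_type"]))
    if len(children):
        children, excl_log = anthro.apply_exclusions(children, geometry)
        excl_log.to_csv(out / "exclusion_log.csv", index=False)
    if config.indicator == "wasting" and len(children):
        children = children.copy()
        children["whz"] = anthro._score_records(children, lms, "wasting")
        children["region_id"] = grid.region_id[grid.nearest_pixel(
            *_child_coords(children, obs_raw))]
        children["country_id"] = grid.country_id[grid.nearest_pixel(
            *_child_coords(children, obs_raw))]
        seasonal = preprocess.fit_seasonal_model(children)
        children = preprocess.adjust_seasonality(children, seasonal)
        collapsed = anthro.collapse_to_cluster(children, lms, "wasting",
                                               z_column="whz")
        obs_raw = obs_raw.drop(columns=["N", "C"]).merge(
            collapsed[["cluster_id", "N", "C"]], on="cluster_id", how="inner")
    obs = preprocess.expand_polygon_observations(obs_raw, grid, seed=config.seed,
                                                 k=config.resample_k)
    obs.to_csv(out / "observations.csv", index=False)
    if done("prep", obs=io.array_checksum(obs[["N", "C"]].to_numpy())):
        return _finish(manifest, out)

    # --- stack ------------------------------------------------------------
    feats = stacking.fit_child_learners(obs, covs, grid, seed=config.seed)
    model_years = tuple(y for y in grid.years if y <= 2015)
    pix_feats = feats.pixel_features(covs, grid, years=model_years)
    if done("stack", features=io.array_checksum(feats.obs_features)):
        return _finish(manifest, out)

    # --- fit + predict ----------------------------------------------------
    posterior = geostat.fit_geostat(obs, feats.obs_features, grid,
                                    n_draws=config.n_draws, seed=config.seed,
                                    maxfev=config.maxfev)
    cube = geostat.predict_pixel_draws(posterior, pix_feats, grid,
                                       seed=config.seed, years=model_years,
                                       indicator=config.indicator)
    manifest["posterior"] = {
        "beta_mean": posterior.beta_draws.mean(axis=0).tolist(),
        "map_hyperparams": posterior.unique_thetas[0].__dict__}
    if done("fit", cube=io.array_checksum(cube.prevalence)):
        return _finish(manifest, out)

    # --- aggregate + rake + mask -----------------------------------------
    national = postestimation.aggregate_admin(cube, grid, "national")
    raking = postestimation.compute_raking_factors(national, series,
                                                   anchors=anchors)
    raked = postestimation.apply_raking(cube, raking, grid)
    for level in ("admin1", "admin2", "national"):
        postestimation.aggregate_admin(raked, grid, level).to_frame().to_csv(
            out / f"aggregate_{level}.csv", index=False)
    mean_map = postestimation.apply_mask(raked.mean(), grid)
    io.write_raster(out / "prevalence_mean.tif", mean_map, grid)
    manifest["raking_factor_median"] = raking.median_factor()
    manifest["raking_clip_events"] = raked.n_clipped
    if done("rake", raked=io.array_checksum(raked.prevalence)):
        return _finish(manifest, out)

    # --- project + targets ------------------------------------------------
    mean_series = raked.mean()                       # (P, T)
    change_years = list(raked.years[1:])
    aroc = targets.annual_logit_aroc(mean_series, expected_length=None)
    mean_aroc = targets.weighted_aroc(aroc, change_years, config.projection)
    p2025 = targets.project_prevalence(mean_series[:, -1], mean_aroc,
                                       config.projection.horizon)
    io.write_raster(out / "prevalence_projected.tif", p2025, grid)
    spec = targets.DEFAULT_TARGETS.get(
        config.indicator, targets.TargetSpec(config.indicator, "fixed", fixed_level=0.05))
    ref_year = 2010 if 2010 in set(series["year"]) else int(series["year"].max())
    pop_ref = {int(c): float(grid.population[(grid.country_id == c) & ~grid.mask,
                                             grid.year_index(ref_year)].sum())
               for c in np.unique(grid.country_id[grid.country_id >= 0])}
    spec = (targets.resolve_targets(spec, series, reference_year=ref_year,
                                    populations=pop_ref)
            if spec.target_type == "relative" else targets.resolve_targets(spec))
    pace = targets.pace_and_acceleration(mean_series, change_years,
                                         spec.require_resolved(), config.projection)
    pace.to_csv(out / "pace_metrics.csv", index=False)
    pix_prob, admin_prob = targets.prob_target_met(raked, spec.require_resolved(),
                                                   grid, level="admin1")
    io.write_raster(out / "prob_target_met.tif", pix_prob, grid)
    admin_prob.to_csv(out / "prob_target_met_admin1.csv", index=False)
    manifest["resolved_target"] = spec.resolved_target
    manifest["mean_projection"] = float(np.nanmean(
        postestimation.apply_mask(p2025, grid)))
    if done("project", p2025=io.array_checksum(p2025)):
        return _finish(manifest, out)

    # --- validate ---------------------------------------------------------
    if config.n_folds_validation:
        report = validation.compare_formulations(
            obs, covs, grid, seed=config.seed,
            n_folds=config.n_folds_validation, n_draws=min(config.n_draws, 100),
            maxfev=min(config.maxfev, 80))
        report.to_csv(out / "cv_report.csv", index=False)
        manifest["cv_best_rmse"] = report.loc[report["rmse"].idxmin(),
                                              "formulation"]
    done("validate")

    # --- report -----------------------------------------------------------
    io.write_boundaries(out / "admin2.geojson", grid, "admin2")
    series.to_csv(out / "national_series.csv", index=False)
    done("report")
    return _finish(manifest, out)


def _child_coords(children, obs_raw):
    ref = obs_raw.set_index("cluster_id")
    x = ref["x"].reindex(children["cluster_id"]).to_numpy(float)
    y = ref["y"].reindex(children["cluster_id"]).to_numpy(float)
    # polygon clusters have no point coordinates; use the polygon centroid pixel
    x = np.nan_to_num(x, nan=np.nanmean(x) if np.isfinite(x).any() else 0.0)
    y = np.nan_to_num(y, nan=np.nanmean(y) if np.isfinite(y).any() else 0.0)
    return x, y


def _finish(manifest: dict, out: Path) -> dict:
    for f in sorted(out.glob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["files"][f.name] = io.file_checksum(f)
    io.write_manifest(out / "manifest.json", manifest)
    return manifest
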