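"""Out-of-sample validation.

Spatially stratified five-fold cross-validation: holdout folds are unions of
whole admin units grouped by a seeded sweep over unit adjacency, so held-out
data are spatially contiguous and the test is stricter than random holdouts.
Four metrics are reported on held-out cluster observations: mean error
(bias), root-mean-square error, 95% coverage of data-level predictive
intervals (the posterior interval for C/N given N, i.e. widened by binomial
sampling noise), and sample-size-weighted Pearson correlation. A harness
compares five model formulations — stacked ensemble with and without the
space-time error, raw covariates with and without it, and the Gaussian
process alone — on identical folds.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import geostat, stacking
from .util import rng_from_seed

FORMULATIONS = (
    "stacked + GP",
    "stacked (no GP)",
    "raw covariates + GP",
    "raw covariates (no GP)",
    "GP only",
)


# ---------------------------------------------------------------------------
# folds


def _unit_adjacency(grid, unit: str) -> dict:
    """Rook adjacency between admin units from the id raster."""
    ids = getattr(grid, f"{unit}_id").reshape(grid.n_rows, grid.n_cols)
    adj: dict = {int(u): set() for u in np.unique(ids)}
    h = ids[:, :-1] != ids[:, 1:]
    v = ids[:-1, :] != ids[1:, :]
    for a, b in zip(ids[:, :-1][h], ids[:, 1:][h]):
        adj[int(a)].add(int(b)); adj[int(b)].add(int(a))
    for a, b in zip(ids[:-1, :][v], ids[1:, :][v]):
        adj[int(a)].add(int(b)); adj[int(b)].add(int(a))
    return adj


def spatial_folds(obs: pd.DataFrame, grid, n_folds: int = 5,
                  unit: str = "admin1", seed: int = 0) -> np.ndarray:
    """Assign observations to spatially contiguous folds of whole admin units.

    Units are grouped by seeded breadth-first growth over unit adjacency into
    ``n_folds`` groups with sizes balanced within +/-1; every observation gets
    the fold of its unit.
    """
    pix = grid.nearest_pixel(obs["x"].to_numpy(float), obs["y"].to_numpy(float))
    unit_of_obs = getattr(grid, f"{unit}_id")[pix]
    units = np.unique(getattr(grid, f"{unit}_id"))
    if len(units) < n_folds:
        raise ValueError(f"only {len(units)} {unit} units for {n_folds} folds")
    adj = _unit_adjacency(grid, unit)
    rng = rng_from_seed(seed, "spatial-folds")
    sizes = np.full(n_folds, len(units) // n_folds)
    sizes[: len(units) % n_folds] += 1
    unassigned = set(int(u) for u in units)
    fold_of_unit: dict = {}
    for f in range(n_folds):
        start = int(rng.choice(sorted(unassigned)))
        group = [start]
        unassigned.discard(start)
        frontier = [start]
        while len(group) < sizes[f] and unassigned:
            cand = sorted({v for u in frontier for v in adj[u]} & unassigned)
            if not cand:
                cand = sorted(unassigned)   # disconnected remainder
            nxt = int(rng.choice(cand))
            group.append(nxt)
            unassigned.discard(nxt)
            frontier.append(nxt)
        for u in group:
            fold_of_unit[u] = f
    return np.array([fold_of_unit[int(u)] for u in unit_of_obs])


# ---------------------------------------------------------------------------
# metrics


def cv_metrics(obs: pd.DataFrame, pred_draws: np.ndarray, seed: int = 0,
               level: str = "pixel", formulation: str = "",
               fold_id: int | None = None) -> dict:
    """The four validation metrics for held-out observations.

    ``pred_draws`` is (D, n_obs) prevalence draws at the observations'
    pixel-years. Coverage is data-level: for each draw a binomial C is
    simulated given N, and the observed C/N is checked against the 2.5-97.5%
    interval of the predictive C/N sample.
    """
    C = obs["C"].to_numpy(float)
    N = obs["N"].to_numpy(float)
    y = C / N
    mean = pred_draws.mean(axis=0)
    resid = mean - y
    me = float(resid.mean())
    rmse = float(np.sqrt((resid**2).mean()))

    rng = rng_from_seed(seed, "coverage")
    Cpred = rng.binomial(N.astype(int)[None, :], pred_draws)   # (D, n)
    frac = Cpred / N[None, :]
    lo = np.quantile(frac, 0.025, axis=0)
    hi = np.quantile(frac, 0.975, axis=0)
    coverage = float(100.0 * np.mean((y >= lo) & (y <= hi)))

    w = N / N.sum()
    my, mp = np.sum(w * y), np.sum(w * mean)
    cov_ = np.sum(w * (y - my) * (mean - mp))
    denom = np.sqrt(np.sum(w * (y - my) ** 2) * np.sum(w * (mean - mp) ** 2))
    corr = float(cov_ / denom) if denom > 0 else np.nan

    return {"level": level, "formulation": formulation, "fold_id": fold_id,
            "n_obs": len(obs), "me": me, "rmse": rmse,
            "coverage_95": coverage, "weighted_corr": corr}


def _draws_at_obs(cube, obs, grid) -> np.ndarray:
    pix = grid.nearest_pixel(obs["x"].to_numpy(float), obs["y"].to_numpy(float))
    t = np.array([cube.years.index(int(y)) for y in obs["year"]])
    return cube.prevalence[:, pix, t]


# ---------------------------------------------------------------------------
# formulation comparison


def _fit_predict_formulation(formulation: str, train, test, covs, grid,
                             seed: int, n_draws: int, maxfev: int,
                             years, stack_cache: dict | None = None) -> np.ndarray:
    """Fit one formulation on the training fold, return draws at test obs."""
    use_stack = formulation.startswith("stacked")
    include_gp = "no GP" not in formulation
    if use_stack:
        if stack_cache is not None and "feats" in stack_cache:
            feats = stack_cache["feats"]
        else:
            feats = stacking.fit_child_learners(train, covs, grid, seed=seed)
            if stack_cache is not None:
                stack_cache["feats"] = feats
        F_train = feats.obs_features
        F_pix = feats.pixel_features(covs, grid, years=years)
        constraint = "simplex"
    elif formulation == "GP only":
        F_train = np.zeros((len(train), 0))
        F_pix = np.zeros((grid.n_pixels, len(years), 0))
        constraint = "linear"      # intercept only (added automatically)
    else:
        pix_tr = grid.nearest_pixel(train["x"].to_numpy(float),
                                    train["y"].to_numpy(float))
        t_tr = np.array([grid.year_index(y) for y in train["year"]])
        F_train = covs.values[pix_tr, t_tr, :]
        t_idx = [grid.year_index(y) for y in years]
        F_pix = covs.values[:, t_idx, :]
        constraint = "linear"
    post = geostat.fit_geostat(train, F_train, grid, constraint=constraint,
                               include_gp=include_gp, n_draws=n_draws,
                               seed=seed, maxfev=maxfev)
    cube = geostat.predict_pixel_draws(post, F_pix, grid, seed=seed, years=years)
    return _draws_at_obs(cube, test, grid)


def compare_formulations(obs: pd.DataFrame, covs, grid, seed: int = 0,
                         n_folds: int = 5, unit: str = "admin1",
                         n_draws: int = 100, maxfev: int = 80,
                         include_learners: bool = False) -> pd.DataFrame:
    """Out-of-sample comparison of the five model formulations.

    All formulations use identical spatially stratified folds; metrics are
    pooled over held-out observations across folds. A formulation whose fit
    fails is reported with NaN metrics while the others continue. With
    ``include_learners`` the three child learners are also scored on the same
    folds (rows labelled ``learner:<name>``).
    """
    folds = spatial_folds(obs, grid, n_folds, unit, seed)
    years = sorted(obs["year"].unique())
    rows = []
    pooled: dict = {f: ([], []) for f in FORMULATIONS}
    for f in range(n_folds):
        train = obs[folds != f].reset_index(drop=True)
        test = obs[folds == f].reset_index(drop=True)
        if len(test) == 0 or len(train) < 10:
            continue
        stack_cache: dict = {}
        for name in FORMULATIONS:
            try:
                draws = _fit_predict_formulation(
                    name, train, test, covs, grid, seed, n_draws, maxfev, years,
                    stack_cache)
                pooled[name][0].append(test)
                pooled[name][1].append(draws)
            except Exception as err:   # keep the other formulations running
                warnings.warn(f"formulation {name!r} failed on fold {f}: {err}")
        if include_learners:
            feats = stack_cache.get("feats") or stacking.fit_child_learners(
                train, covs, grid, seed=seed)
            pix_te = grid.nearest_pixel(test["x"].to_numpy(float),
                                        test["y"].to_numpy(float))
            t_te = np.array([grid.year_index(y) for y in test["year"]])
            X_te = covs.values[pix_te, t_te, :]
            for name in stacking.LEARNER_NAMES:
                region0 = next(iter(feats.full_models))
                pred = feats.full_models[region0][name].predict_logit(X_te)
                key = f"learner:{name}"
                pooled.setdefault(key, ([], []))
                pooled[key][0].append(test)
                pooled[key][1].append(
                    np.tile(1 / (1 + np.exp(-pred)), (1, 1)))
    for name, (tests, draws) in pooled.items():
        if not tests:
            rows.append({"level": "pixel", "formulation": name, "fold_id": None,
                         "n_obs": 0, "me": np.nan, "rmse": np.nan,
                         "coverage_95": np.nan, "weighted_corr": np.nan})
            continue
        all_test = pd.concat(tests, ignore_index=True)
        all_draws = np.concatenate(draws, axis=1)
        rows.append(cv_metrics(all_test, all_draws, seed=seed,
                               formulation=name))
    return pd.DataFrame(rows)
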