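"""Stacked-generalization covariates for the geostatistical model.

Three child learners are fitted to the cluster-level binomial data with the
raw covariates as predictors: an additive spline smoother ("GAM" flavour,
ridge-penalised logistic IRLS), boosted regression trees (xgboost, logistic
loss) and L1-penalised logistic regression (lasso, penalty by internal CV).
Each is fitted under five-fold cross-validation; the out-of-fold predictions
become the meta-model's design matrix (no leakage: the prediction for an
observation never saw that observation's fold), while full-data refits
provide the in-sample feature maps used when predicting on the pixel grid.
All features are stored on the logit scale, never centre-scaled, and clipped
to +/-12 so the simplex weighting downstream stays meaningful.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from sklearn.linear_model import LogisticRegression
from xgboost import XGBRegressor

from .util import clip_logit, expit, logit, rng_from_seed

LEARNER_NAMES = ("smoother", "boosted_trees", "lasso")


def _expand_binary(X, successes, trials, weight):
    """Two-row success/failure expansion with case weights."""
    y = np.concatenate([np.ones(len(X)), np.zeros(len(X))])
    Xe = np.vstack([X, X])
    w = np.concatenate([successes * weight, (trials - successes) * weight])
    keep = w > 0
    return Xe[keep], y[keep], w[keep]


class _ConstantModel:
    def __init__(self, logit_p): self.logit_p = float(logit_p)
    def predict_logit(self, X): return np.full(len(X), self.logit_p)


def _pooled_logit(successes, trials, weight):
    p = np.sum(successes * weight) / max(np.sum(trials * weight), 1e-12)
    return float(clip_logit(logit(np.clip(p, 1e-6, 1 - 1e-6))))


class SmootherLearner:
    """Additive B-spline logistic regression with a ridge penalty.

    Each covariate gets a 5-function cubic B-spline basis; coefficients are
    fitted by penalised IRLS on the weighted binomial deviance.
    """

    def __init__(self, df: int = 5, ridge: float = 1.0, max_iter: int = 50):
        self.df, self.ridge, self.max_iter = df, ridge, max_iter

    def _basis(self, X):
        cols = [np.ones((len(X), 1))]
        for j in range(X.shape[1]):
            x = X[:, j]
            lo, hi = self._ranges[j]
            u = np.clip((x - lo) / max(hi - lo, 1e-9), 0, 1)
            cols.append(np.column_stack(
                [BSpline(self._knots, np.eye(self._nspl)[i], 3)(u)
                 for i in range(self._nspl)]))
        return np.nan_to_num(np.hstack(cols))

    def fit(self, X, successes, trials, weight):
        X = np.asarray(X, float)
        self._ranges = [(X[:, j].min(), X[:, j].max()) for j in range(X.shape[1])]
        inner = max(self.df - 2, 2)
        self._knots = np.concatenate([[0.0] * 3, np.linspace(0, 1, inner), [1.0] * 3])
        self._nspl = len(self._knots) - 4
        B = self._basis(X)
        y = successes / np.maximum(trials, 1)
        w_tot = trials * weight
        pen = np.full(B.shape[1], self.ridge); pen[0] = 0.0
        beta = np.zeros(B.shape[1])
        beta[0] = _pooled_logit(successes, trials, weight)
        for _ in range(self.max_iter):
            eta = B @ beta
            mu = expit(eta)
            Wd = np.maximum(w_tot * mu * (1 - mu), 1e-10)
            zwork = eta + (y - mu) / np.maximum(mu * (1 - mu), 1e-10)
            A = (B * Wd[:, None]).T @ B + np.diag(pen)
            new = np.linalg.solve(A, (B * Wd[:, None]).T @ zwork)
            if np.max(np.abs(new - beta)) < 1e-8:
                beta = new
                break
            beta = new
        self.coef_ = beta
        return self

    def predict_logit(self, X):
        return clip_logit(self._basis(np.asarray(X, float)) @ self.coef_)


class BoostedTreesLearner:
    """Gradient-boosted trees with logistic loss (xgboost backend).

    Binomial observations enter as fractional labels C/N with case weight
    N * w, so cluster sample sizes act as natural weights.
    """

    def __init__(self, n_estimators: int = 200, max_depth: int = 3,
                 learning_rate: float = 0.1, seed: int = 0):
        self.params = dict(n_estimators=n_estimators, max_depth=max_depth,
                           learning_rate=learning_rate)
        self.seed = seed

    def fit(self, X, successes, trials, weight):
        y = successes / np.maximum(trials, 1)
        self.model_ = XGBRegressor(
            objective="binary:logistic", random_state=self.seed,
            n_jobs=1, verbosity=0, base_score=0.5, **self.params)
        self.model_.fit(np.asarray(X, float), y, sample_weight=trials * weight)
        return self

    def predict_logit(self, X):
        p = np.clip(self.model_.predict(np.asarray(X, float)), 1e-6, 1 - 1e-6)
        return clip_logit(logit(p))


class LassoLearner:
    """L1-penalised logistic regression; penalty strength by internal CV.

    The CV is done by hand on the weighted binomial log-loss: sklearn's CV
    wrapper does not pass case weights to its scorer, which matters here
    because binomial observations enter as weighted success/failure rows.
    """

    def __init__(self, n_penalties: int = 7, cv: int = 3, seed: int = 0):
        self.n_penalties, self.cv, self.seed = n_penalties, cv, seed

    def _fit_one(self, C, X, successes, trials, weight):
        Xe, y, w = _expand_binary(X, successes, trials, weight)
        model = LogisticRegression(l1_ratio=1.0, C=C, solver="saga",
                                   max_iter=2000, tol=1e-4,
                                   random_state=self.seed)
        # saga needs O(1) case weights; the CV over C absorbs the rescaling
        model.fit(Xe, y, sample_weight=w / w.mean())
        return model

    def fit(self, X, successes, trials, weight):
        X = np.asarray(X, float)
        successes = np.asarray(successes, float)
        trials = np.asarray(trials, float)
        weight = np.asarray(weight, float)
        if successes.sum() == 0 or (trials - successes).sum() == 0:
            self.model_ = _ConstantModel(_pooled_logit(successes, trials, weight))
            return self
        Cs = np.logspace(-2, 2, self.n_penalties)
        rng = np.random.default_rng(self.seed)
        folds = rng.integers(0, self.cv, len(X))
        losses = np.zeros(len(Cs))
        for f in range(self.cv):
            tr, va = folds != f, folds == f
            if successes[tr].sum() == 0 or (trials[tr] - successes[tr]).sum() == 0 \
                    or not va.any():
                continue
            for ci, C in enumerate(Cs):
                m = self._fit_one(C, X[tr], successes[tr], trials[tr], weight[tr])
                p = np.clip(expit(m.decision_function(X[va])), 1e-9, 1 - 1e-9)
                losses[ci] -= np.sum(weight[va] * (
                    successes[va] * np.log(p)
                    + (trials[va] - successes[va]) * np.log1p(-p)))
        best = Cs[int(np.argmin(losses))]
        self.model_ = self._fit_one(best, X, successes, trials, weight)
        return self

    def predict_logit(self, X):
        if isinstance(self.model_, _ConstantModel):
            return self.model_.predict_logit(X)
        return clip_logit(self.model_.decision_function(np.asarray(X, float)))


def _make_learners(seed: int) -> dict:
    return {"smoother": SmootherLearner(),
            "boosted_trees": BoostedTreesLearner(seed=seed),
            "lasso": LassoLearner(seed=seed)}


@dataclass
class StackedFeatures:
    """Out-of-sample features per observation + full-data fits for prediction."""
    obs_features: np.ndarray          # (n_obs, 3) logit scale
    fold_assignment: np.ndarray       # (n_obs,)
    learner_names: tuple
    full_models: dict                 # region -> {name: fitted learner}
    region_of_obs: np.ndarray

    def pixel_features(self, covs, grid, years=None) -> np.ndarray:
        return predict_pixel_features(self, covs, grid, years)


def _covariates_at_obs(obs: pd.DataFrame, covs, grid) -> np.ndarray:
    pix = grid.nearest_pixel(obs["x"].to_numpy(float), obs["y"].to_numpy(float))
    t = np.array([grid.year_index(y) for y in obs["year"]])
    return covs.values[pix, t, :], pix


def fit_child_learners(obs: pd.DataFrame, covs, grid, n_folds: int = 5,
                       seed: int = 0, per_region: bool = True) -> StackedFeatures:
    """Fit the three child learners with K-fold stacking.

    Folds are plain random observation-level folds (seeded). Learners see the
    binomial response (C of N) with observation weights as case weights.
    Degenerate responses (all C=0 or all C=N) fall back to a clipped constant
    prediction with a warning. With ``per_region`` each region present in the
    data gets its own set of fits (shared hyperparameters).
    """
    n = len(obs)
    if n < n_folds:
        raise ValueError("need at least n_folds observations")
    X, pix = _covariates_at_obs(obs, covs, grid)
    C = obs["C"].to_numpy(float)
    N = obs["N"].to_numpy(float)
    w = obs["weight"].to_numpy(float) if "weight" in obs.columns else np.ones(n)
    region = grid.region_id[pix] if per_region else np.zeros(n, int)

    rng = rng_from_seed(seed, "stack-folds")
    folds = np.tile(np.arange(n_folds), n // n_folds + 1)[:n]
    rng.shuffle(folds)

    obs_features = np.empty((n, len(LEARNER_NAMES)))
    full_models: dict = {}
    for r in np.unique(region):
        in_r = region == r
        idx_r = np.flatnonzero(in_r)
        degenerate = C[in_r].sum() == 0 or (N[in_r] - C[in_r]).sum() == 0
        if degenerate:
            warnings.warn(f"region {r}: degenerate response; learners fall back "
                          "to a clipped constant")
        for f in range(n_folds):
            train = idx_r[folds[idx_r] != f]
            test = idx_r[folds[idx_r] == f]
            if test.size == 0:
                continue
            for li, name in enumerate(LEARNER_NAMES):
                if degenerate or train.size == 0:
                    obs_features[test, li] = _pooled_logit(C[in_r], N[in_r], w[in_r])
                    continue
                model = _make_learners(seed)[name]
                model.fit(X[train], C[train], N[train], w[train])
                obs_features[test, li] = model.predict_logit(X[test])
        fitted = {}
        for name in LEARNER_NAMES:
            if degenerate:
                fitted[name] = _ConstantModel(_pooled_logit(C[in_r], N[in_r], w[in_r]))
            else:
                fitted[name] = _make_learners(seed)[name].fit(
                    X[in_r], C[in_r], N[in_r], w[in_r])
        full_models[int(r)] = fitted

    return StackedFeatures(clip_logit(obs_features), folds, LEARNER_NAMES,
                           full_models, region)


def predict_pixel_features(features: StackedFeatures, covs, grid,
                           years=None) -> np.ndarray:
    """In-sample (full-data) learner predictions on the pixel grid.

    Returns (P, T, 3) logit-scale maps, one per learner, clipped to +/-12.
    Pixels take the models of their own region; regions unseen at fit time
    use the first fitted region's models.
    """
    if covs.values.shape[2] == 0:
        raise ValueError("covariate stack is empty")
    years = tuple(years) if years is not None else grid.years
    t_idx = [grid.year_index(y) for y in years]
    P, T = grid.n_pixels, len(t_idx)
    out = np.empty((P, T, len(features.learner_names)))
    default_region = next(iter(features.full_models))
    for r in np.unique(grid.region_id):
        models = features.full_models.get(int(r),
                                          features.full_models[default_region])
        sel = grid.region_id == r
        for ti, t in enumerate(t_idx):
            Xp = covs.values[sel, t, :]
            for li, name in enumerate(features.learner_names):
                out[sel, ti, li] = models[name].predict_logit(Xp)
    return clip_logit(out)
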