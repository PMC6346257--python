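"""Bayesian hierarchical binomial space-time model.

Cluster counts are modelled as

    C_i ~ Binomial(N_i, p_i),
    logit(p_i) = X_i . beta + Z_i + eps_i,

where X_i are the (logit-scale) stacked sub-model predictions, beta lies on
the probability simplex (sum to 1, nonnegative) so it acts as a predictive
weighting of the sub-models, Z is a zero-mean Gaussian process whose
space-time covariance is the Kronecker product of an isotropic stationary
Matern kernel over pixels and an annual AR1 kernel over years, and eps is an
independent nugget. Weighted likelihood terms (w_i times the binomial
log-likelihood) carry the down-weighting of polygon pseudo-observations.

Inference is an INLA-like empirical-Bayes scheme: MAP over the covariance
hyperparameters with a Laplace approximation of the latent field, then
hyperparameters sampled from a Gaussian approximation at the mode and the
field from its conditional Gaussian. Candidate maps are produced by
conditional simulation of the residual field on the full grid (nugget
excluded from the surface by default: it is observation-level noise).

The latent residual is represented at *observation* level with covariance
sigma^2 * Matern(d_ij) * rho^|t_i - t_j| + tau^2 * I, which is the Kronecker
space-time covariance restricted to the observed pixel-years: observations
snapped to the same pixel-year share the field value exactly but keep
independent nuggets.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.special import gammaln, kv
from scipy.stats import norm

from .util import expit, rng_from_seed

__all__ = [
    "GPHyperParams", "GPPriors", "ModelPosterior", "PosteriorCube",
    "matern_cov", "ar1_corr", "st_covariance", "fit_geostat",
    "predict_pixel_draws", "laplace_latent",
]


# ---------------------------------------------------------------------------
# covariance kernels


@dataclass
class GPHyperParams:
    """Hyperparameters of the space-time residual process.

    spatial_range uses the sqrt(8*nu) convention: the Matern correlation at
    d = range is ~0.14 regardless of smoothness. Variances are on the logit
    scale. matern_smoothness defaults to 1 (the alpha = 2 SPDE convention in
    two dimensions).
    """
    spatial_range: float
    spatial_var: float
    ar1_rho: float
    nugget_var: float = 0.0
    matern_smoothness: float = 1.0

    def validate(self) -> None:
        if self.spatial_range <= 0:
            raise ValueError("spatial_range must be > 0")
        if self.spatial_var < 0 or self.nugget_var < 0:
            raise ValueError("variances must be >= 0")
        if not (-1.0 < self.ar1_rho < 1.0):
            raise ValueError("ar1_rho must lie strictly inside (-1, 1)")
        if self.matern_smoothness <= 0:
            raise ValueError("matern_smoothness must be > 0")


def matern_cov(d, var, spatial_range, nu: float = 1.0):
    """Matern covariance with the sqrt(8*nu)/range scaling.

    C(d) = var * 2^(1-nu)/Gamma(nu) * (kappa d)^nu * K_nu(kappa d),
    kappa = sqrt(8 nu)/range, with C(0) = var.
    """
    if spatial_range <= 0:
        raise ValueError("spatial_range must be > 0")
    if nu <= 0:
        raise ValueError("nu must be > 0")
    d = np.asarray(d, dtype=float)
    kd = np.sqrt(8.0 * nu) * d / spatial_range
    with np.errstate(invalid="ignore", over="ignore"):
        c = np.exp((1.0 - nu) * np.log(2.0) - gammaln(nu)
                   + nu * np.log(np.where(kd > 0, kd, 1.0))) * kv(nu, np.where(kd > 0, kd, 1.0))
    c = np.where(kd > 0, c, 1.0)
    c = np.where(np.isfinite(c), c, 0.0)  # kv underflows to 0 at large kd
    out = var * c
    return out if out.ndim else float(out)


def ar1_corr(years, rho: float) -> np.ndarray:
    """AR1 correlation matrix rho^|t-s| over a set of (integer) years."""
    years = np.asarray(years, dtype=float)
    lag = np.abs(years[:, None] - years[None, :])
    return np.power(float(rho), lag) if rho != 0 else (lag == 0).astype(float)


def st_covariance(pixel_coords, years, gp: GPHyperParams,
                  allow_large: bool = False) -> np.ndarray:
    """Dense Kronecker space-time covariance over pixel-years, year-major.

    Entry ((t, p), (s, q)) = rho^|t-s| * Matern(|x_p - x_q|). A memory guard
    refuses more than 20,000 pixel-years unless ``allow_large``.
    """
    gp.validate()
    coords = np.atleast_2d(np.asarray(pixel_coords, float))
    years = np.atleast_1d(years)
    n = coords.shape[0] * len(years)
    if n > 20_000 and not allow_large:
        raise MemoryError(
            f"{n} pixel-years would need a dense {n}x{n} matrix; "
            "pass allow_large=True to override")
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    Ks = matern_cov(d, gp.spatial_var, gp.spatial_range, gp.matern_smoothness)
    Kt = ar1_corr(years, gp.ar1_rho)
    return np.kron(Kt, Ks)


# ---------------------------------------------------------------------------
# priors and hyperparameter transforms


@dataclass
class GPPriors:
    """Weakly informative priors on the transformed hyperparameters.

    Log-normal(mu, sd^2) on range, sigma (field s.d.) and tau (nugget s.d.);
    the AR1 coefficient is transformed as r = logit((rho+1)/2) with a
    standard normal prior on r.
    """
    log_range_mu: float = 0.0
    log_range_sd: float = 1.5
    log_sigma_mu: float = 0.0
    log_sigma_sd: float = 1.5
    log_tau_mu: float = 0.0
    log_tau_sd: float = 1.5
    rho_t_mu: float = 0.0
    rho_t_sd: float = 1.0
    beta_linear_sd: float = 5.0   # Gaussian prior sd for unconstrained coefficients


_PARAM_NAMES = ("log_range", "log_sigma", "rho_t", "log_tau")


class _ThetaSpec:
    """Bookkeeping between the free optimisation vector and GPHyperParams."""

    def __init__(self, include_gp: bool, fixed: dict | None, priors: GPPriors,
                 smoothness: float):
        fixed = dict(fixed or {})
        self.include_gp = include_gp
        self.smoothness = smoothness
        self.fixed = fixed
        names = []
        if include_gp:
            if "spatial_range" not in fixed:
                names.append("log_range")
            if "spatial_var" not in fixed:
                names.append("log_sigma")
            if "ar1_rho" not in fixed:
                names.append("rho_t")
        if "nugget_var" not in fixed:
            names.append("log_tau")
        self.free_names = names
        self.priors = priors

    def to_params(self, x: np.ndarray) -> GPHyperParams:
        vals = dict(zip(self.free_names, x))
        rng_ = np.exp(vals["log_range"]) if "log_range" in vals else \
            self.fixed.get("spatial_range", 1.0)
        sig2 = np.exp(2 * vals["log_sigma"]) if "log_sigma" in vals else \
            self.fixed.get("spatial_var", 0.0)
        rho = (2 * expit(vals["rho_t"]) - 1) if "rho_t" in vals else \
            self.fixed.get("ar1_rho", 0.0)
        tau2 = np.exp(2 * vals["log_tau"]) if "log_tau" in vals else \
            self.fixed.get("nugget_var", 0.0)
        if not self.include_gp:
            sig2 = 0.0
        return GPHyperParams(max(rng_, 1e-6), sig2, float(np.clip(rho, -0.999, 0.999)),
                             tau2, self.smoothness)

    def log_prior(self, x: np.ndarray) -> float:
        p = self.priors
        lp = 0.0
        for name, v in zip(self.free_names, x):
            if name == "log_range":
                lp += norm.logpdf(v, p.log_range_mu, p.log_range_sd)
            elif name == "log_sigma":
                lp += norm.logpdf(v, p.log_sigma_mu, p.log_sigma_sd)
            elif name == "log_tau":
                lp += norm.logpdf(v, p.log_tau_mu, p.log_tau_sd)
            else:
                lp += norm.logpdf(v, p.rho_t_mu, p.rho_t_sd)
        return float(lp)

    def x0(self, grid_extent: float) -> np.ndarray:
        init = {"log_range": np.log(max(grid_extent / 4.0, 1.0)),
                "log_sigma": np.log(0.7),
                "rho_t": 1.0,
                "log_tau": np.log(0.3)}
        return np.array([init[n] for n in self.free_names])


# ---------------------------------------------------------------------------
# Laplace machinery


def _softmax(b_free: np.ndarray) -> np.ndarray:
    b = np.append(b_free, 0.0)
    b -= b.max()
    e = np.exp(b)
    return e / e.sum()


class _LatentModel:
    """Joint Laplace model over (coefficients b, residual field e)."""

    def __init__(self, F, C, N, w, constraint: str, beta_prior_sd: float = 5.0):
        self.F = np.asarray(F, float)
        self.C = np.asarray(C, float)
        self.N = np.asarray(N, float)
        self.w = np.asarray(w, float)
        self.constraint = constraint
        self.n = len(self.C)
        if constraint == "simplex":
            self.p_b = self.F.shape[1] - 1
        elif constraint == "linear":
            self.p_b = self.F.shape[1]
        elif constraint == "none":
            self.p_b = 0
        else:
            raise ValueError(f"unknown constraint {constraint!r}")
        self.beta_prior_prec = 1.0 / beta_prior_sd**2

    # mean structure -------------------------------------------------------
    def eta_mean(self, b):
        if self.constraint == "simplex":
            return self.F @ _softmax(b)
        if self.constraint == "linear":
            return self.F @ b
        return np.zeros(self.n)

    def beta_of(self, b):
        if self.constraint == "simplex":
            return _softmax(b)
        if self.constraint == "linear":
            return np.asarray(b, float).copy()
        return np.zeros(0)

    def _jacobian(self, b):
        """d eta_mean / d b, (n, p_b)."""
        if self.constraint == "simplex":
            pi = _softmax(b)
            base = self.F @ pi
            return pi[None, :-1] * (self.F[:, :-1] - base[:, None])
        if self.constraint == "linear":
            return self.F
        return np.zeros((self.n, 0))

    def _b_prior(self, b):
        """(neg-log-prior gradient, Hessian) for the coefficient block."""
        if self.constraint == "simplex":
            # Dirichlet(1) on the simplex via the additive logistic transform:
            # log p(b) = sum_k log pi_k(b) + const
            pi = _softmax(b)
            K = len(pi)
            grad = -(1.0 - K * pi[:-1])
            pf = pi[:-1]
            hess = K * (np.diag(pf) - np.outer(pf, pf))
            lp = float(np.sum(np.log(np.maximum(pi, 1e-300))))
            return lp, grad, hess
        if self.constraint == "linear":
            lp = -0.5 * self.beta_prior_prec * float(b @ b)
            return lp, self.beta_prior_prec * b, self.beta_prior_prec * np.eye(self.p_b)
        return 0.0, np.zeros(0), np.zeros((0, 0))

    def loglik(self, eta):
        p = expit(eta)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return float(np.sum(self.w * (self.C * np.log(p)
                                      + (self.N - self.C) * np.log1p(-p))))

    def lik_grad_w(self, eta):
        p = expit(eta)
        g = self.w * (self.C - self.N * p)
        W = np.maximum(self.w * self.N * p * (1 - p), 1e-10)
        return g, W


def _newton_mode(model: _LatentModel, Kinv, logdetK, u0=None, max_iter=40,
                 tol=1e-4):
    """Mode and Hessian of the joint negative log posterior over u = [b, e].

    Kinv/logdetK may be (None, None) when there is no residual field.
    Returns (u_hat, H, psi_min) with H the negative-log-posterior Hessian.
    """
    n, p_b = model.n, model.p_b
    n_e = 0 if Kinv is None else n
    dim = p_b + n_e
    u = np.zeros(dim) if u0 is None or len(u0) != dim else u0.copy()

    def psi(u):
        b, e = u[:p_b], u[p_b:]
        eta = model.eta_mean(b) + (e if n_e else 0.0)
        lp_b, _, _ = model._b_prior(b)
        val = -model.loglik(eta) - lp_b
        if n_e:
            val += 0.5 * float(e @ (Kinv @ e))
        return val

    cur = psi(u)
    H = None
    for _ in range(max_iter):
        b, e = u[:p_b], u[p_b:]
        eta = model.eta_mean(b) + (e if n_e else 0.0)
        g, W = model.lik_grad_w(eta)
        J = model._jacobian(b)
        _, gb_prior, Hb_prior = model._b_prior(b)
        grad = np.empty(dim)
        grad[:p_b] = -J.T @ g + gb_prior
        H = np.empty((dim, dim))
        H[:p_b, :p_b] = (J * W[:, None]).T @ J + Hb_prior
        if n_e:
            grad[p_b:] = -g + Kinv @ e
            H[:p_b, p_b:] = (J * W[:, None]).T
            H[p_b:, :p_b] = H[:p_b, p_b:].T
            H[p_b:, p_b:] = Kinv + np.diag(W)
        if np.max(np.abs(grad)) < tol:
            break
        try:
            cf = cho_factor(H, lower=True, check_finite=False)
            step = cho_solve(cf, grad, check_finite=False)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(H + 1e-6 * np.eye(dim), grad)
        # backtracking line search
        t = 1.0
        for _ls in range(30):
            new = u - t * step
            val = psi(new)
            if np.isfinite(val) and val <= cur - 1e-4 * t * float(grad @ step):
                u, cur = new, val
                break
            t *= 0.5
        else:
            break
    # final Hessian at the mode
    b, e = u[:p_b], u[p_b:]
    eta = model.eta_mean(b) + (e if n_e else 0.0)
    _, W = model.lik_grad_w(eta)
    J = model._jacobian(b)
    _, _, Hb_prior = model._b_prior(b)
    H = np.empty((dim, dim))
    H[:p_b, :p_b] = (J * W[:, None]).T @ J + Hb_prior
    if n_e:
        H[:p_b, p_b:] = (J * W[:, None]).T
        H[p_b:, :p_b] = H[:p_b, p_b:].T
        H[p_b:, p_b:] = Kinv + np.diag(W)
    return u, H, cur


def laplace_latent(C, N, weights, offset, K):
    """Laplace approximation of the latent field posterior with fixed mean.

    Model: C_i ~ Binomial(N_i, expit(offset_i + e_i)), e ~ N(0, K), weighted
    log-likelihood. Returns (posterior mean, posterior covariance).
    """
    C = np.asarray(C, float)
    n = len(C)
    model = _LatentModel(np.zeros((n, 0)), C, N, weights, "none")
    model.eta_mean = lambda b, off=np.asarray(offset, float): off
    cf = cho_factor(np.asarray(K, float) + 1e-10 * np.eye(n), lower=True)
    Kinv = cho_solve(cf, np.eye(n))
    u, H, _ = _newton_mode(model, Kinv, None)
    cov = np.linalg.inv(H)
    return u, cov


# ---------------------------------------------------------------------------
# posterior containers


@dataclass
class ModelPosterior:
    """Joint draws of (simplex weights, hyperparameters, latent residual)."""
    beta_draws: np.ndarray        # (D, K) — simplex rows when constraint="simplex"
    hyper_draws: list             # D GPHyperParams (shared within theta groups)
    field_draws: np.ndarray       # (D, n_obs) residual-plus-nugget at observations
    theta_group: np.ndarray       # (D,) index into unique_thetas
    unique_thetas: list
    obs_pixel: np.ndarray
    obs_year: np.ndarray
    years: tuple
    constraint: str
    include_gp: bool
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.beta_draws.shape[0]


@dataclass
class PosteriorCube:
    """Candidate maps: prevalence draws over (draw, pixel, year)."""
    prevalence: np.ndarray        # (D, P, T) in [0, 1]
    years: tuple
    indicator: str = ""
    raked: bool = False
    n_clipped: int = 0

    @property
    def n_draws(self) -> int:
        return self.prevalence.shape[0]

    def mean(self) -> np.ndarray:
        return self.prevalence.mean(axis=0)

    def interval(self, level: float = 0.95):
        a = (1 - level) / 2
        return (np.quantile(self.prevalence, a, axis=0),
                np.quantile(self.prevalence, 1 - a, axis=0))


# ---------------------------------------------------------------------------
# fitting


def _obs_arrays(obs, grid):
    if "x" in obs.columns and obs["x"].notna().all():
        pix = grid.nearest_pixel(obs["x"].to_numpy(float), obs["y"].to_numpy(float))
    elif "pixel" in obs.columns:
        pix = obs["pixel"].to_numpy(int)
    else:
        raise ValueError("observations need point coordinates (x, y); resample "
                         "polygon observations to pseudo-points first")
    years = obs["year"].to_numpy(int)
    w = obs["weight"].to_numpy(float) if "weight" in obs.columns else np.ones(len(obs))
    return pix, years, obs["C"].to_numpy(float), obs["N"].to_numpy(float), w


class _KernelCache:
    """Caches unique distances/lags so repeated kernel builds avoid the
    Bessel evaluation on every matrix entry (observations snap to pixel
    centers, so pairwise distances take few unique values)."""

    def __init__(self, coords, years):
        d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
        self.du, self.dinv = np.unique(np.round(d, 9).ravel(), return_inverse=True)
        lag = np.abs(np.asarray(years, float)[:, None] - np.asarray(years, float)[None, :])
        self.lu, self.linv = np.unique(lag.ravel(), return_inverse=True)
        self.n = len(years)
        self.shape = d.shape

    def correlation(self, gp: GPHyperParams) -> np.ndarray:
        cs = matern_cov(self.du, 1.0, gp.spatial_range, gp.matern_smoothness)
        ct = np.power(float(gp.ar1_rho), self.lu) if gp.ar1_rho != 0 \
            else (self.lu == 0).astype(float)
        return (cs[self.dinv] * ct[self.linv]).reshape(self.shape)

    def covariance(self, gp: GPHyperParams) -> np.ndarray:
        K = gp.spatial_var * self.correlation(gp) if gp.spatial_var > 0 \
            else np.zeros(self.shape)
        K[np.diag_indices_from(K)] += gp.nugget_var + 1e-8
        return K


def _obs_covariance(coords, years, gp: GPHyperParams):
    """sigma^2 * Matern(d) * rho^|dt| + tau^2 I at observation level."""
    return _KernelCache(np.asarray(coords, float), years).covariance(gp)


def fit_geostat(obs, features, grid, priors: GPPriors | None = None,
                constraint: str = "simplex", include_gp: bool = True,
                fixed: dict | None = None, n_draws: int = 250,
                n_theta: int | None = None, seed: int = 0,
                smoothness: float = 1.0, maxfev: int = 200) -> ModelPosterior:
    """Fit the binomial space-time model and return posterior draws.

    Parameters
    ----------
    obs : DataFrame with columns x, y, year, N, C and optional weight
        (polygon pseudo-observations carry fractional weights).
    features : (n_obs, K) logit-scale design matrix; with
        ``constraint="simplex"`` the K columns are the child-learner
        predictions and beta is constrained to the simplex. With
        ``constraint="linear"`` coefficients are unconstrained Gaussian
        (an intercept column is appended automatically).
    include_gp : include the Matern x AR1 residual field; ``False`` keeps
        only the nugget (the "without space-time error" formulations).
    fixed : optional dict pinning any of spatial_range, spatial_var,
        ar1_rho, nugget_var.
    """
    priors = priors or GPPriors()
    if len(obs) < 10:
        raise ValueError("refusing to fit with fewer than 10 observations")
    if len(obs) > 3000:
        raise MemoryError(
            f"{len(obs)} observations need a dense {len(obs)}^2 covariance; "
            "this engine targets desk-scale problems (<= 3000 obs). Reduce "
            "clusters per year, lower the polygon-resampling k, or fit per "
            "region.")
    pix, years, C, N, w = _obs_arrays(obs, grid)
    F = np.asarray(features, float)
    if F.ndim != 2 or F.shape[0] != len(obs):
        raise ValueError("features must be (n_obs, K)")
    if constraint == "linear":
        F = np.column_stack([np.ones(len(obs)), F])
    if not np.all(np.isfinite(F)):
        raise ValueError("features must be finite")
    coords = grid.pixel_centers[pix]

    model = _LatentModel(F, C, N, w, constraint, priors.beta_linear_sd)
    spec = _ThetaSpec(include_gp, fixed, priors, smoothness)
    extent = float(np.ptp(grid.pixel_centers, axis=0).max())
    kcache = _KernelCache(coords, years)

    warm: dict = {"u": None}

    def neg_log_evidence(x):
        gp = spec.to_params(np.asarray(x))
        try:
            has_field = gp.spatial_var > 0 or gp.nugget_var > 0
            if has_field:
                K = kcache.covariance(gp)
                cf = cho_factor(K, lower=True, check_finite=False)
                logdetK = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
                Kinv = cho_solve(cf, np.eye(len(C)), check_finite=False)
            else:
                Kinv, logdetK = None, 0.0
            u, H, psi_min = _newton_mode(model, Kinv, logdetK, u0=warm["u"])
            warm["u"] = u
            sign, logdetH = np.linalg.slogdet(H)
            if sign <= 0:
                return 1e10
            # Laplace: log q = -psi(u_hat) - 0.5 logdet K - 0.5 logdet H + prior
            val = psi_min + 0.5 * logdetK + 0.5 * logdetH - spec.log_prior(np.asarray(x))
            return float(val) if np.isfinite(val) else 1e10
        except (np.linalg.LinAlgError, ValueError):
            return 1e10

    if spec.free_names:
        x0 = spec.x0(extent)
        res = optimize.minimize(
            neg_log_evidence, x0, method="Nelder-Mead",
            options={"maxfev": maxfev, "xatol": 0.01, "fatol": 0.01})
        if not np.isfinite(res.fun) or res.fun >= 1e10:
            raise RuntimeError(
                f"hyperparameter optimisation failed to converge: {res.message}; "
                f"final objective {res.fun}")
        x_hat = res.x
        diag = {"opt_fun": float(res.fun), "opt_nfev": int(res.nfev),
                "opt_message": str(res.message)}
        # Gaussian approximation over theta from a finite-difference Hessian
        cov_theta = _theta_covariance(neg_log_evidence, x_hat)
    else:
        x_hat = np.zeros(0)
        diag = {"opt_fun": float(neg_log_evidence(x_hat))}
        cov_theta = np.zeros((0, 0))

    rng = rng_from_seed(seed, "geostat-draws")
    if n_theta is None:
        n_theta = min(25, n_draws) if spec.free_names else 1
    n_theta = max(1, min(n_theta, n_draws))
    if len(x_hat):
        Lth = np.linalg.cholesky(cov_theta + 1e-12 * np.eye(len(x_hat)))
        theta_samples = [x_hat] + [
            x_hat + Lth @ rng.standard_normal(len(x_hat))
            for _ in range(n_theta - 1)]
    else:
        theta_samples = [x_hat]

    counts = np.full(n_theta, n_draws // n_theta)
    counts[: n_draws % n_theta] += 1

    beta_draws = np.empty((n_draws, model.F.shape[1] if constraint != "none" else 0))
    field_draws = np.zeros((n_draws, len(C)))
    theta_group = np.empty(n_draws, int)
    hyper_draws: list = []
    unique_thetas: list = []
    pos = 0
    for gidx, (x_s, cnt) in enumerate(zip(theta_samples, counts)):
        gp = spec.to_params(np.asarray(x_s))
        unique_thetas.append(gp)
        has_field = gp.spatial_var > 0 or gp.nugget_var > 0
        if has_field:
            K = kcache.covariance(gp)
            cf = cho_factor(K, lower=True, check_finite=False)
            Kinv = cho_solve(cf, np.eye(len(C)), check_finite=False)
        else:
            Kinv = None
        u, H, _ = _newton_mode(model, Kinv, None, u0=warm["u"])
        L = cholesky(H + 1e-10 * np.eye(H.shape[0]), lower=True)
        for _ in range(cnt):
            z = rng.standard_normal(H.shape[0])
            # u ~ N(u_hat, H^{-1}):  u_hat + L^{-T} z
            ud = u + np.linalg.solve(L.T, z)
            beta_draws[pos] = model.beta_of(ud[:model.p_b])
            if Kinv is not None:
                field_draws[pos] = ud[model.p_b:]
            theta_group[pos] = gidx
            hyper_draws.append(gp)
            pos += 1

    return ModelPosterior(beta_draws, hyper_draws, field_draws, theta_group,
                          unique_thetas, pix, years,
                          tuple(sorted(set(int(y) for y in years))), constraint,
                          include_gp, diag)


def _theta_covariance(fun, x_hat, step: float = 0.1) -> np.ndarray:
    """Covariance from a central finite-difference Hessian, eigenvalue-floored."""
    k = len(x_hat)
    H = np.zeros((k, k))
    f0 = fun(x_hat)
    for i in range(k):
        ei = np.zeros(k); ei[i] = step
        H[i, i] = (fun(x_hat + ei) - 2 * f0 + fun(x_hat - ei)) / step**2
        for j in range(i + 1, k):
            ej = np.zeros(k); ej[j] = step
            H[i, j] = H[j, i] = (
                fun(x_hat + ei + ej) - fun(x_hat + ei - ej)
                - fun(x_hat - ei + ej) + fun(x_hat - ei - ej)) / (4 * step**2)
    vals, vecs = np.linalg.eigh(H)
    vals = np.clip(vals, 1e-2, None)   # floor guards FD noise / flat directions
    return (vecs / vals) @ vecs.T


# ---------------------------------------------------------------------------
# prediction


def predict_pixel_draws(posterior: ModelPosterior, pixel_features, grid,
                        seed: int = 0, years=None, indicator: str = "",
                        include_nugget: bool = False) -> PosteriorCube:
    """Candidate maps by conditional simulation of the residual field.

    For each draw the field on the grid is simulated unconditionally via the
    Kronecker factorisation (chol Matern over pixels x chol AR1 over years)
    and corrected by kriging against that draw's residual at the observed
    pixel-years, giving an exact draw from the conditional Gaussian. The
    nugget is excluded from the surface unless ``include_nugget``.
    """
    X = np.asarray(pixel_features, float)
    if years is None:
        years = tuple(y for y in grid.years if y <= max(posterior.years))
    years = tuple(int(y) for y in years)
    P, T = grid.n_pixels, len(years)
    if X.shape[:2] != (P, T):
        raise ValueError(f"pixel_features must be (P={P}, T={T}, K), got {X.shape}")
    D = posterior.n_draws
    if posterior.constraint != "none" and X.shape[2] + (
            1 if posterior.constraint == "linear" else 0) != posterior.beta_draws.shape[1]:
        raise ValueError("feature dimension does not match fitted coefficients")

    rng = rng_from_seed(seed, "predict")
    cube = np.empty((D, P, T))
    yr_arr = np.asarray(years, float)
    obs_pix, obs_yr = posterior.obs_pixel, posterior.obs_year
    n_obs = len(obs_pix)
    yr_index = {y: i for i, y in enumerate(years)}

    if posterior.constraint == "linear":
        Xd = np.concatenate([np.ones((P, T, 1)), X], axis=2)
    else:
        Xd = X

    d_grid = np.linalg.norm(grid.pixel_centers[:, None, :]
                            - grid.pixel_centers[None, :, :], axis=-1)
    kcache = _KernelCache(grid.pixel_centers[obs_pix], obs_yr)
    for gidx, gp in enumerate(posterior.unique_thetas):
        draws_g = np.flatnonzero(posterior.theta_group == gidx)
        if draws_g.size == 0:
            continue
        if posterior.include_gp and gp.spatial_var > 0:
            Rs = matern_cov(d_grid, 1.0, gp.spatial_range, gp.matern_smoothness)
            Ls = np.linalg.cholesky(Rs + 1e-8 * np.eye(P))
            Rt = ar1_corr(yr_arr, gp.ar1_rho)
            Lt = np.linalg.cholesky(Rt + 1e-10 * np.eye(T))
            sig = np.sqrt(gp.spatial_var)
            obs_t = np.array([yr_index[int(y)] for y in obs_yr])
            K_oo = kcache.covariance(gp)
            cf_oo = cho_factor(K_oo, lower=True)
            # field-only cross covariance grid-pixel-year x observation
            Rs_o = Rs[:, obs_pix]                      # (P, n)
            Rt_o = Rt[:, obs_t]                        # (T, n)
            tau = np.sqrt(gp.nugget_var)
            for di in draws_g:
                f_grid = sig * (Ls @ rng.standard_normal((P, T)) @ Lt.T)
                e_unc = f_grid[obs_pix, obs_t] + tau * rng.standard_normal(n_obs)
                alpha = cho_solve(cf_oo, posterior.field_draws[di] - e_unc)
                # sum_n Rs_o[p,n] * Rt_o[t,n] * alpha_n as two matmuls
                correction = gp.spatial_var * (Rs_o @ (Rt_o * alpha[None, :]).T)
                f_cond = f_grid + correction
                eta = np.einsum("ptk,k->pt", Xd, posterior.beta_draws[di]) + f_cond
                if include_nugget:
                    eta = eta + tau * rng.standard_normal((P, T))
                cube[di] = expit(eta)
        else:
            tau = np.sqrt(gp.nugget_var)
            for di in draws_g:
                eta = np.einsum("ptk,k->pt", Xd, posterior.beta_draws[di])
                if include_nugget and tau > 0:
                    eta = eta + tau * rng.standard_normal((P, T))
                cube[di] = expit(eta)

    return PosteriorCube(cube, years, indicator=indicator)
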