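"""Pre-model data adjustments.

Two concerns live here:

* **Seasonality of wasting.** Weight-for-height is acutely sensitive to the
  time of year a child is measured. A per-region additive model
  ``WHZ ~ f_per(month) + f_trend(time) + country offset`` is fitted with a
  12-month periodic cubic B-spline for the interview month and a smooth
  long-term spline across the study duration; individual WHZ values are then
  shifted by ``-f_per(month)`` so every measurement looks like it was taken
  on a mean day of the seasonal cycle. The periodic component is centered to
  integrate to zero over the cycle, so the adjustment does not move annual
  means. Country offsets are ridge-shrunk by default (random-effect-like).

* **Polygon observations.** Survey clusters located only to an admin polygon
  are resampled to 10,000 population-weighted coordinate locations, reduced
  by k-means to k centroid pseudo-points, and down-weighted in the
  likelihood by their cluster shares (weights sum to 1 per parent polygon,
  so one polygon contributes one observation's worth of information).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from sklearn.cluster import KMeans

from .util import rng_from_seed

MONTH_PERIOD = 12.0


# ---------------------------------------------------------------------------
# cyclic spline basis


def cyclic_bspline_design(x, n_basis: int = 6, period: float = MONTH_PERIOD,
                          degree: int = 3) -> np.ndarray:
    """Design matrix of periodic cubic B-splines on [0, period).

    Built from an extended uniform knot sequence with columns folded modulo
    ``n_basis``, the standard construction for periodic splines.
    """
    x = np.asarray(x, dtype=float) % period
    delta = period / n_basis
    knots = np.arange(-degree, n_basis + degree + 1) * delta
    n_splines = n_basis + degree
    design = np.zeros((len(x), n_basis))
    for i in range(n_splines):
        c = np.zeros(n_splines)
        c[i] = 1.0
        design[:, i % n_basis] += BSpline(knots, c, degree, extrapolate=False)(x)
    return np.nan_to_num(design)


def _trend_design(t, n_basis: int = 4) -> np.ndarray:
    """Plain cubic B-spline design over the observed time span."""
    t = np.asarray(t, dtype=float)
    lo, hi = t.min(), t.max()
    if hi - lo < 1e-9:
        return np.ones((len(t), 1))
    u = (t - lo) / (hi - lo)
    degree = 3
    inner = max(n_basis - degree + 1, 2)
    knots = np.concatenate([[0.0] * degree, np.linspace(0, 1, inner), [1.0] * degree])
    n_splines = len(knots) - degree - 1
    cols = [BSpline(knots, np.eye(n_splines)[i], degree)(u) for i in range(n_splines)]
    return np.nan_to_num(np.column_stack(cols))


@dataclass
class SeasonalModel:
    """Fitted per-region seasonal adjustment for WHZ."""
    region_id: int
    periodic_coefs: np.ndarray
    trend_coefs: np.ndarray
    country_effects: dict
    intercept: float
    fitted_scale: float           # residual s.d., z-score units
    n_basis: int = 6
    trend_span: tuple = (0.0, 1.0)
    _periodic_offset: float = 0.0

    def f_periodic(self, month) -> np.ndarray:
        """Centered periodic component at (1-based) interview month."""
        B = cyclic_bspline_design(np.asarray(month, float) - 1.0, self.n_basis)
        return B @ self.periodic_coefs - self._periodic_offset

    def to_frame(self) -> pd.DataFrame:
        rows = [("periodic", i, c) for i, c in enumerate(self.periodic_coefs)]
        rows += [("trend", i, c) for i, c in enumerate(self.trend_coefs)]
        rows += [("country", k, v) for k, v in self.country_effects.items()]
        rows += [("intercept", 0, self.intercept), ("scale", 0, self.fitted_scale)]
        out = pd.DataFrame(rows, columns=["component", "index", "value"])
        out.insert(0, "region_id", self.region_id)
        return out


def fit_seasonal_model(records: pd.DataFrame, whz_column: str = "whz",
                       n_basis: int = 6, country_ridge: float = 1.0,
                       spline_ridge: float = 1e-3) -> dict:
    """Fit the seasonal WHZ model per region.

    ``records`` needs columns region_id, country_id, interview_year,
    interview_month and the WHZ column. Returns {region_id: SeasonalModel}.
    ``country_ridge`` shrinks country offsets toward zero (random-effect
    flavour); set to 0 for plain fixed effects.
    """
    months = records["interview_month"]
    if months.isna().any():
        raise ValueError("records with missing interview month; drop them first")
    if ((months < 1) | (months > 12)).any():
        raise ValueError("interview_month must lie in 1..12")
    models = {}
    for region, g in records.groupby("region_id"):
        if g["interview_month"].nunique() < 2:
            raise ValueError(
                f"region {region}: seasonal model needs >= 2 distinct interview "
                "months; skip this region")
        y = g[whz_column].to_numpy(float)
        m = g["interview_month"].to_numpy(float) - 1.0
        t = g["interview_year"].to_numpy(float) + m / 12.0
        Bp = cyclic_bspline_design(m, n_basis)
        Bt = _trend_design(t)
        countries = np.sort(g["country_id"].unique())
        Dc = (g["country_id"].to_numpy()[:, None] == countries[None, :]).astype(float)
        X = np.column_stack([np.ones(len(g)), Bp, Bt, Dc])
        pen = np.concatenate([
            [0.0], np.full(n_basis, spline_ridge), np.full(Bt.shape[1], spline_ridge),
            np.full(len(countries), country_ridge)])
        XtX = X.T @ X + np.diag(pen)
        coef = np.linalg.solve(XtX, X.T @ y)
        k = 1
        per = coef[k:k + n_basis]; k += n_basis
        trend = coef[k:k + Bt.shape[1]]; k += Bt.shape[1]
        ceff = dict(zip((int(c) for c in countries), coef[k:]))
        resid = y - X @ coef
        # center the periodic component over a fine cycle grid
        grid = np.linspace(0, MONTH_PERIOD, 241, endpoint=False)
        offset = float((cyclic_bspline_design(grid, n_basis) @ per).mean())
        models[int(region)] = SeasonalModel(
            int(region), per, trend, ceff, float(coef[0]),
            float(resid.std()), n_basis, (float(t.min()), float(t.max())),
            offset)
    return models


def adjust_seasonality(records: pd.DataFrame, models: dict,
                       whz_column: str = "whz") -> pd.DataFrame:
    """Subtract the fitted periodic component from each WHZ measurement.

    Records lacking an interview month cannot be placed in the cycle and are
    dropped. Only the periodic spline is used: trend and country terms are
    untouched. Raises if a record's region has no fitted model.
    """
    rec = records[records["interview_month"].notna()].copy()
    adj = np.empty(len(rec))
    for region, g in rec.groupby("region_id"):
        if int(region) not in models:
            raise KeyError(f"no seasonal model fitted for region {region}")
        adj[rec.index.get_indexer(g.index)] = models[int(region)].f_periodic(
            g["interview_month"].to_numpy(float))
    rec[whz_column] = rec[whz_column].to_numpy(float) - adj
    return rec


# ---------------------------------------------------------------------------
# polygon resampling


def resample_polygon_obs(obs_row, grid, n_samples: int = 10_000,
                         k: int | None = None, seed: int = 0,
                         level: str | None = None) -> pd.DataFrame:
    """Resample one polygon observation to weighted pseudo-points.

    Draws ``n_samples`` locations inside the referenced admin unit with
    probability proportional to pixel population (uniform within a pixel),
    reduces them to ``k`` k-means centroids, and weights each centroid by its
    cluster share. Returns a PseudoObs frame with the parent's N, C, year and
    month and weights ``w_j`` summing to 1.
    """
    level = level or ("admin2" if not np.isnan(obs_row.get("admin_ref", np.nan))
                      else None)
    unit = int(obs_row["admin_ref"])
    pixels = grid.pixels_of_unit(level or "admin2", unit)
    t = grid.year_index(obs_row["year"])
    pop = grid.population[pixels, t].astype(float)
    pop[grid.mask[pixels]] = 0.0
    live = pop > 0
    if not live.any():
        raise ValueError(f"polygon unit {unit} has no populated pixels")
    pixels, pop = pixels[live], pop[live]
    if k is None:
        k = min(10, len(pixels))
    if k > n_samples:
        raise ValueError("k cannot exceed n_samples")

    rng = rng_from_seed(seed, "resample", int(obs_row["cluster_id"]))
    chosen = rng.choice(pixels, size=n_samples, p=pop / pop.sum())
    jitter = (rng.random((n_samples, 2)) - 0.5) * grid.pixel_size
    pts = grid.pixel_centers[chosen] + jitter

    km = KMeans(n_clusters=k, n_init=4,
                random_state=int(rng.integers(2**31))).fit(pts)
    counts = np.bincount(km.labels_, minlength=k)
    keep = counts > 0
    centroids = km.cluster_centers_[keep]
    weights = counts[keep] / n_samples

    return pd.DataFrame({
        "parent_obs_id": obs_row["cluster_id"],
        "cluster_id": [f"{obs_row['cluster_id']}_k{j}" for j in range(keep.sum())],
        "indicator": obs_row.get("indicator", ""),
        "year": int(obs_row["year"]),
        "month": obs_row.get("month", np.nan),
        "x": centroids[:, 0], "y": centroids[:, 1],
        "N": int(obs_row["N"]), "C": int(obs_row["C"]),
        "weight": float(obs_row.get("weight", 1.0)) * weights,
        "geometry_type": "pseudo_point",
    })


def expand_polygon_observations(obs: pd.DataFrame, grid, n_samples: int = 10_000,
                                k: int | None = None, seed: int = 0,
                                level: str = "admin2") -> pd.DataFrame:
    """Replace every polygon row of a ClusterObs table by its pseudo-points."""
    parts = []
    for _, row in obs.iterrows():
        if row.get("geometry_type") == "polygon":
            parts.append(resample_polygon_obs(row, grid, n_samples, k, seed, level))
        else:
            parts.append(row.to_frame().T)
    out = pd.concat(parts, ignore_index=True)
    for c in ("year", "N", "C"):
        out[c] = out[c].astype(int)
    out["weight"] = out["weight"].astype(float)
    out["x"] = out["x"].astype(float)
    out["y"] = out["y"].astype(float)
    return out
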