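"""Projections and WHO Global Nutrition Target attainment.

Annualized rates of change (AROC) are year-over-year differences of logit
prevalence; a recency-weighted average with weights w_t proportional to
(t - 2000)^gamma (gamma = 1 gives the linear scheme) is applied for ten
years beyond the final estimate to project 2025 prevalence on the logit
scale. Relative targets (e.g. a 40% stunting reduction) are resolved against
the population-weighted continental aggregate in 2010 so early-achieving
places are not penalised; fixed targets (e.g. wasting below 5%) apply as
given. Attainment probabilities are the fraction of candidate maps below the
target, at pixel level or for population-weighted admin aggregates.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .postestimation import AdminAggregate, aggregate_admin
from .util import expit, logit

# Fig-style pace/acceleration classes
STATUS_MET = "met"
STATUS_NON_DECREASING = "non-decreasing"
STATUS_BEHIND = "behind"
ACCELERATION_CAP = 4.0


@dataclass
class ProjectionConfig:
    """Recency weighting and horizon for the logit-AROC projection."""
    gamma: float = 1.0
    horizon: int = 10
    base_year: int = 2015
    first_year: int = 2000

    def weights(self, years) -> np.ndarray:
        """Normalised weights over change-years (t = first_year+1, ...)."""
        t = np.asarray(years, float)
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        w = np.power(t - self.first_year, self.gamma)
        s = w.sum()
        if s <= 0:
            raise ValueError("degenerate weight vector")
        return w / s


@dataclass
class TargetSpec:
    """A WHO GNT-style prevalence target for one indicator."""
    indicator: str
    target_type: str                      # "relative" or "fixed"
    reduction_fraction: float | None = None
    fixed_level: float | None = None
    resolved_target: float | None = None

    def require_resolved(self) -> float:
        if self.resolved_target is None:
            raise ValueError(f"target for {self.indicator} not resolved")
        return self.resolved_target


#: The 2025 WHO GNT relevant here: 40% stunting reduction relative to 2010,
#: wasting held below 5%, and (GNT-derived) 30% underweight reduction.
DEFAULT_TARGETS = {
    "stunting": TargetSpec("stunting", "relative", reduction_fraction=0.40),
    "wasting": TargetSpec("wasting", "fixed", fixed_level=0.05),
    "underweight": TargetSpec("underweight", "relative", reduction_fraction=0.30),
}


def annual_logit_aroc(p_series: np.ndarray, expected_length: int | None = 16) -> np.ndarray:
    """Adjacent-year changes of logit prevalence along the last axis.

    AROC_t = logit(p_t) - logit(p_{t-1}) for t = second year onward.
    ``expected_length`` guards the canonical 16-year (2000-2015) series;
    pass None to accept any length >= 2.
    """
    p = np.asarray(p_series, float)
    if expected_length is not None and p.shape[-1] != expected_length:
        raise ValueError(
            f"expected a series of length {expected_length}, got {p.shape[-1]}")
    if p.shape[-1] < 2:
        raise ValueError("need at least two years")
    lg = logit(p)
    return np.diff(lg, axis=-1)


def weighted_aroc(aroc: np.ndarray, change_years, config: ProjectionConfig | None = None
                  ) -> np.ndarray:
    """Recency-weighted mean AROC: sum_t w_t * AROC_t, w_t ~ (t - 2000)^gamma."""
    config = config or ProjectionConfig()
    w = config.weights(change_years)
    aroc = np.asarray(aroc, float)
    if aroc.shape[-1] != len(w):
        raise ValueError("aroc/year length mismatch")
    return aroc @ w


def project_prevalence(p_base, mean_aroc, horizon: int = 10):
    """logit-linear projection: p_future = expit(logit(p_base) + horizon*AROC)."""
    return expit(logit(p_base) + horizon * np.asarray(mean_aroc, float))


def resolve_targets(spec: TargetSpec, series: pd.DataFrame | None = None,
                    reference_year: int = 2010,
                    populations: dict | None = None) -> TargetSpec:
    """Resolve a target to an absolute prevalence.

    Relative targets need the national series at the reference year (2010)
    and per-country population weights; the resolved target is
    (1 - reduction) times the population-weighted continental aggregate.
    Fixed targets resolve to their fixed level.
    """
    out = TargetSpec(**spec.__dict__)
    if spec.target_type == "fixed":
        if spec.fixed_level is None:
            raise ValueError("fixed target needs fixed_level")
        out.resolved_target = float(spec.fixed_level)
        return out
    if spec.target_type != "relative":
        raise ValueError(f"unknown target type {spec.target_type!r}")
    if series is None:
        raise ValueError("relative target needs the national series")
    ref = series[series["year"] == reference_year]
    if ref.empty:
        raise ValueError(f"national series has no {reference_year} aggregate")
    if populations:
        w = np.array([populations[int(c)] for c in ref["country_id"]], float)
    else:
        w = np.ones(len(ref))
    agg = float(np.average(ref["prevalence"].to_numpy(float), weights=w))
    out.resolved_target = (1.0 - float(spec.reduction_fraction)) * agg
    return out


def pace_and_acceleration(p_series: np.ndarray, change_years, target: float,
                          config: ProjectionConfig | None = None) -> pd.DataFrame:
    """Progress metrics per pixel against a resolved target.

    achieved = -(weighted AROC) (positive when prevalence declines);
    required = max(0, (logit(p_base) - logit(target)) / horizon);
    pace_ratio = 100 * achieved / required (% of the required 2015-2025 pace
    achieved during 2000-2015); acceleration = required / achieved, capped
    into the ">400%" class above 4. Pixels already at or below the target are
    "met"; non-declining pixels are "non-decreasing".
    """
    config = config or ProjectionConfig()
    p = np.asarray(p_series, float)
    aroc = annual_logit_aroc(p, expected_length=None)
    achieved = -weighted_aroc(aroc, change_years, config)
    p_base = p[..., -1]
    required = np.maximum(
        (logit(p_base) - logit(target)) / config.horizon, 0.0)

    met = p_base <= target
    non_decreasing = (~met) & (achieved <= 0)
    status = np.where(met, STATUS_MET,
                      np.where(non_decreasing, STATUS_NON_DECREASING, STATUS_BEHIND))
    with np.errstate(divide="ignore", invalid="ignore"):
        pace = 100.0 * achieved / required
        accel = required / achieved
    pace = np.where(met | non_decreasing | (required == 0), np.nan, pace)
    accel = np.where(met | non_decreasing, np.nan,
                     np.minimum(accel, ACCELERATION_CAP))
    return pd.DataFrame({"achieved": np.ravel(achieved),
                         "required": np.ravel(required),
                         "pace_ratio": np.ravel(pace),
                         "acceleration": np.ravel(accel),
                         "status": np.ravel(status)})


def prob_target_met(cube, target: float, grid, year: int | None = None,
                    level: str | None = None,
                    from_pixel_probs: bool = False):
    """Probability the target is met: fraction of draws with p < target.

    Pixel level by default. With ``level`` set, admin-unit probabilities are
    computed from the units' population-weighted aggregate draws (or, behind
    the ``from_pixel_probs`` flag, as the population-weighted mean of pixel
    probabilities).
    """
    if cube.n_draws == 0:
        raise ValueError("no posterior draws")
    year = int(year) if year is not None else max(cube.years)
    t = cube.years.index(year)
    pix_prob = (cube.prevalence[:, :, t] < target).mean(axis=0)
    if level is None:
        return pix_prob
    if from_pixel_probs:
        ids = grid.country_id if level == "national" else getattr(grid, f"{level}_id")
        pop = grid.population[:, grid.year_index(year)]
        rows = []
        for u in np.unique(ids[ids >= 0]):
            sel = (ids == u) & ~grid.mask
            if sel.any():
                rows.append({"unit_id": int(u),
                             "probability": float(np.average(pix_prob[sel],
                                                             weights=pop[sel]))})
        return pix_prob, pd.DataFrame(rows)
    agg = aggregate_admin(cube, grid, level)
    ti = list(agg.years).index(year)
    unit_prob = (agg.draws[:, :, ti] < target).mean(axis=1)
    return pix_prob, pd.DataFrame({"unit_id": agg.unit_ids,
                                   "probability": unit_prob})
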