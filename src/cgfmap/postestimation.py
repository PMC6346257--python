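"""From candidate maps to calibrated, policy-ready estimates.

Candidate maps (posterior prevalence draws per pixel-year) are aggregated to
admin2 / admin1 / national level by population-weighted means over unmasked
pixels (year-matched population). National aggregates are then *raked* to an
external national prevalence series: per draw, the raking factor for a
country-year is the ratio target/estimate at the anchor years, linearly
interpolated across the full year span, and each pixel in the country-year
is multiplied by its factor (clipped at prevalence 1; clip events counted).
After raking, national re-aggregates reproduce the external series exactly
at anchor years whenever no clipping occurred, while within-country spatial
and temporal variation is preserved.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .geostat import PosteriorCube

ANCHOR_YEARS = (2000, 2005, 2010, 2016)


@dataclass
class AdminAggregate:
    """Population-weighted prevalence draws per admin unit and year."""
    level: str
    unit_ids: np.ndarray          # (U,)
    years: tuple
    draws: np.ndarray             # (U, D, T)
    population: np.ndarray        # (U, T)

    def mean(self) -> np.ndarray:
        return self.draws.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        lo = np.quantile(self.draws, 0.025, axis=1)
        hi = np.quantile(self.draws, 0.975, axis=1)
        mean = self.mean()
        rows = []
        for ui, u in enumerate(self.unit_ids):
            for ti, y in enumerate(self.years):
                rows.append({"level": self.level, "unit_id": int(u), "year": int(y),
                             "mean": mean[ui, ti], "lower": lo[ui, ti],
                             "upper": hi[ui, ti],
                             "population": self.population[ui, ti]})
        return pd.DataFrame(rows)


@dataclass
class RakingTable:
    """Per-draw multiplicative raking factors per country and year."""
    country_ids: np.ndarray       # (Uc,)
    years: tuple
    factors: np.ndarray           # (Uc, D, T), positive

    def median_factor(self) -> float:
        return float(np.median(self.factors))


def aggregate_admin(cube: PosteriorCube, grid, level: str = "national") -> AdminAggregate:
    """Population-weighted aggregation of candidate maps to an admin level."""
    ids = grid.country_id if level == "national" else getattr(grid, f"{level}_id")
    t_idx = np.array([grid.year_index(y) for y in cube.years])
    pop = grid.population[:, t_idx]                  # (P, T)
    live = ~grid.mask
    units, draws, pops = [], [], []
    for u in np.unique(ids[ids >= 0]):
        sel = (ids == u) & live
        if not sel.any():
            warnings.warn(f"{level} unit {u} fully masked; omitted")
            continue
        w = pop[sel]                                 # (p_u, T)
        tot = w.sum(axis=0)
        if np.any(tot <= 0):
            warnings.warn(f"{level} unit {u} has zero population; omitted")
            continue
        agg = np.einsum("dpt,pt->dt", cube.prevalence[:, sel, :], w) / tot
        units.append(int(u)); draws.append(agg); pops.append(tot)
    return AdminAggregate(level, np.array(units), cube.years,
                          np.stack(draws), np.stack(pops))


def compute_raking_factors(national: AdminAggregate, series: pd.DataFrame,
                           anchors=ANCHOR_YEARS) -> RakingTable:
    """Per-draw raking factors target/estimate, interpolated to all years.

    Anchor years beyond the modelled span contribute through linear
    interpolation of the *target*: e.g. with anchors (..., 2010, 2016) and a
    2000-2015 span, the 2015 target is interpolated between the 2010 and 2016
    series values, mirroring the GBD calibration convention. Factors are then
    linearly interpolated per draw across the full span.
    """
    years = np.asarray(national.years, float)
    last = years.max()
    anchors = np.asarray(sorted(anchors), float)
    # factor anchor years inside the modelled span (the final span year stands
    # in for any anchor beyond it)
    fy = sorted({float(np.clip(a, years.min(), last)) for a in anchors})
    factors = np.empty((len(national.unit_ids), national.draws.shape[1], len(years)))
    for ui, country in enumerate(national.unit_ids):
        s = series[series["country_id"] == country]
        if s.empty:
            raise ValueError(f"national series missing country {country}")
        sy = s["year"].to_numpy(float)
        sp = s["prevalence"].to_numpy(float)
        order = np.argsort(sy)
        targets = np.interp(fy, sy[order], sp[order])
        ti = [int(np.flatnonzero(years == y)[0]) for y in fy]
        est = national.draws[ui][:, ti]              # (D, len(fy))
        if np.any(est <= 0):
            raise ValueError(f"zero national estimate for country {country}")
        f_anchor = targets[None, :] / est            # (D, len(fy))
        for d in range(f_anchor.shape[0]):
            factors[ui, d] = np.interp(years, fy, f_anchor[d])
    return RakingTable(national.unit_ids.copy(), national.years, factors)


def apply_raking(cube: PosteriorCube, table: RakingTable, grid) -> PosteriorCube:
    """Multiply each pixel draw by its country-year raking factor (clipped at 1)."""
    out = cube.prevalence.copy()
    n_clip = 0
    cid = grid.country_id
    for ui, country in enumerate(table.country_ids):
        sel = cid == country
        f = table.factors[ui][:, None, :]            # (D, 1, T)
        raked = out[:, sel, :] * f
        n_clip += int((raked > 1.0).sum())
        out[:, sel, :] = np.minimum(raked, 1.0)
    missing = set(np.unique(cid[(cid >= 0) & ~grid.mask])) - set(
        int(c) for c in table.country_ids)
    if missing:
        raise ValueError(f"raking factors missing for countries {sorted(missing)}")
    return PosteriorCube(out, cube.years, cube.indicator, raked=True,
                         n_clipped=cube.n_clipped + n_clip)


def apply_mask(values: np.ndarray, grid, sentinel=np.nan) -> np.ndarray:
    """Set masked pixels to the missing-value sentinel (idempotent).

    ``values`` has pixels on its first axis (or its second for a draws cube).
    """
    out = np.array(values, float, copy=True)
    if out.shape[0] == grid.n_pixels:
        out[grid.mask] = sentinel
    elif out.ndim >= 2 and out.shape[1] == grid.n_pixels:
        out[:, grid.mask] = sentinel
    else:
        raise ValueError("no pixel axis of the expected length")
    return out


def pw_quantile_classes(values: np.ndarray, population: np.ndarray,
                        fractions=(0.10, 0.25), mask=None) -> dict:
    """Population-weighted lowest/highest tail classes of a pixel field.

    Pixels are sorted by value (ties broken by pixel index); the lowest class
    is the maximal prefix whose cumulative population does not exceed
    ``fraction`` of the total, and symmetrically for the highest class.
    Returns {fraction: (lowest_mask, highest_mask)} boolean arrays.
    """
    values = np.asarray(values, float)
    population = np.asarray(population, float)
    live = np.isfinite(values)
    if mask is not None:
        live &= ~np.asarray(mask, bool)
    tot = population[live].sum()
    if tot <= 0:
        raise ValueError("zero total population")
    idx = np.flatnonzero(live)
    order = idx[np.lexsort((idx, values[idx]))]      # value asc, index tie-break
    cum = np.cumsum(population[order])
    out = {}
    for frac in fractions:
        lowest = np.zeros(len(values), bool)
        lowest[order[cum <= frac * tot]] = True
        cum_hi = np.cumsum(population[order[::-1]])
        highest = np.zeros(len(values), bool)
        highest[order[::-1][cum_hi <= frac * tot]] = True
        out[frac] = (lowest, highest)
    return out
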