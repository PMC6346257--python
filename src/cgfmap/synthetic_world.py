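"""Synthetic study worlds with known truth.

Everything the mapping pipeline consumes is generated here with the
statistical structure the model assumes: a rectangular pixel grid carrying
nested admin partitions (region > country > admin1 > admin2), per-year
covariate and under-5 population layers, a true logit-prevalence surface
(covariate signal plus one draw of a Matern (x) AR1 Gaussian process),
cluster surveys with binomial counts at points and polygons plus per-child
anthropometry microdata, and a national "GBD-like" prevalence series at the
calibration anchor years for raking.

Coordinates are abstract planar pixel units (no map projection); distances
are Euclidean. Every generator is deterministic for a fixed seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter
from scipy.special import ndtri

from . import anthro
from .util import expit, logit, rng_from_seed


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# configuration & containers


@dataclass
class WorldConfig:
    """Study-world geometry, partitions, covariates and population.

    Defaults define the standard synthetic study conditions: a 20x20 grid of
    5x5-km-like pixels spanning 2000-2016 (the final year exists only to
    anchor the national calibration series; the analysis window is 2000-2015),
    two countries in one region, a 2x2 admin hierarchy per country, five
    covariates of which two are static, and a log-normal under-5 population
    surface with spatial and temporal smoothness.
    """
    n_rows: int = 20
    n_cols: int = 20
    pixel_size: float = 1.0
    n_regions: int = 1
    n_countries: int = 2
    n_admin1_per_country: int = 2
    n_admin2_per_admin1: int = 2
    years: tuple = tuple(range(2000, 2017))
    n_covariates: int = 5
    n_static: int = 2
    covariate_smoothness: float = 3.0   # Gaussian-filter sigma, pixels
    covariate_ar1: float = 0.9          # year-to-year correlation of dynamic layers
    pop_median: float = 200.0           # under-5 persons per pixel
    pop_log_sd: float = 0.8
    pop_smoothness: float = 2.0
    pop_growth: float = 0.01            # annual log growth
    mask_pop_threshold: float = 1.0     # pixels below this under-5 pop are masked

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump({**self.__dict__, "years": list(self.years)}, fh)

    @classmethod
    def from_yaml(cls, path) -> "WorldConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["years"] = tuple(raw["years"])
        return cls(**raw)


@dataclass
class PixelGrid:
    """The raster world: pixel centers, nested id layers, population, mask."""
    n_rows: int
    n_cols: int
    pixel_size: float
    pixel_centers: np.ndarray     # (P, 2) x, y
    region_id: np.ndarray         # (P,) int
    country_id: np.ndarray
    admin1_id: np.ndarray
    admin2_id: np.ndarray
    population: np.ndarray        # (P, T) under-5 persons
    years: tuple
    mask: np.ndarray              # (P,) bool, True = masked OUT

    @property
    def n_pixels(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def n_years(self) -> int:
        return len(self.years)

    def year_index(self, year) -> int:
        return self.years.index(int(year))

    def nearest_pixel(self, x, y) -> np.ndarray:
        """Index of the pixel whose center is nearest to (x, y) (vectorised)."""
        col = np.clip(np.rint(np.asarray(x) / self.pixel_size - 0.5), 0, self.n_cols - 1)
        row = np.clip(np.rint(np.asarray(y) / self.pixel_size - 0.5), 0, self.n_rows - 1)
        return (row * self.n_cols + col).astype(int)

    def pixels_of_unit(self, level: str, unit_id: int) -> np.ndarray:
        ids = getattr(self, f"{level}_id")
        return np.flatnonzero(ids == unit_id)

    def validate(self) -> None:
        for child, parent in (("admin2", "admin1"), ("admin1", "country"),
                              ("country", "region")):
            cid = getattr(self, f"{child}_id")
            pid = getattr(self, f"{parent}_id")
            for u in np.unique(cid):
                if len(np.unique(pid[cid == u])) != 1:
                    raise ConfigError(f"{child} unit {u} spans multiple {parent} units")
        if not np.all(np.isfinite(self.population)) or np.any(self.population < 0):
            raise ConfigError("population must be finite and nonnegative")
        if np.any(self.country_id[~self.mask] < 0):
            raise ConfigError("unmasked pixel without a country id")


@dataclass
class CovariateStack:
    """Per-pixel-per-year covariate layers; static layers repeat across years."""
    values: np.ndarray            # (P, T, n_cov)
    names: list
    is_static: np.ndarray         # (n_cov,) bool

    def at(self, pixel, year_idx) -> np.ndarray:
        return self.values[pixel, year_idx, :]


@dataclass
class TruthSurface:
    """True logit-prevalence surface and the parameters that generated it."""
    logit_prev: np.ndarray        # (P, T)
    gp_params_true: "object"
    beta_true: np.ndarray
    intercept_true: float
    seed: int

    @property
    def prevalence(self) -> np.ndarray:
        return expit(self.logit_prev)


@dataclass
class SurveyDesign:
    """Cluster-survey design: how many clusters, how big, where, and when.

    Defaults follow the standard study conditions: 150 clusters per survey
    year, ~24 children per cluster, a 60:40 point:polygon mix (the paper-like
    share of GPS-located clusters is a free choice), polygons referenced at
    the second administrative subdivision, and a 0.4 z-unit 12-month seasonal
    sinusoid injected into per-child WHZ.
    """
    clusters_per_year: int = 150
    mean_children: float = 24.0
    point_fraction: float = 0.6
    polygon_level: str = "admin2"
    seasonal_amplitude_whz: float = 0.4
    seasonal_phase: float = 0.0
    survey_years: tuple | None = None   # default: all world years up to 2015
    microdata: bool = True


# ---------------------------------------------------------------------------
# world construction


def _split_blocks(n_items: int, n_groups: int) -> list:
    """Contiguous near-equal partition of range(n_items) into n_groups."""
    return [list(a) for a in np.array_split(np.arange(n_items), n_groups)]


def make_world(config: WorldConfig, seed: int) -> tuple[PixelGrid, CovariateStack]:
    """Build the raster world and its covariate stack.

    Admin partitions are contiguous rectangles: regions are column slabs,
    countries split each region by rows, admin1 splits countries by columns
    and admin2 splits admin1 by rows, so nesting holds by construction.
    """
    cfg = config
    if cfg.n_rows < 4 or cfg.n_cols < 4:
        raise ConfigError("grid must be at least 4x4")
    if cfg.n_countries < 1 or cfg.n_regions < 1:
        raise ConfigError("need at least one region and one country")
    if cfg.n_regions > cfg.n_countries:
        raise ConfigError("cannot nest: more regions than countries")
    if cfg.n_regions > cfg.n_cols:
        raise ConfigError("cannot nest: more regions than grid columns")

    P = cfg.n_rows * cfg.n_cols
    T = len(cfg.years)
    rows, cols = np.divmod(np.arange(P), cfg.n_cols)
    centers = np.column_stack([(cols + 0.5) * cfg.pixel_size,
                               (rows + 0.5) * cfg.pixel_size])

    region_id = np.full(P, -1, int)
    country_id = np.full(P, -1, int)
    admin1_id = np.full(P, -1, int)
    admin2_id = np.full(P, -1, int)

    countries_per_region = [len(b) for b in _split_blocks(cfg.n_countries, cfg.n_regions)]
    col_slabs = _split_blocks(cfg.n_cols, cfg.n_regions)
    next_country = next_a1 = next_a2 = 0
    for r, (slab, n_ctry) in enumerate(zip(col_slabs, countries_per_region)):
        in_region = np.isin(cols, slab)
        region_id[in_region] = r
        row_blocks = _split_blocks(cfg.n_rows, n_ctry)
        if min(len(b) for b in row_blocks) < 1:
            raise ConfigError("cannot nest: too many countries for grid rows")
        for rb in row_blocks:
            in_ctry = in_region & np.isin(rows, rb)
            country_id[in_ctry] = next_country
            a1_cols = _split_blocks(len(slab), cfg.n_admin1_per_country)
            for a1b in a1_cols:
                in_a1 = in_ctry & np.isin(cols, [slab[j] for j in a1b])
                if not in_a1.any():
                    raise ConfigError("cannot nest: empty admin1 block")
                admin1_id[in_a1] = next_a1
                a2_rows = _split_blocks(len(rb), cfg.n_admin2_per_admin1)
                for a2b in a2_rows:
                    in_a2 = in_a1 & np.isin(rows, [rb[j] for j in a2b])
                    if not in_a2.any():
                        raise ConfigError("cannot nest: empty admin2 block")
                    admin2_id[in_a2] = next_a2
                    next_a2 += 1
                next_a1 += 1
            next_country += 1

    # covariates: smoothed white noise; dynamic layers evolve as AR1 in time
    rng = rng_from_seed(seed, "covariates")
    n_cov = cfg.n_covariates
    is_static = np.zeros(n_cov, bool)
    is_static[: cfg.n_static] = True
    values = np.empty((P, T, n_cov))
    shape2d = (cfg.n_rows, cfg.n_cols)

    def smooth_field() -> np.ndarray:
        f = gaussian_filter(rng.standard_normal(shape2d), cfg.covariate_smoothness,
                            mode="nearest")
        f -= f.mean()
        sd = f.std()
        return (f / sd if sd > 0 else f).ravel()

    for j in range(n_cov):
        base = smooth_field()
        if is_static[j]:
            values[:, :, j] = base[:, None]
        else:
            phi = cfg.covariate_ar1
            cur = base
            for t in range(T):
                if t > 0:
                    cur = phi * cur + np.sqrt(1 - phi**2) * smooth_field()
                values[:, t, j] = cur
    names = [f"cov_{j}{'_static' if is_static[j] else ''}" for j in range(n_cov)]

    # under-5 population: log-normal, spatially smooth, gentle growth
    prng = rng_from_seed(seed, "population")
    pop_field = gaussian_filter(prng.standard_normal(shape2d), cfg.pop_smoothness,
                                mode="nearest")
    pop_field = (pop_field - pop_field.mean()) / max(pop_field.std(), 1e-9)
    logpop_base = np.log(cfg.pop_median) + cfg.pop_log_sd * pop_field.ravel()
    t_idx = np.arange(T)
    population = np.exp(
        logpop_base[:, None]
        + cfg.pop_growth * t_idx[None, :]
        + 0.01 * prng.standard_normal((P, T))
    )

    mask = population.mean(axis=1) < cfg.mask_pop_threshold

    grid = PixelGrid(cfg.n_rows, cfg.n_cols, cfg.pixel_size, centers, region_id,
                     country_id, admin1_id, admin2_id, population, tuple(cfg.years),
                     mask)
    grid.validate()
    return grid, CovariateStack(values, names, is_static)


# ---------------------------------------------------------------------------
# truth surface


def simulate_truth(grid: PixelGrid, covs: CovariateStack, gp, beta,
                   seed: int, intercept: float = -1.0) -> TruthSurface:
    """One draw of the generative model: logit p = b0 + X beta + Matern(x)AR1 GP.

    The GP draw uses the exact Kronecker factorisation over the full grid
    (chol(Matern) over pixels, chol(AR1) over years), so its marginal
    variance and space-time correlation match ``gp`` exactly in distribution.
    """
    from .geostat import ar1_corr, matern_cov  # local import avoids cycle

    beta = np.asarray(beta, float)
    if beta.shape[0] != covs.values.shape[2]:
        raise ValueError("beta length must match number of covariates")
    P, T = grid.n_pixels, grid.n_years
    linear = intercept + covs.values @ beta        # (P, T)

    field = np.zeros((P, T))
    if gp.spatial_var > 0:
        d = np.linalg.norm(grid.pixel_centers[:, None, :]
                           - grid.pixel_centers[None, :, :], axis=-1)
        Ks = matern_cov(d, 1.0, gp.spatial_range, gp.matern_smoothness)
        Ks[np.diag_indices_from(Ks)] += 1e-8
        Ls = np.linalg.cholesky(Ks)
        Lt = np.linalg.cholesky(ar1_corr(np.asarray(grid.years), gp.ar1_rho)
                                + 1e-10 * np.eye(T))
        rng = rng_from_seed(seed, "truth-gp")
        field = np.sqrt(gp.spatial_var) * (Ls @ rng.standard_normal((P, T)) @ Lt.T)

    return TruthSurface(linear + field, gp, beta, intercept, seed)


# ---------------------------------------------------------------------------
# surveys


def _seasonal_shift(month, amplitude, phase):
    return amplitude * np.sin(2 * np.pi * (np.asarray(month) - 1) / 12.0 + phase)


def simulate_surveys(truth: TruthSurface, grid: PixelGrid, design: SurveyDesign,
                     seed: int, indicator: str = "stunting",
                     lms: pd.DataFrame | None = None):
    """Simulate cluster surveys against the truth surface.

    Returns ``(obs, children)``: ``obs`` is the ClusterObs table (point rows
    carry coordinates, polygon rows carry an admin reference with counts
    aggregated over the polygon's population-weighted prevalence), and
    ``children`` is per-child microdata whose measurements invert the shipped
    LMS tables so that re-scoring them recovers the intended z-scores. When
    the indicator is wasting, a 12-month sinusoid of the configured amplitude
    is injected into per-child WHZ; cluster counts are drawn from the annual
    truth surface.
    """
    rng = rng_from_seed(seed, "surveys", indicator)
    if lms is None:
        lms = anthro.make_synthetic_lms_tables()
    years = design.survey_years or tuple(y for y in grid.years if y <= 2015)
    unmasked = np.flatnonzero(~grid.mask)
    if unmasked.size == 0:
        raise ValueError("cannot place clusters: every pixel is masked")

    prev = truth.prevalence
    obs_rows, child_rows = [], []
    cluster_counter = 0
    poly_level = design.polygon_level
    for year in years:
        t = grid.year_index(year)
        w = grid.population[unmasked, t]
        w = w / w.sum()
        pix = rng.choice(unmasked, size=design.clusters_per_year, p=w)
        n_children = 1 + rng.poisson(max(design.mean_children - 1, 0),
                                     size=design.clusters_per_year)
        is_point = rng.random(design.clusters_per_year) < design.point_fraction
        months = rng.integers(1, 13, size=design.clusters_per_year)
        for j in range(design.clusters_per_year):
            cid = cluster_counter
            cluster_counter += 1
            px = pix[j]
            N = int(n_children[j])
            if is_point[j]:
                p_cl = prev[px, t]
                x, y = grid.pixel_centers[px]
                geom = {"geometry_type": "point", "x": x, "y": y,
                        "admin_ref": np.nan}
            else:
                unit = getattr(grid, f"{poly_level}_id")[px]
                members = grid.pixels_of_unit(poly_level, unit)
                members = members[~grid.mask[members]]
                pops = grid.population[members, t]
                p_cl = float(np.average(prev[members, t], weights=pops))
                geom = {"geometry_type": "polygon", "x": np.nan, "y": np.nan,
                        "admin_ref": int(unit)}
            C = int(rng.binomial(N, p_cl))
            obs_rows.append({"cluster_id": cid, "indicator": indicator,
                             "year": int(year), "month": int(months[j]),
                             "N": N, "C": C, "weight": 1.0, **geom})
            if design.microdata:
                mu = -2.0 - ndtri(np.clip(p_cl, 1e-12, 1 - 1e-12))
                z = mu + rng.standard_normal(N)
                if indicator == "wasting" and design.seasonal_amplitude_whz:
                    z = z + _seasonal_shift(months[j],
                                            design.seasonal_amplitude_whz,
                                            design.seasonal_phase)
                sexes = np.where(rng.random(N) < 0.5, "male", "female")
                ages = rng.integers(0, 60, size=N)
                child_rows.extend(_children_from_z(
                    cid, z, sexes, ages, int(year), int(months[j]),
                    indicator, lms))

    obs = pd.DataFrame(obs_rows)
    children = pd.DataFrame(child_rows)
    return obs, children


def _children_from_z(cid, z, sexes, ages, year, month, indicator, lms):
    """Invert LMS tables so each child's measurement carries the target z-score."""
    zind = anthro.ZSCORE_OF_INDICATOR[indicator]
    ref = lms.set_index(["indicator", "sex", "index"])
    rows = []
    for zi, sex, age in zip(z, sexes, ages):
        rec = {"cluster_id": cid, "sex": sex, "age_months": int(age),
               "interview_year": year, "interview_month": month,
               "survey_weight": 1.0}
        if zind == "HAZ":
            L, M, S = ref.loc[("HAZ", sex, int(age))]
            rec["height_cm"] = anthro.lms_inverse(zi, L, M, S)
            La, Ma, Sa = ref.loc[("WAZ", sex, int(age))]
            rec["weight_kg"] = float(Ma)
        elif zind == "WAZ":
            L, M, S = ref.loc[("WAZ", sex, int(age))]
            rec["weight_kg"] = anthro.lms_inverse(zi, L, M, S)
            Lh, Mh, Sh = ref.loc[("HAZ", sex, int(age))]
            rec["height_cm"] = float(Mh)
        else:  # WHZ: give the child its median height, set weight from the band
            Lh, Mh, Sh = ref.loc[("HAZ", sex, int(age))]
            h = float(np.clip(np.rint(Mh), 45, 120))
            rec["height_cm"] = h
            L, M, S = ref.loc[("WHZ", sex, int(h))]
            rec["weight_kg"] = anthro.lms_inverse(zi, L, M, S)
        rows.append(rec)
    return rows


# ---------------------------------------------------------------------------
# national series


def simulate_national_series(truth: TruthSurface, grid: PixelGrid,
                             perturbation_sd: float = 0.0, seed: int = 0,
                             years: tuple = (2000, 2005, 2010, 2016),
                             indicator: str = "stunting") -> pd.DataFrame:
    """Population-weighted national truth at the anchor years, optionally
    perturbed by logit-scale Gaussian noise (a GBD-like calibration series).

    With ``perturbation_sd = 0`` the series reproduces the truth aggregates
    exactly.
    """
    if perturbation_sd < 0:
        raise ValueError("perturbation_sd must be >= 0")
    rng = rng_from_seed(seed, "national", indicator)
    prev = truth.prevalence
    rows = []
    for year in years:
        if year not in grid.years:
            raise ValueError(f"anchor year {year} outside the simulated span")
        t = grid.year_index(year)
        for c in np.unique(grid.country_id[grid.country_id >= 0]):
            sel = (grid.country_id == c) & ~grid.mask
            pops = grid.population[sel, t]
            p = float(np.average(prev[sel, t], weights=pops))
            if perturbation_sd > 0:
                p = float(expit(logit(p) + perturbation_sd * rng.standard_normal()))
            rows.append({"country_id": int(c), "indicator": indicator,
                         "year": int(year), "prevalence": p})
    return pd.DataFrame(rows)
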