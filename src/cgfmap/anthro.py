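"""Child anthropometry: LMS z-scores, growth-failure classification, exclusion
rules, and collapse of microdata to cluster-level binomial observations.

The LMS method maps a skewed measurement distribution to Gaussian z-scores
through three reference parameters per (indicator, sex, index) stratum:
L (Box-Cox skewness power), M (median) and S (coefficient of variation):

    z = ((x / M)**L - 1) / (L * S),    with the L -> 0 limit  log(x / M) / S.

Growth failure is the strict threshold z < -2: stunting for height-for-age
(HAZ), wasting for weight-for-height (WHZ) and underweight for weight-for-age
(WAZ). HAZ/WAZ strata are indexed by completed age in months (0..59); WHZ
strata are indexed by height rounded to the nearest table band.

Reference tables ship as *synthetic* LMS tables (smooth, monotone growth
curves with realistic orders of magnitude); a CSV loader accepts externally
supplied tables in (indicator, sex, index, L, M, S) layout.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

INDICATORS = ("HAZ", "WHZ", "WAZ")
#: anthropometric indicator backing each prevalence indicator
ZSCORE_OF_INDICATOR = {"stunting": "HAZ", "wasting": "WHZ", "underweight": "WAZ"}

LMS_COLUMNS = ["indicator", "sex", "index", "L", "M", "S"]

_L_LIMIT = 1e-8


def lms_zscore(x, L, M, S):
    """LMS z-score of measurement ``x`` given reference (L, M, S).

    Vectorised over all arguments. Uses the log-limit form where |L| < 1e-8,
    so the function is continuous in L at 0.
    """
    x, L, M, S = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (x, L, M, S))
    )
    if np.any(x <= 0) or np.any(M <= 0) or np.any(S <= 0):
        raise ValueError("lms_zscore requires x > 0, M > 0, S > 0")
    ratio = x / M
    small = np.abs(L) < _L_LIMIT
    Lsafe = np.where(small, 1.0, L)
    z = np.where(
        small,
        np.log(ratio) / S,
        (np.power(ratio, Lsafe) - 1.0) / (Lsafe * S),
    )
    return z if z.ndim else float(z)


def lms_inverse(z, L, M, S):
    """Measurement with z-score ``z``: x = M*(1 + L*S*z)**(1/L), limit M*exp(S*z)."""
    z, L, M, S = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (z, L, M, S))
    )
    small = np.abs(L) < _L_LIMIT
    Lsafe = np.where(small, 1.0, L)
    base = np.maximum(1.0 + Lsafe * S * z, 1e-12)
    x = np.where(small, M * np.exp(S * z), M * np.power(base, 1.0 / Lsafe))
    return x if x.ndim else float(x)


def classify_cgf(z, threshold: float = -2.0):
    """True iff z is strictly below the threshold (ties are NOT afflicted)."""
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z must be finite")
    out = z < threshold
    return out if out.ndim else bool(out)


# ---------------------------------------------------------------------------
# synthetic reference tables


def make_synthetic_lms_tables() -> pd.DataFrame:
    """Synthetic LMS reference tables for HAZ, WHZ and WAZ.

    These are NOT the WHO 2006 growth standards: they are smooth synthetic
    curves with plausible magnitudes (birth length ~50 cm, birth weight
    ~3.3 kg, small sex offsets) sufficient to exercise the z-score machinery
    and the round-trip microdata simulation.
    """
    rows = []
    ages = np.arange(60)
    for sex, off in (("male", 1.0), ("female", 0.0)):
        # height-for-age: M in cm, grows 50 -> ~108
        m_h = 49.5 + off + 58.0 * (ages / 59.0) ** 0.75
        s_h = 0.035 + 0.002 * (ages / 59.0)
        for a, m, s in zip(ages, m_h, s_h):
            rows.append(("HAZ", sex, int(a), 1.0, float(m), float(s)))
        # weight-for-age: M in kg
        m_w = 3.2 + 0.1 * off + 13.0 * (ages / 59.0) ** 0.9
        for a, m in zip(ages, m_w):
            rows.append(("WAZ", sex, int(a), 0.2, float(m), 0.12))
    # weight-for-height, indexed by height band (cm, 1-cm bands)
    heights = np.arange(45, 121)
    for sex, off in (("male", 0.1), ("female", 0.0)):
        m_wh = 2.3 + off + 0.185 * (heights - 45.0) ** 1.12
        for h, m in zip(heights, m_wh):
            rows.append(("WHZ", sex, int(h), -0.35, float(m), 0.085))
    return pd.DataFrame(rows, columns=LMS_COLUMNS)


def load_lms_table(path) -> pd.DataFrame:
    """Load an external LMS reference table in (indicator, sex, index, L, M, S) layout."""
    tab = pd.read_csv(path)
    missing = set(LMS_COLUMNS) - set(tab.columns)
    if missing:
        raise ValueError(f"LMS table missing columns: {sorted(missing)}")
    if (tab["M"] <= 0).any() or (tab["S"] <= 0).any():
        raise ValueError("LMS table requires M > 0 and S > 0")
    return tab[LMS_COLUMNS].copy()


# ---------------------------------------------------------------------------
# exclusions


EXCLUSION_RULES = (
    "missing_sex",
    "missing_age",
    "age_out_of_range",
    "nonpositive_measurement",
    "missing_interview_date",
    "polygon_singleton_cluster",
)


def apply_exclusions(records: pd.DataFrame, cluster_geometry: dict | None = None,
                     require_interview_date: bool = False,
                     flag_abs_z: float | None = None):
    """Apply record-level exclusion rules; returns (clean records, log).

    Rules: missing/invalid sex; missing age or age outside [0, 59] months;
    nonpositive height/weight; optionally missing interview month; and
    polygon survey clusters containing a single child (``cluster_geometry``
    maps cluster_id -> "point"/"polygon"). ``flag_abs_z`` is an optional
    biologically-implausible flag threshold applied later at scoring time;
    it defaults to off and is recorded here only for the log schema.
    The operation is idempotent.
    """
    rec = records.copy()
    counts = dict.fromkeys(EXCLUSION_RULES, 0)

    bad_sex = ~rec["sex"].isin(["male", "female"])
    counts["missing_sex"] = int(bad_sex.sum())
    rec = rec[~bad_sex]

    age = pd.to_numeric(rec["age_months"], errors="coerce")
    bad_age = age.isna()
    counts["missing_age"] = int(bad_age.sum())
    out_age = ~bad_age & ((age < 0) | (age > 59))
    counts["age_out_of_range"] = int(out_age.sum())
    rec = rec[~(bad_age | out_age)]

    meas_cols = [c for c in ("height_cm", "weight_kg") if c in rec.columns]
    bad_meas = np.zeros(len(rec), dtype=bool)
    for c in meas_cols:
        v = pd.to_numeric(rec[c], errors="coerce")
        bad_meas |= (v <= 0).fillna(False).to_numpy()
    counts["nonpositive_measurement"] = int(bad_meas.sum())
    rec = rec[~bad_meas]

    if require_interview_date:
        bad_date = rec["interview_month"].isna()
        counts["missing_interview_date"] = int(bad_date.sum())
        rec = rec[~bad_date]

    if cluster_geometry:
        sizes = rec.groupby("cluster_id").size()
        singleton_poly = {
            cid for cid, n in sizes.items()
            if n == 1 and cluster_geometry.get(cid) == "polygon"
        }
        drop = rec["cluster_id"].isin(singleton_poly)
        counts["polygon_singleton_cluster"] = int(drop.sum())
        rec = rec[~drop]

    log = pd.DataFrame(
        {"rule": list(counts), "n_excluded": [counts[r] for r in counts]}
    )
    return rec.reset_index(drop=True), log


# ---------------------------------------------------------------------------
# collapse


def _score_records(records: pd.DataFrame, lms: pd.DataFrame, indicator: str) -> pd.Series:
    """z-score every record for one prevalence indicator via LMS table lookup."""
    zind = ZSCORE_OF_INDICATOR.get(indicator, indicator)
    if zind not in INDICATORS:
        raise ValueError(f"unknown indicator {indicator!r}")
    tab = lms[lms["indicator"] == zind]
    if tab.empty:
        raise KeyError(f"LMS table has no rows for {zind}")
    if zind == "HAZ":
        x = records["height_cm"].to_numpy(float)
        idx = records["age_months"].to_numpy(int)
    elif zind == "WAZ":
        x = records["weight_kg"].to_numpy(float)
        idx = records["age_months"].to_numpy(int)
    else:  # WHZ: index by height rounded to nearest band
        x = records["weight_kg"].to_numpy(float)
        idx = np.rint(records["height_cm"].to_numpy(float)).astype(int)
    key = pd.MultiIndex.from_arrays([records["sex"].to_numpy(), idx])
    ref = tab.set_index(["sex", "index"])
    missing = ~key.isin(ref.index)
    if missing.any():
        sex_m, idx_m = key[missing][0]
        raise KeyError(
            f"LMS lookup miss for {zind}: no stratum (sex={sex_m!r}, index={idx_m})"
        )
    sub = ref.loc[key]
    return pd.Series(
        lms_zscore(x, sub["L"].to_numpy(), sub["M"].to_numpy(), sub["S"].to_numpy()),
        index=records.index,
    )


def collapse_to_cluster(records: pd.DataFrame, lms: pd.DataFrame, indicator: str,
                        threshold: float = -2.0, z_column: str | None = None,
                        flag_abs_z: float | None = None) -> pd.DataFrame:
    """Collapse child microdata to per-cluster binomial observations.

    Per cluster: N = number of scoreable children, C = number with z strictly
    below ``threshold``; interview month is the modal month. Clusters with no
    scoreable children are omitted. ``z_column`` uses precomputed z-scores
    (e.g. seasonality-adjusted WHZ) instead of the LMS lookup. ``flag_abs_z``
    optionally drops biologically implausible |z| before counting (off by
    default).
    """
    if records.empty:
        return pd.DataFrame(columns=["cluster_id", "indicator", "year", "month", "N", "C"])
    if z_column is not None:
        z = pd.to_numeric(records[z_column], errors="coerce")
    else:
        z = _score_records(records, lms, indicator)
    keep = z.notna()
    if flag_abs_z is not None:
        keep &= z.abs() <= flag_abs_z
    rec = records.loc[keep].copy()
    rec["_z"] = z[keep]
    if rec.empty:
        return pd.DataFrame(columns=["cluster_id", "indicator", "year", "month", "N", "C"])

    def _one(g: pd.DataFrame) -> pd.Series:
        month = g["interview_month"].mode()
        return pd.Series({
            "year": int(g["interview_year"].iloc[0]),
            "month": int(month.iloc[0]) if len(month) else np.nan,
            "N": int(len(g)),
            "C": int((g["_z"] < threshold).sum()),
        })

    out = rec.groupby("cluster_id").apply(_one, include_groups=False).reset_index()
    out.insert(1, "indicator", indicator)
    return out
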