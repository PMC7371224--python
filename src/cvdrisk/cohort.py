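"""Survey-cohort pipeline: variable derivation, complete-case filtering,
risk scoring, and the stratified distribution / flag / eligibility tables.

The cohort is a pandas DataFrame in the cohort CSV dialect (one row per
participant).  Scoring proceeds in fixed stages:

1. derive analysis variables — final BP as the mean of the two seated
   readings (single-reading fallback flagged), final BMI from direct entry
   or weight/height²;
2. complete-case filtering — drop records missing any chart input
   (smoking, SBP, DBP, BMI), records beyond the chart's age range under the
   exclude policy, and (by default) records reporting prior CVD, counting
   each exclusion once under the first applicable reason;
3. chart lookup and 5-level categorisation per record;
4. clinical threshold flags — hypertension (BP >= 140/90, OR semantics
   across SBP/DBP), severe hypertension (>= 160/100), hyperglycaemia
   (random glucose >= 11.1 mmol/L), overweight/obesity (BMI >= 25 by
   default).

Tables are crude (unweighted) proportions: survey-design weighting is out
of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from . import chart as chart_mod
from .chart import AgePolicy, RiskChart, CATEGORY_ORDER
from .errors import DomainError
from .stats import CiMethod, proportion_ci, sex_comparison_test
from ._util import round_half_up

COHORT_COLUMNS = [
    "id", "age", "sex", "smoker", "sbp1", "sbp2", "dbp1", "dbp2",
    "height_cm", "weight_kg", "bmi", "glucose", "residence", "prior_cvd",
]

# Plausibility guards for provided (non-missing) values; violations are
# data errors, reported with the offending record ids.
GUARDS: dict[str, tuple[float, float]] = {
    "age": (40, 120),
    "sbp1": chart_mod.SBP_GUARD, "sbp2": chart_mod.SBP_GUARD,
    "dbp1": (30.0, 200.0), "dbp2": (30.0, 200.0),
    "height_cm": (100.0, 250.0), "weight_kg": (20.0, 300.0),
    "bmi": chart_mod.BMI_GUARD,
    "glucose": (1.0, 50.0),
}

HTN_SBP, HTN_DBP = 140.0, 90.0
SEVERE_SBP, SEVERE_DBP = 160.0, 100.0
HYPERGLYCAEMIA_MMOL_L = 11.1

Stratum = Literal["total", "men", "women"]
STRATA: tuple[Stratum, ...] = ("total", "men", "women")

# First-applicable-reason precedence for exclusion accounting.
EXCLUSION_REASONS = ("prior_cvd", "age_policy", "smoking", "sbp", "dbp", "bmi")


@dataclass
class PipelineConfig:
    """Tunable analysis choices for scoring a cohort."""

    age_policy: AgePolicy = "exclude"
    drop_prior_cvd: bool = True
    overweight_bmi_threshold: float = 25.0
    ci_method: CiMethod = "wilson"
    ci_level: float = 0.95


@dataclass
class ExclusionReport:
    """Accounting of the complete-case filter; reasons are non-overlapping
    (each dropped record counted once under the first applicable reason)."""

    input_n: int
    retained_n: int
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def excluded_n(self) -> int:
        return sum(self.counts.values())

    def to_dict(self) -> dict:
        return {"input_n": self.input_n, "retained_n": self.retained_n,
                "excluded": dict(self.counts)}


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV; empty fields are missing values."""
    df = pd.read_csv(path, dtype={"id": str}, float_precision="round_trip")
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise DomainError(f"cohort CSV missing columns {sorted(missing)}")
    validate_cohort(df)
    return df


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=COHORT_COLUMNS)


def validate_cohort(df: pd.DataFrame) -> None:
    """Check id uniqueness and plausibility guards on provided values."""
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].head(3).tolist()
        raise DomainError(f"duplicate record ids, e.g. {dupes}")
    bad_sex = df.loc[~df["sex"].isin(list(chart_mod.SEXES)), "id"]
    if len(bad_sex):
        raise DomainError(f"invalid sex for records {bad_sex.head(3).tolist()}")
    for col, (lo, hi) in GUARDS.items():
        values = pd.to_numeric(df[col], errors="coerce")
        bad = df.loc[values.notna() & ~values.between(lo, hi), "id"]
        if len(bad):
            raise DomainError(
                f"{col} outside plausibility guard [{lo}, {hi}] for records "
                f"{bad.head(3).tolist()}"
            )


def mean_bp(reading1: float, reading2: float) -> tuple[float, bool]:
    """Final BP as the mean of two readings.

    Returns ``(value, single_reading)``: with one reading missing the
    available reading is used and flagged; with both missing the result is
    NaN (a missing value, not an error).
    """
    r1_ok = reading1 is not None and not math.isnan(reading1)
    r2_ok = reading2 is not None and not math.isnan(reading2)
    if r1_ok and r2_ok:
        return (reading1 + reading2) / 2.0, False
    if r1_ok:
        return reading1, True
    if r2_ok:
        return reading2, True
    return math.nan, False


def compute_bmi(height_cm: float, weight_kg: float) -> float:
    """BMI = weight (kg) / height (m) squared."""
    if height_cm <= 0 or weight_kg <= 0:
        raise DomainError(f"nonpositive height/weight ({height_cm}, {weight_kg})")
    return weight_kg / (height_cm / 100.0) ** 2


def derive_variables(df: pd.DataFrame) -> pd.DataFrame:
    """Add sbp_mean, dbp_mean, bmi_final and single-reading provenance flags."""
    out = df.copy()
    for side in ("sbp", "dbp"):
        r1 = pd.to_numeric(out[f"{side}1"], errors="coerce")
        r2 = pd.to_numeric(out[f"{side}2"], errors="coerce")
        mean = (r1 + r2) / 2.0
        single = r1.isna() ^ r2.isna()
        out[f"{side}_mean"] = mean.where(~single, r1.fillna(r2))
        out[f"{side}_single_reading"] = single
    direct = pd.to_numeric(out["bmi"], errors="coerce")
    height = pd.to_numeric(out["height_cm"], errors="coerce")
    weight = pd.to_numeric(out["weight_kg"], errors="coerce")
    computed = weight / (height / 100.0) ** 2
    out["bmi_final"] = direct.where(direct.notna(), computed)
    return out


def _missing_bool(series: pd.Series) -> pd.Series:
    """Parse a 0/1 column with missing values to pandas nullable boolean."""
    numeric = pd.to_numeric(series, errors="coerce")
    return pd.Series(numeric, dtype="Float64").astype("boolean")


def complete_case_filter(
    df: pd.DataFrame, config: PipelineConfig | None = None
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop records that cannot be scored, with non-overlapping accounting.

    Exclusion reasons, in precedence order: prior CVD (if configured),
    age beyond the chart under the exclude policy, then missing smoking,
    SBP, DBP, BMI.  Input must already carry the derived variables
    (see :func:`derive_variables`).
    """
    config = config or PipelineConfig()
    work = df if "sbp_mean" in df.columns else derive_variables(df)
    prior = _missing_bool(work["prior_cvd"])
    smoker = _missing_bool(work["smoker"])
    age = pd.to_numeric(work["age"], errors="coerce")

    reason_masks = {
        "prior_cvd": (prior.fillna(False).to_numpy(dtype=bool)
                      if config.drop_prior_cvd
                      else np.zeros(len(work), dtype=bool)),
        # missing age is unchartable under either policy
        "age_policy": (age.isna() | (
            (age >= chart_mod.AGE_BANDS[-1].upper)
            if config.age_policy == "exclude"
            else False)).to_numpy(dtype=bool),
        "smoking": smoker.isna().to_numpy(dtype=bool),
        "sbp": work["sbp_mean"].isna().to_numpy(dtype=bool),
        "dbp": work["dbp_mean"].isna().to_numpy(dtype=bool),
        "bmi": work["bmi_final"].isna().to_numpy(dtype=bool),
    }
    assigned = np.zeros(len(work), dtype=bool)
    counts: dict[str, int] = {}
    for reason in EXCLUSION_REASONS:
        hit = reason_masks[reason] & ~assigned
        counts[reason] = int(hit.sum())
        assigned |= reason_masks[reason]
    retained = work.loc[~assigned].copy()
    report = ExclusionReport(input_n=len(work), retained_n=len(retained),
                             counts=counts)
    return retained, report


def derive_flags(df: pd.DataFrame,
                 config: PipelineConfig | None = None) -> pd.DataFrame:
    """Add clinical threshold flags as nullable booleans.

    A flag is missing (pd.NA) — never silently false — when its inputs are
    missing.
    """
    config = config or PipelineConfig()
    out = df.copy()
    sbp, dbp = out["sbp_mean"], out["dbp_mean"]
    bp_known = sbp.notna() & dbp.notna()
    htn = (sbp >= HTN_SBP) | (dbp >= HTN_DBP)
    severe = (sbp >= SEVERE_SBP) | (dbp >= SEVERE_DBP)
    out["htn"] = pd.Series(htn, dtype="boolean").mask(~bp_known)
    out["severe_htn"] = pd.Series(severe, dtype="boolean").mask(~bp_known)
    glucose = pd.to_numeric(out["glucose"], errors="coerce")
    out["hyperglycaemia"] = pd.Series(
        glucose >= HYPERGLYCAEMIA_MMOL_L, dtype="boolean").mask(glucose.isna())
    bmi = out["bmi_final"]
    out["overweight_obesity"] = pd.Series(
        bmi >= config.overweight_bmi_threshold, dtype="boolean").mask(bmi.isna())
    return out


def score_cohort(
    df: pd.DataFrame, chart: RiskChart, config: PipelineConfig | None = None
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Run the full pipeline: derive, filter, look up risk, categorise, flag.

    Returns the retained records (input order preserved) with
    ``risk_percent``, ``risk_category`` and the clinical flags, plus the
    exclusion report.
    """
    config = config or PipelineConfig()
    validate_cohort(df)
    work = derive_variables(df)
    retained, report = complete_case_filter(work, config)
    if retained.empty:
        scored = retained.assign(
            age_band=pd.Series(dtype=object), sbp_band=pd.Series(dtype=object),
            bmi_band=pd.Series(dtype=object), age_clamped=pd.Series(dtype=bool),
            risk_percent=pd.Series(dtype=float),
            risk_category=pd.Series(dtype=object))
        return derive_flags(scored, config), report

    age = pd.to_numeric(retained["age"], errors="coerce")
    bad_age = retained.loc[age < chart_mod.AGE_MIN, "id"]
    if len(bad_age):
        raise DomainError(f"age below 40 for records {bad_age.head(3).tolist()}")

    scored = retained.copy()
    scored["age_band"] = _cut(age, chart_mod.AGE_BANDS)
    scored["age_clamped"] = scored["age_band"].isna()
    if config.age_policy == "clamp":
        scored["age_band"] = scored["age_band"].fillna(
            chart_mod.AGE_BANDS[-1].label)
    scored["sbp_band"] = _cut(scored["sbp_mean"], chart_mod.SBP_BANDS)
    scored["bmi_band"] = _cut(scored["bmi_final"], chart_mod.BMI_BANDS)

    smoker = _missing_bool(scored["smoker"])
    key = pd.DataFrame({
        "sex": scored["sex"].to_numpy(),
        "smoker": smoker.astype(bool).to_numpy(),
        "age_band": scored["age_band"].to_numpy(),
        "sbp_band": scored["sbp_band"].to_numpy(),
        "bmi_band": scored["bmi_band"].to_numpy(),
    })
    chart_frame = chart.to_frame()
    chart_frame["smoker"] = chart_frame["smoker"].astype(bool)
    merged = key.merge(chart_frame, how="left",
                       on=["sex", "smoker", "age_band", "sbp_band", "bmi_band"])
    scored["risk_percent"] = merged["risk_percent"].to_numpy()
    scored["risk_category"] = [
        chart_mod.categorize(r).value for r in scored["risk_percent"]
    ]
    return derive_flags(scored, config), report


def _cut(values: pd.Series, bands) -> pd.Series:
    edges = [bands[0].lower] + [b.upper for b in bands]
    labels = [b.label for b in bands]
    cut = pd.cut(values, bins=edges, labels=labels, right=False)
    return cut.astype(object)


def _sex_mask(df: pd.DataFrame, stratum: Stratum) -> pd.Series:
    if stratum == "total":
        return pd.Series(True, index=df.index)
    return df["sex"] == ("male" if stratum == "men" else "female")


def risk_distribution(scored: pd.DataFrame,
                      config: PipelineConfig | None = None) -> pd.DataFrame:
    """Stratified risk-category distribution with CIs and per-category
    sex-comparison p-values.

    One row per (category, stratum) with n, percent, CI bounds; the
    p-value of the men-vs-women 2x2 chi-square is repeated on every
    stratum row of its category.
    """
    config = config or PipelineConfig()
    if scored.empty:
        raise ValueError("scored cohort is empty")
    men = scored[_sex_mask(scored, "men")]
    women = scored[_sex_mask(scored, "women")]
    rows = []
    for cat in CATEGORY_ORDER:
        in_cat = scored["risk_category"] == cat.value
        men_k = int((men["risk_category"] == cat.value).sum())
        women_k = int((women["risk_category"] == cat.value).sum())
        if len(men) and len(women):
            test = sex_comparison_test(men_k, len(men), women_k, len(women))
            p_value = test.p_value
        else:
            p_value = math.nan
        for stratum in STRATA:
            sub = scored[_sex_mask(scored, stratum)]
            k = int((sub["risk_category"] == cat.value).sum())
            if len(sub) == 0:
                rows.append({"category": cat.value, "stratum": stratum,
                             "n": 0, "stratum_n": 0, "percent": math.nan,
                             "ci_low": math.nan, "ci_high": math.nan,
                             "p_value": p_value, "undefined": True})
                continue
            est = proportion_ci(k, len(sub), level=config.ci_level,
                                method=config.ci_method)
            rows.append({"category": cat.value, "stratum": stratum,
                         "n": k, "stratum_n": len(sub),
                         "percent": est.percent, "ci_low": est.ci_low,
                         "ci_high": est.ci_high, "p_value": p_value,
                         "undefined": False})
    return pd.DataFrame(rows)


def flags_by_risk_group(scored: pd.DataFrame, flag: str) -> pd.DataFrame:
    """Percent of records with ``flag`` true per risk category, among
    records where the flag is non-missing."""
    if flag not in scored.columns:
        raise KeyError(f"unknown flag {flag!r}")
    rows = []
    for cat in CATEGORY_ORDER:
        sub = scored.loc[scored["risk_category"] == cat.value, flag]
        known = sub.dropna()
        n_true = int(known.sum())
        rows.append({
            "category": cat.value,
            "n_known": len(known),
            "n_true": n_true,
            "percent": 100.0 * n_true / len(known) if len(known) else math.nan,
            "undefined": len(known) == 0,
        })
    return pd.DataFrame(rows)


# Treatment-eligibility rules compared in the costing analysis:
#   total_risk        — chart risk >= 20%
#   total_risk_severe — chart risk >= 20% OR severe hypertension (>=160/100)
#   single_risk       — hypertension (>=140/90), the single-risk-factor rule
ELIGIBILITY_RULES = ("total_risk", "total_risk_severe", "single_risk")


def eligibility(scored: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-record eligibility membership and prevalence by sex.

    Returns ``(membership, prevalence)``.  Membership holds one nullable
    boolean column per rule; a record with missing flags is
    eligible-unknown (pd.NA) and counted separately in the prevalence
    table, whose percents are among known records.
    """
    if scored.empty:
        raise ValueError("scored cohort is empty")
    membership = scored[["id", "sex"]].copy()
    high_risk = pd.Series(scored["risk_percent"] >= 20.0, dtype="boolean").mask(
        scored["risk_percent"].isna())
    membership["total_risk"] = high_risk
    membership["total_risk_severe"] = high_risk | scored["severe_htn"]
    membership["single_risk"] = scored["htn"]

    rows = []
    for stratum in STRATA:
        sub = membership[_sex_mask(membership, stratum)]
        row: dict = {"stratum": stratum, "n": len(sub)}
        for rule in ELIGIBILITY_RULES:
            col = sub[rule]
            known = col.dropna()
            row[f"{rule}_n"] = int(known.sum())
            row[f"{rule}_unknown"] = int(col.isna().sum())
            row[f"{rule}_percent"] = (
                100.0 * int(known.sum()) / len(known) if len(known) else math.nan)
        rows.append(row)
    return membership, pd.DataFrame(rows)


FLAG_COLUMNS = ("htn", "severe_htn", "hyperglycaemia", "overweight_obesity")


def write_scored(df: pd.DataFrame, path: str | Path) -> None:
    """Write a scored cohort to CSV; nullable flags as 0/1/empty."""
    out = df.copy()
    for col in FLAG_COLUMNS:
        if col in out.columns:
            out[col] = out[col].astype("boolean").astype("Int64")
    out.to_csv(path, index=False)


def read_scored(path: str | Path) -> pd.DataFrame:
    """Read back a scored-cohort CSV written by :func:`write_scored`."""
    df = pd.read_csv(path, dtype={"id": str}, float_precision="round_trip")
    for col in FLAG_COLUMNS:
        if col in df.columns:
            df[col] = pd.Series(df[col], dtype="Int64").astype("boolean")
    return df


def render_distribution(table: pd.DataFrame) -> str:
    """Aligned-text rendering of the distribution table (1-decimal,
    half-up percentages)."""
    disp = table.copy()
    for col in ("percent", "ci_low", "ci_high"):
        disp[col] = disp[col].map(
            lambda x: "" if pd.isna(x) else f"{round_half_up(x, 1):.1f}")
    disp["p_value"] = disp["p_value"].map(
        lambda x: "" if pd.isna(x) else f"{x:.3f}")
    return disp.to_string(index=False)
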