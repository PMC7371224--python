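"""Synthetic survey cohorts and fixture risk charts.

The generator emulates the marginal structure of a national risk-factor
survey of adults aged 40 and above: truncated-normal age, SBP and per-sex
BMI; DBP linearly coupled to SBP; per-sex smoking prevalence; right-skewed
(lognormal) random blood glucose; two BP readings per person placed
symmetrically around the person-level value so their mean recovers it
exactly; and independent (MCAR) per-variable missingness.  Default
parameters are the survey's summary statistics: n 6189, age 52.9 (SD 9.9)
years, SBP 119.7 (15.2) mm Hg, DBP 80.3 (9.5) mm Hg, BMI 21.4 (3.7) men /
22.3 (4.4) women, current smoking 50.7% men / 1.8% women, glucose 6.9
(3.0) mmol/L, per-variable missingness 0.3-0.5%.

The joint SBP-DBP correlation, the glucose skew shape, heights and the
prior-CVD rate are not identified by published marginals and are synthetic
choices; see the methods note.

``expected_prevalences`` integrates the generator's distributions over the
chart's band rectangles to give exact category and eligibility
expectations, the oracle for parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import optimize
from scipy import stats as sps

from . import chart as chart_mod
from .chart import Band, RiskChart, CATEGORY_ORDER
from .cohort import COHORT_COLUMNS, SEVERE_SBP, SEVERE_DBP, HTN_SBP, HTN_DBP
from .errors import ConfigError


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort; defaults are the study conditions."""

    n: int = 6189
    seed: int = 0
    prop_female: float = 3365 / 6189
    # age: truncated normal, years
    age_mean: float = 52.9
    age_sd: float = 9.9
    age_min: float = 40.0
    age_max: float = 95.0
    # systolic BP: truncated normal, mm Hg (person-level final value)
    sbp_mean: float = 119.7
    sbp_sd: float = 15.2
    sbp_lo: float = 70.0
    sbp_hi: float = 250.0
    # diastolic BP: linear mean shift in SBP plus Gaussian residual
    dbp_mean: float = 80.3
    dbp_sd: float = 9.5
    sbp_dbp_corr: float = 0.6
    # BMI: per-sex truncated normal, kg/m²
    bmi_male_mean: float = 21.4
    bmi_male_sd: float = 3.7
    bmi_female_mean: float = 22.3
    bmi_female_sd: float = 4.4
    bmi_lo: float = 12.0
    bmi_hi: float = 60.0
    # current smoking prevalence per sex
    smoking_male: float = 0.507
    smoking_female: float = 0.018
    # random blood glucose: lognormal matched to mean/SD, mmol/L
    glucose_mean: float = 6.9
    glucose_sd: float = 3.0
    # heights (cm) used to emit height/weight pairs consistent with BMI
    height_male_mean: float = 162.0
    height_male_sd: float = 6.0
    height_female_mean: float = 151.0
    height_female_sd: float = 5.5
    # symmetric within-person spread of the two BP readings, mm Hg
    reading_sd: float = 4.0
    # MCAR missingness rates (study: 18, 22, 25, 30, 84 of 6189)
    missing_smoker: float = 18 / 6189
    missing_sbp: float = 22 / 6189
    missing_dbp: float = 25 / 6189
    missing_bmi: float = 30 / 6189
    missing_glucose: float = 84 / 6189
    prior_cvd_rate: float = 0.01
    urban_prop: float = 0.302

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigError("n must be at least 1")
        for name in ("prop_female", "smoking_male", "smoking_female",
                     "missing_smoker", "missing_sbp", "missing_dbp",
                     "missing_bmi", "missing_glucose", "prior_cvd_rate",
                     "urban_prop"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be a proportion, got {v}")
        for name in ("age_sd", "sbp_sd", "dbp_sd", "bmi_male_sd",
                     "bmi_female_sd", "glucose_sd"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for lo, hi, what in ((self.age_min, self.age_max, "age"),
                             (self.sbp_lo, self.sbp_hi, "sbp"),
                             (self.bmi_lo, self.bmi_hi, "bmi")):
            if lo >= hi:
                raise ConfigError(f"impossible truncation bounds for {what}")
        if not -1.0 < self.sbp_dbp_corr < 1.0:
            raise ConfigError("sbp_dbp_corr must be in (-1, 1)")

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "GeneratorConfig":
        """Build from a (possibly nested) key/value mapping; nested keys are
        flattened with underscores (``age: {mean: 52.9}`` -> ``age_mean``)."""
        flat: dict = {}

        def _flatten(prefix: str, obj) -> None:
            if isinstance(obj, Mapping):
                for k, v in obj.items():
                    _flatten(f"{prefix}_{k}" if prefix else str(k), v)
            else:
                flat[prefix] = obj

        _flatten("", mapping)
        known = {f.name for f in fields(cls)}
        unknown = set(flat) - known
        if unknown:
            raise ConfigError(f"unknown generator config keys {sorted(unknown)}")
        return cls(**flat)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_mapping(data)


def _truncnorm(mean: float, sd: float, lo: float, hi: float):
    return sps.truncnorm((lo - mean) / sd, (hi - mean) / sd, loc=mean, scale=sd)


def _matched_truncnorm(mean: float, sd: float, lo: float, hi: float):
    """Truncated normal on [lo, hi] whose *truncated* mean and SD equal the
    targets.

    Survey summary statistics describe the observed (already truncated)
    variable, so the underlying location and scale are solved for rather
    than used directly; with distant bounds they coincide with the targets.
    """
    if not lo < mean < hi:
        raise ConfigError(f"target mean {mean} outside bounds [{lo}, {hi}]")

    def residual(params):
        mu, log_sigma = params
        sigma = math.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = sps.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [float(m) - mean, math.sqrt(float(v)) - sd]

    sol = optimize.root(residual, [mean, math.log(sd)], method="hybr")
    if not sol.success or not np.all(np.isfinite(sol.x)):
        raise ConfigError(
            f"cannot match truncated normal to mean {mean}, sd {sd} on "
            f"[{lo}, {hi}]")
    mu, sigma = float(sol.x[0]), float(math.exp(sol.x[1]))
    return sps.truncnorm((lo - mu) / sigma, (hi - mu) / sigma,
                         loc=mu, scale=sigma)


def _lognorm_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal with the given arithmetic mean and SD."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _age_dist(config: GeneratorConfig):
    """Distribution of exact age.  Recorded ages are completed years
    (floored), which lowers the mean by almost exactly 0.5, so the exact-age
    target mean is offset by +0.5 to make the recorded ages match."""
    return _matched_truncnorm(config.age_mean + 0.5, config.age_sd,
                              config.age_min, config.age_max)


def _sbp_dist(config: GeneratorConfig):
    return _matched_truncnorm(config.sbp_mean, config.sbp_sd,
                              config.sbp_lo, config.sbp_hi)


def _bmi_dist(config: GeneratorConfig, sex: str):
    mean = config.bmi_male_mean if sex == "male" else config.bmi_female_mean
    sd = config.bmi_male_sd if sex == "male" else config.bmi_female_sd
    return _matched_truncnorm(mean, sd, config.bmi_lo, config.bmi_hi)


def generate_cohort(config: GeneratorConfig | None = None,
                    seed: int | None = None) -> pd.DataFrame:
    """Draw a synthetic cohort in the cohort CSV dialect.

    Deterministic given ``(config, seed)``; ``seed`` overrides
    ``config.seed`` when given.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n

    female = rng.random(n) < config.prop_female
    sex = np.where(female, "female", "male")

    age_cont = _age_dist(config).rvs(n, random_state=rng)
    age = np.floor(age_cont).astype(int)  # completed years, as surveys record

    sbp = _sbp_dist(config).rvs(n, random_state=rng)
    slope = config.sbp_dbp_corr * config.dbp_sd / config.sbp_sd
    resid_sd = config.dbp_sd * math.sqrt(1.0 - config.sbp_dbp_corr ** 2)
    dbp = (config.dbp_mean + slope * (sbp - config.sbp_mean)
           + rng.normal(0.0, resid_sd, n))
    dbp = np.clip(dbp, 40.0, 150.0)

    # readings placed symmetrically so their mean is exactly the final value
    sbp_off = rng.normal(0.0, config.reading_sd, n)
    dbp_off = rng.normal(0.0, config.reading_sd, n)
    sbp1, sbp2 = (np.clip(sbp + sbp_off, *chart_mod.SBP_GUARD),
                  np.clip(sbp - sbp_off, *chart_mod.SBP_GUARD))
    dbp1, dbp2 = (np.clip(dbp + dbp_off, 30.0, 200.0),
                  np.clip(dbp - dbp_off, 30.0, 200.0))

    bmi = np.empty(n)
    for sex_name, mask in (("male", ~female), ("female", female)):
        if mask.any():
            bmi[mask] = _bmi_dist(config, sex_name).rvs(
                int(mask.sum()), random_state=rng)

    h_mean = np.where(female, config.height_female_mean, config.height_male_mean)
    h_sd = np.where(female, config.height_female_sd, config.height_male_sd)
    height = rng.normal(h_mean, h_sd)
    height = np.clip(height, 120.0, 210.0)
    weight = bmi * (height / 100.0) ** 2

    smoke_p = np.where(female, config.smoking_female, config.smoking_male)
    smoker = (rng.random(n) < smoke_p).astype(float)

    mu, sigma = _lognorm_params(config.glucose_mean, config.glucose_sd)
    glucose = np.clip(rng.lognormal(mu, sigma, n), 1.5, 45.0)

    prior_cvd = (rng.random(n) < config.prior_cvd_rate).astype(float)
    urban = rng.random(n) < config.urban_prop

    df = pd.DataFrame({
        "id": [f"P{i:06d}" for i in range(1, n + 1)],
        "age": age,
        "sex": sex,
        "smoker": smoker,
        "sbp1": sbp1, "sbp2": sbp2,
        "dbp1": dbp1, "dbp2": dbp2,
        "height_cm": height, "weight_kg": weight,
        "bmi": np.full(n, np.nan),
        "glucose": glucose,
        "residence": np.where(urban, "urban", "rural"),
        "prior_cvd": prior_cvd,
    }, columns=COHORT_COLUMNS)

    # MCAR missingness, independent per variable
    df.loc[rng.random(n) < config.missing_smoker, "smoker"] = np.nan
    df.loc[rng.random(n) < config.missing_sbp, ["sbp1", "sbp2"]] = np.nan
    df.loc[rng.random(n) < config.missing_dbp, ["dbp1", "dbp2"]] = np.nan
    df.loc[rng.random(n) < config.missing_bmi, ["height_cm", "weight_kg"]] = np.nan
    df.loc[rng.random(n) < config.missing_glucose, "glucose"] = np.nan
    return df


@dataclass(frozen=True)
class ChartFixtureConfig:
    """A synthetic multiplicative risk chart: risk grows geometrically along
    every axis and is capped at 100%.  All factors >= 1 make the chart
    monotone along each axis."""

    base_risk: float = 1.0
    age_factor: float = 1.55
    sbp_factor: float = 1.35
    bmi_factor: float = 1.15
    smoking_factor: float = 1.6
    male_factor: float = 1.4
    cap: float = 100.0

    def cell_risk(self, sex: str, smoker: bool, age_idx: int, sbp_idx: int,
                  bmi_idx: int) -> float:
        risk = (self.base_risk
                * (self.male_factor if sex == "male" else 1.0)
                * (self.smoking_factor if smoker else 1.0)
                * self.age_factor ** age_idx
                * self.sbp_factor ** sbp_idx
                * self.bmi_factor ** bmi_idx)
        return min(self.cap, risk)


def generate_chart_fixture(config: ChartFixtureConfig | None = None) -> RiskChart:
    """Build the full 700-cell synthetic chart from a multiplicative model."""
    config = config or ChartFixtureConfig()
    cells = {}
    for sex in chart_mod.SEXES:
        for smoker in (False, True):
            for i, ab in enumerate(chart_mod.AGE_BANDS):
                for j, sb in enumerate(chart_mod.SBP_BANDS):
                    for k, bb in enumerate(chart_mod.BMI_BANDS):
                        cells[(sex, smoker, ab.label, sb.label, bb.label)] = \
                            config.cell_risk(sex, smoker, i, j, k)
    return RiskChart(cells)


def _band_probs(dist, bands: tuple[Band, ...]) -> np.ndarray:
    """Probability mass of each band under a (truncated) distribution."""
    edges = [b.lower for b in bands] + [bands[-1].upper]
    cdf = np.array([dist.cdf(e) if math.isfinite(e) else 1.0 for e in edges])
    return np.diff(cdf)


def expected_prevalences(config: GeneratorConfig,
                         chart: RiskChart) -> pd.DataFrame:
    """Exact expected category and eligibility prevalences (percent) among
    scorable records, per sex stratum and total.

    Integrates the generator's distributions over each chart band
    rectangle.  Age is conditioned on lying under the chart's upper limit
    (the exclude policy); MCAR missingness and the independent prior-CVD
    exclusion do not change the conditional distribution.
    """
    # band edges are integers, so floor-recorded ages hit a band exactly
    # when the exact age does
    p_age = _band_probs(_age_dist(config), chart_mod.AGE_BANDS)
    p_age = p_age / p_age.sum()  # condition on age < chart upper limit

    sbp_dist = _sbp_dist(config)
    p_sbp = _band_probs(sbp_dist, chart_mod.SBP_BANDS)

    slope = config.sbp_dbp_corr * config.dbp_sd / config.sbp_sd
    resid_sd = config.dbp_sd * math.sqrt(1.0 - config.sbp_dbp_corr ** 2)

    # dense SBP grid for quantities that mix banded and continuous BP
    grid = np.linspace(config.sbp_lo, config.sbp_hi, 4001)
    pdf = sbp_dist.pdf(grid)
    pdf = pdf / np.trapezoid(pdf, grid)
    dbp_mu = config.dbp_mean + slope * (grid - config.sbp_mean)
    p_dbp_ge = lambda thr: 1.0 - sps.norm.cdf((thr - dbp_mu) / resid_sd)
    sbp_band_idx = np.searchsorted(
        [b.upper for b in chart_mod.SBP_BANDS[:-1]], grid, side="right")

    per_sex: dict[str, dict[str, float]] = {}
    for sex in chart_mod.SEXES:
        smoke_p = config.smoking_male if sex == "male" else config.smoking_female
        p_bmi = _band_probs(_bmi_dist(config, sex), chart_mod.BMI_BANDS)

        cat_probs = {cat: 0.0 for cat in CATEGORY_ORDER}
        # P(chart risk >= 20 | SBP band j), marginal over smoking, age, BMI
        p_high_given_sbp = np.zeros(len(chart_mod.SBP_BANDS))
        for smoker, w_smoke in ((False, 1 - smoke_p), (True, smoke_p)):
            for i, ab in enumerate(chart_mod.AGE_BANDS):
                for j, sb in enumerate(chart_mod.SBP_BANDS):
                    for k, bb in enumerate(chart_mod.BMI_BANDS):
                        risk = chart.risk(sex, smoker, ab.label, sb.label, bb.label)
                        w = w_smoke * p_age[i] * p_bmi[k]
                        cat_probs[chart_mod.categorize(risk)] += w * p_sbp[j]
                        if risk >= 20.0:
                            p_high_given_sbp[j] += w

        p_high = p_high_given_sbp @ p_sbp
        # clinical BP rules on the continuous (SBP, DBP) joint
        severe_given_s = np.where(grid >= SEVERE_SBP, 1.0, p_dbp_ge(SEVERE_DBP))
        htn_given_s = np.where(grid >= HTN_SBP, 1.0, p_dbp_ge(HTN_DBP))
        p_a_given_s = p_high_given_sbp[sbp_band_idx]
        either = p_a_given_s + (1.0 - p_a_given_s) * severe_given_s
        per_sex[sex] = {
            **{f"cat_{cat.value}": 100.0 * p for cat, p in cat_probs.items()},
            "total_risk": 100.0 * p_high,
            "total_risk_severe": 100.0 * np.trapezoid(either * pdf, grid),
            "single_risk": 100.0 * np.trapezoid(htn_given_s * pdf, grid),
        }

    w_f = config.prop_female
    total = {k: (1 - w_f) * per_sex["male"][k] + w_f * per_sex["female"][k]
             for k in per_sex["male"]}
    rows = [{"stratum": "total", **total},
            {"stratum": "men", **per_sex["male"]},
            {"stratum": "women", **per_sex["female"]}]
    return pd.DataFrame(rows)


def expected_retention(config: GeneratorConfig) -> float:
    """Expected number of records surviving the complete-case filter under
    the default pipeline (exclude age policy, prior-CVD records dropped)."""
    p_age_ok = _age_dist(config).cdf(chart_mod.AGE_BANDS[-1].upper)
    return (config.n
            * (1 - config.missing_smoker)
            * (1 - config.missing_sbp)
            * (1 - config.missing_dbp)
            * (1 - config.missing_bmi)
            * (1 - config.prior_cvd_rate)
            * p_age_ok)
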