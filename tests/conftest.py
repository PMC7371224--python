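import math

import pandas as pd
import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")

from cvdrisk.cohort import COHORT_COLUMNS
from cvdrisk.simulate import ChartFixtureConfig, generate_chart_fixture


@pytest.fixture(scope="session")
def monotone_chart():
    """Synthetic multiplicative chart: risk strictly grows along every axis."""
    return generate_chart_fixture(ChartFixtureConfig())


@pytest.fixture(scope="session")
def constant_chart():
    """Chart with every cell at 1% (all increments 1)."""
    return generate_chart_fixture(ChartFixtureConfig(
        base_risk=1.0, age_factor=1.0, sbp_factor=1.0, bmi_factor=1.0,
        smoking_factor=1.0, male_factor=1.0))


def make_cohort(rows: list[dict]) -> pd.DataFrame:
    """Build a cohort frame from sparse per-record dicts; unset fields are
    missing except for a minimal scorable default."""
    defaults = dict(age=55, sex="male", smoker=0, sbp1=120.0, sbp2=120.0,
                    dbp1=80.0, dbp2=80.0, height_cm=math.nan,
                    weight_kg=math.nan, bmi=22.0, glucose=math.nan,
                    residence="rural", prior_cvd=0)
    records = []
    for i, row in enumerate(rows):
        rec = {"id": f"R{i:03d}", **defaults, **row}
        records.append(rec)
    return pd.DataFrame(records, columns=COHORT_COLUMNS)


@pytest.fixture
def cohort_factory():
    return make_cohort


def brute_force_category(risk: float) -> str:
    """Independent re-statement of the 5-level categorisation."""
    if risk < 5:
        return "very_low"
    if risk < 10:
        return "low"
    if risk < 20:
        return "moderate"
    if risk < 30:
        return "high"
    return "very_high"


def brute_force_band(value: float, bands) -> str | None:
    """Linear scan interval-membership oracle."""
    for band in bands:
        upper = band.upper if math.isfinite(band.upper) else math.inf
        if band.lower <= value < upper:
            return band.label
    return None
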