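"""Non-laboratory CVD risk chart: axis binning, cell lookup, risk categorisation.

The chart is a complete lookup table over five axes — sex, current smoking,
5-year age band, systolic blood pressure band and BMI band — giving the
10-year risk (percent) of a fatal or non-fatal myocardial infarction or
stroke.  The numeric content of a chart is data, shipped and loaded as CSV;
this module only encodes the axis structure and the lookup semantics.

All printed band labels follow a half-open convention: a band "120-139"
covers [120, 140).  This closes the apparent gaps between printed bands
(e.g. between "20-24" and "25-29") and matches the explicit "<120" /
"160 to <180" phrasing of the adjacent bands.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, NamedTuple

import pandas as pd

from .errors import ChartValidationError, DomainError

Sex = Literal["male", "female"]
SEXES: tuple[Sex, Sex] = ("male", "female")

# Plausibility guards: values outside these are treated as data errors,
# not as extreme-but-real physiology.
AGE_MIN = 40
SBP_GUARD = (50.0, 300.0)
BMI_GUARD = (10.0, 80.0)


@dataclass(frozen=True, order=True)
class Band:
    """Half-open interval [lower, upper) on one chart axis."""

    lower: float
    upper: float  # math.inf allowed
    label: str

    def contains(self, value: float) -> bool:
        return self.lower <= value < self.upper


AGE_BANDS: tuple[Band, ...] = tuple(
    Band(lo, lo + 5, f"{lo}-{lo + 4}") for lo in range(40, 75, 5)
)
SBP_BANDS: tuple[Band, ...] = (
    Band(0.0, 120.0, "lt120"),
    Band(120.0, 140.0, "120-139"),
    Band(140.0, 160.0, "140-159"),
    Band(160.0, 180.0, "160-179"),
    Band(180.0, math.inf, "ge180"),
)
BMI_BANDS: tuple[Band, ...] = (
    Band(0.0, 20.0, "lt20"),
    Band(20.0, 25.0, "20-24"),
    Band(25.0, 30.0, "25-29"),
    Band(30.0, 35.0, "30-34"),
    Band(35.0, math.inf, "ge35"),
)

N_CELLS = 2 * 2 * len(AGE_BANDS) * len(SBP_BANDS) * len(BMI_BANDS)  # 700


class RiskCategory(enum.Enum):
    """Five-level categorisation of 10-year CVD risk percent.

    Boundaries partition [0, inf): [0,5) very low, [5,10) low, [10,20)
    moderate, [20,30) high, [30,inf) very high.  Boundary values fall
    upward (a risk of exactly 20% is HIGH).
    """

    VERY_LOW = "very_low"
    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"
    VERY_HIGH = "very_high"

    @property
    def bounds(self) -> tuple[float, float]:
        return _CATEGORY_BOUNDS[self]


_CATEGORY_BOUNDS = {
    RiskCategory.VERY_LOW: (0.0, 5.0),
    RiskCategory.LOW: (5.0, 10.0),
    RiskCategory.MODERATE: (10.0, 20.0),
    RiskCategory.HIGH: (20.0, 30.0),
    RiskCategory.VERY_HIGH: (30.0, math.inf),
}

CATEGORY_ORDER: tuple[RiskCategory, ...] = tuple(RiskCategory)


def categorize(risk_percent: float) -> RiskCategory:
    """Map a risk percent to its 5-level category."""
    if risk_percent < 0:
        raise DomainError(f"risk percent must be non-negative, got {risk_percent}")
    for cat, (lo, hi) in _CATEGORY_BOUNDS.items():
        if lo <= risk_percent < hi:
            return cat
    raise AssertionError("unreachable: categories partition [0, inf)")


@dataclass(frozen=True)
class RiskProfile:
    """One person's chartable risk factors."""

    age_years: int
    sex: Sex
    current_smoker: bool
    sbp_mmHg: float
    bmi_kg_m2: float

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise DomainError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.age_years < AGE_MIN:
            raise DomainError(f"age {self.age_years} below chart minimum {AGE_MIN}")
        if not SBP_GUARD[0] <= self.sbp_mmHg <= SBP_GUARD[1]:
            raise DomainError(f"SBP {self.sbp_mmHg} outside guard {SBP_GUARD}")
        if not BMI_GUARD[0] <= self.bmi_kg_m2 <= BMI_GUARD[1]:
            raise DomainError(f"BMI {self.bmi_kg_m2} outside guard {BMI_GUARD}")


class AgeBin(NamedTuple):
    """Result of age binning: the band (None if unscorable) and whether the
    over-range clamping policy was applied."""

    band: Band | None
    clamped: bool


AgePolicy = Literal["exclude", "clamp"]


def bin_age(age_years: int, policy: AgePolicy = "exclude") -> AgeBin:
    """Assign an age to its 5-year chart band.

    Ages 75 and above lie beyond the chart's top band (70-74).  Under
    ``policy="exclude"`` they are unscorable (``band=None``); under
    ``policy="clamp"`` they are assigned the top band with the ``clamped``
    flag set.
    """
    if policy not in ("exclude", "clamp"):
        raise ValueError(f"unknown age policy {policy!r}")
    if age_years < AGE_MIN:
        raise DomainError(f"age {age_years} below chart minimum {AGE_MIN}")
    for band in AGE_BANDS:
        if band.contains(age_years):
            return AgeBin(band, False)
    if policy == "clamp":
        return AgeBin(AGE_BANDS[-1], True)
    return AgeBin(None, False)


def _bin_value(value: float, bands: tuple[Band, ...], guard: tuple[float, float],
               what: str) -> Band:
    if not guard[0] <= value <= guard[1]:
        raise DomainError(f"{what} {value} outside plausibility guard {guard}")
    for band in bands:
        if band.contains(value):
            return band
    raise AssertionError("unreachable: bands cover the guard range")


def bin_sbp(sbp_mmHg: float) -> Band:
    """Assign a systolic BP (mm Hg) to its chart band."""
    return _bin_value(sbp_mmHg, SBP_BANDS, SBP_GUARD, "SBP")


def bin_bmi(bmi_kg_m2: float) -> Band:
    """Assign a BMI (kg/m²) to its chart band."""
    return _bin_value(bmi_kg_m2, BMI_BANDS, BMI_GUARD, "BMI")


CellKey = tuple[str, bool, str, str, str]  # sex, smoker, age, sbp, bmi labels

CHART_COLUMNS = ["sex", "smoker", "age_band", "sbp_band", "bmi_band", "risk_percent"]


class RiskChart:
    """A validated, complete 700-cell risk lookup table."""

    def __init__(self, cells: dict[CellKey, float]):
        self._validate(cells)
        self._cells = dict(cells)

    @staticmethod
    def _validate(cells: dict[CellKey, float]) -> None:
        expected = {
            (sex, smoker, a.label, s.label, b.label)
            for sex in SEXES
            for smoker in (False, True)
            for a in AGE_BANDS
            for s in SBP_BANDS
            for b in BMI_BANDS
        }
        got = set(cells)
        missing = expected - got
        extra = got - expected
        if missing:
            raise ChartValidationError(
                f"chart missing {len(missing)} cell(s), e.g. {sorted(missing)[:3]}"
            )
        if extra:
            raise ChartValidationError(
                f"chart has {len(extra)} unrecognised cell coordinate(s), "
                f"e.g. {sorted(extra)[:3]}"
            )
        bad = {k: v for k, v in cells.items() if not 0.0 <= v <= 100.0}
        if bad:
            raise ChartValidationError(
                f"risk percent outside [0, 100] at {len(bad)} cell(s), "
                f"e.g. {sorted(bad.items())[:3]}"
            )

    def risk(self, sex: Sex, smoker: bool, age_band: str, sbp_band: str,
             bmi_band: str) -> float:
        return self._cells[(sex, smoker, age_band, sbp_band, bmi_band)]

    def __len__(self) -> int:
        return len(self._cells)

    def items(self) -> Iterable[tuple[CellKey, float]]:
        return self._cells.items()

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sex": k[0], "smoker": int(k[1]), "age_band": k[2],
             "sbp_band": k[3], "bmi_band": k[4], "risk_percent": v}
            for k, v in sorted(self._cells.items())
        ]
        return pd.DataFrame(rows, columns=CHART_COLUMNS)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "RiskChart":
        missing_cols = set(CHART_COLUMNS) - set(frame.columns)
        if missing_cols:
            raise ChartValidationError(f"chart CSV missing columns {sorted(missing_cols)}")
        cells: dict[CellKey, float] = {}
        for row in frame.itertuples(index=False):
            sex = str(row.sex)
            if sex not in SEXES:
                raise ChartValidationError(f"unknown sex {sex!r} in chart")
            key: CellKey = (sex, bool(int(row.smoker)), str(row.age_band),
                            str(row.sbp_band), str(row.bmi_band))
            value = float(row.risk_percent)
            if key in cells and cells[key] != value:
                raise ChartValidationError(f"conflicting duplicate cell {key}")
            cells[key] = value
        return cls(cells)


def load_chart(path: str | Path) -> RiskChart:
    """Read and validate a chart CSV (700 rows, one per cell)."""
    frame = pd.read_csv(path, float_precision="round_trip")
    return RiskChart.from_frame(frame)


def lookup_risk(profile: RiskProfile, chart: RiskChart,
                age_policy: AgePolicy = "exclude") -> float | None:
    """Bin the profile on each axis and read the unique chart cell.

    Returns ``None`` (unscorable) when the age lies beyond the chart under
    the exclude policy; deterministic and side-effect free otherwise.
    """
    age_bin = bin_age(profile.age_years, age_policy)
    if age_bin.band is None:
        return None
    sbp_band = bin_sbp(profile.sbp_mmHg)
    bmi_band = bin_bmi(profile.bmi_kg_m2)
    return chart.risk(profile.sex, profile.current_smoker,
                      age_bin.band.label, sbp_band.label, bmi_band.label)
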