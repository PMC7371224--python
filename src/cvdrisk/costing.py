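"""Annual drug-cost projection per million adults aged >= 40, and
strategy comparison between total-risk and single-risk-factor eligibility.

Costing is deliberately simple and exactly linear: an eligibility
prevalence is scaled to a headcount per notional million adults, each
eligible person takes one tablet per day of every drug in the regimen for
365 days, and each drug is costed at its lowest generic market price per
100 tablets.  Non-drug costs (facilities, wages) are assumed equal across
strategies and excluded.

The default regimen covers the four recommended drug classes: aspirin,
an ACE inhibitor (enalapril), a thiazide diuretic (hydrochlorothiazide)
and a statin (simvastatin).  The default simvastatin price is 4.26
USD/100 tablets — the value implied by every published per-person cost
(15.549 USD/year = 4.26/100 x 365); the alternative 4.29 figure that
appears in some price listings is available via
``simvastatin_price=4.29``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping

import pandas as pd

from .errors import DomainError
from ._util import round_half_up

DAYS_PER_YEAR = 365

RoundingMode = Literal["printed", "exact"]

AGE_GROUPS = ("40-49", "50-59", "60-69", "ge70")


@dataclass(frozen=True)
class DrugPrice:
    name: str
    price_per_100_tablets: float  # USD
    tablets_per_day: float = 1.0

    def __post_init__(self) -> None:
        if self.price_per_100_tablets < 0:
            raise DomainError(f"negative price for {self.name}")
        if self.tablets_per_day <= 0:
            raise DomainError(f"tablets_per_day must be positive for {self.name}")


@dataclass(frozen=True)
class Regimen:
    """An ordered set of drugs, all taken concurrently."""

    drugs: tuple[DrugPrice, ...]

    def __post_init__(self) -> None:
        names = [d.name for d in self.drugs]
        if len(set(names)) != len(names):
            raise DomainError(f"duplicate drug names in regimen: {names}")

    def __iter__(self):
        return iter(self.drugs)


def default_regimen(simvastatin_price: float = 4.26,
                    antihypertensive_only: bool = False) -> Regimen:
    """The four-drug regimen (or its antihypertensive-only subset)."""
    drugs = [
        DrugPrice("aspirin", 0.45),
        DrugPrice("enalapril", 2.38),
        DrugPrice("hydrochlorothiazide", 0.83),
        DrugPrice("simvastatin", simvastatin_price),
    ]
    if antihypertensive_only:
        drugs = [d for d in drugs if d.name in ("enalapril", "hydrochlorothiazide")]
    return Regimen(tuple(drugs))


def load_prices(path: str | Path) -> Regimen:
    """Read a price CSV: drug,price_per_100_tablets_usd,tablets_per_day."""
    df = pd.read_csv(path)
    return Regimen(tuple(
        DrugPrice(str(r.drug), float(r.price_per_100_tablets_usd),
                  float(getattr(r, "tablets_per_day", 1.0)))
        for r in df.itertuples(index=False)
    ))


def annual_cost_per_person(drug: DrugPrice) -> float:
    """USD per person-year: price/100 tablets x tablets/day x 365 days."""
    return drug.price_per_100_tablets / 100.0 * drug.tablets_per_day * DAYS_PER_YEAR


def people_per_million(prevalence_percent: float) -> int:
    """Headcount per notional million adults; half-up integer rounding."""
    if not 0.0 <= prevalence_percent <= 100.0:
        raise DomainError(f"prevalence {prevalence_percent} outside [0, 100]")
    return int(round_half_up(prevalence_percent * 10_000.0))


def cost_per_million(prevalence_percent: float, regimen: Regimen,
                     rounding: RoundingMode = "printed") -> dict:
    """One costing row: per-drug and total annual USD per million adults.

    ``rounding="printed"`` (default) first rounds the prevalence to one
    decimal half-up, matching how published report tables carry
    prevalences; ``"exact"`` uses the prevalence as given.
    """
    if rounding not in ("printed", "exact"):
        raise ValueError(f"unknown rounding mode {rounding!r}")
    prev = (round_half_up(prevalence_percent, 1) if rounding == "printed"
            else prevalence_percent)
    people = people_per_million(prev)
    per_drug = {d.name: people * annual_cost_per_person(d) for d in regimen}
    return {
        "prevalence_percent": prev,
        "people_per_million": people,
        **{f"cost_{name}": cost for name, cost in per_drug.items()},
        "total_cost": sum(per_drug.values()),
    }


def cost_report(prevalence_table: pd.DataFrame, regimen: Regimen,
                rounding: RoundingMode = "printed") -> pd.DataFrame:
    """Cost every stratum of a prevalence table.

    ``prevalence_table`` needs columns ``stratum`` (free-form label) and
    ``prevalence_percent``; the output appends the costing columns.
    """
    rows = []
    for r in prevalence_table.itertuples(index=False):
        row = {"stratum": r.stratum,
               **cost_per_million(float(r.prevalence_percent), regimen, rounding)}
        rows.append(row)
    return pd.DataFrame(rows)


def load_population(path: str | Path) -> pd.DataFrame:
    """Read a population CSV: sex,age_group,population_thousands."""
    df = pd.read_csv(path)
    missing = {"sex", "age_group", "population_thousands"} - set(df.columns)
    if missing:
        raise DomainError(f"population CSV missing columns {sorted(missing)}")
    if (df["population_thousands"] < 0).any():
        raise DomainError("negative population")
    return df


def project_population(strata: pd.DataFrame,
                       prevalence_by_stratum: Mapping[tuple[str, str], float]
                       ) -> pd.DataFrame:
    """People requiring treatment per population stratum.

    ``strata`` has columns sex, age_group, population_thousands; the
    mapping gives the prevalence percent per (sex, age_group).  Output is
    the per-stratum headcount (persons, exactly population x prevalence,
    no rounding) with per-sex and overall totals appended.
    """
    rows = []
    for r in strata.itertuples(index=False):
        key = (str(r.sex), str(r.age_group))
        if key not in prevalence_by_stratum:
            raise DomainError(f"no prevalence supplied for stratum {key}")
        prev = float(prevalence_by_stratum[key])
        persons = float(r.population_thousands) * 1000.0 * prev / 100.0
        rows.append({"sex": key[0], "age_group": key[1],
                     "population_thousands": float(r.population_thousands),
                     "prevalence_percent": prev, "persons": persons})
    out = pd.DataFrame(rows)
    totals = [{
        "sex": sex, "age_group": "total",
        "population_thousands": g["population_thousands"].sum(),
        "prevalence_percent": math.nan,
        "persons": g["persons"].sum(),
    } for sex, g in out.groupby("sex", sort=False)]
    totals.append({
        "sex": "all", "age_group": "total",
        "population_thousands": out["population_thousands"].sum(),
        "prevalence_percent": math.nan,
        "persons": out["persons"].sum(),
    })
    return pd.concat([out, pd.DataFrame(totals)], ignore_index=True)


def compare_approaches(report_a: pd.DataFrame,
                       report_b: pd.DataFrame) -> pd.DataFrame:
    """Per-stratum absolute difference and ratio of total costs (A vs B).

    Both reports must come from :func:`cost_report` over the same strata
    and regimen.  A zero total in B leaves the ratio undefined (NaN,
    flagged)."""
    a = report_a.set_index("stratum")["total_cost"]
    b = report_b.set_index("stratum")["total_cost"]
    if set(a.index) != set(b.index):
        raise ValueError("reports cover different strata")
    b = b.reindex(a.index)
    diff = a - b
    ratio = a.where(b != 0) / b.where(b != 0)
    return pd.DataFrame({
        "stratum": a.index,
        "total_cost_a": a.to_numpy(),
        "total_cost_b": b.to_numpy(),
        "difference": diff.to_numpy(),
        "ratio": ratio.to_numpy(),
        "ratio_undefined": (b == 0).to_numpy(),
    }).reset_index(drop=True)
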