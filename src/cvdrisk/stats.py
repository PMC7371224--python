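"""Proportion confidence intervals and the sex-comparison chi-square test.

Wilson is the default interval (better behaviour for the very small
proportions in the high-risk categories); the Wald (normal-approximation)
interval is available for audit.  The sex comparison is an uncorrected
Pearson chi-square on the 2x2 table {in/out of category} x {men/women}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

CiMethod = Literal["wilson", "wald"]

# statsmodels calls the Wald interval "normal"
_SM_METHOD = {"wilson": "wilson", "wald": "normal"}


@dataclass(frozen=True)
class ProportionEstimate:
    """A proportion with its confidence interval, all on the percent scale."""

    successes: int
    n: int
    percent: float
    ci_low: float
    ci_high: float
    method: CiMethod

    def render_ci(self, decimals: int = 1) -> str:
        return f"{self.ci_low:.{decimals}f} to {self.ci_high:.{decimals}f}"


def proportion_ci(successes: int, n: int, level: float = 0.95,
                  method: CiMethod = "wilson") -> ProportionEstimate:
    """Confidence interval for a binomial proportion, bounds clipped to [0, 100]%."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if not 0 <= successes <= n:
        raise ValueError(f"successes {successes} outside [0, {n}]")
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    if method not in _SM_METHOD:
        raise ValueError(f"unknown CI method {method!r}")
    lo, hi = proportion_confint(successes, n, alpha=1 - level,
                                method=_SM_METHOD[method])

    def _clip(x: float) -> float:
        x = min(100.0, max(0.0, 100.0 * x))
        # snap float noise at the analytic endpoints
        if x < 1e-9:
            return 0.0
        if x > 100.0 - 1e-9:
            return 100.0
        return x

    return ProportionEstimate(
        successes=successes,
        n=n,
        percent=100.0 * successes / n,
        ci_low=_clip(lo),
        ci_high=_clip(hi),
        method=method,
    )


@dataclass(frozen=True)
class ChiSquareResult:
    chi2: float
    p_value: float
    defined: bool


def sex_comparison_test(in_category_men: int, men_n: int,
                        in_category_women: int, women_n: int) -> ChiSquareResult:
    """Pearson chi-square (1 df, no continuity correction) comparing the
    proportion of men vs women falling in one risk category.

    A zero margin (nobody, or everybody, in the category; or an empty sex
    stratum) leaves the statistic undefined: ``defined=False`` and NaN values.
    """
    if min(in_category_men, in_category_women) < 0:
        raise ValueError("counts must be non-negative")
    if men_n < in_category_men or women_n < in_category_women:
        raise ValueError("in-category count exceeds stratum size")
    if men_n < 1 or women_n < 1:
        raise ValueError("stratum totals must be at least 1")
    table = [
        [in_category_men, men_n - in_category_men],
        [in_category_women, women_n - in_category_women],
    ]
    col_totals = [table[0][0] + table[1][0], table[0][1] + table[1][1]]
    if 0 in col_totals:
        return ChiSquareResult(math.nan, math.nan, defined=False)
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return ChiSquareResult(float(chi2), float(p), defined=True)
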