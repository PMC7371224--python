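# Methods

## The analysis

`cvdrisk` implements a population-level total-cardiovascular-risk analysis
for survey cohorts of adults aged 40 and above, of the kind used to compare
treatment policies in low-resource settings:

1. **Risk stratification.** Each participant's 10-year risk of a fatal or
   non-fatal myocardial infarction or stroke is read from a
   *non-laboratory* risk chart — a complete lookup table over sex, current
   smoking, 5-year age band (40–44 … 70–74), systolic blood pressure band
   (<120, 120–139, 140–159, 160–179, ≥180 mm Hg) and BMI band (<20, 20–24,
   25–29, 30–34, ≥35 kg/m²); 2×2×7×5×5 = 700 cells. Risk percent is then
   categorised as very low (<5%), low (5 to <10%), moderate (10 to <20%),
   high (20 to <30%) or very high (≥30%), boundary values falling upward.
2. **Eligibility rules.** Three treatment-eligibility rules are compared:
   *total risk* (chart risk ≥20%), *total risk extended* (risk ≥20% OR
   severe hypertension, BP ≥160/100) and *single risk factor*
   (hypertension, BP ≥140/90). BP thresholds use OR semantics across
   systolic and diastolic readings, thresholds inclusive.
3. **Costing.** An eligibility prevalence is converted into an annual drug
   cost per notional million adults ≥40: `people = prevalence% × 10 000`
   (half-up to an integer), each person taking one tablet per day of every
   drug in the regimen for 365 days, each drug at its lowest generic price
   per 100 tablets. Strategy comparison reports absolute differences and
   ratios. Population projections multiply stratum populations by stratum
   prevalences, exactly and linearly.

The chart's numeric content is data, not code: charts are loaded from CSV
and validated for completeness (all 700 cells), uniqueness and range. The
repository ships no real chart values; synthetic fixture charts are
generated by `cvdrisk.simulate.generate_chart_fixture`.

## Interval conventions

Printed chart bands ("120–139", "20–24") leave gaps and one overlap
("30–35 and ≥35"). All bands are implemented half-open,
`[lower, upper+1 unit)`, i.e. [120,140), [20,25); the BMI overlap at 35 is
resolved as [30,35) and [35,∞), mirroring the explicit "160 to <180 and
≥180" phrasing of the SBP axis. The printed age list's "64–69" band is
implemented as 65–69 (5-year banding). Ages 75+ lie beyond the chart: the
default policy excludes such records (reported as unscorable); a clamp
policy assigns the 70–74 band and flags the record.

## Pipeline rules

- Final BP is the mean of the two seated readings; with one reading
  missing the available reading is used and flagged (single-reading
  fallback) rather than dropping the record.
- BMI uses the direct field when present, else weight/(height/100)².
- Complete-case filtering drops records missing any chart input (smoking,
  SBP, DBP, BMI), records unchartable by age, and (by default) records
  reporting prior CVD — the charts apply to people without established
  disease. Each dropped record is counted once under the first applicable
  reason, in the fixed precedence order prior CVD → age → smoking → SBP →
  DBP → BMI, so exclusion counts are non-overlapping and reproducible.
- Flags (hypertension ≥140/90, severe hypertension ≥160/100,
  hyperglycaemia ≥11.1 mmol/L random glucose, overweight/obesity BMI ≥25
  by default, configurable) are nullable: missing inputs give a missing
  flag, never a silent false.
- Distribution tables are crude (unweighted) proportions with Wilson
  confidence intervals by default (better behaviour for the near-zero
  proportions in the high-risk rows); Wald intervals are available for
  audit. Sex comparisons per category use the uncorrected Pearson
  chi-square on the 2×2 in/out-of-category × men/women table. Survey-design
  weighting and cluster-robust variance are out of scope.

## Costing parameters

Default regimen (USD per 100 tablets, one tablet/day): aspirin 0.45,
enalapril 2.38, hydrochlorothiazide 0.83, simvastatin 4.26. The 4.26
simvastatin price is the value implied by published per-person annual
costs (15.549 USD/year = 4.26/100 × 365); a 4.29 listing also circulates
and is selectable via `default_regimen(simvastatin_price=4.29)`. The year
is fixed at 365 days. Both strategies are costed with the full four-drug
regimen by default; an antihypertensive-only regimen (enalapril +
hydrochlorothiazide) is available by flag for the single-risk strategy.

Costing has two rounding modes. `printed` (default) first rounds the
prevalence to one decimal, half-up — the precision at which report tables
carry prevalences — so results match published tables cell for cell
(0.4852% → 0.5% → US$144 540/million). `exact` uses the prevalence as
given (0.4852% → US$140 282/million). Report percentages render at one
decimal, half-up.

## The synthetic cohort generator

The generator emulates the marginal structure of a national risk-factor
survey (defaults in parentheses): cohort size (n=6189), proportion female
(0.544), age (mean 52.9, SD 9.9 years, range 40–95), SBP (119.7, 15.2
mm Hg), DBP (80.3, 9.5 mm Hg), per-sex BMI (men 21.4/3.7, women 22.3/4.4
kg/m²), per-sex current smoking (50.7% men, 1.8% women), random glucose
(lognormal matched to mean 6.9, SD 3.0 mmol/L), per-variable MCAR
missingness (smoking 0.29%, SBP 0.36%, DBP 0.40%, BMI 0.48%, glucose
1.36%) and urban residence 30.2%.

Design choices with no published counterpart, used only to make the joint
distribution well-defined:

- **Moment matching.** Survey summary statistics describe the observed —
  already truncated — variables, so for each truncated normal the
  underlying location and scale are solved (Newton iteration on the
  truncated mean and SD) rather than used directly; the generated
  marginals then converge to the configured values exactly. Ages are
  emitted as completed years (floored), and the exact-age target mean is
  offset by +0.5 so recorded ages average to the configured mean.
- **SBP–DBP coupling.** DBP is linear in SBP with correlation 0.6 plus a
  Gaussian residual; only the marginals are published.
- **Two BP readings** are placed symmetrically around the person-level
  value (±N(0, 4 mm Hg)), so their mean recovers the person-level value
  exactly; analytic recovery oracles therefore need no measurement-error
  correction.
- **Heights** (men 162±6 cm, women 151±5.5 cm, plausible for the region)
  exist only to emit height/weight pairs consistent with the drawn BMI.
- **Prior CVD** is Bernoulli(1%), independent of everything else.
- **MCAR** missingness is used because sub-2% missingness justifies
  ignorability in a complete-case analysis.

`expected_prevalences` integrates these distributions over each chart band
rectangle (with a dense-grid quadrature over SBP for the rules mixing
banded and continuous BP) to give *exact* expected category and
eligibility prevalences among scorable records; conditioning on
scorability only renormalises the age distribution because missingness and
prior CVD are independent. This is the oracle for the parameter-recovery
tests: pooled over 20 seeds at n=6189, observed prevalences must sit
within 3 binomial standard errors of the analytic values, per sex and
overall.

What the generator does **not** emulate — hence what passing tests do not
show about real data: multistage cluster sampling and intra-cluster
correlation; the real joint dependence of risk factors (age–BP–BMI
correlations beyond the SBP–DBP pair); skewed or digit-preferenced BP
distributions; informative missingness; real chart cell values. Under the
symmetric default SBP distribution, hypertension prevalence (~20%) and the
scorable fraction (~94%, vs ~97% observed in the real survey, whose
additional exclusions are not fully documented) differ from the real
cohort's; tests therefore compare the pipeline against the generator's own
expectations, not against published prevalences, which enter the costing
stage as inputs.

## Numerical choices

- Band edges and category boundaries are exact floating-point integers, so
  half-open binning has no tie ambiguity; boundary values fall upward.
- Half-up decimal rounding (`decimal` module) for report percentages and
  per-million headcounts, matching printed-table conventions, rather than
  banker's rounding.
- CSV readers use round-trip float precision so write→read cycles are
  byte-identical.
- CI bounds are clipped to [0, 100]% and snapped when within 1e-9 of an
  endpoint (the Wilson bound at 0 successes is analytically 0 but
  numerically ~1e-16).
- A zero margin in the 2×2 test, an empty stratum, or a zero-cost
  denominator yields an explicit undefined/NaN flag, never an exception or
  a silent 0.
- Degenerate inputs: empty cohorts score to empty outputs with a complete
  exclusion report; a chart fixture with all increments 1 is a valid
  constant chart.

## Problem sizes

Default test problem sizes: property sweeps over dense guard-range grids
(~1000 points/axis), brute-force table recounts at n ≤ 50, marginal
recovery at n=50 000 × 5 seeds, parameter recovery at n=6189 × 20 seeds,
and one Monte-Carlo cross-check of the analytic expectations at n=10⁶
(tolerance 0.2 percentage points, ≈4 binomial SDs). The acceptance script
runs the full synthetic pipeline once at n=6189.

## Known limitations

- The chart engine validates but cannot verify chart content; users supply
  their own region's chart CSV.
- Crude proportions only; no design weights, so sex-specific CIs from
  weighted analyses will not be reproduced (one published women's
  moderate-risk CI, "7.0 to 8.9" around 7.95%, is asymmetric beyond any
  crude computation and is deliberately not reproduced).
- Published "number requiring treatment (in thousands)" columns that are
  internally inconsistent with their own population × prevalence products
  are not reproduced; projections here are the exact linear product.
- Costing covers drugs only — no facilities, wages, diagnostics, currency
  conversion, discounting or cost-effectiveness.
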