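"""Cohort pipeline: derivation, filtering, scoring and summary tables."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cvdrisk.cohort import (
    PipelineConfig, complete_case_filter, compute_bmi, derive_flags,
    derive_variables, eligibility, flags_by_risk_group, mean_bp,
    read_cohort, risk_distribution, score_cohort, write_cohort,
)
from cvdrisk.chart import CATEGORY_ORDER, categorize
from cvdrisk.errors import DomainError
from cvdrisk.simulate import GeneratorConfig, generate_cohort

from conftest import make_cohort


class TestDerivedVariables:
    def test_mean_of_two_readings(self):
        assert mean_bp(120.0, 130.0) == (125.0, False)
        assert mean_bp(118.0, 118.0) == (118.0, False)

    def test_single_reading_fallback_is_flagged(self):
        assert mean_bp(120.0, math.nan) == (120.0, True)
        assert mean_bp(math.nan, 95.0) == (95.0, True)

    def test_both_missing_gives_missing_not_error(self):
        value, flagged = mean_bp(math.nan, math.nan)
        assert math.isnan(value) and not flagged

    @pytest.mark.parametrize("height, weight, expected", [
        (170.0, 70.0, 70.0 / 1.7 ** 2),
        (200.0, 80.0, 20.0),
        (150.0, 45.0, 20.0),
    ])
    def test_bmi_formula(self, height, weight, expected):
        assert compute_bmi(height, weight) == pytest.approx(expected)

    def test_nonpositive_height_rejected(self):
        with pytest.raises(DomainError):
            compute_bmi(0.0, 70.0)

    def test_direct_bmi_takes_precedence_over_height_weight(self):
        df = make_cohort([{"bmi": 28.0, "height_cm": 170.0, "weight_kg": 60.0}])
        derived = derive_variables(df)
        assert derived.loc[0, "bmi_final"] == 28.0

    def test_bmi_computed_when_direct_entry_missing(self):
        df = make_cohort([{"bmi": math.nan, "height_cm": 170.0,
                           "weight_kg": 70.0}])
        derived = derive_variables(df)
        assert derived.loc[0, "bmi_final"] == pytest.approx(70.0 / 1.7 ** 2)

    def test_vectorised_bp_matches_scalar_rule(self):
        df = make_cohort([
            {"sbp1": 120.0, "sbp2": 130.0},
            {"sbp1": 120.0, "sbp2": math.nan},
            {"sbp1": math.nan, "sbp2": math.nan},
        ])
        derived = derive_variables(df)
        assert derived["sbp_mean"].tolist()[:2] == [125.0, 120.0]
        assert math.isnan(derived["sbp_mean"].iloc[2])
        assert derived["sbp_single_reading"].tolist() == [False, True, False]


class TestCompleteCaseFilter:
    def test_missing_smoking_dropped_and_counted(self):
        rows = [{} for _ in range(97)] + [{"smoker": math.nan}] * 3
        retained, report = complete_case_filter(make_cohort(rows))
        assert report.retained_n == 97
        assert report.counts["smoking"] == 3
        assert report.input_n == 100

    def test_multiple_reasons_counted_once_under_first(self):
        df = make_cohort([{"smoker": math.nan, "bmi": math.nan}])
        _, report = complete_case_filter(df)
        assert report.counts["smoking"] == 1
        assert report.counts["bmi"] == 0

    def test_precedence_order_prior_cvd_first(self):
        df = make_cohort([{"prior_cvd": 1, "smoker": math.nan, "age": 80}])
        _, report = complete_case_filter(df)
        assert report.counts == {"prior_cvd": 1, "age_policy": 0, "smoking": 0,
                                 "sbp": 0, "dbp": 0, "bmi": 0}

    def test_age_policy_clamp_retains_old_records(self):
        df = make_cohort([{"age": 80}])
        retained, _ = complete_case_filter(
            df, PipelineConfig(age_policy="clamp"))
        assert len(retained) == 1
        retained, _ = complete_case_filter(
            df, PipelineConfig(age_policy="exclude"))
        assert len(retained) == 0

    def test_counts_conservation(self):
        cohort = generate_cohort(GeneratorConfig(n=3000, seed=5))
        _, report = complete_case_filter(derive_variables(cohort))
        assert report.retained_n + report.excluded_n == report.input_n == 3000

    def test_expected_retention_matches_closed_form(self):
        """With independent per-variable missingness at the study rates and
        no other exclusions, mean retention over seeds matches
        n * prod(1 - rate): 6189 x 0.997 x 0.996^2 x 0.995 ~ 6090.6."""
        config = GeneratorConfig(
            n=6189, missing_smoker=0.003, missing_sbp=0.004,
            missing_dbp=0.004, missing_bmi=0.005, prior_cvd_rate=0.0)
        expected = 6189 * (1 - 0.003) * (1 - 0.004) ** 2 * (1 - 0.005)
        pipeline = PipelineConfig(age_policy="clamp")
        retained = []
        for seed in range(20):
            cohort = generate_cohort(config, seed=seed)
            _, report = complete_case_filter(derive_variables(cohort), pipeline)
            retained.append(report.retained_n)
        # binomial sd per seed ~9.9; 3 SE of the 20-seed mean
        se_mean = math.sqrt(6189 * 0.984 * 0.016 / 20)
        assert abs(np.mean(retained) - expected) < 3 * se_mean
        assert round(expected) == 6091


class TestFlags:
    @pytest.mark.parametrize("sbp, dbp, htn, severe", [
        (138.0, 92.0, True, False),
        (160.0, 80.0, True, True),
        (139.5, 89.5, False, False),
        (140.0, 60.0, True, False),
        (120.0, 100.0, True, True),
        (159.9, 99.9, True, False),
    ])
    def test_bp_thresholds_or_semantics(self, sbp, dbp, htn, severe):
        df = make_cohort([{"sbp1": sbp, "sbp2": sbp, "dbp1": dbp, "dbp2": dbp}])
        flagged = derive_flags(derive_variables(df))
        assert flagged.loc[0, "htn"] == htn
        assert flagged.loc[0, "severe_htn"] == severe

    def test_hyperglycaemia_threshold(self):
        df = make_cohort([{"glucose": 11.1}, {"glucose": 11.0}, {}])
        flagged = derive_flags(derive_variables(df))
        assert flagged["hyperglycaemia"].tolist()[:2] == [True, False]
        assert pd.isna(flagged.loc[2, "hyperglycaemia"])

    def test_missing_inputs_give_missing_flag_never_false(self):
        df = make_cohort([{"sbp1": math.nan, "sbp2": math.nan}])
        flagged = derive_flags(derive_variables(df))
        assert pd.isna(flagged.loc[0, "htn"])
        assert pd.isna(flagged.loc[0, "severe_htn"])

    def test_overweight_threshold_configurable(self):
        df = make_cohort([{"bmi": 24.0}])
        default = derive_flags(derive_variables(df))
        assert not default.loc[0, "overweight_obesity"]
        lowered = derive_flags(derive_variables(df),
                               PipelineConfig(overweight_bmi_threshold=23.0))
        assert lowered.loc[0, "overweight_obesity"]


class TestScoreCohort:
    def test_empty_cohort(self, monotone_chart):
        scored, report = score_cohort(make_cohort([]), monotone_chart)
        assert scored.empty and report.input_n == 0

    def test_single_record_composition(self, monotone_chart):
        df = make_cohort([{"age": 62, "sex": "male", "smoker": 1,
                           "sbp1": 165.0, "sbp2": 165.0, "bmi": 27.0}])
        scored, _ = score_cohort(df, monotone_chart)
        expected = monotone_chart.risk("male", True, "60-64", "160-179", "25-29")
        assert scored.loc[0, "risk_percent"] == expected
        assert scored.loc[0, "risk_category"] == categorize(expected).value

    def test_deterministic_and_order_preserving(self, monotone_chart):
        cohort = generate_cohort(GeneratorConfig(n=500, seed=11))
        s1, r1 = score_cohort(cohort, monotone_chart)
        s2, r2 = score_cohort(cohort, monotone_chart)
        pd.testing.assert_frame_equal(s1, s2)
        assert r1.to_dict() == r2.to_dict()
        assert list(s1["id"]) == [i for i in cohort["id"] if i in set(s1["id"])]

    def test_underage_record_is_named_in_error(self, monotone_chart):
        df = make_cohort([{"age": 30}])
        with pytest.raises(DomainError, match="R000"):
            score_cohort(df, monotone_chart)

    def test_scoring_matches_per_record_lookup(self, monotone_chart):
        """Vectorised scoring equals the scalar bin-and-read path."""
        from cvdrisk.chart import RiskProfile, lookup_risk
        cohort = generate_cohort(GeneratorConfig(n=200, seed=3))
        scored, _ = score_cohort(cohort, monotone_chart)
        for row in scored.itertuples(index=False):
            profile = RiskProfile(int(row.age), row.sex, bool(row.smoker),
                                  float(row.sbp_mean), float(row.bmi_final))
            assert row.risk_percent == lookup_risk(profile, monotone_chart)


class TestDistributionTable:
    def test_matches_brute_force_recount(self, monotone_chart):
        cohort = generate_cohort(GeneratorConfig(n=50, seed=21))
        scored, _ = score_cohort(cohort, monotone_chart)
        table = risk_distribution(scored)
        for row in table.itertuples(index=False):
            if row.stratum == "total":
                sub = scored
            else:
                sub = scored[scored["sex"] ==
                             ("male" if row.stratum == "men" else "female")]
            expected_n = sum(1 for c in sub["risk_category"]
                             if c == row.category)
            assert row.n == expected_n
            assert row.stratum_n == len(sub)
            if len(sub):
                assert row.percent == pytest.approx(100 * expected_n / len(sub))

    def test_counts_sum_to_stratum_totals(self, monotone_chart):
        cohort = generate_cohort(GeneratorConfig(n=800, seed=2))
        scored, _ = score_cohort(cohort, monotone_chart)
        table = risk_distribution(scored)
        for stratum, group in table.groupby("stratum"):
            assert group["n"].sum() == group["stratum_n"].iloc[0]
            assert group["percent"].sum() == pytest.approx(100.0)

    def test_degenerate_single_category(self, constant_chart):
        cohort = generate_cohort(GeneratorConfig(n=60, seed=4))
        scored, _ = score_cohort(cohort, constant_chart)
        table = risk_distribution(scored)
        total = table[table["stratum"] == "total"].set_index("category")
        assert total.loc["very_low", "percent"] == 100.0
        assert (total.drop("very_low")["percent"] == 0.0).all()


class TestFlagsByRiskGroup:
    def test_matches_brute_force_recount(self, monotone_chart):
        cohort = generate_cohort(GeneratorConfig(n=50, seed=9))
        scored, _ = score_cohort(cohort, monotone_chart)
        table = flags_by_risk_group(scored, "htn").set_index("category")
        for cat in CATEGORY_ORDER:
            sub = scored[scored["risk_category"] == cat.value]["htn"].dropna()
            row = table.loc[cat.value]
            assert row["n_known"] == len(sub)
            if len(sub):
                assert row["percent"] == pytest.approx(
                    100.0 * sum(bool(v) for v in sub) / len(sub))
            else:
                assert row["undefined"]

    def test_all_flagged_gives_100_percent(self, monotone_chart,
                                           cohort_factory):
        rows = [{"sbp1": 150.0, "sbp2": 150.0, "age": 45 + i} for i in range(10)]
        scored, _ = score_cohort(cohort_factory(rows), monotone_chart)
        table = flags_by_risk_group(scored, "htn")
        occupied = table[~table["undefined"]]
        assert (occupied["percent"] == 100.0).all()

    def test_unknown_flag_rejected(self, monotone_chart):
        cohort = generate_cohort(GeneratorConfig(n=20, seed=1))
        scored, _ = score_cohort(cohort, monotone_chart)
        with pytest.raises(KeyError):
            flags_by_risk_group(scored, "nonexistent")


class TestEligibility:
    def test_rule_semantics_on_known_records(self, monotone_chart,
                                             cohort_factory):
        # high risk + severe hypertension; low risk + severe; low risk + mild
        rows = [
            {"age": 72, "sex": "male", "smoker": 1, "sbp1": 190.0,
             "sbp2": 190.0, "dbp1": 95.0, "dbp2": 95.0, "bmi": 36.0},
            {"age": 45, "sex": "female", "smoker": 0, "sbp1": 165.0,
             "sbp2": 165.0, "dbp1": 95.0, "dbp2": 95.0, "bmi": 21.0},
            {"age": 45, "sex": "female", "smoker": 0, "sbp1": 145.0,
             "sbp2": 145.0, "dbp1": 85.0, "dbp2": 85.0, "bmi": 21.0},
        ]
        scored, _ = score_cohort(cohort_factory(rows), monotone_chart)
        membership, prevalence = eligibility(scored)
        assert scored.loc[0, "risk_percent"] >= 20
        assert membership["total_risk"].tolist() == [True, False, False]
        assert membership["total_risk_severe"].tolist() == [True, True, False]
        assert membership["single_risk"].tolist() == [True, True, True]
        total = prevalence.set_index("stratum").loc["total"]
        assert total["single_risk_percent"] == pytest.approx(100.0)

    def test_matches_brute_force_recount(self, monotone_chart):
        cohort = generate_cohort(GeneratorConfig(n=50, seed=33))
        scored, _ = score_cohort(cohort, monotone_chart)
        membership, prevalence = eligibility(scored)
        merged = scored.merge(membership[["id", "total_risk",
                                          "total_risk_severe", "single_risk"]],
                              on="id")
        for row in merged.itertuples(index=False):
            assert row.total_risk == (row.risk_percent >= 20)
            assert row.total_risk_severe == (
                row.risk_percent >= 20 or bool(row.severe_htn))
            assert row.single_risk == bool(row.htn)
        men = merged[merged["sex"] == "male"]
        men_row = prevalence.set_index("stratum").loc["men"]
        assert men_row["single_risk_n"] == men["htn"].sum()
        assert men_row["single_risk_percent"] == pytest.approx(
            100.0 * men["htn"].sum() / len(men))

    @given(seed=st.integers(min_value=0, max_value=10_000))
    @settings(deadline=None, max_examples=30)
    def test_extended_rule_contains_base_rule(self, monotone_chart, seed):
        """Eligibility under risk>=20 OR severe hypertension is always a
        superset of eligibility under risk>=20 alone."""
        cohort = generate_cohort(GeneratorConfig(n=80), seed=seed)
        scored, _ = score_cohort(cohort, monotone_chart)
        if scored.empty:
            return
        membership, _ = eligibility(scored)
        a = membership["total_risk"].fillna(False)
        b = membership["total_risk_severe"].fillna(False)
        assert bool((b | ~a).all())

    def test_single_risk_contains_extended_rule_when_high_risk_implies_htn(
            self, monotone_chart, cohort_factory):
        """On a cohort where every chart-high-risk record is hypertensive
        (the pattern seen in real data), the single-risk rule contains the
        extended total-risk rule."""
        rows = []
        for i in range(30):
            high = i % 3 == 0
            rows.append({
                "age": 70 + (i % 5) if high else 45,
                "sex": "male", "smoker": 1 if high else 0,
                "sbp1": 185.0 if high else 125.0,
                "sbp2": 185.0 if high else 125.0,
                "dbp1": 95.0 if high else 80.0,
                "dbp2": 95.0 if high else 80.0,
                "bmi": 36.0 if high else 22.0,
            })
        scored, _ = score_cohort(cohort_factory(rows), monotone_chart)
        high_risk = scored[scored["risk_percent"] >= 20]
        assert len(high_risk) and high_risk["htn"].all()
        membership, _ = eligibility(scored)
        b = membership["total_risk_severe"].fillna(False)
        c = membership["single_risk"].fillna(False)
        assert bool((c | ~b).all())


class TestCohortIO:
    def test_round_trip(self, tmp_path):
        cohort = generate_cohort(GeneratorConfig(n=40, seed=8))
        path = tmp_path / "cohort.csv"
        write_cohort(cohort, path)
        back = read_cohort(path)
        pd.testing.assert_frame_equal(back, cohort, check_dtype=False)

    def test_duplicate_ids_rejected(self, tmp_path):
        cohort = make_cohort([{}, {}])
        cohort["id"] = ["X", "X"]
        path = tmp_path / "cohort.csv"
        cohort.to_csv(path, index=False)
        with pytest.raises(DomainError, match="duplicate"):
            read_cohort(path)

    def test_out_of_guard_value_names_record(self, tmp_path):
        cohort = make_cohort([{"sbp1": 400.0}])
        path = tmp_path / "cohort.csv"
        cohort.to_csv(path, index=False)
        with pytest.raises(DomainError, match="R000"):
            read_cohort(path)
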