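"""Subgroup profiling: table arithmetic, SOFA trends, incidence filter,
hypothesis tests, Elixhauser scoring."""

import numpy as np
import pandas as pd
import pytest

from sanmf import profiling, synthetic
from sanmf.registry import ELIXHAUSER_CATEGORIES, SOFA_SUBSCORES


def outcomes_frame(rows):
    defaults = dict(age=60.0, sex="male", weight=80.0, bmi=25.0,
                    ethnicity="white", icu_los=3.0, day1_sofa=6,
                    elixhauser_index=0.0, mortality_30d=False,
                    mortality_inhosp=False)
    return pd.DataFrame([{**defaults, **r} for r in rows])


def flags_frame(ids, true_by_patient=()):
    rows = []
    for pid in ids:
        row = {"patient_id": pid, **{c: False for c in ELIXHAUSER_CATEGORIES}}
        for p, cat in true_by_patient:
            if p == pid:
                row[cat] = True
        rows.append(row)
    return pd.DataFrame(rows)


class TestDemographics:
    def test_mean_and_sample_sd(self):
        out = outcomes_frame([
            {"patient_id": "a", "age": 60.0}, {"patient_id": "b", "age": 70.0},
        ])
        table = profiling.demographics_table(out, {"a": 1, "b": 1})
        assert table[1]["age_mean"] == pytest.approx(65.0)
        assert table[1]["age_sd"] == pytest.approx(np.sqrt(50.0))  # 7.071

    def test_all_male_subgroup(self):
        out = outcomes_frame([
            {"patient_id": "a", "sex": "male"}, {"patient_id": "b", "sex": "male"},
        ])
        table = profiling.demographics_table(out, {"a": 1, "b": 1})
        assert table[1]["sex_male_pct"] == 100.0
        assert table[1]["sex_female_pct"] == 0.0

    def test_bmi_strata_boundaries(self):
        assert profiling.bmi_stratum(24.9) == "healthy"
        assert profiling.bmi_stratum(25.0) == "overweight"
        assert profiling.bmi_stratum(18.5) == "healthy"
        assert profiling.bmi_stratum(18.4) == "underweight"
        assert profiling.bmi_stratum(30.0) == "obese"

    def test_missing_outcome_row_is_error(self):
        out = outcomes_frame([{"patient_id": "a"}])
        with pytest.raises(KeyError, match="b"):
            profiling.demographics_table(out, {"a": 1, "b": 1})

    def test_subgroup_sizes_sum_to_cohort(self):
        out = outcomes_frame([{"patient_id": f"p{i}"} for i in range(10)])
        assignment = {f"p{i}": 1 + i % 3 for i in range(10)}
        table = profiling.demographics_table(out, assignment)
        assert table.loc["n", [1, 2, 3]].sum() == table.loc["n", "overall"] == 10

    def test_percentage_blocks_sum_to_100(self):
        out = outcomes_frame([
            {"patient_id": "a", "bmi": 17.0}, {"patient_id": "b", "bmi": 27.0},
            {"patient_id": "c", "bmi": 31.0},
        ])
        table = profiling.demographics_table(out, {"a": 1, "b": 1, "c": 1})
        bmi_pct = [table[1][f"bmi_{name}_pct"] for name, _, _ in profiling.BMI_STRATA]
        assert sum(bmi_pct) == pytest.approx(100.0)


def sofa_frame(rows):
    out = []
    for pid, day, total in rows:
        sub = [0] * 6
        i = 0
        left = total
        while left > 0:
            add = min(4, left)
            sub[i] = add
            left -= add
            i += 1
        out.append({"patient_id": pid, "day": day,
                    **dict(zip(SOFA_SUBSCORES, sub)), "total": total})
    return pd.DataFrame(out)


class TestSofaTrend:
    def test_flat_trend(self):
        sofa = sofa_frame([("a", d, 8) for d in range(1, 8)])
        trend = profiling.sofa_trend(sofa, {"a": 1})
        assert (trend["total"] == 8.0).all()

    def test_day_mean(self):
        sofa = sofa_frame([("a", 1, 6), ("b", 1, 10)])
        trend = profiling.sofa_trend(sofa, {"a": 1, "b": 1})
        assert trend.loc[trend["day"] == 1, "total"].iloc[0] == 8.0

    def test_observed_days_only_by_default(self):
        sofa = sofa_frame([("a", 1, 10), ("a", 2, 10), ("b", 1, 2)])
        trend = profiling.sofa_trend(sofa, {"a": 1, "b": 1})
        day2 = trend.loc[trend["day"] == 2, "total"].iloc[0]
        assert day2 == 10.0  # b dropped out after day 1

    def test_carry_forward_switch(self):
        sofa = sofa_frame([("a", 1, 10), ("a", 2, 10), ("b", 1, 2)])
        trend = profiling.sofa_trend(sofa, {"a": 1, "b": 1}, carry_forward=True)
        day2 = trend.loc[trend["day"] == 2, "total"].iloc[0]
        assert day2 == 6.0  # b's day-1 total carried forward

    def test_day_out_of_range_rejected(self):
        sofa = sofa_frame([("a", 8, 5)])
        with pytest.raises(ValueError, match="1..7"):
            profiling.sofa_trend(sofa, {"a": 1})

    def test_total_mismatch_rejected(self):
        sofa = sofa_frame([("a", 1, 8)])
        sofa.loc[0, "total"] = 9
        with pytest.raises(ValueError, match="sum of subscores"):
            profiling.sofa_trend(sofa, {"a": 1})

    def test_slope_recovery_on_synthetic_cohort(self):
        spec = synthetic.make_paperlike_spec(500, seed=17)
        spec.sofa_slope = (-0.5, -0.5, -0.5)
        spec.sampling_rate = 1.0  # physiological records irrelevant here
        cohort = synthetic.generate_cohort(spec)
        # all groups share the planted slope; pool them for a tight estimate
        trend = profiling.sofa_trend(cohort.sofa, {p: 1 for p in cohort.truth})
        slope = np.polyfit(trend["day"], trend["total"], 1)[0]
        assert abs(slope - (-0.5)) < 0.1


class TestComorbidityIncidence:
    def test_below_threshold_everywhere_excluded(self):
        ids = [f"p{i}" for i in range(30)]
        assignment = {p: 1 + i % 3 for i, p in enumerate(ids)}
        # one flag in subgroup 1 only: incidence 10% in that subgroup
        flags = flags_frame(ids, [("p0", "coagulopathy")])
        table = profiling.comorbidity_incidence(flags, assignment, min_incidence=0.10)
        assert "coagulopathy" in set(table["category"])
        table_strict = profiling.comorbidity_incidence(flags, assignment,
                                                       min_incidence=0.11)
        assert "coagulopathy" not in set(table_strict["category"])

    def test_max_subgroup_rule_with_exact_boundary(self):
        ids = [f"p{i}" for i in range(10)]
        assignment = {p: 1 for p in ids}
        flags = flags_frame(ids, [("p0", "liver_disease")])  # exactly 10%
        table = profiling.comorbidity_incidence(flags, assignment)
        assert "liver_disease" in set(table["category"])

    def test_all_false_category_excluded(self):
        ids = ["a", "b"]
        flags = flags_frame(ids)
        table = profiling.comorbidity_incidence(flags, {"a": 1, "b": 2})
        assert table.empty

    def test_sorted_by_cohort_incidence_descending(self):
        ids = [f"p{i}" for i in range(10)]
        assignment = {p: 1 for p in ids}
        marks = [(p, "hypertension") for p in ids[:8]]
        marks += [(p, "renal_failure") for p in ids[:4]]
        marks += [(p, "coagulopathy") for p in ids[:6]]
        table = profiling.comorbidity_incidence(flags_frame(ids, marks), assignment)
        assert list(table["category"]) == ["hypertension", "coagulopathy", "renal_failure"]
        assert table["cohort_pct"].is_monotonic_decreasing


class TestSubgroupTests:
    def _cohort(self, rng, shift=0.0, n=200):
        rows = []
        for g in (1, 2):
            for i in range(n):
                rows.append({
                    "patient_id": f"g{g}_{i}",
                    "age": rng.normal(60.0 + shift * (g - 1), 15.0),
                })
        out = outcomes_frame(rows)
        assignment = {r["patient_id"]: int(r["patient_id"][1]) for _, r in out.iterrows()}
        flags = flags_frame(list(out["patient_id"]))
        return out, flags, assignment

    def test_identical_distributions_not_rejected(self, rng):
        out, flags, assignment = self._cohort(rng, shift=0.0, n=50)
        table = profiling.subgroup_tests(out, flags, assignment, continuous=("age",))
        anova = table[(table["variable"] == "age") & (table["test"] == "welch_anova")]
        assert not anova["reject"].iloc[0]

    def test_large_shift_rejected(self, rng):
        out, flags, assignment = self._cohort(rng, shift=13.0, n=200)
        table = profiling.subgroup_tests(out, flags, assignment, continuous=("age",))
        age_rows = table[table["variable"] == "age"]
        assert age_rows["reject"].all()

    def test_zero_variance_equal_means_p_one(self):
        out = outcomes_frame([
            {"patient_id": "a", "age": 60.0}, {"patient_id": "b", "age": 60.0},
            {"patient_id": "c", "age": 60.0}, {"patient_id": "d", "age": 60.0},
        ])
        flags = flags_frame(["a", "b", "c", "d"])
        table = profiling.subgroup_tests(out, flags, {"a": 1, "b": 1, "c": 2, "d": 2},
                                         continuous=("age",))
        anova = table[(table["variable"] == "age") & (table["test"] == "welch_anova")]
        assert anova["p"].iloc[0] == 1.0

    def test_default_alpha_is_005(self, rng):
        out, flags, assignment = self._cohort(rng, shift=13.0, n=100)
        table = profiling.subgroup_tests(out, flags, assignment, continuous=("age",))
        assert ((table["p"] < 0.05) == table["reject"]).all()

    def test_holm_correction_never_more_liberal(self, rng):
        out, flags, assignment = self._cohort(rng, shift=5.0, n=60)
        raw = profiling.subgroup_tests(out, flags, assignment, continuous=("age",))
        holm = profiling.subgroup_tests(out, flags, assignment, continuous=("age",),
                                        correction="holm")
        assert (holm["p"].to_numpy() >= raw["p"].to_numpy() - 1e-12).all()

    def test_single_subgroup_rejected(self):
        out = outcomes_frame([{"patient_id": "a"}, {"patient_id": "b"}])
        flags = flags_frame(["a", "b"])
        with pytest.raises(ValueError):
            profiling.subgroup_tests(out, flags, {"a": 1, "b": 1})


class TestElixhauserScore:
    def test_all_false_zero(self):
        assert profiling.elixhauser_score({}) == 0.0

    def test_single_flag_gives_its_weight(self):
        weights = {c: 0.0 for c in ELIXHAUSER_CATEGORIES}
        weights["lymphoma"] = 9.0
        assert profiling.elixhauser_score({"lymphoma": True}, weights) == 9.0

    def test_two_flags_sum(self):
        weights = {c: 0.0 for c in ELIXHAUSER_CATEGORIES}
        weights["congestive_heart_failure"] = 7.0
        weights["coagulopathy"] = 3.0
        flags = {"congestive_heart_failure": True, "coagulopathy": True}
        assert profiling.elixhauser_score(flags, weights) == 10.0

    def test_incomplete_weight_table_rejected(self):
        with pytest.raises(KeyError):
            profiling.elixhauser_score({}, {"lymphoma": 9.0})

    def test_mortality_ordering_matches_planted_logits(self):
        spec = synthetic.make_paperlike_spec(2000, seed=29)
        spec.sampling_rate = 1.0  # physiological records irrelevant here
        cohort = synthetic.generate_cohort(spec)
        table = profiling.demographics_table(cohort.patients, cohort.truth)
        rates = {g: table[g]["mortality_30d_pct"] for g in (1, 2, 3)}
        # planted 30-day mortality: group 2 > group 1 > group 3
        assert rates[2] > rates[1] > rates[3]
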