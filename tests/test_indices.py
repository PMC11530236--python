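"""Cohort×sex z-scoring, the Addiction Index, and phenotype labels."""

import collections

import numpy as np
import pandas as pd
import pytest

from ratpheno.indices import (
    GroupZScorer,
    addiction_index,
    build_indices,
    classify_vulnerability,
    group_zscore,
    severity_groups,
)
from ratpheno.metrics import summarize_behavior


class TestGroupZScore:
    def test_single_group_unit_steps(self):
        z, stats = group_zscore([1, 2, 3], ["a", "a", "a"])
        assert z == pytest.approx([-1, 0, 1])
        assert stats.loc["a", "mu"] == 2 and stats.loc["a", "sigma"] == 1

    def test_constant_group_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            group_zscore([5, 5, 5], ["a", "a", "a"])

    def test_two_groups_hand_values(self):
        z, _ = group_zscore([0, 2, 10, 30], ["A", "A", "B", "B"])
        assert z == pytest.approx([-0.7071, 0.7071, -0.7071, 0.7071], abs=1e-4)

    def test_missing_values_stay_missing(self):
        z, _ = group_zscore([1, 2, 3, np.nan], ["a"] * 4)
        assert np.isnan(z[3]) and not np.isnan(z[:3]).any()

    def test_sklearn_estimator_contract(self):
        frame = pd.DataFrame({"cohort": [1, 1, 1, 2, 2, 2],
                              "sex": ["F"] * 6,
                              "x": [1.0, 2.0, 3.0, 5.0, 9.0, 13.0]})
        scorer = GroupZScorer(columns=["x"])
        assert scorer.get_params()["by"] == ("cohort", "sex")
        z = scorer.fit(frame).transform(frame)
        assert z["x"].to_numpy() == pytest.approx([-1, 0, 1, -1, 0, 1])
        clone_params = scorer.get_params()
        assert GroupZScorer(**clone_params).fit(frame) is not scorer

    def test_per_group_mean_zero_sd_one(self, rng):
        frame = pd.DataFrame({
            "cohort": rng.integers(1, 5, size=200),
            "sex": rng.choice(["F", "M"], size=200),
            "x": rng.normal(10, 3, size=200),
        })
        z = GroupZScorer(columns=["x"]).fit(frame).transform(frame)
        out = frame.assign(z=z["x"])
        for _, grp in out.groupby(["cohort", "sex"]):
            assert grp["z"].mean() == pytest.approx(0, abs=1e-9)
            assert grp["z"].std(ddof=1) == pytest.approx(1, abs=1e-9)


class TestAddictionIndex:
    @pytest.mark.parametrize("triple, expected", [
        ((0, 0, 0), 0.0), ((1, 1, 1), 1.0), ((0.6, -0.3, 0.9), 0.4)])
    def test_mean_of_three(self, triple, expected):
        assert addiction_index(*triple) == pytest.approx(expected)

    def test_missing_component_gives_missing_index(self):
        ai = addiction_index([0.5, np.nan], [0.5, 1.0], [0.5, 1.0])
        assert ai[0] == pytest.approx(0.5) and np.isnan(ai[1])


class TestVulnerability:
    @pytest.mark.parametrize("intake, label", [
        (35.0, "resilient"), (49.99, "resilient"),
        (50.0, "vulnerable"), (120.0, "vulnerable")])
    def test_threshold_rule(self, intake, label):
        assert classify_vulnerability(intake) == label

    def test_negative_intake_rejected(self):
        with pytest.raises(ValueError):
            classify_vulnerability(-1.0)

    def test_missing_intake_gives_no_label(self):
        labels = classify_vulnerability([35.0, np.nan])
        assert labels[0] == "resilient" and labels[1] is None


class TestSeverityGroups:
    def count(self, labels):
        return collections.Counter(l for l in labels if l is not None)

    def test_divisible_population_splits_evenly(self):
        labels = severity_groups(np.arange(8, dtype=float))
        assert self.count(labels) == {"Low": 2, "Mild": 2, "Moderate": 2,
                                      "Severe": 2}

    def test_published_population_size_split(self, rng):
        values = rng.standard_normal(511)
        counts = self.count(severity_groups(values))
        assert (counts["Low"], counts["Mild"], counts["Moderate"],
                counts["Severe"]) == (128, 128, 127, 128)

    def test_five_rats_hand_convention(self):
        labels = severity_groups([5.0, 1.0, 3.0, 2.0, 4.0])
        # ranks: 1 -> Low, 2-3 -> Mild, 4 -> Moderate, 5 -> Severe
        assert list(labels) == ["Severe", "Low", "Mild", "Mild", "Moderate"]

    def test_labels_ordered_by_index_value(self, rng):
        values = rng.standard_normal(100)
        labels = severity_groups(values)
        order = {"Low": 0, "Mild": 1, "Moderate": 2, "Severe": 3}
        ranked = sorted(zip(values, labels))
        codes = [order[l] for _, l in ranked]
        assert codes == sorted(codes)

    def test_partition_sizes_differ_by_at_most_one(self, rng):
        for n in [4, 5, 6, 7, 9, 10, 37, 101, 511, 567]:
            counts = self.count(severity_groups(rng.standard_normal(n)))
            assert sum(counts.values()) == n
            assert max(counts.values()) - min(counts.values()) <= 1

    def test_invariant_under_monotone_transform(self, rng):
        values = rng.standard_normal(53)
        base = severity_groups(values)
        warped = severity_groups(np.exp(3 * values) + 7)
        assert list(base) == list(warped)

    def test_missing_ai_left_unassigned(self, rng):
        values = np.append(rng.standard_normal(20), np.nan)
        labels = severity_groups(values)
        assert labels[-1] is None
        assert sum(l is not None for l in labels) == 20

    def test_too_few_rats_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            severity_groups([1.0, 2.0, 3.0])


class TestBuildIndices:
    def test_hand_zscores_single_group(self):
        rats = pd.DataFrame({
            "rat_id": list("abcd"), "sex": ["F"] * 4, "cohort": [1] * 4,
            "group": ["cocaine"] * 4, "excluded": [False] * 4})
        summaries = pd.DataFrame({
            "rat_id": list("abcd"),
            "esc_mean_last3": [30.0, 50.0, 70.0, 90.0],
            "pr_rewards_post_lga": [1.0, 2.0, 3.0, 4.0],
            "shock_infusions": [4.0, 3.0, 2.0, 1.0],
            "irritability_delta_total": [0.0, 1.0, 2.0, 4.0],
            "preshock_infusions": [5.0] * 4,
        })
        table = build_indices(summaries, rats)
        assert table["escalation_z"].to_numpy() == pytest.approx(
            [-1.162, -0.387, 0.387, 1.162], abs=1e-3)
        assert list(table["vulnerability"]) == [
            "resilient", "vulnerable", "vulnerable", "vulnerable"]
        assert list(table["severity"]) == ["Low", "Mild", "Moderate", "Severe"]

    def test_missing_assay_propagates_but_ai_complete_cases(self):
        rats = pd.DataFrame({
            "rat_id": list("abcd"), "sex": ["M"] * 4, "cohort": [1] * 4,
            "group": ["cocaine"] * 4, "excluded": [False] * 4})
        summaries = pd.DataFrame({
            "rat_id": list("abcd"),
            "esc_mean_last3": [30.0, 50.0, 70.0, 90.0],
            "pr_rewards_post_lga": [1.0, 2.0, 3.0, 4.0],
            "shock_infusions": [4.0, 3.0, 2.0, 1.0],
            "irritability_delta_total": [0.0, 1.0, np.nan, 4.0],
        })
        table = build_indices(summaries, rats)
        row = table[table.rat_id == "c"].iloc[0]
        assert np.isnan(row.irritability_z)
        assert not np.isnan(row.addiction_index)  # AI ignores irritability

    def test_constant_metric_in_group_rejected(self):
        rats = pd.DataFrame({
            "rat_id": list("abc"), "sex": ["F"] * 3, "cohort": [1] * 3,
            "group": ["cocaine"] * 3, "excluded": [False] * 3})
        summaries = pd.DataFrame({
            "rat_id": list("abc"),
            "esc_mean_last3": [60.0, 60.0, 60.0],
            "pr_rewards_post_lga": [1.0, 2.0, 3.0],
            "shock_infusions": [3.0, 2.0, 1.0],
            "irritability_delta_total": [0.0, 1.0, 2.0],
        })
        with pytest.raises(ValueError, match="esc_mean_last3"):
            build_indices(summaries, rats)

    def test_excluded_rats_do_not_enter_group_statistics(self):
        rats = pd.DataFrame({
            "rat_id": list("abcde"), "sex": ["F"] * 5, "cohort": [1] * 5,
            "group": ["cocaine"] * 5, "excluded": [False] * 4 + [True]})
        summaries = pd.DataFrame({
            "rat_id": list("abcde"),
            "esc_mean_last3": [30.0, 50.0, 70.0, 90.0, 1000.0],
            "pr_rewards_post_lga": [1.0, 2.0, 3.0, 4.0, 5.0],
            "shock_infusions": [4.0, 3.0, 2.0, 1.0, 0.0],
            "irritability_delta_total": [0.0, 1.0, 2.0, 4.0, 5.0],
        })
        table = build_indices(summaries, rats)
        assert len(table) == 4
        assert table["escalation_z"].to_numpy() == pytest.approx(
            [-1.162, -0.387, 0.387, 1.162], abs=1e-3)


class TestOnSyntheticCohort:
    def test_indices_mean_zero_sd_one_per_group(self, sim_cohort):
        tables, _ = sim_cohort
        summaries = summarize_behavior(tables)
        table = build_indices(summaries, tables.rats)
        joined = table.merge(tables.rats[["rat_id", "cohort", "sex"]], on="rat_id")
        for col in ("escalation_z", "motivation_z", "compulsivity_z",
                    "irritability_z"):
            for _, grp in joined.groupby(["cohort", "sex"]):
                vals = grp[col].dropna()
                assert vals.mean() == pytest.approx(0, abs=1e-9)
                assert vals.std(ddof=1) == pytest.approx(1, abs=1e-9)

    def test_severity_groups_sex_balanced(self):
        # per-sex normalisation should equalise sexes across severity groups;
        # a large cohort keeps the binomial noise well inside the 5-point band
        from ratpheno import GeneratorConfig, simulate_cohort
        tables, _ = simulate_cohort(
            GeneratorConfig(n_rats=4000, n_naive=0), seed=99)
        summaries = summarize_behavior(tables)
        table = build_indices(summaries, tables.rats)
        joined = table.merge(tables.rats[["rat_id", "sex"]], on="rat_id")
        assigned = joined[joined.severity.notna()]
        overall = (assigned.sex == "F").mean()
        for label, grp in assigned.groupby("severity"):
            assert abs((grp.sex == "F").mean() - overall) < 0.05
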