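import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import matthews_corrcoef

from emgbicoh.evaluate import (
    ConfusionMatrix,
    SplitPlan,
    aggregate_runs,
    compare_groups,
    compute_metrics,
    confusion_from_predictions,
    split_dataset,
)


def image_manifest(n=100, n_subjects=20):
    subj = np.repeat([f"S{i:02d}" for i in range(n_subjects)], n // n_subjects)
    cls = np.where(np.arange(n) < n // 2, "Normal", "KOA")
    return pd.DataFrame({"subject_id": subj, "class_label": cls})


class TestSplit:
    def test_100_items_split_70_15_15(self):
        plan = SplitPlan(unit="image", seed=0)
        tr, va, te = split_dataset(image_manifest(), plan, 0)
        assert (len(tr), len(va), len(te)) == (70, 15, 15)

    def test_partitions_disjoint_and_exhaustive(self):
        manifest = image_manifest().reset_index().rename(columns={"index": "i"})
        tr, va, te = split_dataset(manifest, SplitPlan(unit="image", seed=1), 0)
        ids = pd.concat([tr, va, te])["i"]
        assert sorted(ids) == list(range(100))

    def test_stratified_within_rounding(self):
        tr, va, te = split_dataset(
            image_manifest(), SplitPlan(unit="image", seed=2), 0
        )
        for part, size in ((tr, 70), (va, 15), (te, 15)):
            counts = part["class_label"].value_counts()
            assert abs(counts.get("KOA", 0) - size / 2) <= 1

    def test_subject_unit_never_splits_a_subject(self):
        manifest = image_manifest()
        plan = SplitPlan(unit="subject", seed=3)
        for run in range(plan.n_runs):
            parts = split_dataset(manifest, plan, run)
            seen = [set(p["subject_id"]) for p in parts]
            assert not (seen[0] & seen[1] | seen[0] & seen[2] | seen[1] & seen[2])

    def test_deterministic_per_seed_and_run(self):
        manifest = image_manifest()
        plan = SplitPlan(unit="subject", seed=4)
        a = split_dataset(manifest, plan, 1)
        b = split_dataset(manifest, plan, 1)
        for x, y in zip(a, b):
            assert x.equals(y)
        c = split_dataset(manifest, plan, 2)
        assert not a[2].equals(c[2])

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SplitPlan(fractions=(0.7, 0.3, 0.2)).validate()

    def test_empty_partition_rejected(self):
        small = image_manifest(n=4, n_subjects=4)
        with pytest.raises(ValueError):
            split_dataset(small, SplitPlan(unit="subject", seed=0), 0)


class TestMetrics:
    def test_perfect_classifier_scores_one_everywhere(self):
        cm = ConfusionMatrix(tp=10, fn=0, fp=0, tn=10)
        scores = [1.0] * 10 + [0.0] * 10
        labels = ["KOA"] * 10 + ["Normal"] * 10
        m = compute_metrics(cm, scores, labels)
        for name in ("accuracy", "precision", "sensitivity", "specificity",
                     "f_measure", "mcc", "auc"):
            assert m[name] == pytest.approx(1.0)

    def test_constructed_matrix_reproduces_formula_oracle(self):
        cm = ConfusionMatrix(tp=48, fn=2, fp=3, tn=47)
        m = compute_metrics(cm)
        assert m["accuracy"] == pytest.approx(0.95)
        assert m["sensitivity"] == pytest.approx(0.96)
        assert m["specificity"] == pytest.approx(0.94)
        assert m["precision"] == pytest.approx(48 / 51)
        assert m["mcc"] == pytest.approx(0.9002, abs=5e-5)
        # cross-check MCC against the sklearn implementation
        y_true = [1] * 50 + [0] * 50
        y_pred = [1] * 48 + [0] * 2 + [1] * 3 + [0] * 47
        assert m["mcc"] == pytest.approx(matthews_corrcoef(y_true, y_pred))

    def test_tied_scores_give_auc_half(self):
        cm = ConfusionMatrix(tp=5, fn=0, fp=5, tn=0)
        m = compute_metrics(cm, [0.5] * 10, ["KOA"] * 5 + ["Normal"] * 5)
        assert m["auc"] == pytest.approx(0.5)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        scores = rng.random(30)
        labels = np.where(rng.random(30) < 0.5, "KOA", "Normal")
        cm = confusion_from_predictions(labels, labels)
        a1 = compute_metrics(cm, scores, labels)["auc"]
        a2 = compute_metrics(cm, np.exp(5 * scores), labels)["auc"]
        assert a1 == pytest.approx(a2)

    def test_undefined_ratios_are_nan_not_zero(self):
        cm = ConfusionMatrix(tp=0, fn=0, fp=3, tn=7)  # no true positives
        m = compute_metrics(cm)
        assert math.isnan(m["sensitivity"])
        assert math.isnan(m["mcc"])
        assert m["accuracy"] == pytest.approx(0.7)

    def test_accuracy_between_sensitivity_and_specificity(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            tp, fn, fp, tn = rng.integers(1, 30, size=4)
            m = compute_metrics(ConfusionMatrix(int(tp), int(fn), int(fp), int(tn)))
            lo = min(m["sensitivity"], m["specificity"])
            hi = max(m["sensitivity"], m["specificity"])
            assert lo - 1e-12 <= m["accuracy"] <= hi + 1e-12
            assert -1.0 <= m["mcc"] <= 1.0

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_metrics(ConfusionMatrix(0, 0, 0, 0))

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        tp=st.integers(0, 50), fn=st.integers(0, 50),
        fp=st.integers(0, 50), tn=st.integers(0, 50),
    )
    def test_metric_invariants_hold_for_any_confusion_matrix(
        self, tp, fn, fp, tn
    ):
        """Ranges, accuracy bracketing, and the MCC=1 condition."""
        if tp + fn + fp + tn == 0:
            return
        m = compute_metrics(ConfusionMatrix(tp, fn, fp, tn))
        assert 0.0 <= m["accuracy"] <= 1.0
        for name in ("precision", "sensitivity", "specificity", "f_measure"):
            assert math.isnan(m[name]) or 0.0 <= m[name] <= 1.0
        if not math.isnan(m["mcc"]):
            assert -1.0 - 1e-12 <= m["mcc"] <= 1.0 + 1e-12
            both_present = (tp + fn) > 0 and (tn + fp) > 0
            if both_present:
                assert (m["mcc"] == pytest.approx(1.0)) == (fn == 0 and fp == 0)
        if not (math.isnan(m["sensitivity"]) or math.isnan(m["specificity"])):
            lo = min(m["sensitivity"], m["specificity"]) - 1e-12
            hi = max(m["sensitivity"], m["specificity"]) + 1e-12
            assert lo <= m["accuracy"] <= hi


class TestAggregate:
    def test_mean_and_sample_std(self):
        per_run = pd.DataFrame(
            {
                "run": [0, 1],
                "positive_class": ["KOA", "KOA"],
                "accuracy": [0.9, 1.0],
            }
        )
        rep = aggregate_runs(per_run, group="MG")
        assert rep.summary.loc["KOA", ("accuracy", "mean")] == pytest.approx(0.95)
        assert rep.summary.loc["KOA", ("accuracy", "std")] == pytest.approx(
            0.070710678, abs=1e-8
        )

    def test_identical_runs_have_zero_std(self):
        per_run = pd.DataFrame(
            {"run": [0, 1, 2], "positive_class": "KOA", "accuracy": 0.8}
        )
        rep = aggregate_runs(per_run)
        assert rep.summary.loc["KOA", ("accuracy", "std")] == 0.0

    def test_default_plan_runs_five_times(self):
        assert SplitPlan().n_runs == 5


class TestCompareGroups:
    def test_type_one_error_rate_under_null(self):
        """Groups from one distribution: ANOVA false-positive rate <= 10%.

        400 replicates keep the empirical rate's sampling error well below
        the margin between the nominal 5% level and the 10% bound.
        """
        rng = np.random.default_rng(0)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            groups = {m: rng.normal(0.9, 0.02, size=5) for m in "ABCDE"}
            if compare_groups(groups)["p_value"] < 0.05:
                rejections += 1
        assert rejections / n_rep <= 0.10

    def test_separated_groups_detected(self):
        # means 0.90 vs 0.96 with sd 0.01, n=5: F is enormous, p < 0.05
        base = np.array([-1.2649111, -0.6324555, 0.0, 0.6324555, 1.2649111])
        g1 = 0.90 + 0.01 * base  # mean exactly 0.90, sd exactly 0.01
        g2 = 0.96 + 0.01 * base
        res = compare_groups({"A": g1, "B": g2})
        # textbook one-way ANOVA oracle: F = n*(between var)/(within var)
        grand = (0.90 + 0.96) / 2
        ss_between = 5 * ((0.90 - grand) ** 2 + (0.96 - grand) ** 2)
        ss_within = np.sum((g1 - 0.90) ** 2) + np.sum((g2 - 0.96) ** 2)
        f_expected = (ss_between / 1) / (ss_within / 8)
        assert res["f_statistic"] == pytest.approx(f_expected, rel=1e-9)
        assert res["p_value"] < 0.05

    def test_tukey_flags_only_shifted_group(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.90, 0.01, size=6)
        b = rng.normal(0.90, 0.01, size=6)
        c = rng.normal(0.98, 0.01, size=6)
        res = compare_groups({"A": a, "B": b, "C": c})
        t = res["tukey"]
        flagged = {
            frozenset((r["group1"], r["group2"]))
            for _, r in t.iterrows()
            if r["reject"]
        }
        assert flagged == {frozenset({"A", "C"}), frozenset({"B", "C"})}

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            compare_groups({"A": np.ones(5), "B": np.ones(5)})
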