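"""Metrics layer vs. independent oracles, conventions, and invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import (
    count_confusion,
    metric_from_counts,
    pairwise_auroc,
    random_instance,
    sweep_pr_points,
    sweep_roc_points,
)
from priobench.errors import DegenerateLabels, UnknownMetric
from priobench.metrics import (
    METRIC_NAMES,
    ConfusionMatrix,
    apply_cutoff,
    auroc,
    auroc_mann_whitney,
    confusion_matrix,
    decode_classes,
    encode_classes,
    metric,
    pr_curve,
    roc_curve,
)


class TestEncoding:
    def test_label_encoding(self):
        assert encode_classes(["benign", "pathogenic", "benign"]).tolist() == [0, 1, 0]
        assert encode_classes([]).tolist() == []

    def test_involution(self):
        classes = ["pathogenic", "benign", "benign", "pathogenic"]
        assert decode_classes(encode_classes(classes)) == classes


class TestApplyCutoff:
    @pytest.mark.parametrize("score, cutoff, direction, expected", [
        (0.7, 0.5, "higher", 1),
        (0.3, 0.5, "higher", 0),
        (0.5, 0.5, "higher", 1),   # tie calls pathogenic
        (0.3, 0.5, "lower", 1),
        (0.7, 0.5, "lower", 0),
        (0.5, 0.5, "lower", 1),
    ])
    def test_threshold_semantics(self, score, cutoff, direction, expected):
        assert apply_cutoff([score], cutoff, direction)[0] == expected


class TestConfusionAndMetrics:
    def test_mixed_example(self):
        cm = confusion_matrix([1, 1, 0, 0], [1, 0, 0, 1])
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (1, 1, 1, 1)

    def test_sensitivity_example(self):
        assert metric(ConfusionMatrix(tp=3, fn=1, fp=0, tn=0), "sensitivity") == 0.75

    def test_mcc_zero_numerator(self):
        assert metric(ConfusionMatrix(tp=1, fp=1, tn=1, fn=1), "mcc") == 0.0

    def test_perfect_classifier_scores_one_everywhere(self):
        cm = ConfusionMatrix(tp=5, tn=5, fp=0, fn=0)
        for name in METRIC_NAMES:
            expected = 10.0 if name == "concordance_count" else 1.0
            assert metric(cm, name) == expected

    def test_unknown_metric(self):
        with pytest.raises(UnknownMetric):
            metric(ConfusionMatrix(1, 1, 1, 1), "f1")

    def test_zero_denominator_policy(self):
        # nothing predicted positive: precision undefined -> 0.0
        cm = ConfusionMatrix(tp=0, fp=0, tn=3, fn=2)
        assert metric(cm, "precision") == 0.0

    def test_counts_match_oracle_on_random_labels(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(1, 200))
            t = rng.integers(0, 2, size=n)
            p = rng.integers(0, 2, size=n)
            cm = confusion_matrix(t, p)
            assert (cm.tp, cm.fp, cm.tn, cm.fn) == count_confusion(t, p)
            for name in METRIC_NAMES:
                assert metric(cm, name) == pytest.approx(
                    metric_from_counts(*count_confusion(t, p), name), abs=1e-12
                )


class TestRocCurve:
    def test_perfect_separation_passes_top_left(self):
        curve = roc_curve([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert any(f == 0.0 and t == 1.0 for f, t in curve.points)
        assert auroc(curve) == 1.0

    def test_inverted_scores_area_zero(self):
        curve = roc_curve([0, 0, 1, 1], [0.9, 0.8, 0.2, 0.1])
        assert auroc(curve) == 0.0

    def test_identical_scores_degenerate_diagonal(self):
        curve = roc_curve([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
        assert curve.points.tolist() == [[0.0, 0.0], [1.0, 1.0]]
        assert auroc(curve) == pytest.approx(0.5)

    def test_single_class_raises(self):
        with pytest.raises(DegenerateLabels):
            roc_curve([1, 1, 1], [0.1, 0.2, 0.3])

    def test_monotone_and_anchored(self):
        rng = np.random.default_rng(11)
        y, s = random_instance(rng)
        curve = roc_curve(y, s)
        assert (np.diff(curve.fpr) >= 0).all()
        assert (np.diff(curve.tpr) >= 0).all()
        assert (curve.fpr[0], curve.tpr[0]) == (0.0, 0.0)
        assert (curve.fpr[-1], curve.tpr[-1]) == (1.0, 1.0)

    def test_direction_lower_mirrors_higher(self):
        y = [0, 1, 0, 1, 1, 0]
        s = [0.9, 0.2, 0.7, 0.1, 0.3, 0.5]
        low = roc_curve(y, s, "lower")
        high = roc_curve(y, [-v for v in s], "higher")
        assert low.points.tolist() == high.points.tolist()
        assert auroc(low) == auroc(high)


class TestPrCurve:
    def test_perfect_separation_contains_perfect_point(self):
        curve = pr_curve([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert any(r == 1.0 and p == 1.0 for r, p in curve.points)

    def test_recall_starts_at_lowest_attained_value(self):
        curve = pr_curve([1, 1, 0], [0.9, 0.5, 0.1])
        assert curve.recall[0] == 0.5  # strictest cutoff catches 1 of 2
        assert (np.diff(curve.recall) >= 0).all()

    def test_no_positives_raises(self):
        with pytest.raises(DegenerateLabels):
            pr_curve([0, 0], [0.1, 0.2])


class TestAurocProperties:
    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_invariant_under_strictly_increasing_transforms(self, seed):
        rng = np.random.default_rng(seed)
        y, s = random_instance(rng, max_n=60)
        base = auroc(roc_curve(y, s))
        assert auroc(roc_curve(y, np.exp(s / 4))) == pytest.approx(base, abs=1e-12)
        assert auroc(roc_curve(y, 3.0 * s + 7)) == pytest.approx(base, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_complement_identity_on_tie_free_scores(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        y = rng.integers(0, 2, size=n)
        y[:2] = [0, 1]
        s = rng.permutation(np.arange(n, dtype=float))  # distinct scores
        forward = auroc(roc_curve(y, s, "higher"))
        mirrored = auroc(roc_curve(y, -s, "lower"))
        assert forward + auroc(roc_curve(y, -s, "higher")) == pytest.approx(1.0)
        assert mirrored == pytest.approx(forward)

    def test_trapezoid_equals_pairwise_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            y, s = random_instance(rng)
            expected = pairwise_auroc(y, s)
            assert auroc(roc_curve(y, s)) == pytest.approx(expected, abs=1e-12)
            assert auroc_mann_whitney(y, s) == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(5)
        for _ in range(25):
            y, s = random_instance(rng)
            assert auroc(roc_curve(y, s)) == pytest.approx(
                roc_auc_score(y, s), abs=1e-12
            )


class TestSweepOracles:
    def test_roc_and_pr_points_match_brute_force(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            y, s = random_instance(rng)
            assert roc_curve(y, s).points.tolist() == [
                list(p) for p in sweep_roc_points(y, s)
            ]
            assert pr_curve(y, s).points.tolist() == [
                list(p) for p in sweep_pr_points(y, s)
            ]

    def test_cutoff_metrics_lie_on_roc_curve(self):
        """Sensitivity/specificity at any cutoff give a point on the curve."""
        rng = np.random.default_rng(31)
        y, s = random_instance(rng)
        curve = roc_curve(y, s)
        for cutoff in np.linspace(s.min() - 0.5, s.max() + 0.5, 9):
            cm = confusion_matrix(y, apply_cutoff(s, cutoff))
            point = [cm.fp / (cm.fp + cm.tn), metric(cm, "sensitivity")]
            assert point in curve.points.tolist()
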