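"""Confusion counts, the metric formulas and one-vs-rest ROC/AUC."""

import numpy as np
import pytest
from sklearn.metrics import precision_recall_fscore_support

from haini.errors import DimensionError
from haini.evaluation import (
    ConfusionCounts,
    confusion,
    evaluate,
    metrics_from_counts,
    roc_auc_ovr,
)


class TestConfusion:
    def test_hand_counted_example(self):
        counts = confusion([1, 1, 2], [1, 2, 2])
        assert counts.for_class(1) == {"tp": 1, "fp": 0, "tn": 1, "fn": 1}
        assert counts.for_class(2) == {"tp": 1, "fp": 1, "tn": 1, "fn": 0}

    def test_perfect_prediction_has_no_errors(self):
        counts = confusion([1, 2, 3], [1, 2, 3])
        assert not counts.fp.any() and not counts.fn.any()

    def test_counts_sum_to_n_for_every_class(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 4, 50)
        y_pred = rng.integers(0, 4, 50)
        counts = confusion(y_true, y_pred)
        total = counts.tp + counts.fp + counts.tn + counts.fn
        np.testing.assert_array_equal(total, 50)

    def test_empty_inputs_give_all_zeros(self):
        counts = confusion([], [], classes=[1, 2])
        assert counts.n_samples == 0
        assert not (counts.tp.any() or counts.fp.any() or counts.fn.any())

    def test_length_mismatch_rejected(self):
        with pytest.raises(DimensionError):
            confusion([1, 2], [1])


class TestMetricsFromCounts:
    def test_direct_formula_evaluation(self):
        counts = ConfusionCounts((1,), np.array([9]), np.array([1]),
                                 np.array([7]), np.array([3]), 20)
        report = metrics_from_counts(counts)
        assert report.precision[0] == pytest.approx(0.9)
        assert report.recall[0] == pytest.approx(0.75)
        assert report.f1[0] == pytest.approx(2 * 0.9 * 0.75 / 1.65)  # 0.81818...

    def test_zero_denominator_flags_instead_of_raising(self):
        counts = ConfusionCounts((1,), np.array([0]), np.array([0]),
                                 np.array([5]), np.array([0]), 5)
        report = metrics_from_counts(counts)
        assert report.precision[0] == 0.0
        assert "precision" in report.zero_division_flags[1]

    def test_f1_equals_p_when_p_equals_r(self):
        counts = ConfusionCounts((1,), np.array([6]), np.array([2]),
                                 np.array([0]), np.array([2]), 10)
        report = metrics_from_counts(counts)
        assert report.precision[0] == report.recall[0]
        assert report.f1[0] == pytest.approx(report.precision[0])

    def test_macro_averages_only_over_present_classes(self):
        report = evaluate([1, 1, 2, 2], [1, 1, 2, 3], classes=[1, 2, 3])
        # class 3 absent from y_true: excluded from macro averages
        assert report.macro_recall == pytest.approx((1.0 + 0.5) / 2)


def test_metric_identities_on_random_labelings():
    """Micro P = micro R = accuracy; min(P,R) <= F1 <= max(P,R); and the
    per-class values match an independent recount (sklearn)."""
    rng = np.random.default_rng(11)
    for _ in range(20):
        n = int(rng.integers(5, 60))
        k = int(rng.integers(2, 5))
        y_true = rng.integers(0, k, n)
        y_pred = rng.integers(0, k, n)
        report = evaluate(y_true, y_pred, classes=range(k))
        assert report.micro_precision == pytest.approx(report.accuracy)
        assert report.micro_recall == pytest.approx(report.accuracy)
        for i in range(k):
            p, r, f = report.precision[i], report.recall[i], report.f1[i]
            if p + r > 0:
                assert min(p, r) - 1e-12 <= f <= max(p, r) + 1e-12
        sp, sr, sf, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=range(k), zero_division=0)
        np.testing.assert_allclose(report.precision, sp)
        np.testing.assert_allclose(report.recall, sr)
        np.testing.assert_allclose(report.f1, sf)


class TestRocAuc:
    def test_perfectly_ranked_scores(self):
        y = [0, 0, 1, 1]
        scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        aucs, macro = roc_auc_ovr(y, scores, classes=[0, 1])
        assert aucs == {0: 1.0, 1: 1.0} and macro == 1.0

    def test_reversed_ranking_scores_zero(self):
        y = [0, 0, 1, 1]
        scores = np.array([[0.1, 0.9], [0.2, 0.8], [0.9, 0.1], [0.8, 0.2]])
        aucs, _ = roc_auc_ovr(y, scores, classes=[0, 1])
        assert aucs == {0: 0.0, 1: 0.0}

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        n = 10000
        y = rng.integers(0, 2, n)
        scores = rng.random((n, 2))
        aucs, _ = roc_auc_ovr(y, scores, classes=[0, 1])
        assert aucs[0] == pytest.approx(0.5, abs=0.02)

    def test_absent_class_reported_missing(self):
        aucs, macro = roc_auc_ovr([0, 0, 1, 1],
                                  np.full((4, 3), 1 / 3), classes=[0, 1, 2])
        assert aucs[2] is None
        assert macro is not None
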