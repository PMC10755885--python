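"""Confusion-matrix scores and Cohen's kappa, cross-checked against sklearn."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score, precision_recall_fscore_support

from mfocnn.exceptions import UndefinedMetricError
from mfocnn.metrics import (
    ConfusionMatrix,
    basic_scores,
    cohen_kappa,
    confusion_matrix,
    evaluate_predictions,
)


class TestConfusionMatrix:
    def test_diagonal_for_perfect_predictions(self):
        y = np.array([0, 1, 2, 2, 1])
        cm = confusion_matrix(y, y, 3)
        np.testing.assert_array_equal(cm.counts, np.diag([1, 2, 2]))

    def test_hand_counted_entries(self):
        cm = confusion_matrix([0, 0, 1], [0, 1, 1], 2)
        np.testing.assert_array_equal(cm.counts, [[1, 1], [0, 1]])

    def test_total_conservation(self, rng):
        truth = rng.integers(0, 4, size=200)
        pred = rng.integers(0, 4, size=200)
        assert confusion_matrix(truth, pred, 4).total == 200

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 3], [0, 1], 2)


class TestBasicScores:
    def test_binary_hand_computed(self):
        # TP=9, TN=9, FP=1, FN=1 -> all four scores 90
        cm = ConfusionMatrix(np.array([[9, 1], [1, 9]]))
        rep = basic_scores(cm)
        assert rep.accuracy == pytest.approx(90.0)
        assert rep.precision == pytest.approx(90.0)
        assert rep.recall == pytest.approx(90.0)
        assert rep.f1 == pytest.approx(90.0)

    def test_perfect_multiclass(self):
        cm = ConfusionMatrix(np.diag([10, 20, 30, 40, 50]))
        rep = basic_scores(cm)
        for v in (rep.accuracy, rep.precision, rep.recall, rep.f1):
            assert v == pytest.approx(100.0)

    def test_zero_prediction_class_precision_zero(self):
        # class 1 never predicted
        cm = ConfusionMatrix(np.array([[5, 0], [5, 0]]))
        rep = basic_scores(cm)
        assert rep.per_class["precision"].iloc[1] == 0.0

    def test_accuracy_identity_trace_over_total(self, rng):
        for k in (2, 3, 5):
            truth = rng.integers(0, k, size=300)
            pred = rng.integers(0, k, size=300)
            cm = confusion_matrix(truth, pred, k)
            rep = basic_scores(cm)
            assert rep.accuracy == pytest.approx(100.0 * np.trace(cm.counts) / cm.total)

    def test_weighted_matches_sklearn(self, rng):
        truth = rng.integers(0, 5, size=400)
        pred = rng.integers(0, 5, size=400)
        rep = basic_scores(confusion_matrix(truth, pred, 5), averaging="weighted")
        p, r, f, _ = precision_recall_fscore_support(
            truth, pred, average="weighted", zero_division=0
        )
        assert rep.precision == pytest.approx(100 * p)
        assert rep.recall == pytest.approx(100 * r)
        assert rep.f1 == pytest.approx(100 * f, abs=0.2)  # F1-of-averages on balanced data

    def test_macro_weighted_coincide_on_balanced_binary(self):
        cm = ConfusionMatrix(np.array([[40, 10], [10, 40]]))
        w = basic_scores(cm, averaging="weighted")
        m = basic_scores(cm, averaging="macro")
        assert w.per_class.equals(m.per_class)
        for k in ("accuracy", "precision", "recall", "f1"):
            assert getattr(w, k) == pytest.approx(getattr(m, k))

    def test_empty_matrix_rejected(self):
        with pytest.raises(UndefinedMetricError):
            basic_scores(ConfusionMatrix(np.zeros((3, 3), dtype=int)))

    def test_permutation_invariance(self, rng):
        truth = rng.integers(0, 4, size=250)
        pred = rng.integers(0, 4, size=250)
        perm = rng.permutation(4)
        rep1 = basic_scores(confusion_matrix(truth, pred, 4))
        rep2 = basic_scores(confusion_matrix(perm[truth], perm[pred], 4))
        for k in ("accuracy", "precision", "recall", "f1"):
            assert getattr(rep1, k) == pytest.approx(getattr(rep2, k))


class TestCohenKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa(ConfusionMatrix(np.diag([5, 5, 5]))) == pytest.approx(1.0)

    def test_chance_agreement_outer_product(self):
        # independent marginals: p_o == p_e -> kappa 0
        row = np.array([0.6, 0.4])
        col = np.array([0.3, 0.7])
        cm = ConfusionMatrix(np.rint(np.outer(row, col) * 100).astype(int))
        assert cohen_kappa(cm) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        # p_o = 0.8, p_e = 0.5 -> kappa = 0.6
        cm = ConfusionMatrix(np.array([[45, 5], [15, 35]]))
        assert cohen_kappa(cm) == pytest.approx(0.6)

    def test_matches_sklearn(self, rng):
        truth = rng.integers(0, 5, size=500)
        pred = np.where(rng.random(500) < 0.6, truth, rng.integers(0, 5, size=500))
        ours = cohen_kappa(confusion_matrix(truth, pred, 5))
        assert ours == pytest.approx(cohen_kappa_score(truth, pred))

    def test_single_cell_perfect(self):
        cm = ConfusionMatrix(np.array([[10]]))
        assert cohen_kappa(cm) == 1.0


class TestEvaluatePredictions:
    def test_full_report(self, rng):
        truth = rng.integers(0, 3, size=120)
        rep = evaluate_predictions(truth, truth, 3)
        assert rep.accuracy == 100.0 and rep.kappa == 1.0
        frame = rep.to_frame(group="demo", classes="A vs B vs C")
        assert list(frame.columns) == [
            "Group", "Class", "Accuracy", "Precision", "Recall", "F1-score", "Kappa",
        ]
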