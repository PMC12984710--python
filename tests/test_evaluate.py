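"""Metrics and ROC against independent oracles (hand tally, pairwise AUC,
scikit-learn cross-checks)."""

import numpy as np
import pytest
from sklearn.metrics import precision_recall_fscore_support, roc_auc_score

from oct_its import (
    CLASSES,
    classification_metrics,
    confusion_matrix,
    roc_analysis,
)
from oct_its.evaluate import ConfusionMatrix3, one_hot


def random_labels(rng, n):
    return [CLASSES[k] for k in rng.integers(0, 3, n)]


def random_probs(rng, n):
    p = rng.dirichlet(np.ones(3), size=n)
    return p


def mann_whitney_auc(y: np.ndarray, scores: np.ndarray) -> float:
    """Pairwise oracle: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        labels = ["normal"] * 5 + ["drusen"] * 3 + ["cnv"] * 2
        cm = confusion_matrix(labels, labels)
        assert np.array_equal(cm.counts, np.diag([5, 3, 2]))

    def test_constant_predictor_fills_first_column(self):
        labels = ["normal"] * 5 + ["drusen"] * 3 + ["cnv"] * 2
        cm = confusion_matrix(labels, ["normal"] * 10)
        expected = np.zeros((3, 3), dtype=int)
        expected[:, 0] = [5, 3, 2]
        assert np.array_equal(cm.counts, expected)

    def test_matches_bruteforce_tally(self, rng):
        yt, yp = random_labels(rng, 200), random_labels(rng, 200)
        cm = confusion_matrix(yt, yp)
        assert cm.total == 200
        for i, ci in enumerate(CLASSES):
            for j, cj in enumerate(CLASSES):
                manual = sum(1 for a, b in zip(yt, yp) if a == ci and b == cj)
                assert cm.counts[i, j] == manual

    def test_unknown_token_rejected(self):
        with pytest.raises(ValueError, match="dme"):
            confusion_matrix(["normal"], ["dme"])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            confusion_matrix(["normal"], ["normal", "cnv"])


class TestClassificationMetrics:
    def test_perfect_matrix(self):
        rep = classification_metrics(ConfusionMatrix3(np.diag([10, 10, 10])))
        assert rep.accuracy == 1.0
        assert rep.macro_precision == rep.macro_recall == rep.macro_f1 == 1.0

    def test_hand_computed_example(self):
        cm = ConfusionMatrix3(np.array([[8, 1, 1], [2, 6, 2], [0, 2, 8]]))
        rep = classification_metrics(cm)
        assert abs(rep.accuracy - 22 / 30) < 1e-12
        # columns sums: 10, 9, 11; row sums: 10 each
        p = (8 / 10, 6 / 9, 8 / 11)
        r = (8 / 10, 6 / 10, 8 / 10)
        for c, pi, ri in zip(CLASSES, p, r):
            assert abs(rep.precision[c] - pi) < 1e-12
            assert abs(rep.recall[c] - ri) < 1e-12
            assert abs(rep.f1[c] - 2 * pi * ri / (pi + ri)) < 1e-12
        assert abs(rep.macro_precision - np.mean(p)) < 1e-12

    def test_zero_support_class_convention(self):
        cm = ConfusionMatrix3(np.array([[5, 0, 0], [0, 5, 0], [0, 0, 0]]))
        with pytest.warns(UserWarning, match="cnv"):
            rep = classification_metrics(cm)
        assert rep.precision["cnv"] == 0.0 and rep.recall["cnv"] == 0.0
        assert abs(rep.macro_precision - (1 + 1 + 0) / 3) < 1e-12

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            classification_metrics(ConfusionMatrix3(np.zeros((3, 3), dtype=int)))

    def test_agrees_with_sklearn_on_random_matrices(self, rng):
        for _ in range(100):
            yt, yp = random_labels(rng, 60), random_labels(rng, 60)
            rep = classification_metrics(confusion_matrix(yt, yp))
            p, r, f, _ = precision_recall_fscore_support(
                yt, yp, labels=list(CLASSES), average="macro", zero_division=0
            )
            assert abs(rep.macro_precision - p) < 1e-9
            assert abs(rep.macro_recall - r) < 1e-9
            assert abs(rep.macro_f1 - f) < 1e-9

    def test_accuracy_from_cm_equals_direct(self, rng):
        yt, yp = random_labels(rng, 150), random_labels(rng, 150)
        rep = classification_metrics(confusion_matrix(yt, yp))
        direct = np.mean([a == b for a, b in zip(yt, yp)])
        assert abs(rep.accuracy - direct) < 1e-12


class TestROC:
    def test_perfect_separation_gives_auc_one(self):
        labels = ["normal"] * 4 + ["drusen"] * 4 + ["cnv"] * 4
        probs = np.repeat(np.eye(3) * 0.85 + 0.05, 4, axis=0)
        roc = roc_analysis(labels, probs)
        for curve in (*roc.per_class.values(), roc.micro, roc.macro):
            assert curve.auc == pytest.approx(1.0)

    def test_uninformative_scores_give_auc_half(self):
        labels = ["normal"] * 3 + ["drusen"] * 3 + ["cnv"] * 3
        probs = np.full((9, 3), 1 / 3)
        roc = roc_analysis(labels, probs)
        for curve in (*roc.per_class.values(), roc.micro, roc.macro):
            assert curve.auc == pytest.approx(0.5, abs=1e-12)

    def test_per_class_auc_equals_pairwise_oracle(self, rng):
        labels = random_labels(rng, 50)
        probs = random_probs(rng, 50)
        roc = roc_analysis(labels, probs)
        onehot = one_hot(labels)
        for i, c in enumerate(CLASSES):
            oracle = mann_whitney_auc(onehot[:, i], probs[:, i])
            assert abs(roc.per_class[c].auc - oracle) < 1e-9

    def test_micro_and_macro_match_sklearn(self, rng):
        labels = random_labels(rng, 80)
        probs = random_probs(rng, 80)
        roc = roc_analysis(labels, probs)
        onehot = one_hot(labels)
        micro_sk = roc_auc_score(onehot.ravel(), probs.ravel())
        macro_sk = np.mean(
            [roc_auc_score(onehot[:, i], probs[:, i]) for i in range(3)]
        )
        assert abs(roc.micro.auc - micro_sk) < 1e-9
        assert abs(roc.macro.auc - macro_sk) < 1e-9

    def test_auc_invariant_to_class_permutation(self, rng):
        labels = random_labels(rng, 60)
        probs = random_probs(rng, 60)
        base = roc_analysis(labels, probs)
        perm = [2, 0, 1]
        relabeled = [CLASSES[perm.index(CLASSES.index(lab))] for lab in labels]
        roc_p = roc_analysis(relabeled, probs[:, perm])
        assert abs(base.micro.auc - roc_p.micro.auc) < 1e-12
        assert abs(base.macro.auc - roc_p.macro.auc) < 1e-12

    def test_curves_are_proper(self, rng):
        labels = random_labels(rng, 40)
        probs = random_probs(rng, 40)
        roc = roc_analysis(labels, probs)
        for curve in (*roc.per_class.values(), roc.micro, roc.macro):
            assert curve.fpr[0] == 0.0 and curve.tpr[0] == 0.0
            assert curve.fpr[-1] == pytest.approx(1.0)
            assert curve.tpr[-1] == pytest.approx(1.0)
            assert np.all(np.diff(curve.fpr) >= 0)
            assert np.all(np.diff(curve.tpr) >= -1e-12)
            assert 0.0 <= curve.auc <= 1.0

    def test_missing_class_curve_omitted_with_warning(self):
        labels = ["normal"] * 5 + ["drusen"] * 5
        probs = random_probs(np.random.default_rng(0), 10)
        with pytest.warns(UserWarning, match="cnv"):
            roc = roc_analysis(labels, probs)
        assert "cnv" not in roc.per_class

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            roc_analysis(["normal", "cnv"], np.array([[0.5, 0.2, 0.1],
                                                      [0.3, 0.3, 0.4]]))
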