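"""Pseudo-labeling, reliability filtering and the teacher-student loop."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oct_its import (
    ITSConfig,
    TrainConfig,
    assign_pseudo_labels,
    build_student_trainset,
    patient_wise_split,
    reliability_filter,
    run_its,
    subset_labels,
)
from oct_its.dataset import class_weights
from oct_its.its import PseudoLabel
from oct_its.phantom import ImageRecord


class _StubTeacher:
    """Fixed-probability classifier for contract tests."""

    is_fitted = True

    def __init__(self, rows):
        self.rows = np.asarray(rows, dtype=float)

    def predict_proba(self, X):
        return self.rows[: len(X)]


def _records(n, label="normal"):
    rng = np.random.default_rng(0)
    return [
        ImageRecord(f"u{k}", f"p{k}", f"v{k}", label, rng.uniform(size=(64, 64)))
        for k in range(n)
    ]


class TestAssignPseudoLabels:
    def test_argmax_and_confidence(self):
        teacher = _StubTeacher([[0.97, 0.02, 0.01]])
        [p] = assign_pseudo_labels(teacher, _records(1))
        assert p.predicted_class == "normal"
        assert p.confidence == pytest.approx(0.97)

    def test_tie_breaks_toward_earlier_class(self):
        teacher = _StubTeacher([[0.5, 0.5, 0.0]])
        [p] = assign_pseudo_labels(teacher, _records(1))
        assert p.predicted_class == "normal"
        assert p.confidence == pytest.approx(0.5)

    def test_confidence_is_row_maximum_for_every_record(self, rng):
        rows = rng.dirichlet(np.ones(3), size=500)
        teacher = _StubTeacher(rows)
        pseudo = assign_pseudo_labels(teacher, _records(500))
        assert len(pseudo) == 500
        for p, row in zip(pseudo, rows):
            assert p.confidence == pytest.approx(row.max())
            assert p.predicted_class == ("normal", "drusen", "cnv")[row.argmax()]

    def test_empty_pool_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="empty"):
            assert assign_pseudo_labels(_StubTeacher([[1, 0, 0]]), []) == []


class TestReliabilityFilter:
    def _pseudo(self, confidences):
        return [
            PseudoLabel(f"u{k}", "normal", c, 1)
            for k, c in enumerate(confidences)
        ]

    def test_zero_threshold_accepts_all(self):
        acc, rej = reliability_filter(self._pseudo([0.1, 0.5, 0.0]), 0.0)
        assert len(acc) == 3 and not rej

    def test_geq_convention(self):
        acc, rej = reliability_filter(self._pseudo([0.99, 0.95, 0.90, 0.50]), 0.95)
        assert [p.confidence for p in acc] == [0.99, 0.95]
        assert [p.confidence for p in rej] == [0.90, 0.50]
        assert all(p.accepted for p in acc) and not any(p.accepted for p in rej)

    def test_matches_bruteforce_count(self, rng):
        conf = rng.uniform(size=1000)
        acc, rej = reliability_filter(self._pseudo(conf), 0.95)
        assert len(acc) == int(np.sum(conf >= 0.95))
        assert len(acc) + len(rej) == 1000

    @given(
        st.lists(st.floats(0, 1), min_size=1, max_size=50),
        st.floats(0, 1),
        st.floats(0, 1),
    )
    def test_monotone_and_partition(self, confs, t1, t2):
        pseudo = self._pseudo(confs)
        lo, hi = sorted((t1, t2))
        acc_lo, rej_lo = reliability_filter(pseudo, lo)
        acc_hi, rej_hi = reliability_filter(pseudo, hi)
        assert len(acc_lo) + len(rej_lo) == len(confs)
        assert len(acc_hi) <= len(acc_lo)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            reliability_filter([], 1.5)


class TestBuildStudentTrainset:
    def test_empty_accepted_is_identity(self):
        labeled = [
            ImageRecord(f"l{k}", f"pl{k}", f"vl{k}", "normal", r.pixels)
            for k, r in enumerate(_records(5))
        ]
        out, _, pseudo_ids = build_student_trainset(labeled, [], _records(3))
        assert out == labeled and pseudo_ids == set()

    def test_disjoint_union_counts(self):
        labeled = [
            ImageRecord(f"l{k}", f"pl{k}", f"vl{k}",
                        ("normal", "drusen")[k % 2], np.zeros((32, 32)))
            for k in range(100)
        ]
        unlabeled = _records(60)
        accepted = [
            PseudoLabel(f"u{k}", "cnv", 0.99, 1, accepted=True) for k in range(40)
        ]
        out, weights, pseudo_ids = build_student_trainset(labeled, accepted, unlabeled)
        assert len(out) == 140
        assert len({r.image_id for r in out}) == 140
        assert len(pseudo_ids) == 40
        # class weights recomputed on the union differ from labeled-only
        base = class_weights(labeled)
        assert weights.weights != base.weights
        assert all(r.label == "cnv" for r in out[100:])

    def test_unknown_image_id_rejected(self):
        labeled = _records(2)
        with pytest.raises(ValueError, match="ghost"):
            build_student_trainset(
                labeled, [PseudoLabel("ghost", "cnv", 0.99, 1)], _records(2)
            )


@pytest.fixture(scope="module")
def its_setup(small_cohort):
    split = patient_wise_split(small_cohort, (0.5, 0.25, 0.25), seed=0)
    split = subset_labels(split, small_cohort, 0.4, seed=0)
    cfg = TrainConfig(seed=0, max_epochs=12, lr_reduce_patience=3,
                      early_stop_patience=6)
    return small_cohort, split, cfg


class TestRunITS:
    def test_structure_of_seeded_run(self, its_setup):
        cohort, split, train_cfg = its_setup
        result = run_its(
            split, cohort, train_cfg,
            ITSConfig(confidence_threshold=0.95, max_iterations=2, seed=1),
        )
        assert 1 <= len(result.iterations) <= 2
        n_unlabeled = len(split.unlabeled_ids)
        for it in result.iterations:
            assert it.n_accepted + it.n_rejected == n_unlabeled
            assert set(it.n_accepted_per_class) == {"normal", "drusen", "cnv"}
            if it.purity is not None:
                assert 0.0 <= it.purity <= 1.0
            # pseudo-labels only ever extend the labeled pool
            assert set(split.labeled_ids) <= set(it.train_ids)
            assert not (set(it.train_ids) - set(split.train_ids))
        assert result.best_iteration in [it.iteration for it in result.iterations]
        assert result.final_model is not None
        assert result.baseline_test_metrics is not None

    def test_no_leakage_into_val_or_test(self, its_setup):
        cohort, split, train_cfg = its_setup
        result = run_its(
            split, cohort, train_cfg,
            ITSConfig(confidence_threshold=0.0, max_iterations=1, seed=2),
        )
        eval_ids = set(split.val_ids) | set(split.test_ids)
        for it in result.iterations:
            assert not (set(it.train_ids) & eval_ids)

    def test_empty_unlabeled_pool_degenerates_to_supervised(self, small_cohort):
        split = patient_wise_split(small_cohort, (0.5, 0.25, 0.25), seed=0)
        cfg = TrainConfig(seed=0, max_epochs=5, lr_reduce_patience=2,
                          early_stop_patience=3)
        with pytest.warns(UserWarning, match="empty"):
            result = run_its(
                split, small_cohort, cfg,
                ITSConfig(confidence_threshold=0.9, max_iterations=2, seed=0),
            )
        assert result.iterations == []
        assert result.best_iteration == 0
        assert result.final_model is not None
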