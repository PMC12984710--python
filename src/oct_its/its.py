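"""Iterative teacher-student self-training with confidence filtering.

The loop: a teacher is trained on the labeled pool; each iteration it
predicts the *entire* unlabeled pool, its most probable class per image
becomes a hard pseudo-label with confidence equal to the maximum softmax
probability, pseudo-labels at or above the confidence threshold are accepted,
a fresh student is trained on labeled + accepted pseudo-labeled data with
class weights recomputed on that union, and the student becomes the next
teacher. Pseudo-labels are never sticky — every iteration rebuilds them from
scratch through the current teacher, so early mistakes can be revised.

When the cohort carries ground truth for the unlabeled pool (phantom mode),
each iteration also reports pseudo-label purity: the fraction of accepted
pseudo-labels whose predicted class matches the hidden true label.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._common import CLASSES, UNLABELED, child_seed, logger
from .dataset import ClassWeights, CohortSplit, class_weights
from .evaluate import MetricsReport, classification_metrics, confusion_matrix
from .phantom import Cohort, ImageRecord
from .preprocess import Pipeline
from .train import Classifier, TrainConfig, predict_proba, train_supervised

__all__ = [
    "PseudoLabel",
    "ITSConfig",
    "ITSIteration",
    "ITSResult",
    "assign_pseudo_labels",
    "reliability_filter",
    "build_student_trainset",
    "run_its",
    "evaluate_model",
]


@dataclass(frozen=True)
class PseudoLabel:
    """A model-assigned label for one unlabeled image."""

    image_id: str
    predicted_class: str
    confidence: float
    iteration: int
    accepted: bool = False


@dataclass(frozen=True)
class ITSConfig:
    """Loop parameters: threshold, iteration budget, stopping rule."""

    confidence_threshold: float = 0.95
    max_iterations: int = 4
    stop_on_val_decline: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.confidence_threshold <= 1.0):
            raise ValueError("confidence_threshold must be in [0, 1]")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass(frozen=True)
class ITSIteration:
    """Bookkeeping for one teacher → student step."""

    iteration: int
    n_accepted_per_class: dict[str, int]
    n_rejected: int
    purity: float | None
    val_metrics: MetricsReport
    test_metrics: MetricsReport
    student_seed: int
    train_ids: tuple[str, ...]

    @property
    def n_accepted(self) -> int:
        return sum(self.n_accepted_per_class.values())


@dataclass
class ITSResult:
    iterations: list[ITSIteration] = field(default_factory=list)
    baseline_val_metrics: MetricsReport | None = None
    baseline_test_metrics: MetricsReport | None = None
    best_iteration: int = 0
    final_model: Classifier | None = None
    warnings: tuple[str, ...] = ()


def assign_pseudo_labels(
    teacher: Classifier,
    unlabeled_records,
    pipeline: Pipeline | None = None,
    iteration: int = 1,
) -> list[PseudoLabel]:
    """One pseudo-label per record: argmax class, max-probability confidence.

    Probability ties break toward the earlier class in (normal, drusen, cnv).
    An empty pool yields an empty list with a warning so threshold sweeps
    degrade gracefully.
    """
    unlabeled_records = list(unlabeled_records)
    if not unlabeled_records:
        warnings.warn("assign_pseudo_labels: empty unlabeled pool", stacklevel=2)
        return []
    probs = predict_proba(teacher, unlabeled_records, pipeline=pipeline)
    # np.argmax returns the first maximal index, which is the class-order
    # tie-break
    pred = probs.argmax(axis=1)
    conf = probs.max(axis=1)
    return [
        PseudoLabel(
            image_id=rec.image_id,
            predicted_class=CLASSES[k],
            confidence=float(c),
            iteration=iteration,
        )
        for rec, k, c in zip(unlabeled_records, pred, conf)
    ]


def reliability_filter(
    pseudo: list[PseudoLabel],
    threshold: float,
) -> tuple[list[PseudoLabel], list[PseudoLabel]]:
    """Partition into (accepted, rejected) by confidence >= threshold.

    The >= convention makes threshold 0 mean "accept everything". Input
    order is preserved in both outputs.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    accepted, rejected = [], []
    for p in pseudo:
        if p.confidence >= threshold:
            accepted.append(dataclasses.replace(p, accepted=True))
        else:
            rejected.append(dataclasses.replace(p, accepted=False))
    return accepted, rejected


def build_student_trainset(
    labeled_records,
    accepted: list[PseudoLabel],
    unlabeled_records,
) -> tuple[list[ImageRecord], ClassWeights, set[str]]:
    """Labeled records plus accepted pseudo-labeled records, reweighted.

    Returns the union (each image at most once), class weights recomputed on
    it, and the set of pseudo-labeled image ids (so training can optionally
    down-weight them).
    """
    labeled_records = list(labeled_records)
    by_id = {r.image_id: r for r in unlabeled_records}
    labeled_ids = {r.image_id for r in labeled_records}
    out = list(labeled_records)
    pseudo_ids: set[str] = set()
    for p in accepted:
        if p.image_id not in by_id:
            raise ValueError(
                f"pseudo-label references unknown image_id {p.image_id!r}"
            )
        if p.image_id in labeled_ids or p.image_id in pseudo_ids:
            raise ValueError(f"duplicate image in student train set: {p.image_id!r}")
        out.append(by_id[p.image_id].with_label(p.predicted_class))
        pseudo_ids.add(p.image_id)
    return out, class_weights(out), pseudo_ids


def evaluate_model(model, records, pipeline=None) -> MetricsReport:
    """Classification metrics of ``model`` on fully labeled records."""
    records = list(records)
    probs = predict_proba(model, records, pipeline=pipeline)
    pred = [CLASSES[k] for k in probs.argmax(axis=1)]
    return classification_metrics(
        confusion_matrix([r.label for r in records], pred)
    )


def run_its(
    split: CohortSplit,
    cohort: Cohort,
    train_cfg: TrainConfig,
    its_cfg: ITSConfig,
) -> ITSResult:
    """Run the full iterative teacher-student loop on one split.

    The initial teacher trains on the labeled pool only (its metrics are the
    supervised baseline of the run). Each subsequent iteration promotes the
    newly trained student to teacher. If ``stop_on_val_decline`` is set and
    validation accuracy falls below the previous iteration's, the loop stops
    after recording the declining iteration. The best iteration (and the
    returned final model) is chosen by validation accuracy — never test.
    """
    its_cfg.validate()
    train_cfg.validate()
    split.validate()

    labeled = cohort.subset(split.labeled_ids)
    unlabeled = cohort.subset(split.unlabeled_ids)
    val = cohort.subset(split.val_ids)
    test = cohort.subset(split.test_ids)
    eval_ids = set(split.val_ids) | set(split.test_ids)

    pipeline = Pipeline(image_size=train_cfg.image_size,
                        augment_config=train_cfg.augment)
    result = ITSResult()

    teacher_cfg = dataclasses.replace(
        train_cfg, seed=child_seed(its_cfg.seed, "teacher")
    )
    teacher, _ = train_supervised(
        labeled, val, class_weights(labeled), teacher_cfg, pipeline=pipeline
    )
    result.baseline_val_metrics = evaluate_model(teacher, val, pipeline)
    result.baseline_test_metrics = evaluate_model(teacher, test, pipeline)
    result.final_model = teacher

    if not unlabeled:
        msg = "unlabeled pool is empty; degenerating to one supervised run"
        warnings.warn(msg, stacklevel=2)
        result.warnings = (msg,)
        return result

    truth_known = all(r.label != UNLABELED for r in unlabeled)
    prev_val_acc = -np.inf
    best_val_acc = -np.inf

    for t in range(1, its_cfg.max_iterations + 1):
        pseudo = assign_pseudo_labels(teacher, unlabeled, pipeline, iteration=t)
        accepted, rejected = reliability_filter(pseudo, its_cfg.confidence_threshold)
        if len(accepted) + len(rejected) != len(unlabeled):
            raise AssertionError("accepted + rejected must partition the pool")
        if any(p.image_id in eval_ids for p in accepted):
            raise AssertionError("pseudo-labeled record leaked into val/test")

        train_records, union_weights, pseudo_ids = build_student_trainset(
            labeled, accepted, unlabeled
        )
        student_seed = child_seed(its_cfg.seed, "student", t)
        student_cfg = dataclasses.replace(train_cfg, seed=student_seed)
        student, _ = train_supervised(
            train_records, val, union_weights, student_cfg,
            pipeline=pipeline, pseudo_ids=pseudo_ids,
        )

        purity = None
        if truth_known and accepted:
            truth = {r.image_id: r.label for r in unlabeled}
            purity = float(
                np.mean([p.predicted_class == truth[p.image_id] for p in accepted])
            )

        val_metrics = evaluate_model(student, val, pipeline)
        test_metrics = evaluate_model(student, test, pipeline)
        per_class = {c: 0 for c in CLASSES}
        for p in accepted:
            per_class[p.predicted_class] += 1
        row = ITSIteration(
            iteration=t,
            n_accepted_per_class=per_class,
            n_rejected=len(rejected),
            purity=purity,
            val_metrics=val_metrics,
            test_metrics=test_metrics,
            student_seed=student_seed,
            train_ids=tuple(r.image_id for r in train_records),
        )
        result.iterations.append(row)
        logger.info(
            "ITS iteration %d: accepted %d/%d (purity %s), val acc %.3f",
            t, row.n_accepted, len(unlabeled),
            "n/a" if purity is None else f"{purity:.3f}",
            val_metrics.accuracy,
        )

        if val_metrics.accuracy > best_val_acc:
            best_val_acc = val_metrics.accuracy
            result.best_iteration = t
            result.final_model = student
        if (
            its_cfg.stop_on_val_decline
            and t > 1
            and val_metrics.accuracy < prev_val_acc
        ):
            logger.info("validation accuracy declined; stopping at iteration %d", t)
            break
        prev_val_acc = val_metrics.accuracy
        teacher = student

    return result
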