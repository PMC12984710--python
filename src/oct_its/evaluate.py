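"""Multiclass evaluation: confusion matrix, P/R/F1 and micro/macro ROC.

Conventions, stated explicitly because they matter on imbalanced 3-class
problems:

* The confusion matrix has true classes on rows, predicted on columns, in
  the fixed order (normal, drusen, cnv).
* Precision/recall/F1 with a zero denominator are defined as 0 and a warning
  is emitted; macro averages are unweighted means over the 3 classes,
  weighted averages are support-weighted. Both are reported.
* ROC curves are one-vs-rest threshold sweeps with tied scores grouped into
  one operating point; the micro curve pools all (record, class) binary
  decisions; the macro curve averages per-class true-positive rates on the
  union of all per-class false-positive-rate breakpoints, which makes the
  piecewise-linear average exact. AUC is the trapezoidal integral.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._common import CLASSES, CLASS_TO_INDEX, encode_labels

__all__ = [
    "ConfusionMatrix3",
    "MetricsReport",
    "ROCCurve",
    "ROCResult",
    "confusion_matrix",
    "classification_metrics",
    "roc_analysis",
    "one_hot",
]


@dataclass(frozen=True)
class ConfusionMatrix3:
    """3x3 count table, rows = true class, columns = predicted class."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (3, 3):
            raise ValueError(f"confusion matrix must be 3x3, got {counts.shape}")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            raise ValueError("confusion matrix entries must be non-negative integers")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    support: dict[str, int]


@dataclass(frozen=True)
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass(frozen=True)
class ROCResult:
    per_class: dict[str, ROCCurve]
    micro: ROCCurve
    macro: ROCCurve
    warnings: tuple[str, ...] = field(default=())


def one_hot(labels) -> np.ndarray:
    y = encode_labels(labels)
    out = np.zeros((len(y), len(CLASSES)))
    out[np.arange(len(y)), y] = 1.0
    return out


def confusion_matrix(true_labels, predicted_labels) -> ConfusionMatrix3:
    """Tally true vs predicted labels into the fixed 3x3 class grid."""
    yt = encode_labels(true_labels)
    yp = encode_labels(predicted_labels)
    if len(yt) != len(yp):
        raise ValueError(
            f"label sequences differ in length: {len(yt)} vs {len(yp)}"
        )
    counts = np.zeros((3, 3), dtype=np.int64)
    np.add.at(counts, (yt, yp), 1)
    return ConfusionMatrix3(counts=counts)


def classification_metrics(cm: ConfusionMatrix3) -> MetricsReport:
    """Accuracy plus per-class and averaged precision/recall/F1."""
    counts = cm.counts
    total = cm.total
    if total == 0:
        raise ValueError("confusion matrix is empty (all-zero)")
    diag = np.diag(counts).astype(float)
    col_sums = counts.sum(axis=0).astype(float)
    row_sums = counts.sum(axis=1).astype(float)

    def safe_div(num: float, den: float, what: str, cls: str) -> float:
        if den == 0:
            warnings.warn(
                f"{what} undefined for class {cls!r} (zero denominator); "
                "reporting 0", stacklevel=3,
            )
            return 0.0
        return num / den

    precision, recall, f1 = {}, {}, {}
    for i, c in enumerate(CLASSES):
        p = safe_div(diag[i], col_sums[i], "precision", c)
        r = safe_div(diag[i], row_sums[i], "recall", c)
        precision[c] = p
        recall[c] = r
        f1[c] = 0.0 if (p + r) == 0 else 2 * p * r / (p + r)

    support = {c: int(row_sums[i]) for i, c in enumerate(CLASSES)}
    sup = row_sums / total
    return MetricsReport(
        accuracy=float(diag.sum() / total),
        precision=precision,
        recall=recall,
        f1=f1,
        macro_precision=float(np.mean(list(precision.values()))),
        macro_recall=float(np.mean(list(recall.values()))),
        macro_f1=float(np.mean(list(f1.values()))),
        weighted_precision=float(np.dot(sup, list(precision.values()))),
        weighted_recall=float(np.dot(sup, list(recall.values()))),
        weighted_f1=float(np.dot(sup, list(f1.values()))),
        support=support,
    )


def _binary_roc(y: np.ndarray, scores: np.ndarray) -> ROCCurve:
    """ROC for one binary problem; tied scores form a single point."""
    n_pos = float(y.sum())
    n_neg = float(len(y) - y.sum())
    order = np.argsort(-scores, kind="stable")
    y_sorted = y[order]
    s_sorted = scores[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(1 - y_sorted)
    # keep only the last index of each tied-score group
    last_of_group = np.r_[np.diff(s_sorted) != 0, True]
    tps = tps[last_of_group]
    fps = fps[last_of_group]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, auc=auc)


def roc_analysis(true_labels, probabilities) -> ROCResult:
    """Per-class one-vs-rest, micro-average and macro-average ROC.

    ``true_labels`` may be class tokens or a one-hot matrix;
    ``probabilities`` is (n, 3) with rows summing to 1.
    """
    probs = np.asarray(probabilities, dtype=float)
    if probs.ndim != 2 or probs.shape[1] != len(CLASSES):
        raise ValueError(f"probability matrix must be (n, 3), got {probs.shape}")
    if np.any(probs < -1e-9) or np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("probability rows must be non-negative and sum to 1")
    Y = np.asarray(true_labels)
    if Y.ndim == 2:
        onehot = np.asarray(Y, dtype=float)
        if onehot.shape != probs.shape:
            raise ValueError("one-hot labels and probabilities differ in shape")
    else:
        onehot = one_hot(Y)
    if len(onehot) == 0:
        raise ValueError("no records to evaluate")

    warns: list[str] = []
    per_class: dict[str, ROCCurve] = {}
    for c, i in CLASS_TO_INDEX.items():
        y = onehot[:, i]
        if y.sum() == 0 or y.sum() == len(y):
            msg = (
                f"class {c!r} has no {'positives' if y.sum() == 0 else 'negatives'}; "
                "curve omitted"
            )
            warnings.warn(msg, stacklevel=2)
            warns.append(msg)
            continue
        per_class[c] = _binary_roc(y, probs[:, i])
    if not per_class:
        raise ValueError("no class has both positives and negatives")

    micro = _binary_roc(onehot.ravel(), probs.ravel())

    # Macro curve: average the per-class upper envelopes (max tpr at each
    # fpr, so vertical segments collapse) on the union of all breakpoints;
    # the interpolation is then exact piecewise-linear. The macro AUC is the
    # unweighted mean of the per-class AUCs — the convention consistent with
    # the pairwise-comparison definition of AUC — which can differ from the
    # trapezoidal area of the averaged curve only through those vertical
    # segments.
    envelopes = []
    for cv in per_class.values():
        keep = np.r_[np.diff(cv.fpr) != 0, True]
        envelopes.append((cv.fpr[keep], cv.tpr[keep]))
    grid = np.unique(np.concatenate([f for f, _ in envelopes]))
    mean_tpr = np.mean([np.interp(grid, f, t) for f, t in envelopes], axis=0)
    if mean_tpr[0] != 0.0:
        grid = np.r_[0.0, grid]
        mean_tpr = np.r_[0.0, mean_tpr]
    macro_auc = float(np.mean([cv.auc for cv in per_class.values()]))
    macro = ROCCurve(fpr=grid, tpr=mean_tpr, auc=macro_auc)
    return ROCResult(per_class=per_class, micro=micro, macro=macro,
                     warnings=tuple(warns))
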