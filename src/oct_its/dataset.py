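"""Patient-wise splitting, label-fraction subsetting and class weights.

The experimental-design layer: a cohort is partitioned into train /
validation / test with whole patients as atomic units (no identity leakage),
the training partition is further divided into labeled and unlabeled pools
by whole volumes, and inverse-frequency class weights compensate the
imbalanced class mix during training.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._common import CLASSES, logger
from .phantom import Cohort

__all__ = [
    "CohortSplit",
    "ClassWeights",
    "patient_wise_split",
    "subset_labels",
    "class_weights",
    "save_split",
    "load_split",
]

_SPLIT_NAMES = ("train", "val", "test")


@dataclass(frozen=True)
class CohortSplit:
    """Disjoint patient-wise train/val/test plus labeled/unlabeled train."""

    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    labeled_ids: tuple[str, ...]
    unlabeled_ids: tuple[str, ...]
    seed: int
    fractions: tuple[float, float, float]
    labeled_fraction: float = 1.0
    warnings: tuple[str, ...] = ()

    def validate(self, cohort: Cohort | None = None) -> None:
        train, val, test = map(set, (self.train_ids, self.val_ids, self.test_ids))
        if train & val or train & test or val & test:
            raise ValueError("train/val/test image sets overlap")
        labeled, unlabeled = set(self.labeled_ids), set(self.unlabeled_ids)
        if labeled | unlabeled != train or labeled & unlabeled:
            raise ValueError("labeled/unlabeled pools do not partition train")
        if cohort is not None:
            if train | val | test != set(cohort.image_ids):
                raise ValueError("splits do not cover the cohort")
            patients = {
                name: {cohort[i].patient_id for i in ids}
                for name, ids in zip(_SPLIT_NAMES, (train, val, test))
            }
            for a in _SPLIT_NAMES:
                for b in _SPLIT_NAMES:
                    if a < b and patients[a] & patients[b]:
                        raise ValueError(
                            f"patients shared between {a} and {b}: "
                            f"{sorted(patients[a] & patients[b])[:3]}"
                        )


@dataclass(frozen=True)
class ClassWeights:
    """Per-class loss weights, inverse to class frequency."""

    weights: dict[str, float]
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for c, w in self.weights.items():
            if not np.isfinite(w) or w < 0:
                raise ValueError(f"weight for class {c!r} must be finite and >= 0")

    def for_labels(self, labels) -> np.ndarray:
        return np.asarray([self.weights[lab] for lab in labels], dtype=float)


def patient_wise_split(
    cohort: Cohort,
    fractions: tuple[float, float, float],
    seed: int,
) -> CohortSplit:
    """Assign whole patients to train/val/test near the target image fractions.

    Patients are shuffled by ``seed``, stably ordered largest-first by image
    count, and each is assigned greedily to the split with the largest
    remaining image deficit. The assignment is a pure function of
    (cohort, fractions, seed), so the test set can be held constant across
    every downstream experiment.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValueError("fractions must be three positive values")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions):.12f}")
    patients = cohort.patients()
    if len(patients) < 3:
        raise ValueError(
            f"need at least 3 patients to form 3 splits, got {len(patients)}"
        )

    rng = np.random.default_rng(seed)
    order = [str(p) for p in rng.permutation(sorted(patients))]
    order.sort(key=lambda p: -len(patients[p]))  # stable: keeps shuffle for ties

    total = len(cohort)
    targets = [f * total for f in fractions]
    assigned: dict[str, list[str]] = {name: [] for name in _SPLIT_NAMES}
    counts = [0, 0, 0]
    for pid in order:
        deficits = [targets[k] - counts[k] for k in range(3)]
        k = int(np.argmax(deficits))
        assigned[_SPLIT_NAMES[k]].extend(r.image_id for r in patients[pid])
        counts[k] += len(patients[pid])

    split = CohortSplit(
        train_ids=tuple(assigned["train"]),
        val_ids=tuple(assigned["val"]),
        test_ids=tuple(assigned["test"]),
        labeled_ids=tuple(assigned["train"]),
        unlabeled_ids=(),
        seed=seed,
        fractions=fractions,
    )
    split.validate(cohort)
    return split


def _volume_priority(cohort: Cohort, train_ids, seed: int) -> list[str]:
    """Class-stratified, seed-permuted priority order over training volumes.

    The order does not depend on the labeled fraction, so the labeled pools
    of different fractions are nested prefixes of one list.
    """
    train_set = set(train_ids)
    volumes: dict[str, list[str]] = {}
    vol_label: dict[str, str] = {}
    for iid in train_ids:
        rec = cohort[iid]
        volumes.setdefault(rec.volume_id, []).append(iid)
        vol_label[rec.volume_id] = rec.label
    del train_set

    rng = np.random.default_rng(seed)
    queues: dict[str, list[str]] = {c: [] for c in CLASSES}
    for vid in (str(v) for v in rng.permutation(sorted(volumes))):
        queues.setdefault(vol_label[vid], []).append(vid)

    class_total = {
        c: sum(len(volumes[v]) for v in queues.get(c, [])) for c in CLASSES
    }
    taken = {c: 0 for c in CLASSES}
    order: list[str] = []
    while any(queues.get(c) for c in CLASSES):
        # pick the class currently most under-represented among selected images
        candidates = [c for c in CLASSES if queues.get(c)]
        c = min(candidates, key=lambda c: (taken[c] / class_total[c], CLASSES.index(c)))
        vid = queues[c].pop(0)
        taken[c] += len(volumes[vid])
        order.append(vid)
    return order


def subset_labels(
    split: CohortSplit,
    cohort: Cohort,
    labeled_fraction: float,
    seed: int,
) -> CohortSplit:
    """Mark ~``labeled_fraction`` of training images labeled, by whole volumes.

    Volumes enter the labeled pool in a seed-determined, class-stratified
    priority order; the pool is the minimal prefix whose image count reaches
    the target, so pools for smaller fractions are subsets of pools for
    larger ones under the same seed. Validation and test are untouched.
    """
    if not (0.0 < labeled_fraction <= 1.0):
        raise ValueError(f"labeled_fraction must be in (0, 1], got {labeled_fraction}")
    split.validate()
    if labeled_fraction == 1.0:
        return dataclasses.replace(
            split,
            labeled_ids=split.train_ids,
            unlabeled_ids=(),
            labeled_fraction=1.0,
        )

    order = _volume_priority(cohort, split.train_ids, seed)
    vol_images: dict[str, list[str]] = {}
    for iid in split.train_ids:
        vol_images.setdefault(cohort[iid].volume_id, []).append(iid)

    target = labeled_fraction * len(split.train_ids)
    labeled: list[str] = []
    labeled_vols: set[str] = set()
    for vid in order:
        if len(labeled) >= target:
            break
        labeled.extend(vol_images[vid])
        labeled_vols.add(vid)
    labeled_set = set(labeled)
    unlabeled = tuple(i for i in split.train_ids if i not in labeled_set)
    labeled_tuple = tuple(i for i in split.train_ids if i in labeled_set)

    warn: list[str] = list(split.warnings)
    labeled_classes = {cohort[i].label for i in labeled_tuple}
    train_classes = {cohort[i].label for i in split.train_ids}
    for c in sorted(train_classes - labeled_classes):
        msg = f"labeled fraction {labeled_fraction} leaves class {c!r} with zero labeled volumes"
        logger.warning(msg)
        warn.append(msg)

    return dataclasses.replace(
        split,
        labeled_ids=labeled_tuple,
        unlabeled_ids=unlabeled,
        labeled_fraction=labeled_fraction,
        warnings=tuple(warn),
    )


def class_weights(labeled_records) -> ClassWeights:
    """Inverse-frequency weights w(c) = N / (K * N_c) over the K = 3 classes.

    Balanced counts give uniform weights of 1. A class absent from the
    labeled pool gets weight 0 and a recorded warning rather than an
    infinite weight.
    """
    labels = [r.label if hasattr(r, "label") else r for r in labeled_records]
    if not labels:
        raise ValueError("class_weights requires at least one labeled record")
    counts = {c: 0 for c in CLASSES}
    for lab in labels:
        if lab not in counts:
            raise ValueError(f"unknown class label: {lab!r}")
        counts[lab] += 1
    n_total = len(labels)
    k = len(CLASSES)
    weights = {}
    warn = []
    for c in CLASSES:
        if counts[c] == 0:
            weights[c] = 0.0
            msg = f"class {c!r} has zero labeled examples; weight set to 0"
            logger.warning(msg)
            warn.append(msg)
        else:
            weights[c] = n_total / (k * counts[c])
    return ClassWeights(weights=weights, warnings=tuple(warn))


def save_split(split: CohortSplit, path: str | Path) -> None:
    """Serialize as CSV with columns image_id, split, is_labeled."""
    rows = []
    labeled = set(split.labeled_ids)
    for name, ids in zip(_SPLIT_NAMES, (split.train_ids, split.val_ids, split.test_ids)):
        for iid in ids:
            rows.append(
                {
                    "image_id": iid,
                    "split": name,
                    "is_labeled": name != "train" or iid in labeled,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def load_split(path: str | Path, seed: int = -1) -> CohortSplit:
    df = pd.read_csv(path)
    by = {name: df[df["split"] == name] for name in _SPLIT_NAMES}
    train = by["train"]
    labeled = tuple(train[train["is_labeled"]]["image_id"])
    unlabeled = tuple(train[~train["is_labeled"]]["image_id"])
    n = len(df)
    fractions = tuple(len(by[name]) / n for name in _SPLIT_NAMES)
    return CohortSplit(
        train_ids=tuple(train["image_id"]),
        val_ids=tuple(by["val"]["image_id"]),
        test_ids=tuple(by["test"]["image_id"]),
        labeled_ids=labeled,
        unlabeled_ids=unlabeled,
        seed=seed,
        fractions=fractions,
        labeled_fraction=len(labeled) / max(1, len(train)),
    )
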