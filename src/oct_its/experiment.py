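"""Study orchestration: supervised baselines, TS and ITS sweeps.

One run of :func:`run_plan` replays the study design: for each replicate
seed a cohort is generated (or loaded), split patient-wise once — the test
set is constant across every cell of that seed — then each (mode,
label-fraction, threshold) cell is trained and evaluated. SL trains on the
labeled subset only; TS is the teacher-student scheme with a single
iteration; ITS iterates. Results accumulate in a long-format table with one
row per evaluated model.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._common import CLASSES, child_seed, logger
from .dataset import class_weights, patient_wise_split, subset_labels
from .evaluate import roc_analysis
from .its import ITSConfig, evaluate_model, run_its
from .phantom import Cohort, PhantomSpec, generate_cohort, load_manifest
from .preprocess import Pipeline
from .train import TrainConfig, predict_proba, train_supervised

__all__ = ["ExperimentPlan", "run_plan", "summarize",
           "plot_fraction_sweep", "plot_iteration_sweep"]

_MODES = ("SL", "TS", "ITS")


@dataclass(frozen=True)
class ExperimentPlan:
    """Everything needed to reproduce a sweep from (plan, base_seed) alone."""

    label_fractions: tuple[float, ...] = (1.0, 0.7, 0.5, 0.2, 0.05)
    thresholds: tuple[float, ...] = (0.0, 0.90, 0.95, 0.99)
    modes: tuple[str, ...] = ("SL", "TS", "ITS")
    n_seeds: int = 5
    base_seed: int = 0
    split_fractions: tuple[float, float, float] = (0.64, 0.17, 0.19)
    phantom_spec: PhantomSpec | None = None
    manifest_path: str | None = None
    train_config: TrainConfig = field(default_factory=TrainConfig)
    its_config: ITSConfig = field(default_factory=ITSConfig)

    def validate(self) -> None:
        if not self.label_fractions or any(
            not (0.0 < f <= 1.0) for f in self.label_fractions
        ):
            raise ValueError("label_fractions must be in (0, 1]")
        if not self.modes or any(m not in _MODES for m in self.modes):
            raise ValueError(f"modes must be a non-empty subset of {_MODES}")
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")
        if self.phantom_spec is None and self.manifest_path is None:
            raise ValueError("plan needs a phantom_spec or a manifest_path")

    def config_hash(self) -> str:
        blob = json.dumps(
            dataclasses.asdict(self), sort_keys=True, default=str
        ).encode()
        return hashlib.blake2b(blob, digest_size=8).hexdigest()


def _ids_hash(ids) -> str:
    return hashlib.blake2b(
        "\n".join(sorted(ids)).encode(), digest_size=8
    ).hexdigest()


def _roc_aucs(model, records, pipeline) -> tuple[float, float]:
    probs = predict_proba(model, records, pipeline=pipeline)
    try:
        roc = roc_analysis([r.label for r in records], probs)
    except ValueError:  # degenerate evaluation set (single class)
        return np.nan, np.nan
    return roc.micro.auc, roc.macro.auc


def _row(plan, mode, fraction, threshold, iteration, seed_idx, metrics,
         auc_micro, auc_macro, n_pseudo, purity, n_train, test_hash,
         val_accuracy=np.nan, is_best_iteration=True) -> dict:
    return {
        "mode": mode,
        "label_fraction": fraction,
        "threshold": threshold,
        "iteration": iteration,
        "seed": seed_idx,
        "accuracy": metrics.accuracy,
        "val_accuracy": val_accuracy,
        "is_best_iteration": is_best_iteration,
        "precision_macro": metrics.macro_precision,
        "recall_macro": metrics.macro_recall,
        "f1_macro": metrics.macro_f1,
        "precision_weighted": metrics.weighted_precision,
        "recall_weighted": metrics.weighted_recall,
        "f1_weighted": metrics.weighted_f1,
        "auc_micro": auc_micro,
        "auc_macro": auc_macro,
        "n_pseudo_accepted": n_pseudo,
        "purity": purity,
        "n_train": n_train,
        "test_id_hash": test_hash,
        "config_hash": plan.config_hash(),
    }


def run_plan(plan: ExperimentPlan) -> pd.DataFrame:
    """Execute the sweep; one report row per evaluated model.

    Failures of individual cells are logged and recorded in the table's
    ``attrs["errors"]`` rather than aborting the sweep.
    """
    plan.validate()
    rows: list[dict] = []
    errors: list[str] = []

    for s in range(plan.n_seeds):
        root = child_seed(plan.base_seed, "replicate", s)
        if plan.phantom_spec is not None:
            spec = dataclasses.replace(
                plan.phantom_spec, seed=child_seed(root, "cohort")
            )
            cohort = generate_cohort(spec)
        else:
            cohort = load_manifest(plan.manifest_path)
        base_split = patient_wise_split(
            cohort, plan.split_fractions, seed=child_seed(root, "split")
        )
        test_hash = _ids_hash(base_split.test_ids)
        subset_seed = child_seed(root, "subset")
        pipeline = Pipeline(image_size=plan.train_config.image_size)

        for fraction in plan.label_fractions:
            split = subset_labels(base_split, cohort, fraction, seed=subset_seed)
            for mode in plan.modes:
                if mode == "SL":
                    cells = [(mode, None)]
                else:
                    cells = [(mode, thr) for thr in plan.thresholds]
                for mode_, thr in cells:
                    try:
                        rows.extend(
                            _run_cell(
                                plan, cohort, split, mode_, fraction, thr,
                                s, root, test_hash, pipeline,
                            )
                        )
                    except Exception as exc:  # cell failure is not fatal
                        msg = (
                            f"cell failed (seed={s}, mode={mode_}, "
                            f"fraction={fraction}, threshold={thr}): {exc}"
                        )
                        logger.error(msg)
                        errors.append(msg)

    report = pd.DataFrame(rows)
    report.attrs["errors"] = errors
    report.attrs["config_hash"] = plan.config_hash()
    return report


def _run_cell(plan, cohort, split, mode, fraction, threshold, seed_idx,
              root, test_hash, pipeline) -> list[dict]:
    train_cfg = plan.train_config
    test = cohort.subset(split.test_ids)
    if mode == "SL":
        labeled = cohort.subset(split.labeled_ids)
        val = cohort.subset(split.val_ids)
        cfg = dataclasses.replace(
            train_cfg, seed=child_seed(root, "SL", fraction)
        )
        model, _ = train_supervised(
            labeled, val, class_weights(labeled), cfg, pipeline=pipeline
        )
        metrics = evaluate_model(model, test, pipeline)
        val_metrics = evaluate_model(model, val, pipeline)
        auc_mi, auc_ma = _roc_aucs(model, test, pipeline)
        return [
            _row(plan, "SL", fraction, np.nan, 0, seed_idx, metrics,
                 auc_mi, auc_ma, 0, np.nan, len(labeled), test_hash,
                 val_accuracy=val_metrics.accuracy)
        ]

    max_iter = 1 if mode == "TS" else plan.its_config.max_iterations
    its_cfg = dataclasses.replace(
        plan.its_config,
        confidence_threshold=threshold,
        max_iterations=max_iter,
        seed=child_seed(root, mode, fraction, threshold),
    )
    result = run_its(split, cohort, train_cfg, its_cfg)
    out = []
    for it in result.iterations:
        is_best = it.iteration == result.best_iteration
        auc_mi, auc_ma = _roc_aucs(result.final_model, test, pipeline) \
            if is_best else (np.nan, np.nan)
        out.append(
            _row(plan, mode, fraction, threshold, it.iteration, seed_idx,
                 it.test_metrics, auc_mi, auc_ma, it.n_accepted,
                 np.nan if it.purity is None else it.purity,
                 len(it.train_ids), test_hash,
                 val_accuracy=it.val_metrics.accuracy,
                 is_best_iteration=is_best)
        )
    return out


def summarize(report: pd.DataFrame) -> pd.DataFrame:
    """Mean ± sd over seeds per (mode, fraction, threshold, iteration).

    Adds ``is_best``: within each (mode, label_fraction), the threshold/
    iteration cell with the highest mean accuracy.
    """
    if report.empty:
        raise ValueError("report is empty")
    keys = ["mode", "label_fraction", "threshold", "iteration"]
    metrics = ["accuracy", "precision_macro", "recall_macro", "f1_macro",
               "n_pseudo_accepted", "purity"]
    grouped = report.groupby(keys, dropna=False)[metrics]
    summary = grouped.agg(["mean", "std"])
    summary.columns = [f"{m}_{s}" for m, s in summary.columns]
    summary["n_seeds"] = grouped.size()
    summary = summary.reset_index()
    summary["accuracy_std"] = summary["accuracy_std"].fillna(0.0)
    best = summary.groupby(["mode", "label_fraction"])["accuracy_mean"] \
                  .transform("max")
    summary["is_best"] = summary["accuracy_mean"] >= best - 1e-12
    return summary


def plot_fraction_sweep(summary: pd.DataFrame, ax=None):
    """Mean test metrics vs labeled fraction, one line per metric (SL rows)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    sl = summary[summary["mode"] == "SL"].sort_values("label_fraction")
    for metric in ("accuracy", "precision_macro", "recall_macro", "f1_macro"):
        ax.plot(sl["label_fraction"], sl[f"{metric}_mean"], marker="o",
                label=metric)
    ax.set_xlabel("labeled fraction of training data")
    ax.set_ylabel("test metric (mean over seeds)")
    ax.legend()
    ax.set_title("Supervised performance under label scarcity")
    return ax


def plot_iteration_sweep(summary: pd.DataFrame, mode: str = "ITS", ax=None):
    """Mean test accuracy vs iteration, one line per labeled fraction."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    sub = summary[summary["mode"] == mode]
    for (frac, thr), grp in sub.groupby(["label_fraction", "threshold"]):
        grp = grp.sort_values("iteration")
        ax.plot(grp["iteration"], grp["accuracy_mean"], marker="o",
                label=f"fraction={frac}, thr={thr}")
    ax.set_xlabel("teacher-student iteration")
    ax.set_ylabel("test accuracy (mean over seeds)")
    ax.legend(fontsize=8)
    ax.set_title(f"{mode} accuracy across iterations")
    return ax
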