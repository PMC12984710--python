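"""Supervised training protocol around a pluggable probabilistic classifier.

The protocol: mini-batch Adam at an initial learning rate of 1e-3 on a
class-weighted categorical cross-entropy, learning-rate reduction by a
factor of 0.1 after 10 epochs without validation-loss improvement, early
stopping after 15 such epochs, and restoration of the best-epoch (minimum
validation loss) parameters. "Improvement" means a decrease of at least
``min_delta`` (1e-4).

Backbones implement the :class:`Classifier` contract and register by name.
The reference backbone is a small multilayer perceptron on mean-pooled
pixels — deliberately lightweight so the full iterative teacher-student
experiment runs on one CPU in minutes; heavier convolutional backbones can
be registered without touching the protocol.
"""

from __future__ import annotations

import dataclasses
from abc import ABC, abstractmethod
from dataclasses import dataclass, field

import numpy as np

from ._common import CLASSES, encode_labels, logger
from .dataset import ClassWeights
from .preprocess import AugmentConfig, Pipeline

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "Classifier",
    "SmallMLP",
    "BACKBONES",
    "register_backbone",
    "make_backbone",
    "train_supervised",
    "predict_proba",
]


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one supervised training run."""

    batch_size: int = 64
    max_epochs: int = 100
    learning_rate: float = 1e-3
    lr_reduce_factor: float = 0.1
    lr_reduce_patience: int = 10
    early_stop_patience: int = 15
    min_delta: float = 1e-4
    seed: int = 0
    backbone: str = "small_mlp"
    image_size: tuple[int, int] = (64, 64)
    augment: AugmentConfig | None = None
    #: loss-weight multiplier applied to pseudo-labeled samples (1 = full)
    pseudo_label_weight: float = 1.0

    def validate(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.lr_reduce_patience < 1 or self.early_stop_patience < 1:
            raise ValueError("patiences must be >= 1")
        if self.lr_reduce_patience >= self.early_stop_patience:
            raise ValueError(
                "lr_reduce_patience must be < early_stop_patience so the "
                "learning-rate reduction can fire before training stops"
            )
        if not (0.0 < self.lr_reduce_factor < 1.0):
            raise ValueError("lr_reduce_factor must be in (0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class TrainHistory:
    """Per-epoch curves plus the checkpointing outcome."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_early: bool = False

    @property
    def n_epochs(self) -> int:
        return len(self.val_loss)


class Classifier(ABC):
    """Abstract probabilistic 3-class image classifier.

    ``predict_proba`` rows are ordered (normal, drusen, cnv), non-negative
    and sum to 1. ``clone_untrained`` yields an architecturally identical but
    unfitted instance, used to give each student a fresh start.
    """

    is_fitted: bool = False

    @abstractmethod
    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        sample_weight: np.ndarray,
        config: TrainConfig,
        X_val: np.ndarray,
        y_val: np.ndarray,
    ) -> TrainHistory: ...

    @abstractmethod
    def predict_proba(self, X: np.ndarray) -> np.ndarray: ...

    @abstractmethod
    def clone_untrained(self) -> "Classifier": ...


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _weighted_ce(probs: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    # normalized by the weight sum: scaling all weights leaves the loss
    # (and its gradient) unchanged
    p = np.clip(probs[np.arange(len(y)), y], 1e-12, None)
    return float(-(w * np.log(p)).sum() / w.sum())


class SmallMLP(Classifier):
    """Reference backbone: mean-pool to a coarse grid, then a small MLP.

    Images are block-averaged to ``pool_to`` (bilinear resampling when the
    shape does not divide evenly), flattened, and passed through one ReLU
    hidden layer into a 3-way softmax. About 12k parameters at the defaults:
    enough to learn the phantom task, small enough to train in seconds.
    """

    def __init__(self, hidden: tuple[int, ...] = (48,), pool_to: tuple[int, int] = (16, 16)):
        self.hidden = tuple(hidden)
        self.pool_to = tuple(pool_to)
        self.params: list[np.ndarray] | None = None
        self.is_fitted = False

    def clone_untrained(self) -> "SmallMLP":
        return SmallMLP(hidden=self.hidden, pool_to=self.pool_to)

    # -- features ---------------------------------------------------------
    def _featurize(self, X: np.ndarray) -> np.ndarray:
        n, h, w = X.shape
        ph, pw = self.pool_to
        if h % ph == 0 and w % pw == 0:
            F = X.reshape(n, ph, h // ph, pw, w // pw).mean(axis=(2, 4))
        else:
            from .preprocess import resize

            F = np.stack([resize(img, (ph, pw)) for img in X])
        return F.reshape(n, ph * pw)

    # -- forward / backward ----------------------------------------------
    def _init_params(self, d_in: int, rng: np.random.Generator) -> list[np.ndarray]:
        dims = (d_in, *self.hidden, len(CLASSES))
        params: list[np.ndarray] = []
        for a, b in zip(dims[:-1], dims[1:]):
            params.append(rng.normal(0.0, np.sqrt(2.0 / a), size=(a, b)))
            params.append(np.zeros(b))
        return params

    def _forward(self, F: np.ndarray, params: list[np.ndarray]):
        acts = [F]
        a = F
        n_layers = len(params) // 2
        for i in range(n_layers):
            z = a @ params[2 * i] + params[2 * i + 1]
            a = np.maximum(z, 0.0) if i < n_layers - 1 else z
            acts.append(a)
        return _softmax(acts[-1]), acts

    def _backward(self, acts, probs, y, w, params):
        n = len(y)
        wn = w / w.sum()
        delta = probs.copy()
        delta[np.arange(n), y] -= 1.0
        delta *= wn[:, None]
        grads: list[np.ndarray] = []
        n_layers = len(params) // 2
        for i in reversed(range(n_layers)):
            a_prev = acts[i]
            grads.insert(0, delta.sum(axis=0))
            grads.insert(0, a_prev.T @ delta)
            if i > 0:
                delta = (delta @ params[2 * i].T) * (acts[i] > 0)
        return grads

    # -- protocol ---------------------------------------------------------
    def fit(self, X, y, sample_weight, config, X_val, y_val) -> TrainHistory:
        config.validate()
        rng = np.random.default_rng(config.seed)
        F = self._featurize(np.asarray(X, dtype=float))
        Fv = self._featurize(np.asarray(X_val, dtype=float))
        y = np.asarray(y)
        w = np.asarray(sample_weight, dtype=float)
        params = self._init_params(F.shape[1], rng)
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0

        history = TrainHistory()
        lr = config.learning_rate
        best_loss = np.inf   # patience reference: improvements >= min_delta
        ckpt_loss = np.inf   # checkpoint reference: any strict improvement
        best_params = [p.copy() for p in params]
        wait_lr = wait_es = 0
        wv = np.ones(len(y_val))

        for epoch in range(config.max_epochs):
            perm = rng.permutation(len(y))
            epoch_loss = 0.0
            weight_seen = 0.0
            for start in range(0, len(y), config.batch_size):
                idx = perm[start : start + config.batch_size]
                probs, acts = self._forward(F[idx], params)
                grads = self._backward(acts, probs, y[idx], w[idx], params)
                step += 1
                for k, g in enumerate(grads):
                    m[k] = beta1 * m[k] + (1 - beta1) * g
                    v[k] = beta2 * v[k] + (1 - beta2) * g**2
                    mhat = m[k] / (1 - beta1**step)
                    vhat = v[k] / (1 - beta2**step)
                    params[k] -= lr * mhat / (np.sqrt(vhat) + eps)
                bw = w[idx].sum()
                epoch_loss += _weighted_ce(probs, y[idx], w[idx]) * bw
                weight_seen += bw

            val_probs, _ = self._forward(Fv, params)
            val_loss = _weighted_ce(val_probs, np.asarray(y_val), wv)
            val_acc = float((val_probs.argmax(axis=1) == np.asarray(y_val)).mean())
            history.train_loss.append(epoch_loss / max(weight_seen, 1e-12))
            history.val_loss.append(val_loss)
            history.val_accuracy.append(val_acc)
            history.learning_rate.append(lr)

            if val_loss < ckpt_loss:
                ckpt_loss = val_loss
                best_params = [p.copy() for p in params]
                history.best_epoch = epoch
            if val_loss < best_loss - config.min_delta:
                best_loss = val_loss
                wait_lr = wait_es = 0
            else:
                wait_lr += 1
                wait_es += 1
                if wait_lr >= config.lr_reduce_patience:
                    lr *= config.lr_reduce_factor
                    wait_lr = 0
                    logger.debug("epoch %d: reducing learning rate to %.2g", epoch, lr)
                if wait_es >= config.early_stop_patience:
                    history.stopped_early = True
                    break

        if history.best_epoch < 0:  # no epoch improved on +inf guard epoch 0
            history.best_epoch = int(np.argmin(history.val_loss))
            best_params = params
        self.params = best_params
        self.is_fitted = True
        return history

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if not self.is_fitted or self.params is None:
            raise RuntimeError("classifier is not trained; call fit first")
        F = self._featurize(np.asarray(X, dtype=float))
        probs, _ = self._forward(F, self.params)
        return probs


BACKBONES: dict[str, type] = {}


def register_backbone(name: str):
    """Register a :class:`Classifier` factory under ``name``."""

    def deco(cls):
        BACKBONES[name] = cls
        return cls

    return deco


BACKBONES["small_mlp"] = SmallMLP


@register_backbone("softmax_linear")
class SoftmaxLinear(SmallMLP):
    """Linear softmax regression on pooled pixels; fastest sanity backbone."""

    def __init__(self, pool_to: tuple[int, int] = (16, 16)):
        super().__init__(hidden=(), pool_to=pool_to)

    def clone_untrained(self) -> "SoftmaxLinear":
        return SoftmaxLinear(pool_to=self.pool_to)


def make_backbone(name: str) -> Classifier:
    try:
        return BACKBONES[name]()
    except KeyError:
        raise ValueError(
            f"unknown backbone {name!r}; registered: {sorted(BACKBONES)}"
        ) from None


def save_model(model: Classifier, path) -> None:
    """Serialize a fitted MLP-family backbone to an .npz archive."""
    if not isinstance(model, SmallMLP) or not model.is_fitted:
        raise ValueError("can only save fitted SmallMLP-family backbones")
    name = next((n for n, cls in BACKBONES.items() if type(model) is cls), None)
    np.savez(
        path,
        backbone=np.array(name or "small_mlp"),
        hidden=np.array(model.hidden, dtype=np.int64),
        pool_to=np.array(model.pool_to, dtype=np.int64),
        **{f"param_{i}": p for i, p in enumerate(model.params)},
    )


def load_model(path) -> Classifier:
    with np.load(path) as data:
        model = SmallMLP(
            hidden=tuple(int(h) for h in data["hidden"]),
            pool_to=tuple(int(p) for p in data["pool_to"]),
        )
        n_params = sum(1 for k in data.files if k.startswith("param_"))
        model.params = [data[f"param_{i}"] for i in range(n_params)]
    model.is_fitted = True
    return model


def _sample_weights(records, weights: ClassWeights, config: TrainConfig,
                    pseudo_ids: set[str] | None = None) -> np.ndarray:
    w = weights.for_labels([r.label for r in records])
    if pseudo_ids:
        mask = np.asarray([r.image_id in pseudo_ids for r in records])
        w = np.where(mask, w * config.pseudo_label_weight, w)
    return w


def train_supervised(
    labeled_records,
    val_records,
    weights: ClassWeights,
    config: TrainConfig,
    pipeline: Pipeline | None = None,
    pseudo_ids: set[str] | None = None,
) -> tuple[Classifier, TrainHistory]:
    """Train a backbone on labeled records under the full protocol.

    ``pseudo_ids`` marks records whose labels are model-predicted rather than
    ground truth; their loss weight is multiplied by
    ``config.pseudo_label_weight`` (1 by default).
    """
    config.validate()
    labeled_records = list(labeled_records)
    val_records = list(val_records)
    if not labeled_records:
        raise ValueError("labeled set is empty")
    if not val_records:
        raise ValueError("validation set is empty")
    present = {r.label for r in labeled_records}
    if len(present) < 2:
        missing = sorted(set(CLASSES) - present)
        raise ValueError(
            f"labeled set covers a single class; missing classes: {missing}"
        )

    pipeline = pipeline or Pipeline(image_size=config.image_size,
                                    augment_config=config.augment)
    rng = np.random.default_rng(config.seed)
    X = pipeline.transform(labeled_records, role="train", rng=rng)
    X_val = pipeline.transform(val_records, role="val")
    y = encode_labels([r.label for r in labeled_records])
    y_val = encode_labels([r.label for r in val_records])
    w = _sample_weights(labeled_records, weights, config, pseudo_ids)

    model = make_backbone(config.backbone)
    history = model.fit(X, y, w, config, X_val, y_val)
    logger.info(
        "trained %s on %d records: %d epochs, best epoch %d, val acc %.3f",
        config.backbone, len(labeled_records), history.n_epochs,
        history.best_epoch, history.val_accuracy[history.best_epoch],
    )
    return model, history


def predict_proba(
    model: Classifier,
    records,
    pipeline: Pipeline | None = None,
    image_size: tuple[int, int] = (64, 64),
) -> np.ndarray:
    """Class-probability matrix, one row per record, columns (normal, drusen, cnv)."""
    if not getattr(model, "is_fitted", False):
        raise RuntimeError("classifier is not trained; call fit first")
    pipeline = pipeline or Pipeline(image_size=image_size)
    X = pipeline.transform(list(records), role="unlabeled")
    return model.predict_proba(X)
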