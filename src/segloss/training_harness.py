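"""Desk-scale trainable segmenter with a pluggable loss.

The model is deliberately small: a fixed multi-scale feature bank (raw
intensity, Gaussian smoothings, gradient magnitude, normalised pixel
coordinates) feeding a trained per-pixel linear softmax classifier.  It
exists to exercise the loss family, not to compete with deep
architectures: every loss spec the losses module accepts is trainable
through the same value-and-gradient contract, optimised with stochastic
gradient descent with momentum (SGDM) under a piecewise learning-rate
schedule (initial rate 0.005, drop factor 0.9 every 20 epochs,
momentum 0.9 — the reference training recipe, at a reduced default epoch
count of 50 for desk-scale runs).

Gradients flow analytically: d(loss)/d(scores) comes from the losses
module, is pulled back through the softmax Jacobian, then through the
linear layer.  No autodiff framework is involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .losses import LossSpec, class_balance_weights, evaluate_loss, one_hot
from .metrics_core import (
    ClassSet,
    ConfusionCounts,
    LabelMap,
    metric_suite,
    per_class_confusion,
)

__all__ = [
    "TrainConfig",
    "TrainResult",
    "LinearSoftmaxModel",
    "TrainingDiverged",
    "extract_features",
    "train",
    "evaluate",
]

Record = tuple[int, np.ndarray, LabelMap]  # (patient id, image, groundtruth)


class TrainingDiverged(RuntimeError):
    """Raised when the training loss becomes non-finite."""

    def __init__(self, epoch: int, value: float):
        super().__init__(f"training loss became non-finite ({value}) at epoch {epoch}")
        self.epoch = epoch


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters; defaults follow the SGDM reference recipe."""

    loss: LossSpec
    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 0.005
    drop_period: int = 20
    drop_factor: float = 0.9
    momentum: float = 0.9
    auto_balance: bool = True   # inverse-frequency weights for crossE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch size must be positive")
        if self.learning_rate < 0:
            raise ValueError("learning rate must be nonnegative")

    def rate_at(self, epoch: int) -> float:
        """Piecewise schedule: rate drops by ``drop_factor`` every ``drop_period``."""
        return self.learning_rate * self.drop_factor ** (epoch // self.drop_period)


def extract_features(image: np.ndarray) -> np.ndarray:
    """Fixed per-pixel feature bank: (H*W, F) with a leading bias column.

    Features: bias, intensity, Gaussian smoothings at sigma 1/2/4,
    gradient magnitude, and normalised row/column coordinates.
    """
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    gy, gx = np.gradient(img)
    yy, xx = np.mgrid[0:h, 0:w]
    feats = np.stack(
        [
            np.ones_like(img),
            img,
            ndimage.gaussian_filter(img, 1.0),
            ndimage.gaussian_filter(img, 2.0),
            ndimage.gaussian_filter(img, 4.0),
            np.hypot(gy, gx),
            yy / max(h - 1, 1),
            xx / max(w - 1, 1),
        ],
        axis=-1,
    )
    return feats.reshape(-1, feats.shape[-1])


N_FEATURES = 8


@dataclass
class LinearSoftmaxModel:
    """Per-pixel linear softmax classifier over the fixed feature bank."""

    weights: np.ndarray  # (F, C)
    class_set: ClassSet

    def predict_prob(self, image: np.ndarray) -> np.ndarray:
        """Per-pixel class probabilities, shape (H, W, C)."""
        h, w = np.asarray(image).shape
        z = extract_features(image) @ self.weights
        z -= z.max(axis=1, keepdims=True)
        e = np.exp(z)
        probs = e / e.sum(axis=1, keepdims=True)
        return probs.reshape(h, w, self.class_set.n_classes)

    def predict(self, image: np.ndarray) -> LabelMap:
        probs = self.predict_prob(image)
        labels = np.asarray(self.class_set.labels)[np.argmax(probs, axis=-1)]
        return LabelMap(labels, self.class_set)


@dataclass
class TrainResult:
    """Outcome of one training run."""

    model: LinearSoftmaxModel
    loss_history: np.ndarray          # full-training-set loss after each epoch
    metrics: pd.DataFrame | None      # held-out per-class metric table
    config: TrainConfig = field(repr=False, default=None)  # type: ignore[assignment]


def _pooled_loss_and_grad(
    model_w: np.ndarray,
    feats: list[np.ndarray],
    targets: list[np.ndarray],
    spec: LossSpec,
    class_set: ClassSet,
    want_grad: bool,
):
    """Loss over a set of images with counts pooled across the batch."""
    X = np.vstack(feats)
    T = np.vstack(targets)
    z = X @ model_w
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    S = e / e.sum(axis=1, keepdims=True)
    if not want_grad:
        return evaluate_loss(S, T, spec, class_set=class_set), None
    value, dS = evaluate_loss(S, T, spec, class_set=class_set, return_grad=True)
    # softmax pullback: dZ = S * (dS - sum(dS * S))
    dZ = S * (dS - np.sum(dS * S, axis=1, keepdims=True))
    dW = X.T @ dZ
    return value, dW


def train(
    train_records: list[Record],
    config: TrainConfig,
    class_set: ClassSet | None = None,
    warm_start: LinearSoftmaxModel | None = None,
) -> TrainResult:
    """Train the segmenter on a set of (patient, image, labelmap) records.

    Minibatches are whole images; per-class counts are pooled over the
    minibatch before the loss ratio is formed (micro-averaging).  With a
    crossE loss and ``auto_balance``, inverse-frequency class weights are
    computed from the training labelmaps unless the spec already carries
    weights.  Raises :class:`TrainingDiverged` if the loss becomes
    non-finite.  Returns a :class:`TrainResult` whose ``loss_history`` is
    the full-training-set loss after each epoch.

    ``warm_start`` continues from an existing model's weights instead of
    random initialisation.  Count-based losses (IoU/dice family) have a
    gradient plateau at the all-background prediction, so fine-tuning
    them from a cross-entropy warm start is the reliable recipe —
    mirroring the standard practice of training from pretrained weights.
    """
    if not train_records:
        raise ValueError("empty training set")
    cs = class_set or train_records[0][2].class_set
    if warm_start is not None and warm_start.class_set != cs:
        raise ValueError("warm-start model has a different class set")
    spec = config.loss
    if spec.family == "crossE" and config.auto_balance and spec.class_weights is None:
        w = class_balance_weights([r[2] for r in train_records], cs)
        spec = LossSpec(
            "crossE", class_weights=tuple(w), smoothing_eps=spec.smoothing_eps
        )
    feats = [extract_features(img) for _, img, _ in train_records]
    targets = [one_hot(lab).reshape(-1, cs.n_classes) for _, _, lab in train_records]
    rng = np.random.default_rng(config.seed)
    if warm_start is not None:
        W = warm_start.weights.copy()
    else:
        W = rng.normal(0.0, 0.01, size=(N_FEATURES, cs.n_classes))
    velocity = np.zeros_like(W)
    n = len(train_records)
    history = np.empty(config.epochs)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        lr = config.rate_at(epoch)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            _, dW = _pooled_loss_and_grad(
                W, [feats[i] for i in idx], [targets[i] for i in idx], spec, cs, True
            )
            velocity = config.momentum * velocity - lr * dW
            W = W + velocity
        value, _ = _pooled_loss_and_grad(W, feats, targets, spec, cs, False)
        history[epoch] = value.value
        if not np.isfinite(history[epoch]):
            raise TrainingDiverged(epoch, history[epoch])
    model = LinearSoftmaxModel(weights=W, class_set=cs)
    return TrainResult(model=model, loss_history=history, metrics=None, config=config)


def evaluate(
    model: LinearSoftmaxModel, test_records: list[Record]
) -> pd.DataFrame:
    """Per-class metric table over a test set, counts pooled across slices.

    Predictions are per-pixel argmax of the model's probabilities; the
    per-class confusion counts of all slices are summed before the
    metrics are formed.
    """
    if not test_records:
        raise ValueError("empty test set")
    cs = model.class_set
    tp = np.zeros(cs.n_classes, dtype=np.int64)
    fp = np.zeros_like(tp)
    fn = np.zeros_like(tp)
    tn = np.zeros_like(tp)
    for _, img, gnd in test_records:
        if gnd.class_set != cs:
            raise ValueError("test labelmap class set does not match the model's")
        counts = per_class_confusion(gnd, model.predict(img))
        tp += counts.tp
        fp += counts.fp
        fn += counts.fn
        tn += counts.tn
    return metric_suite(ConfusionCounts(cs, tp, fp, fn, tn))
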