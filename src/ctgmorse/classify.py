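"""Splitting, transfer-learning classification, and confusion-matrix metrics.

The classification stage follows the transfer-learning pattern: a frozen
feature-extracting backbone consuming 224 x 224 x 3 scalogram images, with a
freshly initialized two-class softmax head trained on top.  The backbone is
pluggable — anything exposing ``transform(images) -> features`` works, from a
pretrained deep network to the lightweight fixed-random-convolution extractor
provided here, which lets the whole pipeline run without any weight download.

The head is trained with minibatch Adam (defaults: learning rate 0.001,
minibatch 30) with validation measured every ``validation_frequency``
iterations on a per-class 10% draw from the training pool, mirroring the
training protocol used for the fine-tuned ResNet-50 experiments.  Splits are
stratified per class: 10% of items to the held-out test set, the rest to the
training pool.  An optional record-grouped split keeps all augmented slices
of one recording on the same side, preventing leakage between train and test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Protocol, Sequence

import numpy as np

from .augment import LabeledDataset
from .errors import SplitError
from .record_io import ClassLabel

logger = logging.getLogger(__name__)


def round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# --- splitting ----------------------------------------------------------

@dataclass
class SplitIndices:
    """Disjoint, exhaustive item-id partition; validation is carved from train."""

    train: list[str]
    validation: list[str]
    test: list[str]
    seed: int = 0

    def check(self) -> None:
        parts = [set(self.train), set(self.validation), set(self.test)]
        total = sum(len(p) for p in parts)
        if len(set().union(*parts)) != total:
            raise SplitError("split parts are not pairwise disjoint")


def _per_class_ids(dataset: LabeledDataset) -> dict[ClassLabel, list[str]]:
    out: dict[ClassLabel, list[str]] = {c: [] for c in ClassLabel}
    for it in dataset.items:
        out[it.label].append(it.item_id)
    return out


def stratified_split(
    dataset: LabeledDataset,
    test_frac: float = 0.10,
    seed: int = 0,
    by_record: bool = False,
    validation_frac: float = 0.10,
) -> SplitIndices:
    """Per-class stratified train/validation/test split.

    Per class, ``round(test_frac * n)`` items go to test and the remainder to
    the training pool, from which a per-class ``validation_frac`` draw is set
    aside for monitoring.  With ``by_record`` the units being split are
    recordings rather than items, so augmented slices of one recording can
    never span train and test.
    """
    rng = np.random.default_rng(seed)
    train: list[str] = []
    validation: list[str] = []
    test: list[str] = []

    if by_record:
        groups: dict[ClassLabel, dict[str, list[str]]] = {c: {} for c in ClassLabel}
        for it in dataset.items:
            groups[it.label].setdefault(it.record_id, []).append(it.item_id)
        for label in ClassLabel:
            recs = sorted(groups[label])
            if len(recs) < 2:
                raise SplitError(f"class {label.value} has fewer than 2 records")
            recs = list(rng.permutation(recs))
            n_test = int(np.floor(len(recs) * test_frac + 0.5))
            n_test = min(max(n_test, 1), len(recs) - 1)
            test_recs, pool = recs[:n_test], recs[n_test:]
            n_val = int(np.floor(len(pool) * validation_frac + 0.5))
            val_recs, train_recs = pool[:n_val], pool[n_val:]
            for r in test_recs:
                test.extend(groups[label][r])
            for r in val_recs:
                validation.extend(groups[label][r])
            for r in train_recs:
                train.extend(groups[label][r])
    else:
        for label, ids in _per_class_ids(dataset).items():
            if len(ids) < 2:
                raise SplitError(f"class {label.value} has fewer than 2 items")
            ids = list(rng.permutation(ids))
            n_test = int(np.floor(len(ids) * test_frac + 0.5))
            n_test = min(max(n_test, 1), len(ids) - 1)
            test.extend(ids[:n_test])
            pool = ids[n_test:]
            n_val = int(np.floor(len(pool) * validation_frac + 0.5))
            validation.extend(pool[:n_val])
            train.extend(pool[n_val:])

    split = SplitIndices(train=train, validation=validation, test=test, seed=seed)
    split.check()
    return split


# --- backbone -----------------------------------------------------------

class Backbone(Protocol):
    """A frozen feature extractor over H x W x 3 uint8 images."""

    input_size: tuple[int, int]

    def transform(self, images: np.ndarray) -> np.ndarray:
        """(n, H, W, 3) uint8 -> (n, d) float features."""
        ...


class TinyConvBackbone:
    """A small fixed-random convolutional feature extractor.

    Images are block-mean downsampled, convolved with ``n_filters`` random
    5 x 5 x 3 kernels (frozen at construction from ``seed``), passed through
    ReLU, and block-mean pooled.  It is not pretrained — it stands in for a
    deep backbone wherever the pipeline structure, not ImageNet features, is
    under study — and it is fully deterministic for a fixed seed.
    """

    def __init__(
        self,
        n_filters: int = 8,
        kernel: int = 5,
        downsample: int = 4,
        pool: int = 4,
        seed: int = 0,
        input_size: tuple[int, int] = (224, 224),
    ) -> None:
        rng = np.random.default_rng(seed)
        self.filters = rng.standard_normal((n_filters, kernel, kernel, 3))
        self.filters /= np.sqrt(kernel * kernel * 3)
        self.kernel = kernel
        self.downsample = downsample
        self.pool = pool
        self.input_size = input_size

    @staticmethod
    def _block_mean(x: np.ndarray, b: int) -> np.ndarray:
        n, h, w = x.shape[:3]
        rest = x.shape[3:]
        h2, w2 = (h // b) * b, (w // b) * b
        x = x[:, :h2, :w2]
        return x.reshape(n, h2 // b, b, w2 // b, b, *rest).mean(axis=(2, 4))

    def transform(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=float) / 255.0
        if x.ndim != 4 or x.shape[3] != 3:
            raise ValueError("expected (n, H, W, 3) images")
        x = x.reshape(x.shape[0], x.shape[1], x.shape[2], 3)
        small = self._block_mean(x, self.downsample)  # (n, h, w, 3)
        k = self.kernel
        n, h, w, _ = small.shape
        windows = np.lib.stride_tricks.sliding_window_view(
            small, (k, k), axis=(1, 2)
        )  # (n, h-k+1, w-k+1, 3, k, k)
        resp = np.einsum("nijckl,fklc->nijf", windows, self.filters)
        resp = np.maximum(resp, 0.0)
        pooled = self._block_mean(resp, self.pool)  # (n, h', w', f)
        return pooled.reshape(n, -1)


# --- training -----------------------------------------------------------

@dataclass
class TrainConfig:
    """Softmax-head fine-tuning hyperparameters."""

    optimizer: str = "adam"
    learning_rate: float = 0.001
    minibatch: int = 30
    max_epochs: int = 15
    validation_frequency: int = 15   # iterations between validation passes
    n_classes: int = 2
    seed: int = 20210000

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.minibatch < 1:
            raise ValueError("learning_rate must be > 0 and minibatch >= 1")


@dataclass
class LearningCurves:
    iteration: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_iteration: list[int] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)


@dataclass
class TrainedModel:
    backbone: Backbone
    weights: np.ndarray          # (d, n_classes)
    bias: np.ndarray             # (n_classes,)
    feature_mean: np.ndarray
    feature_std: np.ndarray
    config: TrainConfig
    curves: LearningCurves

    def _features(self, images: np.ndarray) -> np.ndarray:
        f = self.backbone.transform(images)
        return (f - self.feature_mean) / self.feature_std

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        z = self._features(images) @ self.weights + self.bias
        z -= z.max(axis=1, keepdims=True)
        p = np.exp(z)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, images: np.ndarray) -> list[ClassLabel]:
        order = [ClassLabel.NORMAL, ClassLabel.DISTRESSED]
        return [order[i] for i in self.predict_proba(images).argmax(axis=1)]


def _encode_labels(labels: Sequence[ClassLabel]) -> np.ndarray:
    return np.array([1 if l is ClassLabel.DISTRESSED else 0 for l in labels])


def _softmax_loss_grad(z: np.ndarray, y: np.ndarray):
    z = z - z.max(axis=1, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=1, keepdims=True)
    n = len(y)
    loss = -np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean()
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n, p


def train_classifier(
    images: np.ndarray,
    labels: Sequence[ClassLabel],
    config: TrainConfig = TrainConfig(),
    backbone: Backbone | None = None,
    val_images: np.ndarray | None = None,
    val_labels: Sequence[ClassLabel] | None = None,
) -> TrainedModel:
    """Fit the two-class softmax head on backbone features with Adam.

    ``images`` is (n, H, W, 3) uint8; validation metrics are recorded every
    ``config.validation_frequency`` iterations when a validation set is given.
    Deterministic for fixed seeds (numpy-only arithmetic).
    """
    if backbone is None:
        backbone = TinyConvBackbone(seed=config.seed)
    if config.optimizer.lower() != "adam":
        raise ValueError(f"unsupported optimizer {config.optimizer!r}")

    feats = backbone.transform(images)
    mean = feats.mean(axis=0)
    std = feats.std(axis=0)
    std[std < 1e-8] = 1.0
    X = (feats - mean) / std
    y = _encode_labels(labels)
    if val_images is not None:
        Xv = (backbone.transform(val_images) - mean) / std
        yv = _encode_labels(val_labels)
    else:
        Xv = yv = None

    rng = np.random.default_rng(config.seed)
    d = X.shape[1]
    W = rng.standard_normal((d, config.n_classes)) * 0.01
    b = np.zeros(config.n_classes)
    mW = np.zeros_like(W); vW = np.zeros_like(W)
    mb = np.zeros_like(b); vb = np.zeros_like(b)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    curves = LearningCurves()

    t = 0
    n = len(X)
    for _epoch in range(config.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.minibatch):
            idx = order[start : start + config.minibatch]
            t += 1
            z = X[idx] @ W + b
            loss, dz, p = _softmax_loss_grad(z, y[idx])
            gW = X[idx].T @ dz
            gb = dz.sum(axis=0)
            for g, m_, v_, param in (
                (gW, mW, vW, W),
                (gb, mb, vb, b),
            ):
                m_ *= beta1; m_ += (1 - beta1) * g
                v_ *= beta2; v_ += (1 - beta2) * g * g
                mhat = m_ / (1 - beta1 ** t)
                vhat = v_ / (1 - beta2 ** t)
                param -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)
            curves.iteration.append(t)
            curves.train_loss.append(float(loss))
            curves.train_accuracy.append(float((p.argmax(1) == y[idx]).mean()))
            if Xv is not None and t % config.validation_frequency == 0:
                zv = Xv @ W + b
                vloss, _, pv = _softmax_loss_grad(zv, yv)
                curves.val_iteration.append(t)
                curves.val_loss.append(float(vloss))
                curves.val_accuracy.append(float((pv.argmax(1) == yv).mean()))

    return TrainedModel(
        backbone=backbone,
        weights=W,
        bias=b,
        feature_mean=mean,
        feature_std=std,
        config=config,
        curves=curves,
    )


# --- evaluation ---------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """Binary confusion counts with distressed as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @classmethod
    def from_predictions(
        cls, truth: Sequence[ClassLabel], predicted: Sequence[ClassLabel]
    ) -> "ConfusionMatrix":
        tp = fn = fp = tn = 0
        for t_, p_ in zip(truth, predicted, strict=True):
            if t_ is ClassLabel.DISTRESSED:
                if p_ is ClassLabel.DISTRESSED:
                    tp += 1
                else:
                    fn += 1
            else:
                if p_ is ClassLabel.DISTRESSED:
                    fp += 1
                else:
                    tn += 1
        return cls(tp=tp, fn=fn, fp=fp, tn=tn)


def evaluate(
    model: TrainedModel,
    images: np.ndarray,
    labels: Sequence[ClassLabel],
) -> ConfusionMatrix:
    """Confusion matrix of model predictions on a held-out test set."""
    if len(images) == 0:
        raise ValueError("empty test set")
    return ConfusionMatrix.from_predictions(labels, model.predict(images))


@dataclass
class Metrics:
    """Accuracy / sensitivity / specificity in percent (1 decimal, half-up).

    A metric whose denominator is zero is reported as None rather than
    raising (the ``undefined`` tuple says which).
    """

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None

    @property
    def undefined(self) -> tuple[str, ...]:
        return tuple(
            name
            for name, v in (
                ("accuracy", self.accuracy),
                ("sensitivity", self.sensitivity),
                ("specificity", self.specificity),
            )
            if v is None
        )


def metrics(cm: ConfusionMatrix) -> Metrics:
    """Acc = (tp+tn)/total, Se = tp/(tp+fn), Sp = tn/(tn+fp), as percentages."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")

    def pct(num: int, den: int) -> float | None:
        if den == 0:
            return None
        return round_half_up(100.0 * num / den, 1)

    return Metrics(
        accuracy=pct(cm.tp + cm.tn, cm.total),
        sensitivity=pct(cm.tp, cm.tp + cm.fn),
        specificity=pct(cm.tn, cm.tn + cm.fp),
    )
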