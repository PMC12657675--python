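"""Genome-defined CNN: build, train with class-weighted loss, evaluate.

A genome expands into n_layers conv blocks (3x3 kernels by default,
leaky-rectifier activation, each followed by 2x2 max-pooling), flatten,
dropout at the genome's rate, and a dense softmax head. Training minimizes
class-weighted categorical cross-entropy (sample weight = w_label) with
Adam at the genome's learning rate, and stops early after ``patience``
epochs without validation-loss improvement.

The evaluation surface mirrors the standard multi-class report: confusion
matrix, per-class precision/recall/F1/support, accuracy, macro and
support-weighted aggregates, and one-vs-rest ROC-AUC per class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support, roc_auc_score

from . import _nn
from .medga import ClassWeights, Genome


class ArchitectureError(ValueError):
    pass


class ShapeError(ValueError):
    pass


class DegenerateClassError(ValueError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """Resolved layer plan for one genome on one input shape."""

    genome: Genome
    input_shape: tuple[int, int]  # (H, W), single channel
    n_classes: int
    kernel_sizes: tuple[int, ...] = ()
    leaky_slope: float = 0.2

    def __post_init__(self):
        if not self.kernel_sizes:
            object.__setattr__(self, "kernel_sizes", (3,) * self.genome.n_layers)
        if len(self.kernel_sizes) != self.genome.n_layers:
            raise ArchitectureError("one kernel size per conv layer required")
        side = min(self.input_shape)
        if side < 2**self.genome.n_layers:
            raise ArchitectureError(
                f"input side {side} cannot survive {self.genome.n_layers} 2x2 pools"
            )

    def spatial_sizes(self) -> list[tuple[int, int]]:
        """(H, W) after each conv+pool block."""
        h, w = self.input_shape
        out = []
        for _ in range(self.genome.n_layers):
            h, w = h // 2, w // 2
            out.append((h, w))
        return out

    def flatten_size(self) -> int:
        h, w = self.spatial_sizes()[-1]
        return h * w * self.genome.filters[-1]


def build_cnn(
    genome: Genome, input_shape: tuple[int, int], n_classes: int = 4, **kw
) -> ModelSpec:
    """Resolve a genome into a deterministic layer plan."""
    return ModelSpec(genome=genome, input_shape=tuple(input_shape), n_classes=n_classes, **kw)


def count_parameters(spec: ModelSpec) -> int:
    """Exact trainable-parameter count of the spec'd network."""
    total = 0
    c_in = 1
    for f, k in zip(spec.genome.filters, spec.kernel_sizes):
        total += k * k * c_in * f + f
        c_in = f
    total += spec.flatten_size() * spec.n_classes + spec.n_classes
    return int(total)


def genome_param_counter(input_shape: tuple[int, int], n_classes: int = 4):
    """(n_layers, filters) -> parameter count, for GA fitness normalization."""

    def counter(n_layers: int, filters: tuple[int, ...]) -> int:
        g = Genome(lr=1e-3, n_layers=n_layers, filters=tuple(filters), dropout=0.5)
        return count_parameters(build_cnn(g, input_shape, n_classes))

    return counter


def _materialize(spec: ModelSpec, rng: np.random.Generator) -> _nn.Sequential:
    layers: list[_nn.Layer] = []
    c_in = 1
    for f, k in zip(spec.genome.filters, spec.kernel_sizes):
        layers.append(_nn.Conv2D(c_in, f, k, rng))
        layers.append(_nn.LeakyReLU(spec.leaky_slope))
        layers.append(_nn.MaxPool2D(2))
        c_in = f
    layers.append(_nn.Flatten())
    layers.append(_nn.Dropout(spec.genome.dropout, rng))
    layers.append(_nn.Dense(spec.flatten_size(), spec.n_classes, rng))
    return _nn.Sequential(layers)


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 32
    max_epochs: int = 50
    patience: int = 10
    class_weights: ClassWeights | None = None
    seed: int = 0

    def __post_init__(self):
        if self.patience > self.max_epochs:
            raise ValueError("patience must be <= max_epochs")


@dataclass
class TrainedModel:
    spec: ModelSpec
    net: _nn.Sequential
    curves: dict = field(default_factory=dict)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=_nn.DTYPE)
        out = []
        for start in range(0, len(images), 256):
            batch = images[start : start + 256][:, None]
            out.append(_nn.softmax(self.net.forward(batch, train=False)))
        return np.concatenate(out) if out else np.zeros((0, self.spec.n_classes))

    def predict(self, images: np.ndarray) -> np.ndarray:
        return self.predict_proba(images).argmax(axis=1)


def train(
    spec: ModelSpec,
    train_images: np.ndarray,
    train_labels: np.ndarray,
    val_images: np.ndarray,
    val_labels: np.ndarray,
    config: TrainConfig,
) -> TrainedModel:
    """Fit the genome's CNN; images in [0, 1], labels 0..n_classes-1."""
    train_images = np.asarray(train_images, dtype=np.float64)
    train_labels = np.asarray(train_labels, dtype=np.int64)
    present = np.unique(train_labels)
    if len(present) < spec.n_classes:
        raise DegenerateClassError(
            f"training data covers classes {present.tolist()} of {spec.n_classes}"
        )
    rng = np.random.default_rng(config.seed)
    net = _materialize(spec, rng)
    train_images = train_images.astype(_nn.DTYPE)
    opt = _nn.Adam(net.params, net.grads, lr=spec.genome.lr)
    if config.class_weights is not None:
        sample_w = config.class_weights.per_sample(train_labels)
    else:
        sample_w = np.ones(len(train_labels))

    curves = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
    best_val, since_best = np.inf, 0
    n, bs = len(train_images), config.batch_size
    for _ in range(config.max_epochs):
        order = rng.permutation(n)
        losses, correct, seen = [], 0, 0
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            x = train_images[idx][:, None]
            y = train_labels[idx]
            logits = net.forward(x, train=True)
            loss, grad = _nn.softmax_cross_entropy(logits, y, sample_w[idx])
            net.backward(grad.astype(_nn.DTYPE))
            opt.step()
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == y).sum())
            seen += len(idx)
        curves["train_loss"].append(float(np.mean(losses)))
        curves["train_acc"].append(correct / seen)

        vl, va = _eval_loss_acc(net, val_images, val_labels, spec.n_classes)
        curves["val_loss"].append(vl)
        curves["val_acc"].append(va)
        if vl < best_val - 1e-12:
            best_val, since_best = vl, 0
        else:
            since_best += 1
            # patience k: stop after k stagnant epochs (k=0 behaves like k=1)
            if since_best >= max(config.patience, 1):
                break
    return TrainedModel(spec=spec, net=net, curves=curves)


def _eval_loss_acc(net, images, labels, n_classes) -> tuple[float, float]:
    images = np.asarray(images, dtype=_nn.DTYPE)
    labels = np.asarray(labels, dtype=np.int64)
    if len(images) == 0:
        return 0.0, 0.0
    losses, correct = [], 0
    for start in range(0, len(images), 256):
        x = images[start : start + 256][:, None]
        y = labels[start : start + 256]
        logits = net.forward(x, train=False)
        loss, _ = _nn.softmax_cross_entropy(logits, y)
        losses.append(loss * len(y))
        correct += int((logits.argmax(axis=1) == y).sum())
    return float(np.sum(losses) / len(labels)), correct / len(labels)


@dataclass
class EvalReport:
    confusion: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    accuracy: float
    macro: dict
    weighted: dict
    auc: np.ndarray

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1": self.f1.tolist(),
            "support": self.support.tolist(),
            "accuracy": self.accuracy,
            "macro": self.macro,
            "weighted": self.weighted,
            "auc": [None if np.isnan(a) else float(a) for a in self.auc],
        }


def evaluate(predicted_probs: np.ndarray, true_labels: np.ndarray) -> EvalReport:
    """Full multi-class report from softmax scores and integer labels."""
    probs = np.asarray(predicted_probs, dtype=np.float64)
    labels = np.asarray(true_labels, dtype=np.int64)
    if probs.ndim != 2 or len(probs) != len(labels):
        raise ShapeError("predicted_probs must be (n_samples, n_classes)")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ShapeError("probability rows must sum to 1")
    k = probs.shape[1]
    preds = probs.argmax(axis=1)
    conf = _sk_confusion(labels, preds, labels=np.arange(k))
    prec, rec, f1, support = precision_recall_fscore_support(
        labels, preds, labels=np.arange(k), zero_division=0
    )
    acc = float(np.trace(conf) / conf.sum())
    auc = np.full(k, np.nan)
    for c in range(k):
        mask = labels == c
        if mask.any() and (~mask).any():
            auc[c] = roc_auc_score(mask.astype(int), probs[:, c])
    macro_p, macro_w = aggregate_metrics(prec, support)
    _, w_r = aggregate_metrics(rec, support)
    _, w_f = aggregate_metrics(f1, support)
    macro = {
        "precision": macro_p,
        "recall": float(rec.mean()),
        "f1": float(f1.mean()),
        "auc": float(np.nanmean(auc)) if not np.isnan(auc).all() else None,
    }
    weighted = {"precision": macro_w, "recall": w_r, "f1": w_f}
    return EvalReport(
        confusion=conf,
        precision=prec,
        recall=rec,
        f1=f1,
        support=support,
        accuracy=acc,
        macro=macro,
        weighted=weighted,
        auc=auc,
    )


def format_2dp(value: float) -> str:
    """Display helper: round half up at 2 dp (0.955 -> "0.96"), the rounding
    convention of printed metric tables."""
    from decimal import ROUND_HALF_UP, Decimal

    return str(Decimal(repr(round(value, 10))).quantize(Decimal("0.01"), ROUND_HALF_UP))


def aggregate_metrics(per_class_values, supports) -> tuple[float, float]:
    """(macro, support-weighted) means of a per-class metric."""
    v = np.asarray(per_class_values, dtype=np.float64)
    s = np.asarray(supports, dtype=np.float64)
    if v.shape != s.shape:
        raise ShapeError("per-class values and supports must have equal length")
    if (s <= 0).any():
        raise ShapeError("supports must be > 0")
    return float(v.mean()), float((v * s).sum() / s.sum())


__all__ = [
    "ArchitectureError",
    "ShapeError",
    "DegenerateClassError",
    "ModelSpec",
    "TrainConfig",
    "TrainedModel",
    "EvalReport",
    "build_cnn",
    "count_parameters",
    "genome_param_counter",
    "train",
    "evaluate",
    "aggregate_metrics",
    "format_2dp",
]
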