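"""Small feedforward classifiers and evaluation metrics.

The inner loop of sequential forward selection retrains a fresh network for
every candidate subset, so the classifier here is a deliberately small
fully-connected net (one or two hidden layers of 10-20 ReLU units, softmax
output, cross-entropy loss, full-batch Adam) with explicit seed discipline:
given the same seed and data, training is bit-reproducible.

Two weight initializers are available: "default" (Glorot uniform kernels,
zero biases) and "random_uniform" (kernels and biases drawn uniformly from
+-init_scale), the latter mirroring the scheme that improves multiclass
activity-recognition accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ClassifierSpec",
    "MLPModel",
    "MetricsReport",
    "train",
    "evaluate",
    "zero_rule",
    "count_parameters",
    "metrics_from_confusion",
]


@dataclass
class ClassifierSpec:
    hidden_sizes: list[int] = field(default_factory=lambda: [10])
    n_classes: int = 2
    initializer: str = "default"  # or "random_uniform"
    init_scale: float = 0.05
    epochs: int = 1500
    seed: int = 0
    learning_rate: float = 0.01

    def __post_init__(self) -> None:
        if any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.initializer not in ("default", "random_uniform"):
            raise ValueError(f"unknown initializer {self.initializer!r}")


class MLPModel:
    """Trained multilayer perceptron handle."""

    def __init__(self, spec: ClassifierSpec, weights: list[np.ndarray],
                 biases: list[np.ndarray]):
        self.spec = spec
        self.weights = weights
        self.biases = biases

    @property
    def n_inputs(self) -> int:
        return self.weights[0].shape[0]

    def n_parameters(self) -> int:
        return sum(w.size for w in self.weights) + sum(b.size for b in self.biases)

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        a = np.asarray(X, dtype=float)
        if a.ndim != 2 or a.shape[1] != self.n_inputs:
            raise ValueError(
                f"X has shape {a.shape}, model expects (*, {self.n_inputs})"
            )
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            a = np.maximum(a @ w + b, 0.0)
        return a @ self.weights[-1] + self.biases[-1]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return _softmax(self.decision_scores(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.decision_scores(X), axis=1)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _init_layers(spec: ClassifierSpec, n_inputs: int, rng: np.random.Generator):
    sizes = [n_inputs, *spec.hidden_sizes, spec.n_classes]
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        if spec.initializer == "random_uniform":
            w = rng.uniform(-spec.init_scale, spec.init_scale, (fan_in, fan_out))
            b = rng.uniform(-spec.init_scale, spec.init_scale, fan_out)
        else:
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            w = rng.uniform(-limit, limit, (fan_in, fan_out))
            b = np.zeros(fan_out)
        weights.append(w)
        biases.append(b)
    return weights, biases


def train(spec: ClassifierSpec, X_train: np.ndarray, y_train: np.ndarray) -> MLPModel:
    """Full-batch Adam training of the softmax/cross-entropy MLP.

    Rejects degenerate label sets: every class in [0, n_classes) must occur
    at least once in ``y_train``.
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X_train and y_train shapes are inconsistent")
    present = set(np.unique(y).tolist())
    missing = set(range(spec.n_classes)) - present
    if missing:
        raise ValueError(f"classes absent from training labels: {sorted(missing)}")
    if not present <= set(range(spec.n_classes)):
        raise ValueError("labels outside [0, n_classes)")

    rng = np.random.default_rng(spec.seed)
    weights, biases = _init_layers(spec, X.shape[1], rng)
    onehot = np.eye(spec.n_classes)[y]

    # Adam state
    mw = [np.zeros_like(w) for w in weights]
    vw = [np.zeros_like(w) for w in weights]
    mb = [np.zeros_like(b) for b in biases]
    vb = [np.zeros_like(b) for b in biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = spec.learning_rate
    n = X.shape[0]

    for t in range(1, spec.epochs + 1):
        # forward
        activations = [X]
        a = X
        for w, b in zip(weights[:-1], biases[:-1]):
            a = np.maximum(a @ w + b, 0.0)
            activations.append(a)
        logits = a @ weights[-1] + biases[-1]
        probs = _softmax(logits)

        # backward (cross-entropy + softmax)
        delta = (probs - onehot) / n
        grads_w, grads_b = [], []
        for layer in range(len(weights) - 1, -1, -1):
            grads_w.append(activations[layer].T @ delta)
            grads_b.append(delta.sum(axis=0))
            if layer > 0:
                delta = (delta @ weights[layer].T) * (activations[layer] > 0)
        grads_w.reverse()
        grads_b.reverse()

        corr1 = 1 - beta1 ** t
        corr2 = 1 - beta2 ** t
        for i in range(len(weights)):
            mw[i] = beta1 * mw[i] + (1 - beta1) * grads_w[i]
            vw[i] = beta2 * vw[i] + (1 - beta2) * grads_w[i] ** 2
            weights[i] -= lr * (mw[i] / corr1) / (np.sqrt(vw[i] / corr2) + eps)
            mb[i] = beta1 * mb[i] + (1 - beta1) * grads_b[i]
            vb[i] = beta2 * vb[i] + (1 - beta2) * grads_b[i] ** 2
            biases[i] -= lr * (mb[i] / corr1) / (np.sqrt(vb[i] / corr2) + eps)

    return MLPModel(spec, weights, biases)


@dataclass
class MetricsReport:
    confusion: np.ndarray          # rows: true class, cols: predicted
    accuracy: float
    sensitivity: float | None      # binary only (class 1 positive)
    specificity: float | None
    mcc: float | None
    per_class_recall: np.ndarray
    per_class_precision: np.ndarray
    degenerate_mcc: bool = False

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "mcc": self.mcc,
            "per_class_recall": self.per_class_recall.tolist(),
            "per_class_precision": self.per_class_precision.tolist(),
        }


def metrics_from_confusion(cm: np.ndarray) -> MetricsReport:
    """All metrics derive from the confusion matrix.

    Binary case (class 1 positive): accuracy = (TP+TN)/total,
    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), and the Matthews
    correlation coefficient
    (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),
    reported as 0 with a degeneracy flag when any denominator factor is 0.
    """
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    accuracy = float(np.trace(cm) / total) if total else 0.0
    row = cm.sum(axis=1)
    col = cm.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(row > 0, np.diag(cm) / row, 0.0)
        precision = np.where(col > 0, np.diag(cm) / col, 0.0)
    sensitivity = specificity = mcc = None
    degenerate = False
    if cm.shape == (2, 2):
        tn, fp = cm[0]
        fn, tp = cm[1]
        sensitivity = float(tp / (tp + fn)) if tp + fn else 0.0
        specificity = float(tn / (tn + fp)) if tn + fp else 0.0
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        if denom == 0:
            mcc, degenerate = 0.0, True
        else:
            mcc = float((tp * tn - fp * fn) / np.sqrt(denom))
    return MetricsReport(cm.astype(int), accuracy, sensitivity, specificity,
                         mcc, recall, precision, degenerate)


def evaluate(model: MLPModel, X_test: np.ndarray, y_test: np.ndarray) -> MetricsReport:
    X = np.asarray(X_test, dtype=float)
    y = np.asarray(y_test, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X_test and y_test lengths differ")
    pred = model.predict(X)
    k = model.spec.n_classes
    cm = np.zeros((k, k), dtype=int)
    np.add.at(cm, (y, pred), 1)
    return metrics_from_confusion(cm)


def zero_rule(y_train: Sequence[int], y_test: Sequence[int]) -> float:
    """Majority-class proportion of the evaluated set: the accuracy of a
    classifier that always predicts the most frequent class there."""
    y_test = np.asarray(y_test)
    if y_test.size == 0:
        raise ValueError("empty label set")
    _, counts = np.unique(y_test, return_counts=True)
    return float(counts.max() / y_test.size)


def count_parameters(n_inputs: int, hidden_sizes: Sequence[int], n_outputs: int) -> int:
    """Trainable parameters of a fully connected net with biases."""
    sizes = [n_inputs, *hidden_sizes, n_outputs]
    if any(s < 1 for s in sizes):
        raise ValueError("all layer sizes must be >= 1")
    return sum(a * b + b for a, b in zip(sizes[:-1], sizes[1:]))
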