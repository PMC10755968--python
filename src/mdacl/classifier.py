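"""Pair classification head: concatenate, MLP, sigmoid, binary cross-entropy.

After the encoder is trained, its readout embeddings are frozen; a pair
``(m, d)`` is represented by the concatenation of the miRNA readout
embedding followed by the disease readout embedding and fed through a small
multilayer perceptron with a logistic output.  The head is trained with
mean binary cross-entropy on balanced positive/negative pairs, and its
probabilities are the final association scores used for ranking and
evaluation (the encoder's inner-product score remains available for
diagnostics).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .graph import derive_seed

__all__ = [
    "MlpHead",
    "HeadConfig",
    "concat_pairs",
    "sigmoid",
    "bce_loss",
    "train_classifier",
    "predict_pairs",
]

_CLIP = 1e-12


def sigmoid(x):
    """Logistic function ``1 / (1 + exp(-x))`` (numerically stable)."""
    return expit(x)


def concat_pairs(X_m: np.ndarray, X_d: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    """Feature matrix of (miRNA embedding, disease embedding) concatenations."""
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    if pairs.size and (
        pairs.min() < 0
        or pairs[:, 0].max() >= X_m.shape[0]
        or pairs[:, 1].max() >= X_d.shape[0]
    ):
        raise IndexError("pair index out of range")
    return np.concatenate([X_m[pairs[:, 0]], X_d[pairs[:, 1]]], axis=1)


def bce_loss(pred: np.ndarray, label: np.ndarray) -> float:
    """Mean binary cross-entropy; predictions clipped away from {0, 1}."""
    pred = np.asarray(pred, dtype=np.float64)
    label = np.asarray(label, dtype=np.float64)
    if pred.shape != label.shape:
        raise ValueError("pred and label must have equal length")
    p = np.clip(pred, _CLIP, 1.0 - _CLIP)
    return float(np.mean(-label * np.log(p) - (1.0 - label) * np.log(1.0 - p)))


@dataclass(frozen=True)
class HeadConfig:
    hidden: tuple[int, ...] = (128, 32)
    learning_rate: float = 1e-3
    epochs: int = 200
    batch_size: int = 4096
    weight_decay: float = 1e-6
    seed: int = 0


@dataclass
class MlpHead:
    """Fully connected ReLU network with a single logistic output unit."""

    weights: list = field(default_factory=list)
    biases: list = field(default_factory=list)

    @classmethod
    def init(cls, in_dim: int, hidden: tuple[int, ...], seed: int) -> "MlpHead":
        rng = np.random.default_rng(derive_seed(seed, 801))
        sizes = [in_dim, *hidden, 1]
        W, b = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            W.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)))
            b.append(np.zeros(fan_out))
        return cls(W, b)

    def logits(self, X: np.ndarray) -> np.ndarray:
        h = X
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.maximum(h @ W + b, 0.0)
        return (h @ self.weights[-1] + self.biases[-1]).ravel()

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return np.clip(sigmoid(self.logits(X)), _CLIP, 1.0 - _CLIP)

    def l2_squared(self) -> float:
        return float(sum(np.sum(W**2) for W in self.weights))

    def _forward_backward(self, X, y):
        """Mean-BCE gradient; logistic + BCE collapse to (p - y) at the logit."""
        acts = [X]
        h = X
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.maximum(h @ W + b, 0.0)
            acts.append(h)
        logits = (h @ self.weights[-1] + self.biases[-1]).ravel()
        p = sigmoid(logits)
        n = X.shape[0]
        delta = ((p - y) / n)[:, None]
        gW, gb = [None] * len(self.weights), [None] * len(self.biases)
        for layer in range(len(self.weights) - 1, -1, -1):
            gW[layer] = acts[layer].T @ delta
            gb[layer] = delta.sum(axis=0)
            if layer > 0:
                delta = (delta @ self.weights[layer].T) * (acts[layer] > 0)
        return gW, gb


def train_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    head_config: HeadConfig | None = None,
    seed: int | None = None,
) -> MlpHead:
    """Fit the MLP head with Adam on mean BCE plus a small L2 penalty.

    Training with ``epochs=0`` returns the freshly initialized head, which
    is still deterministic under the seed.  Single-class label sets are
    refused: the head would only learn the base rate.
    """
    cfg = head_config or HeadConfig()
    if seed is not None:
        cfg = HeadConfig(**{**cfg.__dict__, "seed": seed})
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels must have equal length")
    classes = np.unique(y)
    if not np.isin(classes, (0.0, 1.0)).all():
        raise ValueError("labels must be 0/1")
    if classes.size < 2:
        raise ValueError("training labels contain a single class; cannot fit")

    head = MlpHead.init(X.shape[1], cfg.hidden, cfg.seed)
    if cfg.epochs == 0:
        return head
    flat = head.weights + head.biases
    m_state = [np.zeros_like(p) for p in flat]
    v_state = [np.zeros_like(p) for p in flat]
    t = 0
    rng = np.random.default_rng(derive_seed(cfg.seed, 802))
    for _ in range(cfg.epochs):
        order = rng.permutation(X.shape[0])
        for start in range(0, X.shape[0], cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            gW, gb = head._forward_backward(X[sel], y[sel])
            grads = [g + cfg.weight_decay * 2.0 * W for g, W in zip(gW, head.weights)]
            grads += gb
            t += 1
            for p, g, m, v in zip(flat, grads, m_state, v_state):
                m *= 0.9
                m += 0.1 * g
                v *= 0.999
                v += 0.001 * g * g
                p -= cfg.learning_rate * (m / (1 - 0.9**t)) / (
                    np.sqrt(v / (1 - 0.999**t)) + 1e-8
                )
    return head


def predict_pairs(
    head: MlpHead, X_m: np.ndarray, X_d: np.ndarray, pairs: np.ndarray
) -> np.ndarray:
    """Association probability for each ``(m, d)`` pair, strictly in (0, 1)."""
    return head.predict_proba(concat_pairs(X_m, X_d, pairs))
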