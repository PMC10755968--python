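"""Contrastive objectives over node embeddings.

Two InfoNCE-style losses sharpen the encoder's representations:

* **Structure (topology) contrast** — even-length walks on a bipartite graph
  stay on one side, so a node's even-layer embedding aggregates its
  same-side structural neighbors.  Each node's even-layer embedding is
  contrasted against its own base (layer-0) embedding as the positive, with
  all other same-side base embeddings as negatives.

* **Prototype (semantic) contrast** — k-means cluster centers of one side's
  embeddings act as prototypes; each node is pulled toward its own
  prototype and pushed from the others.  This links nodes that are similar
  in embedding space even when they are unreachable on the graph.

Each loss is provided both as a plain evaluation (used in tests and
diagnostics) and in a fused value-and-gradient form used by the trainer.
Embeddings are L2-normalized before similarities by default; prototypes are
treated as constants during gradient computation (the expectation step of
the EM schedule re-estimates them between gradient epochs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp, softmax

from .graph import derive_seed

__all__ = [
    "PrototypeAssignment",
    "l2_normalize",
    "structure_contrast_loss",
    "combine_structure_losses",
    "cluster_prototypes",
    "prototype_contrast_loss",
    "combine_prototype_losses",
]

_NORM_EPS = 1e-12


def l2_normalize(X: np.ndarray) -> np.ndarray:
    """Row-wise L2 normalization; all-zero rows stay zero."""
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    return X / np.maximum(norms, _NORM_EPS)


def _normalize_backward(X: np.ndarray, Z: np.ndarray, dZ: np.ndarray) -> np.ndarray:
    """Gradient of row-normalization: dX = (dZ - (Z.dZ) Z) / ||X||."""
    norms = np.maximum(np.linalg.norm(X, axis=1, keepdims=True), _NORM_EPS)
    inner = np.sum(Z * dZ, axis=1, keepdims=True)
    return (dZ - inner * Z) / norms


def _check_finite(X: np.ndarray, name: str) -> None:
    if not np.isfinite(X).all():
        raise FloatingPointError(f"non-finite values in {name}")


# ---------------------------------------------------------------------------
# Structure (topology-neighbor) contrast
# ---------------------------------------------------------------------------

def structure_contrast_loss(
    layer0: np.ndarray,
    layerk: np.ndarray,
    tau: float,
    normalize: bool = True,
) -> float:
    """InfoNCE between each node's even-layer and base embedding.

    loss = sum_n -log[ exp(sim(z_n^(k), z_n^(0)) / tau)
                       / sum_{n'} exp(sim(z_n^(k), z_{n'}^(0)) / tau) ]
    """
    loss, _, _ = _structure_value_grad(layer0, layerk, tau, normalize)
    return loss


def _structure_value_grad(
    layer0: np.ndarray,
    layerk: np.ndarray,
    tau: float,
    normalize: bool = True,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Loss plus gradients with respect to the raw layer-0 / layer-k tables."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    _check_finite(layer0, "layer-0 embeddings")
    _check_finite(layerk, "layer-k embeddings")
    Z0 = l2_normalize(layer0) if normalize else layer0
    Zk = l2_normalize(layerk) if normalize else layerk
    n = Z0.shape[0]
    sims = (Zk @ Z0.T) / tau  # anchor rows x candidate columns
    loss = float(np.sum(logsumexp(sims, axis=1) - np.diagonal(sims)))
    P = softmax(sims, axis=1)
    dS = P.copy()
    dS[np.arange(n), np.arange(n)] -= 1.0
    dZk = (dS @ Z0) / tau
    dZ0 = (dS.T @ Zk) / tau
    if normalize:
        d_layerk = _normalize_backward(layerk, Zk, dZk)
        d_layer0 = _normalize_backward(layer0, Z0, dZ0)
    else:
        d_layerk, d_layer0 = dZk, dZ0
    return loss, d_layer0, d_layerk


def combine_structure_losses(L_SM: float, L_SD: float, alpha: float) -> float:
    """Side-balanced total: miRNA-side loss + alpha * disease-side loss."""
    return float(L_SM) + float(alpha) * float(L_SD)


# ---------------------------------------------------------------------------
# Prototypes: seeded Lloyd k-means
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrototypeAssignment:
    """K-means prototypes (centers) and node-to-cluster labels for one side."""

    centers: np.ndarray  # (n_clusters, dim)
    labels: np.ndarray  # (n_nodes,)

    @property
    def n_clusters(self) -> int:
        return int(self.centers.shape[0])

    def to_json(self) -> dict:
        return {"labels": self.labels.tolist(), "centers": self.centers.tolist()}


def cluster_prototypes(
    embeddings: np.ndarray, n_clusters: int, seed: int = 0, max_iter: int = 100
) -> PrototypeAssignment:
    """Lloyd k-means with deterministic seeding.

    Centers start at ``n_clusters`` distinct rows chosen uniformly;
    iteration stops at an assignment fixed point or after ``max_iter``
    rounds.  An emptied cluster is re-seeded from the point farthest from
    its assigned center, which keeps every prototype the mean of a
    non-empty member set.
    """
    X = np.asarray(embeddings, dtype=np.float64)
    n = X.shape[0]
    if n_clusters < 1 or n_clusters > n:
        raise ValueError("n_clusters must be in [1, n_nodes]")
    rng = np.random.default_rng(derive_seed(seed, 501))
    centers = X[rng.choice(n, size=n_clusters, replace=False)].copy()
    labels = np.full(n, -1, dtype=np.int64)
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = np.argmin(d2, axis=1)
        for c in range(n_clusters):
            members = new_labels == c
            if members.any():
                centers[c] = X[members].mean(axis=0)
            else:  # re-seed an emptied cluster from the worst-fit point
                farthest = int(np.argmax(d2[np.arange(n), new_labels]))
                centers[c] = X[farthest]
                new_labels[farthest] = c
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    # final tightening so each center is exactly its members' mean
    for c in range(n_clusters):
        members = labels == c
        if members.any():
            centers[c] = X[members].mean(axis=0)
    return PrototypeAssignment(centers, labels)


# ---------------------------------------------------------------------------
# Prototype (semantic-neighbor) contrast
# ---------------------------------------------------------------------------

def prototype_contrast_loss(
    embeddings: np.ndarray,
    assignment: PrototypeAssignment,
    tau: float,
    normalize: bool = True,
) -> float:
    """InfoNCE of each node against its own prototype vs all prototypes."""
    loss, _ = _prototype_value_grad(embeddings, assignment, tau, normalize)
    return loss


def _prototype_value_grad(
    embeddings: np.ndarray,
    assignment: PrototypeAssignment,
    tau: float,
    normalize: bool = True,
) -> tuple[float, np.ndarray]:
    """Loss plus gradient with respect to the raw embeddings (centers fixed)."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    X = np.asarray(embeddings, dtype=np.float64)
    labels = np.asarray(assignment.labels, dtype=np.int64)
    if labels.shape[0] != X.shape[0]:
        raise ValueError("assignment does not cover all nodes")
    C = assignment.centers
    E = l2_normalize(X) if normalize else X
    sims = (E @ C.T) / tau
    n = X.shape[0]
    loss = float(np.sum(logsumexp(sims, axis=1) - sims[np.arange(n), labels]))
    P = softmax(sims, axis=1)
    P[np.arange(n), labels] -= 1.0
    dE = (P @ C) / tau
    dX = _normalize_backward(X, E, dE) if normalize else dE
    return loss, dX


def combine_prototype_losses(L_PM: float, L_PD: float, alpha: float) -> float:
    """Side-balanced total: miRNA-side loss + alpha * disease-side loss."""
    return float(L_PM) + float(alpha) * float(L_PD)
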