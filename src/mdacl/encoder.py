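"""LightGCN-style graph collaborative-filtering encoder.

Embeddings are propagated over the bipartite association graph with pure
degree-normalized neighborhood sums — no feature transforms, nonlinearities
or self-loops between layers:

    X_m^(l+1) = sum_{d in N_m} X_d^(l) / sqrt(|N_m| |N_d|)
    X_d^(l+1) = sum_{m in N_d} X_m^(l) / sqrt(|N_d| |N_m|)

The readout is the uniform mean of the layer-0..L tables, and the raw
association score of a pair is the inner product of its readout embeddings.
Because every step is linear, the whole encoder is a fixed linear map of the
base embedding tables — which is what makes exact analytic gradients of the
training objective practical.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .graph import NormalizedAdjacency, derive_seed

__all__ = [
    "ModelParams",
    "LayerEmbeddings",
    "init_params",
    "propagate_layer",
    "encode",
    "score_inner",
    "save_embeddings_tsv",
    "load_embeddings_tsv",
]


@dataclass
class ModelParams:
    """Trainable base embedding tables for both node sides."""

    mirna: np.ndarray  # (n_mirna, dim)
    disease: np.ndarray  # (n_disease, dim)

    def __post_init__(self) -> None:
        self.mirna = np.asarray(self.mirna, dtype=np.float64)
        self.disease = np.asarray(self.disease, dtype=np.float64)
        if self.mirna.ndim != 2 or self.disease.ndim != 2:
            raise ValueError("embedding tables must be 2-D")
        if self.mirna.shape[1] != self.disease.shape[1]:
            raise ValueError("miRNA and disease embeddings must share a dimension")
        if not (np.isfinite(self.mirna).all() and np.isfinite(self.disease).all()):
            raise ValueError("embedding tables must be finite")

    @property
    def dim(self) -> int:
        return int(self.mirna.shape[1])

    def copy(self) -> "ModelParams":
        return ModelParams(self.mirna.copy(), self.disease.copy())

    def l2_squared(self) -> float:
        return float(np.sum(self.mirna**2) + np.sum(self.disease**2))


@dataclass(frozen=True)
class LayerEmbeddings:
    """Per-layer embedding tables and their mean readout."""

    layers_mirna: tuple[np.ndarray, ...]  # X_m^(0..L)
    layers_disease: tuple[np.ndarray, ...]
    readout_mirna: np.ndarray
    readout_disease: np.ndarray

    @property
    def n_layers(self) -> int:
        """L: number of propagation steps (tables stored = L + 1)."""
        return len(self.layers_mirna) - 1


def init_params(
    n_mirna: int, n_disease: int, dim: int = 64, seed: int = 0, std: float = 0.1
) -> ModelParams:
    """Gaussian base embeddings, zero mean, standard deviation ``std``."""
    if dim < 1:
        raise ValueError("dim must be >= 1")
    rng = np.random.default_rng(derive_seed(seed, 401))
    return ModelParams(
        rng.normal(0.0, std, size=(n_mirna, dim)),
        rng.normal(0.0, std, size=(n_disease, dim)),
    )


def propagate_layer(
    op: NormalizedAdjacency, X_m: np.ndarray, X_d: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """One propagation step; both outputs are computed from the input layer."""
    if X_m.shape[0] != op.n_mirna or X_d.shape[0] != op.n_disease:
        raise ValueError("embedding table shapes do not match the graph")
    return op.matrix @ X_d, op.matrix.T @ X_m


def encode(op: NormalizedAdjacency, params: ModelParams, L: int = 4) -> LayerEmbeddings:
    """Run ``L`` propagation layers and average them into the readout."""
    if L < 0:
        raise ValueError("L must be >= 0")
    Xm, Xd = params.mirna, params.disease
    layers_m = [Xm]
    layers_d = [Xd]
    for _ in range(L):
        Xm, Xd = propagate_layer(op, layers_m[-1], layers_d[-1])
        layers_m.append(Xm)
        layers_d.append(Xd)
    read_m = np.mean(layers_m, axis=0)
    read_d = np.mean(layers_d, axis=0)
    if not (np.isfinite(read_m).all() and np.isfinite(read_d).all()):
        raise FloatingPointError("non-finite values produced during propagation")
    return LayerEmbeddings(tuple(layers_m), tuple(layers_d), read_m, read_d)


def score_inner(X_m: np.ndarray, X_d: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    """Inner-product association scores for ``(m, d)`` index pairs."""
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    if pairs.size and (
        pairs.min() < 0
        or pairs[:, 0].max() >= X_m.shape[0]
        or pairs[:, 1].max() >= X_d.shape[0]
    ):
        raise IndexError("pair index out of range")
    return np.einsum("ij,ij->i", X_m[pairs[:, 0]], X_d[pairs[:, 1]])


def save_embeddings_tsv(table: np.ndarray, path, ids=None) -> None:
    ids = ids if ids is not None else np.arange(table.shape[0])
    df = pd.DataFrame(table, index=list(ids))
    df.to_csv(Path(path), sep="\t", header=False)


def load_embeddings_tsv(path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(Path(path), sep="\t", header=None, index_col=0)
    return [str(i) for i in df.index], df.to_numpy(dtype=np.float64)
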