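"""Bipartite miRNA–disease association graphs.

The central object is :class:`BipartiteGraph`, a simple unweighted bipartite
graph whose adjacency matrix ``A`` (rows = miRNAs, columns = diseases) holds
``A[m, d] = 1`` for every experimentally supported association.  This module
also builds the symmetric degree-normalized propagation operator used by the
graph collaborative-filtering encoder, partitions associations into
cross-validation folds, and samples the negative (non-associated) pairs that
ranking and classification losses require.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "BipartiteGraph",
    "NormalizedAdjacency",
    "FoldSplit",
    "TrainingTriples",
    "load_association_matrix",
    "save_association_matrix",
    "save_edge_list",
    "build_propagation_operator",
    "kfold_split",
    "save_folds",
    "load_folds",
    "sample_training_triples",
    "derive_seed",
]


def derive_seed(root_seed: int, *tags: int) -> int:
    """Derive a reproducible sub-seed below 2**31 from a root seed.

    Every source of randomness in the package draws its seed through this
    function so that one root seed fixes an entire run, while distinct
    stages (fold splitting, initialization, per-epoch sampling, ...) receive
    decorrelated streams.
    """
    ss = np.random.SeedSequence([int(root_seed), *[int(t) for t in tags]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass(frozen=True)
class BipartiteGraph:
    """A simple, unweighted miRNA–disease association graph.

    Parameters
    ----------
    n_mirna, n_disease
        Node counts on each side.
    edges
        Integer array of shape ``(E, 2)`` with 0-based ``(mirna, disease)``
        index pairs; duplicates are rejected.
    mirna_names, disease_names
        Optional identifier lists aligned to the indices.
    """

    n_mirna: int
    n_disease: int
    edges: np.ndarray
    mirna_names: tuple[str, ...] | None = None
    disease_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_mirna < 1 or self.n_disease < 1:
            raise ValueError("node counts must be positive")
        edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if edges.size:
            if edges.min() < 0:
                raise IndexError("negative edge index")
            if edges[:, 0].max() >= self.n_mirna or edges[:, 1].max() >= self.n_disease:
                raise IndexError("edge index out of range")
            flat = edges[:, 0] * self.n_disease + edges[:, 1]
            if np.unique(flat).size != flat.size:
                raise ValueError("duplicate edges are not allowed")
            order = np.lexsort((edges[:, 1], edges[:, 0]))
            edges = edges[order]
        object.__setattr__(self, "edges", edges)
        for names, n, side in (
            (self.mirna_names, self.n_mirna, "mirna"),
            (self.disease_names, self.n_disease, "disease"),
        ):
            if names is not None and len(names) != n:
                raise ValueError(f"{side}_names length does not match node count")

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    def matrix(self) -> np.ndarray:
        """Dense 0/1 association matrix ``A`` of shape (n_mirna, n_disease)."""
        A = np.zeros((self.n_mirna, self.n_disease), dtype=np.int8)
        if self.n_edges:
            A[self.edges[:, 0], self.edges[:, 1]] = 1
        return A

    def sparse(self) -> sp.csr_matrix:
        data = np.ones(self.n_edges)
        return sp.csr_matrix(
            (data, (self.edges[:, 0], self.edges[:, 1])),
            shape=(self.n_mirna, self.n_disease),
        )

    def degrees(self) -> tuple[np.ndarray, np.ndarray]:
        deg_m = np.bincount(self.edges[:, 0], minlength=self.n_mirna)
        deg_d = np.bincount(self.edges[:, 1], minlength=self.n_disease)
        return deg_m, deg_d

    def edge_set(self) -> set[tuple[int, int]]:
        return {(int(m), int(d)) for m, d in self.edges}

    def with_edges(self, edges: np.ndarray) -> "BipartiteGraph":
        """Same node sets and names, different edge set."""
        return BipartiteGraph(
            self.n_mirna, self.n_disease, np.asarray(edges),
            self.mirna_names, self.disease_names,
        )


@dataclass(frozen=True)
class NormalizedAdjacency:
    """Degree-normalized propagation operator for a bipartite graph.

    Stores the sparse matrix ``S`` with ``S[m, d] = 1 / sqrt(|N_m| |N_d|)``
    for every association edge.  The same coefficient is used in both
    propagation directions: miRNA updates are ``S @ X_d`` and disease updates
    are ``S.T @ X_m``.  Degree-0 nodes have no coefficients and therefore
    propagate and receive the zero vector.
    """

    matrix: sp.csr_matrix
    deg_mirna: np.ndarray
    deg_disease: np.ndarray

    @property
    def n_mirna(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_disease(self) -> int:
        return self.matrix.shape[1]

    def coefficient(self, m: int, d: int) -> float:
        return float(self.matrix[m, d])


def build_propagation_operator(graph: BipartiteGraph) -> NormalizedAdjacency:
    """Build ``S = D_m^{-1/2} A D_d^{-1/2}`` for the encoder.

    Equivalent to the dense product of inverse square-root degree matrices
    with the biadjacency, except that isolated nodes simply contribute no
    coefficients rather than dividing by zero.
    """
    deg_m, deg_d = graph.degrees()
    if graph.n_edges:
        m_idx = graph.edges[:, 0]
        d_idx = graph.edges[:, 1]
        vals = 1.0 / np.sqrt(deg_m[m_idx] * deg_d[d_idx])
    else:
        m_idx = d_idx = vals = np.array([])
    S = sp.csr_matrix(
        (vals, (m_idx, d_idx)), shape=(graph.n_mirna, graph.n_disease)
    )
    return NormalizedAdjacency(S, deg_m.astype(np.int64), deg_d.astype(np.int64))


# ---------------------------------------------------------------------------
# File input/output
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","


def load_association_matrix(path, format: str = "matrix") -> BipartiteGraph:
    """Load a 0/1 association table from disk.

    Parameters
    ----------
    path
        TSV/CSV file.
    format
        ``"matrix"`` — dense 0/1 matrix, optionally with a header row of
        disease names and a first column of miRNA names (detected from
        non-numeric cells).  ``"edge_list"`` — two or three columns
        ``mirna, disease[, label]``; identifiers may be integer indices or
        names (names are mapped to indices in sorted order).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty input file: {path}")
    sep = _sep_for(path)
    if format == "matrix":
        return _load_matrix(path, sep)
    if format == "edge_list":
        return _load_edge_list(path, sep)
    raise ValueError(f"unknown format: {format!r}")


def _load_matrix(path: Path, sep: str) -> BipartiteGraph:
    raw = pd.read_csv(path, sep=sep, header=None, dtype=str)
    if raw.empty:
        raise ValueError(f"empty input file: {path}")

    def _numeric(cell) -> bool:
        try:
            float(cell)
            return True
        except (TypeError, ValueError):
            return False

    has_header = not _numeric(raw.iloc[0, raw.shape[1] - 1])
    has_index = not _numeric(raw.iloc[raw.shape[0] - 1, 0])
    disease_names = None
    mirna_names = None
    body = raw
    if has_header:
        disease_names = [str(x) for x in raw.iloc[0, (1 if has_index else 0):]]
        body = body.iloc[1:, :]
    if has_index:
        mirna_names = [str(x) for x in body.iloc[:, 0]]
        body = body.iloc[:, 1:]
    try:
        A = body.astype(float).to_numpy()
    except ValueError as exc:
        raise ValueError(f"non-numeric entry in association matrix: {exc}") from exc
    if not np.isin(A, (0.0, 1.0)).all():
        bad = A[~np.isin(A, (0.0, 1.0))][0]
        raise ValueError(f"association matrix must be binary; found {bad!r}")
    m_idx, d_idx = np.nonzero(A)
    return BipartiteGraph(
        A.shape[0], A.shape[1], np.column_stack([m_idx, d_idx]),
        tuple(mirna_names) if mirna_names else None,
        tuple(disease_names) if disease_names else None,
    )


def _load_edge_list(path: Path, sep: str) -> BipartiteGraph:
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("edge list needs at least two columns: mirna, disease")
    cols = [c.lower() for c in df.columns]
    m_col = df.columns[cols.index("mirna")] if "mirna" in cols else df.columns[0]
    d_col = df.columns[cols.index("disease")] if "disease" in cols else df.columns[1]
    if "label" in cols:
        lab = df[df.columns[cols.index("label")]].astype(float)
        if not np.isin(lab, (0.0, 1.0)).all():
            raise ValueError("edge-list labels must be 0/1")
        df = df[lab == 1.0]
    m_raw, d_raw = df[m_col], df[d_col]

    def _resolve(series: pd.Series):
        try:
            idx = series.astype(int).to_numpy()
            if (idx < 0).any():
                raise IndexError("negative index in edge list")
            return idx, None
        except ValueError:
            names = sorted(series.unique())
            lookup = {n: i for i, n in enumerate(names)}
            return series.map(lookup).to_numpy(), tuple(names)

    m_idx, m_names = _resolve(m_raw)
    d_idx, d_names = _resolve(d_raw)
    n_m = len(m_names) if m_names else int(m_idx.max()) + 1
    n_d = len(d_names) if d_names else int(d_idx.max()) + 1
    return BipartiteGraph(n_m, n_d, np.column_stack([m_idx, d_idx]), m_names, d_names)


def save_association_matrix(graph: BipartiteGraph, path) -> None:
    """Write the dense 0/1 matrix, with name headers when available."""
    path = Path(path)
    sep = _sep_for(path)
    A = graph.matrix()
    df = pd.DataFrame(A)
    if graph.disease_names:
        df.columns = list(graph.disease_names)
    if graph.mirna_names:
        df.index = list(graph.mirna_names)
    df.to_csv(path, sep=sep, header=graph.disease_names is not None,
              index=graph.mirna_names is not None)


def save_edge_list(graph: BipartiteGraph, path) -> None:
    path = Path(path)
    sep = _sep_for(path)
    m = graph.edges[:, 0]
    d = graph.edges[:, 1]
    df = pd.DataFrame({
        "mirna": [graph.mirna_names[i] for i in m] if graph.mirna_names else m,
        "disease": [graph.disease_names[j] for j in d] if graph.disease_names else d,
    })
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Cross-validation folds and negative sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldSplit:
    """One cross-validation fold over association edges.

    Positives are a partition of the observed edges; negatives are non-edges
    sampled uniformly without replacement, disjoint between train and test.
    """

    fold_id: int
    train_pos: np.ndarray
    test_pos: np.ndarray
    train_neg: np.ndarray
    test_neg: np.ndarray


def _sample_non_edges(
    graph: BipartiteGraph,
    n: int,
    rng: np.random.Generator,
    forbidden_flat: np.ndarray,
) -> np.ndarray:
    """Uniform sample of ``n`` distinct (m, d) non-edges avoiding ``forbidden_flat``."""
    total = graph.n_mirna * graph.n_disease
    pos_flat = graph.edges[:, 0] * graph.n_disease + graph.edges[:, 1]
    taken = np.zeros(total, dtype=bool)
    taken[pos_flat] = True
    taken[forbidden_flat] = True
    available = np.flatnonzero(~taken)
    if n > available.size:
        raise ValueError(
            f"requested {n} negatives but only {available.size} non-edges remain"
        )
    chosen = rng.choice(available, size=n, replace=False)
    chosen.sort()
    return np.column_stack([chosen // graph.n_disease, chosen % graph.n_disease])


def kfold_split(
    graph: BipartiteGraph,
    k: int,
    seed: int,
    neg_ratio: float = 1.0,
) -> list[FoldSplit]:
    """Partition edges into ``k`` folds and sample matched negatives.

    Folds split associations (edges), not nodes; fold sizes differ by at
    most one.  For each fold, ``neg_ratio`` negatives per positive are drawn
    uniformly from non-edges, separately (and disjointly) for the train and
    test sides.  Fully reproducible for a fixed seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if graph.n_edges < k:
        raise ValueError(f"k={k} exceeds the number of edges ({graph.n_edges})")
    rng = np.random.default_rng(derive_seed(seed, 101))
    perm = rng.permutation(graph.n_edges)
    fold_assign = np.arange(graph.n_edges) % k
    folds: list[FoldSplit] = []
    for f in range(k):
        test_mask = fold_assign[np.argsort(perm)] == f
        test_pos = graph.edges[test_mask]
        train_pos = graph.edges[~test_mask]
        fold_rng = np.random.default_rng(derive_seed(seed, 102, f))
        n_test_neg = int(round(neg_ratio * test_pos.shape[0]))
        n_train_neg = int(round(neg_ratio * train_pos.shape[0]))
        test_neg = _sample_non_edges(
            graph, n_test_neg, fold_rng, np.array([], dtype=np.int64)
        )
        test_neg_flat = test_neg[:, 0] * graph.n_disease + test_neg[:, 1]
        train_neg = _sample_non_edges(graph, n_train_neg, fold_rng, test_neg_flat)
        folds.append(FoldSplit(f, train_pos, test_pos, train_neg, test_neg))
    return folds


def save_folds(folds: Sequence[FoldSplit], path) -> None:
    payload = [
        {
            "fold_id": f.fold_id,
            "train_pos": f.train_pos.tolist(),
            "test_pos": f.test_pos.tolist(),
            "train_neg": f.train_neg.tolist(),
            "test_neg": f.test_neg.tolist(),
        }
        for f in folds
    ]
    Path(path).write_text(json.dumps(payload))


def load_folds(path) -> list[FoldSplit]:
    payload = json.loads(Path(path).read_text())
    return [
        FoldSplit(
            p["fold_id"],
            np.asarray(p["train_pos"], dtype=np.int64).reshape(-1, 2),
            np.asarray(p["test_pos"], dtype=np.int64).reshape(-1, 2),
            np.asarray(p["train_neg"], dtype=np.int64).reshape(-1, 2),
            np.asarray(p["test_neg"], dtype=np.int64).reshape(-1, 2),
        )
        for p in payload
    ]


@dataclass(frozen=True)
class TrainingTriples:
    """Bayesian personalized ranking triples ``(m, i, j)``.

    ``(m, i)`` is an observed association and ``(m, j)`` a sampled
    non-association of the same miRNA, the pairing the ranking loss pushes
    apart.
    """

    mirna: np.ndarray
    pos_disease: np.ndarray
    neg_disease: np.ndarray

    def __len__(self) -> int:
        return int(self.mirna.shape[0])


def sample_training_triples(
    graph: BipartiteGraph,
    train_pos: np.ndarray,
    per_positive: int = 1,
    seed: int = 0,
) -> TrainingTriples:
    """Sample ``per_positive`` ranking triples for every training positive.

    The negative disease ``j`` is drawn uniformly from the diseases not
    associated with ``m`` in ``graph``.  A miRNA associated with every
    disease has no valid negative; its positives are skipped with a warning.
    """
    train_pos = np.asarray(train_pos, dtype=np.int64).reshape(-1, 2)
    if train_pos.shape[0] == 0:
        raise ValueError("train_pos must be non-empty")
    rng = np.random.default_rng(derive_seed(seed, 201))
    A = graph.matrix().astype(bool)
    full_rows = np.flatnonzero(A.all(axis=1))
    keep = ~np.isin(train_pos[:, 0], full_rows)
    if not keep.all():
        warnings.warn(
            f"skipping {np.count_nonzero(~keep)} positives of miRNAs associated "
            "with every disease (no valid negative)",
            stacklevel=2,
        )
        train_pos = train_pos[keep]
    m = np.repeat(train_pos[:, 0], per_positive)
    i = np.repeat(train_pos[:, 1], per_positive)
    j = rng.integers(0, graph.n_disease, size=m.shape[0])
    bad = A[m, j]
    while bad.any():  # rejection sampling; sparse graphs resolve in a few rounds
        j[bad] = rng.integers(0, graph.n_disease, size=int(bad.sum()))
        bad = A[m, j]
    return TrainingTriples(m, i, j)
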