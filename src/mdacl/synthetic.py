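"""Planted-structure synthetic association graphs.

Real miRNA–disease association data is sparse and block-structured: groups
of functionally related miRNAs tend to associate with overlapping groups of
diseases.  The generator here plants that structure explicitly with a
bipartite stochastic block model — nodes on both sides are assigned to
communities, and an association is drawn with probability ``p_in`` when the
two endpoints share a community and ``p_out`` otherwise.  The returned
ground-truth community labels let tests score whether the learned
embeddings recover the planted signal.

The generator does not attempt to reproduce the degree distribution of any
curated database; it provides a controllable, offline stand-in with the
homophily the model assumes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .graph import BipartiteGraph, derive_seed

__all__ = ["PlantedGraphSpec", "generate_planted_graph", "sparsify"]


@dataclass(frozen=True)
class PlantedGraphSpec:
    """Parameters of the planted bipartite block model.

    ``n_blocks`` communities are shared between the two sides; nodes are
    assigned round-robin (node ``i`` to block ``i % n_blocks``) so block
    sizes are balanced and only the edges are random.
    """

    n_mirna: int = 200
    n_disease: int = 150
    n_blocks: int = 2
    p_in: float = 0.25
    p_out: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_out <= self.p_in <= 1.0):
            raise ValueError("need 0 <= p_out <= p_in <= 1")
        if self.n_blocks < 1 or self.n_blocks > min(self.n_mirna, self.n_disease):
            raise ValueError("n_blocks must be in [1, min(n_mirna, n_disease)]")


def generate_planted_graph(
    spec: PlantedGraphSpec,
) -> tuple[BipartiteGraph, np.ndarray, np.ndarray]:
    """Draw a graph from the block model.

    Returns
    -------
    graph, mirna_blocks, disease_blocks
        The association graph plus the ground-truth block label of every
        node on each side.
    """
    rng = np.random.default_rng(derive_seed(spec.seed, 301))
    blocks_m = np.arange(spec.n_mirna) % spec.n_blocks
    blocks_d = np.arange(spec.n_disease) % spec.n_blocks
    same = blocks_m[:, None] == blocks_d[None, :]
    prob = np.where(same, spec.p_in, spec.p_out)
    adj = rng.random((spec.n_mirna, spec.n_disease)) < prob
    m_idx, d_idx = np.nonzero(adj)
    graph = BipartiteGraph(spec.n_mirna, spec.n_disease, np.column_stack([m_idx, d_idx]))
    return graph, blocks_m, blocks_d


def sparsify(graph: BipartiteGraph, keep_fraction: float, seed: int = 0) -> BipartiteGraph:
    """Keep a uniform subset of ``round(keep_fraction * E)`` edges.

    Emulates the sparse-neighborhood regime the contrastive objectives are
    designed for: thinning observed associations leaves many nodes with few
    or no direct neighbors while the planted communities stay fixed.
    """
    if not (0.0 < keep_fraction <= 1.0):
        raise ValueError("keep_fraction must be in (0, 1]")
    if graph.n_edges == 0:
        raise ValueError("graph has no edges to sparsify")
    if keep_fraction == 1.0:
        return graph
    rng = np.random.default_rng(derive_seed(seed, 302))
    n_keep = int(round(keep_fraction * graph.n_edges))
    idx = rng.choice(graph.n_edges, size=n_keep, replace=False)
    return graph.with_edges(graph.edges[np.sort(idx)])


def save_planted(
    graph: BipartiteGraph,
    spec: PlantedGraphSpec,
    blocks_m: np.ndarray,
    blocks_d: np.ndarray,
    prefix,
) -> None:
    """Write the edge list plus a JSON sidecar with the spec and labels."""
    from .graph import save_edge_list

    prefix = Path(prefix)
    save_edge_list(graph, prefix.with_suffix(".edges.tsv"))
    sidecar = {
        "spec": asdict(spec),
        "mirna_blocks": blocks_m.tolist(),
        "disease_blocks": blocks_d.tolist(),
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar))
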