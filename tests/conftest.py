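import numpy as np
import pytest

from mdacl import (
    BipartiteGraph,
    PlantedGraphSpec,
    build_propagation_operator,
    generate_planted_graph,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_graph():
    """3x3 graph with one isolated disease and mixed degrees."""
    return BipartiteGraph(3, 3, np.array([[0, 0], [0, 1], [1, 1], [2, 2], [1, 2]]))


@pytest.fixture
def random_graph(rng):
    """Random 20x15 bipartite graph at density ~0.2."""
    mask = rng.random((20, 15)) < 0.2
    m, d = np.nonzero(mask)
    return BipartiteGraph(20, 15, np.column_stack([m, d]))


@pytest.fixture(scope="session")
def planted_small():
    """Small two-community graph with clear planted signal."""
    spec = PlantedGraphSpec(n_mirna=40, n_disease=30, n_blocks=2,
                            p_in=0.5, p_out=0.05, seed=7)
    graph, bm, bd = generate_planted_graph(spec)
    return graph, bm, bd


def dense_operator(graph):
    """Independent dense oracle: D_m^{-1/2} A D_d^{-1/2} with 0-degree guard."""
    A = graph.matrix().astype(float)
    deg_m = A.sum(axis=1)
    deg_d = A.sum(axis=0)
    inv_m = np.divide(1.0, np.sqrt(deg_m), out=np.zeros_like(deg_m),
                      where=deg_m > 0)
    inv_d = np.divide(1.0, np.sqrt(deg_d), out=np.zeros_like(deg_d),
                      where=deg_d > 0)
    return inv_m[:, None] * A * inv_d[None, :]
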