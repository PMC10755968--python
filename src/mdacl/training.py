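"""Training objective and optimization loop for the encoder.

The total loss is

    L = L_BPR + beta1 * L_S + beta2 * L_P + beta3 * ||Theta||^2

where ``L_BPR`` is the Bayesian-personalized-ranking loss over (miRNA,
positive disease, sampled negative disease) triples, ``L_S`` the structure
(topology) contrast, ``L_P`` the prototype (semantic) contrast, and
``Theta`` the trainable base embeddings.  Optimization follows an EM
schedule: at the start of every epoch the prototypes are re-estimated by
k-means over the current base embeddings (expectation step), then Adam
minibatch steps descend the total loss with the prototypes held fixed
(maximization step).  All gradients are analytic; the encoder is linear in
the base embeddings, so backpropagation through the propagation layers is a
chain of sparse-matrix products.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .contrastive import (
    PrototypeAssignment,
    _prototype_value_grad,
    _structure_value_grad,
    cluster_prototypes,
    l2_normalize,
)
from .encoder import ModelParams, encode, init_params, score_inner
from .graph import (
    BipartiteGraph,
    NormalizedAdjacency,
    TrainingTriples,
    build_propagation_operator,
    derive_seed,
    sample_training_triples,
)

__all__ = ["TrainConfig", "TrainedModel", "bpr_loss", "total_loss", "train_encoder"]


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the encoder training run.

    The loss weights (``alpha``, ``beta1``, ``beta2``, ``beta3``) default to
    the configuration shipped with the model; the optimizer settings are
    implementation defaults.
    """

    alpha: float = 1.0
    beta1: float = 1e-6
    beta2: float = 1e-8
    beta3: float = 1e-6
    learning_rate: float = 1e-3
    epochs: int = 200
    batch_size: int = 2048
    L: int = 4
    dim: int = 64
    tau: float = 0.1
    even_layer_k: int = 2
    n_clusters: int = 10
    per_positive: int = 1
    init_std: float = 0.1
    val_fraction: float = 0.05
    patience: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if min(self.beta1, self.beta2, self.beta3) < 0:
            raise ValueError("beta weights must be >= 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.even_layer_k % 2 != 0 or not (0 < self.even_layer_k <= self.L):
            raise ValueError("even_layer_k must be a positive even integer <= L")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")


@dataclass
class TrainedModel:
    """Encoder state at the end of training."""

    params: ModelParams
    embeddings: "object"  # LayerEmbeddings on the full training graph
    loss_trace: pd.DataFrame
    config: TrainConfig
    best_epoch: int


def bpr_loss(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Sum of ``-log sigmoid(pos - neg)`` over score pairs."""
    pos = np.asarray(pos_scores, dtype=np.float64)
    neg = np.asarray(neg_scores, dtype=np.float64)
    if pos.shape != neg.shape:
        raise ValueError("pos_scores and neg_scores must have equal length")
    return float(np.sum(np.logaddexp(0.0, -(pos - neg))))


def _readout_backward(
    op: NormalizedAdjacency, d_read_m: np.ndarray, d_read_d: np.ndarray, L: int
) -> tuple[np.ndarray, np.ndarray]:
    """Backpropagate a readout-table gradient to the base embeddings.

    The readout is the mean of layers 0..L, and each layer feeds the next
    through the normalized biadjacency, so the gradient at layer l-1 is the
    direct readout share plus the propagated gradient from layer l.
    """
    S = op.matrix
    share_m = d_read_m / (L + 1)
    share_d = d_read_d / (L + 1)
    gm, gd = share_m.copy(), share_d.copy()
    for _ in range(L):
        gm, gd = share_m + S @ gd, share_d + S.T @ gm
    return gm, gd


def _chain_backward(
    op: NormalizedAdjacency, g_m: np.ndarray, g_d: np.ndarray, steps: int
) -> tuple[np.ndarray, np.ndarray]:
    """Backpropagate a layer-``steps`` gradient down to layer 0."""
    S = op.matrix
    for _ in range(steps):
        g_m, g_d = S @ g_d, S.T @ g_m
    return g_m, g_d


def loss_components_and_grads(
    op: NormalizedAdjacency,
    params: ModelParams,
    triples: TrainingTriples,
    assign_m: PrototypeAssignment,
    assign_d: PrototypeAssignment,
    config: TrainConfig,
) -> dict[str, tuple[float, np.ndarray, np.ndarray]]:
    """Unweighted value and base-embedding gradient of each loss component.

    Returns ``{name: (value, d_mirna, d_disease)}`` for the components
    ``bpr``, ``structure``, ``prototype`` and ``l2``; the total objective is
    their beta-weighted sum.  Prototype centers are constants here.
    """
    k = config.even_layer_k
    emb = encode(op, params, max(config.L, k))
    out: dict[str, tuple[float, np.ndarray, np.ndarray]] = {}

    # --- BPR through the readout -------------------------------------------
    Xm, Xd = emb.readout_mirna, emb.readout_disease
    m, i, j = triples.mirna, triples.pos_disease, triples.neg_disease
    margin = np.einsum("ij,ij->i", Xm[m], Xd[i] - Xd[j])
    value = float(np.sum(np.logaddexp(0.0, -margin)))
    g = -expit(-margin)
    d_read_m = np.zeros_like(Xm)
    d_read_d = np.zeros_like(Xd)
    np.add.at(d_read_m, m, g[:, None] * (Xd[i] - Xd[j]))
    np.add.at(d_read_d, i, g[:, None] * Xm[m])
    np.add.at(d_read_d, j, -g[:, None] * Xm[m])
    out["bpr"] = (value, *_readout_backward(op, d_read_m, d_read_d, config.L))

    # --- structure contrast on even-layer vs base embeddings ---------------
    ls_m, d0_m, dk_m = _structure_value_grad(
        emb.layers_mirna[0], emb.layers_mirna[k], config.tau
    )
    ls_d, d0_d, dk_d = _structure_value_grad(
        emb.layers_disease[0], emb.layers_disease[k], config.tau
    )
    s_val = ls_m + config.alpha * ls_d
    gm, gd = _chain_backward(op, dk_m, config.alpha * dk_d, k)
    out["structure"] = (s_val, gm + d0_m, gd + config.alpha * d0_d)

    # --- prototype contrast on base embeddings (centers fixed) -------------
    lp_m, dp_m = _prototype_value_grad(params.mirna, assign_m, config.tau)
    lp_d, dp_d = _prototype_value_grad(params.disease, assign_d, config.tau)
    out["prototype"] = (
        lp_m + config.alpha * lp_d, dp_m, config.alpha * dp_d
    )

    # --- L2 of all trainable parameters ------------------------------------
    out["l2"] = (params.l2_squared(), 2.0 * params.mirna, 2.0 * params.disease)
    return out


def total_loss(
    op: NormalizedAdjacency,
    params: ModelParams,
    triples: TrainingTriples,
    assign_m: PrototypeAssignment,
    assign_d: PrototypeAssignment,
    config: TrainConfig,
) -> tuple[float, dict[str, float]]:
    """Beta-weighted total objective and its unweighted component breakdown."""
    comps = loss_components_and_grads(op, params, triples, assign_m, assign_d, config)
    values = {name: v for name, (v, _, _) in comps.items()}
    total = (
        values["bpr"]
        + config.beta1 * values["structure"]
        + config.beta2 * values["prototype"]
        + config.beta3 * values["l2"]
    )
    if not np.isfinite(total):
        bad = [n for n, v in values.items() if not np.isfinite(v)]
        raise FloatingPointError(f"non-finite loss component(s): {bad}")
    return float(total), values


class _Adam:
    """Minimal Adam optimizer over a list of arrays."""

    def __init__(self, shapes, lr: float, b1: float = 0.9, b2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            m_hat = m / (1 - self.b1**self.t)
            v_hat = v / (1 - self.b2**self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _cluster_both(params: ModelParams, config: TrainConfig, seed: int):
    assign_m = cluster_prototypes(
        l2_normalize(params.mirna),
        min(config.n_clusters, params.mirna.shape[0]),
        seed=derive_seed(seed, 1),
    )
    assign_d = cluster_prototypes(
        l2_normalize(params.disease),
        min(config.n_clusters, params.disease.shape[0]),
        seed=derive_seed(seed, 2),
    )
    return assign_m, assign_d


def train_encoder(
    graph: BipartiteGraph,
    config: TrainConfig,
    train_pos: np.ndarray | None = None,
) -> TrainedModel:
    """Fit base embeddings on the (training) association edges.

    ``train_pos`` restricts the visible edges (e.g. one cross-validation
    fold); by default all edges of ``graph`` are used.  A small fraction of
    the training positives is held out to monitor the ranking loss for
    early stopping; the propagation operator seen during gradient steps is
    built without them, and the returned readout embeddings are re-encoded
    on the full training edge set.
    """
    edges = graph.edges if train_pos is None else np.asarray(train_pos).reshape(-1, 2)
    if edges.shape[0] < 1:
        raise ValueError("training edge set is empty")
    train_graph = graph.with_edges(edges)

    rng = np.random.default_rng(derive_seed(config.seed, 701))
    n_val = int(round(config.val_fraction * edges.shape[0]))
    use_val = n_val >= 5 and edges.shape[0] - n_val >= 5
    if use_val:
        perm = rng.permutation(edges.shape[0])
        val_pos, fit_pos = edges[perm[:n_val]], edges[perm[n_val:]]
    else:
        val_pos, fit_pos = edges[:0], edges
    fit_graph = graph.with_edges(fit_pos)
    op = build_propagation_operator(fit_graph)

    params = init_params(
        graph.n_mirna, graph.n_disease, config.dim,
        seed=derive_seed(config.seed, 702), std=config.init_std,
    )
    adam = _Adam([params.mirna.shape, params.disease.shape], config.learning_rate)

    val_triples = None
    if use_val:
        val_triples = sample_training_triples(
            train_graph, val_pos, config.per_positive,
            seed=derive_seed(config.seed, 703),
        )

    trace_rows = []
    best_val = np.inf
    best_params = params.copy()
    best_epoch = 0
    stale = 0
    for epoch in range(config.epochs):
        # E-step: re-estimate prototypes from the current base embeddings.
        assign_m, assign_d = _cluster_both(
            params, config, derive_seed(config.seed, 704, epoch)
        )
        # Fresh negatives each epoch for the ranking triples.
        triples = sample_training_triples(
            train_graph, fit_pos, config.per_positive,
            seed=derive_seed(config.seed, 705, epoch),
        )
        order = np.random.default_rng(
            derive_seed(config.seed, 706, epoch)
        ).permutation(len(triples))
        epoch_vals = {"bpr": 0.0, "structure": 0.0, "prototype": 0.0, "l2": 0.0}
        n_total = len(triples)
        for start in range(0, n_total, config.batch_size):
            sel = order[start : start + config.batch_size]
            batch = TrainingTriples(
                triples.mirna[sel], triples.pos_disease[sel], triples.neg_disease[sel]
            )
            frac = len(batch) / n_total  # graph-level terms charged once per epoch
            comps = loss_components_and_grads(
                op, params, batch, assign_m, assign_d, config
            )
            gm = (
                comps["bpr"][1]
                + frac * (
                    config.beta1 * comps["structure"][1]
                    + config.beta2 * comps["prototype"][1]
                    + config.beta3 * comps["l2"][1]
                )
            )
            gd = (
                comps["bpr"][2]
                + frac * (
                    config.beta1 * comps["structure"][2]
                    + config.beta2 * comps["prototype"][2]
                    + config.beta3 * comps["l2"][2]
                )
            )
            adam.step([params.mirna, params.disease], [gm, gd])
            epoch_vals["bpr"] += comps["bpr"][0]
            for name in ("structure", "prototype", "l2"):
                epoch_vals[name] += frac * comps[name][0]
        total = (
            epoch_vals["bpr"]
            + config.beta1 * epoch_vals["structure"]
            + config.beta2 * epoch_vals["prototype"]
            + config.beta3 * epoch_vals["l2"]
        )
        if not np.isfinite(total):
            break  # keep the last finite checkpoint in best_params
        row = {"epoch": epoch, "total": total, **epoch_vals}
        if use_val:
            emb = encode(op, params, config.L)
            val_pairs_pos = np.column_stack([val_triples.mirna, val_triples.pos_disease])
            val_pairs_neg = np.column_stack([val_triples.mirna, val_triples.neg_disease])
            v = bpr_loss(
                score_inner(emb.readout_mirna, emb.readout_disease, val_pairs_pos),
                score_inner(emb.readout_mirna, emb.readout_disease, val_pairs_neg),
            ) / max(len(val_triples), 1)
            row["val_bpr"] = v
            if v < best_val - 1e-9:
                best_val, best_params, best_epoch, stale = v, params.copy(), epoch, 0
            else:
                stale += 1
        else:
            best_params, best_epoch = params.copy(), epoch
        trace_rows.append(row)
        if use_val and stale >= config.patience:
            break

    final_op = build_propagation_operator(train_graph)
    embeddings = encode(final_op, best_params, config.L)
    return TrainedModel(
        params=best_params,
        embeddings=embeddings,
        loss_trace=pd.DataFrame(trace_rows),
        config=config,
        best_epoch=best_epoch,
    )


def ablation_config(config: TrainConfig, ablation: str) -> TrainConfig:
    """Zero the loss weights corresponding to a named ablation.

    ``no_tcl`` removes the topology (structure) contrast, ``no_scl`` the
    semantic (prototype) contrast, ``no_cl`` both; ``full`` is unchanged.
    """
    if ablation == "full":
        return config
    if ablation == "no_tcl":
        return replace(config, beta1=0.0)
    if ablation == "no_scl":
        return replace(config, beta2=0.0)
    if ablation == "no_cl":
        return replace(config, beta1=0.0, beta2=0.0)
    raise ValueError(f"unknown ablation: {ablation!r}")
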