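# Methods

This note records the model as implemented, the defaults and why they were
chosen, the places where the design was genuinely open, and what the
synthetic benchmark does and does not establish.

## Model and assumptions

The data is a simple, unweighted bipartite graph: `n_m` miRNA nodes, `n_d`
disease nodes, and an edge per experimentally supported association.  The
model assumes homophily on both sides — miRNAs (diseases) that share
association partners are likely to share further partners — and no node
features: everything is learned from topology, starting from free base
embeddings.

**Propagation.** One layer sends each node the degree-normalized sum of its
neighbors' embeddings, with the shared coefficient `1/√(deg(m)·deg(d))` per
edge in both directions.  In matrix form, with `S = D_m^{-1/2} A D_d^{-1/2}`:
`X_m ← S X_d`, `X_d ← Sᵀ X_m`, both computed from the input layer.  Isolated
nodes send and receive the zero vector (no division by zero); they keep
their base embedding in the readout.  The symmetric normalization bounds the
operator's spectral norm by 1, so propagation never amplifies.  The readout
averages layers 0..L uniformly.  Everything is linear in the base tables,
which is what makes exact analytic gradients a few sparse products.

**Ranking loss.** BPR over triples `(m, i, j)` — `(m,i)` observed, `(m,j)` a
uniformly sampled non-association of the same miRNA: `Σ −log σ(ŷ_mi − ŷ_mj)`
with inner-product scores on the readout.  Triples are resampled every
epoch (fresh negatives), one per training positive by default.

**Structure contrast.** Even-length walks on a bipartite graph return to the
starting side, so the layer-k embedding (k even) is an aggregate over
same-side structural neighbors.  Per side, InfoNCE with the node's own
layer-0 embedding as the positive and all other same-side layer-0
embeddings as negatives; embeddings are row-L2-normalized before the dot
products (zero rows stay zero, guarded by a 1e-12 norm floor).  Sides
combine as `L_SM + α·L_SD`.  Default k = 2 — the cheapest even layer and the
least over-smoothed; k is configurable up to L.

**Prototype contrast.** Each side's L2-normalized *base* embeddings are
clustered by k-means; per node, InfoNCE of the node against its own cluster
center versus all centers of its side.  Using layer-0 embeddings keeps the
clustering independent of propagation depth.  Centers are constants during
gradient steps (no gradient through the means); the EM schedule — re-cluster
once per epoch, then Adam minibatch steps — is what optimizes the pair.

**Total objective and weights.** `L = L_BPR + β₁L_S + β₂L_P + β₃‖Θ‖²` with
`Θ` the base embedding tables (the classifier head carries its own small
weight-decay term instead).  Shipped weights `α = 1.0, β₁ = 1e-6,
β₂ = 1e-8, β₃ = 1e-6`; a single `α` is shared by both contrastive combiners.
The tiny βs mean the contrastive terms act as gentle regularizers on top of
the ranking loss rather than competing objectives.

**Classifier head.** Two-stage training: the encoder is fit first, its
readout embeddings are frozen, and an MLP (hidden layers 128/32, ReLU,
logistic output) is trained with mean BCE on balanced pairs — training
positives plus an equal number of uniformly sampled non-edges.  Reported
probabilities are clipped to (1e-12, 1−1e-12).  The head's probabilities are
the final scores for AUC, thresholded metrics and ranking; the inner-product
score remains available for diagnostics.  Joint end-to-end training of
encoder and head is a possible alternative; the staged version matches the
"encode, then classify pairs" architecture and keeps each stage separately
testable.

## Optimization defaults

| parameter | default | notes |
|---|---|---|
| embedding dim | 64 | standard for collaborative filtering at this scale |
| layers L | 4 | four aggregation steps; readout averages 5 tables |
| even layer k | 2 | structure-contrast anchor layer |
| temperature τ | 0.1 | common InfoNCE setting; sweep helper in the CLI |
| clusters per side | 10 | prototype count; capped at the node count |
| optimizer | Adam, lr 1e-3 | minibatches of 2048 triples |
| epochs | 200 | early stop on a 5% held-out split of training positives (patience 20), monitored by per-triple BPR; final embeddings re-encoded on the full training edge set |
| init | N(0, 0.1²) | base embeddings, run-level seed |

Every random draw (init, folds, negatives, k-means seeding, batch order)
derives its seed from one root seed through a `SeedSequence`-based helper,
so an entire run — including byte-identical cross-validation reports — is
reproducible from a single integer.

## Evaluation protocol

Folds partition *edges* (not nodes) into k near-equal parts; each fold's
test positives are removed from the propagation operator and all losses
during that fold's training.  Negatives are sampled uniformly from non-edges
without replacement, one per positive by default (balanced test sets),
disjoint between train and test within a fold.  AUC uses the rank
(Mann–Whitney) statistic with ties at ½; ACC/SPE/PRE/REC/F1 threshold at
0.5, with zero-denominator ratios reported as NaN with a warning.  Ablations
(`no_tcl`: β₁=0, `no_scl`: β₂=0, `no_cl`: both) share splits, seeds and
initial conditions with the full model.  Stability summaries use
linear-interpolation quartiles and the 1.5·IQR outlier rule.

## Synthetic benchmark: what it shows and what it does not

The generator is a bipartite stochastic block model: communities shared
between sides, round-robin node assignment (balanced blocks; only edges are
random), edge probability `p_in` within and `p_out` across communities.  The
study conditions used by the tests and the acceptance script are 200 × 150
nodes, two communities, `p_in = 0.25`, `p_out = 0.02` (≈ 4.1k edges), with a
30%-edge sparsified copy for the ablation comparison; the gradient check
runs on a 3 + 3-node instance and the dense-oracle check on 20 random 20 × 15
graphs.  These sizes keep a complete run in minutes on one CPU while leaving
the planted signal clearly detectable.

The planted model emulates the homophily the method exploits and the
sparse-neighborhood regime it targets.  It does not reproduce the heavy-
tailed degree distribution, the correlated disease hierarchy, or the
biased sampling of curated databases — so passing here demonstrates that
the machinery recovers block structure from partial observations, not that
any particular real-data score will be attained.

One limitation surfaced by the benchmark is worth stating explicitly: in
leave-one-out case-study ranking the target node is deleted from the graph
entirely, so its embedding carries no community information.  The resulting
top-k list is *coherent* (one community dominates) but which community is
essentially the luck of the cold embedding's position.  On real association
data, apparent cold-start success largely rides on degree/popularity
structure (well-studied miRNAs associate broadly), which a balanced block
model deliberately lacks.

## Numerical choices

* L2-normalization guards zero rows with a 1e-12 floor; a zero even-layer
  embedding (isolated node) contributes a uniform-softmax term.
* k-means: Lloyd iterations from uniformly chosen distinct rows, stopping at
  an assignment fixed point or 100 rounds; an emptied cluster is re-seeded
  from the point farthest from its assigned center, and final centers are
  exact member means.
* Ranking ties are broken by node index; the confusion threshold counts
  `score == threshold` as positive.
* Graph-level loss terms (contrastive, L2) are charged to minibatches in
  proportion to batch size, so the per-epoch total equals the objective
  evaluated once.
* Non-finite losses abort training at the last finite checkpoint; non-finite
  inputs to the losses raise immediately, naming the offending component.

## Known limitations

* No side information (sequence, semantic similarity, ontology) — topology
  only, by design.
* The prototype count and temperature are not auto-tuned; the CLI `sweep`
  command covers one-axis grids only.
* Case-study ranking for truly isolated targets is uninformative (above).
* The implementation is CPU/NumPy; very large graphs (≫10⁵ edges) would
  want batched sparse kernels or a GPU port.
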