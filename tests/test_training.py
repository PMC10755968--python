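"""BPR loss, total objective, and the EM training loop."""

import numpy as np
import pytest

from mdacl import (
    BipartiteGraph,
    ModelParams,
    PrototypeAssignment,
    TrainConfig,
    ablation_config,
    bpr_loss,
    build_propagation_operator,
    derive_seed,
    encode,
    generate_planted_graph,
    init_params,
    score_inner,
    total_loss,
    train_encoder,
)
from mdacl.graph import TrainingTriples
from mdacl.synthetic import PlantedGraphSpec
from mdacl.training import _Adam, loss_components_and_grads


def small_config(**kw):
    defaults = dict(dim=4, L=4, even_layer_k=2, n_clusters=2, tau=0.1,
                    epochs=3, val_fraction=0.0)
    defaults.update(kw)
    return TrainConfig(**defaults)


class TestBprLoss:
    def test_zero_margin_is_ln2(self):
        assert bpr_loss([1.0], [1.0]) == pytest.approx(np.log(2), abs=1e-12)

    def test_unit_margin_closed_form(self):
        assert bpr_loss([1.0], [0.0]) == pytest.approx(np.log(1 + np.exp(-1)),
                                                       abs=1e-12)

    def test_strictly_decreasing_in_margin(self):
        margins = np.linspace(-10, 10, 100)
        losses = [bpr_loss([m], [0.0]) for m in margins]
        assert np.all(np.diff(losses) < 0)

    def test_limits(self):
        assert bpr_loss([50.0], [0.0]) < 1e-20
        assert bpr_loss([-50.0], [0.0]) > 40

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bpr_loss([1.0, 2.0], [0.0])


class TestTotalLoss:
    @pytest.fixture
    def instance(self, tiny_graph, rng):
        op = build_propagation_operator(tiny_graph)
        params = ModelParams(rng.normal(0, 0.3, (3, 4)), rng.normal(0, 0.3, (3, 4)))
        triples = TrainingTriples(np.array([0, 1]), np.array([0, 1]), np.array([2, 0]))
        assign_m = PrototypeAssignment(rng.normal(size=(2, 4)), np.array([0, 1, 0]))
        assign_d = PrototypeAssignment(rng.normal(size=(2, 4)), np.array([1, 0, 1]))
        return op, params, triples, assign_m, assign_d

    def test_zero_betas_reduce_to_bpr(self, instance):
        op, params, triples, am, ad = instance
        cfg = small_config(beta1=0.0, beta2=0.0, beta3=0.0)
        total, comps = total_loss(op, params, triples, am, ad, cfg)
        assert total == pytest.approx(comps["bpr"], abs=1e-15)

    def test_all_zero_embeddings_analytic_values(self, tiny_graph):
        # zero embeddings: every margin is 0 (bpr = n ln 2), every softmax is
        # uniform (structure = n_m ln n_m + alpha n_d ln n_d; prototype =
        # n ln k per side), and the L2 term vanishes.
        op = build_propagation_operator(tiny_graph)
        params = ModelParams(np.zeros((3, 4)), np.zeros((3, 4)))
        triples = TrainingTriples(np.array([0, 1]), np.array([0, 1]), np.array([2, 0]))
        k = 2
        am = PrototypeAssignment(np.zeros((k, 4)), np.array([0, 1, 0]))
        ad = PrototypeAssignment(np.zeros((k, 4)), np.array([1, 0, 1]))
        cfg = small_config(alpha=1.0)
        _, comps = total_loss(op, params, triples, am, ad, cfg)
        assert comps["bpr"] == pytest.approx(2 * np.log(2), abs=1e-12)
        assert comps["structure"] == pytest.approx(
            3 * np.log(3) + 3 * np.log(3), abs=1e-12
        )
        assert comps["prototype"] == pytest.approx(6 * np.log(k), abs=1e-12)
        assert comps["l2"] == 0.0

    def test_default_weights_are_shipped_configuration(self):
        cfg = TrainConfig()
        assert (cfg.alpha, cfg.beta1, cfg.beta2, cfg.beta3) == (1.0, 1e-6, 1e-8, 1e-6)

    def test_non_finite_component_raises(self, instance):
        op, params, triples, am, ad = instance
        params.mirna[0, 0] = np.inf
        with pytest.raises((FloatingPointError, ValueError)):
            total_loss(op, params, triples, am, ad, small_config())


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self, tiny_graph, rng):
        op = build_propagation_operator(tiny_graph)
        params = ModelParams(rng.normal(0, 0.3, (3, 4)), rng.normal(0, 0.3, (3, 4)))
        triples = TrainingTriples(np.array([0, 1, 2]), np.array([0, 1, 2]),
                                  np.array([2, 0, 1]))
        from mdacl.contrastive import cluster_prototypes, l2_normalize

        am = cluster_prototypes(l2_normalize(params.mirna), 2, seed=1)
        ad = cluster_prototypes(l2_normalize(params.disease), 2, seed=2)
        cfg = small_config()
        comps = loss_components_and_grads(op, params, triples, am, ad, cfg)
        h = 1e-6
        for name, (_, gm, gd) in comps.items():
            for arr, grad in ((params.mirna, gm), (params.disease, gd)):
                num = np.zeros_like(arr)
                for idx in np.ndindex(arr.shape):
                    orig = arr[idx]
                    arr[idx] = orig + h
                    up = loss_components_and_grads(op, params, triples, am, ad,
                                                   cfg)[name][0]
                    arr[idx] = orig - h
                    dn = loss_components_and_grads(op, params, triples, am, ad,
                                                   cfg)[name][0]
                    arr[idx] = orig
                    num[idx] = (up - dn) / (2 * h)
                rel = np.abs(grad - num).max() / max(np.abs(num).max(), 1e-10)
                assert rel <= 1e-4, f"{name} gradient mismatch: rel err {rel}"


class TestTrainEncoder:
    def test_zero_learning_rate_is_identity(self, planted_small):
        graph, _, _ = planted_small
        cfg = small_config(learning_rate=0.0, epochs=1, seed=3)
        model = train_encoder(graph, cfg)
        expected = init_params(graph.n_mirna, graph.n_disease, cfg.dim,
                               seed=derive_seed(cfg.seed, 702), std=cfg.init_std)
        assert np.array_equal(model.params.mirna, expected.mirna)
        assert np.array_equal(model.params.disease, expected.disease)

    def test_margin_increases_on_single_positive(self):
        # one observed pair: each Adam step should widen the score margin
        graph = BipartiteGraph(1, 2, np.array([[0, 0]]))
        op = build_propagation_operator(graph)
        params = init_params(1, 2, dim=4, seed=0)
        cfg = small_config(beta1=0.0, beta2=0.0, beta3=0.0, L=2)
        triples = TrainingTriples(np.array([0]), np.array([0]), np.array([1]))
        am = PrototypeAssignment(np.zeros((1, 4)), np.zeros(1, dtype=int))
        ad = PrototypeAssignment(np.zeros((1, 4)), np.zeros(2, dtype=int))
        adam = _Adam([params.mirna.shape, params.disease.shape], lr=1e-2)
        margins = []
        for _ in range(10):
            emb = encode(op, params, cfg.L)
            s = score_inner(emb.readout_mirna, emb.readout_disease,
                            [[0, 0], [0, 1]])
            margins.append(s[0] - s[1])
            comps = loss_components_and_grads(op, params, triples, am, ad, cfg)
            adam.step([params.mirna, params.disease],
                      [comps["bpr"][1], comps["bpr"][2]])
        assert np.all(np.diff(margins) > 0)

    def test_loss_decreases_over_epochs(self, planted_small):
        graph, _, _ = planted_small
        cfg = small_config(dim=8, epochs=10, seed=1)
        model = train_encoder(graph, cfg)
        trace = model.loss_trace["total"].to_numpy()
        assert trace[9] < trace[0]

    def test_reproducible_under_seed(self, planted_small):
        graph, _, _ = planted_small
        cfg = small_config(epochs=2, seed=11)
        a = train_encoder(graph, cfg)
        b = train_encoder(graph, cfg)
        assert np.array_equal(a.params.mirna, b.params.mirna)
        assert a.loss_trace.equals(b.loss_trace)

    def test_score_separation_on_planted_blocks(self):
        # held-out within-community pairs should score above cross-community
        spec = PlantedGraphSpec(60, 45, 2, p_in=0.4, p_out=0.03, seed=0)
        graph, bm, bd = generate_planted_graph(spec)
        cfg = TrainConfig(dim=16, epochs=60, n_clusters=4, val_fraction=0.0)
        model = train_encoder(graph, cfg)
        A = graph.matrix().astype(bool)
        same = bm[:, None] == bd[None, :]
        scores = model.embeddings.readout_mirna @ model.embeddings.readout_disease.T
        within = scores[~A & same].mean()
        across = scores[~A & ~same].mean()
        assert within > across

    def test_empty_training_set_rejected(self, planted_small):
        graph, _, _ = planted_small
        with pytest.raises(ValueError):
            train_encoder(graph, small_config(), train_pos=np.empty((0, 2)))


class TestAblationConfig:
    def test_mapping(self):
        cfg = TrainConfig()
        assert ablation_config(cfg, "full") is cfg
        assert ablation_config(cfg, "no_tcl").beta1 == 0.0
        assert ablation_config(cfg, "no_scl").beta2 == 0.0
        no_cl = ablation_config(cfg, "no_cl")
        assert no_cl.beta1 == 0.0 and no_cl.beta2 == 0.0
        assert no_cl.beta3 == cfg.beta3
        with pytest.raises(ValueError):
            ablation_config(cfg, "bogus")
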