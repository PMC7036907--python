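"""Layer semantics, batched-vs-naive oracles, permutation invariance, checkpoints."""

import numpy as np
import pytest

from meridiangcn.chem_io import smiles_to_graph
from meridiangcn.graph_net import (
    GCNConfig,
    GraphBatch,
    N_DEGREES,
    ShapeError,
    forward,
    graph_conv,
    graph_gather,
    graph_max_pool,
    init_params,
    load_params,
    node_batch_norm,
    save_params,
)
from meridiangcn.synthetic_data import random_molgraphs

from conftest import make_graph


# ---------------------------------------------------------------------------
# naive per-node loop oracles, deliberately slow and index-by-index
# ---------------------------------------------------------------------------

def naive_conv(h, graph, W, b):
    out = np.empty((len(graph.neighbors), W.shape[1]))
    for v, nbrs in enumerate(graph.neighbors):
        d = min(len(nbrs), N_DEGREES - 1)
        s = h[v].copy()
        for u in nbrs:
            s = s + h[u]
        out[v] = np.maximum(W[d] @ s + b[d], 0.0)
    return out


def naive_max_pool(h, graph):
    out = np.empty_like(h)
    for v, nbrs in enumerate(graph.neighbors):
        members = [v] + list(nbrs)
        for c in range(h.shape[1]):
            out[v, c] = max(h[u, c] for u in members)
    return out


def naive_gather(h, graph, Phi, beta):
    pre = beta.astype(float).copy()
    for v, nbrs in enumerate(graph.neighbors):
        d = min(len(nbrs), N_DEGREES - 1)
        pre = pre + Phi[d] @ h[v]
    return np.tanh(pre)


def two_node_path(f0, f1):
    return make_graph([f0, f1], [[1], [0]])


class TestGraphConv:
    def test_hand_evaluated_two_node_path(self):
        # scalar features [1, 2], identity weight for degree 1, zero bias:
        # each node sees self + neighbor = 3, ReLU inert
        g = two_node_path([1.0], [2.0])
        W = np.zeros((N_DEGREES, 1, 1))
        W[1] = 1.0
        b = np.zeros((N_DEGREES, 1))
        out = graph_conv(np.array([[1.0], [2.0]]), GraphBatch([g]), W, b)
        assert np.allclose(out, [[3.0], [3.0]])

    def test_zero_parameters_give_zero_output(self, rng):
        g = smiles_to_graph("CC(C)Cc1ccccc1")
        batch = GraphBatch([g])
        W = np.zeros((N_DEGREES, 4, g.feature_dim))
        out = graph_conv(batch.features, batch, W, np.zeros((N_DEGREES, 4)))
        assert (out == 0).all()

    def test_isolated_atom_uses_degree_zero_and_empty_neighbor_sum(self, rng):
        g = smiles_to_graph("[Na+]")
        batch = GraphBatch([g])
        W = rng.normal(size=(N_DEGREES, 3, g.feature_dim))
        b = rng.normal(size=(N_DEGREES, 3))
        out = graph_conv(batch.features, batch, W, b)
        expected = np.maximum(W[0] @ batch.features[0] + b[0], 0.0)
        assert np.allclose(out[0], expected)

    def test_dimension_mismatch_raises_shape_error(self, rng):
        g = two_node_path([1.0, 2.0], [3.0, 4.0])
        W = rng.normal(size=(N_DEGREES, 3, 5))  # expects dim 5, state has 2
        with pytest.raises(ShapeError):
            graph_conv(np.zeros((2, 2)), GraphBatch([g]), W, np.zeros((N_DEGREES, 3)))


class TestNodeBatchNorm:
    def test_two_node_channel_normalized_to_unit_spread(self):
        out = node_batch_norm(np.array([[1.0], [3.0]]), np.ones(1), np.zeros(1),
                              np.zeros(1), np.ones(1), mode="train")
        assert np.allclose(out, [[-1.0], [1.0]], atol=1e-2)

    def test_constant_channel_maps_to_zero(self):
        out = node_batch_norm(np.full((4, 2), 7.0), np.ones(2), np.zeros(2),
                              np.zeros(2), np.ones(2), mode="train")
        assert np.allclose(out, 0.0)

    def test_eval_mode_with_unit_running_stats_is_near_identity(self):
        x = np.array([[0.3, -1.2], [2.0, 0.1]])
        out = node_batch_norm(x, np.ones(2), np.zeros(2),
                              np.zeros(2), np.ones(2), mode="eval")
        assert np.allclose(out, x, atol=1e-4)

    def test_single_node_batch_rejected_in_train_mode(self):
        with pytest.raises(ValueError, match="2 nodes"):
            node_batch_norm(np.ones((1, 3)), np.ones(3), np.zeros(3),
                            np.zeros(3), np.ones(3), mode="train")

    def test_running_statistics_updated_with_momentum(self):
        run_mean, run_var = np.zeros(1), np.ones(1)
        x = np.array([[2.0], [4.0]])  # batch mean 3, population var 1
        node_batch_norm(x, np.ones(1), np.zeros(1), run_mean, run_var,
                        mode="train", momentum=0.9)
        assert np.allclose(run_mean, 0.3)
        assert np.allclose(run_var, 0.9 * 1.0 + 0.1 * 1.0)


class TestGraphMaxPool:
    def test_two_node_path_exchanges_elementwise_maximum(self):
        g = two_node_path([1.0, 5.0], [3.0, 2.0])
        out = graph_max_pool(np.array([[1.0, 5.0], [3.0, 2.0]]), GraphBatch([g]))
        assert np.allclose(out, [[3.0, 5.0], [3.0, 5.0]])

    def test_isolated_node_unchanged(self):
        g = make_graph([[4.0, -2.0]], [[]])
        out = graph_max_pool(np.array([[4.0, -2.0]]), GraphBatch([g]))
        assert np.allclose(out, [[4.0, -2.0]])

    def test_idempotent_on_constant_state(self, rng):
        g = smiles_to_graph("c1ccccc1O")
        x = np.tile([1.5, -0.5], (g.num_atoms, 1))
        out = graph_max_pool(x, GraphBatch([g]))
        assert np.allclose(out, x)


class TestGraphGather:
    def test_zero_parameters_give_zero_embedding(self):
        g = two_node_path([1.0], [2.0])
        out = graph_gather(np.array([[1.0], [2.0]]), GraphBatch([g]),
                           np.zeros((N_DEGREES, 3, 1)), np.zeros(3))
        assert np.allclose(out, 0.0)

    def test_single_node_identity_weights_closed_form_tanh(self):
        g = make_graph([[0.5]], [[]])
        Phi = np.zeros((N_DEGREES, 1, 1))
        Phi[0] = 1.0
        out = graph_gather(np.array([[0.5]]), GraphBatch([g]), Phi, np.zeros(1))
        assert np.allclose(out, np.tanh(0.5))
        assert abs(out[0, 0] - 0.46211715726) < 1e-8

    def test_atom_permutation_leaves_embedding_unchanged(self, rng):
        feats = rng.normal(size=(4, 3))
        neighbors = [[1], [0, 2, 3], [1], [1]]
        g = make_graph(feats, neighbors)
        perm = np.array([2, 0, 3, 1])
        inv = np.argsort(perm)
        g_perm = make_graph(feats[perm], [[inv[u].item() for u in neighbors[p]]
                                          for p in perm])
        Phi = rng.normal(size=(N_DEGREES, 5, 3))
        beta = rng.normal(size=5)
        a = graph_gather(feats, GraphBatch([g]), Phi, beta)
        b = graph_gather(feats[perm], GraphBatch([g_perm]), Phi, beta)
        assert np.allclose(a, b)


class TestLayerOracles:
    """Batched implementations agree with naive per-node loops to 1e-10."""

    def test_all_layers_match_naive_loops_on_random_graphs(self, rng):
        for _ in range(60):
            g = random_molgraphs(1, rng, max_atoms=6, feature_dim=4)[0]
            batch = GraphBatch([g])
            h = rng.normal(size=(g.num_atoms, 4))
            W = rng.normal(size=(N_DEGREES, 3, 4))
            b = rng.normal(size=(N_DEGREES, 3))
            Phi = rng.normal(size=(N_DEGREES, 2, 4))
            beta = rng.normal(size=2)
            assert np.allclose(graph_conv(h, batch, W, b), naive_conv(h, g, W, b),
                               atol=1e-10)
            assert np.allclose(graph_max_pool(h, batch), naive_max_pool(h, g),
                               atol=1e-10)
            assert np.allclose(graph_gather(h, batch, Phi, beta),
                               naive_gather(h, g, Phi, beta), atol=1e-10)


class TestForward:
    def test_zero_head_weights_give_sigmoid_of_bias(self, small_params):
        graphs = [smiles_to_graph("CCO"), smiles_to_graph("c1ccccc1")]
        cfg = GCNConfig(feature_dim=graphs[0].feature_dim, num_tasks=2,
                        depth=1, width=4)
        params = init_params(cfg, np.random.default_rng(1))
        params.head_W[:] = 0.0
        params.head_b[:] = [0.0, 1.0]
        probs = forward(params, GraphBatch(graphs))
        expected = 1.0 / (1.0 + np.exp(-params.head_b))
        assert np.allclose(probs, np.tile(expected, (2, 1)))

    def test_output_shape_is_molecules_by_tasks(self):
        graphs = [smiles_to_graph(s) for s in ("CCO", "CCN", "c1ccncc1")]
        cfg = GCNConfig(feature_dim=graphs[0].feature_dim, num_tasks=5,
                        depth=2, width=6)
        params = init_params(cfg, np.random.default_rng(2))
        probs = forward(params, GraphBatch(graphs))
        assert probs.shape == (3, 5)

    def test_full_chain_matches_hand_composed_oracle(self, rng):
        """One layer, eval-mode identity BN: conv -> pool -> gather -> sigmoid."""
        g = smiles_to_graph("CCO")
        cfg = GCNConfig(feature_dim=g.feature_dim, num_tasks=2, depth=1,
                        width=3, gather_dim=2, bn_eps=0.0)
        params = init_params(cfg, rng)
        batch = GraphBatch([g])
        probs = forward(params, batch, mode="eval")

        h = naive_conv(batch.features, g, params.conv_W[0], params.conv_b[0])
        # eval BN with running mean 0 / var 1 and the freshly initialized
        # scale 1 / shift 0 is the identity
        h = naive_max_pool(h, g)
        emb = naive_gather(h, g, params.gather_W, params.gather_b)
        logits = params.head_W @ emb + params.head_b
        assert np.allclose(probs[0], 1.0 / (1.0 + np.exp(-logits)), atol=1e-10)

    def test_batched_equals_single_molecule_eval(self, rng):
        graphs = [smiles_to_graph(s) for s in ("CCO", "CC(=O)O", "c1ccccc1C")]
        cfg = GCNConfig(feature_dim=graphs[0].feature_dim, num_tasks=3,
                        depth=2, width=5)
        params = init_params(cfg, rng)
        together = forward(params, GraphBatch(graphs))
        singly = np.vstack([forward(params, GraphBatch([g])) for g in graphs])
        assert np.allclose(together, singly, atol=1e-6)

    def test_outputs_strictly_inside_open_intervals(self, rng):
        graphs = random_molgraphs(10, rng, feature_dim=8)
        cfg = GCNConfig(feature_dim=8, num_tasks=4, depth=2, width=6)
        params = init_params(cfg, rng)
        batch = GraphBatch(graphs)
        probs, cache = forward(params, batch, return_cache=True)
        assert ((cache["g"] > -1) & (cache["g"] < 1)).all()
        assert ((probs > 0) & (probs < 1)).all()

    def test_untied_self_neighbor_matrices_change_the_output(self, rng):
        g = smiles_to_graph("CCO")
        cfg = GCNConfig(feature_dim=g.feature_dim, num_tasks=1, depth=1,
                        width=4, tie_self_neighbor=False)
        params = init_params(cfg, rng)
        probs = forward(params, GraphBatch([g]))
        assert probs.shape == (1, 1)
        params.conv_Wn[0][:] = 0.0  # kill the neighbor term
        probs2 = forward(params, GraphBatch([g]))
        assert not np.allclose(probs, probs2)

    def test_feature_dim_mismatch_raises(self, small_params):
        g = smiles_to_graph("CCO")  # feature_dim 28, config expects 8
        with pytest.raises(ShapeError):
            forward(small_params, GraphBatch([g]))


class TestCheckpoint:
    def test_roundtrip_is_bit_exact(self, tmp_path, small_params, rng):
        # perturb away from init so the test is not trivially symmetric
        for v in small_params.trainable().values():
            v += rng.normal(size=v.shape)
        path = tmp_path / "ckpt.npz"
        save_params(path, small_params)
        loaded = load_params(path)
        for k, v in small_params.trainable().items():
            assert np.array_equal(loaded.trainable()[k], v), k
        for t in range(small_params.config.depth):
            assert np.array_equal(loaded.bn_run_mean[t], small_params.bn_run_mean[t])
            assert np.array_equal(loaded.bn_run_var[t], small_params.bn_run_var[t])
        assert loaded.config == small_params.config
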