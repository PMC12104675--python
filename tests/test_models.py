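"""Structural and arithmetic checks of the classifiers: hand-computed
layer outputs on tiny graphs, limit behaviors of the gated bi-kernel layer,
ego/neighbor separation in H2GCN, and permutation equivariance of every
model's forward pass."""

import numpy as np
import pytest

from heterocell.autodiff import Tensor, parameter
from heterocell.ccc_graph import CellGraph
from heterocell.models import (
    MODEL_NAMES,
    GraphOperators,
    ModelConfig,
    baseline_forward,
    build_model,
    gbk_layer,
    gbk_loss,
    h2gcn_classify,
    h2gcn_final,
    h2gcn_round,
)


def path_graph(values):
    """Chain graph 0-1-...-(n-1) with scalar features."""
    n = len(values)
    edges = np.array([[i, i + 1] for i in range(n - 1)])
    return GraphOperators.from_edges(n, edges), np.asarray(values, float).reshape(-1, 1)


# ---------------------------------------------------------------------------
# H2GCN
# ---------------------------------------------------------------------------


class TestH2GCN:
    def test_two_node_path_swaps_scalar_features(self):
        ops, X = path_graph([3.0, 5.0])
        out = h2gcn_round(X, ops.hop_means)
        # N1 means swap the values; there are no 2-hop neighbors
        assert np.allclose(out.data[:, 0], [5.0, 3.0])
        assert np.allclose(out.data[:, 1], 0.0)

    def test_three_node_path_hand_computed(self):
        ops, X = path_graph([1.0, 2.0, 4.0])
        out = h2gcn_round(X, ops.hop_means)
        # node 0: N1 = {1} -> 2; N2 = {2} -> 4
        # node 1: N1 = {0, 2} -> 2.5; N2 = {} -> 0
        assert np.allclose(out.data, [[2.0, 4.0], [2.5, 0.0], [2.0, 1.0]])

    def test_round_output_dim_is_hops_times_input(self):
        rng = np.random.default_rng(0)
        edges = np.array([[0, 1], [1, 2], [2, 3], [0, 3]])
        ops = GraphOperators.from_edges(4, edges)
        X = rng.normal(size=(4, 7))
        assert h2gcn_round(X, ops.hop_means).data.shape == (4, 14)

    def test_empty_graph_gives_zero_neighbor_terms(self):
        ops = GraphOperators.from_edges(3, np.zeros((0, 2)))
        X = np.ones((3, 2))
        assert np.allclose(h2gcn_round(X, ops.hop_means).data, 0.0)

    def test_final_concatenates_all_rounds(self):
        r0 = np.ones((5, 3))
        r1 = np.ones((5, 6))
        r2 = np.ones((5, 12))
        assert h2gcn_final([r0, r1, r2]).data.shape == (5, 21)
        assert h2gcn_final([r0]).data.shape == (5, 3)  # K=0: ego only

    def test_classify_is_row_stochastic_and_shift_invariant(self):
        rng = np.random.default_rng(1)
        final = rng.normal(size=(6, 4))
        W = rng.normal(size=(4, 3))
        p = h2gcn_classify(final, W)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.array_equal(
            np.argmax(p, 1), np.argmax(h2gcn_classify(final, W + 0.0), 1)
        )
        # zero weights -> uniform probabilities
        assert np.allclose(h2gcn_classify(final, np.zeros((4, 3))), 1 / 3)
        with pytest.raises(ValueError):
            h2gcn_classify(final, np.zeros((5, 3)))

    def test_ego_and_neighbor_paths_never_mix_in_a_round(self):
        """Zeroing the ego features changes nothing in the hop-aggregation
        terms of OTHER nodes' rounds only through those nodes' features;
        structurally, the round output contains no ego contribution."""
        rng = np.random.default_rng(2)
        edges = np.array([[0, 1], [1, 2], [2, 3]])
        ops = GraphOperators.from_edges(4, edges)
        X = rng.normal(size=(4, 3))
        ref = h2gcn_round(X, ops.hop_means).data.copy()
        X2 = X.copy()
        X2[1] = 0.0  # node 1's round output must be unchanged
        out = h2gcn_round(X2, ops.hop_means).data
        assert np.allclose(out[1], ref[1])

    def test_model_final_dim_is_sum_of_round_dims(self):
        rng = np.random.default_rng(3)
        edges = np.array([[0, 1], [1, 2], [2, 3], [3, 4]])
        ops = GraphOperators.from_edges(5, edges)
        cfg = ModelConfig(model_name="H2GCN", hidden_dim=8, n_layers=2)
        model = build_model(cfg, in_dim=6, n_classes=3, ops=ops)
        # d0 = 8, d1 = 16, d2 = 32 -> classifier input 56
        assert model.Wc.data.shape[0] == 8 + 16 + 32


# ---------------------------------------------------------------------------
# GBK-GNN
# ---------------------------------------------------------------------------


def _gbk_parts(rng, d_in, d_out, n_gate=4):
    kernels = (
        parameter(rng.normal(size=(d_in, d_out))),
        parameter(rng.normal(size=(d_out,))),
        parameter(rng.normal(size=(d_in, d_out))),
        parameter(rng.normal(size=(d_in, d_out))),
    )
    gate = (
        parameter(rng.normal(size=(2 * d_in, n_gate))),
        parameter(rng.normal(size=(n_gate,))),
        parameter(rng.normal(size=(n_gate, 1))),
        parameter(rng.normal(size=(1,))),
    )
    return kernels, gate


class TestGBKLayer:
    def test_forced_gate_one_ignores_heterophily_kernel(self):
        """With the gate saturated at alpha = 1, replacing W_d by garbage
        must not change the output."""
        rng = np.random.default_rng(4)
        ops, X = path_graph([1.0, -2.0, 0.5])
        kernels, gate = _gbk_parts(rng, 1, 2)
        # saturate the gate: huge positive bias on the output unit
        gate[3].data[:] = 1e4
        out1, gs = gbk_layer(X, ops, kernels, gate)
        assert np.allclose(gs.alpha.data, 1.0)
        Wf, bf, Ws, Wd = kernels
        garbage = (Wf, bf, Ws, parameter(rng.normal(size=Wd.data.shape) * 99))
        out2, _ = gbk_layer(X, ops, garbage, gate)
        assert np.array_equal(out1.data, out2.data)

    def test_forced_gate_zero_ignores_homophily_kernel(self):
        rng = np.random.default_rng(5)
        ops, X = path_graph([1.0, -2.0, 0.5])
        kernels, gate = _gbk_parts(rng, 1, 2)
        gate[3].data[:] = -1e4
        out1, gs = gbk_layer(X, ops, kernels, gate)
        assert np.allclose(gs.alpha.data, 0.0)
        Wf, bf, Ws, Wd = kernels
        garbage = (Wf, bf, parameter(rng.normal(size=Ws.data.shape) * 99), Wd)
        out2, _ = gbk_layer(X, ops, garbage, gate)
        assert np.array_equal(out1.data, out2.data)

    def test_two_node_scalar_hand_computation(self):
        """Direct arithmetic substitution on a 2-node graph with scalar
        weights and the identity activation."""
        ops, X = path_graph([2.0, 3.0])
        wf, bf, ws, wd = 0.5, 0.1, 1.5, -0.7
        kernels = (
            parameter([[wf]]),
            parameter([bf]),
            parameter([[ws]]),
            parameter([[wd]]),
        )
        # gate MLP: hidden relu(zi + zj), output = hidden - 1
        gate = (
            parameter([[1.0], [1.0]]),
            parameter([0.0]),
            parameter([[1.0]]),
            parameter([-1.0]),
        )
        out, gs = gbk_layer(X, ops, kernels, gate, activation="identity")

        def sig(v):
            return 1 / (1 + np.exp(-v))

        # directed edges (dst=1,src=0) and (dst=0,src=1); both gates relu(5)-1=4
        a = sig(4.0)
        exp0 = wf * 2.0 + bf + (a * ws * 3.0 + (1 - a) * wd * 3.0)
        exp1 = wf * 3.0 + bf + (a * ws * 2.0 + (1 - a) * wd * 2.0)
        assert np.allclose(out.data.ravel(), [exp0, exp1])
        assert np.allclose(gs.alpha.data, a)

    def test_isolated_node_gets_zero_neighbor_term(self):
        rng = np.random.default_rng(6)
        ops = GraphOperators.from_edges(3, np.array([[0, 1]]))
        kernels, gate = _gbk_parts(rng, 2, 2)
        X = rng.normal(size=(3, 2))
        out, _ = gbk_layer(X, ops, kernels, gate, activation="identity")
        Wf, bf = kernels[0], kernels[1]
        assert np.allclose(out.data[2], X[2] @ Wf.data + bf.data)


class TestGBKLoss:
    def _setup(self):
        rng = np.random.default_rng(7)
        ops, X = path_graph([1.0, 2.0, 3.0, 4.0])
        kernels, gate = _gbk_parts(rng, 1, 3)
        logits, gs = gbk_layer(X, ops, kernels, gate, activation="identity")
        labels = np.array([0, 0, 1, 2])
        mask = np.array([True, True, True, False])
        return logits, gs, labels, mask

    def test_lambda_zero_is_plain_cross_entropy(self):
        from heterocell.autodiff import gather, softmax_cross_entropy

        logits, gs, labels, mask = self._setup()
        loss = gbk_loss(logits, labels, [gs], lam=0.0, train_mask=mask)
        plain = softmax_cross_entropy(
            gather(logits, np.where(mask)[0]), labels[mask]
        )
        assert loss.data == pytest.approx(plain.data)

    def test_gate_term_scales_linearly_in_lambda(self):
        logits, gs, labels, mask = self._setup()
        l0 = gbk_loss(logits, labels, [gs], 0.0, mask).data
        l1 = gbk_loss(logits, labels, [gs], 1.0, mask).data
        l2 = gbk_loss(logits, labels, [gs], 2.0, mask).data
        assert l2 - l0 == pytest.approx(2 * (l1 - l0))

    def test_perfect_gates_drive_gate_term_to_zero(self):
        logits, gs, labels, mask = self._setup()
        # overwrite gate logits with saturated correct predictions
        same = (labels[gs.src] == labels[gs.dst]).astype(float)
        gs.logits.data[:] = np.where(same, 50.0, -50.0).reshape(-1, 1)
        l1 = gbk_loss(logits, labels, [gs], 1.0, mask).data
        l0 = gbk_loss(logits, labels, [gs], 0.0, mask).data
        assert l1 - l0 == pytest.approx(0.0, abs=1e-8)

    def test_no_train_train_edges_warns_and_drops_term(self):
        logits, gs, labels, _ = self._setup()
        lonely = np.array([True, False, False, True])  # nodes 0,3 not adjacent
        with pytest.warns(UserWarning):
            loss = gbk_loss(logits, labels, [gs], 1.0, lonely)
        assert np.isfinite(loss.data)

    def test_gradients_match_numeric_on_full_objective(self):
        """End-to-end gradient of the gated layer plus combined loss."""
        rng = np.random.default_rng(8)
        ops, X = path_graph([0.5, -1.0, 2.0])
        labels = np.array([0, 1, 0])
        mask = np.array([True, True, True])

        def objective(params):
            kernels = tuple(params[:4])
            gate = tuple(params[4:])
            logits, gs = gbk_layer(X, ops, kernels, gate, activation="identity")
            return gbk_loss(logits, labels, [gs], lam=0.7, train_mask=mask)

        kernels, gate = _gbk_parts(rng, 1, 2)
        params = list(kernels) + list(gate)
        loss = objective(params)
        loss.backward()
        eps = 1e-6
        for p in params:
            it = np.nditer(p.data, flags=["multi_index"])
            while not it.finished:
                i = it.multi_index
                orig = p.data[i]
                p.data[i] = orig + eps
                fp = objective(params).data
                p.data[i] = orig - eps
                fm = objective(params).data
                p.data[i] = orig
                num = (fp - fm) / (2 * eps)
                rel = abs(p.grad[i] - num) / max(abs(num), 1e-4)
                assert rel < 1e-4
                it.iternext()


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------


class TestBaselines:
    def test_mlp_ignores_edges(self, blob_graph):
        g = blob_graph
        dense = CellGraph(
            n_nodes=g.n_nodes,
            edges=np.array([[i, (i + 7) % g.n_nodes] for i in range(g.n_nodes)]),
            y=g.y,
            X=g.X,
        )
        a = baseline_forward("MLP", g.X, g)
        b = baseline_forward("MLP", g.X, dense)
        assert np.array_equal(a, b)

    def test_gcn_two_node_identity_weights_average_features(self):
        """2-node oracle: with identity weights, one GCN propagation equals
        D~^-1/2 (A + I) D~^-1/2 X."""
        edges = np.array([[0, 1]])
        ops = GraphOperators.from_edges(2, edges)
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        expected = np.full((2, 2), 0.5)  # each entry (1*1 + 1*1)/2 per norm
        assert np.allclose(ops.gcn_norm.toarray() @ X, expected)

    def test_mixhop_power_zero_is_per_node_linear_map(self):
        rng = np.random.default_rng(9)
        n = 6
        edges = np.array([[i, (i + 1) % n] for i in range(n)])
        g1 = CellGraph(n_nodes=n, edges=edges, y=np.zeros(n, int), X=rng.normal(size=(n, 4)))
        g2 = CellGraph(
            n_nodes=n,
            edges=np.array([[i, (i + 2) % n] for i in range(n)]),
            y=np.zeros(n, int),
            X=g1.X,
        )
        cfg = ModelConfig.for_model("MixHop", powers=(0,))
        a = baseline_forward("MixHop", g1.X, g1, config=cfg, n_classes=3)
        b = baseline_forward("MixHop", g2.X, g2, config=cfg, n_classes=3)
        assert np.allclose(a, b)  # A^0 = I: edges cannot matter

    def test_unknown_model_rejected(self, blob_graph):
        with pytest.raises(ValueError):
            baseline_forward("GraphTransformer", blob_graph.X, blob_graph)
        with pytest.raises(ValueError):
            ModelConfig(model_name="nope")


@pytest.mark.parametrize("name", MODEL_NAMES)
def test_permutation_equivariance(name, blob_graph):
    """Relabeling nodes permutes every model's output rows identically."""
    g = blob_graph
    rng = np.random.default_rng(10)
    perm = rng.permutation(g.n_nodes)  # perm[old] = new index
    g_perm = CellGraph(
        n_nodes=g.n_nodes, edges=perm[g.edges], y=g.y[np.argsort(perm)],
        X=g.X[np.argsort(perm)],
    )
    cfg = ModelConfig.for_model(name, seed=5)
    out = baseline_forward(name, g.X, g, config=cfg, n_classes=5)
    out_p = baseline_forward(name, g_perm.X, g_perm, config=cfg, n_classes=5)
    assert np.allclose(out_p[perm], out, atol=1e-10)
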