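"""Attention layers, readout heads and full forward passes against
explicit-loop oracles, plus the structural invariants of the attention
mechanism."""

import numpy as np
import pytest

from braingat.models import (GAT2, DenseLayer, GATAverage, GATFC, GATLayer,
                             GATLearn, GCNAttention, GCNLayer,
                             attention_pool, attention_predict,
                             gat_average_predict, graphs_to_arrays,
                             learn_pool)
from braingat.tensor import Tensor, constant, parameter


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _leaky(x, s=0.2):
    return np.where(x > 0, x, s * x)


def gat_layer_oracle(x, mask, W, a_src, a_dst, combine, final_sigmoid,
                     bias=None):
    """Explicit loops over heads, nodes and neighbors."""
    K, _, fo = W.shape
    n = x.shape[0]
    heads = np.zeros((K, n, fo))
    for k in range(K):
        wh = np.array([W[k].T @ x[i] for i in range(n)])
        for i in range(n):
            nbr = np.nonzero(mask[i])[0]
            scores = np.array([_leaky(a_src[k, :, 0] @ wh[i]
                                      + a_dst[k, :, 0] @ wh[j])
                               for j in nbr])
            e = np.exp(scores - scores.max())
            att = e / e.sum()
            heads[k, i] = sum(a * wh[j] for a, j in zip(att, nbr))
            if bias is not None:
                heads[k, i] = heads[k, i] + bias
    if combine == "concat":
        return np.concatenate([_leaky(heads[k]) for k in range(K)], axis=1)
    avg = heads.mean(axis=0)
    return _sigmoid(avg) if final_sigmoid else _leaky(avg)


class TestAttentionCoefficients:
    def test_identical_features_give_uniform_coefficients(self):
        n = 4
        x = np.ones((1, n, 3))
        mask = np.ones((1, n, n), dtype=bool)
        layer = GATLayer(3, 2, heads=2, rng=np.random.default_rng(0))
        att, _ = layer.attention(constant(x), mask)
        assert np.allclose(att.data, 1.0 / n, atol=1e-12)

    def test_single_neighbor_gets_coefficient_one(self):
        x = np.random.default_rng(1).standard_normal((1, 3, 2))
        mask = np.eye(3, dtype=bool)[None]  # only self-loops
        layer = GATLayer(2, 2, heads=1, rng=np.random.default_rng(2))
        att, _ = layer.attention(constant(x), mask)
        assert np.allclose(np.diagonal(att.data[0, 0]), 1.0)

    def test_rows_sum_to_one_and_nonnegative(self, micro_graphs):
        x, mask, _ = graphs_to_arrays(micro_graphs)
        layer = GATLayer(x.shape[2], 4, heads=3,
                         rng=np.random.default_rng(3))
        att, _ = layer.attention(constant(x), mask)
        assert np.all(att.data >= 0)
        assert np.allclose(att.data.sum(axis=-1), 1.0, atol=1e-12)

    def test_scalar_transcript_of_three_node_graph(self):
        # 1-D features, scalar W and attention halves, fixed by hand
        x = np.array([[[1.0], [2.0], [-1.0]]])
        mask = np.ones((1, 3, 3), dtype=bool)
        layer = GATLayer(1, 1, heads=1)
        layer.W.data = np.full((1, 1, 1), 0.5)
        layer.a_src.data = np.full((1, 1, 1), 1.0)
        layer.a_dst.data = np.full((1, 1, 1), -2.0)
        att, _ = layer.attention(constant(x), mask)
        wh = 0.5 * x[0, :, 0]                      # [0.5, 1.0, -0.5]
        for i in range(3):
            scores = _leaky(1.0 * wh[i] - 2.0 * wh)
            e = np.exp(scores - scores.max())
            assert np.allclose(att.data[0, 0, i], e / e.sum(), atol=1e-12)


class TestGATLayerForward:
    def test_single_head_concat_equals_average_before_activation(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((1, 4, 3))
        mask = np.ones((1, 4, 4), dtype=bool)
        con = GATLayer(3, 2, heads=1, combine="concat",
                       activation="identity", rng=np.random.default_rng(5))
        avg = GATLayer(3, 2, heads=1, combine="average",
                       activation="identity", rng=np.random.default_rng(5))
        assert np.allclose(con.forward(constant(x), mask).data,
                           avg.forward(constant(x), mask).data, atol=1e-14)

    def test_zero_weight_matrix_gives_activation_of_zero(self):
        x = np.random.default_rng(6).standard_normal((1, 3, 2))
        mask = np.ones((1, 3, 3), dtype=bool)
        layer = GATLayer(2, 2, heads=2, activation="sigmoid",
                         combine="average", rng=np.random.default_rng(7))
        layer.W.data[:] = 0.0
        out = layer.forward(constant(x), mask)
        assert np.allclose(out.data, 0.5, atol=1e-15)

    @pytest.mark.parametrize("combine,act", [("concat", False),
                                             ("average", True)])
    def test_matches_explicit_loop_oracle(self, combine, act, micro_graphs):
        x, mask, _ = graphs_to_arrays(micro_graphs[:3])
        layer = GATLayer(x.shape[2], 3, heads=2, combine=combine,
                         activation="sigmoid" if act else "leaky_relu",
                         rng=np.random.default_rng(8))
        out = layer.forward(constant(x), mask).data
        for b in range(x.shape[0]):
            expect = gat_layer_oracle(x[b], mask[b], layer.W.data,
                                      layer.a_src.data, layer.a_dst.data,
                                      combine, final_sigmoid=act)
            assert np.allclose(out[b], expect, atol=1e-10)

    def test_shape_mismatch_rejected(self):
        layer = GATLayer(3, 2, heads=1, rng=np.random.default_rng(9))
        with pytest.raises(ValueError):
            layer.forward(constant(np.zeros((1, 2, 5))),
                          np.ones((1, 2, 2), dtype=bool))


class TestReadoutHeads:
    def test_zero_pool_weight_gives_half_everywhere(self):
        h = constant(np.random.default_rng(0).standard_normal((2, 5, 3)))
        p = attention_pool(h, parameter(np.zeros((3, 1))))
        assert np.allclose(p.data, 0.5)

    def test_pool_saturates_toward_one(self):
        h = constant(np.ones((1, 2, 1)) * 50.0)
        p = attention_pool(h, parameter(np.ones((1, 1))))
        assert np.all(p.data > 1 - 1e-12)

    def test_pool_matches_scalar_sigmoid_oracle(self):
        h = np.array([[[0.2, -0.4], [1.0, 0.5]]])
        wp = np.array([[0.3], [-0.7]])
        p = attention_pool(constant(h), parameter(wp))
        expect = _sigmoid(h[0] @ wp[:, 0])
        assert np.allclose(p.data[0], expect, atol=1e-14)

    def test_zero_prediction_weight_equals_average_head(self):
        p = constant(np.random.default_rng(1).uniform(0.1, 0.9, (3, 6)))
        via_attention = attention_predict(p, parameter(np.zeros((6, 6))))
        via_average = gat_average_predict(p)
        assert np.array_equal(via_attention.data, via_average.data)  # bitwise

    def test_constant_p_gives_prob_equal_to_constant(self):
        p = constant(np.full((1, 4), 0.37))
        w = parameter(np.random.default_rng(2).standard_normal((4, 4)))
        assert np.allclose(attention_predict(p, w).data, 0.37, atol=1e-14)

    def test_attention_predict_matches_hand_softmax(self):
        p = np.array([[0.2, 0.7, 0.5]])
        wa = np.arange(9.0).reshape(3, 3) / 10.0
        prob = attention_predict(constant(p), parameter(wa)).data[0]
        logits = wa @ p[0]
        e = np.exp(logits - logits.max())
        a = e / e.sum()
        assert prob == pytest.approx(float(a @ p[0]), abs=1e-14)

    def test_prob_is_convex_combination_of_p(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0, 1, (5, 7))
        w = parameter(rng.standard_normal((7, 7)))
        prob = attention_predict(constant(p), w).data
        assert np.all(prob >= p.min(axis=1)) and np.all(prob <= p.max(axis=1))

    def test_average_head_examples(self):
        assert gat_average_predict(constant(np.full((1, 4), 0.5))
                                   ).data[0] == pytest.approx(0.5)
        rng = np.random.default_rng(4)
        p = rng.uniform(0, 1, (1, 7))
        assert gat_average_predict(constant(p)).data[0] == pytest.approx(
            p.mean(), abs=1e-14)

    def test_learn_pool_examples(self):
        rng = np.random.default_rng(5)
        y = rng.standard_normal((1, 6, 11))
        s_uniform = np.full((1, 6, 1), 1.0 / 6)
        pooled = learn_pool(constant(y), constant(s_uniform)).data
        assert np.allclose(pooled[0, 0], y[0].mean(axis=0), atol=1e-14)
        s_onehot = np.zeros((1, 6, 1))
        s_onehot[0, 2, 0] = 1.0
        assert np.allclose(learn_pool(constant(y),
                                      constant(s_onehot)).data[0, 0],
                           y[0, 2], atol=1e-15)
        # explicit-loop product
        s = rng.standard_normal((1, 6, 1))
        expect = sum(s[0, i, 0] * y[0, i] for i in range(6))
        assert np.allclose(learn_pool(constant(y), constant(s)).data[0, 0],
                           expect, atol=1e-12)


class TestGCNLayer:
    def test_identity_adjacency_reduces_to_linear_transform(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((1, 4, 3))
        layer = GCNLayer(3, 2, rng=np.random.default_rng(7))
        out = layer.forward(constant(x), np.eye(4)[None])
        expect = _leaky(x[0] @ layer.W[0].data)
        assert np.allclose(out.data[0], expect, atol=1e-12)

    def test_first_order_matches_dense_matrix_oracle(self):
        rng = np.random.default_rng(8)
        adj = rng.uniform(0, 1, (3, 3))
        adj = (adj + adj.T) / 2
        np.fill_diagonal(adj, 1.0)
        x = rng.standard_normal((1, 3, 2))
        layer = GCNLayer(2, 2, rng=np.random.default_rng(9))
        d = 1.0 / np.sqrt(adj.sum(axis=1))
        norm = np.diag(d) @ adj @ np.diag(d)
        expect = _leaky(norm @ x[0] @ layer.W[0].data)
        out = layer.forward(constant(x), adj[None])
        assert np.allclose(out.data[0], expect, atol=1e-12)

    def test_chebyshev_order_one_is_affine_in_scaled_laplacian(self):
        rng = np.random.default_rng(10)
        adj = np.ones((3, 3))
        x = rng.standard_normal((1, 3, 2))
        layer = GCNLayer(2, 2, filter_type="chebyshev", order=1,
                         rng=np.random.default_rng(11))
        d = 1.0 / np.sqrt(adj.sum(axis=1))
        lap = -(np.diag(d) @ adj @ np.diag(d))
        expect = _leaky(x[0] @ layer.W[0].data
                        + lap @ x[0] @ layer.W[1].data)
        out = layer.forward(constant(x), adj[None])
        assert np.allclose(out.data[0], expect, atol=1e-12)

    def test_zero_degree_clamped_with_warning(self, caplog):
        adj = np.zeros((2, 2))
        layer = GCNLayer(2, 2, rng=np.random.default_rng(12))
        with caplog.at_level("WARNING"):
            layer.forward(constant(np.zeros((1, 2, 2))), adj[None])
        assert "clamped" in caplog.text


class TestFullModels:
    def test_gat2_with_zero_pred_weight_equals_gat_average(self, micro_graphs):
        gat2 = GAT2(micro_graphs, heads=(2, 2), units=(3, 3), seed=21)
        gat2.pred_weight.data[:] = 0.0
        avg = GATAverage(micro_graphs, heads=(2, 2), units=(3, 3), seed=99)
        # copy the upstream parameters so only the head differs
        for la, lb in zip(gat2._layers, avg._layers):
            lb.W.data = la.W.data.copy()
            lb.a_src.data = la.a_src.data.copy()
            lb.a_dst.data = la.a_dst.data.copy()
        avg.pool_weight.data = gat2.pool_weight.data.copy()
        assert np.array_equal(gat2.predict_proba(micro_graphs),
                              avg.predict_proba(micro_graphs))  # bitwise

    def test_prob_always_in_open_unit_interval(self, micro_graphs,
                                               untrained_gat2):
        prob = untrained_gat2.predict_proba(micro_graphs)
        assert np.all((prob > 0) & (prob < 1))

    def test_forward_matches_composition_oracle(self, micro_graphs):
        model = GAT2(micro_graphs[:2], heads=(2, 2), units=(3, 3), seed=13)
        x, mask, _ = graphs_to_arrays(micro_graphs[:2])
        h = x
        for li, layer in enumerate(model._layers):
            h = np.stack([
                gat_layer_oracle(h[b], mask[b], layer.W.data,
                                 layer.a_src.data, layer.a_dst.data,
                                 layer.combine,
                                 final_sigmoid=(layer.activation == "sigmoid"))
                for b in range(h.shape[0])])
        p = _sigmoid(h @ model.pool_weight.data[:, 0])
        logits = p @ model.pred_weight.data.T
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        a = e / e.sum(axis=1, keepdims=True)
        expect = (a * p).sum(axis=1)
        assert np.allclose(model.predict_proba(micro_graphs[:2]), expect,
                           atol=1e-10)

    def test_gradient_check_on_four_node_graph(self):
        from braingat.synthetic import SyntheticSpec, generate_synthetic_dataset
        graphs = generate_synthetic_dataset(
            SyntheticSpec(n_graphs=3, n_nodes=4, n_selected=2, seed=17)).graphs
        model = GAT2(graphs, heads=(2,), units=(2,), seed=18)
        x, mask, y = model.x, model.adj, model.y
        loss = model.loss(constant(x), mask, y)
        loss.backward()
        eps = 1e-5
        for p in model.parameters():
            flat_idx = np.unravel_index(
                np.argmax(np.abs(p.grad)), p.data.shape)
            orig = p.data[flat_idx]
            p.data[flat_idx] = orig + eps
            lp = model.loss(constant(x), mask, y).item()
            p.data[flat_idx] = orig - eps
            lm = model.loss(constant(x), mask, y).item()
            p.data[flat_idx] = orig
            fd = (lp - lm) / (2 * eps)
            assert fd == pytest.approx(p.grad[flat_idx], rel=1e-4)

    def test_gat_fc_probabilities_sum_to_one(self, micro_graphs):
        model = GATFC(micro_graphs, heads=(2, 2), units=(3, 3),
                      fc_units=8, seed=19)
        x, mask, _ = graphs_to_arrays(micro_graphs)
        probs = model.class_probabilities(constant(x), mask).data
        assert np.allclose(probs.sum(axis=-1), 1.0, atol=1e-12)
        assert np.allclose(model.predict_proba(micro_graphs), probs[:, 1])

    def test_gat_fc_zero_final_layer_gives_half(self, micro_graphs):
        model = GATFC(micro_graphs, heads=(2, 2), units=(3, 3),
                      fc_units=8, seed=20)
        model.fc2.W.data[:] = 0.0
        model.fc2.b.data[:] = 0.0
        assert np.allclose(model.predict_proba(micro_graphs), 0.5)

    def test_gat_learn_pooled_shape_and_range(self, micro_graphs):
        model = GATLearn(micro_graphs, heads=(2, 2), units=(3, 3), seed=22)
        prob = model.predict_proba(micro_graphs)
        assert prob.shape == (len(micro_graphs),)
        assert np.all((prob > 0) & (prob < 1))

    @pytest.mark.parametrize("ft", ["first_order", "chebyshev"])
    def test_gcn_attention_forward_in_unit_interval(self, micro_graphs, ft):
        model = GCNAttention(micro_graphs, units=4, filter_type=ft, seed=23)
        prob = model.predict_proba(micro_graphs)
        assert np.all((prob > 0) & (prob < 1))

    def test_node_permutation_leaves_average_head_unchanged(self,
                                                            micro_graphs):
        g = micro_graphs[0]
        model = GATAverage([g], heads=(2, 2), units=(3, 3), seed=24)
        prob = model.predict_proba([g])
        rng = np.random.default_rng(25)
        perm = rng.permutation(g.n_nodes)
        from dataclasses import replace
        gp = replace(g,
                     node_features=g.node_features[perm][:, perm],
                     adj_weights=g.adj_weights[perm][:, perm])
        # permuting nodes together with their feature coordinates requires
        # permuting the first-layer input weights the same way
        model2 = GATAverage([gp], heads=(2, 2), units=(3, 3), seed=24)
        for la, lb in zip(model._layers, model2._layers):
            lb.W.data = la.W.data.copy()
            lb.a_src.data = la.a_src.data.copy()
            lb.a_dst.data = la.a_dst.data.copy()
        model2.pool_weight.data = model.pool_weight.data.copy()
        model2._layers[0].W.data = model._layers[0].W.data[:, perm, :]
        prob_p = model2.predict_proba([gp])
        assert prob_p[0] == pytest.approx(prob[0], abs=1e-12)
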