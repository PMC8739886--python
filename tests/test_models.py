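"""Layer semantics, receptive fields, attention normalization, serialization."""

import numpy as np
import pytest

from parcelgnn.autograd import Tensor
from parcelgnn.models import (
    ModelSpec,
    TrainedModel,
    closed_neighborhood_edges,
    forward,
    gat_layer,
    gcn_layer,
    init_params,
    jk_aggregate,
    load_model,
    save_model,
)
from parcelgnn.surface import geodesic_hops
from conftest import graph_from_edges, path_graph


def _model(arch, g=None, in_features=4, num_classes=3, depth=2, **kw):
    spec = ModelSpec(
        architecture=arch,
        in_features=in_features,
        num_classes=num_classes,
        depth=depth,
        hidden_channels=kw.pop("hidden_channels", 6),
        attention_heads=kw.pop("attention_heads", 2),
        dropout=kw.pop("dropout", 0.0),
        **kw,
    )
    return TrainedModel(spec=spec, params=init_params(spec, seed=42))


class TestGCNLayer:
    def test_edgeless_graph_propagates_self_only(self):
        g = graph_from_edges([], 4)
        h = np.random.default_rng(0).normal(size=(4, 3))
        out = gcn_layer(h, g, np.eye(3))
        # with self-loops only, D̃ = I, so the layer is the identity map
        np.testing.assert_allclose(out.data, h)

    def test_one_hop_receptive_field(self):
        g = path_graph(5)
        rng = np.random.default_rng(1)
        h = rng.normal(size=(5, 3))
        w = rng.normal(size=(3, 3))
        base = gcn_layer(h, g, w).data
        h2 = h.copy()
        h2[0] += 10.0
        pert = gcn_layer(h2, g, w).data
        changed = np.abs(pert - base).sum(axis=1) > 0
        np.testing.assert_array_equal(changed, [True, True, False, False, False])

    def test_constant_signal_hand_product_on_path(self):
        g = path_graph(4)
        h = np.ones((4, 1))
        out = gcn_layer(h, g, np.eye(1)).data.ravel()
        # Â row sums for a 4-path with self-loops (degrees 2,3,3,2):
        deg = np.array([2.0, 3, 3, 2])
        expected = np.array(
            [
                1 / 2 + 1 / np.sqrt(2 * 3),
                1 / np.sqrt(3 * 2) + 1 / 3 + 1 / 3,
                1 / 3 + 1 / 3 + 1 / np.sqrt(3 * 2),
                1 / np.sqrt(2 * 3) + 1 / 2,
            ]
        )
        np.testing.assert_allclose(out, expected)

    def test_shape_mismatch_rejected(self):
        g = path_graph(3)
        with pytest.raises(ValueError, match="shape mismatch"):
            gcn_layer(np.zeros((3, 4)), g, np.zeros((5, 2)))


class TestGATLayer:
    def _heads(self, k_in, k_out, m, seed=0):
        rng = np.random.default_rng(seed)
        ws = [rng.normal(size=(k_in, k_out)) for _ in range(m)]
        avs = [
            (rng.normal(size=(k_out, 1)), rng.normal(size=(k_out, 1)))
            for _ in range(m)
        ]
        return ws, avs

    def test_identical_features_give_uniform_attention(self):
        g = path_graph(4)
        h = np.ones((4, 3))
        ws, avs = self._heads(3, 5, 2)
        _, alphas = gat_layer(h, g, ws, avs, return_attention=True)
        centers, _ = closed_neighborhood_edges(g)
        sizes = np.bincount(centers)
        for alpha in alphas:
            np.testing.assert_allclose(alpha.data, 1.0 / sizes[centers], atol=1e-12)

    def test_attention_sums_to_one_per_vertex(self, icosahedron):
        rng = np.random.default_rng(2)
        h = rng.normal(size=(12, 4))
        ws, avs = self._heads(4, 6, 3)
        _, alphas = gat_layer(h, g=icosahedron, w_heads=ws, a_heads=avs,
                              return_attention=True)
        centers, _ = closed_neighborhood_edges(icosahedron)
        for alpha in alphas:
            sums = np.zeros(12)
            np.add.at(sums, centers, alpha.data)
            np.testing.assert_allclose(sums, 1.0, atol=1e-6)

    def test_three_node_star_matches_hand_attention(self):
        """Node update equals the explicit attention formula on a star."""
        g = graph_from_edges([(0, 1), (0, 2)], 3)
        rng = np.random.default_rng(3)
        h = rng.normal(size=(3, 2))
        w = rng.normal(size=(2, 2))
        a_src = rng.normal(size=(2, 1))
        a_dst = rng.normal(size=(2, 1))
        out = gat_layer(h, g, [w], [(a_src, a_dst)]).data

        def leaky(x):
            return x if x > 0 else 0.2 * x

        z = h @ w
        a = np.concatenate([a_src, a_dst]).ravel()
        for i in range(3):
            nbrs = sorted(set(np.nonzero(g.adjacency[i].toarray().ravel())[0]) | {i})
            scores = [leaky(a @ np.concatenate([z[i], z[j]])) for j in nbrs]
            e = np.exp(scores - np.max(scores))
            alpha = e / e.sum()
            expected = sum(al * z[j] for al, j in zip(alpha, nbrs))
            np.testing.assert_allclose(out[i], expected, atol=1e-12)


class TestJKAggregate:
    def test_single_layer_reduces_to_identity(self):
        e = np.random.default_rng(4).normal(size=(5, 3))
        for mode in ("concat", "maxpool"):
            out = jk_aggregate([Tensor(e)], mode)
            np.testing.assert_allclose(out.data, e)

    def test_concat_width(self):
        embs = [Tensor(np.zeros((7, 32))) for _ in range(3)]
        assert jk_aggregate(embs, "concat").shape == (7, 96)

    def test_maxpool_elementwise(self):
        a = Tensor(np.array([[1.0, 5.0]]))
        b = Tensor(np.array([[4.0, 2.0]]))
        np.testing.assert_allclose(jk_aggregate([a, b], "maxpool").data, [[4, 5]])

    def test_lstm_attention_convex_combination(self):
        spec = ModelSpec(
            architecture="jkgat", in_features=4, num_classes=3, depth=3,
            hidden_channels=4, attention_heads=2, aggregation="lstm",
        )
        params = init_params(spec, seed=0)
        embs = [Tensor(np.random.default_rng(i).normal(size=(6, 8))) for i in range(3)]
        out, attn = jk_aggregate(embs, "lstm", params, return_attention=True)
        assert out.shape == (6, 8)
        assert (attn.data >= 0).all()
        np.testing.assert_allclose(attn.data.sum(axis=1), 1.0, atol=1e-6)

    def test_lstm_single_layer_weight_is_one(self):
        spec = ModelSpec(
            architecture="jkgat", in_features=4, num_classes=3, depth=1,
            hidden_channels=4, attention_heads=2, aggregation="lstm",
        )
        params = init_params(spec, seed=0)
        e = Tensor(np.random.default_rng(9).normal(size=(5, 8)))
        out, attn = jk_aggregate([e], "lstm", params, return_attention=True)
        np.testing.assert_allclose(attn.data, 1.0)
        np.testing.assert_allclose(out.data, e.data)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="unknown aggregation"):
            jk_aggregate([Tensor(np.zeros((2, 2)))], "median")


class TestForward:
    def test_baseline_ignores_graph(self):
        m = _model("baseline")
        x = np.random.default_rng(5).normal(size=(6, 4))
        a = forward(m, path_graph(6), x).data
        b = forward(m, graph_from_edges([(0, 5), (1, 3)], 6), x).data
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("arch", ["gcn", "gat", "jkgat"])
    @pytest.mark.parametrize("depth", [1, 2, 3])
    def test_receptive_field_bounded_by_depth(self, arch, depth):
        """Perturbing features beyond L hops leaves logits bit-identical."""
        g = path_graph(8)
        m = _model(arch, depth=depth)
        rng = np.random.default_rng(6)
        x = rng.normal(size=(8, 4))
        base = forward(m, g, x).data
        hops = geodesic_hops(g, [7])
        x2 = x.copy()
        x2[7] += rng.normal(size=4) * 5
        pert = forward(m, g, x2).data
        unchanged = hops > depth
        np.testing.assert_array_equal(base[unchanged], pert[unchanged])
        assert np.abs(base[~unchanged] - pert[~unchanged]).max() > 0

    @pytest.mark.parametrize("arch", ["baseline", "gcn", "gat", "jkgat"])
    def test_permutation_equivariance(self, arch):
        g = path_graph(6)
        m = _model(arch)
        rng = np.random.default_rng(7)
        x = rng.normal(size=(6, 4))
        base = forward(m, g, x).data
        perm = rng.permutation(6)
        inv = np.argsort(perm)  # new index of old vertex i
        g2 = graph_from_edges(
            [(inv[i], inv[i + 1]) for i in range(5)], 6
        )
        out = forward(m, g2, x[perm]).data
        np.testing.assert_allclose(out, base[perm], atol=1e-10)

    def test_eval_mode_deterministic(self):
        m = _model("gat")
        g = path_graph(5)
        x = np.random.default_rng(8).normal(size=(5, 4))
        a = forward(m, g, x).data
        b = forward(m, g, x).data
        assert a.tobytes() == b.tobytes()

    def test_feature_width_mismatch_named(self):
        m = _model("gcn")
        with pytest.raises(ValueError, match="expects 4, got 9"):
            forward(m, path_graph(3), np.zeros((3, 9)))

    def test_dropout_only_in_train_mode(self):
        m = _model("baseline", dropout=0.5)
        g = path_graph(5)
        x = np.random.default_rng(9).normal(size=(5, 4))
        rng1 = np.random.default_rng(1)
        rng2 = np.random.default_rng(2)
        a = forward(m, g, x, train_mode=True, rng=rng1).data
        b = forward(m, g, x, train_mode=True, rng=rng2).data
        assert not np.allclose(a, b)
        np.testing.assert_array_equal(forward(m, g, x).data, forward(m, g, x).data)


class TestSerialization:
    @pytest.mark.parametrize("arch", ["baseline", "gcn", "gat", "jkgat"])
    def test_round_trip_reproduces_logits_bit_exactly(self, arch, tmp_path):
        m = _model(arch, depth=3)
        m.training_log = [{"epoch": 1, "train_loss": 0.5, "val_loss": 0.6}]
        g = path_graph(6)
        x = np.random.default_rng(10).normal(size=(6, 4))
        before = forward(m, g, x).data
        path = tmp_path / "model.ckpt"
        save_model(m, path)
        loaded = load_model(path)
        assert loaded.spec == m.spec
        assert loaded.training_log == m.training_log
        after = forward(loaded, g, x).data
        assert before.tobytes() == after.tobytes()
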