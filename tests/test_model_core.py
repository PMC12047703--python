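import numpy as np
import pytest

from chromgae.graph_dataset import SamplerConfig, SegmentGraph, signed_weight
from chromgae.model_core import (
    Adam,
    EncoderParams,
    attention_coefficients,
    decode,
    edge_message,
    encode,
    forward_loss,
    load_params,
    mse_loss,
    save_params,
)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def dense_reference_forward(X, edges, omega, params):
    """Independent re-implementation: explicit per-node loops, dense math."""
    heads = params.heads
    h = np.pad(np.asarray(X, dtype=float), ((0, 0), (0, 16 - X.shape[1])))
    directed = []
    for (i, j), w in zip(edges, omega):
        directed.append((j, i, w))  # source j -> target i
        directed.append((i, j, w))
    for layer in params.layers:
        W, b = layer.W.data, layer.b.data
        Q, K = layer.Q.data, layer.K.data
        d_in = layer.d_in
        d_head = d_in // heads
        new_h = np.zeros((len(h), layer.d_out))
        for i in range(len(h)):
            nbrs = [(s, w) for (s, t, w) in directed if t == i]
            acc = np.zeros(layer.d_out)
            if nbrs:
                logits = np.zeros((len(nbrs), heads))
                for e, (s, _w) in enumerate(nbrs):
                    qi = (h[i] @ Q).reshape(heads, d_head)
                    ks = (h[s] @ K).reshape(heads, d_head)
                    logits[e] = (qi * ks).sum(axis=1) / np.sqrt(d_head)
                alpha = np.exp(logits - logits.max(axis=0))
                alpha /= alpha.sum(axis=0)
                for e, (s, w) in enumerate(nbrs):
                    a = w * alpha[e].mean()
                    msg = np.concatenate([h[s] - h[i], h[i]]) @ W + b
                    acc += a * msg
            new_h[i] = _sigmoid(acc)
        h = new_h
    return h


def _graph(n=6, seed=0, span=4, with_labels=True):
    rng = np.random.default_rng(seed)
    X = rng.random((n, 14))
    edges = np.array(
        [(i, j) for i in range(n) for j in range(i + 1, min(i + span + 1, n))]
    )
    keep = rng.random(len(edges)) < 0.8
    edges = edges[keep]
    omega = signed_weight(edges[:, 0], edges[:, 1], 3)
    labels = rng.random(len(edges)) * 3 if with_labels else None
    return SegmentGraph(
        chrom="chr1", first_index=0, size=n, node_features=X,
        edges=edges, edge_weight=np.atleast_1d(omega), edge_label=labels,
    )


class TestEncoderOracle:
    def test_three_node_graph_matches_dense_reference(self):
        g = _graph(n=3, seed=2, span=2)
        params = EncoderParams.init(np.random.default_rng(1))
        z = encode(g, params).z
        ref = dense_reference_forward(g.node_features, g.edges, g.edge_weight, params)
        assert np.max(np.abs(z - ref)) < 1e-6

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_larger_graphs_match_dense_reference(self, seed):
        g = _graph(n=10, seed=seed)
        params = EncoderParams.init(np.random.default_rng(seed + 10))
        z = encode(g, params).z
        ref = dense_reference_forward(g.node_features, g.edges, g.edge_weight, params)
        assert np.max(np.abs(z - ref)) < 1e-6

    def test_output_shape_is_n_by_32(self):
        g = _graph(n=9, seed=3)
        params = EncoderParams.init(np.random.default_rng(0))
        assert encode(g, params).z.shape == (9, 32)

    def test_isolated_node_embeds_at_one_half(self):
        g = _graph(n=5, seed=1)
        # disconnect node 4 entirely
        mask = (g.edges != 4).all(axis=1)
        g = SegmentGraph(
            chrom="chr1", first_index=0, size=5, node_features=g.node_features,
            edges=g.edges[mask], edge_weight=g.edge_weight[mask],
            edge_label=None,
        )
        z = encode(g, EncoderParams.init(np.random.default_rng(0))).z
        assert np.allclose(z[4], 0.5)


class TestGradient:
    def test_numeric_vs_analytic_gradient(self):
        """Full-chain gradient check on a 5-node graph, 1e-4 relative."""
        g = _graph(n=5, seed=4)
        params = EncoderParams.init(np.random.default_rng(7))
        loss = forward_loss(g, params)
        loss.backward()
        rng = np.random.default_rng(0)
        for t in params.tensors():
            flat = t.data.reshape(-1)
            gflat = t.grad.reshape(-1)
            for k in rng.choice(flat.size, size=min(5, flat.size), replace=False):
                eps = 1e-5
                orig = flat[k]
                flat[k] = orig + eps
                lp = forward_loss(g, params).data
                flat[k] = orig - eps
                lm = forward_loss(g, params).data
                flat[k] = orig
                num = (lp - lm) / (2 * eps)
                denom = max(abs(num), abs(gflat[k]), 1e-6)
                assert abs(num - gflat[k]) / denom < 1e-4


class TestEdgeMessage:
    def test_identical_nodes_leave_difference_term_zero(self):
        params = EncoderParams.init(np.random.default_rng(0))
        layer = params.layers[1]
        h = np.random.default_rng(1).random(layer.d_in)
        msg = edge_message(h, h, layer)
        expected = np.concatenate([np.zeros_like(h), h]) @ layer.W.data + layer.b.data
        assert np.allclose(msg, expected)

    def test_difference_selecting_weights(self):
        params = EncoderParams.init(np.random.default_rng(0))
        layer = params.layers[1]  # 32 -> 16
        layer.W.data[:] = 0.0
        layer.W.data[:16, :16] = np.eye(16)  # pick h_j − h_i (first half), first 16 dims
        layer.b.data[:] = 0.0
        rng = np.random.default_rng(2)
        hi, hj = rng.random(32), rng.random(32)
        assert np.allclose(edge_message(hi, hj, layer), (hj - hi)[:16])


class TestAttention:
    def test_single_neighbor_attention_equals_omega(self):
        params = EncoderParams.init(np.random.default_rng(0))
        h = np.random.default_rng(1).random((2, 16))
        a = attention_coefficients(h, np.array([[0, 1]]), np.array([0.7]),
                                   params.layers[0])
        assert a[(0, 1)] == pytest.approx(0.7)
        assert a[(1, 0)] == pytest.approx(0.7)

    def test_identical_keys_split_evenly(self):
        params = EncoderParams.init(np.random.default_rng(0))
        h = np.random.default_rng(1).random((3, 16))
        h[2] = h[1]  # sources 1 and 2 present identical keys to target 0
        a = attention_coefficients(
            h, np.array([[0, 1], [0, 2]]), np.array([1.0, 1.0]),
            params.layers[0],
        )
        assert a[(0, 1)] == pytest.approx(0.5)
        assert a[(0, 2)] == pytest.approx(0.5)

    def test_attention_normalizes_over_neighborhoods(self):
        """Σ_j a_ij / ω = 1 per target when ω is constant 1."""
        g = _graph(n=8, seed=5)
        params = EncoderParams.init(np.random.default_rng(3))
        a = attention_coefficients(
            g.node_features @ np.zeros((14, 16)) + 0.3 + 0 * np.arange(16),
            g.edges, np.ones(g.n_edges), params.layers[0],
        )
        per_target = {}
        for (i, _j), v in a.items():
            per_target[i] = per_target.get(i, 0.0) + v
        for total in per_target.values():
            assert total == pytest.approx(1.0)


class TestDecodeLoss:
    def test_decode_unit_and_orthogonal(self):
        z = np.eye(4, 32)
        assert decode(z, [(0, 0)])[0] == pytest.approx(1.0)
        assert decode(z, [(0, 1)])[0] == pytest.approx(0.0)

    def test_decode_symmetric(self, rng):
        z = rng.random((6, 32))
        pairs = [(i, j) for i in range(6) for j in range(6)]
        fwd = decode(z, pairs)
        rev = decode(z, [(j, i) for i, j in pairs])
        assert np.allclose(fwd, rev)

    def test_mse_oracle(self, rng):
        a, b = rng.random(100), rng.random(100)
        two_pass = sum((x - y) ** 2 for x, y in zip(a, b)) / 100
        assert mse_loss(a, b) == pytest.approx(two_pass, abs=1e-12)
        assert mse_loss(a, a) == 0.0
        assert mse_loss(np.ones(10), np.zeros(10)) == 1.0

    def test_empty_labels_rejected(self):
        with pytest.raises(ValueError):
            mse_loss(np.zeros(0), np.zeros(0))


class TestProperties:
    def test_permutation_equivariance(self):
        g = _graph(n=7, seed=6)
        params = EncoderParams.init(np.random.default_rng(2))
        z = encode(g, params).z
        perm = np.random.default_rng(0).permutation(7)
        inv = np.argsort(perm)
        gp = SegmentGraph(
            chrom="chr1", first_index=0, size=7,
            node_features=g.node_features[perm],
            edges=np.vectorize(lambda v: inv[v])(g.edges),
            edge_weight=g.edge_weight, edge_label=None,
        )
        zp = encode(gp, params).z
        assert np.max(np.abs(zp - z[perm])) < 1e-10

    def test_omega_scales_edge_contribution(self):
        """Doubling ω of an edge doubles its (pre-activation) contribution."""
        from chromgae.autodiff import constant
        from chromgae.model_core import _attention, _directed, _messages

        g = _graph(n=4, seed=8)
        params = EncoderParams.init(np.random.default_rng(1))
        layer = params.layers[0]
        X = np.pad(g.node_features, ((0, 0), (0, 2)))
        src, tgt, orig = _directed(g.edges)
        h = constant(X)
        for scale in (1.0, 2.0):
            omega = g.edge_weight[orig] * scale
            a = _attention(h, src, tgt, omega, layer, params.heads)
            if scale == 1.0:
                base = a.data.copy()
        assert np.allclose(a.data, 2.0 * base)


def test_checkpoint_round_trip(tmp_path):
    params = EncoderParams.init(np.random.default_rng(5))
    save_params(tmp_path / "p.json", params, meta={"seed": 5})
    back = load_params(tmp_path / "p.json")
    g = _graph(n=6, seed=0)
    assert np.array_equal(encode(g, params).z, encode(g, back).z)


def test_adam_reduces_loss_on_quadratic():
    from chromgae.autodiff import parameter

    x = parameter(np.array([3.0, -2.0]))
    opt = Adam([x], lr=0.1)
    for _ in range(200):
        opt.zero_grad()
        loss = x.square().sum()
        loss.backward()
        opt.step()
    assert np.max(np.abs(x.data)) < 1e-2
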