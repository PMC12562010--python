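"""Encoder/decoder forward-backward correctness and architectural contracts."""

import numpy as np
import pytest
import scipy.sparse as sp

from pathokg.errors import ShapeError
from pathokg.graph_store import HeteroGraph, NodeRef
from pathokg.model import (
    BaselineState,
    GCNParams,
    MLPParams,
    ModelState,
    bce_loss,
    decode_pairs,
    gcn_backward,
    gcn_encode,
    mlp_backward,
    mlp_forward,
    normalized_adjacency,
    sigmoid,
)


def _adjacency_from_edges(n, edges):
    g = HeteroGraph()
    for i in range(n):
        g.add_node(NodeRef(f"P{i:02d}", "protein", f"P{i:02d}"))
    for i, j in edges:
        g.add_edge(f"P{i:02d}", f"P{j:02d}", "Protein-Protein (PPI)")
    return normalized_adjacency(g.adjacency())


class TestNormalizedAdjacency:
    def test_single_node_self_loop(self):
        a = _adjacency_from_edges(1, [])
        assert np.allclose(a.toarray(), [[1.0]])

    def test_two_nodes_one_edge_closed_form(self):
        a = _adjacency_from_edges(2, [(0, 1)])
        assert np.allclose(a.toarray(), 0.5)

    def test_symmetric_with_unit_spectral_bound(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            n = int(rng.integers(3, 12))
            edges = {(int(i), int(j)) for i, j in rng.integers(0, n, size=(n, 2)) if i != j}
            a = _adjacency_from_edges(n, edges).toarray()
            assert np.allclose(a, a.T)
            assert np.all((a >= 0) & (a <= 1))
            # symmetric normalization bounds the spectrum by 1, not row sums
            assert np.max(np.abs(np.linalg.eigvalsh(a))) <= 1.0 + 1e-9


class TestGradients:
    """Analytic gradients vs central finite differences (float64, eval mode)."""

    def test_end_to_end_gradcheck(self):
        rng = np.random.default_rng(3)
        n, d = 6, 5
        enc = GCNParams.init(d, rng, d_hidden=7, d_out=4)
        dec = MLPParams.init(8, (5, 3), rng)
        X = rng.standard_normal((n, d))
        a = sp.random(n, n, density=0.5, random_state=1)
        a = ((a + a.T) > 0).astype(float) + sp.identity(n)
        deg = np.asarray(a.sum(1)).ravel()
        D = sp.diags(1 / np.sqrt(deg))
        A = (D @ a @ D).tocsr()
        vi, di = np.array([0, 1, 2]), np.array([3, 4, 5])
        y = np.array([1.0, 0.0, 1.0])

        def loss():
            Z, _ = gcn_encode(X, A, enc, training=False)
            p, _, _ = decode_pairs(Z[vi], Z[di], dec, training=False)
            return bce_loss(p, y)

        Z, ec = gcn_encode(X, A, enc, training=False)
        p, _, dc = decode_pairs(Z[vi], Z[di], dec, training=False)
        dg, dP = mlp_backward(dc, (p - y) / 3, dec)
        dZ = np.zeros_like(Z)
        np.add.at(dZ, vi, dP[:, :4])
        np.add.at(dZ, di, dP[:, 4:])
        eg = gcn_backward(ec, dZ, enc)

        eps = 1e-6
        rng2 = np.random.default_rng(0)
        for arr, grad in zip(enc.arrays() + dec.arrays(), eg + dg):
            grad = np.asarray(grad).reshape(arr.shape)
            for _ in range(min(arr.size, 8)):
                ix = tuple(int(rng2.integers(0, s)) for s in arr.shape)
                old = arr[ix]
                arr[ix] = old + eps
                up = loss()
                arr[ix] = old - eps
                down = loss()
                arr[ix] = old
                assert abs((up - down) / (2 * eps) - grad[ix]) < 1e-6


class TestEncoder:
    def test_zero_weights_give_zero_embeddings(self):
        rng = np.random.default_rng(0)
        enc = GCNParams.init(4, rng, d_hidden=3, d_out=2)
        for a in enc.arrays():
            a[...] = 0.0
        A = _adjacency_from_edges(3, [(0, 1)])
        Z, _ = gcn_encode(rng.standard_normal((3, 4)), A, enc, training=False)
        assert np.allclose(Z, 0.0)

    def test_single_node_matches_hand_forward(self):
        rng = np.random.default_rng(1)
        enc = GCNParams.init(3, rng, d_hidden=4, d_out=2)
        x = rng.standard_normal((1, 3))
        A = sp.identity(1, format="csr")
        Z, _ = gcn_encode(x, A, enc, training=False)
        h1 = np.maximum(x @ enc.W0 + enc.b0, 0.0)
        expected = np.maximum(h1 @ enc.W1 + enc.b1, 0.0)
        assert np.allclose(Z, expected)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        n, d = 9, 6
        enc = GCNParams.init(d, rng, d_hidden=8, d_out=5)
        X = rng.standard_normal((n, d))
        edges = [(0, 1), (1, 2), (3, 4), (5, 6), (6, 7), (7, 8), (2, 5)]
        A = _adjacency_from_edges(n, edges)
        Z, _ = gcn_encode(X, A, enc, training=False)
        perm = rng.permutation(n)
        P = sp.csr_matrix((np.ones(n), (np.arange(n), perm)), shape=(n, n))
        A_perm = P @ A @ P.T
        Z_perm, _ = gcn_encode(X[perm], A_perm, enc, training=False)
        # row i of the permuted run corresponds to original node perm[i]
        assert np.allclose(Z_perm, Z[perm], atol=1e-10)

    def test_width_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        enc = GCNParams.init(4, rng)
        with pytest.raises(ShapeError):
            gcn_encode(np.zeros((2, 5)), sp.identity(2, format="csr"), enc)

    def test_eval_mode_reproducible(self):
        rng = np.random.default_rng(5)
        enc = GCNParams.init(4, rng, d_hidden=6, d_out=3)
        X = rng.standard_normal((5, 4))
        A = _adjacency_from_edges(5, [(0, 1), (2, 3)])
        Z1, _ = gcn_encode(X, A, enc, training=False)
        Z2, _ = gcn_encode(X, A, enc, training=False)
        assert np.array_equal(Z1, Z2)


class TestDecoder:
    def test_zero_weights_give_half(self):
        rng = np.random.default_rng(0)
        dec = MLPParams.init(8, (5, 3), rng)
        for a in dec.arrays():
            a[...] = 0.0
        p, _, _ = decode_pairs(np.ones((3, 4)), np.ones((3, 4)), dec)
        assert np.allclose(p, 0.5)

    def test_output_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(1)
        dec = MLPParams.init(8, (5, 3), rng)
        p, _, _ = decode_pairs(rng.standard_normal((20, 4)) * 3,
                               rng.standard_normal((20, 4)) * 3, dec)
        assert np.all((p > 0) & (p < 1))

    def test_hand_computed_forward(self):
        # 1-dim embeddings, 2-wide decoder input, tiny integer weights
        dec = MLPParams(
            Ws=[np.array([[1.0], [2.0]]), np.array([[1.0]]), np.array([[2.0]])],
            bs=[np.array([-1.0]), np.array([0.5]), np.array([0.0])],
        )
        zv, zd = np.array([[1.0]]), np.array([[1.0]])
        # pre1 = 1*1 + 1*2 - 1 = 2; relu 2; pre2 = 2 + .5 = 2.5; logit = 5
        p, logits, _ = decode_pairs(zv, zd, dec)
        assert np.isclose(logits[0], 5.0)
        assert np.isclose(p[0], sigmoid(np.array([5.0]))[0])

    def test_concatenation_order_is_variant_first(self):
        rng = np.random.default_rng(2)
        dec = MLPParams.init(4, (3, 2), rng)
        zv, zd = np.array([[1.0, 0.0]]), np.array([[0.0, 1.0]])
        p_vd, _, _ = decode_pairs(zv, zd, dec)
        p_dv, _, _ = decode_pairs(zd, zv, dec)
        assert not np.isclose(p_vd[0], p_dv[0])


class TestBaselines:
    def test_zero_weights_half_and_range(self):
        state = BaselineState.init(6, seed=0, pair_input=True)
        for a in state.arrays():
            a[...] = 0.0
        rng = np.random.default_rng(0)
        p, _, _ = state.forward(rng.standard_normal((4, 6)), rng.standard_normal((4, 6)))
        assert np.allclose(p, 0.5)

    def test_variant_only_ignores_disease(self):
        state = BaselineState.init(6, seed=1, pair_input=False)
        rng = np.random.default_rng(0)
        xv = rng.standard_normal((3, 6))
        p1, _, _ = state.forward(xv)
        p2, _, _ = state.forward(xv)
        assert np.array_equal(p1, p2)
        assert np.all((p1 > 0) & (p1 < 1))

    def test_pair_baseline_requires_disease(self):
        state = BaselineState.init(6, seed=0, pair_input=True)
        with pytest.raises(ShapeError):
            state.forward(np.zeros((1, 6)))


def test_model_state_save_load_round_trip(tmp_path):
    state = ModelState.init(10, seed=42)
    path = tmp_path / "model.json"
    state.save(path)
    back = ModelState.load(path)
    assert back.seed == 42
    for a, b in zip(state.arrays(), back.arrays()):
        assert np.array_equal(a, b)


def test_dropout_only_in_training_mode():
    rng = np.random.default_rng(0)
    dec = MLPParams.init(8, (64, 32), rng)
    X = rng.standard_normal((16, 8))
    eval1, _ = mlp_forward(X, dec, training=False)
    eval2, _ = mlp_forward(X, dec, training=False)
    assert np.array_equal(eval1, eval2)
    t1, _ = mlp_forward(X, dec, training=True, rng=np.random.default_rng(1))
    t2, _ = mlp_forward(X, dec, training=True, rng=np.random.default_rng(2))
    assert not np.array_equal(t1, t2)
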