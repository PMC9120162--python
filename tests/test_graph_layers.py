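import math

import numpy as np
import pytest

from conftest import random_adjacency
from ppigraph import (
    GATLayerParams,
    GCNLayerParams,
    gat_attention,
    gat_forward,
    gcn_forward,
    mean_pool,
)
from ppigraph.errors import GraphInputError, ShapeError
from ppigraph.graph_layers import gat_backward, gcn_backward


def gcn_oracle(A, X, W):
    """Independent dense implementation: ReLU(D^-1/2 (A+I) D^-1/2 X W)."""
    L = A.shape[0]
    A_hat = A + np.eye(L)
    D = np.diag(A_hat.sum(axis=1))
    D_inv_sqrt = np.diag(1.0 / np.sqrt(np.diag(D)))
    return np.maximum(D_inv_sqrt @ A_hat @ D_inv_sqrt @ X @ W, 0.0)


def gat_attention_oracle(A, X, params):
    """Per-node explicit softmax over the self-inclusive neighborhood."""
    L = A.shape[0]
    Z = X @ params.W
    F = Z.shape[1]
    alpha = np.zeros((L, L))
    for i in range(L):
        nbrs = [j for j in range(L) if A[i, j] == 1] + [i]
        scores = []
        for j in nbrs:
            s = float(params.a @ np.concatenate([Z[i], Z[j]]))
            scores.append(s if s >= 0 else params.leaky_slope * s)
        scores = np.array(scores)
        e = np.exp(scores - scores.max())
        for j, w in zip(nbrs, e / e.sum()):
            alpha[i, j] = w
    return alpha


def test_gcn_isolated_node_identity():
    x = np.array([[2.0, -3.0]])
    out = gcn_forward(np.zeros((1, 1)), x, GCNLayerParams(np.eye(2)))
    np.testing.assert_allclose(out, [[2.0, 0.0]])  # ReLU(x)


def test_gcn_two_nodes_one_edge_analytic():
    A = np.array([[0.0, 1.0], [1.0, 0.0]])
    X = np.array([[1.0], [0.0]])
    out = gcn_forward(A, X, GCNLayerParams(np.array([[1.0]])))
    np.testing.assert_allclose(out, [[0.5], [0.5]], atol=1e-12)


@pytest.mark.parametrize("seed", range(20))
def test_gcn_matches_dense_oracle(seed):
    r = np.random.default_rng(seed)
    L, Fi, Fo = int(r.integers(1, 11)), int(r.integers(1, 7)), int(r.integers(1, 7))
    A = random_adjacency(r, L)
    X = r.normal(size=(L, Fi))
    W = r.normal(size=(Fi, Fo))
    np.testing.assert_allclose(gcn_forward(A, X, GCNLayerParams(W)),
                               gcn_oracle(A, X, W), atol=1e-10)


def test_gcn_zero_features_give_zero_output(rng):
    A = random_adjacency(rng, 6)
    out = gcn_forward(A, np.zeros((6, 4)), GCNLayerParams(rng.normal(size=(4, 3))))
    np.testing.assert_array_equal(out, 0.0)


def test_gcn_input_validation(rng):
    W = GCNLayerParams(np.eye(2))
    asym = np.array([[0.0, 1.0], [0.0, 0.0]])
    with pytest.raises(GraphInputError):
        gcn_forward(asym, np.ones((2, 2)), W)
    loops = np.eye(2)
    with pytest.raises(GraphInputError):
        gcn_forward(loops, np.ones((2, 2)), W)
    with pytest.raises(ShapeError):
        gcn_forward(np.zeros((2, 2)), np.ones((2, 3)), W)


def test_gat_uniform_attention_with_zero_vector(rng):
    L = 5
    A = random_adjacency(rng, L)
    params = GATLayerParams(rng.normal(size=(3, 4)), np.zeros(8))
    alpha = gat_attention(A, rng.normal(size=(L, 3)), params)
    for i in range(L):
        n = int(A[i].sum()) + 1
        nz = alpha[i][alpha[i] > 0]
        assert len(nz) == n
        np.testing.assert_allclose(nz, 1.0 / n, atol=1e-12)


def test_gat_uniform_attention_with_identical_features(rng):
    L = 6
    A = random_adjacency(rng, L)
    params = GATLayerParams(rng.normal(size=(3, 4)), rng.normal(size=8))
    X = np.tile(rng.normal(size=3), (L, 1))
    alpha = gat_attention(A, X, params)
    for i in range(L):
        nz = alpha[i][alpha[i] > 0]
        np.testing.assert_allclose(nz, nz[0], atol=1e-12)


@pytest.mark.parametrize("seed", range(20))
def test_gat_attention_matches_oracle(seed):
    r = np.random.default_rng(seed)
    L, Fi, Fo = int(r.integers(1, 9)), int(r.integers(1, 5)), int(r.integers(1, 5))
    A = random_adjacency(r, L)
    params = GATLayerParams(r.normal(size=(Fi, Fo)), r.normal(size=2 * Fo))
    X = r.normal(size=(L, Fi))
    alpha = gat_attention(A, X, params)
    np.testing.assert_allclose(alpha, gat_attention_oracle(A, X, params), atol=1e-10)
    # rows sum to one over the neighborhood, entries non-negative
    np.testing.assert_allclose(alpha.sum(axis=1), 1.0, atol=1e-10)
    assert np.all(alpha >= 0)


@pytest.mark.parametrize("seed", range(10))
def test_gat_forward_composition_oracle(seed):
    r = np.random.default_rng(seed)
    L, Fi, Fo = int(r.integers(2, 9)), int(r.integers(1, 5)), int(r.integers(1, 5))
    A = random_adjacency(r, L)
    params = GATLayerParams(r.normal(size=(Fi, Fo)), r.normal(size=2 * Fo))
    X = r.normal(size=(L, Fi))
    alpha = gat_attention_oracle(A, X, params)
    expected = alpha @ (X @ params.W)
    expected = np.where(expected >= 0, expected, 0.01 * expected)
    np.testing.assert_allclose(gat_forward(A, X, params), expected, atol=1e-10)


def test_gat_isolated_node_self_attention():
    X = np.array([[1.5, -2.0]])
    params = GATLayerParams(np.eye(2), np.zeros(4))
    np.testing.assert_allclose(gat_forward(np.zeros((1, 1)), X, params),
                               [[1.5, -0.02]])  # LeakyReLU(x), alpha_ii = 1


def test_gat_identical_features_identical_outputs(rng):
    A = np.array([[0.0, 1.0], [1.0, 0.0]])
    params = GATLayerParams(rng.normal(size=(3, 2)), rng.normal(size=4))
    X = np.tile(rng.normal(size=3), (2, 1))
    H = gat_forward(A, X, params)
    np.testing.assert_allclose(H[0], H[1], atol=1e-12)


def test_mean_pool_examples():
    np.testing.assert_allclose(mean_pool([[1.0, 2.0], [3.0, 4.0]]), [[2.0, 3.0]])
    row = np.array([[5.0, -1.0, 2.0]])
    np.testing.assert_allclose(mean_pool(row), row)
    with pytest.raises(ShapeError):
        mean_pool(np.zeros((0, 3)))


@pytest.mark.parametrize("layer", ["gcn", "gat"])
@pytest.mark.parametrize("seed", range(8))
def test_permutation_equivariance(layer, seed):
    """layer(PAP^T, PX) == P @ layer(A, X); pooled output is invariant."""
    r = np.random.default_rng(seed)
    L, Fi, Fo = int(r.integers(2, 10)), int(r.integers(1, 6)), int(r.integers(1, 6))
    A = random_adjacency(r, L)
    X = r.normal(size=(L, Fi))
    perm = r.permutation(L)
    P = np.eye(L)[perm]
    if layer == "gcn":
        params = GCNLayerParams(r.normal(size=(Fi, Fo)))
        H = gcn_forward(A, X, params)
        Hp = gcn_forward(P @ A @ P.T, P @ X, params)
    else:
        params = GATLayerParams(r.normal(size=(Fi, Fo)), r.normal(size=2 * Fo))
        H = gat_forward(A, X, params)
        Hp = gat_forward(P @ A @ P.T, P @ X, params)
    np.testing.assert_allclose(Hp, P @ H, atol=1e-8)
    np.testing.assert_allclose(mean_pool(Hp), mean_pool(H), atol=1e-8)


def _finite_diff(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        xp, xm = x.copy(), x.copy()
        xp[idx] += eps
        xm[idx] -= eps
        g[idx] = (f(xp) - f(xm)) / (2 * eps)
        it.iternext()
    return g


def test_gcn_backward_matches_finite_differences(rng):
    L, Fi, Fo = 5, 3, 4
    A = random_adjacency(rng, L)
    X = rng.normal(size=(L, Fi))
    W = rng.normal(size=(Fi, Fo))
    G = rng.normal(size=(L, Fo))
    cache = {}
    gcn_forward(A, X, GCNLayerParams(W), cache)
    dX, dW = gcn_backward(cache, G, GCNLayerParams(W))
    np.testing.assert_allclose(
        dW, _finite_diff(lambda w: np.sum(gcn_forward(A, X, GCNLayerParams(w)) * G), W),
        atol=1e-5)
    np.testing.assert_allclose(
        dX, _finite_diff(lambda x: np.sum(gcn_forward(A, x, GCNLayerParams(W)) * G), X),
        atol=1e-5)


def test_gat_backward_matches_finite_differences(rng):
    L, Fi, Fo = 5, 3, 2
    A = random_adjacency(rng, L)
    X = rng.normal(size=(L, Fi))
    W = rng.normal(size=(Fi, Fo))
    a = rng.normal(size=2 * Fo)
    G = rng.normal(size=(L, Fo))
    cache = {}
    gat_forward(A, X, GATLayerParams(W, a), cache=cache)
    dX, dW, da = gat_backward(cache, G, GATLayerParams(W, a))

    def loss(Wv, av, Xv):
        return np.sum(gat_forward(A, Xv, GATLayerParams(Wv, av)) * G)

    np.testing.assert_allclose(dW, _finite_diff(lambda w: loss(w, a, X), W), atol=1e-5)
    np.testing.assert_allclose(da, _finite_diff(lambda v: loss(W, v, X), a), atol=1e-5)
    np.testing.assert_allclose(dX, _finite_diff(lambda x: loss(W, a, x), X), atol=1e-5)
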