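"""From-scratch GCN and GAT layers with global mean pooling.

The GCN layer is the symmetric-normalized convolution

    H' = ReLU( D^-1/2 (A + I) D^-1/2 X W )

where the self-loop-augmented degree D is never zero, so the per-node
normalization is always defined. The GAT layer computes single-head
attention over each node's neighborhood (self included),

    e_ij   = LeakyReLU( a . [W x_i || W x_j] )           (slope 0.2)
    alpha  = softmax over j in N(i) of e_ij              (max-subtracted)
    H'_i   = LeakyReLU( sum_j alpha_ij W x_j )           (slope 0.01)

Both layers are pure functions of (adjacency, features, params). Each
forward pass has a companion backward pass returning exact gradients,
verified against central finite differences in the test suite; training
code threads the cache dicts between them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ppigraph.errors import GraphInputError, ShapeError

ATTENTION_SLOPE = 0.2
ACTIVATION_SLOPE = 0.01


@dataclass
class GCNLayerParams:
    """Trainable weight of one GCN layer: W of shape (F_in, F_out)."""

    W: np.ndarray


@dataclass
class GATLayerParams:
    """Trainable weights of one GAT layer.

    W has shape (F_in, F_out); the attention vector ``a`` has length
    2 * F_out and is split into the source half (applied to W x_i) and the
    target half (applied to W x_j).
    """

    W: np.ndarray
    a: np.ndarray
    leaky_slope: float = ATTENTION_SLOPE

    def __post_init__(self) -> None:
        if self.a.shape != (2 * self.W.shape[1],):
            raise ShapeError(
                f"attention vector length {self.a.shape} does not match "
                f"2 * F_out = {2 * self.W.shape[1]}"
            )


def leaky_relu(x: np.ndarray, slope: float = ACTIVATION_SLOPE) -> np.ndarray:
    return np.where(x >= 0, x, slope * x)


def _leaky_grad(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x >= 0, 1.0, slope)


def check_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Validate the symmetric binary zero-diagonal adjacency contract."""
    A = np.asarray(adjacency, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ShapeError(f"adjacency must be square, got shape {A.shape}")
    if not np.array_equal(A, A.T):
        raise GraphInputError("adjacency matrix is not symmetric")
    if np.any(np.diag(A) != 0):
        raise GraphInputError("adjacency diagonal must be zero (no stored self-loops)")
    return A


def gcn_norm(adjacency: np.ndarray) -> np.ndarray:
    """Return S = D^-1/2 (A + I) D^-1/2 for a validated adjacency."""
    A = check_adjacency(adjacency)
    A_hat = A + np.eye(A.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(A_hat.sum(axis=1))
    return d_inv_sqrt[:, None] * A_hat * d_inv_sqrt[None, :]


def gcn_forward(
    adjacency: np.ndarray,
    X: np.ndarray,
    params: GCNLayerParams,
    cache: dict | None = None,
) -> np.ndarray:
    """One GCN layer: ReLU(S X W) with S the symmetric-normalized adjacency."""
    X = np.asarray(X, dtype=float)
    S = gcn_norm(adjacency)
    if X.shape[0] != S.shape[0]:
        raise ShapeError(f"{X.shape[0]} feature rows for {S.shape[0]} nodes")
    if X.shape[1] != params.W.shape[0]:
        raise ShapeError(
            f"feature width {X.shape[1]} does not match W input width {params.W.shape[0]}"
        )
    SX = S @ X
    Z = SX @ params.W
    H = np.maximum(Z, 0.0)
    if cache is not None:
        cache.update(S=S, X=X, SX=SX, Z=Z)
    return H


def gcn_backward(cache: dict, dH: np.ndarray, params: GCNLayerParams):
    """Gradients of the GCN layer; returns (dX, dW)."""
    dZ = dH * (cache["Z"] > 0)
    dW = cache["SX"].T @ dZ
    dX = cache["S"].T @ (dZ @ params.W.T)
    return dX, dW


def _gat_scores(adjacency, X, params, cache=None):
    """Shared forward plumbing: masked attention logits and softmax."""
    X = np.asarray(X, dtype=float)
    A = check_adjacency(adjacency)
    L = A.shape[0]
    if X.shape[0] != L:
        raise ShapeError(f"{X.shape[0]} feature rows for {L} nodes")
    if X.shape[1] != params.W.shape[0]:
        raise ShapeError(
            f"feature width {X.shape[1]} does not match W input width {params.W.shape[0]}"
        )
    F_out = params.W.shape[1]
    Z = X @ params.W
    a_src, a_dst = params.a[:F_out], params.a[F_out:]
    s_src = Z @ a_src  # contribution of node i as attention source
    s_dst = Z @ a_dst  # contribution of node j as attention target
    pre = s_src[:, None] + s_dst[None, :]
    E = leaky_relu(pre, params.leaky_slope)
    mask = (A + np.eye(L)) > 0  # neighborhood includes self
    # Max-subtracted masked softmax per row.
    neg = np.where(mask, E, -np.inf)
    shifted = neg - neg.max(axis=1, keepdims=True)
    expE = np.where(mask, np.exp(shifted), 0.0)
    alpha = expE / expE.sum(axis=1, keepdims=True)
    if cache is not None:
        cache.update(X=X, Z=Z, pre=pre, mask=mask, alpha=alpha)
    return alpha, Z, mask


def gat_attention(adjacency, X, params: GATLayerParams) -> np.ndarray:
    """Normalized attention coefficients alpha (L x L).

    alpha[i, j] is node i's attention on neighbor j (self included) and is
    zero outside the neighborhood; each row sums to 1 over N(i).
    """
    alpha, _, _ = _gat_scores(adjacency, X, params)
    return alpha


def gat_forward(
    adjacency,
    X,
    params: GATLayerParams,
    out_slope: float = ACTIVATION_SLOPE,
    cache: dict | None = None,
) -> np.ndarray:
    """One single-head GAT layer: LeakyReLU(alpha @ (X W))."""
    local: dict = {}
    alpha, Z, _ = _gat_scores(adjacency, X, params, cache=local)
    P = alpha @ Z
    H = leaky_relu(P, out_slope)
    if cache is not None:
        cache.update(local, P=P, out_slope=out_slope)
    return H


def gat_backward(cache: dict, dH: np.ndarray, params: GATLayerParams):
    """Gradients of the GAT layer; returns (dX, dW, da)."""
    X, Z = cache["X"], cache["Z"]
    alpha, pre, mask = cache["alpha"], cache["pre"], cache["mask"]
    F_out = params.W.shape[1]
    a_src, a_dst = params.a[:F_out], params.a[F_out:]

    dP = dH * _leaky_grad(cache["P"], cache["out_slope"])
    dalpha = dP @ Z.T
    dZ = alpha.T @ dP

    # Row-wise softmax backward over the masked neighborhood.
    inner = (dalpha * alpha).sum(axis=1, keepdims=True)
    dE = alpha * (dalpha - inner)
    dpre = np.where(mask, dE * _leaky_grad(pre, params.leaky_slope), 0.0)

    ds_src = dpre.sum(axis=1)
    ds_dst = dpre.sum(axis=0)
    dZ += np.outer(ds_src, a_src) + np.outer(ds_dst, a_dst)
    da = np.concatenate([Z.T @ ds_src, Z.T @ ds_dst])
    dW = X.T @ dZ
    dX = dZ @ params.W.T
    return dX, dW, da


def mean_pool(H: np.ndarray) -> np.ndarray:
    """Global mean pooling: column-wise mean, (L, F) -> (1, F)."""
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or H.shape[0] == 0:
        raise ShapeError(f"mean_pool needs a non-empty 2-D matrix, got shape {H.shape}")
    return H.mean(axis=0, keepdims=True)
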