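"""Siamese pair model for protein-protein interaction classification.

One shared encoder maps each protein graph to a fixed-size vector: a stack
of GNN layers (GCN or GAT, default one layer), global mean pooling, then a
fully connected layer with LeakyReLU. The two encodings of a pair are
concatenated and fed to a classifier with two hidden layers (256 and 64
units, LeakyReLU, dropout 0.2 after every FC layer) and a sigmoid output;
a pair is called interacting iff the probability is >= 0.5. Training
minimizes the MSE loss with Adam (learning rate 0.001 by default).

A mean-embedding baseline (``gnn_type="baseline"``) replaces the graph
encoder by the column-wise mean of the per-residue features, feeding the
same classifier head — the graph-free reference the GNN models are
compared against.

All forward/backward passes are NumPy with hand-written exact gradients;
given (seed, config, data) a full training run is reproducible
bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import h5py
import numpy as np

from ppigraph.data import PairDataset
from ppigraph.errors import DataError, ShapeError
from ppigraph.graph_layers import (
    ACTIVATION_SLOPE,
    ATTENTION_SLOPE,
    GATLayerParams,
    GCNLayerParams,
    gat_backward,
    gat_forward,
    gcn_backward,
    gcn_forward,
    leaky_relu,
    _leaky_grad,
    mean_pool,
)
from ppigraph.node_features import FeatureMatrix, ProteinGraph, attach_features


@dataclass
class ModelConfig:
    """Hyper-parameters of the pair model.

    Defaults follow the reference setup: one GNN layer, classifier hidden
    sizes (256, 64), dropout 0.2 after every FC layer, Adam at 0.001, MSE
    loss. ``gnn_out_dim`` and ``protein_dim`` default to 128 so the
    concatenated pair vector (256) matches the first classifier layer.
    """

    gnn_type: str = "gcn"  # {"gcn", "gat", "baseline"}
    n_gnn_layers: int = 1
    gnn_out_dim: int = 128
    protein_dim: int = 128
    classifier_units: tuple[int, int] = (256, 64)
    dropout_rate: float = 0.2
    learning_rate: float = 0.001
    epochs: int = 50
    batch_size: int = 32
    seed: int = 0
    attention_slope: float = ATTENTION_SLOPE
    activation_slope: float = ACTIVATION_SLOPE
    symmetrize_inference: bool = False

    def __post_init__(self) -> None:
        if self.gnn_type not in ("gcn", "gat", "baseline"):
            raise ValueError(f"unknown gnn_type {self.gnn_type!r}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.gnn_type != "baseline" and self.n_gnn_layers not in (1, 2, 3):
            raise ValueError("n_gnn_layers must be 1, 2 or 3")


@dataclass
class ModelParams:
    """All trainable arrays: encoder (GNN layers + FC) and classifier head."""

    gnn_layers: list
    fc_W: np.ndarray | None
    fc_b: np.ndarray | None
    clf_W1: np.ndarray
    clf_b1: np.ndarray
    clf_W2: np.ndarray
    clf_b2: np.ndarray
    out_W: np.ndarray
    out_b: np.ndarray

    def to_dict(self) -> dict[str, np.ndarray]:
        d: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.gnn_layers):
            d[f"gnn{i}.W"] = layer.W
            if isinstance(layer, GATLayerParams):
                d[f"gnn{i}.a"] = layer.a
        if self.fc_W is not None:
            d["fc.W"], d["fc.b"] = self.fc_W, self.fc_b
        d.update({"clf.W1": self.clf_W1, "clf.b1": self.clf_b1,
                  "clf.W2": self.clf_W2, "clf.b2": self.clf_b2,
                  "out.W": self.out_W, "out.b": self.out_b})
        return d

    def apply_dict(self, d: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.gnn_layers):
            layer.W = d[f"gnn{i}.W"]
            if isinstance(layer, GATLayerParams):
                layer.a = d[f"gnn{i}.a"]
        if self.fc_W is not None:
            self.fc_W, self.fc_b = d["fc.W"], d["fc.b"]
        self.clf_W1, self.clf_b1 = d["clf.W1"], d["clf.b1"]
        self.clf_W2, self.clf_b2 = d["clf.W2"], d["clf.b2"]
        self.out_W, self.out_b = d["out.W"], d["out.b"]


@dataclass
class TrainingHistory:
    """Per-epoch mean training loss (and optional validation metrics)."""

    losses: list[float] = field(default_factory=list)
    val_metrics: list[dict] = field(default_factory=list)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


def init_params(config: ModelConfig, feature_dim: int) -> ModelParams:
    """Glorot-uniform initialization from the config seed."""
    rng = np.random.default_rng(config.seed)
    layers: list = []
    pair_in = 2 * feature_dim  # baseline: concatenated mean embeddings
    if config.gnn_type != "baseline":
        f_in = feature_dim
        for _ in range(config.n_gnn_layers):
            W = _glorot(rng, f_in, config.gnn_out_dim)
            if config.gnn_type == "gat":
                a = _glorot(rng, 2 * config.gnn_out_dim, 1,
                            shape=(2 * config.gnn_out_dim,))
                layers.append(GATLayerParams(W, a, config.attention_slope))
            else:
                layers.append(GCNLayerParams(W))
            f_in = config.gnn_out_dim
        fc_W = _glorot(rng, config.gnn_out_dim, config.protein_dim)
        fc_b = np.zeros(config.protein_dim)
        pair_in = 2 * config.protein_dim
    else:
        fc_W = fc_b = None
    u1, u2 = config.classifier_units
    return ModelParams(
        gnn_layers=layers,
        fc_W=fc_W, fc_b=fc_b,
        clf_W1=_glorot(rng, pair_in, u1), clf_b1=np.zeros(u1),
        clf_W2=_glorot(rng, u1, u2), clf_b2=np.zeros(u2),
        out_W=_glorot(rng, u2, 1), out_b=np.zeros(1),
    )


def _dropout_mask(rng, shape, rate):
    # Inverted dropout: scale kept units so inference needs no rescaling.
    return (rng.random(shape) >= rate) / (1.0 - rate)


def encode_protein(
    pg: ProteinGraph,
    params: ModelParams,
    config: ModelConfig,
    train_mode: bool = False,
    rng: np.random.Generator | None = None,
    cache: dict | None = None,
) -> np.ndarray:
    """Encode one protein graph into a (1, protein_dim) vector.

    GNN layers -> mean pool -> FC + LeakyReLU (+ dropout in train mode).
    Deterministic when ``train_mode`` is off. For the baseline model this
    is the column-wise mean of the feature matrix (the graph is unused).
    """
    X = pg.features.values
    if config.gnn_type == "baseline":
        return mean_pool(X)
    A = pg.graph.adjacency
    layer_caches = []
    H = X
    for layer in params.gnn_layers:
        c: dict = {}
        if isinstance(layer, GATLayerParams):
            H = gat_forward(A, H, layer, config.activation_slope, cache=c)
        else:
            H = gcn_forward(A, H, layer, cache=c)
        layer_caches.append(c)
    pooled = mean_pool(H)
    z = pooled @ params.fc_W + params.fc_b
    enc = leaky_relu(z, config.activation_slope)
    if train_mode and config.dropout_rate > 0:
        mask = _dropout_mask(rng, enc.shape, config.dropout_rate)
        enc = enc * mask
    else:
        mask = None
    if cache is not None:
        cache.update(layer_caches=layer_caches, L=H.shape[0],
                     pooled=pooled, z=z, mask=mask)
    return enc


def _encoder_backward(d_enc: np.ndarray, cache: dict, params: ModelParams,
                      config: ModelConfig, grads: dict[str, np.ndarray]) -> None:
    """Accumulate encoder gradients for one protein into ``grads``."""
    if cache["mask"] is not None:
        d_enc = d_enc * cache["mask"]
    dz = d_enc * _leaky_grad(cache["z"], config.activation_slope)
    grads["fc.W"] += cache["pooled"].T @ dz
    grads["fc.b"] += dz[0]
    dpooled = dz @ params.fc_W.T
    dH = np.repeat(dpooled / cache["L"], cache["L"], axis=0)
    for i in reversed(range(len(params.gnn_layers))):
        layer = params.gnn_layers[i]
        if isinstance(layer, GATLayerParams):
            dH, dW, da = gat_backward(cache["layer_caches"][i], dH, layer)
            grads[f"gnn{i}.a"] += da
        else:
            dH, dW = gcn_backward(cache["layer_caches"][i], dH, layer)
        grads[f"gnn{i}.W"] += dW


def _classifier_forward(H: np.ndarray, params: ModelParams, config: ModelConfig,
                        train_mode: bool = False,
                        rng: np.random.Generator | None = None,
                        cache: dict | None = None) -> np.ndarray:
    """Pair classifier head: FC(256)+LeakyReLU+dropout -> FC(64)+... -> sigmoid."""
    if H.shape[1] != params.clf_W1.shape[0]:
        raise ShapeError(
            f"pair vector width {H.shape[1]} does not match classifier "
            f"input width {params.clf_W1.shape[0]}"
        )
    slope = config.activation_slope
    drop = train_mode and config.dropout_rate > 0
    z1 = H @ params.clf_W1 + params.clf_b1
    a1 = leaky_relu(z1, slope)
    m1 = _dropout_mask(rng, a1.shape, config.dropout_rate) if drop else None
    d1 = a1 * m1 if drop else a1
    z2 = d1 @ params.clf_W2 + params.clf_b2
    a2 = leaky_relu(z2, slope)
    m2 = _dropout_mask(rng, a2.shape, config.dropout_rate) if drop else None
    d2 = a2 * m2 if drop else a2
    z3 = d2 @ params.out_W + params.out_b
    p = 1.0 / (1.0 + np.exp(-z3))
    if cache is not None:
        cache.update(H=H, z1=z1, m1=m1, d1=d1, z2=z2, m2=m2, d2=d2, p=p)
    return p[:, 0]


def _classifier_backward(dp: np.ndarray, cache: dict, params: ModelParams,
                         config: ModelConfig, grads: dict[str, np.ndarray]) -> np.ndarray:
    slope = config.activation_slope
    p = cache["p"]
    dz3 = dp[:, None] * p * (1.0 - p)
    grads["out.W"] += cache["d2"].T @ dz3
    grads["out.b"] += dz3.sum(axis=0)
    dd2 = dz3 @ params.out_W.T
    da2 = dd2 * cache["m2"] if cache["m2"] is not None else dd2
    dz2 = da2 * _leaky_grad(cache["z2"], slope)
    grads["clf.W2"] += cache["d1"].T @ dz2
    grads["clf.b2"] += dz2.sum(axis=0)
    dd1 = dz2 @ params.clf_W2.T
    da1 = dd1 * cache["m1"] if cache["m1"] is not None else dd1
    dz1 = da1 * _leaky_grad(cache["z1"], slope)
    grads["clf.W1"] += cache["H"].T @ dz1
    grads["clf.b1"] += dz1.sum(axis=0)
    return dz1 @ params.clf_W1.T


def predict_pair(enc_a: np.ndarray, enc_b: np.ndarray, params: ModelParams,
                 config: ModelConfig, train_mode: bool = False,
                 rng: np.random.Generator | None = None) -> float:
    """Interaction probability for a pair of protein encodings.

    Concatenates [enc_a || enc_b] and applies the classifier head; the
    label convention is interacting iff probability >= 0.5. With
    ``symmetrize_inference`` the two concatenation orders are averaged.
    """
    H = np.hstack([np.atleast_2d(enc_a), np.atleast_2d(enc_b)])
    p = _classifier_forward(H, params, config, train_mode, rng)[0]
    if config.symmetrize_inference and not train_mode:
        H_rev = np.hstack([np.atleast_2d(enc_b), np.atleast_2d(enc_a)])
        p = 0.5 * (p + _classifier_forward(H_rev, params, config)[0])
    return float(p)


def baseline_embed(features: FeatureMatrix) -> np.ndarray:
    """Graph-free protein vector: column-wise mean across sequence length."""
    return mean_pool(features.values)


def baseline_predict_pair(vec_a, vec_b, params: ModelParams, config: ModelConfig,
                          train_mode: bool = False,
                          rng: np.random.Generator | None = None) -> float:
    """Classifier head applied to concatenated mean embeddings."""
    return predict_pair(vec_a, vec_b, params, config, train_mode, rng)


def mse_loss(probs, labels) -> float:
    """Mean squared error between probabilities and 0/1 labels."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if probs.size == 0 or probs.shape != labels.shape:
        raise ValueError(f"need equal non-empty lengths, got {probs.shape} vs {labels.shape}")
    return float(np.mean((probs - labels) ** 2))


class _Adam:
    """Standard Adam (beta1=0.9, beta2=0.999, eps=1e-8) over an array dict."""

    def __init__(self, shapes: dict[str, tuple], lr: float):
        self.lr = lr
        self.t = 0
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        out = {}
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            out[k] = params[k] - self.lr * mhat / (np.sqrt(vhat) + eps)
        return out


def build_protein_graphs(graphs: dict, features: dict) -> dict[str, ProteinGraph]:
    """Zip contact graphs with their feature matrices, validating alignment."""
    missing = sorted(set(graphs) - set(features)) + sorted(set(features) - set(graphs))
    if missing:
        raise DataError(f"graphs/features id mismatch: {missing}")
    return {pid: attach_features(graphs[pid], features[pid]) for pid in graphs}


def train(dataset: PairDataset, graphs: dict, features: dict,
          config: ModelConfig) -> tuple[ModelParams, TrainingHistory]:
    """Train the Siamese pair model with Adam on the MSE loss.

    ``graphs`` maps protein id -> ContactGraph and ``features`` maps
    protein id -> FeatureMatrix; every id referenced by ``dataset`` must
    resolve in both before any training step. Returns the final parameters
    and the per-epoch training-loss history.
    """
    pgs = build_protein_graphs(graphs, features)
    dataset.check_resolvable(pgs)
    feature_dim = next(iter(pgs.values())).features.F

    params = init_params(config, feature_dim)
    pdict = params.to_dict()
    optimizer = _Adam({k: v.shape for k, v in pdict.items()}, config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    history = TrainingHistory()

    n = len(dataset)
    baseline = config.gnn_type == "baseline"
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            batch = [dataset[int(i)] for i in order[start:start + config.batch_size]]
            enc_rows, enc_caches = [], []
            labels = np.array([lab for _, _, lab in batch], dtype=float)
            for a, b, _ in batch:
                for pid in (a, b):
                    if baseline:
                        enc_rows.append(baseline_embed(pgs[pid].features))
                        enc_caches.append(None)
                    else:
                        c: dict = {}
                        enc_rows.append(encode_protein(pgs[pid], params, config,
                                                       train_mode=True, rng=rng, cache=c))
                        enc_caches.append(c)
            E = np.vstack(enc_rows)                        # (2B, dim)
            H = np.hstack([E[0::2], E[1::2]])              # (B, 2*dim)
            clf_cache: dict = {}
            probs = _classifier_forward(H, params, config, train_mode=True,
                                        rng=rng, cache=clf_cache)
            epoch_losses.append(mse_loss(probs, labels))

            grads = {k: np.zeros_like(v) for k, v in pdict.items()}
            dp = 2.0 * (probs - labels) / len(batch)
            dH = _classifier_backward(dp, clf_cache, params, config, grads)
            if not baseline:
                dim = E.shape[1]
                for i, _pair in enumerate(batch):
                    _encoder_backward(dH[i:i + 1, :dim], enc_caches[2 * i],
                                      params, config, grads)
                    _encoder_backward(dH[i:i + 1, dim:], enc_caches[2 * i + 1],
                                      params, config, grads)
            pdict = optimizer.step(pdict, grads)
            params.apply_dict(pdict)
        if epoch_losses:
            history.losses.append(float(np.mean(epoch_losses)))
    return params, history


def predict_dataset(dataset: PairDataset, graphs: dict, features: dict,
                    params: ModelParams, config: ModelConfig) -> np.ndarray:
    """Deterministic interaction probabilities for every pair (train mode off)."""
    pgs = build_protein_graphs(graphs, features)
    dataset.check_resolvable(pgs)
    enc: dict[str, np.ndarray] = {}
    for pid in dataset.protein_ids:
        if config.gnn_type == "baseline":
            enc[pid] = baseline_embed(pgs[pid].features)
        else:
            enc[pid] = encode_protein(pgs[pid], params, config)
    return np.array([predict_pair(enc[a], enc[b], params, config)
                     for a, b, _ in dataset])


def save_checkpoint(path, params: ModelParams, config: ModelConfig) -> None:
    """Write all parameter arrays plus the serialized config to HDF5."""
    with h5py.File(path, "w") as fh:
        cfg = asdict(config)
        cfg["classifier_units"] = list(cfg["classifier_units"])
        fh.attrs["config"] = json.dumps(cfg)
        for k, v in params.to_dict().items():
            fh.create_dataset(k, data=v)


def load_checkpoint(path) -> tuple[ModelParams, ModelConfig]:
    """Round-trip counterpart of :func:`save_checkpoint` (bit-exact)."""
    with h5py.File(path, "r") as fh:
        cfg = json.loads(fh.attrs["config"])
        cfg["classifier_units"] = tuple(cfg["classifier_units"])
        config = ModelConfig(**cfg)
        arrays = {k: fh[k][()] for k in fh.keys()}
    feature_dim = (arrays["gnn0.W"].shape[0] if "gnn0.W" in arrays
                   else arrays["clf.W1"].shape[0] // 2)
    params = init_params(config, feature_dim)
    params.apply_dict({k: arrays[k] for k in params.to_dict()})
    return params, config
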