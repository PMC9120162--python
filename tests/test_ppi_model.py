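import dataclasses

import numpy as np
import pytest

from ppigraph import (
    ContactGraph,
    FeatureMatrix,
    ModelConfig,
    PairDataset,
    attach_features,
    baseline_embed,
    baseline_predict_pair,
    encode_protein,
    init_params,
    load_checkpoint,
    mse_loss,
    predict_dataset,
    predict_pair,
    save_checkpoint,
    train,
)
from conftest import random_adjacency
from ppigraph.errors import DataError, ShapeError

CFG = ModelConfig(gnn_type="gcn", gnn_out_dim=16, protein_dim=16, epochs=3,
                  batch_size=8, seed=3)


def make_pg(rng, L, F=8, pid="p"):
    A = random_adjacency(rng, L)
    graph = ContactGraph(pid, A.astype(np.int8), [("A", i, "") for i in range(L)])
    feats = FeatureMatrix(pid, rng.normal(size=(L, F)), "embedding")
    return attach_features(graph, feats)


@pytest.mark.parametrize("L", [5, 500])
def test_encoding_width_independent_of_length(rng, L):
    params = init_params(CFG, 8)
    enc = encode_protein(make_pg(rng, L), params, CFG)
    assert enc.shape == (1, CFG.protein_dim)


@pytest.mark.parametrize("gnn", ["gcn", "gat"])
def test_encoding_permutation_invariant(rng, gnn):
    cfg = dataclasses.replace(CFG, gnn_type=gnn)
    params = init_params(cfg, 8)
    pg = make_pg(rng, 12)
    perm = rng.permutation(12)
    pg_perm = attach_features(
        ContactGraph("p", pg.graph.adjacency[np.ix_(perm, perm)],
                     [pg.graph.node_order[i] for i in perm]),
        FeatureMatrix("p", pg.features.values[perm], "embedding"))
    np.testing.assert_allclose(encode_protein(pg, params, cfg),
                               encode_protein(pg_perm, params, cfg), atol=1e-8)


def test_zero_features_zero_biases_zero_encoding(rng):
    params = init_params(CFG, 8)
    pg = make_pg(rng, 6)
    pg.features.values[:] = 0.0
    np.testing.assert_array_equal(encode_protein(pg, params, CFG), 0.0)


def test_encoder_width_mismatch_raises(rng):
    params = init_params(CFG, 8)
    with pytest.raises(ShapeError):
        encode_protein(make_pg(rng, 6, F=5), params, CFG)


def test_predict_pair_range_and_zero_params(rng):
    params = init_params(CFG, 8)
    enc = rng.normal(size=(1, CFG.protein_dim))
    p = predict_pair(enc, enc, params, CFG)
    assert 0.0 < p < 1.0

    zero = init_params(CFG, 8)
    d = zero.to_dict()
    zero.apply_dict({k: np.zeros_like(v) for k, v in d.items()})
    assert predict_pair(enc, enc, zero, CFG) == pytest.approx(0.5)
    # the >= 0.5 convention classifies this as interacting
    assert predict_pair(enc, enc, zero, CFG) >= 0.5


def test_symmetrized_inference_is_order_invariant(rng):
    cfg = dataclasses.replace(CFG, symmetrize_inference=True)
    params = init_params(cfg, 8)
    a, b = rng.normal(size=(1, 16)), rng.normal(size=(1, 16))
    assert predict_pair(a, b, params, cfg) == pytest.approx(
        predict_pair(b, a, params, cfg))


def test_mse_loss_examples(rng):
    assert mse_loss([0.0, 1.0], [0, 1]) == 0.0
    assert mse_loss([0.5, 0.5], [0, 1]) == pytest.approx(0.25)
    probs, labels = rng.random(17), rng.integers(0, 2, 17)
    expected = sum((p - y) ** 2 for p, y in zip(probs, labels)) / 17
    assert mse_loss(probs, labels) == pytest.approx(expected, abs=1e-12)
    with pytest.raises(ValueError):
        mse_loss([], [])
    with pytest.raises(ValueError):
        mse_loss([0.1], [0, 1])


def test_baseline_embed_examples():
    m = FeatureMatrix("p", np.array([[2.0, 4.0], [4.0, 6.0]]), "embedding")
    np.testing.assert_allclose(baseline_embed(m), [[3.0, 5.0]])
    single = FeatureMatrix("p", np.array([[7.0, 1.0]]), "embedding")
    np.testing.assert_allclose(baseline_embed(single), [[7.0, 1.0]])


def test_baseline_predict_zero_params_and_range(rng):
    cfg = ModelConfig(gnn_type="baseline", epochs=1, seed=0)
    params = init_params(cfg, 8)
    v = rng.normal(size=(1, 8))
    assert 0.0 < baseline_predict_pair(v, v, params, cfg) < 1.0
    params.apply_dict({k: np.zeros_like(a) for k, a in params.to_dict().items()})
    assert baseline_predict_pair(v, v, params, cfg) == pytest.approx(0.5)


def _bundle_dicts(tiny_bundle):
    _, _, graphs, features, dataset = tiny_bundle
    return graphs, features, dataset


def test_zero_epochs_returns_seeded_initialization(tiny_bundle):
    graphs, features, dataset = _bundle_dicts(tiny_bundle)
    cfg = dataclasses.replace(CFG, epochs=0)
    params, history = train(dataset, graphs, features, cfg)
    init = init_params(cfg, next(iter(features.values())).F)
    for k, v in params.to_dict().items():
        np.testing.assert_array_equal(v, init.to_dict()[k])
    assert history.losses == []


def test_training_is_deterministic(tiny_bundle):
    graphs, features, dataset = _bundle_dicts(tiny_bundle)
    p1, h1 = train(dataset, graphs, features, CFG)
    p2, h2 = train(dataset, graphs, features, CFG)
    assert h1.losses == h2.losses
    for k, v in p1.to_dict().items():
        np.testing.assert_array_equal(v, p2.to_dict()[k])


@pytest.mark.parametrize("gnn", ["gcn", "gat", "baseline"])
def test_training_reduces_loss_on_planted_signal(tiny_bundle, gnn):
    graphs, features, dataset = _bundle_dicts(tiny_bundle)
    cfg = dataclasses.replace(CFG, gnn_type=gnn, epochs=8)
    _, history = train(dataset, graphs, features, cfg)
    assert history.losses[-1] < history.losses[0]


def test_unresolvable_id_raises_before_training(tiny_bundle):
    graphs, features, _ = _bundle_dicts(tiny_bundle)
    bad = PairDataset([("p0000", "ghost", 1)])
    with pytest.raises(DataError, match="ghost"):
        train(bad, graphs, features, CFG)


def test_trained_baseline_beats_chance(tiny_bundle):
    """Mean-embedding MLP on planted data clears the 3-sigma binomial bound."""
    from ppigraph.evaluation import confusion, train_test_split_pairs

    graphs, features, dataset = _bundle_dicts(tiny_bundle)
    cfg = ModelConfig(gnn_type="baseline", epochs=40, seed=3)
    train_set, test_set = train_test_split_pairs(dataset, 0.25, seed=3)
    params, _ = train(train_set, graphs, features, cfg)
    probs = predict_dataset(test_set, graphs, features, params, cfg)
    c = confusion(probs, test_set.labels)
    n = c.n
    acc = (c.TP + c.TN) / n
    assert acc > 0.5 + 3 * np.sqrt(0.25 / n)


def test_checkpoint_round_trip_bit_exact(tmp_path, tiny_bundle):
    graphs, features, dataset = _bundle_dicts(tiny_bundle)
    params, _ = train(dataset, graphs, features, CFG)
    path = tmp_path / "ckpt.h5"
    save_checkpoint(path, params, CFG)
    loaded, cfg2 = load_checkpoint(path)
    assert cfg2 == CFG
    for k, v in params.to_dict().items():
        np.testing.assert_array_equal(v, loaded.to_dict()[k])
    probs1 = predict_dataset(dataset, graphs, features, params, CFG)
    probs2 = predict_dataset(dataset, graphs, features, loaded, cfg2)
    np.testing.assert_array_equal(probs1, probs2)
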