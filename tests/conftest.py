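import numpy as np
import pytest

from ppigraph import SyntheticSpec, generate_pair_dataset
from ppigraph.synthetic_data import build_graphs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_adjacency(rng, L, p=0.4):
    """Random symmetric binary adjacency with zero diagonal."""
    A = (rng.random((L, L)) < p).astype(float)
    A = np.triu(A, 1)
    return A + A.T


@pytest.fixture(scope="session")
def tiny_bundle():
    """Small planted-signal dataset shared by the slower model tests."""
    spec = SyntheticSpec(n_proteins=20, length_range=(12, 20), feature_dim=8,
                         n_pairs=60, seed=11)
    structures, features, dataset = generate_pair_dataset(spec)
    graphs = build_graphs(structures)
    return spec, structures, graphs, features, dataset
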