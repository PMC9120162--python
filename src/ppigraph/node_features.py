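"""Per-residue node feature matrices.

Three featurizers produce the L x F matrix bound to a contact graph:

* one-hot over the 20 standard amino acids (F = 20),
* the seven Meiler (2001) physicochemical/steric descriptors (F = 7),
* precomputed per-residue language-model embeddings loaded from a keyed
  HDF5 store or a directory of per-protein ``.npy``/``.txt`` matrices
  (F = embedding width, e.g. 1024 for common protein language models).

Unknown residues ('X') get an all-zero one-hot row, and the mean of the
20 descriptor rows in the physicochemical encoding, so the feature matrix
always stays aligned with the graph nodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from ppigraph.contact_graph import ContactGraph
from ppigraph.errors import (
    AlignmentError,
    EmbeddingFormatError,
    EmbeddingLookupError,
    EncodingError,
)
from ppigraph.structure_io import AMINO_ACIDS

#: Meiler et al. (2001) descriptors per residue, in AMINO_ACIDS order.
#: Columns: steric parameter, polarizability, volume, hydrophobicity,
#: isoelectric point, helix propensity, sheet propensity.
MEILER_DESCRIPTORS = {
    "A": (1.28, 0.05, 1.00, 0.31, 6.11, 0.42, 0.23),
    "C": (1.77, 0.13, 2.43, 1.54, 6.35, 0.17, 0.41),
    "D": (1.60, 0.11, 2.78, -0.77, 2.95, 0.25, 0.20),
    "E": (1.56, 0.15, 3.78, -0.64, 3.09, 0.42, 0.21),
    "F": (2.94, 0.29, 5.89, 1.79, 5.67, 0.30, 0.38),
    "G": (0.00, 0.00, 0.00, 0.00, 6.07, 0.13, 0.15),
    "H": (2.99, 0.23, 4.66, 0.13, 7.69, 0.27, 0.30),
    "I": (4.19, 0.19, 4.00, 1.80, 6.04, 0.30, 0.45),
    "K": (1.89, 0.22, 4.77, -0.99, 9.99, 0.32, 0.27),
    "L": (2.59, 0.19, 4.00, 1.70, 6.04, 0.39, 0.31),
    "M": (2.35, 0.22, 4.43, 1.23, 5.71, 0.38, 0.32),
    "N": (1.60, 0.13, 2.95, -0.60, 6.52, 0.21, 0.22),
    "P": (2.67, 0.00, 2.72, 0.72, 6.80, 0.13, 0.34),
    "Q": (1.56, 0.18, 3.95, -0.22, 5.65, 0.36, 0.25),
    "R": (2.34, 0.29, 6.13, -1.01, 10.74, 0.36, 0.25),
    "S": (1.31, 0.06, 1.60, -0.04, 5.70, 0.20, 0.28),
    "T": (3.03, 0.11, 2.60, 0.26, 5.60, 0.21, 0.36),
    "V": (3.67, 0.14, 3.00, 1.22, 6.02, 0.27, 0.49),
    "W": (3.21, 0.41, 8.08, 2.25, 5.94, 0.32, 0.42),
    "Y": (2.94, 0.30, 6.47, 0.96, 5.66, 0.25, 0.41),
}

_MEILER_TABLE = np.array([MEILER_DESCRIPTORS[a] for a in AMINO_ACIDS])
_MEILER_MEAN = _MEILER_TABLE.mean(axis=0)
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass
class FeatureMatrix:
    """L x F real matrix of per-residue features aligned to graph nodes."""

    protein_id: str
    values: np.ndarray
    method: str  # one of {"embedding", "one_hot", "physchem"}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise EmbeddingFormatError(
                f"{self.protein_id}: feature payload must be 2-D, "
                f"got shape {self.values.shape}"
            )
        if not np.isfinite(self.values).all():
            raise EmbeddingFormatError(
                f"{self.protein_id}: non-finite entries in feature matrix"
            )

    @property
    def L(self) -> int:
        return self.values.shape[0]

    @property
    def F(self) -> int:
        return self.values.shape[1]


@dataclass
class ProteinGraph:
    """A contact graph together with its aligned node-feature matrix."""

    graph: ContactGraph
    features: FeatureMatrix


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise EncodingError("empty sequence")
    bad = set(sequence) - set(AMINO_ACIDS) - {"X"}
    if bad:
        raise EncodingError(f"characters outside the amino-acid alphabet: {sorted(bad)}")


def one_hot_features(sequence: str, protein_id: str = "protein") -> FeatureMatrix:
    """One-hot encode a sequence (columns in 'ACDEFGHIKLMNPQRSTVWY' order).

    'X' residues get an all-zero row, keeping row count equal to length.
    """
    _check_sequence(sequence)
    values = np.zeros((len(sequence), 20))
    for i, aa in enumerate(sequence):
        if aa != "X":
            values[i, _AA_INDEX[aa]] = 1.0
    return FeatureMatrix(protein_id, values, "one_hot")


def physicochemical_features(sequence: str, protein_id: str = "protein") -> FeatureMatrix:
    """Meiler 7-descriptor encoding; 'X' rows are the mean over the 20 rows."""
    _check_sequence(sequence)
    values = np.empty((len(sequence), 7))
    for i, aa in enumerate(sequence):
        values[i] = _MEILER_MEAN if aa == "X" else _MEILER_TABLE[_AA_INDEX[aa]]
    return FeatureMatrix(protein_id, values, "physchem")


def load_embeddings(store_path, protein_id: str) -> FeatureMatrix:
    """Load a precomputed L x F per-residue embedding matrix.

    ``store_path`` is either an HDF5 file with one dataset per protein id,
    or a directory containing ``<protein_id>.npy`` / ``<protein_id>.txt``.
    The matrix is returned unchanged, tagged with method ``"embedding"``.
    """
    path = Path(store_path)
    if path.is_dir():
        for candidate, loader in ((path / f"{protein_id}.npy", np.load),
                                  (path / f"{protein_id}.txt", np.loadtxt)):
            if candidate.exists():
                return FeatureMatrix(protein_id, np.atleast_2d(loader(candidate)),
                                     "embedding")
        raise EmbeddingLookupError(
            f"no embedding file for {protein_id!r} in directory {path}"
        )
    with h5py.File(path, "r") as fh:
        if protein_id not in fh:
            raise EmbeddingLookupError(f"protein id {protein_id!r} not in store {path}")
        return FeatureMatrix(protein_id, fh[protein_id][()], "embedding")


def save_embeddings(store_path, matrices: dict[str, np.ndarray]) -> None:
    """Write an HDF5 embedding store, one dataset per protein id."""
    with h5py.File(store_path, "w") as fh:
        for pid, values in matrices.items():
            fh.create_dataset(pid, data=np.asarray(values, dtype=float))


def attach_features(graph: ContactGraph, features: FeatureMatrix) -> ProteinGraph:
    """Bind a feature matrix to a contact graph; lengths must match exactly."""
    if graph.n_nodes != features.L:
        raise AlignmentError(
            f"{graph.protein_id}: graph has {graph.n_nodes} nodes but feature "
            f"matrix has {features.L} rows (no silent truncation)"
        )
    return ProteinGraph(graph, features)


# Registry hook for user-supplied embedder callables (sequence -> L x F array).
EMBEDDER_REGISTRY: dict[str, object] = {}


def register_embedder(name: str, fn) -> None:
    """Register a callable ``sequence -> ndarray(L, F)`` as a featurizer."""
    EMBEDDER_REGISTRY[name] = fn
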