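"""Desk-scale synthetic fixtures for the whole pipeline.

The generator emits exactly the artifact's real input formats — PDB
structure files, a keyed per-residue embedding store, and a 3-column pair
list — at a size where everything trains in seconds:

* structures are self-avoiding random walks with one "CA" pseudo-atom per
  residue, consecutive residues exactly ``step_length`` (3.8 A) apart and
  non-consecutive residues kept at least ``min_clash_distance`` (3.0 A)
  apart, so contact graphs have the chain backbone plus fold-back contacts;
* per-residue features are a class-specific motif (orthogonal unit
  directions scaled by ``signal_strength``) plus Gaussian noise, planting
  a learnable class signal;
* each protein gets a latent class and a pair is labeled interacting iff
  the two classes match (optionally flipped with ``label_noise``), so the
  Bayes-optimal accuracy is 1 at zero label noise and chance at zero
  signal.

Everything is reproducible bit-for-bit from ``SyntheticSpec.seed``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ppigraph.contact_graph import DEFAULT_CUTOFF, ContactGraph, build_contact_graph
from ppigraph.data import PairDataset, save_pairs
from ppigraph.errors import ConfigurationError, GenerationError
from ppigraph.node_features import FeatureMatrix, save_embeddings
from ppigraph.structure_io import (
    AMINO_ACIDS,
    AtomRecord,
    ProteinStructure,
    Residue,
    write_pdb,
)

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    n_proteins: int = 80
    length_range: tuple[int, int] = (30, 60)
    step_length: float = 3.8
    min_clash_distance: float = 3.0
    feature_dim: int = 16
    n_classes: int = 2
    signal_strength: float = 2.0
    noise_sd: float = 1.0
    interaction_rule: str = "same_class"
    label_noise: float = 0.0
    n_pairs: int = 400
    pos_neg_ratio: float = 1.0
    geometry_coupling: float = 0.0  # >0: class index also biases walk compactness
    atoms_per_residue: int = 1
    seed: int = 7

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not lo < hi:
            raise ConfigurationError("length_range must satisfy min < max")
        if self.signal_strength < 0 or self.noise_sd <= 0:
            raise ConfigurationError("need signal_strength >= 0 and noise_sd > 0")
        if not 0.0 <= self.label_noise < 1.0:
            raise ConfigurationError("label_noise must be in [0, 1)")
        if self.n_classes > self.feature_dim:
            raise ConfigurationError("feature_dim must be >= n_classes (orthogonal motifs)")
        if self.interaction_rule != "same_class":
            raise ConfigurationError(f"unknown interaction_rule {self.interaction_rule!r}")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def generate_structure(
    length: int,
    step_length: float = 3.8,
    min_clash_distance: float = 3.0,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
    protein_id: str = "synthetic",
    compactness: float = 0.0,
    atoms_per_residue: int = 1,
) -> ProteinStructure:
    """Self-avoiding walk structure with one CA pseudo-atom per residue.

    Consecutive residues are exactly ``step_length`` apart; every
    non-consecutive pair is at least ``min_clash_distance`` apart
    (rejection sampling with a bounded retry budget). ``compactness`` > 0
    biases steps back toward the centroid, producing denser contact maps.
    With ``atoms_per_residue`` > 1, extra side-chain pseudo-atoms are
    jittered around each CA to exercise the all-atom distance path.
    """
    if length < 2:
        raise GenerationError("need length >= 2")
    rng = rng if rng is not None else np.random.default_rng(seed)

    for _restart in range(60):
        coords = [np.zeros(3)]
        failed = False
        for _ in range(length - 1):
            placed = False
            for _attempt in range(300):
                direction = rng.normal(size=3)
                if compactness > 0 and len(coords) > 2:
                    centroid = np.mean(coords, axis=0)
                    pull = centroid - coords[-1]
                    if np.linalg.norm(pull) > 1e-9:
                        direction = _unit(direction) + compactness * _unit(pull)
                candidate = coords[-1] + step_length * _unit(direction)
                prior = np.array(coords[:-1])
                if len(prior) == 0 or np.min(
                        np.linalg.norm(prior - candidate, axis=1)) >= min_clash_distance:
                    coords.append(candidate)
                    placed = True
                    break
            if not placed:
                failed = True
                break
        if not failed:
            break
    else:
        raise GenerationError(
            f"self-avoiding walk of length {length} failed after 60 restarts; "
            "try another seed or a smaller min_clash_distance"
        )

    residues = []
    serial = 1
    for i, xyz in enumerate(coords):
        aa = AMINO_ACIDS[rng.integers(20)]
        res_name = _ONE_TO_THREE[aa]
        atoms = []
        positions = [("CA", xyz)]
        for extra in range(atoms_per_residue - 1):
            jitter = rng.normal(size=3)
            positions.append((f"CB{extra if extra else ''}".strip() or "CB",
                              xyz + 1.2 * _unit(jitter)))
        for name, pos in positions:
            x, y, z = (float(c) for c in pos)
            atoms.append(AtomRecord(serial, name, "", res_name, "A", i + 1, "",
                                    x, y, z))
            serial += 1
        residues.append(Residue("A", i + 1, "", res_name, aa, atoms))
    return ProteinStructure(protein_id, residues)


def generate_features(
    structure: ProteinStructure,
    class_id: int,
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
) -> FeatureMatrix:
    """Per-residue features: class motif + Gaussian noise.

    The class motif is ``signal_strength`` times the ``class_id``-th unit
    basis vector, so motifs of different classes are orthogonal and the
    expected row-mean separation between classes equals
    ``signal_strength * sqrt(2)``.
    """
    if class_id >= spec.n_classes:
        raise ConfigurationError(f"class_id {class_id} >= n_classes {spec.n_classes}")
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    L = len(structure)
    motif = np.zeros(spec.feature_dim)
    motif[class_id] = spec.signal_strength
    values = motif + rng.normal(0.0, spec.noise_sd, size=(L, spec.feature_dim))
    return FeatureMatrix(structure.protein_id, values, "embedding")


def generate_pair_dataset(
    spec: SyntheticSpec,
    return_classes: bool = False,
):
    """Generate (structures, features, PairDataset) for one SyntheticSpec.

    Proteins are split evenly over latent classes; positive pairs are
    sampled from same-class combinations and negatives from cross-class
    combinations, to ``n_pairs`` total at ``pos_neg_ratio``; labels are
    then flipped independently with probability ``label_noise``.
    """
    if spec.n_proteins < 4:
        raise ConfigurationError("need n_proteins >= 4")
    rng = np.random.default_rng(spec.seed)

    classes = np.array([i % spec.n_classes for i in range(spec.n_proteins)])
    rng.shuffle(classes)
    lo, hi = spec.length_range

    structures: dict[str, ProteinStructure] = {}
    features: dict[str, FeatureMatrix] = {}
    class_of: dict[str, int] = {}
    for i in range(spec.n_proteins):
        pid = f"p{i:04d}"
        length = int(rng.integers(lo, hi + 1))
        compact = spec.geometry_coupling * classes[i]
        structures[pid] = generate_structure(
            length, spec.step_length, spec.min_clash_distance, rng=rng,
            protein_id=pid, compactness=compact,
            atoms_per_residue=spec.atoms_per_residue,
        )
        features[pid] = generate_features(structures[pid], int(classes[i]), spec, rng=rng)
        class_of[pid] = int(classes[i])

    ids = list(structures)
    same, diff = [], []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            (same if class_of[ids[i]] == class_of[ids[j]] else diff).append(
                (ids[i], ids[j]))
    r = spec.pos_neg_ratio
    n_pos = int(round(spec.n_pairs * r / (1.0 + r)))
    n_neg = spec.n_pairs - n_pos
    if n_pos > len(same) or n_neg > len(diff):
        raise ConfigurationError(
            f"cannot draw {n_pos} positive / {n_neg} negative pairs from "
            f"{len(same)} same-class and {len(diff)} cross-class combinations"
        )
    pos_idx = rng.choice(len(same), size=n_pos, replace=False)
    neg_idx = rng.choice(len(diff), size=n_neg, replace=False)
    pairs = [(a, b, 1) for a, b in (same[i] for i in pos_idx)]
    pairs += [(a, b, 0) for a, b in (diff[i] for i in neg_idx)]
    order = rng.permutation(len(pairs))
    flips = rng.random(len(pairs)) < spec.label_noise
    pairs = [(a, b, (1 - lab) if flips[k] else lab)
             for k, (a, b, lab) in ((k, pairs[int(i)]) for k, i in enumerate(order))]
    dataset = PairDataset(pairs)
    if return_classes:
        return structures, features, dataset, class_of
    return structures, features, dataset


def build_graphs(structures: dict[str, ProteinStructure],
                 cutoff: float = DEFAULT_CUTOFF) -> dict[str, ContactGraph]:
    """Contact graphs for every structure in a bundle."""
    return {pid: build_contact_graph(s, cutoff) for pid, s in structures.items()}


def write_bundle(spec: SyntheticSpec, out_dir) -> dict:
    """Generate a dataset and write it in the pipeline's real input formats.

    Layout: ``pdbs/<id>.pdb``, ``embeddings.h5`` (keyed per-residue
    matrices), ``pairs.tsv`` (id_a, id_b, label) and ``spec.json``.
    """
    out = Path(out_dir)
    (out / "pdbs").mkdir(parents=True, exist_ok=True)
    structures, features, dataset = generate_pair_dataset(spec)
    for pid, structure in structures.items():
        (out / "pdbs" / f"{pid}.pdb").write_text(write_pdb(structure))
    save_embeddings(out / "embeddings.h5", {pid: f.values for pid, f in features.items()})
    save_pairs(dataset, out / "pairs.tsv")
    (out / "spec.json").write_text(json.dumps(asdict(spec), indent=2))
    return {"n_proteins": len(structures), "n_pairs": len(dataset),
            "out_dir": str(out)}
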