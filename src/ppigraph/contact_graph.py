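"""Residue contact networks from 3D structures.

Two residues are connected iff any pair of atoms (one from each residue)
lies strictly below the distance cutoff (default 6 A). The stored graph
is a pure contact map: symmetric, binary, zero diagonal; the GCN layer
adds its own self-loops at forward time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from ppigraph.errors import StructuralInputError
from ppigraph.structure_io import ProteinStructure, Residue

DEFAULT_CUTOFF = 6.0  # A


@dataclass
class ContactGraph:
    """Symmetric binary residue-residue adjacency, node order = residue order."""

    protein_id: str
    adjacency: np.ndarray
    node_order: list[tuple[str, int, str]]

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.adjacency, 1).sum())


def _coords(residue: Residue) -> np.ndarray:
    return np.array([[a.x, a.y, a.z] for a in residue.atoms], dtype=float)


def min_interresidue_distance(res_a: Residue, res_b: Residue) -> float:
    """Minimum Euclidean distance over all atom pairs of two residues (A)."""
    if not res_a.atoms or not res_b.atoms:
        raise StructuralInputError("residue without atoms")
    return float(cdist(_coords(res_a), _coords(res_b)).min())


def build_contact_graph(
    structure: ProteinStructure,
    cutoff: float = DEFAULT_CUTOFF,
    heavy_only: bool = False,
    ca_only: bool = False,
) -> ContactGraph:
    """Build the residue contact network of a structure.

    An edge (i, j), i != j, is present iff the minimum inter-atomic distance
    between residues i and j is strictly less than ``cutoff``; equality at
    the cutoff yields no edge.

    Parameters
    ----------
    structure:
        Parsed protein structure with >= 1 residue.
    cutoff:
        Distance threshold in Angstroms (> 0); default 6.0.
    heavy_only:
        Ignore hydrogen atoms when measuring distances.
    ca_only:
        Measure distances between CA pseudo-atoms only (fast approximation).
    """
    if not structure.residues:
        raise StructuralInputError(f"{structure.protein_id}: empty structure")
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")

    coords: list[np.ndarray] = []
    owner: list[int] = []
    for i, residue in enumerate(structure.residues):
        atoms = residue.atoms
        if ca_only:
            cas = [a for a in atoms if a.atom_name == "CA"]
            atoms = cas or atoms
        elif heavy_only:
            heavies = [a for a in atoms if not a.atom_name.startswith("H")]
            atoms = heavies or atoms
        for a in atoms:
            coords.append(np.array([a.x, a.y, a.z]))
            owner.append(i)

    xyz = np.vstack(coords)
    owner_arr = np.asarray(owner)
    L = len(structure.residues)

    # All-atom distance matrix, min-reduced onto residue pairs.
    d = cdist(xyz, xyz)
    mind = np.full((L, L), np.inf)
    np.minimum.at(mind, (owner_arr[:, None], owner_arr[None, :]), d)

    adjacency = (mind < cutoff).astype(np.int8)
    np.fill_diagonal(adjacency, 0)
    return ContactGraph(structure.protein_id, adjacency,
                        [r.key for r in structure.residues])


def graph_summary(graph: ContactGraph) -> dict:
    """Node/edge counts and degree statistics of a contact graph."""
    degrees = graph.adjacency.sum(axis=1)
    return {
        "n_nodes": graph.n_nodes,
        "n_edges": graph.n_edges,
        "degree_min": int(degrees.min()),
        "degree_mean": float(degrees.mean()),
        "degree_max": int(degrees.max()),
        "n_isolated": int((degrees == 0).sum()),
    }


def write_edge_list(graph: ContactGraph, path) -> None:
    """Export as text: one '<i> <j>' 0-based undirected edge per line."""
    i, j = np.nonzero(np.triu(graph.adjacency, 1))
    with open(path, "w") as fh:
        fh.write(f"# contact graph {graph.protein_id}: {graph.n_nodes} nodes, "
                 f"{len(i)} edges, 0-based node indices\n")
        for a, b in zip(i, j):
            fh.write(f"{a} {b}\n")


def read_edge_list(path, protein_id: str, n_nodes: int) -> ContactGraph:
    """Import a 0-based edge-list text file written by :func:`write_edge_list`."""
    adjacency = np.zeros((n_nodes, n_nodes), dtype=np.int8)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, b = (int(tok) for tok in line.split())
            adjacency[a, b] = adjacency[b, a] = 1
    return ContactGraph(protein_id, adjacency, [("", k, "") for k in range(n_nodes)])
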