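"""Read and write PDB-format structures at the residue level.

Only ATOM records of the first MODEL are used; HETATM records (including
waters) are excluded, so the derived one-letter sequence always aligns
one-to-one with the residue nodes of a contact graph. For alternate
locations, only the blank or first-encountered 'A'-style conformer of each
atom name is kept. The sequence comes from the ATOM records themselves
(never SEQRES) so its length equals the node count by construction.

Chains are concatenated in file order by default; pass ``chain`` to
restrict parsing to a single chain. Selenomethionine (MSE) maps to 'M';
any other non-standard residue name maps to 'X'.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from ppigraph.errors import PDBFormatError, PDBParseError, StructuralInputError

#: Standard 3-letter -> 1-letter residue code table (MSE handled as M).
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",
}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class AtomRecord:
    """One ATOM record: name, parent-residue identity and coordinates (A)."""

    serial: int
    atom_name: str
    alt_loc: str
    res_name: str
    chain_id: str
    res_seq: int
    insertion_code: str
    x: float
    y: float
    z: float
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise ValueError(f"non-finite coordinate in atom {self.serial}")
        if not self.res_name:
            raise ValueError("empty residue name")


@dataclass
class Residue:
    """A residue with its ordered atoms; identity is (chain, res_seq, icode)."""

    chain_id: str
    res_seq: int
    insertion_code: str
    res_name: str
    one_letter: str
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.insertion_code)


@dataclass
class ProteinStructure:
    """Ordered residues of one protein plus the aligned one-letter sequence."""

    protein_id: str
    residues: list[Residue]

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)


def _parse_float(line: str, lo: int, hi: int, what: str, lineno: int) -> float:
    raw = line[lo:hi].strip()
    try:
        value = float(raw)
    except ValueError:
        raise PDBParseError(
            f"malformed {what} field {raw!r} on line {lineno}: {line.rstrip()!r}"
        ) from None
    if not math.isfinite(value):
        raise PDBParseError(f"non-finite {what} on line {lineno}")
    return value


def parse_pdb(text: str, protein_id: str = "protein", chain: str | None = None) -> ProteinStructure:
    """Parse PDB-format text into a :class:`ProteinStructure`.

    Parameters
    ----------
    text:
        Contents of a PDB file (fixed-column v3.3 layout).
    protein_id:
        Identifier attached to the structure (typically the filename stem).
    chain:
        If given, keep only ATOM records of this chain id.

    Raises
    ------
    StructuralInputError
        If no usable ATOM records are found.
    PDBParseError
        If a coordinate field cannot be parsed (the message names the line).
    """
    residues: list[Residue] = []
    index: dict[tuple[str, int, str], Residue] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        record = line[:6].strip()
        if record == "ENDMDL":
            break  # first MODEL only
        if record != "ATOM":
            continue
        alt_loc = line[16:17].strip()
        atom_name = line[12:16].strip()
        chain_id = line[21:22]
        if chain is not None and chain_id != chain:
            continue
        res_name = line[17:20].strip()
        if not res_name:
            raise PDBParseError(f"empty residue name on line {lineno}")
        try:
            res_seq = int(line[22:26].strip())
        except ValueError:
            raise PDBParseError(
                f"malformed residue number on line {lineno}: {line.rstrip()!r}"
            ) from None
        icode = line[26:27].strip()
        x = _parse_float(line, 30, 38, "x coordinate", lineno)
        y = _parse_float(line, 38, 46, "y coordinate", lineno)
        z = _parse_float(line, 46, 54, "z coordinate", lineno)
        occ_raw = line[54:60].strip()
        occupancy = float(occ_raw) if occ_raw else 1.0
        try:
            serial = int(line[6:11].strip())
        except ValueError:
            serial = len(index) + 1

        key = (chain_id, res_seq, icode)
        residue = index.get(key)
        if residue is None:
            one = THREE_TO_ONE.get(res_name, "X")
            residue = Residue(chain_id, res_seq, icode, res_name, one)
            index[key] = residue
            residues.append(residue)
        if alt_loc and any(a.atom_name == atom_name for a in residue.atoms):
            continue  # keep only the first-encountered alternate conformer
        residue.atoms.append(
            AtomRecord(serial, atom_name, alt_loc, res_name, chain_id,
                       res_seq, icode, x, y, z, occupancy)
        )
    if not residues:
        raise StructuralInputError(
            f"{protein_id}: no ATOM records found (HETATM/water-only input?)"
        )
    return ProteinStructure(protein_id, residues)


def write_pdb(structure: ProteinStructure) -> str:
    """Serialize a structure into fixed-column PDB v3.3 ATOM records.

    Coordinates are written at 3-decimal precision in the 8.3 field; values
    that do not fit the field raise :class:`PDBFormatError`.
    """
    if not structure.residues:
        raise PDBFormatError(f"{structure.protein_id}: structure has no residues")
    lines = []
    serial = 0
    for residue in structure.residues:
        if not residue.atoms:
            raise PDBFormatError(
                f"{structure.protein_id}: residue {residue.key} has no atoms"
            )
        for atom in residue.atoms:
            serial += 1
            for coord in (atom.x, atom.y, atom.z):
                if not -999.999 <= coord <= 9999.999:
                    raise PDBFormatError(
                        f"coordinate {coord} exceeds the fixed-width 8.3 PDB field"
                    )
            name = atom.atom_name
            # PDB convention: 1-3 char names start in column 14.
            name_field = f" {name:<3s}" if len(name) < 4 else name
            element = name[:1] if name[:1].isalpha() else name[1:2]
            lines.append(
                f"ATOM  {serial:5d} {name_field}{atom.alt_loc or ' ':1s}"
                f"{residue.res_name:>3s} {residue.chain_id:1s}{residue.res_seq:4d}"
                f"{residue.insertion_code or ' ':1s}   "
                f"{atom.x:8.3f}{atom.y:8.3f}{atom.z:8.3f}"
                f"{atom.occupancy:6.2f}{0.0:6.2f}          {element:>2s}"
            )
    lines.append("END")
    return "\n".join(lines) + "\n"


def read_pdb_file(path, protein_id: str | None = None, chain: str | None = None) -> ProteinStructure:
    """Read a PDB file; protein id defaults to the filename stem."""
    from pathlib import Path

    p = Path(path)
    return parse_pdb(p.read_text(), protein_id or p.stem, chain=chain)
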