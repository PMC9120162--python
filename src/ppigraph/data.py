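"""Labeled protein-pair datasets and their delimited-text serialization."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ppigraph.errors import DataError


@dataclass
class PairDataset:
    """List of (id_a, id_b, label in {0,1}) protein pairs."""

    pairs: list[tuple[str, str, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def __getitem__(self, idx):
        if isinstance(idx, (list, tuple)):
            return PairDataset([self.pairs[i] for i in idx])
        return self.pairs[idx]

    @property
    def labels(self) -> list[int]:
        return [label for _, _, label in self.pairs]

    @property
    def protein_ids(self) -> set[str]:
        ids: set[str] = set()
        for a, b, _ in self.pairs:
            ids.add(a)
            ids.add(b)
        return ids

    def subset(self, indices) -> "PairDataset":
        return PairDataset([self.pairs[i] for i in indices])

    def check_resolvable(self, graphs: dict) -> None:
        """Raise DataError listing ids that have no graph/features."""
        missing = sorted(self.protein_ids - set(graphs))
        if missing:
            raise DataError(f"pairs reference unknown protein ids: {missing}")


def load_pairs(path, sep: str | None = None) -> PairDataset:
    """Read a 3-column delimited file (id_a, id_b, label), no header required."""
    df = pd.read_csv(path, sep=sep or r"\s+|,|\t", engine="python",
                     header=None, comment="#")
    if df.shape[1] < 3:
        raise DataError(f"{path}: expected 3 columns (id_a, id_b, label)")
    pairs = []
    for _, row in df.iterrows():
        label = int(row.iloc[2])
        if label not in (0, 1):
            raise DataError(f"{path}: label must be 0/1, got {row.iloc[2]!r}")
        pairs.append((str(row.iloc[0]), str(row.iloc[1]), label))
    return PairDataset(pairs)


def save_pairs(dataset: PairDataset, path) -> None:
    """Write pairs as tab-separated id_a, id_b, label rows."""
    with open(path, "w") as fh:
        for a, b, label in dataset:
            fh.write(f"{a}\t{b}\t{label}\n")
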