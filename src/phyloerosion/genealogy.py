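"""Genotype-level genealogy log: the raw record every analysis derives from.

One record per genotype: parent, origin update, extinction update (absent
while extant), number of traits and viability.  A genotype is "extant" at time
``t`` iff ``origin <= t < extinction``.  Cladogenesis follows the genotype
convention: every mutated birth creates a new genotype record, so branching is
dominated by near-neutral variants and is decoupled from phenotypic change.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

#: Sentinel for "still extant at the end of the run".
EXTANT = -1


class GenealogyLog:
    """Append-only forest of genotype records with a single founder root.

    Records are indexed by integer creation order, which is also temporal
    order: a parent's index (and origin update) always precedes its
    children's.  String ids default to ``G{index}`` but arbitrary opaque ids
    survive a TSV round trip.
    """

    __slots__ = ("parent", "origin", "extinction", "n_traits", "viable", "tag",
                 "_labels")

    def __init__(self) -> None:
        self.parent: list[int] = []
        self.origin: list[int] = []
        self.extinction: list[int] = []
        self.n_traits: list[int] = []
        self.viable: list[bool] = []
        self.tag: list[int] = []
        self._labels: list[str] | None = None

    def __len__(self) -> int:
        return len(self.origin)

    def add(self, parent: int, origin: int, n_traits: int, viable: bool,
            tag: int, label: str | None = None) -> int:
        """Append a genotype record and return its index."""
        if parent >= 0 and self.origin[parent] > origin:
            raise ValueError("child cannot originate before its parent")
        idx = len(self.origin)
        self.parent.append(parent)
        self.origin.append(origin)
        self.extinction.append(EXTANT)
        self.n_traits.append(n_traits)
        self.viable.append(viable)
        self.tag.append(tag)
        if label is not None:
            if self._labels is None:
                self._labels = [f"G{i}" for i in range(idx)]
            self._labels.append(label)
        elif self._labels is not None:
            self._labels.append(f"G{idx}")
        return idx

    def set_extinct(self, idx: int, update: int) -> None:
        if update < self.origin[idx]:
            raise ValueError("extinction_update must be >= origin_update")
        self.extinction[idx] = update

    def label(self, idx: int) -> str:
        if self._labels is not None:
            return self._labels[idx]
        return f"G{idx}"

    @property
    def labels(self) -> list[str]:
        if self._labels is None:
            self._labels = [f"G{i}" for i in range(len(self))]
        return self._labels

    # -- queries ------------------------------------------------------------

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(parent, origin, extinction) as numpy arrays."""
        return (
            np.asarray(self.parent, dtype=np.int64),
            np.asarray(self.origin, dtype=np.int64),
            np.asarray(self.extinction, dtype=np.int64),
        )

    def extant_at(self, t: int) -> np.ndarray:
        """Indices of genotypes extant at time ``t`` (origin <= t < extinction)."""
        _, origin, ext = self.arrays()
        mask = (origin <= t) & ((ext == EXTANT) | (ext > t))
        return np.flatnonzero(mask)

    # -- I/O ----------------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        labels = self.labels
        parent_labels = ["" if p < 0 else labels[p] for p in self.parent]
        return pd.DataFrame(
            {
                "genotype_id": labels,
                "parent_id": parent_labels,
                "origin_update": self.origin,
                "extinction_update": [
                    "" if e == EXTANT else e for e in self.extinction
                ],
                "n_traits": self.n_traits,
                "viable": [int(v) for v in self.viable],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GenealogyLog":
        df = pd.read_csv(
            Path(path), sep="\t", dtype={"genotype_id": str, "parent_id": str},
            keep_default_na=False,
        )
        log = cls()
        index = {gid: i for i, gid in enumerate(df["genotype_id"])}
        for row in df.itertuples(index=False):
            parent = index[row.parent_id] if row.parent_id else -1
            log.add(
                parent=parent,
                origin=int(row.origin_update),
                n_traits=int(row.n_traits),
                viable=bool(int(row.viable)),
                tag=0,
                label=row.genotype_id,
            )
            ext = row.extinction_update
            if ext != "":
                log.set_extinct(index[row.genotype_id], int(float(ext)))
        return log
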