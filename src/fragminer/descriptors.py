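"""Substructure dictionary (SSD) and binary descriptor matrices.

Mined fragments form an ordered dictionary; a compound library is then
vectorized into an n x m binary matrix with L[i, j] = 1 exactly when
dictionary fragment i occurs in compound j.  Two frequency filters are
provided: the 5%-presence floor applied before modeling, and a raw
presence-count threshold for reducing the dictionary to the flat part of
its frequency curve before regression modeling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .mining import SubID, popularity as subid_popularity
from .molgraph import Fragment, MolecularGraph, subgraph_exists, subgraph_match


class DescriptorError(ValueError):
    pass


@dataclass(frozen=True)
class SSDEntry:
    fragment: Fragment
    frequency: int  # molecules containing the fragment in the source library

    @property
    def canonical_key(self) -> str:
        return self.fragment.canonical_key


@dataclass
class SSD:
    """Ordered substructure dictionary with background frequencies."""

    entries: tuple[SSDEntry, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        keys = [e.canonical_key for e in self.entries]
        if len(set(keys)) != len(keys):
            raise DescriptorError("duplicate canonical_key in SSD")

    def __len__(self) -> int:
        return len(self.entries)

    def fragments(self) -> list[Fragment]:
        return [e.fragment for e in self.entries]

    def keys(self) -> list[str]:
        return [e.canonical_key for e in self.entries]


def build_ssd(
    mined: Sequence[tuple[Fragment, SubID | int]],
    provenance: dict | None = None,
) -> SSD:
    """Dictionary from mined fragments with their supports.

    Entries are ordered by descending frequency, then canonical key.
    The support may be given as a subID (popularity is taken) or as a
    plain count.
    """
    if not mined:
        raise DescriptorError("cannot build an SSD from no fragments")
    entries = []
    seen = set()
    for frag, sup in mined:
        key = frag.canonical_key
        if key in seen:
            raise DescriptorError(f"duplicate fragment in mined input: {key}")
        seen.add(key)
        freq = subid_popularity(sup) if isinstance(sup, SubID) else int(sup)
        entries.append(SSDEntry(frag, freq))
    entries.sort(key=lambda e: (-e.frequency, e.canonical_key))
    return SSD(tuple(entries), dict(provenance or {}))


class DescriptorMatrix:
    """n fragments x m compounds binary (or count) matrix with labels."""

    def __init__(self, values: np.ndarray, fragment_keys: list[str], mol_ids: list[str]):
        values = np.asarray(values)
        if values.shape != (len(fragment_keys), len(mol_ids)):
            raise DescriptorError("matrix shape does not match labels")
        self.values = values
        self.fragment_keys = list(fragment_keys)
        self.mol_ids = list(mol_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.fragment_keys, columns=self.mol_ids)

    def column(self, mol_id: str) -> np.ndarray:
        return self.values[:, self.mol_ids.index(mol_id)]

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="fragment")

    def write_mtx(self, path: str | Path) -> None:
        """MatrixMarket matrix plus .rows / .cols label files."""
        path = Path(path)
        scipy.io.mmwrite(str(path), scipy.sparse.csr_matrix(self.values))
        path.with_suffix(".rows").write_text("\n".join(self.fragment_keys) + "\n")
        path.with_suffix(".cols").write_text("\n".join(self.mol_ids) + "\n")


def vectorize(
    library: Sequence[MolecularGraph],
    ssd: SSD,
    mode: str = "binary",
) -> DescriptorMatrix:
    """Binary presence matrix: L[i, j] = 1 iff ssd fragment i matches compound j.

    ``mode="count"`` records the number of distinct embeddings instead;
    binary presence is the canonical descriptor.
    """
    if not library or not len(ssd):
        raise DescriptorError("library and SSD must be nonempty")
    if mode not in ("binary", "count"):
        raise DescriptorError(f"unknown mode {mode!r}")
    values = np.zeros((len(ssd), len(library)), dtype=np.int32)
    for i, entry in enumerate(ssd.entries):
        for j, mol in enumerate(library):
            if mode == "binary":
                values[i, j] = 1 if subgraph_exists(entry.fragment, mol) else 0
            else:
                values[i, j] = len(subgraph_match(entry.fragment, mol))
    return DescriptorMatrix(values, ssd.keys(), [m.mol_id for m in library])


def presence_counts(ssd: SSD, library: Sequence[MolecularGraph]) -> np.ndarray:
    """Molecules of ``library`` containing each dictionary fragment."""
    mat = vectorize(library, ssd, mode="binary")
    return mat.values.sum(axis=1)


def select_descriptors(
    ssd: SSD, library: Sequence[MolecularGraph], min_fraction: float = 0.05
) -> SSD:
    """Drop fragments present in less than ``min_fraction`` of the library.

    A presence fraction exactly at the floor is kept (only "less than"
    is removed).
    """
    if not library:
        raise DescriptorError("library must be nonempty")
    counts = presence_counts(ssd, library)
    n = len(library)
    kept = tuple(
        e for e, c in zip(ssd.entries, counts) if c / n >= min_fraction
    )
    prov = dict(ssd.provenance, min_fraction=min_fraction)
    return SSD(kept, prov)


def frequency_tuning_subset(
    ssd: SSD, library: Sequence[MolecularGraph], min_count: int
) -> tuple[SSD, np.ndarray]:
    """Keep fragments with presence count >= min_count in the library.

    Also returns the descending frequency curve so the flattening point
    can be chosen by inspection.
    """
    if min_count < 1:
        raise DescriptorError("min_count must be >= 1")
    counts = presence_counts(ssd, library)
    curve = np.sort(counts)[::-1]
    kept = tuple(e for e, c in zip(ssd.entries, counts) if c >= min_count)
    if not kept:
        import logging

        logging.getLogger(__name__).warning(
            "min_count=%d exceeds the maximum presence count %d; empty subset",
            min_count,
            int(curve[0]) if len(curve) else 0,
        )
    prov = dict(ssd.provenance, min_count=min_count)
    return SSD(kept, prov), curve
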