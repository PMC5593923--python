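"""Fragment-combination rules inside active molecules.

Given the elected privileged fragments, each active molecule is searched
for co-occurring fragment pairs and the spatial relation of their
embeddings is classified: ``merge`` when the embeddings share an atom,
``direct`` when a single bond joins them, ``linker`` otherwise (with the
linker being the shortest bond path between the two embeddings).  One
vote per molecule per pair, taking the most intimate relation observed
(merge > direct > linker); molecules matched by exactly one privileged
fragment contribute ``standalone`` records.  Aggregated relations with
enough supporting molecules become rule records — the generic machinery
behind assembling leads from privileged building blocks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx

from .molgraph import Fragment, MolecularGraph, fragment_from_bonds, subgraph_match

RELATION_RANK = {"merge": 0, "direct": 1, "linker": 2}


class RuleError(ValueError):
    pass


@dataclass
class RuleRecord:
    fragments: tuple[str, ...]  # canonical keys (one entry for standalone)
    relation: str  # merge | direct | linker | standalone
    linker_fragment: Fragment | None
    support: int
    example_mol_ids: list[str]

    def as_dict(self) -> dict:
        return {
            "fragments": list(self.fragments),
            "relation": self.relation,
            "linker": self.linker_fragment.canonical_key if self.linker_fragment else None,
            "support": self.support,
            "example_mol_ids": self.example_mol_ids,
        }


def _bond_atoms(mol: MolecularGraph, bond_ids: frozenset[int]) -> set[int]:
    return {a for bid in bond_ids for a in mol.bond(bid).atoms()}


def embedding_relation(
    mol: MolecularGraph, emb1: frozenset[int], emb2: frozenset[int]
) -> tuple[str, frozenset[int] | None]:
    """Relation between two embeddings: merge, direct, or linker.

    Shared atom -> merge.  A bond joining an atom of each -> direct.
    Otherwise linker: the bonds on a shortest path between the two atom
    sets (path ties broken by the smallest canonical key of the induced
    linker fragment).  Returns (relation, linker bond set or None).
    """
    known = {b.bond_id for b in mol.bonds}
    if not emb1 <= known or not emb2 <= known:
        raise RuleError("embedding references bonds absent from the molecule")
    atoms1 = _bond_atoms(mol, emb1)
    atoms2 = _bond_atoms(mol, emb2)
    if atoms1 & atoms2:
        return "merge", None
    for b in mol.bonds:
        if (b.a1 in atoms1 and b.a2 in atoms2) or (b.a2 in atoms1 and b.a1 in atoms2):
            return "direct", None
    g = mol.to_networkx()
    best_len = None
    best_paths = []
    for a1 in sorted(atoms1):
        lengths, paths = nx.single_source_dijkstra(g, a1, weight=None)
        for a2 in sorted(atoms2):
            if a2 not in lengths:
                continue
            if best_len is None or lengths[a2] < best_len:
                best_len = lengths[a2]
                best_paths = [paths[a2]]
            elif lengths[a2] == best_len:
                best_paths.append(paths[a2])
    if best_len is None:
        raise RuleError("embeddings lie in disconnected parts of the molecule")
    candidates = []
    for path in best_paths:
        bonds = frozenset(
            g.edges[u, v]["bond_id"] for u, v in zip(path, path[1:])
        )
        frag = fragment_from_bonds(mol, bonds)
        candidates.append((frag.canonical_key, bonds))
    candidates.sort()
    return "linker", candidates[0][1]


def derive_rules(
    privileged_fragments: Sequence[Fragment],
    active_library: Sequence[MolecularGraph],
    min_support: int = 1,
) -> list[RuleRecord]:
    """Discover fragment-combination rules across the active molecules.

    For every unordered pair of privileged fragments present in a
    molecule, the embedding pair with the most intimate relation casts
    that molecule's single vote; linker votes also carry the linker
    fragment identity.  Records are aggregated by (pair, relation,
    linker) and reported with support >= min_support, sorted by
    descending support then keys.
    """
    if not privileged_fragments:
        raise RuleError("no privileged fragments")
    if not active_library:
        raise RuleError("no active molecules")
    frags = sorted(privileged_fragments, key=lambda f: f.canonical_key)
    agg: dict[tuple, dict] = {}
    for mol in active_library:
        embeddings = {
            f.canonical_key: subgraph_match(f, mol)
            for f in frags
        }
        present = [f for f in frags if embeddings[f.canonical_key]]
        if len(present) == 1:
            key = ((present[0].canonical_key,), "standalone", None)
            rec = agg.setdefault(key, {"mols": [], "linker": None})
            rec["mols"].append(mol.mol_id)
            continue
        for i in range(len(present)):
            for j in range(i + 1, len(present)):
                f1, f2 = present[i], present[j]
                best = None  # (rank, linker_size, linker_key, linker_bonds)
                for e1 in embeddings[f1.canonical_key]:
                    for e2 in embeddings[f2.canonical_key]:
                        if e1 & e2 and f1.canonical_key == f2.canonical_key:
                            continue
                        rel, linker = embedding_relation(mol, e1, e2)
                        if rel == "linker":
                            lf = fragment_from_bonds(mol, linker)
                            cand = (RELATION_RANK[rel], len(linker), lf.canonical_key, linker, lf)
                        else:
                            cand = (RELATION_RANK[rel], 0, "", None, None)
                        if best is None or cand[:3] < best[:3]:
                            best = cand
                        if best[0] == 0:
                            break
                    if best is not None and best[0] == 0:
                        break
                if best is None:
                    continue
                rel = {v: k for k, v in RELATION_RANK.items()}[best[0]]
                linker_key = best[2] if rel == "linker" else None
                key = (
                    (f1.canonical_key, f2.canonical_key),
                    rel,
                    linker_key,
                )
                rec = agg.setdefault(key, {"mols": [], "linker": best[4]})
                rec["mols"].append(mol.mol_id)
    records = [
        RuleRecord(
            fragments=key[0],
            relation=key[1],
            linker_fragment=rec["linker"],
            support=len(rec["mols"]),
            example_mol_ids=sorted(rec["mols"])[:10],
        )
        for key, rec in agg.items()
    ]
    records = [r for r in records if r.support >= min_support]
    records.sort(key=lambda r: (-r.support, r.relation, r.fragments))
    return records


def write_rules(records: Sequence[RuleRecord], path: str | Path, renderer=None) -> None:
    path = Path(path)
    render = renderer or (lambda f: f.canonical_key if f else "")
    with open(path.with_suffix(".tsv"), "w") as fh:
        fh.write("fragments\trelation\tlinker\tsupport\texamples\n")
        for r in records:
            fh.write(
                f"{'+'.join(r.fragments)}\t{r.relation}\t"
                f"{render(r.linker_fragment) if r.linker_fragment else ''}\t"
                f"{r.support}\t{','.join(r.example_mol_ids)}\n"
            )
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump([r.as_dict() for r in records], fh, indent=1)
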