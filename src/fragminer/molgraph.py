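"""Core molecular-graph model and exact fragment identity.

Molecules are hydrogen-suppressed labeled graphs: atoms carry
(element, formal charge, aromatic flag), bonds carry an order in
{single, double, triple, aromatic}.  Fragments are connected
bond-induced subgraphs.  Fragment identity is a canonical string
(:func:`canonical_form`) computed by iterative neighborhood-label
refinement with exhaustive tie-breaking, so that two fragments are
isomorphic exactly when their canonical keys are equal.  This exact
string identity is what the mining registry relies on.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx
from networkx.algorithms import isomorphism as nxiso

BOND_ORDERS = ("single", "double", "triple", "aromatic")


class MolGraphError(ValueError):
    """Raised on invalid molecular-graph input."""


@dataclass(frozen=True)
class Atom:
    atom_id: int
    element: str
    charge: int = 0
    aromatic: bool = False

    @property
    def label(self) -> tuple:
        return (self.element, self.charge, self.aromatic)


@dataclass(frozen=True)
class Bond:
    bond_id: int
    a1: int
    a2: int
    order: str = "single"

    def atoms(self) -> tuple[int, int]:
        return (self.a1, self.a2)


def _validate(atoms: Sequence[Atom], bonds: Sequence[Bond]) -> None:
    atom_ids = [a.atom_id for a in atoms]
    if len(set(atom_ids)) != len(atom_ids):
        raise MolGraphError("duplicate atom_id")
    known = set(atom_ids)
    for a in atoms:
        if a.element == "H":
            raise MolGraphError("explicit hydrogen atoms are not allowed")
    bond_ids = [b.bond_id for b in bonds]
    if len(set(bond_ids)) != len(bond_ids):
        raise MolGraphError("duplicate bond_id")
    pairs = set()
    for b in bonds:
        if b.a1 == b.a2:
            raise MolGraphError(f"bond {b.bond_id} is a self-loop")
        if b.a1 not in known or b.a2 not in known:
            raise MolGraphError(f"bond {b.bond_id} references unknown atom")
        if b.order not in BOND_ORDERS:
            raise MolGraphError(f"bond {b.bond_id} has invalid order {b.order!r}")
        key = frozenset((b.a1, b.a2))
        if key in pairs:
            raise MolGraphError(f"duplicate bond between atoms {b.a1} and {b.a2}")
        pairs.add(key)


class MolecularGraph:
    """Hydrogen-suppressed molecule: atom list, bond list, property table."""

    def __init__(
        self,
        mol_id: str,
        atoms: Iterable[Atom],
        bonds: Iterable[Bond],
        properties: Mapping[str, object] | None = None,
    ):
        self.mol_id = mol_id
        self.atoms: tuple[Atom, ...] = tuple(atoms)
        self.bonds: tuple[Bond, ...] = tuple(bonds)
        self.properties: dict[str, object] = dict(properties or {})
        _validate(self.atoms, self.bonds)
        self._atom_by_id = {a.atom_id: a for a in self.atoms}
        self._bond_by_id = {b.bond_id: b for b in self.bonds}
        # atom_id -> list of incident bonds
        self._incident: dict[int, list[Bond]] = {a.atom_id: [] for a in self.atoms}
        for b in self.bonds:
            self._incident[b.a1].append(b)
            self._incident[b.a2].append(b)

    def atom(self, atom_id: int) -> Atom:
        return self._atom_by_id[atom_id]

    def bond(self, bond_id: int) -> Bond:
        return self._bond_by_id[bond_id]

    def incident_bonds(self, atom_id: int) -> list[Bond]:
        return self._incident[atom_id]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for a in self.atoms:
            g.add_node(a.atom_id, label=a.label)
        for b in self.bonds:
            g.add_edge(b.a1, b.a2, order=b.order, bond_id=b.bond_id)
        return g

    def __repr__(self) -> str:
        return (
            f"MolecularGraph({self.mol_id!r}, {self.n_atoms} atoms, "
            f"{self.n_bonds} bonds)"
        )


class Fragment:
    """A connected bond-induced labeled subgraph.

    Atom/bond ids are retained from the source graph but are irrelevant
    for identity: ``canonical_key`` is invariant under relabeling.
    """

    def __init__(self, atoms: Iterable[Atom], bonds: Iterable[Bond]):
        self.atoms: tuple[Atom, ...] = tuple(atoms)
        self.bonds: tuple[Bond, ...] = tuple(bonds)
        _validate(self.atoms, self.bonds)
        if not self.bonds:
            raise MolGraphError("fragment must contain at least one bond")
        if not self._is_connected():
            raise MolGraphError("fragment is not connected")
        self._atom_by_id = {a.atom_id: a for a in self.atoms}

    def _is_connected(self) -> bool:
        adj: dict[int, set[int]] = {a.atom_id: set() for a in self.atoms}
        for b in self.bonds:
            adj[b.a1].add(b.a2)
            adj[b.a2].add(b.a1)
        start = self.atoms[0].atom_id
        seen = {start}
        stack = [start]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == len(self.atoms)

    @property
    def n_edges(self) -> int:
        return len(self.bonds)

    @cached_property
    def canonical_key(self) -> str:
        return canonical_form(self)

    def atom(self, atom_id: int) -> Atom:
        return self._atom_by_id[atom_id]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for a in self.atoms:
            g.add_node(a.atom_id, label=a.label)
        for b in self.bonds:
            g.add_edge(b.a1, b.a2, order=b.order, bond_id=b.bond_id)
        return g

    def __eq__(self, other) -> bool:
        if not isinstance(other, Fragment):
            return NotImplemented
        return self.canonical_key == other.canonical_key

    def __hash__(self) -> int:
        return hash(self.canonical_key)

    def __repr__(self) -> str:
        return f"Fragment({self.canonical_key})"


def fragment_from_bonds(
    mol: MolecularGraph | Fragment, bond_ids: Iterable[int]
) -> Fragment:
    """Bond-induced fragment of ``mol`` over the given bond ids."""
    bond_ids = set(bond_ids)
    lookup = {b.bond_id: b for b in mol.bonds}
    unknown = bond_ids - set(lookup)
    if unknown:
        raise MolGraphError(f"bond ids {sorted(unknown)} absent from {mol!r}")
    bonds = [lookup[b] for b in sorted(bond_ids)]
    atom_ids = sorted({a for b in bonds for a in b.atoms()})
    atoms = [mol.atom(i) for i in atom_ids]
    return Fragment(atoms, bonds)


# ---------------------------------------------------------------------------
# Canonical labeling: individualization-refinement with exhaustive tie-breaks
# ---------------------------------------------------------------------------


def _refine(
    n: int,
    init_colors: list[int],
    adj: list[list[tuple[int, str]]],
) -> list[int]:
    """Iterative neighborhood-color refinement; returns stable coloring."""
    colors = list(init_colors)
    while True:
        sigs = [
            (colors[i], tuple(sorted((adj[i][k][1], colors[adj[i][k][0]])
                                     for k in range(len(adj[i])))))
            for i in range(n)
        ]
        order = sorted(set(sigs))
        rank = {s: r for r, s in enumerate(order)}
        new = [rank[s] for s in sigs]
        if new == colors:
            return colors
        colors = new


def _serialize(
    n: int,
    colors: list[int],
    labels: list[tuple],
    adj: list[list[tuple[int, str]]],
) -> str:
    """Serialize a graph under a discrete (all-singleton) coloring."""
    perm = sorted(range(n), key=lambda i: colors[i])
    pos = {v: i for i, v in enumerate(perm)}
    atom_part = ";".join(
        f"{labels[v][0]}{'%+d' % labels[v][1] if labels[v][1] else ''}"
        f"{'@' if labels[v][2] else ''}"
        for v in perm
    )
    edges = []
    for v in range(n):
        for w, order in adj[v]:
            if pos[v] < pos[w]:
                edges.append((pos[v], pos[w], order))
    edges.sort()
    bond_part = ",".join(f"{i}-{j}:{o}" for i, j, o in edges)
    return atom_part + "|" + bond_part


def _canonical_string(
    n: int,
    colors: list[int],
    labels: list[tuple],
    adj: list[list[tuple[int, str]]],
) -> str:
    colors = _refine(n, colors, adj)
    cells: dict[int, list[int]] = {}
    for v, c in enumerate(colors):
        cells.setdefault(c, []).append(v)
    target = None
    for c in sorted(cells):
        if len(cells[c]) > 1:
            target = cells[c]
            break
    if target is None:
        return _serialize(n, colors, labels, adj)
    best = None
    for v in target:
        branched = [c + (1 if c > colors[v] or (c == colors[v] and u != v) else 0)
                    for u, c in enumerate(colors)]
        # individualize v: give it its current color, push the rest of the
        # cell (and all higher colors) up by one
        s = _canonical_string(n, branched, labels, adj)
        if best is None or s < best:
            best = s
    return best


def canonical_form(fragment: Fragment) -> str:
    """Canonical string identity of a connected fragment.

    Invariant under atom/bond reordering; equal strings iff the
    fragments are isomorphic as labeled graphs (element, charge,
    aromatic flag on atoms; order on bonds).
    """
    atom_ids = [a.atom_id for a in fragment.atoms]
    idx = {aid: i for i, aid in enumerate(atom_ids)}
    n = len(atom_ids)
    labels = [a.label for a in fragment.atoms]
    adj: list[list[tuple[int, str]]] = [[] for _ in range(n)]
    for b in fragment.bonds:
        i, j = idx[b.a1], idx[b.a2]
        adj[i].append((j, b.order))
        adj[j].append((i, b.order))
    order = sorted(set(labels))
    rank = {lab: r for r, lab in enumerate(order)}
    init = [rank[lab] for lab in labels]
    return _canonical_string(n, init, labels, adj)


# ---------------------------------------------------------------------------
# Subgraph matching
# ---------------------------------------------------------------------------


def _node_match(a: dict, b: dict) -> bool:
    return a["label"] == b["label"]


def _edge_match(a: dict, b: dict) -> bool:
    return a["order"] == b["order"]


def subgraph_match(
    fragment: Fragment, mol: MolecularGraph | Fragment
) -> list[frozenset[int]]:
    """All embeddings of ``fragment`` in ``mol`` as distinct bond-id sets.

    An embedding is the set of mol bond ids whose induced labeled
    subgraph is isomorphic to the fragment; automorphic re-mappings onto
    the same bond set are counted once.  Result is sorted for
    determinism.
    """
    g_mol = mol.to_networkx()
    g_frag = fragment.to_networkx()
    if g_frag.number_of_nodes() > g_mol.number_of_nodes():
        return []
    matcher = nxiso.GraphMatcher(
        g_mol, g_frag, node_match=_node_match, edge_match=_edge_match
    )
    frag_edges = [(b.a1, b.a2) for b in fragment.bonds]
    seen: set[frozenset[int]] = set()
    for mapping in matcher.subgraph_monomorphisms_iter():
        inv = {v: k for k, v in mapping.items()}
        bond_set = frozenset(
            g_mol.edges[inv[a], inv[b]]["bond_id"] for a, b in frag_edges
        )
        seen.add(bond_set)
    return sorted(seen, key=lambda s: tuple(sorted(s)))


def fragment_to_dict(fragment: Fragment) -> dict:
    """JSON-serializable form of a fragment (atoms, bonds, key)."""
    return {
        "atoms": [[a.atom_id, a.element, a.charge, a.aromatic] for a in fragment.atoms],
        "bonds": [[b.bond_id, b.a1, b.a2, b.order] for b in fragment.bonds],
        "canonical_key": fragment.canonical_key,
    }


def fragment_from_dict(d: dict) -> Fragment:
    return Fragment(
        [Atom(i, e, c, ar) for i, e, c, ar in d["atoms"]],
        [Bond(i, a, b, o) for i, a, b, o in d["bonds"]],
    )


def subgraph_exists(fragment: Fragment, mol: MolecularGraph | Fragment) -> bool:
    """True iff at least one embedding exists (early-exit matcher)."""
    g_mol = mol.to_networkx()
    g_frag = fragment.to_networkx()
    if g_frag.number_of_nodes() > g_mol.number_of_nodes():
        return False
    matcher = nxiso.GraphMatcher(
        g_mol, g_frag, node_match=_node_match, edge_match=_edge_match
    )
    return any(True for _ in itertools.islice(matcher.subgraph_monomorphisms_iter(), 1))


def enumerate_connected_subgraphs(
    mol: MolecularGraph, max_edges: int
) -> list[Fragment]:
    """Every connected bond-induced subgraph with <= max_edges bonds.

    Exhaustive oracle: one fragment per distinct connected bond subset
    (fragments of the same isomorphism class occurring on different bond
    sets are listed separately; the total is at most 2^n - 1 for n
    bonds).  Exponential in bond count; intended for small molecules.
    """
    if max_edges < 1:
        raise MolGraphError("max_edges must be >= 1")
    return [
        fragment_from_bonds(mol, subset)
        for subset in _connected_bond_subsets(mol, max_edges)
    ]


def _connected_bond_subsets(
    mol: MolecularGraph, max_edges: int
) -> Iterator[frozenset[int]]:
    """Connected bond subsets of size <= max_edges (each yielded once).

    Canonical extension: a subset is only grown by bonds with id greater
    than allowed from the anchor, using the standard "enumerate by
    smallest root bond" scheme with a visited set for safety.
    """
    seen: set[frozenset[int]] = set()

    def adjacent(subset: frozenset[int]) -> set[int]:
        atoms = {a for bid in subset for a in mol.bond(bid).atoms()}
        out = set()
        for aid in atoms:
            for b in mol.incident_bonds(aid):
                if b.bond_id not in subset:
                    out.add(b.bond_id)
        return out

    stack: list[frozenset[int]] = []
    for b in mol.bonds:
        s = frozenset((b.bond_id,))
        seen.add(s)
        stack.append(s)
        yield s
    while stack:
        subset = stack.pop()
        if len(subset) >= max_edges:
            continue
        for bid in adjacent(subset):
            nxt = subset | {bid}
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
                yield nxt
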