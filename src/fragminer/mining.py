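"""Frequent maximal substructure mining over a compound library.

Mining grows a search tree per root fragment (each distinct single-bond
type in the library).  Every tree node carries a subID: the complete
list of embeddings of its fragment across the library, each embedding a
(molecule id, bond-id set) pair.  Because a node's subID is the full
embedding list of its fragment class, the subID's canonical string is a
perfect fragment identity, and a registry of visited subID strings lets
the depth-first search prune any node (and its whole subtree) that was
already explored from another branch or root — without changing the
reported fragment set.

A node is a potential reporting node (PRN) when no single-bond extension
of its fragment keeps the full set of supporting molecules; PRNs with
popularity (distinct supporting molecules) at or above the threshold are
reported.  Post-processing groups reports by supporting-molecule multiset
(FFID), keeps only the larger fragment when one report nests inside
another with the same FFID, and discards fragments that cut through an
aromatic ring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .molgraph import (
    Fragment,
    MolecularGraph,
    MolGraphError,
    enumerate_connected_subgraphs,
    fragment_from_bonds,
    subgraph_match,
)

logger = logging.getLogger(__name__)

DEFAULT_MAX_EDGES = 20


class MiningError(ValueError):
    pass


# ---------------------------------------------------------------------------
# subID / tree node
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubID:
    """Embedding list of a fragment: (mol_id, bond-id set) components."""

    components: tuple[tuple[str, frozenset[int]], ...]

    def __post_init__(self):
        if not self.components:
            raise MiningError("empty subID")
        sizes = {len(b) for _, b in self.components}
        if len(sizes) != 1:
            raise MiningError("subID components differ in bond count")

    @property
    def canonical_string(self) -> str:
        parts = sorted(
            (mid, tuple(sorted(bset))) for mid, bset in self.components
        )
        return ";".join(
            f"{mid}:{','.join(map(str, bids))}" for mid, bids in parts
        )

    @property
    def mol_ids(self) -> tuple[str, ...]:
        """Multiset of molecule ids (one entry per component)."""
        return tuple(sorted(mid for mid, _ in self.components))

    def support_set(self) -> frozenset[str]:
        return frozenset(mid for mid, _ in self.components)


def popularity(subid: SubID) -> int:
    """Number of distinct molecules supporting the fragment."""
    return len(subid.support_set())


@dataclass
class TreeNode:
    fragment: Fragment
    subid: SubID
    parent: "TreeNode | None" = None
    children: list = field(default_factory=list)
    is_prn: bool | None = None

    @property
    def popularity(self) -> int:
        return popularity(self.subid)


# ---------------------------------------------------------------------------
# Tree construction
# ---------------------------------------------------------------------------


def _check_library(library: Sequence[MolecularGraph]) -> dict[str, MolecularGraph]:
    if not library:
        raise MiningError("empty library")
    by_id = {m.mol_id: m for m in library}
    if len(by_id) != len(library):
        raise MiningError("duplicate mol_ids in library")
    return by_id


def init_roots(library: Sequence[MolecularGraph]) -> list[TreeNode]:
    """One root node per distinct single-bond fragment type.

    A root's subID lists every occurrence of that bond type in every
    molecule of the library.
    """
    _check_library(library)
    groups: dict[str, tuple[Fragment, list]] = {}
    for mol in library:
        for b in mol.bonds:
            frag = fragment_from_bonds(mol, [b.bond_id])
            key = frag.canonical_key
            if key not in groups:
                groups[key] = (frag, [])
            groups[key][1].append((mol.mol_id, frozenset((b.bond_id,))))
    if not groups:
        logger.warning("library contains no bonds; no root fragments")
        return []
    roots = []
    for key in sorted(groups):
        frag, comps = groups[key]
        roots.append(TreeNode(frag, SubID(tuple(comps))))
    return roots


def grow_node(
    node: TreeNode, library: Sequence[MolecularGraph]
) -> list[TreeNode]:
    """All one-bond extensions of a node, one child per fragment class.

    Every embedding is extended by every adjacent bond; the resulting
    embeddings are grouped by the canonical key of the induced fragment.
    Children are ordered by canonical key.
    """
    by_id = _check_library(library)
    groups: dict[str, tuple[Fragment, set]] = {}
    for mol_id, bset in node.subid.components:
        mol = by_id[mol_id]
        atoms = {a for bid in bset for a in mol.bond(bid).atoms()}
        adjacent = {
            b.bond_id
            for aid in atoms
            for b in mol.incident_bonds(aid)
            if b.bond_id not in bset
        }
        for bid in adjacent:
            new_bset = bset | {bid}
            frag = fragment_from_bonds(mol, new_bset)
            key = frag.canonical_key
            if key not in groups:
                groups[key] = (frag, set())
            groups[key][1].add((mol_id, frozenset(new_bset)))
    children = []
    for key in sorted(groups):
        frag, comps = groups[key]
        child = TreeNode(frag, SubID(tuple(sorted(comps))), parent=node)
        children.append(child)
    node.children = children
    return children


def is_prn(node: TreeNode, children: Sequence[TreeNode]) -> bool:
    """True when no child keeps the node's full supporting-molecule set.

    Such a node carries a maximal fragment for its support: every
    extension loses at least one supporting molecule.  Leaves are PRNs.
    """
    support = node.subid.support_set()
    return all(c.subid.support_set() != support for c in children)


# ---------------------------------------------------------------------------
# Mining driver
# ---------------------------------------------------------------------------


@dataclass
class MiningResult:
    reported: list[tuple[Fragment, SubID]]
    visited_nodes: int
    pruned_nodes: int
    threshold: int

    def fragment_keys(self) -> set[str]:
        return {f.canonical_key for f, _ in self.reported}


def mine(
    library: Sequence[MolecularGraph],
    t: int = 2,
    max_edges: int = DEFAULT_MAX_EDGES,
    prune: bool = True,
) -> MiningResult:
    """Depth-first maximal frequent fragment mining.

    Reports every PRN fragment with popularity >= t, deduplicated by
    canonical key.  With ``prune`` on, a node whose subID string is
    already in the visited registry is cut off together with its
    subtree; the reported set is identical either way (the registry key
    is a perfect fragment identity).
    """
    _check_library(library)
    if t < 2:
        raise MiningError("popularity threshold t must be >= 2")
    registry: set[str] = set()
    reported: dict[str, tuple[Fragment, SubID]] = {}
    visited = 0
    pruned = 0

    stack = list(reversed(init_roots(library)))
    while stack:
        node = stack.pop()
        sid = node.subid.canonical_string
        if prune and sid in registry:
            pruned += 1
            continue
        registry.add(sid)
        visited += 1
        # support is antimonotone in fragment growth: a node below the
        # threshold has no reportable descendant, so it is undividable
        if node.popularity < t or node.fragment.n_edges >= max_edges:
            children: list[TreeNode] = []
        else:
            children = grow_node(node, library)
        node.is_prn = is_prn(node, children)
        if node.is_prn and node.popularity >= t:
            reported.setdefault(node.fragment.canonical_key, (node.fragment, node.subid))
        for child in reversed(children):
            if child.popularity >= t:
                stack.append(child)
    return MiningResult(
        reported=[reported[k] for k in sorted(reported)],
        visited_nodes=visited,
        pruned_nodes=pruned,
        threshold=t,
    )


# ---------------------------------------------------------------------------
# FFID collapse
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FFID:
    """subID with bond ids removed: the supporting-molecule multiset."""

    mol_ids: tuple[str, ...]

    @property
    def popularity(self) -> int:
        return len(set(self.mol_ids))


def _is_subfragment(small: Fragment, large: Fragment) -> bool:
    if small.n_edges >= large.n_edges:
        return False
    return bool(subgraph_match(small, large))


def collapse_ffid(
    reported: Sequence[tuple[Fragment, SubID]]
) -> list[tuple[Fragment, FFID]]:
    """Group reports by supporting-molecule multiset and drop nested ones.

    Within one FFID group a fragment contained in a larger fragment of
    the same group is removed; mutually non-nested fragments all stay.
    """
    if not reported:
        raise MiningError("nothing to collapse")
    groups: dict[tuple[str, ...], list[Fragment]] = {}
    for frag, subid in reported:
        groups.setdefault(subid.mol_ids, []).append(frag)
    out: list[tuple[Fragment, FFID]] = []
    for mol_ids in sorted(groups):
        frags = groups[mol_ids]
        kept = [
            f
            for f in frags
            if not any(_is_subfragment(f, g) for g in frags if g is not f)
        ]
        ffid = FFID(mol_ids)
        out.extend((f, ffid) for f in sorted(kept, key=lambda f: f.canonical_key))
    return out


# ---------------------------------------------------------------------------
# Chemical integrity
# ---------------------------------------------------------------------------


def _smallest_aromatic_ring(mol: MolecularGraph, bond_id: int) -> frozenset[int] | None:
    """Bond ids of the smallest all-aromatic ring through a bond, if any."""
    g = nx.Graph()
    for b in mol.bonds:
        if b.order == "aromatic":
            g.add_edge(b.a1, b.a2, bond_id=b.bond_id)
    bond = mol.bond(bond_id)
    if not g.has_edge(bond.a1, bond.a2):
        return None
    g.remove_edge(bond.a1, bond.a2)
    try:
        path = nx.shortest_path(g, bond.a1, bond.a2)
    except (nx.NetworkXNoPath, nx.NodeNotFound):
        return None
    ring = {bond_id}
    for u, v in zip(path, path[1:]):
        ring.add(g.edges[u, v]["bond_id"])
    return frozenset(ring)


def integrity_filter(
    reported: Sequence[tuple[Fragment, SubID]],
    library: Sequence[MolecularGraph],
) -> list[tuple[Fragment, SubID]]:
    """Discard fragments that break an aromatic ring.

    A fragment is removed when, in a supporting molecule, it contains an
    aromatic bond whose smallest aromatic ring is not fully inside the
    matched bond set.
    """
    by_id = _check_library(library)
    out = []
    for frag, subid in reported:
        ok = True
        for mol_id, bset in subid.components:
            mol = by_id[mol_id]
            for bid in bset:
                if mol.bond(bid).order != "aromatic":
                    continue
                ring = _smallest_aromatic_ring(mol, bid)
                if ring is not None and not ring <= bset:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            out.append((frag, subid))
    return out


# ---------------------------------------------------------------------------
# Exhaustive oracle (independent of the tree machinery)
# ---------------------------------------------------------------------------


def exhaustive_maximal_frequent(
    library: Sequence[MolecularGraph],
    t: int = 2,
    max_edges: int = DEFAULT_MAX_EDGES,
) -> dict[str, Fragment]:
    """Brute-force maximal frequent fragments, keyed by canonical key.

    Enumerates every connected bond subset of every molecule, counts the
    supporting molecules per fragment class, keeps classes with support
    >= t, then removes any class contained in a larger kept class with
    the identical support set.  Exponential; for small libraries only.
    """
    _check_library(library)
    if t < 2:
        raise MiningError("popularity threshold t must be >= 2")
    support: dict[str, set[str]] = {}
    rep: dict[str, Fragment] = {}
    for mol in library:
        for frag in enumerate_connected_subgraphs(mol, max_edges):
            key = frag.canonical_key
            support.setdefault(key, set()).add(mol.mol_id)
            rep.setdefault(key, frag)
    frequent = {k for k, s in support.items() if len(s) >= t}
    kept: dict[str, Fragment] = {}
    for k in frequent:
        f = rep[k]
        dominated = any(
            support[g] == support[k] and _is_subfragment(f, rep[g])
            for g in frequent
            if g != k
        )
        if not dominated:
            kept[k] = f
    return kept
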