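"""Seeded generator of compound libraries with planted ground truth.

Emulates a focused screening library: a few hundred molecules assembled
from a catalog of named chemical fragments (aromatic and aliphatic
rings, common functional groups), with a chosen subset of "causal"
fragments planted preferentially into active molecules.  Activities
follow an additive model on fragment content — actives draw
pIC50 = baseline + sum(effect * presence) + Gaussian noise and get
IC50 = 10^(9 - pIC50) nM, inactives draw IC50 log-uniformly above the
10 uM activity cutoff — so every downstream stage (mining, descriptors,
classification, regression, enrichment, rule discovery) can be checked
against the manifest of what was planted.

Molecules are built directly as labeled graphs; a small valence table
(C<=4, N<=3, O<=2, S<=6, aromatic bonds counting 1.5) guards every
attachment, so generated structures are chemically sane and survive
round-trips through standard formats.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Sequence

from .chemio import ActivityRecord
from .molgraph import Atom, Bond, Fragment, MolecularGraph

VALENCE = {"C": 4, "N": 3, "O": 2, "S": 6}
# aromatic ring bonds count 1.5 each; aromatic N/O/S get an effective
# allowance of exactly two ring bonds (3.0) and no substituents
AROMATIC_VALENCE = {"C": 4, "N": 3, "O": 3, "S": 3}
ORDER_VALUE = {"single": 1.0, "double": 2.0, "triple": 3.0, "aromatic": 1.5}


def allowed_valence(element: str, aromatic: bool) -> float:
    table = AROMATIC_VALENCE if aromatic else VALENCE
    if element not in table:
        raise SyntheticError(f"element {element} outside the valence table")
    return table[element]
ACTIVITY_CUTOFF_NM = 10_000.0


class SyntheticError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Fragment catalog
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FragmentTemplate:
    """A named catalog fragment with preferred attachment atoms."""

    name: str
    atoms: tuple[tuple[str, int, bool], ...]  # (element, charge, aromatic)
    bonds: tuple[tuple[int, int, str], ...]  # (local a1, local a2, order)
    attach: tuple[int, ...]  # local atom indices usable as junctions

    def as_fragment(self) -> Fragment:
        atoms = [Atom(i, e, c, ar) for i, (e, c, ar) in enumerate(self.atoms)]
        bonds = [Bond(i, a, b, o) for i, (a, b, o) in enumerate(self.bonds)]
        return Fragment(atoms, bonds)


def _ring(name: str, elems: Sequence[str], aromatic: bool) -> FragmentTemplate:
    n = len(elems)
    order = "aromatic" if aromatic else "single"
    atoms = tuple((e, 0, aromatic) for e in elems)
    bonds = tuple((i, (i + 1) % n, order) for i in range(n))
    # carbons with a free valence slot are junction candidates
    attach = tuple(
        i for i, e in enumerate(elems)
        if e == "C" and (allowed_valence("C", aromatic) - 2 * ORDER_VALUE[order]) >= 1
    )
    return FragmentTemplate(name, atoms, bonds, attach)


def _chain(
    name: str,
    elems: Sequence[str],
    orders: Sequence[str],
    attach: Sequence[int],
) -> FragmentTemplate:
    atoms = tuple((e, 0, False) for e in elems)
    bonds = tuple((i, i + 1, o) for i, o in enumerate(orders))
    return FragmentTemplate(name, atoms, bonds, tuple(attach))


# functional groups with branched (non-path) topology, built explicitly
def _branched_templates() -> dict[str, FragmentTemplate]:
    out = {}
    # amide: C-C(=O)-N-C
    out["amide"] = FragmentTemplate(
        "amide",
        (("C", 0, False), ("C", 0, False), ("O", 0, False), ("N", 0, False), ("C", 0, False)),
        ((0, 1, "single"), (1, 2, "double"), (1, 3, "single"), (3, 4, "single")),
        (0, 4),
    )
    # ester: C-C(=O)-O-C
    out["ester"] = FragmentTemplate(
        "ester",
        (("C", 0, False), ("C", 0, False), ("O", 0, False), ("O", 0, False), ("C", 0, False)),
        ((0, 1, "single"), (1, 2, "double"), (1, 3, "single"), (3, 4, "single")),
        (0, 4),
    )
    # sulfonyl: C-S(=O)(=O)-C
    out["sulfonyl"] = FragmentTemplate(
        "sulfonyl",
        (("C", 0, False), ("S", 0, False), ("O", 0, False), ("O", 0, False), ("C", 0, False)),
        ((0, 1, "single"), (1, 2, "double"), (1, 3, "double"), (1, 4, "single")),
        (0, 4),
    )
    # ketone: C-C(=O)-C
    out["ketone"] = FragmentTemplate(
        "ketone",
        (("C", 0, False), ("C", 0, False), ("O", 0, False), ("C", 0, False)),
        ((0, 1, "single"), (1, 2, "double"), (1, 3, "single")),
        (0, 3),
    )
    # urea: N-C(=O)-N
    out["urea"] = FragmentTemplate(
        "urea",
        (("N", 0, False), ("C", 0, False), ("O", 0, False), ("N", 0, False)),
        ((0, 1, "single"), (1, 2, "double"), (1, 3, "single")),
        (0, 3),
    )
    # carboxylic acid: C-C(=O)-O (terminal O carries the suppressed H)
    out["carboxyl"] = FragmentTemplate(
        "carboxyl",
        (("C", 0, False), ("C", 0, False), ("O", 0, False), ("O", 0, False)),
        ((0, 1, "single"), (1, 2, "double"), (1, 3, "single")),
        (0,),
    )
    return out


_BASE_CATALOG: dict[str, FragmentTemplate] | None = None


def catalog() -> dict[str, FragmentTemplate]:
    """Thirty named fragments: rings and functional groups.

    Chosen to be mutually distinguishable under subgraph matching: no
    plain carbon chains (those would fire inside every linker), and the
    heteroatom patterns rarely occur by accident in assembled decoys.
    """
    global _BASE_CATALOG
    if _BASE_CATALOG is None:
        cat: dict[str, FragmentTemplate] = {}
        for t in [
            _ring("benzene", "CCCCCC", True),
            _ring("pyridine", "NCCCCC", True),
            _ring("pyrimidine", "NCNCCC", True),
            _ring("pyrazine", "NCCNCC", True),
            _ring("pyridazine", "NNCCCC", True),
            _ring("triazine", "NCNCNC", True),
            _ring("furan", "OCCCC", True),
            _ring("thiophene", "SCCCC", True),
            _ring("pyrrole", "NCCCC", True),
            _ring("imidazole", "NCNCC", True),
            _ring("oxazole", "OCNCC", True),
            _ring("thiazole", "SCNCC", True),
            _ring("cyclopentane", "CCCCC", False),
            _ring("cyclohexane", "CCCCCC", False),
            _ring("oxolane", "OCCCC", False),
            _ring("piperidine", "NCCCCC", False),
            _ring("morpholine", "OCCNCC", False),
            _ring("piperazine", "NCCNCC", False),
            _ring("oxane", "OCCCCC", False),
            _ring("thiolane", "SCCCC", False),
            _chain("nitrile", "CCN", ["single", "triple"], [0]),
            _chain("ether", "COC", ["single", "single"], [0, 2]),
            _chain("thioether", "CSC", ["single", "single"], [0, 2]),
            _chain("sec-amine", "CNC", ["single", "single"], [0, 2]),
        ]:
            cat[t.name] = t
        cat.update(_branched_templates())
        _BASE_CATALOG = cat
    return dict(_BASE_CATALOG)


# ---------------------------------------------------------------------------
# Molecule assembly
# ---------------------------------------------------------------------------


class MoleculeBuilder:
    """Grow a molecule fragment by fragment, respecting valences."""

    def __init__(self, mol_id: str):
        self.mol_id = mol_id
        self.atoms: list[Atom] = []
        self.bonds: list[Bond] = []
        self._used: dict[int, float] = {}

    def free_valence(self, atom_id: int) -> float:
        a = self.atoms[atom_id]
        return allowed_valence(a.element, a.aromatic) - self._used.get(atom_id, 0.0)

    def add_atom(self, element: str, charge: int = 0, aromatic: bool = False) -> int:
        aid = len(self.atoms)
        self.atoms.append(Atom(aid, element, charge, aromatic))
        self._used.setdefault(aid, 0.0)
        return aid

    def add_bond(self, a1: int, a2: int, order: str = "single") -> int:
        v = ORDER_VALUE[order]
        if self.free_valence(a1) < v or self.free_valence(a2) < v:
            raise SyntheticError("valence overflow")
        bid = len(self.bonds)
        self.bonds.append(Bond(bid, a1, a2, order))
        self._used[a1] = self._used.get(a1, 0.0) + v
        self._used[a2] = self._used.get(a2, 0.0) + v
        return bid

    def add_template(self, tpl: FragmentTemplate) -> list[int]:
        """Insert a catalog fragment; returns its new atom ids."""
        mapping = []
        for e, c, ar in tpl.atoms:
            mapping.append(self.add_atom(e, c, ar))
        for a, b, o in tpl.bonds:
            self.add_bond(mapping[a], mapping[b], o)
        return mapping

    def attachment_points(self, atom_ids: Sequence[int], tpl: FragmentTemplate) -> list[int]:
        return [
            atom_ids[i] for i in tpl.attach if self.free_valence(atom_ids[i]) >= 1
        ]

    def join_linker(self, a1: int, a2: int, n_carbons: int) -> list[int]:
        """Connect two atoms through a chain of n carbons (n >= 1)."""
        prev = a1
        chain = []
        for _ in range(n_carbons):
            c = self.add_atom("C")
            self.add_bond(prev, c)
            chain.append(c)
            prev = c
        self.add_bond(prev, a2)
        return chain

    def build(self, properties: dict | None = None) -> MolecularGraph:
        return MolecularGraph(self.mol_id, self.atoms, self.bonds, properties)


def validate_molecule(mol: MolecularGraph) -> None:
    """Valence sanity, connectivity, hydrogen suppression."""
    used: dict[int, float] = {a.atom_id: 0.0 for a in mol.atoms}
    for b in mol.bonds:
        v = ORDER_VALUE[b.order]
        used[b.a1] += v
        used[b.a2] += v
    for a in mol.atoms:
        if used[a.atom_id] > allowed_valence(a.element, a.aromatic) + 1e-9:
            raise SyntheticError(
                f"{mol.mol_id}: atom {a.atom_id} ({a.element}) exceeds valence"
            )
    if mol.n_atoms > 1:
        seen = set()
        stack = [mol.atoms[0].atom_id]
        seen.add(stack[0])
        while stack:
            aid = stack.pop()
            for b in mol.incident_bonds(aid):
                for nb in b.atoms():
                    if nb not in seen:
                        seen.add(nb)
                        stack.append(nb)
        if len(seen) != mol.n_atoms:
            raise SyntheticError(f"{mol.mol_id} is disconnected")


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------


@dataclass
class PlantedRule:
    pair: tuple[str, str]  # catalog fragment names
    relation: str  # "linker" | "direct"
    linker_carbons: int = 1  # used when relation == "linker"
    prevalence: float = 0.6  # fraction of actives built through this rule


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_molecules: int = 200
    causal_fragments: dict[str, float] = field(
        default_factory=lambda: {
            "pyrimidine": 1.5,
            "thiazole": 1.2,
            "sulfonyl": 1.0,
            "morpholine": 0.8,
            "amide": 0.6,
        }
    )
    decoy_fragments: list[str] | None = None  # default: rest of the catalog
    planted_rules: list[PlantedRule] = field(default_factory=list)
    baseline_pIC50: float = 5.5
    noise_sd: float = 0.2
    active_prevalence: float = 0.5
    causal_rate: float = 0.5  # per-fragment plant rate in an active
    causal_in_inactive_rate: float = 0.05
    max_decoys: int = 2
    decorate_rate: float = 0.5  # chance of a random methyl/ethyl decoration

    def __post_init__(self):
        if self.n_molecules < 10:
            raise SyntheticError("n_molecules must be >= 10")
        if self.noise_sd < 0:
            raise SyntheticError("noise_sd must be >= 0")
        if not (0 < self.active_prevalence < 1):
            raise SyntheticError("active_prevalence must be in (0, 1)")
        cat = catalog()
        for name in self.causal_fragments:
            if name not in cat:
                raise SyntheticError(f"unknown causal fragment {name!r}")
        for rule in self.planted_rules:
            for name in rule.pair:
                if name not in cat:
                    raise SyntheticError(f"rule references absent fragment {name!r}")
            if rule.relation not in ("linker", "direct"):
                raise SyntheticError(f"unsupported planted relation {rule.relation!r}")


def _assemble(
    mol_id: str,
    fragment_names: Sequence[str],
    rng: random.Random,
    rule: PlantedRule | None,
    decorate_rate: float,
) -> MolecularGraph:
    cat = catalog()
    builder = MoleculeBuilder(mol_id)
    placed: list[tuple[str, list[int]]] = []
    names = list(fragment_names)
    if rule is not None:
        # the rule pair goes in first, joined as prescribed
        a, b = rule.pair
        ids_a = builder.add_template(cat[a])
        ids_b = builder.add_template(cat[b])
        pa = rng.choice(builder.attachment_points(ids_a, cat[a]))
        pb = rng.choice(builder.attachment_points(ids_b, cat[b]))
        if rule.relation == "direct":
            builder.add_bond(pa, pb)
        else:
            builder.join_linker(pa, pb, rule.linker_carbons)
        placed.extend([(a, ids_a), (b, ids_b)])
        names = [n for n in names if n not in rule.pair]
    for name in names:
        tpl = cat[name]
        ids = builder.add_template(tpl)
        if placed:
            host_name, host_ids = rng.choice(placed)
            host_pts = builder.attachment_points(host_ids, cat[host_name])
            new_pts = builder.attachment_points(ids, tpl)
            if host_pts and new_pts:
                # join through a short carbon linker (keeps catalog
                # fragments from colliding into accidental superstructures)
                builder.join_linker(
                    rng.choice(host_pts), rng.choice(new_pts), rng.randint(1, 3)
                )
            else:
                # no free junction: fall back to a fresh linker carbon off
                # any atom with capacity
                free = [a.atom_id for a in builder.atoms if builder.free_valence(a.atom_id) >= 1]
                anchor = rng.choice([i for i in free if i in ids] or free)
                others = [i for i in free if i not in ids]
                if others:
                    builder.join_linker(rng.choice(others), anchor, 2)
        placed.append((name, ids))
    if rng.random() < decorate_rate:
        free = [a.atom_id for a in builder.atoms if builder.free_valence(a.atom_id) >= 1]
        if free:
            anchor = rng.choice(free)
            prev = anchor
            for _ in range(rng.randint(1, 2)):
                c = builder.add_atom("C")
                builder.add_bond(prev, c)
                prev = c
    mol = builder.build()
    validate_molecule(mol)
    return mol


def generate_library(
    config: GeneratorConfig,
) -> tuple[list[MolecularGraph], list[ActivityRecord], dict]:
    """Generate molecules, activity records and the ground-truth manifest.

    Fully reproducible from ``config.seed``.  Actives carry the planted
    causal fragments and IC50 values from the additive pIC50 model;
    inactives draw IC50 log-uniformly from (10^4, 10^6] nM.
    """
    rng = random.Random(config.seed)
    cat = catalog()
    causal = sorted(config.causal_fragments)
    decoys = (
        sorted(config.decoy_fragments)
        if config.decoy_fragments is not None
        else sorted(set(cat) - set(causal))
    )
    library: list[MolecularGraph] = []
    records: list[ActivityRecord] = []
    manifest_mols = []
    for i in range(config.n_molecules):
        mol_id = f"M{i:04d}"
        active = rng.random() < config.active_prevalence
        rule = None
        if active:
            planted = [n for n in causal if rng.random() < config.causal_rate]
            if not planted:
                planted = [rng.choice(causal)]
            for r in config.planted_rules:
                if rng.random() < r.prevalence:
                    rule = r
                    for n in r.pair:
                        if n not in planted and n in causal:
                            planted.append(n)
                    break
        else:
            planted = [n for n in causal if rng.random() < config.causal_in_inactive_rate]
        n_dec = rng.randint(0 if planted else 1, config.max_decoys)
        planted_decoys = rng.sample(decoys, min(n_dec, len(decoys)))
        all_names = planted + planted_decoys
        if rule is not None:
            missing = [n for n in rule.pair if n not in all_names]
            all_names = missing + all_names
        mol = _assemble(mol_id, all_names, rng, rule, config.decorate_rate)
        if active:
            pic50 = config.baseline_pIC50 + sum(
                config.causal_fragments[n] for n in planted if n in config.causal_fragments
            ) + rng.gauss(0.0, config.noise_sd)
            ic50 = min(10.0 ** (9.0 - pic50), ACTIVITY_CUTOFF_NM)
        else:
            pic50 = None
            ic50 = 10.0 ** (4.0 + rng.random() * 2.0)
            if ic50 <= ACTIVITY_CUTOFF_NM:
                ic50 = ACTIVITY_CUTOFF_NM * 1.0001
        mol.properties["IC50_nM"] = f"{ic50:.6g}"
        library.append(mol)
        records.append(ActivityRecord(mol_id, ic50_nM=float(f"{ic50:.6g}")))
        manifest_mols.append(
            {
                "mol_id": mol_id,
                "active": active,
                "planted": sorted(all_names),
                "planted_causal": sorted(n for n in planted if n in config.causal_fragments),
                "rule": None
                if rule is None
                else {
                    "pair": list(rule.pair),
                    "relation": rule.relation,
                    "linker_carbons": rule.linker_carbons,
                },
                "pIC50": pic50,
                "ic50_nM": float(f"{ic50:.6g}"),
            }
        )
    manifest = {
        "seed": config.seed,
        "n_molecules": config.n_molecules,
        "causal_fragments": dict(config.causal_fragments),
        "baseline_pIC50": config.baseline_pIC50,
        "noise_sd": config.noise_sd,
        "active_prevalence": config.active_prevalence,
        "catalog_keys": {n: cat[n].as_fragment().canonical_key for n in sorted(cat)},
        "molecules": manifest_mols,
    }
    return library, records, manifest


# ---------------------------------------------------------------------------
# Benchmark fixtures
# ---------------------------------------------------------------------------


def worked_example_library() -> list[MolecularGraph]:
    """Four small molecules whose C-C single-bond root has popularity 4.

    Molecule D contributes two C-C bonds, the others one each, so the
    root subID has five components from four molecules.
    """
    # A: C-C-O   (bond 0 is the C-C bond, "n")
    a = MolecularGraph(
        "A",
        [Atom(0, "C"), Atom(1, "C"), Atom(2, "O")],
        [Bond(0, 0, 1), Bond(1, 1, 2)],
    )
    # B: C-C=C   (bond 0 is the C-C single bond, "m")
    b = MolecularGraph(
        "B",
        [Atom(0, "C"), Atom(1, "C"), Atom(2, "C")],
        [Bond(0, 0, 1), Bond(1, 1, 2, "double")],
    )
    # C: C-C-N   (bond 0 is the C-C bond, "h")
    c = MolecularGraph(
        "C",
        [Atom(0, "C"), Atom(1, "C"), Atom(2, "N")],
        [Bond(0, 0, 1), Bond(1, 1, 2)],
    )
    # D: C-C-C   (bonds 0 and 1 both C-C, "e" and "k")
    d = MolecularGraph(
        "D",
        [Atom(0, "C"), Atom(1, "C"), Atom(2, "C")],
        [Bond(0, 0, 1), Bond(1, 1, 2)],
    )
    return [a, b, c, d]


def random_small_library(
    seed: int, max_molecules: int = 25, max_bonds: int = 10
) -> list[MolecularGraph]:
    """A random library small enough for the brute-force mining oracle."""
    rng = random.Random(seed)
    elems = ["C", "C", "C", "N", "O", "S"]
    orders = ["single", "single", "single", "double"]
    n_mols = rng.randint(5, max_molecules)
    library = []
    for i in range(n_mols):
        n_bonds = rng.randint(2, max_bonds)
        builder = MoleculeBuilder(f"m{i}")
        builder.add_atom(rng.choice(elems))
        made = 0
        tries = 0
        while made < n_bonds and tries < 20 * n_bonds:
            tries += 1
            order = rng.choice(orders)
            v = ORDER_VALUE[order]
            free = [a.atom_id for a in builder.atoms if builder.free_valence(a.atom_id) >= v]
            if not free:
                break
            if len(builder.atoms) > 2 and rng.random() < 0.2:
                pairs = [
                    (x, y)
                    for xi, x in enumerate(free)
                    for y in free[xi + 1:]
                    if not any({bb.a1, bb.a2} == {x, y} for bb in builder.bonds)
                ]
                if pairs:
                    x, y = rng.choice(pairs)
                    builder.add_bond(x, y, order)
                    made += 1
                    continue
            src = rng.choice(free)
            elem = rng.choice(elems)
            if VALENCE[elem] < v:
                continue
            new = builder.add_atom(elem)
            builder.add_bond(src, new, order)
            made += 1
        mol = builder.build()
        validate_molecule(mol)
        library.append(mol)
    return library


def make_benchmark_suite(seed: int = 0) -> dict:
    """Named small libraries exercising each pipeline stage.

    Keys: ``worked_example`` (the 4-molecule root/popularity fixture),
    ``mining_oracle`` (brute-force-tractable random libraries),
    ``qsar_classification`` / ``qsar_regression`` (fragment-driven
    activities), ``rule_recovery`` (a planted linker rule).
    """
    rng = random.Random(seed)

    def sub(k: int) -> int:
        return (seed * 1_000_003 + k) % (2**31 - 1)

    classification_cfg = GeneratorConfig(
        seed=sub(1),
        n_molecules=600,
        active_prevalence=0.5,
        noise_sd=0.2,
    )
    regression_cfg = GeneratorConfig(
        seed=sub(2),
        n_molecules=300,
        causal_fragments={"pyrimidine": 1.5, "sulfonyl": 1.0},
        baseline_pIC50=5.5,
        noise_sd=0.2,
        active_prevalence=0.999,  # regression uses the active rows only
        causal_rate=0.5,
    )
    rule_cfg = GeneratorConfig(
        seed=sub(3),
        n_molecules=80,
        causal_fragments={"pyrimidine": 1.2, "thiazole": 1.0},
        planted_rules=[
            PlantedRule(("pyrimidine", "thiazole"), "linker", linker_carbons=1,
                        prevalence=0.7)
        ],
        active_prevalence=0.5,
    )
    return {
        "worked_example": worked_example_library(),
        "mining_oracle": [
            random_small_library(sub(100 + i)) for i in range(5)
        ],
        "qsar_classification": classification_cfg,
        "qsar_regression": regression_cfg,
        "rule_recovery": rule_cfg,
    }
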