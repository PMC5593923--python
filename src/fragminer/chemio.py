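"""Reading, writing and preprocessing of compound libraries.

Structures travel as SDF (V2000 mol blocks) or SMILES tables (TSV with
columns id, smiles and optional activity columns); RDKit does the
parsing and writing.  Preprocessing covers salt stripping (keep the
largest connected component), duplicate removal by canonical identity,
and IC50 handling: a 10,000 nM cutoff splits actives from inactives for
classification, and rows at or below the cutoff are converted to pIC50
(-log10 of the molar concentration) for regression.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit import RDLogger

from .molgraph import (
    Atom,
    Bond,
    Fragment,
    MolecularGraph,
    MolGraphError,
    fragment_from_bonds,
)

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

IC50_FIELD = "IC50_nM"
ACTIVITY_CUTOFF_NM = 10_000.0

_ORDER_FROM_RDKIT = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}
_ORDER_TO_RDKIT = {v: k for k, v in _ORDER_FROM_RDKIT.items()}


class ChemIOError(ValueError):
    """Raised on unusable chemical input."""


@dataclass
class ActivityRecord:
    """Per-compound activity: raw IC50 (nM) and derived label / pIC50."""

    mol_id: str
    ic50_nM: float | None = None
    label: int | None = None
    pIC50: float | None = None

    def __post_init__(self):
        if self.label is not None and self.label not in (0, 1):
            raise ChemIOError(f"label must be 0/1, got {self.label}")


# ---------------------------------------------------------------------------
# RDKit conversion
# ---------------------------------------------------------------------------


def mol_from_rdkit(
    rdmol: Chem.Mol, mol_id: str, properties: dict | None = None
) -> MolecularGraph:
    props = dict(properties or {})
    for name in rdmol.GetPropNames():
        props.setdefault(name, rdmol.GetProp(name))
    atoms = []
    for a in rdmol.GetAtoms():
        if a.GetSymbol() == "H":
            continue
        atoms.append(
            Atom(a.GetIdx(), a.GetSymbol(), a.GetFormalCharge(), a.GetIsAromatic())
        )
    kept = {a.atom_id for a in atoms}
    bonds = []
    for b in rdmol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i not in kept or j not in kept:
            continue
        order = _ORDER_FROM_RDKIT.get(b.GetBondType())
        if order is None:
            raise ChemIOError(f"unsupported bond type {b.GetBondType()}")
        bonds.append(Bond(b.GetIdx(), i, j, order))
    return MolecularGraph(mol_id, atoms, bonds, props)


def _five_ring_nh_atoms(mol: MolecularGraph) -> set[int]:
    """Atom ids of pyrrole-type nitrogens that must carry a ring N-H.

    In a five-membered all-aromatic ring with no O/S to donate the lone
    pair, exactly one nitrogen is the donor; the lowest-id candidate is
    chosen so the assignment is deterministic.
    """
    import networkx as nx

    g = nx.Graph()
    for b in mol.bonds:
        if b.order == "aromatic":
            g.add_edge(b.a1, b.a2)
    donors: set[int] = set()
    for ring in nx.cycle_basis(g):
        if len(ring) != 5:
            continue
        elems = {aid: mol.atom(aid).element for aid in ring}
        if any(e in ("O", "S") for e in elems.values()):
            continue
        candidates = sorted(
            aid
            for aid in ring
            if elems[aid] == "N"
            and mol.atom(aid).charge == 0
            and len(mol.incident_bonds(aid)) == 2
        )
        if candidates:
            donors.add(candidates[0])
    return donors


def mol_to_rdkit(mol: MolecularGraph) -> Chem.Mol:
    rw = Chem.RWMol()
    idx = {}
    nh = _five_ring_nh_atoms(mol)
    for a in mol.atoms:
        ra = Chem.Atom(a.element)
        ra.SetFormalCharge(a.charge)
        ra.SetIsAromatic(a.aromatic)
        if a.atom_id in nh:
            ra.SetNumExplicitHs(1)
        idx[a.atom_id] = rw.AddAtom(ra)
    for b in mol.bonds:
        rw.AddBond(idx[b.a1], idx[b.a2], _ORDER_TO_RDKIT[b.order])
    m = rw.GetMol()
    try:
        Chem.SanitizeMol(m)
    except Exception:
        # partial aromatic systems etc.: keep the explicit flags as given
        Chem.SanitizeMol(
            m,
            Chem.SanitizeFlags.SANITIZE_FINDRADICALS
            | Chem.SanitizeFlags.SANITIZE_SETCONJUGATION,
            catchErrors=True,
        )
    return m


def to_smiles(obj: MolecularGraph | Fragment) -> str:
    """SMILES rendering for reports; falls back to the canonical key."""
    try:
        if isinstance(obj, Fragment):
            mg = MolecularGraph("frag", obj.atoms, obj.bonds)
        else:
            mg = obj
        return Chem.MolToSmiles(mol_to_rdkit(mg))
    except Exception:
        if isinstance(obj, Fragment):
            return obj.canonical_key
        return mol_canonical_key(obj)


# ---------------------------------------------------------------------------
# Library I/O
# ---------------------------------------------------------------------------


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = path.suffix.lower()
    if suffix in (".sdf", ".sd", ".mol"):
        return "sdf"
    return "smiles"


def read_library(
    path: str | Path,
    fmt: str | None = None,
    activity_field: str = IC50_FIELD,
) -> list[MolecularGraph]:
    """Read an SDF or SMILES-table library into molecular graphs.

    Malformed records are skipped with a logged warning; an input with
    zero valid records is an error.  Activity values found in SDF data
    fields / table columns land in ``properties[activity_field]``.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    mols: list[MolecularGraph] = []
    n_bad = 0
    if fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=True)
        for i, rdmol in enumerate(supplier):
            if rdmol is None:
                n_bad += 1
                logger.warning("skipping malformed SDF record %d in %s", i, path)
                continue
            mol_id = (
                rdmol.GetProp("_Name").strip()
                if rdmol.HasProp("_Name") and rdmol.GetProp("_Name").strip()
                else f"mol{i}"
            )
            try:
                mols.append(mol_from_rdkit(rdmol, mol_id))
            except (ChemIOError, MolGraphError) as exc:
                n_bad += 1
                logger.warning("skipping record %s: %s", mol_id, exc)
    else:
        with open(path) as fh:
            for i, line in enumerate(fh):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if i == 0 and parts[0].lower() in ("id", "mol_id"):
                    continue
                if len(parts) < 2:
                    n_bad += 1
                    logger.warning("skipping short line %d in %s", i + 1, path)
                    continue
                mol_id, smiles = parts[0], parts[1]
                rdmol = Chem.MolFromSmiles(smiles)
                if rdmol is None:
                    n_bad += 1
                    logger.warning("skipping unparsable SMILES %r (%s)", smiles, mol_id)
                    continue
                props = {}
                if len(parts) >= 3 and parts[2].strip():
                    props[activity_field] = parts[2].strip()
                try:
                    mols.append(mol_from_rdkit(rdmol, mol_id, props))
                except (ChemIOError, MolGraphError) as exc:
                    n_bad += 1
                    logger.warning("skipping record %s: %s", mol_id, exc)
    if not mols:
        raise ChemIOError(f"no valid records in {path} ({n_bad} malformed)")
    if n_bad:
        logger.warning("%d malformed records skipped in %s", n_bad, path)
    return mols


def write_library(
    library: Sequence[MolecularGraph],
    path: str | Path,
    fmt: str | None = None,
    activity_field: str = IC50_FIELD,
) -> None:
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "sdf":
        writer = Chem.SDWriter(str(path))
        try:
            for mol in library:
                rdmol = mol_to_rdkit(mol)
                rdmol.SetProp("_Name", str(mol.mol_id))
                for k, v in mol.properties.items():
                    rdmol.SetProp(str(k), str(v))
                writer.write(rdmol)
        finally:
            writer.close()
    else:
        with open(path, "w") as fh:
            fh.write(f"id\tsmiles\t{activity_field}\n")
            for mol in library:
                act = mol.properties.get(activity_field, "")
                fh.write(f"{mol.mol_id}\t{to_smiles(mol)}\t{act}\n")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def _components(mol: MolecularGraph) -> list[tuple[list[Atom], list[Bond]]]:
    parent = {a.atom_id: a.atom_id for a in mol.atoms}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for b in mol.bonds:
        ra, rb = find(b.a1), find(b.a2)
        if ra != rb:
            parent[ra] = rb
    groups: dict[int, tuple[list[Atom], list[Bond]]] = {}
    for a in mol.atoms:
        groups.setdefault(find(a.atom_id), ([], []))[0].append(a)
    for b in mol.bonds:
        groups[find(b.a1)][1].append(b)
    return list(groups.values())


def _component_key(atoms: list[Atom], bonds: list[Bond]) -> str:
    if bonds:
        return Fragment(atoms, bonds).canonical_key
    return "atom:" + ";".join(
        sorted(f"{a.element}{'%+d' % a.charge if a.charge else ''}" for a in atoms)
    )


def strip_salt(mol: MolecularGraph) -> MolecularGraph:
    """Keep the connected component with the most heavy atoms.

    Ties break on atom count, then bond count, then the lexicographically
    smallest canonical key — deterministic regardless of input order.
    """
    comps = _components(mol)
    if len(comps) <= 1:
        return mol
    best = min(
        comps,
        key=lambda c: (-len(c[0]), -len(c[1]), _component_key(*c)),
    )
    return MolecularGraph(mol.mol_id, best[0], best[1], mol.properties)


def mol_canonical_key(mol: MolecularGraph) -> str:
    """Whole-molecule identity: sorted component canonical keys."""
    return "&".join(sorted(_component_key(*c) for c in _components(mol)))


def deduplicate(library: Sequence[MolecularGraph]) -> list[MolecularGraph]:
    """Drop repeated structures, keeping the first occurrence.

    Identity is the canonical key after salt stripping; order of the
    survivors is preserved.
    """
    if not library:
        raise ChemIOError("cannot deduplicate an empty library")
    seen: set[str] = set()
    out = []
    for mol in library:
        key = mol_canonical_key(strip_salt(mol))
        if key not in seen:
            seen.add(key)
            out.append(mol)
    return out


def records_from_library(
    library: Sequence[MolecularGraph], activity_field: str = IC50_FIELD
) -> list[ActivityRecord]:
    """Pull raw IC50 values out of molecule properties."""
    out = []
    for mol in library:
        raw = mol.properties.get(activity_field)
        ic50 = float(raw) if raw is not None and str(raw).strip() else None
        out.append(ActivityRecord(mol.mol_id, ic50_nM=ic50))
    return out


def prepare_activity(
    records: Iterable[ActivityRecord],
    mode: str,
    cutoff_nM: float = ACTIVITY_CUTOFF_NM,
) -> list[ActivityRecord]:
    """IC50 preprocessing for modeling.

    classification: label 0 (inactive) iff IC50 strictly exceeds the
    cutoff, else 1; all rows kept.  regression: rows above the cutoff
    removed, pIC50 = -log10(IC50 in molar) on the rest.  Non-positive
    IC50 values are rejected rows.
    """
    if mode not in ("classification", "regression"):
        raise ChemIOError(f"unknown mode {mode!r}")
    out = []
    for rec in records:
        if rec.ic50_nM is None:
            raise ChemIOError(f"record {rec.mol_id} lacks ic50_nM")
        if rec.ic50_nM <= 0:
            logger.warning("rejecting %s: non-positive IC50 %r", rec.mol_id, rec.ic50_nM)
            continue
        if mode == "classification":
            label = 0 if rec.ic50_nM > cutoff_nM else 1
            out.append(ActivityRecord(rec.mol_id, rec.ic50_nM, label=label))
        else:
            if rec.ic50_nM > cutoff_nM:
                continue
            pic50 = -math.log10(rec.ic50_nM * 1e-9)
            out.append(ActivityRecord(rec.mol_id, rec.ic50_nM, pIC50=pic50))
    return out
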