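import random

import pytest

from fragminer.molgraph import Atom, Bond, Fragment, MolecularGraph


def make_mol(mol_id, atom_spec, bond_spec, props=None):
    """atom_spec: list of 'C'/'N+1@'-style strings or (elem, charge, arom);
    bond_spec: list of (a1, a2[, order])."""
    atoms = []
    for i, s in enumerate(atom_spec):
        if isinstance(s, tuple):
            atoms.append(Atom(i, *s))
        else:
            atoms.append(Atom(i, s))
    bonds = [
        Bond(i, *(b if len(b) == 3 else (*b, "single")))
        for i, b in enumerate(bond_spec)
    ]
    return MolecularGraph(mol_id, atoms, bonds, props or {})


def make_fragment(atom_spec, bond_spec):
    m = make_mol("tmp", atom_spec, bond_spec)
    return Fragment(m.atoms, m.bonds)


@pytest.fixture
def ethane():
    return make_mol("ethane", ["C", "C"], [(0, 1)])


@pytest.fixture
def propane():
    return make_mol("propane", ["C", "C", "C"], [(0, 1), (1, 2)])


@pytest.fixture
def ethanol():
    return make_mol("ethanol", ["C", "C", "O"], [(0, 1), (1, 2)])


@pytest.fixture
def cyclopropane():
    return make_mol("cp", ["C", "C", "C"], [(0, 1), (1, 2), (2, 0)])


def benzene_graph(mol_id="benzene", extra_methyl=False):
    atoms = [("C", 0, True)] * 6
    bonds = [(i, (i + 1) % 6, "aromatic") for i in range(6)]
    if extra_methyl:
        atoms = atoms + [("C", 0, False)]
        bonds = bonds + [(0, 6, "single")]
    return make_mol(mol_id, atoms, bonds)


@pytest.fixture
def benzene():
    return benzene_graph()


@pytest.fixture
def toluene():
    return benzene_graph("toluene", extra_methyl=True)


@pytest.fixture
def benzene_fragment():
    m = benzene_graph()
    return Fragment(m.atoms, m.bonds)


@pytest.fixture
def cc_fragment():
    return make_fragment(["C", "C"], [(0, 1)])


def random_fragment(rng: random.Random, max_edges: int = 7) -> Fragment:
    """Random connected labeled fragment for canonicalization oracles."""
    elems = ["C", "C", "C", "N", "O"]
    orders = ["single", "single", "double", "aromatic"]
    n_edges = rng.randint(1, max_edges)
    atoms = [Atom(0, rng.choice(elems), 0, rng.random() < 0.3)]
    bonds = []
    for b in range(n_edges):
        if len(atoms) > 2 and rng.random() < 0.25:
            pairs = [
                (i, j)
                for i in range(len(atoms))
                for j in range(i + 1, len(atoms))
                if not any({bb.a1, bb.a2} == {i, j} for bb in bonds)
            ]
            if pairs:
                i, j = rng.choice(pairs)
                bonds.append(Bond(b, i, j, rng.choice(orders)))
                continue
        src = rng.randrange(len(atoms))
        atoms.append(Atom(len(atoms), rng.choice(elems), 0, rng.random() < 0.3))
        bonds.append(Bond(b, src, len(atoms) - 1, rng.choice(orders)))
    return Fragment(atoms, bonds)


def relabel_fragment(frag: Fragment, rng: random.Random) -> Fragment:
    """Same labeled graph under a random atom/bond permutation."""
    atom_ids = [a.atom_id for a in frag.atoms]
    new_ids = list(range(100, 100 + len(atom_ids)))
    rng.shuffle(new_ids)
    mapping = dict(zip(atom_ids, new_ids))
    atoms = [Atom(mapping[a.atom_id], a.element, a.charge, a.aromatic) for a in frag.atoms]
    bonds = [
        Bond(200 + i, mapping[b.a1], mapping[b.a2], b.order)
        for i, b in enumerate(rng.sample(frag.bonds, len(frag.bonds)))
    ]
    rng.shuffle(atoms)
    return Fragment(atoms, bonds)
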