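import itertools
import random

import networkx as nx
import pytest

from fragminer.molgraph import (
    Atom,
    Bond,
    Fragment,
    MolecularGraph,
    MolGraphError,
    canonical_form,
    enumerate_connected_subgraphs,
    fragment_from_bonds,
    fragment_from_dict,
    fragment_to_dict,
    subgraph_exists,
    subgraph_match,
)

from conftest import benzene_graph, make_fragment, make_mol, random_fragment, relabel_fragment


class TestConstruction:
    def test_duplicate_atom_ids_rejected(self):
        with pytest.raises(MolGraphError):
            MolecularGraph("m", [Atom(0, "C"), Atom(0, "C")], [Bond(0, 0, 0)])

    def test_self_loop_rejected(self):
        with pytest.raises(MolGraphError):
            make_mol("m", ["C", "C"], [(0, 0)])

    def test_duplicate_bond_pair_rejected(self):
        with pytest.raises(MolGraphError):
            make_mol("m", ["C", "C"], [(0, 1), (1, 0)])

    def test_unknown_bond_order_rejected(self):
        with pytest.raises(MolGraphError):
            make_mol("m", ["C", "C"], [(0, 1, "quadruple")])

    def test_hydrogen_rejected(self):
        with pytest.raises(MolGraphError):
            make_mol("m", ["C", "H"], [(0, 1)])

    def test_bond_to_missing_atom_rejected(self):
        with pytest.raises(MolGraphError):
            make_mol("m", ["C", "C"], [(0, 7)])

    def test_disconnected_fragment_rejected(self):
        atoms = [Atom(i, "C") for i in range(4)]
        bonds = [Bond(0, 0, 1), Bond(1, 2, 3)]
        with pytest.raises(MolGraphError):
            Fragment(atoms, bonds)

    def test_bondless_fragment_rejected(self):
        with pytest.raises(MolGraphError):
            Fragment([Atom(0, "C")], [])


class TestCanonicalForm:
    def test_relabeling_invariance_benzene(self):
        m1 = benzene_graph()
        f1 = Fragment(m1.atoms, m1.bonds)
        # same ring entered with scrambled atom ids and bond order
        atoms = [Atom(i, "C", 0, True) for i in (5, 3, 1, 0, 2, 4)]
        ring = [(5, 3), (3, 1), (1, 0), (0, 2), (2, 4), (4, 5)]
        bonds = [Bond(10 + i, a, b, "aromatic") for i, (a, b) in enumerate(ring)]
        f2 = Fragment(atoms, bonds)
        assert canonical_form(f1) == canonical_form(f2)
        assert f1 == f2

    def test_distinguishes_element(self):
        cc = make_fragment(["C", "C"], [(0, 1)])
        co = make_fragment(["C", "O"], [(0, 1)])
        assert cc.canonical_key != co.canonical_key

    def test_distinguishes_bond_order(self):
        single = make_fragment(["C", "C"], [(0, 1, "single")])
        double = make_fragment(["C", "C"], [(0, 1, "double")])
        assert single.canonical_key != double.canonical_key

    def test_distinguishes_charge_and_aromaticity(self):
        neutral = make_fragment(["C", "N"], [(0, 1)])
        charged = make_fragment(["C", ("N", 1, False)], [(0, 1)])
        aromatic = make_fragment([("C", 0, True), ("N", 0, True)], [(0, 1, "aromatic")])
        keys = {neutral.canonical_key, charged.canonical_key, aromatic.canonical_key}
        assert len(keys) == 3

    def test_distinguishes_topology_same_multiset(self):
        # n-butane path vs isobutane star: same atoms, same bond count
        path = make_fragment(["C"] * 4, [(0, 1), (1, 2), (2, 3)])
        star = make_fragment(["C"] * 4, [(0, 1), (0, 2), (0, 3)])
        assert path.canonical_key != star.canonical_key

    def test_random_oracle_against_networkx_isomorphism(self):
        """Canonical keys agree exactly when the labeled graphs are isomorphic."""
        rng = random.Random(42)
        frags = [random_fragment(rng) for _ in range(60)]
        # add relabeled copies so positives occur often
        frags += [relabel_fragment(f, rng) for f in frags[:30]]

        def iso(f1, f2):
            return nx.is_isomorphic(
                f1.to_networkx(),
                f2.to_networkx(),
                node_match=lambda a, b: a["label"] == b["label"],
                edge_match=lambda a, b: a["order"] == b["order"],
            )

        for f1, f2 in itertools.combinations(frags, 2):
            same_key = f1.canonical_key == f2.canonical_key
            assert same_key == iso(f1, f2), (f1, f2)

    def test_relabeling_invariance_random(self):
        rng = random.Random(7)
        for _ in range(40):
            f = random_fragment(rng)
            g = relabel_fragment(f, rng)
            assert f.canonical_key == g.canonical_key


class TestSubgraphMatch:
    def test_benzene_in_toluene_once(self, benzene_fragment, toluene):
        matches = subgraph_match(benzene_fragment, toluene)
        assert len(matches) == 1
        assert matches[0] == frozenset(range(6))

    def test_cc_in_propane_twice(self, cc_fragment, propane):
        matches = subgraph_match(cc_fragment, propane)
        assert sorted(matches) == [frozenset({0}), frozenset({1})]

    def test_no_match(self, propane):
        co = make_fragment(["C", "O"], [(0, 1)])
        assert subgraph_match(co, propane) == []
        assert not subgraph_exists(co, propane)

    def test_exists_agrees_with_match(self, ethanol, toluene, cc_fragment):
        for mol in (ethanol, toluene):
            for frag in (cc_fragment, make_fragment(["C", "O"], [(0, 1)])):
                assert subgraph_exists(frag, mol) == bool(subgraph_match(frag, mol))

    def test_match_is_bond_induced(self):
        # C=C fragment must not match a C-C bond
        double = make_fragment(["C", "C"], [(0, 1, "double")])
        propene = make_mol("p", ["C", "C", "C"], [(0, 1), (1, 2, "double")])
        assert subgraph_match(double, propene) == [frozenset({1})]

    def test_fragment_in_fragment(self, cc_fragment):
        path = make_fragment(["C"] * 3, [(0, 1), (1, 2)])
        assert len(subgraph_match(cc_fragment, path)) == 2


class TestEnumeration:
    def test_cyclopropane_has_seven_subsets(self, cyclopropane):
        frags = enumerate_connected_subgraphs(cyclopropane, max_edges=3)
        assert len(frags) == 7  # 3 singles + 3 pairs + 1 triangle

    def test_propane_counts(self, propane):
        frags = enumerate_connected_subgraphs(propane, max_edges=2)
        assert len(frags) == 3  # two single bonds + the full path

    def test_max_edges_bound(self, cyclopropane):
        frags = enumerate_connected_subgraphs(cyclopropane, max_edges=1)
        assert len(frags) == 3
        assert all(f.n_edges == 1 for f in frags)

    def test_every_enumerated_fragment_matches_back(self, toluene):
        for frag in enumerate_connected_subgraphs(toluene, max_edges=4):
            assert subgraph_exists(frag, toluene)


class TestFragmentFromBonds:
    def test_induced_atoms(self, ethanol):
        frag = fragment_from_bonds(ethanol, [1])
        assert sorted(a.element for a in frag.atoms) == ["C", "O"]

    def test_disconnected_bond_set_rejected(self):
        mol = make_mol("m", ["C"] * 4, [(0, 1), (1, 2), (2, 3)])
        with pytest.raises(MolGraphError):
            fragment_from_bonds(mol, [0, 2])

    def test_unknown_bond_id_rejected(self, ethanol):
        with pytest.raises(MolGraphError):
            fragment_from_bonds(ethanol, [99])


class TestSerialization:
    def test_round_trip_preserves_identity(self):
        rng = random.Random(3)
        for _ in range(20):
            f = random_fragment(rng)
            g = fragment_from_dict(fragment_to_dict(f))
            assert g == f
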