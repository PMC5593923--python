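import pytest

from fragminer.mining import (
    MiningError,
    SubID,
    collapse_ffid,
    exhaustive_maximal_frequent,
    grow_node,
    init_roots,
    integrity_filter,
    is_prn,
    mine,
    popularity,
)
from fragminer.synthetic import random_small_library, worked_example_library

from conftest import benzene_graph, make_fragment, make_mol


class TestSubID:
    def test_popularity_counts_distinct_molecules(self):
        sid = SubID(
            (
                ("A", frozenset({0})),
                ("B", frozenset({0})),
                ("C", frozenset({0})),
                ("D", frozenset({0})),
                ("D", frozenset({1})),
            )
        )
        assert popularity(sid) == 4
        assert sid.mol_ids == ("A", "B", "C", "D", "D")

    def test_canonical_string_order_independent(self):
        a = SubID((("m1", frozenset({0})), ("m2", frozenset({3}))))
        b = SubID((("m2", frozenset({3})), ("m1", frozenset({0}))))
        assert a.canonical_string == b.canonical_string

    def test_empty_rejected(self):
        with pytest.raises(MiningError):
            SubID(())

    def test_mixed_sizes_rejected(self):
        with pytest.raises(MiningError):
            SubID((("m1", frozenset({0})), ("m1", frozenset({0, 1}))))


class TestRoots:
    def test_worked_example_root(self):
        """The C-C single-bond root collects 5 components over 4 molecules."""
        roots = init_roots(worked_example_library())
        cc = make_fragment(["C", "C"], [(0, 1)])
        root = next(r for r in roots if r.fragment == cc)
        assert len(root.subid.components) == 5
        assert root.popularity == 4

    def test_one_root_per_bond_type(self):
        roots = init_roots(worked_example_library())
        # bond types present: C-C, C-O, C=C, C-N
        assert len(roots) == 4
        keys = [r.fragment.canonical_key for r in roots]
        assert keys == sorted(keys)

    def test_duplicate_mol_ids_rejected(self, ethane):
        with pytest.raises(MiningError):
            init_roots([ethane, ethane])


class TestGrowAndPrn:
    def test_grow_extends_each_embedding(self, propane):
        roots = init_roots([propane])
        (root,) = roots
        children = grow_node(root, [propane])
        assert len(children) == 1  # both extensions give the same C-C-C class
        assert len(children[0].subid.components) == 1
        assert children[0].fragment.n_edges == 2

    def test_prn_when_every_child_loses_support(self, ethanol, propane):
        lib = [ethanol, propane]
        roots = init_roots(lib)
        cc = make_fragment(["C", "C"], [(0, 1)])
        root = next(r for r in roots if r.fragment == cc)
        children = grow_node(root, lib)
        # C-C extends to C-C-O (ethanol only) and C-C-C (propane only)
        assert is_prn(root, children)

    def test_not_prn_when_a_child_keeps_support(self, propane):
        lib = [propane]
        (root,) = init_roots(lib)
        children = grow_node(root, lib)
        assert not is_prn(root, children)  # C-C-C still supported by propane

    def test_leaf_is_prn(self, ethane):
        (root,) = init_roots([ethane])
        assert is_prn(root, [])


class TestMine:
    def test_three_ethanols_report_whole_molecule(self):
        lib = [
            make_mol(f"e{i}", ["C", "C", "O"], [(0, 1), (1, 2)]) for i in range(3)
        ]
        result = mine(lib, t=2)
        cco = make_fragment(["C", "C", "O"], [(0, 1), (1, 2)])
        assert result.fragment_keys() == {cco.canonical_key}

    def test_ethane_propane_share_cc(self, ethane, propane):
        result = mine([ethane, propane], t=2)
        cc = make_fragment(["C", "C"], [(0, 1)])
        assert result.fragment_keys() == {cc.canonical_key}

    def test_single_molecule_reports_nothing(self, propane, ethane):
        assert mine([propane, ethane], t=2).reported != []  # baseline
        lonely = mine([propane, make_mol("x", ["N", "O"], [(0, 1)])], t=2)
        assert lonely.reported == []

    def test_t_below_two_rejected(self, ethane, propane):
        with pytest.raises(MiningError):
            mine([ethane, propane], t=1)

    def test_empty_library_rejected(self):
        with pytest.raises(MiningError):
            mine([], t=2)

    def test_reported_subids_are_complete_embedding_lists(self, ethane, propane):
        result = mine([ethane, propane], t=2)
        ((frag, subid),) = result.reported
        # C-C occurs once in ethane, twice in propane
        assert len(subid.components) == 3
        assert subid.support_set() == {"ethane", "propane"}

    @pytest.mark.parametrize("seed", [11, 12, 13])
    @pytest.mark.parametrize("t", [2, 3])
    def test_oracle_equivalence_small(self, seed, t):
        lib = random_small_library(seed, max_molecules=8, max_bonds=6)
        got = mine(lib, t=t).fragment_keys()
        want = set(exhaustive_maximal_frequent(lib, t=t))
        assert got == want

    @pytest.mark.parametrize("seed", [21, 22])
    def test_pruning_preserves_output(self, seed):
        lib = random_small_library(seed, max_molecules=8, max_bonds=6)
        on = mine(lib, t=2, prune=True)
        off = mine(lib, t=2, prune=False)
        assert on.fragment_keys() == off.fragment_keys()
        assert on.visited_nodes <= off.visited_nodes
        assert off.pruned_nodes == 0


class TestCollapseFFID:
    def test_nested_fragment_dropped(self):
        """Case 1: same FFID, one fragment inside the other -> keep the larger."""
        small = make_fragment(["C", "C"], [(0, 1)])
        large = make_fragment(["C", "C", "O"], [(0, 1), (1, 2)])
        sid = lambda bonds: SubID((("m1", frozenset(bonds)), ("m2", frozenset(bonds))))
        out = collapse_ffid([(small, sid({0})), (large, sid({0, 1}))])
        assert [f.canonical_key for f, _ in out] == [large.canonical_key]

    def test_non_nested_fragments_kept(self):
        """Case 2: same FFID, disjoint chemistry -> both stay."""
        f1 = make_fragment(["C", "N"], [(0, 1)])
        f2 = make_fragment(["C", "O"], [(0, 1)])
        sid = SubID((("m1", frozenset({0})), ("m2", frozenset({0}))))
        out = collapse_ffid([(f1, sid), (f2, sid)])
        assert len(out) == 2
        assert out[0][1] == out[1][1]  # shared FFID

    def test_different_ffid_not_compared(self):
        small = make_fragment(["C", "C"], [(0, 1)])
        large = make_fragment(["C", "C", "O"], [(0, 1), (1, 2)])
        s1 = SubID((("m1", frozenset({0})), ("m2", frozenset({0}))))
        s2 = SubID((("m1", frozenset({0, 1})), ("m3", frozenset({0, 1}))))
        out = collapse_ffid([(small, s1), (large, s2)])
        assert len(out) == 2

    def test_empty_rejected(self):
        with pytest.raises(MiningError):
            collapse_ffid([])


class TestIntegrityFilter:
    def make_lib(self):
        return [benzene_graph("b1", extra_methyl=True), benzene_graph("b2", extra_methyl=True)]

    def test_partial_aromatic_ring_removed(self):
        lib = self.make_lib()
        frag = make_fragment(
            [("C", 0, True), ("C", 0, True)], [(0, 1, "aromatic")]
        )
        sid = SubID((("b1", frozenset({0})), ("b2", frozenset({0}))))
        assert integrity_filter([(frag, sid)], lib) == []

    def test_whole_ring_kept(self):
        lib = self.make_lib()
        ring = benzene_graph()
        from fragminer.molgraph import Fragment

        frag = Fragment(ring.atoms, ring.bonds)
        sid = SubID((("b1", frozenset(range(6))), ("b2", frozenset(range(6)))))
        out = integrity_filter([(frag, sid)], lib)
        assert len(out) == 1

    def test_aliphatic_fragment_untouched(self, ethane, propane):
        result = mine([ethane, propane], t=2)
        assert integrity_filter(result.reported, [ethane, propane]) == result.reported
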