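"""Haplogroup tree: nomenclature, small parsimony, tree search, panels."""

import numpy as np
import pytest

import albomito as am
from albomito.haplotree import (
    HaplogroupTree,
    Node,
    SitePattern,
    build_site_patterns,
    fitch_assign,
    is_under,
    mp_search_exhaustive,
    parsimony_score,
    unrooted_splits,
)
from albomito.mito_io import MitoIOError, MitoSequence
from conftest import (
    brute_best_parsimony,
    brute_site_score,
    enumerate_unrooted_edge_lists,
    random_multifurcating_tree,
)


class TestNomenclature:
    @pytest.mark.parametrize("group, count", [
        ("A1", 21), ("A2", 5), ("A3", 1), ("B1", 0), ("A1a1a1", 7),
        ("A1b", 5), ("A1a2", 7),
    ])
    def test_membership_counts(self, table1, group, count):
        assert am.haplogroup_members(table1["haplogroup"], group) == count

    def test_nesting_respects_letter_digit_alternation(self):
        assert is_under("A1a2a1", "A1")
        assert not is_under("A11", "A1")
        assert not is_under("A1", "A1a")
        assert is_under("A1b (Brazilian motif)", "A1b")
        assert not is_under("A1a1a1", "A1a1a (Japanese motif)")

    def test_parent_count_dominates_child(self, table1):
        labels = list(table1["haplogroup"])
        for parent, child in [("A1", "A1a"), ("A1a", "A1a1"),
                              ("A1a1", "A1a1a1"), ("A1b", "A1b1"),
                              ("A2", "A2a")]:
            assert am.haplogroup_members(labels, parent) >= \
                am.haplogroup_members(labels, child)

    def test_malformed_group_rejected(self):
        with pytest.raises(MitoIOError):
            am.haplogroup_members(["A1"], "1A")


def chain_tree():
    """Caterpillar (L1,(L2,(L3,L4))) for reversion tests."""
    root = Node("r")
    root.add_child(Node("L1"))
    n2 = root.add_child(Node("n2"))
    n2.add_child(Node("L2"))
    n3 = n2.add_child(Node("n3"))
    n3.add_child(Node("L3"))
    n3.add_child(Node("L4"))
    return HaplogroupTree(root)


class TestSmallParsimony:
    def test_identical_leaves_need_no_changes(self):
        t = chain_tree()
        pat = SitePattern(1, {"L1": "A", "L2": "A", "L3": "A", "L4": "A"})
        assert parsimony_score([pat], t) == 0

    def test_perfect_clade_character_maps_to_stem(self, tree, genomes):
        pats = build_site_patterns(genomes.leaves, region=(1990, 1990))
        res = fitch_assign(pats, tree)
        assert list(res.branch_mutations) == ["A2"]  # the A2 stem marker
        assert res.total_changes == 1

    def test_missing_states_never_force_changes(self):
        t = chain_tree()
        pat = SitePattern(1, {"L1": "A", "L2": None, "L3": "A", "L4": None})
        assert parsimony_score([pat], t) == 0

    def test_all_missing_site_skipped_with_flag(self):
        t = chain_tree()
        pat = SitePattern(9, {"L1": None, "L2": None, "L3": None, "L4": None})
        res = fitch_assign([pat], t)
        assert res.skipped_sites == {9}
        assert res.total_changes == 0

    def test_absent_leaf_is_an_error(self):
        t = chain_tree()
        with pytest.raises(MitoIOError, match="L4"):
            parsimony_score([SitePattern(1, {"L1": "A", "L2": "A",
                                             "L3": "A"})], t)

    def test_reversion_flagged_back_and_recurrent(self):
        t = chain_tree()
        pat = SitePattern(1, {"L1": "A", "L2": "G", "L3": "G", "L4": "A"})
        res = fitch_assign([pat], t)
        assert res.total_changes == 2
        muts = [m for ms in res.branch_mutations.values() for m in ms]
        assert all(m.recurrent for m in muts)
        (back,) = [m for m in muts if m.back_mutation]
        assert "L4" in res.branch_mutations and \
            res.branch_mutations["L4"] == [back]

    def test_hartigan_matches_labeling_enumeration(self):
        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(30):
            n = int(rng.integers(4, 7))
            taxa = [f"t{i}" for i in range(n)]
            t = random_multifurcating_tree(rng, taxa)
            for _ in range(5):
                states = {x: (None if rng.random() < 0.15 else
                              "ACGT"[int(rng.integers(4))]) for x in taxa}
                pat = SitePattern(1, states)
                if not pat.observed():
                    continue
                assert parsimony_score([pat], t) == brute_site_score(t, pat)
                checked += 1
        assert checked > 100

    def test_assignment_total_equals_score(self, tree, genomes):
        pats = build_site_patterns(genomes.leaves)
        res = fitch_assign(pats, tree)
        assert res.total_changes == parsimony_score(pats, tree)

    def test_score_invariant_under_leaf_order_and_rerooting(self, tree,
                                                            genomes):
        pats = build_site_patterns(genomes.leaves, region=(1, 3000))
        base = parsimony_score(pats, tree)
        shuffled = tree.rerooted(tree.root.name)  # deep copy
        for node in shuffled.preorder():
            node.children.reverse()
        assert parsimony_score(pats, shuffled) == base
        for name in ("A1b", "A3", "Rim1"):
            assert parsimony_score(pats, tree.rerooted(name)) == base

    def test_simulated_ledger_recovered_exactly(self, tree, genomes):
        """Round trip: mutations applied along the tree come back on the
        same branches, including the recurrent np 2550 pair."""
        pats = build_site_patterns(genomes.leaves)
        res = fitch_assign(pats, tree)
        led = genomes.ledger
        expected = {(r.branch, r.position)
                    for r in led[~led.private].itertuples()
                    if not r.mutation.endswith("d")}
        got = {(b, m.position) for b, ms in res.branch_mutations.items()
               for m in ms}
        assert got == expected
        assert {m.position for ms in res.branch_mutations.values()
                for m in ms if m.recurrent} == {2550}


class TestExhaustiveSearch:
    def test_three_taxa_have_one_topology(self):
        pats = [SitePattern(1, {"a": "A", "b": "C", "c": "G"})]
        assert len(mp_search_exhaustive(pats, ["a", "b", "c"])) == 1

    def test_topology_counts_match_double_factorial(self):
        assert len(enumerate_unrooted_edge_lists(5)) == 15
        assert len(enumerate_unrooted_edge_lists(6)) == 105

    def test_perfect_split_selects_matching_quartet(self):
        pats = [SitePattern(i, {"a": "A", "b": "A", "c": "G", "d": "G"})
                for i in range(1, 4)]
        best = mp_search_exhaustive(pats, ["a", "b", "c", "d"])
        assert len(best) == 1
        assert unrooted_splits(best[0]) == {frozenset({"a", "b"})}

    def test_clean_simulation_recovers_generating_tree(self):
        root = Node("r")
        ab = root.add_child(Node("ab")); ab.add_child(Node("a")); ab.add_child(Node("b"))
        cd = root.add_child(Node("cd")); cd.add_child(Node("c")); cd.add_child(Node("d"))
        ef = root.add_child(Node("ef")); ef.add_child(Node("e")); ef.add_child(Node("f"))
        gen = HaplogroupTree(root)
        from albomito.haplotree import BranchEvent
        from albomito.mito_io import parse_mutation_label
        pos = iter(range(10, 200, 10))
        for name in ("ab", "cd", "ef", "a", "b", "c", "d", "e", "f"):
            node = gen.find(name)
            k = 3 if len(name) == 2 else 1
            node.events = [BranchEvent(parse_mutation_label(str(next(pos))))
                           for _ in range(k)]
        gen._mark_recurrent()
        sim = am.simulate_along_tree(gen, seed=5, length=250)
        pats = build_site_patterns(sim.leaves)
        best = mp_search_exhaustive(pats, sorted(gen.leaf_names()))
        assert len(best) == 1
        assert unrooted_splits(best[0]) == unrooted_splits(gen)

    def test_search_score_matches_full_enumeration_oracle(self):
        rng = np.random.default_rng(19)
        taxa = [f"t{i}" for i in range(6)]
        pats = [SitePattern(i + 1, {x: "ACGT"[int(rng.integers(4))]
                                    for x in taxa}) for i in range(6)]
        best = mp_search_exhaustive(pats, taxa)
        score = parsimony_score(pats, best[0])
        assert score == brute_best_parsimony(pats, 6, taxa)

    def test_too_many_taxa_rejected(self):
        taxa = [f"t{i}" for i in range(10)]
        with pytest.raises(MitoIOError, match="fixed topology"):
            mp_search_exhaustive([SitePattern(1, {t: "A" for t in taxa})],
                                 taxa)


class TestMarkerPanel:
    def test_homoplasy_free_roundtrip_matches_generating_branches(self):
        """On clean synthetic data, presence markers equal the in-window
        generating branch mutations."""
        root = Node("r")
        a = root.add_child(Node("A1")); a.add_child(Node("x"))
        b = root.add_child(Node("A2")); b.add_child(Node("y"))
        gen = HaplogroupTree(root, reference_leaf="x")
        from albomito.haplotree import BranchEvent
        from albomito.mito_io import parse_mutation_label
        gen.find("A2").events = [BranchEvent(parse_mutation_label("1500")),
                                 BranchEvent(parse_mutation_label("5000"))]
        gen._mark_recurrent()
        panel = am.derive_marker_panel(gen)
        assert [(e.haplogroup, e.mutation.label(), e.mode)
                for e in panel.entries] == [("A2", "1500", "presence")]
        assert "A1" in panel.not_distinguishable

    def test_no_recurrent_marker_in_fixture_panel(self, tree, panel):
        assert 2550 in tree.recurrent_positions()
        assert 2550 not in panel.positions()

    def test_haplogroups_ordered_by_nesting_depth(self, panel):
        hgs = panel.haplogroups()
        assert hgs.index("A1b") < hgs.index("A1b (Brazilian motif)")
        assert hgs.index("A1a1a1") < hgs.index("A1a1a1a1")

    def test_undistinguishable_haplogroups_flagged(self, panel):
        assert {"A1", "A1a", "A1a1"} <= set(panel.not_distinguishable)


def test_newick_round_trip_preserves_topology_and_ledger(tree, tmp_path):
    text = tree.to_newick()
    assert "[&mutations=" in text
    p = tmp_path / "t.nwk"
    p.write_text(am.HaplogroupTree.load_fixture().to_newick(
        include_mutations=False) + "\n")
    back = HaplogroupTree.from_newick(p)
    assert sorted(back.leaf_names()) == sorted(tree.leaf_names())
    assert unrooted_splits(back) == unrooted_splits(tree)
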