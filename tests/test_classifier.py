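"""Fragment classification: marker scoring, deepest-call rule, batching."""

import pytest

import albomito as am
from albomito.classifier import (
    OTHERS,
    FragmentRecord,
    classify_batch,
    classify_fragment,
    score_fragment,
)
from albomito.mito_io import COI_WINDOW, MitoIOError, MitoSequence, ND5_WINDOW


def fragment_of(genomes, node, window=COI_WINDOW, wname="COI", fid=None,
                population=""):
    lo, hi = window
    seq = genomes.node_seqs[node]
    return FragmentRecord(
        sequence=MitoSequence(id=fid or node, seq=seq[lo - 1:hi],
                              region_covered=(lo, hi), population=population),
        window=wname)


class TestScoring:
    def test_a3_coi_motif_fully_satisfied(self, genomes, panel, reference):
        f = fragment_of(genomes, "A3")
        tally = score_fragment(f, panel, reference)["A3"]
        assert sorted(e.mutation.label() for e in tally.satisfied) == \
            ["1503", "1578C", "1676C", "1704", "1964"]
        assert not tally.violated and not tally.unobservable

    def test_absence_markers_satisfied_by_observed_ancestral(self, genomes,
                                                             panel, reference):
        f = fragment_of(genomes, "A1a1a1")
        tally = score_fragment(f, panel, reference)["A1a1a1"]
        assert sorted(e.mutation.label() for e in tally.satisfied) == \
            ["1536@", "2165@"]

    def test_uncovered_markers_are_unobservable(self, genomes, panel,
                                                reference):
        f = fragment_of(genomes, "A1a1a1", window=(1700, 2100))
        tally = score_fragment(f, panel, reference)["A1a1a1"]
        assert sorted(e.mutation.label() for e in tally.unobservable) == \
            ["1536@", "2165@"]

    def test_frame_mismatch_rejected(self, genomes, panel, reference):
        f = fragment_of(genomes, "A3")
        f.sequence.frame = "reference_taiwan"
        with pytest.raises(am.FrameMismatchError):
            score_fragment(f, panel, reference)


class TestClassifyFragment:
    @pytest.mark.parametrize("node, expected", [
        ("A3", "A3"),
        ("A1a1a1", "A1a1a1"),
        ("A1a1a1a1", "A1a1a1a1"),  # 1823 on top of the A1a1a1 background
        ("A1a2", "A1a2"),
        ("A2", "A2"),
        ("A1b", "A1b"),
        ("A1a1a (Japanese motif)", "A1a1a (Japanese motif)"),
    ])
    def test_coi_lineage_fragments_called_to_their_haplogroup(
            self, genomes, panel, reference, node, expected):
        call = classify_fragment(fragment_of(genomes, node), panel, reference)
        assert call.call == expected
        assert call.supporting and not call.conflicting

    def test_nd5_7210_routes_to_brazilian_motif(self, genomes, panel,
                                                reference):
        f = fragment_of(genomes, "A1b (Brazilian motif)", window=ND5_WINDOW,
                        wname="ND5")
        call = classify_fragment(f, panel, reference)
        assert call.call == "A1b (Brazilian motif)"
        assert "7210" in call.supporting

    def test_japanese_motif_shows_1536_and_2435_derived(self, genomes, panel,
                                                        reference):
        """The Japanese A1a1a lineage carries both COI transitions: np 2435
        on its own branch and np 1536 retained (not back-mutated)."""
        f = fragment_of(genomes, "A1a1a (Japanese motif)")
        from albomito.classifier import observe_marker
        states = {e.mutation.position: observe_marker(f, e, reference)
                  for e in panel.entries}
        assert states[1536] == "derived" and states[2435] == "derived"

    def test_all_missing_fragment_is_others_with_no_confidence(
            self, panel, reference):
        lo, hi = COI_WINDOW
        f = FragmentRecord(sequence=MitoSequence(
            id="nn", seq="N" * (hi - lo + 1), region_covered=(lo, hi)))
        call = classify_fragment(f, panel, reference)
        assert (call.call, call.confidence) == (OTHERS, "none")

    def test_basal_lineage_rejected_by_absence_markers(self, tree, genomes,
                                                       panel, reference):
        """An unknown basal lineage still carries the nps 1536/2165
        transitions, so it cannot masquerade as A1a1a1."""
        from albomito.synthetic_data import _others_haplotype
        lo, hi = COI_WINDOW
        seq = _others_haplotype(tree, genomes)
        f = FragmentRecord(sequence=MitoSequence(
            id="x", seq=seq[lo - 1:hi], region_covered=(lo, hi)))
        call = classify_fragment(f, panel, reference)
        assert call.call == OTHERS
        assert "1536@" in call.conflicting or "2165@" in call.conflicting

    def test_extending_coverage_never_flips_a_full_call(self, genomes, panel,
                                                        reference):
        """Monotonicity: a sub-window call is only refined (confidence
        upgraded or call deepened along the same path) by more coverage."""
        for node in ("A1a1a1a1", "A1a2", "A3", "A1b"):
            narrow = classify_fragment(
                fragment_of(genomes, node, window=(1500, 1900)),
                panel, reference)
            full = classify_fragment(
                fragment_of(genomes, node), panel, reference)
            if narrow.call != OTHERS:
                assert am.is_under(full.call, narrow.call) or \
                    full.call == narrow.call
            if narrow.confidence == "full":
                assert full.call == narrow.call

    def test_hierarchical_consistency_of_deep_calls(self, genomes, panel,
                                                    reference):
        """A call to a child haplogroup satisfies every observable marker on
        the ancestor path (e.g. A1a1a1a1 implies the A1a1a1 absences)."""
        call = classify_fragment(fragment_of(genomes, "A1a1a1a1"),
                                 panel, reference)
        assert call.call == "A1a1a1a1"
        assert {"1823", "1536@", "2165@"} <= set(call.supporting)


class TestBatch:
    def test_uniform_batch_counts(self, genomes, panel, reference):
        frags = [fragment_of(genomes, "A3", fid=f"a3_{i}") for i in range(10)]
        calls = classify_batch(frags, panel, reference)
        assert (calls["call"] == "A3").all() and len(calls) == 10

    def test_mixture_counts_equal_composition(self, tree, genomes, panel,
                                              reference):
        from albomito.synthetic_data import _others_haplotype
        lo, hi = COI_WINDOW
        frags = [fragment_of(genomes, "A1b", fid=f"b{i}") for i in range(6)]
        basal = _others_haplotype(tree, genomes)
        frags += [FragmentRecord(sequence=MitoSequence(
            id=f"o{i}", seq=basal[lo - 1:hi], region_covered=(lo, hi)))
            for i in range(4)]
        calls = classify_batch(frags, panel, reference)
        assert calls["call"].value_counts().to_dict() == \
            {"A1b": 6, OTHERS: 4}

    def test_duplicate_ids_rejected(self, genomes, panel, reference):
        frags = [fragment_of(genomes, "A3", fid="dup") for _ in range(2)]
        with pytest.raises(MitoIOError, match="duplicate"):
            classify_batch(frags, panel, reference)

    def test_empty_batch_rejected(self, panel, reference):
        with pytest.raises(MitoIOError, match="no fragments"):
            classify_batch([], panel, reference)

    def test_noise_away_from_markers_keeps_accuracy(self, tree, panel):
        """Private mutations that avoid marker sites leave classification
        perfect."""
        g = am.simulate_along_tree(tree, seed=23, private_noise_rate=0.002,
                                   forbidden_positions=panel.positions())
        ref = g.node_seqs[tree.reference_leaf]
        lo, hi = COI_WINDOW
        names = {"Rim1": "A1a1a1", "Fo2": "A1a2", "Bra": "A1b",
                 "Los4": "A2", "NC006817": "A3"}
        frags = [FragmentRecord(sequence=MitoSequence(
            id=n, seq=g.node_seqs[n][lo - 1:hi], region_covered=(lo, hi)))
            for n in names]
        calls = classify_batch(frags, panel, ref)
        for n, expected_parent in names.items():
            got = calls.loc[calls.id == n, "call"].iloc[0]
            assert am.is_under(got, expected_parent) or got == expected_parent
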