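"""Substitution/indel calling, interval normalization, deduplication."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import tespectrum as ts
from tespectrum.model import DELETION, GAP, INSERTION, SUBSTITUTION, MutationEvent
from tespectrum.variants import SubstitutionCall, _runs

from conftest import make_alignment


def twenty_copies(base_row, variants):
    """20-copy alignment: ``variants`` maps copy index -> row string."""
    rows = [variants.get(i, base_row) for i in range(20)]
    return make_alignment(rows)


class TestCallSubstitutions:
    def test_single_minority_base_called(self):
        aln = twenty_copies("ACGTA", {3: "ACGGA"})
        prof = ts.call_ancestral_profile(aln)
        calls = ts.call_substitutions(aln, prof)
        assert calls == [SubstitutionCall("c04", 4, 4, "T", "G")]

    def test_identity_copy_yields_no_calls(self):
        aln = twenty_copies("ACGTACGT", {})
        prof = ts.call_ancestral_profile(aln)
        assert ts.call_substitutions(aln, prof) == []

    def test_ambiguous_column_yields_no_calls(self):
        aln = twenty_copies("ACGTA", {i: "ACGGA" for i in range(8)})
        prof = ts.call_ancestral_profile(aln)
        assert ts.call_substitutions(aln, prof) == []

    def test_profile_alignment_mismatch(self):
        aln = twenty_copies("ACGTA", {})
        prof = ts.call_ancestral_profile(twenty_copies("ACGT", {}))
        with pytest.raises(ts.TESpectrumError):
            ts.call_substitutions(aln, prof)


class TestMergeAdjacent:
    def test_adjacent_calls_merge(self):
        aln = twenty_copies("AAGAA", {0: "AGAAA"})  # positions 2,3: AG->GA
        prof = ts.call_ancestral_profile(aln)
        events = ts.merge_adjacent(ts.call_substitutions(aln, prof), prof)
        assert len(events) == 1
        (e,) = events
        assert (e.anc_alleles, e.der_alleles) == ("AG", "GA")
        assert (e.interval_start, e.interval_end) == (2, 3)

    def test_non_adjacent_calls_stay_separate(self):
        aln = twenty_copies("ACGTA", {0: "GCGTG"})  # positions 1 and 5
        prof = ts.call_ancestral_profile(aln)
        events = ts.merge_adjacent(ts.call_substitutions(aln, prof), prof)
        assert sorted(e.interval_start for e in events) == [1, 5]
        assert all(e.length == 1 for e in events)

    @given(st.lists(st.booleans(), min_size=1, max_size=40))
    def test_matches_run_length_encoding(self, mask):
        """Planted runs merge exactly per run-length encoding of positions."""
        positions = [i + 1 for i, m in enumerate(mask) if m]
        calls = [SubstitutionCall("c", p, p, "A", "G") for p in positions]
        events = ts.merge_adjacent(calls, profile=None)
        # independent RLE oracle
        runs, run = [], []
        for p in positions:
            if run and p == run[-1] + 1:
                run.append(p)
            else:
                if run:
                    runs.append(run)
                run = [p]
        if run:
            runs.append(run)
        assert sorted((e.interval_start, e.interval_end) for e in events) == [
            (r[0], r[-1]) for r in runs
        ]


class TestCallIndels:
    def test_single_copy_multi_column_deletion(self):
        base = "ACGTACGTAC"
        aln = twenty_copies(base, {2: "ACG----TAC"[:10]})
        # copy 2 gapped at columns 4-7
        prof = ts.call_ancestral_profile(aln)
        events = ts.call_indels(aln, prof)
        assert len(events) == 1
        (e,) = events
        assert e.event_kind == DELETION and len(e.anc_alleles) == 4

    def test_insertion_run_called_with_bases(self):
        rows = {0: "ACGTA" + "GGTATAC" + "CGT"}
        base = "ACGTA" + "-------" + "CGT"
        aln = twenty_copies(base, rows)
        prof = ts.call_ancestral_profile(aln)
        events = ts.call_indels(aln, prof)
        assert len(events) == 1
        (e,) = events
        assert e.event_kind == INSERTION and e.der_alleles == "GGTATAC"

    def test_no_gaps_no_indels(self):
        aln = twenty_copies("ACGTACGT", {0: "ACGTACGA"})
        prof = ts.call_ancestral_profile(aln)
        assert ts.call_indels(aln, prof) == []


class TestNormalizeIndelInterval:
    def _del(self, pos, bases):
        return MutationEvent(DELETION, bases, "", pos - 1, pos + len(bases))

    def test_unique_placement_gets_flank_interval(self):
        # ACGTAG, delete G at 3: no sliding; flanks are 2 and 4
        e = ts.normalize_indel_interval(self._del(3, "G"), "ACGTAG")
        assert (e.interval_start, e.interval_end) == (2, 4)

    def test_homopolymer_deletion_right_normalizes(self):
        # ACTTTG: deleting any one T is equivalent; right-most placement is 5
        for start in (3, 4, 5):
            e = ts.normalize_indel_interval(self._del(start, "T"), "ACTTTG")
            assert (e.interval_start, e.interval_end) == (4, 6)

    def test_dinucleotide_repeat_slides_by_unit(self):
        # AGAGAGC: deleting AG at 1, 3 or 5 is equivalent
        e = ts.normalize_indel_interval(self._del(1, "AG"), "AGAGAGC")
        assert (e.interval_start, e.interval_end) == (4, 7)

    def test_flank_arithmetic_for_multibase_deletion(self):
        anc = "ACGTACGTACGT"
        e = ts.normalize_indel_interval(self._del(3, "GTAC"), anc)
        # length L deletion reported with end - start - 1 == L
        assert e.interval_end - e.interval_start - 1 == 4

    def test_insertion_reported_between_flanks(self):
        e = MutationEvent(INSERTION, "", "A", 4, 5)
        out = ts.normalize_indel_interval(e, "ACGTCG")
        assert (out.interval_start, out.interval_end) == (4, 5)

    def test_insertion_right_normalizes_through_homopolymer(self):
        # inserting T before a TT run equals inserting after it
        e = MutationEvent(INSERTION, "", "T", 2, 3)
        out = ts.normalize_indel_interval(e, "ACTTG")
        assert (out.interval_start, out.interval_end) == (4, 5)
        assert out.der_alleles == "T"


class TestDeduplicate:
    def test_recurrent_event_counted_once(self):
        evs = [
            MutationEvent(SUBSTITUTION, "A", "G", 500, 500, copy_ids=(c,))
            for c in ("c1", "c2", "c3")
        ]
        out = ts.deduplicate(evs)
        assert len(out) == 1 and out[0].copy_ids == ("c1", "c2", "c3")

    def test_distinct_derived_alleles_stay_separate(self):
        evs = [
            MutationEvent(SUBSTITUTION, "A", "G", 500, 500, copy_ids=("c1",)),
            MutationEvent(SUBSTITUTION, "A", "C", 500, 500, copy_ids=("c2",)),
        ]
        assert len(ts.deduplicate(evs)) == 2

    @given(
        st.lists(
            st.tuples(st.integers(1, 5), st.sampled_from("CG"), st.integers(0, 3)),
            max_size=20,
        )
    )
    def test_idempotent(self, specs):
        evs = [
            MutationEvent(SUBSTITUTION, "A", der, pos, pos, copy_ids=(f"c{c}",))
            for pos, der, c in specs
        ]
        once = ts.deduplicate(evs)
        twice = ts.deduplicate(once)
        assert [e.key for e in once] == [e.key for e in twice]
        assert [e.copy_ids for e in once] == [e.copy_ids for e in twice]


class TestPartitionInvariant:
    def test_every_copy_column_pair_explained(self):
        """Each (copy, column) is exactly one of: match, substitution call,
        indel run member, ambiguous column, insertion-gap, or missing."""
        cfg = ts.SimulationConfig(
            ancestral_length=400,
            orfs=(ts.OrfAnnotation("orf", 31, 330),),
            populations=7,
            copies_per_population=3,
            seed=9,
        )
        aln, _ = ts.simulate_family(cfg)
        prof = ts.call_ancestral_profile(aln)
        calls = ts.call_substitutions(aln, prof)
        indels = ts.call_indels(aln, prof)
        sub_cells = {(c.copy_id, c.column) for c in calls}
        M = aln.matrix
        state = prof.ancestral_state
        # columns of each indel per copy
        indel_cells = set()
        pos_to_col = {
            int(p): j for j, p in enumerate(prof.ancestral_position) if p > 0
        }
        for e in indels:
            for cid in e.copy_ids:
                i = aln.copy_ids.index(cid)
                if e.event_kind == DELETION:
                    # the called run is the copy's gap stretch; mark all
                    # positional columns where this copy is gapped
                    for j in range(aln.n_columns):
                        if prof.ancestral_position[j] > 0 and M[i, j] == GAP:
                            indel_cells.add((cid, j + 1))
                else:
                    for j in range(aln.n_columns):
                        if prof.ancestral_position[j] == 0 and M[i, j] in "ACGT":
                            indel_cells.add((cid, j + 1))
        for i, cid in enumerate(aln.copy_ids):
            for j in range(aln.n_columns):
                cell = (cid, j + 1)
                ch = M[i, j]
                ambiguous = prof.column_class[j] == "ambiguous"
                insertion_col = prof.ancestral_position[j] == 0
                explanations = sum(
                    [
                        ch == state[j] and not ambiguous,
                        cell in sub_cells,
                        cell in indel_cells,
                        ambiguous,
                        ch == "N",
                        insertion_col and ch == GAP,
                    ]
                )
                assert explanations >= 1, (cell, ch, state[j])


def test_runs_helper():
    assert _runs(np.array([0, 1, 1, 0, 1], dtype=bool)) == [(1, 3), (4, 5)]
    assert _runs(np.zeros(4, dtype=bool)) == []
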