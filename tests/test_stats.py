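"""Grouping scheme, spectrum summary, and the statistical tests."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

import tespectrum as ts
from tespectrum.model import AlignedCopy, SUBSTITUTION, MutationEvent
from tespectrum.stats import SamplingError, compact_letter_display


def labelled_copies(n_pops, per_pop):
    return [
        AlignedCopy(f"p{p:02d}-{c:02d}", "ACGT", population=f"p{p:02d}")
        for p in range(n_pops)
        for c in range(per_pop)
    ]


class TestAssignGroups:
    def test_one_copy_per_population_scheme(self):
        copies = labelled_copies(21, 4)
        groups = ts.assign_groups(copies, ts.GroupingScheme(1, 4, seed=1))
        assert len(groups) == 4
        assert all(len(g) == 21 for g in groups)
        assert len(set(itertools.chain.from_iterable(groups))) == 84

    def test_five_copies_per_population_scheme(self):
        copies = labelled_copies(7, 20)
        groups = ts.assign_groups(copies, ts.GroupingScheme(5, 4, seed=1))
        assert len(groups) == 4 and all(len(g) == 35 for g in groups)

    def test_deterministic_under_seed(self):
        copies = labelled_copies(5, 8)
        a = ts.assign_groups(copies, ts.GroupingScheme(2, 4, seed=7))
        b = ts.assign_groups(copies, ts.GroupingScheme(2, 4, seed=7))
        assert a == b

    def test_insufficient_copies(self):
        with pytest.raises(SamplingError):
            ts.assign_groups(labelled_copies(3, 3), ts.GroupingScheme(1, 4))


def substitution_events(n_transitions, n_transversions):
    """Synthetic annotated single-base events, distinct positions."""
    events = []
    for i in range(n_transitions):
        events.append(
            MutationEvent(SUBSTITUTION, "A", "G", i + 1, i + 1,
                          pattern="A>G", ts_tv="transition")
        )
    for i in range(n_transversions):
        p = 1000 + i
        events.append(
            MutationEvent(SUBSTITUTION, "A", "T", p, p,
                          pattern="A>T", ts_tv="transversion")
        )
    return events


class TestSummarizeSpectrum:
    def test_mean_and_se(self):
        groups = [substitution_events(c, 0) for c in (44, 45, 44, 45)]
        summ = ts.summarize_spectrum(groups)
        assert summ.mean("transition") == pytest.approx(44.5)
        sd = np.std([44, 45, 44, 45], ddof=1)
        assert summ.se("transition") == pytest.approx(sd / 2)

    def test_identical_groups_have_zero_se(self):
        groups = [substitution_events(10, 5)] * 4
        summ = ts.summarize_spectrum(groups)
        assert summ.se("total") == 0

    def test_totals_partition_into_ts_tv(self):
        groups = [substitution_events(7, 3), substitution_events(5, 9)]
        summ = ts.summarize_spectrum(groups)
        counts = summ.group_counts
        assert (counts("transition") + counts("transversion") == counts("total")).all()
        assert summ.mean("transition") + summ.mean("transversion") == summ.mean("total")

    def test_pooled_pairs_follow_patterns(self):
        groups = [substitution_events(4, 2)]
        summ = ts.summarize_spectrum(groups)
        assert summ.mean("A:T>G:C") == summ.mean("A>G")  # only A>G transitions present


class TestTTest:
    def test_textbook_pooled_t(self):
        res = ts.t_test_independent([1, 2, 3], [2, 3, 4])
        assert res.statistic == pytest.approx(-1.2247, abs=1e-3)
        assert res.stars == ""

    def test_equal_samples(self):
        res = ts.t_test_independent([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0 and res.p_value == pytest.approx(1.0)

    def test_zero_variance_convention(self):
        assert ts.t_test_independent([2, 2], [2, 2]).p_value == 1.0
        assert ts.t_test_independent([2, 2], [3, 3]).p_value == 0.0

    def test_sample_size_validation(self):
        with pytest.raises(ts.TESpectrumError):
            ts.t_test_independent([1], [1, 2])

    def test_stars_thresholds(self):
        strong = ts.t_test_independent([1, 1, 1, 2], [9, 9, 9, 10])
        assert strong.p_value <= 0.01 and strong.stars == "**"


class TestAnovaTukey:
    def test_identical_samples(self):
        res = ts.anova_tukey([[5, 5], [5, 5], [5, 5]])
        assert res.statistic == 0 and res.p_value == 1.0
        assert set(res.letters[0.05].values()) == {"a"}

    def test_two_group_equivalence_f_is_t_squared(self):
        a, b = [3.0, 5.0, 4.0, 6.0], [7.0, 9.0, 8.0, 10.0]
        t = ts.t_test_independent(a, b)
        f = ts.anova_tukey([a, b])
        assert f.statistic == pytest.approx(t.statistic**2, rel=1e-9)
        assert f.p_value == pytest.approx(t.p_value, rel=1e-9)
        # with two groups the single Tukey p equals the ANOVA p
        assert f.pairwise["p"].iloc[0] == pytest.approx(f.p_value, abs=1e-6)

    def test_matches_scipy_reference(self):
        """Fixed 4-group fixture against scipy's independent Tukey HSD."""
        groups = [
            [12.0, 15.0, 14.0, 13.0],
            [16.0, 18.0, 17.0, 19.0],
            [11.0, 12.0, 13.0, 12.0],
            [21.0, 20.0, 22.0, 23.0],
        ]
        res = ts.anova_tukey(groups)
        f_ref, p_ref = sps.f_oneway(*groups)
        assert res.statistic == pytest.approx(float(f_ref), abs=1e-9)
        assert res.p_value == pytest.approx(float(p_ref), abs=1e-9)
        ref = sps.tukey_hsd(*groups)
        for row in res.pairwise.itertuples():
            i = int(row.group1.split("_")[1]) - 1
            j = int(row.group2.split("_")[1]) - 1
            assert row.p == pytest.approx(ref.pvalue[i, j], abs=1e-6)

    def test_letters_consistent_with_pairwise(self):
        groups = [[1.0, 2.0, 1.5, 2.5], [1.2, 2.2, 1.7, 2.7], [30.0, 31.0, 30.5, 31.5]]
        res = ts.anova_tukey(groups)
        letters = res.letters[0.05]
        for row in res.pairwise.itertuples():
            share = set(letters[row.group1]) & set(letters[row.group2])
            assert bool(share) == (row.p > 0.05)

    def test_alpha_001_never_finer_than_005(self):
        groups = [[1.0, 2.0, 1.5], [2.0, 3.0, 2.5], [8.0, 9.0, 8.5], [8.2, 9.2, 8.7]]
        res = ts.anova_tukey(groups)
        n_letters_005 = len(set("".join(res.letters[0.05].values())))
        n_letters_001 = len(set("".join(res.letters[0.01].values())))
        assert n_letters_001 <= n_letters_005


class TestCompactLetterDisplay:
    def test_forced_chain(self):
        labels = ["1", "2", "3"]
        sig = {frozenset(("1", "3"))}
        assert compact_letter_display(labels, sig) == {"1": "a", "2": "ab", "3": "b"}

    def test_no_significant_pairs(self):
        assert compact_letter_display(["a", "b", "c"], set()) == {
            "a": "a", "b": "a", "c": "a"
        }

    @given(st.integers(2, 5), st.data())
    def test_sharing_iff_nonsignificant(self, n, data):
        labels = [f"g{i}" for i in range(n)]
        pairs = list(itertools.combinations(labels, 2))
        sig = {
            frozenset(p)
            for p in pairs
            if data.draw(st.booleans(), label=str(p))
        }
        letters = compact_letter_display(labels, sig)
        for a, b in pairs:
            share = bool(set(letters[a]) & set(letters[b]))
            assert share == (frozenset((a, b)) not in sig), (letters, sig)
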