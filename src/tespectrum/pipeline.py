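"""End-to-end drivers tying the pipeline stages together.

Two analysis scopes mirror the study design: single-base substitution
spectra are computed per group (each group's alignment gets its own
ancestral profile), while indels and multi-base substitutions are called
once on the pooled copy set, where the larger sample makes the
insertion-versus-deletion direction decidable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .ancestral import call_ancestral_profile
from .effects import annotate_event
from .model import (
    AlignmentSet,
    MutationEvent,
    OrfAnnotation,
    SUBSTITUTION,
    TRANSITION,
    TRANSVERSION,
)
from .stats import (
    GroupingScheme,
    SpectrumSummary,
    StatResult,
    anova_tukey,
    split_alignment,
    summarize_spectrum,
    t_test_independent,
)
from .variants import call_indels, call_substitutions, deduplicate, merge_adjacent

Orfs = Sequence[OrfAnnotation]


def call_group_events(
    aln: AlignmentSet,
    orfs: Orfs = (),
    major_threshold: float = 0.85,
    reference_id: Optional[str] = None,
) -> list[MutationEvent]:
    """Substitution events (deduplicated, annotated) for one group alignment."""
    profile = call_ancestral_profile(
        aln, major_threshold=major_threshold, reference_id=reference_id
    )
    events = deduplicate(merge_adjacent(call_substitutions(aln, profile), profile))
    anc = profile.ancestral_sequence
    return [annotate_event(e, anc, orfs) for e in events]


def call_pooled_events(
    aln: AlignmentSet,
    orfs: Orfs = (),
    major_threshold: float = 0.85,
    reference_id: Optional[str] = None,
) -> list[MutationEvent]:
    """Full-scope calling on the pooled copy set: indels plus substitutions."""
    profile = call_ancestral_profile(
        aln, major_threshold=major_threshold, reference_id=reference_id
    )
    subs = merge_adjacent(call_substitutions(aln, profile), profile)
    indels = call_indels(aln, profile)
    anc = profile.ancestral_sequence
    return [annotate_event(e, anc, orfs) for e in deduplicate(subs + indels)]


@dataclass
class SpectrumAnalysis:
    """Result bundle of the full mutation-spectrum analysis."""

    groups: list[list[str]]
    per_group_events: list[list[MutationEvent]]
    pooled_events: list[MutationEvent]
    summary: SpectrumSummary
    tests: dict[str, StatResult] = field(default_factory=dict)

    @property
    def indel_events(self) -> list[MutationEvent]:
        return [e for e in self.pooled_events if e.event_kind != SUBSTITUTION]

    @property
    def multi_base_substitutions(self) -> list[MutationEvent]:
        return [
            e
            for e in self.pooled_events
            if e.event_kind == SUBSTITUTION and e.length >= 2
        ]


def run_spectrum_analysis(
    aln: AlignmentSet,
    orfs: Orfs = (),
    scheme: GroupingScheme = GroupingScheme(),
    major_threshold: float = 0.85,
    reference_id: Optional[str] = None,
) -> SpectrumAnalysis:
    """Group the copies, call and summarize substitutions per group, call
    indels at full scope, and run the headline significance tests."""
    group_alns = split_alignment(aln, scheme)
    per_group = [
        call_group_events(g, orfs, major_threshold, reference_id) for g in group_alns
    ]
    single = [[e for e in g if e.length == 1] for g in per_group]
    summary = summarize_spectrum(single)
    pooled = call_pooled_events(aln, orfs, major_threshold, reference_id)

    tests: dict[str, StatResult] = {}
    ts = summary.group_counts(TRANSITION)
    tv = summary.group_counts(TRANSVERSION)
    tests["transition_vs_transversion"] = t_test_independent(ts, tv)
    tests["AT_GC_vs_GC_AT"] = t_test_independent(
        summary.group_counts("A:T>G:C"), summary.group_counts("G:C>A:T")
    )
    tests["transition_patterns"] = anova_tukey(
        [summary.group_counts(p) for p in ("A>G", "G>A", "T>C", "C>T")],
        labels=["A>G", "G>A", "T>C", "C>T"],
    )
    tests["codon_positions"] = anova_tukey(
        [summary.group_counts(f"pos{i}") for i in (1, 2, 3)],
        labels=["pos1", "pos2", "pos3"],
    )
    tests["effect_classes"] = anova_tukey(
        [
            summary.group_counts(c)
            for c in ("synonymous", "missense", "nonsense", "no_stop")
        ],
        labels=["synonymous", "missense", "nonsense", "no_stop"],
    )
    return SpectrumAnalysis(
        groups=[g.copy_ids for g in group_alns],
        per_group_events=per_group,
        pooled_events=pooled,
        summary=summary,
        tests=tests,
    )


def stats_frame(tests: dict[str, StatResult]):
    """Flatten test results into a report table."""
    import pandas as pd

    rows = []
    for name, r in tests.items():
        letters = ""
        if r.letters:
            alpha = max(r.letters)  # the 0.05-level display
            letters = ";".join(f"{k}={v}" for k, v in sorted(r.letters[alpha].items()))
        rows.append(
            {
                "comparison": name,
                "test": r.test,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "stars": r.stars,
                "letters_0.05": letters,
            }
        )
    return pd.DataFrame(rows)
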