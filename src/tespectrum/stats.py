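"""Group resampling and statistical summaries of the mutation spectrum.

The study design draws disjoint groups of copies — one copy per population
(21 populations) or five per population (7 populations) — analyses each
group's alignment independently, and reports per-category event counts as
mean ± SE across groups.  Group differences are tested with the pooled
independent-sample t-test and one-way ANOVA with Tukey's HSD post hoc test,
summarised as compact letter displays.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .effects import ALL_PATTERNS, EFFECT_CLASSES, POOLED_PAIRS, pool_complementary
from .model import (
    AlignedCopy,
    AlignmentSet,
    MutationEvent,
    REGION_INSIDE,
    REGION_OUTSIDE,
    REGION_SPANNING,
    SUBSTITUTION,
    TESpectrumError,
    TRANSITION,
    TRANSVERSION,
)


class SamplingError(TESpectrumError):
    """A population has too few copies for the requested grouping scheme."""


@dataclass(frozen=True)
class GroupingScheme:
    """How copies are drawn into groups: ``copies_per_population`` copies
    from every population into each of ``n_groups`` disjoint groups,
    sampled without replacement within population."""

    copies_per_population: int = 1
    n_groups: int = 4
    seed: int = 0


def assign_groups(
    copies: Sequence[AlignedCopy], scheme: GroupingScheme
) -> list[list[str]]:
    """Partition copy ids into disjoint groups under the scheme.

    Each group receives exactly ``copies_per_population`` copies from every
    population; the draw is without replacement and reproducible under the
    scheme's seed.
    """
    by_pop: dict[str, list[str]] = defaultdict(list)
    for c in copies:
        by_pop[c.population].append(c.copy_id)
    need = scheme.copies_per_population * scheme.n_groups
    rng = np.random.default_rng(scheme.seed)
    groups: list[list[str]] = [[] for _ in range(scheme.n_groups)]
    for pop in sorted(by_pop):
        ids = by_pop[pop]
        if len(ids) < need:
            raise SamplingError(
                f"population {pop!r} has {len(ids)} copies; scheme needs {need}"
            )
        chosen = rng.choice(len(ids), size=need, replace=False)
        for g in range(scheme.n_groups):
            take = chosen[
                g * scheme.copies_per_population : (g + 1) * scheme.copies_per_population
            ]
            groups[g].extend(ids[k] for k in sorted(take))
    return groups


def split_alignment(aln: AlignmentSet, scheme: GroupingScheme) -> list[AlignmentSet]:
    """Apply :func:`assign_groups` and return one sub-alignment per group."""
    return [aln.subset(ids) for ids in assign_groups(aln.copies, scheme)]


# --------------------------------------------------------------------------
# Spectrum summary


CATEGORY_TOTAL = "total"


def _categorize(events: Sequence[MutationEvent]) -> dict[str, int]:
    """Count unique single-base substitution events per spectrum category."""
    counts: dict[str, int] = defaultdict(int)
    for e in events:
        if e.event_kind != SUBSTITUTION or e.length != 1:
            continue
        counts[CATEGORY_TOTAL] += 1
        if e.ts_tv:
            counts[e.ts_tv] += 1
        if e.pattern:
            counts[e.pattern] += 1
        if e.region == REGION_INSIDE:
            counts[REGION_INSIDE] += 1
        elif e.region == REGION_OUTSIDE:
            counts[REGION_OUTSIDE] += 1
        elif e.region == REGION_SPANNING:
            counts[REGION_SPANNING] += 1
        if e.codon_position is not None:
            counts[f"pos{e.codon_position}"] += 1
        if e.effect:
            counts[e.effect] += 1
    return dict(counts)


SPECTRUM_CATEGORIES: list[str] = (
    [CATEGORY_TOTAL, TRANSITION, TRANSVERSION]
    + list(ALL_PATTERNS)
    + list(POOLED_PAIRS)
    + [REGION_INSIDE, REGION_OUTSIDE, REGION_SPANNING]
    + ["pos1", "pos2", "pos3"]
    + list(EFFECT_CLASSES)
)


@dataclass
class SpectrumSummary:
    """Per-group counts and cross-group mean ± SE for every category."""

    table: pd.DataFrame  # index: category; columns: group_*, mean, se
    n_groups: int

    def mean(self, category: str) -> float:
        return float(self.table.loc[category, "mean"])

    def se(self, category: str) -> float:
        return float(self.table.loc[category, "se"])

    def group_counts(self, category: str) -> np.ndarray:
        cols = [c for c in self.table.columns if c.startswith("group_")]
        return self.table.loc[category, cols].to_numpy(dtype=float)


def summarize_spectrum(
    per_group_events: Sequence[Sequence[MutationEvent]],
) -> SpectrumSummary:
    """Build the spectrum summary from per-group (deduplicated) event lists.

    SE is the sample standard deviation (n−1) over groups divided by
    √n_groups, the conventional "mean ± SE" of a small number of groups.
    """
    if len(per_group_events) == 0:
        raise TESpectrumError("summarize_spectrum needs at least one group")
    per_group = [_categorize(evts) for evts in per_group_events]
    n = len(per_group)
    rows = {}
    for cat in SPECTRUM_CATEGORIES:
        counts = np.array([g.get(cat, 0) for g in per_group], dtype=float)
        rows[cat] = counts
    # pooled pairs derive from the pattern counts within each group
    for pooled in POOLED_PAIRS:
        pooled_counts = []
        for g in per_group:
            pooled_counts.append(
                pool_complementary({p: g.get(p, 0) for p in ALL_PATTERNS})[pooled]
            )
        rows[pooled] = np.array(pooled_counts, dtype=float)
    table = pd.DataFrame(
        rows, index=[f"group_{i + 1}" for i in range(n)]
    ).T
    table["mean"] = table.mean(axis=1)
    sd = table[[f"group_{i + 1}" for i in range(n)]].std(axis=1, ddof=1)
    table["se"] = (sd / np.sqrt(n)).fillna(0.0) if n > 1 else 0.0
    return SpectrumSummary(table=table, n_groups=n)


# --------------------------------------------------------------------------
# Tests


def _stars(p: float) -> str:
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


@dataclass
class StatResult:
    """Outcome of a t-test or one-way ANOVA with post hoc comparisons."""

    test: str
    statistic: float
    p_value: float
    stars: str = ""
    pairwise: Optional[pd.DataFrame] = None      # columns: group1, group2, p
    letters: dict[float, dict] = field(default_factory=dict)  # alpha -> {group: letters}


def t_test_independent(
    a: Sequence[float], b: Sequence[float], equal_var: bool = True
) -> StatResult:
    """Two-sided independent-sample t-test (pooled variance by default).

    With zero variance in both samples: p = 1 when the means agree (no
    evidence of difference), else p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise TESpectrumError("t-test needs at least 2 observations per sample")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return StatResult("t", 0.0, 1.0)
        return StatResult("t", np.inf, 0.0, "**")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return StatResult("t", float(t), float(p), _stars(float(p)))


def anova_tukey(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
    alphas: Sequence[float] = (0.05, 0.01),
) -> StatResult:
    """One-way ANOVA with Tukey HSD pairwise comparisons and letter displays.

    Tukey p-values come from the studentized-range distribution via
    statsmodels; letters at each alpha share a character iff the pair is
    not significantly different at that level.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise TESpectrumError("ANOVA needs >= 2 samples with >= 2 observations each")
    if labels is None:
        labels = [f"group_{i + 1}" for i in range(len(groups))]
    labels = list(labels)
    arrays = [np.asarray(g, dtype=float) for g in groups]
    flat = np.concatenate(arrays)
    if np.ptp(flat) == 0:  # all observations identical
        pairs = [
            (labels[i], labels[j], 1.0)
            for i in range(len(groups))
            for j in range(i + 1, len(groups))
        ]
        pairwise = pd.DataFrame(pairs, columns=["group1", "group2", "p"])
        letters = {a: {lab: "a" for lab in labels} for a in alphas}
        return StatResult("anova", 0.0, 1.0, "", pairwise, letters)
    f, p = sps.f_oneway(*arrays)
    f, p = float(f), float(p)
    tags = np.repeat(labels, [len(a) for a in arrays])
    hsd = pairwise_tukeyhsd(flat, tags, alpha=min(alphas))
    summary_rows = hsd.summary().data[1:]  # header row first
    pairwise = pd.DataFrame(
        {
            "group1": [str(r[0]) for r in summary_rows],
            "group2": [str(r[1]) for r in summary_rows],
            "p": np.asarray(hsd.pvalues, dtype=float),
        }
    )
    letters = {}
    for alpha in alphas:
        sig = {
            frozenset((r.group1, r.group2))
            for r in pairwise.itertuples()
            if r.p <= alpha
        }
        letters[alpha] = compact_letter_display(labels, sig)
    return StatResult("anova", f, p, _stars(p), pairwise, letters)


def compact_letter_display(
    labels: Sequence[str], significant_pairs: set[frozenset]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Returns a letter string per group such that two groups share at least
    one letter iff their pair is NOT in ``significant_pairs``.  Intransitive
    significance patterns are representable because a group may carry
    several letters.
    """
    labels = list(labels)
    # start with one letter covering everything; split on each significant pair
    groups: list[set[str]] = [set(labels)]
    for pair in sorted(significant_pairs, key=lambda p: sorted(p)):
        a, b = sorted(pair)
        for g in [g for g in groups if a in g and b in g]:
            groups.remove(g)
            for cand in (g - {a}, g - {b}):
                # absorb: keep only maximal sets
                if cand and not any(cand <= other for other in groups):
                    groups = [o for o in groups if not (o <= cand)]
                    groups.append(cand)
    # deterministic letter order: by earliest member appearance
    order = {lab: i for i, lab in enumerate(labels)}
    groups.sort(key=lambda g: (min(order[m] for m in g), sorted(g)))
    out: dict[str, list[str]] = {lab: [] for lab in labels}
    for i, g in enumerate(groups):
        letter = _letter(i)
        for member in sorted(g, key=lambda m: order[m]):
            out[member].append(letter)
    return {lab: "".join(chars) for lab, chars in out.items()}


def _letter(i: int) -> str:
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    s = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        s = alphabet[rem] + s
    return s
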