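"""Substitution pattern and coding-effect classification.

Single-base substitutions fall into 12 ordered patterns (4 transitions:
A→G, G→A, T→C, C→T; 8 transversions), optionally pooled with their
complementary-strand partner so bias is expressed per base pair
(e.g. A:T→G:C = A→G + T→C).  Inside an ORF each single-base substitution
gets a codon position (1-3) and a protein effect: synonymous, missense,
nonsense (sense codon to stop) or no-stop (stop codon to sense).  Indels
touching the ORF are frameshift or in-frame according to the number of
coding bases gained or lost.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence, Union

from Bio.Data import CodonTable

from .model import (
    BASES,
    DELETION,
    FRAMESHIFT,
    IN_FRAME,
    INSERTION,
    SUBSTITUTION,
    MutationEvent,
    OrfAnnotation,
    REGION_INSIDE,
    REGION_OUTSIDE,
    REGION_SPANNING,
    TRANSITION,
    TRANSVERSION,
)

_PURINES = {"A", "G"}

#: Effect classes for coding single-base substitutions.
SYNONYMOUS = "synonymous"
MISSENSE = "missense"
NONSENSE = "nonsense"
NO_STOP = "no_stop"
EFFECT_CLASSES = (SYNONYMOUS, MISSENSE, NONSENSE, NO_STOP)

TRANSITION_PATTERNS = ("A>G", "G>A", "T>C", "C>T")
TRANSVERSION_PATTERNS = ("A>T", "T>A", "A>C", "C>A", "G>T", "T>G", "G>C", "C>G")
ALL_PATTERNS = TRANSITION_PATTERNS + TRANSVERSION_PATTERNS

#: Complementary-strand pattern pooling: each pooled pair sums one pattern
#: with its reverse-complement partner.
POOLED_PAIRS: Mapping[str, tuple[str, str]] = {
    "A:T>G:C": ("A>G", "T>C"),
    "G:C>A:T": ("G>A", "C>T"),
    "A:T>T:A": ("A>T", "T>A"),
    "A:T>C:G": ("A>C", "T>G"),
    "G:C>T:A": ("G>T", "C>A"),
    "G:C>C:G": ("G>C", "C>G"),
}


class GeneticCode:
    """The standard nuclear genetic code (64 codons, 3 stops)."""

    def __init__(self) -> None:
        table = CodonTable.unambiguous_dna_by_id[1]
        self.codon_to_aa: dict[str, str] = dict(table.forward_table)
        for stop in table.stop_codons:
            self.codon_to_aa[stop] = "*"
        self.stop_codons = frozenset(table.stop_codons)
        assert len(self.codon_to_aa) == 64 and len(self.stop_codons) == 3

    def translate(self, codon: str) -> str:
        codon = codon.upper()
        if codon not in self.codon_to_aa:
            raise ValueError(f"unclassifiable codon {codon!r}")
        return self.codon_to_aa[codon]

    def is_stop(self, codon: str) -> bool:
        return codon.upper() in self.stop_codons


STANDARD_CODE = GeneticCode()


def classify_pattern(anc: str, der: str) -> tuple[str, str]:
    """Pattern label and transition/transversion class of one base change."""
    anc, der = anc.upper(), der.upper()
    if anc not in BASES or der not in BASES:
        raise ValueError(f"bases must be A/C/G/T; got {anc!r}->{der!r}")
    if anc == der:
        raise ValueError("not a substitution: ancestral and derived base equal")
    ts = (anc in _PURINES) == (der in _PURINES)
    return f"{anc}>{der}", TRANSITION if ts else TRANSVERSION


def pool_complementary(pattern_counts: Mapping[str, float]) -> dict[str, float]:
    """Pool each pattern with its complementary-strand partner.

    Accepts labels in either ``A>G`` or ``A→G`` form; absent patterns count
    as zero.  The six pooled pairs conserve the total of the 12 patterns.
    """
    counts = {k.replace("→", ">"): v for k, v in pattern_counts.items()}
    if any(v < 0 for v in counts.values()):
        raise ValueError("pattern counts must be non-negative")
    return {
        pooled: counts.get(a, 0) + counts.get(b, 0)
        for pooled, (a, b) in POOLED_PAIRS.items()
    }


Orfs = Union[OrfAnnotation, Sequence[OrfAnnotation]]


def _orf_list(orfs: Orfs) -> list[OrfAnnotation]:
    return [orfs] if isinstance(orfs, OrfAnnotation) else list(orfs)


def _affected_range(event: MutationEvent) -> tuple[int, int]:
    """Ancestral positions [first, last] materially affected by the event.

    For indels the reported interval is the flank pair, so the affected
    bases sit strictly inside it; an insertion affects no ancestral base
    and is located by its two flanking positions.
    """
    if event.event_kind == SUBSTITUTION:
        return event.interval_start, event.interval_end
    if event.event_kind == DELETION:
        return event.interval_start + 1, event.interval_end - 1
    return event.interval_start, event.interval_end  # insertion: flanks


def assign_region(event: MutationEvent, orfs: Orfs) -> str:
    """inside_orf / outside_orf / spanning, against one or more ORFs.

    "Inside" means the whole affected range lies within a single ORF;
    "outside" means it is disjoint from every ORF; anything else spans an
    ORF boundary.
    """
    lo, hi = _affected_range(event)
    for orf in _orf_list(orfs):
        if orf.start <= lo and hi <= orf.end:
            return REGION_INSIDE
        if lo <= orf.end and hi >= orf.start:
            return REGION_SPANNING
    return REGION_OUTSIDE


def codon_position(pos: int, orf: OrfAnnotation) -> int:
    """Position (1, 2 or 3) of an ancestral coordinate within its codon."""
    if pos not in orf:
        raise ValueError(f"position {pos} outside ORF {orf.name} [{orf.start},{orf.end}]")
    return (pos - orf.start) % 3 + 1


def containing_orf(pos: int, orfs: Orfs) -> Optional[OrfAnnotation]:
    for orf in _orf_list(orfs):
        if pos in orf:
            return orf
    return None


def classify_effect(
    ancestral: str,
    orf: OrfAnnotation,
    pos: int,
    der: str,
    code: GeneticCode = STANDARD_CODE,
) -> str:
    """Protein effect of a single-base substitution at ``pos`` in ``orf``.

    The derived base is substituted into the ancestral codon; stop-to-stop
    changes count as synonymous (the product, termination, is unchanged).
    """
    if pos not in orf:
        raise ValueError(f"position {pos} outside ORF {orf.name}")
    if orf.end > len(ancestral):
        raise ValueError("ORF extends beyond ancestral sequence")
    offset = (pos - orf.start) % 3
    codon_start = pos - offset  # 1-based
    anc_codon = ancestral[codon_start - 1 : codon_start + 2].upper()
    der = der.upper()
    if anc_codon[offset] == der:
        raise ValueError("derived base equals ancestral base")
    der_codon = anc_codon[:offset] + der + anc_codon[offset + 1 :]
    anc_aa = code.translate(anc_codon)  # raises on N/gap in codon
    der_aa = code.translate(der_codon)
    if anc_aa == der_aa:
        return SYNONYMOUS
    if code.is_stop(der_codon):
        return NONSENSE
    if code.is_stop(anc_codon):
        return NO_STOP
    return MISSENSE


def orf_bases_affected(event: MutationEvent, orfs: Orfs) -> int:
    """Number of coding bases inserted into or deleted from the ORF(s)."""
    orf_list = _orf_list(orfs)
    if event.event_kind == DELETION:
        lo, hi = event.interval_start + 1, event.interval_end - 1
        return sum(
            max(0, min(hi, o.end) - max(lo, o.start) + 1) for o in orf_list
        )
    if event.event_kind == INSERTION:
        # bases land between the flanks; they are coding iff the insertion
        # point is strictly inside an ORF
        f = event.interval_start
        for o in orf_list:
            if o.start <= f < o.end:
                return len(event.der_alleles)
        return 0
    raise ValueError("orf_bases_affected applies to indels only")


def classify_indel_frame(event: MutationEvent, orfs: Orfs) -> str:
    """frameshift / in_frame for an indel touching the ORF."""
    if event.event_kind not in (INSERTION, DELETION):
        raise ValueError("frame classification applies to indels only")
    affected = orf_bases_affected(event, orfs)
    if affected == 0:
        raise ValueError("event does not affect any ORF base")
    return FRAMESHIFT if affected % 3 != 0 else IN_FRAME


def annotate_event(
    event: MutationEvent,
    ancestral: str,
    orfs: Orfs,
    code: GeneticCode = STANDARD_CODE,
) -> MutationEvent:
    """Fill region, pattern, ts/tv, codon position, effect and frame fields.

    Pattern/effect fields are set for single-base substitutions only; indels
    inside (or spanning into) the ORF get a frame effect.
    """
    from dataclasses import replace

    region = assign_region(event, orfs)
    updates: dict = {"region": region}
    if event.event_kind == SUBSTITUTION and event.length == 1:
        pattern, ts_tv = classify_pattern(event.anc_alleles, event.der_alleles)
        updates.update(pattern=pattern, ts_tv=ts_tv)
        orf = containing_orf(event.interval_start, orfs)
        if orf is not None:
            updates["codon_position"] = codon_position(event.interval_start, orf)
            try:
                updates["effect"] = classify_effect(
                    ancestral, orf, event.interval_start, event.der_alleles, code
                )
            except ValueError:
                updates["effect"] = None  # codon context not classifiable
    elif event.event_kind in (INSERTION, DELETION):
        if orf_bases_affected(event, orfs) > 0:
            updates["frame_effect"] = classify_indel_frame(event, orfs)
    return replace(event, **updates)
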