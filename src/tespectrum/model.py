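"""Core domain types for transposon mutation-spectrum analysis.

The pipeline's central object is a gapped multiple sequence alignment of
transposable-element (TE) copies cloned from the same genomic locus in
different individuals, each copy labelled with the field population it came
from.  Variation among copies is read off the alignment relative to an
ancestral state called per column, and summarised as substitution/indel
events.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from functools import cached_property
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

#: Alignment alphabet: the four bases, the gap character, and N for missing.
BASES = ("A", "C", "G", "T")
GAP = "-"
MISSING = "N"
ALPHABET = frozenset(BASES) | {GAP, MISSING}

_VALID_RE = re.compile(r"^[ACGTN-]+$")


class TESpectrumError(Exception):
    """Base class for errors raised by this package."""


class AlignmentError(TESpectrumError):
    """Malformed alignment input (ragged rows, bad characters, ...)."""


class MetadataError(TESpectrumError):
    """Copy metadata does not match the alignment."""


@dataclass(frozen=True)
class AlignedCopy:
    """One sequenced TE copy (a per-individual locus clone) in the alignment."""

    copy_id: str
    residues: str
    population: str = ""
    group: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.copy_id:
            raise AlignmentError("copy_id must be non-empty")
        seq = self.residues.upper()
        if not seq:
            raise AlignmentError(f"{self.copy_id}: empty sequence")
        if "U" in seq:
            raise AlignmentError(f"{self.copy_id}: RNA base 'U' not allowed")
        if not _VALID_RE.match(seq):
            bad = sorted(set(seq) - ALPHABET)
            raise AlignmentError(f"{self.copy_id}: invalid characters {bad}")
        object.__setattr__(self, "residues", seq)

    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")


class AlignmentSet:
    """An ordered collection of equal-length aligned TE copies.

    Parameters
    ----------
    copies:
        The aligned copies; all must share one alignment length and have
        unique ids.
    reference_id:
        Optional id of the copy designated as the ancestral reference
        (e.g. the CsuPLE1-A01 / Csu-Ty3-A01 convention).
    """

    def __init__(self, copies: Sequence[AlignedCopy], reference_id: Optional[str] = None):
        copies = list(copies)
        if not copies:
            raise AlignmentError("alignment must contain at least one copy")
        lengths = {len(c.residues) for c in copies}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged alignment: lengths {sorted(lengths)}")
        ids = [c.copy_id for c in copies]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentError(f"duplicate copy ids: {dup}")
        if reference_id is not None and reference_id not in set(ids):
            raise MetadataError(f"reference_id {reference_id!r} not in alignment")
        self.copies: list[AlignedCopy] = copies
        self.reference_id = reference_id
        self.n_columns = lengths.pop()

    def __len__(self) -> int:
        return len(self.copies)

    def __iter__(self) -> Iterator[AlignedCopy]:
        return iter(self.copies)

    def __getitem__(self, copy_id: str) -> AlignedCopy:
        for c in self.copies:
            if c.copy_id == copy_id:
                return c
        raise KeyError(copy_id)

    @property
    def copy_ids(self) -> list[str]:
        return [c.copy_id for c in self.copies]

    @cached_property
    def matrix(self) -> np.ndarray:
        """(n_copies, n_columns) array of single characters."""
        arr = np.frombuffer(
            "".join(c.residues for c in self.copies).encode("ascii"), dtype="S1"
        )
        return arr.reshape(len(self.copies), self.n_columns).astype("U1")

    def subset(self, copy_ids: Iterable[str]) -> "AlignmentSet":
        wanted = list(copy_ids)
        index = {c.copy_id: c for c in self.copies}
        missing = [i for i in wanted if i not in index]
        if missing:
            raise MetadataError(f"unknown copy ids: {missing}")
        ref = self.reference_id if self.reference_id in wanted else None
        return AlignmentSet([index[i] for i in wanted], reference_id=ref)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlignmentSet):
            return NotImplemented
        return self.copies == other.copies and self.reference_id == other.reference_id


@dataclass(frozen=True)
class OrfAnnotation:
    """An open reading frame on the ungapped ancestral sequence.

    ``start`` is the 1-based position of the first codon base, ``end`` the
    1-based position of the last base (inclusive); the span must be a whole
    number of codons.
    """

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start < self.end):
            raise ValueError(f"ORF {self.name}: need 1 <= start < end")
        if (self.end - self.start + 1) % 3 != 0:
            raise ValueError(f"ORF {self.name}: length not divisible by 3")

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1


# Column classification labels on the ancestral profile.
COL_FIXED = "fixed"
COL_SUBSTITUTION = "substitution"
COL_INSERTION = "insertion"
COL_DELETION = "deletion"
COL_AMBIGUOUS = "ambiguous"


@dataclass
class AncestralProfile:
    """Per-column ancestral calls for one alignment.

    Arrays are indexed by 0-based alignment column.  ``ancestral_position``
    holds the 1-based coordinate on the ungapped ancestral sequence for
    positional (non-insertion) columns and 0 for insertion columns.
    ``ancestral_state`` is the called state ('A','C','G','T','-'); for
    ambiguous columns it holds the plurality state used only to anchor
    coordinates, and ``column_class`` is ``ambiguous``.
    """

    counts: np.ndarray            # shape (5, n_columns), rows A,C,G,T,-
    n_missing: np.ndarray         # per-column N count
    ancestral_state: np.ndarray   # '<U1'
    ancestral_frequency: np.ndarray
    column_class: np.ndarray      # '<U12'
    ancestral_position: np.ndarray  # int, 0 for insertion columns
    major_threshold: float
    minor_threshold: float
    reference_id: Optional[str] = None

    ALLELE_ORDER = ("A", "C", "G", "T", GAP)

    @property
    def n_columns(self) -> int:
        return self.ancestral_state.shape[0]

    @cached_property
    def is_positional(self) -> np.ndarray:
        return self.ancestral_position > 0

    @cached_property
    def ancestral_sequence(self) -> str:
        """Ungapped ancestral sequence implied by the per-column calls."""
        states = self.ancestral_state[self.is_positional]
        return "".join(states.tolist())

    @property
    def ancestral_length(self) -> int:
        return int(self.is_positional.sum())

    def column_counts(self, column: int) -> dict[str, int]:
        """Allele counts (1-based column), for inspection and debugging."""
        if not (1 <= column <= self.n_columns):
            raise IndexError(f"column {column} out of range 1..{self.n_columns}")
        col = self.counts[:, column - 1]
        out = {a: int(col[i]) for i, a in enumerate(self.ALLELE_ORDER)}
        out[MISSING] = int(self.n_missing[column - 1])
        return out


# Event kinds / regions / classifications.
SUBSTITUTION = "substitution"
INSERTION = "insertion"
DELETION = "deletion"

REGION_INSIDE = "inside_orf"
REGION_OUTSIDE = "outside_orf"
REGION_SPANNING = "spanning"

TRANSITION = "transition"
TRANSVERSION = "transversion"

FRAMESHIFT = "frameshift"
IN_FRAME = "in_frame"


@dataclass(frozen=True)
class MutationEvent:
    """A substitution or indel event on the ancestral coordinate system.

    ``interval_start``/``interval_end`` follow the ``start_end`` reporting
    convention: for substitutions the first and last substituted ancestral
    positions; for indels the two ancestral positions flanking the
    (right-normalized) inserted/deleted bases, so a deletion of L bases
    satisfies ``interval_end - interval_start - 1 == L`` and an insertion has
    ``interval_end == interval_start + 1``.
    """

    event_kind: str
    anc_alleles: str
    der_alleles: str
    interval_start: int
    interval_end: int
    copy_ids: tuple[str, ...] = ()
    region: Optional[str] = None
    pattern: Optional[str] = None
    ts_tv: Optional[str] = None
    codon_position: Optional[int] = None
    effect: Optional[str] = None
    frame_effect: Optional[str] = None

    def __post_init__(self) -> None:
        if self.event_kind not in (SUBSTITUTION, INSERTION, DELETION):
            raise ValueError(f"unknown event kind {self.event_kind!r}")
        if self.event_kind == SUBSTITUTION:
            if len(self.anc_alleles) != len(self.der_alleles) or not self.anc_alleles:
                raise ValueError("substitution alleles must be same non-zero length")
            if any(a == d for a, d in zip(self.anc_alleles, self.der_alleles)):
                raise ValueError("substitution alleles must differ at every position")
        elif self.event_kind == INSERTION:
            if self.anc_alleles or not self.der_alleles:
                raise ValueError("insertion must have derived alleles only")
            if self.interval_end != self.interval_start + 1:
                raise ValueError("insertion interval must be a flank pair (f, f+1)")
        elif self.event_kind == DELETION:
            if self.der_alleles or not self.anc_alleles:
                raise ValueError("deletion must have ancestral alleles only")

    @property
    def length(self) -> int:
        return max(len(self.anc_alleles), len(self.der_alleles))

    @property
    def interval_label(self) -> str:
        """The ``start_end`` coordinate string used in report tables."""
        return f"{self.interval_start}_{self.interval_end}"

    @property
    def key(self) -> tuple:
        """Identity used for deduplication of recurrent events."""
        return (
            self.event_kind,
            self.interval_start,
            self.interval_end,
            self.anc_alleles,
            self.der_alleles,
        )

    def with_carriers(self, copy_ids: Iterable[str]) -> "MutationEvent":
        return replace(self, copy_ids=tuple(copy_ids))


@dataclass
class SimTruth:
    """Ground-truth ledger emitted by the simulator / fixture builder."""

    events: list[MutationEvent] = field(default_factory=list)
    config: Optional[object] = None

    @property
    def keys(self) -> set[tuple]:
        return {e.key for e in self.events}


def gc_content(residues: str) -> float:
    """GC fraction of a nucleotide string.

    Gaps and ``N`` are excluded from both numerator and denominator, so the
    value is invariant under gap insertion and case change.

    Raises
    ------
    ValueError
        If the string contains no A/C/G/T base.
    """
    seq = residues.upper()
    counts = {b: seq.count(b) for b in BASES}
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("GC content undefined: no A/C/G/T bases")
    return (counts["G"] + counts["C"]) / denom
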