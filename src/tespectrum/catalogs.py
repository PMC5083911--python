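"""Published reference catalogs for the two C. suppressalis TE families.

The study this pipeline reproduces reports, for the piggyBac-like element
CsuPLE1.1 (GenBank JX294476) and the Ty3/gypsy element Csu-Ty3 (KJ191261):

* per-group mean counts of single-base substitution categories
  (transitions/transversions and the four transition patterns), and
* the complete catalog of indels and multi-base substitutions observed
  across all copies, with ``start_end`` flank intervals.

Individual copy sequences were not deposited, so the catalogs are
re-embedded here as structured data and replayed onto synthetic ancestral
sequences (the sequences are synthetic scaffolds: random context
constrained only so that each catalog event reproduces its published
interval string).  This lets the whole caller stack be exercised against
the published event counts without the original chromatograms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model import (
    BASES,
    DELETION,
    INSERTION,
    SUBSTITUTION,
    AlignmentSet,
    MutationEvent,
    OrfAnnotation,
    SimTruth,
)
from .simulate import PlantedEvent, build_fixture

CSUPLE1 = "CsuPLE1.1"
CSUTY3 = "Csu-Ty3"

#: Published per-group means of the single-base substitution summary
#: (4 groups per element; values are means across groups).
PUBLISHED_CATEGORY_MEANS = {
    CSUPLE1: {"transition": 44.5, "transversion": 18.25},
    CSUTY3: {"transition": 51.75, "transversion": 24.5},
}

#: Published per-group means of the four transition patterns.
PUBLISHED_TRANSITION_MEANS = {
    CSUPLE1: {"A>G": 15.75, "T>C": 14.5, "G>A": 7.25, "C>T": 7.0},
    CSUTY3: {"A>G": 17.75, "T>C": 15.5, "G>A": 10.25, "C>T": 8.25},
}

#: Published GC compositions of the two reference elements (percent).
PUBLISHED_GC_PERCENT = {CSUPLE1: 35.9, CSUTY3: 37.3}


@dataclass(frozen=True)
class CatalogRow:
    """One published indel: flank interval plus bases (or length only)."""

    kind: str
    start: int          # left flank (deletions/insertions)
    end: int            # right flank
    bases: Optional[str] = None   # stated base content, when printed
    length: Optional[int] = None  # for rows printed as "<n> nt"
    region: str = ""

    def __post_init__(self) -> None:
        if self.kind == DELETION:
            stated = self.length if self.length is not None else len(self.bases or "")
            assert stated == self.end - self.start - 1, (
                f"deletion {self.start}_{self.end} inconsistent with length {stated}"
            )
        elif self.kind == INSERTION:
            assert self.end == self.start + 1

    @property
    def del_length(self) -> int:
        return self.length if self.length is not None else len(self.bases or "")

    @property
    def interval_label(self) -> str:
        return f"{self.start}_{self.end}"


@dataclass(frozen=True)
class MultiBaseRow:
    """One published adjacent multi-base substitution."""

    position: int
    anc: str
    der: str
    region: str = ""


_IN, _OUT = "inside", "outside"

#: CsuPLE1.1 indel catalog: 8 single-base deletions, 5 longer deletions,
#: 5 single-base insertions, 6 longer insertions.
CSUPLE1_INDELS = [
    # inside the transposase ORF
    CatalogRow(DELETION, 1415, 1417, bases="T", region=_IN),
    CatalogRow(DELETION, 1531, 1533, bases="A", region=_IN),
    CatalogRow(DELETION, 1735, 1737, bases="G", region=_IN),
    CatalogRow(DELETION, 750, 761, length=10, region=_IN),
    CatalogRow(DELETION, 1530, 1533, bases="AA", region=_IN),
    CatalogRow(DELETION, 1606, 1732, length=125, region=_IN),
    CatalogRow(DELETION, 2118, 2128, length=9, region=_IN),
    CatalogRow(INSERTION, 1532, 1533, bases="A", region=_IN),
    CatalogRow(INSERTION, 1798, 1799, bases="AGGTATA", region=_IN),
    # outside the ORF
    CatalogRow(DELETION, 49, 51, bases="A", region=_OUT),
    CatalogRow(DELETION, 50, 52, bases="T", region=_OUT),
    CatalogRow(DELETION, 77, 79, bases="T", region=_OUT),
    CatalogRow(DELETION, 556, 558, bases="A", region=_OUT),
    CatalogRow(DELETION, 2312, 2314, bases="T", region=_OUT),
    CatalogRow(DELETION, 79, 91, length=11, region=_OUT),
    CatalogRow(INSERTION, 50, 51, bases="A", region=_OUT),
    CatalogRow(INSERTION, 129, 130, bases="A", region=_OUT),
    CatalogRow(INSERTION, 548, 549, bases="G", region=_OUT),
    CatalogRow(INSERTION, 2313, 2314, bases="T", region=_OUT),
    CatalogRow(INSERTION, 207, 208, bases="ACG", region=_OUT),
    CatalogRow(INSERTION, 539, 540, bases="CCTGCCT", region=_OUT),
    CatalogRow(INSERTION, 2313, 2314, bases="TT", region=_OUT),
    CatalogRow(INSERTION, 2313, 2314, bases="TTT", region=_OUT),
    CatalogRow(INSERTION, 2313, 2314, bases="TC", region=_OUT),
]

#: Csu-Ty3 indel catalog: 8 single-base deletions, 4 longer deletions,
#: 6 single-base insertions, 4 longer insertions.
CSUTY3_INDELS = [
    # inside the ORFs
    CatalogRow(DELETION, 1133, 1135, bases="G", region=_IN),
    CatalogRow(DELETION, 1389, 1391, bases="G", region=_IN),
    CatalogRow(DELETION, 1397, 1399, bases="T", region=_IN),
    CatalogRow(DELETION, 1646, 1648, bases="A", region=_IN),
    CatalogRow(DELETION, 1810, 1812, bases="T", region=_IN),
    CatalogRow(DELETION, 65, 1029, length=963, region=_IN),
    CatalogRow(DELETION, 1539, 1567, length=27, region=_IN),
    CatalogRow(INSERTION, 272, 273, bases="C", region=_IN),
    CatalogRow(INSERTION, 555, 556, bases="A", region=_IN),
    CatalogRow(INSERTION, 576, 577, bases="G", region=_IN),
    CatalogRow(INSERTION, 1852, 1853, bases="A", region=_IN),
    CatalogRow(INSERTION, 896, 897, bases="TTCA", region=_IN),
    CatalogRow(INSERTION, 1163, 1164, bases="TTAT", region=_IN),
    CatalogRow(INSERTION, 1529, 1530, length=30, region=_IN),
    # outside the ORFs
    CatalogRow(DELETION, 47, 49, bases="A", region=_OUT),
    CatalogRow(DELETION, 128, 130, bases="A", region=_OUT),
    CatalogRow(DELETION, 729, 731, bases="A", region=_OUT),
    CatalogRow(DELETION, 696, 701, bases="CTTT", region=_OUT),
    CatalogRow(DELETION, 695, 701, bases="TCTTT", region=_OUT),
    CatalogRow(INSERTION, 19, 20, bases="A", region=_OUT),
    CatalogRow(INSERTION, 200, 201, bases="T", region=_OUT),
    CatalogRow(INSERTION, 139, 140, bases="TGTGA", region=_OUT),
]

#: Published multi-base substitutions (positions chosen on the synthetic
#: scaffold; the base changes are as published).
CSUPLE1_MULTIBASE = [
    MultiBaseRow(1001, "AG", "GA", region=_IN),
    MultiBaseRow(2250, "GT", "AA", region=_OUT),
]
CSUTY3_MULTIBASE = [
    MultiBaseRow(300, "AA", "TT", region=_IN),
    MultiBaseRow(350, "GA", "TC", region=_IN),
    MultiBaseRow(400, "CG", "GA", region=_IN),
    MultiBaseRow(450, "AT", "TA", region=_IN),
    MultiBaseRow(500, "AT", "CC", region=_IN),
    MultiBaseRow(800, "ACA", "TTG", region=_IN),
]

#: Synthetic scaffold geometry per element: (length, ORFs, copies).
_GEOMETRY = {
    CSUPLE1: (2406, (OrfAnnotation("transposase", 601, 2196),), 84),
    CSUTY3: (
        1900,
        (OrfAnnotation("ORF1", 265, 693), OrfAnnotation("ORF2", 736, 1863)),
        140,
    ),
}
_CATALOGS = {
    CSUPLE1: (CSUPLE1_INDELS, CSUPLE1_MULTIBASE),
    CSUTY3: (CSUTY3_INDELS, CSUTY3_MULTIBASE),
}


def _scaffold_sequence(
    length: int,
    indels: list[CatalogRow],
    multibase: list[MultiBaseRow],
    rng: np.random.Generator,
    gc: float,
) -> tuple[str, dict[int, str]]:
    """Random ancestral scaffold constrained so every catalog row reproduces
    its published interval after right-normalization.

    Returns the sequence and the generated base content for length-only
    rows (keyed by left flank), used to fill in planted deletions.
    """
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = list(rng.choice(list(BASES), size=length, p=p))

    for row in multibase:
        for i, b in enumerate(row.anc):
            seq[row.position - 1 + i] = b
    for row in indels:
        if row.kind == DELETION and row.bases:
            for i, b in enumerate(row.bases):
                seq[row.start + i] = b
    # collect every "must differ" constraint per position, then apply jointly
    generated: dict[int, str] = {}
    banned: dict[int, set[str]] = {}
    for row in indels:
        if row.kind == DELETION:
            # no right slide: base after the deletion differs from its first base
            banned.setdefault(row.end, set()).add(seq[row.start])
        else:
            first = (row.bases or "")[:1]
            if not first:  # length-only insertion: generate content now
                content = "".join(rng.choice(list(BASES), size=row.length))
                generated[row.start] = content
                first = content[0]
            banned.setdefault(row.end, set()).add(first)
    for pos, bad in banned.items():
        if seq[pos - 1] in bad:
            allowed = [b for b in BASES if b not in bad]
            seq[pos - 1] = allowed[int(rng.integers(len(allowed)))]
    return "".join(seq), generated


def catalog_fixture(
    element: str, seed: int = 0
) -> tuple[AlignmentSet, SimTruth, tuple[OrfAnnotation, ...], list[CatalogRow]]:
    """Synthetic alignment replaying an element's published event catalog.

    Every catalog indel and multi-base substitution is planted in its own
    carrier copy of a scaffold alignment sized like the study (84 copies
    for CsuPLE1.1 over 21 populations, 140 for Csu-Ty3 over 7); all other
    copies equal the scaffold ancestor.  Returns the alignment, the truth
    ledger, the ORF annotations and the catalog rows.
    """
    if element not in _GEOMETRY:
        raise KeyError(f"unknown element {element!r}; try {sorted(_GEOMETRY)}")
    length, orfs, n_copies = _GEOMETRY[element]
    indels, multibase = _CATALOGS[element]
    rng = np.random.default_rng(seed)
    gc = PUBLISHED_GC_PERCENT[element] / 100.0
    seq, generated = _scaffold_sequence(length, indels, multibase, rng, gc)

    planted: list[PlantedEvent] = []
    carrier = 0
    for row in indels:
        if row.kind == DELETION:
            planted.append(
                PlantedEvent(
                    kind=DELETION,
                    position=row.start + 1,
                    bases=row.bases or "",
                    length=row.del_length,
                    carriers=(carrier,),
                )
            )
        else:
            bases = row.bases or generated[row.start]
            planted.append(
                PlantedEvent(
                    kind=INSERTION, position=row.start, bases=bases, carriers=(carrier,)
                )
            )
        carrier += 1
    for row in multibase:
        planted.append(
            PlantedEvent(
                kind=SUBSTITUTION, position=row.position, bases=row.der, carriers=(carrier,)
            )
        )
        carrier += 1
    populations = 21 if element == CSUPLE1 else 7
    aln, truth = build_fixture(seq, planted, copies=n_copies, populations=populations)
    return aln, truth, orfs, indels


def indel_category_counts(events: list[MutationEvent]) -> dict[str, int]:
    """Tally indel events into the four published categories."""
    return {
        "single_base_deletions": sum(
            1 for e in events if e.event_kind == DELETION and e.length == 1
        ),
        "multi_base_deletions": sum(
            1 for e in events if e.event_kind == DELETION and e.length >= 2
        ),
        "single_base_insertions": sum(
            1 for e in events if e.event_kind == INSERTION and e.length == 1
        ),
        "multi_base_insertions": sum(
            1 for e in events if e.event_kind == INSERTION and e.length >= 2
        ),
    }
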