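"""Substitution and indel event detection against the ancestral profile.

Substitutions are read per copy at called base columns where the copy
carries a minority base; maximal runs of adjacent substituted ancestral
positions in one copy merge into multi-base events.  Indels are read as
maximal runs of gapped (deletion) or occupied (insertion) columns per copy.
Indel placements are right-normalized within repeated sequence context and
reported with the ``start_end`` flank convention: a deletion of L bases has
``end - start - 1 == L`` and an insertion is reported between its two
flanking ancestral positions.  Recurrent events deduplicate on the identity
of the change (kind, interval, alleles), pooling carrier copies.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import replace
from typing import NamedTuple, Sequence

import numpy as np

from .model import (
    BASES,
    DELETION,
    GAP,
    INSERTION,
    SUBSTITUTION,
    AlignmentSet,
    AncestralProfile,
    COL_AMBIGUOUS,
    COL_INSERTION,
    MutationEvent,
    TESpectrumError,
)


class SubstitutionCall(NamedTuple):
    """One (copy, column) single-base substitution observation."""

    copy_id: str
    column: int          # 1-based alignment column
    ancestral_position: int
    anc: str
    der: str


def _check_consistency(aln: AlignmentSet, profile: AncestralProfile) -> None:
    if aln.n_columns != profile.n_columns:
        raise TESpectrumError(
            f"profile has {profile.n_columns} columns, alignment {aln.n_columns}"
        )


def call_substitutions(
    aln: AlignmentSet, profile: AncestralProfile
) -> list[SubstitutionCall]:
    """Per-copy single-column substitution calls.

    A call requires: the column's ancestral state is a called base, the
    copy carries a different base there, and that base is a minority allele
    under the profile's thresholds.  Ambiguous columns yield no calls.
    """
    _check_consistency(aln, profile)
    M = aln.matrix
    anc = profile.ancestral_state
    callable_col = (
        (profile.column_class != COL_AMBIGUOUS)
        & (profile.column_class != COL_INSERTION)
        & profile.is_positional
    )
    is_base = np.isin(M, BASES)
    denom = profile.counts.sum(axis=0)
    diff = is_base & (M != anc[None, :]) & callable_col[None, :]
    calls: list[SubstitutionCall] = []
    allele_index = {a: i for i, a in enumerate(AncestralProfile.ALLELE_ORDER)}
    copy_ids = aln.copy_ids
    for i, j in zip(*np.nonzero(diff)):
        der = M[i, j]
        if profile.counts[allele_index[der], j] / denom[j] > profile.minor_threshold + 1e-12:
            continue  # too common to be a derived minority allele
        calls.append(
            SubstitutionCall(
                copy_id=copy_ids[i],
                column=int(j) + 1,
                ancestral_position=int(profile.ancestral_position[j]),
                anc=str(anc[j]),
                der=str(der),
            )
        )
    return calls


def merge_adjacent(
    calls: Sequence[SubstitutionCall], profile: AncestralProfile
) -> list[MutationEvent]:
    """Merge per-copy calls at consecutive ancestral positions into events.

    Maximal runs become one substitution event whose alleles are the
    concatenated ancestral/derived bases; isolated calls become single-base
    events.  Events are not yet deduplicated across copies.
    """
    by_copy: dict[str, list[SubstitutionCall]] = defaultdict(list)
    for c in calls:
        by_copy[c.copy_id].append(c)
    events: list[MutationEvent] = []
    for copy_id, copy_calls in by_copy.items():
        copy_calls.sort(key=lambda c: c.ancestral_position)
        run: list[SubstitutionCall] = []
        for call in copy_calls:
            if run and call.ancestral_position == run[-1].ancestral_position + 1:
                run.append(call)
            else:
                if run:
                    events.append(_run_to_event(run, copy_id))
                run = [call]
        if run:
            events.append(_run_to_event(run, copy_id))
    return events


def _run_to_event(run: list[SubstitutionCall], copy_id: str) -> MutationEvent:
    return MutationEvent(
        event_kind=SUBSTITUTION,
        anc_alleles="".join(c.anc for c in run),
        der_alleles="".join(c.der for c in run),
        interval_start=run[0].ancestral_position,
        interval_end=run[-1].ancestral_position,
        copy_ids=(copy_id,),
    )


def call_indels(aln: AlignmentSet, profile: AncestralProfile) -> list[MutationEvent]:
    """Detect insertion and deletion events, one per maximal per-copy run.

    Deletions: maximal runs of adjacent ancestral positions at which a copy
    is gapped while the called ancestral state is a base.  Insertions:
    maximal runs of adjacent insertion columns occupied by a copy.  Events
    are interval-normalized (see :func:`normalize_indel_interval`) but not
    deduplicated.
    """
    _check_consistency(aln, profile)
    M = aln.matrix
    ancestral = profile.ancestral_sequence
    events: list[MutationEvent] = []

    # --- deletions, scanned along ancestral coordinates ---------------
    positional_cols = np.nonzero(profile.is_positional)[0]
    callable_mask = profile.column_class[positional_cols] != COL_AMBIGUOUS
    sub_matrix = M[:, positional_cols]  # (copies, L) in ancestral order
    gap_mask = (sub_matrix == GAP) & callable_mask[None, :]
    for i, copy_id in enumerate(aln.copy_ids):
        for start, stop in _runs(gap_mask[i]):
            pos = start + 1  # 1-based ancestral position of first deleted base
            length = stop - start
            ev = MutationEvent(
                event_kind=DELETION,
                anc_alleles=ancestral[start:stop],
                der_alleles="",
                interval_start=pos - 1,
                interval_end=pos + length,
                copy_ids=(copy_id,),
            )
            events.append(normalize_indel_interval(ev, ancestral))

    # --- insertions, scanned along alignment columns ------------------
    ins_cols = profile.column_class == COL_INSERTION
    if ins_cols.any():
        # ancestral position of the nearest positional column to the left
        left_flank = np.maximum.accumulate(profile.ancestral_position)
        occupied = np.isin(M, BASES) & ins_cols[None, :]
        for i, copy_id in enumerate(aln.copy_ids):
            for start, stop in _runs(occupied[i]):
                flank = int(left_flank[start])
                ev = MutationEvent(
                    event_kind=INSERTION,
                    anc_alleles="",
                    der_alleles="".join(M[i, start:stop].tolist()),
                    interval_start=flank,
                    interval_end=flank + 1,
                    copy_ids=(copy_id,),
                )
                events.append(normalize_indel_interval(ev, ancestral))
    return events


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean vector as [start, stop) pairs."""
    if not mask.any():
        return []
    padded = np.diff(np.concatenate(([0], mask.astype(np.int8), [0])))
    starts = np.nonzero(padded == 1)[0]
    stops = np.nonzero(padded == -1)[0]
    return list(zip(starts.tolist(), stops.tolist()))


def normalize_indel_interval(event: MutationEvent, ancestral: str) -> MutationEvent:
    """Right-normalize an indel and set its reported flank interval.

    Within repeated context (homopolymers, tandem repeats) an indel has
    several equivalent placements; the placement is shifted as far right
    as possible and the event is reported between its flanking ancestral
    positions: a deletion of bases ``s..e`` becomes ``(s-1)_(e+1)`` and an
    insertion after position ``f`` becomes ``f_(f+1)``.  ``anc_alleles`` of
    a deletion keeps the bases of the given (left-most) placement.
    """
    n = len(ancestral)
    if event.event_kind == DELETION:
        length = len(event.anc_alleles)
        s = event.interval_start + 1  # 1-based first deleted base
        # deleting [s, s+L-1] equals deleting [s+1, s+L] iff anc[s] == anc[s+L]
        while s + length <= n and ancestral[s - 1] == ancestral[s + length - 1]:
            s += 1
        return replace(event, interval_start=s - 1, interval_end=s + length)
    if event.event_kind == INSERTION:
        f = event.interval_start
        ins = event.der_alleles
        while f + 1 <= n and ancestral[f] == ins[0]:
            f += 1
            ins = ins[1:] + ins[0]
        return replace(event, der_alleles=ins, interval_start=f, interval_end=f + 1)
    return event


def deduplicate(events: Sequence[MutationEvent]) -> list[MutationEvent]:
    """Collapse recurrent events: a mutation observed at the same position
    with the same alleles in several copies is counted once, carriers pooled.

    The identity key includes the derived allele, so distinct changes at one
    position remain distinct events.  Idempotent.
    """
    grouped: dict[tuple, list[MutationEvent]] = defaultdict(list)
    for e in events:
        grouped[e.key].append(e)
    out = []
    for key in sorted(grouped, key=lambda k: (k[1], k[2], k[0], k[4], k[3])):
        members = grouped[key]
        carriers = sorted({cid for m in members for cid in m.copy_ids})
        out.append(members[0].with_carriers(carriers))
    return out
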