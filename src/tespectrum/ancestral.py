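"""Majority-rule ancestral state calling on a TE copy alignment.

Per alignment column, the ancestral state is the majority allele when its
frequency (excluding missing data) reaches the major threshold; otherwise,
if a designated ancestral reference copy is given and its allele reaches
the threshold, the reference allele; otherwise the column is ambiguous and
contributes no mutation calls.  Columns whose ancestral state is the gap
are insertion columns and carry no ancestral coordinate; all other columns
are numbered 1..L along the ungapped ancestral sequence.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .model import (
    GAP,
    MISSING,
    AlignmentSet,
    AncestralProfile,
    COL_AMBIGUOUS,
    COL_DELETION,
    COL_FIXED,
    COL_INSERTION,
    COL_SUBSTITUTION,
    TESpectrumError,
)

ALLELES = AncestralProfile.ALLELE_ORDER  # A, C, G, T, '-'


class ThresholdError(TESpectrumError):
    """Invalid majority/minority threshold combination."""


def column_allele_counts(aln: AlignmentSet, column: int) -> dict[str, int]:
    """Allele counts over {A,C,G,T,-} at a 1-based column, plus ``N`` count.

    Missing (``N``) characters are tracked separately and excluded from
    frequency denominators downstream.
    """
    if not (1 <= column <= aln.n_columns):
        raise IndexError(f"column {column} out of range 1..{aln.n_columns}")
    col = aln.matrix[:, column - 1]
    out = {a: int((col == a).sum()) for a in ALLELES}
    out[MISSING] = int((col == MISSING).sum())
    return out


def call_ancestral_profile(
    aln: AlignmentSet,
    major_threshold: float = 0.85,
    minor_threshold: Optional[float] = None,
    reference_id: Optional[str] = None,
) -> AncestralProfile:
    """Build the per-column :class:`AncestralProfile` for an alignment.

    Parameters
    ----------
    aln:
        Alignment with at least two copies.
    major_threshold:
        Minimum frequency for the majority allele to be called ancestral.
        Comparison is ``>=`` so that e.g. 17/20 copies at 85% is callable.
    minor_threshold:
        Maximum frequency for a derived allele; defaults to
        ``1 - major_threshold``.
    reference_id:
        Overrides ``aln.reference_id``; used to anchor coordinates at
        ambiguous columns and to break ties at the threshold boundary.
    """
    if len(aln) < 2:
        raise TESpectrumError("ancestral calling needs >= 2 copies")
    if not (0.5 < major_threshold <= 1.0):
        raise ThresholdError(f"major_threshold must be in (0.5, 1]; got {major_threshold}")
    if minor_threshold is None:
        minor_threshold = 1.0 - major_threshold
    if minor_threshold >= major_threshold:
        raise ThresholdError(
            f"minor_threshold {minor_threshold} must be < major_threshold {major_threshold}"
        )
    reference_id = reference_id or aln.reference_id
    ref_row = None
    if reference_id is not None:
        ref_row = aln.matrix[aln.copy_ids.index(reference_id)]

    M = aln.matrix
    ncol = aln.n_columns
    counts = np.stack([(M == a).sum(axis=0) for a in ALLELES])  # (5, ncol)
    n_missing = (M == MISSING).sum(axis=0)
    denom = counts.sum(axis=0)  # copies minus missing

    state = np.empty(ncol, dtype="<U1")
    freq = np.zeros(ncol, dtype=float)
    col_class = np.empty(ncol, dtype="<U12")

    allele_arr = np.array(ALLELES)
    for j in range(ncol):
        if denom[j] == 0:  # every copy missing: unusable column
            state[j] = MISSING
            col_class[j] = COL_AMBIGUOUS
            continue
        col_counts = counts[:, j]
        top = int(np.argmax(col_counts))
        # tie at the maximum: prefer the designated reference allele
        if ref_row is not None:
            ref_allele = ref_row[j]
            if ref_allele in ALLELES:
                k = ALLELES.index(ref_allele)
                if col_counts[k] == col_counts[top]:
                    top = k
        top_freq = col_counts[top] / denom[j]
        plurality = allele_arr[top]
        if top_freq >= major_threshold:
            state[j] = plurality
            freq[j] = top_freq
            n_gap = col_counts[ALLELES.index(GAP)]
            n_bases_minor = denom[j] - col_counts[top] - (0 if plurality == GAP else n_gap)
            if plurality == GAP:
                col_class[j] = COL_INSERTION if denom[j] > col_counts[top] else COL_FIXED
            elif denom[j] == col_counts[top]:
                col_class[j] = COL_FIXED
            elif n_bases_minor > 0:
                # minority bases present (possibly alongside gaps): the
                # substitution caller reads bases here, the indel caller gaps
                col_class[j] = COL_SUBSTITUTION
            else:
                col_class[j] = COL_DELETION
        else:
            # no callable direction; keep the plurality (or reference) state
            # purely to anchor ancestral coordinates
            state[j] = plurality
            freq[j] = top_freq
            col_class[j] = COL_AMBIGUOUS

    positional = (state != GAP) & (state != MISSING)
    position = np.zeros(ncol, dtype=int)
    position[positional] = np.arange(1, positional.sum() + 1)

    return AncestralProfile(
        counts=counts,
        n_missing=n_missing,
        ancestral_state=state,
        ancestral_frequency=freq,
        column_class=col_class,
        ancestral_position=position,
        major_threshold=major_threshold,
        minor_threshold=minor_threshold,
        reference_id=reference_id,
    )


def profile_frame(profile: AncestralProfile):
    """Profile dump as a DataFrame (column, position, alleles, class)."""
    import pandas as pd

    data = {
        "column": np.arange(1, profile.n_columns + 1),
        "ancestral_position": profile.ancestral_position,
        "ancestral_state": profile.ancestral_state,
        "ancestral_frequency": profile.ancestral_frequency,
        "column_class": profile.column_class,
        "n_missing": profile.n_missing,
    }
    for i, a in enumerate(ALLELES):
        data[f"count_{'gap' if a == GAP else a}"] = profile.counts[i]
    return pd.DataFrame(data)
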