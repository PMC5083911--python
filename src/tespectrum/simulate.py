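"""Synthetic TE-family generator with a planted-event truth ledger.

The generator emulates the study design the pipeline targets: a few
thousand bases of low-GC ancestral element containing one or more ORFs,
copied into 84 (21 populations x 4) or 140 (7 x 20) per-individual copies,
each copy carrying a handful of independent single-base substitutions drawn
from a 12-pattern spectrum with transition and A:T>G:C bias, rare adjacent
multi-base substitutions, and rare indels whose lengths mix a dominant
1-bp class with a long tail.  Events are emitted directly as a gapped
alignment (insertions open their own column blocks), so alignment noise is
out of scope by construction, and every planted event is recorded in a
:class:`~tespectrum.model.SimTruth` ledger after the same interval
normalization and deduplication the caller applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .model import (
    BASES,
    DELETION,
    GAP,
    INSERTION,
    SUBSTITUTION,
    AlignedCopy,
    AlignmentSet,
    MutationEvent,
    OrfAnnotation,
    SimTruth,
    TESpectrumError,
)
from .effects import ALL_PATTERNS, TRANSITION_PATTERNS, TRANSVERSION_PATTERNS
from .variants import deduplicate, normalize_indel_interval


class ConfigError(TESpectrumError):
    """Unsatisfiable simulation configuration."""


class FixtureError(TESpectrumError):
    """Planted fixture events overlap or do not fit the ancestral sequence."""


def pattern_rates_from_bias(
    total: float, kappa: float = 2.44, at_gc_bias: float = 2.0
) -> dict[str, float]:
    """Build 12 per-pattern expected event counts per copy.

    ``kappa`` is the transition:transversion event ratio; ``at_gc_bias``
    multiplies the A>G / T>C patterns relative to G>A / C>T within the
    transitions.  Transversions are uniform.
    """
    ts_total = total * kappa / (1.0 + kappa)
    tv_total = total - ts_total
    unit = ts_total / (2.0 * at_gc_bias + 2.0)
    rates = {
        "A>G": at_gc_bias * unit,
        "T>C": at_gc_bias * unit,
        "G>A": unit,
        "C>T": unit,
    }
    rates.update({p: tv_total / 8.0 for p in TRANSVERSION_PATTERNS})
    return rates


def _default_rates() -> dict[str, float]:
    # Per-copy expected counts tuned to the magnitude observed for a
    # 21-copy group of a piggyBac-like element: ~62.75 unique single-base
    # substitutions per group, transitions 15.75/14.5/7.25/7, transversions
    # near-uniform at 18.25 total.
    rates = {
        "A>G": 15.75 / 21,
        "T>C": 14.5 / 21,
        "G>A": 7.25 / 21,
        "C>T": 7.0 / 21,
    }
    rates.update({p: 18.25 / 8 / 21 for p in TRANSVERSION_PATTERNS})
    return rates


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale defaults for the synthetic TE family.

    Rates are expected event counts per copy (Poisson).  The defaults mirror
    the piggyBac-like-element arm of the study design: 21 populations of 4
    copies, ~2.4 kb element at 35.9% GC with a transposase ORF, ~3
    substitutions per copy with transition and A:T>G:C bias, and rare
    indels dominated by 1-bp events with a long-tailed length mixture.
    """

    ancestral_length: int = 2400
    gc_fraction: float = 0.359
    orfs: tuple[OrfAnnotation, ...] = (OrfAnnotation("transposase", 601, 2196),)
    populations: int = 21
    copies_per_population: int = 4
    pattern_rates: Mapping[str, float] = field(default_factory=_default_rates)
    multi_base_rate: float = 2.0 / 84
    indel_rate: float = 24.0 / 84
    indel_single_fraction: float = 0.55
    indel_tail_p: float = 0.12          # geometric tail for multi-base lengths
    indel_max_length: int = 300
    max_carrier_fraction: float = 0.15  # planted-event frequency guarantee
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.gc_fraction < 1.0):
            raise ConfigError("gc_fraction must be in (0, 1)")
        if any(r < 0 for r in self.pattern_rates.values()):
            raise ConfigError("pattern rates must be non-negative")
        if self.multi_base_rate < 0 or self.indel_rate < 0:
            raise ConfigError("rates must be non-negative")
        spans = sorted((o.start, o.end) for o in self.orfs)
        for (s1, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ConfigError("ORFs must not overlap")
        for o in self.orfs:
            if o.end > self.ancestral_length:
                raise ConfigError(f"ORF {o.name} exceeds ancestral_length")

    @property
    def n_copies(self) -> int:
        return self.populations * self.copies_per_population


_STOPS = ("TAA", "TAG", "TGA")


def simulate_ancestral(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> tuple[str, tuple[OrfAnnotation, ...]]:
    """Random ancestral sequence at the configured GC with valid ORFs.

    ORF spans begin with ATG, end with a stop codon, and contain no internal
    in-frame stop; bases elsewhere are i.i.d. with expected GC equal to
    ``gc_fraction``.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    gc = config.gc_fraction
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = list(rng.choice(list(BASES), size=config.ancestral_length, p=p))
    for orf in config.orfs:
        if orf.length < 9:
            raise ConfigError(f"ORF {orf.name} too short for start + codon + stop")
        seq[orf.start - 1 : orf.start + 2] = ["A", "T", "G"]
        stop = _STOPS[rng.integers(len(_STOPS))]
        seq[orf.end - 3 : orf.end] = list(stop)
        for cpos in range(orf.start + 2, orf.end - 3, 3):
            while "".join(seq[cpos : cpos + 3]) in _STOPS:
                seq[cpos : cpos + 3] = rng.choice(list(BASES), size=3, p=p)
    return "".join(seq), tuple(config.orfs)


@dataclass(frozen=True)
class PlantedEvent:
    """A deterministic event specification for :func:`build_fixture`.

    ``position`` is the 1-based ancestral coordinate of the first affected
    base for substitutions and deletions, and the left flanking position
    for insertions.  ``bases`` holds derived bases (substitution), inserted
    bases (insertion) or, optionally, the expected ancestral bases
    (deletion, for validation); ``length`` is required for deletions whose
    bases are unspecified.
    """

    kind: str
    position: int
    bases: str = ""
    length: Optional[int] = None
    carriers: tuple[int, ...] = (0,)

    def del_length(self) -> int:
        if self.length is not None:
            return self.length
        return len(self.bases)


class _CopyPlan:
    """Accumulates non-overlapping events for one copy."""

    def __init__(self) -> None:
        self.blocked: set[int] = set()
        self.subs: list[tuple[int, str]] = []      # (pos, derived string)
        self.dels: list[tuple[int, int]] = []      # (pos, length)
        self.ins: list[tuple[int, str]] = []       # (flank, string)

    def try_block(self, lo: int, hi: int) -> bool:
        span = set(range(lo, hi + 1))
        if span & self.blocked:
            return False
        self.blocked |= span
        return True


def _assemble(
    ancestral: str,
    plans: Sequence[_CopyPlan],
    copy_ids: Sequence[str],
    populations: Sequence[str],
    groups: Optional[Sequence[Optional[str]]] = None,
) -> AlignmentSet:
    """Emit the gapped alignment implied by per-copy event plans.

    Insertions in different copies at the same flank share a column block
    only when the inserted strings are identical; distinct strings open
    separate blocks (as an MSA of distinct clones would represent them).
    """
    n = len(ancestral)
    n_copies = len(plans)
    M = np.frombuffer(ancestral.encode("ascii"), dtype="S1").astype("U1")
    M = np.tile(M, (n_copies, 1))
    for i, plan in enumerate(plans):
        for pos, der in plan.subs:
            M[i, pos - 1 : pos - 1 + len(der)] = list(der)
        for pos, length in plan.dels:
            M[i, pos - 1 : pos - 1 + length] = GAP
    blocks: dict[tuple[int, str], list[int]] = {}
    for i, plan in enumerate(plans):
        for flank, string in plan.ins:
            blocks.setdefault((flank, string), []).append(i)
    pieces: list[np.ndarray] = []
    cursor = 0
    for (flank, string), carriers in sorted(blocks.items()):
        if flank > cursor:
            pieces.append(M[:, cursor:flank])
            cursor = flank
        block = np.full((n_copies, len(string)), GAP, dtype="U1")
        for i in carriers:
            block[i, :] = list(string)
        pieces.append(block)
    pieces.append(M[:, cursor:n])
    full = np.concatenate(pieces, axis=1) if len(pieces) > 1 else pieces[0]
    if groups is None:
        groups = [None] * n_copies
    copies = [
        AlignedCopy(
            copy_id=copy_ids[i],
            residues="".join(full[i].tolist()),
            population=populations[i],
            group=groups[i],
        )
        for i in range(n_copies)
    ]
    return AlignmentSet(copies)


def _truth_from_plans(
    ancestral: str, plans: Sequence[_CopyPlan], copy_ids: Sequence[str]
) -> SimTruth:
    raw: list[MutationEvent] = []
    for i, plan in enumerate(plans):
        cid = (copy_ids[i],)
        for pos, der in plan.subs:
            raw.append(
                MutationEvent(
                    event_kind=SUBSTITUTION,
                    anc_alleles=ancestral[pos - 1 : pos - 1 + len(der)],
                    der_alleles=der,
                    interval_start=pos,
                    interval_end=pos + len(der) - 1,
                    copy_ids=cid,
                )
            )
        for pos, length in plan.dels:
            ev = MutationEvent(
                event_kind=DELETION,
                anc_alleles=ancestral[pos - 1 : pos - 1 + length],
                der_alleles="",
                interval_start=pos - 1,
                interval_end=pos + length,
                copy_ids=cid,
            )
            raw.append(normalize_indel_interval(ev, ancestral))
        for flank, string in plan.ins:
            ev = MutationEvent(
                event_kind=INSERTION,
                anc_alleles="",
                der_alleles=string,
                interval_start=flank,
                interval_end=flank + 1,
                copy_ids=cid,
            )
            raw.append(normalize_indel_interval(ev, ancestral))
    return SimTruth(events=deduplicate(raw))


def simulate_family(
    config: SimulationConfig = SimulationConfig(),
) -> tuple[AlignmentSet, SimTruth]:
    """Simulate one TE family: gapped alignment plus planted-event truth.

    Substitution events are drawn per pattern as Poisson counts per copy and
    placed uniformly over ancestral sites carrying the pattern's source
    base; indels are placed uniformly with the configured length mixture.
    Placement enforces a margin of one base between events within a copy
    (so distinct planted events never merge into one run) and caps the
    carriers touching any site at ``max_carrier_fraction`` of the copies
    (so every planted event stays below the caller's minority threshold).
    """
    rng = np.random.default_rng(config.seed)
    ancestral, _orfs = simulate_ancestral(config, rng)
    n = len(ancestral)
    n_copies = config.n_copies
    cap = max(1, int(np.floor(config.max_carrier_fraction * n_copies)))
    site_usage = np.zeros(n + 2, dtype=int)

    pos_by_base = {
        b: (np.nonzero(np.frombuffer(ancestral.encode(), dtype="S1").astype("U1") == b)[0] + 1)
        for b in BASES
    }
    for b in BASES:
        if len(pos_by_base[b]) == 0 and any(
            config.pattern_rates.get(p, 0) > 0 for p in ALL_PATTERNS if p[0] == b
        ):
            raise ConfigError(f"no ancestral site carries source base {b}")

    copy_ids, populations = [], []
    for p in range(config.populations):
        pop = f"P{p + 1:02d}"
        for c in range(config.copies_per_population):
            copy_ids.append(f"{pop}-{c + 1:02d}")
            populations.append(pop)

    plans = [_CopyPlan() for _ in range(n_copies)]
    budget_errors = 0
    for plan in plans:
        # single-base substitutions, per pattern
        for pattern in ALL_PATTERNS:
            rate = config.pattern_rates.get(pattern, 0.0)
            if rate <= 0:
                continue
            src, der = pattern[0], pattern[2]
            sites = pos_by_base[src]
            for _ in range(rng.poisson(rate)):
                if not _place_sub(plan, rng, sites, der, site_usage, cap):
                    budget_errors += 1
        # adjacent multi-base substitutions
        for _ in range(rng.poisson(config.multi_base_rate)):
            length = 2 if rng.random() < 0.8 else 3
            if not _place_multi(plan, rng, ancestral, length, site_usage, cap):
                budget_errors += 1
        # indels
        for _ in range(rng.poisson(config.indel_rate)):
            if rng.random() < config.indel_single_fraction:
                length = 1
            else:
                length = min(1 + int(rng.geometric(config.indel_tail_p)), config.indel_max_length)
            is_del = rng.random() < 0.5
            ok = (
                _place_del(plan, rng, n, length, site_usage, cap)
                if is_del
                else _place_ins(plan, rng, n, length, site_usage, cap)
            )
            if not ok:
                budget_errors += 1
    if budget_errors:
        raise ConfigError(
            f"could not place {budget_errors} events without collisions; "
            "rates too high for ancestral_length"
        )
    aln = _assemble(ancestral, plans, copy_ids, populations)
    truth = _truth_from_plans(ancestral, plans, copy_ids)
    truth.config = config
    return aln, truth


_MAX_TRIES = 200


def _place_sub(plan, rng, sites, der, usage, cap) -> bool:
    for _ in range(_MAX_TRIES):
        pos = int(sites[rng.integers(len(sites))])
        if usage[pos] >= cap:
            continue
        if plan.try_block(pos - 1, pos + 1):
            plan.subs.append((pos, der))
            usage[pos] += 1
            return True
    return False


def _place_multi(plan, rng, ancestral, length, usage, cap) -> bool:
    n = len(ancestral)
    others = {b: [x for x in BASES if x != b] for b in BASES}
    for _ in range(_MAX_TRIES):
        pos = int(rng.integers(1, n - length + 2))
        span = range(pos, pos + length)
        if any(usage[p] >= cap for p in span):
            continue
        if plan.try_block(pos - 1, pos + length):
            der = "".join(
                others[ancestral[p - 1]][rng.integers(3)] for p in span
            )
            plan.subs.append((pos, der))
            for p in span:
                usage[p] += 1
            return True
    return False


def _place_del(plan, rng, n, length, usage, cap) -> bool:
    if length >= n // 2:
        return False
    for _ in range(_MAX_TRIES):
        pos = int(rng.integers(1, n - length + 2))
        span = range(pos, pos + length)
        if any(usage[p] >= cap for p in span):
            continue
        if plan.try_block(pos - 1, pos + length):
            plan.dels.append((pos, length))
            for p in span:
                usage[p] += 1
            return True
    return False


def _place_ins(plan, rng, n, length, usage, cap) -> bool:
    for _ in range(_MAX_TRIES):
        flank = int(rng.integers(1, n))
        if usage[flank] >= cap:
            continue
        if plan.try_block(flank, flank + 1):
            string = "".join(rng.choice(list(BASES), size=length))
            plan.ins.append((flank, string))
            usage[flank] += 1
            return True
    return False


def build_fixture(
    ancestral: str,
    planted: Sequence[PlantedEvent],
    copies: int,
    populations: int = 1,
    reference_id: Optional[str] = None,
) -> tuple[AlignmentSet, SimTruth]:
    """Deterministic alignment in which each planted event appears exactly
    in its stated carrier copies and nowhere else.

    Carrier indices are 0-based copy indices; copies are labelled
    ``F01-01`` style and distributed round-robin over ``populations``.
    Raises :class:`FixtureError` on per-copy overlap (a one-base margin is
    enforced so adjacent planted events cannot merge) or when an event's
    carrier fraction exceeds the caller's minority threshold.
    """
    n = len(ancestral)
    plans = [_CopyPlan() for _ in range(copies)]
    for ev in planted:
        if len(ev.carriers) / copies > 0.15:
            raise FixtureError(f"event at {ev.position} carried by too many copies")
        for who in ev.carriers:
            if not (0 <= who < copies):
                raise FixtureError(f"carrier index {who} out of range")
            plan = plans[who]
            if ev.kind == SUBSTITUTION:
                anc = ancestral[ev.position - 1 : ev.position - 1 + len(ev.bases)]
                if len(anc) != len(ev.bases) or any(
                    a == d for a, d in zip(anc, ev.bases)
                ):
                    raise FixtureError(
                        f"substitution at {ev.position}: derived {ev.bases!r} "
                        f"does not differ from ancestral {anc!r} at every base"
                    )
                if not plan.try_block(ev.position - 1, ev.position + len(ev.bases)):
                    raise FixtureError(f"overlap at {ev.position} in copy {who}")
                plan.subs.append((ev.position, ev.bases))
            elif ev.kind == DELETION:
                length = ev.del_length()
                if ev.position + length - 1 > n:
                    raise FixtureError(f"deletion at {ev.position} exceeds sequence")
                anc = ancestral[ev.position - 1 : ev.position - 1 + length]
                if ev.bases and anc != ev.bases:
                    raise FixtureError(
                        f"deletion at {ev.position}: ancestral is {anc!r}, "
                        f"fixture expects {ev.bases!r}"
                    )
                if not plan.try_block(ev.position - 1, ev.position + length):
                    raise FixtureError(f"overlap at {ev.position} in copy {who}")
                plan.dels.append((ev.position, length))
            elif ev.kind == INSERTION:
                if not (0 <= ev.position <= n):
                    raise FixtureError(f"insertion flank {ev.position} out of range")
                if not plan.try_block(ev.position, ev.position + 1):
                    raise FixtureError(f"overlap at flank {ev.position} in copy {who}")
                plan.ins.append((ev.position, ev.bases))
            else:
                raise FixtureError(f"unknown event kind {ev.kind!r}")
    pops = [f"F{(i % populations) + 1:02d}" for i in range(copies)]
    copy_ids = [f"F{(i % populations) + 1:02d}-{i // populations + 1:02d}" for i in range(copies)]
    aln = _assemble(ancestral, plans, copy_ids, pops)
    if reference_id is not None:
        aln.reference_id = reference_id
    truth = _truth_from_plans(ancestral, plans, copy_ids)
    return aln, truth
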