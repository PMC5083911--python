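# Methods

## The analysis

`tespectrum` estimates the mutation spectrum of a transposable-element (TE)
family from a gapped multiple sequence alignment of per-locus copies cloned
from different individuals across field populations. Because every copy
descends from a recent shared ancestral insertion, differences among copies
read out the spontaneous mutation process with little interference from
selection — the same logic that motivates pseudogene-based mutation studies,
without the ambiguity about which lineage changed.

### Ancestral state calling

For each alignment column the allele counts over {A, C, G, T, –} are taken
with `N` (missing) excluded from the denominator. The ancestral state is the
majority allele when its frequency reaches the **major threshold**
(default 0.85); a minority allele (frequency at most 1 − 0.85 = 0.15) is then
interpreted as the derived state, i.e. "A in ≥85% of copies, G in ≤15%" is
recorded as A→G. Columns with no allele at the threshold are *ambiguous* and
yield no calls. The threshold comparison is `>=`, not strict `>`: with 20
copies, 17/20 = 85% exactly, and a strict rule would make such columns
uncallable; the threshold is a config knob (`--major-threshold`).

Columns whose ancestral state is the gap are *insertion columns* and carry no
ancestral coordinate; all other columns are numbered 1..L along the ungapped
ancestral sequence. When a designated ancestral copy is supplied (the
`*-A01` convention), it breaks count ties and anchors coordinates at
ambiguous columns; the frequency rule otherwise has precedence, since a
designated copy is itself just one sequenced clone.

### Two analysis scopes

Single-base substitution spectra are computed **per group** (each group's
alignment gets its own profile), matching the sampling design below. Indels
and multi-base substitutions are called **once on the pooled copy set**:
they are rare, and the larger sample is what makes the
insertion-versus-deletion direction decidable (bases present in ≥85% of all
copies and absent in ≤15% are a deletion in the minority, and vice versa).

### Events

Per copy, minority-base columns at consecutive ancestral positions merge
into one substitution event (so adjacent changes are counted as one 2- or
3-base event, not two or three independent ones); gap runs over called base
columns become deletions; occupied runs over insertion columns become
insertions. Recurrent events deduplicate on the identity of the change
(kind, interval, ancestral and derived alleles), pooling carriers — a
mutation observed in several copies at the same position counts once.
Distinct derived alleles at one position remain distinct events: collapsing
them would silently delete observed patterns. A multi-base run deduplicates
as a unit and requires a single carrier copy per run.

### Indel interval convention

Indels are reported in `start_end` form on the ancestral coordinates: the
two positions *flanking* the affected bases, so a deletion of L bases
satisfies `end − start − 1 = L` and an insertion sits between `start` and
`start + 1`. Within repeated context (homopolymers, tandem repeats) an indel
has several equivalent placements; placements are normalized by shifting as
far **right** as possible before the flanks are taken. This convention is
the one the published event catalogs replayed in `tespectrum.catalogs`
follow — their flank arithmetic and the paired single-A/double-A deletion
entries at one locus are consistent only with right-normalized flank
reporting — so the package adopts it throughout. `anc_alleles` of a deletion
records the bases of the left-most placement.

### Classification

The 12 ordered single-base patterns split into 4 transitions (A→G, G→A,
T→C, C→T) and 8 transversions. Complementary-strand pooling sums each
pattern with its reverse-complement partner (A:T→G:C = A→G + T→C, etc.) so
that bias is expressed per base pair; pooling conserves totals. Inside an
ORF, a substitution at ancestral position *p* has codon position
`((p − start) mod 3) + 1` and a protein effect obtained by substituting the
derived base into the ancestral codon under the standard nuclear code:
synonymous, missense, nonsense (sense→stop) or no-stop (stop→sense).
Stop→different-stop counts as synonymous (the product, termination, is
unchanged). Each event is classified against the ancestral reading frame
independently; frameshifts caused by upstream indels are not propagated.
Multiple ORFs are supported: "inside" means wholly within a single ORF, and
codon context comes from the containing ORF. Indels touching the ORF are
frameshift or in-frame according to the number of *coding* bases gained or
lost (so a deletion spanning an ORF boundary is judged by its in-ORF bases
only); events partially overlapping an ORF get region `spanning`.

### Grouping and statistics

The sampling design forms disjoint groups of copies — by default 4 groups,
each with 1 copy per population from 21 populations (or 5 per population
from 7), drawn without replacement under a seeded generator. Category
counts are reported per group, with mean and SE = sd(n−1)/√n_groups across
groups. Group contrasts use the pooled-variance two-sided t-test (Student,
the conventional "independent-samples t-test" default; Welch available via
a flag) and one-way ANOVA with Tukey's HSD post hoc comparisons
(studentized-range p-values via statsmodels, cross-checked in the tests
against SciPy's independent implementation). All-pairs outcomes are
summarized as compact letter displays built by insert-and-absorb: two
groups share a letter iff their Tukey pair is not significant at the level;
the α = 0.01 display is never finer than the α = 0.05 one. Degenerate
inputs: identical samples give t = 0, p = 1 (no evidence of difference);
an all-identical ANOVA gives F = 0 with a single shared letter.

## The synthetic generator

`simulate_family` emulates the study conditions: a ~2.4 kb ancestral
element at 35.9% GC containing a transposase ORF, copied into
21 populations × 4 copies (the 7 × 20 design is one config change), each
copy receiving per-pattern Poisson substitution counts placed uniformly on
sites carrying the source base, rare adjacent 2–3-base substitutions, and
rare indels whose lengths mix a dominant 1-bp class (55%) with a geometric
long tail (p = 0.12, capped at 300 bp) — the magnitudes of the published
per-group means and indel catalogs. Default per-pattern rates are those
observed magnitudes divided by the 21 copies of a group (≈3 substitutions
per copy, ts:tv ≈ 2.4, A:T→G:C ≈ 2× G:C→A:T); a
`pattern_rates_from_bias(total, kappa, at_gc_bias)` helper builds
parametric spectra for recovery experiments.

Placement enforces (a) a one-base margin between events within a copy, so
distinct planted events can never merge into one run, and (b) a cap of
15% of copies touching any one site, so every planted event stays below
the caller's minority threshold. Within those guarantees the caller's
output equals the planted truth exactly (set equality on event keys), which
the tests exploit for precision/recall = 1.0 checks. Insertions at the same
flank share a column block only when the inserted strings are identical;
distinct strings open separate blocks, as an MSA of distinct clones would
show them. The generator emits the true alignment directly: misalignment
noise, PCR/sequencing error, transposition bursts, phylogenetic structure
among copies and methylation-dependent rate variation are all *not*
modelled — passing tests therefore validate the calling and summary
machinery, not robustness to alignment artefacts in real data.

`build_fixture` plants an explicit event list deterministically and is used
to replay the published indel/multi-base catalogs of the two reference
elements (CsuPLE1.1, a piggyBac-like DNA transposon, and Csu-Ty3, a
Ty3/gypsy LTR retrotransposon of *Chilo suppressalis*). The individual copy
sequences behind those catalogs were never deposited, so the scaffold
sequences are synthetic: random context at the published GC, constrained
only so that each replayed event reproduces its published interval string
(e.g. a single-A deletion next to an AA run, or the T-insertion hotspot
where four distinct insertions share one flank). The published per-group
*means* are consequently reproducible in distribution but not numerically;
the printed worked examples (pooled sums 30.25/14.25 and 33.25/18.5, totals
62.75 and 76.25) are checked as arithmetic identities through the
aggregation code instead.

## Numerical and design choices

- Frequencies always exclude `N`; `N` is absence of information, not an
  allele, and never creates or suppresses a call by itself.
- Count ties at a column resolve to the designated reference allele if one
  is given, else to the first allele in A, C, G, T, – order
  (deterministic).
- The minority check allows a 1e-12 slack so that exact-boundary fractions
  (3/20 at threshold 0.15) are not lost to float rounding.
- Ambiguous columns keep their plurality state purely to anchor ancestral
  coordinates and codon context; they are excluded from calling, and
  deletion runs break across them.
- ORF sequences in the generator are built codon-wise: ATG start, sampled
  stop, internal codons rejected-resampled to avoid in-frame stops (a small
  upward GC nudge relative to the i.i.d. target, well inside binomial
  noise at element lengths).
- Group draws, simulations and fixtures are all seeded; identical seeds
  give byte-identical FASTA and report output.

## Problem sizes used by the test-suite

Property suites run at sizes chosen to finish quickly while still
exercising every code path: brute-force oracle equivalence on 1000 random
alignments of ≤10 copies × ≤50 columns; exhaustive 576-case genetic-code
partition; truth recovery on full study-scale families (84 copies × 2.4 kb);
parameter recovery over 100 replicate families at the study regime with
3-SE tolerances; and a power check of the headline t-tests in an explicit
large-effect regime (κ = 3, A:T→G:C bias 4 — roughly double the observed
bias) where rejection at p ≤ 0.01 is expected in ≥95% of runs. At the
observed-study effect size the pooled-bias test's power at p ≤ 0.01 is
~85% with 4 groups, which is why the power check states its own regime.

## Known limitations

- No phylogenetic (parsimony/likelihood) ancestral reconstruction; the
  frequency rule is the model, by design.
- The pipeline consumes a given alignment; it never realigns or refines
  gaps, and simulator output bypasses alignment entirely.
- Each sequenced clone is one copy; allelic copies within a heterozygous
  individual are not collapsed.
- Sequences are compared on the given strand only (copies are assumed
  cloned and sequenced in the same orientation).
- Indel placement ambiguity is resolved for reporting intervals only;
  overlap of an indel with a substitution in the same copy produces two
  independent events, never a complex-event type.
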