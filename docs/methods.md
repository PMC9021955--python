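# Methods

`equistr` re-implements, as a tested library, the computational pipeline
behind a 17-plex tetra/penta-nucleotide short-tandem-repeat (STR) panel for
horse DNA profiling and paternity testing: marker discovery and scoring,
multiplex primer QC, electropherogram genotyping, forensic population
genetics, candidate-gene exclusion, and a mutation-rate predictor.  The
study's individual genotypes were never released, so the package pairs the
published per-marker tables (shipped as fixtures) with a synthetic-data
generator whose defaults emulate the published regime.

## Repeat discovery and scoring

Tandem repeats with 4–5 bp units are found by exact periodicity scanning:
maximal perfect runs of a primitive unit are detected per phase, and runs of
the same motif (up to rotation) separated by short interruptions (≤ 6 bp by
default — a variant unit or a small indel remnant) merge into one locus.  A
locus is reported when its longest perfect run reaches `min_copies`
(default 4).  `N` breaks runs; motifs are reported as the upper-strand unit
at the first full copy, with no rotation canonicalization in output.

**SW score.** Each locus is scored by local alignment against a perfect
tandem array of its motif with weights match +9, mismatch −9, gap open −13,
gap extend −4 (a gap of length L costs `13 + 4(L−1)`); the production path
uses Biopython's `PairwiseAligner`, and an independent hand-written Gotoh DP
in the test suite checks it on random inputs.  The +9 match weight makes a
perfect array of total length L score exactly `9·L`, which reproduces the
published scores of the panel's perfect-repeat loci (`[TAAAA]9` → 405,
`[AGAT]13` → 468, `[TCTCT]11` → 495).  Scores of *imperfect* loci depend on
the exact annotated extent used by the original genome-browser track, which
is not recoverable; parity there is explicitly not a goal.

**Structure strings and LUS.** Loci decompose greedily left-to-right into
bracketed unit runs (`[TCTA]4[TCTG][TCTA]11`): a unit-length block is
bracketed when it equals the motif, or is one substitution away with the
reading frame confirmed by the next block; anything else becomes a bare
literal (`ATC`).  The decomposition is lossless by construction (property
tested on random structures and random sequences).  The LUS (longest
uninterrupted stretch) is the largest run count of exact motif copies.
Higher-order repeats (6–20 bp units, ≥ 3 copies, unit not itself a
short-period repeat) are reported separately: they explain markers that are
polymorphic despite a short motif LUS.

**Candidate rules.** Hard failures: LUS < 8 (insufficient polymorphism no
matter the score) and co-amplified repeats in the flanking span.  Soft
warnings: score outside 450–700 and LUS ≥ 16 (stutter/mutation risk).  The
published panel itself fields a score-931 and an LUS-18 marker, so those are
deliberately warnings, not failures.  With one-per-chromosome triage the
highest-scoring pass per sequence keeps PASS; others demote to WARN.

## Primer QC

The dimer score is the package's operational definition: best ungapped
antiparallel register, Watson–Crick matches minus mismatches, no G:T wobble,
pigtails included (they are physically in the tube); a pair fails at score
≥ 7.  The 3′-templating count is the longest pairing run anchored at the
extending primer's 3′ terminus against any position of the partner's
templated sequence (both orientations searched), failing above 2 bases, and
is applied within each marker's primer set.  The original screening tool's
scoring is unpublished; under this package's operational score a handful of
published primer pairs reach 7–8, and several reverse primers show 3-base 3′
anchors.  These reports are informative output, not a contradiction — they
measure the panel under a different, documented metric.  The AA-3′ census
(fraction of primers whose templated sequence ends in `AA`; 27/36 in the
packaged panel) reflects the design strategy that suppresses dimer seeding,
since A:A cannot pair.

## Genotyping

Peak tables arrive pre-sized (sample, dye, size in bp, height in RFU).
Sizes cluster by single linkage with a 0.7 bp gap — comfortably above sizing
noise (~0.05–0.1 bp), safely below the 1 bp micro-variant spacing — which
implements the "100.48 and 100.52 are the same allele" correction.  Alleles
are named by repeat count relative to the sequenced reference allele
(`ref_repeats` counts all unit-length blocks of the printed structure,
interrupting units included, e.g. 16 = 4+1+11 for the `[TCTA]4[TCTG][TCTA]11`
marker).  A residual within 0.5 bp of a whole unit gives a whole-repeat
name; otherwise the allele is a micro-variant `n.p`.  Under the
deletion-derived policy (default ON only for the Eca12 marker, whose
38%-frequency variant was sequenced as a single-base deletion outside the
repeat), `n.(u−1)` bins with `n+1`.

The end-to-end genotyper pads each marker's size window by 1.5 bp so sizing
noise cannot push a boundary allele off the ladder (peaks in the two
published 1–2 bp same-dye boundary overlaps resolve to the nearer range
center), sums co-located rows into one physical peak, removes −1-repeat
stutter peaks (a peak is stutter when a peak one unit above is ≥ ~3× taller),
ignores peaks below 30% of the tallest survivor, and calls the top two
survivors (one → homozygote).

**Stutter protocol.** Ratios are measured only at eligible parents:
homozygous calls, or heterozygous calls more than one repeat apart; parents
whose stutter position coincides with another called allele or a
pull-up-flagged peak are skipped; the first 10 eligible parents in sample
order are used.  An undefined mean (no eligible parents) is reported as
missing, never 0.  Only −1-repeat stutter is modeled; −2 and forward stutter
are out of scope.

**Sex calling.** The amelogenin-region marker yields a short invariant
product from the Y chromosome (a deletion on Y) and X products from ~134 bp
up (the X product carries a variable GA di-STR).  MALE = Y-bin peak
(113 ± 1 bp) plus an X-size peak; FEMALE = X-size peaks only (one or two);
no peaks = INCONCLUSIVE.  Which of the two published product classes (113 vs
134) is the Y product is not stated in the source material; the package
assumes the invariant 113 bp class is Y (configurable), since the X product
is the one carrying the variable di-STR.

## Forensic statistics

With power sums `S_k = Σ p_i^k`:

    He    = 1 − S2
    PI    = 2·S2² − S4
    PIsib = 1/4 + S2/2 + S2²/2 − S4/4
    PE1   = 1 − 4·S2 + 2·S2² + 4·S3 − 3·S4        NE1P = 1 − PE1
    PE2   = 1 − 2·S2 + S3 + 3(S2·S3 − S5) − 2(S2² − S4)   NE2P = 1 − PE2

PI is the match probability for unrelated individuals, PIsib for full
siblings; PE1/PE2 are the Jamieson–Taylor exclusion powers for a first
parent (no known parent) and a second parent (one parent known).  All four
closed forms are verified against exhaustive enumeration oracles (genotype
pairs, sib transmissions, parent/child/candidate configurations) to 1e-10
and against 100,000-triple Monte-Carlo simulation.  He is plain `1 − S2`
(the cited software's default); an unbiased small-sample variant sits behind
a flag.  The Brookfield estimator `(He − Ho)/(1 + He)` screens for null
alleles, alongside a Hardy–Weinberg test: a chi-square goodness-of-fit with
rare-class pooling, or (default) a Monte-Carlo permutation of alleles among
individuals whose p-value is the one-sided probability of a heterozygote
count at most the observed — the deficiency direction, because a segregating
null allele masquerades as excess homozygosity.

**The published combined row.** The packaged per-locus summary table stores
the printed parentage columns (`pe1`, `pe2`) as-is.  Their per-locus ordering
(pe1 > pe2 at every locus) identifies them as *non-exclusion* style values,
yet the printed combined row is reproduced — to three significant figures
(9.11e-9, 1.11e-5) — by the product of the per-locus *complements*
`(1 − pe1)`, not of the columns themselves.  The package therefore computes
the published combined row as `Π(1 − col)` and documents this reading here;
the package's own `LocusStats` always reports non-exclusion (`ne1p`, `ne2p`)
whose panel-wide product is the standard combined non-exclusion probability.
PI and PIsib combine as plain products over the loci where they are defined
(one locus is ND in the published table because of a then-unresolved null
allele; it is excluded from those products and reported as excluded).

**Breed assignment** maximizes `Σ log P(genotype | HWE, breed frequencies)`
with 0.005 substituted for unseen alleles and optional leave-one-out removal
of the individual's own alleles; ties break by name order and are flagged.
At the study's scale (16 breeds of 8, divergence F = 0.05) mean
leave-one-out self-assignment sits far above the 1/16 chance rate but well
below 1 — the weak-assignment regime the panel showed on real breeds.  With
only two breeds at the same divergence, 17 multiallelic loci assign almost
perfectly; a two-class band in the 50–85% range is not a property of this
statistic and is not asserted anywhere.

## Parentage and candidate-gene exclusion

Trio checks compute, per locus, the minimal total repeat-step edit that
makes the trio Mendelian over both maternal/paternal assignments: 0 =
compatible, exactly 1 = mutation suspect, ≥ 2 = mismatch; loci with missing
genotypes are skipped.  A trio is excluded at ≥ 2 mismatching loci (a
package convention — single-locus conflicts are treated as possible
mutations, consistent with predicted rates of ~0.1–0.9 per 100 meioses per
marker).

Candidate-gene exclusion uses markers within 2 Mb of the gene (marker
positions are encoded in their names).  RECESSIVE: excluded iff any affected
individual is heterozygous with alleles more than one repeat apart at a
flanking marker (one-repeat heterozygotes are tolerated as possible
mutations).  DOMINANT_OR_XLINKED: excluded iff two affected individuals are
homozygous for different alleles at the same flanking marker.  A gene with
no marker in the window is UNTESTABLE — a distinct verdict, never silently
"not excluded".

## Mutation-rate model

The mapping from repeat-alignment score to predicted mutation rate is
unpublished; a two-parameter power law `rate = a·SWS^b`, least-squares
fitted in log-log space, reproduces the entire printed per-marker column
within ±0.01 per 100 meioses (b ≈ 2.35 emerges from the data).  This is a
reverse-engineered calibration, stored with its calibration pairs and
refittable; it is not claimed to be the original method.  Rates are per 100
meioses throughout.

## Synthetic-data generator

Defaults are the published study conditions: the builtin 17-plex, 128
individuals in 16 breeds, ~8.3 alleles per marker (Poisson-like, clipped to
[4, 17] and to what each marker's size range can hold), expected
heterozygosity rejection-sampled into the published within-breed band
0.62–0.82 (mean ≈ 0.72 across seeds; extreme bands are reached by
deterministic mixing toward a point mass or the uniform vector when
rejection cannot land), one micro-variant allele at 38% frequency on the
Eca12 marker, breed structure via the Balding–Nichols construction (breed
frequencies Dirichlet with mean = base and concentration (1−F)/F, default
F = 0.05), HWE genotypes, null alleles as a segregating hidden allele
(carriers look homozygous, null/null is missing — a population property, as
a primer-site variant would be), pedigrees with per-marker stepwise mutation
(probability rate/100 per meiosis; ±1 unit with probability 0.9, else ±2 —
the single-step share is a convention motivated by tetra-STRs mutating
predominantly in single steps), and peak tables with lognormal heights
(CV 0.25), Gaussian sizing jitter (σ = 0.05 bp), per-marker stutter at the
published ratios with 0.5 pp noise, and optional pull-up flags.  Every
output is a pure function of the seed; the bundle generator derives
per-stage sub-seeds deterministically.

What the generator does **not** emulate: linkage and recombination,
allele-frequency clines within breeds, split peaks / ±A tailing, dye-specific
migration shifts, off-scale or saturated peaks, and degraded-sample dropout.
Passing round-trip tests therefore demonstrates the pipeline's correctness
under clean fragment-analysis conditions, not robustness to every artifact
of real capillary data.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen to keep sampling error
well inside the asserted tolerances: 60–300 individuals for genotyping round
trips (≥ 99% cell recovery asserted), n = 500 for frequency/He recovery
(3 binomial SE), 100,000 triples for the Monte-Carlo parentage check,
1,000 simulated cohorts of 13 affected individuals for exclusion-rate
calibration, and 1,500 trios with spaced allele grids for the
mutation-suspect rate (spacing makes every single-step event detectable as
exactly a one-unit edit).  Tie-breaks and degenerate inputs: monomorphic
loci report He = 0 and PI = PIsib = NE = 1; empty frequency maps and
non-positive rates raise; undefined stutter means are missing, not zero;
assignment ties are flagged and broken by name order; all randomness flows
from explicit seeds.

## Known limitations

* SW-score parity with the historical genome-browser annotation holds only
  for perfect repeats; imperfect-locus scores depend on unrecoverable
  annotation extents.
* Dimer and templating scores are operational definitions, not a
  re-implementation of the original screening tool.
* The "He SW" column of the published summary table (an SW-based He
  prediction) is stored but not modeled: it is undefined in the source text
  and non-monotone in the score.
* No likelihood-ratio (LOD) paternity scoring, no linkage/recombination
  modeling, no raw trace (.fsa) parsing, no allelic-ladder construction.
* Within-breed PI/PIsib of the real study population cannot be reproduced
  (genotypes unreleased); the package reproduces the published panel-level
  table arithmetic and validates the statistical machinery on synthetic data
  with known truth instead.
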