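# Methods

`solor` re-implements, as a tested library, the computational analyses used
to characterise *solitary* odorant-receptor (OR) genes: OR genes isolated
from every other OR gene by more than 1 Mb on both sides of their
transcript. Such genes are candidate simplified models for studying OR gene
choice, because their regulatory sequences cannot be confounded with those
of cluster neighbours. The pipeline runs from genome annotation to a final
per-gene evidence table: isolation scanning, 5' RACE-based promoter
definition, homeodomain (HD) binding-site prediction, promoter allele
comparison against wild and laboratory mice, conservation ranking, and
expression-count statistics.

## Isolation scanning (`solor.solitary`)

Transcript intervals are held 0-based half-open. The gap between two
transcripts is `start(downstream) − end(upstream)`; a gene is **solitary**
when every flanking gap strictly exceeds the isolation threshold (default
1,000,000 bp). The **MDAS** (maximum distance as solitary) is the smaller
of the two flanking gaps, reported in Mb at one decimal.

Decisions the verbal definition leaves open, fixed here:

* *One-sided neighbours.* The first/last OR gene on a sequence has only one
  defined gap; that gap serves for both the test and the MDAS. A gene alone
  on its sequence is solitary with MDAS reported as "alone".
* *Gap anchor.* Edge-to-edge between transcript intervals (not midpoints);
  this makes the two members of an isolated gene pair quote the same MDAS,
  matching how such pairs are conventionally reported.
* *Pseudogenes* count as isolating neighbours by default and receive calls
  themselves; both switches are in `SolitaryConfig`.
* *Ordering ties.* Neighbour sides follow `(start, end, gene_id)` order, so
  duplicated coordinates behave deterministically. Overlapping transcripts
  have non-positive gaps and are never isolated from each other.

The classifier is an O(n log n) sorted scan; tests hold it to an
independent all-pairs oracle over random annotations, including overlapping
and tied intervals.

## Promoter definition from 5' RACE (`solor.race`)

Clones are polished by stripping adapter/vector sequence from either end
(forward or reverse-complement, within a substitution budget, iterated to a
fixed point). Polished clones are spliced-aligned to a genomic window by
exact 15-mer seeding, collinear chaining, and bounded extension — not full
DP: windows may reach 100 kb while RACE clones are short and near-identical
to the genome, so anchors recover exon structure directly. Reference gaps
of at least `min_intron` (20 bp, so a documented 21-bp OR intron remains
representable) are introns, annotated canonical when flanked by GT..AG;
shorter gaps are alignment deletions. When seed runs overlap ambiguously
around a junction (chance matches across the boundary), the junction is
re-placed over the ambiguous bases to maximise matches, preferring a
canonical intron, then the shortest left extension. Unseeded clone ends are
extended while bases match exactly; a disagreement leaves the residue
soft-clipped rather than extended across an intron on chance matches.

Each clone's TSS is the reference coordinate of its 5'-terminal base; the
gene's TSS is the most upstream one (minimum on +, maximum on −), with all
clone ends kept in the call's support metadata — no peak clustering, since
nearby alternative ends are biologically real. The **putative minimal
promoter** is the 301-bp window centred on that TSS, reported on the plus
strand, clamped and flagged at sequence edges.

Riboprobe specificity follows the rule that a probe may share at most 75%
homology with non-target OR coding sequences. Homology is measured as
matched bases of the best local alignment divided by the length of the
shorter sequence. The alternative (matches over local-alignment columns)
was measured and rejected: on unrelated random 400-bp pairs the best local
alignment is a short near-perfect segment with column identity 0.6–0.9, so
that statistic cannot separate cross-hybridising probes from noise, whereas
the probe-wide denominator gives ~0.05–0.2 for unrelated sequences and 1.0
for identical or reverse-complement targets.

## HD binding-site model (`solor.motifs`)

The PSWM is derived the way an HD motif is built from a handful of enhancer
binding sites: each annotated seed site is located on its element, extended
to the boundaries of the imperfect inverted repeat (hemi-palindrome)
containing it, oriented consistently (minus-strand occurrences are
reverse-complemented), padded to equal width, and tallied. Inverted repeats
are found by growing arms outward from every loop placement (loop ≤
`max_loop`, mismatches ≤ `max_mismatch`) until the budget blocks extension;
all maximal, possibly overlapping repeats are reported. The original tool's
overlap conventions are version-dependent, so this definition is pinned by
an enumeration oracle in the tests.

Frequencies use a pseudocount (default 0.1) distributed by the background
(default uniform; switchable to the composition of the scanned set).
Scores are log-odds in bits, discretised at 1/1000 bit. Word scores and
p-values share the discretised grid: the null distribution of the integer
word score under i.i.d. background is computed exactly by per-column
convolution, so the p-value attached to a reported score is exact for that
score (the discretisation perturbs scores by < width/2000 bits). Scanning
reports every position × strand with p ≤ threshold (default 1e-4, the
conventional scanning default, consistent with a search designed to control
false positives rather than false negatives); a palindromic match scoring
equally on both strands is reported once, on plus. Calibration is tested:
1 Mb of uniform background yields ≈ 2·10⁶·10⁻⁴ = 200 hits within binomial
noise.

Zero-frequency cells (possible only at pseudocount 0) are floored at −32
bits per column so the score grid stays finite; no realistic threshold is
affected. No FDR correction is applied across windows, deliberately: the
analysis relies on per-test p-values.

## Allele comparison (`solor.alleles`)

Panels hold the C57BL/6J reference allele, wild alleles from three
populations (France, Germany, Iran; default 8 each, matching the sampling
design of eight sequenced individuals per site) and 36 laboratory strains.
The aligner is progressive: edlib edit distances normalised by the longer
sequence give guide distances, neighbor joining gives the guide tree, and
profiles are merged along it with affine-gap Gotoh DP (match +2, mismatch
−1, gap open −5 for the first gap base, extend −1; N scores 0; an existing
gap column scores like a gap extension against a base and 0 against a gap).
Traceback preference is fixed (diagonal, then gap in the second profile,
then gap in the first), so output is deterministic. The exact parameters of
the original GUI aligner are unrecoverable; promoter alleles are
near-identical, so any sane parametrisation yields the same columns — the
tests pin the behaviour with Needleman–Wunsch and exhaustive three-sequence
sum-of-pairs oracles on small cases.

Per-population **consensus** is called column-wise at a 51% threshold over
the members' symbols (gap counts as a fifth symbol); columns under
threshold become N. The reference allele is **mutant** when some column has
*every individual wild allele* differing from the reference symbol (the
strict reading; evaluation against population consensuses is exposed via
`mutant_against="consensus"`), and **polymorphic** when any allele differs
anywhere. Population mismatch totals count columns where the population
consensus and the reference both hold bases and differ — gap-versus-base
and N columns are excluded, and indel columns are reported separately
rather than counted, since the original totals are substitution counts.
Totals are additive across genes.

## Conservation ranking (`solor.phylo`)

Pairwise distances are Tamura–Nei (TN93), which separates the two
transition classes from transversions under unequal base frequencies:

    d = −k₁ ln w₁ − k₂ ln w₂ − k₃ ln w₃
    k₁ = 2πAπG/πR, k₂ = 2πCπT/πY,
    k₃ = 2(πRπY − πAπGπY/πR − πCπTπR/πY)
    w₁ = 1 − P₁/k₁ − Q/2πR, w₂ = 1 − P₂/k₂ − Q/2πY, w₃ = 1 − Q/2πRπY

Columns with a gap or N in either row are excluded pairwise (complete
deletion is available as an option); base frequencies are averaged over the
pair by default (alignment-wide optional). Saturated pairs (any log
argument ≤ 0) raise a diagnostic error and flag the matrix entry;
downstream operations reject flagged matrices rather than silently
imputing. The implementation agrees with ape's `dist.dna(model="TN93")` to
machine precision on a frozen fixture.

Trees are Saitou–Nei neighbor joining with lexicographic tie-breaking on
the Q criterion; branch lengths follow the standard update equations, and
negative lengths are retained but flagged. The conservation score of a
promoter is the arithmetic mean of the strict upper triangle of its TN93
matrix — identical to averaging the distance matrix the NJ tree is built
from — and genes are ranked most-varied-first, ties broken by gene id.

## Expression statistics (`solor.expression`)

Counts taken on every eighth 12-µm section are corrected with Abercrombie's
method, N = n·T/(T+h) (T section thickness, default 12 µm as in the
protocol; h the mean nuclear height, a required parameter with no default
because it is a property of the measured particles, not of the protocol),
then multiplied by the sampling stride. Per-gene totals over animals (n = 3
in the reference data) are summarised as mean, sample (n−1) SD and CV =
sd/mean; which SD estimator the original table used is not recorded, and at
n = 3 the choice shifts CVs in the third decimal. The shipped reference
table (`solor/data/cell_counts.tsv`) reproduces the reference CVs (0.669
for the most dispersed gene down to 0.013) at three decimals, and the
mean-vs-CV Pearson correlation computed from it is r = −0.8144,
p = 0.01385 on 6 df (two-sided, via the t transform) against the reference
−0.8145 / 0.013926 — the residual difference is rounding of the printed
integer means and SDs.

## Synthetic data (`solor.simulate`)

Every generator is a pure function of its config (seed included) and
returns planted truth alongside the data, so each stage can be held to
exact recovery in the noise-free limit.

* **OR annotation**: ~50 clusters of 5–40 genes at ~25 kb intra-cluster
  spacing across 19 chromosomes of 120 Mb (≈1100 genes, the scale of the
  mouse OR repertoire), with 8 planted intact solitary genes and 3 solitary
  pseudogenes whose flanking gaps are drawn from 1.2–45 Mb (the span of
  reported MDAS values). Truth MDAS is derived from the placement
  arithmetic, not from any classifier. A quarter of cluster genes are
  pseudogenised (named with a `-ps` suffix).
* **Allele panels**: 301-bp reference, 3×8 wild alleles, 36 lab strains.
  Planted patterns mirror the observed classes: mutant sites (one shared
  alternative base in all wild alleles), single-lab-strain variants, and
  per-population consensus substitutions; independent background
  substitutions at 5×10⁻⁴ per site per allele by default (truth is exact
  only at background 0). Single-base deletions optional.
* **RACE clones**: adapter-prefixed spliced 5' fragments from a random gene
  model (2–3 exons ≥ 60 bp, GT..AG introns, up to 3 alternative TSSs in
  exon 1), each planted TSS sampled at least once, per-base substitution
  errors optional.
* **Cell counts**: negative-binomial totals with per-gene size parameter
  drawn log-uniformly from (2, 5000) — heterogeneous dispersion is what
  produces the observed CV spread of two orders of magnitude.

What the generators do not emulate: real OR sequence composition and
repeats (mapping ambiguity is milder than in the genome), linkage and
demographic structure among wild alleles (sites are independent), RACE
truncation artefacts, and section-level count correlations. Passing the
recovery tests therefore demonstrates correctness of the algorithms under
the stated statistical structure, not performance on raw sequencing data.

## Problem sizes and numerics

The test suite runs the full MSA pipeline on 100 61-allele panels, the
isolation scan against an all-pairs oracle on 200 annotations of up to
1000 genes, 100 NJ recoveries (n ≤ 10), 100 RACE gene models, five 1-Mb
calibration scans, and enumeration checks of the p-value DP at width ≤ 6 —
sizes chosen so the whole suite completes in about two minutes while every
claim is still exercised end to end. Floating-point contracts: p-value DP
vs enumeration < 1e-9; TN93 vs independent closed form < 1e-12; NJ path
lengths vs additive matrices < 1e-9.

## Known limitations

* The spliced mapper assumes exons ≥ the seed length (15 bp) and clones
  that begin inside the first exon; micro-exons would be missed.
* Numeric agreement with the original study's unreported distance matrices
  and alignments cannot be asserted, only procedure-level agreement; the
  supplementary clone and allele files are consumed as inputs when
  available, and synthetic panels with planted truth stand in for them in
  the tests.
* `progressive_msa` guarantees optimality per profile merge, not the global
  sum-of-pairs optimum; for 301-bp near-identical alleles this is
  immaterial (verified on small exhaustive cases).
* The mutant/polymorphic classifier works column-wise on the alignment; a
  "local" difference spanning an indel run is reported via the separate
  gap-column channel, not as a mutant site.
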