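# Methods

This note documents the models, conventions, default parameters, and design
choices behind `a3sig`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Coordinates, orientation, and the signature definition

Input mutation tables use 1-based inclusive positions (VCF/MAF convention);
all internal interval arithmetic is 0-based half-open. Every SBS is
*pyrimidine-oriented*: records whose reference base is G or A are
reverse-complemented so the mutated base is C or T, the standard convention
for signature channels. Orientation is an involution — applying it to an
already-oriented context is the identity.

The APOBEC3 signature set is C>T and C>G at TCW (W = A/T) on the oriented
strand. C>A is excluded by default because the background mutational process
in the cell-line system this package models has its own C>A bias
(ganciclovir selection), which would contaminate the channel; a flag
restores it where wanted.

Context windows that overlap a contig edge or contain N are *flagged*: they
are excluded from motif fractions, spectra, and clustering (which need the
complete k-mer) but retained for position-only analyses such as
intermutation distances. Records whose stated reference allele disagrees
with the genome are dropped with a logged warning rather than failing the
run, to tolerate liftover artifacts in real MAFs.

## TCW enrichment score

Per sample, with M_TCW / M_C the counts of signature-class mutations at TCW
and at any cytosine, and C_TCW / C_C the motif and cytosine counts in the
union of ±`window` nt (default 20) windows around each mutated cytosine:

    E = (M_TCW · C_C) / (M_C · C_TCW)

Window intervals are merged before counting so overlapping windows are not
double-counted. Motif counting is strand-symmetric: a TCW instance is
attributed to its C, and the reverse-strand motif (reading WGA on the
reference) to its G; C_C counts C and G bases. E is therefore invariant to
reverse-complementing the genome. Significance is a one-sided Fisher exact
test (excess of TCW among mutations relative to local opportunity) on
[[M_TCW, C_TCW], [M_C − M_TCW, C_C − C_TCW]], with Benjamini–Hochberg
correction across samples; samples with C_TCW = 0 or M_C = 0 are flagged
undefined and excluded from the correction. No minimum-mutation gate is
applied; the four counts are reported so users can filter. Under uniform
placement of mutations on cytosines E concentrates near 1 and the Fisher
test's type-I error is controlled, which the test suite checks over 200
simulated null samples.

## Hairpin model

A hairpin is a perfect Watson–Crick inverted repeat: 5' arm, single-stranded
loop of 3–11 nt, 3' arm equal to the reverse complement of the 5' arm, stem
≥ 6 bp. Mismatches, bulges, and G·T wobble pairs are not allowed — the
mismatch tolerance of secondary-structure prediction tools is not well
specified, and perfect matching is reproducible and conservative. For each
loop placement only the maximal stem is reported (no sub-stem duplicates),
capped at `max_stem` (default 15 bp) for tractability. N never participates
in a stem or loop. The scanner is vectorized per loop offset and verified
against an exhaustive enumerator on random sequences.

Loop bases form the single-stranded compartment for rate comparisons; stem
bases count toward the non-hairpin denominator, so loop_bp + nonhairpin_bp
equals the assembled genome length (matching the convention of published
genome-wide loop-region estimates, e.g. 8.625 Mbp of loop versus
2991.375 Mbp of non-hairpin DNA out of 3000 Mbp). Rates are mutations per
Mbp of compartment; contrasts use two-sided Welch t-tests across clones.
Genome-scale scans of a mammalian reference are possible but slow; the
published denominators can be supplied directly to the rate computation.

## Kataegis

An event is ≥ `min_members` (default 2) strand-coordinated APOBEC3 signature
mutations with consecutive gaps ≤ `window` (default 10 kb). "Strand
coordinated" means identical reference strand of the mutated cytosine (all
C-reference or all G-reference). "Within 10 kb of each other" is implemented
as consecutive-gap chaining, the convention of rainfall-plot practice; a
strict-diameter mode (whole event span ≤ window) is available by flag.
Chaining components are identical to the transitive closure of all pairs at
distance ≤ window, which is how the brute-force oracle in the test suite is
formulated. Note the definition is density-sensitive: on small demo genomes
with human-scale mutation counts, chance clusters are expected and the
simulator's truth labels are the reference for recall, not event counts.

## Pentanucleotide clustering and the mixture weight

The clustering matrix has 48 channels — positions −2, (−1 = T), C>T,
+1 ∈ {A, C, T}, +2 — restricted to C>T at TCA/TCC/TCT. TCG is excluded to
avoid overlap with spontaneous deamination of methyl-CpG; C>G is excluded
from this matrix (while remaining part of the signature set used for YTCW
fractions, mirroring the dual usage in the source analyses). Rows are
normalized to frequencies. Clustering is hierarchical on Euclidean
distances, complete linkage by default (single/average selectable); the
distance is the specified part of the method, the linkage an implementation
choice. Group assignment cuts the tree into k = 3 clusters and labels each
by the anchor samples (known A3A, A3B, and non-APOBEC profiles) it
contains; anchors of different conditions landing in one cluster, or one
condition splitting, raise an explicit ambiguity error rather than guessing.
A nearest-anchor-by-cosine fallback exists for cohorts without enough
cluster structure.

The mixture weight linearly interpolates a sample's YTCW fraction between
the two enzyme anchors, w = clamp((f − 0.472)/(0.727 − 0.472), 0, 1). The
anchors are configuration, not constants: 0.472 and 0.727 are the default
endpoints (the measured A3B and A3A preferences) and can be overridden.
The weight is a one-dimensional summary: it assumes the sample's APOBEC
mutations come from a two-component mix of processes that differ only in
their −2 preference, and it says nothing about absolute APOBEC burden.

## Simulator

The simulator generates what the analyses assume, with full truth labels:

- **Genome**: i.i.d. bases, P(G) = P(C) = gc/2; default GC 0.4 (human-like).
- **Counts**: per-clone SBS totals drawn from a normal distribution
  truncated at 0 and rounded — A3A mean 3494 / SD 1358, A3B 2334 / 278,
  controls 1729 / 388 (the measured condition-level values). No count
  distribution is asserted by the source data beyond these summaries; the
  truncated normal matches them without extra structure.
- **APOBEC mutations**: placed on TCW cytosines of either strand. The motif
  model draws the −2 class (pyrimidine with probability 0.727 in A3A mode,
  0.472 in A3B mode) and the +1 base (A:T odds 48.3:36.3 for A3A,
  33.9:41.2 for A3B, renormalized within W), then samples a site of that
  category uniformly without replacement — so the configured −2 probability
  is exactly the expected YTCW fraction of the emitted APOBEC mutations.
  C>T vs C>G is split 0.6:0.4 (an SBS2:SBS13-like ratio; the split is not
  pinned by the summary data and does not affect motif fractions).
- **APOBEC fractions** per condition (A3A 0.29, A3B 0.13, controls 0) are
  estimates derived from pooled tallies (≈6070 signature mutations of
  ≈21,000 SBS for A3A; ≈1528 of ≈11,700 for A3B), not directly measured
  per-clone values.
- **Background**: the six pyrimidine classes with a configurable C>A excess
  (default: C>A at twice the weight of each other class), emulating the
  ganciclovir-associated background; an explicit weight vector can replace
  this. Sites are uniform over eligible bases.
- **Kataegis**: a Poisson number of runs per clone (default expectation 0.7
  for A3A, 0.2 for A3B), each 2–5 same-strand TCW mutations spanning
  0.5–9.5 kb, so planted runs fall unambiguously inside the caller's 10 kb
  window.
- **Hairpin loops**: planted perfect inverted repeats overwrite the genome
  at non-overlapping sites, with guard bases preventing chance stem
  extension so recovered coordinates are exact. The loop rate multiplier m
  splits the dispersed APOBEC count between loop and non-hairpin
  compartments with probability m·L/(m·L + NH) (L, NH in bp) and samples
  uniformly within each compartment. This makes the expected per-Mbp rate
  ratio exactly m under unique-position sampling; per-site weighted
  sampling without replacement would saturate the small loop-site pool and
  could not realize large multipliers.
- Positions are unique within a clone; emitted reference alleles always
  match the genome; everything is byte-deterministic under the master seed
  (clone seeds are derived from it and kept below 2^31).

What the simulator does *not* model: replication timing, transcriptional
strand bias, chromatin state, indels, mutation hotspots under selection, and
real genome base composition (no repeats, no CpG depletion). Passing the
recovery suites therefore shows the estimators are correct under the stated
generative assumptions, not that those assumptions capture every property of
tumor genomes.

## Deamination kinetics

Single-hit time courses follow P(t) = S0·(1 − e^(−vt/S0)) with initial slope
v (nM/min); Gaussian noise is clipped to [0, S0]. The initial-rate fit uses
points in the low-conversion window (product/S0 ≤ 0.15 by default) and
regresses the linearized product −S0·ln(1 − P/S0) on t through the origin.
Two estimator details matter: (1) the linearization removes the curvature
bias (≈ half the maximum conversion) that a raw through-origin line has on
exponential-approach data, making the noiseless fit exact for any window;
(2) the window is re-selected on the *fitted model's* predicted conversion
and the fit iterated, because thresholding on noisy observed conversion
preferentially keeps downward-fluctuated points and biases the rate low.
When fewer than two points sit in the window the full exponential model is
fitted instead (flagged `exponential`); a standalone full-model estimator is
also provided since reported assay rates are sometimes fit parameters rather
than initial velocities. Fold preference is the plain hairpin/linear rate
ratio (e.g. 120/31 ≈ 4-fold, 41/5.1 ≈ 8-fold).

## Problem sizes used in tests

The test and reference computations choose sizes that keep the full suite
fast while leaving comfortable statistical margins: 200 kb–10 Mbp genomes,
100,000-mutation catalogs for motif-fraction calibration (3-SE band ±0.42
percentage points), 200 null samples of 150 mutations for enrichment
calibration, 100 random 10 kb sequences for the scanner/oracle comparison,
15 samples × 2,000 mutations for clustering recovery, and 10,000 mutations
for mixture-weight recovery (observed error well inside the 0.05 band).

## Known limitations

- The hairpin scanner's perfect-stem model under-reports the looser
  structures a mismatch-tolerant predictor would emit; genome-wide loop
  totals are therefore not comparable across tools.
- The k = 3 anchor cut presumes the cohort actually contains three groups;
  cohorts dominated by one etiology should use the nearest-anchor mode.
- The mixture weight inherits the binomial noise of f_YTCW; for catalogs
  with fewer than ~1,000 TCW mutations its confidence interval spans a
  large part of [0, 1].
- Kataegis event counts are only comparable between samples at similar
  genome sizes and mutation loads.
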