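# a3sig — APOBEC3 mutation-signature analysis

`a3sig` analyzes somatic single-base-substitution (SBS) catalogs for the
footprint of APOBEC3 cytosine deaminases, the enzymes behind COSMIC
signatures SBS2 and SBS13. It is written for researchers who have a mutation
table (MAF-style TSV or VCF) and a reference FASTA and want to answer, with
tested code: *does this sample carry APOBEC3 signature mutations, and do
they look more like APOBEC3A or APOBEC3B activity?*

## What it computes

The APOBEC3 signature is C>T and C>G substitution in 5'-TCW motifs
(W = A/T), after every SBS is pyrimidine-oriented (G/A-reference records are
reverse-complemented). On top of that definition the package provides:

- **Context spectra** — SBS-96 trinucleotide profiles and 48-channel
  pentanucleotide C>T profiles (N T[C>T] H N).
- **Motif fractions** — +1 and −2 base composition of TC-context cytosine
  mutations, including f(YTCW) and f(RTCW) (Y = C/T, R = A/G). The −2 base
  separates the two enzymes: A3A prefers YTCW (~72.7% of its TCW
  mutations), A3B slightly prefers RTCW (47.2% YTCW).
- **TCW enrichment score** with significance:

  `E = (M_TCW × C_C) / (M_C × C_TCW)`

  where M are mutation counts (TCW vs all cytosine mutations) and C are
  strand-symmetric motif counts in ±20 nt windows around each mutated
  cytosine; a one-sided Fisher exact test on
  `[[M_TCW, C_TCW], [M_C − M_TCW, C_C − C_TCW]]` with Benjamini–Hochberg
  correction across samples.
- **Hairpin analysis** — a scanner for perfect inverted repeats (stem ≥ 6 bp,
  single-stranded loop 3–11 nt), a merged loop mask, and per-Mbp mutation
  rates in loop vs non-hairpin DNA with Welch t-tests.
- **Kataegis** — intermutation distances (rainfall-plot input) and clustered
  events: ≥ 2 strand-coordinated APOBEC3 signature mutations with
  consecutive gaps ≤ 10 kb.
- **Etiology assignment** — hierarchical clustering (Euclidean distance) of
  pentanucleotide C>T profiles (TCG excluded), a k = 3 anchor-labelled cut
  into A3A-like / A3B-like / non-APOBEC groups, and a two-anchor mixture
  weight `w = clamp((f_YTCW − 0.472) / (0.727 − 0.472), 0, 1)` placing a
  sample between the A3B (w = 0) and A3A (w = 1) endpoints.
- **Single-hit deamination kinetics** — exponential-approach time courses
  `P(t) = S0·(1 − e^(−vt/S0))`, initial-rate fitting, and hairpin/linear
  fold preferences.
- **A truth-labelled simulator** — random genomes, planted hairpins, and
  mutation catalogs with condition-level count models, tunable TCW motif
  preferences, kataegis runs, and loop rate multipliers, so every analysis
  stage can be validated against known ground truth.

## Worked example

Simulate one A3A-mode clone at a human-like mutation density and run the
core analyses:

```python
from a3sig import (SimulationConfig, make_genome, simulate_clone,
                   annotate_contexts, motif_fractions, enrichment_score,
                   call_kataegis, a3_mixture_weight)

genome = make_genome(10_000_000, gc=0.4, seed=1)
cfg = SimulationConfig(seed=1)
records, truth = simulate_clone(genome, cfg, "A3A", seed=7,
                                sample_id="A3A_demo", n_mutations=250)
contexts = annotate_contexts(records, genome, flank=2)

mf = motif_fractions(contexts)
print(f"mutations: {len(records)} total, {mf.n_tc} C>T/C>G at TC, {mf.n_tcw} at TCW")
print(f"f_YTCW = {mf.f_YTCW:.3f}  (f_W = {mf.f_W:.3f}, +1 A = {mf.f_plus1_A:.3f})")
(res,) = enrichment_score(contexts, genome, window=20)
print(f"TCW enrichment E = {res.E:.2f}  (M_TCW={res.M_TCW}, M_C={res.M_C}, Fisher p = {res.p:.3g})")
events = call_kataegis(contexts, window=10_000, min_members=2)
print(f"kataegis events: {len(events)} (planted: {truth.frame.kataegis_id.max() + 1})")
print(f"A3A:A3B mixture weight w = {a3_mixture_weight(mf.f_YTCW):.2f}")
```

prints

```text
mutations: 250 total, 79 C>T/C>G at TC, 76 at TCW
f_YTCW = 0.618  (f_W = 0.962, +1 A = 0.443)
TCW enrichment E = 3.34  (M_TCW=76, M_C=111, Fisher p = 1.5e-25)
kataegis events: 5 (planted: 2)
A3A:A3B mixture weight w = 0.57
```

Reading the output: the clone's cytosine mutations are strongly concentrated
at TCW (E = 3.3, overwhelmingly significant), as expected for an
APOBEC3-driven catalog. At only 76 TCW mutations the YTCW fraction is a
noisy estimate — 0.618 here against a generating preference of 0.727 (about
1.7 binomial SE low, further diluted by the non-APOBEC background fraction of
the catalog) — which is why the mixture weight of a small catalog should be
read with its sample size. The kataegis caller reports the two planted
strand-coordinated runs plus chance clusters, which are common at this demo
density (250 mutations on 10 Mbp is sparse in absolute terms but ~30× denser
per Mbp than a 3,500-mutation human genome).

A command-line surface wraps the same functions:

```sh
a3 simulate --seed 3 --out simdir/
a3 hairpin scan --fasta genome.fa --min-stem 6 --loop 3:11 --out hairpins.tsv
a3 kataegis --maf muts.maf.tsv --fasta genome.fa --window 10000 --out events.tsv
a3 etiology --maf muts.maf.tsv --fasta genome.fa --anchors anchors.tsv --k 3 --out calls.tsv
a3 kinetics fit --csv timecourse.csv --s0 800
```

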