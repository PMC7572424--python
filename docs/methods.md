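# Methods

This note documents the models, parameter choices, numerical conventions,
and known limitations of `ffpeqc`.  It states no empirical result beyond
what the test suite and `scripts/acceptance.py` compute.

## Transcript integrity (TIN)

Coverage along a transcript is treated as a discrete probability
distribution.  With depth `d_i` at sampled positions `i = 1..k`
(`sample_step = 1` by default, i.e. every base), `p_i = d_i / Σd`, and
Shannon entropy `H = −Σ_{p_i>0} p_i ln p_i` (with the `0·ln 0 := 0`
convention), the score is

```
TIN = 100 · e^H / k .
```

`e^H` is the *effective number* of covered positions, so TIN is the
percentage of the transcript that is effectively covered: 100 for perfectly
uniform non-zero coverage, `100/k` for a single-base spike, strictly between
0 and 100 otherwise.  By convention an all-zero profile scores 0 and is
flagged unexpressed.  TIN is invariant to uniform depth scaling and
decreases under any mean-preserving concentration of coverage mass (entropy
is Schur-concave); both properties are verified by tests against an
independent entropy loop.

Aggregation conventions:

* **Sample TIN** = median of the sample's *non-zero* transcript TINs;
  even-sized multisets average the two central values.  A sample is high
  quality iff sample TIN **strictly** exceeds 50 (a sample at exactly 50
  fails the gate).  A sample with no expressed transcript is flagged rather
  than scored 0, since 0 would conflate "unexpressed" with "fully degraded".
* **Gene TIN** = the TIN of the gene's canonical transcript.  When no
  isoform is designated canonical the maximum TIN across isoforms is used:
  the best-covered isoform bounds how intact the gene's RNA can be, and the
  choice is deterministic.
* **Bimodality summary.**  Per-gene TIN distributions of degraded samples
  are bimodal (a degraded low mode and an intact high mode).  The low-mode
  fraction is the fraction of genes strictly below a fixed valley threshold
  (default 50, matching the sample gate).  A fixed valley was chosen over
  mode-finding because it is deterministic, testable, and comparable across
  samples; it misestimates the fraction when a sample's valley sits far
  from 50.

## Transcript bias (TB)

TB measures signed 5'→3' coverage skew as the integral difference between
the observed coverage distribution and the uniform distribution.  With
relative positions `x_i = (i + ½)/L`,

```
TB = 2 · ( Σ d_i x_i / Σ d_i − ½ ) = 2 ∫ x (dF_obs − dF_unif) .
```

TB is 0 for uniform or 5'/3'-symmetric coverage, positive when mass is
skewed 3', antisymmetric under reversal of the coverage vector (so
mis-annotated strands flip its sign), scale invariant, and bounded in
(−1, 1) with the extremes reached only in the limit of all mass on a
terminal base of an arbitrarily long transcript.  The weighted-mean form was
chosen because it is cheap, analytically checkable, and directly
interpretable as "where the average read sits".  Coverage vectors are always
stored 5'→3' in transcript orientation; genome-coordinate ingestion
reverses minus-strand transcripts, which fixes the sign convention.

TB is undefined (an error, not 0) for unexpressed transcripts.

## Feature composition

Aligned bases are assigned to exactly one of
`exon, ncRNA, intron, repeat, enhancer, intergenic`.  Overlaps are resolved
by a configurable priority order, default
`exon > ncRNA > intron > repeat > enhancer > intergenic`, which charges
ambiguous bases to the transcribed feature most likely to have produced the
RNA.  Uncovered bases are intergenic, so category counts always conserve
total aligned bases.  Coordinates are half-open 0-based throughout;
mitochondrial contigs (default blocklist `{chrM, MT}`) are excluded.

Strand concordance of a category is the fraction of its bases whose fragment
strand matches the annotated feature strand, restricted to bases with no
annotation of any category on the opposite strand (such bases cannot be
attributed).  Enhancers carry no strand annotation; they are scored against
the forward strand, reported as "sense" by convention, so dual-strand
enhancer transcription shows up as a sense fraction near 0.5.  Zero eligible
bases yield a flagged NaN, never 0.  Both base-level and read-level
(majority category, priority tie-break) counts are emitted; fractions
default to bases.

Mean category depth = assigned bases / union span of the category's
annotated intervals; zero-span categories are flagged undefined.

## Replicate concordance

All comparisons run on `log2(rescaled TPM + 1)`.  Genes are filtered to mean
rescaled TPM **strictly** greater than 1 across the samples being compared
(rescaling happens first, then filtering), removing detection-limit noise.
Per pair:

* Pearson r of the two log profiles (NaN when a profile is constant; never
  imputed);
* per-gene divergence `|x_g − y_g|` — variance is undefined from two
  replicates, so the 99th percentile of divergence summarises a pair's most
  extreme disagreements.  Percentiles use linear interpolation of order
  statistics (the convention is stated because percentile dialects differ).
  The divergence scale matches the correlation transform (`log2(TPM+1)`),
  keeping the two statistics comparable;
* Bland–Altman tables `((x+y)/2, x−y)` per gene for plotting.

Pairs are stratified by replicate type (library, extraction,
microdissection, fixation) and by the TIN gate (a pair is high-TIN iff both
samples pass).  Summaries report the median r and median divergence
percentile per stratum, plus the per-pair table underlying the
r-vs-divergence scatter.

## Cohort mapping

Two cohorts measured on different platforms differ by strong, largely
monotone technical effects.  The mapper learns, per shared gene, the
empirical quantile correspondence between the source and reference cohorts
on `log2(TPM+1)`:  a source value is carried through the source cohort's
empirical CDF (linear interpolation between order statistics) and evaluated
under the reference quantile function.  Properties: monotone (within-cohort
rank order preserved per gene); exact marginal equalisation when training
cohorts have equal sizes and distinct values (permutation matching); values
outside the training range clamp to the endpoint quantiles; a gene constant
in the reference collapses to that constant (flagged); a gene constant in
the source carries no rank information and maps to the reference median
(flagged).  Gene-wise quantile mapping was chosen over a latent-space
correction because it is exactly evaluable, preserves gene-level
interpretability, and removes any monotone per-gene platform effect.

The comparison baseline standardises each gene to the reference mean/SD — it
fully corrects affine effects but cannot reshape non-affine monotone
distortions, which is precisely what separates the two methods on the
synthetic platform warp.

Before mapping, matrices are rescaled to sum 1e6 per sample after dropping a
user-supplied exclusion list (rRNA-like and mitochondrial-like features by
default for the simulations); this normalises out sample-to-sample
variation in ribosomal depletion efficiency.

**Mixing diagnostics** run PCA (2 components by default, reduced with a
warning when samples are scarce) on the `n_top_genes = 3000` most-varying
genes of the combined matrix (variance computed before mapping on the log
scale) and report: the silhouette of the cohort labels in PC space (≈0 when
platforms mix), the variance-weighted eta-squared of the cohort label over
PCs 1–2, and the adjusted Rand index between k-means clusters (k = number of
cancer types, fixed `random_state`, `n_init=10`) and the type labels.  A
single cancer type makes the ARI undefined (NaN, flagged).

## Sequencing success bookkeeping

Samples pass a two-stage funnel (RNA extraction → library prep; library →
sufficient non-ribosomal RNA); passing stage 2 requires passing stage 1, so
the overall rate is exactly the product of the stage rates.  Rates are
reported as exact fractions alongside rounded whole percents because
rounding is lossy: stage rates of 86% and 94% compose to 80.84%, printed
as 81%.

## Synthetic data generator

The generator defines the conditions every other module is tested under.
What it emulates, and how:

* **Transcriptome.**  Transcript lengths are log-normal
  (`ln`-mean 7.3, `ln`-SD 0.6 — median ≈ 1.5 kb, a realistic mRNA length
  scale); each gene has one canonical transcript (the longest) and a 30%
  chance of a shorter isoform.  Genes carry role tags (histone-like 5%,
  mitochondrial-like 5%, rRNA-like 2%, zinc-finger-like 5%) embedded in
  their ids so enrichment-style checks are label-based.  A toy single
  chromosome hosts exons/introns with repeats and unstranded enhancers in
  intergenic gaps.
* **Coverage.**  Degradation is a Poisson breakage process with per-base
  rate λ.  Under poly-A selection only the 3'-terminal surviving piece is
  captured, so a captured fragment's 3'-end distance from the transcript
  terminus is truncated-exponential(λ) and expected depth decays like
  `e^{−λd}` — producing 3' bias that grows with λ and transcript length,
  the signature of poly-A libraries on degraded RNA.  λ = 0 reduces to
  uniform fragment placement.  Ribo-deplete mode places fragments uniformly
  (optional linear 5' tilt emulating the slight 5' bias of ribo-deplete
  FFPE data).  A "hotspot" mode concentrates fragments around a random
  anchor to produce low-TIN transcripts; a configurable fraction of a
  sample's transcripts uses it, reproducing bimodal per-gene TIN.  Fragment
  lengths are log-normal (median ≈ 180 nt); every fragment lies fully inside
  the transcript, so total depth equals total fragment bases exactly.
  Default simulation depth is 2000 fragments per transcript (10⁴ where bias
  measurements need tight Monte-Carlo error).
* **Cohorts.**  Gene base expression is `N(3.5, 1.5)` on the log2 scale
  (clipped ≥ 0.1); 3 cancer types shift disjoint marker blocks (30% of
  generic genes, split evenly) by `σ_type = 2`; per-sample noise SD 0.4;
  60 samples per cohort by default (200 in the mapping evaluation).  The
  ribo-deplete (FFPE-like) cohort elevates histone-like genes by 2 log2
  units (non-polyadenylated transcripts that poly-A selection misses),
  depletes mitochondrial-like genes by 2.5 (removed with rRNA by depleting
  oligos), and adds per-sample residual rRNA (`N(4, 1)` log2, clipped ≥ 0) —
  the variation the TPM-rescaling exclusion list removes.  The poly-A
  cohort receives the platform batch effect the mapper must undo: a global
  monotone non-affine warp `x → 0.3 + x^1.3 / 6^0.3` plus a per-gene
  multiplicative capture-efficiency gain (log-SD 0.15).  Both effects are
  strictly monotone per gene, so they are removable in principle by a
  gene-wise monotone map; the gain magnitude makes the two cohorts clearly
  separable in PC space before correction, as combined FFPE/poly-A cohorts
  are in practice.  Log-signal is converted to TPM via `2^x − 1` and each
  column rescaled to 1e6.
* **Replicates.**  Pairs share a base profile plus independent per-sample
  log2 noise with SD 0.10 / 0.25 / 0.40 / 0.60 for library / extraction /
  microdissection / fixation replicates — the protocol-stage ordering of
  technical variability.  25% of pairs are low-TIN (sample TINs drawn around
  38 vs 72 for high-TIN pairs) with doubled noise, reproducing the
  association between poor integrity and poor concordance.  Platform
  effects and residual rRNA are shared within a pair so the ladder ordering
  reflects the configured noise alone.

No quantitative degradation parameters are available for real FFPE
material, so coverage defaults are illustrative and exposed in
`SimulationConfig`.

### What the generator does *not* emulate

Sequence-realistic GC structure (GC is random per transcript), alignment
and multi-mapping artifacts (relevant to homologous gene families such as
zinc fingers), read-level errors, gene–gene correlation beyond the type
blocks, length-dependent expression quantification bias, and count noise
(expression noise is Gaussian on the log scale).  Passing tests therefore
demonstrate the correctness and self-consistency of the statistics and of
the mapping machinery under the stated generative assumptions — not
performance on real FFPE libraries, where violations of monotonicity
(e.g. gene-specific saturation) would degrade the quantile map.

## Numerical conventions

* Percentiles: linear interpolation between order statistics.
* Medians of even-sized sets: mean of the central pair.
* Quality gates: strict inequalities.
* `0·ln 0 := 0` in entropy; TIN of an all-zero profile is 0 by convention.
* Undefined statistics (constant profiles, zero eligible bases, single
  cancer type) are NaN-flagged, never imputed as 0.
* TSVs are tab-separated with a mandatory header and `.` for missing;
  expression round-trips are bitwise exact (`float_precision="round_trip"`).
* All genomic intervals are half-open 0-based; BED12/GTF-style minus-strand
  transcripts are reversed on projection so coverage is 5'→3'.
* All randomness flows through explicit seeds; k-means uses a fixed
  `random_state` and `n_init=10`.

## Problem sizes

The shipped test suite and acceptance script use 600–1000 genes, 60–200
samples per cohort, 8–10 replicate pairs per type, coverage depth 10⁴
fragments for bias measurements, and ≤ 10 kb composition fixtures.  These
sizes give stable Monte-Carlo estimates (binomial/KS error well inside the
asserted tolerances) while keeping a full run to a couple of minutes.

## Known limitations

* The TB statistic is one of several reasonable integral-difference skew
  measures; it saturates slowly and is insensitive to symmetric coverage
  loss (by design — that is TIN's job).
* Gene-wise quantile mapping forces marginal agreement even for genes whose
  cohort difference is biological (e.g. histone capture); such differences
  are erased in the mapped space, which is why role tags are kept for
  downstream enrichment checks.
* With tied source values (zero-inflated genes) the quantile map cannot
  split the tie; all tied samples map to one reference quantile.
* The location-scale baseline is a deliberately simple comparator, not a
  reimplementation of empirical-Bayes batch correction.
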