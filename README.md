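# ffpeqc

Quality, concordance, and cross-platform mapping toolkit for degraded
(FFPE-derived) bulk RNA-seq expression data.

RNA extracted from formalin-fixed paraffin-embedded (FFPE) tissue — the
material most readily available in clinical settings — is chemically
crosslinked and fragmented, so its sequencing data carries characteristic
artifacts: non-uniform transcript coverage, platform-dependent 5'/3' end
bias, variable residual ribosomal RNA, and reduced replicate concordance.
`ffpeqc` implements the post-sequencing analyses needed to quantify these
artifacts and to decide whether a sample's expression profile is usable:

* **Transcript integrity (TIN).**  For a coverage vector `d` along a
  transcript sampled at `k` positions, with `p_i = d_i / Σd` and Shannon
  entropy `H = −Σ p_i ln p_i`,

  `TIN = 100 · e^H / k ∈ [0, 100]`.

  Uniform coverage (intact RNA) scores 100; a single-base spike over `k`
  bases scores `100/k`.  A sample is called **high quality** when the median
  of its non-zero transcript TINs strictly exceeds 50; per-gene TIN is the
  canonical transcript's TIN.

* **Transcript bias (TB).**  A signed score of 5'→3' coverage skew: with
  relative positions `x_i = (i + ½)/L`,

  `TB = 2·(Σ d_i x_i / Σ d_i − ½) ∈ (−1, 1)`,

  i.e. twice the difference between the depth-weighted mean position and the
  uniform-coverage value ½.  TB > 0 means 3'-weighted coverage — the
  signature of poly-A selection acting on degraded RNA; ribo-depleted
  libraries stay near 0 with a slight 5' tilt.

* **Feature composition.**  Aligned bases are classified into exon, ncRNA,
  intron, repeat, enhancer, or intergenic categories (overlaps resolved by a
  priority order), with per-category coverage and sense-strand fractions.

* **Replicate concordance.**  For replicate pairs at successive protocol
  stages (library, extraction, microdissection, fixation): genes filtered at
  mean rescaled TPM > 1, Pearson correlation of `log2(TPM+1)` profiles,
  per-gene divergence `|x_g − y_g|` with its 99th-percentile summary, and
  Bland–Altman tables, stratified by the TIN gate.

* **Cohort mapping.**  A per-gene empirical quantile map (scikit-learn-style
  `fit`/`transform` estimator) that projects a poly-A cohort into a
  ribo-deplete cohort's `log2(TPM+1)` space, removing monotone platform
  effects that a per-gene location/scale baseline cannot; PCA silhouette,
  cohort variance share, and cluster/type agreement quantify the result.

* **Synthetic data.**  A seeded generator producing transcript models,
  platform-specific coverage (Poisson-breakage degradation with 3'-anchored
  capture under poly-A), two-platform expression cohorts with cancer-type
  structure, and replicate ladders — so every analysis runs end to end
  without external data.

## Worked example

```python
import numpy as np
from ffpeqc import (SimulationConfig, TranscriptModel, simulate_coverage,
                    compute_tin, compute_tb)

tm = TranscriptModel("tx1", "gene1", "+", length_nt=2000, canonical=True)
rng = np.random.default_rng(5)

cfg = SimulationConfig(seed=1, depth=10_000, degradation_rate=0.01)
polya = simulate_coverage(tm, cfg, rng, mode="polyA")
ribo = simulate_coverage(tm, cfg, rng, mode="ribodeplete")

print(f"polyA:      TIN={compute_tin(polya):5.1f}  TB={compute_tb(polya):+.3f}")
print(f"ribodeplete: TIN={compute_tin(ribo):5.1f}  TB={compute_tb(ribo):+.3f}")
```

prints

```
polyA:      TIN= 23.4  TB=+0.790
ribodeplete: TIN= 95.4  TB=-0.003
```

Under poly-A selection of degraded RNA (breakage rate λ = 0.01 per base),
coverage collapses onto the 3' end of the 2 kb transcript: integrity drops
to 23 and the bias score approaches +0.8.  The same transcript under
ribo-depletion keeps near-uniform coverage (TIN ≈ 96, TB ≈ 0).

The same operations are available from the shell:

```bash
ffpeqc simulate --seed 3 --n-genes 100 --out sim/
ffpeqc qc --coverage sim/coverage.tsv --out qc/
ffpeqc concordance --expr sim/replicates_tpm.tsv --pairs sim/pairs.tsv --out conc/
ffpeqc map --reference sim/reference_tpm.tsv --source sim/source_tpm.tsv \
           --labels sim/labels.tsv --exclude sim/exclude_genes.txt --out map/
ffpeqc success --outcomes outcomes.tsv --out succ/
```

## Layout

```
src/ffpeqc/
  models.py       core containers (transcripts, coverage, matrices, pairs)
  quality.py      TIN / TB scoring and sample/gene aggregation
  composition.py  feature classification and strand concordance
  concordance.py  replicate filtering, correlation, divergence
  mapping.py      quantile & location-scale mappers, mixing diagnostics
  simulate.py     synthetic transcriptomes, coverage, cohorts
  io.py           TSV/BED/bedGraph/JSON readers and writers
  reporting.py    sequencing success-rate bookkeeping
  cli.py          `ffpeqc` command line
docs/methods.md   model assumptions, parameter choices, limitations
```
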