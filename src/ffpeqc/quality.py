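"""Transcript-level RNA integrity and 5'-3' bias scoring.

Two complementary statistics are computed from per-base coverage along a
transcript:

* **TIN (transcript integrity number)** — an entropy-based score of coverage
  uniformity.  Positions are sampled every ``sample_step`` bases; with
  sampled depths ``d_i`` and ``p_i = d_i / sum(d)``, the Shannon entropy is
  ``H = -sum(p_i ln p_i)`` and ``TIN = 100 * exp(H) / k`` where ``k`` is the
  number of sampled positions.  Perfectly uniform non-zero coverage scores
  100; a single-base spike over ``k`` positions scores ``100/k``.  Intact RNA
  yields near-uniform coverage, so TIN is a post-sequencing proxy for RNA
  intactness.

* **TB (transcript bias)** — a signed score of 5' vs 3' coverage skew,
  defined as twice the difference between the depth-weighted mean relative
  position and the uniform-coverage value 1/2:
  ``TB = 2 * (sum(d_i * x_i) / sum(d_i) - 1/2)`` with ``x_i = (i + 1/2) / L``.
  TB is 0 for uniform or 5'/3'-symmetric coverage, positive when coverage
  mass is skewed toward the 3' end (the signature of poly-A selection on
  degraded RNA), and bounded in (-1, 1).

Aggregation follows the sample gate used throughout the package: a sample is
high quality iff the median of its non-zero transcript TINs strictly exceeds
50; per-gene TIN is the canonical transcript's TIN (max across isoforms when
no canonical isoform is designated).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import entropy as _shannon_entropy

from .models import (
    TIN_GATE,
    CoverageProfile,
    GeneQuality,
    QualityRecord,
    SampleQuality,
    TranscriptModel,
)

__all__ = [
    "compute_tin",
    "compute_tb",
    "compute_sample_tin",
    "compute_gene_tin",
    "per_gene_tin_distribution",
    "score_profiles",
    "summarize_sample_quality",
    "SampleTinSummary",
    "TinDistribution",
]


def _as_depth(profile: CoverageProfile | np.ndarray | Sequence[float]) -> np.ndarray:
    if isinstance(profile, CoverageProfile):
        return np.asarray(profile.depth, dtype=float)
    depth = np.asarray(profile, dtype=float)
    if depth.ndim != 1 or depth.size == 0:
        raise ValueError("empty profile")
    if np.any(depth < 0):
        raise ValueError("negative depth")
    return depth


def compute_tin(
    profile: CoverageProfile | np.ndarray | Sequence[float], sample_step: int = 1
) -> float:
    """Transcript integrity number in [0, 100].

    Parameters
    ----------
    profile
        Coverage profile or raw depth vector (5'->3').
    sample_step
        Sampling interval in bases; 1 (default) scores every base.
        Larger steps emulate subsampled TIN implementations.

    Returns
    -------
    float
        100 for perfectly uniform non-zero sampled coverage, 0 for all-zero
        coverage (by convention), strictly between 0 and 100 otherwise.
    """
    depth = _as_depth(profile)
    if sample_step < 1:
        raise ValueError("sample_step must be >= 1")
    if sample_step > depth.size:
        raise ValueError("step exceeds transcript length")
    sampled = depth[::sample_step]
    total = sampled.sum()
    if total == 0:
        return 0.0
    k = sampled.size
    # scipy normalises and applies the 0*ln(0) := 0 convention
    h = _shannon_entropy(sampled)
    return float(100.0 * np.exp(h) / k)


def compute_tb(profile: CoverageProfile | np.ndarray | Sequence[float]) -> float:
    """Transcript bias score in (-1, 1); positive = 3'-weighted coverage.

    Raises
    ------
    ValueError
        If the profile has zero total depth (TB is undefined for
        unexpressed transcripts).
    """
    depth = _as_depth(profile)
    total = depth.sum()
    if total == 0:
        raise ValueError("TB undefined for unexpressed transcript")
    n = depth.size
    x = (np.arange(n) + 0.5) / n
    m = float(np.dot(depth, x) / total)
    return 2.0 * (m - 0.5)


@dataclass
class SampleTinSummary:
    """Median non-zero TIN of a sample and the resulting quality call."""

    sample_tin: float
    high_quality: bool
    n_nonzero: int
    no_expressed_transcripts: bool = False


def compute_sample_tin(
    tins: Iterable[float], gate: float = TIN_GATE
) -> SampleTinSummary:
    """Aggregate per-transcript TINs to the sample-level quality score.

    Zeros (unexpressed transcripts) are excluded before taking the median;
    an even count averages the two central values.  The quality gate is a
    strict inequality: a sample sitting exactly at the gate is *not* high
    quality.  If every TIN is zero the score is undefined and the summary is
    flagged rather than reported as 0.
    """
    values = np.asarray(list(tins), dtype=float)
    if values.size == 0:
        raise ValueError("no TIN values supplied")
    nonzero = values[values > 0]
    if nonzero.size == 0:
        return SampleTinSummary(
            sample_tin=float("nan"),
            high_quality=False,
            n_nonzero=0,
            no_expressed_transcripts=True,
        )
    med = float(np.median(nonzero))
    return SampleTinSummary(
        sample_tin=med, high_quality=med > gate, n_nonzero=int(nonzero.size)
    )


def compute_gene_tin(
    records: Sequence[QualityRecord],
    annotation: Mapping[str, TranscriptModel] | Sequence[TranscriptModel],
) -> GeneQuality:
    """Per-gene TIN for one gene in one sample.

    Uses the canonical transcript's TIN when the annotation designates one;
    otherwise falls back to the maximum TIN across the gene's isoforms.
    """
    if not records:
        raise ValueError("gene absent from sample")
    if isinstance(annotation, Mapping):
        models = annotation
    else:
        models = {t.transcript_id: t for t in annotation}
    missing = [r.transcript_id for r in records if r.transcript_id not in models]
    if missing:
        raise ValueError(f"transcripts missing from annotation: {missing}")
    tx_models = [models[r.transcript_id] for r in records]
    genes = {t.gene_id for t in tx_models}
    if len(genes) > 1:
        raise ValueError(f"records span multiple genes: {sorted(genes)}")
    samples = {r.sample_id for r in records}
    if len(samples) > 1:
        raise ValueError(f"records span multiple samples: {sorted(samples)}")
    gene_id = genes.pop()
    sample_id = records[0].sample_id

    canonical_ids = {t.transcript_id for t in tx_models if t.canonical}
    by_tx = {r.transcript_id: r.tin for r in records}
    if canonical_ids:
        canon_in_sample = canonical_ids & by_tx.keys()
        if canon_in_sample:
            tin = by_tx[next(iter(canon_in_sample))]
        else:  # canonical isoform not covered in this sample
            tin = max(by_tx.values())
    else:
        tin = max(by_tx.values())
    return GeneQuality(gene_id=gene_id, sample_id=sample_id, gene_tin=float(tin))


@dataclass
class TinDistribution:
    """Binned per-gene TIN distribution with a bimodality summary."""

    bin_edges: np.ndarray
    counts: np.ndarray
    low_mode_fraction: float
    valley: float
    n_genes: int


def per_gene_tin_distribution(
    gene_tins: Iterable[float] | Iterable[GeneQuality],
    bin_width: float = 2.5,
    valley: float = TIN_GATE,
) -> TinDistribution:
    """Histogram of per-gene TINs over [0, 100] plus the low-mode fraction.

    Degraded FFPE samples show a bimodal per-gene TIN distribution (a low
    integrity peak and a high one); ``low_mode_fraction`` is the fraction of
    genes strictly below the ``valley`` threshold separating the two modes.
    A fixed valley (default 50, matching the sample gate) keeps the summary
    deterministic; no mode finding is attempted.
    """
    vals = [g.gene_tin if isinstance(g, GeneQuality) else float(g) for g in gene_tins]
    if len(vals) == 0:
        raise ValueError("no gene TINs supplied")
    arr = np.asarray(vals, dtype=float)
    if bin_width <= 0 or bin_width > 100:
        raise ValueError("bin_width must be in (0, 100]")
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    edges[-1] = max(edges[-1], 100.0)
    counts, edges = np.histogram(arr, bins=edges)
    low_frac = float(np.mean(arr < valley))
    return TinDistribution(
        bin_edges=edges,
        counts=counts,
        low_mode_fraction=low_frac,
        valley=valley,
        n_genes=arr.size,
    )


def score_profiles(
    profiles: Iterable[CoverageProfile], sample_step: int = 1
) -> list[QualityRecord]:
    """Score a batch of coverage profiles into per-transcript quality records."""
    records = []
    for p in profiles:
        tin = compute_tin(p, sample_step=sample_step)
        expressed = p.expressed
        tb = compute_tb(p) if expressed else float("nan")
        records.append(
            QualityRecord(
                transcript_id=p.transcript_id,
                sample_id=p.sample_id,
                tin=tin,
                tb=tb,
                mean_depth=p.mean_depth,
                expressed=expressed,
            )
        )
    return records


def _weighted_gc(
    profiles: Sequence[CoverageProfile], sequences: Mapping[str, str]
) -> float | None:
    """Depth-weighted GC fraction over expressed transcripts with sequences."""
    gc_mass = 0.0
    total_mass = 0.0
    for p in profiles:
        seq = sequences.get(p.transcript_id)
        if seq is None or not p.expressed:
            continue
        if len(seq) != p.length:
            raise ValueError(
                f"sequence length {len(seq)} != profile length {p.length} "
                f"for {p.transcript_id}"
            )
        is_gc = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        gc_mask = (is_gc == ord("G")) | (is_gc == ord("C"))
        depth = np.asarray(p.depth, dtype=float)
        gc_mass += float(depth[gc_mask].sum())
        total_mass += float(depth.sum())
    if total_mass == 0:
        return None
    return gc_mass / total_mass


def summarize_sample_quality(
    profiles: Sequence[CoverageProfile],
    annotation: Sequence[TranscriptModel] | None = None,
    sequences: Mapping[str, str] | None = None,
    template_lengths: Iterable[float] | None = None,
    sample_step: int = 1,
    gate: float = TIN_GATE,
) -> SampleQuality:
    """Full per-sample quality summary from all of a sample's profiles.

    Computes sample TIN (median non-zero transcript TIN) and the quality
    call, the median TB over expressed transcripts, the number of expressed
    transcripts, and — when auxiliary data are given — the depth-weighted GC
    content of expressed transcripts and the mean sequencing template
    (fragment) length.
    """
    if len(profiles) == 0:
        raise ValueError("no profiles supplied")
    sample_ids = {p.sample_id for p in profiles}
    if len(sample_ids) > 1:
        raise ValueError(f"profiles span multiple samples: {sorted(sample_ids)}")
    sample_id = sample_ids.pop()

    records = score_profiles(profiles, sample_step=sample_step)
    tin_summary = compute_sample_tin([r.tin for r in records], gate=gate)
    tbs = [r.tb for r in records if r.expressed]
    median_tb = float(np.median(tbs)) if tbs else float("nan")

    gc = _weighted_gc(profiles, sequences) if sequences else None
    mean_tl = None
    if template_lengths is not None:
        tl = np.asarray(list(template_lengths), dtype=float)
        if tl.size:
            mean_tl = float(tl.mean())

    return SampleQuality(
        sample_id=sample_id,
        sample_tin=tin_summary.sample_tin,
        high_quality=tin_summary.high_quality,
        median_tb=median_tb,
        n_expressed=sum(r.expressed for r in records),
        gc_content=gc,
        mean_template_length=mean_tl,
        no_expressed_transcripts=tin_summary.no_expressed_transcripts,
    )
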