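"""Synthetic transcriptomes, coverage profiles, and expression cohorts.

The generator emulates the statistical structure that degraded-RNA QC
analysis assumes, so every other module is testable without real data:

* **Coverage under fragmentation with platform-dependent end bias.**
  Degradation is modelled as a Poisson breakage process with per-base rate
  ``lambda``.  Under poly-A selection only fragments whose 3' end survives
  near the transcript's 3' terminus are captured, so the distance of a
  captured fragment's 3' end from the transcript terminus is (truncated)
  exponential with rate ``lambda`` and expected depth decays like
  ``exp(-lambda * d)`` with distance ``d`` from the 3' end — coverage bias
  grows with both ``lambda`` and transcript length.  Under ribo-depletion
  fragments start uniformly along the transcript (optionally with a small
  linear 5' tilt), giving near-uniform coverage.  A configurable fraction of
  transcripts can receive concentrated "hotspot" coverage to reproduce the
  bimodal per-gene TIN distributions of heavily degraded FFPE samples.

* **Two expression cohorts with cancer-type structure plus platform
  effects.**  Gene base expression is log-normal; cancer types shift
  type-specific marker blocks; the ribo-deplete cohort elevates
  non-polyadenylated histone-like genes and carries per-sample residual
  rRNA, while the poly-A cohort elevates mitochondrial-like genes (which
  ribo-depleting oligos remove) and is distorted by a global monotone,
  non-affine warp on the log scale — the batch effect the quantile mapper
  must undo and a location-scale baseline cannot.

* **Replicate pairs of four protocol types** with noise ordered
  library < extraction < microdissection < fixation, and a low-TIN
  subpopulation with inflated noise, reproducing the replicate ladder.

All outputs are deterministic functions of ``SimulationConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .composition import FeatureAnnotation
from .models import (
    CoverageProfile,
    ExpressionMatrix,
    ReplicatePair,
    TranscriptModel,
    validate_annotation_set,
)

__all__ = [
    "SimulationConfig",
    "TranscriptomeSim",
    "CohortSim",
    "assign_gene_roles",
    "make_transcriptome",
    "simulate_coverage",
    "simulate_sample_profiles",
    "simulate_cohorts",
    "default_exclusion_list",
]

GENE_ROLES = ("generic", "histone_like", "mito_like", "rrna_like", "zf_like")

_ROLE_TAGS = {
    "generic": "gen",
    "histone_like": "histl",
    "mito_like": "mtl",
    "rrna_like": "rrnal",
    "zf_like": "zfl",
}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic generator; defaults define the study
    conditions the rest of the package is exercised under.

    Coverage: ``degradation_rate`` is the per-base breakage rate (lambda);
    ``depth`` is fragments per transcript; fragment lengths are log-normal
    (median ~180 nt).  Transcript lengths are log-normal with median
    ~1500 nt.  Cohorts: 3 cancer types, 60 samples per cohort, type effect
    size 2 on the log2 scale.  Replicate noise (log2 SD per sample) is
    ordered library < extraction < microdissection < fixation.
    """

    seed: int = 0
    # transcriptome
    n_genes: int = 1000
    length_log_mean: float = 7.3
    length_log_sd: float = 0.6
    gc_mean: float = 0.45
    gc_sd: float = 0.05
    isoform_fraction: float = 0.3  # fraction of genes with a second isoform
    role_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "histone_like": 0.05,
            "mito_like": 0.05,
            "rrna_like": 0.02,
            "zf_like": 0.05,
        }
    )
    # coverage
    platform: str = "ribodeplete"  # "polyA" or "ribodeplete"
    degradation_rate: float = 0.002
    depth: int = 2000
    fragment_log_mean: float = 5.2
    fragment_log_sd: float = 0.35
    tilt5: float = 0.0  # linear 5' tilt of ribo-deplete fragment starts, in [-1, 1]
    low_tin_fraction: float = 0.0  # transcripts given hotspot (low-TIN) coverage
    hotspot_width_frac: float = 0.02
    # cohorts
    n_types: int = 3
    n_samples_per_cohort: int = 60
    sigma_type: float = 2.0
    sigma_sample: float = 0.4
    marker_fraction: float = 0.3  # generic genes carrying type structure
    histone_boost: float = 2.0  # ribo-deplete log2 elevation of histone-like genes
    mito_depletion: float = 2.5  # ribo-deplete log2 depletion of mito-like genes
    rrna_capture_mean: float = 4.0  # residual rRNA in ribo-deplete samples (log2)
    rrna_capture_sd: float = 1.0
    platform_warp_gamma: float = 1.3  # monotone non-affine warp of the poly-A cohort
    platform_warp_shift: float = 0.3
    platform_gene_effect_sd: float = 0.15  # per-gene capture-efficiency gain (log SD)
    # replicates
    n_pairs_per_type: int = 8
    pair_noise: Mapping[str, float] = field(
        default_factory=lambda: {
            "library": 0.10,
            "extraction": 0.25,
            "microdissection": 0.40,
            "fixation": 0.60,
        }
    )
    low_tin_pair_fraction: float = 0.25
    low_tin_noise_multiplier: float = 2.0

    def __post_init__(self) -> None:
        if self.degradation_rate < 0:
            raise ValueError("degradation rate must be >= 0")
        if self.platform not in ("polyA", "ribodeplete"):
            raise ValueError(f"unknown platform {self.platform!r}")
        if any(v < 0 for v in self.pair_noise.values()):
            raise ValueError("replicate noise SDs must be >= 0")
        if not -1.0 <= self.tilt5 <= 1.0:
            raise ValueError("tilt5 must be in [-1, 1]")


def assign_gene_roles(n_genes: int, rng: np.random.Generator) -> pd.Series:
    """Deterministically tag genes with functional roles.

    Role counts are fixed fractions of ``n_genes`` (histone-like 5%,
    mito-like 5%, rRNA-like 2%, zinc-finger-like 5%); which genes get which
    role is a seeded permutation.  Ids embed the role tag so that
    enrichment-style checks are label-based.
    """
    fracs = {"histone_like": 0.05, "mito_like": 0.05, "rrna_like": 0.02, "zf_like": 0.05}
    roles = np.array(["generic"] * n_genes, dtype=object)
    order = rng.permutation(n_genes)
    cursor = 0
    for role, frac in fracs.items():
        k = int(round(frac * n_genes))
        roles[order[cursor : cursor + k]] = role
        cursor += k
    ids = [f"G{i:05d}_{_ROLE_TAGS[str(roles[i])]}" for i in range(n_genes)]
    return pd.Series(roles, index=pd.Index(ids, name="gene_id"), name="role")


@dataclass
class TranscriptomeSim:
    """A toy annotated transcriptome."""

    transcripts: list[TranscriptModel]
    sequences: dict[str, str]
    annotation: FeatureAnnotation
    gene_roles: pd.Series
    exon_blocks: dict[str, list[tuple[int, int]]]  # genome coords per transcript
    transcript_chrom: dict[str, str]


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def make_transcriptome(config: SimulationConfig) -> TranscriptomeSim:
    """Generate transcript models, sequences, and a toy feature annotation.

    Each gene gets one canonical transcript (the longest isoform) laid out
    on a single chromosome with 1-3 exons; intergenic gaps are sprinkled
    with repeat and (unstranded) enhancer features so the composition module
    can be exercised.  Deterministic under ``config.seed``.
    """
    if config.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(config.seed)
    roles = assign_gene_roles(config.n_genes, rng)

    transcripts: list[TranscriptModel] = []
    sequences: dict[str, str] = {}
    anno_rows: list[dict] = []
    exon_blocks: dict[str, list[tuple[int, int]]] = {}
    tx_chrom: dict[str, str] = {}
    chrom = "chr1"
    cursor = 1000

    lengths = np.rint(
        rng.lognormal(config.length_log_mean, config.length_log_sd, config.n_genes)
    ).astype(int)
    lengths = np.maximum(lengths, 50)

    for i, gene_id in enumerate(roles.index):
        strand = "+" if rng.random() < 0.5 else "-"
        length = int(lengths[i])
        is_nc = roles.iloc[i] == "rrna_like" or rng.random() < 0.08
        category = "ncRNA" if is_nc else "exon"

        # canonical transcript, 1-3 exons with intron gaps
        tx_id = f"{gene_id}.t1"
        n_exons = int(rng.integers(1, 4))
        cuts = np.sort(rng.choice(np.arange(1, length), size=n_exons - 1, replace=False)) if n_exons > 1 else np.array([], dtype=int)
        exon_lens = np.diff(np.concatenate(([0], cuts, [length])))
        blocks = []
        pos = cursor
        for j, el in enumerate(exon_lens):
            blocks.append((pos, pos + int(el)))
            anno_rows.append(
                {"chrom": chrom, "start": pos, "end": pos + int(el),
                 "category": category, "strand": strand}
            )
            pos += int(el)
            if j < len(exon_lens) - 1:
                intron_len = int(rng.integers(60, 400))
                anno_rows.append(
                    {"chrom": chrom, "start": pos, "end": pos + intron_len,
                     "category": "intron", "strand": strand}
                )
                pos += intron_len
        transcripts.append(
            TranscriptModel(tx_id, gene_id, strand, length, canonical=True)
        )
        gc = float(np.clip(rng.normal(config.gc_mean, config.gc_sd), 0.2, 0.8))
        sequences[tx_id] = _random_sequence(rng, length, gc)
        exon_blocks[tx_id] = blocks
        tx_chrom[tx_id] = chrom

        # optional shorter non-canonical isoform (no separate genome layout)
        if rng.random() < config.isoform_fraction and length >= 100:
            alt_len = max(50, int(length * rng.uniform(0.4, 0.9)))
            alt_id = f"{gene_id}.t2"
            transcripts.append(
                TranscriptModel(alt_id, gene_id, strand, alt_len, canonical=False)
            )
            sequences[alt_id] = sequences[tx_id][:alt_len]

        # intergenic gap, sometimes hosting a repeat or enhancer
        gap = int(rng.integers(300, 1500))
        u = rng.random()
        if u < 0.35 and gap > 200:
            r_start = pos + int(rng.integers(20, gap // 2))
            r_len = int(rng.integers(50, min(400, gap // 2)))
            anno_rows.append(
                {"chrom": chrom, "start": r_start, "end": r_start + r_len,
                 "category": "repeat",
                 "strand": "+" if rng.random() < 0.5 else "-"}
            )
        elif u < 0.5 and gap > 200:
            e_start = pos + int(rng.integers(20, gap // 2))
            e_len = int(rng.integers(100, min(600, gap // 2)))
            anno_rows.append(
                {"chrom": chrom, "start": e_start, "end": e_start + e_len,
                 "category": "enhancer", "strand": "."}
            )
        cursor = pos + gap

    validate_annotation_set(transcripts)
    annotation = FeatureAnnotation(pd.DataFrame(anno_rows))
    return TranscriptomeSim(
        transcripts=transcripts,
        sequences=sequences,
        annotation=annotation,
        gene_roles=roles,
        exon_blocks=exon_blocks,
        transcript_chrom=tx_chrom,
    )


def _fragment_lengths(
    rng: np.random.Generator, n: int, config: SimulationConfig, max_len: int
) -> np.ndarray:
    f = np.rint(
        rng.lognormal(config.fragment_log_mean, config.fragment_log_sd, n)
    ).astype(int)
    return np.clip(f, 1, max_len)


def _tilted_uniform(rng: np.random.Generator, n: int, tilt: float) -> np.ndarray:
    """Sample from density 1 + tilt*(1-2x) on [0,1]; tilt>0 favours the 5' end."""
    u = rng.random(n)
    if tilt == 0:
        return u
    # invert CDF x + tilt*x*(1-x) = u
    a = tilt
    b = -(1.0 + tilt)
    disc = b * b - 4.0 * a * (u)
    return (-b - np.sqrt(disc)) / (2.0 * a)


def simulate_coverage(
    model: TranscriptModel,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    sample_id: str = "sim",
    mode: str | None = None,
) -> CoverageProfile:
    """Simulate per-base coverage for one transcript.

    ``mode`` overrides ``config.platform``; the extra mode ``"hotspot"``
    concentrates all fragments around a random anchor, producing the
    low-TIN coverage typical of heavily degraded transcripts.  The total
    simulated depth always equals the summed fragment lengths.
    """
    if config.depth <= 0:
        raise ValueError("depth must be > 0")
    if config.degradation_rate < 0:
        raise ValueError("degradation rate must be >= 0")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    mode = config.platform if mode is None else mode
    L = model.length_nt
    n = config.depth
    frag = _fragment_lengths(rng, n, config, L)

    if mode == "polyA":
        lam = config.degradation_rate
        max_d3 = L - frag  # keep fragments fully inside the transcript
        if lam > 0:
            u = rng.random(n)
            # truncated exponential on [0, max_d3]
            trunc = 1.0 - np.exp(-lam * (max_d3 + 1.0))
            d3 = np.floor(-np.log1p(-u * trunc) / lam).astype(int)
            d3 = np.minimum(d3, max_d3)
        else:
            d3 = np.floor(rng.random(n) * (max_d3 + 1)).astype(int)
        end = L - d3
        start = end - frag
    elif mode == "ribodeplete":
        max_start = L - frag
        x = _tilted_uniform(rng, n, config.tilt5)
        start = np.floor(x * (max_start + 1)).astype(int)
        start = np.minimum(start, max_start)
        end = start + frag
    elif mode == "hotspot":
        center = int(rng.integers(0, L))
        width = max(1.0, config.hotspot_width_frac * L)
        start = np.rint(rng.normal(center, width, n)).astype(int)
        start = np.clip(start, 0, L - frag)
        end = start + frag
    else:
        raise ValueError(f"unknown coverage mode {mode!r}")

    diff = np.zeros(L + 1, dtype=np.int64)
    np.add.at(diff, start, 1)
    np.add.at(diff, end, -1)
    depth = np.cumsum(diff[:-1])
    return CoverageProfile(
        transcript_id=model.transcript_id, sample_id=sample_id, depth=depth
    )


def simulate_sample_profiles(
    transcripts: list[TranscriptModel],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    sample_id: str = "sim",
) -> list[CoverageProfile]:
    """Coverage profiles for a whole sample.

    A seeded fraction ``low_tin_fraction`` of transcripts receives hotspot
    coverage, producing the bimodal per-gene TIN distribution seen in
    degraded samples; the rest follow the configured platform model.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n_low = int(round(config.low_tin_fraction * len(transcripts)))
    low_idx = set(rng.choice(len(transcripts), size=n_low, replace=False).tolist())
    profiles = []
    for i, t in enumerate(transcripts):
        mode = "hotspot" if i in low_idx else None
        profiles.append(
            simulate_coverage(t, config, rng=rng, sample_id=sample_id, mode=mode)
        )
    return profiles


@dataclass
class CohortSim:
    """Two-platform expression cohorts plus a replicate ladder."""

    reference: ExpressionMatrix  # ribo-deplete / FFPE-like cohort
    source: ExpressionMatrix  # poly-A / FF-like cohort
    labels: pd.DataFrame  # sample_id, cohort, cancer_type
    replicates: ExpressionMatrix  # replicate-pair samples (reference platform)
    pairs: list[ReplicatePair]
    pair_manifest: pd.DataFrame
    gene_roles: pd.Series
    replicate_sample_tin: pd.Series
    type_markers: dict[str, list[str]]


def default_exclusion_list(gene_roles: pd.Series) -> list[str]:
    """rRNA-like plus mito-like gene ids — the default rescaling exclusion."""
    return list(gene_roles.index[gene_roles.isin(["rrna_like", "mito_like"])])


def _warp(x: np.ndarray, gamma: float, shift: float) -> np.ndarray:
    """Monotone, rank-preserving, non-affine distortion on the log2 scale."""
    return shift + np.power(np.maximum(x, 0.0), gamma) / (6.0 ** (gamma - 1.0))


def _to_tpm(log2_vals: np.ndarray, gene_ids, sample_ids) -> ExpressionMatrix:
    tpm = np.maximum(np.exp2(log2_vals) - 1.0, 0.0)
    df = pd.DataFrame(tpm, index=gene_ids, columns=sample_ids)
    totals = df.sum(axis=0)
    df = df * (1e6 / totals)
    return ExpressionMatrix(values=df, rescaled=True)


def simulate_cohorts(config: SimulationConfig) -> CohortSim:
    """Generate the two-platform cohort design and the replicate ladder.

    The reference cohort emulates ribo-depleted FFPE profiles (histone-like
    genes elevated, mito-like depleted, per-sample residual rRNA); the
    source cohort emulates poly-A fresh-frozen profiles (mito-like retained,
    no rRNA, a global monotone warp as the platform batch effect).  Both
    share the cancer-type structure.  Replicate pairs are drawn on the
    reference platform with per-type noise.
    """
    if config.n_types < 2:
        raise ValueError("need at least 2 cancer types")
    if config.n_samples_per_cohort < 4 * config.n_types:
        raise ValueError("need at least 4 samples per type per cohort")
    rng = np.random.default_rng(config.seed)

    roles = assign_gene_roles(config.n_genes, rng)
    gene_ids = roles.index
    n_genes = config.n_genes
    base_mu = np.clip(rng.normal(3.5, 1.5, n_genes), 0.1, None)

    # cancer-type marker blocks among generic genes
    generic = np.flatnonzero((roles == "generic").to_numpy())
    n_markers = int(round(config.marker_fraction * generic.size))
    marker_idx = rng.choice(generic, size=n_markers, replace=False)
    blocks = np.array_split(marker_idx, config.n_types)
    type_names = [f"type_{t + 1}" for t in range(config.n_types)]
    type_markers = {
        name: [gene_ids[i] for i in blk] for name, blk in zip(type_names, blocks)
    }

    role_arr = roles.to_numpy()
    hist_mask = role_arr == "histone_like"
    mito_mask = role_arr == "mito_like"
    rrna_mask = role_arr == "rrna_like"

    def _signal(n_samples: int, types: np.ndarray) -> np.ndarray:
        x = base_mu[:, None] + rng.normal(0.0, config.sigma_sample, (n_genes, n_samples))
        for t, name in enumerate(type_names):
            cols = np.flatnonzero(types == name)
            rows = blocks[t]
            x[np.ix_(rows, cols)] += config.sigma_type
        return x

    def _apply_reference_platform(x: np.ndarray) -> np.ndarray:
        x = x.copy()
        x[hist_mask] += config.histone_boost
        x[mito_mask] -= config.mito_depletion
        rr = rng.normal(
            config.rrna_capture_mean, config.rrna_capture_sd, x.shape[1]
        )
        x[rrna_mask] += np.clip(rr, 0.0, None)[None, :]
        return np.clip(x, 0.0, None)

    # gene-specific capture-efficiency differences between poly-A and
    # ribo-deplete library prep: a fixed multiplicative per-gene gain on the
    # log2 scale (strictly monotone, never censors a gene)
    gene_platform_gain = np.exp(
        rng.normal(0.0, config.platform_gene_effect_sd, n_genes)
    )

    def _apply_source_platform(x: np.ndarray) -> np.ndarray:
        x = np.clip(x, 0.0, None)
        warped = _warp(x, config.platform_warp_gamma, config.platform_warp_shift)
        return warped * gene_platform_gain[:, None]

    n_per = config.n_samples_per_cohort
    types_ref = np.array([type_names[i % config.n_types] for i in range(n_per)])
    types_src = np.array([type_names[i % config.n_types] for i in range(n_per)])

    ref_log = _apply_reference_platform(_signal(n_per, types_ref))
    src_log = _apply_source_platform(_signal(n_per, types_src))

    ref_ids = [f"FFPE_{i:04d}" for i in range(n_per)]
    src_ids = [f"POLYA_{i:04d}" for i in range(n_per)]
    reference = _to_tpm(ref_log, gene_ids, ref_ids)
    source = _to_tpm(src_log, gene_ids, src_ids)

    labels = pd.DataFrame(
        {
            "sample_id": ref_ids + src_ids,
            "cohort": ["ffpe_ribo"] * n_per + ["ff_polya"] * n_per,
            "cancer_type": np.concatenate([types_ref, types_src]),
        }
    )

    # replicate ladder on the reference platform
    pairs: list[ReplicatePair] = []
    rep_cols: list[np.ndarray] = []
    rep_ids: list[str] = []
    tins: dict[str, float] = {}
    manifest_rows = []
    for pair_type, sigma in config.pair_noise.items():
        for k in range(config.n_pairs_per_type):
            t = type_names[k % config.n_types]
            base = base_mu + rng.normal(0.0, config.sigma_sample, n_genes)
            blk = blocks[type_names.index(t)]
            base[blk] += config.sigma_type
            low_tin = rng.random() < config.low_tin_pair_fraction
            s = sigma * (config.low_tin_noise_multiplier if low_tin else 1.0)
            a = base + rng.normal(0.0, s, n_genes)
            b = base + rng.normal(0.0, s, n_genes)
            # shared residual rRNA and platform effects within the pair
            shared = np.zeros(n_genes)
            shared[hist_mask] += config.histone_boost
            shared[mito_mask] -= config.mito_depletion
            shared[rrna_mask] += max(
                0.0, rng.normal(config.rrna_capture_mean, config.rrna_capture_sd)
            )
            a = np.clip(a + shared, 0.0, None)
            b = np.clip(b + shared, 0.0, None)
            ida = f"REP_{pair_type}_{k:02d}_a"
            idb = f"REP_{pair_type}_{k:02d}_b"
            if low_tin:
                tin_a, tin_b = rng.normal(38, 6), rng.normal(38, 6)
            else:
                tin_a, tin_b = rng.normal(72, 6), rng.normal(72, 6)
            tins[ida] = float(np.clip(tin_a, 1, 99))
            tins[idb] = float(np.clip(tin_b, 1, 99))
            high = tins[ida] > 50 and tins[idb] > 50
            pairs.append(ReplicatePair(ida, idb, pair_type, high_tin_pair=high))
            manifest_rows.append(
                {"sample_a": ida, "sample_b": idb, "pair_type": pair_type,
                 "high_tin_pair": high}
            )
            rep_cols.extend([a, b])
            rep_ids.extend([ida, idb])

    replicates = _to_tpm(np.column_stack(rep_cols), gene_ids, rep_ids)
    return CohortSim(
        reference=reference,
        source=source,
        labels=labels,
        replicates=replicates,
        pairs=pairs,
        pair_manifest=pd.DataFrame(manifest_rows),
        gene_roles=roles,
        replicate_sample_tin=pd.Series(tins, name="sample_tin"),
        type_markers=type_markers,
    )
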