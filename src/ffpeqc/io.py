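"""Readers and writers for the plain-text formats the pipeline exchanges.

Formats: expression TSV (genes x samples), long-format coverage TSV,
bedGraph, BED6 feature/fragment files, BED12 transcript models, gene lists,
replicate-pair manifests, and JSON reports.  TSVs are tab-separated with a
mandatory header row and ``.`` for missing values.  Genomic records are
half-open 0-based; coverage vectors are stored in transcript orientation
(5'->3'), so projecting genome-coordinate coverage onto a minus-strand
transcript reverses it.  Malformed rows raise errors carrying ``file:line``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .composition import CATEGORIES, AlignedSegment, FeatureAnnotation
from .models import CoverageProfile, ExpressionMatrix, ReplicatePair, TranscriptModel

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_coverage_tsv",
    "write_coverage_tsv",
    "read_bedgraph",
    "read_bed6_features",
    "write_bed6_features",
    "read_bed6_fragments",
    "write_bed6_fragments",
    "read_bed12",
    "project_transcript_coverage",
    "coverage_to_bedgraph_frame",
    "read_gene_list",
    "write_gene_list",
    "read_pair_manifest",
    "write_pair_manifest",
    "write_json_report",
]

MISSING = "."


def _fail(path, lineno: int, msg: str) -> None:
    raise ValueError(f"{path}:{lineno}: {msg}")


# ---------------------------------------------------------------- expression


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    df = matrix.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", na_rep=MISSING)


def read_expression_tsv(path, rescaled: bool = False) -> ExpressionMatrix:
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=[MISSING], float_precision="round_trip"
    )
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate gene ids")
    return ExpressionMatrix(values=df, rescaled=rescaled)


# ------------------------------------------------------------------ coverage


def write_coverage_tsv(profiles: Iterable[CoverageProfile], path) -> None:
    """Long format: transcript_id, sample_id, pos_0based, depth."""
    with open(path, "w") as fh:
        fh.write("transcript_id\tsample_id\tpos_0based\tdepth\n")
        for p in profiles:
            for pos, d in enumerate(p.depth):
                fh.write(f"{p.transcript_id}\t{p.sample_id}\t{pos}\t{int(d)}\n")


def read_coverage_tsv(path) -> list[CoverageProfile]:
    rows: dict[tuple[str, str], list[tuple[int, int]]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["transcript_id", "sample_id", "pos_0based", "depth"]
        if header != expected:
            _fail(path, 1, f"expected header {expected}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                _fail(path, lineno, f"expected 4 columns, got {len(parts)}")
            tx, sample, pos_s, depth_s = parts
            try:
                pos, depth = int(pos_s), int(depth_s)
            except ValueError:
                _fail(path, lineno, "pos_0based and depth must be integers")
            if depth < 0:
                _fail(path, lineno, f"negative depth {depth}")
            rows.setdefault((tx, sample), []).append((pos, depth))
    profiles = []
    for (tx, sample), entries in rows.items():
        entries.sort()
        positions = [p for p, _ in entries]
        if positions != list(range(len(positions))):
            raise ValueError(
                f"{path}: coverage for {tx}/{sample} is not contiguous from 0"
            )
        depth = np.array([d for _, d in entries], dtype=np.int64)
        profiles.append(CoverageProfile(transcript_id=tx, sample_id=sample, depth=depth))
    return profiles


def read_bedgraph(path) -> dict[str, list[tuple[int, int, float]]]:
    """Per-chromosome (start, end, value) intervals; half-open 0-based."""
    out: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                _fail(path, lineno, f"expected 4 columns, got {len(parts)}")
            chrom, s, e, v = parts[:4]
            try:
                start, end, val = int(s), int(e), float(v)
            except ValueError:
                _fail(path, lineno, "malformed bedGraph fields")
            if start >= end:
                _fail(path, lineno, f"start >= end ({start} >= {end})")
            out.setdefault(chrom, []).append((start, end, val))
    return out


# -------------------------------------------------------------- BED features


def write_bed6_features(annotation: FeatureAnnotation, path) -> None:
    """Combined BED6 with the category in the name column."""
    with open(path, "w") as fh:
        for row in annotation.intervals.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.category}\t0\t{row.strand}\n"
            )


def read_bed6_features(path) -> FeatureAnnotation:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                _fail(path, lineno, f"expected 6 columns, got {len(parts)}")
            chrom, s, e, name, _score, strand = parts[:6]
            try:
                start, end = int(s), int(e)
            except ValueError:
                _fail(path, lineno, "start/end must be integers")
            if start >= end:
                _fail(path, lineno, f"start >= end ({start} >= {end})")
            if name not in CATEGORIES:
                _fail(path, lineno, f"unknown category {name!r}")
            if strand not in ("+", "-", "."):
                _fail(path, lineno, f"invalid strand {strand!r}")
            rows.append(
                {"chrom": chrom, "start": start, "end": end,
                 "category": name, "strand": strand}
            )
    return FeatureAnnotation(pd.DataFrame(rows))


def write_bed6_fragments(segments: Iterable[AlignedSegment], path) -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(segments):
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\tfrag{i}\t0\t{s.strand}\n")


def read_bed6_fragments(path) -> list[AlignedSegment]:
    segs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                _fail(path, lineno, f"expected 6 columns, got {len(parts)}")
            chrom, s, e, _name, _score, strand = parts[:6]
            try:
                start, end = int(s), int(e)
            except ValueError:
                _fail(path, lineno, "start/end must be integers")
            if start >= end:
                _fail(path, lineno, f"start >= end ({start} >= {end})")
            if strand not in ("+", "-"):
                _fail(path, lineno, f"fragment strand must be + or -, got {strand!r}")
            segs.append(AlignedSegment(chrom, start, end, strand))
    return segs


# ---------------------------------------------------------------- BED12/GTF


def read_bed12(path) -> tuple[list[TranscriptModel], dict[str, list[tuple[int, int]]], dict[str, str]]:
    """Read transcript models from BED12.

    The name field may be ``transcript_id`` or ``transcript_id|gene_id`` or
    ``transcript_id|gene_id|canonical``.  Returns the models, per-transcript
    genomic exon blocks (half-open, ascending), and per-transcript chrom.
    """
    models: list[TranscriptModel] = []
    blocks: dict[str, list[tuple[int, int]]] = {}
    chroms: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                _fail(path, lineno, f"expected 12 columns, got {len(parts)}")
            chrom, s, e, name, _score, strand = parts[:6]
            try:
                start, end = int(s), int(e)
                n_blocks = int(parts[9])
                sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
                starts = [int(x) for x in parts[11].rstrip(",").split(",")]
            except ValueError:
                _fail(path, lineno, "malformed BED12 numeric fields")
            if start >= end:
                _fail(path, lineno, f"start >= end ({start} >= {end})")
            if strand not in ("+", "-"):
                _fail(path, lineno, f"invalid strand {strand!r}")
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                _fail(path, lineno, "block count mismatch")
            fields = name.split("|")
            tx_id = fields[0]
            gene_id = fields[1] if len(fields) > 1 else tx_id
            canonical = len(fields) > 2 and fields[2] in ("1", "canonical", "true")
            exons = [(start + st, start + st + sz) for st, sz in zip(starts, sizes)]
            for (bs, be) in exons:
                if bs >= be or be > end:
                    _fail(path, lineno, "block outside transcript bounds")
            length = sum(sz for sz in sizes)
            models.append(TranscriptModel(tx_id, gene_id, strand, length, canonical))
            blocks[tx_id] = exons
            chroms[tx_id] = chrom
    return models, blocks, chroms


def project_transcript_coverage(
    bedgraph: Mapping[str, Sequence[tuple[int, int, float]]],
    chrom: str,
    exon_blocks: Sequence[tuple[int, int]],
    strand: str,
    transcript_id: str,
    sample_id: str,
) -> CoverageProfile:
    """Project genome-coordinate coverage onto a transcript (5'->3').

    Exon blocks are concatenated in genomic order and the resulting vector
    is reversed for minus-strand transcripts, so index 0 is always the
    5'-most transcribed base.
    """
    length = sum(e - s for s, e in exon_blocks)
    depth = np.zeros(length, dtype=float)
    intervals = bedgraph.get(chrom, [])
    offset = 0
    for bs, be in exon_blocks:
        for s, e, v in intervals:
            lo, hi = max(s, bs), min(e, be)
            if lo < hi:
                depth[offset + (lo - bs) : offset + (hi - bs)] += v
        offset += be - bs
    if strand == "-":
        depth = depth[::-1].copy()
    return CoverageProfile(transcript_id=transcript_id, sample_id=sample_id, depth=depth)


def coverage_to_bedgraph_frame(
    profile: CoverageProfile,
    chrom: str,
    exon_blocks: Sequence[tuple[int, int]],
    strand: str,
) -> list[tuple[str, int, int, float]]:
    """Inverse of :func:`project_transcript_coverage` for round-trip checks:
    lay a transcript-oriented profile back onto genome coordinates
    (per-base rows)."""
    depth = np.asarray(profile.depth, dtype=float)
    if strand == "-":
        depth = depth[::-1]
    rows = []
    offset = 0
    for bs, be in exon_blocks:
        for i in range(be - bs):
            rows.append((chrom, bs + i, bs + i + 1, float(depth[offset + i])))
        offset += be - bs
    return rows


# ------------------------------------------------------------------- various


def read_gene_list(path) -> list[str]:
    genes = []
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if g and not g.startswith("#"):
                genes.append(g)
    return genes


def write_gene_list(genes: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_pair_manifest(path) -> list[ReplicatePair]:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_a", "sample_b", "pair_type"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    pairs = []
    for row in df.itertuples(index=False):
        high = bool(getattr(row, "high_tin_pair", True))
        pairs.append(ReplicatePair(row.sample_a, row.sample_b, row.pair_type, high))
    return pairs


def write_pair_manifest(pairs: Sequence[ReplicatePair], path) -> None:
    pd.DataFrame([vars(p) for p in pairs]).to_csv(path, sep="\t", index=False)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Mapping):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json_report(report: Mapping, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True) + "\n")
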