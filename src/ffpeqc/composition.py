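"""Genomic feature composition of aligned RNA fragments.

Classifies each aligned base into one genomic feature category (exon, ncRNA,
intron, repeat, enhancer, intergenic) and computes per-category base counts,
coverage, and strand concordance.  In degraded-RNA libraries most sequenced
bases fall in exons and genomic repeats, and the fraction of bases whose
fragment strand matches the annotated feature strand ("sense fraction") is a
useful library-strandedness diagnostic: exonic bases are predominantly
sense, repeat-derived bases carry a higher antisense share.

Overlapping annotations are resolved by a configurable priority order
(default ``exon > ncRNA > intron > repeat > enhancer > intergenic``); bases
not covered by any annotation are intergenic.  All coordinates are half-open
0-based.  Mitochondrial contigs are excluded via a configurable blocklist.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CATEGORIES = ("exon", "ncRNA", "intron", "repeat", "enhancer", "intergenic")
DEFAULT_PRIORITY = ("exon", "ncRNA", "intron", "repeat", "enhancer", "intergenic")
DEFAULT_MITO_CONTIGS = frozenset({"chrM", "MT"})

__all__ = [
    "CATEGORIES",
    "DEFAULT_PRIORITY",
    "DEFAULT_MITO_CONTIGS",
    "FeatureAnnotation",
    "AlignedSegment",
    "CompositionReport",
    "SenseFraction",
    "CategoryDepth",
    "classify_bases",
    "classify_reads",
    "strand_concordance",
    "category_mean_depth",
    "compose_report",
]


@dataclass(frozen=True)
class AlignedSegment:
    """An aligned fragment interval: half-open 0-based, with the strand of
    the originating RNA fragment."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"malformed segment {self.chrom}:{self.start}-{self.end} (start >= end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"segment strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class FeatureAnnotation:
    """A set of categorised genomic intervals.

    ``intervals`` is a DataFrame with columns (chrom, start, end, category,
    strand); strand may be "." for unstranded features such as enhancers.
    """

    intervals: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.intervals)
        required = ["chrom", "start", "end", "category", "strand"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"annotation missing columns {missing}")
        if (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise ValueError(
                f"malformed interval {bad['chrom']}:{bad['start']}-{bad['end']} "
                "(start >= end)"
            )
        unknown = set(df["category"]) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories {sorted(unknown)}")
        bad_strand = set(df["strand"]) - {"+", "-", "."}
        if bad_strand:
            raise ValueError(f"invalid strands {sorted(bad_strand)}")
        self.intervals = df.reset_index(drop=True)

    def on_chrom(self, chrom: str) -> pd.DataFrame:
        return self.intervals[self.intervals["chrom"] == chrom]

    @property
    def chroms(self) -> set[str]:
        return set(self.intervals["chrom"].unique())


@dataclass
class SenseFraction:
    """Sense fraction of a stranded category; NaN when no base is eligible."""

    category: str
    fraction: float
    n_sense: int
    n_eligible: int

    @property
    def defined(self) -> bool:
        return self.n_eligible > 0


@dataclass
class CategoryDepth:
    """Mean depth of a category; NaN-flagged when the category has no span."""

    category: str
    mean_depth: float
    assigned_bases: int
    span: int

    @property
    def defined(self) -> bool:
        return self.span > 0


@dataclass
class CompositionReport:
    """Per-category composition of an aligned fragment set."""

    base_counts: dict[str, int]
    base_fractions: dict[str, float]
    read_counts: dict[str, int]
    mean_depth: dict[str, CategoryDepth]
    sense_fraction: dict[str, SenseFraction]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cat in CATEGORIES:
            md = self.mean_depth.get(cat)
            sf = self.sense_fraction.get(cat)
            rows.append(
                {
                    "category": cat,
                    "bases": self.base_counts.get(cat, 0),
                    "base_fraction": self.base_fractions.get(cat, 0.0),
                    "reads": self.read_counts.get(cat, 0),
                    "mean_depth": md.mean_depth if md is not None else float("nan"),
                    "sense_fraction": sf.fraction if sf is not None else float("nan"),
                }
            )
        return pd.DataFrame(rows)


def _validate_priority(priority: Sequence[str]) -> list[str]:
    pr = list(priority)
    if "intergenic" not in pr:
        pr.append("intergenic")
    unknown = set(pr) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories in priority: {sorted(unknown)}")
    if len(set(pr)) != len(pr):
        raise ValueError("priority contains duplicates")
    return pr


def _chrom_sweep(
    segments: Sequence[AlignedSegment],
    anno: pd.DataFrame,
    priority: Sequence[str],
):
    """Boundary sweep over one chromosome.

    Yields atomic intervals ``(length, category, strand_set, feature_strand,
    mult_plus, mult_minus)`` where ``category`` is the priority-resolved
    category, ``strand_set`` the set of annotated strands (excluding '.')
    over the interval, ``feature_strand`` the strand of the winning
    category's interval ('.'' mapped to '+'), and the multiplicities count
    covering segments by fragment strand.
    """
    rank = {c: i for i, c in enumerate(priority)}
    bounds = set()
    for s in segments:
        bounds.add(s.start)
        bounds.add(s.end)
    for st, en in zip(anno["start"], anno["end"]):
        bounds.add(int(st))
        bounds.add(int(en))
    edges = np.array(sorted(bounds), dtype=np.int64)
    if edges.size < 2:
        return
    n_atoms = edges.size - 1
    idx = {int(e): i for i, e in enumerate(edges)}

    # segment multiplicity per fragment strand, via difference arrays
    mult = {"+": np.zeros(n_atoms + 1, dtype=np.int64),
            "-": np.zeros(n_atoms + 1, dtype=np.int64)}
    for s in segments:
        mult[s.strand][idx[s.start]] += 1
        mult[s.strand][idx[s.end]] -= 1
    mult_plus = np.cumsum(mult["+"][:-1])
    mult_minus = np.cumsum(mult["-"][:-1])

    # per-(category, strand) coverage indicators
    cov: dict[tuple[str, str], np.ndarray] = {}
    for st, en, cat, strand in zip(
        anno["start"], anno["end"], anno["category"], anno["strand"]
    ):
        key = (cat, strand)
        if key not in cov:
            cov[key] = np.zeros(n_atoms + 1, dtype=np.int64)
        # clip annotation to the swept window (atoms only exist where
        # segments or annotations have boundaries; both were included)
        cov[key][idx[int(st)]] += 1
        cov[key][idx[int(en)]] -= 1
    cov_cum = {k: np.cumsum(v[:-1]) for k, v in cov.items()}

    lengths = np.diff(edges)
    for i in range(n_atoms):
        mp, mm = int(mult_plus[i]), int(mult_minus[i])
        covering = [(c, s) for (c, s), arr in cov_cum.items() if arr[i] > 0]
        if covering:
            best = min(covering, key=lambda cs: rank.get(cs[0], len(rank)))
            category = best[0]
            # feature strand of the winning category over this atom; if the
            # winning category has intervals on both strands here, both are
            # recorded in strand_set and the base is ineligible anyway
            win_strands = [s for c, s in covering if c == category]
            feature_strand = "+" if win_strands[0] == "." else win_strands[0]
            strand_set = frozenset(s for _, s in covering if s != ".")
        else:
            category = "intergenic"
            feature_strand = "+"
            strand_set = frozenset()
        yield int(lengths[i]), category, strand_set, feature_strand, mp, mm


def _prepare(
    segments: Sequence[AlignedSegment],
    annotation: FeatureAnnotation,
    blocklist: Iterable[str],
) -> list[AlignedSegment]:
    block = set(blocklist)
    return [s for s in segments if s.chrom not in block]


def classify_bases(
    segments: Sequence[AlignedSegment],
    annotation: FeatureAnnotation,
    priority: Sequence[str] = DEFAULT_PRIORITY,
    blocklist: Iterable[str] = DEFAULT_MITO_CONTIGS,
) -> dict[str, int]:
    """Assign every aligned base to exactly one feature category.

    Overlaps are resolved by ``priority`` (first match wins); bases outside
    all annotations count as intergenic.  Returns per-category base counts;
    their sum equals the total number of aligned bases on non-blocklisted
    contigs (each base of each segment counts once, so overlapping segments
    contribute multiply).
    """
    pr = _validate_priority(priority)
    segs = _prepare(segments, annotation, blocklist)
    counts = {c: 0 for c in CATEGORIES}
    for chrom in sorted({s.chrom for s in segs}):
        chrom_segs = [s for s in segs if s.chrom == chrom]
        anno = annotation.on_chrom(chrom)
        for length, cat, _strands, _fs, mp, mm in _chrom_sweep(chrom_segs, anno, pr):
            counts[cat] += length * (mp + mm)
    return {c: n for c, n in counts.items() if n > 0}


def classify_reads(
    segments: Sequence[AlignedSegment],
    annotation: FeatureAnnotation,
    priority: Sequence[str] = DEFAULT_PRIORITY,
    blocklist: Iterable[str] = DEFAULT_MITO_CONTIGS,
) -> dict[str, int]:
    """Assign each read (segment) to the category holding most of its bases.

    Ties break by the priority order.  Complements :func:`classify_bases`
    for consumers that count reads rather than bases.
    """
    pr = _validate_priority(priority)
    rank = {c: i for i, c in enumerate(pr)}
    counts: dict[str, int] = {}
    for seg in _prepare(segments, annotation, blocklist):
        per_cat = classify_bases([seg], annotation, priority=pr, blocklist=())
        best = min(per_cat.items(), key=lambda kv: (-kv[1], rank[kv[0]]))[0]
        counts[best] = counts.get(best, 0) + 1
    return counts


def strand_concordance(
    segments: Sequence[AlignedSegment],
    annotation: FeatureAnnotation,
    category: str,
    priority: Sequence[str] = DEFAULT_PRIORITY,
    blocklist: Iterable[str] = DEFAULT_MITO_CONTIGS,
) -> SenseFraction:
    """Fraction of a category's bases whose fragment strand matches the
    annotated feature strand.

    A base is eligible only when no other genomic feature is annotated on
    the opposite strand over it (bases under opposite-strand annotations are
    excluded from the denominator, since their fragments cannot be
    attributed).  Unstranded features (enhancers) are scored against the
    forward strand, which is reported as "sense" by convention.  With zero
    eligible bases the fraction is NaN-flagged, never 0.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    pr = _validate_priority(priority)
    segs = _prepare(segments, annotation, blocklist)
    n_sense = 0
    n_eligible = 0
    for chrom in sorted({s.chrom for s in segs}):
        chrom_segs = [s for s in segs if s.chrom == chrom]
        anno = annotation.on_chrom(chrom)
        for length, cat, strands, feat_strand, mp, mm in _chrom_sweep(
            chrom_segs, anno, pr
        ):
            if cat != category:
                continue
            if strands - {feat_strand}:
                continue  # another feature annotated on the opposite strand
            sense_mult = mp if feat_strand == "+" else mm
            n_sense += length * sense_mult
            n_eligible += length * (mp + mm)
    frac = n_sense / n_eligible if n_eligible else float("nan")
    return SenseFraction(
        category=category, fraction=frac, n_sense=n_sense, n_eligible=n_eligible
    )


def _category_spans(
    annotation: FeatureAnnotation, blocklist: Iterable[str]
) -> dict[str, int]:
    """Union span (bp) of each category's intervals, per category."""
    block = set(blocklist)
    spans: dict[str, int] = {c: 0 for c in CATEGORIES}
    df = annotation.intervals
    df = df[~df["chrom"].isin(block)]
    for (chrom, cat), grp in df.groupby(["chrom", "category"]):
        ivs = sorted(zip(grp["start"], grp["end"]))
        total = 0
        cur_s, cur_e = None, None
        for s, e in ivs:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            total += cur_e - cur_s
        spans[cat] += total
    return spans


def category_mean_depth(
    segments: Sequence[AlignedSegment],
    annotation: FeatureAnnotation,
    priority: Sequence[str] = DEFAULT_PRIORITY,
    blocklist: Iterable[str] = DEFAULT_MITO_CONTIGS,
) -> dict[str, CategoryDepth]:
    """Mean depth per category: assigned bases / annotated category span.

    Categories with no annotated span (e.g. intergenic, or a category absent
    from the annotation) are flagged undefined (NaN mean depth).
    """
    counts = classify_bases(segments, annotation, priority=priority, blocklist=blocklist)
    spans = _category_spans(annotation, blocklist)
    out: dict[str, CategoryDepth] = {}
    for cat in CATEGORIES:
        span = spans.get(cat, 0)
        assigned = counts.get(cat, 0)
        mean = assigned / span if span > 0 else float("nan")
        out[cat] = CategoryDepth(
            category=cat, mean_depth=mean, assigned_bases=assigned, span=span
        )
    return out


def compose_report(
    segments: Sequence[AlignedSegment],
    annotation: FeatureAnnotation,
    priority: Sequence[str] = DEFAULT_PRIORITY,
    blocklist: Iterable[str] = DEFAULT_MITO_CONTIGS,
) -> CompositionReport:
    """Full composition report: base/read counts, fractions, depth, strandness."""
    base_counts = classify_bases(segments, annotation, priority, blocklist)
    total = sum(base_counts.values())
    fractions = {c: n / total for c, n in base_counts.items()} if total else {}
    read_counts = classify_reads(segments, annotation, priority, blocklist)
    depth = category_mean_depth(segments, annotation, priority, blocklist)
    stranded = [c for c in CATEGORIES if c != "intergenic"]
    sense = {
        c: strand_concordance(segments, annotation, c, priority, blocklist)
        for c in stranded
    }
    return CompositionReport(
        base_counts=base_counts,
        base_fractions=fractions,
        read_counts=read_counts,
        mean_depth=depth,
        sense_fraction=sense,
    )
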