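import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ffpeqc import ExpressionMatrix, SimulationConfig, simulate_cohorts
from ffpeqc.composition import AlignedSegment, FeatureAnnotation

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def cohort_sim():
    """Default-condition two-platform cohort with replicate ladder."""
    return simulate_cohorts(SimulationConfig(seed=7, n_genes=600))


@pytest.fixture()
def toy_annotation():
    """A small two-chromosome annotation with overlapping features."""
    rows = [
        # chr1: gene with 2 exons and an intron, plus a repeat overlapping exon 2
        {"chrom": "chr1", "start": 100, "end": 200, "category": "exon", "strand": "+"},
        {"chrom": "chr1", "start": 200, "end": 300, "category": "intron", "strand": "+"},
        {"chrom": "chr1", "start": 300, "end": 400, "category": "exon", "strand": "+"},
        {"chrom": "chr1", "start": 350, "end": 450, "category": "repeat", "strand": "-"},
        # chr1: unstranded enhancer in the intergenic space
        {"chrom": "chr1", "start": 600, "end": 700, "category": "enhancer", "strand": "."},
        # chr2: minus-strand ncRNA
        {"chrom": "chr2", "start": 0, "end": 150, "category": "ncRNA", "strand": "-"},
    ]
    return FeatureAnnotation(pd.DataFrame(rows))


def brute_force_classify(segments, annotation, priority):
    """Per-base oracle: scan every base of every segment against every
    annotation interval and resolve by priority order."""
    pr = list(priority)
    if "intergenic" not in pr:
        pr.append("intergenic")
    rank = {c: i for i, c in enumerate(pr)}
    counts = {}
    df = annotation.intervals
    for seg in segments:
        rows = df[df["chrom"] == seg.chrom]
        for pos in range(seg.start, seg.end):
            hits = rows[(rows["start"] <= pos) & (pos < rows["end"])]
            if len(hits):
                cat = min(hits["category"], key=lambda c: rank[c])
            else:
                cat = "intergenic"
            counts[cat] = counts.get(cat, 0) + 1
    return counts


def random_fixture(rng, n_segments=40, n_features=30, span=10_000):
    """A random annotation + fragment set within a 10 kb window."""
    cats = ["exon", "ncRNA", "intron", "repeat", "enhancer"]
    rows = []
    for _ in range(n_features):
        start = int(rng.integers(0, span - 50))
        end = start + int(rng.integers(20, 500))
        cat = cats[int(rng.integers(len(cats)))]
        strand = "." if cat == "enhancer" else ("+" if rng.random() < 0.5 else "-")
        rows.append(
            {"chrom": "chr1", "start": start, "end": min(end, span),
             "category": cat, "strand": strand}
        )
    anno = FeatureAnnotation(pd.DataFrame(rows))
    segs = []
    for _ in range(n_segments):
        start = int(rng.integers(0, span - 20))
        end = start + int(rng.integers(10, 300))
        segs.append(
            AlignedSegment("chr1", start, min(end, span),
                           "+" if rng.random() < 0.5 else "-")
        )
    return segs, anno


def expr_matrix(values, genes=None, samples=None, rescaled=True):
    """Build a small ExpressionMatrix from a 2-D array (genes x samples)."""
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(
        values=pd.DataFrame(arr, index=genes, columns=samples), rescaled=rescaled
    )
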