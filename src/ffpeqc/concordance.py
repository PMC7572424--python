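"""Agreement between replicate expression profiles.

Replicate pairs arise at successive protocol stages (library prep,
extraction, microdissection, fixation method), each adding its own
technical variability.  The module quantifies agreement on the
``log2(rescaled TPM + 1)`` scale:

* genes are first filtered to those with at least moderate expression,
  mean rescaled TPM strictly greater than 1 across the samples considered;
* **correlation**: Pearson r of the two log-expression profiles;
* **divergence**: per-gene absolute log-expression difference; because
  variance cannot be estimated from two replicates, its 99th percentile
  summarises the most extreme disagreements of a pair;
* **Bland–Altman** tables (per-gene mean vs. difference) for plotting.

Pairs are stratified by the sample TIN gate (a pair is high-TIN iff both
samples pass) and can be restricted to a gene list, e.g. a cancer-gene
panel, via ``gene_sets``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import ExpressionMatrix, PairConcordance, ReplicatePair

__all__ = [
    "filter_expressed",
    "log_expression",
    "pair_correlation",
    "pair_divergence",
    "bland_altman",
    "concordance_by_type",
    "PairDivergence",
]

LOG_OFFSET = 1.0  # TPM offset before log2


def filter_expressed(
    matrix: ExpressionMatrix,
    sample_subset: Sequence[str] | None = None,
    cutoff: float = 1.0,
) -> pd.Index:
    """Genes with mean rescaled TPM strictly greater than ``cutoff``.

    The strict inequality means a gene averaging exactly 1 TPM is excluded.
    Requires a rescaled matrix so the cutoff is comparable across samples.
    """
    if not matrix.rescaled:
        raise ValueError("filter_expressed requires a rescaled expression matrix")
    if sample_subset is not None:
        if len(sample_subset) == 0:
            raise ValueError("empty sample subset")
        missing = [s for s in sample_subset if s not in matrix.values.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        sub = matrix.values[list(sample_subset)]
    else:
        sub = matrix.values
    means = sub.mean(axis=1)
    return matrix.values.index[means > cutoff]


def log_expression(
    matrix: ExpressionMatrix,
    genes: Iterable[str] | None = None,
    samples: Iterable[str] | None = None,
    offset: float = LOG_OFFSET,
) -> pd.DataFrame:
    """log2(TPM + offset) view of (a slice of) an expression matrix."""
    df = matrix.values
    if genes is not None:
        df = df.loc[list(genes)]
    if samples is not None:
        df = df[list(samples)]
    return np.log2(df + offset)


def _pair_profiles(
    matrix: ExpressionMatrix, pair: ReplicatePair, gene_subset: Iterable[str]
) -> tuple[np.ndarray, np.ndarray]:
    genes = list(gene_subset)
    if len(genes) == 0:
        raise ValueError("empty gene set")
    for s in (pair.sample_a, pair.sample_b):
        if s not in matrix.values.columns:
            raise KeyError(f"sample {s!r} not in matrix")
    logx = log_expression(matrix, genes=genes, samples=[pair.sample_a, pair.sample_b])
    return logx[pair.sample_a].to_numpy(), logx[pair.sample_b].to_numpy()


def pair_correlation(
    matrix: ExpressionMatrix, pair: ReplicatePair, gene_subset: Iterable[str]
) -> tuple[float, int]:
    """Pearson correlation of a replicate pair on log2(TPM+1).

    Returns ``(r, n_genes)``; r is NaN (flagged undefined, never imputed)
    when either profile has zero variance.
    """
    x, y = _pair_profiles(matrix, pair, gene_subset)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), x.size
    r = stats.pearsonr(x, y).statistic
    return float(r), x.size


@dataclass
class PairDivergence:
    """Per-gene divergences of a pair and their percentile summary."""

    divergences: pd.Series
    p99: float
    percentile: float


def pair_divergence(
    matrix: ExpressionMatrix,
    pair: ReplicatePair,
    gene_subset: Iterable[str],
    percentile: float = 99.0,
) -> PairDivergence:
    """Per-gene absolute log-expression difference and its high percentile.

    Divergence of gene g is ``|x_g - y_g|`` on the log2(TPM+1) scale; the
    summary percentile (default 99) is computed by linear interpolation
    between order statistics.
    """
    genes = list(gene_subset)
    x, y = _pair_profiles(matrix, pair, genes)
    div = np.abs(x - y)
    p = float(np.percentile(div, percentile, method="linear"))
    return PairDivergence(
        divergences=pd.Series(div, index=pd.Index(genes, name="gene_id")),
        p99=p,
        percentile=percentile,
    )


def bland_altman(
    matrix: ExpressionMatrix, pair: ReplicatePair, gene_subset: Iterable[str]
) -> pd.DataFrame:
    """Per-gene (mean, difference) table on log2(TPM+1), for Bland–Altman plots."""
    genes = list(gene_subset)
    x, y = _pair_profiles(matrix, pair, genes)
    return pd.DataFrame(
        {"mean": (x + y) / 2.0, "diff": x - y},
        index=pd.Index(genes, name="gene_id"),
    )


def concordance_by_type(
    pairs: Sequence[ReplicatePair],
    matrix: ExpressionMatrix,
    gene_sets: Mapping[str, Iterable[str]] | None = None,
    cutoff: float = 1.0,
    percentile: float = 99.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Concordance of every pair, summarised per replicate type and TIN stratum.

    For each pair and gene set the expression filter is applied to the
    pair's two samples, then Pearson r and the divergence percentile are
    computed on the retained genes.

    Returns
    -------
    per_pair : DataFrame
        One row per (pair, gene set): sample ids, pair_type, TIN stratum,
        pearson_r, n_genes, divergence_p99.  This is the r-vs-divergence
        table behind the correlation/divergence scatter.
    summary : DataFrame
        Median r and median divergence percentile per
        (pair_type, TIN stratum, gene set).
    """
    if len(pairs) == 0:
        raise ValueError("no replicate pairs supplied")
    if gene_sets is None:
        gene_sets = {"whole_transcriptome": None}

    rows = []
    for pair in pairs:
        expressed = filter_expressed(
            matrix, sample_subset=[pair.sample_a, pair.sample_b], cutoff=cutoff
        )
        for label, gene_list in gene_sets.items():
            if gene_list is None:
                genes = expressed
            else:
                genes = expressed.intersection(pd.Index(gene_list))
            r, n = pair_correlation(matrix, pair, genes)
            div = pair_divergence(matrix, pair, genes, percentile=percentile)
            rows.append(
                PairConcordance(
                    sample_a=pair.sample_a,
                    sample_b=pair.sample_b,
                    pair_type=pair.pair_type,
                    high_tin_pair=pair.high_tin_pair,
                    pearson_r=r,
                    n_genes=n,
                    divergence_p99=div.p99,
                    gene_set_label=label,
                )
            )
    per_pair = pd.DataFrame([vars(pc) for pc in rows])
    summary = (
        per_pair.groupby(["pair_type", "high_tin_pair", "gene_set_label"])
        .agg(
            median_r=("pearson_r", "median"),
            median_divergence_p99=("divergence_p99", "median"),
            n_pairs=("pearson_r", "size"),
        )
        .reset_index()
    )
    return per_pair, summary
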