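"""Cross-platform cohort mapping of expression matrices.

Expression cohorts generated on different platforms (e.g. poly-A-selected
fresh-frozen RNA vs. ribo-depleted FFPE RNA) differ by strong, largely
monotone technical effects.  This module projects a *source* cohort into the
expression space of a *reference* cohort:

* :class:`QuantileCohortMapper` — per-gene empirical quantile mapping on the
  log2(TPM+1) scale: each source value is carried through the source
  cohort's empirical CDF and read off the reference cohort's quantile
  function.  The map is monotone per gene (rank-preserving within the
  source cohort), clamps values outside the training range to the endpoint
  quantiles, and exactly equalises per-gene marginals when the two training
  cohorts have equal sample counts with distinct values.
* :class:`LocationScaleMapper` — a per-gene mean/SD standardisation
  baseline; corrects affine platform effects only, serving as the
  comparison point for the quantile map.

Both are scikit-learn style transformers (``fit``/``transform`` with
trailing-underscore fitted attributes); matrices are samples x genes at the
estimator level.  :func:`fit_map`/:func:`apply_map` wrap them for the
package's gene-by-sample :class:`~ffpeqc.models.ExpressionMatrix` TPM
containers, handling the log transform.

:func:`evaluate_mixing` quantifies residual platform structure after
mapping: PCA on the top-variance genes, silhouette of the cohort labels in
PC space, the cohort-label variance share in PCs 1-2, and agreement between
unsupervised clusters and biological (cancer-type) labels — platform
correction should drive the silhouette toward 0 without degrading the
type-cluster agreement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score, silhouette_score

from .models import ExpressionMatrix

__all__ = [
    "rescale_tpm",
    "QuantileCohortMapper",
    "LocationScaleMapper",
    "fit_map",
    "apply_map",
    "location_scale_baseline",
    "evaluate_mixing",
    "MixingReport",
]


def rescale_tpm(
    matrix: ExpressionMatrix, excluded_genes: Iterable[str] = ()
) -> ExpressionMatrix:
    """Drop excluded features (e.g. rRNA, mitochondrial genes) and rescale
    each sample column to sum to 1e6.

    Removing residual rRNA before rescaling normalises out sample-to-sample
    variation in ribosomal depletion efficiency.
    """
    excluded = set(excluded_genes)
    keep = [g for g in matrix.values.index if g not in excluded]
    if not keep:
        raise ValueError("exclusion list removes every gene")
    sub = matrix.values.loc[keep]
    totals = sub.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(
            f"samples with zero total expression after exclusion: {list(zero.index)}"
        )
    rescaled = sub * (1e6 / totals)
    return ExpressionMatrix(values=rescaled, rescaled=True)


def _check_frames(X: pd.DataFrame, reference: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, pd.Index]:
    if not isinstance(X, pd.DataFrame) or not isinstance(reference, pd.DataFrame):
        raise TypeError("expected pandas DataFrames (samples x genes)")
    shared = X.columns.intersection(reference.columns)
    if len(shared) == 0:
        raise ValueError("no shared genes between source and reference")
    return X[shared], reference[shared], shared


class QuantileCohortMapper(BaseEstimator, TransformerMixin):
    """Per-gene empirical quantile map from a source cohort onto a reference.

    ``fit(X, reference)`` learns, for every shared gene, the sorted source
    values and sorted reference values; ``transform`` rank-interpolates each
    input value through the source CDF and evaluates the reference quantile
    function there, clamping beyond the training range.

    Parameters
    ----------
    min_samples : int
        Minimum training samples required in each cohort (default 2).

    Attributes
    ----------
    genes_ : pd.Index
        Shared genes the map is defined for.
    source_quantiles_ : np.ndarray, shape (n_source_samples, n_genes)
        Sorted source training values per gene.
    reference_quantiles_ : np.ndarray, shape (n_reference_samples, n_genes)
        Sorted reference training values per gene.
    constant_reference_genes_ : list[str]
        Genes whose reference distribution is a single value; the map
        collapses every source value of such a gene to that constant.
    constant_source_genes_ : list[str]
        Genes constant in the source cohort; their values map to the
        reference median.
    """

    def __init__(self, min_samples: int = 2):
        self.min_samples = min_samples

    def fit(self, X: pd.DataFrame, reference: pd.DataFrame) -> "QuantileCohortMapper":
        """Learn the per-gene quantile correspondence.

        Parameters
        ----------
        X : DataFrame (samples x genes)
            Source-cohort training matrix, log2(TPM+1) scale.
        reference : DataFrame (samples x genes)
            Reference-cohort matrix on the same scale.
        """
        Xs, ref, shared = _check_frames(X, reference)
        if Xs.shape[0] < self.min_samples or ref.shape[0] < self.min_samples:
            raise ValueError(
                f"need >= {self.min_samples} samples per cohort, got "
                f"{Xs.shape[0]} source / {ref.shape[0]} reference"
            )
        self.genes_ = shared
        self.source_quantiles_ = np.sort(Xs.to_numpy(dtype=float), axis=0)
        self.reference_quantiles_ = np.sort(ref.to_numpy(dtype=float), axis=0)
        src_rng = self.source_quantiles_[-1] - self.source_quantiles_[0]
        ref_rng = self.reference_quantiles_[-1] - self.reference_quantiles_[0]
        self.constant_source_genes_ = list(shared[src_rng == 0])
        self.constant_reference_genes_ = list(shared[ref_rng == 0])
        self.n_source_samples_ = Xs.shape[0]
        self.n_reference_samples_ = ref.shape[0]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Project source values into the reference space, gene by gene."""
        if not hasattr(self, "genes_"):
            raise RuntimeError("mapper is not fitted")
        missing = [g for g in X.columns if g not in set(self.genes_)]
        if missing:
            raise KeyError(f"genes not seen during fit: {missing}")
        gene_pos = {g: i for i, g in enumerate(self.genes_)}
        n_src = self.n_source_samples_
        n_ref = self.n_reference_samples_
        p_src = np.linspace(0.0, 1.0, n_src)
        p_ref = np.linspace(0.0, 1.0, n_ref)
        out = np.empty((X.shape[0], X.shape[1]), dtype=float)
        const_src = set(self.constant_source_genes_)
        vals = X.to_numpy(dtype=float)
        for j, gene in enumerate(X.columns):
            gi = gene_pos[gene]
            sq = self.source_quantiles_[:, gi]
            rq = self.reference_quantiles_[:, gi]
            if gene in const_src:
                # degenerate source CDF: rank is uninformative, use the
                # reference median
                out[:, j] = np.median(rq)
                continue
            p = np.interp(vals[:, j], sq, p_src)  # clamps outside range
            out[:, j] = np.interp(p, p_ref, rq)
        return pd.DataFrame(out, index=X.index, columns=X.columns)


class LocationScaleMapper(BaseEstimator, TransformerMixin):
    """Per-gene location/scale standardisation onto a reference cohort.

    Each gene's source values are z-scored with the source training mean
    and SD and rescaled to the reference mean and SD.  Fully corrects
    affine platform effects; cannot correct non-affine monotone
    distortions, which is what the quantile mapper is for.
    """

    def __init__(self, min_samples: int = 2):
        self.min_samples = min_samples

    def fit(self, X: pd.DataFrame, reference: pd.DataFrame) -> "LocationScaleMapper":
        Xs, ref, shared = _check_frames(X, reference)
        if Xs.shape[0] < self.min_samples or ref.shape[0] < self.min_samples:
            raise ValueError(
                f"need >= {self.min_samples} samples per cohort, got "
                f"{Xs.shape[0]} source / {ref.shape[0]} reference"
            )
        self.genes_ = shared
        self.source_mean_ = Xs.mean(axis=0).to_numpy()
        self.source_std_ = Xs.std(axis=0, ddof=0).to_numpy()
        self.reference_mean_ = ref.mean(axis=0).to_numpy()
        self.reference_std_ = ref.std(axis=0, ddof=0).to_numpy()
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "genes_"):
            raise RuntimeError("mapper is not fitted")
        missing = [g for g in X.columns if g not in set(self.genes_)]
        if missing:
            raise KeyError(f"genes not seen during fit: {missing}")
        pos = {g: i for i, g in enumerate(self.genes_)}
        idx = np.array([pos[g] for g in X.columns])
        mu_s = self.source_mean_[idx]
        sd_s = self.source_std_[idx]
        mu_r = self.reference_mean_[idx]
        sd_r = self.reference_std_[idx]
        vals = X.to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (vals - mu_s) / sd_s
        out = z * sd_r + mu_r
        # zero-variance source genes carry no rank information: reference mean
        out[:, sd_s == 0] = np.broadcast_to(mu_r, out.shape)[:, sd_s == 0]
        return pd.DataFrame(out, index=X.index, columns=X.columns)


def _to_log_samples_by_genes(matrix: ExpressionMatrix) -> pd.DataFrame:
    return np.log2(matrix.values + 1.0).T


def fit_map(
    reference_matrix: ExpressionMatrix, source_matrix: ExpressionMatrix
) -> QuantileCohortMapper:
    """Fit the per-gene quantile map source -> reference on log2(TPM+1)."""
    ref = _to_log_samples_by_genes(reference_matrix)
    src = _to_log_samples_by_genes(source_matrix)
    return QuantileCohortMapper().fit(src, ref)


def apply_map(
    model: QuantileCohortMapper, source_matrix: ExpressionMatrix
) -> pd.DataFrame:
    """Project a TPM matrix through a fitted map.

    Returns a gene-by-sample DataFrame on the log2(TPM+1) scale (the scale
    the map is defined on).
    """
    src = _to_log_samples_by_genes(source_matrix)
    return model.transform(src).T


def location_scale_baseline(
    reference_matrix: ExpressionMatrix, source_matrix: ExpressionMatrix
) -> pd.DataFrame:
    """Project via the per-gene mean/SD baseline; gene-by-sample log2 output."""
    ref = _to_log_samples_by_genes(reference_matrix)
    src = _to_log_samples_by_genes(source_matrix)
    model = LocationScaleMapper().fit(src, ref)
    return model.transform(src).T


@dataclass
class MixingReport:
    """Cohort-mixing diagnostics on a PCA embedding.

    ``silhouette_cohort`` near 0 means the cohorts are indistinguishable in
    PC space; ``cohort_variance_share`` is the variance-weighted fraction of
    PC1-2 variance explained by the cohort label; ``type_ari`` measures how
    well unsupervised clusters recover the biological type labels (NaN when
    fewer than two types are present).
    """

    silhouette_cohort: float
    cohort_variance_share: float
    type_ari: float
    n_genes_used: int
    n_components: int
    pc_coords: pd.DataFrame
    explained_variance_ratio: np.ndarray


def _label_variance_share(pcs: np.ndarray, labels: np.ndarray, evr: np.ndarray) -> float:
    """Variance-weighted eta-squared of a label across the given PCs."""
    shares = []
    for j in range(pcs.shape[1]):
        col = pcs[:, j]
        grand = col.mean()
        ss_tot = float(((col - grand) ** 2).sum())
        if ss_tot == 0:
            shares.append(0.0)
            continue
        ss_between = 0.0
        for lab in np.unique(labels):
            grp = col[labels == lab]
            ss_between += grp.size * (grp.mean() - grand) ** 2
        shares.append(ss_between / ss_tot)
    w = evr[: len(shares)]
    if w.sum() == 0:
        return 0.0
    return float(np.average(shares, weights=w))


def evaluate_mixing(
    combined: pd.DataFrame,
    cohort_labels: Sequence[str],
    type_labels: Sequence[str],
    n_top_genes: int = 3000,
    n_components: int = 2,
    random_state: int = 0,
) -> MixingReport:
    """Quantify cohort separation and biology preservation after mapping.

    Parameters
    ----------
    combined : DataFrame (genes x samples)
        Combined cohorts on the log2(TPM+1) scale.
    cohort_labels, type_labels
        Per-sample cohort (platform) and cancer-type labels, aligned with
        the matrix columns.
    n_top_genes : int
        Number of most-varying genes (variance across the combined matrix)
        used for the embedding; capped at the number of genes available.
    """
    cohorts = np.asarray(list(cohort_labels))
    types = np.asarray(list(type_labels))
    n_samples = combined.shape[1]
    if cohorts.size != n_samples or types.size != n_samples:
        raise ValueError("label length does not match number of samples")
    if len(np.unique(cohorts)) < 2:
        raise ValueError("need at least two cohorts")

    variances = combined.var(axis=1)
    top = variances.sort_values(ascending=False).index[: min(n_top_genes, len(variances))]
    X = combined.loc[top].T.to_numpy(dtype=float)  # samples x genes

    max_comp = min(n_samples, X.shape[1])
    if n_components > max_comp:
        warnings.warn(
            f"reducing n_components from {n_components} to {max_comp} "
            "(fewer samples than requested components)",
            stacklevel=2,
        )
        n_components = max_comp
    pca = PCA(n_components=n_components, random_state=random_state)
    pcs = pca.fit_transform(X)

    sil = float(silhouette_score(pcs, cohorts))
    share = _label_variance_share(
        pcs[:, : min(2, n_components)], cohorts, pca.explained_variance_ratio_
    )

    k = len(np.unique(types))
    if k < 2:
        ari = float("nan")
    else:
        km = KMeans(n_clusters=k, random_state=random_state, n_init=10)
        clusters = km.fit_predict(pcs)
        ari = float(adjusted_rand_score(types, clusters))

    coords = pd.DataFrame(
        pcs,
        index=combined.columns,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    coords["cohort"] = cohorts
    coords["cancer_type"] = types
    return MixingReport(
        silhouette_cohort=sil,
        cohort_variance_share=share,
        type_ari=ari,
        n_genes_used=len(top),
        n_components=n_components,
        pc_coords=coords,
        explained_variance_ratio=pca.explained_variance_ratio_,
    )
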