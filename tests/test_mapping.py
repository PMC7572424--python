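"""Quantile cohort mapping, location-scale baseline, and mixing diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ks_2samp

from ffpeqc import (
    LocationScaleMapper,
    QuantileCohortMapper,
    apply_map,
    evaluate_mixing,
    fit_map,
    location_scale_baseline,
    rescale_tpm,
)

from conftest import expr_matrix


def _frame(arr, genes=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, columns=genes)


# ------------------------------------------------------------------ rescaling


def test_rescale_noop_when_already_normalised():
    m = expr_matrix([[600000.0], [400000.0]], rescaled=False)
    out = rescale_tpm(m)
    np.testing.assert_allclose(out.values.to_numpy().ravel(), [600000, 400000])
    assert out.rescaled


def test_rescale_renormalises_after_exclusion():
    m = expr_matrix(
        [[500000.0], [300000.0], [200000.0]],
        genes=["rrna1", "A", "B"],
        rescaled=False,
    )
    out = rescale_tpm(m, excluded_genes=["rrna1"])
    assert list(out.values.index) == ["A", "B"]
    np.testing.assert_allclose(out.values.to_numpy().ravel(), [600000, 400000])


def test_rescale_excluding_zero_gene_changes_nothing():
    m = expr_matrix([[600000.0], [400000.0], [0.0]], genes=["A", "B", "Z"])
    out = rescale_tpm(m, excluded_genes=["Z"])
    np.testing.assert_allclose(out.values.to_numpy().ravel(), [600000, 400000])


def test_rescale_zero_total_sample_errors():
    m = expr_matrix([[1e6], [0.0]], genes=["rrna1", "A"])
    with pytest.raises(ValueError, match="zero total"):
        rescale_tpm(m, excluded_genes=["rrna1"])


# ------------------------------------------------------------- quantile model


def test_identity_map_on_identical_cohorts():
    rng = np.random.default_rng(0)
    X = _frame(rng.uniform(0, 10, size=(30, 5)))
    model = QuantileCohortMapper().fit(X, X)
    out = model.transform(X)
    np.testing.assert_allclose(out.to_numpy(), X.to_numpy(), atol=1e-9)


def test_shift_recovery():
    # source = reference + 2 per gene on the log scale: the learned map
    # subtracts 2 (up to empirical-quantile error at n=200)
    rng = np.random.default_rng(1)
    ref = _frame(rng.normal(5, 1.5, size=(200, 10)))
    src = ref + 2.0
    model = QuantileCohortMapper().fit(src, ref)
    heldout = _frame(rng.normal(7, 1.5, size=(50, 10)), genes=list(src.columns))
    out = model.transform(heldout)
    # interpolation is only defined inside the training range; values beyond
    # it are clamped to the endpoint quantiles by design
    vals = heldout.to_numpy()
    lo = src.to_numpy().min(axis=0)
    hi = src.to_numpy().max(axis=0)
    interior = (vals > lo) & (vals < hi)
    np.testing.assert_allclose(
        out.to_numpy()[interior], vals[interior] - 2.0, atol=0.1
    )
    assert interior.mean() > 0.9


def test_constant_reference_gene_collapses_and_is_flagged():
    rng = np.random.default_rng(2)
    ref = _frame(np.column_stack([np.full(20, 3.0), rng.normal(5, 1, 20)]))
    src = _frame(rng.normal(4, 1, size=(20, 2)), genes=list(ref.columns))
    model = QuantileCohortMapper().fit(src, ref)
    assert model.constant_reference_genes_ == ["g0"]
    out = model.transform(src)
    assert (out["g0"] == 3.0).all()


def test_constant_source_gene_maps_to_reference_median():
    rng = np.random.default_rng(3)
    ref = _frame(rng.normal(5, 1, size=(21, 1)))
    src = _frame(np.full((10, 1), 2.0))
    model = QuantileCohortMapper().fit(src, ref)
    out = model.transform(src)
    assert (out["g0"] == np.median(ref["g0"])).all()


def test_unseen_gene_rejected_with_ids():
    rng = np.random.default_rng(4)
    X = _frame(rng.uniform(0, 1, (5, 2)))
    model = QuantileCohortMapper().fit(X, X)
    bad = _frame(rng.uniform(0, 1, (3, 3)), genes=["g0", "g1", "novel"])
    with pytest.raises(KeyError, match="novel"):
        model.transform(bad)


def test_permutation_matching_at_equal_sample_counts():
    # with equal cohort sizes and distinct values, quantile mapping sends
    # the sorted source exactly onto the sorted reference
    rng = np.random.default_rng(5)
    for n in (3, 7, 20):
        ref = _frame(rng.normal(0, 1, size=(n, 4)))
        src = _frame(rng.normal(3, 2, size=(n, 4)))
        model = QuantileCohortMapper().fit(src, ref)
        out = model.transform(src)
        np.testing.assert_allclose(
            np.sort(out.to_numpy(), axis=0), np.sort(ref.to_numpy(), axis=0), atol=1e-9
        )


def test_mapping_preserves_within_cohort_rank_order():
    rng = np.random.default_rng(6)
    ref = _frame(rng.normal(0, 1, size=(40, 6)))
    src = _frame(rng.normal(2, 3, size=(35, 6)))
    model = QuantileCohortMapper().fit(src, ref)
    out = model.transform(src)
    for g in src.columns:
        order = np.argsort(src[g].to_numpy(), kind="stable")
        mapped = out[g].to_numpy()[order]
        assert (np.diff(mapped) >= -1e-12).all()


def test_out_of_range_values_clamped_to_endpoint_quantiles():
    ref = _frame(np.linspace(0, 1, 11)[:, None])
    src = _frame(np.linspace(5, 6, 11)[:, None])
    model = QuantileCohortMapper().fit(src, ref)
    out = model.transform(_frame(np.array([[-100.0], [100.0]])))
    assert out.iloc[0, 0] == 0.0 and out.iloc[1, 0] == 1.0


def test_min_samples_enforced():
    X = _frame(np.ones((1, 2)))
    with pytest.raises(ValueError, match="samples per cohort"):
        QuantileCohortMapper().fit(X, X)


# -------------------------------------------------------- ExpressionMatrix API


def test_fit_apply_roundtrip_identity_matrix():
    rng = np.random.default_rng(7)
    m = expr_matrix(rng.uniform(0, 1000, size=(50, 12)))
    model = fit_map(m, m)
    out = apply_map(model, m)
    np.testing.assert_allclose(
        out.to_numpy(), np.log2(m.values.to_numpy() + 1), atol=1e-9
    )


def test_single_sample_source_is_pure_lookup():
    rng = np.random.default_rng(8)
    train = expr_matrix(rng.uniform(0, 100, size=(20, 10)))
    model = fit_map(train, train)
    single = expr_matrix(rng.uniform(0, 100, size=(20, 1)),
                         genes=list(train.gene_ids))
    out = apply_map(model, single)
    assert out.shape == (20, 1)
    assert np.isfinite(out.to_numpy()).all()


def test_shift_model_equalises_marginals_ks():
    rng = np.random.default_rng(9)
    n = 200
    base = rng.normal(6, 1.2, size=(20, n))
    ref = expr_matrix(np.maximum(2.0**base - 1, 0))
    src_log = base[:, rng.permutation(n)] + 2.0
    src = expr_matrix(np.maximum(2.0**src_log - 1, 0), genes=list(ref.gene_ids))
    model = fit_map(ref, src)
    proj = apply_map(model, src)
    ref_log = np.log2(ref.values + 1)
    for g in ref.gene_ids:
        ks = ks_2samp(proj.loc[g], ref_log.loc[g]).statistic
        assert ks <= 0.1


# ------------------------------------------------------- location-scale model


def test_loc_scale_identity_when_source_equals_reference():
    rng = np.random.default_rng(10)
    X = _frame(rng.normal(3, 2, size=(30, 4)))
    out = LocationScaleMapper().fit(X, X).transform(X)
    np.testing.assert_allclose(out.to_numpy(), X.to_numpy(), atol=1e-9)


def test_loc_scale_fully_corrects_affine_effects():
    rng = np.random.default_rng(11)
    ref = _frame(rng.normal(5, 1, size=(100, 5)))
    src = ref * 2.0 + 3.0
    model = LocationScaleMapper().fit(src, ref)
    out = model.transform(src)
    np.testing.assert_allclose(out.to_numpy(), ref.to_numpy(), atol=1e-9)


def test_loc_scale_zero_variance_gene_maps_to_reference_mean():
    rng = np.random.default_rng(12)
    ref = _frame(rng.normal(5, 1, size=(10, 1)))
    src = _frame(np.full((10, 1), 9.0))
    out = LocationScaleMapper().fit(src, ref).transform(src)
    np.testing.assert_allclose(out["g0"], ref["g0"].mean())


def test_quantile_map_beats_baseline_under_nonlinear_distortion():
    # a rank-preserving but non-affine platform effect leaves residual
    # distribution shape the location-scale baseline cannot remove
    rng = np.random.default_rng(13)
    n = 200
    base = rng.normal(6, 1.5, size=(30, n))
    ref = expr_matrix(np.maximum(2.0**base - 1, 0))
    warped = 0.5 + np.maximum(base[:, rng.permutation(n)], 0) ** 1.4 / 6 ** 0.4
    src = expr_matrix(np.maximum(2.0**warped - 1, 0), genes=list(ref.gene_ids))
    proj_q = apply_map(fit_map(ref, src), src)
    proj_ls = location_scale_baseline(ref, src)
    ref_log = np.log2(ref.values + 1)
    ks_q, ks_ls = [], []
    for g in ref.gene_ids:
        ks_q.append(ks_2samp(proj_q.loc[g], ref_log.loc[g]).statistic)
        ks_ls.append(ks_2samp(proj_ls.loc[g], ref_log.loc[g]).statistic)
    assert np.median(ks_q) < np.median(ks_ls)


# ----------------------------------------------------------------- mixing QC


def _two_cohorts(rng, offset=0.0, n=100, n_genes=60, n_types=2, type_shift=3.0):
    types = np.array([f"t{i % n_types}" for i in range(2 * n)])
    x = rng.normal(5, 1, size=(n_genes, 2 * n))
    for t in range(n_types):
        block = slice(t * 5, t * 5 + 5)
        x[block, types == f"t{t}"] += type_shift
    x[:, n:] += offset
    cohorts = np.array(["ref"] * n + ["src"] * n)
    df = pd.DataFrame(x, index=[f"g{i}" for i in range(n_genes)])
    return df, cohorts, types


def test_identical_distribution_cohorts_mix():
    rng = np.random.default_rng(14)
    df, cohorts, types = _two_cohorts(rng, offset=0.0)
    rep = evaluate_mixing(df, cohorts, types, n_top_genes=60, random_state=0)
    assert abs(rep.silhouette_cohort) < 0.05


def test_offset_cohorts_separate_before_correction():
    rng = np.random.default_rng(15)
    df, cohorts, types = _two_cohorts(rng, offset=8.0)
    rep = evaluate_mixing(df, cohorts, types, n_top_genes=60, random_state=0)
    assert rep.silhouette_cohort > 0.8
    assert rep.cohort_variance_share > 0.5


def test_single_cancer_type_flags_undefined_agreement():
    rng = np.random.default_rng(16)
    df, cohorts, _ = _two_cohorts(rng, offset=0.0)
    rep = evaluate_mixing(df, cohorts, ["only"] * df.shape[1], n_top_genes=60)
    assert math.isnan(rep.type_ari)


def test_components_reduced_with_warning_when_samples_scarce():
    rng = np.random.default_rng(17)
    df = pd.DataFrame(rng.normal(size=(50, 3)), index=[f"g{i}" for i in range(50)])
    with pytest.warns(UserWarning, match="reducing n_components"):
        rep = evaluate_mixing(
            df, ["a", "a", "b"], ["x", "y", "x"], n_top_genes=50, n_components=10
        )
    assert rep.n_components == 3


def test_mapping_reduces_cohort_silhouette_and_keeps_biology(cohort_sim):
    from ffpeqc import default_exclusion_list

    excl = default_exclusion_list(cohort_sim.gene_roles)
    ref = rescale_tpm(cohort_sim.reference, excl)
    src = rescale_tpm(cohort_sim.source, excl)
    ref_log = np.log2(ref.values + 1)
    src_log = np.log2(src.values + 1)
    proj = apply_map(fit_map(ref, src), src)
    labels = cohort_sim.labels.set_index("sample_id")
    pre = pd.concat([ref_log, src_log], axis=1)
    post = pd.concat([ref_log, proj], axis=1)
    sids = list(pre.columns)
    cohorts = labels.loc[sids, "cohort"].to_numpy()
    types = labels.loc[sids, "cancer_type"].to_numpy()
    mix_pre = evaluate_mixing(pre, cohorts, types, random_state=0)
    mix_post = evaluate_mixing(post, cohorts, types, random_state=0)
    assert mix_pre.silhouette_cohort > 0.5
    assert abs(mix_post.silhouette_cohort) < 0.1
    assert mix_post.type_ari >= mix_pre.type_ari - 0.05
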