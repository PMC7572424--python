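"""Unit and property tests for TIN / TB scoring and quality aggregation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ffpeqc import (
    CoverageProfile,
    QualityRecord,
    TranscriptModel,
    compute_gene_tin,
    compute_sample_tin,
    compute_tb,
    compute_tin,
    per_gene_tin_distribution,
    summarize_sample_quality,
)

# ------------------------------------------------------------------ oracles


def entropy_tin_oracle(depth, step=1):
    """Independent TIN computation via an explicit -sum(p ln p) loop."""
    sampled = list(depth)[::step]
    total = sum(sampled)
    if total == 0:
        return 0.0
    h = 0.0
    for d in sampled:
        if d > 0:
            p = d / total
            h -= p * math.log(p)
    return 100.0 * math.exp(h) / len(sampled)


def weighted_mean_tb_oracle(depth):
    n = len(depth)
    total = sum(depth)
    m = sum(d * (i + 0.5) / n for i, d in enumerate(depth)) / total
    return 2.0 * (m - 0.5)


# ---------------------------------------------------------------------- TIN


@pytest.mark.parametrize(
    "depth, step, expected",
    [
        ([1, 1, 1, 1], 1, 100.0),  # uniform coverage maximises entropy
        ([4, 0, 0, 0], 1, 25.0),  # single-base spike: 100/k
        ([2, 2, 0, 0], 1, 50.0),  # H = ln 2 -> 100 * 2/4
        ([0, 0, 0, 0], 1, 0.0),  # all-zero convention
        ([3, 9, 3, 9], 2, 100.0),  # step=2 samples positions 0 and 2 only
    ],
)
def test_tin_reference_values(depth, step, expected):
    assert compute_tin(depth, sample_step=step) == pytest.approx(expected)


def test_tin_errors():
    with pytest.raises(ValueError, match="empty profile"):
        compute_tin([])
    with pytest.raises(ValueError, match="step exceeds transcript length"):
        compute_tin([1, 2, 3], sample_step=4)
    with pytest.raises(ValueError):
        compute_tin([1, 2], sample_step=0)


def test_tin_matches_entropy_oracle_on_random_vectors():
    rng = np.random.default_rng(42)
    for _ in range(1000):
        n = int(rng.integers(1, 50))
        depth = rng.integers(0, 40, size=n)
        assert compute_tin(depth) == pytest.approx(entropy_tin_oracle(depth), abs=1e-9)


@given(
    depth=st.lists(st.integers(min_value=0, max_value=1000), min_size=1, max_size=40),
    alpha=st.floats(min_value=0.01, max_value=100, allow_nan=False),
)
@settings(deadline=None, max_examples=80)
def test_tin_scale_invariance(depth, alpha):
    d = np.asarray(depth, dtype=float)
    assert compute_tin(d * alpha) == pytest.approx(compute_tin(d), abs=1e-9)


@given(k=st.integers(min_value=1, max_value=200))
@settings(deadline=None, max_examples=40)
def test_tin_spike_is_100_over_k(k):
    depth = np.zeros(k)
    depth[0] = 7
    assert compute_tin(depth) == pytest.approx(100.0 / k)


def test_tin_decreases_under_mass_concentration():
    # moving mass from a low-depth to a high-depth position (mean-preserving
    # concentration) must lower the entropy and hence TIN
    rng = np.random.default_rng(3)
    for _ in range(50):
        n = int(rng.integers(4, 50))
        depth = rng.integers(1, 30, size=n).astype(float)
        i, j = np.argsort(depth)[[0, -1]]
        if depth[i] == depth[j]:
            continue
        concentrated = depth.copy()
        move = depth[i] / 2
        concentrated[i] -= move
        concentrated[j] += move
        assert compute_tin(concentrated) < compute_tin(depth) + 1e-12


def test_tin_bounds_strict_for_nonuniform_nonzero():
    tin = compute_tin([5, 1, 1, 1])
    assert 0.0 < tin < 100.0


# ----------------------------------------------------------------------- TB


@pytest.mark.parametrize(
    "depth, expected",
    [
        ([1, 1, 1, 1], 0.0),  # uniform
        ([0, 0, 4, 4], 0.5),  # mass in the 3' half
        ([5, 0, 0, 5], 0.0),  # 5'/3'-symmetric
    ],
)
def test_tb_reference_values(depth, expected):
    assert compute_tb(depth) == pytest.approx(expected)


def test_tb_undefined_for_unexpressed():
    with pytest.raises(ValueError, match="TB undefined"):
        compute_tb([0, 0, 0])


@given(
    depth=st.lists(st.integers(min_value=0, max_value=100), min_size=1, max_size=40).filter(
        lambda d: sum(d) > 0
    )
)
@settings(deadline=None, max_examples=100)
def test_tb_reversal_antisymmetry(depth):
    d = np.asarray(depth, dtype=float)
    assert compute_tb(d[::-1]) == pytest.approx(-compute_tb(d), abs=1e-12)


@given(
    depth=st.lists(st.integers(min_value=0, max_value=100), min_size=1, max_size=40).filter(
        lambda d: sum(d) > 0
    ),
    alpha=st.floats(min_value=0.01, max_value=100, allow_nan=False),
)
@settings(deadline=None, max_examples=80)
def test_tb_scale_invariance(depth, alpha):
    d = np.asarray(depth, dtype=float)
    assert compute_tb(d * alpha) == pytest.approx(compute_tb(d), abs=1e-9)


def test_tb_matches_weighted_mean_oracle():
    rng = np.random.default_rng(11)
    for _ in range(200):
        depth = rng.integers(0, 50, size=int(rng.integers(2, 60)))
        if depth.sum() == 0:
            continue
        assert compute_tb(depth) == pytest.approx(
            weighted_mean_tb_oracle(list(depth)), abs=1e-12
        )


# --------------------------------------------------------------- aggregation


def test_sample_tin_examples():
    s = compute_sample_tin([0, 20, 60, 80])
    assert s.sample_tin == 60 and s.high_quality
    s = compute_sample_tin([50, 50])  # gate is strict
    assert s.sample_tin == 50 and not s.high_quality
    s = compute_sample_tin([100])
    assert s.sample_tin == 100 and s.high_quality


def test_sample_tin_all_zero_flagged_not_zero():
    s = compute_sample_tin([0.0, 0.0])
    assert s.no_expressed_transcripts
    assert math.isnan(s.sample_tin)


def test_sample_tin_empty_errors():
    with pytest.raises(ValueError):
        compute_sample_tin([])


def test_sample_tin_matches_sort_and_middle_oracle():
    rng = np.random.default_rng(4)
    for _ in range(30):
        n = int(rng.integers(1, 1000))
        tins = rng.uniform(0, 100, size=n)
        tins[rng.random(n) < 0.2] = 0.0
        nonzero = sorted(t for t in tins if t > 0)
        if not nonzero:
            continue
        mid = len(nonzero) // 2
        if len(nonzero) % 2:
            expected = nonzero[mid]
        else:
            expected = (nonzero[mid - 1] + nonzero[mid]) / 2
        assert compute_sample_tin(tins).sample_tin == pytest.approx(expected)


def _rec(tx, tin, sample="s1"):
    return QualityRecord(tx, sample, tin, 0.0, 1.0, True)


def _tx(tx, gene, canonical, length=100):
    return TranscriptModel(tx, gene, "+", length, canonical)


def test_gene_tin_canonical_governs():
    anno = [_tx("A", "g", True), _tx("B", "g", False)]
    gq = compute_gene_tin([_rec("A", 30), _rec("B", 70)], anno)
    assert gq.gene_tin == 30


def test_gene_tin_max_fallback_without_canonical():
    anno = [_tx("A", "g", False), _tx("B", "g", False)]
    gq = compute_gene_tin([_rec("A", 30), _rec("B", 70)], anno)
    assert gq.gene_tin == 70


def test_gene_tin_single_transcript_identity():
    anno = [_tx("A", "g", True)]
    assert compute_gene_tin([_rec("A", 55)], anno).gene_tin == 55


def test_gene_tin_empty_errors():
    with pytest.raises(ValueError, match="gene absent"):
        compute_gene_tin([], [])


def test_tin_distribution_trivial_splits():
    d = per_gene_tin_distribution([90.0] * 10)
    assert d.low_mode_fraction == 0.0
    d = per_gene_tin_distribution([10, 10, 90, 90], valley=50)
    assert d.low_mode_fraction == 0.5
    assert d.counts.sum() == 4


def test_tin_distribution_recovers_mixture_weight():
    # bimodal mixture 0.3*N(25,5) + 0.7*N(80,5): the low-mode fraction at
    # valley 50 estimates the mixture weight
    rng = np.random.default_rng(123)
    comp = rng.random(1000) < 0.3
    tins = np.where(comp, rng.normal(25, 5, 1000), rng.normal(80, 5, 1000))
    tins = np.clip(tins, 0.1, 100)
    d = per_gene_tin_distribution(tins, valley=50)
    assert d.low_mode_fraction == pytest.approx(0.30, abs=0.03)


def test_summarize_sample_quality_uniform_transcript():
    prof = CoverageProfile("t1", "s1", np.full(20, 5))
    sq = summarize_sample_quality([prof])
    assert sq.sample_tin == pytest.approx(100.0)
    assert sq.high_quality
    assert sq.median_tb == pytest.approx(0.0)
    assert sq.n_expressed == 1


def test_summarize_sample_quality_weighted_gc():
    # GGCC at uniform depth 10 and AATT at uniform depth 30:
    # GC mass 4*10, total mass 4*10 + 4*30 -> 0.25
    p1 = CoverageProfile("t1", "s1", np.full(4, 10))
    p2 = CoverageProfile("t2", "s1", np.full(4, 30))
    sq = summarize_sample_quality([p1, p2], sequences={"t1": "GGCC", "t2": "AATT"})
    assert sq.gc_content == pytest.approx(0.25)


def test_summarize_sample_quality_template_lengths():
    prof = CoverageProfile("t1", "s1", np.full(10, 2))
    sq = summarize_sample_quality([prof], template_lengths=[100, 200, 300])
    assert sq.mean_template_length == pytest.approx(200.0)


def test_summarize_sample_quality_rejects_mixed_samples():
    p1 = CoverageProfile("t1", "s1", np.ones(5))
    p2 = CoverageProfile("t2", "s2", np.ones(5))
    with pytest.raises(ValueError, match="multiple samples"):
        summarize_sample_quality([p1, p2])
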