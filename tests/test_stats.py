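"""Balanced subsampling, restricted permutation engines, FDR, mixed model."""

import numpy as np
import pytest

from thetagaze import stats


# ---------------------------------------------------------------------------
# balanced subsampling
# ---------------------------------------------------------------------------

def test_subsample_matches_smaller_group(rng):
    a = rng.standard_normal(100)
    b = rng.standard_normal(60)
    ma, mb, n = stats.balanced_subsample_means(a, b, n_iterations=50, seed=0)
    assert n == 60
    assert mb == pytest.approx(b.mean())


def test_subsample_equal_groups_identity(rng):
    a = rng.standard_normal(80)
    b = rng.standard_normal(80)
    ma, mb, _ = stats.balanced_subsample_means(a, b, seed=0)
    assert ma == pytest.approx(a.mean()) and mb == pytest.approx(b.mean())


def test_subsample_unbiased_vs_full_mean(rng):
    """Averaged subsample mean converges to the full-group mean."""
    big = rng.standard_normal(500) + 0.3
    small = rng.standard_normal(100)
    mb, _, _ = stats.balanced_subsample_means(big, small, n_iterations=2000, seed=1)
    se = big.std() / np.sqrt(100) / np.sqrt(2000) * 10
    assert mb == pytest.approx(big.mean(), abs=max(se, 0.02))


def test_subsample_deterministic(rng):
    a, b = rng.standard_normal(50), rng.standard_normal(30)
    r1 = stats.balanced_subsample_means(a, b, seed=9)
    r2 = stats.balanced_subsample_means(a, b, seed=9)
    assert r1 == r2


def test_subsample_empty_group_raises():
    with pytest.raises(ValueError):
        stats.balanced_subsample_means([], [1.0, 2.0])


# ---------------------------------------------------------------------------
# sign-flip / label-exchange engines
# ---------------------------------------------------------------------------

def test_exhaustive_three_blocks_all_positive():
    """Three independent blocks, all values positive: only the identity
    pattern reaches the observed t, so p = 1/8 exactly."""
    res = stats.signflip_test(np.array([1.0, 2.0, 3.0]), ["a", "b", "c"])
    assert res.exhaustive
    assert res.p == pytest.approx(1.0 / 8.0, abs=1e-12)
    assert res.min_attainable_p == pytest.approx(1.0 / 8.0)


def test_single_block_floor_one_half():
    res = stats.signflip_test(np.array([0.5, 0.7]), ["a", "a"])
    assert res.exhaustive and res.p == pytest.approx(0.5)


def test_monte_carlo_agrees_with_exhaustive(rng):
    values = rng.standard_normal(12) + 0.6
    blocks = np.repeat(np.arange(6), 2)
    ex = stats.signflip_test(values, blocks)
    spec = stats.PermutationSpec(n_permutations=20000, exhaustive_max_blocks=0,
                                 seed=4)
    mc = stats.signflip_test(values, blocks, spec)
    assert ex.exhaustive and not mc.exhaustive
    se = np.sqrt(ex.p * (1 - ex.p) / 20000)
    assert mc.p == pytest.approx(ex.p, abs=4 * se + 1e-4)


def test_all_zero_values_p_one():
    res = stats.signflip_test(np.zeros(6), np.repeat([0, 1, 2], 2))
    assert res.p == 1.0


def test_p_never_zero(rng):
    """Ties included: p is bounded below by the attainable floor."""
    for _ in range(5):
        v = rng.standard_normal(8) + 3.0
        res = stats.signflip_test(v, np.arange(8))
        assert res.p >= 1.0 / 256.0 - 1e-15


def test_null_calibration_signflip(rng):
    """Under a symmetric null the rejection rate at alpha=.05 stays within
    the exact binomial 95% interval (10 blocks, exhaustive nulls)."""
    from scipy.stats import binom
    n_rep, alpha = 400, 0.05
    rejections = 0
    blocks = np.repeat(np.arange(10), 2)
    for _ in range(n_rep):
        v = rng.standard_normal(20)
        rejections += stats.signflip_test(v, blocks).p <= alpha
    lo, hi = binom.ppf([0.025, 0.975], n_rep, alpha)
    assert lo <= rejections <= hi


def test_paired_label_exchange_identical_groups(rng):
    a = rng.standard_normal(10)
    blocks = np.repeat(np.arange(5), 2)
    res = stats.paired_label_test(a, a.copy(), blocks)
    assert res.p == 1.0
    with pytest.raises(ValueError):
        stats.paired_label_test(a, a[:5], blocks)


def test_permutation_audit_blocks_flip_together():
    """Shuffles never mix channels across participants: within each sign
    pattern, all of a participant's channels share one sign."""
    blocks = np.array(["p1", "p1", "p2", "p2", "p2", "p3"])
    signs, exhaustive = stats.permutation_index_audit(blocks)
    assert exhaustive and signs.shape == (8, 6)
    for pat in signs:
        for b in np.unique(blocks):
            assert len(np.unique(pat[blocks == b])) == 1


def test_relabeling_channel_order_invariance(rng):
    v = rng.standard_normal(10) + 0.4
    blocks = np.repeat(np.arange(5), 2)
    perm = rng.permutation(10)
    r1 = stats.signflip_test(v, blocks)
    r2 = stats.signflip_test(v[perm], blocks[perm])
    assert r1.p == pytest.approx(r2.p)


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def test_fdr_hand_computed_case():
    """BH by hand: p=(.01,.02,.03) -> q=(.03,.03,.03)."""
    q = stats.fdr_correct([0.01, 0.02, 0.03])
    assert np.allclose(q, [0.03, 0.03, 0.03], atol=1e-12)


def test_fdr_edge_cases():
    assert stats.fdr_correct([0.2])[0] == pytest.approx(0.2)
    assert np.allclose(stats.fdr_correct([1.0, 1.0, 1.0]), 1.0)
    q = stats.fdr_correct([0.001, 0.5, 0.04])
    order = np.argsort([0.001, 0.5, 0.04])
    assert (np.diff(q[order]) >= -1e-15).all()    # monotone in p
    with pytest.raises(ValueError):
        stats.fdr_correct([])


# ---------------------------------------------------------------------------
# mixed model
# ---------------------------------------------------------------------------

def test_mixed_model_parameter_recovery(rng):
    """beta_eye = 0.5, beta_body = 0: recovery within +-0.1 and a CI
    covering zero for the null predictor."""
    N, n_ch = 6000, 4
    ch = np.repeat(np.arange(n_ch), N // n_ch)
    eye_sp = rng.standard_normal(N)
    body_sp = rng.standard_normal(N)
    icpt = rng.normal(0, 0.5, n_ch)
    y = 0.5 * eye_sp + icpt[ch] + rng.standard_normal(N)
    res = stats.mixed_model_theta(y, eye_sp, body_sp, ch)
    assert res["eye"]["beta"] == pytest.approx(0.5, abs=0.1)
    b = res["body"]
    assert b["beta"] - 1.96 * b["se"] < 0 < b["beta"] + 1.96 * b["se"]


def test_mixed_model_standardization_invariance(rng):
    N, n_ch = 1998, 3
    ch = np.repeat(np.arange(n_ch), N // n_ch)
    eye_sp = rng.standard_normal(N)
    body_sp = rng.standard_normal(N)
    y = 0.3 * eye_sp + rng.standard_normal(N)
    r1 = stats.mixed_model_theta(y, eye_sp, body_sp, ch)
    r2 = stats.mixed_model_theta(y, 100 * eye_sp, 0.01 * body_sp, ch)
    assert r1["eye"]["beta"] == pytest.approx(r2["eye"]["beta"], abs=1e-6)


def test_mixed_model_null_response_nonsignificant(rng):
    """Pure-noise response: neither predictor significant at ~nominal rate.

    A handful of replications keeps runtime low; we assert no systematic
    excess (at most 2/8 false positives at alpha=.05 is within binomial
    range)."""
    hits = 0
    for _ in range(8):
        N, n_ch = 1200, 3
        ch = np.repeat(np.arange(n_ch), N // n_ch)
        res = stats.mixed_model_theta(rng.standard_normal(N),
                                      rng.standard_normal(N),
                                      rng.standard_normal(N), ch)
        hits += (res["eye"]["p"] < 0.05) + (res["body"]["p"] < 0.05)
    assert hits <= 3


def test_mixed_model_input_validation(rng):
    with pytest.raises(ValueError):
        stats.mixed_model_theta([1, 2], [1, 2], [1, 2], [0, 0])   # 1 channel
    N = 100
    ch = np.repeat([0, 1], 50)
    with pytest.raises(ValueError):
        stats.mixed_model_theta(rng.standard_normal(N), np.ones(N),
                                rng.standard_normal(N), ch)
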