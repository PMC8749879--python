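"""Nonparametric battery against independent oracles (enumeration, scipy)."""

import itertools

import numpy as np
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

import fatiguekit as fk
from fatiguekit.stats import _ks_stat_fitted_normal


def brute_force_wilcoxon_p(diffs):
    """Two-sided exact p by explicit iteration over all sign patterns."""
    d = np.asarray(diffs, float)
    ranks = scipy.stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = d.size
    ws = [
        np.sum([r for r, s in zip(ranks, signs) if s > 0])
        for signs in itertools.product([-1, 1], repeat=n)
    ]
    ws = np.asarray(ws, float)
    lo = np.mean(ws <= w_obs + 1e-9)
    hi = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(lo, hi))


class TestWilcoxon:
    def test_three_positive_diffs(self):
        res = fk.wilcoxon_signed_rank([0, 0, 0], [1, 2, 3])
        assert res.exact
        assert res.statistic == 6
        assert res.p_value == pytest.approx(0.25)

    def test_eight_positive_distinct_diffs(self):
        pre = np.zeros(8)
        post = np.arange(1.0, 9.0)
        res = fk.wilcoxon_signed_rank(pre, post)
        assert res.exact
        assert res.p_value == pytest.approx(2 / 256)

    def test_swapping_pre_post_preserves_p(self):
        rng = np.random.default_rng(5)
        pre, post = rng.normal(size=8), rng.normal(size=8)
        a = fk.wilcoxon_signed_rank(pre, post)
        b = fk.wilcoxon_signed_rank(post, pre)
        assert a.p_value == pytest.approx(b.p_value)
        n = 8
        assert a.statistic - n * (n + 1) / 4 == pytest.approx(
            -(b.statistic - n * (n + 1) / 4)
        )

    def test_zero_differences_dropped_and_recorded(self):
        res = fk.wilcoxon_signed_rank([1.0, 2.0, 5.0, 7.0], [1.0, 3.0, 7.0, 8.0])
        assert "zeros_dropped=1" in res.notes
        assert res.n == (3,)

    def test_all_zero_differences_is_an_error(self):
        with pytest.raises(ValueError):
            fk.wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    @given(st.integers(0, 200))
    def test_exact_p_matches_enumeration_oracle(self, case):
        rng = np.random.default_rng(case)
        n = int(rng.integers(4, 11))
        d = rng.normal(size=n)
        res = fk.wilcoxon_signed_rank(np.zeros(n), d)
        assert res.exact
        assert res.p_value == pytest.approx(brute_force_wilcoxon_p(d))

    @given(st.integers(0, 50))
    def test_exact_p_matches_scipy(self, case):
        rng = np.random.default_rng(10_000 + case)
        n = int(rng.integers(5, 11))
        d = rng.normal(size=n)
        ours = fk.wilcoxon_signed_rank(np.zeros(n), d)
        ref = scipy.stats.wilcoxon(d, mode="exact")
        assert ours.p_value == pytest.approx(ref.pvalue)

    def test_large_n_normal_approximation(self):
        rng = np.random.default_rng(3)
        pre = rng.normal(size=40)
        post = pre + rng.normal(0.5, 1.0, size=40)
        ours = fk.wilcoxon_signed_rank(pre, post)
        assert not ours.exact
        ref = scipy.stats.wilcoxon(post - pre, mode="approx", correction=False)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-6)


class TestFriedman:
    def test_identical_rankings_two_blocks(self):
        # both blocks ranked 1<2<3: Q = 12/(2*3*4)*(4+16+36) - 24 = 4
        m = np.array([[1.0, 2.0, 3.0], [10.0, 20.0, 30.0]])
        res = fk.friedman(m)
        assert res.statistic == pytest.approx(4.0)

    def test_identical_columns_give_null(self):
        m = np.tile(np.array([[5.0, 5.0, 5.0]]), (4, 1))
        res = fk.friedman(m)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_invariant_to_monotone_within_block_transform(self, rng):
        m = rng.normal(size=(6, 4))
        a = fk.friedman(m)
        b = fk.friedman(np.exp(3 * m))
        assert a.statistic == pytest.approx(b.statistic)

    @given(st.integers(0, 100))
    def test_matches_scipy_on_random_matrices(self, case):
        rng = np.random.default_rng(case)
        m = rng.normal(size=(5, 4))
        ours = fk.friedman(m)
        ref = scipy.stats.friedmanchisquare(*[m[:, j] for j in range(4)])
        assert ours.statistic == pytest.approx(ref.statistic)
        assert ours.p_value == pytest.approx(ref.pvalue)

    @given(st.integers(0, 30))
    def test_matches_brute_force_rank_computation(self, case):
        rng = np.random.default_rng(500 + case)
        m = rng.normal(size=(5, 4))
        n, k = m.shape
        rank_sums = np.zeros(k)
        for row in m:
            order = np.argsort(np.argsort(row))  # tie-free ranks 0..k-1
            rank_sums += order + 1
        q = 12.0 / (n * k * (k + 1)) * np.sum(rank_sums**2) - 3 * n * (k + 1)
        assert fk.friedman(m).statistic == pytest.approx(q)

    def test_missing_cells_rejected(self):
        m = np.ones((4, 4))
        m[1, 2] = np.nan
        with pytest.raises(ValueError, match="aggregate"):
            fk.friedman(m)


class TestBonferroni:
    def test_pair_count_and_multiplier(self):
        rng = np.random.default_rng(0)
        m = rng.normal(size=(6, 4))
        pairs = fk.bonferroni_posthoc(m)
        assert len(pairs) == 6
        for p in pairs:
            assert p["p_adjusted"] == pytest.approx(min(1.0, p["p_raw"] * 6))
            assert p["p_adjusted"] >= p["p_raw"]

    def test_identical_columns_never_flagged(self):
        m = np.tile(np.arange(5.0)[:, None], (1, 4))
        assert not any(p["significant"] for p in fk.bonferroni_posthoc(m))

    def test_strong_contrast_flagged_by_exact_test(self):
        rng = np.random.default_rng(2)
        base = rng.normal(100.0, 5.0, size=(8, 1))
        jitter = lambda: rng.normal(0.0, 0.5, size=(8, 1))
        m = np.hstack([base, base + jitter(), base + 30 + jitter(), base + 31 + jitter()])
        pairs = {(p["i"], p["j"]): p["significant"] for p in fk.bonferroni_posthoc(m)}
        assert pairs[(1, 3)] and pairs[(1, 4)] and pairs[(2, 3)]
        assert not pairs[(1, 2)]

    def test_rank_difference_variant_runs(self):
        rng = np.random.default_rng(4)
        m = rng.normal(size=(8, 4))
        cfg = fk.AnalysisConfig(posthoc="rank-difference")
        pairs = fk.bonferroni_posthoc(m, cfg)
        assert len(pairs) == 6
        assert all(p["p_adjusted"] >= p["p_raw"] for p in pairs)


class TestCliffsDelta:
    def test_worked_examples(self):
        assert fk.cliffs_delta([1, 2, 3], [1, 2, 3]).delta == 0.0
        assert fk.cliffs_delta([10, 11], [1, 2]).delta == 1.0
        assert fk.cliffs_delta([3, 4, 5], [1, 2, 3]).delta == pytest.approx(8 / 9)

    @given(st.integers(0, 200))
    def test_matches_brute_force_pair_counting(self, case):
        rng = np.random.default_rng(case)
        x = rng.integers(0, 6, size=int(rng.integers(2, 9))).astype(float)
        y = rng.integers(0, 6, size=int(rng.integers(2, 9))).astype(float)
        gt = sum(1 for a in x for b in y if a > b)
        lt = sum(1 for a in x for b in y if a < b)
        expect = (gt - lt) / (x.size * y.size)
        res = fk.cliffs_delta(x, y)
        assert res.delta == pytest.approx(expect)
        assert fk.cliffs_delta(y, x).delta == pytest.approx(-expect)
        assert -1.0 <= res.delta <= 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fk.cliffs_delta([], [1.0])


class TestDescriptives:
    def test_quartile_rule_on_worked_sample(self):
        # linear interpolation at (n-1)p+1: [1..5] -> Q1=2, Q3=4
        assert fk.quartiles([1, 2, 3, 4, 5]) == (2.0, 3.0, 4.0)
        assert fk.median_iqr([1, 2, 3, 4, 5]) == (3.0, 2.0)
        assert fk.median_iqr([5]) == (5.0, 0.0)
        assert fk.cqv([1, 2, 3, 4, 5]) == pytest.approx(100 * 2 / 6)

    def test_cqv_scale_invariance_and_constant(self, rng):
        x = rng.uniform(10, 20, 25)
        assert fk.cqv(3.7 * x) == pytest.approx(fk.cqv(x))
        assert fk.cqv(np.full(6, 4.2)) == 0.0

    def test_cqv_domain_error(self):
        with pytest.raises(ValueError):
            fk.cqv([-5.0, -4.0, 4.0, 5.0])

    def test_median_iqr_permutation_invariance(self, rng):
        x = rng.normal(size=11)
        assert fk.median_iqr(x) == fk.median_iqr(np.sort(x)[::-1])

    def test_normalized_variation(self):
        assert fk.normalized_variation(400.0, 340.0) == pytest.approx(-15.0)
        assert fk.normalized_variation(7.0, 7.0) == 0.0
        with pytest.raises(ValueError):
            fk.normalized_variation(0.0, 1.0)


class TestKsNormality:
    def test_statistic_matches_grid_oracle(self):
        x = np.array([1.0, 1.0, 1.0, 2.0])
        d = float(_ks_stat_fitted_normal(x))
        mu, sd = x.mean(), x.std(ddof=1)
        grid = np.linspace(-5, 8, 400_001)
        emp = np.searchsorted(np.sort(x), grid, side="right") / x.size
        theo = scipy.stats.norm.cdf((grid - mu) / sd)
        assert d == pytest.approx(np.max(np.abs(emp - theo)), abs=1e-3)

    def test_monte_carlo_p_reproducible_and_calibrated(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        cfg = fk.AnalysisConfig(ks_mc_replicates=2000)
        a = fk.ks_normality(x, cfg, seed=42)
        b = fk.ks_normality(x, cfg, seed=42)
        assert a.p_value == b.p_value
        assert a.p_value > 0.05  # sample truly normal

    def test_detects_gross_non_normality(self):
        x = np.concatenate([np.zeros(20), np.ones(20)])
        x = x + np.linspace(0, 1e-6, 40)  # break exact ties, keep bimodality
        cfg = fk.AnalysisConfig(ks_mc_replicates=2000)
        assert fk.ks_normality(x, cfg, seed=0).p_value < 0.01

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError):
            fk.ks_normality(np.ones(10))
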