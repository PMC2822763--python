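"""Enrichment statistics against independent oracles.

Oracles here are deliberately naive: direct pmf summation for tails,
exhaustive draws for the hypergeometric, full permutation enumeration
for the correlation test, and the step-up formula written out for BH.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from concordtf.stats import (
    BinomialEnrichment,
    DegenerateProfileError,
    HypergeomOverlap,
    bh_qvalues,
    binomial_upper_tail,
    fisher_enrichment,
    hypergeom_overlap_pvalue,
    pearson_r,
    permutation_corr_pvalue,
)


def binom_tail_oracle(n_obs, n_trials, p, strict):
    pmf = lambda k: math.comb(n_trials, k) * p**k * (1 - p) ** (n_trials - k)
    lo = n_obs + 1 if strict else n_obs
    return sum(pmf(k) for k in range(lo, n_trials + 1))


class TestBinomial:
    def test_liver_worked_example_strict_tail(self):
        # 30 of 162 liver pairs land in the 820-pair liver-specific subset
        # of the 23,005-pair universe; the strict upper tail reproduces
        # the published 2.3e-14 to two significant figures.
        p = binomial_upper_tail(
            BinomialEnrichment(30, 162, 820 / 23005, strict_tail=True)
        )
        assert p == pytest.approx(2.3e-14, rel=0.05)

    def test_inclusive_tail_matches_brute_force(self):
        spec = BinomialEnrichment(2, 3, 0.5, strict_tail=False)
        assert binomial_upper_tail(spec) == pytest.approx(0.5, abs=1e-12)

    def test_zero_observed_inclusive_is_one(self):
        assert binomial_upper_tail(BinomialEnrichment(0, 50, 0.123)) == 1.0

    @given(
        n_trials=st.integers(1, 40),
        p=st.floats(0.01, 0.99),
        data=st.data(),
    )
    @settings(max_examples=60, deadline=None)
    def test_tail_conventions_differ_by_pmf(self, n_trials, p, data):
        n_obs = data.draw(st.integers(0, n_trials))
        strict = binomial_upper_tail(BinomialEnrichment(n_obs, n_trials, p, True))
        incl = binomial_upper_tail(BinomialEnrichment(n_obs, n_trials, p, False))
        pmf = math.comb(n_trials, n_obs) * p**n_obs * (1 - p) ** (n_trials - n_obs)
        assert strict + pmf == pytest.approx(incl, rel=1e-12, abs=1e-300)

    @given(n_trials=st.integers(1, 25), p=st.floats(0.05, 0.95), data=st.data())
    @settings(max_examples=40, deadline=None)
    def test_matches_pmf_summation_oracle(self, n_trials, p, data):
        n_obs = data.draw(st.integers(0, n_trials))
        for strict in (True, False):
            got = binomial_upper_tail(
                BinomialEnrichment(n_obs, n_trials, p, strict)
            )
            assert got == pytest.approx(
                binom_tail_oracle(n_obs, n_trials, p, strict), rel=1e-9, abs=1e-15
            )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            BinomialEnrichment(5, 3, 0.5)
        with pytest.raises(ValueError):
            BinomialEnrichment(1, 3, 1.5)


def hypergeom_oracle(c, N, S1, S2):
    """Exhaustive enumeration over all draws of S2 items from N."""
    items = range(N)
    set1 = set(range(S1))
    hits = sum(
        1 for draw in itertools.combinations(items, S2) if len(set1 & set(draw)) >= c
    )
    return hits / math.comb(N, S2)


class TestHypergeomAndFisher:
    def test_complete_overlap_of_halves(self):
        p = hypergeom_overlap_pvalue(HypergeomOverlap(5, 10, 5, 5))
        assert p == pytest.approx(1 / 252, rel=1e-12)

    def test_zero_overlap_is_certain(self):
        assert hypergeom_overlap_pvalue(HypergeomOverlap(0, 30, 10, 7)) == 1.0

    @pytest.mark.parametrize(
        "c,N,S1,S2",
        [(8, 20, 10, 10), (3, 12, 5, 6), (1, 9, 3, 3), (4, 15, 7, 4)],
    )
    def test_matches_exhaustive_enumeration(self, c, N, S1, S2):
        got = hypergeom_overlap_pvalue(HypergeomOverlap(c, N, S1, S2))
        assert got == pytest.approx(hypergeom_oracle(c, N, S1, S2), rel=1e-9)

    def test_overlap_larger_than_sets_rejected(self):
        with pytest.raises(ValueError):
            HypergeomOverlap(6, 10, 5, 5)

    def test_fisher_small_table(self):
        assert fisher_enrichment(2, 2, 2, 4) == pytest.approx(1 / 6, rel=1e-12)
        assert fisher_enrichment(0, 5, 5, 20) == 1.0
        assert fisher_enrichment(1, 1, 1, 10) == pytest.approx(0.1, rel=1e-12)

    def test_fisher_equals_scipy_one_sided(self):
        from scipy.stats import fisher_exact

        k, n, K, N = 7, 20, 30, 100
        table = [[k, n - k], [K - k, N - n - K + k]]
        assert fisher_enrichment(k, n, K, N) == pytest.approx(
            fisher_exact(table, alternative="greater")[1], rel=1e-9
        )

    def test_fisher_margin_errors(self):
        with pytest.raises(ValueError):
            fisher_enrichment(5, 3, 10, 20)


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(1, 11)
        assert pearson_r(x, x) == 1.0
        assert pearson_r(x, x[::-1]) == -1.0

    def test_hand_computed_covariance(self):
        x, y = [1, 2, 3, 5], [2, 2, 4, 5]
        xm, ym = sum(x) / 4, sum(y) / 4
        cov = sum((a - xm) * (b - ym) for a, b in zip(x, y))
        sx = math.sqrt(sum((a - xm) ** 2 for a in x))
        sy = math.sqrt(sum((b - ym) ** 2 for b in y))
        assert pearson_r(x, y) == pytest.approx(cov / (sx * sy), rel=1e-12)

    def test_constant_vector_raises(self):
        with pytest.raises(DegenerateProfileError):
            pearson_r([1, 1, 1, 1], [1, 2, 3, 4])


def perm_oracle(x, y):
    """Exhaustive permutation p-value for positive correlation."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    r_obs = pearson_r(x, y)
    rs = [
        pearson_r(x, y[list(p)]) for p in itertools.permutations(range(len(y)))
    ]
    return sum(r >= r_obs - 1e-9 for r in rs) / len(rs)


class TestPermutation:
    def test_identity_vectors_exhaustive(self):
        # only the identity permutation of (1,2,3) reaches r = 1
        assert permutation_corr_pvalue([1, 2, 3], [1, 2, 3]) == pytest.approx(1 / 6)

    @pytest.mark.parametrize(
        "x,y",
        [([1, 2, 3, 4], [2, 1, 4, 3]), ([1, 2, 3, 5, 4], [5, 3, 1, 2, 4])],
    )
    def test_exhaustive_branch_matches_oracle(self, x, y):
        assert permutation_corr_pvalue(x, y) == pytest.approx(perm_oracle(x, y))

    def test_sampling_branch_agrees_with_enumeration(self):
        # length-7 vectors: the sampled estimate must sit within 3 sigma of
        # the exact enumeration over all 5040 pairings
        rng = np.random.default_rng(5)
        x = rng.random(7)
        y = x + rng.normal(0, 0.5, 7)
        exact = perm_oracle(x, y)
        n_perm = 100_000
        est = permutation_corr_pvalue(x, y, n_perm=n_perm, seed=42)
        sigma = math.sqrt(exact * (1 - exact) / n_perm)
        assert abs(est - exact) < 3 * sigma + 1 / n_perm

    def test_bounded_below_and_deterministic(self):
        rng = np.random.default_rng(0)
        x, y = rng.random(10), rng.random(10)
        p1 = permutation_corr_pvalue(x, y, n_perm=999, seed=7)
        p2 = permutation_corr_pvalue(x, y, n_perm=999, seed=7)
        assert p1 == p2
        assert 1 / 1000 <= p1 <= 1.0

    def test_low_n_perm_warns(self):
        with pytest.warns(UserWarning):
            permutation_corr_pvalue(
                np.arange(10.0), np.arange(10.0) ** 2, n_perm=50, seed=0
            )


def bh_oracle(pvals):
    """Step-up formula: q_(i) = min_{j>=i} m p_(j) / j, in input order."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.minimum.accumulate(
        (m * p[order] / np.arange(1, m + 1))[::-1]
    )[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q_sorted, 1.0)
    return out


class TestBH:
    def test_uniform_spacing_example(self):
        got = bh_qvalues([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_single_value_passthrough(self):
        assert bh_qvalues([0.5])[0] == pytest.approx(0.5)

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40)
    )
    @settings(max_examples=80, deadline=None)
    def test_matches_step_up_formula_and_never_decreases(self, pvals):
        got = bh_qvalues(pvals)
        assert np.allclose(got, bh_oracle(pvals), atol=1e-12)
        assert np.all(got >= np.asarray(pvals) - 1e-12)
        assert np.all((got >= 0) & (got <= 1))

    def test_idempotent_on_adjusted_monotone_input(self):
        # evenly spaced p-values adjust to a constant vector, which is a
        # fixed point of the step-up procedure
        q = bh_qvalues([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(bh_qvalues(q), q)
        q2 = bh_qvalues([0.3, 0.3, 0.3])
        assert np.allclose(bh_qvalues(q2), q2)

    def test_empty_input(self):
        assert bh_qvalues([]).size == 0


class TestPermutationAlternatives:
    def test_two_sided_counts_absolute_correlations(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [4.0, 3.0, 2.0, 1.0]  # r = -1
        one = permutation_corr_pvalue(x, y, alternative="greater")
        two = permutation_corr_pvalue(x, y, alternative="two-sided")
        assert one == pytest.approx(1.0)  # every pairing beats r = -1
        assert two == pytest.approx(2 / 24)  # |r| = 1 at the two extremes

    def test_unknown_alternative_rejected(self):
        with pytest.raises(ValueError):
            permutation_corr_pvalue([1, 2, 3], [1, 2, 3], alternative="less")
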