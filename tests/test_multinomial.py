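import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import multinomial as scipy_multinomial

from donorpanel import (
    InvalidInputError,
    marginal_moments,
    marginal_tail,
    multinomial_pmf,
    sample_allocation,
)

from conftest import profile_from_probs


def compositions(total, parts):
    for cuts in itertools.combinations(range(total + parts - 1), parts - 1):
        yield np.diff(np.concatenate(([-1], cuts, [total + parts - 1]))) - 1


class TestPmf:
    def test_single_category_is_certain(self):
        profile = profile_from_probs([1.0])
        assert multinomial_pmf(np.array([5]), profile) == pytest.approx(1.0)

    def test_closed_form_small_case(self):
        profile = profile_from_probs([0.5, 0.3, 0.2])
        # 4!/(2! 1! 1!) * 0.25 * 0.3 * 0.2 = 0.18
        assert multinomial_pmf(np.array([2, 1, 1]), profile) == pytest.approx(0.18)

    @pytest.mark.parametrize("r,S", [(2, 8), (3, 4), (4, 6)])
    def test_normalization_over_all_compositions(self, r, S):
        rng = np.random.default_rng(r * 100 + S)
        profile = profile_from_probs(rng.dirichlet(np.ones(r)))
        total = sum(multinomial_pmf(n, profile) for n in compositions(S, r))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            r = int(rng.integers(2, 6))
            p = rng.dirichlet(np.ones(r))
            profile = profile_from_probs(p)
            n = rng.multinomial(int(rng.integers(1, 40)), p)
            expected = scipy_multinomial(int(n.sum()), p).pmf(n)
            assert multinomial_pmf(n, profile) == pytest.approx(expected, rel=1e-10)

    def test_stable_at_large_cohort(self):
        profile = profile_from_probs([0.41, 0.39, 0.20])
        S = 200_000
        n = np.array([82_000, 78_000, 40_000])
        value = multinomial_pmf(n, profile)
        assert 0.0 < value < 1.0 and np.isfinite(value)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            multinomial_pmf(np.array([1, 2]), profile_from_probs([1.0]))


class TestMarginalMoments:
    def test_formula(self):
        profile = profile_from_probs([0.41, 0.59])
        mm = marginal_moments(100, profile)
        assert mm.expectation[0] == pytest.approx(41.0)
        assert mm.variance[0] == pytest.approx(24.19)

    def test_degenerate_category(self):
        mm = marginal_moments(50, profile_from_probs([1.0]))
        assert mm.expectation[0] == 50.0 and mm.variance[0] == 0.0

    def test_expectations_sum_to_S(self):
        rng = np.random.default_rng(3)
        profile = profile_from_probs(rng.dirichlet(np.ones(7)))
        mm = marginal_moments(123, profile)
        assert mm.expectation.sum() == pytest.approx(123.0, abs=1e-6)
        assert (mm.variance >= 0).all()

    def test_sampled_mean_matches_theory(self):
        profile = profile_from_probs([0.41, 0.39, 0.20])
        S, n_draws = 100, 10_000
        rng = np.random.default_rng(42)
        draws = np.array(
            [sample_allocation(S, profile, rng=rng).counts for _ in range(n_draws)]
        )
        mm = marginal_moments(S, profile)
        se = np.sqrt(mm.variance / n_draws)
        assert (np.abs(draws.mean(axis=0) - mm.expectation) < 4 * se).all()


class TestMarginalTail:
    def test_zero_target_is_vacuous(self):
        assert marginal_tail(10, 0.3, 0) == (0.0, 1.0)

    def test_single_term_cdf(self):
        below, at_or_above = marginal_tail(4, 0.5, 1)
        assert below == pytest.approx(0.0625)
        assert at_or_above == pytest.approx(0.9375)

    def test_matches_direct_summation(self):
        from math import comb

        S, p, k = 20, 0.3, 5
        expected = sum(
            comb(S, j) * p**j * (1 - p) ** (S - j) for j in range(k)
        )
        below, _ = marginal_tail(S, p, k)
        assert below == pytest.approx(expected, rel=1e-12)

    def test_unreachable_target(self):
        assert marginal_tail(5, 0.9, 6) == (1.0, 0.0)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        S=st.integers(1, 200),
        p=st.floats(0.0, 1.0),
        k=st.integers(0, 210),
    )
    def test_split_is_exact_complement(self, S, p, k):
        below, at_or_above = marginal_tail(S, p, k)
        assert below + at_or_above == 1.0
        assert 0.0 <= below <= 1.0


class TestSampling:
    def test_degenerate_distribution(self):
        profile = profile_from_probs([1.0 - 1e-12, 5e-13, 5e-13])
        counts = sample_allocation(10, profile, seed=0).counts
        assert counts[0] == 10

    def test_conservation_and_reproducibility(self):
        profile = profile_from_probs([0.2, 0.3, 0.5])
        a = sample_allocation(1000, profile, seed=99)
        b = sample_allocation(1000, profile, seed=99)
        assert a.S == 1000
        assert (a.counts == b.counts).all()
        assert a.seed == 99

    def test_two_category_split_frequency(self):
        # P[(1,1)] for S=2, p=(1/2,1/2) is exactly 1/2
        profile = profile_from_probs([0.5, 0.5])
        rng = np.random.default_rng(1)
        n_draws = 10_000
        hits = sum(
            (sample_allocation(2, profile, rng=rng).counts == 1).all()
            for _ in range(n_draws)
        )
        se = np.sqrt(0.25 / n_draws)
        assert abs(hits / n_draws - 0.5) < 4 * se
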