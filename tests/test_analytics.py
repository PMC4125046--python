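"""Tests of the exact accuracy analytics against independent oracles
(enumeration, fine grids, Monte-Carlo simulation)."""

import itertools

import numpy as np
import pytest

from colearn.analytics import (
    accuracy_landscape,
    bayes_upper_bound,
    collective_accuracy,
    collective_accuracy_hetero,
    global_optimal_accuracy,
    majority_prob,
    majority_prob_hetero,
    optimal_policy,
    regret_group_size_map,
    regret_reliability_map,
    stationarity_residual,
    threshold_accuracy,
)
from colearn.model import EnvironmentConfig

from conftest import mc_collective_accuracy


def enumerate_majority_prob(q):
    """Brute-force oracle: enumerate all 2^n correctness patterns."""
    q = np.asarray(q, float)
    n = q.size
    total = 0.0
    for pattern in itertools.product([0, 1], repeat=n):
        w = np.prod([qi if b else 1 - qi for qi, b in zip(q, pattern)])
        k = sum(pattern)
        total += w * (1.0 if 2 * k > n else 0.5 if 2 * k == n else 0.0)
    return total


class TestMajorityProb:
    def test_fair_coin_gives_half(self):
        for n in (1, 2, 3, 10, 11):
            assert majority_prob(0.5, n) == pytest.approx(0.5)

    def test_odd_n_matches_enumeration(self):
        assert majority_prob(0.7, 3) == pytest.approx(0.784)

    def test_even_n_tie_contributes_half(self):
        # n=2: q^2 + 0.5 * 2q(1-q) = q
        assert majority_prob(0.7, 2) == pytest.approx(0.7)

    def test_perfect_voters(self):
        assert majority_prob(1.0, 9) == pytest.approx(1.0)

    def test_large_n_is_stable(self):
        assert 0.0 <= majority_prob(0.51, 1001) <= 1.0
        assert majority_prob(0.6, 1001) > 0.999

    def test_monotone_in_competence(self):
        q = np.linspace(0, 1, 201)
        for n in (1, 2, 5, 12, 31):
            vals = majority_prob(q, n)
            assert (np.diff(vals) >= -1e-12).all()

    def test_monotone_in_group_size_for_competent_voters(self):
        """Condorcet: for q > 1/2 accuracy rises with odd group size."""
        for q in (0.55, 0.7, 0.9):
            vals = [majority_prob(q, n) for n in range(1, 32, 2)]
            assert (np.diff(vals) >= -1e-12).all()


class TestHeteroMajority:
    def test_reduces_to_homogeneous_case(self):
        for q, n in [(0.7, 3), (0.6, 8), (0.55, 15)]:
            assert majority_prob_hetero(np.full(n, q)) == pytest.approx(
                majority_prob(q, n), abs=1e-12
            )

    def test_single_competent_voter_loses_majority(self):
        assert majority_prob_hetero(np.array([1.0, 0.0, 0.0])) == 0.0

    def test_matches_exhaustive_enumeration(self):
        for q in ([0.9, 0.6, 0.5], [0.8, 0.7], [0.51, 0.62, 0.73, 0.84]):
            assert majority_prob_hetero(np.array(q)) == pytest.approx(
                enumerate_majority_prob(q), abs=1e-12
            )

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            majority_prob_hetero(np.array([]))


class TestCollectiveAccuracy:
    def test_exclusive_high_cue_gives_flat_r_high(self):
        """Using only the shared cue, accuracy equals r_high for every
        group size — no wisdom of crowds from a single shared draw."""
        env = EnvironmentConfig(0.7, 0.8)
        for n in (1, 2, 5, 16, 31, 101):
            assert collective_accuracy(0.0, n, env) == pytest.approx(0.8, abs=1e-12)

    def test_exclusive_low_cue_is_condorcet(self, env):
        for n in (1, 4, 7, 31):
            assert collective_accuracy(1.0, n, env) == pytest.approx(
                majority_prob(env.r_low, n), abs=1e-12
            )

    def test_three_voter_mixed_strategy_value(self, env):
        # hand enumeration: 0.8*M(0.85,3) + 0.2*M(0.35,3)
        assert collective_accuracy(0.5, 3, env) == pytest.approx(0.80775)

    def test_single_voter_interpolates_linearly(self):
        env = EnvironmentConfig(0.6, 0.8)
        assert collective_accuracy(0.5, 1, env) == pytest.approx(0.70)
        land = accuracy_landscape(1, env, 101)
        assert np.abs(np.diff(land.accuracy, 2)).max() < 1e-10

    @pytest.mark.parametrize("p", [0.0, 0.5, 0.9])
    @pytest.mark.parametrize("n", [1, 4, 11])
    @pytest.mark.parametrize("cfg", [(0.6, 0.9), (0.7, 0.8), (0.9, 0.55)])
    def test_matches_monte_carlo_oracle(self, rng, p, n, cfg):
        """Analytic accuracy agrees with a 1e5-trial simulation of the raw
        generative model within 3 binomial SE."""
        env = EnvironmentConfig(*cfg)
        exact = collective_accuracy(p, n, env)
        trials = 100_000
        mc = mc_collective_accuracy(p, n, env, trials, rng)
        se = np.sqrt(exact * (1 - exact) / trials)
        assert abs(mc - exact) < 3 * se + 1e-12

    def test_hetero_reduces_to_homogeneous(self, env):
        for p, n in [(0.3, 3), (0.8, 10)]:
            assert collective_accuracy_hetero(np.full(n, p), env) == pytest.approx(
                collective_accuracy(p, n, env), abs=1e-12
            )

    def test_hetero_all_high_exclusive_gives_r_high(self, env):
        assert collective_accuracy_hetero(np.zeros(5), env) == pytest.approx(0.8)

    def test_hetero_matches_monte_carlo(self, rng):
        env = EnvironmentConfig(0.7, 0.8)
        p = np.array([1.0, 1.0, 0.0])
        exact = collective_accuracy_hetero(p, env)
        trials = 200_000
        superior = rng.integers(2, size=(trials, 1))
        high = np.where(rng.random((trials, 1)) < env.r_high, superior, 1 - superior)
        low = np.where(rng.random((trials, 3)) < env.r_low, superior, 1 - superior)
        conflict = low != high
        follow = rng.random((trials, 3)) < p
        votes = np.where(conflict & ~follow, high, low)
        votes_A = 3 - votes.sum(axis=1)
        coin = rng.integers(2, size=trials)
        chosen = np.where(2 * votes_A > 3, 0, np.where(2 * votes_A < 3, 1, coin))
        mc = (chosen == superior[:, 0]).mean()
        se = np.sqrt(exact * (1 - exact) / trials)
        assert abs(mc - exact) < 3 * se

    def test_length_mismatch_rejected(self, env):
        with pytest.raises(ValueError):
            collective_accuracy_hetero(np.array([[0.5, 0.5]]), env)


class TestLandscapeAndPolicy:
    def test_landscape_endpoints(self, env):
        land = accuracy_landscape(5, env, 101)
        assert land.p_grid[0] == 0.0 and land.p_grid[-1] == 1.0
        assert land.accuracy[0] == pytest.approx(env.r_high)
        assert land.accuracy[-1] == pytest.approx(majority_prob(env.r_low, 5))

    def test_isolated_individual_follows_more_reliable_cue(self):
        res = optimal_policy(1, EnvironmentConfig(0.6, 0.8))
        assert res.p_star == 0.0 and res.regime == "high_exclusive"
        assert res.a_star == pytest.approx(0.8)
        res2 = optimal_policy(1, EnvironmentConfig(0.8, 0.6))
        assert res2.p_star == 1.0 and res2.regime == "low_exclusive"

    def test_equal_reliabilities_favor_low_cue_in_groups(self):
        res = optimal_policy(3, EnvironmentConfig(0.7, 0.7))
        assert res.p_star == 1.0 and res.regime == "low_exclusive"
        assert res.a_star == pytest.approx(0.784)

    def test_mixed_strategy_witness_beats_exclusive_use(self, env):
        """For n=5, r_low=0.7, r_high=0.8 the interior optimum beats both
        exclusive strategies; checked against a fine independent grid."""
        res = optimal_policy(5, env)
        assert res.regime == "mixed"
        grid = np.linspace(0, 1, 10_001)
        vals = collective_accuracy(grid, 5, env)
        assert res.a_star >= vals.max() - 1e-9
        assert res.a_star > collective_accuracy(0.0, 5, env)
        assert res.a_star > collective_accuracy(1.0, 5, env)
        assert res.p_star == pytest.approx(grid[vals.argmax()], abs=1e-3)

    def test_interior_optimum_satisfies_stationarity(self, env):
        res = optimal_policy(5, env)
        assert abs(stationarity_residual(res.p_star, 5, env)) < 1e-5

    @pytest.mark.parametrize(
        "n,cfg", [(5, (0.7, 0.8)), (11, (0.6, 0.9)), (2, (0.75, 0.85)), (31, (0.55, 0.95))]
    )
    def test_optimizer_dominates_fine_grid(self, n, cfg):
        env = EnvironmentConfig(*cfg)
        res = optimal_policy(n, env)
        grid = np.linspace(0, 1, 10_001)
        assert res.a_star >= collective_accuracy(grid, n, env).max() - 1e-9


class TestBenchmarks:
    def test_single_voter_all_rules_coincide(self):
        env = EnvironmentConfig(0.6, 0.8)
        b = global_optimal_accuracy(1, env)
        assert b.restricted_accuracy == pytest.approx(0.8, abs=1e-9)
        assert b.global_accuracy == pytest.approx(0.8, abs=1e-9)
        assert b.bayes_bound == pytest.approx(0.8, abs=1e-12)

    def test_bayes_weight_enumeration_two_voters(self):
        # 2 ln(0.6/0.4) < ln(0.9/0.1): the shared signal always dominates
        assert bayes_upper_bound(2, EnvironmentConfig(0.6, 0.9)) == pytest.approx(0.9)

    def test_bayes_bound_matches_enumeration(self, env):
        """Independent oracle: enumerate correct-low-vote counts and apply
        the log-odds decision rule directly."""
        n = 5
        w_l = np.log(0.7 / 0.3)
        w_h = np.log(0.8 / 0.2)
        total = 0.0
        for k in range(n + 1):
            from scipy.stats import binom
            wk = binom.pmf(k, n, 0.7)
            margin = (2 * k - n) * w_l
            for high_ok, w in ((True, 0.8), (False, 0.2)):
                x = margin + (w_h if high_ok else -w_h)
                total += wk * w * (1.0 if x > 0 else 0.5 if x == 0 else 0.0)
        assert bayes_upper_bound(n, env) == pytest.approx(total, abs=1e-12)
        assert bayes_upper_bound(n, env) == pytest.approx(0.88102, abs=1e-5)

    def test_perfect_cue_saturates_bound(self):
        assert bayes_upper_bound(3, EnvironmentConfig(1.0, 0.8)) == 1.0

    @pytest.mark.parametrize("n", [1, 2, 5, 8, 13])
    @pytest.mark.parametrize("cfg", [(0.6, 0.9), (0.7, 0.8), (0.9, 0.6)])
    def test_benchmark_ordering(self, n, cfg):
        b = global_optimal_accuracy(n, EnvironmentConfig(*cfg))
        assert b.restricted_accuracy <= b.global_accuracy + 1e-12
        assert b.global_accuracy <= b.bayes_bound + 1e-12

    def test_threshold_accuracy_at_simple_majority_matches(self, env):
        for p in (0.0, 0.4, 1.0):
            assert threshold_accuracy(p, 5, 3, env) == pytest.approx(
                collective_accuracy(p, 5, env), abs=1e-12
            )

    def test_bounded_by_restricted_and_bayes(self, env):
        b = global_optimal_accuracy(5, env)
        assert 0.8477 <= b.global_accuracy <= 0.88102 + 1e-5


class TestRegretMaps:
    def test_diagonal_is_zero_and_entries_nonpositive(self, env):
        m = regret_group_size_map(env, [1, 7, 31], [1, 7, 31])
        assert np.allclose(np.diag(m), 0.0, atol=1e-12)
        assert (m <= 1e-12).all()

    def test_large_group_size_changes_cost_more(self, env):
        m = regret_group_size_map(env, [1, 21], [31])
        assert abs(m[0, 0]) > abs(m[1, 0])

    def test_reliability_map_nonpositive_with_zero_diagonal(self):
        grid = [0.6, 0.75, 0.9]
        m = regret_reliability_map(11, 0.8, grid, grid)
        assert np.allclose(np.diag(m), 0.0, atol=1e-12)
        assert (m <= 1e-12).all()

    def test_drastic_reliability_changes_cost_more(self):
        m = regret_reliability_map(11, 0.8, [0.95, 0.75], [0.55, 0.70])
        assert abs(m[0, 0]) > abs(m[1, 1])
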