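"""Exact collective-accuracy analytics for two-cue consensus decisions.

Everything here is computed without simulation, by conditioning on whether
the shared high-correlation signal is correct.  Given a conflict-following
probability ``p`` (the chance an individual sides with its low-correlation
signal when the two cues disagree), each voter is independently correct with

* q1 = 1 - (1 - r_low) * p  when the shared signal is correct, and
* q0 = r_low * p            when it is wrong,

so the collective accuracy under simple majority rule is

    A(p) = r_high * M(q1, n) + (1 - r_high) * M(q0, n),

where M(q, n) is the Condorcet majority probability with ties broken at
random.  The module locates the optimal voting behavior p*, benchmarks it
against the globally optimal quorum rule and the full-information Bayes
bound, and maps the accuracy cost (regret) of context changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import binom

from .model import EnvironmentConfig

__all__ = [
    "PolicyResult",
    "Landscape",
    "BenchmarkResult",
    "majority_prob",
    "majority_prob_hetero",
    "collective_accuracy",
    "collective_accuracy_hetero",
    "threshold_accuracy",
    "accuracy_landscape",
    "optimal_policy",
    "global_optimal_accuracy",
    "bayes_upper_bound",
    "regret_group_size_map",
    "regret_reliability_map",
]

#: p* within this distance of a boundary is classified as an exclusive regime.
REGIME_TOL = 1e-6


@dataclass(frozen=True)
class PolicyResult:
    """Optimal conflict-following probability and the accuracy it attains.

    ``regime`` is ``low_exclusive`` (p* = 1: rely only on the
    low-correlation cue), ``high_exclusive`` (p* = 0) or ``mixed``.
    """

    p_star: float
    a_star: float
    regime: str


@dataclass(frozen=True)
class Landscape:
    """Collective accuracy evaluated on a grid of voting behaviors."""

    p_grid: np.ndarray
    accuracy: np.ndarray


@dataclass(frozen=True)
class BenchmarkResult:
    """Accuracy of simple majority with optimal p, of the best joint
    (p, quorum threshold) rule, and the full-information Bayes bound."""

    restricted_accuracy: float
    global_accuracy: float
    bayes_bound: float


# ---------------------------------------------------------------------------
# Majority kernels
# ---------------------------------------------------------------------------


def majority_prob(q, n: int):
    """Probability that a majority of ``n`` independent voters, each correct
    with probability ``q``, is correct; even-n ties contribute 1/2.

    Accepts scalar or array ``q`` and is numerically stable for n up to
    at least 10^3 (survival/cdf functions are evaluated in scipy's
    regularized-incomplete-beta form rather than by naive summation).
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    q = np.asarray(q, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ValueError("q must lie in [0, 1]")
    half = n // 2
    if n % 2:
        out = binom.sf(half, n, q)  # P(K >= (n+1)/2)
    else:
        out = binom.sf(half, n, q) + 0.5 * binom.pmf(half, n, q)
    return out if out.ndim else float(out)


def majority_prob_hetero(q: np.ndarray) -> float:
    """Exact majority probability for voters with heterogeneous competences
    (Poisson-binomial), via O(n^2) dynamic programming over the number of
    correct votes; ties get weight 1/2."""
    q = np.asarray(q, dtype=float)
    if q.ndim != 1 or q.size == 0:
        raise ValueError("q must be a non-empty 1-D vector")
    if np.any((q < 0) | (q > 1)):
        raise ValueError("q must lie in [0, 1]")
    n = q.size
    dist = np.zeros(n + 1)
    dist[0] = 1.0
    for i, qi in enumerate(q):
        upper = i + 1
        dist[1 : upper + 1] = dist[1 : upper + 1] * (1 - qi) + dist[:upper] * qi
        dist[0] *= 1 - qi
    k = np.arange(n + 1)
    prob = dist[k > n / 2].sum()
    if n % 2 == 0:
        prob += 0.5 * dist[n // 2]
    return float(prob)


# ---------------------------------------------------------------------------
# Collective accuracy
# ---------------------------------------------------------------------------


def _conditional_competences(p, env: EnvironmentConfig):
    p = np.asarray(p, dtype=float)
    q1 = 1.0 - (1.0 - env.r_low) * p
    q0 = env.r_low * p
    return q1, q0


def collective_accuracy(p, n: int, env: EnvironmentConfig):
    """Probability the group's simple-majority decision picks the superior
    option, for conflict-following probability ``p`` (scalar or array)."""
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr < 0) | (p_arr > 1)):
        raise ValueError("p must lie in [0, 1]")
    q1, q0 = _conditional_competences(p_arr, env)
    out = env.r_high * majority_prob(q1, n) + (1 - env.r_high) * majority_prob(q0, n)
    out = np.asarray(out)
    return out if out.ndim else float(out)


def collective_accuracy_hetero(p: np.ndarray, env: EnvironmentConfig) -> float:
    """Collective accuracy for a group whose members have individual
    conflict-following probabilities ``p_i`` (length = group size)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a non-empty 1-D vector (one entry per member)")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p must lie in [0, 1]")
    q1, q0 = _conditional_competences(p, env)
    return env.r_high * majority_prob_hetero(q1) + (1 - env.r_high) * majority_prob_hetero(q0)


def threshold_accuracy(p, n: int, m: int, env: EnvironmentConfig):
    """Exact accuracy of the quorum rule: the group adopts an option only if
    it receives at least ``m`` votes (supermajority, m > n/2); unresolved
    trials are decided uniformly at random."""
    if not (n / 2 < m <= n):
        raise ValueError(f"supermajority threshold m={m} must satisfy n/2 < m <= n")
    p_arr = np.asarray(p, dtype=float)
    q1, q0 = _conditional_competences(p_arr, env)

    def correct_prob(q):
        # correct iff >= m correct votes; wrong iff <= n - m; else coin flip
        win = binom.sf(m - 1, n, q)
        lose = binom.cdf(n - m, n, q)
        return win + 0.5 * (1.0 - win - lose)

    out = env.r_high * correct_prob(q1) + (1 - env.r_high) * correct_prob(q0)
    out = np.asarray(out)
    return out if out.ndim else float(out)


def accuracy_landscape(
    n: int, env: EnvironmentConfig, resolution: int = 1001
) -> Landscape:
    """Evaluate the accuracy curve A(p) on a uniform grid over [0, 1]."""
    if resolution < 10:
        raise ValueError("resolution must be at least 10 points")
    p_grid = np.linspace(0.0, 1.0, resolution)
    return Landscape(p_grid, np.asarray(collective_accuracy(p_grid, n, env)))


# ---------------------------------------------------------------------------
# Optimal policy
# ---------------------------------------------------------------------------

_GRID_STEP = 1e-3


def _maximize_on_unit_interval(f, grid_step: float = _GRID_STEP):
    """Coarse vectorized grid search followed by bounded local refinement."""
    grid = np.linspace(0.0, 1.0, int(round(1 / grid_step)) + 1)
    vals = np.asarray(f(grid))
    i = int(np.argmax(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    best_p, best_a = float(grid[i]), float(vals[i])
    if hi > lo:
        res = minimize_scalar(
            lambda x: -float(f(x)),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-8},
        )
        if -res.fun >= best_a:
            best_p, best_a = float(res.x), float(-res.fun)
    return best_p, best_a


def optimal_policy(
    n: int, env: EnvironmentConfig, tol: float = REGIME_TOL
) -> PolicyResult:
    """Locate the voting behavior p* maximizing simple-majority collective
    accuracy, and classify the regime (exclusive low cue / mixed /
    exclusive high cue)."""
    if not (0 < tol <= 1e-3):
        raise ValueError("tol must lie in (0, 1e-3]")
    p_star, a_star = _maximize_on_unit_interval(
        lambda p: collective_accuracy(p, n, env)
    )
    # the boundaries are frequent optima; snap when they dominate
    for p_bound in (0.0, 1.0):
        a_bound = collective_accuracy(p_bound, n, env)
        if a_bound >= a_star - 1e-13:
            if a_bound >= a_star or abs(p_star - p_bound) <= tol:
                p_star, a_star = p_bound, max(a_bound, a_star)
    if p_star >= 1.0 - tol:
        regime = "low_exclusive"
    elif p_star <= tol:
        regime = "high_exclusive"
    else:
        regime = "mixed"
    return PolicyResult(p_star, a_star, regime)


def stationarity_residual(p: float, n: int, env: EnvironmentConfig) -> float:
    """Residual of the interior first-order condition dA/dp = 0 for odd n:

        r_high (1-r_low) [q1(1-q1)]^((n-1)/2) = (1-r_high) r_low [q0(1-q0)]^((n-1)/2)

    Used as an independent check on numerically located interior optima.
    """
    if n % 2 == 0:
        raise ValueError("the closed-form stationarity condition assumes odd n")
    q1, q0 = _conditional_competences(p, env)
    half = (n - 1) // 2
    lhs = env.r_high * (1 - env.r_low) * (q1 * (1 - q1)) ** half
    rhs = (1 - env.r_high) * env.r_low * (q0 * (1 - q0)) ** half
    return float(lhs - rhs)


# ---------------------------------------------------------------------------
# Global benchmark
# ---------------------------------------------------------------------------


def global_optimal_accuracy(n: int, env: EnvironmentConfig) -> BenchmarkResult:
    """Benchmark simple majority (with optimal p) against the globally
    optimal quorum rule and the full-information Bayes bound.

    The global rule jointly optimizes the individual behavior p and an
    integer supermajority threshold m in [ceil((n+1)/2), n], with random
    deadlock resolution.  For any n the family contains simple majority,
    so restricted <= global <= bayes.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    restricted = optimal_policy(n, env).a_star
    best = restricted
    for m in range(math.ceil((n + 1) / 2), n + 1):
        _, a_m = _maximize_on_unit_interval(
            lambda p, m=m: threshold_accuracy(p, n, m, env)
        )
        best = max(best, a_m)
    return BenchmarkResult(restricted, best, bayes_upper_bound(n, env))


def bayes_upper_bound(n: int, env: EnvironmentConfig) -> float:
    """Accuracy of the full-information optimal aggregator that sees every
    signal and weighs it by its log-likelihood ratio (Nitzan–Paroush
    weighted majority): each low signal carries weight ln(r_low/(1-r_low)),
    the shared signal ln(r_high/(1-r_high)); exact ties are coin flips.

    A perfectly reliable cue carries infinite weight and dictates the
    decision, giving accuracy 1.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    r_l, r_h = env.r_low, env.r_high
    if r_l >= 1.0 or r_h >= 1.0:
        return 1.0
    w_l = math.log(r_l / (1 - r_l))
    w_h = math.log(r_h / (1 - r_h))
    k = np.arange(n + 1)
    weights = binom.pmf(k, n, r_l)

    def step(x):
        return np.where(x > 0, 1.0, np.where(x < 0, 0.0, 0.5))

    margin = (2 * k - n) * w_l
    acc = weights * (r_h * step(margin + w_h) + (1 - r_h) * step(margin - w_h))
    return float(acc.sum())


# ---------------------------------------------------------------------------
# Regret maps for context changes
# ---------------------------------------------------------------------------


def regret_group_size_map(
    env: EnvironmentConfig, n_start: list[int], n_end: list[int]
) -> np.ndarray:
    """Accuracy cost of carrying the behavior optimized for one group size
    into another.  Entry (i, j) = A(p*(n_start[i]); n_end[j]) -
    A(p*(n_end[j]); n_end[j]) <= 0."""
    p_star_start = [optimal_policy(ns, env).p_star for ns in n_start]
    out = np.empty((len(n_start), len(n_end)))
    for j, ne in enumerate(n_end):
        opt = optimal_policy(ne, env)
        for i, ps in enumerate(p_star_start):
            out[i, j] = collective_accuracy(ps, ne, env) - opt.a_star
    return out


def regret_reliability_map(
    n: int,
    r_high: float,
    r_low_start: list[float],
    r_low_end: list[float],
) -> np.ndarray:
    """Accuracy cost of carrying the behavior optimized for one low-cue
    reliability into another (r_high held fixed); entries are <= 0."""
    p_star_start = [
        optimal_policy(n, EnvironmentConfig(rs, r_high)).p_star for rs in r_low_start
    ]
    out = np.empty((len(r_low_start), len(r_low_end)))
    for j, re_ in enumerate(r_low_end):
        env_end = EnvironmentConfig(re_, r_high)
        opt = optimal_policy(n, env_end)
        for i, ps in enumerate(p_star_start):
            out[i, j] = collective_accuracy(ps, n, env_end) - opt.a_star
    return out
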