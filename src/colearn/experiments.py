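"""Simulation protocols: collective training runs, environment sweeps,
isolated-then-pooled comparisons, and group-size / reliability transitions.

All replicates of a run are simulated simultaneously as numpy arrays of
shape (replicates, groups, members); a "group" axis > 1 is used only while
several independent small groups are trained in parallel before being merged
into one large group (the fission–fusion transition protocol).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import analytics
from .model import (
    ConsensusRule,
    EnvironmentConfig,
    LearningConfig,
    VotingRule,
    decide_counts,
    follow_low_probability,
)

__all__ = [
    "Trajectory",
    "TransitionSpec",
    "run_training",
    "summarize_learned",
    "sweep_grid",
    "run_isolated_then_pooled",
    "run_transition",
]


@dataclass
class Trajectory:
    """Per-trial aggregates of a training run.

    mean_p
        Mean over agents, groups and replicates of the conflict-following
        probability implied by the current strengths.
    success
        Fraction of (replicate, group) decisions that picked the superior
        option on that trial.
    final_v_low / final_v_high
        Agent strengths at the end of the run, shape (replicates, members).
    """

    mean_p: np.ndarray
    success: np.ndarray
    final_v_low: np.ndarray
    final_v_high: np.ndarray

    @property
    def final_p(self) -> np.ndarray:
        return follow_low_probability(self.final_v_low, self.final_v_high, VotingRule())


@dataclass(frozen=True)
class TransitionSpec:
    """An abrupt context change during training.

    Either the group size changes (n_before -> n_after, same environment) or
    the low-cue reliability changes (env_before -> env_after, same group
    size).  The change happens after ``change_trial`` trials; training
    continues in the new context for the remainder of the run.
    """

    change_trial: int
    n_before: int
    n_after: int
    env_before: EnvironmentConfig
    env_after: EnvironmentConfig


# ---------------------------------------------------------------------------
# Core simulation kernel
# ---------------------------------------------------------------------------


class _SimState:
    """Mutable strength field for (reps, groups, members) learners."""

    def __init__(self, n_reps: int, n_groups: int, n: int, v_init: float):
        shape = (n_reps, n_groups, n)
        self.v_low = np.full(shape, v_init, dtype=float)
        self.v_high = np.full(shape, v_init, dtype=float)


def _simulate_phase(
    state: _SimState,
    env: EnvironmentConfig,
    n_trials: int,
    alpha: float,
    voting: VotingRule,
    consensus: ConsensusRule,
    rng: np.random.Generator,
    mean_p_out: np.ndarray,
    success_out: np.ndarray,
    p_window_sum: np.ndarray | None = None,
    window_start: int | None = None,
) -> None:
    """Advance every replicate/group by ``n_trials`` trials in place.

    If ``p_window_sum`` is given, per-agent conflict probabilities are
    accumulated into it for trials >= window_start (used for window-mean
    learned behavior per agent).
    """
    n_reps, n_groups, n = state.v_low.shape
    for t in range(n_trials):
        superior = rng.integers(2, size=(n_reps, n_groups))
        high = np.where(
            rng.random((n_reps, n_groups)) < env.r_high, superior, 1 - superior
        )
        low = np.where(
            rng.random((n_reps, n_groups, n)) < env.r_low,
            superior[..., None],
            1 - superior[..., None],
        )
        p = follow_low_probability(state.v_low, state.v_high, voting)
        conflict = low != high[..., None]
        follow_low = rng.random((n_reps, n_groups, n)) < p
        votes = np.where(conflict & ~follow_low, high[..., None], low)
        votes_A = n - votes.sum(axis=2)
        chosen = decide_counts(votes_A, n, consensus, rng)
        lam = (chosen == superior).astype(float)
        # gated Rescorla-Wagner update: shared error vs total strength
        chosen3 = chosen[..., None]
        low_hit = low == chosen3
        high_hit = (high == chosen)[..., None]
        err = lam[..., None] - (state.v_low + state.v_high)
        state.v_low = np.clip(
            state.v_low + np.where(low_hit, alpha * err, 0.0), 0.0, None
        )
        state.v_high = np.clip(
            state.v_high + np.where(high_hit, alpha * err, 0.0), 0.0, None
        )
        mean_p_out[t] = p.mean()
        success_out[t] = lam.mean()
        if p_window_sum is not None and t >= window_start:
            p_window_sum += follow_low_probability(
                state.v_low, state.v_high, VotingRule()
            )


def run_training(
    env: EnvironmentConfig,
    n: int,
    learning: LearningConfig = LearningConfig(),
    voting: VotingRule = VotingRule(),
    consensus: ConsensusRule = ConsensusRule(),
    seed: int | np.random.SeedSequence = 0,
) -> Trajectory:
    """Train ``learning.n_reps`` independent groups of ``n`` learners for
    ``learning.n_trials`` consensus trials each; reproducible given seed."""
    if n < 1:
        raise ValueError("group size must be at least 1")
    rng = np.random.default_rng(seed)
    state = _SimState(learning.n_reps, 1, n, learning.v_init)
    mean_p = np.empty(learning.n_trials)
    success = np.empty(learning.n_trials)
    _simulate_phase(
        state, env, learning.n_trials, learning.alpha, voting, consensus, rng,
        mean_p, success,
    )
    return Trajectory(mean_p, success, state.v_low[:, 0, :], state.v_high[:, 0, :])


def summarize_learned(
    trajectory: Trajectory, window: int
) -> tuple[float, float]:
    """Mean conflict-following probability and mean decision success over
    the final ``window`` trials."""
    if not (0 < window <= trajectory.mean_p.size):
        raise ValueError("window must satisfy 0 < window <= n_trials")
    return (
        float(trajectory.mean_p[-window:].mean()),
        float(trajectory.success[-window:].mean()),
    )


# ---------------------------------------------------------------------------
# Environment x group-size sweep
# ---------------------------------------------------------------------------


def _achieved_accuracy(traj: Trajectory, env: EnvironmentConfig) -> float:
    """Exact collective accuracy implied by the learned (end-of-run) agent
    strengths, averaged over replicates.

    Evaluating the analytic accuracy of each replicate's learned behavior
    (rather than the raw empirical success rate) matches how performance is
    summarized relative to the optimum and is guaranteed <= the optimal
    accuracy for every replicate.
    """
    p_final = traj.final_p
    return float(
        np.mean([analytics.collective_accuracy_hetero(row, env) for row in p_final])
    )


def sweep_grid(
    group_sizes: list[int],
    r_lows: list[float],
    r_highs: list[float],
    learning: LearningConfig = LearningConfig(),
    voting: VotingRule = VotingRule(),
    consensus: ConsensusRule = ConsensusRule(),
    seed: int = 0,
) -> pd.DataFrame:
    """Run one training experiment per (n, r_low, r_high) cell and join the
    learned behavior with the exact optimum for that cell.

    Returns a tidy frame with columns n, r_low, r_high, learned_p,
    achieved_accuracy, optimal_p, optimal_accuracy, fraction_of_max.
    """
    if not group_sizes or not r_lows or not r_highs:
        raise ValueError("grids must be non-empty")
    ss = np.random.SeedSequence(seed)
    cells = [(n, rl, rh) for n in group_sizes for rl in r_lows for rh in r_highs]
    rows = []
    for child, (n, rl, rh) in zip(ss.spawn(len(cells)), cells):
        env = EnvironmentConfig(rl, rh)
        traj = run_training(env, n, learning, voting, consensus, seed=child)
        learned_p, _ = summarize_learned(traj, learning.window)
        achieved = _achieved_accuracy(traj, env)
        opt = analytics.optimal_policy(n, env)
        rows.append(
            {
                "n": n,
                "r_low": rl,
                "r_high": rh,
                "learned_p": learned_p,
                "achieved_accuracy": achieved,
                "optimal_p": opt.p_star,
                "optimal_accuracy": opt.a_star,
                "fraction_of_max": achieved / opt.a_star,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Isolated learning, then pooled voting
# ---------------------------------------------------------------------------


def run_isolated_then_pooled(
    env: EnvironmentConfig,
    n: int,
    learning: LearningConfig = LearningConfig(),
    seed: int = 0,
) -> dict:
    """Train n individuals in isolation, freeze their learned behavior, and
    pool their votes into one group of n; compare against collective
    learning at the same (env, n) and against the optimum.

    Each replicate trains its own n isolated learners (n independent
    single-member groups), whose window-mean conflict probabilities are then
    pooled exactly via the heterogeneous accuracy computation.
    """
    if n < 1:
        raise ValueError("group size must be at least 1")
    ss = np.random.SeedSequence(seed)
    iso_seed, col_seed = ss.spawn(2)
    rng = np.random.default_rng(iso_seed)

    state = _SimState(learning.n_reps, n, 1, learning.v_init)
    mean_p = np.empty(learning.n_trials)
    success = np.empty(learning.n_trials)
    p_window = np.zeros_like(state.v_low)
    _simulate_phase(
        state, env, learning.n_trials, learning.alpha, VotingRule(),
        ConsensusRule(), rng, mean_p, success,
        p_window_sum=p_window, window_start=learning.n_trials - learning.window,
    )
    p_learned = p_window[:, :, 0] / learning.window  # (reps, n) per-agent means
    pooled = float(
        np.mean([analytics.collective_accuracy_hetero(row, env) for row in p_learned])
    )

    col_traj = run_training(env, n, learning, seed=col_seed)
    collective = _achieved_accuracy(col_traj, env)
    opt = analytics.optimal_policy(n, env)
    return {
        "n": n,
        "r_low": env.r_low,
        "r_high": env.r_high,
        "isolated_mean_p": float(p_learned.mean()),
        "pooled_accuracy": pooled,
        "collective_accuracy": collective,
        "optimal_accuracy": opt.a_star,
        "pooled_fraction_of_max": pooled / opt.a_star,
        "collective_fraction_of_max": collective / opt.a_star,
    }


# ---------------------------------------------------------------------------
# Dynamic transitions (fission-fusion and reliability change)
# ---------------------------------------------------------------------------


def run_transition(
    spec: TransitionSpec,
    learning: LearningConfig = LearningConfig(),
    voting: VotingRule = VotingRule(),
    consensus: ConsensusRule = ConsensusRule(),
    seed: int = 0,
) -> Trajectory:
    """Train through an abrupt context change.

    Phase 1 runs ``change_trial`` trials in the starting context.  For a
    group-size increase, ceil(n_after / n_before) independent groups are
    trained in parallel per replicate and merged (the first n_after members)
    at the change; for a decrease, a uniformly sampled subset of n_after
    members is kept.  For a reliability change, the same agents simply
    continue under the new environment.  Learning continues in phase 2.
    """
    if not (0 < spec.change_trial < learning.n_trials):
        raise ValueError("change_trial must lie strictly inside the run")
    n1, n2 = spec.n_before, spec.n_after
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be at least 1")
    rng = np.random.default_rng(seed)
    n_groups = math.ceil(n2 / n1) if n2 > n1 else 1
    state = _SimState(learning.n_reps, n_groups, n1, learning.v_init)
    mean_p = np.empty(learning.n_trials)
    success = np.empty(learning.n_trials)

    _simulate_phase(
        state, spec.env_before, spec.change_trial, learning.alpha,
        voting, consensus, rng, mean_p[: spec.change_trial],
        success[: spec.change_trial],
    )

    # context change: rebuild the strength field as (reps, 1, n_after)
    pool_low = state.v_low.reshape(learning.n_reps, n_groups * n1)
    pool_high = state.v_high.reshape(learning.n_reps, n_groups * n1)
    if n2 < pool_low.shape[1]:
        idx = np.argsort(rng.random(pool_low.shape), axis=1)[:, :n2]
        pool_low = np.take_along_axis(pool_low, idx, axis=1)
        pool_high = np.take_along_axis(pool_high, idx, axis=1)
    state2 = _SimState(learning.n_reps, 1, n2, learning.v_init)
    state2.v_low[:, 0, :] = pool_low[:, :n2]
    state2.v_high[:, 0, :] = pool_high[:, :n2]

    remaining = learning.n_trials - spec.change_trial
    _simulate_phase(
        state2, spec.env_after, remaining, learning.alpha, voting, consensus,
        rng, mean_p[spec.change_trial :], success[spec.change_trial :],
    )
    return Trajectory(mean_p, success, state2.v_low[:, 0, :], state2.v_high[:, 0, :])
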