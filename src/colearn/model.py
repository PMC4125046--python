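"""Generative model of two-cue consensus decision-making with associative learning.

A group of ``n`` individuals repeatedly chooses between two options (A/B).
On each trial one option is superior; individuals observe two binary cues:

* a *low observational-correlation* cue — every individual receives an
  independent draw that points to the superior option with probability
  ``r_low``;
* a *high observational-correlation* cue — a single shared draw, correct
  with probability ``r_high``.

Each individual keeps an associative strength for each cue and votes for the
option the cues indicate; conflicts are resolved probabilistically from the
strengths.  The group decides by majority (or an alternative consensus rule),
all members experience the shared outcome, and strengths are updated with a
Rescorla–Wagner prediction-error rule, gated so that only cues that indicated
the chosen option are updated.

Options are encoded as integers ``A = 0`` and ``B = 1`` throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "A",
    "B",
    "DEGENERACY_FLOOR",
    "EnvironmentConfig",
    "TrialObservations",
    "AgentState",
    "LearningConfig",
    "VotingRule",
    "ConsensusRule",
    "GroupState",
    "sample_trial",
    "p_from_strengths",
    "vote",
    "majority_decide",
    "threshold_decide",
    "logistic_consensus_decide",
    "update_strengths",
]

A: int = 0
B: int = 1

#: Below this total associative strength the voting probability degenerates
#: to 0/0 and is defined to be 1/2.
DEGENERACY_FLOOR: float = 1e-12


class ConfigurationError(ValueError):
    """An invalid model configuration value."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnvironmentConfig:
    """Cue reliabilities; each is the probability the cue indicates the
    truly superior option and must lie in [0.5, 1]."""

    r_low: float
    r_high: float

    def __post_init__(self) -> None:
        for name, r in (("r_low", self.r_low), ("r_high", self.r_high)):
            if not (0.5 <= r <= 1.0):
                raise ConfigurationError(
                    f"{name}={r!r} outside the admissible range [0.5, 1]"
                )


@dataclass(frozen=True)
class TrialObservations:
    """One trial's hidden state and signals.

    ``high_signal`` is shared by the whole group; ``low_signals`` holds one
    independent draw per individual.
    """

    superior: int
    high_signal: int
    low_signals: np.ndarray

    def __post_init__(self) -> None:
        sig = np.asarray(self.low_signals)
        if sig.ndim != 1 or sig.size < 1:
            raise ValueError("low_signals must be a non-empty 1-D vector")
        if not np.isin(sig, (A, B)).all():
            raise ValueError("low_signals entries must be option labels 0/1")


@dataclass
class AgentState:
    """One learner's associative strengths for the two cues."""

    v_low: float
    v_high: float

    def __post_init__(self) -> None:
        if self.v_low < 0 or self.v_high < 0:
            raise ValueError("associative strengths must be non-negative")


@dataclass(frozen=True)
class LearningConfig:
    """Training protocol parameters.

    alpha
        Rescorla–Wagner learning rate (default 0.1).
    v_init
        Common small initial associative strength for both cues; implies an
        initial conflict-voting probability of 1/2.
    n_trials, n_reps
        Trials per run and independent replicate runs.
    window
        Number of final trials averaged when summarizing learned behavior.
    """

    alpha: float = 0.1
    v_init: float = 0.01
    n_trials: int = 1000
    n_reps: int = 500
    window: int = 100

    def __post_init__(self) -> None:
        # alpha = 0 is allowed as a no-learning control
        if not (0.0 <= self.alpha <= 1.0):
            raise ConfigurationError(f"alpha={self.alpha!r} must be in [0, 1]")
        if not (0.0 < self.v_init <= 0.1):
            raise ConfigurationError(f"v_init={self.v_init!r} must be in (0, 0.1]")
        if self.n_trials < 1 or self.n_reps < 1:
            raise ConfigurationError("n_trials and n_reps must be positive")
        if not (0 < self.window <= self.n_trials):
            raise ConfigurationError("window must satisfy 0 < window <= n_trials")


@dataclass(frozen=True)
class VotingRule:
    """How an individual resolves conflicting cues into a vote.

    ``linear`` votes for the low-correlation option with probability
    v_low / (v_low + v_high); ``logistic`` squashes the normalized strength
    difference through a logistic of the given steepness.
    """

    kind: str = "linear"
    steepness: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "logistic"):
            raise ConfigurationError(f"unknown voting rule kind {self.kind!r}")
        if self.kind == "logistic" and (self.steepness is None or self.steepness <= 0):
            raise ConfigurationError("logistic voting requires steepness > 0")


@dataclass(frozen=True)
class ConsensusRule:
    """How individual votes are aggregated into a group decision."""

    kind: str = "majority"
    threshold_votes: int | None = None
    steepness: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("majority", "threshold", "logistic"):
            raise ConfigurationError(f"unknown consensus rule kind {self.kind!r}")
        if self.kind == "threshold" and (
            self.threshold_votes is None or self.threshold_votes < 1
        ):
            raise ConfigurationError("threshold consensus requires threshold_votes >= 1")
        if self.kind == "logistic" and (self.steepness is None or self.steepness <= 0):
            raise ConfigurationError("logistic consensus requires steepness > 0")


@dataclass
class GroupState:
    """A group of learners."""

    agents: list[AgentState]

    @property
    def n(self) -> int:
        return len(self.agents)

    def __post_init__(self) -> None:
        if len(self.agents) < 1:
            raise ValueError("a group needs at least one individual")


# ---------------------------------------------------------------------------
# Trial sampling
# ---------------------------------------------------------------------------


def sample_trial(
    env: EnvironmentConfig, n: int, rng: np.random.Generator
) -> TrialObservations:
    """Draw one trial: superior option, shared high signal, per-individual
    low signals.

    The superior option is uniform over {A, B}; the high signal equals it
    with probability ``r_high`` (one draw for the whole group); each low
    signal equals it independently with probability ``r_low``.
    """
    if n < 1:
        raise ValueError("group size must be at least 1")
    superior = int(rng.integers(2))
    high_correct = rng.random() < env.r_high
    high_signal = superior if high_correct else 1 - superior
    low_correct = rng.random(n) < env.r_low
    low_signals = np.where(low_correct, superior, 1 - superior)
    return TrialObservations(superior, high_signal, low_signals)


# ---------------------------------------------------------------------------
# Individual voting
# ---------------------------------------------------------------------------


def p_from_strengths(agent: AgentState) -> float:
    """Probability of following the low-correlation cue when cues conflict:
    v_low / (v_low + v_high), with 1/2 when both strengths have decayed
    below the degeneracy floor."""
    total = agent.v_low + agent.v_high
    if total < DEGENERACY_FLOOR:
        return 0.5
    return agent.v_low / total


def _logistic_follow_prob(v_low: float, v_high: float, k: float) -> float:
    total = v_low + v_high
    d = 0.0 if total < DEGENERACY_FLOOR else (v_low - v_high) / total
    with np.errstate(over="ignore"):
        return float(1.0 / (1.0 + np.exp(-k * d)))


def vote(
    agent: AgentState,
    high_signal: int,
    low_signal: int,
    rule: VotingRule,
    rng: np.random.Generator,
) -> int:
    """Cast one vote.  When both cues indicate the same option the
    individual always votes for it; under conflict the low-correlation
    option is followed with the rule's probability."""
    if low_signal == high_signal:
        return low_signal
    if rule.kind == "linear":
        p = p_from_strengths(agent)
    else:
        p = _logistic_follow_prob(agent.v_low, agent.v_high, rule.steepness)
    return low_signal if rng.random() < p else high_signal


# ---------------------------------------------------------------------------
# Consensus rules
# ---------------------------------------------------------------------------


def _random_option(rng: np.random.Generator) -> int:
    return int(rng.integers(2))


def majority_decide(votes_A: int, votes_B: int, rng: np.random.Generator) -> int:
    """Simple majority; a tied vote is broken uniformly at random."""
    if votes_A < 0 or votes_B < 0:
        raise ValueError("vote counts must be non-negative")
    if votes_A + votes_B < 1:
        raise ValueError("at least one vote is required")
    if votes_A > votes_B:
        return A
    if votes_B > votes_A:
        return B
    return _random_option(rng)


def threshold_decide(
    votes_A: int, votes_B: int, m: int, rng: np.random.Generator
) -> int:
    """Quorum rule: an option needs at least ``m`` votes to be adopted.

    With a supermajority threshold (m > n/2) at most one option can qualify;
    deadlock is resolved uniformly at random.  With a submajority threshold
    both options may qualify, in which case the decision falls back to
    simple majority.
    """
    if votes_A < 0 or votes_B < 0:
        raise ValueError("vote counts must be non-negative")
    n = votes_A + votes_B
    if not (1 <= m <= n):
        raise ValueError(f"threshold m={m} outside [1, n={n}]")
    a_ok = votes_A >= m
    b_ok = votes_B >= m
    if a_ok and b_ok:
        return majority_decide(votes_A, votes_B, rng)
    if a_ok:
        return A
    if b_ok:
        return B
    return _random_option(rng)


def logistic_consensus_decide(
    votes_A: int, n: int, s: float, rng: np.random.Generator
) -> int:
    """Graded consensus: P(choose A) = logistic(s * (votes_A/n - 1/2)).

    As the steepness s grows this converges to simple majority rule.
    """
    if s <= 0:
        raise ValueError("steepness must be positive")
    f_A = votes_A / n
    with np.errstate(over="ignore"):
        p_A = 1.0 / (1.0 + np.exp(-s * (f_A - 0.5)))
    return A if rng.random() < p_A else B


# ---------------------------------------------------------------------------
# Learning
# ---------------------------------------------------------------------------


def update_strengths(
    agent: AgentState,
    high_signal: int,
    low_signal: int,
    chosen: int,
    outcome: int,
    alpha: float,
) -> AgentState:
    """Gated Rescorla–Wagner update with a shared prediction error.

    Both cues were observed, so the reward prediction is the total
    associative strength v_low + v_high; the shared prediction error
    (outcome - total) moves only the cue(s) whose signal indicated the
    option the group actually chose, each by alpha times the error.
    ``outcome`` is 1 iff the chosen option was the superior one.  Strengths
    are floored at zero.

    The shared error makes the cues compete for associative strength
    (compound-stimulus competition, the hallmark of the Rescorla–Wagner
    model); the gating means a cue that indicated the rejected option
    learns nothing that trial.  Both cues update together when they agreed
    and their common option was chosen.
    """
    if outcome not in (0, 1):
        raise ValueError("outcome must be 0 or 1")
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    v_low, v_high = agent.v_low, agent.v_high
    err = outcome - (v_low + v_high)
    new_low = max(0.0, v_low + alpha * err) if low_signal == chosen else v_low
    new_high = max(0.0, v_high + alpha * err) if high_signal == chosen else v_high
    return AgentState(new_low, new_high)


# ---------------------------------------------------------------------------
# Vectorized kernels (used by the simulation experiments)
# ---------------------------------------------------------------------------


def follow_low_probability(
    v_low: np.ndarray, v_high: np.ndarray, rule: VotingRule
) -> np.ndarray:
    """Array version of the conflict-resolution probability for a strength
    field of any shape."""
    total = v_low + v_high
    safe = np.where(total < DEGENERACY_FLOOR, 1.0, total)
    if rule.kind == "linear":
        p = np.where(total < DEGENERACY_FLOOR, 0.5, v_low / safe)
    else:
        d = np.where(total < DEGENERACY_FLOOR, 0.0, (v_low - v_high) / safe)
        with np.errstate(over="ignore"):
            p = 1.0 / (1.0 + np.exp(-rule.steepness * d))
    return p


def decide_counts(
    votes_A: np.ndarray, n: int, rule: ConsensusRule, rng: np.random.Generator
) -> np.ndarray:
    """Array version of the consensus decision for per-group A-vote counts."""
    votes_B = n - votes_A
    coin = rng.integers(2, size=votes_A.shape)
    if rule.kind == "majority":
        return np.where(votes_A > votes_B, A, np.where(votes_B > votes_A, B, coin))
    if rule.kind == "threshold":
        m = rule.threshold_votes
        a_ok = votes_A >= m
        b_ok = votes_B >= m
        maj = np.where(votes_A > votes_B, A, np.where(votes_B > votes_A, B, coin))
        out = np.where(a_ok & ~b_ok, A, np.where(b_ok & ~a_ok, B, coin))
        return np.where(a_ok & b_ok, maj, out)
    # logistic
    with np.errstate(over="ignore"):
        p_A = 1.0 / (1.0 + np.exp(-rule.steepness * (votes_A / n - 0.5)))
    return np.where(rng.random(votes_A.shape) < p_A, A, B)
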