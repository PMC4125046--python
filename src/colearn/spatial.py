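"""Zonal collective-motion model validating the majority-rule abstraction.

A minimal 2-D schooling simulator: each individual is repelled from
neighbors inside an inner zone (repulsion overrides everything else), and is
attracted to and aligns with neighbors inside an outer zone; a personal
preference for one of two distant targets is blended into the social
heading.  Running decision bouts with a conflicted group shows that (i) the
group stays cohesive — either none or all members reach a target — and
(ii) which target the group reaches follows the preference of the majority,
justifying the vote-counting abstraction used by the learning model.

Distances are in body lengths, angles in radians, speeds in body lengths
per time step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpatialConfig",
    "SpatialBoutResult",
    "target_positions",
    "spatial_step",
    "run_bout",
    "run_bouts",
    "summarize_bouts",
]

#: Arrival label for an individual that reached no target before max_steps.
NONE_LABEL = -1


@dataclass(frozen=True)
class SpatialConfig:
    """Zonal-model parameters (defaults follow common schooling-model
    conventions and are fully configurable)."""

    n: int = 10
    r_repulsion: float = 1.0
    r_attraction: float = 12.0
    speed: float = 1.0
    max_turn: float = 0.35
    noise_sd: float = 0.05
    pref_weight: float = 0.5
    target_distance: float = 50.0
    target_separation_angle: float = np.pi / 3
    capture_radius: float = 5.0
    max_steps: int = 2000
    dt: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.r_repulsion < self.r_attraction):
            raise ValueError("require 0 < r_repulsion < r_attraction")
        if min(self.speed, self.max_turn, self.capture_radius) <= 0:
            raise ValueError("speed, max_turn and capture_radius must be positive")
        if self.n < 1 or self.max_steps < 1:
            raise ValueError("n and max_steps must be positive")


@dataclass
class SpatialBoutResult:
    """Per-individual arrival outcome of one decision bout.

    ``arrivals[i]`` is 0 (target A), 1 (target B) or -1 (no arrival);
    ``steps_elapsed`` counts simulated steps until termination.
    """

    arrivals: np.ndarray
    steps_elapsed: int


def target_positions(cfg: SpatialConfig) -> np.ndarray:
    """Coordinates of targets A and B, placed ``target_distance`` from the
    start point (the origin) and separated by ``target_separation_angle``."""
    half = cfg.target_separation_angle / 2
    return cfg.target_distance * np.array(
        [[np.cos(half), np.sin(half)], [np.cos(half), -np.sin(half)]]
    )


def _unit(v: np.ndarray, axis: int = -1) -> np.ndarray:
    norm = np.linalg.norm(v, axis=axis, keepdims=True)
    return v / np.where(norm == 0, 1.0, norm)


def _turn_towards(headings, desired, cfg, rng):
    """Rotate headings toward desired angles by at most max_turn, then add
    Gaussian angular noise."""
    delta = (desired - headings + np.pi) % (2 * np.pi) - np.pi
    delta = np.clip(delta, -cfg.max_turn * cfg.dt, cfg.max_turn * cfg.dt)
    return headings + delta + rng.normal(0.0, cfg.noise_sd, size=headings.shape)


def _desired_directions(positions, headings, pref_targets, cfg):
    """Desired unit vectors for a batch of bouts.

    positions: (..., n, 2); headings: (..., n); pref_targets: (..., n, 2).
    Repulsion from inner-zone neighbors overrides all other forces; otherwise
    attraction + alignment within the outer zone is blended with the
    preference vector.
    """
    diff = positions[..., None, :, :] - positions[..., :, None, :]  # i -> j
    dist = np.linalg.norm(diff, axis=-1)
    np.einsum("...ii->...i", dist)[...] = np.inf  # ignore self
    unit_diff = diff / np.where(dist[..., None] == np.inf, 1.0, np.maximum(dist[..., None], 1e-12))

    rep_mask = dist < cfg.r_repulsion
    rep_vec = -(unit_diff * rep_mask[..., None]).sum(axis=-2)

    att_mask = dist < cfg.r_attraction
    att_vec = (unit_diff * att_mask[..., None]).sum(axis=-2)
    head_vec = np.stack([np.cos(headings), np.sin(headings)], axis=-1)
    ali_vec = np.einsum("...ij,...jk->...ik", att_mask.astype(float), head_vec)
    social = att_vec + ali_vec
    has_social = att_mask.any(axis=-1)

    pref_vec = _unit(pref_targets - positions)
    blended = np.where(
        has_social[..., None],
        _unit(_unit(social) + cfg.pref_weight * pref_vec),
        pref_vec,
    )
    desired = np.where(rep_mask.any(axis=-1)[..., None], _unit(rep_vec), blended)
    return desired


def spatial_step(positions, headings, pref_targets, cfg: SpatialConfig, rng):
    """Advance one time step; returns (positions, headings) updated.

    ``pref_targets`` holds each individual's preferred target coordinates
    (shape like positions).  Arrays may carry leading batch dimensions.
    """
    desired = _desired_directions(positions, headings, pref_targets, cfg)
    desired_angle = np.arctan2(desired[..., 1], desired[..., 0])
    new_head = _turn_towards(headings, desired_angle, cfg, rng)
    step = cfg.speed * cfg.dt
    new_pos = positions + step * np.stack(
        [np.cos(new_head), np.sin(new_head)], axis=-1
    )
    return new_pos, new_head


def _init_group(cfg: SpatialConfig, n_bouts: int, rng):
    positions = rng.uniform(-2.0, 2.0, size=(n_bouts, cfg.n, 2))
    headings = rng.uniform(-np.pi, np.pi, size=(n_bouts, cfg.n))
    return positions, headings


def run_bouts(
    cfg: SpatialConfig,
    fraction_preferring_A: float,
    n_bouts: int,
    rng: np.random.Generator,
) -> list[SpatialBoutResult]:
    """Simulate ``n_bouts`` independent decision bouts (batched).

    Each bout starts a compact group at the origin, equidistant from the two
    targets; round(fraction * n) members prefer target A, the rest target B.
    A bout ends when every member is within the capture radius of a target,
    or after max_steps.
    """
    if not (0.0 <= fraction_preferring_A <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    targets = target_positions(cfg)
    n_a = int(round(fraction_preferring_A * cfg.n))
    pref_idx = np.concatenate(
        [np.zeros(n_a, dtype=int), np.ones(cfg.n - n_a, dtype=int)]
    )
    pref_targets = np.broadcast_to(targets[pref_idx], (n_bouts, cfg.n, 2)).copy()

    positions, headings = _init_group(cfg, n_bouts, rng)
    active = np.ones(n_bouts, dtype=bool)
    steps = np.full(n_bouts, cfg.max_steps, dtype=int)
    arrivals = np.full((n_bouts, cfg.n), NONE_LABEL, dtype=int)

    for t in range(cfg.max_steps):
        if not active.any():
            break
        pos_a, head_a = spatial_step(
            positions[active], headings[active], pref_targets[active], cfg, rng
        )
        positions[active] = pos_a
        headings[active] = head_a
        d = np.linalg.norm(
            positions[:, :, None, :] - targets[None, None, :, :], axis=-1
        )
        within = d.min(axis=-1) < cfg.capture_radius  # (bouts, n)
        done = within.all(axis=1) & active
        if done.any():
            arrivals[done] = d[done].argmin(axis=-1)
            steps[done] = t + 1
            active[done] = False

    # individuals inside a capture radius when time ran out still count
    if active.any():
        d = np.linalg.norm(
            positions[:, :, None, :] - targets[None, None, :, :], axis=-1
        )
        within = d.min(axis=-1) < cfg.capture_radius
        nearest = d.argmin(axis=-1)
        arrivals[active] = np.where(within[active], nearest[active], NONE_LABEL)

    return [SpatialBoutResult(arrivals[b], int(steps[b])) for b in range(n_bouts)]


def run_bout(
    cfg: SpatialConfig, fraction_preferring_A: float, rng: np.random.Generator
) -> SpatialBoutResult:
    """Simulate a single decision bout."""
    return run_bouts(cfg, fraction_preferring_A, 1, rng)[0]


def summarize_bouts(results: list[SpatialBoutResult]) -> dict:
    """Cohesion and group outcome summary for a batch of bouts.

    cohesion
        Fraction of bouts in which every individual reached the same target.
    p_group_A
        Among decided bouts (all members arrived somewhere), the fraction
        whose majority arrival was target A; bouts with no arrival majority
        are excluded.
    undecided
        Fraction of bouts in which at least one member never arrived.
    """
    if not results:
        raise ValueError("need at least one bout")
    n_bouts = len(results)
    unanimous = 0
    group_a = 0
    decided = 0
    undecided = 0
    for r in results:
        arr = r.arrivals
        if (arr == NONE_LABEL).any():
            undecided += 1
            continue
        if (arr == arr[0]).all():
            unanimous += 1
        n_a = int((arr == 0).sum())
        n_b = int((arr == 1).sum())
        if n_a != n_b:
            decided += 1
            group_a += n_a > n_b
    return {
        "n_bouts": n_bouts,
        "cohesion": unanimous / n_bouts,
        "p_group_A": group_a / decided if decided else float("nan"),
        "undecided": undecided / n_bouts,
    }
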