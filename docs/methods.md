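# Methods

## Model

A group of `n` individuals chooses between two options (A/B, encoded 0/1);
each trial one option is superior, with a uniform prior. Two binary cues
indicate an option per trial:

* **low-correlation cue** — independent per-individual draws, each equal to
  the superior option with probability `r_low ∈ [0.5, 1]`;
* **high-correlation cue** — a single shared draw, correct with probability
  `r_high ∈ [0.5, 1]`.

Individual `i` holds associative strengths `v_low,i`, `v_high,i ∈ [0, 1]`.
Voting follows the strength-proportional (probability-matching) rule: when
both cues indicate the same option the individual votes for it; under
conflict it votes for the low-cue option with probability
`p_i = v_low,i / (v_low,i + v_high,i)` (defined as 1/2 when the total
strength falls below a 1e-12 degeneracy floor). A logistic voting variant
uses `P = 1/(1 + exp(−k d))` with `d = (v_low − v_high)/(v_low + v_high)`;
as `k → ∞` it becomes the deterministic argmax of the strengths.

Consensus is simple majority with random tie-breaking by default. Two
alternatives are provided: a quorum (threshold) rule that adopts an option
only if it receives at least `m` votes (supermajority `m > n/2`: deadlock →
fair coin; submajority `m ≤ n/2`: if both options qualify the decision
falls back to simple majority), and a graded logistic rule
`P(A) = 1/(1 + exp(−s (f_A − 1/2)))` that converges to majority rule for
large steepness `s`.

### Learning rule

All members experience the shared binary outcome `λ` (1 iff the chosen
option was superior) and update only the cue(s) whose signal indicated the
chosen option, using one **shared prediction error computed against the
total strength of both observed cues**:

    v_X ← max(0, v_X + α (λ − (v_low + v_high)))

This is the Rescorla–Wagner compound-stimulus form: because the error is
shared, cues compete for a limited amount of associative strength, which is
what lets the valuation of a cue reflect more than its raw reliability. An
independent per-cue error (`v_X ← v_X + α(λ − v_X)`) was considered and
rejected: its fixed point sets each strength to the conditional reward
probability given that the cue agreed with the group choice — both near the
group's overall accuracy — which pins the conflict behavior near 1/2
regardless of group size and cannot produce the group-size-dependent cue
weighting that is the phenomenon of interest here. The shared-error rule
reproduces it robustly (see the test suite): isolated learners drift toward
the more reliable cue (matching-like), while groups shift toward the
independent cue as `n` grows, tracking the optimum to within a few percent
of the maximal accuracy.

Strengths are floored at zero (a large punishment can otherwise drive the
less-supported cue negative); with initialization in (0, 0.1] both
strengths then remain in [0, 1] for any event sequence (property-tested).

### Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.1 | learning rate (0 allowed as a no-learning control) |
| `v_init` | 0.01 | initial strength of both cues ("very small"), implying initial p = 1/2 |
| `n_trials` | 1000 | trials per training run |
| `n_reps` | 500 | independent replicate runs |
| `window` | 100 | final trials averaged for the learned-behavior summary |

The `v_init = 0.01` choice is arbitrary below ~0.1: the first rewarded
update moves the total strength to ≈ α, after which the dynamics forget the
initial value; any sufficiently small symmetric initialization gives the
same behavior.

## Exact analytics

Conditioning on whether the shared signal is correct, each individual votes
correctly independently with probability `q1 = 1 − (1 − r_low) p` (shared
signal correct) or `q0 = r_low p` (incorrect), so

    A(p) = r_high · M(q1, n) + (1 − r_high) · M(q0, n),

where `M(q, n)` is the binomial majority probability with even-`n` ties
weighted 1/2 (scipy's regularized-incomplete-beta survival function keeps
this stable to at least n = 1000). Heterogeneous behaviors `p_i` are pooled
with an exact O(n²) Poisson-binomial dynamic program.

`p*` is located by a 1e-3 grid followed by bounded scalar refinement to
|Δp| ≤ 1e-6; boundary optima snap exactly to 0 or 1, and regimes are
classified with tolerance 1e-6 (`low_exclusive` p* = 1, `high_exclusive`
p* = 0, otherwise `mixed`). For odd `n` the interior first-order condition
`r_high (1−r_low) [q1(1−q1)]^((n−1)/2) = (1−r_high) r_low [q0(1−q0)]^((n−1)/2)`
serves as an independent check on located optima, not as the solver. The
accuracy landscape at `n = 5, r_low = 0.7, r_high = 0.8` is very flat near
its peak: the maximizer is p* = 0.8255, while A(0.80) differs from the
maximum 0.84788 only in the fourth decimal — quoted optima around 0.8 are
equivalent in practice.

The **global benchmark** jointly optimizes `p` and an integer supermajority
threshold `m ∈ [⌈(n+1)/2⌉, n]` (deadlock → fair coin), all evaluated
exactly from binomial tail sums; the family contains simple majority, so
`restricted ≤ global` holds by construction. The **Bayes bound** is the
full-information Nitzan–Paroush aggregator: weight each low signal by
`ln(r_low/(1−r_low))` and the shared signal by `ln(r_high/(1−r_high))`,
decide by the sign of the summed signed weights (ties → 1/2); a perfectly
reliable cue carries infinite weight and the bound is 1. Submajority
thresholds are excluded from the benchmark family: with symmetric binary
options and a fallback to majority when both options qualify, they cannot
improve on the included rules.

Regret maps for context changes evaluate
`A(p*(old context); new context) − A(p*(new context); new context) ≤ 0`.

## Simulation protocols

All replicates are advanced simultaneously as (replicates × groups ×
members) arrays drawn from one `numpy` Generator seeded per run (replicates
occupy fixed rows, so runs are bit-for-bit reproducible given the seed;
sub-experiments derive independent child seeds via `SeedSequence.spawn`).

* **Training** (`run_training`): the full trial loop; reports per-trial mean
  conflict probability and decision success plus final agent states.
* **Sweeps** (`sweep_grid`): one training run per (n, r_low, r_high) cell,
  joined with the exact optimum. The *achieved accuracy* of a run is the
  exact accuracy of the learned strengths — each replicate's final
  per-agent probabilities evaluated with the Poisson-binomial formula, then
  averaged — rather than the raw empirical success rate, so it is
  guaranteed ≤ the optimum and free of Monte-Carlo noise.
* **Isolated-then-pooled** (`run_isolated_then_pooled`): each replicate
  trains `n` individuals at group size 1, freezes their window-mean
  behaviors and pools them exactly into one group of `n`. Freezing isolates
  the comparison between what was learned in isolation and what collective
  learning produces.
* **Transitions** (`run_transition`): phase 1 (default 500 trials) trains in
  the starting context; at the change, a group-size increase pools
  `⌈n2/n1⌉` independently trained groups and keeps the first `n2` members,
  a decrease keeps a uniform random subset, and a reliability change keeps
  the same agents; learning continues in phase 2 (remaining 500 trials).

Scaled problem sizes used by the test suite — 100 replicates instead of
500, and a 3 × 4 × 4 sweep grid — keep the default run at desk scale; the
500-replicate protocol remains the library default for report-quality runs.
Replicate counts only shrink Monte-Carlo error, not the learning dynamics,
so summary statistics are unchanged within sampling noise.

## Zonal spatial model

Each individual moves at constant speed (1 body length per step) in 2-D.
Neighbors within the repulsion radius (1 BL) induce pure avoidance,
overriding everything else; otherwise the desired direction is the
normalized sum of attraction toward and alignment with neighbors within the
attraction radius, blended with `pref_weight = 0.5` times the unit vector
toward the individual's preferred target. Headings turn toward the desired
direction by at most 0.35 rad/step plus Gaussian noise (sd 0.05 rad).
Bouts start with the group compact at the origin, equidistant from two
targets 50 BL away separated by 60°; a bout ends when every member is
within 5 BL of a target (or at 2000 steps; stragglers are reported as
undecided and excluded from the outcome curve).

The attraction radius default is 12 BL. Probing the conventional zonal
parameter space showed that smaller outer zones (≈7 BL) sit in a
partially-splitting regime for 10-member groups — single stragglers peel
off near the decision point — which does not represent the cohesive school
this module is meant to emulate; 12 BL puts the model robustly in the
cohesive regime (≥ 0.95 unanimous arrivals) without affecting
majority-following. What the validation shows is that *for a cohesive
school*, group choice follows the majority preference; it does not probe
fission-prone parameter regimes, 3-D motion, visual occlusion or speed
heterogeneity.

## What the synthetic environment does and does not capture

All inputs are synthetic by design: binary options, stationary Bernoulli
cues, equal reward sharing and synchronized trials. Passing tests
demonstrate the internal consistency of theory and simulation and the
qualitative phenomena (group-size-dependent cue weighting, the cost of
pooling isolated learners, recovery after context changes) under these
idealized conditions — not that real animal groups learn this way. Known
limitations: two options and two cues only; homogeneous reliabilities and
learning rates; no per-individual reward asymmetries or differential social
influence; the spatial model is 2-D with metric interactions.

## Numerical choices

* Binomial tails via `scipy.stats.binom` (`sf`/`cdf`/`pmf`), stable for all
  supported `n` without explicit log-space handling.
* Voting degeneracy floor 1e-12 (total strength below it → p = 1/2).
* Even-`n` vote ties contribute probability 1/2 everywhere (consistent with
  random deadlock resolution).
* Optimizer: 1e-3 grid + bounded refinement (xatol 1e-8); soundness is
  tested against independent 1e-4 grids.
* Floats in output tables are serialized at 12 significant digits; every
  written table gets a sibling manifest (config, seed, package version).
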