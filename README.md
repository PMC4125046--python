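# colearn

Collective learning and optimal consensus decisions in animal groups.

Many social animals — fish schools, bird flocks, primate troops — must
repeatedly choose between discrete options (forage patches, escape routes)
as a group, reaching consensus even when members disagree. `colearn` models
a group of `n` individuals choosing between two options using two binary
environmental cues that differ in **reliability** and in **observational
correlation**:

* a *low-correlation* cue: each individual receives an independent draw,
  correct with probability `r_low`;
* a *high-correlation* cue: one shared draw for the whole group, correct
  with probability `r_high`.

Each individual keeps Rescorla–Wagner associative strengths `v_low`, `v_high`
for the two cues and, when the cues conflict, votes for the low-cue option
with probability `p = v_low / (v_low + v_high)`. The group decides by simple
majority (ties broken at random), everyone experiences the shared outcome
`λ ∈ {0, 1}` (1 iff the chosen option was superior), and the cues that
indicated the chosen option are updated with a shared prediction error:

```
v_X ← max(0, v_X + α (λ − (v_low + v_high)))    for each cue X that
                                                indicated the chosen option
```

Because consensus decouples individual preference from experience, this
simple learning rule lets group members *implicitly* learn the value of
statistical independence: the larger the group, the more they come to rely
on the low-correlation cue, closely tracking the provably optimal voting
behavior without ever estimating group size or cue correlation.

The package provides:

* **`colearn.model`** — the generative model: trial sampling, linear and
  logistic voting rules, majority / quorum / logistic consensus rules, and
  the gated learning update.
* **`colearn.analytics`** — exact, simulation-free theory. Conditioning on
  whether the shared signal is correct, each voter is independently correct
  with `q1 = 1 − (1 − r_low) p` or `q0 = r_low p`, so collective accuracy is
  `A(p) = r_high · M(q1, n) + (1 − r_high) · M(q0, n)` with `M` the
  Condorcet majority probability. Includes the optimal behavior `p*`, the
  globally optimal (p, supermajority-threshold) benchmark, the Nitzan–Paroush
  full-information Bayes bound, Poisson-binomial pooling of heterogeneous
  voters, and regret maps for context changes.
* **`colearn.experiments`** — the simulation protocols: training runs,
  environment × group-size sweeps, isolated-learning-then-pooling
  comparisons, and abrupt transitions in group size or cue reliability.
* **`colearn.spatial`** — a zonal (repulsion / attraction + alignment)
  schooling model showing that cohesive spatial groups with conflicting
  target preferences behave like simple-majority voters.
* **`colearn.cli`** — a `colearn` command with subcommands `train`, `sweep`,
  `optimal`, `landscape`, `global-compare`, `transition`, `isolated-pooled`
  and `spatial-validate`; YAML/JSON configs, CSV/JSON outputs and a
  reproducibility manifest per run.

## Worked example

What should an individual in a group of five do when its private cue is
correct 70% of the time but the shared cue 80%?

```
$ colearn optimal --n 5 --r-low 0.7 --r-high 0.8
p_star=0.825467 a_star=0.847883 regime=mixed
```

Alone it should trust the shared cue exclusively (accuracy 0.8), but in a
group of five the best strategy is mixed: side with the private cue in
82.5% of conflicts, for a collective accuracy of 0.848 — better than
exclusive use of either cue (0.800 shared, 0.837 private-majority).

Do learners find this behavior on their own? Training 100 replicate groups
of 31 for 1000 trials at `r_low = 0.7`, `r_high = 0.8`:

```
$ colearn train --n 31 --r-low 0.7 --r-high 0.8 --n-reps 100 --seed 7
learned_p=0.915263 success=0.9853
```

The learned conflict behavior (mean p ≈ 0.92, vs. optimum 0.98 for this
group size) yields 98.5% decision success, essentially the exact optimum
0.991. Pooling individuals that learned the same environment *in isolation*
does much worse, because isolated learners under-value the independent cue:

```
$ colearn isolated-pooled --n 31 --r-low 0.7 --r-high 0.75 --n-reps 100 --seed 9
pooled=0.750918 collective=0.985171 optimal=0.990533
```

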