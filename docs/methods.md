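# Methods

## Model

An age-structured population of `N` individuals (default 200) experiences a
two-state environment `E(t) ∈ {1, 2}` that switches with probability
`p_env` each time step (first event of the step, so everything within step
`t` sees `E(t)`; the initial state is 1, which is irrelevant by symmetry but
fixed for reproducibility).  Waiting times between switches are geometric
with mean `T_change = 1/p_env`.

Cultural variants carry one adaptation value per state, `a(k) ∈ [0, 1]`.
Individuals hold repertoires of up to 500 variants together with
per-variant expression counts `n_ij`, and two heritable, mutable traits:
the social-learning propensity `ξ` and the forgetting probability `φ`
(both initialised at 0.2).

### One time step

1. **Environment** switches with probability `p_env`.
2. **Expression** (every individual, fixed index order; order-independent
   because the social pool is frozen, see below): choose a variant from the
   repertoire — proportionally to `a_i(k)` or by softmax with temperature
   `τ = 0.1` — and express it with probability `a_i(k)`.  Otherwise learn:
   with probability `ξ` copy the variant of a demonstrator sampled
   proportionally to *last* step's benefits (self excluded); with
   probability `1 − ξ` innovate.  The learned/innovated variant is
   expressed regardless of its value and added to the repertoire if
   unknown; known variants are never duplicated.
3. **Forgetting**: with probability `φ` remove one variant `z ≠ i` (the
   expressed variant `i` is protected) with probability
   `f_z = (A − n_z)/Σ_{s≠i}(A − n_s)`, `A = Σ_{s≠i} n_s`.  A size-1
   repertoire never forgets.
4. **Birth-death**: one parent chosen proportionally to *this* step's
   benefits, one death chosen proportionally to age (the newborn is not yet
   in the population and cannot die in its birth step).  Offspring traits
   are the parent's, each perturbed with probability `μ = 0.05` by
   `N(0, σ² = 0.1)` noise truncated (clipped) into `[0, 1]`.  With vertical
   learning the offspring receives a copy of the parent's repertoire with
   every expression count reset to 1; without, it is born naive and must
   acquire its first variant by social learning or innovation.
5. **Aging**: every individual's age increments; the newborn enters its
   first full step at age 1.

A run consists of a 50 000-step burn-in plus 50 000 recorded steps
(500 generations of `N` steps at the defaults); observables are taken from
the post-burn-in window.

### Innovation regimes

New variants get a fresh globally unique id and values:

- **type1** — `a(current) ~ U[0, 1]`, `a(other) = 0`.
- **type2** — with probability 0.95, `a(current) ~ U[0, 0.8]`, else
  `U[0, 1]`; `a(other) = 0`.  High-value innovations are rare
  (`P(a > 0.8) = 0.05 × 0.2 = 0.01`).
- **type3** — with probability 0.95, `a(current) ~ U[0, ε]` (the innovation
  effectively failed), else `U[0, 1]`; `a(other) = 0`.
- **correlated** — `(a1, a2)` marginally `U[0, 1]` with Pearson correlation
  ρ = −0.9 via a Gaussian copula.
- **uniform_both** — `a1, a2` independent `U[0, 1]`.

The width of type3's "failed" draw is not pinned down by the model
description; we use `ε = 0.001` (configurable, `type3_epsilon`): strictly
positive so that choice denominators are rarely all-zero, yet a negligible
benefit.  For the copula we use the closed form
`ρ_latent = 2 sin(πρ/6)` for the latent normal correlation, which makes the
uniform-scale Pearson correlation exactly −0.9 while preserving exact
uniform marginals — no numerical calibration required.

## Observables

- **Fitness**: mean expressed benefit over all individuals during the final
  generation (last `N` steps).
- **Repertoire size**: mean variant count per individual at the final step;
  variants adapted to the current and to the alternative state are also
  counted separately.
- **Sub-optimal choice**: only repertoire-sourced expressions count; an
  expression is sub-optimal when its benefit is below the repertoire's best
  current-state value at the moment of choice.  "Age-normalized" proportion
  = lifetime sub-optimal count / lifetime expression count (an individual's
  expression count equals its age in steps); magnitude = accumulated gap /
  number of sub-optimal events (0 if none).  Both are population means over
  individuals alive at the end; counters reset at birth.
- **Composition**: per-repertoire histogram (10 equal bins on [0, 1],
  configurable) of current-state adaptation values of current-state-adapted
  variants, normalised per repertoire and averaged over individuals;
  individuals holding none contribute nothing.
- **Preservation probability**: replicates run through burn-in and stop at
  the first switch, before any learning; the probability is the fraction of
  replicates in which at least one individual holds a variant with positive
  value in the newly current state.

## Numerical and design choices

- **Degenerate denominators** are completed symmetrically: all-zero
  current-state adaptation values → uniform variant choice; all-zero payoff
  pools (social learning, parent selection) → uniform; a single eligible
  forgetting candidate (the 0/0 case of the removal weights) → removed with
  certainty given a forget event.
- **Expression counting**: a newly inserted variant starts at `n = 1`; the
  insertion-expression then counts, so it ends the step at `n = 2`.  The
  alternative convention (leave it at 1) is available via
  `count_insertion_expression=False`.
- **Social pool semantics**: social learning at step `t` observes only step
  `t − 1` expressions; newborns and the very first step have no observable
  demonstrators and fall back to innovation.  The focal individual never
  copies itself (self-copying would be a no-op that dilutes the meaning of
  `ξ`).
- **Repertoire cap**: insertion into a full repertoire first triggers one
  forced forgetting event (count-based weights, no protected entry), so the
  size never exceeds the cap.
- **Event order within a step** (environment → expression → forgetting →
  birth-death → aging) is a fixed, documented convention covered by trace
  tests; whether forgetting precedes the demographic event is not
  behaviourally identified at the level of the reported observables.
- **Initialisation**: founder ages uniform on `{0, …, N−1}`; each founder
  holds one variant innovated under the configured regime for the initial
  environment (`n = 1`).  Both choices are washed out by burn-in.
- **Mutation truncation** is implemented as clipping to `[0, 1]`.
- **Determinism**: all randomness in a run flows from one integer seed; the
  per-replicate seed is derived with `SeedSequence(base, spawn_key=(arm,
  replicate))`, so each replicate (and each experiment arm in paired
  designs) is an independent, individually reproducible stream.  The hot
  loop is a numba kernel; every stochastic transformation is a shared
  explicit-draw function used identically by the kernel and by the
  object-level API, so unit tests exercise the same code path as full runs.

## What the synthetic experiments do and do not show

All inputs are generated by the model itself; there is no external data.
The default parameters (N = 200, 50 000 + 50 000 steps, ξ = φ = 0.2 at
start, μ = 0.05, σ² = 0.1, 3 000 replicates) define the reference study
conditions.  The bundled directional experiments in
`tests/test_acceptance.py` run at desk scale — N = 50, 10 000 + 10 000
steps, 60–300 replicates per arm, replicate counts sized from pilot
Monte-Carlo standard errors of each comparison — and check signs and
orderings of the vertical-minus-nonvertical fitness difference and of the
preservation probabilities, not the magnitudes obtained at the reference
scale.  Desk scale changes the ratio of `T_change` to the mean individual
lifespan (≈ N steps), so effect sizes are smaller than at N = 200;
qualitative orderings were robust in our runs.

Known limitations: two environmental states only, no spatial structure, no
copying error on adaptation values, no conformist/frequency-biased
transmission, one expression per individual per step, and a single fixed
within-step event order.
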