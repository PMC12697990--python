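"""Per-individual dynamics: variant choice, learning, innovation, forgetting.

The numerical core is a set of ``@njit`` functions that implement the model's
probability rules on flat arrays.  They are written in "explicit draw" style:
every stochastic function takes the uniform (or standard-normal) variates it
consumes as arguments.  The simulation kernel feeds them numba's internal RNG;
the object-level wrappers and the test suite feed them draws from a seeded
``numpy.random.Generator``.  Either way the transformation from random draws
to model events is a single shared code path.

Probability rules
-----------------
* Variant choice from the repertoire is payoff-proportional,
  ``p_i = a_i(k) / sum_s a_s(k)``, or softmax, ``p_i ∝ exp(a_i(k)/tau)``.
* The chosen variant is expressed with probability ``a_i(k)``; otherwise the
  individual learns socially (probability ``xi``) or innovates.
* Payoff-biased social learning samples a demonstrator proportionally to its
  previous-step benefit and copies the variant it expressed.
* Forgetting removes variant ``z`` (never the one expressed this step) with
  probability ``f_z = (A - n_z) / sum_{s != i} (A - n_s)`` where
  ``A = sum_{s != i} n_s``: rarely expressed variants are forgotten first.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .state import Individual, RepertoireEntry, Variant

__all__ = [
    "proportional_probs",
    "softmax_probs",
    "choice_probs",
    "forgetting_probs",
    "draw_choice_index",
    "draw_forget_index",
    "draw_demonstrator",
    "draw_weighted",
    "innovate_from_draws",
    "mutate_from_draws",
    "choose_variant",
    "decide_express",
    "decide_social",
    "social_learning_pick",
    "innovate",
    "add_to_repertoire",
    "record_expression",
    "forget_step",
]

# Innovation regime codes (kept in sync with config.REGIMES).
_TYPE1, _TYPE2, _TYPE3, _CORRELATED, _UNIFORM_BOTH = 0, 1, 2, 3, 4
_SQRT2 = math.sqrt(2.0)


# ---------------------------------------------------------------------------
# choice of a variant from the repertoire
# ---------------------------------------------------------------------------

@njit(cache=True)
def proportional_probs(a_env):
    """Payoff-proportional choice probabilities over repertoire entries.

    ``a_env`` holds the adaptation values in the current environment.  If all
    values are zero the rule degenerates to 0/0; the symmetric completion is
    the uniform distribution (the individual must still express something).
    """
    m = a_env.size
    if m == 0:
        raise ValueError("choice from an empty repertoire")
    total = 0.0
    for s in range(m):
        total += a_env[s]
    out = np.empty(m, dtype=np.float64)
    if total <= 0.0:
        out[:] = 1.0 / m
        return out
    for s in range(m):
        out[s] = a_env[s] / total
    return out


@njit(cache=True)
def softmax_probs(a_env, tau):
    """Softmax choice probabilities ``p_i ∝ exp(a_i/tau)`` (max-shifted)."""
    m = a_env.size
    if m == 0:
        raise ValueError("choice from an empty repertoire")
    if tau <= 0.0:
        raise ValueError("softmax temperature must be > 0")
    mx = a_env[0]
    for s in range(m):
        if a_env[s] > mx:
            mx = a_env[s]
    out = np.empty(m, dtype=np.float64)
    total = 0.0
    for s in range(m):
        w = math.exp((a_env[s] - mx) / tau)
        out[s] = w
        total += w
    for s in range(m):
        out[s] /= total
    return out


@njit(cache=True)
def choice_probs(a_env, rule, tau):
    """Dispatch on the configured rule (0 = proportional, 1 = softmax)."""
    if rule == 0:
        return proportional_probs(a_env)
    return softmax_probs(a_env, tau)


@njit(cache=True)
def draw_choice_index(a_env, rule, tau, u):
    """Sample a repertoire index under the choice rule from one uniform ``u``.

    Allocation-free scan used in the hot loop; distributionally identical to
    sampling from :func:`choice_probs`.
    """
    m = a_env.size
    if rule == 0:
        total = 0.0
        for s in range(m):
            total += a_env[s]
        if total <= 0.0:
            k = int(u * m)
            return k if k < m else m - 1
        uu = u * total
        acc = 0.0
        for s in range(m):
            acc += a_env[s]
            if uu < acc:
                return s
        return m - 1
    mx = a_env[0]
    for s in range(m):
        if a_env[s] > mx:
            mx = a_env[s]
    total = 0.0
    for s in range(m):
        total += math.exp((a_env[s] - mx) / tau)
    uu = u * total
    acc = 0.0
    for s in range(m):
        acc += math.exp((a_env[s] - mx) / tau)
        if uu < acc:
            return s
    return m - 1


# ---------------------------------------------------------------------------
# forgetting
# ---------------------------------------------------------------------------

@njit(cache=True)
def forgetting_probs(counts, protected):
    """Removal probabilities over repertoire entries given a forget event.

    ``counts`` are the expression counts ``n``; ``protected`` is the index of
    the variant expressed this step (it can never be forgotten; pass -1 for a
    forced removal with no protected entry, used at the repertoire cap).

    Entry ``z`` is removed with probability ``(A - n_z) / sum(A - n_s)`` over
    the eligible entries, ``A`` their total count.  With a single eligible
    candidate the denominator is zero (0/0); the symmetric limit assigns it
    probability 1.  Returns a vector over all entries with 0 at ``protected``
    (all-zero if there is no eligible candidate).
    """
    m = counts.size
    out = np.zeros(m, dtype=np.float64)
    n_eligible = m if protected < 0 else m - 1
    if n_eligible <= 0:
        return out
    A = 0.0
    for s in range(m):
        if s != protected:
            A += counts[s]
    denom = 0.0
    for s in range(m):
        if s != protected:
            denom += A - counts[s]
    if denom <= 0.0:
        for s in range(m):
            if s != protected:
                out[s] = 1.0 / n_eligible
        return out
    for s in range(m):
        if s != protected:
            out[s] = (A - counts[s]) / denom
    return out


@njit(cache=True)
def draw_forget_index(counts, protected, u):
    """Sample the entry to remove (see :func:`forgetting_probs`); -1 if none."""
    m = counts.size
    n_eligible = m if protected < 0 else m - 1
    if n_eligible <= 0:
        return -1
    A = 0.0
    for s in range(m):
        if s != protected:
            A += counts[s]
    denom = 0.0
    for s in range(m):
        if s != protected:
            denom += A - counts[s]
    if denom <= 0.0:
        k = int(u * n_eligible)
        if k >= n_eligible:
            k = n_eligible - 1
        c = 0
        for s in range(m):
            if s != protected:
                if c == k:
                    return s
                c += 1
        return -1
    uu = u * denom
    acc = 0.0
    last = -1
    for s in range(m):
        if s != protected:
            acc += A - counts[s]
            last = s
            if uu < acc:
                return s
    return last


# ---------------------------------------------------------------------------
# social learning and generic weighted sampling
# ---------------------------------------------------------------------------

@njit(cache=True)
def draw_weighted(weights, u):
    """Sample an index proportionally to non-negative ``weights``.

    An all-zero weight vector degenerates to the uniform distribution (the
    symmetric completion used throughout the model).
    """
    n = weights.size
    total = 0.0
    for s in range(n):
        total += weights[s]
    if total <= 0.0:
        k = int(u * n)
        return k if k < n else n - 1
    uu = u * total
    acc = 0.0
    for s in range(n):
        acc += weights[s]
        if uu < acc:
            return s
    return n - 1


@njit(cache=True)
def draw_demonstrator(last_payoffs, last_variant_ids, focal, u):
    """Payoff-biased demonstrator choice for social learning.

    Eligible demonstrators are every individual other than ``focal`` that
    expressed a variant last step (``last_variant_ids >= 0``).  Sampling is
    proportional to last-step benefit; an all-zero benefit pool degenerates
    to uniform.  Returns -1 when no demonstrator exists (the caller falls
    back to innovation).
    """
    n = last_payoffs.size
    total = 0.0
    count = 0
    for s in range(n):
        if s != focal and last_variant_ids[s] >= 0:
            total += last_payoffs[s]
            count += 1
    if count == 0:
        return -1
    if total <= 0.0:
        k = int(u * count)
        if k >= count:
            k = count - 1
        c = 0
        for s in range(n):
            if s != focal and last_variant_ids[s] >= 0:
                if c == k:
                    return s
                c += 1
        return -1
    uu = u * total
    acc = 0.0
    last = -1
    for s in range(n):
        if s != focal and last_variant_ids[s] >= 0:
            acc += last_payoffs[s]
            last = s
            if uu < acc:
                return s
    return last


# ---------------------------------------------------------------------------
# innovation
# ---------------------------------------------------------------------------

@njit(cache=True)
def _std_normal_pair(u1, u2):
    # Box-Muller; u1 guarded away from 0.
    if u1 < 1e-300:
        u1 = 1e-300
    r = math.sqrt(-2.0 * math.log(u1))
    return r * math.cos(2.0 * math.pi * u2), r * math.sin(2.0 * math.pi * u2)


@njit(cache=True)
def _norm_cdf(z):
    return 0.5 * (1.0 + math.erf(z / _SQRT2))


@njit(cache=True)
def innovate_from_draws(regime, env, eps3, rho_latent, u1, u2, u3):
    """Adaptation values ``(a1, a2)`` of a freshly innovated variant.

    * type1 (0): ``a(current) ~ U[0,1]``, zero in the other state.
    * type2 (1): with probability 0.95 ``a(current) ~ U[0,0.8]`` else
      ``U[0,1]``; zero in the other state.
    * type3 (2): with probability 0.95 ``a(current) ~ U[0,eps3]`` (the
      innovation effectively failed) else ``U[0,1]``; zero in the other state.
    * correlated (3): both values marginally ``U[0,1]`` with Pearson
      correlation set by the Gaussian copula's ``rho_latent``.
    * uniform_both (4): both values independent ``U[0,1]``.

    ``u1, u2`` are uniforms; ``u3`` gates the type2/type3 mixtures.
    """
    if regime == _CORRELATED:
        z1, z2 = _std_normal_pair(u1, u2)
        zc = rho_latent * z1 + math.sqrt(1.0 - rho_latent * rho_latent) * z2
        return _norm_cdf(z1), _norm_cdf(zc)
    if regime == _UNIFORM_BOTH:
        return u1, u2
    if regime == _TYPE1:
        a = u1
    elif regime == _TYPE2:
        a = 0.8 * u1 if u3 < 0.95 else u2
    elif regime == _TYPE3:
        a = eps3 * u1 if u3 < 0.95 else u2
    else:
        raise ValueError("unknown innovation regime code")
    if env == 1:
        return a, 0.0
    return 0.0, a


@njit(cache=True)
def mutate_from_draws(value, mu, sigma, u, z):
    """Trait mutation: with probability ``mu`` add N(0, sigma^2) noise,
    truncated (clipped) into [0, 1]."""
    if u >= mu:
        return value
    v = value + sigma * z
    if v < 0.0:
        return 0.0
    if v > 1.0:
        return 1.0
    return v


# ---------------------------------------------------------------------------
# object-level API (numpy Generator driven)
# ---------------------------------------------------------------------------

def choose_variant(individual: Individual, env: int, rng: np.random.Generator,
                   rule: str = "proportional", tau: float = 0.1) -> int:
    """Sample the repertoire index of the variant the individual considers."""
    if individual.repertoire_size == 0:
        raise ValueError("choice from an empty repertoire")
    a_env = individual.adaptation_values(env)
    rule_code = 0 if rule == "proportional" else 1
    return int(draw_choice_index(a_env, rule_code, tau, rng.random()))


def decide_express(a_chosen: float, rng: np.random.Generator) -> bool:
    """Express the chosen variant with probability equal to its benefit."""
    return rng.random() < a_chosen


def decide_social(xi: float, rng: np.random.Generator) -> bool:
    """Choose social learning (over innovation) with probability ``xi``."""
    return rng.random() < xi


def social_learning_pick(last_payoffs: np.ndarray,
                         last_variants: list[Variant | None],
                         rng: np.random.Generator,
                         exclude: int = -1) -> Variant | None:
    """Copy the variant of a payoff-biased sampled demonstrator.

    Returns ``None`` when no demonstrator exists (e.g. the very first step);
    the caller then falls back to innovation.
    """
    ids = np.array([-1 if v is None else v.id for v in last_variants],
                   dtype=np.int64)
    idx = int(draw_demonstrator(np.asarray(last_payoffs, dtype=np.float64),
                                ids, exclude, rng.random()))
    if idx < 0:
        return None
    return last_variants[idx]


class _IdAllocator:
    """Monotone source of globally unique variant ids."""

    def __init__(self, start: int = 0):
        self._next = start

    def __call__(self) -> int:
        vid = self._next
        self._next += 1
        return vid


def innovate(regime: str, env: int, rng: np.random.Generator, *,
             type3_epsilon: float = 0.001, rho_latent: float = 0.0,
             new_id: int = 0) -> Variant:
    """Create a fresh variant under the named innovation regime."""
    from .config import REGIME_CODES
    code = REGIME_CODES[regime]
    a1, a2 = innovate_from_draws(code, env, type3_epsilon, rho_latent,
                                 rng.random(), rng.random(), rng.random())
    return Variant(id=new_id, a1=float(a1), a2=float(a2))


def add_to_repertoire(individual: Individual, variant: Variant,
                      rng: np.random.Generator,
                      max_repertoire: int = 500) -> int:
    """Insert a variant (no-op if already known); returns its index.

    A duplicate id never grows the repertoire.  If insertion would exceed the
    cap, one existing entry is first removed by a forced forgetting event
    (count-based weights, no protected entry), so the size never exceeds the
    cap.  New entries start at ``n = 1``.
    """
    pos = individual.find(variant.id)
    if pos >= 0:
        return pos
    if individual.repertoire_size >= max_repertoire:
        victim = int(draw_forget_index(individual.counts(), -1, rng.random()))
        del individual.repertoire[victim]
    individual.repertoire.append(RepertoireEntry(variant=variant, n=1))
    return individual.repertoire_size - 1


def record_expression(individual: Individual, variant_id: int, *,
                      benefit: float = 0.0, best_available: float | None = None,
                      from_repertoire: bool = False) -> None:
    """Count one expression of ``variant_id`` and update the observables.

    Only repertoire-sourced expressions can be sub-optimal: the gap to the
    best current-environment variant in the repertoire is accumulated when
    the expressed one is not the best.
    """
    pos = individual.find(variant_id)
    if pos < 0:
        raise KeyError(f"variant {variant_id} not in repertoire")
    individual.repertoire[pos].n += 1
    individual.expressions += 1
    if from_repertoire and best_available is not None and benefit < best_available:
        individual.suboptimal += 1
        individual.suboptimal_gap += best_available - benefit


def forget_step(individual: Individual, expressed_id: int,
                rng: np.random.Generator) -> int:
    """One per-step forgetting event; returns the removed variant id or -1.

    With probability ``phi`` one entry other than the just-expressed variant
    is removed (count-weighted); a size-1 repertoire never forgets.
    """
    protected = individual.find(expressed_id)
    if protected < 0:
        raise KeyError(f"expressed variant {expressed_id} not in repertoire")
    if individual.repertoire_size <= 1:
        return -1
    if rng.random() >= individual.phi:
        return -1
    victim = int(draw_forget_index(individual.counts(), protected,
                                   rng.random()))
    if victim < 0:
        return -1
    removed = individual.repertoire[victim].variant.id
    del individual.repertoire[victim]
    return removed
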