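"""Population-level measurements: fitness, repertoire statistics, sub-optimal
choice statistics, repertoire composition, and preservation probability.

Conventions
-----------
* *Fitness* is the mean expressed benefit over all individuals during the
  final generation (the last N time steps) of a run.
* *Sub-optimal choice* statistics cover only repertoire-sourced expressions:
  an expression is sub-optimal when the expressed variant's benefit is below
  the best current-environment benefit in the repertoire at the moment of
  choice.  "Age-normalized" proportion = lifetime sub-optimal count divided
  by lifetime expression count; magnitude = accumulated gap divided by the
  number of sub-optimal events (0 if none).
* *Composition* histograms are computed per repertoire over the variants
  adapted to the current environment, normalised within each repertoire,
  then averaged over individuals (and over runs at the batch level).
* *Preservation*: a replicate "preserves" standing variation when, at the
  first environmental switch after burn-in (before any learning), at least
  one individual holds a variant with positive adaptation value in the newly
  current state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import SimParams
from .state import Individual

__all__ = [
    "RunSummary",
    "mean_fitness",
    "suboptimal_stats",
    "composition_histogram",
    "preservation_probability",
    "summarize_state",
    "summaries_to_frame",
    "aggregate_summaries",
]

DEFAULT_BINS = np.linspace(0.0, 1.0, 11)


@dataclass
class RunSummary:
    """Observable bundle produced by one simulation run."""

    replicate: int
    seed: int
    env_final: int
    mean_fitness_last_generation: float
    mean_repertoire_size_last_step: float
    mean_adapted_current: float
    mean_adapted_alternative: float
    suboptimal_proportion: float
    suboptimal_magnitude: float
    mean_best_available: float
    mean_expressed: float
    mean_xi_final: float
    mean_phi_final: float
    composition_histogram: np.ndarray = field(
        default_factory=lambda: np.zeros(len(DEFAULT_BINS) - 1))
    preserved_flag: int | None = None


def mean_fitness(benefits: np.ndarray, N: int) -> float:
    """Mean expressed benefit over the final ``N`` steps of a benefit trace.

    ``benefits`` has one row per time step and one column per individual;
    the window is the last generation (N steps).
    """
    benefits = np.asarray(benefits, dtype=np.float64)
    if benefits.ndim != 2:
        raise ValueError("benefits must be a (steps, individuals) matrix")
    if benefits.shape[0] < N:
        raise ValueError(
            f"trace covers {benefits.shape[0]} steps; need at least N={N}")
    return float(benefits[-N:].mean())


def _suboptimal_from_arrays(expr_count: np.ndarray, subopt_count: np.ndarray,
                            subopt_gap: np.ndarray) -> tuple[float, float]:
    expr_count = np.asarray(expr_count, dtype=np.float64)
    subopt_count = np.asarray(subopt_count, dtype=np.float64)
    subopt_gap = np.asarray(subopt_gap, dtype=np.float64)
    alive = expr_count > 0
    if not alive.any():
        return 0.0, 0.0
    proportion = float(np.mean(subopt_count[alive] / expr_count[alive]))
    mags = np.where(subopt_count[alive] > 0,
                    subopt_gap[alive] / np.maximum(subopt_count[alive], 1.0),
                    0.0)
    return proportion, float(np.mean(mags))


def suboptimal_stats(individuals: Iterable[Individual]) -> tuple[float, float]:
    """Population means of the per-individual age-normalized sub-optimal
    choice proportion and magnitude.  Individuals that have never expressed
    are skipped."""
    inds = list(individuals)
    return _suboptimal_from_arrays(
        np.array([i.expressions for i in inds]),
        np.array([i.suboptimal for i in inds]),
        np.array([i.suboptimal_gap for i in inds]))


def composition_histogram(repertoire_values: Sequence[np.ndarray],
                          bin_edges: np.ndarray = DEFAULT_BINS) -> np.ndarray:
    """Average per-repertoire histogram of current-environment adaptation
    values.

    ``repertoire_values`` holds, per individual, the adaptation values (in
    the current environment) of its current-environment-adapted variants.
    Each repertoire's histogram is normalised to 1 before averaging, so every
    individual contributes equal weight; individuals with no such variant
    contribute nothing.  Returns the per-bin fractions (all-zero when no
    individual holds an adapted variant).
    """
    bin_edges = np.asarray(bin_edges, dtype=np.float64)
    acc = np.zeros(len(bin_edges) - 1)
    contributors = 0
    for values in repertoire_values:
        values = np.asarray(values, dtype=np.float64)
        values = values[values > 0.0]
        if values.size == 0:
            continue
        hist, _ = np.histogram(values, bins=bin_edges)
        acc += hist / values.size
        contributors += 1
    if contributors == 0:
        return acc
    return acc / contributors


def preservation_probability(params: SimParams, reps: int | None = None, *,
                             arm: int = 0) -> dict[str, float]:
    """Fraction of replicates preserving alternative-state variation at the
    first post-burn-in environmental switch (with binomial standard error)."""
    from . import engine  # deferred: engine imports this module

    reps = params.reps if reps is None else reps
    hits = 0
    for r in range(reps):
        hits += engine.run_preservation_replicate(params, r, arm=arm)
    p = hits / reps
    return {
        "probability": p,
        "se": float(np.sqrt(p * (1.0 - p) / reps)),
        "reps": reps,
        "preserved": hits,
    }


def summarize_state(params: SimParams, env: int, fitness_sum: float,
                    arrays: dict[str, np.ndarray], *, replicate_index: int,
                    seed: int,
                    bin_edges: np.ndarray = DEFAULT_BINS) -> RunSummary:
    """Build a :class:`RunSummary` from the final kernel state of a run."""
    N = params.N
    rep_m = arrays["rep_m"]
    a_cur = arrays["rep_a1"] if env == 1 else arrays["rep_a2"]
    a_alt = arrays["rep_a2"] if env == 1 else arrays["rep_a1"]

    cur_values = [a_cur[j, :rep_m[j]] for j in range(N)]
    adapted_cur = np.array([(v > 0).sum() for v in cur_values], dtype=float)
    adapted_alt = np.array(
        [(a_alt[j, :rep_m[j]] > 0).sum() for j in range(N)], dtype=float)

    # best available / expressed benefit at the last step; a newborn without
    # a repertoire (non-vertical, transient) is excluded from both
    with_rep = rep_m > 0
    best = np.array([cur_values[j].max() if rep_m[j] > 0 else 0.0
                     for j in range(N)])
    expressed_mask = arrays["last_vid"] >= 0
    mean_expressed = (float(arrays["last_payoff"][expressed_mask].mean())
                      if expressed_mask.any() else 0.0)

    proportion, magnitude = _suboptimal_from_arrays(
        arrays["expr_count"], arrays["subopt_count"], arrays["subopt_gap"])

    return RunSummary(
        replicate=replicate_index,
        seed=seed,
        env_final=int(env),
        mean_fitness_last_generation=float(fitness_sum / (N * N)),
        mean_repertoire_size_last_step=float(rep_m.mean()),
        mean_adapted_current=float(adapted_cur.mean()),
        mean_adapted_alternative=float(adapted_alt.mean()),
        suboptimal_proportion=proportion,
        suboptimal_magnitude=magnitude,
        mean_best_available=(float(best[with_rep].mean())
                             if with_rep.any() else 0.0),
        mean_expressed=mean_expressed,
        mean_xi_final=float(arrays["xi"].mean()),
        mean_phi_final=float(arrays["phi"].mean()),
        composition_histogram=composition_histogram(cur_values, bin_edges),
    )


def summaries_to_frame(summaries: Sequence[RunSummary]) -> pd.DataFrame:
    """Flatten run summaries to a tidy table (histogram -> hist_<i> columns)."""
    rows = []
    for s in summaries:
        row = {k: v for k, v in s.__dict__.items()
               if k != "composition_histogram"}
        for i, frac in enumerate(s.composition_histogram):
            row[f"hist_{i}"] = float(frac)
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_summaries(summaries: Sequence[RunSummary]) -> pd.DataFrame:
    """One-row aggregate: mean and Monte-Carlo standard error per observable."""
    df = summaries_to_frame(summaries)
    out: dict[str, float] = {"reps": len(summaries)}
    skip = {"replicate", "seed", "env_final", "preserved_flag"}
    for col in df.columns:
        if col in skip or not np.issubdtype(df[col].dtype, np.number):
            continue
        values = df[col].to_numpy(dtype=float)
        out[col] = float(values.mean())
        out[f"{col}_se"] = (float(values.std(ddof=1) / np.sqrt(len(values)))
                            if len(values) > 1 else 0.0)
    return pd.DataFrame([out])
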