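"""Time-step scheduler, replicate runner, and paired experiment driver.

Within one time step the events are ordered:

1. environment update (switch with probability ``p_env``),
2. every individual's expression event — repertoire choice, the
   express-vs-learn gate, payoff-biased social learning or innovation —
   observing the *previous* step's payoffs as the social pool,
3. every individual's forgetting event (the variant expressed this step is
   protected),
4. one birth-death event driven by *this* step's payoffs,
5. age increment for everyone (the newborn enters its first full step at
   age 1).

The step loop is a numba kernel over flat arrays: per-individual repertoires
live in fixed-capacity rows (adaptation values, expression counts, ids).
All stochastic transformations are the shared explicit-draw functions from
:mod:`vertlearn.agents`, fed by numba's sequential RNG seeded once per run,
so a run is bitwise reproducible from ``(params, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

from .agents import (
    draw_choice_index,
    draw_demonstrator,
    draw_forget_index,
    draw_weighted,
    innovate_from_draws,
    mutate_from_draws,
)
from .config import SimParams, replicate_seed
from . import observables

__all__ = ["run_simulation", "run_batch", "run_paired_experiment",
           "run_preservation_replicate", "SimulationResult"]

# expression-event source codes
SOURCE_REPERTOIRE, SOURCE_SOCIAL, SOURCE_INNOVATION = 0, 1, 2


@njit(cache=True)
def _remove_entry(rep_a1, rep_a2, rep_n, rep_id, j, idx, m):
    # O(1) removal: move the last entry into the vacated slot.
    last = m - 1
    rep_a1[j, idx] = rep_a1[j, last]
    rep_a2[j, idx] = rep_a2[j, last]
    rep_n[j, idx] = rep_n[j, last]
    rep_id[j, idx] = rep_id[j, last]
    return last


@njit(cache=True)
def _run_kernel(seed, N, max_rep, burn_in, run_steps, p_env, regime, rule, tau,
                vertical, mu_xi, mu_phi, sd_xi, sd_phi, xi0, phi0, eps3, rho_l,
                count_ins, preserve_mode, max_extra,
                rep_a1, rep_a2, rep_n, rep_id, rep_m,
                age, xi, phi,
                last_payoff, last_vid, last_va1, last_va2,
                expr_count, subopt_count, subopt_gap,
                trace_on, trace,
                log_on, log_benefit, log_source, log_best, log_vid,
                log_forgot, log_parent, log_death):
    np.random.seed(seed)
    env = 1
    next_vid = 0
    # founders: uniform ages on {0..N-1}, one innovated variant each (n=1)
    for j in range(N):
        age[j] = np.random.randint(0, N)
        xi[j] = xi0
        phi[j] = phi0
        a1, a2 = innovate_from_draws(regime, env, eps3, rho_l,
                                     np.random.random(), np.random.random(),
                                     np.random.random())
        rep_a1[j, 0] = a1
        rep_a2[j, 0] = a2
        rep_n[j, 0] = 1
        rep_id[j, 0] = next_vid
        next_vid += 1
        rep_m[j] = 1
        last_payoff[j] = 0.0
        last_vid[j] = -1
        last_va1[j] = 0.0
        last_va2[j] = 0.0
        expr_count[j] = 0
        subopt_count[j] = 0
        subopt_gap[j] = 0.0

    total = burn_in + run_steps
    fit_sum = 0.0
    preserved = -1
    new_payoff = np.empty(N, dtype=np.float64)
    new_vid = np.empty(N, dtype=np.int64)
    new_va1 = np.empty(N, dtype=np.float64)
    new_va2 = np.empty(N, dtype=np.float64)
    expressed_idx = np.empty(N, dtype=np.int64)
    t = 0
    while True:
        # (1) environment update
        if np.random.random() < p_env:
            env = 3 - env
            if preserve_mode == 1 and t >= burn_in:
                # stop at the first post-burn-in switch, before any learning:
                # is a variant adapted to the newly current state preserved?
                preserved = 0
                for j in range(N):
                    for s in range(rep_m[j]):
                        a_new = rep_a1[j, s] if env == 1 else rep_a2[j, s]
                        if a_new > 0.0:
                            preserved = 1
                            break
                    if preserved == 1:
                        break
                break

        # (2) expression events (social pool frozen at last step's payoffs)
        for j in range(N):
            m = rep_m[j]
            expressed = False
            e_idx = -1
            benefit = 0.0
            vid = -1
            va1 = 0.0
            va2 = 0.0
            source = SOURCE_INNOVATION
            best = -1.0
            if m > 0:
                a_env = rep_a1[j, :m] if env == 1 else rep_a2[j, :m]
                ci = draw_choice_index(a_env, rule, tau, np.random.random())
                a_chosen = a_env[ci]
                if np.random.random() < a_chosen:
                    expressed = True
                    e_idx = ci
                    benefit = a_chosen
                    vid = rep_id[j, ci]
                    va1 = rep_a1[j, ci]
                    va2 = rep_a2[j, ci]
                    rep_n[j, ci] += 1
                    source = SOURCE_REPERTOIRE
                    best = 0.0
                    for s in range(m):
                        av = rep_a1[j, s] if env == 1 else rep_a2[j, s]
                        if av > best:
                            best = av
                    if benefit < best:
                        subopt_count[j] += 1
                        subopt_gap[j] += best - benefit
            if not expressed:
                got_social = False
                if np.random.random() < xi[j]:
                    pick = draw_demonstrator(last_payoff, last_vid, j,
                                             np.random.random())
                    if pick >= 0:
                        vid = last_vid[pick]
                        va1 = last_va1[pick]
                        va2 = last_va2[pick]
                        got_social = True
                        source = SOURCE_SOCIAL
                if not got_social:
                    va1, va2 = innovate_from_draws(
                        regime, env, eps3, rho_l, np.random.random(),
                        np.random.random(), np.random.random())
                    vid = next_vid
                    next_vid += 1
                    source = SOURCE_INNOVATION
                benefit = va1 if env == 1 else va2
                # insert if unknown (duplicates never grow the repertoire)
                pos = -1
                for s in range(rep_m[j]):
                    if rep_id[j, s] == vid:
                        pos = s
                        break
                if pos < 0:
                    if rep_m[j] >= max_rep:
                        victim = draw_forget_index(rep_n[j, :rep_m[j]], -1,
                                                   np.random.random())
                        _remove_entry(rep_a1, rep_a2, rep_n, rep_id, j,
                                      victim, rep_m[j])
                        rep_m[j] -= 1
                    pos = rep_m[j]
                    rep_a1[j, pos] = va1
                    rep_a2[j, pos] = va2
                    rep_id[j, pos] = vid
                    rep_n[j, pos] = 2 if count_ins == 1 else 1
                    rep_m[j] += 1
                else:
                    rep_n[j, pos] += 1
                e_idx = pos
            expr_count[j] += 1
            new_payoff[j] = benefit
            new_vid[j] = vid
            new_va1[j] = va1
            new_va2[j] = va2
            expressed_idx[j] = e_idx
            if log_on == 1:
                log_benefit[t, j] = benefit
                log_source[t, j] = source
                log_best[t, j] = best
                log_vid[t, j] = vid
                log_forgot[t, j] = -1

        # fitness window: final N steps of the run
        if preserve_mode == 0 and t >= total - N:
            for j in range(N):
                fit_sum += new_payoff[j]

        # (3) forgetting (expressed variant protected; size-1 never forgets)
        for j in range(N):
            if rep_m[j] > 1 and np.random.random() < phi[j]:
                victim = draw_forget_index(rep_n[j, :rep_m[j]],
                                           expressed_idx[j],
                                           np.random.random())
                if victim >= 0:
                    if log_on == 1:
                        log_forgot[t, j] = rep_id[j, victim]
                    _remove_entry(rep_a1, rep_a2, rep_n, rep_id, j, victim,
                                  rep_m[j])
                    rep_m[j] -= 1

        # commit this step's expressions as the next step's social pool
        for j in range(N):
            last_payoff[j] = new_payoff[j]
            last_vid[j] = new_vid[j]
            last_va1[j] = new_va1[j]
            last_va2[j] = new_va2[j]

        # (4) birth-death on this step's payoffs
        parent = draw_weighted(new_payoff, np.random.random())
        cxi = mutate_from_draws(xi[parent], mu_xi, sd_xi, np.random.random(),
                                np.random.normal())
        cphi = mutate_from_draws(phi[parent], mu_phi, sd_phi,
                                 np.random.random(), np.random.normal())
        death = draw_weighted(age.astype(np.float64), np.random.random())
        if log_on == 1:
            log_parent[t] = parent
            log_death[t] = death
        pm = rep_m[parent]
        if vertical == 1:
            if death != parent:
                for s in range(pm):
                    rep_a1[death, s] = rep_a1[parent, s]
                    rep_a2[death, s] = rep_a2[parent, s]
                    rep_id[death, s] = rep_id[parent, s]
                    rep_n[death, s] = 1
            else:
                for s in range(pm):
                    rep_n[death, s] = 1
            rep_m[death] = pm
        else:
            rep_m[death] = 0
        xi[death] = cxi
        phi[death] = cphi
        age[death] = 0
        last_payoff[death] = 0.0
        last_vid[death] = -1
        last_va1[death] = 0.0
        last_va2[death] = 0.0
        expr_count[death] = 0
        subopt_count[death] = 0
        subopt_gap[death] = 0.0

        # (5) aging
        for j in range(N):
            age[j] += 1

        if trace_on == 1:
            mp = 0.0
            mm = 0.0
            mx = 0.0
            mf = 0.0
            for j in range(N):
                mp += new_payoff[j]
                mm += rep_m[j]
                mx += xi[j]
                mf += phi[j]
            trace[t, 0] = env
            trace[t, 1] = mp / N
            trace[t, 2] = mm / N
            trace[t, 3] = mx / N
            trace[t, 4] = mf / N

        t += 1
        if preserve_mode == 0:
            if t >= total:
                break
        else:
            if t >= burn_in + max_extra:
                break
    return env, fit_sum, preserved, t, next_vid


@dataclass
class SimulationResult:
    """Raw final-state bundle of one run (arrays trimmed to repertoire size)."""

    params: SimParams
    seed: int
    env: int
    steps: int
    fitness_sum: float
    summary: "observables.RunSummary"
    trace: pd.DataFrame | None = None
    event_log: dict[str, np.ndarray] | None = None
    final_state: dict[str, np.ndarray] = field(default_factory=dict)


def _allocate(params: SimParams, trace: bool, event_log: bool):
    N, cap = params.N, params.max_repertoire
    total = params.total_steps
    arrays = dict(
        rep_a1=np.zeros((N, cap)), rep_a2=np.zeros((N, cap)),
        rep_n=np.zeros((N, cap), dtype=np.int64),
        rep_id=np.full((N, cap), -1, dtype=np.int64),
        rep_m=np.zeros(N, dtype=np.int64),
        age=np.zeros(N, dtype=np.int64),
        xi=np.zeros(N), phi=np.zeros(N),
        last_payoff=np.zeros(N), last_vid=np.full(N, -1, dtype=np.int64),
        last_va1=np.zeros(N), last_va2=np.zeros(N),
        expr_count=np.zeros(N, dtype=np.int64),
        subopt_count=np.zeros(N, dtype=np.int64),
        subopt_gap=np.zeros(N),
    )
    trace_arr = np.zeros((total if trace else 0, 5))
    if event_log:
        if total * N > 5_000_000:
            raise ValueError("event log supported only for small runs")
        log = dict(
            log_benefit=np.zeros((total, N)),
            log_source=np.zeros((total, N), dtype=np.int64),
            log_best=np.zeros((total, N)),
            log_vid=np.zeros((total, N), dtype=np.int64),
            log_forgot=np.full((total, N), -1, dtype=np.int64),
            log_parent=np.full(total, -1, dtype=np.int64),
            log_death=np.full(total, -1, dtype=np.int64),
        )
    else:
        log = dict(
            log_benefit=np.zeros((0, 0)),
            log_source=np.zeros((0, 0), dtype=np.int64),
            log_best=np.zeros((0, 0)),
            log_vid=np.zeros((0, 0), dtype=np.int64),
            log_forgot=np.zeros((0, 0), dtype=np.int64),
            log_parent=np.zeros(0, dtype=np.int64),
            log_death=np.zeros(0, dtype=np.int64),
        )
    return arrays, trace_arr, log


def _kernel_args(params: SimParams, seed: int, preserve: bool,
                 max_extra: int, arrays, trace_arr, log, trace: bool,
                 event_log: bool):
    return (
        seed, params.N, params.max_repertoire, params.burn_in_steps,
        params.run_steps, params.p_env, params.regime_code, params.rule_code,
        params.softmax_tau, 1 if params.vertical else 0,
        params.mu_xi, params.mu_phi, params.sigma_xi, params.sigma_phi,
        params.xi_init, params.phi_init, params.type3_epsilon,
        params.rho_latent, 1 if params.count_insertion_expression else 0,
        1 if preserve else 0, max_extra,
        arrays["rep_a1"], arrays["rep_a2"], arrays["rep_n"], arrays["rep_id"],
        arrays["rep_m"], arrays["age"], arrays["xi"], arrays["phi"],
        arrays["last_payoff"], arrays["last_vid"], arrays["last_va1"],
        arrays["last_va2"], arrays["expr_count"], arrays["subopt_count"],
        arrays["subopt_gap"],
        1 if trace else 0, trace_arr,
        1 if event_log else 0, log["log_benefit"], log["log_source"],
        log["log_best"], log["log_vid"], log["log_forgot"],
        log["log_parent"], log["log_death"],
    )


def run_simulation(params: SimParams, replicate_index: int = 0, *,
                   trace: bool = False,
                   event_log: bool = False) -> SimulationResult:
    """Execute one full run (burn-in + recorded window) and summarise it.

    The observables are computed on the post-burn-in window: mean fitness over
    the final generation (N steps), repertoire size/composition and
    sub-optimal-choice statistics at the final step.  ``trace`` records a
    per-step table (environment, mean payoff, mean repertoire size, mean xi,
    mean phi); ``event_log`` records every expression/forgetting/birth-death
    event (small runs only) for brute-force cross-checks.
    """
    seed = replicate_seed(params.seed, replicate_index)
    arrays, trace_arr, log = _allocate(params, trace, event_log)
    env, fit_sum, _, steps, _ = _run_kernel(
        *_kernel_args(params, seed, False, 0, arrays, trace_arr, log,
                      trace, event_log))
    summary = observables.summarize_state(
        params, env, fit_sum, arrays, replicate_index=replicate_index,
        seed=seed)
    trace_df = None
    if trace:
        trace_df = pd.DataFrame(
            trace_arr, columns=["env", "mean_payoff", "mean_repertoire_size",
                                "mean_xi", "mean_phi"])
        trace_df.insert(0, "t", np.arange(len(trace_df)))
    return SimulationResult(
        params=params, seed=seed, env=env, steps=steps, fitness_sum=fit_sum,
        summary=summary, trace=trace_df,
        event_log=log if event_log else None, final_state=arrays)


def run_preservation_replicate(params: SimParams,
                               replicate_index: int = 0,
                               arm: int = 0) -> int:
    """Run burn-in, continue to the first environmental switch, and report
    whether any individual then holds a variant adapted to the newly current
    state (1 preserved / 0 lost)."""
    seed = replicate_seed(params.seed, replicate_index, arm=arm)
    arrays, trace_arr, log = _allocate(params, False, False)
    # cap the post-burn-in wait; P(no switch within 50*T_change) = e^-50
    max_extra = int(50 * params.T_change) + 1
    _, _, preserved, _, _ = _run_kernel(
        *_kernel_args(params, seed, True, max_extra, arrays, trace_arr, log,
                      False, False))
    if preserved < 0:
        raise RuntimeError("no environmental switch observed within the cap")
    return int(preserved)


def run_batch(params: SimParams, reps: int | None = None, *,
              arm: int = 0) -> tuple[list["observables.RunSummary"], pd.DataFrame]:
    """Run ``reps`` independent replicates on derived seeds.

    Returns the per-run summaries and a one-row aggregate with the mean and
    Monte-Carlo standard error of every scalar observable.
    """
    reps = params.reps if reps is None else reps
    summaries = []
    for r in range(reps):
        seed = replicate_seed(params.seed, r, arm=arm)
        arrays, trace_arr, log = _allocate(params, False, False)
        env, fit_sum, _, _, _ = _run_kernel(
            *_kernel_args(params, seed, False, 0, arrays, trace_arr, log,
                          False, False))
        summaries.append(observables.summarize_state(
            params, env, fit_sum, arrays, replicate_index=r, seed=seed))
    agg = observables.aggregate_summaries(summaries)
    return summaries, agg


def run_paired_experiment(params_grid: Sequence[SimParams],
                          reps: int | None = None) -> pd.DataFrame:
    """Vertical vs no-vertical fitness comparison over a parameter grid.

    For each grid point two batches are run on independent seed streams, one
    with and one without vertical learning; the table reports the mean fitness
    of each arm and the vertical-minus-nonvertical difference with its
    standard error.
    """
    rows = []
    for base in params_grid:
        r = base.reps if reps is None else reps
        _, agg_v = run_batch(base.replace(vertical=True), r, arm=0)
        _, agg_n = run_batch(base.replace(vertical=False), r, arm=1)
        fit_v = float(agg_v["mean_fitness_last_generation"].iloc[0])
        fit_n = float(agg_n["mean_fitness_last_generation"].iloc[0])
        se_v = float(agg_v["mean_fitness_last_generation_se"].iloc[0])
        se_n = float(agg_n["mean_fitness_last_generation_se"].iloc[0])
        rows.append({
            "T_change": base.T_change,
            "p_env": base.p_env,
            "regime": base.innovation_regime,
            "choice_rule": base.choice_rule,
            "reps": r,
            "fitness_vertical": fit_v,
            "fitness_vertical_se": se_v,
            "fitness_nonvertical": fit_n,
            "fitness_nonvertical_se": se_n,
            "fitness_difference": fit_v - fit_n,
            "fitness_difference_se": float(np.hypot(se_v, se_n)),
        })
    return pd.DataFrame(rows)
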