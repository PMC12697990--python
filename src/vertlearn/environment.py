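"""Two-state fluctuating environment process.

The environment E(t) takes values in {1, 2} and switches to the other state
with probability ``p_env`` at every time step, independently of its history,
so the waiting time between consecutive switches is geometric with mean
``T_change = 1/p_env``.  The environment update is the first event of each
time step: expression and payoff-biased copying within step t all see E(t).
"""

from __future__ import annotations

import numpy as np

__all__ = ["step_environment", "mean_waiting_time", "simulate_switch_intervals",
           "waiting_time_stats"]


def step_environment(env: int, p_env: float, rng: np.random.Generator) -> int:
    """Advance the environment one step: switch with probability ``p_env``."""
    if env not in (1, 2):
        raise ValueError(f"environment state must be 1 or 2, got {env!r}")
    if rng.random() < p_env:
        return 3 - env
    return env


def mean_waiting_time(p_env: float) -> float:
    """Mean stasis time between two switches, ``T_change = 1/p_env``."""
    if not 0.0 < p_env <= 1.0:
        raise ValueError(f"p_env must lie in (0, 1], got {p_env!r}")
    return 1.0 / p_env


def simulate_switch_intervals(p_env: float, n_switches: int,
                              rng: np.random.Generator,
                              chunk: int = 1_000_000) -> np.ndarray:
    """Run the switching process and collect ``n_switches`` inter-switch gaps.

    The process is stepped explicitly (in vectorised chunks): each step the
    state flips with probability ``p_env``; intervals are the gaps between
    consecutive flip times.
    """
    if not 0.0 < p_env <= 1.0:
        raise ValueError(f"p_env must lie in (0, 1], got {p_env!r}")
    if n_switches < 2:
        raise ValueError("need at least 2 switches to form an interval")
    switch_times: list[np.ndarray] = []
    collected = 0
    offset = 0
    while collected < n_switches:
        flips = rng.random(chunk) < p_env
        times = np.flatnonzero(flips) + offset
        switch_times.append(times)
        collected += times.size
        offset += chunk
    times = np.concatenate(switch_times)[:n_switches]
    return np.diff(times).astype(np.int64)


def waiting_time_stats(p_env: float, n_switches: int,
                       rng: np.random.Generator) -> dict[str, float]:
    """Empirical mean/variance of inter-switch intervals plus standard error."""
    intervals = simulate_switch_intervals(p_env, n_switches, rng)
    mean = float(intervals.mean())
    var = float(intervals.var(ddof=1))
    return {
        "mean": mean,
        "var": var,
        "se": float(np.sqrt(var / intervals.size)),
        "n": int(intervals.size),
    }
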