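"""Small deterministic model objects for tests, docs and examples."""

from __future__ import annotations

import numpy as np

from .config import SimParams
from .state import Individual, PopulationState, RepertoireEntry, Variant

__all__ = ["make_fixture"]


def _repertoire(seed: int) -> list[RepertoireEntry]:
    rng = np.random.default_rng(seed)
    entries = []
    for vid in range(4):
        a1 = round(float(rng.random()), 2)
        entries.append(RepertoireEntry(
            variant=Variant(id=vid, a1=a1, a2=0.0),
            n=int(rng.integers(1, 6))))
    return entries


def _population(seed: int) -> PopulationState:
    rng = np.random.default_rng(seed)
    individuals = []
    for j in range(10):
        ind = Individual(id=j, xi=0.2, phi=0.2, age=int(rng.integers(0, 10)),
                         repertoire=_repertoire(seed + 100 + j))
        ind.last_payoff = round(float(rng.random()), 2)
        individuals.append(ind)
    return PopulationState(individuals=individuals, env=1, t=0)


def _trace(seed: int) -> dict:
    # a genuine short run with full event logging, usable by brute-force
    # recomputation of the sub-optimal-choice observables
    from .engine import run_simulation

    params = SimParams(N=10, burn_in_steps=100, run_steps=100, seed=seed,
                       reps=1, innovation_regime="type1")
    result = run_simulation(params, event_log=True)
    return {"params": params, "result": result, "log": result.event_log}


def make_fixture(kind: str, seed: int = 1):
    """Return a deterministic test object.

    ``kind`` is one of ``repertoire`` (4 fixed-value entries), ``population``
    (a valid N=10 population) or ``trace`` (a short fully-logged run).
    """
    if kind == "repertoire":
        return _repertoire(seed)
    if kind == "population":
        return _population(seed)
    if kind == "trace":
        return _trace(seed)
    raise ValueError(f"unknown fixture kind {kind!r}")
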