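"""Domain objects: variants, repertoire entries, individuals, populations.

These lightweight dataclasses are the object-level view of the model state,
used at the API boundary (fixtures, examples, unit tests, documentation).
The simulation engine itself runs on flat numpy arrays for speed; helpers
here convert between the two representations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Variant:
    """A cultural variant with one adaptation value per environmental state.

    ``a1``/``a2`` are the benefits (in [0, 1]) the variant confers in
    environmental states 1 and 2.  Under the single-state innovation regimes
    (type1/type2/type3) at most one of the two is positive.
    """

    id: int
    a1: float
    a2: float

    def adaptation(self, env: int) -> float:
        return self.a1 if env == 1 else self.a2


@dataclass
class RepertoireEntry:
    """A variant held by an individual, with its expression count ``n``."""

    variant: Variant
    n: int = 1


@dataclass
class Individual:
    """One agent: age, evolvable traits, cultural repertoire and counters.

    ``xi`` is the propensity to choose social learning over innovation,
    ``phi`` the per-step forgetting probability.  The cumulative counters
    feed the sub-optimal-choice observables.
    """

    id: int
    xi: float
    phi: float
    age: int = 0
    repertoire: list[RepertoireEntry] = field(default_factory=list)
    last_payoff: float = 0.0
    expressions: int = 0
    suboptimal: int = 0
    suboptimal_gap: float = 0.0

    @property
    def repertoire_size(self) -> int:
        return len(self.repertoire)

    def adaptation_values(self, env: int) -> np.ndarray:
        """Adaptation values of the repertoire in environment ``env``."""
        return np.array([e.variant.adaptation(env) for e in self.repertoire],
                        dtype=np.float64)

    def counts(self) -> np.ndarray:
        return np.array([e.n for e in self.repertoire], dtype=np.int64)

    def find(self, variant_id: int) -> int:
        """Index of ``variant_id`` in the repertoire, or -1."""
        for i, entry in enumerate(self.repertoire):
            if entry.variant.id == variant_id:
                return i
        return -1


@dataclass
class ExpressionOutcome:
    """The result of one expression event.

    ``source`` says where the expressed variant came from (``repertoire``,
    ``social`` or ``innovation``); ``benefit`` is its adaptation value in the
    current environment.  Only repertoire-sourced expressions can be
    sub-optimal: ``suboptimal_gap`` is the distance to the best
    current-environment variant in the repertoire at the moment of choice
    (0 whenever ``suboptimal_flag`` is false).
    """

    variant_id: int
    benefit: float
    source: str
    suboptimal_flag: bool = False
    suboptimal_gap: float = 0.0

    def __post_init__(self) -> None:
        if self.source not in ("repertoire", "social", "innovation"):
            raise ValueError(f"unknown expression source {self.source!r}")
        if not self.suboptimal_flag and self.suboptimal_gap != 0.0:
            raise ValueError("suboptimal_gap must be 0 for optimal choices")
        if not 0.0 <= self.benefit <= 1.0:
            raise ValueError("benefit must lie in [0, 1]")


@dataclass
class PopulationState:
    """N individuals, the current environmental state and the time step."""

    individuals: list[Individual]
    env: int = 1
    t: int = 0

    @property
    def N(self) -> int:
        return len(self.individuals)

    def last_payoffs(self) -> np.ndarray:
        return np.array([ind.last_payoff for ind in self.individuals],
                        dtype=np.float64)
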