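"""Birth-death process, vertical inheritance, and trait mutation.

Each time step exactly one individual reproduces and one dies (overlapping
generations, constant population size N).  The parent is chosen
proportionally to the benefit generated this step, ``v_j = a_j / sum_s a_s``;
death is age-proportional (older individuals more likely to die), with the
step's newborn excluded.  Offspring inherit the parent's trait values xi and
phi, each perturbed with probability ``mu`` by truncated Gaussian noise.
Under vertical learning the offspring also inherits a copy of the parent's
entire repertoire with every expression count reset to 1; without it the
offspring is born culturally naive.
"""

from __future__ import annotations

import numpy as np

from .agents import draw_weighted, mutate_from_draws
from .config import SimParams
from .state import Individual, RepertoireEntry, Variant

__all__ = [
    "select_parent",
    "select_death",
    "mutate_trait",
    "make_offspring",
    "birth_death_step",
]


def select_parent(current_payoffs: np.ndarray, rng: np.random.Generator) -> int:
    """Fitness-proportional parent choice on this step's payoffs.

    An all-zero payoff vector (transient, e.g. right after an environmental
    switch in a maladapted population) degenerates to a uniform choice.
    """
    payoffs = np.asarray(current_payoffs, dtype=np.float64)
    return int(draw_weighted(payoffs, rng.random()))


def select_death(ages: np.ndarray, rng: np.random.Generator,
                 exclude: int = -1) -> int:
    """Age-proportional death choice; ``exclude`` shields the newborn.

    Age-0 individuals carry zero weight.  If every eligible age is zero
    (degenerate initialisation only) the choice is uniform.
    """
    ages = np.asarray(ages, dtype=np.float64)
    if exclude < 0:
        return int(draw_weighted(ages, rng.random()))
    weights = ages.copy()
    weights[exclude] = 0.0
    if weights.sum() <= 0.0:
        # uniform over the non-excluded set
        weights[:] = 1.0
        weights[exclude] = 0.0
    return int(draw_weighted(weights, rng.random()))


def mutate_trait(value: float, mu: float, sigma2: float,
                 rng: np.random.Generator) -> float:
    """With probability ``mu`` add N(0, sigma2) noise, clipped into [0, 1]."""
    return float(mutate_from_draws(value, mu, float(np.sqrt(sigma2)),
                                   rng.random(), rng.standard_normal()))


def make_offspring(parent: Individual, vertical: bool,
                   rng: np.random.Generator, params: SimParams,
                   new_id: int = 0) -> Individual:
    """Create a newborn from ``parent``.

    Traits are the parent's values passed through :func:`mutate_trait`.  With
    vertical learning the repertoire is a deep copy of the parent's with all
    expression counts reset to 1 (inherited variants start equally forgettable);
    without it the repertoire is empty until the newborn's first expression
    event, which must go through social learning or innovation.
    """
    xi = mutate_trait(parent.xi, params.mu_xi, params.sigma2_xi, rng)
    phi = mutate_trait(parent.phi, params.mu_phi, params.sigma2_phi, rng)
    repertoire: list[RepertoireEntry] = []
    if vertical:
        repertoire = [
            RepertoireEntry(variant=Variant(e.variant.id, e.variant.a1,
                                            e.variant.a2), n=1)
            for e in parent.repertoire
        ]
    return Individual(id=new_id, xi=xi, phi=phi, age=0, repertoire=repertoire)


def birth_death_step(population, current_payoffs: np.ndarray, vertical: bool,
                     rng: np.random.Generator, params: SimParams) -> int:
    """One Moran event on a :class:`~vertlearn.state.PopulationState`.

    Selects a parent on this step's payoffs, replaces the age-selected dying
    individual (the newborn is excluded from death) and increments every
    survivor's age, so the newborn enters its first full step at age 1.
    Returns the index of the replaced individual.  Population size is
    conserved exactly.
    """
    inds = population.individuals
    parent_idx = select_parent(current_payoffs, rng)
    parent = inds[parent_idx]
    child = make_offspring(parent, vertical, rng, params,
                           new_id=max(i.id for i in inds) + 1)
    ages = np.array([i.age for i in inds], dtype=np.float64)
    # The newborn is not yet part of the population, so no explicit exclusion
    # index is needed; the parent itself may die.
    death_idx = select_death(ages, rng)
    inds[death_idx] = child
    for ind in inds:
        ind.age += 1
    return death_idx
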