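"""Simulation parameters, validation, and configuration file handling.

The model simulates an age-structured population of ``N`` individuals in a
two-state environment that switches with per-step probability ``p_env``
(equivalently, mean stasis time ``T_change = 1/p_env``).  Individuals carry
cultural repertoires of variants, each variant holding one adaptation value
per environmental state, and two evolvable traits: the social-learning
propensity ``xi`` and the forgetting probability ``phi``.

All parameters live in :class:`SimParams`; :func:`validate_params` builds a
validated instance from a raw mapping (e.g. a parsed YAML file plus CLI
overrides).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import yaml

#: Innovation regimes.  type1/type2/type3 produce variants adapted to the
#: current environmental state only; `correlated` draws negatively correlated
#: adaptation values for both states; `uniform_both` draws both independently.
REGIMES = ("type1", "type2", "type3", "correlated", "uniform_both")
CHOICE_RULES = ("proportional", "softmax")

REGIME_CODES = {name: i for i, name in enumerate(REGIMES)}
RULE_CODES = {name: i for i, name in enumerate(CHOICE_RULES)}


class ParameterError(ValueError):
    """A configuration value is missing, out of range, or inconsistent."""


@dataclass
class SimParams:
    """Full parameter set for one simulation configuration.

    Defaults are the model's standard operating point: N = 200 individuals,
    50 000 burn-in plus 50 000 recorded steps (500 generations of N steps),
    initial trait values xi = phi = 0.2, mutation probability 0.05 and
    mutation variance 0.1 for both traits.
    """

    N: int = 200
    p_env: float = 0.005
    innovation_regime: str = "type1"
    choice_rule: str = "proportional"
    softmax_tau: float = 0.1
    vertical: bool = True
    mu_xi: float = 0.05
    mu_phi: float = 0.05
    sigma2_xi: float = 0.1
    sigma2_phi: float = 0.1
    xi_init: float = 0.2
    phi_init: float = 0.2
    burn_in_steps: int = 50_000
    run_steps: int = 50_000
    max_repertoire: int = 500
    reps: int = 3000
    seed: int = 0
    rho: float = -0.9
    type3_epsilon: float = 0.001
    # Convention for a newly learned/innovated variant that is immediately
    # expressed: insert with n=1, then count the expression (n becomes 2).
    # Set False to leave the insertion-expression at n=1.
    count_insertion_expression: bool = True

    def __post_init__(self) -> None:
        self.validate()

    # -- derived quantities -------------------------------------------------

    @property
    def T_change(self) -> float:
        """Mean environmental stasis time, 1/p_env."""
        return 1.0 / self.p_env

    @property
    def total_steps(self) -> int:
        return self.burn_in_steps + self.run_steps

    @property
    def generations(self) -> float:
        """Elapsed generations; one generation is N time steps."""
        return self.total_steps / self.N

    @property
    def regime_code(self) -> int:
        return REGIME_CODES[self.innovation_regime]

    @property
    def rule_code(self) -> int:
        return RULE_CODES[self.choice_rule]

    @property
    def sigma_xi(self) -> float:
        return math.sqrt(self.sigma2_xi)

    @property
    def sigma_phi(self) -> float:
        return math.sqrt(self.sigma2_phi)

    @property
    def rho_latent(self) -> float:
        """Latent-normal correlation of the Gaussian copula whose uniform
        marginals have Pearson correlation ``rho`` (closed form
        ``2*sin(pi*rho/6)``)."""
        return 2.0 * math.sin(math.pi * self.rho / 6.0)

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        def check(cond: bool, name: str, msg: str) -> None:
            if not cond:
                raise ParameterError(f"{name}: {msg} (got {getattr(self, name)!r})")

        check(isinstance(self.N, (int, np.integer)) and self.N >= 2, "N",
              "population size must be an integer >= 2")
        check(0.0 < self.p_env <= 1.0, "p_env", "must lie in (0, 1]")
        check(self.innovation_regime in REGIMES, "innovation_regime",
              f"must be one of {REGIMES}")
        check(self.choice_rule in CHOICE_RULES, "choice_rule",
              f"must be one of {CHOICE_RULES}")
        check(self.softmax_tau > 0.0, "softmax_tau", "temperature must be > 0")
        for name in ("mu_xi", "mu_phi", "xi_init", "phi_init"):
            check(0.0 <= getattr(self, name) <= 1.0, name, "must lie in [0, 1]")
        for name in ("sigma2_xi", "sigma2_phi"):
            check(getattr(self, name) >= 0.0, name, "variance must be >= 0")
        check(self.burn_in_steps >= 0, "burn_in_steps", "must be >= 0")
        check(self.run_steps >= self.N, "run_steps",
              "must cover at least one generation (N steps)")
        check(self.max_repertoire >= 1, "max_repertoire", "must be >= 1")
        check(self.reps >= 1, "reps", "must be >= 1")
        check(-1.0 < self.rho < 1.0, "rho", "correlation must lie in (-1, 1)")
        check(0.0 < self.type3_epsilon <= 1.0, "type3_epsilon",
              "must lie in (0, 1]")

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    def replace(self, **kwargs: Any) -> "SimParams":
        return dataclasses.replace(self, **kwargs)


_FIELD_NAMES = {f.name for f in dataclasses.fields(SimParams)}


def validate_params(raw: Mapping[str, Any]) -> SimParams:
    """Build a validated :class:`SimParams` from a raw key/value mapping.

    ``T_change`` may be given instead of ``p_env`` (the two are related by
    ``p_env = 1/T_change``); supplying both is an error.  Unknown keys are
    rejected, missing keys take their defaults.
    """
    raw = dict(raw)
    t_change = raw.pop("T_change", None)
    if t_change is not None:
        if "p_env" in raw:
            raise ParameterError("provide either p_env or T_change, not both")
        if not t_change >= 1.0:
            raise ParameterError(f"T_change: must be >= 1 (got {t_change!r})")
        raw["p_env"] = 1.0 / float(t_change)
    unknown = set(raw) - _FIELD_NAMES
    if unknown:
        raise ParameterError(f"unknown parameter(s): {sorted(unknown)}")
    return SimParams(**raw)


def load_config(path: str) -> dict[str, Any]:
    """Read a YAML config file into a raw mapping (may be empty)."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ParameterError(f"config file {path!r} must contain a mapping")
    return data


def params_from_config(path: str | None, **overrides: Any) -> SimParams:
    """Merge a config file (optional) with keyword overrides and validate."""
    raw: dict[str, Any] = load_config(path) if path else {}
    for key, value in overrides.items():
        if value is not None:
            raw[key] = value
    return validate_params(raw)


def replicate_seed(base_seed: int, replicate: int, arm: int = 0) -> int:
    """Deterministic per-replicate seed derived from one base seed.

    Uses :class:`numpy.random.SeedSequence` with the replicate index (and an
    optional experiment arm, e.g. vertical vs non-vertical) mixed into the
    spawn key, so any replicate is reproducible in isolation and arms are
    statistically independent.  The result fits in a signed 32-bit int.
    """
    ss = np.random.SeedSequence(base_seed, spawn_key=(arm, replicate))
    return int(ss.generate_state(1)[0] % (2**31))
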