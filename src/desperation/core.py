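"""Parameters, state grids, payoff lotteries, and the resource perturbation.

The model describes agents who, each period, either forage alone, join a
cooperative foraging group, or try to exploit one, conditioning the choice
on their current resource level ``s`` and on the trustworthiness ``1 - p``
of the surrounding population (the probability that a cooperating group
contains no exploiter).  Falling below a desperation threshold (``s = 0``)
incurs a fixed fitness penalty ``omega`` each period, which is what makes
desperate agents risk-preferring.

This module holds the shared vocabulary used by both the policy solver and
the population simulator: the parameter set, the discretised state grids,
the per-action payoff outcome distributions, and the mean-reverting
"shuffle" that redistributes resources between periods.
"""

from __future__ import annotations

import dataclasses
import enum
import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np

__all__ = [
    "Action",
    "ActionOutcomeSet",
    "ModelParams",
    "ParameterError",
    "PerturbationLaw",
    "action_outcomes",
    "build_grids",
    "load_params",
    "params_hash",
    "perturbation_law",
    "save_params",
    "table1_defaults",
]


class ParameterError(ValueError):
    """Raised when a model parameter violates its constraints."""


class Action(enum.IntEnum):
    """The three available actions.

    Integer codes double as the deterministic tie-breaking preference
    order used by the solver (lower code wins on an exact tie).
    """

    ALONE = 0
    COOPERATE = 1
    EXPLOIT = 2


PERTURBATION_VARIANTS = ("variance_preserving", "paper")


@dataclass(frozen=True)
class ModelParams:
    """Structural and input parameters of the model.

    Defaults are the canonical parameterisation: ``r=0.1`` social mobility,
    foraging cost/return ``x=1``, below-threshold fitness penalty
    ``omega=5``, cooperation efficiency ``alpha=1.2``, exploitation reward
    ``beta=5`` and punishment ``pi=10`` with punishment probability
    ``gamma=1/3`` (so exploitation has zero expected payoff), horizon
    ``T=50``, population ``N=500`` interacting in groups of ``n=5``, and
    trust observation sample ``K=50``.  ``mu`` and ``sigma`` are the mean
    and standard deviation of the population resource distribution; they
    parameterise the perturbation in the policy computation and the
    initial population in simulations.
    """

    r: float = 0.1
    x: float = 1.0
    omega: float = 5.0
    alpha: float = 1.2
    beta: float = 5.0
    pi: float = 10.0
    gamma: float = 1.0 / 3.0
    T: int = 50
    N: int = 500
    n: int = 5
    K: int = 50
    threshold: float = 0.0
    s_min: float = -50.0
    s_max: float = 50.0
    s_steps: int = 1001
    p_steps: int = 101
    mu: float = 5.5
    sigma: float = 4.0
    perturbation_variant: str = "variance_preserving"

    def __post_init__(self) -> None:
        def _req(cond: bool, msg: str) -> None:
            if not cond:
                raise ParameterError(msg)

        _req(0.0 <= self.r <= 1.0, f"r must lie in [0, 1], got {self.r}")
        _req(self.x > 0.0, f"x must be positive, got {self.x}")
        _req(self.omega >= 0.0, f"omega must be non-negative, got {self.omega}")
        _req(self.alpha > 0.0, f"alpha must be positive, got {self.alpha}")
        _req(self.beta >= 0.0, f"beta must be non-negative, got {self.beta}")
        _req(self.pi >= 0.0, f"pi must be non-negative, got {self.pi}")
        _req(0.0 <= self.gamma <= 1.0, f"gamma must lie in [0, 1], got {self.gamma}")
        _req(self.T >= 1, f"T must be >= 1, got {self.T}")
        _req(self.n >= 2, f"group size n must be >= 2, got {self.n}")
        _req(self.N >= self.n, f"N must be >= n, got N={self.N}, n={self.n}")
        _req(1 <= self.K <= self.N - 1, f"K must lie in [1, N-1], got K={self.K}")
        _req(self.s_steps >= 2, f"s_steps must be >= 2, got {self.s_steps}")
        _req(self.p_steps >= 2, f"p_steps must be >= 2, got {self.p_steps}")
        _req(self.s_min < self.s_max, "s_min must be < s_max")
        _req(
            self.s_min < self.threshold < self.s_max,
            "threshold must lie strictly inside (s_min, s_max)",
        )
        _req(self.sigma >= 0.0, f"sigma must be non-negative, got {self.sigma}")
        _req(
            self.perturbation_variant in PERTURBATION_VARIANTS,
            f"perturbation_variant must be one of {PERTURBATION_VARIANTS}, "
            f"got {self.perturbation_variant!r}",
        )

    @property
    def ds(self) -> float:
        """Resource grid spacing (0.1 at defaults)."""
        return (self.s_max - self.s_min) / (self.s_steps - 1)

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParams":
        """Build parameters from a flat mapping; unknown keys are rejected."""
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(
                f"unknown parameter key(s): {', '.join(sorted(unknown))}"
            )
        return cls(**data)


def params_hash(params: ModelParams) -> str:
    """Short stable identifier of a parameter set (for artifact metadata)."""
    blob = json.dumps(params.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Grids
# ---------------------------------------------------------------------------


def build_grids(params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(resource_grid, trustworthiness_grid)``.

    The resource axis spans ``[s_min, s_max]`` with ``s_steps`` equally
    spaced points (1001 points of spacing 0.1 at defaults); the
    trustworthiness axis spans [0, 1] with ``p_steps`` points.
    """
    s_grid = np.linspace(params.s_min, params.s_max, params.s_steps)
    q_grid = np.linspace(0.0, 1.0, params.p_steps)
    return s_grid, q_grid


# ---------------------------------------------------------------------------
# Action payoff lotteries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ActionOutcomeSet:
    """Net-payoff lottery of one action: pairs of (net payoff, probability)."""

    action: Action
    outcomes: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        total = math.fsum(p for _, p in self.outcomes)
        if abs(total - 1.0) > 1e-12:
            raise ParameterError(f"outcome probabilities sum to {total}, not 1")
        if any(p < 0 for _, p in self.outcomes):
            raise ParameterError("outcome probabilities must be non-negative")

    @property
    def expected_payoff(self) -> float:
        return math.fsum(d * p for d, p in self.outcomes)

    def __iter__(self) -> Iterator[tuple[float, float]]:
        return iter(self.outcomes)


def action_outcomes(
    action: Action, params: ModelParams, p: float
) -> ActionOutcomeSet:
    """Net-payoff distribution of ``action`` when the probability that a
    cooperating group contains an exploiter is ``p``.

    * COOPERATE: invest ``x``; rewarded ``alpha*x`` with probability
      ``1 - p`` (net ``x*(alpha-1)``), nothing with probability ``p``
      (net ``-x``).
    * EXPLOIT: reward ``beta`` with probability ``1 - gamma``, punishment
      ``-pi`` with probability ``gamma`` (independent of ``p``).
    * ALONE: invest ``x``, receive ``x`` — net 0 with certainty.
    """
    if not 0.0 <= p <= 1.0:
        raise ParameterError(f"p must lie in [0, 1], got {p}")
    action = Action(action)
    if action is Action.COOPERATE:
        outcomes = ((params.x * (params.alpha - 1.0), 1.0 - p), (-params.x, p))
    elif action is Action.EXPLOIT:
        outcomes = ((params.beta, 1.0 - params.gamma), (-params.pi, params.gamma))
    else:
        outcomes = ((0.0, 1.0),)
    # drop zero-probability branches so point-mass cases stay single-outcome
    outcomes = tuple((d, w) for d, w in outcomes if w > 0.0)
    return ActionOutcomeSet(action=action, outcomes=outcomes)


# ---------------------------------------------------------------------------
# Perturbation ("shuffle") law
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PerturbationLaw:
    """First-order autoregressive resource shuffle.

    Post-payoff resources evolve as ``s' = (1 - r) * s + r * eps`` with
    ``eps ~ N(noise_mean, noise_sd**2)`` drawn independently per agent.
    ``persistence = 1 - r`` is the desired temporal autocorrelation of
    resources; ``r`` is read as social mobility.
    """

    persistence: float
    noise_mean: float
    noise_sd: float
    variant: str

    @property
    def r(self) -> float:
        return 1.0 - self.persistence

    @property
    def is_identity(self) -> bool:
        return self.persistence == 1.0


def _noise_sd_factor(r: float, variant: str) -> float:
    """SD of eps per unit population SD.

    ``paper`` uses the nominal formula sd = sigma*sqrt((1-r^2)/(1-r)^2).
    ``variance_preserving`` uses sd = sigma*sqrt(1-(1-r)^2)/r, which makes
    Var((1-r)s + r*eps) = sigma^2 exactly when Var(s) = sigma^2.
    """
    if r == 0.0:
        return 0.0
    if variant == "paper":
        if r == 1.0:
            raise ParameterError(
                "r = 1 is degenerate under the 'paper' perturbation variant "
                "(division by zero); use variant='variance_preserving'"
            )
        return math.sqrt((1.0 - r * r)) / (1.0 - r)
    return math.sqrt(1.0 - (1.0 - r) ** 2) / r


def perturbation_law(
    params: ModelParams, pop_mean: float, pop_var: float
) -> PerturbationLaw:
    """Perturbation law given the current population mean and variance."""
    if pop_var < 0.0:
        raise ParameterError(f"population variance must be >= 0, got {pop_var}")
    r = params.r
    if r == 0.0:
        return PerturbationLaw(
            persistence=1.0,
            noise_mean=pop_mean,
            noise_sd=0.0,
            variant=params.perturbation_variant,
        )
    sd = math.sqrt(pop_var) * _noise_sd_factor(r, params.perturbation_variant)
    return PerturbationLaw(
        persistence=1.0 - r,
        noise_mean=pop_mean,
        noise_sd=sd,
        variant=params.perturbation_variant,
    )


# ---------------------------------------------------------------------------
# Parameter file I/O
# ---------------------------------------------------------------------------


def _read_mapping(path: Path) -> dict:
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise ParameterError(f"config file {path} must contain a mapping")
    return data


def load_params(path: str | Path) -> ModelParams:
    """Load a flat parameter mapping (JSON or YAML by extension)."""
    return ModelParams.from_dict(_read_mapping(Path(path)))


def save_params(params: ModelParams, path: str | Path) -> None:
    """Write parameters as a flat mapping (JSON or YAML by extension)."""
    path = Path(path)
    data = params.to_dict()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        path.write_text(yaml.safe_dump(data, sort_keys=True))
    else:
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")


def table1_defaults() -> ModelParams:
    """The bundled canonical default parameter set."""
    from importlib.resources import files

    resource = files("desperation.data").joinpath("table1_defaults.json")
    return ModelParams.from_dict(json.loads(resource.read_text()))
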