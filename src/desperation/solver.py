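"""Optimal-policy computation by backward induction.

We seek, for every resource level ``s`` and trustworthiness ``1 - p``, the
action maximising expected terminal fitness when every period spent below
the desperation threshold costs a fixed penalty ``omega``.  Terminal
fitness at the horizon ``T`` is an increasing linear function of ``s``;
the backward recurrence is

    f_t(s, p) = max_i  E_i[ f_{t+1}(s') - omega * 1{s' < 0} ]

where ``s'`` follows the action-dependent transition: a mixture over the
action's payoff outcomes ``d`` of Gaussians centred on
``(1 - r)(s + d) + r * mu`` with standard deviation ``r * sd_eps``.
Policies stabilise rapidly as the computation moves away from ``T``; the
map at ``t = 1`` is reported as the globally optimal policy.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import ndtr

from .core import (
    Action,
    ModelParams,
    ParameterError,
    PerturbationLaw,
    action_outcomes,
    build_grids,
    params_hash,
    perturbation_law,
)

__all__ = [
    "CriticalResource",
    "Policy",
    "TransitionKernels",
    "ValueFunction",
    "backward_step",
    "build_kernel",
    "cooperation_frontier",
    "exploitation_critical_resource",
    "load_policy",
    "solve_policy",
    "terminal_fitness",
]

logger = logging.getLogger(__name__)

_TIE_TOL = 1e-12


@dataclass
class ValueFunction:
    """Expected-fitness surface f_t over (resource grid x trust grid)."""

    values: np.ndarray  # (s_steps, p_steps)
    t: int
    s_grid: np.ndarray
    q_grid: np.ndarray  # trustworthiness 1 - p


@dataclass
class Policy:
    """Optimal-action map over (resource grid x trust grid).

    ``actions`` holds :class:`~desperation.core.Action` integer codes.
    """

    actions: np.ndarray  # int8 (s_steps, p_steps)
    t: int
    s_grid: np.ndarray
    q_grid: np.ndarray
    params_hash: str = ""
    stable_from_t: int | None = field(default=None, compare=False)

    def action_at(self, s: float, trust: float) -> Action:
        """Policy lookup at the nearest grid cell (no interpolation)."""
        i = int(np.clip(np.rint((s - self.s_grid[0]) / (self.s_grid[1] - self.s_grid[0])), 0, len(self.s_grid) - 1))
        j = int(np.clip(np.rint(trust * (len(self.q_grid) - 1)), 0, len(self.q_grid) - 1))
        return Action(self.actions[i, j])

    # -- serialization ------------------------------------------------------

    def save(self, prefix: str | Path, params: ModelParams | None = None) -> None:
        """Write ``<prefix>.npz`` (arrays) and ``<prefix>.json`` (metadata)."""
        prefix = Path(prefix)
        np.savez_compressed(
            prefix.with_suffix(".npz"),
            actions=self.actions,
            s_grid=self.s_grid,
            q_grid=self.q_grid,
        )
        meta = {
            "t": self.t,
            "params_hash": self.params_hash,
            "stable_from_t": self.stable_from_t,
            "params": params.to_dict() if params is not None else None,
        }
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2) + "\n")

    def to_csv(self, path: str | Path) -> None:
        """Long-format policy map: columns s, trustworthiness, action."""
        import pandas as pd

        ns, nq = self.actions.shape
        frame = pd.DataFrame(
            {
                "s": np.repeat(self.s_grid, nq),
                "trustworthiness": np.tile(self.q_grid, ns),
                "action": [Action(a).name for a in self.actions.ravel()],
            }
        )
        frame.to_csv(path, index=False)


def load_policy(prefix: str | Path) -> Policy:
    prefix = Path(prefix)
    with np.load(prefix.with_suffix(".npz")) as arrays:
        actions = arrays["actions"]
        s_grid = arrays["s_grid"]
        q_grid = arrays["q_grid"]
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return Policy(
        actions=actions,
        t=meta["t"],
        s_grid=s_grid,
        q_grid=q_grid,
        params_hash=meta.get("params_hash", ""),
        stable_from_t=meta.get("stable_from_t"),
    )


# ---------------------------------------------------------------------------
# Transition kernels
# ---------------------------------------------------------------------------


def _cell_edges(s_grid: np.ndarray) -> np.ndarray:
    """Cell boundaries; outermost edges at +-inf so off-grid probability
    mass accumulates in the boundary cells instead of being discarded."""
    edges = np.empty(len(s_grid) + 1)
    edges[1:-1] = 0.5 * (s_grid[:-1] + s_grid[1:])
    edges[0] = -np.inf
    edges[-1] = np.inf
    return edges


def _gaussian_rows(
    means: np.ndarray, sd: float, s_grid: np.ndarray, edges: np.ndarray
) -> np.ndarray:
    """Row-stochastic matrix: row i = destination distribution of a
    Gaussian with mean ``means[i]``, integrated over grid cells."""
    if sd <= 0.0:
        ds = s_grid[1] - s_grid[0]
        idx = np.clip(np.rint((means - s_grid[0]) / ds), 0, len(s_grid) - 1)
        rows = np.zeros((len(means), len(s_grid)))
        rows[np.arange(len(means)), idx.astype(int)] = 1.0
        return rows
    z = (edges[None, :] - means[:, None]) / sd
    cdf = ndtr(z)
    return np.diff(cdf, axis=1)


def _payoff_matrix(
    payoff: float, params: ModelParams, law: PerturbationLaw, s_grid: np.ndarray,
    edges: np.ndarray,
) -> np.ndarray:
    means = law.persistence * (s_grid + payoff) + params.r * law.noise_mean
    return _gaussian_rows(means, params.r * law.noise_sd, s_grid, edges)


@dataclass
class TransitionKernels:
    """Per-payoff destination matrices shared across the backward sweep.

    The transition of every action is a mixture of these rows, weighted by
    the action's outcome probabilities, so only one matrix per distinct net
    payoff is needed: 0 (alone), x(alpha-1) and -x (cooperation success /
    failure), and the gamma-mixture of beta and -pi (exploitation).
    """

    params: ModelParams
    law: PerturbationLaw
    alone: np.ndarray
    coop_success: np.ndarray
    coop_fail: np.ndarray
    exploit: np.ndarray

    @classmethod
    def build(cls, params: ModelParams, law: PerturbationLaw) -> "TransitionKernels":
        s_grid, _ = build_grids(params)
        edges = _cell_edges(s_grid)

        def mat(payoff: float) -> np.ndarray:
            return _payoff_matrix(payoff, params, law, s_grid, edges)

        exploit = (1.0 - params.gamma) * mat(params.beta) + params.gamma * mat(
            -params.pi
        )
        return cls(
            params=params,
            law=law,
            alone=mat(0.0),
            coop_success=mat(params.x * (params.alpha - 1.0)),
            coop_fail=mat(-params.x),
            exploit=exploit,
        )


def build_kernel(
    action: Action,
    s: float,
    p: float,
    params: ModelParams,
    law: PerturbationLaw,
) -> np.ndarray:
    """Single transition row for ``action`` from resource level ``s``.

    Mixture over the action's payoff outcomes of grid-cell-integrated
    Gaussians; the row sums to 1 by construction (boundary cells absorb
    off-grid mass).
    """
    s_grid, _ = build_grids(params)
    edges = _cell_edges(s_grid)
    sd = params.r * law.noise_sd
    row = np.zeros(len(s_grid))
    for payoff, weight in action_outcomes(action, params, p):
        mean = law.persistence * (s + payoff) + params.r * law.noise_mean
        row += weight * _gaussian_rows(np.array([mean]), sd, s_grid, edges)[0]
    return row


# ---------------------------------------------------------------------------
# Backward induction
# ---------------------------------------------------------------------------


def terminal_fitness(
    s_grid: np.ndarray,
    params: ModelParams,
    slope: float = 1.0,
    intercept: float = 0.0,
) -> ValueFunction:
    """Terminal condition f_T(s, p) = slope * s + intercept (slope > 0).

    No threshold penalty is applied at T itself; the penalty enters
    through the recurrence.  Policies are invariant to positive affine
    transforms of the terminal fitness.
    """
    if slope <= 0.0:
        raise ParameterError(f"terminal fitness slope must be positive, got {slope}")
    _, q_grid = build_grids(params)
    values = np.tile((slope * s_grid + intercept)[:, None], (1, len(q_grid)))
    return ValueFunction(values=values, t=params.T, s_grid=s_grid, q_grid=q_grid)


def backward_step(
    f_next: ValueFunction, params: ModelParams, kernels: TransitionKernels
) -> tuple[ValueFunction, Policy]:
    """One step of the recurrence: expected value of each action minus the
    below-threshold penalty, maximised per (s, trustworthiness) cell.

    Exact ties (within 1e-12) break by the fixed preference order
    ALONE > COOPERATE > EXPLOIT.
    """
    s_grid, q_grid = f_next.s_grid, f_next.q_grid
    if f_next.values.shape != (len(s_grid), len(q_grid)):
        raise ParameterError("value function shape does not match its grids")
    if kernels.alone.shape != (len(s_grid), len(s_grid)):
        raise ParameterError("kernel grid does not match the value function grid")

    penalty = params.omega * (s_grid < params.threshold)
    g = f_next.values - penalty[:, None]

    ev_alone = kernels.alone @ g
    ev_coop = q_grid[None, :] * (kernels.coop_success @ g) + (
        1.0 - q_grid[None, :]
    ) * (kernels.coop_fail @ g)
    ev_exploit = kernels.exploit @ g

    stacked = np.stack([ev_alone, ev_coop, ev_exploit])  # preference order
    best = stacked.max(axis=0)
    choice = np.argmax(stacked >= best - _TIE_TOL, axis=0)  # first within tol

    f = ValueFunction(values=best, t=f_next.t - 1, s_grid=s_grid, q_grid=q_grid)
    policy = Policy(
        actions=choice.astype(np.int8),
        t=f_next.t - 1,
        s_grid=s_grid,
        q_grid=q_grid,
        params_hash=params_hash(params),
    )
    return f, policy


def solve_policy(
    params: ModelParams,
    law: PerturbationLaw | None = None,
    terminal_slope: float = 1.0,
    terminal_intercept: float = 0.0,
) -> tuple[Policy, ValueFunction]:
    """Backward induction from T down to 1; returns the t=1 policy and
    value function.

    ``law`` defaults to the perturbation at the exogenous input parameters
    ``mu`` and ``sigma**2``.  The first backward time at which the policy
    map stops changing is recorded on ``Policy.stable_from_t`` as a
    stability diagnostic.
    """
    if law is None:
        law = perturbation_law(params, params.mu, params.sigma**2)
    kernels = TransitionKernels.build(params, law)
    s_grid, _ = build_grids(params)
    f = terminal_fitness(s_grid, params, terminal_slope, terminal_intercept)

    policy: Policy | None = None
    last_change_t = params.T
    for _ in range(params.T - 1):
        f, policy_t = backward_step(f, params, kernels)
        if policy is not None and not np.array_equal(policy_t.actions, policy.actions):
            last_change_t = policy_t.t
        policy = policy_t
    if policy is None:  # T == 1: terminal step only, all-ALONE by tie-break
        policy = Policy(
            actions=np.zeros_like(f.values, dtype=np.int8),
            t=1,
            s_grid=f.s_grid,
            q_grid=f.q_grid,
            params_hash=params_hash(params),
        )
    policy.stable_from_t = last_change_t
    logger.info(
        "policy solved (hash %s); map unchanged below t=%d",
        policy.params_hash,
        last_change_t,
    )
    return policy, f


# ---------------------------------------------------------------------------
# Policy geometry
# ---------------------------------------------------------------------------


@dataclass
class CriticalResource:
    """Exploitation-critical resource values.

    ``per_trust[j]`` is the largest grid ``s`` such that every resource
    level at or below it maps to EXPLOIT at trustworthiness ``q_grid[j]``
    (NaN where EXPLOIT does not extend to the bottom of the grid).
    ``band_edge`` is the minimum over trust levels — the upper edge of the
    unconditional exploit band — or None if no such band exists.
    """

    per_trust: np.ndarray
    band_edge: float | None


def exploitation_critical_resource(policy: Policy) -> CriticalResource:
    exploit = policy.actions == int(Action.EXPLOIT)
    from_bottom = np.logical_and.accumulate(exploit, axis=0)
    depth = from_bottom.sum(axis=0)  # rows of all-exploit prefix per trust level
    per_trust = np.where(depth > 0, policy.s_grid[np.maximum(depth - 1, 0)], np.nan)
    band_edge = None if np.isnan(per_trust).any() else float(per_trust.min())
    return CriticalResource(per_trust=per_trust, band_edge=band_edge)


def cooperation_frontier(policy: Policy, s_probe: float = 40.0) -> float | None:
    """Smallest grid trustworthiness at which the policy at ``s_probe``
    (nearest grid row) is COOPERATE, or None if cooperation never occurs
    there.  For ``s_probe`` far above the threshold this approaches the
    analytic cooperate/alone frontier 1/alpha."""
    ds = policy.s_grid[1] - policy.s_grid[0]
    i = int(np.clip(np.rint((s_probe - policy.s_grid[0]) / ds), 0, len(policy.s_grid) - 1))
    row = policy.actions[i]
    hits = np.nonzero(row == int(Action.COOPERATE))[0]
    if len(hits) == 0:
        return None
    return float(policy.q_grid[hits[0]])
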