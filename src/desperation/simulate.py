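"""Agent-based population simulation.

``N`` agents follow a precomputed optimal policy.  Each time step:
interaction groups of ``n`` are formed at random; every agent picks the
policy action for its resources and its own trust estimate; group payoffs
are resolved (one active exploiter per exploited group, exploiters in
cooperator-free groups forage alone); the mean-reverting perturbation is
applied; and finally every agent re-estimates trustworthiness from the
decisions of a random sample of ``K`` other agents.

Trust is endogenous: an agent observing ``k`` exploiters among ``K``
sampled infers an exploiter prevalence ``k' = round(k*N/K)`` and converts
it by combinatorics into the probability that at least one of its ``n-1``
prospective partners (drawn from the ``N-1`` others) would exploit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Action, ModelParams, ParameterError, params_hash, perturbation_law
from .solver import Policy

__all__ = [
    "PopulationState",
    "SimulationTrace",
    "apply_perturbation",
    "apply_shock",
    "choose_actions",
    "init_population",
    "resolve_groups",
    "run_simulation",
    "step",
    "trust_lookup_table",
    "update_trust",
]


@dataclass
class PopulationState:
    """Per-agent state at one time step."""

    resources: np.ndarray  # (N,) float
    trust: np.ndarray  # (N,) estimated trustworthiness 1 - p_hat, in [0, 1]
    last_action: np.ndarray  # (N,) int8 Action codes, -1 before any action
    t: int = 0
    group_assignment: np.ndarray | None = None  # (N/n, n) agent indices
    realized_exploiter_count: int = 0

    @property
    def size(self) -> int:
        return len(self.resources)


def init_population(
    params: ModelParams,
    mu: float | None = None,
    sigma: float | None = None,
    rng: np.random.Generator | int | None = None,
    initial_trust: float = 1.0,
) -> PopulationState:
    """Draw ``N`` agents with Gaussian(mu, sigma^2) resources, clamped to
    the state-space bounds.  Initial trust defaults to 1.0: agents have no
    observations yet, so above-threshold agents start by cooperating and
    observed exploitation then drives trust down."""
    if params.N % params.n != 0:
        raise ParameterError(
            f"N={params.N} must be divisible by group size n={params.n}"
        )
    if not 0.0 <= initial_trust <= 1.0:
        raise ParameterError("initial_trust must lie in [0, 1]")
    mu = params.mu if mu is None else mu
    sigma = params.sigma if sigma is None else sigma
    rng = np.random.default_rng(rng)
    resources = np.clip(
        rng.normal(mu, sigma, params.N), params.s_min, params.s_max
    )
    return PopulationState(
        resources=resources,
        trust=np.full(params.N, float(initial_trust)),
        last_action=np.full(params.N, -1, dtype=np.int8),
        t=0,
    )


def choose_actions(pop: PopulationState, policy: Policy) -> np.ndarray:
    """Policy lookup per agent at the nearest (s, trust) grid cell."""
    ds = policy.s_grid[1] - policy.s_grid[0]
    i = np.clip(
        np.rint((pop.resources - policy.s_grid[0]) / ds), 0, len(policy.s_grid) - 1
    ).astype(np.intp)
    j = np.clip(
        np.rint(pop.trust * (len(policy.q_grid) - 1)), 0, len(policy.q_grid) - 1
    ).astype(np.intp)
    return policy.actions[i, j]


def form_groups(
    N: int, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Random partition of agents into N/n groups of size n."""
    return rng.permutation(N).reshape(-1, n)


def resolve_groups(
    pop: PopulationState,
    actions: np.ndarray,
    params: ModelParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-agent net payoffs under the group interaction rules.

    Per group: ALONE agents net 0.  If the group holds both exploiters and
    cooperators, one exploiter chosen uniformly at random is active (the
    rest net 0 — there is nothing left to take), each cooperator nets
    ``-x`` whether or not the exploiter is punished, and the active
    exploiter nets ``beta`` with probability ``1 - gamma`` else ``-pi``.
    With no exploiter, cooperators each net ``x*(alpha - 1)``.  With no
    cooperator, all exploiters forage alone (net 0).
    """
    groups = pop.group_assignment
    if groups is None:
        raise ParameterError("groups must be formed before resolving payoffs")
    act = actions[groups]
    is_coop = act == int(Action.COOPERATE)
    is_expl = act == int(Action.EXPLOIT)
    has_coop = is_coop.any(axis=1)
    has_expl = is_expl.any(axis=1)
    exploited = has_coop & has_expl

    n_groups, n = groups.shape
    payoff = np.zeros((n_groups, n))
    payoff[is_coop & ~has_expl[:, None]] = params.x * (params.alpha - 1.0)
    payoff[is_coop & has_expl[:, None]] = -params.x

    # one uniformly chosen active exploiter per exploited group
    draw = rng.random((n_groups, n))
    draw[~is_expl] = -1.0
    active_col = draw.argmax(axis=1)
    success = rng.random(n_groups) >= params.gamma
    reward = np.where(success, params.beta, -params.pi)
    rows = np.nonzero(exploited)[0]
    payoff[rows, active_col[rows]] = reward[rows]

    out = np.zeros(pop.size)
    out[groups.ravel()] = payoff.ravel()
    pop.realized_exploiter_count = int(exploited.sum())
    return out


@lru_cache(maxsize=32)
def trust_lookup_table(N: int, n: int) -> np.ndarray:
    """trust[k'] = C(N-1-k', n-1) / C(N-1, n-1) for k' in 0..N.

    The probability that none of an agent's ``n - 1`` prospective partners,
    drawn without replacement from the ``N - 1`` other agents, is among
    the ``k'`` inferred exploiters; zero (certain exploitation) once
    ``k' > N - n``.
    """
    kp = np.arange(N + 1, dtype=float)
    table = np.ones(N + 1)
    for j in range(n - 1):
        table *= np.clip(N - 1 - kp - j, 0.0, None) / (N - 1 - j)
    return table


def update_trust(
    pop: PopulationState,
    actions: np.ndarray,
    params: ModelParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Re-estimate trustworthiness from a K-sample of others' decisions.

    Each agent observes the just-completed decisions of ``K`` distinct
    other agents; the number of exploiters seen, ``k``, is drawn from its
    exact hypergeometric law.  The inferred prevalence ``k' =
    round(k*N/K)`` (half-to-even, clamped to [0, N]) is converted to a
    trust value via :func:`trust_lookup_table`.
    """
    if params.K > params.N - 1:
        raise ParameterError("K must not exceed N - 1")
    exploited = actions == int(Action.EXPLOIT)
    total = int(exploited.sum())
    ngood = total - exploited.astype(np.int64)  # exploiters among the others
    nbad = (params.N - 1) - ngood
    k = rng.hypergeometric(ngood, nbad, params.K)
    kprime = np.clip(np.rint(k * params.N / params.K), 0, params.N).astype(np.intp)
    return trust_lookup_table(params.N, params.n)[kprime]


def apply_perturbation(
    pop: PopulationState, params: ModelParams, rng: np.random.Generator
) -> np.ndarray:
    """Mean-reverting shuffle s' = (1-r)s + r*eps, eps i.i.d. Gaussian
    centred on the CURRENT population mean with the variant's SD, clamped
    to the state-space bounds.  Identity when r = 0."""
    s = pop.resources
    law = perturbation_law(params, float(s.mean()), float(s.var()))
    if law.is_identity:
        return s
    eps = rng.normal(law.noise_mean, law.noise_sd, pop.size)
    return np.clip(law.persistence * s + params.r * eps, params.s_min, params.s_max)


def apply_shock(pop: PopulationState, new_sigma: float) -> PopulationState:
    """Exogenously rescale resource dispersion about the current mean.

    ``s' = m + (s - m) * new_sigma / sd``: the mean is preserved exactly
    and the population SD becomes ``new_sigma`` exactly.
    """
    if new_sigma < 0.0:
        raise ParameterError("new_sigma must be non-negative")
    m = float(pop.resources.mean())
    sd = float(pop.resources.std())
    if sd == 0.0:
        raise ParameterError("cannot rescale a degenerate (SD = 0) population")
    pop.resources = m + (pop.resources - m) * (new_sigma / sd)
    return pop


def step(
    pop: PopulationState,
    policy: Policy,
    params: ModelParams,
    rng: np.random.Generator,
) -> tuple[PopulationState, dict]:
    """Advance the population one time step.

    Phase order: form groups -> choose actions (trust carried from the end
    of the previous step) -> resolve payoffs -> perturbation -> update
    trust from the just-completed decisions.  Returns the state and a dict
    of per-step statistics.
    """
    pop.group_assignment = form_groups(pop.size, params.n, rng)
    actions = choose_actions(pop, policy)
    payoffs = resolve_groups(pop, actions, params, rng)
    pop.resources = np.clip(
        pop.resources + payoffs, params.s_min, params.s_max
    )
    pop.resources = apply_perturbation(pop, params, rng)
    pop.trust = update_trust(pop, actions, params, rng)
    pop.last_action = actions.astype(np.int8)
    pop.t += 1
    stats = {
        "t": pop.t,
        "n_coop": int((actions == int(Action.COOPERATE)).sum()),
        "n_exploit": int((actions == int(Action.EXPLOIT)).sum()),
        "n_alone": int((actions == int(Action.ALONE)).sum()),
        "mean_s": float(pop.resources.mean()),
        "sd_s": float(pop.resources.std()),
        "mean_trust": float(pop.trust.mean()),
        "frac_below_threshold": float((pop.resources < params.threshold).mean()),
    }
    return pop, stats


@dataclass
class SimulationTrace:
    """Time series of a simulation run plus the metadata to rerun it."""

    params: ModelParams
    seed: int
    mu: float
    sigma: float
    initial_mean_s: float
    initial_sd_s: float
    t: np.ndarray
    n_coop: np.ndarray
    n_exploit: np.ndarray
    n_alone: np.ndarray
    mean_s: np.ndarray
    sd_s: np.ndarray
    mean_trust: np.ndarray
    frac_below_threshold: np.ndarray
    shock_step: int | None = None
    shock_sigma: float | None = None

    def __len__(self) -> int:
        return len(self.t)

    @property
    def first_round_exploit_frac(self) -> float:
        return float(self.n_exploit[0]) / self.params.N

    @property
    def resource_growth(self) -> float:
        """Change in population mean resources over the run."""
        return float(self.mean_s[-1] - self.initial_mean_s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "n_coop": self.n_coop,
                "n_exploit": self.n_exploit,
                "n_alone": self.n_alone,
                "mean_s": self.mean_s,
                "sd_s": self.sd_s,
                "mean_trust": self.mean_trust,
                "frac_below_threshold": self.frac_below_threshold,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "params": self.params.to_dict(),
            "params_hash": params_hash(self.params),
            "seed": self.seed,
            "mu": self.mu,
            "sigma": self.sigma,
            "initial_mean_s": self.initial_mean_s,
            "initial_sd_s": self.initial_sd_s,
            "shock_step": self.shock_step,
            "shock_sigma": self.shock_sigma,
            "trace": self.to_frame().to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def run_simulation(
    params: ModelParams,
    policy: Policy,
    mu: float | None = None,
    sigma: float | None = None,
    steps: int | None = None,
    seed: int = 0,
    initial_trust: float = 1.0,
    shock_step: int | None = None,
    shock_sigma: float | None = None,
    recompute_policy_every: int | None = None,
) -> SimulationTrace:
    """Run ``steps`` time steps (default ``params.T``); deterministic given
    ``seed``.

    ``shock_step``/``shock_sigma`` rescale the resource dispersion after
    that many completed steps.  ``recompute_policy_every`` optionally
    re-solves the policy at the current population mean/variance every so
    many steps (sensitivity mode; by default the policy passed in is used
    throughout, with the exogenous ``mu``, ``sigma`` it was solved at).
    """
    if steps is None:
        steps = params.T
    if steps < 1:
        raise ParameterError("steps must be >= 1")
    if shock_step is not None:
        if shock_sigma is None:
            raise ParameterError("shock_sigma is required when shock_step is set")
        if not 1 <= shock_step < steps:
            raise ParameterError("shock_step must satisfy 1 <= shock_step < steps")
    ss = np.random.SeedSequence(seed)
    rng_init, rng_sim = (np.random.default_rng(c) for c in ss.spawn(2))
    pop = init_population(params, mu, sigma, rng_init, initial_trust)
    initial_mean = float(pop.resources.mean())
    initial_sd = float(pop.resources.std())

    records: list[dict] = []
    for k in range(steps):
        if (
            recompute_policy_every is not None
            and k > 0
            and k % recompute_policy_every == 0
        ):
            from .solver import solve_policy

            live = params.replace(
                mu=float(pop.resources.mean()),
                sigma=float(pop.resources.std()),
            )
            policy, _ = solve_policy(live)
        pop, stats = step(pop, policy, params, rng_sim)
        records.append(stats)
        if shock_step is not None and pop.t == shock_step:
            apply_shock(pop, shock_sigma)

    frame = pd.DataFrame(records)
    return SimulationTrace(
        params=params,
        seed=seed,
        mu=params.mu if mu is None else mu,
        sigma=params.sigma if sigma is None else sigma,
        initial_mean_s=initial_mean,
        initial_sd_s=initial_sd,
        t=frame["t"].to_numpy(),
        n_coop=frame["n_coop"].to_numpy(),
        n_exploit=frame["n_exploit"].to_numpy(),
        n_alone=frame["n_alone"].to_numpy(),
        mean_s=frame["mean_s"].to_numpy(),
        sd_s=frame["sd_s"].to_numpy(),
        mean_trust=frame["mean_trust"].to_numpy(),
        frac_below_threshold=frame["frac_below_threshold"].to_numpy(),
        shock_step=shock_step,
        shock_sigma=shock_sigma,
    )
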