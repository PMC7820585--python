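"""Equilibrium classification and parameter-sweep experiments.

Simulated populations settle into one of two absorbing states: a *poverty
trap* (no cooperation, low trust, stagnant resources, residual
exploitation by the desperate) or a *virtuous circle* (near-universal
cooperation, high trust, growing resources).  This module classifies runs,
maps basins of attraction over parameter planes, estimates the critical
first-round exploitation fraction separating the basins, and runs the
inequality-shock and group-size experiments.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ModelParams, ParameterError
from .simulate import SimulationTrace, run_simulation
from .solver import Policy, solve_policy

__all__ = [
    "Classification",
    "CriticalFractionResult",
    "EquilibriumLabel",
    "SweepResult",
    "classify_equilibrium",
    "critical_exploitation_fraction",
    "group_size_experiment",
    "shock_experiment",
    "sweep",
]


class EquilibriumLabel(str, enum.Enum):
    POVERTY_TRAP = "POVERTY_TRAP"
    VIRTUOUS_CIRCLE = "VIRTUOUS_CIRCLE"
    UNDETERMINED = "UNDETERMINED"


@dataclass
class Classification:
    label: EquilibriumLabel
    final_coop_frac: float
    final_mean_trust: float
    resource_growth: float


def classify_equilibrium(
    trace: SimulationTrace,
    window: int = 10,
    coop_threshold: float = 0.5,
    trap_coop_tol: float = 0.02,
) -> Classification:
    """Label a run from its final ``window`` steps.

    POVERTY_TRAP: cooperation has died out (mean cooperation fraction in
    the window at most ``trap_coop_tol``) while some exploitation still
    occurs.  VIRTUOUS_CIRCLE: mean cooperation fraction above
    ``coop_threshold`` and mean resources grew over the run.  Anything
    else (including an all-alone standstill, where there is neither
    cooperation nor exploitation) is UNDETERMINED.

    ``trap_coop_tol`` allows for the sampling noise in trust estimation:
    in the absorbing no-cooperation state a handful of agents per step
    still draw an unusually favourable K-sample and attempt cooperation,
    so the cooperation count is near zero rather than identically zero.
    """
    if len(trace) < window:
        raise ParameterError(
            f"trace length {len(trace)} is shorter than window {window}"
        )
    N = trace.params.N
    coop = trace.n_coop[-window:]
    exploit = trace.n_exploit[-window:]
    coop_frac = float(coop.mean()) / N
    trust = float(trace.mean_trust[-window:].mean())
    growth = trace.resource_growth
    if coop_frac <= trap_coop_tol and np.any(exploit > 0):
        label = EquilibriumLabel.POVERTY_TRAP
    elif coop_frac > coop_threshold and growth > 0:
        label = EquilibriumLabel.VIRTUOUS_CIRCLE
    else:
        label = EquilibriumLabel.UNDETERMINED
    return Classification(
        label=label,
        final_coop_frac=coop_frac,
        final_mean_trust=trust,
        resource_growth=growth,
    )


def _cell_seeds(seed: int, n_cells: int, reps: int) -> np.ndarray:
    """Deterministic per-run integer seeds (< 2**31) derived from one seed."""
    state = np.random.SeedSequence(seed).generate_state(n_cells * reps, np.uint32)
    return (state & 0x7FFFFFFF).reshape(n_cells, reps)


@dataclass
class SweepResult:
    """Grid of replicate equilibrium labels over two parameter axes."""

    axis1: str
    axis2: str
    frame: pd.DataFrame  # axis1_value, axis2_value, rep, seed, label, ...
    seed: int

    def majority_frame(self) -> pd.DataFrame:
        """Per-cell majority label (ties resolve to UNDETERMINED)."""

        def majority(labels: pd.Series) -> str:
            counts = labels.value_counts()
            top = counts[counts == counts.max()]
            if len(top) > 1:
                return EquilibriumLabel.UNDETERMINED.value
            return top.index[0]

        return (
            self.frame.groupby(["axis1_value", "axis2_value"])["label"]
            .agg(majority)
            .reset_index()
            .rename(columns={"label": "majority_label"})
        )

    def majority_label(self, v1: float, v2: float) -> EquilibriumLabel:
        maj = self.majority_frame()
        row = maj[
            np.isclose(maj["axis1_value"], v1) & np.isclose(maj["axis2_value"], v2)
        ]
        if row.empty:
            raise KeyError(f"no sweep cell at ({v1}, {v2})")
        return EquilibriumLabel(row["majority_label"].iloc[0])

    def to_csv(self, path: str | Path) -> None:
        out = self.frame.rename(
            columns={"axis1_value": self.axis1, "axis2_value": self.axis2}
        )
        out.to_csv(path, index=False)


def _run_cell(
    params: ModelParams,
    policy: Policy,
    seeds: np.ndarray,
    steps: int | None,
    window: int,
) -> list[dict]:
    rows = []
    for rep, run_seed in enumerate(seeds):
        trace = run_simulation(params, policy, steps=steps, seed=int(run_seed))
        cls = classify_equilibrium(trace, window=window)
        rows.append(
            {
                "rep": rep,
                "seed": int(run_seed),
                "label": cls.label.value,
                "final_coop_frac": cls.final_coop_frac,
                "final_mean_trust": cls.final_mean_trust,
                "resource_growth": cls.resource_growth,
                "first_round_exploit_frac": trace.first_round_exploit_frac,
            }
        )
    return rows


def sweep(
    base_params: ModelParams,
    axis1: tuple[str, np.ndarray],
    axis2: tuple[str, np.ndarray],
    reps: int = 5,
    seed: int = 0,
    steps: int | None = None,
    window: int = 10,
) -> SweepResult:
    """Phase-diagram sweep over two parameter axes.

    For every cell the policy is re-solved for that parameter set, then
    ``reps`` simulations with deterministic per-run seeds are run and
    classified.  Axis names must be ``ModelParams`` field names (e.g.
    ``sigma``, ``pi``, ``gamma``, ``r``).
    """
    if reps < 1:
        raise ParameterError("reps must be >= 1")
    name1, values1 = axis1
    name2, values2 = axis2
    cells = [(v1, v2) for v1 in values1 for v2 in values2]
    seeds = _cell_seeds(seed, len(cells), reps)
    rows = []
    for idx, (v1, v2) in enumerate(cells):
        params = base_params.replace(**{name1: float(v1), name2: float(v2)})
        policy, _ = solve_policy(params)
        for row in _run_cell(params, policy, seeds[idx], steps, window):
            rows.append({"axis1_value": float(v1), "axis2_value": float(v2), **row})
    return SweepResult(
        axis1=name1, axis2=name2, frame=pd.DataFrame(rows), seed=seed
    )


@dataclass
class CriticalFractionResult:
    """Estimated minimum first-round exploitation fraction that tips the
    population into the poverty trap."""

    estimate: float  # fraction of the population, in [0, 1]
    ci_low: float
    ci_high: float
    per_sigma: pd.DataFrame
    runs: pd.DataFrame

    @property
    def percent(self) -> float:
        return 100.0 * self.estimate


def _critical_from_groups(runs: pd.DataFrame) -> float | None:
    per = runs.groupby("sigma").agg(
        mean_first_frac=("first_round_exploit_frac", "mean"),
        n_trap=("label", lambda s: (s == EquilibriumLabel.POVERTY_TRAP.value).sum()),
        n=("label", "size"),
    )
    trap = per[per["n_trap"] * 2 > per["n"]]
    if trap.empty or len(trap) == len(per):
        return None
    return float(trap["mean_first_frac"].min())


def critical_exploitation_fraction(
    base_params: ModelParams,
    sigma_grid: np.ndarray,
    reps: int = 20,
    seed: int = 0,
    steps: int | None = None,
    window: int = 10,
    n_boot: int = 200,
) -> CriticalFractionResult:
    """Estimate the tipping frequency of first-round exploitation.

    Varies initial inequality ``sigma`` over ``sigma_grid``; for each
    value, runs ``reps`` seeded simulations recording the realized
    first-round exploitation fraction and the final equilibrium label.
    The estimate is the smallest per-sigma mean first-round fraction whose
    majority outcome is the poverty trap, with a bootstrap percentile
    interval over replicates.
    """
    rows = []
    seeds = _cell_seeds(seed, len(sigma_grid), reps)
    for idx, sigma in enumerate(sigma_grid):
        params = base_params.replace(sigma=float(sigma))
        policy, _ = solve_policy(params)
        for row in _run_cell(params, policy, seeds[idx], steps, window):
            rows.append({"sigma": float(sigma), **row})
    runs = pd.DataFrame(rows)

    estimate = _critical_from_groups(runs)
    if estimate is None:
        raise ParameterError(
            "sigma grid does not bracket the basin boundary: all cells gave "
            "the same majority outcome"
        )

    boot_rng = np.random.default_rng(np.random.SeedSequence([seed, 0x_B007]))
    boot: list[float] = []
    grouped = {s: g.reset_index(drop=True) for s, g in runs.groupby("sigma")}
    for _ in range(n_boot):
        pieces = []
        for s, g in grouped.items():
            take = boot_rng.integers(0, len(g), len(g))
            pieces.append(g.iloc[take])
        est = _critical_from_groups(pd.concat(pieces, ignore_index=True))
        if est is not None:
            boot.append(est)
    if boot:
        ci_low, ci_high = np.percentile(boot, [2.5, 97.5])
    else:
        ci_low = ci_high = estimate

    per_sigma = runs.groupby("sigma").agg(
        mean_first_frac=("first_round_exploit_frac", "mean"),
        n_trap=("label", lambda s: (s == EquilibriumLabel.POVERTY_TRAP.value).sum()),
        n=("label", "size"),
    ).reset_index()
    return CriticalFractionResult(
        estimate=estimate,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        per_sigma=per_sigma,
        runs=runs,
    )


def group_size_experiment(
    base_params: ModelParams,
    n_values: list[int],
    sigma_grid: np.ndarray,
    reps: int = 5,
    seed: int = 0,
    steps: int | None = None,
    window: int = 10,
) -> tuple[pd.DataFrame, dict[int, float | None]]:
    """Basin boundary along sigma for different interaction group sizes.

    Returns the per-run frame and, per ``n``, the largest sigma whose
    majority outcome is still the virtuous circle (None if none is).
    Smaller groups are less likely to contain at least one exploiter at a
    given exploiter prevalence, so reducing ``n`` enlarges the
    virtuous-circle basin.
    """
    rows = []
    for n in n_values:
        if base_params.N % n != 0:
            raise ParameterError(f"group size n={n} does not divide N={base_params.N}")
        seeds = _cell_seeds(seed, len(sigma_grid), reps)
        for idx, sigma in enumerate(sigma_grid):
            params = base_params.replace(n=int(n), sigma=float(sigma))
            policy, _ = solve_policy(params)
            for row in _run_cell(params, policy, seeds[idx], steps, window):
                rows.append({"n": int(n), "sigma": float(sigma), **row})
    frame = pd.DataFrame(rows)

    boundaries: dict[int, float | None] = {}
    for n in n_values:
        sub = frame[frame["n"] == n]
        per = sub.groupby("sigma")["label"].agg(
            lambda s: (s == EquilibriumLabel.VIRTUOUS_CIRCLE.value).sum() * 2
            > len(s)
        )
        good = per[per].index
        boundaries[int(n)] = float(good.max()) if len(good) else None
    return frame, boundaries


def shock_experiment(
    base_params: ModelParams,
    mu: float,
    sigma_initial: float,
    sigma_after: float,
    shock_step: int = 16,
    steps: int = 50,
    seed: int = 0,
    policy: Policy | None = None,
) -> SimulationTrace:
    """Run with an exogenous change of inequality after ``shock_step``
    completed steps: resources are rescaled about the current mean so the
    population SD becomes ``sigma_after``."""
    if not shock_step < steps:
        raise ParameterError("shock_step must be < steps")
    params = base_params.replace(mu=float(mu), sigma=float(sigma_initial))
    if policy is None:
        policy, _ = solve_policy(params)
    return run_simulation(
        params,
        policy,
        steps=steps,
        seed=seed,
        shock_step=shock_step,
        shock_sigma=float(sigma_after),
    )
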