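"""Independent reference implementations used to cross-check the solver.

These deliberately share no code with the package internals: the value
function is computed by exhaustively enumerating every action/outcome
path, which is tractable only for tiny grids, zero social mobility
(deterministic transitions) and short horizons.
"""

from functools import lru_cache

import numpy as np

from desperation import Action, ModelParams, action_outcomes


def enumerate_backward_induction(params: ModelParams):
    """Exhaustive-path value function and policy at t=1 for r=0.

    Transitions are deterministic given the action outcome: next resources
    snap to the nearest grid point of s + payoff, clamped to the grid.
    Returns (values, actions) arrays over (s grid x trust grid).
    """
    assert params.r == 0.0, "enumeration oracle only covers r = 0"
    s_grid = np.linspace(params.s_min, params.s_max, params.s_steps)
    q_grid = np.linspace(0.0, 1.0, params.p_steps)
    ds = s_grid[1] - s_grid[0]

    def snap(value: float) -> int:
        return int(np.clip(np.rint((value - s_grid[0]) / ds), 0, len(s_grid) - 1))

    @lru_cache(maxsize=None)
    def best(i: int, j: int, t: int) -> tuple[float, int]:
        """(value, argmax action) at grid cell (i, j) and time t."""
        if t == params.T:
            return float(s_grid[i]), int(Action.ALONE)
        evs = []
        for action in (Action.ALONE, Action.COOPERATE, Action.EXPLOIT):
            p = 1.0 - q_grid[j]
            ev = 0.0
            for payoff, prob in action_outcomes(action, params, p):
                k = snap(s_grid[i] + payoff)
                future, _ = best(k, j, t + 1)
                penalty = params.omega if s_grid[k] < params.threshold else 0.0
                ev += prob * (future - penalty)
            evs.append(ev)
        top = max(evs)
        choice = next(a for a, ev in enumerate(evs) if ev >= top - 1e-12)
        return top, choice

    values = np.empty((len(s_grid), len(q_grid)))
    actions = np.empty((len(s_grid), len(q_grid)), dtype=np.int8)
    for i in range(len(s_grid)):
        for j in range(len(q_grid)):
            values[i, j], actions[i, j] = best(i, j, 1)
    return values, actions
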