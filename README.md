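# desperation

A model of cooperation and exploitation under a **desperation threshold**,
for researchers in behavioural ecology and the social sciences studying why
inequality breeds exploitation ("crime") and erodes social trust.

Agents repeatedly choose one of three actions: **forage alone** (invest *x*,
get *x* back — safe, no surplus), **cooperate** in a group of *n* (invest
*x*, receive *αx* with *α* > 1 unless the group is exploited), or **exploit**
a cooperating group (reward *β* on success, punishment −*π* with probability
*γ*). Falling below a resource threshold (*s* = 0) costs a fixed fitness
penalty *ω* every period, which makes agents near the threshold
risk-preferring. Between periods, resources are shuffled by a mean-reverting
perturbation *s*′ = (1 − *r*)*s* + *r·ε* whose strength *r* is read as
social mobility.

The package has two stages:

1. **Policy solver** (`desperation.solver`) — stochastic dynamic programming
   by backward induction over a discretised (resources × trustworthiness)
   state space:

   *f*<sub>t</sub>(*s*, *p*) = max<sub>i</sub> ∫ (*f*<sub>t+1</sub>(*x*) −
   *ω*·1<sub>x&lt;0</sub>) *φ*<sup>i</sup>(*s*, *p*, *x*) d*x*

   where 1 − *p* is the trustworthiness of the population (probability that
   a cooperating group contains no exploiter) and *φ*<sup>i</sup> is the
   action-dependent Gaussian-mixture transition kernel.

2. **Population simulator** (`desperation.simulate`) — *N* agents follow the
   solved policy; groups re-form randomly every step; each agent estimates
   trustworthiness from the observed decisions of *K* random others via
   hypergeometric combinatorics. `desperation.experiments` classifies runs
   into the two absorbing equilibria — the **poverty trap** (no cooperation,
   low trust, stagnant resources) and the **virtuous circle** (near-universal
   cooperation, high trust, growing resources) — and sweeps phase diagrams.

## Worked example

Solve the default policy and run the two canonical simulations (a policy
solve takes ~2 s; a 50-step simulation of 500 agents well under a second):

```sh
$ desperation simulate --sigma 4 --seed 0 --out trace_a.csv
simulate seed=0 params=507324736b0fbc7c -> POVERTY_TRAP (final coop frac 0.00, trust 0.42); trace written to trace_a.csv

$ desperation simulate --sigma 3 --seed 0 --out trace_b.csv
simulate seed=0 params=27d187a87d206b46 -> VIRTUOUS_CIRCLE (final coop frac 1.00, trust 1.00); trace written to trace_b.csv
```

Both populations start with mean resources μ = 5.5; only the initial
inequality σ differs (4 vs 3). In the first run enough agents start below
the exploitation-critical resource level that observed exploitation
collapses everyone's trust estimates: the well-off switch to lone foraging,
the desperate keep exploiting, and mean resources never grow. In the second,
exploitation is rare enough that trust stays above the cooperation frontier
(analytically 1/α ≈ 0.833 for *s* ≫ 0), cooperation compounds a surplus of
*x*(α − 1) = 0.2 per cooperator per step, and the population escapes upward.

The same machinery is available as a library:

```python
from desperation import ModelParams, solve_policy, run_simulation

params = ModelParams(sigma=3.0)          # Gaussian(5.5, 3) start
policy, value = solve_policy(params)     # (1001 x 101) action map at t=1
trace = run_simulation(params, policy, seed=0)
print(trace.n_coop[-1], trace.resource_growth)   # 500  9.41...
```

Phase-diagram sweeps and the inequality-shock experiment:

```sh
desperation sweep --axis1 sigma:2.5:4.5:5 --axis2 pi:0:25:6 --reps 5 --seed 1 --out phase.csv
desperation shock --sigma-initial 4 --sigma-after 3 --shock-step 16 --seed 0 --out shock.csv
```

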