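# Methods

## Model

Agents maximise expected fitness over a finite horizon of T discrete
periods, one economic interaction per period. State: current resources
`s`, bounded to [−50, 50] and discretised into 1001 points of spacing 0.1,
and the trustworthiness of the surrounding population `1 − p` ∈ [0, 1]
(the probability that a cooperating group contains no exploiter),
discretised into 101 points. Three actions:

* **alone** — net payoff 0 with certainty;
* **cooperate** — net `x(α − 1)` with probability `1 − p`, net `−x` with
  probability `p`;
* **exploit** — net `β` with probability `1 − γ`, net `−π` with
  probability `γ` (independent of `p` in the decision model; the
  "no cooperator in the group" contingency is a simulation-stage rule).

Fitness is linear in terminal resources, but every period spent below the
desperation threshold (`s = 0`) costs a fixed penalty `ω`. This is the
single nonlinearity that generates state-dependent risk preference:
desperate agents gamble on exploitation because success clears the
threshold in one jump while failure scarcely worsens an already-penalised
state.

Between periods, post-payoff resources are shuffled by a first-order
autoregressive perturbation `s′ = (1 − r)s + r·ε`, `ε ~ N(mean, sd²)`
i.i.d. per agent. `1 − r` is the temporal autocorrelation of resources;
`r` is interpreted as social mobility.

### Perturbation variants

The nominal form of the noise, `sd = σ·sqrt((1 − r²)/(1 − r)²)`
(`variant="paper"`), does **not** preserve population variance under the
update above: at `r = 0.1` one application multiplies the variance by
≈ 0.82, so a simulated population contracts towards its mean within a few
periods and inequality-driven dynamics disappear. Because the perturbation
is explicitly meant to be a variance-neutral "shuffle", the default
variant is `variance_preserving`, `sd = σ·sqrt(1 − (1 − r)²)/r`, which
makes `Var(s′) = σ²` exactly and gives `Corr(s, s′) = 1 − r`. Both
variants are implemented; the nominal formula is kept behind the
`perturbation_variant` flag for fidelity comparisons. `r = 1` is rejected
under the nominal variant (division by zero); under the default variant it
is valid but degenerate: next-period resources are independent of the
current action, so the solved policy is all-ALONE by tie-break.

## Policy computation

Backward induction from a terminal condition `f_T(s) = a·s + b` (defaults
`a = 1`, `b = 0`). Policies are invariant to the intercept `b`, but **not**
to the slope `a`: the penalty `ω` sets an absolute fitness scale, so `a`
controls the exchange rate between resource units and threshold penalties.
The default pairs one fitness unit per resource unit with the canonical
`ω = 5`; this is a substantive modelling choice, not a normalisation.

Transition kernels are Gaussian mixtures — one component per action
outcome, weight = outcome probability, mean `(1 − r)(s + payoff) + r·mean(ε)`,
sd `r·sd(ε)` — integrated over grid cells via the Gaussian CDF, so every
row sums to 1 by construction. Probability mass outside [−50, 50]
accumulates in the boundary cells: this conserves mass exactly and keeps
desperate states desperate instead of deleting their tail. With `r = 0`
the kernel is a point mass at the nearest grid cell of `s + payoff`.

The DP treats the perturbation's `mean(ε) = μ` and `sd(ε) ∝ σ` as fixed
exogenous inputs; the package solves the policy once per simulation at the
initial population's (μ, σ). Argmax ties within 1e−12 resolve by the fixed
order ALONE > COOPERATE > EXPLOIT. Policy maps stabilise within roughly
ten backward steps of T = 50; the map at t = 1 is reported as the global
policy, with the first unchanged step recorded as a diagnostic.

At the defaults (μ = 5.5, σ = 4, the canonical initial population — the
model statement does not pin the DP inputs for the policy figures) the
solved policy has an unconditional exploitation band below s ≈ −1.5, a
cooperation region at high resources and trustworthiness above the
analytic frontier 1/α, a lone-foraging region at low trustworthiness, and
the narrow bands near the threshold (cooperation at low trust just above
the exploit zone; lone foraging just above that even at high trust).

### Sensitivity to the perturbation centre

The attraction term `r·(μ − s)` gives every below-threshold agent an
expected drift of about +0.55 per period towards μ = 5.5. This "rescue"
shortens below-threshold dwell times to a few periods, which has two
consequences that differ from behaviour reported for this model family:

* the trust-1 exploitation-critical value sits at ≈ −1.4 rather than at
  the threshold itself, so first-round exploitation fractions are a few
  per cent rather than ≈ 10% at the basin boundary;
* severe punishment deters near-threshold exploitation (at π = 20 the
  near-threshold band shrinks to the thin interval from which β just
  clears the threshold), because deepening a fall now costs more than the
  few avoidable penalty periods.

Solving the policy with a neutral centre (μ = 0) instead puts the critical
value exactly at the threshold and makes exploitation insensitive to π,
but its pessimistic drift suppresses cooperation at moderate inequality,
so the virtuous circle disappears. No single choice reproduces every
reported behaviour; the package keeps the initial-(μ, σ) coupling and
documents the divergences. The relevant checks in the acceptance suite are
left failing rather than re-tuned.

## Population simulation

N = 500 agents (divisibility by n enforced), initial resources
Gaussian(μ, σ²) clamped to the state bounds, initial trust 1.0 (agents
have no observations before the first interaction; alternative priors are
an argument). Each step: random re-partition into groups of n = 5 →
policy lookup at each agent's nearest grid cell (own resources, own trust
estimate) → payoff resolution → perturbation at the *current* population
mean and variance → trust update from the just-completed decisions.

Group resolution: with both exploiters and cooperators present, one
uniformly chosen exploiter is active (the rest net 0), each cooperator
nets −x whether or not the exploiter is punished (presence, not
punishment, spoils the harvest), and the active exploiter draws β / −π.
Exploiters without cooperators forage alone.

Trust estimation: each agent observes the decisions of K = 50 distinct
others; the exploiter count k is drawn from its exact hypergeometric law
(equivalent to materialising a without-replacement sample). The inferred
prevalence `k′ = round(k·N/K)` (half-to-even, clamped to [0, N]) converts
to `p̂ = 1 − C(N−1−k′, n−1)/C(N−1, n−1)`, the probability that at least
one of the agent's n − 1 prospective partners exploits. Finite K makes
trust heterogeneous — the source of the straggler cooperation noted below.

## Experiments and classification

A run is labelled from its final 10 steps: **poverty trap** if the mean
cooperation fraction is ≤ 2% while exploitation persists; **virtuous
circle** if the mean cooperation fraction exceeds 50% and mean resources
grew over the run; otherwise undetermined (an all-alone standstill is
deliberately undetermined). The 2% tolerance exists because finite-K
sampling lets a handful of agents per step draw an unusually favourable
trust estimate and attempt cooperation even in the absorbed trap state; a
strict zero-cooperation rule fires unreliably at any horizon. Thresholds
are exposed as arguments.

Phase-diagram sweeps re-solve the policy per cell and run several
replicates with per-run seeds derived deterministically from one master
seed (recorded in the output, all below 2³¹). The critical-fraction
estimator varies σ over 2.5–4.5 (step 0.25, 20 replicates per value, 50
steps per run — scales chosen to keep a full estimate under a minute on
one CPU), records each run's realized first-round exploitation fraction
and label, and reports the smallest per-σ mean fraction whose majority
outcome is the trap, with a bootstrap percentile interval over replicates.
Under the initial-(μ, σ) policy coupling this boundary fraction is ≈ 1–3%
(see the sensitivity discussion above).

The shock experiment rescales resources about the current mean so the
population SD becomes `sigma_after` exactly, after a chosen number of
completed steps. Reducing σ from 4 to 2.5 reliably produces the staged
trap-to-circle transition (exploiters lifted into lone foraging, then
trust recovery, then mass cooperation); at `sigma_after = 3` the rescaled
failed-exploiter tail usually remains below the critical value and most
runs relapse — the corresponding acceptance check is left failing.

## What the synthetic populations do and do not capture

Populations are well-mixed with no spatial structure, reputation,
relationships, or assortment; groups are memoryless across steps; the
punishment institution is exogenous. Gaussian initial resources and the
variance-preserving shuffle are idealisations: real resource distributions
are skewed and mobility is not an AR(1) shuffle. Passing tests therefore
demonstrate internal consistency of the decision model and the
population dynamics, not calibration to empirical crime or trust data.

## Numerical choices

* Trust grid step 0.01 resolves the 1/α frontier to two decimals; the
  frontier estimator returns a grid value, so comparisons are made to the
  nearest grid representation of the analytic value.
* Tie tolerance 1e−12 on action values; kernel rows validated to 1e−9.
* All randomness flows from numpy `SeedSequence` spawns of a single seed;
  identical configuration and seed reproduce traces byte-for-byte.
* Simulation resources are clamped to [−50, 50] after payoffs and after
  the perturbation, mirroring the solver's truncated state space.
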