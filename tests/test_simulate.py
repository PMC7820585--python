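"""Population simulation: groups, payoffs, trust estimation, dynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from desperation import (
    Action,
    ModelParams,
    ParameterError,
    apply_perturbation,
    apply_shock,
    choose_actions,
    init_population,
    resolve_groups,
    run_simulation,
    solve_policy,
    update_trust,
)
from desperation.simulate import PopulationState, form_groups, step, trust_lookup_table


def make_pop(resources, trust=1.0, n=5):
    resources = np.asarray(resources, dtype=float)
    pop = PopulationState(
        resources=resources,
        trust=np.full(len(resources), trust),
        last_action=np.full(len(resources), -1, dtype=np.int8),
    )
    if len(resources) % n == 0:
        pop.group_assignment = np.arange(len(resources)).reshape(-1, n)
    return pop


class TestInitPopulation:
    def test_sample_moments(self):
        params = ModelParams()
        pop = init_population(params, mu=5.5, sigma=4.0, rng=0)
        assert pop.size == 500
        assert pop.resources.mean() == pytest.approx(5.5, abs=3 * 4.0 / math.sqrt(500))
        assert (pop.trust == 1.0).all()

    def test_degenerate_sigma(self):
        pop = init_population(ModelParams(), mu=7.0, sigma=0.0, rng=0)
        assert (pop.resources == 7.0).all()

    def test_same_seed_same_population(self):
        a = init_population(ModelParams(), rng=42)
        b = init_population(ModelParams(), rng=42)
        np.testing.assert_array_equal(a.resources, b.resources)

    def test_group_size_must_divide_population(self):
        with pytest.raises(ParameterError):
            init_population(ModelParams(N=501, n=5), rng=0)


class TestChooseActions:
    def test_policy_lookup_by_state_and_trust(self, default_policy):
        policy, _ = default_policy
        pop = make_pop([-10.0, 40.0, 40.0])
        pop.trust = np.array([0.5, 1.0, 0.2])
        pop.group_assignment = None
        actions = choose_actions(pop, policy)
        assert actions[0] == int(Action.EXPLOIT)  # desperate, regardless of trust
        assert actions[1] == int(Action.COOPERATE)  # rich and trusting
        assert actions[2] == int(Action.ALONE)  # rich but distrustful


class TestResolveGroups:
    def test_all_cooperators_share_the_surplus(self):
        params = ModelParams(N=5, K=4)
        pop = make_pop(np.zeros(5))
        payoffs = resolve_groups(
            pop, np.full(5, int(Action.COOPERATE)), params, np.random.default_rng(0)
        )
        np.testing.assert_allclose(payoffs, 0.2)
        assert pop.realized_exploiter_count == 0

    def test_exploiters_without_victims_forage_alone(self):
        params = ModelParams(N=5, K=4)
        pop = make_pop(np.zeros(5))
        payoffs = resolve_groups(
            pop, np.full(5, int(Action.EXPLOIT)), params, np.random.default_rng(0)
        )
        np.testing.assert_array_equal(payoffs, 0.0)

    def test_single_active_exploiter_spoils_cooperators(self):
        params = ModelParams(N=5, K=4, gamma=0.0)
        pop = make_pop(np.zeros(5))
        actions = np.array([2, 2, 1, 1, 1], dtype=np.int8)
        payoffs = resolve_groups(pop, actions, params, np.random.default_rng(0))
        exploiter_pay = sorted(payoffs[:2])
        assert exploiter_pay == [0.0, 5.0]  # one active (unpunished), one demoted
        np.testing.assert_allclose(payoffs[2:], -1.0)
        assert pop.realized_exploiter_count == 1

    def test_punished_exploiter_still_spoils_cooperators(self):
        params = ModelParams(N=5, K=4, gamma=1.0)
        pop = make_pop(np.zeros(5))
        actions = np.array([2, 1, 1, 1, 1], dtype=np.int8)
        payoffs = resolve_groups(pop, actions, params, np.random.default_rng(0))
        assert payoffs[0] == -10.0
        np.testing.assert_allclose(payoffs[1:], -1.0)

    @given(data=st.data())
    def test_group_rules_hold_for_arbitrary_action_profiles(self, data):
        params = ModelParams(N=20, K=10, gamma=0.5)
        actions = np.array(
            data.draw(st.lists(st.integers(0, 2), min_size=20, max_size=20)),
            dtype=np.int8,
        )
        seed = data.draw(st.integers(0, 2**16))
        pop = make_pop(np.zeros(20))
        payoffs = resolve_groups(pop, actions, params, np.random.default_rng(seed))
        for g in pop.group_assignment:
            act, pay = actions[g], payoffs[g]
            coop, expl = act == 1, act == 2
            assert (pay[act == 0] == 0.0).all()
            if coop.any() and expl.any():
                np.testing.assert_allclose(pay[coop], -1.0)
                active = pay[expl][pay[expl] != 0.0]
                assert len(active) == 1 and active[0] in (5.0, -10.0)
            elif coop.any():
                np.testing.assert_allclose(pay[coop], 0.2)
            else:
                assert (pay[expl] == 0.0).all()


class TestUpdateTrust:
    def test_no_exploiters_full_trust(self):
        params = ModelParams()
        pop = make_pop(np.zeros(500))
        trust = update_trust(
            pop, np.full(500, int(Action.ALONE), np.int8), params, np.random.default_rng(0)
        )
        assert (trust == 1.0).all()

    def test_all_exploiters_zero_trust(self):
        params = ModelParams()
        pop = make_pop(np.zeros(500))
        trust = update_trust(
            pop, np.full(500, int(Action.EXPLOIT), np.int8), params, np.random.default_rng(0)
        )
        assert (trust == 0.0).all()

    def test_lookup_matches_direct_combinatorics(self):
        """k = 5 of K = 50 implies k' = 50 inferred exploiters; the no-
        exploiter-in-my-group probability is the product of four draws
        without replacement from the remaining 499 agents."""
        table = trust_lookup_table(500, 5)
        oracle = (449 / 499) * (448 / 498) * (447 / 497) * (446 / 496)
        assert table[50] == pytest.approx(oracle, rel=1e-12)
        assert 1 - table[50] == pytest.approx(0.345, abs=5e-4)
        assert table[0] == 1.0
        assert (table[500 - 5 + 1 :] == 0.0).all()
        assert (np.diff(table) <= 0).all()

    def test_sampled_prevalence_is_unbiased(self):
        """Average observed exploiter share k/K matches the true share."""
        params = ModelParams()
        pop = make_pop(np.zeros(500))
        actions = np.zeros(500, dtype=np.int8)
        actions[:100] = int(Action.EXPLOIT)
        table = trust_lookup_table(500, 5)
        rng = np.random.default_rng(3)
        ks = []
        for _ in range(50):
            trust = update_trust(pop, actions, params, rng)
            kprime = np.array([np.argmin(np.abs(table - t)) for t in trust])
            ks.append(kprime / 500 * 50)  # invert k' = k * N / K
        k_mean = np.mean(ks)
        # SE of the mean of 50*500 hypergeometric draws
        se = math.sqrt(50 * 0.2 * 0.8 * (449 / 499)) / math.sqrt(50 * 500)
        assert k_mean / 50 == pytest.approx(100 / 500, abs=3 * se / 50 + 1e-3)

    def test_oversized_sample_rejected(self):
        params = ModelParams(N=10, K=5, n=5)
        pop = make_pop(np.zeros(10))
        object.__setattr__(params, "K", 20)  # bypass constructor check
        with pytest.raises(ParameterError):
            update_trust(pop, np.zeros(10, np.int8), params, np.random.default_rng(0))


class TestPerturbationAndShock:
    def test_immobile_population_unchanged(self):
        pop = make_pop(np.arange(5.0))
        out = apply_perturbation(pop, ModelParams(r=0.0, N=5, K=4), np.random.default_rng(0))
        np.testing.assert_array_equal(out, np.arange(5.0))

    def test_shuffle_preserves_population_moments(self):
        params = ModelParams(r=0.1, N=100_000, n=5)
        rng = np.random.default_rng(11)
        pop = make_pop(rng.normal(5.5, 4.0, 100_000))
        before_m, before_v = pop.resources.mean(), pop.resources.var()
        out = apply_perturbation(pop, params, rng)
        n = params.N
        assert out.mean() == pytest.approx(before_m, abs=3 * 4.0 / math.sqrt(n))
        assert out.var() == pytest.approx(before_v, abs=3 * 16.0 * math.sqrt(2 / n))

    def test_full_mobility_decorrelates(self):
        params = ModelParams(r=1.0, N=100_000, n=5)
        rng = np.random.default_rng(12)
        pop = make_pop(rng.normal(5.5, 4.0, 100_000))
        before = pop.resources.copy()
        out = apply_perturbation(pop, params, rng)
        assert abs(np.corrcoef(before, out)[0, 1]) < 3 / math.sqrt(params.N)

    def test_shock_rescales_exactly(self):
        pop = make_pop(np.array([0.0, 2.0, 4.0, 6.0, 8.0]))
        mean = pop.resources.mean()
        apply_shock(pop, 1.0)
        assert pop.resources.mean() == pytest.approx(mean)
        assert pop.resources.std() == pytest.approx(1.0)
        apply_shock(pop, 0.0)
        assert (pop.resources == mean).all()

    def test_shock_requires_dispersion(self):
        with pytest.raises(ParameterError):
            apply_shock(make_pop(np.full(5, 3.0)), 1.0)


class TestStepAndRun:
    def test_cooperative_step_without_mobility_gains_surplus(self, default_policy):
        """All agents rich and trusting, r=0: everyone cooperates and the
        population mean rises by exactly x*(alpha-1)."""
        policy, _ = default_policy
        params = ModelParams(r=0.0, N=100)
        pop = make_pop(np.full(100, 40.0))
        pop, stats = step(pop, policy, params, np.random.default_rng(0))
        assert stats["n_coop"] == 100
        assert stats["mean_s"] == pytest.approx(40.2)

    def test_action_counts_partition_population(self, default_policy):
        policy, _ = default_policy
        trace = run_simulation(ModelParams(), policy, steps=10, seed=5)
        np.testing.assert_array_equal(
            trace.n_coop + trace.n_exploit + trace.n_alone, 500
        )

    def test_same_seed_bit_identical_traces(self, default_policy):
        policy, _ = default_policy
        a = run_simulation(ModelParams(), policy, steps=15, seed=9)
        b = run_simulation(ModelParams(), policy, steps=15, seed=9)
        assert a.to_frame().equals(b.to_frame())

    def test_trace_round_trips_to_files(self, default_policy, tmp_path):
        import json

        import pandas as pd

        policy, _ = default_policy
        trace = run_simulation(ModelParams(), policy, steps=12, seed=3)
        trace.to_csv(tmp_path / "trace.csv")
        frame = pd.read_csv(tmp_path / "trace.csv")
        assert len(frame) == 12
        trace.to_json(tmp_path / "trace.json")
        payload = json.loads((tmp_path / "trace.json").read_text())
        assert payload["seed"] == 3
        assert payload["params"]["N"] == 500

    def test_shock_requires_sigma(self, default_policy):
        policy, _ = default_policy
        with pytest.raises(ParameterError):
            run_simulation(ModelParams(), policy, steps=10, seed=0, shock_step=5)
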