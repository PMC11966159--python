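"""Unit tests for the core model: initialization, payoff, selection, stages."""

import math

import numpy as np
import pytest

from normsim import (
    ConfigurationError,
    PayoffVector,
    PopulationState,
    SimulationParams,
    compute_payoff,
    imitation_stage,
    init_population,
    interaction_stage,
    outgroup_mean,
    run_simulation,
    select_imitation_target,
    select_partner,
)


def payoff_oracle(x_i, x_j, x_out, theta, alpha, beta, gamma):
    """Independent arithmetic evaluation of the payoff, coded from scratch."""
    return math.exp(-alpha * (x_i - theta) ** 2) * math.exp(
        -beta * (x_i - x_j) ** 2
    ) + (1.0 - math.exp(-gamma * (x_i - x_out) ** 2))


class TestParams:
    @pytest.mark.parametrize(
        "kwargs, key",
        [
            (dict(rho=1.5), "rho"),
            (dict(r=-0.1), "r"),
            (dict(p=1.2), "p"),
            (dict(alpha=-1.0), "alpha"),
            (dict(init_sd=-0.5), "init_sd"),
            (dict(n_agents=1), "n_agents"),
            (dict(t_max=-1), "t_max"),
            (dict(group_means=(0.0, 1.0, 2.0)), "group_means"),
        ],
    )
    def test_invalid_values_name_the_field(self, kwargs, key):
        with pytest.raises(ValueError, match=key):
            SimulationParams(**kwargs)

    def test_empty_group_is_a_configuration_error_naming_the_group(self):
        with pytest.raises(ConfigurationError, match="group 0"):
            SimulationParams(n_agents=10, p=0.01)

    def test_scalar_p_splits_floor(self):
        assert SimulationParams(n_agents=100, p=0.5).group_sizes() == (50, 50)
        assert SimulationParams(n_agents=10, p=0.33).group_sizes() == (3, 7)

    def test_proportion_list_allocates_all_agents(self):
        params = SimulationParams(
            n_agents=10, n_groups=3, p=(0.5, 0.25, 0.25), group_means=(0, 1, 2)
        )
        sizes = params.group_sizes()
        assert sum(sizes) == 10 and all(s >= 1 for s in sizes)

    def test_per_group_theta(self):
        params = SimulationParams(theta=(0.0, 2.0))
        assert params.theta_per_group().tolist() == [0.0, 2.0]


class TestInitPopulation:
    def test_equal_group_sizes_at_p_half(self):
        state = init_population(SimulationParams(n_agents=100, p=0.5))
        assert state.members(0).size == 50 and state.members(1).size == 50

    def test_degenerate_sd_puts_all_traits_at_group_means(self):
        state = init_population(SimulationParams(init_sd=0.0, group_means=(0.0, 1.0)))
        assert np.all(state.traits[state.members(0)] == 0.0)
        assert np.all(state.traits[state.members(1)] == 1.0)

    def test_large_sample_group_mean_within_standard_error(self):
        state = init_population(SimulationParams(n_agents=10_000, seed=5))
        sample_mean = state.traits[state.members(1)].mean()
        assert abs(sample_mean - 1.0) < 3.0 / math.sqrt(5_000)

    def test_reproducible_given_seed(self):
        a = init_population(SimulationParams(seed=9))
        b = init_population(SimulationParams(seed=9))
        assert np.array_equal(a.traits, b.traits)

    def test_starts_at_t_zero(self):
        assert init_population(SimulationParams()).t == 0


class TestOutgroupMean:
    def test_identical_outgroup_values(self):
        state = PopulationState(traits=[0, 0, 4, 4], groups=[0, 0, 1, 1])
        assert outgroup_mean(state, 0) == 4.0

    def test_mean_of_two_values(self):
        state = PopulationState(traits=[1, 2, 3, 6], groups=[0, 0, 1, 1])
        assert outgroup_mean(state, 1) == 1.5

    def test_three_groups_pools_all_other_groups(self):
        state = PopulationState(traits=[0, 3, 9], groups=[0, 1, 2])
        assert outgroup_mean(state, 0) == 6.0

    def test_no_outgroup_is_an_error(self):
        state = PopulationState(traits=[1.0, 2.0], groups=[0, 0])
        with pytest.raises(ValueError):
            outgroup_mean(state, 0)


class TestComputePayoff:
    def test_identity_case_is_one(self):
        assert compute_payoff(0, 0, 0, 0, 0.02, 0.5, 0.05) == pytest.approx(1.0)

    def test_gamma_zero_two_force_special_case(self):
        assert compute_payoff(1.0, 1.0, 5.0, 1.0, 0.3, 0.7, 0.0) == 1.0

    def test_worked_example(self):
        # e^{-0.5} + (1 - e^{-0.05})
        value = compute_payoff(0.0, 1.0, 1.0, 0.0, 0.02, 0.5, 0.05)
        assert value == pytest.approx(0.655302, abs=1e-6)

    def test_matches_independent_oracle_on_random_tuples(self, rng):
        for _ in range(1000):
            x_i, x_j, x_out, theta = rng.normal(0, 3, size=4)
            alpha, beta, gamma = rng.uniform(0, 2, size=3)
            assert compute_payoff(x_i, x_j, x_out, theta, alpha, beta, gamma) == pytest.approx(
                payoff_oracle(x_i, x_j, x_out, theta, alpha, beta, gamma), abs=1e-12
            )

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            compute_payoff(np.nan, 0, 0, 0, 1, 1, 1)
        with pytest.raises(ValueError):
            compute_payoff(np.inf, 0, 0, 0, 1, 1, 1)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            compute_payoff(0, 0, 0, 0, -1.0, 1, 1)


class TestSelectPartner:
    def test_full_assortment_keeps_partner_ingroup(self, rng):
        state = init_population(SimulationParams(seed=1))
        for focal in [0, 10, 60, 99]:
            for _ in range(50):
                j = select_partner(state, focal, r=1.0, rng=rng)
                assert state.groups[j] == state.groups[focal] and j != focal

    def test_well_mixed_draw_is_uniform_over_others(self, rng):
        state = PopulationState(traits=np.zeros(5), groups=[0, 0, 0, 1, 1])
        counts = np.zeros(5)
        n = 20_000
        for _ in range(n):
            counts[select_partner(state, 2, r=0.0, rng=rng)] += 1
        assert counts[2] == 0
        # each of the 4 others ~ n/4; 5 sigma binomial band
        sigma = math.sqrt(n * 0.25 * 0.75)
        assert np.all(np.abs(counts[[0, 1, 3, 4]] - n / 4) < 5 * sigma)

    def test_ingroup_frequency_matches_analytic_mixture(self, rng):
        # r + (1-r) * 49/99 with N=100, equal groups
        state = init_population(SimulationParams(n_agents=100, p=0.5, seed=2))
        n, r = 100_000, 0.5
        expected = r + (1 - r) * 49 / 99
        hits = sum(
            state.groups[select_partner(state, 3, r, rng)] == state.groups[3]
            for _ in range(n)
        )
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(hits / n - expected) < 3 * se

    def test_singleton_ingroup_falls_back_to_population(self, rng, caplog):
        state = PopulationState(traits=np.zeros(3), groups=[0, 1, 1])
        with caplog.at_level("WARNING", logger="normsim"):
            j = select_partner(state, 0, r=1.0, rng=rng)
        assert j in (1, 2)
        assert "sole member" in caplog.text


class TestInteractionStage:
    def test_all_traits_at_theta_gives_unit_payoffs(self, rng):
        params = SimulationParams(n_agents=10, theta=0.0)
        state = PopulationState(traits=np.zeros(10), groups=[0] * 5 + [1] * 5)
        payoffs = interaction_stage(state, params, rng)
        assert np.allclose(payoffs.values, 1.0)

    def test_separated_clusters_gain_dissimilarity_payoff(self, rng):
        # two tight clusters 5 apart, only the outgroup term active
        params = SimulationParams(n_agents=10, alpha=0.0, beta=0.0, gamma=0.05, r=1.0)
        state = PopulationState(
            traits=np.array([0.0] * 5 + [5.0] * 5), groups=[0] * 5 + [1] * 5
        )
        payoffs = interaction_stage(state, params, rng)
        expected = 1.0 + (1.0 - math.exp(-0.05 * 25.0))
        assert np.allclose(payoffs.values, expected)
        assert expected == pytest.approx(1.7135, abs=1e-4)

    def test_payoffs_strictly_inside_bounds(self, rng):
        for seed in range(5):
            params = SimulationParams(seed=seed)
            state = init_population(params, np.random.default_rng(seed))
            payoffs = interaction_stage(state, params, rng)
            assert np.all(payoffs.values > 0.0) and np.all(payoffs.values < 2.0)

    def test_payoff_vector_rejects_out_of_bounds(self):
        with pytest.raises(ValueError):
            PayoffVector(values=np.array([0.5, 2.5]))
        with pytest.raises(ValueError):
            PayoffVector(values=np.array([0.0, 1.0]))


class TestSelectImitationTarget:
    def test_equal_payoffs_give_uniform_choice(self, rng):
        state = PopulationState(traits=np.zeros(4), groups=[0, 0, 1, 1])
        payoffs = PayoffVector(values=np.full(4, 0.7))
        n = 20_000
        counts = np.zeros(4)
        for _ in range(n):
            counts[select_imitation_target(payoffs, state, 0, rho=0.0, rng=rng)] += 1
        sigma = math.sqrt(n * 0.25 * 0.75)
        assert np.all(np.abs(counts - n / 4) < 5 * sigma)

    def test_full_coalitional_copying_stays_ingroup(self, rng):
        state = PopulationState(traits=np.zeros(6), groups=[0, 0, 0, 1, 1, 1])
        payoffs = PayoffVector(values=np.linspace(0.2, 1.8, 6))
        for focal in range(6):
            for _ in range(30):
                t = select_imitation_target(payoffs, state, focal, rho=1.0, rng=rng)
                assert state.groups[t] == state.groups[focal]

    def test_selection_probability_proportional_to_payoff(self, rng):
        # payoff ratio 1:3 -> probabilities 1/4 and 3/4
        state = PopulationState(traits=np.zeros(2), groups=[0, 1])
        payoffs = PayoffVector(values=np.array([0.5, 1.5]))
        n = 100_000
        hits = sum(
            select_imitation_target(payoffs, state, 0, rho=0.0, rng=rng) == 1
            for _ in range(n)
        )
        se = math.sqrt(0.75 * 0.25 / n)
        assert abs(hits / n - 0.75) < 3 * se


class TestImitationStage:
    def _uniform_payoffs(self, n):
        return PayoffVector(values=np.full(n, 1.0))

    def test_uniform_trait_population_is_fixed_point(self, rng):
        params = SimulationParams(n_agents=8)
        state = PopulationState(traits=np.full(8, 3.3), groups=[0] * 4 + [1] * 4)
        new = imitation_stage(state, self._uniform_payoffs(8), params, rng)
        assert np.all(new.traits == 3.3)
        assert new.t == state.t + 1
        assert np.array_equal(new.groups, state.groups)

    def test_copying_creates_no_new_values(self, rng):
        params = SimulationParams(n_agents=12, copy_noise_sd=0.0)
        state = init_population(params, np.random.default_rng(0))
        payoffs = interaction_stage(state, params, rng)
        new = imitation_stage(state, payoffs, params, rng)
        assert set(new.traits) <= set(state.traits)

    def test_full_coalitional_copying_keeps_values_within_groups(self):
        # with rho=1 and no noise, each group's trait set can only shrink
        params = SimulationParams(n_agents=6, rho=1.0, copy_noise_sd=0.0)
        rng = np.random.default_rng(99)
        state = PopulationState(
            traits=np.arange(6, dtype=float), groups=[0, 0, 0, 1, 1, 1]
        )
        for _ in range(1000):
            payoffs = interaction_stage(state, params, rng)
            new = imitation_stage(state, payoffs, params, rng)
            for g in (0, 1):
                assert set(new.traits[new.members(g)]) <= set(
                    state.traits[state.members(g)]
                )
            state = new

    def test_copy_noise_perturbs_adopted_values(self, rng):
        params = SimulationParams(n_agents=10, copy_noise_sd=0.5)
        state = init_population(params, np.random.default_rng(3))
        new = imitation_stage(state, self._uniform_payoffs(10), params, rng)
        assert not set(new.traits) <= set(state.traits)

    def test_asynchronous_mode_still_conserves_values(self):
        params = SimulationParams(n_agents=10, synchronous=False)
        rng = np.random.default_rng(4)
        state = init_population(params, rng)
        payoffs = interaction_stage(state, params, rng)
        new = imitation_stage(state, payoffs, params, rng)
        assert set(new.traits) <= set(state.traits)


class TestRunSimulation:
    def test_zero_steps_returns_only_initial_state(self):
        traj = run_simulation(SimulationParams(t_max=0, seed=1))
        assert traj.per_step_group_medians.shape == (1, 2)
        assert np.array_equal(traj.final_state.traits, traj.initial_state.traits)

    def test_records_one_row_per_step_plus_initial(self):
        traj = run_simulation(SimulationParams(n_agents=30, t_max=17, seed=1))
        assert traj.per_step_group_medians.shape == (18, 2)
        assert traj.final_state.t == 17

    def test_record_states_keeps_full_history(self):
        traj = run_simulation(
            SimulationParams(n_agents=10, t_max=5, seed=1), record_states=True
        )
        assert [s.t for s in traj.states] == list(range(6))
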