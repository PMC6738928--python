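import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

import frailsim as fs
from frailsim.econ import CostModel, UtilityModel
from frailsim.engine import (
    ScenarioConfig,
    SimConfig,
    build_uniform_block,
    max_cycle_count,
    run_comparison,
    simulate_cohort,
    simulate_individual,
)
from frailsim.errors import ConfigurationError, InvalidInputError
from frailsim.frailty import FrailtyCategory
from frailsim.risks import FrailtyTransitionModel, RiskEquation, RiskParams
from frailsim.validation import combined_markov_kernel, markov_oracle, memoryless_test_model


def const_params(q_death: float, extra: dict | None = None, transitions=None) -> RiskParams:
    eqs = {"death": RiskEquation("death", {"intercept": float(logit(q_death)) if 0 < q_death < 1
                                           else (1e3 if q_death >= 1 else -1e3)})}
    for name, coeffs in (extra or {}).items():
        eqs[name] = RiskEquation(name, coeffs)
    return RiskParams(equations=eqs, transitions=transitions or FrailtyTransitionModel(np.eye(3)))


@pytest.fixture(scope="module")
def flat_cohort():
    n = 200
    return pd.DataFrame({"id": np.arange(n), "age": np.full(n, 65.0),
                         "frailty_status": np.zeros(n)})


def base_individual():
    return {"age": 65.0, "frailty_status": 0.0}


class TestSimulateIndividual:
    def test_no_risk_limit_survives_to_max_age(self, mini_structure):
        params = const_params(0.0, {"hip_fracture": {"intercept": -1e3},
                                    "falls": {"intercept": -1e3}})
        baseline = {**base_individual(), "n_prev_fractures": 0.0}
        config = SimConfig(max_age=80.0, seed=1)
        traj = simulate_individual(baseline, mini_structure, params, ScenarioConfig(), config)
        assert traj.death_cycle is None
        assert traj.life_years == pytest.approx(80.0 - 65.0)

    def test_certain_death_single_cycle(self, mini_structure):
        params = const_params(1.0, {"hip_fracture": {"intercept": -1e3},
                                    "falls": {"intercept": -1e3}})
        baseline = {**base_individual(), "n_prev_fractures": 0.0}
        traj = simulate_individual(baseline, mini_structure, params, ScenarioConfig(),
                                   SimConfig(seed=2))
        assert len(traj.records) == 1
        assert traj.death_cycle == 0
        assert traj.records[0].events["death"]

    def test_fracture_increments_counter_by_one(self, mini_structure):
        # fracture certain every cycle, death never
        params = const_params(0.0, {"hip_fracture": {"intercept": 1e3},
                                    "falls": {"intercept": -1e3}})
        baseline = {**base_individual(), "n_prev_fractures": 0.0}
        traj = simulate_individual(baseline, mini_structure, params, ScenarioConfig(),
                                   SimConfig(max_age=70.0, seed=3))
        for prev, nxt in zip(traj.records, traj.records[1:]):
            assert prev.events["hip_fracture"]
            assert nxt.attributes["n_prev_fractures"] == prev.attributes["n_prev_fractures"] + 1

    def test_missing_attribute_rejected(self, mini_structure, mini_truth):
        with pytest.raises(InvalidInputError):
            simulate_individual(base_individual(), mini_structure, mini_truth,
                                ScenarioConfig(), SimConfig(seed=0))

    def test_memory_property_prior_fracture_raises_risk(self, mini_structure, mini_truth):
        # positive history coefficient: identical individuals except the
        # counter must differ strictly in next-cycle fracture probability
        from frailsim.risks import cycle_probability, linear_predictor

        eq = mini_truth.equations["hip_fracture"]
        assert eq.coefficients["n_prev_fractures"] > 0
        state0 = {"age": 75.0, "frailty_status": 1.0, "n_prev_fractures": 0.0}
        state1 = {**state0, "n_prev_fractures": 1.0}
        p0 = cycle_probability(linear_predictor(eq, state0))
        p1 = cycle_probability(linear_predictor(eq, state1))
        assert p1 > p0


class TestSimulateCohort:
    def test_geometric_closed_form(self, flat_cohort):
        # constant q=0.25 with no other events: mean recorded cycles = 1/q
        q = 0.25
        n = 20_000
        cohort = pd.DataFrame({"id": np.arange(n), "age": np.zeros(n),
                               "frailty_status": np.zeros(n)})
        structure, _, _ = memoryless_test_model()
        res = simulate_cohort(cohort, structure, const_params(q), ScenarioConfig(),
                              SimConfig(seed=9, max_age=500.0))
        assert abs(res.mean_life_years - 1 / q) < 3 * res.se_life_years

    def test_determinism(self, mini_structure, mini_truth):
        cohort = pd.DataFrame({"id": np.arange(500), "age": np.full(500, 70.0),
                               "frailty_status": np.zeros(500), "n_prev_fractures": np.zeros(500)})
        kwargs = dict(discount_rate=0.05)
        a = simulate_cohort(cohort, mini_structure, mini_truth, ScenarioConfig(),
                            SimConfig(seed=5), **kwargs)
        b = simulate_cohort(cohort, mini_structure, mini_truth, ScenarioConfig(),
                            SimConfig(seed=5), **kwargs)
        assert np.array_equal(a.qalys, b.qalys)
        assert np.array_equal(a.costs, b.costs)
        assert np.array_equal(a.death_cycle, b.death_cycle)

    def test_mc_error_scales_with_sqrt_n(self, mini_structure, mini_truth):
        def se_at(n, seed):
            cohort = pd.DataFrame({"id": np.arange(n), "age": np.full(n, 70.0),
                                   "frailty_status": np.zeros(n),
                                   "n_prev_fractures": np.zeros(n)})
            res = simulate_cohort(cohort, mini_structure, mini_truth, ScenarioConfig(),
                                  SimConfig(seed=seed))
            return res.se_qalys

        ratio = se_at(2_000, 1) / se_at(8_000, 2)
        assert 1.5 < ratio < 2.5  # expect ~2 when n quadruples

    def test_alive_dead_conservation(self, mini_structure, mini_truth):
        n = 1_000
        cohort = pd.DataFrame({"id": np.arange(n), "age": np.full(n, 75.0),
                               "frailty_status": np.ones(n), "n_prev_fractures": np.zeros(n)})
        res = simulate_cohort(cohort, mini_structure, mini_truth, ScenarioConfig(),
                              SimConfig(seed=3))
        assert np.allclose(res.occupancy.sum(axis=1), n)

    def test_empty_cohort_rejected(self, mini_structure, mini_truth):
        with pytest.raises(InvalidInputError):
            simulate_cohort(pd.DataFrame({"age": []}), mini_structure, mini_truth,
                            ScenarioConfig(), SimConfig(seed=0))

    def test_missing_attribute_rejected(self, mini_structure, mini_truth):
        cohort = pd.DataFrame({"id": [0], "age": [70.0]})
        with pytest.raises(InvalidInputError):
            simulate_cohort(cohort, mini_structure, mini_truth, ScenarioConfig(),
                            SimConfig(seed=0))


class TestScalarVectorEquivalence:
    def test_same_uniform_block_same_outcomes(self, structure, params):
        cohort = fs.generate_cohort(fs.synth.default_cohort_spec(n=40, seed=21))
        config = SimConfig(seed=22)
        cycles = max_cycle_count(config, float(cohort["age"].min()))
        block = build_uniform_block(config.seed, len(cohort), cycles, structure)
        util, cost = UtilityModel(), CostModel(event_costs={"hip_fracture": 100.0})
        res = simulate_cohort(cohort, structure, params, ScenarioConfig(), config,
                              utility_model=util, cost_model=cost,
                              discount_rate=0.03, uniforms=block)
        for i in range(len(cohort)):
            traj = simulate_individual(cohort.iloc[i].to_dict(), structure, params,
                                       ScenarioConfig(), config, uniforms=block[i],
                                       utility_model=util, cost_model=cost)
            assert traj.life_years == res.life_years[i]
            assert fs.accrue_qalys(traj, rate=0.03) == pytest.approx(res.qalys[i], abs=1e-9)
            assert fs.accrue_costs(traj, rate=0.03) == pytest.approx(res.costs[i], abs=1e-9)
            expected_dc = traj.death_cycle if traj.death_cycle is not None else -1
            assert expected_dc == res.death_cycle[i]


def two_cycle_expected_qalys(death_probs, transitions, pi0, utilities, cycles=2):
    """Exact per-capita expected QALYs for a memoryless model: everyone alive
    at a cycle start accrues that cycle at the cycle-start category utility."""
    P = combined_markov_kernel(np.asarray(death_probs), transitions)
    trace = markov_oracle(P, np.append(pi0, 0.0), cycles)
    u = np.append(np.asarray(utilities), 0.0)
    return float(sum(trace[c] @ u for c in range(cycles)))


class TestRunComparison:
    def test_self_comparison_exact_zero(self, mini_structure, mini_truth):
        cohort = pd.DataFrame({"id": np.arange(300), "age": np.full(300, 78.0),
                               "frailty_status": np.ones(300), "n_prev_fractures": np.zeros(300)})
        comp = run_comparison(cohort, mini_structure, mini_truth, ScenarioConfig(),
                              ScenarioConfig(), SimConfig(seed=13), discount_rate=0.05)
        assert np.all(comp.delta_costs == 0.0)
        assert np.all(comp.delta_qalys == 0.0)
        assert comp.ce.label.value == "equal effectiveness"

    def test_pure_cost_intervention_exact_accounting(self, mini_structure, mini_truth):
        cohort = pd.DataFrame({"id": np.arange(200), "age": np.full(200, 78.0),
                               "frailty_status": np.ones(200), "n_prev_fractures": np.zeros(200)})
        C = 1234.5
        comp = run_comparison(
            cohort, mini_structure, mini_truth, ScenarioConfig(),
            ScenarioConfig(name="costly", intervention=True, one_off_cost=C),
            SimConfig(seed=14), discount_rate=0.05,
        )
        # one-off cost falls at cycle 0 where the discount factor is 1
        assert np.all(comp.delta_costs == C)
        assert np.all(comp.delta_qalys == 0.0)

    def test_halved_worsening_dominates_enumeration_oracle(self):
        structure, params, pi0 = memoryless_test_model(
            death_probs=(0.05, 0.10, 0.20),
            transitions=FrailtyTransitionModel(
                [[0.6, 0.3, 0.1], [0.1, 0.6, 0.3], [0.0, 0.1, 0.9]]
            ),
        )
        utilities = UtilityModel().frailty_vector
        q = (0.05, 0.10, 0.20)
        base_T = params.transitions
        from frailsim.risks import transition_matrix_for_scenario

        treated_T = FrailtyTransitionModel(transition_matrix_for_scenario(base_T, 0.5))
        exp_base = two_cycle_expected_qalys(q, base_T, pi0, utilities)
        exp_treat = two_cycle_expected_qalys(q, treated_T, pi0, utilities)
        assert exp_treat >= exp_base  # exact stochastic-dominance check

        n = 20_000
        rng = np.random.default_rng(31)
        frailty0 = rng.choice(3, size=n, p=pi0)
        cohort = pd.DataFrame({
            "id": np.arange(n), "age": np.zeros(n),
            "frailty_status": frailty0.astype(float),
        })
        # condition the oracle on the realised baseline mix so the engine's
        # only discrepancy is its own Monte-Carlo error
        pi_emp = np.bincount(frailty0, minlength=3) / n
        exp_base = two_cycle_expected_qalys(q, base_T, pi_emp, utilities)
        exp_treat = two_cycle_expected_qalys(q, treated_T, pi_emp, utilities)
        config = SimConfig(seed=32, max_age=3.0, horizon_cycles=2)
        comp = run_comparison(
            cohort, structure, params, ScenarioConfig(),
            ScenarioConfig(name="treat", frailty_worsening_multiplier=0.5),
            config,
        )
        # engine agrees with the exact enumeration on both arms
        assert comp.result_a.mean_qalys == pytest.approx(exp_base, abs=3 * comp.result_a.se_qalys)
        assert comp.result_b.mean_qalys == pytest.approx(exp_treat, abs=3 * comp.result_b.se_qalys)
        # and the intervention is no worse than comparator within MC error
        assert comp.mean_delta_qalys >= -3 * comp.se_delta_qalys


class TestConfigs:
    def test_scenario_validation(self):
        with pytest.raises(ConfigurationError):
            ScenarioConfig(frailty_worsening_multiplier=-0.1)
        with pytest.raises(ConfigurationError):
            ScenarioConfig(event_hazard_multipliers={"falls": 0.0})
        with pytest.raises(ConfigurationError):
            ScenarioConfig(one_off_cost=-5.0)

    def test_sim_config_validation(self):
        with pytest.raises(ConfigurationError):
            SimConfig(cycle_length=0.0)
        with pytest.raises(ConfigurationError):
            SimConfig(max_age=float("inf"))

    def test_hazard_multiplier_shifts_probability(self, mini_structure, mini_truth):
        n = 20_000
        cohort = pd.DataFrame({"id": np.arange(n), "age": np.full(n, 80.0),
                               "frailty_status": np.ones(n), "n_prev_fractures": np.zeros(n)})
        config = SimConfig(seed=40, horizon_cycles=1)
        comp = run_comparison(
            cohort, mini_structure, mini_truth, ScenarioConfig(),
            ScenarioConfig(name="protect", event_hazard_multipliers={"falls": 0.5}),
            config,
        )
        base_rate = comp.result_a.cycle_events["falls"][0] / n
        treat_rate = comp.result_b.cycle_events["falls"][0] / n
        assert treat_rate < base_rate

    def test_half_cycle_correction_halves_first_cycle(self, mini_structure):
        params = const_params(0.0, {"hip_fracture": {"intercept": -1e3},
                                    "falls": {"intercept": -1e3}})
        baseline = {"age": 65.0, "frailty_status": 0.0, "n_prev_fractures": 0.0}
        on = simulate_individual(baseline, mini_structure, params, ScenarioConfig(),
                                 SimConfig(max_age=67.0, half_cycle_correction=True, seed=1))
        off = simulate_individual(baseline, mini_structure, params, ScenarioConfig(),
                                  SimConfig(max_age=67.0, seed=1))
        assert on.records[0].utility == pytest.approx(0.5 * off.records[0].utility)
        assert on.records[1].utility == off.records[1].utility
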