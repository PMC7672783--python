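import copy
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as hs

import mscea
from mscea.analysis import (
    DOMINANT,
    DOMINATED,
    ICER,
    NOT_ACHIEVABLE,
    PSAConfig,
    ceac,
    compare,
    evaluate_pair,
    one_way_sensitivity,
    run_psa,
    table4_registry,
    threshold_sdm_cost,
)
from mscea.economics import OUTCOME_COST_KEYS, Outcomes
from mscea.parameters import validate_parameter_set


def fake_outcomes(cost: float, qalys: float) -> Outcomes:
    costs = {k: 0.0 for k in OUTCOME_COST_KEYS}
    costs["health_state_healthcare"] = cost
    return Outcomes(qalys, qalys, 0, 0, 0, 0, 0, 0, costs, dict(costs),
                    1.0, 1.0, "societal_friction")


class TestCompare:
    def test_cheaper_and_better_is_dominant(self):
        res = compare(fake_outcomes(-807.0, 0.33), fake_outcomes(0.0, 0.0))
        assert res.classification == DOMINANT
        assert res.icer is None

    def test_plain_icer(self):
        res = compare(fake_outcomes(1000.0, 1.0), fake_outcomes(0.0, 0.0))
        assert res.classification == ICER
        assert res.icer == pytest.approx(1000.0)

    def test_costlier_without_benefit_is_dominated(self):
        res = compare(fake_outcomes(1000.0, 0.0), fake_outcomes(0.0, 0.0))
        assert res.classification == DOMINATED

    def test_mismatched_perspectives_rejected(self):
        a = fake_outcomes(1.0, 1.0)
        b = fake_outcomes(0.0, 0.0)
        b.perspective = "healthcare"
        with pytest.raises(ValueError):
            compare(a, b)

    @given(hs.floats(-1e5, 1e5), hs.floats(-10, 10),
           hs.floats(-1e5, 1e5), hs.floats(-10, 10))
    def test_swapping_arms_negates_deltas(self, c1, q1, c2, q2):
        a, b = fake_outcomes(c1, q1), fake_outcomes(c2, q2)
        fwd, rev = compare(a, b), compare(b, a)
        assert fwd.delta_cost == pytest.approx(-rev.delta_cost)
        assert fwd.delta_qaly == pytest.approx(-rev.delta_qaly)


class TestThreshold:
    def test_rerun_confirms_linear_solve(self, params, cau, sdm):
        wtp = 50_000.0
        c_star = threshold_sdm_cost(cau, sdm, params, wtp)
        assert isinstance(c_star, float)
        res = compare(
            mscea.evaluate_strategy(replace(sdm, sdm_cost_per_decision=c_star), params),
            mscea.evaluate_strategy(cau, params))
        assert res.delta_cost / res.delta_qaly == pytest.approx(wtp, rel=1e-6)

    def test_qaly_losing_configuration_not_achievable(self, params, cau, sdm):
        # reverse the arms: usual care gains no QALYs over SDM
        cau_as_sdm = replace(cau, sdm_cost_per_decision=100.0)
        assert threshold_sdm_cost(sdm, cau_as_sdm, params, 20_000) == NOT_ACHIEVABLE


class TestOneWaySensitivity:
    @pytest.fixture(scope="class")
    def owsa(self, params, cau, sdm):
        return one_way_sensitivity(table4_registry(params), params, cau, sdm)

    def test_identity_scenario_reproduces_base_case(self, params, cau, sdm, owsa):
        base = evaluate_pair(cau, sdm, params)
        row = owsa.set_index("scenario").loc["base_case"]
        assert row["delta_cost"] == pytest.approx(base.delta_cost)
        assert row["delta_qaly"] == pytest.approx(base.delta_qaly)

    def test_preset_covers_the_standard_scenarios(self, owsa):
        names = set(owsa["scenario"])
        assert "sdm_cost_0" in names
        assert {"drug_costs_+20%", "drug_costs_-20%", "discount_0%",
                "healthcare_perspective", "entry_100%_edss1",
                "transitions_+10%"} <= names
        assert len(names) == len(owsa)

    def test_zero_delivery_cost_lowers_incremental_cost(self, owsa):
        t = owsa.set_index("scenario")
        assert t.loc["sdm_cost_0", "delta_cost"] < t.loc["base_case", "delta_cost"]
        assert t.loc["sdm_cost_0", "delta_qaly"] == pytest.approx(
            t.loc["base_case", "delta_qaly"])

    def test_transition_scaling_keeps_rows_stochastic(self, params, cau, sdm):
        for sc in table4_registry(params):
            if sc.name.startswith("transitions"):
                p, _, _ = sc.transform(params, cau, sdm)
                assert validate_parameter_set(p) == []

    def test_unknown_scenario_parameter_rejected(self, params, cau, sdm):
        from mscea.analysis import Scenario, _set_settings
        bad = Scenario("typo", _set_settings(no_such_setting=1))
        with pytest.raises(AttributeError):
            one_way_sensitivity([bad], params, cau, sdm)

    def test_lower_progression_risk_never_hurts_low_edss_time(self, params, cau):
        """Lowering every drug's progression relative risk cannot decrease
        the time the treated cohort spends at low EDSS."""
        from mscea.engine import initial_occupancy, run_cohort
        from mscea.states import EDSS_OF_INDEX, IS_ALIVE
        low = IS_ALIVE & (EDSS_OF_INDEX <= 3)
        p_lo = copy.deepcopy(params)
        for d in p_lo.dmds.values():
            d.rr_progression *= 0.6
        t_base = run_cohort(params, cau, initial_occupancy(cau, params))
        t_lo = run_cohort(p_lo, cau, initial_occupancy(cau, p_lo))
        time_low_base = t_base.occupancy[..., low].sum()
        time_low_lo = t_lo.occupancy[..., low].sum()
        assert time_low_lo >= time_low_base


class TestPSA:
    @pytest.fixture(scope="class")
    def psa(self, params, cau, sdm):
        return run_psa(cau, sdm, params, n=40, seed=11)

    def test_same_seed_is_bit_identical(self, params, cau, sdm, psa):
        again = run_psa(cau, sdm, params, n=40, seed=11)
        assert np.array_equal(psa.delta_cost, again.delta_cost)
        assert np.array_equal(psa.delta_qaly, again.delta_qaly)
        assert np.array_equal(psa.ceac, again.ceac)

    def test_degenerate_distributions_reproduce_the_point_estimate(
            self, params, cau, sdm):
        cfg = PSAConfig(sample_transitions=False, sample_relative_risks=False,
                        sample_utilities=False, sample_state_costs=False,
                        sample_relapse_model=False, sample_discontinuation=False,
                        sample_sdm_effects=False)
        r = run_psa(cau, sdm, params, config=cfg, n=3, seed=0)
        det = evaluate_pair(cau, sdm, params)
        assert np.allclose(r.delta_cost, det.delta_cost)
        assert np.allclose(r.delta_qaly, det.delta_qaly)

    def test_ceac_equals_brute_force_counting(self, psa):
        grid = psa.wtp_grid
        brute = np.array([
            np.mean([w * q - c >= 0 for c, q in zip(psa.delta_cost, psa.delta_qaly)])
            for w in grid])
        assert np.array_equal(psa.ceac, brute)

    def test_ceac_at_zero_wtp_counts_cost_saving_draws(self, psa):
        assert ceac(psa, np.array([0.0]))[0] == np.mean(psa.delta_cost <= 0)

    def test_ceac_limit_counts_qaly_gaining_draws(self, psa):
        huge = ceac(psa, np.array([1e12]))[0]
        expected = np.mean(
            (psa.delta_qaly > 0)
            | ((psa.delta_qaly == 0) & (psa.delta_cost <= 0)))
        assert huge == pytest.approx(expected)

    def test_ceac_values_bounded_and_monotone_for_gaining_draws(self, psa):
        assert ((psa.ceac >= 0) & (psa.ceac <= 1)).all()
        if (psa.delta_qaly >= 0).all():
            assert (np.diff(psa.ceac) >= 0).all()

    def test_empty_grid_rejected(self, psa):
        with pytest.raises(ValueError):
            ceac(psa, np.array([]))

    def test_invalid_iteration_count_rejected(self, params, cau, sdm):
        with pytest.raises(ValueError):
            run_psa(cau, sdm, params, n=0, seed=1)
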