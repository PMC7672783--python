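import copy
from dataclasses import replace

import numpy as np
import pytest

import mscea
from mscea.economics import (
    accrue,
    cycle_person_costs,
    cycle_treatment_costs,
    discount_factor,
    OUTCOME_COST_KEYS,
)
from mscea.engine import initial_occupancy, run_cohort
from mscea.states import DEAD_INDEX


class TestDiscounting:
    def test_zero_rate_never_discounts(self):
        assert np.all(discount_factor(0.0, np.arange(50)) == 1.0)

    def test_cycle_zero_is_undiscounted(self):
        assert discount_factor(0.04, 0) == 1.0

    def test_unit_stream_three_cycles_at_cost_rate(self):
        total = discount_factor(0.04, np.arange(3)).sum()
        assert total == pytest.approx(2.8861, abs=1e-4)

    def test_default_rates_follow_dutch_guideline(self, params):
        assert params.economics.discount_effects == 0.015
        assert params.economics.discount_costs == 0.040

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(-0.01, 1)


class TestTreatmentCosts:
    def test_first_year_dispensing_fee_schedule(self, params):
        d = replace(params.dmds["dimethyl_fumarate"], annual_drug_cost=0.0,
                    monitoring_pretreatment=0.0, monitoring_annual=0.0)
        assert cycle_treatment_costs(d, 0, params.economics) == pytest.approx(
            14 + 11 * 7)
        assert cycle_treatment_costs(d, 1, params.economics) == pytest.approx(12 * 7)

    def test_infused_drugs_pay_no_dispensing_fee(self, params):
        d = replace(params.dmds["natalizumab"], annual_drug_cost=0.0,
                    admin_cost_first_year=0.0, admin_cost_subsequent=0.0,
                    monitoring_pretreatment=0.0, monitoring_annual=0.0)
        assert cycle_treatment_costs(d, 0, params.economics) == 0.0

    def test_pretreatment_monitoring_first_year_only(self, params):
        d = params.dmds["teriflunomide_14mg"]
        first = cycle_treatment_costs(d, 0, params.economics)
        later = cycle_treatment_costs(d, 1, params.economics)
        assert first - later == pytest.approx(d.monitoring_pretreatment + 7.0)


class TestPersonCosts:
    def test_healthcare_perspective_excludes_societal_categories(self, params):
        eco = params.economics
        hc = cycle_person_costs(5, "healthcare", eco)
        assert hc == pytest.approx(eco.state_costs[5, 0] * (1 + eco.ae_cost_fraction))

    def test_perspective_nesting(self, params):
        eco = params.economics
        for j in range(19):
            hc = cycle_person_costs(j, "healthcare", eco)
            fr = cycle_person_costs(j, "societal_friction", eco)
            assert fr >= hc

    def test_human_capital_dominates_when_its_losses_are_larger(self, params):
        eco = copy.deepcopy(params.economics)
        eco.state_costs[:, 5] = eco.state_costs[:, 4] + 100.0
        for j in range(19):
            assert cycle_person_costs(j, "societal_human_capital", eco) \
                >= cycle_person_costs(j, "societal_friction", eco)

    def test_dead_state_and_unknown_perspective_rejected(self, params):
        with pytest.raises(ValueError):
            cycle_person_costs(DEAD_INDEX, "healthcare", params.economics)
        with pytest.raises(ValueError):
            cycle_person_costs(0, "payer", params.economics)


class TestAccrual:
    @pytest.fixture(scope="class")
    def trace(self, params, cau):
        return run_cohort(params, cau, initial_occupancy(cau, params))

    def test_zero_utilities_zero_qalys_life_years_unchanged(self, params, cau, trace):
        p = copy.deepcopy(params)
        p.economics.utilities[:] = 0.0
        p.economics.relapse_disutility_severe = 0.0
        p.economics.relapse_disutility_mild = 0.0
        for d in p.dmds.values():
            d.ae_disutility = 0.0
        out = accrue(trace, cau, p)
        ref = accrue(trace, cau, params)
        assert out.qalys == 0.0
        assert out.life_years == pytest.approx(ref.life_years)

    def test_zero_discount_rates_collapse_to_undiscounted(self, params, cau, trace):
        p = copy.deepcopy(params)
        p.economics.discount_effects = p.economics.discount_costs = 0.0
        out = accrue(trace, cau, p)
        assert out.qalys == pytest.approx(out.qalys_undiscounted)
        assert out.total_cost() == pytest.approx(out.total_cost_undiscounted())
        for k in OUTCOME_COST_KEYS:
            assert out.costs[k] == pytest.approx(out.costs_undiscounted[k])

    def test_discounted_below_undiscounted_for_positive_streams(self, params, cau, trace):
        out = accrue(trace, cau, params)
        assert out.qalys < out.qalys_undiscounted
        assert out.life_years < out.life_years_undiscounted
        for k in OUTCOME_COST_KEYS:
            assert out.costs[k] <= out.costs_undiscounted[k]

    def test_doubling_unit_costs_doubles_every_component(self, params, cau, trace):
        p = copy.deepcopy(params)
        p.economics.state_costs = p.economics.state_costs * 2
        p.economics.relapse_cost_severe *= 2
        p.economics.relapse_cost_mild *= 2
        p.economics.dispensing_fee_first *= 2
        p.economics.dispensing_fee_subsequent *= 2
        for d in p.dmds.values():
            d.annual_drug_cost *= 2
            d.admin_cost_first_year *= 2
            d.admin_cost_subsequent *= 2
            d.monitoring_pretreatment *= 2
            d.monitoring_annual *= 2
            d.monitoring_post_discontinuation *= 2
        doubled = accrue(trace, replace(cau, sdm_cost_per_decision=0.0), p)
        base = accrue(trace, replace(cau, sdm_cost_per_decision=0.0), params)
        for k in OUTCOME_COST_KEYS:
            if k == "sdm_delivery":
                continue
            assert doubled.costs[k] == pytest.approx(2 * base.costs[k])

    def test_linearity_in_occupancy_mass(self, params, cau, trace):
        half = copy.copy(trace)
        half.occupancy = trace.occupancy * 0.5
        half.voluntary_disc = trace.voluntary_disc * 0.5
        half.forced_stop = trace.forced_stop * 0.5
        half.newcomers = trace.newcomers * 0.5
        half.decisions = trace.decisions * 0.5
        out = accrue(half, cau, params)
        ref = accrue(trace, cau, params)
        assert out.qalys == pytest.approx(0.5 * ref.qalys)
        assert out.total_cost() == pytest.approx(0.5 * ref.total_cost())

    def test_totals_equal_sum_of_their_categories(self, params, cau, trace):
        out = accrue(trace, cau, params)
        hc_keys = ("drug", "administration", "monitoring", "dispensing",
                   "adverse_events", "relapse", "health_state_healthcare",
                   "sdm_delivery")
        assert out.total_cost("healthcare") == pytest.approx(
            sum(out.costs[k] for k in hc_keys), abs=1e-6)
        assert out.total_cost("societal_friction") == pytest.approx(
            out.total_cost("healthcare") + out.costs["community"]
            + out.costs["equipment"] + out.costs["informal_care"]
            + out.costs["productivity_friction"], abs=1e-6)

    def test_perspective_totals_nest(self, params, cau, trace):
        out = accrue(trace, cau, params)
        assert out.total_cost("healthcare") <= out.total_cost("societal_friction")

    def test_outcome_frame_lists_all_quantities(self, params, cau, trace):
        df = accrue(trace, cau, params).to_frame()
        assert "qalys" in set(df["quantity"])
        assert len(df) == 4 + len(OUTCOME_COST_KEYS) + 3
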