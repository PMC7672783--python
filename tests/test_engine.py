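import copy
from dataclasses import replace

import numpy as np
import pytest

import mscea
from mscea.economics import accrue
from mscea.engine import (
    StageKind,
    StageSpace,
    TreatmentStage,
    effective_discontinuation,
    initial_occupancy,
    run_cohort,
    run_pathway,
    switch_distribution,
)
from mscea.states import DEAD_INDEX, EDSS_OF_INDEX, IS_ALIVE, N_STATES


def neutralize_treatment(params):
    """All drugs behave exactly like best supportive care and cost nothing."""
    p = copy.deepcopy(params)
    for d in p.dmds.values():
        d.rr_progression = d.rr_relapse = 1.0
        d.annual_drug_cost = d.admin_cost_first_year = d.admin_cost_subsequent = 0.0
        d.monitoring_pretreatment = d.monitoring_annual = 0.0
        d.monitoring_post_discontinuation = 0.0
        d.prescriptions_per_year = 0
        d.ae_disutility = 0.0
    p.settings.nonadherent_relapse_multiplier = 1.0
    p.settings.nonadherent_severe_multiplier = 1.0
    return p


class TestDiscontinuation:
    def test_sdm_halves_usual_care_rate(self, params, sdm):
        dmf = params.dmds["dimethyl_fumarate"]
        assert effective_discontinuation(dmf, sdm, 3, params.settings) \
            == pytest.approx(0.107)

    def test_multiplier_one_leaves_rate_unchanged(self, params, cau):
        dmf = params.dmds["dimethyl_fumarate"]
        assert effective_discontinuation(dmf, cau, 0, params.settings) \
            == pytest.approx(dmf.cau_discontinuation)

    def test_high_edss_forces_certain_stop(self, params, cau, sdm):
        for strat in (cau, sdm):
            for d in params.dmds.values():
                assert effective_discontinuation(d, strat, 7, params.settings) == 1.0


class TestSwitchDistribution:
    def test_second_dmd_always_ends_on_best_supportive_care(self, params, cau):
        for name in params.dmds:
            dist = switch_distribution(
                TreatmentStage(StageKind.ON_SECOND_DMD, name), cau, params)
            assert dist == {TreatmentStage(StageKind.BSC_AFTER_DMD): 1.0}

    @pytest.mark.parametrize("drug", ["dimethyl_fumarate", "natalizumab"])
    def test_distribution_is_normalized(self, params, cau, sdm, drug):
        for strat in (cau, sdm):
            dist = switch_distribution(
                TreatmentStage(StageKind.ON_FIRST_DMD, drug), strat, params)
            assert sum(dist.values()) == pytest.approx(1.0)
            assert all(v >= 0 for v in dist.values())

    def test_first_line_switchers_split_by_reason(self, params, cau):
        dist = switch_distribution(
            TreatmentStage(StageKind.ON_FIRST_DMD, "dimethyl_fumarate"), cau, params)
        first_mass = sum(v for k, v in dist.items()
                         if k.is_dmd and params.dmds[k.dmd].line == "first")
        second_mass = sum(v for k, v in dist.items()
                          if k.is_dmd and params.dmds[k.dmd].line == "second")
        assert first_mass == pytest.approx(0.95 * 0.79)
        assert second_mass == pytest.approx(0.95 * 0.21)
        assert dist[TreatmentStage(StageKind.BSC_AFTER_DMD)] == pytest.approx(0.05)
        assert not any(k.dmd == "dimethyl_fumarate" for k in dist if k.is_dmd)

    def test_second_line_first_drug_stays_within_second_line(self, params, cau):
        dist = switch_distribution(
            TreatmentStage(StageKind.ON_FIRST_DMD, "natalizumab"), cau, params)
        dmd_mass = {k.dmd: v for k, v in dist.items() if k.is_dmd}
        assert all(params.dmds[d].line == "second" for d in dmd_mass)
        assert "natalizumab" not in dmd_mass
        assert sum(dmd_mass.values()) == pytest.approx(0.95)

    def test_single_candidate_gets_full_side_effect_mass(self):
        p = mscea.generate_parameter_set(mscea.GeneratorConfig(seed=7, n_dmds=3))
        first = [d for d, pr in p.dmds.items() if pr.line == "first"]
        assert len(first) == 2
        dist = switch_distribution(
            TreatmentStage(StageKind.ON_FIRST_DMD, first[0]),
            p.strategies["CAU"], p)
        other = TreatmentStage(StageKind.ON_SECOND_DMD, first[1])
        assert dist[other] == pytest.approx(0.95 * 0.79)

    def test_bsc_stage_rejected(self, params, cau):
        with pytest.raises(ValueError):
            switch_distribution(TreatmentStage(StageKind.BSC_INITIAL), cau, params)


class TestCohortDynamics:
    def test_mass_is_conserved_every_cycle(self, params, cau, sdm):
        for strat in (cau, sdm):
            trace = run_cohort(params, strat, initial_occupancy(strat, params))
            totals = trace.occupancy.sum(axis=(1, 2, 3))
            assert np.allclose(totals, 1.0, atol=1e-9)
            assert (trace.occupancy >= -1e-12).all()

    def test_forced_stop_clears_high_edss_treated_occupancy(self, params, sdm):
        trace = run_cohort(params, sdm, initial_occupancy(sdm, params))
        high = IS_ALIVE & (EDSS_OF_INDEX > params.settings.edss_stop_level)
        on_dmd = trace.occupancy[1:, :, trace.space.is_dmd, :]
        assert on_dmd[..., high].sum() == pytest.approx(0.0, abs=1e-12)

    def test_switch_decisions_bounded_by_discontinuations(self, params, sdm):
        trace = run_cohort(params, sdm, initial_occupancy(sdm, params))
        assert (trace.decisions.sum(axis=1)
                <= trace.voluntary_disc.sum(axis=(1, 2)) + 1e-12).all()

    def test_dead_cohort_produces_nothing(self, params, cau):
        space = StageSpace(params)
        occ0 = np.zeros((2, space.n, N_STATES))
        occ0[0, 0, DEAD_INDEX] = 1.0
        trace = run_cohort(params, cau, occ0)
        out = accrue(trace, cau, params)
        assert out.qalys == 0.0
        assert out.total_cost() == 0.0
        assert out.relapses == 0.0
        assert trace.occupancy[:, 0, 0, DEAD_INDEX].min() == pytest.approx(1.0)

    def test_zero_horizon_rejected(self, params, cau):
        p = copy.deepcopy(params)
        p.settings.start_age = p.settings.max_age
        with pytest.raises(ValueError):
            run_pathway(TreatmentStage(StageKind.BSC_INITIAL), "adherent", cau, p)

    def test_geometric_occupancy_yields_closed_form_qalys(self, params, cau):
        """One absorbing RRMS state, 10% annual death, utility 0.8 over
        three undiscounted cycles: QALYs = 0.8 (1 + 0.9 + 0.81)."""
        p = copy.deepcopy(params)
        nh = p.natural_history
        nh.rrms[:] = 0.0
        for i in range(10):
            nh.rrms[i, i] = 1.0
        nh.spms[:] = np.eye(9)
        nh.relapse_rate[:] = 0.0
        nh.mortality_multiplier[:] = 1.0
        nh.life_table_male[:] = 0.1
        nh.life_table_female[:] = 0.1
        p.economics.utilities[:] = 0.8
        p.economics.discount_effects = p.economics.discount_costs = 0.0
        p.settings.start_age, p.settings.max_age = 97, 100
        entry = np.zeros(10)
        entry[0] = 1.0
        p.settings.entry_distribution = entry
        strat = replace(cau, sdm_cost_per_decision=0.0)
        trace = run_pathway(TreatmentStage(StageKind.BSC_INITIAL), "adherent", strat, p)
        out = accrue(trace, strat, p)
        assert out.qalys == pytest.approx(0.8 * (1 + 0.9 + 0.81))
        assert out.life_years == pytest.approx(1 + 0.9 + 0.81)

    def test_neutral_treatment_pathway_equals_supportive_care(self, params, cau):
        p = neutralize_treatment(params)
        strat = replace(cau, sdm_cost_per_decision=0.0)
        bsc = accrue(run_pathway(TreatmentStage(StageKind.BSC_INITIAL),
                                 "adherent", strat, p), strat, p)
        for drug in ("dimethyl_fumarate", "natalizumab"):
            for klass in ("adherent", "nonadherent"):
                path = accrue(run_pathway(TreatmentStage(StageKind.ON_FIRST_DMD, drug),
                                          klass, strat, p), strat, p)
                assert path.qalys == pytest.approx(bsc.qalys)
                assert path.total_cost() == pytest.approx(bsc.total_cost(), abs=1e-6)
                assert path.relapses == pytest.approx(bsc.relapses)


class TestStrategyEvaluation:
    def test_adherence_split_follows_published_proportions(self, params, cau):
        occ0 = initial_occupancy(cau, params)
        space = StageSpace(params)
        s = space.index(TreatmentStage(StageKind.ON_FIRST_DMD, "dimethyl_fumarate"))
        share = cau.initiation["dimethyl_fumarate"]
        assert occ0[0, s].sum() == pytest.approx(share * 0.589)
        assert occ0[1, s].sum() == pytest.approx(share * 0.411)
        s_inf = space.index(TreatmentStage(StageKind.ON_FIRST_DMD, "natalizumab"))
        assert occ0[1, s_inf].sum() == 0.0  # infused drugs: optimal adherence

    def test_mixture_degenerates_when_classes_are_identical(self, params, cau):
        p = copy.deepcopy(params)
        p.settings.nonadherent_relapse_multiplier = 1.0
        p.settings.nonadherent_severe_multiplier = 1.0
        lo = replace(cau, adherent_proportion={d: 0.3 for d in p.dmds})
        hi = replace(cau, adherent_proportion={d: 0.9 for d in p.dmds})
        out_lo = mscea.evaluate_strategy(lo, p)
        out_hi = mscea.evaluate_strategy(hi, p)
        assert out_lo.qalys == pytest.approx(out_hi.qalys)
        assert out_lo.total_cost() == pytest.approx(out_hi.total_cost())

    def test_sdm_delivery_cost_for_pure_bsc_arm_is_one_decision(self, params, sdm):
        strat = replace(sdm, initiation={mscea.BSC: 1.0})
        out = mscea.evaluate_strategy(strat, params)
        assert out.costs["sdm_delivery"] == pytest.approx(100.0)
        assert out.costs_undiscounted["sdm_delivery"] == pytest.approx(100.0)
        assert out.sdm_decisions == pytest.approx(1.0)

    def test_unknown_dmd_in_initiation_rejected(self, params, cau):
        bad = replace(cau, initiation={mscea.BSC: 0.5, "nonexistent_drug": 0.5})
        with pytest.raises(ValueError, match="nonexistent_drug"):
            mscea.evaluate_strategy(bad, params)

    def test_outcomes_are_linear_in_initiation_shares(self, params, cau):
        """Convexity: evaluating a mixed initiation vector equals mixing
        the outcomes of its components.  Exact when switch destinations do
        not themselves depend on the initiation shares, so the check uses
        the equal-split switch rule."""
        rng = np.random.default_rng(5)
        names = [mscea.BSC] + params.dmd_names
        a = rng.dirichlet(np.ones(len(names)))
        b = rng.dirichlet(np.ones(len(names)))
        lam = 0.3
        cau = replace(cau, switch_rule="all_lines_equal")
        strat_a = replace(cau, initiation=dict(zip(names, a)))
        strat_b = replace(cau, initiation=dict(zip(names, b)))
        strat_mix = replace(cau, initiation=dict(zip(names, lam * a + (1 - lam) * b)))
        oa = mscea.evaluate_strategy(strat_a, params)
        ob = mscea.evaluate_strategy(strat_b, params)
        om = mscea.evaluate_strategy(strat_mix, params)
        assert om.qalys == pytest.approx(lam * oa.qalys + (1 - lam) * ob.qalys)
        assert om.total_cost() == pytest.approx(
            lam * oa.total_cost() + (1 - lam) * ob.total_cost())

    def test_trace_exports_are_well_formed(self, small_params):
        cau = small_params.strategies["CAU"]
        trace = run_cohort(small_params, cau, initial_occupancy(cau, small_params))
        df = trace.to_frame()
        assert df["mass"].min() >= 0
        per_cycle = df.groupby("cycle")["mass"].sum()
        assert np.allclose(per_cycle, 1.0, atol=1e-9)
        ev = trace.events_frame()
        assert {"deaths", "switch_decisions"} <= set(ev.columns)
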