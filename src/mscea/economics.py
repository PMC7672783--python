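"""Valuation of a cohort trace: discounted QALYs, life years, relapses
and cost components under the healthcare and societal perspectives.

Costs follow Dutch accounting conventions: a dispensing fee per
prescription (higher for the first), pretreatment monitoring in the first
treatment year, a one-off post-discontinuation monitoring contact in the
year of stopping, adverse-event costs as a fixed proportion of health-state
healthcare costs, and productivity losses by either the friction-cost or
the human-capital method.  Effects and costs are discounted at separate
annual rates (cycle 0 undiscounted); undiscounted twins are kept for
every stream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import (
    COST_CATEGORIES,
    PERSPECTIVES,
    DMDProfile,
    EconomicInputs,
    ParameterSet,
    StrategyProfile,
)
from .states import DEAD_INDEX, IS_ALIVE, N_STATES

_NONADHERENT = 1  # adherence-class axis convention shared with the engine

#: cost categories reported in Outcomes.costs
OUTCOME_COST_KEYS = (
    "drug", "administration", "monitoring", "dispensing", "adverse_events",
    "relapse", "health_state_healthcare", "community", "equipment",
    "informal_care", "productivity_friction", "productivity_human_capital",
    "sdm_delivery",
)

_HEALTHCARE_KEYS = ("drug", "administration", "monitoring", "dispensing",
                    "adverse_events", "relapse", "health_state_healthcare",
                    "sdm_delivery")
_SOCIETAL_EXTRA = ("community", "equipment", "informal_care")


def discount_factor(rate: float, cycle: int | np.ndarray) -> float | np.ndarray:
    """1/(1+rate)^cycle, with cycle 0 undiscounted."""
    if np.any(np.asarray(rate) < 0):
        raise ValueError("discount rate must be >= 0")
    return (1.0 + rate) ** (-np.asarray(cycle, dtype=float))


def _treatment_cost_parts(
    dmd: DMDProfile, first_year: bool, inputs: EconomicInputs
) -> dict[str, float]:
    p = dmd.prescriptions_per_year
    if p > 0:
        fees = inputs.dispensing_fee_first + (p - 1) * inputs.dispensing_fee_subsequent \
            if first_year else p * inputs.dispensing_fee_subsequent
    else:
        fees = 0.0
    return {
        "drug": dmd.annual_drug_cost,
        "administration": dmd.admin_cost_first_year if first_year
        else dmd.admin_cost_subsequent,
        "monitoring": dmd.monitoring_annual
        + (dmd.monitoring_pretreatment if first_year else 0.0),
        "dispensing": fees,
    }


def cycle_treatment_costs(
    dmd: DMDProfile, cycle_in_treatment: int, inputs: EconomicInputs
) -> float:
    """Annual on-treatment cost: drug price, administration, monitoring
    (pretreatment monitoring in the first year) and dispensing fees."""
    parts = _treatment_cost_parts(dmd, cycle_in_treatment == 0, inputs)
    return float(sum(parts.values()))


def cycle_person_costs(state_index: int, perspective: str, inputs: EconomicInputs) -> float:
    """Annual non-treatment cost of occupying one health state under a
    perspective.  Healthcare costs (plus proportional adverse-event costs)
    always count; societal perspectives add community services, equipment/
    aids, informal care and one of the two productivity-loss methods."""
    if perspective not in PERSPECTIVES:
        raise ValueError(f"unknown perspective {perspective!r}")
    if state_index == DEAD_INDEX:
        raise ValueError("person costs are undefined for the dead state")
    row = dict(zip(COST_CATEGORIES, inputs.state_costs[state_index]))
    total = row["healthcare"] * (1.0 + inputs.ae_cost_fraction)
    if perspective == "healthcare":
        return total
    total += row["community_services"] + row["equipment_aids"] + row["informal_care"]
    if perspective == "societal_friction":
        return total + row["productivity_friction"]
    return total + row["productivity_human_capital"]


@dataclass
class Outcomes:
    """Discounted and undiscounted lifetime outcomes of one strategy arm,
    per patient entering the model."""

    qalys: float
    qalys_undiscounted: float
    life_years: float
    life_years_undiscounted: float
    relapses: float
    relapses_undiscounted: float
    relapses_severe: float
    relapses_severe_undiscounted: float
    costs: dict[str, float]
    costs_undiscounted: dict[str, float]
    sdm_decisions: float               # cost-discounted expected decision count
    sdm_decisions_undiscounted: float
    perspective: str

    def total_cost(self, perspective: str | None = None) -> float:
        return self._total(self.costs, perspective or self.perspective)

    def total_cost_undiscounted(self, perspective: str | None = None) -> float:
        return self._total(self.costs_undiscounted, perspective or self.perspective)

    @staticmethod
    def _total(costs: dict[str, float], perspective: str) -> float:
        if perspective not in PERSPECTIVES:
            raise ValueError(f"unknown perspective {perspective!r}")
        total = sum(costs[k] for k in _HEALTHCARE_KEYS)
        if perspective == "healthcare":
            return total
        total += sum(costs[k] for k in _SOCIETAL_EXTRA)
        key = "productivity_friction" if perspective == "societal_friction" \
            else "productivity_human_capital"
        return total + costs[key]

    def to_frame(self) -> pd.DataFrame:
        rows = [("qalys", self.qalys, self.qalys_undiscounted),
                ("life_years", self.life_years, self.life_years_undiscounted),
                ("relapses", self.relapses, self.relapses_undiscounted),
                ("relapses_severe", self.relapses_severe, self.relapses_severe_undiscounted)]
        rows += [(f"cost_{k}", self.costs[k], self.costs_undiscounted[k])
                 for k in OUTCOME_COST_KEYS]
        rows += [(f"total_cost_{p}", self._total(self.costs, p),
                  self._total(self.costs_undiscounted, p)) for p in PERSPECTIVES]
        return pd.DataFrame(rows, columns=["quantity", "discounted", "undiscounted"])


def accrue(
    trace,
    strategy: StrategyProfile,
    params: ParameterSet,
    perspective: str | None = None,
) -> Outcomes:
    """Value a cohort trace on start-of-cycle occupancy.

    QALYs take the state utility minus relapse disutilities and the
    on-treatment adverse-event disutility; relapse, treatment, health-state
    and SDM-delivery costs accrue per cycle and are discounted at the
    matching rate.
    """
    st, eco, nh = params.settings, params.economics, params.natural_history
    perspective = perspective or st.perspective
    if perspective not in PERSPECTIVES:
        raise ValueError(f"unknown perspective {perspective!r}")
    space = trace.space
    S, C = space.n, trace.n_cycles
    if trace.occupancy.shape[2] != S or trace.occupancy.shape[3] != N_STATES:
        raise ValueError("trace and parameter set have mismatched shapes")

    occ = trace.occupancy[:C]
    if st.half_cycle_correction:
        occ = 0.5 * (occ + trace.occupancy[1:])

    alive = IS_ALIVE.astype(float)

    # --- epidemiology vectors over (class, stage, state) ------------------
    rate = np.append(nh.relapse_rate, 0.0)
    frac = np.append(nh.severe_fraction, 0.0)
    rr_rel = np.array([params.dmds[d].rr_relapse if d else 1.0 for d in space.dmd_of])
    adh_mult = np.ones((2, S))
    sev_mult = np.ones((2, S))
    for s in range(S):
        drug = space.profile(params, s)
        if drug is not None and drug.adherence_applicable:
            adh_mult[_NONADHERENT, s] = st.nonadherent_relapse_multiplier
            sev_mult[_NONADHERENT, s] = st.nonadherent_severe_multiplier
    total_vec = adh_mult[:, :, None] * rr_rel[None, :, None] * rate[None, None, :]
    sev_frac = np.minimum(1.0, sev_mult[:, :, None] * frac[None, None, :])
    severe_vec = total_vec * sev_frac

    util = np.append(eco.utilities, 0.0)
    ae_dis = np.array([params.dmds[d].ae_disutility if d else 0.0 for d in space.dmd_of])
    util_vec = util[None, None, :] - ae_dis[None, :, None] * alive[None, None, :]

    # --- per-cycle effect streams ----------------------------------------
    tot_rel = np.einsum("cksj,ksj->c", occ, total_vec)
    sev_rel = np.einsum("cksj,ksj->c", occ, severe_vec)
    mild_rel = tot_rel - sev_rel
    qaly = (np.einsum("cksj,ksj->c", occ, np.broadcast_to(util_vec, (2, S, N_STATES)))
            - eco.relapse_disutility_severe * sev_rel
            - eco.relapse_disutility_mild * mild_rel)
    ly = np.einsum("cksj,j->c", occ, alive)

    # --- per-cycle cost streams by category ------------------------------
    streams: dict[str, np.ndarray] = {}
    state_cost = {cat: np.append(eco.state_costs[:, k], 0.0)
                  for k, cat in enumerate(COST_CATEGORIES)}
    hc = np.einsum("cksj,j->c", occ, state_cost["healthcare"])
    streams["health_state_healthcare"] = hc
    streams["adverse_events"] = eco.ae_cost_fraction * hc
    streams["community"] = np.einsum("cksj,j->c", occ, state_cost["community_services"])
    streams["equipment"] = np.einsum("cksj,j->c", occ, state_cost["equipment_aids"])
    streams["informal_care"] = np.einsum("cksj,j->c", occ, state_cost["informal_care"])
    streams["productivity_friction"] = np.einsum(
        "cksj,j->c", occ, state_cost["productivity_friction"])
    streams["productivity_human_capital"] = np.einsum(
        "cksj,j->c", occ, state_cost["productivity_human_capital"])
    streams["relapse"] = (eco.relapse_cost_severe * sev_rel
                          + eco.relapse_cost_mild * mild_rel)

    stage_mass = np.einsum("cksj,j->cks", occ, alive).sum(axis=1)      # (C, S)
    new_mass = trace.newcomers[:C].sum(axis=1)                          # (C, S)
    disc_mass = (trace.voluntary_disc + trace.forced_stop)[:C].sum(axis=1)
    sub_parts = np.zeros((4, S))
    extra_parts = np.zeros((4, S))
    post_monitor = np.zeros(S)
    keys = ("drug", "administration", "monitoring", "dispensing")
    for s in range(S):
        drug = space.profile(params, s)
        if drug is None:
            continue
        sub = _treatment_cost_parts(drug, False, eco)
        first = _treatment_cost_parts(drug, True, eco)
        for k, key in enumerate(keys):
            sub_parts[k, s] = sub[key]
            extra_parts[k, s] = first[key] - sub[key]
        post_monitor[s] = drug.monitoring_post_discontinuation
    for k, key in enumerate(keys):
        streams[key] = stage_mass @ sub_parts[k] + new_mass @ extra_parts[k]
    streams["monitoring"] = streams["monitoring"] + disc_mass @ post_monitor

    decisions = trace.decisions[:C].sum(axis=1).astype(float).copy()
    decisions[0] += trace.occupancy[0].sum(axis=(0, 1)) @ alive
    streams["sdm_delivery"] = strategy.sdm_cost_per_decision * decisions

    # --- discounting ------------------------------------------------------
    cycles = np.arange(C)
    df_e = discount_factor(eco.discount_effects, cycles)
    df_c = discount_factor(eco.discount_costs, cycles)

    costs = {k: float(streams[k] @ df_c) for k in OUTCOME_COST_KEYS}
    costs_undisc = {k: float(streams[k].sum()) for k in OUTCOME_COST_KEYS}
    return Outcomes(
        qalys=float(qaly @ df_e),
        qalys_undiscounted=float(qaly.sum()),
        life_years=float(ly @ df_e),
        life_years_undiscounted=float(ly.sum()),
        relapses=float(tot_rel @ df_e),
        relapses_undiscounted=float(tot_rel.sum()),
        relapses_severe=float(sev_rel @ df_e),
        relapses_severe_undiscounted=float(sev_rel.sum()),
        costs=costs,
        costs_undiscounted=costs_undisc,
        sdm_decisions=float(decisions @ df_c),
        sdm_decisions_undiscounted=float(decisions.sum()),
        perspective=perspective,
    )
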