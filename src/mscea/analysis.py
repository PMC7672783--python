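"""Strategy comparison and sensitivity machinery: ICER/dominance
classification, the one-way scenario registry, the SDM-cost threshold
(headroom) analysis, and the probabilistic sensitivity analysis with
cost-effectiveness plane and acceptability-curve outputs.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .economics import Outcomes
from .engine import build_progression_set, compile_strategy, evaluate_strategy
from .parameters import BSC, ModelSettings, ParameterSet, StrategyProfile
from .states import N_RRMS

DOMINANT = "Dominant"
DOMINATED = "Dominated"
COST_SAVING_QALY_LOSING = "CostSavingQalyLosing"
ICER = "ICER"


@dataclass
class CEResult:
    """Incremental comparison of an intervention against a comparator."""

    intervention: Outcomes
    comparator: Outcomes
    delta_cost: float
    delta_qaly: float
    classification: str
    icer: float | None  # EUR per QALY; None when dominance makes it moot

    def describe(self) -> str:
        if self.classification == ICER:
            return f"ICER {self.icer:,.0f}"
        return self.classification


def compare(intervention: Outcomes, comparator: Outcomes) -> CEResult:
    """Classify an incremental comparison on discounted totals.

    Dominant: cheaper and more effective.  Dominated: costlier and no
    more effective.  South-west quadrant (cheaper but less effective)
    keeps its ICER under a separate label because a plain ratio would
    read misleadingly there.
    """
    if intervention.perspective != comparator.perspective:
        raise ValueError("outcomes computed under different perspectives")
    dc = intervention.total_cost() - comparator.total_cost()
    dq = intervention.qalys - comparator.qalys
    if dc < 0 and dq > 0:
        cls, icer = DOMINANT, None
    elif dc > 0 and dq <= 0:
        cls, icer = DOMINATED, None
    elif dc < 0 and dq < 0:
        cls, icer = COST_SAVING_QALY_LOSING, dc / dq
    elif dq == 0:
        cls, icer = (DOMINANT, None) if dc < 0 else (ICER, 0.0 if dc == 0 else None)
    else:
        cls, icer = ICER, dc / dq
    return CEResult(intervention, comparator, dc, dq, cls, icer)


def evaluate_pair(
    cau: StrategyProfile,
    sdm: StrategyProfile,
    params: ParameterSet,
    perspective: str | None = None,
) -> CEResult:
    """Evaluate both arms on one parameter set and compare SDM against CAU.

    The per-drug progression matrices are shared between the arms."""
    prog = build_progression_set(params)
    out_cau = evaluate_strategy(
        cau, params, perspective=perspective,
        compiled=compile_strategy(params, cau, prog))
    out_sdm = evaluate_strategy(
        sdm, params, perspective=perspective,
        compiled=compile_strategy(params, sdm, prog))
    return compare(out_sdm, out_cau)


def effect_profiles(
    cau: StrategyProfile, sdm: StrategyProfile
) -> dict[str, StrategyProfile]:
    """Decompose the SDM profile into its three modelled effects.

    Each returned arm keeps the SDM delivery cost but applies only one
    mechanism relative to usual care: ``choice`` changes the initiation
    mix, ``discontinuation`` halves the stopping rates, ``adherence``
    raises the adherent proportions; ``combined`` is the full profile.
    """
    return {
        "choice": replace(sdm,
                          discontinuation_multiplier=cau.discontinuation_multiplier,
                          adherent_proportion=dict(cau.adherent_proportion)),
        "discontinuation": replace(sdm, initiation=dict(cau.initiation),
                                   adherent_proportion=dict(cau.adherent_proportion)),
        "adherence": replace(sdm, initiation=dict(cau.initiation),
                             discontinuation_multiplier=cau.discontinuation_multiplier),
        "combined": sdm,
    }


# ---------------------------------------------------------------------------
# Threshold (headroom) analysis
# ---------------------------------------------------------------------------

NOT_ACHIEVABLE = "not_achievable"


def threshold_sdm_cost(
    cau: StrategyProfile,
    sdm: StrategyProfile,
    params: ParameterSet,
    wtp: float,
    perspective: str | None = None,
) -> float | str:
    """Maximum per-decision SDM delivery cost at which the ICER equals the
    willingness-to-pay threshold.

    The delivery cost enters total costs linearly through the expected
    discounted decision count, so the threshold is a linear solve
    ``c* = (wtp * dQALY - dCost_excluding_delivery) / E[decisions]``,
    verified by one re-run.  Returns ``"not_achievable"`` when the QALY
    gain is non-positive.  The threshold may be negative when the arm is
    cost-ineffective even at zero delivery cost.
    """
    sdm_free = replace(sdm, sdm_cost_per_decision=0.0)
    out_cau = evaluate_strategy(cau, params, perspective=perspective)
    out_free = evaluate_strategy(sdm_free, params, perspective=perspective)
    dq = out_free.qalys - out_cau.qalys
    if dq <= 0:
        return NOT_ACHIEVABLE
    decisions = out_free.sdm_decisions
    if decisions <= 0:
        raise ValueError("SDM arm has zero expected decision epochs")
    dc0 = out_free.total_cost() - out_cau.total_cost()
    c_star = (wtp * dq - dc0) / decisions

    check = compare(
        evaluate_strategy(replace(sdm, sdm_cost_per_decision=c_star), params,
                          perspective=perspective),
        out_cau,
    )
    achieved = check.delta_cost / check.delta_qaly
    if abs(achieved - wtp) / wtp >= 1e-6:
        raise AssertionError(
            f"threshold re-run check failed: ICER {achieved} at c*={c_star}"
        )
    return c_star


# ---------------------------------------------------------------------------
# One-way sensitivity registry
# ---------------------------------------------------------------------------

Transform = Callable[
    [ParameterSet, StrategyProfile, StrategyProfile],
    tuple[ParameterSet, StrategyProfile, StrategyProfile],
]


@dataclass
class Scenario:
    name: str
    transform: Transform
    perspective: str | None = None


def _scale_drug_costs(factor: float) -> Transform:
    def fn(p, cau, sdm):
        p = copy.deepcopy(p)
        for d in p.dmds.values():
            d.annual_drug_cost *= factor
        return p, cau, sdm
    return fn


def _scale_rr_progression(factor: float) -> Transform:
    def fn(p, cau, sdm):
        p = copy.deepcopy(p)
        for d in p.dmds.values():
            d.rr_progression = min(2.0, d.rr_progression * factor)
        return p, cau, sdm
    return fn


def _set_settings(**kwargs) -> Transform:
    def fn(p, cau, sdm):
        p = copy.deepcopy(p)
        for k, v in kwargs.items():
            if not hasattr(p.settings, k):
                raise AttributeError(f"unknown model setting {k!r}")
            setattr(p.settings, k, v)
        return p, cau, sdm
    return fn


def _set_discounts(effects: float, costs: float) -> Transform:
    def fn(p, cau, sdm):
        p = copy.deepcopy(p)
        p.economics.discount_effects = effects
        p.economics.discount_costs = costs
        return p, cau, sdm
    return fn


def _entry(vector: np.ndarray) -> Transform:
    v = np.asarray(vector, dtype=float)

    def fn(p, cau, sdm):
        p = copy.deepcopy(p)
        p.settings.entry_distribution = v.copy()
        return p, cau, sdm
    return fn


def _entry_shift(p_entry: np.ndarray) -> np.ndarray:
    """The preset entry-distribution shift: 3.75 percentage points out of
    each of EDSS 0-3, 5 points into each of EDSS 4-6 (mass preserved)."""
    v = p_entry.copy()
    v[0:4] -= 0.0375
    v[4:7] += 0.05
    if (v < 0).any():
        v = np.clip(v, 0.0, None)
    return v / v.sum()


def _sdm_cost(value: float) -> Transform:
    def fn(p, cau, sdm):
        return p, cau, replace(sdm, sdm_cost_per_decision=value)
    return fn


def _scale_transitions(factor: float) -> Transform:
    """Scale all off-diagonal transition mass, renormalizing the
    stay-probability so rows remain stochastic."""
    def fn(p, cau, sdm):
        p = copy.deepcopy(p)
        nh = p.natural_history
        for i in range(nh.rrms.shape[0]):
            row = nh.rrms[i].copy()
            stay = row[i]
            moved = row.sum() - stay
            row *= factor
            row[i] = 1.0 - moved * factor
            if row[i] < 0:
                raise ValueError("transition scaling leaves the simplex")
            nh.rrms[i] = row
        for i in range(nh.spms.shape[0]):
            row = nh.spms[i].copy()
            stay = row[i]
            moved = row.sum() - stay
            row *= factor
            row[i] = 1.0 - moved * factor
            if row[i] < 0:
                raise ValueError("transition scaling leaves the simplex")
            nh.spms[i] = row
        return p, cau, sdm
    return fn


def _initiation_variant(kind: str) -> Transform:
    """Initial-choice scenario variants, applied to both arms."""
    def fn(p, cau, sdm):
        first = [d for d, pr in p.dmds.items() if pr.line == "first"]
        if kind == "first_line_equal_no_bsc":
            init = {d: 1.0 / len(first) for d in first}
        elif kind == "first_line_equal_25_bsc":
            init = {BSC: 0.25, **{d: 0.75 / len(first) for d in first}}
        else:  # pragma: no cover
            raise ValueError(kind)
        return p, replace(cau, initiation=init), replace(sdm, initiation=init)
    return fn


def _switch_rule(rule: str) -> Transform:
    def fn(p, cau, sdm):
        return p, replace(cau, switch_rule=rule), replace(sdm, switch_rule=rule)
    return fn


def table4_registry(params: ParameterSet) -> list[Scenario]:
    """The standard one-way scenario set for the combined-effects
    comparison: drug costs, progression relative risks, SDM delivery
    cost, discount rates, perspectives, demographics, entry distribution,
    initial- and second-choice variants, and transition probabilities."""
    p_entry = params.settings.entry_distribution
    equal = np.full(N_RRMS, 1.0 / N_RRMS)
    edss1 = np.zeros(N_RRMS)
    edss1[1] = 1.0
    edss4 = np.zeros(N_RRMS)
    edss4[4] = 1.0
    identity: Transform = lambda p, cau, sdm: (p, cau, sdm)
    return [
        Scenario("base_case", identity),
        Scenario("drug_costs_+20%", _scale_drug_costs(1.2)),
        Scenario("drug_costs_-20%", _scale_drug_costs(0.8)),
        Scenario("rr_progression_lower", _scale_rr_progression(0.8)),
        Scenario("rr_progression_upper", _scale_rr_progression(1.25)),
        Scenario("sdm_cost_0", _sdm_cost(0.0)),
        Scenario("discount_0%", _set_discounts(0.0, 0.0)),
        Scenario("discount_3%", _set_discounts(0.03, 0.03)),
        Scenario("healthcare_perspective", identity, perspective="healthcare"),
        Scenario("human_capital_perspective", identity,
                 perspective="societal_human_capital"),
        Scenario("onset_age_29", _set_settings(start_age=29)),
        Scenario("onset_age_45", _set_settings(start_age=45)),
        Scenario("proportion_male_18%", _set_settings(proportion_male=0.18)),
        Scenario("proportion_male_40%", _set_settings(proportion_male=0.40)),
        Scenario("entry_100%_edss1", _entry(edss1)),
        Scenario("entry_100%_edss4", _entry(edss4)),
        Scenario("entry_equal", _entry(equal)),
        Scenario("entry_shift_to_edss_4_6", _entry(_entry_shift(p_entry))),
        Scenario("initial_first_line_equal_no_bsc",
                 _initiation_variant("first_line_equal_no_bsc")),
        Scenario("initial_first_line_equal_25%_bsc",
                 _initiation_variant("first_line_equal_25_bsc")),
        Scenario("second_choice_second_line_equal", _switch_rule("second_line_equal")),
        Scenario("second_choice_all_lines_equal", _switch_rule("all_lines_equal")),
        Scenario("transitions_+10%", _scale_transitions(1.1)),
        Scenario("transitions_-10%", _scale_transitions(0.9)),
    ]


def one_way_sensitivity(
    registry: list[Scenario],
    params: ParameterSet,
    cau: StrategyProfile,
    sdm: StrategyProfile,
    perspective: str | None = None,
) -> pd.DataFrame:
    """Re-run the comparison under each scenario of the registry."""
    rows = []
    for sc in registry:
        p, c, s = sc.transform(params, cau, sdm)
        res = evaluate_pair(c, s, p, perspective=sc.perspective or perspective)
        rows.append({
            "scenario": sc.name,
            "cau_cost": res.comparator.total_cost(),
            "cau_qalys": res.comparator.qalys,
            "sdm_cost": res.intervention.total_cost(),
            "sdm_qalys": res.intervention.qalys,
            "delta_cost": res.delta_cost,
            "delta_qaly": res.delta_qaly,
            "icer": res.icer,
            "classification": res.classification,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class PSAConfig:
    """Distribution families for the probabilistic analysis.

    By default transition rows are Dirichlet (concentration 100 x the
    point probabilities), relative risks lognormal, utilities and
    probabilities/proportions beta, and costs gamma, each moment-matched
    to the point estimate with a standard error of ``se_fraction`` times
    the mean.  Any group can be switched off.
    """

    se_fraction: float = 0.10
    dirichlet_concentration: float = 100.0
    sample_transitions: bool = True
    sample_relative_risks: bool = True
    sample_utilities: bool = True
    sample_state_costs: bool = True
    sample_relapse_model: bool = True
    sample_discontinuation: bool = True
    sample_sdm_effects: bool = True


@dataclass
class PSAResult:
    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    seed: int
    n_iterations: int
    wtp_grid: np.ndarray
    ceac: np.ndarray

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        plane = pd.DataFrame({"delta_cost": self.delta_cost,
                              "delta_qaly": self.delta_qaly})
        curve = pd.DataFrame({"wtp": self.wtp_grid, "probability": self.ceac})
        return plane, curve

    def probability_cost_effective(self, wtp: float) -> float:
        return float(np.mean(wtp * self.delta_qaly - self.delta_cost >= 0))


def _beta_from_moments(rng, mean, sd):
    mean = np.asarray(mean, dtype=float)
    sd = np.minimum(np.asarray(sd, dtype=float),
                    0.95 * np.sqrt(np.clip(mean * (1 - mean), 1e-12, None)))
    keep = (mean > 0) & (mean < 1) & (sd > 0)
    out = mean.copy()
    if np.any(keep):
        m, s = mean[keep], sd[keep]
        nu = m * (1 - m) / s**2 - 1
        out[keep] = rng.beta(m * nu, (1 - m) * nu)
    return out


def _gamma_from_moments(rng, mean, sd):
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    keep = (mean > 0) & (sd > 0)
    out = mean.copy()
    if np.any(keep):
        shape = (mean[keep] / sd[keep]) ** 2
        out[keep] = rng.gamma(shape, mean[keep] / shape)
    return out


def _lognormal_from_moments(rng, mean, sd_frac):
    mean = np.asarray(mean, dtype=float)
    sigma = np.sqrt(np.log(1 + sd_frac**2))
    return mean * np.exp(rng.normal(-sigma**2 / 2, sigma, size=mean.shape))


def sample_parameter_set(
    params: ParameterSet,
    cau: StrategyProfile,
    sdm: StrategyProfile,
    config: PSAConfig,
    rng: np.random.Generator,
) -> tuple[ParameterSet, StrategyProfile, StrategyProfile]:
    """Draw one probabilistic replicate of the uncertain inputs."""
    p = copy.deepcopy(params)
    f = config.se_fraction
    nh = p.natural_history

    if config.sample_transitions:
        k = config.dirichlet_concentration
        for table in (nh.rrms, nh.spms):
            for i in range(table.shape[0]):
                pos = table[i] > 0
                if pos.sum() > 1:
                    table[i, pos] = rng.dirichlet(k * table[i, pos])
    if config.sample_relative_risks:
        for d in p.dmds.values():
            d.rr_progression = float(np.clip(
                _lognormal_from_moments(rng, np.array(d.rr_progression), f), 1e-6, 2.0))
            d.rr_relapse = float(np.clip(
                _lognormal_from_moments(rng, np.array(d.rr_relapse), f), 1e-6, 2.0))
    if config.sample_utilities:
        u = _beta_from_moments(rng, p.economics.utilities,
                               f * np.abs(p.economics.utilities))
        # preserve the monotone decline in EDSS within each course
        p.economics.utilities = np.concatenate([
            np.sort(u[:10])[::-1], np.sort(u[10:])[::-1]])
    if config.sample_state_costs:
        c = _gamma_from_moments(rng, p.economics.state_costs,
                                f * p.economics.state_costs)
        c[:10] = np.sort(c[:10], axis=0)       # keep EDSS-increasing shape
        c[10:] = np.sort(c[10:], axis=0)
        p.economics.state_costs = c
        p.economics.relapse_cost_severe = float(_gamma_from_moments(
            rng, np.array(p.economics.relapse_cost_severe),
            f * np.array(p.economics.relapse_cost_severe)))
        p.economics.relapse_cost_mild = float(_gamma_from_moments(
            rng, np.array(p.economics.relapse_cost_mild),
            f * np.array(p.economics.relapse_cost_mild)))
    if config.sample_relapse_model:
        nh.relapse_rate = _gamma_from_moments(rng, nh.relapse_rate, f * nh.relapse_rate)
        nh.severe_fraction = _beta_from_moments(rng, nh.severe_fraction,
                                                f * nh.severe_fraction)
        p.economics.relapse_disutility_severe = float(_beta_from_moments(
            rng, np.array(p.economics.relapse_disutility_severe),
            f * np.array(p.economics.relapse_disutility_severe)))
        p.economics.relapse_disutility_mild = float(_beta_from_moments(
            rng, np.array(p.economics.relapse_disutility_mild),
            f * np.array(p.economics.relapse_disutility_mild)))
    if config.sample_discontinuation:
        for d in p.dmds.values():
            d.cau_discontinuation = float(_beta_from_moments(
                rng, np.array(d.cau_discontinuation),
                f * np.array(d.cau_discontinuation)))
    cau_s, sdm_s = cau, sdm
    if config.sample_sdm_effects:
        mult = float(_beta_from_moments(
            rng, np.array(sdm.discontinuation_multiplier),
            f * np.array(sdm.discontinuation_multiplier)))
        adh = {d: float(_beta_from_moments(rng, np.array(v), f * np.array(v)))
               for d, v in sdm.adherent_proportion.items()}
        sdm_s = replace(sdm, discontinuation_multiplier=mult, adherent_proportion=adh)
    return p, cau_s, sdm_s


def run_psa(
    cau: StrategyProfile,
    sdm: StrategyProfile,
    params: ParameterSet,
    config: PSAConfig | None = None,
    n: int = 10_000,
    seed: int = 0,
    wtp_grid: np.ndarray | None = None,
    perspective: str | None = None,
) -> PSAResult:
    """Monte-Carlo re-evaluation of the incremental comparison under
    parameter uncertainty; deterministic given the seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    config = config or PSAConfig()
    if wtp_grid is None:
        wtp_grid = np.arange(0, 100_001, 1_000, dtype=float)
    rng = np.random.default_rng(seed)
    dc = np.empty(n)
    dq = np.empty(n)
    for i in range(n):
        p, c, s = sample_parameter_set(params, cau, sdm, config, rng)
        res = evaluate_pair(c, s, p, perspective=perspective)
        dc[i] = res.delta_cost
        dq[i] = res.delta_qaly
    result = PSAResult(dc, dq, seed, n, np.asarray(wtp_grid, dtype=float),
                       np.empty(0))
    result.ceac = ceac(result, result.wtp_grid)
    return result


def ceac(result: PSAResult, wtp_grid: np.ndarray) -> np.ndarray:
    """Probability of non-negative net monetary benefit per grid point."""
    grid = np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty willingness-to-pay grid")
    nmb = grid[:, None] * result.delta_qaly[None, :] - result.delta_cost[None, :]
    return (nmb >= 0).mean(axis=1)
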