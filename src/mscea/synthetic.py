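"""Synthetic parameter sets, the printed strategy-profile fixture, and an
individual-level Monte-Carlo oracle for verifying the cohort engine.

The strategy profiles (initiation mix, real-world first-year
discontinuation rates, adherent proportions) are published and encoded
verbatim.  Everything the published model keeps in supplementary tables —
natural-history transitions, relative risks, utilities, unit costs, drug
prices — is *synthetic*: structurally faithful, magnitude-plausible
stand-ins generated from a seed, clearly not the original values.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from . import economics
from .engine import (
    ADHERENCE_CLASSES,
    StageKind,
    StageSpace,
    TreatmentStage,
    effective_discontinuation,
    switch_distribution,
)
from .natural_history import build_progression_matrix, death_vector, relapse_outcomes
from .parameters import (
    BSC,
    DMDProfile,
    EconomicInputs,
    ModelSettings,
    NaturalHistory,
    ParameterSet,
    StrategyProfile,
    interpolate_state_costs,
)
from .states import DEAD_INDEX, EDSS_OF_INDEX, IS_ALIVE, N_RRMS, N_SPMS, N_STATES

# ---------------------------------------------------------------------------
# Published strategy-profile table (initiation %, first-year discontinuation
# %, adherent proportion %), transcribed as printed.
# ---------------------------------------------------------------------------

TABLE2 = pd.DataFrame(
    [
        # name, line, route, init_cau, init_sdm, disc_cau, disc_sdm, adh_cau, adh_sdm
        (BSC, None, None, 25.0, 20.0, np.nan, np.nan, 100.0, 100.0),
        ("alemtuzumab", "second", "infusion", 0.2, 0.3, 10.4, 5.2, 100.0, 100.0),
        ("dimethyl_fumarate", "first", "self_administered", 33.6, 41.3, 21.4, 10.7, 58.9, 63.9),
        ("fingolimod", "second", "self_administered", 0.0, 0.0, 10.6, 5.3, 58.9, 63.9),
        ("glatiramer_acetate_20mg_generic", "first", "self_administered", 0.2, 0.1, 26.7, 13.4, 58.9, 63.9),
        ("glatiramer_acetate_20mg_brand", "first", "self_administered", 10.6, 3.5, 26.7, 13.4, 58.9, 63.9),
        ("glatiramer_acetate_40mg_brand", "first", "self_administered", 0.2, 0.1, 21.5, 10.8, 58.9, 63.9),
        ("interferon_beta_1a", "first", "self_administered", 1.0, 0.3, 26.8, 13.4, 58.9, 63.9),
        ("interferon_beta_1a_22mcg", "first", "self_administered", 0.5, 0.2, 27.1, 13.6, 58.9, 63.9),
        ("interferon_beta_1a_44mcg", "first", "self_administered", 0.5, 0.2, 30.1, 15.1, 58.9, 63.9),
        ("interferon_beta_1b", "first", "self_administered", 1.0, 0.3, 25.9, 13.0, 58.9, 63.9),
        ("natalizumab", "second", "infusion", 4.0, 6.0, 13.0, 6.5, 100.0, 100.0),
        ("ocrelizumab", "second", "infusion", 0.8, 1.2, 13.1, 6.6, 100.0, 100.0),
        ("peginterferon_beta_1a", "first", "self_administered", 1.0, 0.3, 26.4, 13.2, 58.9, 63.9),
        ("teriflunomide_14mg", "first", "self_administered", 21.4, 26.3, 20.8, 10.4, 58.9, 63.9),
    ],
    columns=["name", "line", "route", "init_cau", "init_sdm",
             "disc_cau", "disc_sdm", "adh_cau", "adh_sdm"],
)

#: per-decision SDM delivery cost (EUR) and its consultation-time component
SDM_COST_PER_DECISION = 100.0
SDM_CONSULTATION_COMPONENT = 51.77

#: plausibility band (undiscounted life years from model entry) for
#: realistic synthetic parameter sets
LIFE_EXPECTANCY_BAND = (25.0, 42.0)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal rounding with ties away from zero (as in printed tables)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _strategy_from_table(arm: str) -> StrategyProfile:
    col = f"init_{arm}"
    shares = TABLE2.set_index("name")[col] / TABLE2[col].sum()
    adh = TABLE2[TABLE2["name"] != BSC].set_index("name")[f"adh_{arm}"] / 100.0
    return StrategyProfile(
        label=arm.upper(),
        initiation=shares.to_dict(),
        discontinuation_multiplier=1.0 if arm == "cau" else 0.5,
        adherent_proportion=adh.to_dict(),
        sdm_cost_per_decision=0.0 if arm == "cau" else SDM_COST_PER_DECISION,
    )


def table2_fixture() -> tuple[StrategyProfile, StrategyProfile]:
    """The printed usual-care and SDM strategy profiles.

    Initiation shares are normalized to sum to one (the printed SDM
    column carries a 0.1-point rounding residue).
    """
    return _strategy_from_table("cau"), _strategy_from_table("sdm")


# ---------------------------------------------------------------------------
# Parameter-set generator
# ---------------------------------------------------------------------------

@dataclass
class GeneratorConfig:
    seed: int = 20260101
    n_dmds: int = 14          # 14 -> the named drug portfolio above
    severity_scale: float = 1.0
    cost_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_dmds < 2:
            raise ValueError("need at least two DMDs (one per line)")
        if self.severity_scale <= 0 or self.cost_scale <= 0:
            raise ValueError("scales must be positive")


def _life_table() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gompertz-Makeham annual death probabilities, ages 0..100, with a
    Dutch-like level (female life expectancy at birth in the low 80s)."""
    age = np.arange(0, 101)
    male = np.minimum(1.0, 1.2e-4 + 1.6e-5 * np.exp(0.102 * age))
    female = np.minimum(1.0, 1.0e-4 + 1.1e-5 * np.exp(0.102 * age))
    return age, male, female


def _natural_history(rng: np.random.Generator, severity: float) -> NaturalHistory:
    rrms = np.zeros((N_RRMS, N_RRMS + 1))
    for i in range(N_RRMS):
        worsen = severity * (0.14 + 0.005 * i) if i < 9 else 0.0
        improve = 0.07 if i > 0 else 0.0
        convert = severity * (0.03 + 0.012 * i)
        row = np.zeros(N_RRMS + 1)
        if i > 0:
            row[i - 1] = improve
        if i < 9:
            row[i + 1] = worsen
        row[N_RRMS] = convert
        row[i] = 1.0 - row.sum()
        pos = row > 0
        row[pos] = rng.dirichlet(400 * row[pos])  # mild seeded jitter
        rrms[i] = row

    spms = np.zeros((N_SPMS, N_SPMS))
    for i in range(N_SPMS):
        row = np.zeros(N_SPMS)
        if i < N_SPMS - 1:
            row[i + 1] = severity * 0.18
        row[i] = 1.0 - row.sum()
        pos = row > 0
        if pos.sum() > 1:
            row[pos] = rng.dirichlet(400 * row[pos])
        spms[i] = row

    relapse = np.concatenate([
        0.65 - 0.04 * np.arange(10),            # RRMS EDSS 0..9
        0.30 - 0.02 * np.arange(9),             # SPMS EDSS 1..9
    ])
    age, male, female = _life_table()
    return NaturalHistory(
        rrms=rrms,
        spms=spms,
        relapse_rate=relapse,
        severe_fraction=np.full(19, 0.22),
        mortality_multiplier=np.array(
            [1.0, 1.1, 1.25, 1.45, 1.7, 2.0, 2.4, 2.9, 3.5, 4.5]),
        life_table_age=age,
        life_table_male=male,
        life_table_female=female,
    )


def _economics(cost_scale: float) -> EconomicInputs:
    anchors = {
        "healthcare": {0: 2000, 3: 5000, 6: 12000, 9: 30000},
        "community_services": {0: 200, 6: 3000, 9: 9000},
        "equipment_aids": {0: 100, 6: 1500, 9: 4000},
        "informal_care": {0: 500, 6: 8000, 9: 18000},
        "productivity_friction": {0: 1800, 3: 2600, 6: 1500, 9: 400},
        "productivity_human_capital": {0: 3500, 4: 15000, 7: 24000, 9: 10000},
    }
    dense = {cat: interpolate_state_costs(a) for cat, a in anchors.items()}
    costs = np.zeros((19, 6))
    for k, cat in enumerate(anchors):
        rr = dense[cat]
        sp = dense[cat][1:]
        if cat == "healthcare":
            sp = sp * 1.1                        # SPMS care is somewhat costlier
        costs[:10, k] = rr
        costs[10:, k] = sp
    utilities = np.concatenate([
        [0.87, 0.82, 0.76, 0.70, 0.62, 0.55, 0.48, 0.38, 0.25, 0.10],
        np.array([0.82, 0.76, 0.70, 0.62, 0.55, 0.48, 0.38, 0.25, 0.10]) - 0.04,
    ])
    return EconomicInputs(
        state_costs=costs * cost_scale,
        utilities=utilities,
        relapse_cost_severe=3500.0 * cost_scale,
        relapse_cost_mild=600.0 * cost_scale,
        relapse_disutility_severe=0.11,
        relapse_disutility_mild=0.04,
        ae_cost_fraction=0.012,
    )


def _draw_dmd(rng, name, line, route, disc, trial_disc=None) -> DMDProfile:
    second = line == "second"
    infused = route == "infusion"
    return DMDProfile(
        name=name,
        line=line,
        rr_progression=float(rng.uniform(0.55, 0.75) if second else rng.uniform(0.75, 0.95)),
        rr_relapse=float(rng.uniform(0.30, 0.50) if second else rng.uniform(0.60, 0.80)),
        annual_drug_cost=float(rng.uniform(11000, 20000) if second
                               else rng.uniform(4000, 13000)),
        admin_cost_first_year=float(rng.uniform(1800, 3000)) if infused else 0.0,
        admin_cost_subsequent=float(rng.uniform(1200, 2200)) if infused else 0.0,
        monitoring_pretreatment=float(rng.uniform(300, 800)),
        monitoring_annual=float(rng.uniform(150, 500)),
        monitoring_post_discontinuation=float(rng.uniform(120, 250)),
        prescriptions_per_year=0 if infused else 12,
        route=route,
        cau_discontinuation=float(disc),
        adherence_applicable=not infused,
        ae_disutility=float(rng.uniform(0.002, 0.02)),
        trial_discontinuation=float(trial_disc if trial_disc is not None
                                    else rng.uniform(0.05, 0.15)),
    )


DEFAULT_ENTRY = np.array(
    [0.05, 0.20, 0.25, 0.20, 0.12, 0.08, 0.05, 0.03, 0.015, 0.005])


def generate_parameter_set(config: GeneratorConfig | None = None) -> ParameterSet:
    """Generate a complete, valid parameter set from a seed.

    With ``n_dmds=14`` (the default) the drug portfolio, real-world
    discontinuation rates, initiation mixes and adherent proportions are
    the published ones; efficacy, prices and natural history are seeded
    synthetic stand-ins.  Other sizes produce a fully synthetic portfolio
    with first-year discontinuation drawn from the real-world 10-31%
    range.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)

    nh = _natural_history(rng, config.severity_scale)
    eco = _economics(config.cost_scale)

    dmds: dict[str, DMDProfile] = {}
    if config.n_dmds == 14:
        for rec in TABLE2.itertuples():
            if rec.name == BSC:
                continue
            dmds[rec.name] = _draw_dmd(rng, rec.name, rec.line, rec.route,
                                       rec.disc_cau / 100.0)
        cau, sdm = table2_fixture()
    else:
        n_second = max(2, config.n_dmds // 3) if config.n_dmds >= 5 else 1
        lines = ["first"] * (config.n_dmds - n_second) + ["second"] * n_second
        for i, line in enumerate(lines):
            name = f"dmd_{i + 1:02d}"
            route = "infusion" if (line == "second" and i % 2 == 0) else "self_administered"
            dmds[name] = _draw_dmd(rng, name, line, route,
                                   rng.uniform(0.10, 0.31))
        # a sole second-line drug is reachable only by switching (a patient
        # initiating it would have no second-line drug left to switch to)
        weights = np.array([2.0 if d.line == "first"
                            else (0.3 if n_second > 1 else 0.0)
                            for d in dmds.values()])
        pos = weights > 0
        cau_sh = np.zeros(len(weights))
        sdm_sh = np.zeros(len(weights))
        cau_sh[pos] = 0.75 * rng.dirichlet(weights[pos] * 4)
        sdm_sh[pos] = 0.80 * rng.dirichlet(weights[pos] * 4)
        names = list(dmds)
        adh = {d: 0.589 if dmds[d].adherence_applicable else 1.0 for d in names}
        adh_sdm = {d: 0.639 if dmds[d].adherence_applicable else 1.0 for d in names}
        cau = StrategyProfile("CAU", {BSC: 0.25, **dict(zip(names, cau_sh))},
                              1.0, adh, 0.0)
        sdm = StrategyProfile("SDM", {BSC: 0.20, **dict(zip(names, sdm_sh))},
                              0.5, adh_sdm, SDM_COST_PER_DECISION)

    settings = ModelSettings(entry_distribution=DEFAULT_ENTRY.copy())
    return ParameterSet(natural_history=nh, dmds=dmds, economics=eco,
                        settings=settings, strategies={"CAU": cau, "SDM": sdm})


# ---------------------------------------------------------------------------
# Individual-level Monte-Carlo oracle
# ---------------------------------------------------------------------------

@dataclass
class MicrosimEstimate:
    """Mean outcomes and Monte-Carlo standard errors from the
    individual-level simulation."""

    mean: dict[str, float]
    se: dict[str, float]
    n_patients: int
    seed: int


def microsim_oracle(
    strategy: StrategyProfile,
    params: ParameterSet,
    n_patients: int,
    seed: int,
    perspective: str | None = None,
) -> MicrosimEstimate:
    """Simulate individual trajectories with the engine's event order
    (death, transition, forced stop, voluntary discontinuation/switch)
    and per-unit valuation rules, independent of the cohort algebra.

    Relapse counts, QALY decrements and event costs are accrued as
    per-state expectations, so the Monte-Carlo error reflects trajectory
    variation only.  Returns discounted means with standard errors for
    QALYs, total cost, relapses and life years.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    st, eco = params.settings, params.economics
    perspective = perspective or st.perspective
    rng = np.random.default_rng(seed)
    space = StageSpace(params)
    S = space.n
    n = n_patients

    # per-stage constants from the public per-unit operations
    rr_group: dict[str | None, int] = {}
    prog_mats = []
    g_of_stage = np.zeros(S, dtype=int)
    for s, stage in enumerate(space.stages):
        key = stage.dmd
        if key not in rr_group:
            rr = params.dmds[key].rr_progression if key else 1.0
            rr_group[key] = len(prog_mats)
            prog_mats.append(build_progression_matrix(params.natural_history, rr, st))
        g_of_stage[s] = rr_group[key]
    prog_cum = np.cumsum(np.stack(prog_mats), axis=2)      # (G, 20, 20)

    q = np.zeros(S)
    treat_first = np.zeros(S)
    treat_sub = np.zeros(S)
    post_monitor = np.zeros(S)
    ae_dis = np.zeros(S)
    for s in range(S):
        drug = space.profile(params, s)
        if drug is None:
            continue
        q[s] = effective_discontinuation(drug, strategy, 0, st)
        treat_first[s] = economics.cycle_treatment_costs(drug, 0, eco)
        treat_sub[s] = economics.cycle_treatment_costs(drug, 1, eco)
        post_monitor[s] = drug.monitoring_post_discontinuation
        ae_dis[s] = drug.ae_disutility

    w_cum = np.full((S, S), np.nan)
    for s, stage in enumerate(space.stages):
        if not stage.is_dmd:
            continue
        try:
            dist = switch_distribution(stage, strategy, params)
        except ValueError:
            if stage.kind is StageKind.ON_FIRST_DMD and \
                    strategy.initiation.get(stage.dmd, 0.0) == 0.0:
                continue
            raise
        row = np.zeros(S)
        for target, w in dist.items():
            row[space.index(target)] = w
        w_cum[s] = np.cumsum(row)

    person_cost = np.zeros(N_STATES)
    util20 = np.zeros(N_STATES)
    for j in range(N_STATES - 1):
        person_cost[j] = economics.cycle_person_costs(j, perspective, eco)
        util20[j] = eco.utilities[j]
    # expected relapses per (class, stage, state) from the per-unit op
    tot_rel = np.zeros((2, S, N_STATES))
    sev_rel = np.zeros((2, S, N_STATES))
    for s in range(S):
        drug = space.profile(params, s)
        rr_r = drug.rr_relapse if drug else 1.0
        for k in range(2):
            nonadh = bool(k == 1 and drug is not None and drug.adherence_applicable)
            for j in range(N_STATES - 1):
                tot_rel[k, s, j], sev_rel[k, s, j] = relapse_outcomes(
                    j, rr_r, nonadh, st, params.natural_history)

    # initial draws
    opts = list(strategy.initiation)
    shares = np.array([strategy.initiation[o] for o in opts])
    pick = rng.choice(len(opts), size=n, p=shares / shares.sum())
    stage = np.zeros(n, dtype=int)
    klass = np.zeros(n, dtype=int)
    for i_opt, opt in enumerate(opts):
        sel = pick == i_opt
        if opt == BSC or not sel.any():
            continue
        drug = params.dmds[opt]
        stage[sel] = space.index(TreatmentStage(StageKind.ON_FIRST_DMD, opt))
        if drug.adherence_applicable:
            a = strategy.adherent_proportion.get(opt, 1.0)
            klass[sel] = (rng.random(sel.sum()) >= a).astype(int)
    entry_cum = np.cumsum(st.entry_distribution)
    hs = np.searchsorted(entry_cum, rng.random(n), side="right").astype(int)
    entered = np.zeros(n, dtype=int)

    C = int(st.max_age - st.start_age)
    df_e = economics.discount_factor(eco.discount_effects, np.arange(C))
    df_c = economics.discount_factor(eco.discount_costs, np.arange(C))
    stop_mask20 = IS_ALIVE & (EDSS_OF_INDEX > st.edss_stop_level)
    bsc_after = space.bsc_after
    is_dmd = space.is_dmd
    is_first = space.is_first

    qaly = np.zeros(n)
    cost = np.zeros(n)
    relapses = np.zeros(n)
    lifey = np.zeros(n)
    if strategy.sdm_cost_per_decision:
        cost += df_c[0] * strategy.sdm_cost_per_decision  # initiation decision

    for cyc in range(C):
        alive = hs != DEAD_INDEX
        on_drug = alive & is_dmd[stage]
        tr = tot_rel[klass, stage, hs]
        sv = sev_rel[klass, stage, hs]
        qaly += df_e[cyc] * (util20[hs] - ae_dis[stage] * on_drug
                             - eco.relapse_disutility_severe * sv
                             - eco.relapse_disutility_mild * (tr - sv))
        relapses += df_e[cyc] * tr
        lifey += df_e[cyc] * alive
        tc = np.where(entered == cyc, treat_first[stage], treat_sub[stage])
        cost += df_c[cyc] * (person_cost[hs]
                             + eco.relapse_cost_severe * sv
                             + eco.relapse_cost_mild * (tr - sv)
                             + on_drug * tc)

        # death
        d20 = death_vector(st.start_age + cyc, st, params.natural_history)
        dies = alive & (rng.random(n) < d20[hs])
        hs = np.where(dies, DEAD_INDEX, hs)
        alive = hs != DEAD_INDEX

        # EDSS / SPMS transition
        if alive.any():
            rows = prog_cum[g_of_stage[stage[alive]], hs[alive]]
            u = rng.random(alive.sum())
            hs[alive] = (rows < u[:, None]).sum(axis=1)

        # forced stop above the EDSS threshold
        forced = alive & is_dmd[stage] & stop_mask20[hs]
        cost += df_c[cyc] * forced * post_monitor[stage]
        stage = np.where(forced, bsc_after, stage)

        # voluntary discontinuation and switch
        vol = alive & is_dmd[stage] & ~forced & (rng.random(n) < q[stage])
        if vol.any():
            src = stage[vol]
            cost[vol] += df_c[cyc] * post_monitor[src]
            dec = is_first[src]
            if strategy.sdm_cost_per_decision:
                cost[vol] += df_c[cyc] * dec * strategy.sdm_cost_per_decision
            rows = w_cum[src]
            if np.isnan(rows).any():
                raise RuntimeError("discontinuation from a stage without switch rules")
            dest = (rows < rng.random(vol.sum())[:, None]).sum(axis=1)
            stage[vol] = dest
            ent = entered[vol]
            ent[is_dmd[dest]] = cyc + 1
            entered[vol] = ent

    def summarize(x: np.ndarray) -> tuple[float, float]:
        return float(x.mean()), float(x.std(ddof=1) / np.sqrt(n))

    metrics = {"qalys": qaly, "total_cost": cost,
               "relapses": relapses, "life_years": lifey}
    means, ses = {}, {}
    for key, arr in metrics.items():
        means[key], ses[key] = summarize(arr)
    return MicrosimEstimate(means, ses, n, seed)
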