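"""Cohort engine: the health-state space expanded by treatment stage and
adherence class, run in annual cycles over the lifetime horizon.

Treatment pathways allow at most two DMDs.  Patients start on best
supportive care (BSC) or a first DMD; on voluntarily discontinuing the
first DMD they switch to a second DMD or BSC, and after the second DMD
they move to BSC for good.  Progression beyond the EDSS stop level forces
treatment stop without a new choice.  Within a cycle the event order is
death, then EDSS/SPMS transition, then forced stop, then voluntary
discontinuation; a newly chosen treatment takes effect at the start of
the next cycle, so the full cycle's drug cost falls in the
discontinuation year.

The per-cycle map factorizes as an age-dependent survival scaling
followed by an age-independent routing operator over the expanded space,
which is what makes the probabilistic sensitivity analysis affordable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import economics
from .natural_history import build_progression_matrix, death_matrix
from .parameters import BSC, DMDProfile, ModelSettings, ParameterSet, StrategyProfile
from .states import DEAD_INDEX, EDSS_OF_INDEX, IS_ALIVE, N_STATES, alive_above_edss

ADHERENT, NONADHERENT = 0, 1
ADHERENCE_CLASSES = ("adherent", "nonadherent")


class StageKind(enum.Enum):
    BSC_INITIAL = "BSC_INITIAL"
    BSC_AFTER_DMD = "BSC_AFTER_DMD"
    ON_FIRST_DMD = "ON_FIRST_DMD"
    ON_SECOND_DMD = "ON_SECOND_DMD"


@dataclass(frozen=True)
class TreatmentStage:
    kind: StageKind
    dmd: str | None = None

    def __post_init__(self) -> None:
        on_drug = self.kind in (StageKind.ON_FIRST_DMD, StageKind.ON_SECOND_DMD)
        if on_drug != (self.dmd is not None):
            raise ValueError("DMD identity is required exactly for on-treatment stages")

    @property
    def is_dmd(self) -> bool:
        return self.dmd is not None


class StageSpace:
    """Fixed enumeration of treatment stages for one parameter set."""

    def __init__(self, params: ParameterSet):
        names = params.dmd_names
        self.stages: list[TreatmentStage] = [
            TreatmentStage(StageKind.BSC_INITIAL),
            TreatmentStage(StageKind.BSC_AFTER_DMD),
        ]
        self.stages += [TreatmentStage(StageKind.ON_FIRST_DMD, d) for d in names]
        self.stages += [TreatmentStage(StageKind.ON_SECOND_DMD, d) for d in names]
        self.n = len(self.stages)
        self._index = {s: i for i, s in enumerate(self.stages)}
        self.bsc_after = 1
        self.dmd_of = [s.dmd for s in self.stages]
        self.is_dmd = np.array([s.is_dmd for s in self.stages])
        self.is_first = np.array([s.kind is StageKind.ON_FIRST_DMD for s in self.stages])

    def index(self, stage: TreatmentStage) -> int:
        return self._index[stage]

    def profile(self, params: ParameterSet, i: int) -> DMDProfile | None:
        d = self.dmd_of[i]
        return params.dmds[d] if d is not None else None


def effective_discontinuation(
    dmd: DMDProfile, strategy: StrategyProfile, edss: int, settings: ModelSettings
) -> float:
    """Annual probability of stopping the current DMD.

    Above the EDSS stop level treatment stops with certainty (no new
    choice is made); otherwise the drug's usual-care rate is scaled by
    the strategy's persistence multiplier.
    """
    if edss > settings.edss_stop_level:
        return 1.0
    p = dmd.cau_discontinuation * strategy.discontinuation_multiplier
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"effective discontinuation {p} outside [0, 1]")
    return p


def switch_distribution(
    current: TreatmentStage, strategy: StrategyProfile, params: ParameterSet
) -> dict[TreatmentStage, float]:
    """Destination mix after a voluntary discontinuation.

    From the first DMD, a fixed share moves to BSC and the rest switches:
    side-effect discontinuers of a first-line drug pick another first-line
    drug, efficacy discontinuers escalate to a second-line drug, and
    patients whose first DMD was second-line stay within the second line.
    Within the eligible set (current drug excluded) destinations follow
    the strategy's initiation shares, renormalized; a uniform split is
    used when those shares carry no mass.  After the second DMD everyone
    moves to BSC.
    """
    if not current.is_dmd:
        raise ValueError("switching is defined for on-treatment stages only")
    bsc_after = TreatmentStage(StageKind.BSC_AFTER_DMD)
    if current.kind is StageKind.ON_SECOND_DMD:
        return {bsc_after: 1.0}

    def weights(eligible: list[str], mass: float, by_shares: bool) -> dict[TreatmentStage, float]:
        if not eligible:
            raise ValueError(
                f"no eligible switch destination from {current.dmd!r}"
            )
        if by_shares:
            w = np.array([strategy.initiation.get(d, 0.0) for d in eligible])
            w = w / w.sum() if w.sum() > 0 else np.full(len(eligible), 1 / len(eligible))
        else:
            w = np.full(len(eligible), 1 / len(eligible))
        return {TreatmentStage(StageKind.ON_SECOND_DMD, d): mass * wi
                for d, wi in zip(eligible, w)}

    drug = params.dmds[current.dmd]
    first_line = [d for d, p in params.dmds.items() if p.line == "first" and d != current.dmd]
    second_line = [d for d, p in params.dmds.items() if p.line == "second" and d != current.dmd]
    s2d = strategy.switch_to_dmd_share
    dist: dict[TreatmentStage, float] = {bsc_after: 1.0 - s2d}

    rule = strategy.switch_rule
    if rule == "line_based":
        if drug.line == "first":
            for k, v in weights(first_line, s2d * strategy.side_effect_share, True).items():
                dist[k] = dist.get(k, 0.0) + v
            for k, v in weights(second_line, s2d * (1 - strategy.side_effect_share), True).items():
                dist[k] = dist.get(k, 0.0) + v
        else:
            dist.update(weights(second_line, s2d, True))
    elif rule == "second_line_equal":
        dist.update(weights(second_line, s2d, False))
    elif rule == "all_lines_equal":
        dist.update(weights(first_line + second_line, s2d, False))
    else:
        raise ValueError(f"unknown switch rule {rule!r}")
    return dist


@dataclass
class CohortTrace:
    """Occupancy and event streams of one cohort run.

    ``occupancy`` has shape (cycles + 1, 2 adherence classes, stages, 20
    health states); row ``c`` is the start of cycle ``c`` and the final
    row is the terminal state.  Event arrays are per cycle: voluntary
    discontinuation mass, forced (EDSS) stop mass and arriving newcomer
    mass per (class, stage), plus expected deaths and treatment-choice
    decision mass (voluntary first-DMD discontinuations).
    """

    space: StageSpace
    start_age: int
    occupancy: np.ndarray          # (C+1, 2, S, 20)
    voluntary_disc: np.ndarray     # (C, 2, S)
    forced_stop: np.ndarray        # (C, 2, S)
    newcomers: np.ndarray          # (C+1, 2, S), mass in its first on-stage cycle
    deaths: np.ndarray             # (C,)
    decisions: np.ndarray          # (C, 2)

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def to_frame(self) -> pd.DataFrame:
        """Long-format trace export (cycle, stage, class, course, edss, mass)."""
        C = self.n_cycles
        rows = []
        for c in range(C + 1):
            for k, cls in enumerate(ADHERENCE_CLASSES):
                for s, stage in enumerate(self.space.stages):
                    for j in range(N_STATES):
                        m = self.occupancy[c, k, s, j]
                        if m > 0:
                            rows.append((c, stage.kind.value, stage.dmd or "", cls,
                                         "DEAD" if j == DEAD_INDEX
                                         else ("RRMS" if j < 10 else "SPMS"),
                                         int(EDSS_OF_INDEX[j]), m))
        return pd.DataFrame(
            rows, columns=["cycle", "stage", "dmd", "adherence", "course", "edss", "mass"]
        )

    def events_frame(self) -> pd.DataFrame:
        C = self.n_cycles
        return pd.DataFrame({
            "cycle": np.arange(C),
            "deaths": self.deaths,
            "voluntary_discontinuations": self.voluntary_disc.sum(axis=(1, 2)),
            "forced_stops": self.forced_stop.sum(axis=(1, 2)),
            "switch_decisions": self.decisions.sum(axis=1),
        })


def build_progression_set(params: ParameterSet) -> dict[str | None, np.ndarray]:
    """Progression matrix per DMD (and ``None`` for best supportive care)."""
    prog: dict[str | None, np.ndarray] = {
        None: build_progression_matrix(params.natural_history, 1.0, params.settings)
    }
    for name, d in params.dmds.items():
        prog[name] = build_progression_matrix(
            params.natural_history, d.rr_progression, params.settings)
    return prog


@dataclass
class _Compiled:
    space: StageSpace
    routing: np.ndarray            # (S*20, S*20) age-independent
    e_vdisc: np.ndarray            # (S*20, S) voluntary-discontinuation extractor
    e_forced: np.ndarray           # (S*20, S)
    e_inflow: np.ndarray           # (S*20, S) inflow into DMD stages
    progression: dict[str | None, np.ndarray] = field(default_factory=dict)


def compile_strategy(
    params: ParameterSet,
    strategy: StrategyProfile,
    progression: dict[str | None, np.ndarray] | None = None,
) -> _Compiled:
    """Assemble the routing operator and event extractors for one strategy.

    ``progression`` allows sharing the per-drug progression matrices when
    compiling several strategies over the same parameter set.
    """
    st = params.settings
    space = StageSpace(params)
    S, N = space.n, N_STATES

    if progression is None:
        progression = build_progression_set(params)
    prog = progression

    m_stop = alive_above_edss(st.edss_stop_level).astype(float)
    m_stay = (IS_ALIVE & ~alive_above_edss(st.edss_stop_level)).astype(float)
    m_dead = (~IS_ALIVE).astype(float)

    R = np.zeros((S * N, S * N))
    e_vd = np.zeros((S * N, S))
    e_fs = np.zeros((S * N, S))
    e_in = np.zeros((S * N, S))

    def blk(i: int) -> slice:
        return slice(i * N, (i + 1) * N)

    for s, stage in enumerate(space.stages):
        P = prog[stage.dmd]
        if not stage.is_dmd:
            R[blk(s), blk(s)] = P
            continue
        drug = params.dmds[stage.dmd]
        q = effective_discontinuation(drug, strategy, edss=0, settings=st)
        try:
            dist = switch_distribution(stage, strategy, params)
        except ValueError:
            if stage.kind is StageKind.ON_FIRST_DMD and \
                    strategy.initiation.get(stage.dmd, 0.0) == 0.0:
                dist = None  # unreachable stage; leave its routing empty
            else:
                raise
        R[blk(s), blk(s)] = P * (m_stay * (1 - q) + m_dead)[None, :]
        R[blk(s), blk(space.bsc_after)] += P * m_stop[None, :]
        vd = P @ (m_stay * q)
        e_vd[blk(s), s] = vd
        e_fs[blk(s), s] = P @ m_stop
        if dist is None:
            continue
        for target, w in dist.items():
            t = space.index(target)
            R[blk(s), blk(t)] += P * (m_stay * q * w)[None, :]
            if target.is_dmd:
                e_in[blk(s), t] += vd * w

    return _Compiled(space, R, e_vd, e_fs, e_in, prog)


def run_cohort(
    params: ParameterSet,
    strategy: StrategyProfile,
    initial_occupancy: np.ndarray,
    compiled: _Compiled | None = None,
) -> CohortTrace:
    """Evolve an initial occupancy (2 classes x stages x 20 states) over
    the lifetime horizon and record occupancy and event streams."""
    st = params.settings
    C = int(st.max_age - st.start_age)
    if C <= 0:
        raise ValueError("horizon must cover at least one cycle")
    c = compiled or compile_strategy(params, strategy)
    S, N = c.space.n, N_STATES

    occupancy = np.zeros((C + 1, 2, S, N))
    vdisc = np.zeros((C, 2, S))
    forced = np.zeros((C, 2, S))
    newcomers = np.zeros((C + 1, 2, S))
    deaths = np.zeros(C)
    decisions = np.zeros((C, 2))

    occ = initial_occupancy.reshape(2, S * N).copy()
    newcomers[0] = initial_occupancy.sum(axis=2) * c.space.is_dmd

    dmat = death_matrix(st.start_age + np.arange(C), st, params.natural_history)
    events = np.hstack([c.e_vdisc, c.e_forced, c.e_inflow])     # (S*N, 3S)
    for cyc in range(C):
        occupancy[cyc] = occ.reshape(2, S, N)
        d = dmat[cyc]
        dead_gain = (occupancy[cyc] * d).sum(axis=2)            # (2, S)
        occa = occ * np.tile(1.0 - d, S)
        ev = occa @ events
        vdisc[cyc], forced[cyc], newcomers[cyc + 1] = \
            ev[:, :S], ev[:, S:2 * S], ev[:, 2 * S:]
        occ = occa @ c.routing
        occ3 = occ.reshape(2, S, N)
        occ3[:, :, DEAD_INDEX] += dead_gain
        occ = occ3.reshape(2, S * N)
        deaths[cyc] = dead_gain.sum()
        decisions[cyc] = vdisc[cyc][:, c.space.is_first].sum(axis=1)

    occupancy[C] = occ.reshape(2, S, N)
    return CohortTrace(c.space, st.start_age, occupancy, vdisc, forced,
                       newcomers, deaths, decisions)


def _class_index(adherence_class: str | int) -> int:
    if isinstance(adherence_class, str):
        return ADHERENCE_CLASSES.index(adherence_class)
    return int(adherence_class)


def run_pathway(
    initial: TreatmentStage,
    adherence_class: str | int,
    strategy: StrategyProfile,
    params: ParameterSet,
    entry: np.ndarray | None = None,
) -> CohortTrace:
    """Run a unit cohort that starts in one treatment stage and one
    adherence class, entering over the RRMS EDSS entry distribution."""
    space = StageSpace(params)
    occ0 = np.zeros((2, space.n, N_STATES))
    e = params.settings.entry_distribution if entry is None else entry
    occ0[_class_index(adherence_class), space.index(initial), : len(e)] = e
    return run_cohort(params, strategy, occ0)


def initial_occupancy(strategy: StrategyProfile, params: ParameterSet) -> np.ndarray:
    """Mix the strategy's initiation shares and per-DMD adherence split
    into a (2, stages, states) starting occupancy."""
    space = StageSpace(params)
    st = params.settings
    occ0 = np.zeros((2, space.n, N_STATES))
    entry = st.entry_distribution
    for opt, share in strategy.initiation.items():
        if share == 0.0:
            continue
        if opt == BSC:
            occ0[ADHERENT, 0, : len(entry)] += share * entry
            continue
        if opt not in params.dmds:
            raise ValueError(f"initiation references unknown DMD {opt!r}")
        drug = params.dmds[opt]
        s = space.index(TreatmentStage(StageKind.ON_FIRST_DMD, opt))
        a = strategy.adherent_proportion.get(opt, 1.0) if drug.adherence_applicable else 1.0
        occ0[ADHERENT, s, : len(entry)] += share * a * entry
        occ0[NONADHERENT, s, : len(entry)] += share * (1.0 - a) * entry
    return occ0


def evaluate_strategy(
    strategy: StrategyProfile,
    params: ParameterSet,
    perspective: str | None = None,
    compiled: _Compiled | None = None,
) -> "economics.Outcomes":
    """Discounted lifetime outcomes of one strategy arm: the weighted
    average over initiation options and adherence classes."""
    occ0 = initial_occupancy(strategy, params)
    trace = run_cohort(params, strategy, occ0, compiled=compiled)
    return economics.accrue(trace, strategy, params, perspective=perspective)
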