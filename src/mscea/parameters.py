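"""Model inputs: domain types, file readers/writers, validation, and the
small input-preparation calculations (EDSS cost interpolation, trial-scaled
discontinuation, adverse-event costs).

A parameter set is stored on disk as a directory of plain delimited text
tables bound together by a small YAML manifest, so that supplementary
tables from the literature can be transcribed without code changes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .states import IS_RRMS, IS_SPMS, N_RRMS, N_SPMS, N_STATES

COST_CATEGORIES = (
    "healthcare",
    "community_services",
    "equipment_aids",
    "informal_care",
    "productivity_friction",
    "productivity_human_capital",
)

PERSPECTIVES = ("healthcare", "societal_friction", "societal_human_capital")

#: key for the no-active-treatment option in initiation distributions
BSC = "best_supportive_care"

ROW_SUM_TOL = 1e-9


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class NaturalHistory:
    """Untreated disease dynamics.

    ``rrms`` is a (10, 11) annual probability table: for each RRMS EDSS
    row, columns 0..9 are the RRMS EDSS targets and column 10 is the
    probability of converting to SPMS.  ``spms`` is a (9, 9) table over
    SPMS EDSS 1..9 targets; SPMS patients cannot improve, so rows place
    no mass below the diagonal.  Rows of both tables sum to one before
    mortality is applied.  Mortality multipliers are indexed by EDSS and
    apply identically to RRMS and SPMS at the same level.
    """

    rrms: np.ndarray                    # (10, 11)
    spms: np.ndarray                    # (9, 9)
    relapse_rate: np.ndarray            # (19,) per alive state index
    severe_fraction: np.ndarray         # (19,)
    mortality_multiplier: np.ndarray    # (10,) per EDSS 0..9
    life_table_age: np.ndarray          # (A,) integer ages
    life_table_male: np.ndarray         # (A,) annual death probability
    life_table_female: np.ndarray       # (A,)


@dataclass
class DMDProfile:
    """One disease-modifying drug: efficacy, costs, and persistence inputs."""

    name: str
    line: str                           # "first" | "second"
    rr_progression: float               # relative risk on worsening/conversion
    rr_relapse: float                   # relative risk on relapse rate
    annual_drug_cost: float
    admin_cost_first_year: float = 0.0
    admin_cost_subsequent: float = 0.0
    monitoring_pretreatment: float = 0.0
    monitoring_annual: float = 0.0
    monitoring_post_discontinuation: float = 0.0
    prescriptions_per_year: int = 12    # 0 for infused drugs
    route: str = "self_administered"    # "self_administered" | "infusion"
    cau_discontinuation: float = 0.2    # annual probability under usual care
    adherence_applicable: bool = True   # infused drugs have optimal adherence
    ae_disutility: float = 0.0          # QALY decrement per on-treatment year
    trial_discontinuation: float = 0.1  # used for proportional scaling only


@dataclass
class StrategyProfile:
    """One arm's decision-making profile (usual care, SDM, or custom).

    ``initiation`` maps the best-supportive-care key and DMD names to
    initial-choice probabilities (summing to one).  ``adherent_proportion``
    gives the per-DMD probability of the optimally adherent class (>80%
    of days covered); it is ignored for drugs whose adherence is assumed
    optimal.  ``discontinuation_multiplier`` scales each drug's usual-care
    annual discontinuation probability (0.5 in the SDM base case).
    """

    label: str
    initiation: dict[str, float]
    discontinuation_multiplier: float = 1.0
    adherent_proportion: dict[str, float] = field(default_factory=dict)
    sdm_cost_per_decision: float = 0.0
    switch_to_dmd_share: float = 0.95
    side_effect_share: float = 0.79
    switch_rule: str = "line_based"
    # "line_based" (default): side-effect switchers go to another first-line
    # drug, efficacy switchers to a second-line drug.  The one-way scenario
    # variants use "second_line_equal" and "all_lines_equal".


@dataclass
class EconomicInputs:
    """Utilities, disutilities and unit costs."""

    state_costs: np.ndarray             # (19, 6) per alive state x category
    utilities: np.ndarray               # (19,) per alive state
    relapse_cost_severe: float
    relapse_cost_mild: float
    relapse_disutility_severe: float
    relapse_disutility_mild: float
    ae_cost_fraction: float             # AE costs as share of healthcare costs
    dispensing_fee_first: float = 14.0
    dispensing_fee_subsequent: float = 7.0
    discount_effects: float = 0.015
    discount_costs: float = 0.040


@dataclass
class ModelSettings:
    start_age: int = 37
    proportion_male: float = 0.29
    max_age: int = 100
    cycle_length: float = 1.0
    entry_distribution: np.ndarray = field(
        default_factory=lambda: np.zeros(N_RRMS)
    )                                   # over RRMS EDSS 0..9
    perspective: str = "societal_friction"
    nonadherent_relapse_multiplier: float = 1.42
    nonadherent_severe_multiplier: float = 1.075
    edss_stop_level: int = 6            # forced stop above this level
    spms_entry_offset: int = 0          # EDSS shift on RRMS->SPMS conversion
    rr_applies_in_spms: bool = True     # DMD slows SPMS worsening too
    half_cycle_correction: bool = False


@dataclass
class ParameterSet:
    natural_history: NaturalHistory
    dmds: dict[str, DMDProfile]
    economics: EconomicInputs
    settings: ModelSettings
    strategies: dict[str, StrategyProfile] = field(default_factory=dict)

    @property
    def dmd_names(self) -> list[str]:
        return list(self.dmds)


@dataclass
class Violation:
    table: str
    row: object
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.table}:{self.row}] {self.rule}: {self.message}"


# ---------------------------------------------------------------------------
# Input-preparation operations
# ---------------------------------------------------------------------------

def interpolate_state_costs(anchors: dict[int, float]) -> np.ndarray:
    """Densify a sparse EDSS -> annual cost table by linear interpolation.

    Anchor levels are returned exactly; between adjacent anchors costs are
    linear; beyond the outermost anchors the nearest anchor value is held
    constant (so extrapolation can neither go negative nor explode).
    Returns a length-10 array over EDSS 0..9.
    """
    if len(anchors) < 2:
        raise ValueError("need at least two EDSS cost anchors")
    levels = np.array(sorted(anchors))
    values = np.array([anchors[int(l)] for l in levels], dtype=float)
    if (values < 0).any():
        raise ValueError("anchor costs must be non-negative")
    return np.interp(np.arange(10), levels, values)


def scale_discontinuation_from_trials(
    reference_real_world: float, trial_reference: float, trial_target: float
) -> float:
    """Carry a real-world discontinuation probability over to a drug with no
    real-world data, scaling proportionately by trial discontinuation rates."""
    for name, p in (
        ("reference_real_world", reference_real_world),
        ("trial_reference", trial_reference),
        ("trial_target", trial_target),
    ):
        if not 0 < p <= 1:
            raise ValueError(f"{name} must be in (0, 1], got {p}")
    return min(1.0, reference_real_world * trial_target / trial_reference)


def ae_costs(healthcare_cost: float, fraction: float) -> float:
    """Adverse-event costs expressed as a proportion of healthcare costs."""
    if healthcare_cost < 0:
        raise ValueError("healthcare_cost must be non-negative")
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    return healthcare_cost * fraction


def sdm_cost_components(total: float, consultation_component: float) -> float:
    """Headroom left for decision-aid development/training once the extra
    consultation time is paid, out of the per-decision SDM delivery cost."""
    if consultation_component > total:
        raise ValueError("consultation component exceeds the total")
    return round(total - consultation_component, 2)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _check_prob(v: float) -> bool:
    return 0.0 <= v <= 1.0


def validate_parameter_set(params: ParameterSet) -> list[Violation]:
    """Check every structural invariant; violations are data, not exceptions."""
    out: list[Violation] = []
    nh = params.natural_history
    eco = params.economics
    st = params.settings

    def bad(table, row, rule, message):
        out.append(Violation(table, row, rule, message))

    # transition tables
    if nh.rrms.shape != (N_RRMS, N_RRMS + 1):
        bad("transitions_rrms", None, "shape", f"expected (10, 11), got {nh.rrms.shape}")
    else:
        for i, row in enumerate(nh.rrms):
            if not np.isclose(row.sum(), 1.0, rtol=0, atol=ROW_SUM_TOL):
                bad("transitions_rrms", i, "row_sum", f"row sums to {row.sum():.12f}")
            if ((row < 0) | (row > 1)).any():
                bad("transitions_rrms", i, "probability_range", "entries outside [0, 1]")
    if nh.spms.shape != (N_SPMS, N_SPMS):
        bad("transitions_spms", None, "shape", f"expected (9, 9), got {nh.spms.shape}")
    else:
        for i, row in enumerate(nh.spms):
            if not np.isclose(row.sum(), 1.0, rtol=0, atol=ROW_SUM_TOL):
                bad("transitions_spms", i, "row_sum", f"row sums to {row.sum():.12f}")
            if ((row < 0) | (row > 1)).any():
                bad("transitions_spms", i, "probability_range", "entries outside [0, 1]")
            if row[:i].sum() > 0:
                bad("transitions_spms", i, "no_improvement",
                    "SPMS rows must place zero mass on lower EDSS")

    # relapse model
    if (nh.relapse_rate < 0).any():
        bad("relapse_rates", None, "non_negative", "relapse rates must be >= 0")
    if ((nh.severe_fraction < 0) | (nh.severe_fraction > 1)).any():
        bad("relapse_rates", None, "severe_fraction_range", "severe fractions outside [0, 1]")

    # mortality
    if (nh.mortality_multiplier < 1).any():
        bad("mortality_multipliers", None, "at_least_one",
            "EDSS mortality multipliers must be >= 1")
    if len(nh.life_table_age) == 0:
        bad("life_table", None, "empty", "life table has no rows")
    else:
        for arr, sex in ((nh.life_table_male, "male"), (nh.life_table_female, "female")):
            if ((arr < 0) | (arr > 1)).any():
                bad("life_table", sex, "probability_range", "death probabilities outside [0, 1]")
        if nh.life_table_age.max() < st.max_age - 1:
            bad("life_table", None, "age_coverage",
                f"life table ends at {nh.life_table_age.max()} but horizon needs {st.max_age - 1}")

    # utilities: bounded and non-increasing in EDSS within each course
    if ((eco.utilities < -1) | (eco.utilities > 1)).any():
        bad("utilities", None, "range", "utilities outside [-1, 1]")
    for mask, course in ((IS_RRMS[:-1], "RRMS"), (IS_SPMS[:-1], "SPMS")):
        u = eco.utilities[mask[: len(eco.utilities)]]
        if (np.diff(u) > 1e-12).any():
            bad("utilities", course, "monotone_nonincreasing",
                f"{course} utilities must be non-increasing in EDSS")

    # costs: non-negative everywhere, healthcare non-decreasing in EDSS
    if (eco.state_costs < 0).any():
        bad("state_costs", None, "non_negative", "state costs must be >= 0")
    hc = eco.state_costs[:, COST_CATEGORIES.index("healthcare")]
    for mask, course in ((IS_RRMS[:-1], "RRMS"), (IS_SPMS[:-1], "SPMS")):
        c = hc[mask[: len(hc)]]
        if (np.diff(c) < -1e-9).any():
            bad("state_costs", course, "healthcare_monotone",
                f"{course} healthcare costs must be non-decreasing in EDSS")
    for name in ("relapse_cost_severe", "relapse_cost_mild"):
        if getattr(eco, name) < 0:
            bad("settings", name, "non_negative", "relapse costs must be >= 0")
    if not 0 <= eco.ae_cost_fraction <= 1:
        bad("settings", "ae_cost_fraction", "range", "AE cost fraction outside [0, 1]")
    for name in ("discount_effects", "discount_costs"):
        if not 0 <= getattr(eco, name) < 1:
            bad("settings", name, "range", "discount rates must be in [0, 1)")

    # DMD profiles
    for name, d in params.dmds.items():
        if not 0 < d.rr_progression <= 2:
            bad("dmd_profiles", name, "rr_range", f"rr_progression {d.rr_progression} outside (0, 2]")
        if not 0 < d.rr_relapse <= 2:
            bad("dmd_profiles", name, "rr_range", f"rr_relapse {d.rr_relapse} outside (0, 2]")
        if d.line not in ("first", "second"):
            bad("dmd_profiles", name, "line", f"unknown line {d.line!r}")
        if d.route not in ("self_administered", "infusion"):
            bad("dmd_profiles", name, "route", f"unknown route {d.route!r}")
        if d.route == "infusion" and d.adherence_applicable:
            bad("dmd_profiles", name, "infusion_adherence",
                "infused drugs are assumed optimally adherent")
        if not _check_prob(d.cau_discontinuation):
            bad("dmd_profiles", name, "discontinuation_range",
                f"cau_discontinuation {d.cau_discontinuation} outside [0, 1]")
        for f in ("annual_drug_cost", "admin_cost_first_year", "admin_cost_subsequent",
                  "monitoring_pretreatment", "monitoring_annual",
                  "monitoring_post_discontinuation"):
            if getattr(d, f) < 0:
                bad("dmd_profiles", name, "non_negative", f"{f} must be >= 0")

    # strategies
    for label, strat in params.strategies.items():
        total = sum(strat.initiation.values())
        if not np.isclose(total, 1.0, rtol=0, atol=ROW_SUM_TOL):
            bad(f"strategy_{label.lower()}", None, "initiation_sum",
                f"initiation shares sum to {total:.12f}")
        for opt, p in strat.initiation.items():
            if opt != BSC and opt not in params.dmds:
                bad(f"strategy_{label.lower()}", opt, "unknown_dmd",
                    f"initiation references unknown DMD {opt!r}")
            if not _check_prob(p):
                bad(f"strategy_{label.lower()}", opt, "probability_range",
                    f"initiation share {p} outside [0, 1]")
        for opt, p in strat.adherent_proportion.items():
            if not _check_prob(p):
                bad(f"strategy_{label.lower()}", opt, "probability_range",
                    f"adherent proportion {p} outside [0, 1]")
        for f in ("discontinuation_multiplier", "switch_to_dmd_share", "side_effect_share"):
            v = getattr(strat, f)
            if not (0 <= v <= 1):
                bad(f"strategy_{label.lower()}", f, "range", f"{f} = {v} outside [0, 1]")

    # settings
    if not np.isclose(st.entry_distribution.sum(), 1.0, rtol=0, atol=ROW_SUM_TOL):
        bad("settings", "entry_distribution", "sum",
            f"entry distribution sums to {st.entry_distribution.sum():.12f}")
    if not 0 < st.start_age < st.max_age:
        bad("settings", "start_age", "range", "need 0 < start_age < max_age")
    if not 0 <= st.proportion_male <= 1:
        bad("settings", "proportion_male", "range", "proportion male outside [0, 1]")
    for f in ("nonadherent_relapse_multiplier", "nonadherent_severe_multiplier"):
        if getattr(st, f) < 1:
            bad("settings", f, "at_least_one", f"{f} must be >= 1")
    if st.perspective not in PERSPECTIVES:
        bad("settings", "perspective", "unknown", f"unknown perspective {st.perspective!r}")

    return out


# ---------------------------------------------------------------------------
# File format
# ---------------------------------------------------------------------------

_FILES = (
    "transitions_rrms", "transitions_spms", "relapse_rates",
    "mortality_multipliers", "life_table", "dmd_profiles", "utilities",
    "state_costs", "strategy_cau", "strategy_sdm", "settings",
)

_SETTINGS_SCALARS = {
    "start_age": int, "proportion_male": float, "max_age": int,
    "cycle_length": float, "perspective": str,
    "nonadherent_relapse_multiplier": float, "nonadherent_severe_multiplier": float,
    "edss_stop_level": int, "spms_entry_offset": int,
    "rr_applies_in_spms": lambda v: str(v).lower() in ("true", "1"),
    "half_cycle_correction": lambda v: str(v).lower() in ("true", "1"),
}

_ECON_SCALARS = (
    "relapse_cost_severe", "relapse_cost_mild", "relapse_disutility_severe",
    "relapse_disutility_mild", "ae_cost_fraction", "dispensing_fee_first",
    "dispensing_fee_subsequent", "discount_effects", "discount_costs",
)


def _state_rows() -> pd.DataFrame:
    course = ["RRMS"] * N_RRMS + ["SPMS"] * N_SPMS
    edss = list(range(10)) + list(range(1, 10))
    return pd.DataFrame({"course": course, "edss": edss})


def write_parameter_set(params: ParameterSet, directory: str | Path) -> Path:
    """Write every table of a parameter set as delimited text plus a manifest.

    Floats are written with ``repr`` so that a load/write round trip is
    bit-identical.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nh, eco, st = params.natural_history, params.economics, params.settings

    def save(name: str, df: pd.DataFrame) -> None:
        # %.17g round-trips IEEE doubles, keeping the directory bit-identical
        # under a load/write cycle
        df.to_csv(directory / f"{name}.csv", index=False, float_format="%.17g")

    rrms = pd.DataFrame(nh.rrms, columns=[f"to_rrms_{j}" for j in range(10)] + ["to_spms"])
    rrms.insert(0, "from_edss", range(10))
    save("transitions_rrms", rrms)

    spms = pd.DataFrame(nh.spms, columns=[f"to_spms_{j}" for j in range(1, 10)])
    spms.insert(0, "from_edss", range(1, 10))
    save("transitions_spms", spms)

    rel = _state_rows()
    rel["relapse_rate"] = nh.relapse_rate
    rel["severe_fraction"] = nh.severe_fraction
    save("relapse_rates", rel)

    save("mortality_multipliers",
         pd.DataFrame({"edss": range(10), "multiplier": nh.mortality_multiplier}))

    save("life_table", pd.DataFrame({
        "age": nh.life_table_age,
        "male": nh.life_table_male,
        "female": nh.life_table_female,
    }))

    save("dmd_profiles", pd.DataFrame([dataclasses.asdict(d) for d in params.dmds.values()]))

    util = _state_rows()
    util["utility"] = eco.utilities
    save("utilities", util)

    costs = _state_rows()
    for k, cat in enumerate(COST_CATEGORIES):
        costs[cat] = eco.state_costs[:, k]
    save("state_costs", costs)

    for label in ("cau", "sdm"):
        strat = params.strategies[label.upper()]
        rows = [("scalar", f, getattr(strat, f)) for f in
                ("label", "discontinuation_multiplier", "sdm_cost_per_decision",
                 "switch_to_dmd_share", "side_effect_share", "switch_rule")]
        rows += [("initiation", opt, p) for opt, p in strat.initiation.items()]
        rows += [("adherent_proportion", opt, p)
                 for opt, p in strat.adherent_proportion.items()]
        save(f"strategy_{label}", pd.DataFrame(rows, columns=["field", "option", "value"]))

    srows = [(k, getattr(st, k)) for k in _SETTINGS_SCALARS]
    srows += [(f"entry_edss_{i}", st.entry_distribution[i]) for i in range(N_RRMS)]
    srows += [(k, getattr(eco, k)) for k in _ECON_SCALARS]
    save("settings", pd.DataFrame(srows, columns=["key", "value"]))

    manifest = {"format": "mscea-parameter-set", "version": 1,
                "files": {name: f"{name}.csv" for name in _FILES}}
    (directory / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return directory


class ParameterLoadError(Exception):
    pass


class ParameterValidationError(Exception):
    def __init__(self, violations: list[Violation]):
        self.violations = violations
        super().__init__(
            "parameter set failed validation:\n" + "\n".join(map(str, violations))
        )


def _read_strategy(df: pd.DataFrame) -> StrategyProfile:
    scalars = {r.option: r.value for r in df.itertuples() if r.field == "scalar"}
    return StrategyProfile(
        label=str(scalars["label"]),
        initiation={r.option: float(r.value) for r in df.itertuples()
                    if r.field == "initiation"},
        discontinuation_multiplier=float(scalars["discontinuation_multiplier"]),
        adherent_proportion={r.option: float(r.value) for r in df.itertuples()
                             if r.field == "adherent_proportion"},
        sdm_cost_per_decision=float(scalars["sdm_cost_per_decision"]),
        switch_to_dmd_share=float(scalars["switch_to_dmd_share"]),
        side_effect_share=float(scalars["side_effect_share"]),
        switch_rule=str(scalars.get("switch_rule", "line_based")),
    )


def load_parameter_set(directory: str | Path, validate: bool = True) -> ParameterSet:
    """Load and validate a parameter-set directory written by
    :func:`write_parameter_set` (or transcribed by hand in the same format)."""
    directory = Path(directory)
    manifest_path = directory / "manifest.yaml"
    if not manifest_path.exists():
        raise ParameterLoadError(f"missing manifest.yaml in {directory}")
    manifest = yaml.safe_load(manifest_path.read_text())
    files = manifest.get("files", {})

    tables: dict[str, pd.DataFrame] = {}
    for name in _FILES:
        rel = files.get(name, f"{name}.csv")
        path = directory / rel
        if not path.exists():
            raise ParameterLoadError(f"missing input file for table {name!r}: {path}")
        tables[name] = pd.read_csv(path, float_precision="round_trip")

    rrms = tables["transitions_rrms"].sort_values("from_edss")
    spms = tables["transitions_spms"].sort_values("from_edss")
    rel = tables["relapse_rates"]
    life = tables["life_table"].sort_values("age")
    nh = NaturalHistory(
        rrms=rrms[[f"to_rrms_{j}" for j in range(10)] + ["to_spms"]].to_numpy(float),
        spms=spms[[f"to_spms_{j}" for j in range(1, 10)]].to_numpy(float),
        relapse_rate=rel["relapse_rate"].to_numpy(float),
        severe_fraction=rel["severe_fraction"].to_numpy(float),
        mortality_multiplier=tables["mortality_multipliers"]
            .sort_values("edss")["multiplier"].to_numpy(float),
        life_table_age=life["age"].to_numpy(int),
        life_table_male=life["male"].to_numpy(float),
        life_table_female=life["female"].to_numpy(float),
    )

    dmds: dict[str, DMDProfile] = {}
    for rec in tables["dmd_profiles"].to_dict("records"):
        rec["adherence_applicable"] = bool(rec["adherence_applicable"])
        rec["prescriptions_per_year"] = int(rec["prescriptions_per_year"])
        dmds[rec["name"]] = DMDProfile(**rec)

    kv = {str(r.key): r.value for r in tables["settings"].itertuples()}
    eco = EconomicInputs(
        state_costs=tables["state_costs"][list(COST_CATEGORIES)].to_numpy(float),
        utilities=tables["utilities"]["utility"].to_numpy(float),
        **{k: float(kv[k]) for k in _ECON_SCALARS},
    )
    settings = ModelSettings(
        entry_distribution=np.array([float(kv[f"entry_edss_{i}"]) for i in range(N_RRMS)]),
        **{k: conv(kv[k]) for k, conv in _SETTINGS_SCALARS.items()},
    )

    params = ParameterSet(
        natural_history=nh, dmds=dmds, economics=eco, settings=settings,
        strategies={
            "CAU": _read_strategy(tables["strategy_cau"]),
            "SDM": _read_strategy(tables["strategy_sdm"]),
        },
    )
    if validate:
        violations = validate_parameter_set(params)
        if violations:
            raise ParameterValidationError(violations)
    return params
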