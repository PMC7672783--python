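"""Per-cycle transition structure: EDSS progression, SPMS conversion and
death, with DMD efficacy applied as a relative risk on the worsening and
conversion probabilities.

Relative-risk scaling renormalizes each row through the stay-probability
only: improvement probabilities are never touched, so a drug slows
worsening without inventing extra recovery.  Mortality competes first
within a cycle: the background life-table probability (sex-blended,
multiplied by an EDSS-indexed hazard multiplier) is taken off the top
and the remaining mass follows the progression row.
"""

from __future__ import annotations

import numpy as np

from .parameters import ModelSettings, NaturalHistory
from .states import (
    DEAD_INDEX,
    EDSS_OF_INDEX,
    N_RRMS,
    N_SPMS,
    N_STATES,
    state_index,
    Course,
)


def build_progression_matrix(
    nat_hist: NaturalHistory,
    rr_progression: float,
    settings: ModelSettings,
    rr_in_spms: bool | None = None,
) -> np.ndarray:
    """20x20 annual transition matrix before mortality (rows sum to 1).

    Worsening (to higher EDSS, within course) and RRMS->SPMS conversion
    probabilities are multiplied by ``rr_progression``; the freed or extra
    mass is absorbed by the stay-probability.  RRMS->SPMS conversion lands
    at the same EDSS level shifted by ``settings.spms_entry_offset`` and
    clamped to the SPMS range 1..9.  Whether the relative risk also slows
    SPMS worsening while treatment continues is controlled by
    ``rr_in_spms`` (defaults to ``settings.rr_applies_in_spms``).
    """
    if rr_progression < 0:
        raise ValueError("rr_progression must be >= 0")
    if rr_in_spms is None:
        rr_in_spms = settings.rr_applies_in_spms

    P = np.zeros((N_STATES, N_STATES))

    for i in range(N_RRMS):
        row = nat_hist.rrms[i]
        improve = row[:i]                       # RRMS targets below i
        worsen = row[i + 1: N_RRMS] * rr_progression
        convert = row[N_RRMS] * rr_progression
        stay = 1.0 - improve.sum() - worsen.sum() - convert
        if stay < -1e-12 or worsen.max(initial=0.0) > 1 or convert > 1:
            raise ValueError(
                f"relative risk {rr_progression} pushes RRMS row {i} out of the simplex"
            )
        P[i, :i] = improve
        P[i, i] = max(stay, 0.0)
        P[i, i + 1: N_RRMS] = worsen
        target = min(9, max(1, i + settings.spms_entry_offset))
        P[i, state_index(Course.SPMS, target)] += convert

    rr_s = rr_progression if rr_in_spms else 1.0
    for i in range(N_SPMS):
        row = nat_hist.spms[i]
        worsen = row[i + 1:] * rr_s
        stay = 1.0 - worsen.sum()
        if stay < -1e-12 or worsen.max(initial=0.0) > 1:
            raise ValueError(
                f"relative risk {rr_progression} pushes SPMS row {i + 1} out of the simplex"
            )
        j = N_RRMS + i
        P[j, j] = max(stay, 0.0)
        P[j, j + 1: N_RRMS + N_SPMS] = worsen

    P[DEAD_INDEX, DEAD_INDEX] = 1.0
    return P


def death_probability(
    age: float,
    settings: ModelSettings,
    edss: int,
    nat_hist: NaturalHistory,
) -> float:
    """Annual death probability at a given age and EDSS level.

    Background mortality is the cohort sex blend of the life table
    (``proportion_male`` male + remainder female), multiplied by the EDSS
    hazard multiplier and capped at 1.  Identical for RRMS and SPMS at
    equal EDSS.
    """
    ages = nat_hist.life_table_age
    idx = np.searchsorted(ages, int(age))
    if idx >= len(ages) or ages[idx] != int(age):
        raise ValueError(f"age {age} outside life table range "
                         f"[{ages.min()}, {ages.max()}]")
    pm = settings.proportion_male
    background = pm * nat_hist.life_table_male[idx] + (1 - pm) * nat_hist.life_table_female[idx]
    return min(1.0, background * nat_hist.mortality_multiplier[int(edss)])


def death_vector(age: float, settings: ModelSettings, nat_hist: NaturalHistory) -> np.ndarray:
    """Death probability per state index at one age (0 for DEAD)."""
    return death_matrix(np.array([age]), settings, nat_hist)[0]


def death_matrix(
    ages: np.ndarray, settings: ModelSettings, nat_hist: NaturalHistory
) -> np.ndarray:
    """Death probabilities for a vector of ages: (len(ages), 20), with a
    zero column for the dead state.  Vectorized twin of
    :func:`death_probability`."""
    ages = np.asarray(ages, dtype=int)
    table = nat_hist.life_table_age
    idx = np.searchsorted(table, ages)
    if (idx >= len(table)).any() or (table[np.minimum(idx, len(table) - 1)] != ages).any():
        raise ValueError(f"ages {ages.min()}..{ages.max()} outside life table range "
                         f"[{table.min()}, {table.max()}]")
    pm = settings.proportion_male
    background = pm * nat_hist.life_table_male[idx] \
        + (1 - pm) * nat_hist.life_table_female[idx]
    mult = np.zeros(N_STATES)
    alive_edss = EDSS_OF_INDEX[:-1]
    mult[:-1] = nat_hist.mortality_multiplier[alive_edss]
    return np.minimum(1.0, background[:, None] * mult[None, :])


def build_transition_matrix(
    nat_hist: NaturalHistory,
    rr_progression: float,
    age: float,
    settings: ModelSettings,
    rr_in_spms: bool | None = None,
) -> np.ndarray:
    """Full annual transition matrix at one age: mortality first, then
    progression on the surviving mass.  Rows sum to 1; death is absorbing."""
    P = build_progression_matrix(nat_hist, rr_progression, settings, rr_in_spms)
    d = death_vector(age, settings, nat_hist)
    M = (1.0 - d)[:, None] * P
    M[:, DEAD_INDEX] += d
    return M


def relapse_outcomes(
    state_idx: int,
    rr_relapse: float,
    nonadherent: bool,
    settings: ModelSettings,
    nat_hist: NaturalHistory,
) -> tuple[float, float]:
    """Expected (total, severe) relapses per person-year in one state.

    On treatment the DMD's relapse relative risk applies; nonadherent
    patients lose part of the benefit, modelled as a multiplier on the
    total relapse rate (1.42) and on the severe fraction (1.075).
    """
    if state_idx == DEAD_INDEX:
        raise ValueError("relapse outcomes are undefined for the dead state")
    total = nat_hist.relapse_rate[state_idx] * rr_relapse
    frac = nat_hist.severe_fraction[state_idx]
    if nonadherent:
        total *= settings.nonadherent_relapse_multiplier
        frac = min(1.0, frac * settings.nonadherent_severe_multiplier)
    severe = total * frac
    return total, severe
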