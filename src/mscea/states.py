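"""Health-state space for the EDSS-based MS cohort model.

The model distinguishes 20 health states: 10 relapsing-remitting (RRMS)
states at EDSS 0-9, 9 secondary-progressive (SPMS) states at EDSS 1-9,
and an absorbing death state.  States are addressed by a fixed integer
index used throughout the engine:

    0..9   RRMS, EDSS 0..9
    10..18 SPMS, EDSS 1..9
    19     DEAD
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

N_STATES = 20
N_RRMS = 10
N_SPMS = 9
DEAD_INDEX = 19


class Course(enum.Enum):
    RRMS = "RRMS"
    SPMS = "SPMS"
    DEAD = "DEAD"


@dataclass(frozen=True)
class HealthState:
    """One of the 20 model health states."""

    course: Course
    edss: int | None  # None for DEAD

    def __post_init__(self) -> None:
        if self.course is Course.DEAD:
            if self.edss is not None:
                raise ValueError("DEAD state carries no EDSS level")
        elif self.course is Course.RRMS:
            if self.edss is None or not 0 <= self.edss <= 9:
                raise ValueError("RRMS EDSS must be an integer in 0..9")
        else:
            if self.edss is None or not 1 <= self.edss <= 9:
                raise ValueError("SPMS EDSS must be an integer in 1..9")

    @property
    def index(self) -> int:
        return state_index(self.course, self.edss)


def state_index(course: Course, edss: int | None) -> int:
    if course is Course.DEAD:
        return DEAD_INDEX
    if course is Course.RRMS:
        return int(edss)
    return N_RRMS + int(edss) - 1


def all_states() -> list[HealthState]:
    states = [HealthState(Course.RRMS, e) for e in range(10)]
    states += [HealthState(Course.SPMS, e) for e in range(1, 10)]
    states.append(HealthState(Course.DEAD, None))
    return states


# Per-index EDSS level (-1 for DEAD) and course arrays used by the engine.
EDSS_OF_INDEX = np.array(list(range(10)) + list(range(1, 10)) + [-1])
IS_RRMS = np.array([True] * N_RRMS + [False] * N_SPMS + [False])
IS_SPMS = np.array([False] * N_RRMS + [True] * N_SPMS + [False])
IS_ALIVE = np.array([True] * (N_STATES - 1) + [False])


def alive_above_edss(level: int) -> np.ndarray:
    """Boolean mask over state indices: alive with EDSS strictly above ``level``."""
    return IS_ALIVE & (EDSS_OF_INDEX > level)
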