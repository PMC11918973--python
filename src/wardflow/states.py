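"""Shared domain types: daily states, score bands, trajectories, cohorts.

The daily nursing-demand state of one admission ("case") is one of 15
labels: an integer care-burden score 0..12 (higher = more nursing care),
``OTHER`` (the patient spent the day in another ward or a specialized
bed, so the target ward recorded no score), or ``DISCHARGED`` (every day
after the discharge record's entry date).  The fixed display/matrix
order is score 12 down to score 0, then OTHER, then DISCHARGED; all
transition matrices in this package are indexed in that order.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional

#: Analysis horizon: day 1 is the admission day, day 18 the last analysed day.
HORIZON: int = 18

#: Day pairs d -> d+1 used for transitions.
TRANSITION_DAYS: range = range(1, HORIZON)

#: Number of distinct daily states (13 scores + OTHER + DISCHARGED).
N_STATES: int = 15

MIN_SCORE: int = 0
MAX_SCORE: int = 12


class StateKind(Enum):
    SCORE = "score"
    OTHER = "other"
    DISCHARGED = "discharged"


@dataclass(frozen=True)
class State:
    """One of the 15 daily labels.

    ``score`` is present iff ``kind`` is SCORE.
    """

    kind: StateKind
    score: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind is StateKind.SCORE:
            if self.score is None or not (MIN_SCORE <= self.score <= MAX_SCORE):
                raise ValueError(f"score must be in {MIN_SCORE}..{MAX_SCORE}, got {self.score}")
        elif self.score is not None:
            raise ValueError(f"{self.kind.name} state carries no score")

    @property
    def is_score(self) -> bool:
        return self.kind is StateKind.SCORE

    @property
    def label(self) -> str:
        """Serialized form: ``"0"``..``"12"``, ``"other"``, ``"discharged"``."""
        if self.kind is StateKind.SCORE:
            return str(self.score)
        return self.kind.value

    def __repr__(self) -> str:  # compact, label-based
        return f"State({self.label!r})"


def score(value: int) -> State:
    """The SCORE state with the given 0..12 value."""
    return State(StateKind.SCORE, value)


OTHER: State = State(StateKind.OTHER)
DISCHARGED: State = State(StateKind.DISCHARGED)

#: All 15 states in fixed display order: 12, 11, ..., 0, OTHER, DISCHARGED.
STATES: tuple[State, ...] = tuple(
    [score(s) for s in range(MAX_SCORE, MIN_SCORE - 1, -1)] + [OTHER, DISCHARGED]
)

_STATE_RANK: dict[State, int] = {s: i for i, s in enumerate(STATES)}
_LABEL_TO_STATE: dict[str, State] = {s.label: s for s in STATES}

OTHER_INDEX: int = _STATE_RANK[OTHER]
DISCHARGED_INDEX: int = _STATE_RANK[DISCHARGED]


def state_order(s: State) -> int:
    """Fixed display rank: score 12 -> 0, ..., score 0 -> 12, OTHER -> 13, DISCHARGED -> 14.

    Bijective over the 15 states; also the row/column index of every
    transition matrix in this package.
    """
    return _STATE_RANK[s]


def state_from_label(label: str) -> State:
    """Inverse of :attr:`State.label`; raises ``KeyError`` on unknown labels."""
    return _LABEL_TO_STATE[label]


def score_index(value: int) -> int:
    """Matrix index of the SCORE state with the given value."""
    return MAX_SCORE - value


class BandLabel(Enum):
    """Score band used for trajectory description.

    Scores 0-2 are LOW, 3-5 MEDIUM, 6-9 HIGH, 10-12 ULTRA_HIGH; the two
    non-score states keep their own labels.
    """

    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"
    ULTRA_HIGH = "ultra_high"
    OTHER = "other"
    DISCHARGED = "discharged"


def classify_band(s: State) -> BandLabel:
    """Band of a daily state; total over the 15 states."""
    if s.kind is StateKind.OTHER:
        return BandLabel.OTHER
    if s.kind is StateKind.DISCHARGED:
        return BandLabel.DISCHARGED
    v = s.score
    if v <= 2:
        return BandLabel.LOW
    if v <= 5:
        return BandLabel.MEDIUM
    if v <= 9:
        return BandLabel.HIGH
    return BandLabel.ULTRA_HIGH


def check_day(d: int, *, transition: bool = False) -> int:
    """Validate a 1-based day index (occupancy 1..18, transitions 1..17)."""
    hi = HORIZON - 1 if transition else HORIZON
    if not 1 <= d <= hi:
        raise ValueError(f"day must be in 1..{hi}, got {d}")
    return d


@dataclass(frozen=True)
class CaseTrajectory:
    """One admission's processed sequence of 18 daily states.

    ``states[d-1]`` is the state on day ``d``.  A ``None`` entry marks a
    missing daily score (the case is then ineligible and is dropped by
    eligibility filtering; cohorts contain complete trajectories only).
    DISCHARGED is absorbing.
    """

    case_id: str
    states: tuple[Optional[State], ...]

    def __post_init__(self) -> None:
        if len(self.states) != HORIZON:
            raise ValueError(f"trajectory must have exactly {HORIZON} days, got {len(self.states)}")
        discharged = False
        for d, s in enumerate(self.states, start=1):
            if discharged and s is not DISCHARGED:
                raise ValueError(f"case {self.case_id}: state on day {d} after discharge is not DISCHARGED")
            if s is DISCHARGED:
                discharged = True

    @property
    def is_complete(self) -> bool:
        return all(s is not None for s in self.states)

    def state_on(self, d: int) -> Optional[State]:
        check_day(d)
        return self.states[d - 1]


@dataclass(frozen=True)
class Cohort:
    """Eligible cases for one (ward, fiscal year); all trajectories complete."""

    ward: str
    fiscal_year: str
    cases: tuple[CaseTrajectory, ...]

    def __post_init__(self) -> None:
        for c in self.cases:
            if not c.is_complete:
                raise ValueError(f"cohort contains incomplete case {c.case_id}")

    @property
    def n_eligible(self) -> int:
        return len(self.cases)

    def __len__(self) -> int:
        return len(self.cases)

    def __iter__(self):
        return iter(self.cases)


def trajectory_from_labels(case_id: str, labels: Iterable[str]) -> CaseTrajectory:
    """Build a trajectory from 18 serialized state labels ('' = missing)."""
    states = tuple(None if lab == "" else state_from_label(lab) for lab in labels)
    return CaseTrajectory(case_id, states)
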