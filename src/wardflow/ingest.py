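"""Cohort ingestion: raw records -> eligible 18-day trajectories.

Processing follows the study design for ward-level analysis of daily
nursing-demand scores:

* each (patient, admission date) pair is a separate case;
* days spent in another ward or a specialized (non-general) bed are
  relabelled OTHER, masking whatever score was recorded there;
* every day after the discharge record's entry date is labelled
  DISCHARGED (absorbing); the discharge day itself keeps its recorded
  state;
* a case is eligible iff its admission date falls in the fiscal window
  (April 1 to March 14), it occupies a general bed of the target ward on
  at least one of days 1..18, and no day 1..18 is missing a state (a day
  is missing iff it is neither OTHER nor DISCHARGED and has no score).

Quartiles in the per-day summary use linear interpolation between order
statistics (numpy's default); the convention is recorded in the summary
metadata because published tables rarely state theirs.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .states import (
    DISCHARGED,
    HORIZON,
    MAX_SCORE,
    MIN_SCORE,
    OTHER,
    CaseTrajectory,
    Cohort,
    State,
    StateKind,
    check_day,
    score,
    state_from_label,
)
from .synthetic import SPECIALIZED_BED_PREFIXES, RawRecord, fiscal_window

QUANTILE_METHOD = "linear"


class InvalidRecordError(ValueError):
    """A raw record violates the schema (e.g. score outside 0..12)."""


class AmbiguousRecordError(ValueError):
    """Conflicting duplicate rows exist for one patient-day."""


@dataclass(frozen=True)
class ProcessedCase:
    """A processed trajectory plus the metadata eligibility filtering needs."""

    trajectory: CaseTrajectory
    admission_date: date
    n_target_ward_days: int  # general-bed days in the target ward among days 1..18

    @property
    def case_id(self) -> str:
        return self.trajectory.case_id


@dataclass(frozen=True)
class Exclusion:
    case_id: str
    reason: str


def is_general_bed(bed: str) -> bool:
    return not bed.upper().startswith(SPECIALIZED_BED_PREFIXES)


def case_id_of(patient_id: str, admission_date: date) -> str:
    return f"{patient_id}@{admission_date.isoformat()}"


def process_case(records_for_case: Sequence[RawRecord], target_ward: str) -> ProcessedCase:
    """Turn one admission's raw rows into an 18-day trajectory.

    Days with no row and no applicable discharge label remain missing
    (``None``); eligibility filtering decides their fate.
    """
    if not records_for_case:
        raise ValueError("process_case requires at least one record")
    first = records_for_case[0]
    admission = first.admission_date
    pid = first.patient_id
    for r in records_for_case:
        if r.patient_id != pid or r.admission_date != admission:
            raise ValueError("records_for_case must belong to a single (patient, admission) case")

    by_day: dict[int, RawRecord] = {}
    discharge_day: Optional[int] = None
    for r in records_for_case:
        d = (r.date - admission).days + 1
        if d in by_day:
            prev = by_day[d]
            if (prev.ward, prev.bed, prev.score) != (r.ward, r.bed, r.score):
                raise AmbiguousRecordError(f"case {case_id_of(pid, admission)}: conflicting rows for day {d}")
            continue
        by_day[d] = r
        if r.score is not None and not (MIN_SCORE <= r.score <= MAX_SCORE):
            raise InvalidRecordError(
                f"case {case_id_of(pid, admission)}: score {r.score} outside {MIN_SCORE}..{MAX_SCORE} on day {d}"
            )
        if r.discharge_date is not None:
            discharge_day = (r.discharge_date - admission).days + 1

    states: list[Optional[State]] = []
    n_target_days = 0
    for d in range(1, HORIZON + 1):
        rec = by_day.get(d)
        if discharge_day is not None and d > discharge_day:
            states.append(DISCHARGED)
            continue
        if rec is None:
            states.append(None)  # missing: no row, not yet discharged
            continue
        if rec.ward != target_ward or not is_general_bed(rec.bed):
            states.append(OTHER)
            continue
        n_target_days += 1
        states.append(score(rec.score) if rec.score is not None else None)

    traj = CaseTrajectory(case_id_of(pid, admission), tuple(states))
    return ProcessedCase(trajectory=traj, admission_date=admission, n_target_ward_days=n_target_days)


REASON_WINDOW = "outside window"
REASON_NO_WARD_DAY = "no target ward day"
REASON_MISSING = "missing score"


def filter_eligible(
    cases: Iterable[ProcessedCase],
    target_ward: str,
    window: tuple[date, date],
) -> tuple[Cohort, list[Exclusion]]:
    """Apply the eligibility rules; returns the cohort and an exclusion log.

    Each input case lands either in the cohort or in the log, so
    ``len(input) == cohort.n_eligible + len(log)``.
    """
    start, end = window
    kept: list[CaseTrajectory] = []
    log: list[Exclusion] = []
    for case in cases:
        if not (start <= case.admission_date <= end):
            log.append(Exclusion(case.case_id, REASON_WINDOW))
        elif case.n_target_ward_days < 1:
            log.append(Exclusion(case.case_id, REASON_NO_WARD_DAY))
        elif not case.trajectory.is_complete:
            log.append(Exclusion(case.case_id, REASON_MISSING))
        else:
            kept.append(case.trajectory)
    fiscal_year = str(start.year)
    return Cohort(ward=target_ward, fiscal_year=fiscal_year, cases=tuple(kept)), log


def read_records_csv(path: str | Path) -> list[RawRecord]:
    """Read the patient-day CSV written by the synthetic generator."""
    frame = pd.read_csv(
        path,
        dtype={"patient_id": str, "ward": str, "bed": str},
        parse_dates=["date", "admission_date", "discharge_date"],
    )
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            RawRecord(
                date=row.date.date(),
                patient_id=row.patient_id,
                admission_date=row.admission_date.date(),
                discharge_date=None if pd.isna(row.discharge_date) else row.discharge_date.date(),
                ward=row.ward,
                bed=row.bed,
                score=None if pd.isna(row.score) else int(row.score),
            )
        )
    return records


def build_cohort(
    records: Sequence[RawRecord],
    target_ward: str,
    fiscal_year: int,
) -> tuple[Cohort, list[Exclusion]]:
    """Full pipeline: group records into cases, process, and filter."""
    groups: dict[tuple[str, date], list[RawRecord]] = {}
    for r in records:
        groups.setdefault((r.patient_id, r.admission_date), []).append(r)
    processed = [process_case(rows, target_ward) for rows in groups.values()]
    cohort, log = filter_eligible(processed, target_ward, fiscal_window(fiscal_year))
    return Cohort(ward=target_ward, fiscal_year=str(fiscal_year), cases=cohort.cases), log


def summarize_cohort(cohort: Cohort, days: Sequence[int]) -> pd.DataFrame:
    """Per-day inpatient counts and score quartiles.

    For each requested day: the number of cases still inpatient (SCORE
    and OTHER count, DISCHARGED does not), that number as a percentage
    of the eligible count (one decimal, half-up), and the median and
    Q1-Q3 of the scores among cases holding a SCORE state that day.
    """
    from .stats import round_half_up  # local import to avoid a cycle

    if cohort.n_eligible == 0:
        raise ValueError("summarize_cohort requires a non-empty cohort")
    rows = []
    for d in days:
        check_day(d)
        states = [c.state_on(d) for c in cohort]
        n_inpatient = sum(1 for s in states if s.kind is not StateKind.DISCHARGED)
        scores = np.array([s.score for s in states if s.is_score], dtype=float)
        if scores.size:
            q1, med, q3 = np.quantile(scores, [0.25, 0.5, 0.75], method=QUANTILE_METHOD)
        else:
            q1 = med = q3 = np.nan
        rows.append(
            {
                "day": d,
                "n_inpatient": n_inpatient,
                "pct_inpatient": round_half_up(100.0 * n_inpatient / cohort.n_eligible, 1),
                "score_median": med,
                "score_q1": q1,
                "score_q3": q3,
            }
        )
    frame = pd.DataFrame(rows)
    frame.attrs["quantile_method"] = QUANTILE_METHOD
    frame.attrs["n_eligible"] = cohort.n_eligible
    return frame


COHORT_COLUMNS = ["case_id", "ward", "fiscal_year"] + [f"day{d}" for d in range(1, HORIZON + 1)]


def write_cohort_csv(cohort: Cohort, path: str | Path) -> None:
    """One row per case: case_id, ward, fiscal_year, day1..day18 state labels."""
    rows = [
        [c.case_id, cohort.ward, cohort.fiscal_year] + [s.label for s in c.states]
        for c in cohort
    ]
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> Cohort:
    frame = pd.read_csv(path, dtype=str)
    cases = []
    for row in frame.itertuples(index=False):
        labels = [getattr(row, f"day{d}") for d in range(1, HORIZON + 1)]
        cases.append(CaseTrajectory(row.case_id, tuple(state_from_label(lab) for lab in labels)))
    ward = frame["ward"].iloc[0] if len(frame) else ""
    fy = frame["fiscal_year"].iloc[0] if len(frame) else ""
    return Cohort(ward=ward, fiscal_year=fy, cases=tuple(cases))


def write_exclusion_log(log: Sequence[Exclusion], path: str | Path) -> None:
    pd.DataFrame([(e.case_id, e.reason) for e in log], columns=["case_id", "reason"]).to_csv(path, index=False)
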