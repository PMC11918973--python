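"""Synthetic patient-day record generator.

Real daily nursing-demand records cannot be redistributed, so this
module emulates their statistical structure: a 13-level ordinal daily
score per admission over an 18-day horizon, transfers to other wards or
specialized beds, discharge as an absorbing terminal event, ward- and
day-specific transition behaviour, and occasional missing scores.

Three ward archetypes are provided, each a fully specified
day-inhomogeneous Markov chain over the 15 daily states:

``orthopaedic``
    post-operative surge — a large share of patients jumps from low
    scores (0-2) into high scores (6-9) at the day 2 -> 3 transition,
    then declines after day 4;
``cardiology``
    early discharge — a substantial fraction of the cohort reaches
    DISCHARGED by day 4, with a narrow, low-score state range;
``neurosurgery``
    trajectory diversity — transitions are dispersed over many score
    levels every day, giving strictly higher per-day transition entropy
    than the other two archetypes.

Kernels are constructed parametrically (a local random-walk component
around the current score, an archetype-specific band-shift component,
and per-day discharge and transfer hazards) rather than entered as raw
17x225 tables, so every number is auditable from the construction code.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .states import (
    DISCHARGED_INDEX,
    HORIZON,
    MAX_SCORE,
    N_STATES,
    OTHER_INDEX,
    score_index,
)

ARCHETYPE_NAMES = ("orthopaedic", "neurosurgery", "cardiology")

#: Bed labels with these prefixes are specialized (non-general) beds.
SPECIALIZED_BED_PREFIXES = ("ICU", "CCU", "HCU")

RECORD_COLUMNS = ["date", "patient_id", "admission_date", "discharge_date", "ward", "bed", "score"]


@dataclass(frozen=True)
class RawRecord:
    """One patient-day row as the hospital information system would store it."""

    date: date
    patient_id: str
    admission_date: date
    discharge_date: Optional[date]
    ward: str
    bed: str
    score: Optional[int]

    def __post_init__(self) -> None:
        if self.date < self.admission_date:
            raise ValueError("record date precedes admission date")
        if self.discharge_date is not None and self.discharge_date < self.admission_date:
            raise ValueError("discharge date precedes admission date")


@dataclass(frozen=True)
class WardArchetype:
    """A fully specified generating process for one ward.

    ``kernels[d-1]`` is the row-stochastic 15x15 conditional matrix for
    the day d -> d+1 transition, indexed in the fixed state order
    (score 12..0, OTHER, DISCHARGED).
    """

    name: str
    initial_dist: np.ndarray
    kernels: np.ndarray
    missing_rate: float = 0.0
    other_ward_rate: float = 0.02

    def __post_init__(self) -> None:
        init = np.asarray(self.initial_dist, dtype=float)
        ker = np.asarray(self.kernels, dtype=float)
        if init.shape != (N_STATES,):
            raise ValueError(f"initial_dist must have shape ({N_STATES},)")
        if ker.shape != (HORIZON - 1, N_STATES, N_STATES):
            raise ValueError(f"kernels must have shape ({HORIZON - 1}, {N_STATES}, {N_STATES})")
        if abs(init.sum() - 1.0) > 1e-9 or init.min() < 0:
            raise ValueError("initial_dist must be a probability vector")
        if init[DISCHARGED_INDEX] != 0.0:
            raise ValueError("initial mass on DISCHARGED must be 0")
        if np.abs(ker.sum(axis=2) - 1.0).max() > 1e-9 or ker.min() < 0:
            raise ValueError("every kernel row must be a probability vector")
        unit = np.zeros(N_STATES)
        unit[DISCHARGED_INDEX] = 1.0
        if not np.array_equal(ker[:, DISCHARGED_INDEX, :], np.tile(unit, (HORIZON - 1, 1))):
            raise ValueError("DISCHARGED row must be the unit vector on DISCHARGED")
        object.__setattr__(self, "initial_dist", init)
        object.__setattr__(self, "kernels", ker)


def _score_support(weights_by_score: dict[int, float]) -> np.ndarray:
    """Length-15 vector (fixed state order) from a {score: weight} map, normalized."""
    v = np.zeros(N_STATES)
    for s, w in weights_by_score.items():
        v[score_index(s)] = w
    total = v.sum()
    if total <= 0:
        raise ValueError("empty score support")
    return v / total


def _local_walk(center: float, sd: float) -> np.ndarray:
    """Discretized normal over scores 0..12 centred at ``center`` (length-15 vector)."""
    scores = np.arange(MAX_SCORE + 1, dtype=float)
    w = np.exp(-0.5 * ((scores - center) / sd) ** 2)
    return _score_support({s: w[s] for s in range(MAX_SCORE + 1) if w[s] > 1e-12})


def _row(
    score_part: np.ndarray,
    discharge_hazard: float,
    other_hazard: float,
) -> np.ndarray:
    row = (1.0 - discharge_hazard - other_hazard) * score_part
    row[DISCHARGED_INDEX] += discharge_hazard
    row[OTHER_INDEX] += other_hazard
    return row


def _other_row(return_dist: np.ndarray, stay: float, discharge_hazard: float) -> np.ndarray:
    row = (1.0 - stay - discharge_hazard) * return_dist
    row[OTHER_INDEX] += stay
    row[DISCHARGED_INDEX] += discharge_hazard
    return row


def _uniform_scores() -> np.ndarray:
    return _score_support({s: 1.0 for s in range(MAX_SCORE + 1)})


def _build_kernels(name: str) -> tuple[np.ndarray, np.ndarray, float]:
    """Return (initial_dist, kernels, other_ward_rate) for an archetype name."""
    kernels = np.zeros((HORIZON - 1, N_STATES, N_STATES))
    unit_dis = np.zeros(N_STATES)
    unit_dis[DISCHARGED_INDEX] = 1.0

    if name == "orthopaedic":
        other_rate = 0.015
        init = _score_support({0: 0.40, 1: 0.38, 2: 0.12, 3: 0.04, 4: 0.02, 5: 0.01, 6: 0.01}) * 0.98
        init[OTHER_INDEX] = 0.02
        surge = _score_support({6: 0.12, 7: 0.58, 8: 0.22, 9: 0.08})
        for d in range(1, HORIZON):
            for s in range(MAX_SCORE + 1):
                if d == 2 and s <= 2:
                    # post-operative surge: low scores jump into the high band
                    part = 0.55 * _local_walk(s, 0.45) + 0.45 * surge
                    h, o = 0.005, other_rate
                elif d == 3 and 6 <= s <= 9:
                    part = _local_walk(s - 0.3, 0.6)
                    h, o = 0.01, other_rate
                elif d == 4 and 6 <= s <= 9:
                    # decline after the surge: high scores fall toward 4-5
                    part = _local_walk(s - 2.0, 0.8)
                    h, o = 0.01, other_rate
                else:
                    part = _local_walk(s, 0.5)
                    base = 0.01 if d < 5 else min(0.02 + 0.012 * (d - 5), 0.09)
                    h = base if s <= 2 else 0.3 * base
                    o = other_rate
                kernels[d - 1, score_index(s)] = _row(part, h, o)
            kernels[d - 1, OTHER_INDEX] = _other_row(
                _score_support({1: 0.3, 2: 0.3, 3: 0.2, 4: 0.2}), stay=0.35, discharge_hazard=0.03
            )
            kernels[d - 1, DISCHARGED_INDEX] = unit_dis
    elif name == "cardiology":
        other_rate = 0.02
        init = _score_support({0: 0.62, 1: 0.24, 2: 0.07, 3: 0.02, 4: 0.02, 10: 0.005, 11: 0.005}) * 0.98
        init[OTHER_INDEX] = 0.02
        for d in range(1, HORIZON):
            for s in range(MAX_SCORE + 1):
                if d == 1 and s == 0:
                    # slight ascent: about half of the score-0 mass moves to 1-2
                    part = 0.55 * _local_walk(0, 0.35) + 0.45 * _score_support({1: 0.7, 2: 0.3})
                    h, o = 0.01, other_rate
                elif d == 2 and 1 <= s <= 2:
                    # descent back to 0
                    part = 0.35 * _local_walk(s, 0.35) + 0.65 * _score_support({0: 1.0})
                    h, o = 0.02, other_rate
                else:
                    part = _local_walk(s, 0.4)
                    if d == 3:
                        h = 0.33 if s <= 2 else 0.08
                    elif d == 5:
                        h = 0.14 if s <= 2 else 0.05
                    else:
                        h = 0.05 if s <= 2 else 0.02
                    if s >= 10:  # a few patients stay at very high scores throughout
                        part = _local_walk(s, 0.3)
                        h = 0.01
                    o = other_rate
                kernels[d - 1, score_index(s)] = _row(part, h, o)
            kernels[d - 1, OTHER_INDEX] = _other_row(
                _score_support({4: 0.3, 5: 0.3, 6: 0.25, 7: 0.15}), stay=0.30, discharge_hazard=0.05
            )
            kernels[d - 1, DISCHARGED_INDEX] = unit_dis
    elif name == "neurosurgery":
        other_rate = 0.035
        init = (
            _score_support(
                {0: 0.33, 1: 0.17, 2: 0.10, 3: 0.08, 4: 0.07, 5: 0.06, 6: 0.05, 7: 0.04,
                 8: 0.03, 9: 0.025, 10: 0.02, 11: 0.01, 12: 0.005}
            )
            * 0.96
        )
        init[OTHER_INDEX] = 0.04
        uniform = _uniform_scores()
        for d in range(1, HORIZON):
            for s in range(MAX_SCORE + 1):
                # diffuse dynamics: wide local walk plus a uniform exploration
                # component keeps every day's transitions dispersed
                part = 0.96 * _local_walk(s, 1.1) + 0.04 * uniform
                h = 0.035 if s <= 2 else 0.025
                kernels[d - 1, score_index(s)] = _row(part, h, other_rate)
            kernels[d - 1, OTHER_INDEX] = _other_row(
                0.6 * _score_support({9: 0.3, 10: 0.3, 11: 0.25, 12: 0.15}) + 0.4 * uniform,
                stay=0.30,
                discharge_hazard=0.04,
            )
            kernels[d - 1, DISCHARGED_INDEX] = unit_dis
    else:
        raise ValueError(f"unknown archetype {name!r}; expected one of {ARCHETYPE_NAMES}")

    return init, kernels, other_rate


def make_archetype(name: str, seed: int, *, missing_rate: float = 0.0, jitter: float = 0.015) -> WardArchetype:
    """Build a ward archetype; ``seed`` applies a small reproducible jitter.

    The jitter perturbs kernel rows multiplicatively (log-normal, scale
    ``jitter``) and renormalizes, emulating fiscal-year-to-year variation
    around the ward's inherent dynamics without disturbing the archetype's
    headline behaviours.  Structural zeros and the DISCHARGED row are
    preserved exactly.
    """
    init, kernels, other_rate = _build_kernels(name)
    rng = np.random.default_rng(seed)
    if jitter > 0:
        noise = np.exp(jitter * rng.standard_normal(kernels.shape))
        kernels = kernels * noise
        kernels[:, DISCHARGED_INDEX, :] = 0.0
        kernels[:, DISCHARGED_INDEX, DISCHARGED_INDEX] = 1.0
        kernels = kernels / kernels.sum(axis=2, keepdims=True)
        init_noise = np.exp(jitter * rng.standard_normal(init.shape))
        init = init * init_noise
        init[DISCHARGED_INDEX] = 0.0
        init = init / init.sum()
    return WardArchetype(name=name, initial_dist=init, kernels=kernels, missing_rate=missing_rate, other_ward_rate=other_rate)


def marginal_occupancy(archetype: WardArchetype, d: int) -> np.ndarray:
    """State distribution on day ``d`` implied by the archetype (1 <= d <= 18)."""
    if not 1 <= d <= HORIZON:
        raise ValueError(f"day must be in 1..{HORIZON}")
    p = archetype.initial_dist.copy()
    for k in range(d - 1):
        p = p @ archetype.kernels[k]
    return p


def transition_entropy(archetype: WardArchetype, d: int) -> float:
    """Occupancy-weighted mean Shannon entropy (nats) of the day-d kernel rows.

    Weights are the day-d marginal occupancy restricted to non-DISCHARGED
    states, so wards that discharge early are not scored as "simple"
    merely because the absorbed mass has a deterministic row.
    """
    occ = marginal_occupancy(archetype, d)
    w = occ.copy()
    w[DISCHARGED_INDEX] = 0.0
    w = w / w.sum()
    rows = archetype.kernels[d - 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(rows > 0, np.log(rows), 0.0)
    row_entropy = -(rows * logp).sum(axis=1)
    return float(w @ row_entropy)


def sample_trajectories(archetype: WardArchetype, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample ``n`` latent 18-day state-index paths from the archetype chain."""
    if n < 1:
        raise ValueError("n must be >= 1")
    paths = np.empty((n, HORIZON), dtype=np.intp)
    paths[:, 0] = rng.choice(N_STATES, size=n, p=archetype.initial_dist)
    for d in range(1, HORIZON):
        kernel = archetype.kernels[d - 1]
        cur = paths[:, d - 1]
        nxt = np.empty(n, dtype=np.intp)
        for i in np.unique(cur):
            mask = cur == i
            nxt[mask] = rng.choice(N_STATES, size=int(mask.sum()), p=kernel[i])
        paths[:, d] = nxt
    return paths


def fiscal_window(fiscal_year: int) -> tuple[date, date]:
    """Admission window of a fiscal year: April 1 to March 14 of the next year.

    The window stops on March 14 so that the full 18-day horizon ends by
    March 31, keeping every analysed day inside the fiscal year.
    """
    return date(fiscal_year, 4, 1), date(fiscal_year + 1, 3, 14)


def generate_cohort(
    archetype: WardArchetype,
    n: int,
    seed: int,
    *,
    ward: Optional[str] = None,
    fiscal_year: int = 2017,
    other_ward_label: str = "OtherWard",
) -> list[RawRecord]:
    """Generate raw patient-day records for ``n`` admissions.

    One record is emitted per patient-day from admission up to day 18 or
    the last day before discharge.  Days spent outside the target ward
    carry either another ward's label or a specialized-bed label in the
    target ward (both are masked to OTHER downstream).  In-ward scores
    are dropped with probability ``archetype.missing_rate`` to exercise
    the missing-data exclusion rule.  Identical inputs yield identical
    record lists.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ward = ward or archetype.name
    rng = np.random.default_rng(seed)
    paths = sample_trajectories(archetype, n, rng)
    win_start, win_end = fiscal_window(fiscal_year)
    n_days = (win_end - win_start).days + 1
    admission_offsets = rng.integers(0, n_days, size=n)

    records: list[RawRecord] = []
    for p in range(n):
        admission = win_start + timedelta(days=int(admission_offsets[p]))
        pid = f"P{p:05d}"
        path = paths[p]
        discharged_days = np.nonzero(path == DISCHARGED_INDEX)[0]
        last_day = int(discharged_days[0]) if discharged_days.size else HORIZON  # 1-based day before discharge
        discharge_date = admission + timedelta(days=last_day - 1) if discharged_days.size else None
        general_bed = f"G{int(rng.integers(1, 41)):02d}"
        for d in range(1, last_day + 1):
            state = path[d - 1]
            day_date = admission + timedelta(days=d - 1)
            if state == OTHER_INDEX:
                if rng.random() < 0.5:
                    rec_ward, rec_bed = other_ward_label, f"G{int(rng.integers(1, 41)):02d}"
                else:
                    rec_ward, rec_bed = ward, f"CCU{int(rng.integers(1, 5))}"
                rec_score: Optional[int] = int(rng.integers(0, MAX_SCORE + 1))
            else:
                rec_ward, rec_bed = ward, general_bed
                rec_score = MAX_SCORE - int(state)  # invert matrix index back to score
                if archetype.missing_rate > 0 and rng.random() < archetype.missing_rate:
                    rec_score = None
            records.append(
                RawRecord(
                    date=day_date,
                    patient_id=pid,
                    admission_date=admission,
                    discharge_date=discharge_date,
                    ward=rec_ward,
                    bed=rec_bed,
                    score=rec_score,
                )
            )
    return records


def records_to_frame(records: Sequence[RawRecord]) -> pd.DataFrame:
    """Records as a DataFrame with the canonical column order."""
    return pd.DataFrame(
        [dataclasses.asdict(r) for r in records],
        columns=RECORD_COLUMNS,
    )


def write_records_csv(records: Sequence[RawRecord], path: str | Path) -> None:
    """Write records as CSV (ISO-8601 dates, empty string for absent fields)."""
    frame = records_to_frame(records)
    frame["score"] = frame["score"].astype("Int64")
    frame.to_csv(path, index=False, date_format="%Y-%m-%d")


def generate_from_config(config: dict | str | Path) -> list[RawRecord]:
    """Generate records from a config mapping or YAML/JSON file.

    Keys: ``archetype`` (name), ``n``, ``seed``; optional ``missing_rate``,
    ``fiscal_year``, ``ward``, ``jitter``.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    arch = make_archetype(
        config["archetype"],
        seed=int(config["seed"]),
        missing_rate=float(config.get("missing_rate", 0.0)),
        jitter=float(config.get("jitter", 0.015)),
    )
    return generate_cohort(
        arch,
        n=int(config["n"]),
        seed=int(config["seed"]),
        ward=config.get("ward"),
        fiscal_year=int(config.get("fiscal_year", 2017)),
    )
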