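"""Shared fixtures: compact trajectory builders and hypothesis strategies."""

from __future__ import annotations

import hypothesis.strategies as st
import pytest

import wardflow as wf


def make_traj(labels: str, case_id: str = "c") -> wf.CaseTrajectory:
    """Trajectory from space-separated state labels, padded by repeating
    the last label to the full 18-day horizon."""
    toks = labels.split()
    toks = toks + [toks[-1]] * (wf.HORIZON - len(toks))
    return wf.CaseTrajectory(case_id, tuple(wf.state_from_label(t) for t in toks))


def make_cohort(label_rows: list[str], ward: str = "ward", fiscal_year: str = "2017") -> wf.Cohort:
    cases = tuple(make_traj(row, case_id=f"c{i}") for i, row in enumerate(label_rows))
    return wf.Cohort(ward=ward, fiscal_year=fiscal_year, cases=cases)


# non-absorbing labels a patient can hold before discharge
_TRANSIENT_LABELS = [str(s) for s in range(13)] + ["other"]


@st.composite
def trajectories(draw, case_id: str = "c"):
    """A valid 18-day trajectory: transient states, then (optionally) an
    absorbing DISCHARGED tail starting no earlier than day 2."""
    discharge_day = draw(st.integers(min_value=2, max_value=wf.HORIZON + 1))
    n_active = min(discharge_day - 1, wf.HORIZON)
    labels = draw(
        st.lists(st.sampled_from(_TRANSIENT_LABELS), min_size=n_active, max_size=n_active)
    )
    labels += ["discharged"] * (wf.HORIZON - n_active)
    return wf.CaseTrajectory(case_id, tuple(wf.state_from_label(t) for t in labels))


@st.composite
def cohorts(draw, max_cases: int = 20):
    n = draw(st.integers(min_value=1, max_value=max_cases))
    cases = tuple(draw(trajectories(case_id=f"c{i}")) for i in range(n))
    return wf.Cohort(ward="w", fiscal_year="2017", cases=cases)


@pytest.fixture
def three_case_cohort() -> wf.Cohort:
    """Day-1 transitions: (0 -> 1) twice and (other -> 2) once."""
    return make_cohort(["0 1 1", "0 1 2", "other 2 2"])
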