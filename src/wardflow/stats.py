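"""Day-indexed transition counts, proportions, band paths, and diversity.

For a cohort of N_e eligible cases and a day pair d -> d+1 (d in 1..17),
the count matrix M(d) holds in cell (i, j) the number of cases in state
i on day d and state j on day d+1; the proportion matrix P(d) = M(d)/N_e
is the share of the whole cohort following that single-step path.  P is
a joint distribution over the 225 (i, j) cells — conditional (row-wise)
probabilities live in :mod:`wardflow.markov`, and conflating the two is
the classic mistake with these statistics.

Band-path summaries aggregate M(d) into five named categories (low->low,
medium->medium, high->high, ultra-high->ultra-high, and score 0 ->
discharged) plus a residual; the "0 -> discharged" category requires the
source state to be exactly score 0, not any low score.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .states import (
    BandLabel,
    DISCHARGED,
    N_STATES,
    STATES,
    CaseTrajectory,
    Cohort,
    State,
    check_day,
    classify_band,
    score,
    state_order,
)

N_POSSIBLE_TRANSITIONS: int = N_STATES * N_STATES  # 15^2 = 225

#: The five named band paths, in reporting order.
BAND_CATEGORIES = (
    "low-low",
    "medium-medium",
    "high-high",
    "ultra_high-ultra_high",
    "zero-discharged",
)

_BAND_PAIRS = {
    "low-low": (BandLabel.LOW, BandLabel.LOW),
    "medium-medium": (BandLabel.MEDIUM, BandLabel.MEDIUM),
    "high-high": (BandLabel.HIGH, BandLabel.HIGH),
    "ultra_high-ultra_high": (BandLabel.ULTRA_HIGH, BandLabel.ULTRA_HIGH),
}


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero (the convention behind printed tables)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent_str(count: int, total: int, decimals: int = 1) -> str:
    """Render count/total as a percentage string, half-up (e.g. ``'38.7%'``).

    The division is exact (rational) before rounding, so boundary cases
    are not at the mercy of binary floats.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    frac = Fraction(count, total) * 100
    q = Decimal(1).scaleb(-decimals)
    value = (Decimal(frac.numerator) / Decimal(frac.denominator)).quantize(q, rounding=ROUND_HALF_UP)
    return f"{value}%"


def indicator(traj: CaseTrajectory, d: int, i: State) -> int:
    """1 iff the case is in state ``i`` on day ``d`` (1..18), else 0."""
    check_day(d)
    return 1 if traj.state_on(d) == i else 0


@dataclass(frozen=True)
class TransitionCounts:
    """M(d): 15x15 integer counts for the day pair d -> d+1."""

    day: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        check_day(self.day, transition=True)
        c = np.asarray(self.counts)
        if c.shape != (N_STATES, N_STATES):
            raise ValueError(f"counts must be {N_STATES}x{N_STATES}")
        if c.min() < 0 or not np.issubdtype(c.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class TransitionProportions:
    """P(d) = M(d) / N_e: joint single-step path shares of the whole cohort."""

    day: int
    proportions: np.ndarray
    n_eligible: int


def compute_transition_counts(cohort: Cohort, d: int) -> TransitionCounts:
    """Count cases in state i on day d and state j on day d+1."""
    check_day(d, transition=True)
    counts = np.zeros((N_STATES, N_STATES), dtype=np.int64)
    for case in cohort:
        i = state_order(case.state_on(d))
        j = state_order(case.state_on(d + 1))
        counts[i, j] += 1
    return TransitionCounts(day=d, counts=counts)


def compute_transition_proportions(counts: TransitionCounts, n_eligible: int) -> TransitionProportions:
    """Elementwise M(d)/N_e."""
    if n_eligible < 1:
        raise ValueError("n_eligible must be >= 1")
    if counts.total > n_eligible:
        raise ValueError("matrix total exceeds n_eligible")
    return TransitionProportions(
        day=counts.day,
        proportions=counts.counts / n_eligible,
        n_eligible=n_eligible,
    )


@dataclass(frozen=True)
class BandTransitionSummary:
    """Named band-path counts for one day pair, plus the residual.

    A case discharged on both days sits in the residual: the named
    categories deliberately exclude discharged -> discharged, which is
    why published category shares do not sum to 100%.
    """

    day: int
    n_eligible: int
    counts: dict[str, int]
    residual: int

    def proportion(self, category: str) -> float:
        return self.counts[category] / self.n_eligible

    def percent(self, category: str) -> str:
        return percent_str(self.counts[category], self.n_eligible)

    @property
    def top2_categories(self) -> tuple[str, str]:
        """The two largest named categories (ties broken by reporting order)."""
        ranked = sorted(BAND_CATEGORIES, key=lambda c: -self.counts[c])
        return ranked[0], ranked[1]

    @property
    def top2_count(self) -> int:
        a, b = self.top2_categories
        return self.counts[a] + self.counts[b]

    @property
    def top2_share(self) -> float:
        return self.top2_count / self.n_eligible


def _categorize(src: State, tgt: State) -> Optional[str]:
    if src == score(0) and tgt == DISCHARGED:
        return "zero-discharged"
    pair = (classify_band(src), classify_band(tgt))
    for name, want in _BAND_PAIRS.items():
        if pair == want:
            return name
    return None


def band_transition_summary(cohort: Cohort, d: int) -> BandTransitionSummary:
    """Aggregate M(d) into the five named band paths and a residual."""
    tc = compute_transition_counts(cohort, d)
    return band_summary_from_counts(tc, cohort.n_eligible)


def band_summary_from_counts(tc: TransitionCounts, n_eligible: int) -> BandTransitionSummary:
    """Band-path summary directly from a count matrix (published tables count too)."""
    if tc.total > n_eligible:
        raise ValueError("matrix total exceeds n_eligible")
    counts = {name: 0 for name in BAND_CATEGORIES}
    residual = 0
    for i, src in enumerate(STATES):
        for j, tgt in enumerate(STATES):
            c = int(tc.counts[i, j])
            if c == 0:
                continue
            cat = _categorize(src, tgt)
            if cat is None:
                residual += c
            else:
                counts[cat] += c
    residual += n_eligible - tc.total  # cases not in the matrix (none, normally)
    return BandTransitionSummary(day=tc.day, n_eligible=n_eligible, counts=counts, residual=residual)


@dataclass(frozen=True)
class DiversitySummary:
    """How dispersed one day pair's transitions are across the 225 cells."""

    day: int
    n_observed_transitions: int
    n_possible: int
    score_range: Optional[tuple[int, int]]
    top2_share: float


def transition_diversity(cohort: Cohort, d: int) -> DiversitySummary:
    """Distinct occupied cells of M(d), out of the 225 possible, plus
    the occupied score range on days d and d+1 and the top-2 band-path
    concentration."""
    tc = compute_transition_counts(cohort, d)
    band = band_summary_from_counts(tc, cohort.n_eligible)
    occupied_scores = [
        s.score
        for case in cohort
        for s in (case.state_on(d), case.state_on(d + 1))
        if s.is_score
    ]
    score_range = (min(occupied_scores), max(occupied_scores)) if occupied_scores else None
    return DiversitySummary(
        day=d,
        n_observed_transitions=int(np.count_nonzero(tc.counts)),
        n_possible=N_POSSIBLE_TRANSITIONS,
        score_range=score_range,
        top2_share=band.top2_share,
    )


def counts_to_frame(tc: TransitionCounts, n_eligible: Optional[int] = None) -> pd.DataFrame:
    """Long-format table (day, source_state, target_state, count[, proportion]),
    occupied cells only."""
    rows = []
    for i, src in enumerate(STATES):
        for j, tgt in enumerate(STATES):
            c = int(tc.counts[i, j])
            if c == 0:
                continue
            row = {"day": tc.day, "source_state": src.label, "target_state": tgt.label, "count": c}
            if n_eligible is not None:
                row["proportion"] = c / n_eligible
            rows.append(row)
    return pd.DataFrame(rows)


def all_transition_counts(cohort: Cohort) -> list[TransitionCounts]:
    """M(d) for every day pair d = 1..17."""
    from .states import TRANSITION_DAYS

    return [compute_transition_counts(cohort, d) for d in TRANSITION_DAYS]
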