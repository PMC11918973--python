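"""Day-inhomogeneous absorbing Markov model of ward nursing demand.

The empirical transition structure of a cohort is turned into a
generative model: a day-1 initial distribution over the 15 daily states
plus 17 conditional (row-stochastic) matrices Q(d), one per day pair,
with Q(d)[i, j] = P(state j on day d+1 | state i on day d).  Rows are
estimated by normalizing the count matrices M(d); rows never observed
are flagged rather than imputed (an optional Laplace pseudocount is
available for users who want smoothing).  DISCHARGED is absorbing.

The model supports forward forecasting of day-d marginals, simulation of
complete synthetic cohorts, and a bounded dissimilarity between two
fitted kernels (support-weighted mean total-variation distance between
conditional rows) for cross-ward / cross-year comparison.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .states import (
    DISCHARGED_INDEX,
    HORIZON,
    N_STATES,
    CaseTrajectory,
    Cohort,
    STATES,
    check_day,
    state_order,
)
from .stats import compute_transition_counts


@dataclass(frozen=True)
class DemandKernel:
    """Estimated day-indexed conditional transition model.

    ``kernels[d-1]`` is Q(d); ``support_counts[d-1, i]`` is the number of
    cases whose day-d state was i (the denominator behind row i), with 0
    marking an unobserved row whose probabilities are meaningless.
    """

    initial_dist: np.ndarray
    kernels: np.ndarray
    support_counts: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        init = np.asarray(self.initial_dist, dtype=float)
        ker = np.asarray(self.kernels, dtype=float)
        sup = np.asarray(self.support_counts)
        if init.shape != (N_STATES,) or ker.shape != (HORIZON - 1, N_STATES, N_STATES):
            raise ValueError("kernel dimensions do not match the 15-state, 18-day model")
        if sup.shape != (HORIZON - 1, N_STATES):
            raise ValueError("support_counts must be (17, 15)")
        if abs(init.sum() - 1.0) > 1e-9:
            raise ValueError("initial_dist must sum to 1")
        observed = sup > 0
        row_sums = ker.sum(axis=2)
        if np.abs(row_sums[observed] - 1.0).max(initial=0.0) > 1e-9:
            raise ValueError("observed rows must sum to 1")
        object.__setattr__(self, "initial_dist", init)
        object.__setattr__(self, "kernels", ker)
        object.__setattr__(self, "support_counts", sup)

    def observed_rows(self, d: int) -> np.ndarray:
        """Boolean mask of states with at least one observed day-d departure."""
        check_day(d, transition=True)
        return self.support_counts[d - 1] > 0

    def effective_kernel(self, d: int) -> np.ndarray:
        """Q(d) with unobserved rows replaced by stay-in-place (identity) rows.

        Used by forecasting and simulation so that probability mass
        reaching a never-observed state is carried forward rather than
        silently destroyed.
        """
        check_day(d, transition=True)
        q = self.kernels[d - 1].copy()
        for i in np.nonzero(~self.observed_rows(d))[0]:
            q[i] = 0.0
            q[i, i] = 1.0
        return q


def estimate_kernel(cohort: Cohort, alpha: float = 0.0) -> DemandKernel:
    """Fit the day-inhomogeneous model to a cohort.

    Rows are M(d) row-normalized; ``alpha`` > 0 adds a Laplace
    pseudocount to every cell of observed rows before normalizing.
    The DISCHARGED row is pinned to its absorbing unit vector.
    """
    if cohort.n_eligible == 0:
        raise ValueError("cannot estimate from an empty cohort")
    init = np.zeros(N_STATES)
    for case in cohort:
        init[state_order(case.state_on(1))] += 1
    init /= init.sum()

    kernels = np.zeros((HORIZON - 1, N_STATES, N_STATES))
    support = np.zeros((HORIZON - 1, N_STATES), dtype=np.int64)
    for d in range(1, HORIZON):
        m = compute_transition_counts(cohort, d).counts.astype(float)
        row_tot = m.sum(axis=1)
        support[d - 1] = row_tot.astype(np.int64)
        for i in range(N_STATES):
            if row_tot[i] > 0:
                if alpha > 0:
                    kernels[d - 1, i] = (m[i] + alpha) / (row_tot[i] + alpha * N_STATES)
                else:
                    kernels[d - 1, i] = m[i] / row_tot[i]
        # absorbing by construction, even under smoothing
        if support[d - 1, DISCHARGED_INDEX] > 0:
            kernels[d - 1, DISCHARGED_INDEX] = 0.0
            kernels[d - 1, DISCHARGED_INDEX, DISCHARGED_INDEX] = 1.0
    meta = {"ward": cohort.ward, "fiscal_year": cohort.fiscal_year, "smoothing_alpha": alpha}
    return DemandKernel(initial_dist=init, kernels=kernels, support_counts=support, metadata=meta)


def forecast_demand(kernel: DemandKernel, d: int) -> np.ndarray:
    """Marginal state distribution on day ``d`` (1..18) under the model."""
    check_day(d)
    p = kernel.initial_dist.copy()
    for k in range(1, d):
        p = p @ kernel.effective_kernel(k)
    return p


def simulate_cohort(
    kernel: DemandKernel,
    n: int,
    seed: int,
    *,
    fallback: str = "stay",
    ward: Optional[str] = None,
    fiscal_year: Optional[str] = None,
) -> Cohort:
    """Sample ``n`` complete 18-day trajectories from the fitted model.

    ``fallback`` controls unobserved rows that are actually reached:
    ``"stay"`` keeps the case in place for that step, ``"error"`` raises.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if fallback not in ("stay", "error"):
        raise ValueError("fallback must be 'stay' or 'error'")
    rng = np.random.default_rng(seed)
    paths = np.empty((n, HORIZON), dtype=np.intp)
    paths[:, 0] = rng.choice(N_STATES, size=n, p=kernel.initial_dist)
    for d in range(1, HORIZON):
        observed = kernel.observed_rows(d)
        q = kernel.effective_kernel(d)
        cur = paths[:, d - 1]
        nxt = np.empty(n, dtype=np.intp)
        for i in np.unique(cur):
            if not observed[i] and i != DISCHARGED_INDEX and fallback == "error":
                raise ValueError(f"day {d}: unobserved row {STATES[i].label!r} reached with fallback disabled")
            mask = cur == i
            nxt[mask] = rng.choice(N_STATES, size=int(mask.sum()), p=q[i])
        paths[:, d] = nxt
    cases = tuple(
        CaseTrajectory(f"S{p:05d}", tuple(STATES[i] for i in paths[p]))
        for p in range(n)
    )
    return Cohort(
        ward=ward or str(kernel.metadata.get("ward", "simulated")),
        fiscal_year=fiscal_year or str(kernel.metadata.get("fiscal_year", "simulated")),
        cases=cases,
    )


def compare_kernels(a: DemandKernel, b: DemandKernel) -> float:
    """Support-weighted mean total-variation dissimilarity in [0, 1].

    For every day pair and every conditional row observed in BOTH
    kernels, the total-variation distance between the two rows is
    weighted by the smaller of the two support counts; the result is the
    weighted mean.  Symmetric; 0 iff all compared rows are identical;
    1 iff every compared pair of rows has disjoint support.
    """
    if a.kernels.shape != b.kernels.shape:
        raise ValueError("kernels have mismatched dimensions")
    total_weight = 0.0
    accum = 0.0
    for d in range(HORIZON - 1):
        both = (a.support_counts[d] > 0) & (b.support_counts[d] > 0)
        for i in np.nonzero(both)[0]:
            w = float(min(a.support_counts[d, i], b.support_counts[d, i]))
            tv = 0.5 * float(np.abs(a.kernels[d, i] - b.kernels[d, i]).sum())
            accum += w * tv
            total_weight += w
    if total_weight == 0:
        raise ValueError("kernels share no observed rows")
    return accum / total_weight


def observed_row_tv(kernel: DemandKernel, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total-variation distance of each observed row from a reference chain.

    ``reference`` is a (17, 15, 15) array of true conditional matrices
    (e.g. the generating archetype's kernels).  Returns ``(tv, weights)``
    over all observed rows, flattened across days; ``weights`` are the
    support counts.  The support-weighted mean of ``tv`` is the
    recovery error reported by this package: rows seen a handful of
    times are individually noisy by construction (a row observed once
    is a point mass), so only a support-weighted aggregate can be held
    to a tight tolerance.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.shape != kernel.kernels.shape:
        raise ValueError("reference has mismatched dimensions")
    tvs, weights = [], []
    for d in range(HORIZON - 1):
        obs = kernel.support_counts[d] > 0
        tv = 0.5 * np.abs(kernel.kernels[d] - reference[d]).sum(axis=1)
        tvs.append(tv[obs])
        weights.append(kernel.support_counts[d][obs])
    return np.concatenate(tvs), np.concatenate(weights).astype(float)


def kernel_to_json(kernel: DemandKernel, path: str | Path) -> None:
    payload = {
        "state_order": [s.label for s in STATES],
        "initial_dist": kernel.initial_dist.tolist(),
        "kernels": kernel.kernels.tolist(),
        "support_counts": kernel.support_counts.tolist(),
        "metadata": kernel.metadata,
    }
    Path(path).write_text(json.dumps(payload))


def kernel_from_json(path: str | Path) -> DemandKernel:
    payload = json.loads(Path(path).read_text())
    expected = [s.label for s in STATES]
    if payload.get("state_order") != expected:
        raise ValueError("kernel file uses an unexpected state order")
    return DemandKernel(
        initial_dist=np.array(payload["initial_dist"]),
        kernels=np.array(payload["kernels"]),
        support_counts=np.array(payload["support_counts"], dtype=np.int64),
        metadata=payload.get("metadata", {}),
    )
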