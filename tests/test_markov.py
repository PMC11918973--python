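"""Kernel estimation, forecasting, simulation, and kernel dissimilarity."""

from fractions import Fraction

import numpy as np
import pytest

import wardflow as wf
from wardflow.markov import observed_row_tv
from wardflow.states import DISCHARGED_INDEX, HORIZON, N_STATES, score_index

from conftest import make_cohort


def manual_kernel(rows_by_day: dict, initial: dict, support_value: int = 1) -> wf.DemandKernel:
    """Build a kernel by hand; unspecified rows are unobserved.

    ``rows_by_day[(d, src_idx)] = {tgt_idx: prob}``; ``initial[idx] = prob``.
    """
    init = np.zeros(N_STATES)
    for i, p in initial.items():
        init[i] = p
    kernels = np.zeros((HORIZON - 1, N_STATES, N_STATES))
    support = np.zeros((HORIZON - 1, N_STATES), dtype=np.int64)
    for (d, i), row in rows_by_day.items():
        for j, p in row.items():
            kernels[d - 1, i, j] = p
        support[d - 1, i] = support_value
    return wf.DemandKernel(initial_dist=init, kernels=kernels, support_counts=support)


def identity_kernel(initial: dict) -> wf.DemandKernel:
    init = np.zeros(N_STATES)
    for i, p in initial.items():
        init[i] = p
    kernels = np.tile(np.eye(N_STATES), (HORIZON - 1, 1, 1))
    support = np.ones((HORIZON - 1, N_STATES), dtype=np.int64)
    return wf.DemandKernel(initial_dist=init, kernels=kernels, support_counts=support)


# ---------------------------------------------------------------- estimation
def test_estimate_deterministic_cohort():
    cohort = make_cohort(["0 1 1"] * 4)
    k = wf.estimate_kernel(cohort)
    assert k.kernels[0, score_index(0), score_index(1)] == 1.0
    assert k.initial_dist[score_index(0)] == 1.0
    assert k.support_counts[0, score_index(0)] == 4


def test_estimate_hand_arithmetic():
    # day-1 departures from score 0: three stay, one moves to score 1
    cohort = make_cohort(["0 0 0", "0 0 0", "0 0 0", "0 1 1"])
    k = wf.estimate_kernel(cohort)
    assert k.kernels[0, score_index(0), score_index(0)] == pytest.approx(0.75)
    assert k.kernels[0, score_index(0), score_index(1)] == pytest.approx(0.25)


def test_estimate_flags_unobserved_rows_without_imputing():
    cohort = make_cohort(["0 0 0"])
    k = wf.estimate_kernel(cohort)
    assert not k.observed_rows(1)[score_index(5)]
    assert k.kernels[0, score_index(5)].sum() == 0.0
    # effective kernel substitutes a stay-in-place row
    eff = k.effective_kernel(1)
    assert eff[score_index(5), score_index(5)] == 1.0


def test_estimate_with_laplace_smoothing():
    cohort = make_cohort(["0 0 0"] * 3)
    k = wf.estimate_kernel(cohort, alpha=1.0)
    row = k.kernels[0, score_index(0)]
    assert row.sum() == pytest.approx(1.0)
    assert row[score_index(0)] == pytest.approx(4 / 18)  # (3+1)/(3+15)
    assert row[score_index(7)] == pytest.approx(1 / 18)


def test_estimate_empty_cohort_rejected():
    with pytest.raises(ValueError):
        wf.estimate_kernel(wf.Cohort("w", "2017", ()))


# ---------------------------------------------------------------- forecast
def test_forecast_day1_is_initial_dist():
    k = identity_kernel({score_index(3): 0.4, score_index(0): 0.6})
    assert np.array_equal(wf.forecast_demand(k, 1), k.initial_dist)


def test_forecast_two_state_toy_matches_hand_computation():
    # states A=score 0, B=score 1; P(A->A)=3/4, P(A->B)=1/4, P(B->B)=1/2, P(B->A)=1/2
    a, b = score_index(0), score_index(1)
    rows = {}
    for d in (1, 2):
        rows[(d, a)] = {a: 0.75, b: 0.25}
        rows[(d, b)] = {a: 0.5, b: 0.5}
    k = manual_kernel(rows, initial={a: 1.0})
    # day 2: (3/4, 1/4); day 3: (3/4*3/4 + 1/4*1/2, 3/4*1/4 + 1/4*1/2)
    p3 = wf.forecast_demand(k, 3)
    assert p3[a] == pytest.approx(0.6875)
    assert p3[b] == pytest.approx(0.3125)


def test_forecast_matches_exact_path_enumeration():
    # 3-state chain (scores 0, 1, discharged), dyadic probabilities, 3 days;
    # oracle: enumerate all paths with exact rational arithmetic
    a, b, dis = score_index(0), score_index(1), DISCHARGED_INDEX
    probs = {
        (1, a): {a: Fraction(1, 2), b: Fraction(1, 4), dis: Fraction(1, 4)},
        (1, b): {b: Fraction(3, 4), dis: Fraction(1, 4)},
        (2, a): {a: Fraction(1, 4), b: Fraction(1, 2), dis: Fraction(1, 4)},
        (2, b): {a: Fraction(1, 2), b: Fraction(1, 2)},
        (1, dis): {dis: Fraction(1)},
        (2, dis): {dis: Fraction(1)},
    }
    init = {a: Fraction(1, 2), b: Fraction(1, 2)}
    marginal = {s: Fraction(0) for s in (a, b, dis)}
    for s1, p1 in init.items():
        for s2, p2 in probs[(1, s1)].items():
            for s3, p3 in probs[(2, s2)].items():
                marginal[s3] += p1 * p2 * p3
    assert sum(marginal.values()) == 1
    k = manual_kernel(
        {key: {j: float(p) for j, p in row.items()} for key, row in probs.items()},
        initial={i: float(p) for i, p in init.items()},
    )
    p3 = wf.forecast_demand(k, 3)
    for s in (a, b, dis):
        assert p3[s] == float(marginal[s])  # dyadic probabilities are float-exact


def test_forecast_discharged_mass_is_monotone():
    arch = wf.make_archetype("cardiology", seed=1)
    records = wf.generate_cohort(arch, n=400, seed=2)
    cohort, _ = wf.build_cohort(records, "cardiology", 2017)
    k = wf.estimate_kernel(cohort)
    masses = [wf.forecast_demand(k, d)[DISCHARGED_INDEX] for d in range(1, 19)]
    assert all(m2 >= m1 - 1e-12 for m1, m2 in zip(masses, masses[1:]))
    for d in range(1, 19):
        assert wf.forecast_demand(k, d).sum() == pytest.approx(1.0, abs=1e-9)
    with pytest.raises(ValueError):
        wf.forecast_demand(k, 19)


# ---------------------------------------------------------------- simulate
def test_simulate_identity_kernel_constant_trajectories():
    k = identity_kernel({score_index(4): 1.0})
    cohort = wf.simulate_cohort(k, n=7, seed=1)
    assert cohort.n_eligible == 7
    assert all(all(s == wf.score(4) for s in c.states) for c in cohort)


def test_simulate_is_seed_deterministic():
    cohort = make_cohort(["0 1 1 2"] * 5 + ["3 3 discharged discharged"] * 5)
    k = wf.estimate_kernel(cohort)
    c1 = wf.simulate_cohort(k, n=50, seed=9)
    c2 = wf.simulate_cohort(k, n=50, seed=9)
    assert all(a.states == b.states for a, b in zip(c1, c2))


def test_simulate_error_fallback_on_reachable_unobserved_row():
    a, b = score_index(0), score_index(1)
    # day-1 row sends mass to score 1, whose day-2 row was never observed
    rows = {(1, a): {b: 1.0}}
    k = manual_kernel(rows, initial={a: 1.0})
    with pytest.raises(ValueError, match="unobserved"):
        wf.simulate_cohort(k, n=5, seed=1, fallback="error")
    cohort = wf.simulate_cohort(k, n=5, seed=1, fallback="stay")
    assert all(c.state_on(3) == wf.score(1) for c in cohort)


# ---------------------------------------------------------------- recovery
def test_estimation_recovers_generating_kernel_as_n_grows():
    arch = wf.make_archetype("orthopaedic", seed=1)
    medians = []
    for n, seed in ((500, 3), (5000, 4)):
        records = wf.generate_cohort(arch, n, seed=seed)
        cohort, _ = wf.build_cohort(records, "orthopaedic", 2017)
        k = wf.estimate_kernel(cohort)
        tv, w = observed_row_tv(k, arch.kernels)
        medians.append(float(np.median(tv)))
    assert medians[1] < medians[0]  # median row TV decreases with n


# ---------------------------------------------------------------- compare
def test_compare_identical_kernels_is_zero():
    k = wf.estimate_kernel(make_cohort(["0 1 1", "0 0 0"]))
    assert wf.compare_kernels(k, k) == 0.0


def test_compare_disjoint_deterministic_kernels_is_one():
    a, b, c = score_index(0), score_index(1), score_index(2)
    rows_x = {(d, a): {b: 1.0} for d in range(1, 18)}
    rows_y = {(d, a): {c: 1.0} for d in range(1, 18)}
    kx = manual_kernel(rows_x, initial={a: 1.0})
    ky = manual_kernel(rows_y, initial={a: 1.0})
    assert wf.compare_kernels(kx, ky) == 1.0


def test_compare_is_symmetric_and_bounded():
    arch1 = wf.make_archetype("orthopaedic", seed=1)
    arch2 = wf.make_archetype("neurosurgery", seed=1)
    cohorts = []
    for arch, seed in ((arch1, 5), (arch2, 6)):
        records = wf.generate_cohort(arch, n=300, seed=seed)
        cohort, _ = wf.build_cohort(records, arch.name, 2017)
        cohorts.append(cohort)
    ka, kb = (wf.estimate_kernel(c) for c in cohorts)
    d_ab, d_ba = wf.compare_kernels(ka, kb), wf.compare_kernels(kb, ka)
    assert d_ab == d_ba
    assert 0.0 < d_ab <= 1.0


def test_compare_mismatched_dimensions_rejected():
    k = identity_kernel({score_index(0): 1.0})
    bad = wf.DemandKernel(
        initial_dist=k.initial_dist,
        kernels=k.kernels,
        support_counts=k.support_counts,
    )
    object.__setattr__(bad, "kernels", np.zeros((2, 2, 2)))
    with pytest.raises(ValueError):
        wf.compare_kernels(k, bad)


# ---------------------------------------------------------------- round trip
def test_kernel_json_round_trip(tmp_path):
    cohort = make_cohort(["0 1 2 3"] * 3 + ["5 5 5 discharged"] * 2)
    k = wf.estimate_kernel(cohort)
    path = tmp_path / "kernel.json"
    wf.kernel_to_json(k, path)
    back = wf.kernel_from_json(path)
    assert np.array_equal(back.initial_dist, k.initial_dist)
    assert np.array_equal(back.kernels, k.kernels)
    assert np.array_equal(back.support_counts, k.support_counts)
    assert back.metadata["ward"] == "ward"
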