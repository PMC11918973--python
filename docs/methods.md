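# Methods

## State space and horizon

Each admission ("case": one patient × one admission date) is reduced to
a sequence of 18 daily states, day 1 being the admission day.  The state
space has 15 elements: the integer care-burden scores 0–12 (a daily
ordinal summary of assistance with rolling over, transferring, oral
health, dietary intake, changing clothes, instruction compliance and
risk behaviour; only the 0–12 total is modelled, not the sub-items),
plus `other` (the day was spent in another ward or in a specialized bed
such as a coronary care unit, so the target ward has no meaningful
score) and `discharged`.  `discharged` is absorbing.  The fixed display
and matrix order is score 12 down to score 0, then `other`, then
`discharged`; placing the two non-score labels after score 0 keeps the
ordinal score axis contiguous (their exact position is a package
convention — only the descending score order is inherited from the
field's practice).

The 18-day horizon matches wards run at a 7:1 patient-to-nurse ratio,
where the average stay is optimized to be within 18 days.  Day pairs
d → d+1 with d ∈ {1,…,17} carry all transition statistics.

## Ingestion and eligibility

Raw data are patient-day rows (date, patient id, admission date,
optional discharge date, ward, bed, optional score).  Processing per
case:

1. days on which the patient occupied a different ward or a
   non-general bed (bed label prefixes `ICU`/`CCU`/`HCU`) are
   relabelled `other`, masking any recorded score;
2. every day strictly after the discharge record's entry date is
   `discharged`; the discharge day itself keeps its recorded state;
3. a day that is neither `other` nor `discharged` and has no score is
   *missing*.

A case is eligible iff (a) its admission date lies in the fiscal
window April 1 → March 14 (so the 18-day horizon ends inside the fiscal
year), (b) it has at least one target-ward general-bed day among days
1–18 inclusive (day 18 is inside the analysis horizon, since day-18
occupancy is reported), and (c) no day 1–18 is missing.  Exclusions are
logged one reason per case, checked in that order, so input size =
eligible + logged.  Two readings were genuinely open and are resolved
as follows: a specialized bed *inside* the target ward counts as
`other` (the eligibility language is about general beds), and an
`other` day with no score is *not* missing (the score was deliberately
replaced; treating it as missing would exclude every transferred
patient, contradicting observed `other` flows).  Days labelled
`discharged` likewise need no score.

Per-day summaries report cases still inpatient (`other` counts,
`discharged` does not), the share of the eligible cohort (one decimal,
half-up), and median/Q1–Q3 of scores among cases holding a score that
day.  Quartiles use linear interpolation between order statistics
(numpy's default); the convention is stored in the summary metadata
because published tables rarely state theirs.

## Transition statistics

With indicator Iᵢ(e,d) = 1 iff case e is in state i on day d:
M⁽ᵈ⁾ᵢⱼ = Σₑ Iᵢ(e,d)·Iⱼ(e,d+1), and P⁽ᵈ⁾ᵢⱼ = M⁽ᵈ⁾ᵢⱼ/Nₑ.  Because every
eligible trajectory is complete, Σᵢⱼ M⁽ᵈ⁾ = Nₑ for every d and inflow
equals outflow at every interior (day, state) node — the flow-continuity
property the Sankey layout relies on.  P is a *joint* distribution over
the 225 cells; the conditional (row-normalized) probabilities used for
forecasting are kept in a separate module precisely because conflating
the two is the standard pitfall.

Percentages are rendered by exact rational division followed by
round-half-up to one decimal — this reproduces every published worked
example (e.g. 265/684 → 38.7%, 8/839 → 1.0%, 5/994 → 0.5%), which
banker's rounding would not.

Band summaries group scores as low 0–2, medium 3–5, high 6–9,
ultra-high 10–12 ("very high" and "ultra-high" are the same band) and
count five named single-step paths: each band to itself, plus score 0 →
discharged (source exactly 0, not any low score).  A case discharged on
both days belongs to the residual, not to any named category, which is
why published category shares do not sum to 100%.  The top-2
concentration is the share of the two largest *named* categories — this
convention reproduces the published 62.7% = (265+164)/684, 50.5% =
(314+110)/839 and 54.6% = (325+218)/994.  Diversity is the number of
non-empty cells of M⁽ᵈ⁾ out of 225; the 225 "possible trajectories" are
read as single-step transitions (15² = 225 confirms this reading).

## The demand kernel

Estimation: Q⁽ᵈ⁾ᵢⱼ = M⁽ᵈ⁾ᵢⱼ / Σₖ M⁽ᵈ⁾ᵢₖ where the row total is
positive; rows never observed are flagged, not imputed (no smoothing by
default — the statistics are purely empirical; optional Laplace α is
exposed for users who want it, recorded in the kernel metadata).  The
`discharged` row is pinned to its absorbing unit vector.

Forecasting propagates the day-1 empirical distribution through the
kernels by vector–matrix products.  Both forecasting and simulation
replace a *reached* unobserved row by a stay-in-place (identity) row —
the same fallback in both paths, so Monte-Carlo marginals are an
unbiased check of the matrix products.  Simulation with
`fallback="error"` raises instead, for users who want to know.

Dissimilarity between two fitted kernels: for every day and every row
observed in both, the total-variation distance between the conditional
rows, weighted by the smaller of the two support counts, averaged.
This is symmetric, bounded in [0,1], 0 iff all compared rows agree, and
1 iff they are all disjoint.  The underlying claim being quantified —
same ward across years more similar than different wards — is
qualitative, so any bounded divergence would serve; the choice is
recorded in kernel metadata.

Recovery error against a known generating chain is reported as the
*support-weighted mean* row total-variation.  A per-row worst case is
not a meaningful target: a row whose state is occupied once is
estimated as a point mass and sits at TV ≈ 0.5–0.9 from any dispersed
truth regardless of cohort size; rows need support of order 10³ for
TV ≤ 0.05.  The weighted aggregate at n = 5000 is ≈ 0.02–0.05 per
archetype, and the median row TV decreases monotonically from n = 500
to n = 5000 (both tested).

The Markov assumption itself is a modelling choice: the daily score's
risk-behaviour sub-item looks back seven days, which could induce
non-Markov dependence; this is noted, not modelled.

## Synthetic cohort generator

The generator is first-class, tested code: it defines the study
conditions under which every stochastic claim is exercised.  Each of
three ward archetypes is a fully specified day-inhomogeneous chain,
constructed parametrically (a discretized-normal local walk around the
current score, an archetype-specific band-shift component, per-day
discharge and transfer hazards, and parametric `other`-day return
distributions) rather than entered as raw 17×225 tables, so every
number is auditable:

* **orthopaedic** — initial mass concentrated on scores 0–2 (day-1
  median 1); at day 2 → 3 the low-score rows put 45% of their mass on a
  high-band target distribution peaked at score 7 (≥ 0.20 into any
  single high score, ≥ 0.20 low→high overall, emulating the ≈ 23% of an
  orthopaedic cohort that jumps from 0 to 6–9 after surgery); decline
  toward scores 4–5 at day 4 → 5; low discharge hazard rising late.
* **cardiology** — initial mass mostly on score 0 (day-1 median 0); a
  slight ascent day 1 → 2 and descent day 2 → 3; a large discharge
  hazard at day 3 → 4 (0.33 from low scores) and a secondary one at
  day 5 → 6, so ≥ 0.20 of the cohort is discharged by day 4 (≈ 0.34 in
  the default construction, emulating ≈ 30% discharged at day 3 → 4);
  a small persistent very-high-score subpopulation.
* **neurosurgery** — a broad initial distribution and, every day, a
  wide local walk (sd 1.1 score levels) mixed with a 4% uniform
  exploration component and `other`-day returns into high scores.  Its
  per-day occupancy-weighted transition entropy (≥ 1.65 nats) strictly
  exceeds the other archetypes' (≤ 1.43 nats) on all 17 day pairs.  The
  dispersion is deliberately moderate: entropy must dominate the other
  wards while empirical estimation at n = 5000 still recovers the
  kernel to the stated aggregate tolerance — dispersion and estimability
  pull in opposite directions, and the default sits where both
  contracts hold with margin.

Entropy is measured as the mean Shannon entropy of kernel rows weighted
by the day's marginal occupancy restricted to non-discharged states, so
early-discharging wards are not scored "simple" merely because absorbed
mass has a deterministic row.

Archetype seeds apply a small multiplicative log-normal jitter
(scale 0.015) to rows, emulating fiscal-year-to-year variation around
the ward's inherent dynamics; structural zeros and the absorbing row
are preserved.  Admission dates are uniform over the fiscal window (no
seasonality is modelled, matching the analysis design).  Missingness
drops in-ward scores independently per day with probability
`missing_rate` — the simplest mechanism that exercises the exclusion
rule.  Transfers are realized as either an other-ward row or a
specialized-bed row in the target ward (both masked to `other`
downstream).  Generation is byte-deterministic in (archetype, n, seed).

What the generator does *not* emulate: diagnoses, age/sex structure,
inter-patient correlation (shared nurses, bed capacity), readmission
dependence between cases, and informative (state-dependent)
missingness.  Passing tests therefore demonstrate correctness of the
pipeline's arithmetic and the *qualitative* reproducibility of
ward-specific regularities, not calibration to any real hospital.

## Sankey layout

x = (day − 1)/17 exactly; within a day, occupied states are packed
uniformly over [0,1] in display order (the order is fixed; the spacing
is a package convention, since only the order is prescribed by
practice).  Zero-occupancy nodes are omitted.  Node occupancy equals
inflow (= outflow at interior days).  Links carry counts; a renderer
comparing wards of different sizes can divide by Nₑ.  Highlight rules
mark either all named band-path links or the top-2 categories at a
chosen day pair.  JSON output is lossless and round-trips; HTML output
is a self-contained static SVG honoring the fixed geometry.

## Problem sizes and numerics

Default test/verification sizes: parameter recovery n = 5000 per
archetype; forecast-vs-Monte-Carlo n = 10000 (L1 ≤ 0.05 per day);
within/between-ward comparison n = 2000 per cohort, two fiscal years
per ward; day-1 goodness-of-fit n = 10000 (χ², α = 0.01); brute-force
oracle equivalence on cohorts of ≤ 20 cases.  These sizes give the
stochastic checks comfortable margins (measured recovery error is at
worst ≈ 0.048 vs the 0.05 tolerance, with seed-to-seed standard
deviation ≈ 0.0005) while the whole suite runs in seconds.  Row
normalization tolerances are 1e-9; probability-mass assertions 1e-12;
percentage rendering is exact-rational then half-up.  Degenerate
inputs: empty cohorts are valid for counting (all-zero matrix) but
rejected for estimation and summarization; day 18 has no outgoing
transition; conflicting duplicate patient-day rows raise an ambiguity
error, identical duplicates are tolerated.

## Known limitations

Horizons other than 18 days and score ranges other than 0–12 are not
configurable.  The band edges are fixed; the published analysis calls
them provisional.  The dissimilarity weights rows by support, so a ward
pair differing only on rarely occupied states can look similar.  No
formal inference (confidence intervals, tests) is attached to the
transition statistics — the underlying analysis makes none.
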