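"""Compare day 3 -> 4 band trajectories and diversity across three wards.

Scores are banded low (0-2), medium (3-5), high (6-9) and ultra-high
(10-12).  For each ward the five named single-step paths (band -> same
band, plus score 0 -> discharged) are counted over the whole eligible
cohort; the residual holds every other path.  Diversity is the number
of occupied cells of the 15 x 15 transition matrix, out of 225.
"""

import wardflow as wf

for name in wf.ARCHETYPE_NAMES:
    archetype = wf.make_archetype(name, seed=2017)
    records = wf.generate_cohort(archetype, n=900, seed=7)
    cohort, _ = wf.build_cohort(records, name, fiscal_year=2017)

    band = wf.band_transition_summary(cohort, 3)
    div = wf.transition_diversity(cohort, 3)
    print(f"--- {name} (N_e = {cohort.n_eligible}) ---")
    for cat in wf.BAND_CATEGORIES:
        print(f"  {cat:24s} {band.counts[cat]:4d}  ({band.percent(cat)})")
    print(f"  {'other paths':24s} {band.residual:4d}")
    print(f"  top-2 concentration      {wf.percent_str(band.top2_count, band.n_eligible)}")
    print(f"  occupied transitions     {div.n_observed_transitions} / {div.n_possible}")
    print(f"  score range              {div.score_range}")
    print()

print("The orthopaedic ward concentrates in high-high paths (post-operative")
print("surge), cardiology in low-low and 0->discharged (early discharge),")
print("and neurosurgery spreads over the most cells: the ward-specific")
print("regularities the transition statistics are designed to expose.")
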