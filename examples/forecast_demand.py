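"""Fit the day-inhomogeneous Markov model and forecast future demand.

One fiscal year of synthetic records is used to estimate the kernel
(17 conditional transition matrices plus the day-1 distribution); the
fitted model then forecasts the state distribution of the NEXT year's
admissions, which is checked against a fresh cohort drawn from the same
ward process.  Finally, kernels of different wards are compared with the
bounded dissimilarity (support-weighted total variation).
"""

import numpy as np

import wardflow as wf

ward = "cardiology"
train = wf.build_cohort(
    wf.generate_cohort(wf.make_archetype(ward, seed=2017), n=1000, seed=1), ward, 2017
)[0]
kernel = wf.estimate_kernel(train)

future = wf.build_cohort(
    wf.generate_cohort(wf.make_archetype(ward, seed=2018), n=1000, seed=2, fiscal_year=2018),
    ward,
    2018,
)[0]

print(f"model fitted on {train.n_eligible} cases of fiscal 2017 ({ward})")
print("\n day | forecast %discharged | observed %discharged (fiscal 2018)")
for d in (2, 4, 6, 10, 18):
    forecast = wf.forecast_demand(kernel, d)[wf.state_order(wf.DISCHARGED)]
    observed = sum(1 for c in future if c.state_on(d) == wf.DISCHARGED) / future.n_eligible
    print(f"  {d:2d} | {100 * forecast:19.1f} | {100 * observed:.1f}")

print("\nkernel dissimilarities (0 = identical conditional dynamics, 1 = disjoint):")
kernels = {}
for name in wf.ARCHETYPE_NAMES:
    cohort = wf.build_cohort(
        wf.generate_cohort(wf.make_archetype(name, seed=2017), n=1000, seed=3), name, 2017
    )[0]
    kernels[name] = wf.estimate_kernel(cohort)
k18 = wf.estimate_kernel(future)
print(f"  {ward} 2017 vs {ward} 2018      : {wf.compare_kernels(kernels[ward], k18):.3f}")
for other in wf.ARCHETYPE_NAMES:
    if other != ward:
        d = wf.compare_kernels(kernels[ward], kernels[other])
        print(f"  {ward} 2017 vs {other} 2017: {d:.3f}")

print("\nThe same ward's two fiscal years are closer than any cross-ward")
print("pair: demand dynamics are a stable, ward-specific property, which is")
print("what makes probabilistic forecasting from past years defensible.")
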