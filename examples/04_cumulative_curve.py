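"""Cumulative 6-SNP PAF model, women and men separately.

SNPs are added one by one in the published model order; the exposure at
each step is the union indicator "carrier at >= 1 SNP of the set" against
the all-noncarrier reference, on one shared complete-case set so the curve
is internally comparable.
"""

from thrombopaf import (
    CUMULATIVE_6SNP_ORDER,
    CohortConfig,
    cumulative_paf_curve,
    sample_case_cohort,
    simulate_cohort,
)

cohort = simulate_cohort(CohortConfig(n_individuals=30_000, seed=4))
sample = sample_case_cohort(cohort, subcohort_size=3_000, seed=1)

for sex in ("female", "male"):
    curve = cumulative_paf_curve(sample, list(CUMULATIVE_6SNP_ORDER), sex)
    print(f"{sex}:")
    for k, r in enumerate(curve.results, start=1):
        snp = curve.snp_ids[k - 1]
        print(f"  +{snp:<10s} prevalence {r.p:.2f}  HR {r.hr:.2f}  "
              f"cumulative PAF {100 * r.paf:5.1f}%")
print()
print("each line: the combined exposure after adding that SNP; prevalence")
print("can only grow along the curve, the PAF need not be monotone.")
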