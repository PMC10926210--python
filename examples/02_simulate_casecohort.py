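"""Simulate a source cohort and draw a case-cohort sample.

The generator produces a two-sex adult cohort with Hardy-Weinberg genotypes
for the default 17-SNP prothrombotic panel and event ages from a Gompertz
proportional-hazards model on the age scale. The case-cohort sample keeps
all incident cases plus a random subcohort; cases can land in both.
"""

from thrombopaf import CohortConfig, sample_case_cohort, simulate_cohort

config = CohortConfig(n_individuals=30_000, seed=4)
cohort = simulate_cohort(config)
print(f"source cohort: {len(cohort)} individuals, "
      f"{int(cohort['event'].sum())} incident events "
      f"({100 * cohort['event'].mean():.1f}% over follow-up)")

sample = sample_case_cohort(cohort, subcohort_size=3_000, seed=1)
print(f"case-cohort sample: {sample.n} rows = {sample.n_cases} cases "
      f"+ {sample.subcohort_size} subcohort "
      f"({sample.n_overlap} cases fell in the subcohort by chance)")
print(f"sampling fraction: {sample.sampling_fraction:.3f}")
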