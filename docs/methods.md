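# Methods

## Model and estimands

The package estimates the population attributable fraction (PAF) of venous
thromboembolism for carrier-coded genotypes, by sex and optionally by
attained-age band, from a case-cohort sample.

**Carrier coding.** Genotypes are risk-allele counts (0/1/2/missing).
Carrier = ≥ 1 risk allele; dosage beyond presence/absence is ignored
throughout (no additive model). Three coding rules determine what the risk
allele is: minor-allele risk (the common case), major-allele risk (six
panel SNPs — rs2036914, rs1801020, rs1039084, rs1884841, rs1613662, rs4524
— where the *major* allele carries the risk), and the ABO rs8176719 rule
where the G (non-deletion) allele marks non-O blood type and homozygous
deletion (blood type O) is the reference. Internally ABO is stored directly
as a G-allele count so carrier classification needs no special case; the
rule only matters for VCF import.

**Levin's formula.** PAF = p(HR−1)/(p(HR−1)+1). It is strictly increasing
in HR for p > 0 and in p for HR > 1, negative for protective exposures,
always < 1, and equals (HR−1)/HR at p = 1. PAF is reported as a percent
with one decimal in outputs; internal values are unrounded.

**Prevalence.** Always estimated from subcohort members only, because the
subcohort is the population-representative piece of the design; pooling
cases would overstate p. Missing genotypes are excluded per SNP from the
denominator (complete case), the standard epidemiological convention; the
numerator and denominator are reported alongside the proportion.

**Hazard ratios.** Cox proportional hazards with attained age as the time
scale and delayed entry at the age of inclusion (left truncation), adjusted
for BMI standardized to a z-score (numerical conditioning; the exposure HR
is unaffected). Case-cohort structure enters through Prentice risk sets:
subcohort members are at risk over (entry, exit]; cases outside the
subcohort enter the risk set only immediately before their own event age
(implemented by moving their entry to the largest representable float below
their exit age). An `unweighted` option treats the sample as a plain
cohort; it is a sensitivity probe, not a recommended analysis — whether any
weighting was used in the original analyses is not documentable, so the
statistically valid default was chosen.

**Cumulative model.** The exposure for a SNP set is the union carrier
indicator (carrier at ≥ 1 SNP of the set) against the all-noncarrier
reference, added one SNP at a time. The default order is the fixed 6-SNP
sequence rs8176719, rs2036914, rs2289252, rs6025, rs2066865, rs1799963; a
data-derived order (descending single-SNP PAF, forced-inclusion SNPs
appended last — prothrombin rs1799963 by default, kept for its high HR
despite a low PAF) is available. All prefixes of one curve share a single
complete-case set (individuals nonmissing at *every* SNP of the full model
and BMI), so the points are mutually comparable. Combined prevalence is
non-decreasing along the curve by construction.

**Age stratification.** Each individual's risk interval is intersected
with half-open bands (low, high], default (0,50], (50,75], (75,∞): entry
clipped up, exit clipped down, the event kept only in the band containing
the event age. One person can contribute censored person-time to an early
band and an event to a later one. Published descriptions of such analyses
are ambiguous about both the boundary convention and whether risk time was
clipped or individuals classified once; clipping with configurable
boundaries was chosen as the estimand that uses all person-time, and the
ambiguity is left documented rather than resolved.

**Bootstrap.** Bias-corrected (BC) percentile intervals: z₀ =
Φ⁻¹((#{θ*<θ̂} + ½#{θ*=θ̂})/B), endpoints at empirical quantiles
Φ(2z₀+z_{α/2}) and Φ(2z₀+z_{1−α/2}). BC, not BCa — no acceleration term.
Default B = 10,000 at α = 0.05; B below 100 warns. The default resampling
respects the design: subcohort members and outside-subcohort cases are
resampled separately with replacement, preserving both stratum sizes; an
`iid_rows` option exists for sensitivity since the "right" resampling unit
for this design is itself a modeling choice. Replicates on which the
estimator fails (no events, constant exposure, separation) are dropped and
counted; more than 10% failures is an error. Each replicate re-runs the
full chain: prevalence, Cox fit, PAF.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
any particular population's data:

- **Genotypes:** independent loci, Hardy–Weinberg genotype frequencies
  (1−q)², 2q(1−q), q² at the panel allele frequency q. The packaged 17-SNP
  panel uses published subcohort allele frequencies (mean of the two sexes,
  which agree closely) and per-sex log-HRs equal to the log of published
  per-SNP hazard ratio estimates.
- **Entry ages:** truncated normal, mean 47, SD 15 y, range 25–80 y,
  mimicking an adult population survey with inclusion from age 25.
- **Sex:** independent Bernoulli, P(female) = 0.529 (the subcohort's
  composition).
- **BMI:** normal, mean 26.2, SD 4.0 kg/m²; log-HR 0.2 per SD.
- **Event ages:** Gompertz baseline h₀(a) = λ·exp(γa) with λ = 3·10⁻⁶/y,
  γ = 0.07/y, times exp(Σβ·carrier + β_bmi·z). Drawn by inverse transform
  from the conditional cumulative hazard given survival to entry; γ = 0 is
  handled as the exponential limit. Exit is the minimum of the event age,
  entry + 18 y of follow-up, and administrative censoring at age 90.
  The defaults were calibrated so that, with the full default panel, the
  population-average cumulative incidence by age 90 is ≈ 9% and ≈ 2% of a
  simulated cohort has an event during follow-up — case counts of the same
  order as the motivating studies (≈ 1,500 cases per ≈ 93,000 persons).
- **Sampling:** the subcohort is a uniform draw from the full cohort,
  cases included, so the case/subcohort overlap is random; the sampling
  fraction is a free parameter (the original fraction is not documented).
- **Randomness:** one global seed feeds named substreams (sex, ages, BMI,
  per-SNP genotypes, event times, sampling), so adding a SNP does not
  perturb unrelated draws; everything is deterministic given the seed.

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: linkage disequilibrium (the two F11 SNPs are
correlated in reality; loci are simulated independently), competing risks
of death, reproductive and other environmental risk factors, cohort-period
effects, and genotyping error. Parameter-recovery and coverage results
therefore validate the estimator under its own assumptions, not the
field behavior of any particular study.

## Numerical choices

- Newton–Raphson on the partial likelihood, start at 0 (or a warm start),
  gradient max-norm tolerance 1e−8, at most 50 iterations, step-halving on
  likelihood decrease; decreases below 1e−10·|ℓ| are treated as roundoff
  and accepted. Linear predictors are clipped at ±500 before
  exponentiation.
- Ties: Breslow by default (the default of the commercial package
  typically used for such analyses), Efron optional. Simulated event ages
  are continuous, so the two coincide there.
- Separation: a monotone likelihood is detected either by a coefficient
  exceeding 50 during iteration or by a flat gradient at |β| > 15; the fit
  is flagged `converged=False` with a diagnostic and no finite estimate is
  fabricated. PAF routines refuse non-converged fits; cumulative curves
  truncate at the first non-estimable prefix and say so.
- Robust variance: dfbeta (infinitesimal-jackknife) sandwich aggregated
  per individual — the standard approximation to the grouped jackknife
  used for case-cohort robust errors; score residuals use the Breslow
  form, exact when event times are distinct. Model-based inverse
  information is also reported for diagnostics.
- Proportional hazards: Grambsch–Therneau score test of the Schoenfeld
  residuals against event age (identity transform), per-covariate χ² with
  1 df, using the average-information approximation V̄ = I/m; agrees
  closely with R's `cox.zph` on shared data.
- The bootstrap fast path re-runs fits at gradient tolerance 1e−6 with a
  warm start from the original fit (coefficient error O(1e−9), far below
  replicate noise). Per-replicate seeds derive from (seed, replicate
  index), so results are independent of execution order. Empirical
  quantiles use numpy's default linear interpolation; intervals are
  bit-for-bit reproducible given the seed.
- z₀ uses the half-tie convention so that small-B ties with the point
  estimate do not produce Φ⁻¹(0); if *all* replicates fall on one side the
  interval is clamped to the replicate extremes with a warning.

## Problem sizes in the test suite

The estimator-validity check simulates 200 case-cohort replicates
(n = 20,000; subcohort 2,000; true HR 2.0; carrier prevalence 0.2) and
verifies |bias| < 0.05 on the log-HR and 92–98% coverage of the true PAF
(16.7%) by BC intervals at B = 1,000 — B is reduced from the 10,000 used
for production intervals because coverage, not interval smoothness, is the
property under test. Oracle checks run a 1e−4 grid search on a
six-individual fixture and compare full-cohort fits against lifelines and
R `survival` at 1e−6. Hardy–Weinberg and sampling properties use cohorts
of 3,000–50,000.

## Known limitations

- Levin's formula with a single adjusted HR is the classical approximation;
  with very high exposure prevalence (the saturated cumulative models reach
  ≈ 98%) PAF estimates are prevalence-dominated and can be overstated, and
  the all-noncarrier reference group becomes tiny — on small strata the fit
  can separate, which the package reports rather than papers over.
- BC (not BCa) intervals; no studentization.
- No time-varying coefficients, frailty, stratified baselines, or
  Barlow/Self–Prentice weighting variants.
- A published per-SNP table cell can differ from its recomputation by
  ~0.1 percentage point because the printed HR is rounded to two decimals
  (e.g. 16.9% vs 16.8% for ABO in women); such cells are documented, not
  treated as arithmetic targets.
- One published genotype-distribution cell is internally inconsistent
  (percentage vs count for FGG in women); the packaged panel stores allele
  frequencies, which are printed directly, so the inconsistency does not
  propagate, and it is not resolved here.
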