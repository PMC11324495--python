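# Methods

## The analysis in brief

The package operationalises risk-adapted PSA screening: instead of one
universal positivity threshold, the PSA cut-off is chosen per age group
and per polygenic-risk stratum so that each subgroup's threshold is the
Youden-optimal point of that subgroup's time-dependent ROC for 10-year
prostate-cancer risk. The pipeline therefore needs, in order: a scored
and dichotomised PRS, per-cell tdROC cut-offs, survival models linking
the resulting strata to incidence and mortality, and a confusion-matrix
evaluation of the candidate positivity rules against observed diagnoses.

## Synthetic cohort model

The generator (`prscreen.synthetic`) emulates a PLCO-like screening
cohort of men aged 55–74 through an explicit causal chain; all
randomness flows from one `numpy` generator per run (default seed
20240801).

**Genotypes.** `n_snps` (default 80) independent risk SNPs with
risk-allele frequencies uniform on `maf_range` (default 0.05–0.5) and
per-allele log-odds-ratios |N(0.08, 0.04)| — the risk allele is by
construction the allele with the positive effect. Dosages are
Binomial(2, f) (Hardy–Weinberg); a fraction (default 2%) is set missing
completely at random to exercise the imputation rule without dominating
results.

**Outcomes.** Diagnosis times are exponential proportional hazards with
linear predictor Σβ·dosage plus modest covariate effects (log-HR
0.1–0.4; family history, enlarged prostate, diabetes), both centred so
`baseline_hazard` (default 0.0095/person-year) is the cohort-typical
rate. Censoring is the minimum of administrative follow-up, uniform on
8–16 years, and exponential dropout (0.01/person-year). An exponential
baseline (rather than Weibull) suffices because every downstream
estimator consumes times and rates, not hazard shapes. Mortality runs
on its own, longer time scale: follow-up extends 6 years past the
incidence window, and prostate-cancer death is simulated only among
diagnosed cases (0.015/person-year after diagnosis). Non-cancer death
is subsumed in censoring; competing-risk structure is deliberately out
of scope.

**PSA.** log-PSA = intercept + 0.025·(age−55) + 0.3·(Σβ·dosage, centred)
+ 1.7·w(Δt)·1{case} + N(0, 0.7²), with the pre-clinical elevation weight
w(Δt) = max(0, 1 − Δt/10) linear over a 10-year window before an
observed diagnosis — chosen so that baseline PSA is informative at
exactly the analysis horizon. The age slope corresponds to the observed
rise of screening cut-offs across the 55–74 age span.

**Gleason grade.** Among cases, P(Gleason ≥ 7) follows a logistic link
on centred log-PSA (0.35) and latent risk (0.20) with intercept −0.80.

**Calibration.** The defaults were set once so that a 30,000-man cohort
reproduces the headline structure of the reference screening arm:
incidence ≈ 10–11 events per 1,000 person-years (≈ 11–12% cumulative
over ~12 years), PRS AUC ≈ 0.61–0.63, baseline-PSA 10-year tdAUC ≈ 0.80,
and Gleason ≥ 7 in ≈ 38% of detected cases. What the simulator does
*not* emulate: linkage disequilibrium between SNPs, multi-round PSA
trajectories, PSA assay noise structure, ancestry stratification, DRE
screening, or informative censoring. Passing tests on synthetic cohorts
therefore validate the estimators and the pipeline logic, not the
transportability of any specific cut-off value to real populations.

## PRS construction

Missing dosages are imputed as the homozygous-major-allele genotype
with the major allele determined among controls (cancer-free men):
dosage 0 when the risk allele is minor among controls (frequency
< 0.5), else 2. Per-SNP association is a univariate additive logistic
regression of case status on dosage; a SNP is validated when its Wald
p < α (default 0.05, two-sided, no multiplicity correction — exposed in
config) *and* its fitted log-OR is positive under risk-allele coding,
i.e. direction-consistent with the published risk allele. Strand or
allele mismatches against the panel are hard errors, never
auto-corrected: a silent flip corrupts the score's sign.

PRS1/PRS2 are unweighted dosage sums over all / validated SNPs; PRS3/
PRS4 weight dosages by the in-cohort univariate log-ORs (published
betas are kept only for the direction check). AUC is the Mann–Whitney
statistic with ties counted ½; the DeLong structural-components
estimator provides AUC variances and pairwise tests. The variant with
the largest AUC is selected (ties → fewest SNPs, then unweighted) and
the cohort is split at the Youden-optimal score threshold, with ties
broken toward the smaller threshold (favouring sensitivity). The same
Youden convention is used for every threshold in the package.

## Time-dependent ROC with IPCW

The estimator is the cumulative-case / dynamic-control variant: at
horizon t (default 10 years) cases are subjects with an event by t
(events at exactly t count as cases) and controls are subjects
event-free and under observation at t. Censoring is corrected with
Kaplan–Meier IPCW: Ĝ is the KM estimator of the censoring survivor
function (ties convention: events precede censorings at equal times, so
the at-risk set for a censoring at t is {T ≥ t}); cases weight 1/Ĝ(T−),
controls 1/Ĝ(t), subjects censored before t weight 0. The threshold
grid is the sorted unique marker values — the exact empirical curve, not
a lattice — and tdAUC is the trapezoid over that curve, which reduces
*exactly*, at every threshold, to the binary ROC when censoring is
absent. Riser conventions differ across published tdROC
implementations (conditional vs marginal weighting, tie handling); the
conventions here are fully specified so results are bit-reproducible
given a cohort, but are not asserted to be identical to any particular
package.

Stratified cut-off tables run this estimator per (PRS stratum × age
group) cell, flagging cells with fewer than 20 horizon cases as
unreliable rather than silently reporting them. Percentile bootstrap
intervals (default B = 2,000, matching the reference analysis) resample
participants with replacement. A fixed table of the published cut-offs
(overall 1.41/1.46/1.59/2.12 ng/mL by age; low-PRS 1.42/1.65/1.60/2.24;
high-PRS 1.48/1.47/1.89/2.72; stratum-level 1.42 and 1.62) can be used
instead of derivation (`cutoff_source: published`).

## Survival analyses

Person-year rates are events divided by person-years in thousands
(hence directly "per 1,000 PYs"); incidence and mortality keep separate
follow-up columns. Cox models are fitted by partial likelihood with
Efron tie handling; categorical covariates are expanded with an
explicit "missing" level so incomplete covariate data never drop
participants; CIs are Wald on the log scale. The Newton stopping
tolerance is exposed (`precision`): the default 1e-9 suits
cohort-scale fits, while tiny fixtures compared against grid-search
optima need ~1e-14 because the stop rule includes the log-likelihood
change, which is quadratic in the parameter error. When the
unpenalised fit diverges (monotone likelihood from a sparse factor
level — expected occasionally in 16-level codings on small cohorts),
the fit is retried with a light ridge penalty (1e-3) and flagged
`penalized`.

The two interaction codings follow the analysis design: (i) within each
age group, a 4-level factor {low/PSA−, low/PSA+, high/PSA−, high/PSA+}
with low/PSA− as the within-stratum reference; (ii) a single 16-level
factor (4 combinations × 4 age groups) with low/PSA− aged <60 as the
uniform reference. Reference levels are reported as HR 1 with no CI.

## Screening strategies

All four rules act on baseline PSA with strict inequality
(PSA > cut-off), making the traditional rule's boundary behaviour
(PSA = 4.0 → negative) explicit. The high-PRS-restricted strategy
classifies every low-PRS participant negative regardless of PSA. The
case definition for confusion matrices is diagnosis during available
incidence follow-up (a 10-year-restricted variant is a config switch).
Two false-positive proportions are reported and labelled, because both
appear in practice: FP among positive screens (= 100 − PPV) and FP
among all participants. High-grade detection is Gleason ≥ 7 true
positives over all true positives. Proportions get exact
Clopper–Pearson CIs; paired strategy comparisons use McNemar restricted
to cases (sensitivity) or non-cases (specificity) — exact binomial below
25 discordant pairs, else the χ² form (b−c)²/(b+c) without continuity
correction; no discordant pairs gives p = 1 by convention.

## Numerical and design choices

- Youden index everywhere a "ROC-based cut-off" is needed; ties toward
  the smaller threshold.
- Imputation tie (risk-allele frequency exactly 0.5 in controls) counts
  the risk allele as major → dosage 2.
- ROC/tdROC curves computed by sorted cumulative sums, O(n log n), so
  cohort-scale inputs need no quadratic memory; the O(n²) pair-counting
  definition is retained in the tests as the oracle.
- Single-seed policy: one master seed spawns per-stage substreams
  (`numpy` SeedSequence), so any stage can be re-run in isolation.
- All artifacts are CSV/JSON — audit-friendly at this data scale.

## Problem sizes in tests and the acceptance script

Monte-Carlo checks use the smallest sizes at which the signal under
test clearly exceeds its sampling noise: calibration and Hardy–Weinberg
at n = 30,000; null tdAUC at n = 20,000; Cox parameter recovery at 50
replicates of n = 5,000; logistic type-I error over 1,000 replicates of
n = 2,000; the age-monotonicity of derived cut-offs over 20 seeds of
n = 25,000 (per-cell Youden thresholds are noisy below roughly 2,000
cases per stratum, so smaller cohorts mostly measure noise). The
acceptance script's synthetic run uses n = 25,000.

## Known limitations

- PRS weights are in-cohort univariate log-ORs; no shrinkage, LD
  adjustment or external-weight option.
- The tdROC estimator is marginal KM-IPCW; covariate-conditional
  censoring models and competing-risk (Fine–Gray) variants are not
  implemented.
- The 16-level interaction coding can be event-sparse in small cohorts;
  the ridge fallback stabilises the fit but shrinks extreme levels
  toward the null — inspect the `penalized` flag.
- Bootstrap cut-off intervals are percentile-only (no BCa).
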