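# Methods

## Case ascertainment from claims

A person is a case under window length k (years) when, inside the lookback
(claims from 1983-01-01, hospitalizations from 1987-01-01, both until the
person's interview date), they have ≥ 1 asthma hospitalization or ≥ 2 asthma
physician claims at most ⌊k × 365.25⌋ days apart. The day-difference rule is
used rather than calendar-year anniversaries because it is unambiguous,
leap-safe, and monotone in k; with k = 30 no eligible pair can exceed the
threshold, so that algorithm reduces to "any two claims in the lookback".
After normalization claim dates are distinct per person, so the minimum gap
over consecutive sorted dates equals the minimum over all pairs and the
detection runs in linear time (the equivalence is property-tested against an
all-pairs oracle).

Diagnosis codes match on the three-character rubric after stripping
punctuation: 493 (ICD-9) for all physician claims and for hospitalizations
through 2005, J45 (ICD-10) for hospitalizations from 2006. Wrong-era codes
(e.g. an ICD-9 hospital code after 2005) are accepted with a warning by
default and can be rejected with `strict_era`; the claims file is documented
as ICD-9 throughout, so ICD-10 claims are accepted but flagged. Encounters
collapse to one per person-day, a hospitalization winning a shared day.
The pre-1995 sampling definition (≥ 2 claims or ≥ 1 hospitalization until
1994-12-31, any spacing) is the same rule with a fixed lookback end and an
effectively infinite window.

## Design weights and agreement statistics

Strata cross BCG vaccination with childhood asthma under the sampling
definition. The weight in stratum s is n_cohort(s)/n_survey(s), computed
from realized counts; weights are deliberately not normalized, and all
interval estimates use the actual number of contributing respondents as the
effective sample size. This convention is simple and honest about the
information content of the survey, but it ignores the variance inflation
from unequal weighting; intervals for strongly design-dependent quantities
are therefore somewhat anti-conservative. Kappa intervals use the
Fleiss–Cohen–Everitt large-sample variance evaluated at the weighted cell
proportions. The standard error used for overall, positive and negative
agreement is √(P(1−P)/n); for Ppos/Pneg no closed form is canonical, so a
person-level multinomial bootstrap is available as an alternative
(`method="bootstrap"`). All intervals are clipped to their valid ranges.
Persons with a missing self-report are dropped pairwise; administrative
status is complete by construction.

## Determinants of agreement

The outcome is concordance between the 30-year algorithm and self-reported
physician-diagnosed asthma. Models are fitted by IRLS on the weighted score
equations (gradient max-norm < 1e-8, ≤ 50 sweeps) with sandwich covariance
B⁻¹MB⁻¹, where B is the weighted information and M the outer-product sum of
per-person weighted scores w·x·(y−p) — weight-only linearization, the same
estimator SAS's survey logistic procedure uses without finite-population
correction. Stratification is not additionally absorbed into the variance;
with near-equal stratum sizes the effect is small. Quasi-separation is
reported as an error when a coefficient exceeds 25 on the logit scale, and
rank-deficient designs name their aliased columns.

Purposeful selection screens each candidate's univariable multi-degree Wald
p-value against 0.25 (strict `<`, configurable), fits all entrants jointly,
and retains those still under the threshold. Categorical reference levels
are the field-conventional baselines (males, French, both parents born in
Quebec, etc.).

Missing categorical covariates are multiply imputed (m = 20 by default) by
weighted multinomial draws from the observed distribution within
(outcome × sampling stratum) cells, falling back to coarser margins when a
cell has no donor; fits are pooled by Rubin's rules (total variance =
mean within + (1 + 1/m) × between). A chained-equations MCMC imputer was
deliberately not used: every covariate here is categorical, cell-conditional
draws preserve the outcome association that matters for congeniality, and
the imputer stays fully seedable with no extra dependency. With no missing
data each imputation is the observed data and pooling reproduces the single
fit exactly.

## Sensitivity analyses

*Re-inclusion.* The survey frame excluded persons who failed the sampling
definition but had one asthma claim before 1995 (≈ 5.9% of eligible
non-asthma persons; the generator reproduces this rate and the pipeline uses
the realized value). The scenario adds
excluded_fraction/(1 − excluded_fraction) × (surveyed non-asthma count)
hypothetical participants — rounded to whole persons, allocated
proportionally across the two non-asthma strata (the original allocation is
unknown; proportionality is the neutral choice) — as administrative
negatives, routes report_fraction of them to the self-positive cell and the
rest to the concordant-negative cell with their stratum weights, and
recomputes κ. κ is monotone non-increasing in report_fraction
(property-tested), so report_fraction = 1 is the worst case.

*Coverage gaps.* Persons with any insurance interruption intersecting
1983–1994 (the checkable period) are removed and statistics recomputed.

*Stratified agreement.* Among persons with ≥ 1 asthma service who are
positive by either source, percent agreement is tabulated by age at first
service (8–11, 12–17, ≥ 18), age at last service (same bins), service-span
duration (0–5, 6–10, 11–20, ≥ 21 years) and hospitalization history. Ages
are floors of years since the common birth anchor 1974-07-01 (exact
birthdates are synthetic); duration is (last − first)/365.25. Empty bins are
reported as empty, not 0%.

## The synthetic cohort generator

Each person draws a latent class — never (83.5%), transient childhood
asthma (9.5%), persistent (4.0%), adult-onset (3.0%) — with onset and
duration in years (transient: onset U[2,8], duration U[3,12]; persistent:
onset U[2,12] to interview; adult-onset: onset U[18,35] to interview).
Claims arise as a homogeneous Poisson process over the active disease period
intersected with the claims era (rates 0.9/0.7/0.7 per active year),
hospitalizations likewise at 0.012–0.02 per year within the hospital era.
The never class holds 0/1/2 stray claims with probabilities
0.885/0.100/0.015, which reproduces a ~5.9% single-claim exclusion rate in
the pre-1995 frame. Self-report sensitivity is logistic in disease duration
with a hospitalization bonus, expit(−0.8 + 0.20·duration + 1.5·hosp), and
never-class persons falsely report at 5.5%; physician confirmation follows
at 95% (true disease) or 55% (false positives). These coefficients are
configuration chosen once so the sampled survey sits in the intended regime
— crude algorithm prevalence near one half, design-corrected prevalence in
the low teens, self-report a few points higher, agreement in the good band,
and a rising duration→agreement gradient — not estimates of any real
utilization process.

Covariates are categorical draws matching the published corrected
distributions, independent of disease except parental asthma history
(enriched in disease classes) and the allergy-services indicator, which is
generated at a higher rate among persons whose two sources disagree so that
the determinant analysis has a recoverable signal with OR < 1.

Sampling invites per-stratum target/participation persons (participation
0.56), thins by Bernoulli response, and computes weights from the realized
counts over the eligible frame (post-exclusion), so weight totals equal the
eligible cohort size. Recovery tests compare survey-weighted estimates with
eligible-frame cohort values: on 200 draws from a 20,000-person cohort the
mean weighted prevalence is within 0.25 points and mean weighted κ within
0.015 of the cohort values. The generated cohort also exhibits the
inflation the re-inclusion scenario probes: κ on the full cohort is visibly
lower than on the eligible frame.

What the generator does not emulate: real billing behaviour and code
miscoding, within-person utilization correlation beyond the latent class,
the BCG–asthma association (BCG is an independent coin flip), covariate
correlation structure, and informative nonresponse. Passing recovery tests
therefore demonstrates correctness of the estimators under the assumed
data-generating process, not the validity of any substantive claim about
real administrative data.

## Problem sizes and numerical choices

Tests run the generator at 8,000–20,000 persons and 200 Monte-Carlo
replicates where distributional claims are made; the end-to-end
reproducibility check uses a 20,000-person cohort, chosen as the smallest
size at which all realized strata stay comfortably above the per-stratum
target. The acceptance script uses 40,000. Logistic fits converge at
gradient max-norm 1e-8; weighted proportions must sum to 1 within 1e-9;
kappa is undefined (error) when chance agreement reaches 1. All randomness
flows through `numpy.random.default_rng` from explicit seeds; reruns with
the same config and seed are byte-identical.
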