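# Methods

## Study design and data model

The package analyzes retrospective case-control samples: fixed numbers of
cases and controls, binary exposures, and interest in exposure-disease
odds ratios (which a case-control design identifies) and in the fraction
of cases attributable to modifiable exposures. Every indicator is
three-valued — *yes*, *no*, *unknown* — and *unknown* is never collapsed
into *no*; all estimators operate on the complete-case subset for exactly
the variables they use (listwise deletion per model), and report the
per-model case/control counts so that the filtering is auditable.

Two derivation rules convert raw questionnaire-style fields into analysis
variables for cases:

* an event (first head injury, start of pesticide exposure) occurring in
  the same whole year as disease onset or later is not counted as an
  event, because it cannot have preceded the disease;
* a sensitivity recode additionally discounts head injuries within a
  10-year window before onset, guarding against reverse causation
  (prodromal balance impairment causing falls). The window is a parameter
  (`ten_year_window`, years, default 10).

Ages compare on floored whole years because the source instrument
collects whole-year ages. Exposure duration is `end − start` with no
inclusive +1 adjustment; no authoritative rule exists for partial years,
and the choice only affects a per-year continuous covariate. Controls
have no onset age and are never censored.

## Association estimators

**Crude odds ratios.** Cross-product `ad/bc` with the Woolf interval
`exp(log OR ± z·√(Σ 1/cell))`. The Haldane–Anscombe correction adds 0.5
to all four cells — always, not only on zero cells — before both the
point estimate and the variance; it is the estimator used for the
descriptive feature table and is mandatory when a cell is zero (an
uncorrected zero-cell table raises an error that points to the
correction). Note the corrected estimator equals 1 for an all-absent
exposure only when the two arms have equal size.

**Directional convention.** Risk factors are tested one-sided (the
alternative is increased risk), so the reported interval is a lower bound
only: the lower limit of the two-sided `2L−1` interval for a one-sided
level `L` (e.g. the two-sided 90% lower bound for one-sided 95%), with an
upper-tail Wald p-value. Feature tables use ordinary two-sided 95%
intervals. The upper limit of a one-sided interval is reported as +∞.

**Adjusted odds ratios.** Multivariable logistic regression maximized by
damped Newton/IRLS: relative log-likelihood tolerance 1e-10, at most 100
iterations, step-halving (up to 30 halvings) whenever a full Newton step
would decrease the likelihood. The covariance is the inverse observed
information at the optimum. Rank deficiency raises a collinearity error
naming the most involved column (via the smallest right singular vector);
any coefficient exceeding 15 in absolute value on the log-odds scale
raises a separation error naming the column. This bound is far outside
any plausible epidemiological odds ratio (e^15 ≈ 3.3M) while small enough
to trigger within a few diverging iterations. Sex is structurally
excluded as a covariate inside sex strata, and sex-restricted exposures
(present only in males) make the pooled model prone to separation — the
error is raised and named, never silently smoothed, and stratified models
are the supported route. Continuous covariates (age, exposure duration)
enter untransformed, so their odds ratios are per year.

**Interaction screens.** A pairwise product term added to the conditional
model, tested two-sided by Wald. Whether published interaction screens of
this kind are one- or two-sided is typically unstated; two-sided is the
conservative reading and is what the package implements.

**One-proportion test.** `z = (k/n − p0)/√(p0(1−p0)/n)` with a two-sided
normal p-value and no continuity correction. Against the exact binomial
this is accurate to about 0.01–0.015 in the tail regimes the package
reports; a continuity-corrected variant was deliberately not added
because the plain z-statistic is the stated method of the workflows this
package supports.

## Attributable fractions

**Miettinen point estimate.** `PAF = pc·(1 − 1/OR)` with `pc` the
exposure prevalence among analyzed cases and the adjusted odds ratio
standing in for the relative risk under the rare-disease assumption. For
adjustment, the OR is the exposure coefficient of the multivariable
logistic fit, and — deliberately — `pc` is computed on the cases of that
same complete-case subset, not on the larger marginal sample, so both
determinants describe one sample.

**Bruzzi (model-based) estimate.** `PAF = 1 − (1/n_cases)·Σ exp(−xᵢβ)`
over the cases' observed exposure values with confounders held at their
observed values. For a single binary exposure this reduces algebraically
to the Miettinen formula (the package tests the identity to 1e-10);
under confounding it is the preferable estimator and is validated
against enumerated generative truth.

**Joint PAF.** `1 − Π(1 − PAFᵢ)` for independent, non-interacting
exposures; the package's interaction screen is the empirical check of
that assumption. Interval bounds propagate by applying the same formula
to the component lower bounds and to the component upper bounds. This
bound set is not a formal confidence procedure — it inherits whatever
coverage the component intervals have — but it is the standard reporting
convention for joint fractions.

**Intervals.** The primary interval is a stratified case-control
percentile bootstrap: cases and controls are resampled with replacement
as separate strata (preserving the design's fixed margins), the full
adjusted-PAF pipeline (complete-case filter, refit, prevalence) is
recomputed per resample, and the percentile interval is taken. Resamples
whose fit fails (separation/collinearity, possible when an exposure is
rare) are dropped and counted; more than 5% failures is an error rather
than a silently biased interval. A delta-method variance (binomial `pc`,
Wald coefficient variance, covariance ignored) is provided as a fast
cross-check; influence-function sandwich variances exist in the
literature for this estimator, but the bootstrap is fully specifiable
within the package and is therefore the primary method. Protective
exposures (OR < 1) yield negative PAFs, which are flagged with a warning
and never clamped.

## Synthetic cohort generator

The generator defines the conditions under which the estimators are
validated: a super-population with sex drawn at `male_fraction` (default
0.45), independent Bernoulli exposures (male-only exposures forced absent
in females), disease probability
`logistic(baseline_logit + Σ log ORᵢ·xᵢ + interaction terms)`, and
rejection sampling until the case and control quotas are met — which
reproduces the retrospective design exactly, so realized sample odds
ratios are unbiased for the generative ones. The study-scale default is
808 cases / 415 controls, baseline log-odds −6 (rare disease, so the
OR ≈ RR approximation underlying Miettinen's formula holds in the
generator), and five exposures at prevalences 15%, 11%, 3% (male-only),
14% and 0.6% (male-only) with odds ratios 2.8, 1.3, 3.7, 2.2 and 10.8.
Ages are truncated normal per arm (cases 68.3 ± 8.7, controls 66.1 ± 8.6,
minimum 18), onset lags the questionnaire age by |N(9, 5)| years, head
injuries are placed uniformly before onset, pesticide exposure windows
start uniformly in [5, 40] with exponential (mean 12 y) durations capped
at the pre-onset horizon, and per-item missingness is completely at
random with default rates mirroring per-item response accounting (late-
added items missing for ~25–40% of subjects).

With the 0.6%-prevalence male-only exposure, the expected number of
exposed controls is about one, and the pooled or male conditional model
separates on a substantial fraction of seeds — faithfully reproducing how
borderline such an exposure is at this design size (its one-sided
interval stretches to +∞ from a lower bound barely above 1). Validation
experiments that require a stable full-model fit therefore use the
four-exposure configuration without it.

What the generator does **not** emulate: exposure-exposure correlation
(independence is assumed and the interaction screen is calibrated under
it), enrollment bias in the sex ratio (the real-world analogue had
spouse controls and a strong case-control sex differential; here the sex
difference between arms arises only through male-only risk exposures),
informative missingness, recall error, and post-onset event reporting
(event ages are always pre-onset, so the pre-onset censoring rule is a
no-op on clean synthetic data; the censoring logic itself is unit-tested
on hand-constructed records). Passing recovery tests therefore
demonstrate correctness of the estimators under the stated model, not
robustness to those real-data pathologies.

`true_paf` enumerates the generative model (all exposure combinations ×
sex) and returns `1 − P₀(D)/P(D)` where `P₀` sets the exposure to zero
for everyone — the exact causal PAF implied by a configuration, used as
ground truth in coverage experiments.

## Validation problem sizes

The suite validates calibration at the study's own scale, chosen as the
realistic regime for these estimators: adjusted-OR recovery and Wald
coverage over 200 replicates of 808/415 cohorts; interaction type-I
error over 200 null replicates; bootstrap PAF coverage over 200
replicates with B = 200 resamples each, against the enumerated truth;
2×2-versus-logistic equivalence over 1,000 random tables. Monte-Carlo
acceptance bands are ±3.3σ binomial bands around the nominal rate
(coverage within [0.90, 1.00], type-I rate within [0.02, 0.10]); the
percentile bootstrap is allowed mild undercoverage ([0.88, 0.99]), its
known small-sample behavior.

## Known limitations

* Wald inference throughout; no exact/conditional (Fisher-style) methods
  and no Firth penalization for separated designs.
* The joint-PAF interval is bound propagation, not a joint resampling
  interval.
* Complete-case analysis assumes missingness at random per model.
* The CSV schema is the package's own canonical snake_case layout (a
  header-mapping option accommodates alternate names); it is not a
  standard interchange format.
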