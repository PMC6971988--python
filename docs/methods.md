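# Methods

This note records the statistical model behind `pediprev`, the defaults
and why they were chosen, and what the simulation evidence does and
does not show.

## Setting and estimands

A birth cohort of children is followed in a primary-care EHR. At
baseline (ages 2–5) essentially every child has a BMI measurement; at
follow-up (ages 6–9 or 10–14) a fraction does not. Four covariates are
observed for everyone: sex, rural/urban residence, ordinal household
income (1 = basic subsistence, 2 = <18k€, 3 = 18–<100k€, 4 = ≥100k€)
and baseline weight status. The estimand is the full-cohort prevalence
of the four follow-up weight-status categories; the threat is selection
on who gets measured.

Three estimators are compared on identical cohorts:

* **complete case** — category proportions among measured children;
* **stabilized IPW** — SW_i = f(measured)/f(measured | x_i), numerator
  the unconditional empirical fraction (no model), denominator a
  logistic fit on the four covariates; prevalence Σwy/Σw;
* **MI** — m completed datasets from a multinomial-logistic imputation
  model on the same covariates, pooled by Rubin's rules.

Both corrections assume missingness is MAR given the four covariates.
The package deliberately ships an MNAR switch (missingness driven by
the unobserved follow-up status) as a negative control: under it all
three estimators fail together, which is the honest boundary of the
method.

## Weight-status classification

z = ((x/M)^L − 1)/(L·S), with the log form ln(x/M)/S used for
|L| < 1e-8 where the Box-Cox expression degenerates (the two forms
differ by ~L·z²/2, so the switch point is far below measurement
resolution). Category cut points are shared by both age schemes:
z < −2, −2 ≤ z ≤ 1, 1 < z ≤ 2, z > 2; the boundary values −2 and +1
belong to "normal" and +2 to the third category. |z| ≥ 5 on either
measurement occasion is treated as a data-entry artifact and the record
dropped before estimation; the count of exclusions is reported for the
study flowchart. The shipped LMS table
(`growth_status.synthetic_lms_table`) is a synthetic reference with
smooth, plausible L/M/S curves for exercising the machinery — it is not
any published growth standard, and analyses that need real z-scores
must supply their own table (CSV: sex, age_months, L, M, S).

## Synthetic cohort generator

The generator is the ground truth for every validation claim, so its
defaults are fixed to the motivating cohort's published marginals
(n = 10,811; 49.1% girls; 40.4% urban; income split 4.7/43.1/51.3/0.9%;
baseline status 0.7/70.6/21.2/7.5%). Two printed-table quirks are worth
recording: the income counts sum to 10,810 rather than 10,811 (the
probabilities are normalized accordingly), and one coverage-table cell
prints 30.4% where its own counts give 30.3% (recomputation reports
30.3).

Baseline z is drawn by category-then-quantile: the category comes from
the configured multinomial, then z is a truncated standard normal on
that category's z-interval (tails truncated at |z| = 4.99 so every
generated record passes the plausibility filter). This guarantees exact
label/z consistency while keeping a continuous z. Follow-up z is
ρ·z_base + √(1−ρ²)·ε. The baseline–follow-up correlation ρ is a free
simulation parameter — no published value exists for it — set to 0.6 by
default (tracking across 4–9 years of childhood); the designed-bias
experiments use 0.8 to make baseline status strongly predictive.
Because the category probabilities are not the standard-normal interval
masses, the marginal z is a reweighted normal mixture; the follow-up
category probabilities are therefore computed analytically
(`true_followup_probs`) by integrating the conditional normal over each
baseline category's truncated density. The minute mass of follow-up
draws beyond |z| = 5 (removed later by the filter) is below Monte-Carlo
resolution and ignored in the oracle.

Missingness is generated as P(measured) = expit(β₀ + Σ log-OR · x) with
β₀ calibrated by root-finding (Brent on [−20, 20], monotone in β₀, mean
fitted probability within 1e-6 of the target rate). Keys on observed
covariates give MAR; optional `follow_*` keys give MNAR. Target rates 0
and 1 are feasible only with all log-ORs zero. The calibrated configs
use the published adjusted ORs (e.g. basic income 0.40, mid income
1.70, urban 0.79 at ages 6–9) and the published measured rates 95.1% /
88.9%.

One record per child per analysis window; ages are sampled uniformly
within the window for per-age analyses. Real-data features the
generator does **not** emulate: longitudinal trajectories and
growth-velocity correlation beyond a single ρ, household clustering,
migration, age-varying missingness within a window, and the rise of
obesity prevalence with age (the generator's follow-up marginal is
whatever the mixture implies, ~4% obese at ρ = 0.6 rather than the
published ~13%). Passing tests therefore validate the estimators'
statistical behaviour under the assumed structure, not the cohort's
actual prevalence levels.

## Missingness model and weights

Dummy coding with the published reference levels (boy, normal weight,
income <18k€, rural) keeps the OR table comparable to the published
layout. CIs are Wald on the log-odds scale (the source does not state a
CI method; Wald matches standard logistic output). The default fit is
plain ML via statsmodels; `ridge > 0` switches to a MAP fit under a
Gaussian prior (shared Newton solver, see below) for small samples
where a rare covariate level can have zero not-measured children — at
n = 5,000 the ≥100k€ income level holds ~45 children and ~4% of them
unmeasured, so occasional replicates are separated. On the full-size
cohort the ridge changes coefficients by <0.02.

Weights exist only for measured children; any fitted denominator below
1e-6 raises a positivity error. No truncation is applied by default.
Under a saturated model Σ SW over measured children equals the measured
count exactly; under the main-effects model it agrees within a fraction
of a percent. Variance treats the weights as fixed (the survey
`pweight` convention, and explicitly out of scope to correct):
var = n/(n−1) · Σ(w(y−p̂))²/(Σw)². This is known to be conservative
when the weight model is strongly predictive of the outcome — measured
empirically below.

## Prevalence, CIs, standardization

All four categories are estimated from one multinomial indicator set,
so they sum to 1 by construction. CIs are Wald on the logit scale
back-transformed (kept inside (0,1); plain Wald optional; degenerate
p ∈ {0,1} collapses the interval). The finite-sample factor n/(n−1)
makes the unweighted variance exactly p(1−p)/(n−1). Age adjustment is
direct standardization, p_adj = Σ π_a p̂_a, var = Σ π_a² var_a, with the
full cohort's age distribution as the internal standard when none is
given (the source does not state its age-adjustment method).

## Imputation

The 4-level status is imputed directly with a multinomial-logistic
model (baseline category: normal weight) rather than imputing a
continuous z and classifying — the analysis target is categorical and
the published predictor list matches a categorical model. The fit is a
MAP estimate under a Gaussian prior of precision 0.16 (SD 2.5 on the
log-odds scale, the usual weakly-informative default for logistic
models) on slopes only; intercepts are unpenalized so an intercept-only
model reproduces observed frequencies exactly. The prior is not
cosmetic: realistic cohorts have structural zeros (no underweight
follow-ups among baseline at-risk children), where the MLE diverges,
and — more subtly — an almost-flat likelihood direction gives the
proper-imputation draws β* ~ MVN(β̂, V̂) enormous spread, whose softmax
nonlinearity then biases imputed probabilities (a Jensen effect). With
SD 10 priors this bias was measurable (≈0.14 pp on a 9.9% prevalence);
with SD 2.5 it is statistically indistinguishable from zero at 200
replicates while well-identified coefficients shrink by ~λ/I ≈ 0.2%.

Imputation is proper (parameter draw per imputation), approximating a
posterior-draw MCMC scheme; with a single categorical target variable
full chained equations add nothing. Pooling uses the classic
large-sample Rubin df (n ≫ m here; the Barnard–Rubin correction is a
one-line switch if ever needed); B = 0 falls back to the normal
quantile, and identical estimates up to float noise are snapped to
B = 0. m defaults to 10.

## Numerical choices

* Shared Newton solver for the (penalized) multinomial likelihood:
  step-halving on the penalized log-likelihood, convergence at max
  |gradient| < 1e-6 (log-likelihood units; parameter error ~1e-10 at
  that point) or at a vanishing accepted step, which signals the
  objective has reached float precision. `ridge = 0` reproduces
  statsmodels MNLogit to ~1e-14 on dense data (asserted in a test).
* Truncated-normal draws by inverse-CDF on the category's quantile
  interval; intercept calibration by Brent root-finding (unique root,
  expit monotone in β₀).
* All randomness flows from integer seeds through
  `numpy.random.SeedSequence`; identical seeds give byte-identical
  cohort CSVs.

## Simulation evidence (computed by the tests / acceptance script)

Problem sizes: marginal checks at n = 10⁵; parameter recovery at
n = 50,000; the designed-bias MAR experiment at 200 replicates of
n = 5,000; the MNAR control at 50 replicates; CI coverage at 500
replicates of n = 5,000; concordance on single calibrated cohorts of
n = 10,811.

* Designed-bias scenario (obesity-enriched baseline, ρ = 0.8, measured
  rate 0.70, baseline-overweight/obese measurement OR 0.15): exact
  stratum enumeration gives a −3.4 pp complete-case obesity bias;
  simulated IPW and MI means sit within Monte-Carlo error of the
  analytic truth.
* Calibrated scenario: the three estimators' obesity prevalences agree
  within a few hundredths of a pp — the concordance the motivating
  study reported.
* MNAR control: complete case, IPW and MI are all ≈3 pp low; no
  covariate-based correction can see outcome-driven missingness.
* CI coverage: under calibrated missingness the logit-Wald IPW
  intervals cover at ~95% for all four categories. Under the strongly
  status-driven bias scenario coverage rises to ~97–98% — the expected
  conservatism of fixed-weight variance, not a CI defect; it is why the
  coverage experiment is run under the calibrated regime.

## Known limitations

* MAR-given-covariates is assumed, not testable from the data; the MNAR
  control quantifies the failure mode but cannot fix it.
* Weight-estimation uncertainty is ignored in the IPW variance
  (conservative); no doubly-robust estimator is provided.
* The generator's cross-sectional model understates follow-up obesity
  relative to real cohorts; level-dependent conclusions should not be
  read off the synthetic prevalences.
* The WHO-style tail ("restricted") z-score adjustment beyond ±3 SD is
  not applied; the plausibility filter acts on raw z.
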