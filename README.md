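# pediprev

Selection-bias evaluation for childhood weight-status prevalence
estimated from incomplete electronic-health-record (EHR) anthropometrics.

## The problem

Primary-care EHRs hold routine height/weight measurements and are an
attractive, cheap source for childhood obesity surveillance. But
children are only measured when they attend (and are measured at) a
visit, and attendance is not random: family income, sex, residence and
the child's own weight history all shift the probability that a BMI
value exists in the record. Prevalence computed from the measured
children alone (*complete-case* analysis) is then potentially biased.

`pediprev` implements the standard correction toolkit for this setting
and a synthetic cohort generator that serves as ground truth for
validating it:

* **Weight-status classification.** BMI = kg/m²; BMI-for-age z-scores
  via the LMS method, z = ((x/M)^L − 1)/(L·S) with the L → 0 log limit;
  categories cut at −2, +1, +2 SD (for ages 2–5: underweight / normal /
  at risk of overweight / overweight-obese; above 5: underweight /
  normal / overweight / obese). Records with |z| ≥ 5 are excluded as
  implausible.
* **Missingness model.** Logistic regression of the measured /
  not-measured flag on sex, baseline (2–5 y) weight status, household
  income (4 ordinal levels) and rural/urban residence, reported as an
  adjusted odds-ratio table with Wald 95% CIs.
* **Stabilized IPW.** SW_i = P(measured) / P(measured | x_i): the
  numerator is the empirical measured fraction, the denominator the
  fitted probability. Weighted prevalence p̂ = Σwy/Σw with linearized
  (fixed-weight, survey `pweight`-style) variance and logit-Wald CIs.
* **Multiple imputation.** The 4-level follow-up status is imputed from
  a multinomial-logistic model on the same four covariates (MAP fit
  under a weakly-informative Gaussian prior, which sparse categories
  require), with proper parameter draws per imputation; m = 10 by
  default, pooled by Rubin's rules
  (T = W + (1 + 1/m)·B, t reference with the classic large-sample df).
* **Synthetic cohort generator.** Reproduces the motivating cohort's
  covariate marginals (n = 10,811), draws a baseline z-score consistent
  with its category, a correlated follow-up z-score
  (z' = ρz + √(1−ρ²)ε), and applies logistic missingness whose odds
  ratios and marginal measured rate are calibrated to the published
  values (95.1% measured at 6–9 y, 88.9% at 10–14 y). MAR and MNAR
  regimes are both available; analytic truth for every follow-up
  category probability is provided for oracle comparisons.

## Worked example

```python
from pediprev import run_comparison, mask_unmeasured
from pediprev.synthetic_cohort import calibrated_config, simulate_cohort, true_followup_probs

cfg = calibrated_config("6-9", seed=1)       # published ORs, 95.1% measured
cohort = mask_unmeasured(simulate_cohort(cfg))
print("measured:", int(cohort.measured.sum()), "of", len(cohort))
table = run_comparison(cohort, seed=1)
print(table[["method", "category", "estimate", "ci_low", "ci_high"]].round(4).to_string(index=False))
print("generator truth:", true_followup_probs(cfg).round(4))
```

prints

```
measured: 10269 of 10811
       method    category  estimate  ci_low  ci_high
complete_case underweight    0.0167  0.0143   0.0193
complete_case      normal    0.7748  0.7666   0.7827
complete_case  overweight    0.1700  0.1629   0.1774
complete_case       obese    0.0386  0.0350   0.0425
          ipw underweight    0.0167  0.0144   0.0194
          ipw      normal    0.7752  0.7670   0.7831
          ipw  overweight    0.1696  0.1625   0.1770
          ipw       obese    0.0385  0.0349   0.0424
           mi underweight    0.0167  0.0142   0.0192
           mi      normal    0.7752  0.7670   0.7834
           mi  overweight    0.1696  0.1623   0.1769
           mi       obese    0.0385  0.0348   0.0422
generator truth: [0.0166 0.7684 0.1747 0.0403]
```

Under the calibrated (mild, covariate-driven) missingness the three
estimators agree to a few hundredths of a percentage point and all sit
on the generator truth — the study's headline concordance finding. The
designed-bias scenario in `pediprev.experiments` shows the flip side:
when the heaviest children are strongly under-measured, complete-case
obesity prevalence is off by ≈3.4 pp while IPW and MI stay on truth,
and under MNAR missingness (driven by the unobserved outcome itself)
all three estimators fail together.

A CLI wraps the same pipeline:

```bash
pediprev simulate --seed 1 --out cohort.csv
pediprev missingness --cohort cohort.csv      # adjusted-OR table
pediprev prevalence --cohort cohort.csv --method all
```

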