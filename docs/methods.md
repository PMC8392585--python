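# Methods

This note records the statistical methods, numerical choices and known
limitations of the package. Nothing here depends on patient data; all
empirical statements are about the package's own seeded simulations.

## Model

The endpoint is binary: any on-treatment weekly CTCAE grade >= 2 of acute
salivary dysfunction. Patients with a non-zero baseline grade are excluded at
endpoint derivation. A longitudinal variant (mean weekly grade >= 1.5) and
actuarial (risk-set) weekly incidence are computed alongside.

Risk is modelled with multivariable logistic regression on four terms:
combined-parotid D98% (Gy), oral-cavity generalized equivalent uniform dose
with volume-effect parameter n = 0.05 (Gy), age in 5-year units, and smoking
history. The bundled `reference_model()` carries fixed coefficients
(intercept -7.233; slopes 0.038, 0.103, 0.079, 0.318) with Wald standard
errors, and is used both as the default generating model for synthetic
cohorts and as the frozen model in external-validation examples.

## Dose reduction

- DVHs are handled in cumulative (k+1 values on k+1 edges) and differential
  (k bin masses) forms with exact round-trip conversion. Readers accept
  Gy/cGy and cc/percent dialects; errors name the offending row.
- gEUD is `(sum_i v_i d_i^(1/n))^n` over the relative differential DVH,
  computed with the maximum bin dose factored out so small n (strongly
  serial) cannot overflow. The screening grid is n = 0.05 to 1.00 in steps
  of 0.05; n = 1 equals the mean dose analytically.
- Both parotids are pooled into one organ by summing differential volumes on
  a common 0.1 Gy grid (mass-preserving overlap rebinning).
- D98% is read off the cumulative curve by linear interpolation.

## Variable selection and fitting

- Candidate dose metrics are screened by two-sample t tests (pooled variance
  by default) of events vs non-events; the EUD n with the smallest p-value is
  selected, with a V30–V70/Dmean/Dmax/D98%/D2% cut-point family as fallback.
  Degenerate screens raise rather than fabricate an association.
- Clinical covariates enter a cross-validated L1-penalised logistic path
  (deviance loss). The penalty is chosen by the minimum-deviance or 1-SE
  rule; selection is read from a single L1 fit at the chosen penalty on the
  full standardized data.
- Selected features (dosimetric terms always retained) are refit by
  unpenalised maximum likelihood (Newton) to obtain the reported
  coefficients and Wald standard errors; odds ratios are `exp(beta)` with
  `exp(beta +/- 1.959964 * SE)` intervals. Perfect separation raises an
  error naming the culprit feature.

## Validation

- Discrimination: ROC AUC in the rank (Mann–Whitney) formulation, ties at
  1/2; its p-value by the asymptotic Mann–Whitney test.
- Calibration: slope from a logistic regression of outcome on the logit
  prediction; calibration-in-the-large from an intercept-only logistic model
  with the logit prediction as a fixed offset.
- Hosmer–Lemeshow: six equal-count risk groups (remainder to the lowest-risk
  groups; tied predictions never straddle a boundary), chi-squared with
  groups - 2 degrees of freedom.
- Classification at a 0.65 cutoff reports PPV/NPV; an empty call class
  leaves the value undefined (None), never zero.
- Internal validation uses Harrell's bootstrap optimism correction. The
  default recipe repeats LASSO selection inside each resample; a fit-only
  recipe is available. Resamples with a single outcome class or failed
  refits are skipped; more than 10% skips aborts the run.
- External validation applies a frozen model's coefficients unchanged and
  can report the validation cohort's own univariable odds ratios for
  effect-size comparison.
- Residuals (observed minus predicted) beyond +/-0.7 flag apparent
  radiosensitive/radioresistant outliers.

## Synthetic data generator

Each organ DVH is a plateau followed by a power-law fall-off on the
cumulative curve: three shape parameters (plateau end, fall-off end,
exponent) solved per patient by root-finding so the drawn (D98%, mean, max)
triple is matched exactly. (Mean, D98%) pairs are drawn bivariate normal with
correlation 0.88 for the combined parotids; targets are the development
cohort's moment table (cPG volume 53.3±19.3 cc, mean 47.2±9.5 Gy, max
74.2±3.5 Gy, D98% 26.8±9.5 Gy; oral cavity 64.8±20.4 cc, 46.7±6.4 Gy,
71.9±3.7 Gy).

Covariates are drawn independently from published prevalences (correlation
structure is not reported and is not modelled — a documented limitation).
Events are Bernoulli draws from the true model's predictions, optionally
odds-shifted; first-event weeks follow the cohort's cumulative weekly
incidence pattern (12, 26.5, 42, 53, 60, 68.2%), and weekly grade
trajectories are assembled so endpoint derivation reproduces the drawn event.
Everything is reproducible bit-for-bit from a seed
(`numpy.random.default_rng`, PCG64).

Scope notes:

- The oral-cavity D98% spread and correlation are assumptions (no published
  moments); only its volume/mean/max are matched to targets.
- With the reference coefficients the generator's mean event rate is
  ~0.73–0.75, self-consistent with the model's own predicted probabilities
  rather than pinned to any cohort's crude rate; an intercept-only model
  reproduces a chosen rate exactly.
- DVH-level realism only: no 3D dose, no anatomy, no longitudinal dose
  accumulation.

## Numerical choices

- EUD power means are computed in log space relative to the maximum dose.
- Probabilities are clipped to [1e-10, 1-1e-10] before logits in validation
  metrics.
- Logistic fits use statsmodels' Newton optimiser (tolerance 1e-8); the
  L1 path uses liblinear on standardized features.
- The nomogram scales the widest coefficient-times-range term to exactly
  100 points and maps total points back through the stored linear-predictor
  offset, so table lookups and the logistic formula agree to interpolation
  accuracy.

## Limitations

- All validation behaviour is demonstrated on synthetic cohorts; no claims
  are made about performance on real patients.
- Pooled-variance t screening assumes equal group variances (Welch is
  available but not the default).
- Harrell's correction underestimates optimism for severely overfit null
  models at small n; the acceptance check therefore averages over seeds.
- The bundled reference coefficients are fixed inputs, not re-derived from
  data by this package.
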