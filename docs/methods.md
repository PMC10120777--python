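# Methods

This note documents the statistical models implemented in `genderdx`,
the synthetic-data generator they are tested against, and the numerical
and design choices a maintainer should know about.

## Gender-diagnosticity score

The estimand is the posterior probability of female sex given a person's
diagnostic-code indicator vector.  The pipeline estimates it in four
steps on a random 50/25/25 train/validation/test partition
(largest-remainder rounding of fold sizes; ties broken train-first so the
split is deterministic in the seed and independent of row order).

1. **Indicator matrix.**  Code tokens are opaque strings, upper-cased and
   whitespace-stripped; no ICD-hierarchy truncation is attempted because
   administrative extracts mix 3- to 6-character codes.  Duplicate codes
   within a person collapse to a single indicator.
2. **Filters.**  A code is dropped if, in either the training or the
   validation fold, it occurs in fewer than two people or in only one
   sex.  The "either fold" reading keeps every retained code estimable in
   both folds, which the both-fold significance rule below requires.
3. **Screening.**  Univariate logistic regression of sex (female = 1) on
   each indicator.  With one binary predictor the MLE is closed-form: the
   slope is the log 2×2 cross-product odds ratio with Wald standard
   error sqrt(1/a + 1/b + 1/c + 1/d), so the screen is fully vectorized.
   The Wald test is the default; the equivalent-at-scale 2×2 G-statistic
   (LRT) is available via `method="lrt"` since sources differ on which
   was intended.  Benjamini–Hochberg adjustment is applied per fold
   (Bonferroni available by configuration) and a code is selected iff its
   adjusted p-value is below α = 0.05 in both folds.  Under a global
   null this intersection rule is far stricter than either fold's FDR
   alone; the acceptance suite checks a selection rate below 1%.
4. **Score model.**  One multivariable logistic regression of sex on all
   selected indicators, fitted on training only, without regularization.
   Perfectly collinear columns are dropped greedily in vocabulary order
   (incremental-Cholesky rank test, tolerance 1e-9 relative) with a
   logged warning.  IRLS convergence tolerance 1e-12 on deviance change,
   300 iterations maximum.  Scores for any fold apply the training
   coefficients; codes absent from a fold's vocabulary count as absent,
   and scores are clipped to [1e-12, 1 − 1e-12] so they are never exactly
   0 or 1.  An empty selection degrades to the intercept-only model,
   whose score is the training female fraction for everyone; the pipeline
   then skips score-based outcome models with a warning rather than fit a
   constant regressor.

By the logistic score equation, the mean fitted training score equals the
training female fraction exactly; this is asserted to 1e-8.

## Excess mortality

The analysis set is restricted to severe injuries with known 30-day
survival status and complete covariates (complete-case analysis; rows
in/out are logged per filter).  Each person contributes person-time t
(deaths on day d contribute d days, survivors 30 — the day-of-death
convention) and expected deaths E = annual_rate(sex, age, year) / 365.25
× t.  The annual rate is treated as constant within the window, which is
short relative to life-table resolution.

The default model is multiplicative relative mortality: Poisson
regression of the death indicator with log E as offset, so
log E[death] = log E + x'β and exp(β) are excess rate ratios relative to
the population baseline.  The intercept-only special case reproduces the
standardized mortality ratio O/E in closed form (asserted to 1e-8), and
doubling all offsets shifts only the intercept by −log 2 (the offset
contract).  An additive excess-hazard variant (mean = E + t·exp(x'β)) is
available as `form="additive"` for sensitivity; it is fitted by direct
likelihood maximization and does not support profiling.

Controls in Models 1–3: age (continuous), mechanism of injury
(categorical, reference "falls" — the most common mechanism in TBI
cohorts; the reference is logged), rurality, income quintile (linear),
and ADG comorbidity score.  Model 1 adds sex, Model 2 the gender score,
Model 3 both.  Models 1 and 2 therefore always share the same degrees of
freedom, which the Bayes-factor identity below requires.

## Discharge location

The analysis keeps acute-care records of people alive at discharge with a
recorded destination and complete covariates.  "Alive at discharge" is
operationalized as excluding records whose death follow-up time falls
within the length of stay; because the source taxonomy lists
died-in-facility under "other" while the analysis requires survival to
discharge, the alive filter is applied first and died-in-facility records
never enter the analysis set.  This is a documented resolution of a
genuine tension in the category definitions.

The outcome is a six-group baseline-category logit with "discharged
home" as reference.  Observed categories with fewer than two records are
dropped with a warning (reducing the df accordingly).  The intercept-only
fit equals log(n_k/n_home) per category exactly.  Controls: age, length
of stay (untransformed days; log-LOS by configuration), ADG score,
rurality, income quintile (linear, matching the mortality model;
categorical by configuration).  A single covariate spans five equations,
so its LRT carries 5 df.

Sub-locations inside "other" get one binary logistic fit each versus the
"home" records, same covariates, skipping sub-locations with fewer than
two events; a binary fit on a two-category subset coincides with the
2-category baseline logit (asserted to 1e-6).

## Inference

* **LRT**: 2Δloglik, clipped at zero to absorb optimizer noise on nested
  refits, with the chi-square upper tail on the df difference.
* **Profile CIs**: endpoints where the profiled deviance rises by
  chi-square(1; 0.95) = 3.8415, found by bracket expansion from the MLE
  (steps of one Wald SE, doubling) and Brent root finding to 1e-6 on the
  coefficient scale.  A side that never crosses is reported as an open
  endpoint with a warning.  For GLMs the constrained refit absorbs
  value·x into the offset; for the multinomial, a masked damped-Newton
  iteration on the analytic score/Hessian re-optimizes all other
  coefficients, including other categories' (the standard profiling
  contract).  By construction the 95% interval excludes the null value
  exactly when the term's LRT p < 0.05; this duality is exercised over 50
  simulated fits.  Coverage studies use the equivalent membership test
  (profiled deviance at the candidate value ≤ 3.8415) rather than tracing
  both endpoints, which is the same event at a fraction of the cost.
* **Bayes factor**: for two models of equal complexity nested in a common
  encompassing model, ΔBIC = LRT_a − LRT_b and the Schwarz approximation
  gives BF = exp((LRT_a − LRT_b)/2).  Unequal-df comparisons are refused
  (the penalty would not cancel).  Kass–Raftery bins use the 1995
  boundaries 3 / 20 / 150 with boundary values assigned to the lower bin;
  factors below 1 are inverted and labelled for the favored model.

## The synthetic-cohort generator

The generator's defaults are the study conditions the tests run under.

* Sex ~ Bernoulli(0.445 female); age uniform 16–64; calendar year uniform
  2002–2019; 12.7% acute-care records.
* **Codes** are conditionally independent given sex — the simplest
  structure consistent with per-code univariate screening — with
  prevalence p_{s,k} = logistic(logit(0.02) + s·β_k/2), s = ±1.  Default
  vocabulary: 160 male-skewed and 40 female-skewed codes (|β_k| uniform
  on 0.4–2.0, mirroring the ~80/20 male/female split among informative
  codes in administrative TBI data), 100 neutral codes, 20 ultra-rare
  codes (≤ 1 expected carrier, to exercise the rarity filter) and 4
  sex-exclusive codes (to exercise the exclusivity filter).  Draws use a
  per-(code, sex) binomial count plus uniform subset, distributionally
  identical to independent Bernoulli draws but much cheaper at 2%
  prevalence.
* The **latent gender score** is the closed-form conditional-independence
  posterior P(female | codes), computable exactly from the recorded
  prevalences; its mean equals the female fraction by construction.  It
  is the oracle the empirical score is measured against (Spearman ≥ 0.8
  required; observed ≈ 0.99 at n = 50,000).
* **Mortality** is exponential with daily hazard = life-table daily rate
  × exp(x'β), censored at day 30.  The synthetic life table is
  Gompertz-like (male rates higher, −0.5%/year secular drift), not any
  published table.  Default β: sex log 1.5 (the recovery target),
  severity effects calibrated so roughly 9–11% of severe cases die within
  30 days, small age and comorbidity effects, all other covariates null.
  The design intentionally puts the mortality effect on sex and the
  discharge effect on the latent score, so recovery tests can
  discriminate the two constructs.
* **Discharge** follows a baseline-category logit over eight fine
  categories (six groups; "other" split into acute-transfer, palliative,
  against-medical-advice sub-locations with their own coefficients, so
  sub-location-vs-home log odds ratios are exact generative quantities).
  Default per-unit-score log odds: rehab log 0.54, acute transfer
  log 0.22, LTC log 3.68, CCC log 1.72, home-with-support log 1.22.
* Missingness: 10% ADG, 10% LOS, 2% survival status, 2% discharge
  location; severity includes a literal "unknown" category (48.6%).
* One `numpy` Generator seeded from the single config seed drives every
  draw; identical configs give byte-identical cohorts.

What the generator does **not** emulate: within-person code correlation
beyond sex (real comorbidity clusters), repeat TBI events, secular coding
drift, informative missingness, or realistic marginal frequencies of any
specific code.  Passing recovery tests therefore demonstrates estimator
correctness under the model's own assumptions, not robustness to their
violation in real administrative data.

## Problem sizes and numerical choices

Simulation-backed tests use n = 50,000 (score validity), n = 20,000 ×
200 replicates (profile-CI coverage of the true sex rate ratio 1.5 and
rehab log-OR log 0.54; the latent score serves as the score column, since
re-deriving the empirical score per replicate would only re-test the
score module), and n = 10,000 × 20 replicates (null screening
calibration).  Multinomial fits use statsmodels' Newton step followed by
a damped-Newton polish with backtracking line search (gradient tolerance
1e-6), which also guards against overshoot under quasi-separation in
sparse categories; covariances come from the analytic Hessian at the
optimum.  LRT statistics are clipped at zero; BH adjustment implements
the step-up definition directly so it is bit-exact against a
definition-based reimplementation.

## Known limitations

* The additive excess-hazard variant has no profile-CI support.
* Sparse-category handling (drop below two records) changes model df;
  with very small analysis sets the five-equation LRT df is therefore
  data-dependent.
* The gender score is treated as a fixed covariate in outcome models;
  no propagation of its estimation uncertainty is attempted.
* The BIC Bayes factor is an asymptotic approximation, not a marginal
  likelihood under explicit priors.
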