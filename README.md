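# genderdx

Gender-diagnosticity scoring from diagnostic codes, with sex-versus-gender
contrasts on 30-day excess mortality and hospital discharge location.

## The problem

Administrative health data record binary sex but not gender — the social
roles, behaviours and exposures that shape injury and recovery.  For
traumatic brain injury (TBI) cohorts drawn from emergency-department and
hospital-discharge databases, this package operationalizes gender through
*gender diagnosticity*: the probability that a person would be classified
female from their pattern of ICD-10-style diagnostic codes.  Codes such as
occupational falls, motorcycle collisions, or partner-violence injuries
carry gendered information beyond biology, and a score built from them can
be contrasted with recorded sex to ask which construct better predicts an
outcome.

It is written for epidemiologists and biostatisticians who hold (or
simulate) person-level cohort extracts and want the full pipeline —
score derivation, outcome models, and formal model comparison — as a
tested, reusable library.

## The method

**Gender score.**  Person-level code lists become a binary indicator
matrix X.  Codes occurring in ≤ 1 person, or in only one sex, in either
the training or validation fold (a random 50/25/25 split) are removed.
Each remaining code *k* is screened with a univariate logistic regression

&nbsp;&nbsp;logit P(female) = a + b·x_k,

whose MLE is the 2×2 cross-product odds ratio; codes significant at 5%
after Benjamini–Hochberg adjustment in **both** folds enter one
multivariable logistic model fitted on training.  Its fitted probability
is the gender score g ∈ (0, 1): 0 male-like, 1 female-like.

**Excess mortality.**  On severe injuries with known 30-day status, a
Poisson regression with the life-table expected deaths as offset:

&nbsp;&nbsp;log E[death] = log(μ·t) + β₀ + β₁·sex (and/or g) + controls,

where μ is the (sex, age, year) annual population death rate / 365.25 and
t the person-days.  exp(β) are excess-mortality rate ratios; the
intercept-only model is the standardized mortality ratio O/E.

**Discharge location.**  A baseline-category multinomial logit over six
destinations with "discharged home" as reference, so each non-reference
category gets its own equation and a single covariate carries 5 df; the
"other" group's sub-locations get follow-up binary fits against home.

**Sex versus gender.**  For each outcome, Model 1 (sex + controls),
Model 2 (score + controls) and Model 3 (both) are fitted.  Effects are
judged by likelihood-ratio tests and profile-likelihood CIs, and the two
equal-complexity models are compared directly through the Schwarz
approximation: since their BIC penalties cancel,

&nbsp;&nbsp;BF(1 over 2) = exp[(LRT_sex − LRT_gender) / 2],

interpreted on the Kass–Raftery scale (3 / 20 / 150 boundaries).

A fully parameterized synthetic-cohort generator (`SimConfig`,
`simulate_cohort`) emulates the statistical structure this analysis
assumes — sex-differential code prevalences, a latent gender propensity
with a closed-form Bayes-optimal score, a life-table-anchored mortality
process, and score-driven discharge — and records its ground truth for
recovery testing.

## Worked example

```bash
python examples/05_sex_vs_gender_comparison.py
```

prints (abridged):

```
published mortality statistics: LRT (sex) = 11.50 (df 1, p = 0.000696);
  LRT (gender score) = 1.18 (df 1, p = 0.2774);
  BF (sex-only over gender-only) = 174 — very strong evidence.
simulated mortality: LRT (sex) = 2.92 (df 1, p = 0.08754); ...
simulated discharge: LRT (sex) = 2.77 (df 5, p = 0.7358);
  LRT (gender score) = 122.37 (df 5, p = 9.859e-25);
  BF (gender-only over sex-only) = 9.38e+25 — very strong evidence.
```

The first line turns two single-degree-of-freedom LRT statistics into a
Bayes factor of 174: the sex-only mortality model is very strongly
preferred.  The simulated lines run the identical machinery on a
generated cohort in which mortality depends on sex and discharge on the
latent gender score — and the comparison recovers exactly that
asymmetry.  The other example scripts walk through simulation
(`01`), score derivation (`02`, Spearman 0.993 against the generative
posterior), the mortality models (`03`, sex rate ratio 1.44 with 95%
profile CI 1.16–1.78 at simulated truth 1.50) and the discharge models
(`04`, rehab-vs-home odds ratio 0.57 at simulated truth 0.54).

The same pipeline is available from the shell:

```bash
genderdx --seed 1 --outdir out run-all
```

which writes the scored cohort, screening table, model reports and
comparison JSON to `out/`.

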