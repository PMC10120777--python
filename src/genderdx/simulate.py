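"""Synthetic administrative-cohort simulator.

Generates person-level cohorts with the statistical structure the
downstream analysis assumes: sex-differential diagnostic-code prevalences
(a minority of codes female-skewed, a larger set male-skewed, many
neutral, some ultra-rare, a few sex-exclusive), a latent gender propensity
linking codes to sex, a 30-day mortality process that multiplies a
population life-table baseline by covariate effects, and a six-group
discharge process driven by the latent gender score.

The generative model for codes is conditional independence given sex:
code k occurs with probability

    p_{s,k} = logistic(logit(p0) + s * beta_k / 2),   s = +1 female, -1 male,

so beta_k is the per-code log odds ratio (female vs male).  Under this
model the posterior probability of being female given a code vector is
available in closed form (`bayes_optimal_gender_score`) and serves as the
ground-truth "gender score" that the empirical score estimates.

Thirty-day survival is exponential with daily hazard

    lambda_i = (annual life-table rate / 365.25) * exp(x_i' beta_true),

censored at day 30, so exp(beta) are excess-mortality rate ratios
relative to the population baseline.  Discharge destination (acute-care
survivors only) follows a baseline-category logit over eight fine
categories (collapsed to the six analysis groups, "other" keeping its
sub-location label), with per-category log odds linear in the latent
gender score.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import DegenerateCodeError, InvalidConfigError
from .mortality import LifeTable

SEVERITY_LEVELS = ("unknown", "mild", "moderate", "severe")
# Marginal shares typical of an adult TBI administrative cohort.
SEVERITY_PROBS = (0.486, 0.415, 0.028, 0.071)

MECHANISMS = ("falls", "struck", "mvc", "cyclist", "other")
MECHANISM_PROBS = (0.45, 0.20, 0.18, 0.05, 0.12)

DISCHARGE_GROUPS = ("home", "home_support", "ltc", "ccc", "rehab", "other")

# Fine-grained discharge categories; the three "other_*" ones collapse
# into the analysis group "other" but keep a sub-location label.
FINE_CATEGORIES = (
    "home",
    "home_support",
    "ltc",
    "ccc",
    "rehab",
    "other_acute_transfer",
    "other_palliative",
    "other_ama",
)
FINE_TO_GROUP = {
    "home": "home",
    "home_support": "home_support",
    "ltc": "ltc",
    "ccc": "ccc",
    "rehab": "rehab",
    "other_acute_transfer": "other",
    "other_palliative": "other",
    "other_ama": "other",
}

# Target discharge shares at the mean latent score (intercepts are solved
# from these); "home" dominates as in acute-care discharge data.
FINE_TARGET_SHARES = {
    "home": 0.570,
    "home_support": 0.150,
    "ltc": 0.020,
    "ccc": 0.030,
    "rehab": 0.120,
    "other_acute_transfer": 0.070,
    "other_palliative": 0.025,
    "other_ama": 0.015,
}

# Per-unit-latent-score log odds (vs home) for each fine category.
# Rehab and the acute-transfer sub-location decrease in female-likeness;
# LTC and CCC increase.
DEFAULT_DISCHARGE_LOG_OR = {
    "home_support": math.log(1.22),
    "ltc": math.log(3.68),
    "ccc": math.log(1.72),
    "rehab": math.log(0.54),
    "other_acute_transfer": math.log(0.22),
    "other_palliative": math.log(0.45),
    "other_ama": math.log(0.45),
}

# Log relative-mortality coefficients multiplying the life-table hazard.
# Severity reference is "unknown"; mild carries no extra excess; severe
# TBI carries a large standardized-mortality-ratio style excess so that
# roughly 9% of severe cases die within 30 days.
DEFAULT_EXCESS_LOG_SMR = {
    "intercept": 1.35,
    "age": 0.01,
    "adg_score": 0.05,
    "severity[mild]": 0.0,
    "severity[moderate]": 1.5,
    "severity[severe]": 4.3,
}

_DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic-cohort generative model.

    Defaults encode the study conditions: ~44.5% female, ages 16-64,
    an 80/20 male/female split among informative codes, a female:male
    30-day excess mortality rate ratio of 1.5, and discharge effects
    whose signs mirror the analysis the simulator feeds.
    """

    n_persons: int = 20_000
    prop_female: float = 0.445
    n_codes_male_skewed: int = 160
    n_codes_female_skewed: int = 40
    n_codes_neutral: int = 100
    n_codes_rare: int = 20
    n_codes_sex_exclusive: int = 4
    code_base_prevalence: float = 0.02
    code_log_or_range: tuple[float, float] = (0.4, 2.0)
    sex_mortality_rr: float = 1.5
    excess_log_smr: Mapping[str, float] | None = None
    gender_discharge_log_or: Mapping[str, float] | None = None
    prop_acute: float = 0.127
    age_range: tuple[int, int] = (16, 64)
    year_range: tuple[int, int] = (2002, 2019)
    adg_missing_rate: float = 0.10
    los_missing_rate: float = 0.10
    status_missing_rate: float = 0.02
    discharge_missing_rate: float = 0.02
    seed: int = 1

    def validate(self) -> None:
        if not (0.0 < self.prop_female < 1.0):
            raise InvalidConfigError("prop_female must lie strictly in (0, 1)")
        counts = (
            self.n_codes_male_skewed,
            self.n_codes_female_skewed,
            self.n_codes_neutral,
            self.n_codes_rare,
            self.n_codes_sex_exclusive,
        )
        if any(c < 0 for c in counts):
            raise InvalidConfigError("code class counts must be non-negative")
        if sum(counts) < 2:
            raise InvalidConfigError("need at least two codes in total")
        if self.sex_mortality_rr <= 0:
            raise InvalidConfigError("sex_mortality_rr must be positive")
        if not (0.0 < self.code_base_prevalence < 1.0):
            raise InvalidConfigError("code_base_prevalence must lie in (0, 1)")
        if self.n_persons <= 0:
            raise InvalidConfigError("n_persons must be positive")
        lo, hi = self.code_log_or_range
        if lo < 0 or hi < lo:
            raise InvalidConfigError("code_log_or_range must be 0 <= lo <= hi")
        if not (0.0 <= self.prop_acute <= 1.0):
            raise InvalidConfigError("prop_acute must lie in [0, 1]")
        if self.age_range[0] > self.age_range[1] or self.year_range[0] > self.year_range[1]:
            raise InvalidConfigError("age_range and year_range must be ordered pairs")

    def mortality_coefficients(self) -> dict[str, float]:
        coeffs = dict(DEFAULT_EXCESS_LOG_SMR if self.excess_log_smr is None else self.excess_log_smr)
        coeffs["sex"] = math.log(self.sex_mortality_rr)
        return coeffs

    def discharge_log_or(self) -> dict[str, float]:
        src = DEFAULT_DISCHARGE_LOG_OR if self.gender_discharge_log_or is None else self.gender_discharge_log_or
        return {k: float(src.get(k, 0.0)) for k in FINE_CATEGORIES if k != "home"}


@dataclass
class GroundTruth:
    """Simulation truth recorded for recovery tests.

    ``bayes_optimal_score`` is the posterior P(female | code vector)
    under the conditional-independence generative model, aligned with the
    cohort rows; it is the estimand the empirical gender score targets.
    """

    code_classes: dict[str, str]
    per_code_prevalence_by_sex: dict[str, tuple[float, float]]  # code -> (p_male, p_female)
    per_code_log_or: dict[str, float]
    bayes_optimal_score: np.ndarray
    true_mortality_coefficients: dict[str, float]
    true_discharge_coefficients: dict[str, dict[str, float]]
    prop_female: float
    covariate_distributions: dict[str, str] = field(default_factory=dict)

    def scoring_codes(self) -> list[str]:
        """Codes with both-sex prevalences strictly inside (0, 1)."""
        return [
            c
            for c, (pm, pf) in self.per_code_prevalence_by_sex.items()
            if 0.0 < pm < 1.0 and 0.0 < pf < 1.0
        ]

    def to_json(self, path) -> None:
        payload = {
            "prop_female": self.prop_female,
            "code_classes": self.code_classes,
            "per_code_prevalence_by_sex": {
                c: [pm, pf] for c, (pm, pf) in self.per_code_prevalence_by_sex.items()
            },
            "per_code_log_or": self.per_code_log_or,
            "true_mortality_coefficients": self.true_mortality_coefficients,
            "true_discharge_coefficients": self.true_discharge_coefficients,
            "covariate_distributions": self.covariate_distributions,
            "bayes_optimal_score": [float(x) for x in self.bayes_optimal_score],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _code_vocabulary(config: SimConfig) -> tuple[list[str], list[str], np.ndarray]:
    """Return (codes, classes, beta) with deterministic class-prefixed names."""
    codes: list[str] = []
    classes: list[str] = []
    for prefix, cls, count in (
        ("CF", "female", config.n_codes_female_skewed),
        ("CM", "male", config.n_codes_male_skewed),
        ("CN", "neutral", config.n_codes_neutral),
        ("CR", "rare", config.n_codes_rare),
        ("CX", "exclusive", config.n_codes_sex_exclusive),
    ):
        for i in range(count):
            codes.append(f"{prefix}{i:03d}")
            classes.append(cls)
    return codes, classes, np.zeros(len(codes))


def simulate_cohort(config: SimConfig) -> tuple[pd.DataFrame, LifeTable, GroundTruth]:
    """Simulate a person-level cohort, its life table, and the truth record.

    All randomness flows from ``config.seed`` through one generator, so
    identical configs give byte-identical cohorts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_persons

    sex = (rng.random(n) < config.prop_female).astype(np.int64)  # female = 1
    age = rng.integers(config.age_range[0], config.age_range[1] + 1, size=n)
    year = rng.integers(config.year_range[0], config.year_range[1] + 1, size=n)

    codes, classes, beta = _code_vocabulary(config)
    k = len(codes)
    lo, hi = config.code_log_or_range
    base_logit = logit(config.code_base_prevalence)
    p_male = np.full(k, config.code_base_prevalence)
    p_female = np.full(k, config.code_base_prevalence)
    for j, cls in enumerate(classes):
        if cls == "female":
            beta[j] = rng.uniform(lo, hi)
        elif cls == "male":
            beta[j] = -rng.uniform(lo, hi)
        elif cls == "neutral":
            beta[j] = 0.0
        elif cls == "rare":
            # At most one carrier in expectation, sex-neutral.
            beta[j] = 0.0
            p_male[j] = p_female[j] = 0.5 / n
        else:  # exclusive: alternate female-only / male-only
            if j % 2 == 0:
                p_female[j], p_male[j] = 0.004, 0.0
            else:
                p_female[j], p_male[j] = 0.0, 0.004
    informative = np.array([c in ("female", "male") for c in classes])
    p_female = np.where(informative, expit(base_logit + beta / 2.0), p_female)
    p_male = np.where(informative, expit(base_logit - beta / 2.0), p_male)

    # Draw the indicator matrix sparsely: per (code, sex) a binomial
    # carrier count, then a uniform subset of that sex — distributionally
    # identical to independent Bernoulli draws per person but far cheaper
    # at low prevalence.
    idx_by_sex = (np.flatnonzero(sex == 0), np.flatnonzero(sex == 1))
    person_hits: list[np.ndarray] = []
    code_hits: list[np.ndarray] = []
    for j in range(k):
        for prev, idx in ((p_male[j], idx_by_sex[0]), (p_female[j], idx_by_sex[1])):
            if prev <= 0.0 or len(idx) == 0:
                continue
            m = rng.binomial(len(idx), prev)
            if m == 0:
                continue
            chosen = idx[rng.choice(len(idx), size=m, replace=False)]
            person_hits.append(chosen)
            code_hits.append(np.full(m, j))
    if person_hits:
        rows_arr = np.concatenate(person_hits)
        cols_arr = np.concatenate(code_hits)
    else:
        rows_arr = cols_arr = np.empty(0, dtype=int)
    from scipy import sparse as _sparse

    indicators = _sparse.csr_matrix(
        (np.ones(len(rows_arr)), (rows_arr, cols_arr)), shape=(n, k)
    )

    truth_prev = {c: (float(p_male[j]), float(p_female[j])) for j, c in enumerate(codes)}
    scorable = (p_male > 0.0) & (p_male < 1.0) & (p_female > 0.0) & (p_female < 1.0)
    score = _posterior_female(
        indicators[:, scorable], p_male[scorable], p_female[scorable], config.prop_female
    )

    # Per-person "|"-joined code strings, codes in vocabulary order.
    order = np.lexsort((cols_arr, rows_arr))
    code_col = [""] * n
    code_names = np.array(codes)
    boundaries = np.flatnonzero(np.diff(rows_arr[order])) + 1
    for chunk in np.split(order, boundaries) if len(order) else []:
        code_col[rows_arr[chunk[0]]] = "|".join(code_names[cols_arr[chunk]])

    adg = rng.poisson(2.0, size=n).astype(float)
    rurality = (rng.random(n) < 0.155).astype(np.int64)
    income = rng.integers(1, 6, size=n)
    los = np.round(np.exp(rng.normal(1.1, 0.9, size=n)), 1)
    los = np.maximum(los, 0.1)
    severity = rng.choice(SEVERITY_LEVELS, size=n, p=SEVERITY_PROBS)
    mechanism = rng.choice(MECHANISMS, size=n, p=MECHANISM_PROBS)
    record_source = np.where(rng.random(n) < config.prop_acute, "acute", "ed")

    lifetable = make_lifetable(config.age_range, config.year_range)
    annual = lifetable.rate(sex, age, year)
    coeffs = config.mortality_coefficients()
    eta = np.full(n, coeffs.get("intercept", 0.0))
    eta += coeffs.get("sex", 0.0) * sex
    eta += coeffs.get("age", 0.0) * age
    eta += coeffs.get("adg_score", 0.0) * adg
    eta += coeffs.get("rurality", 0.0) * rurality
    eta += coeffs.get("income_quintile", 0.0) * income
    for lev in SEVERITY_LEVELS[1:]:
        eta += coeffs.get(f"severity[{lev}]", 0.0) * (severity == lev)
    for mech in MECHANISMS[1:]:
        eta += coeffs.get(f"mechanism[{mech}]", 0.0) * (mechanism == mech)
    daily_rate = annual / _DAYS_PER_YEAR * np.exp(eta)
    t_death = rng.exponential(1.0 / daily_rate)
    death = (t_death <= 30.0).astype(float)
    followup = np.where(death == 1.0, np.round(np.maximum(t_death, 0.01), 2), 30.0)

    # Discharge destination for acute-care survivors-to-discharge.
    disc_or = config.discharge_log_or()
    non_ref = [c for c in FINE_CATEGORIES if c != "home"]
    intercepts = {
        c: math.log(FINE_TARGET_SHARES[c] / FINE_TARGET_SHARES["home"])
        - disc_or[c] * config.prop_female
        for c in non_ref
    }
    eta_disc = np.zeros((n, len(FINE_CATEGORIES)))
    for idx, c in enumerate(FINE_CATEGORIES):
        if c != "home":
            eta_disc[:, idx] = intercepts[c] + disc_or[c] * score
    probs = np.exp(eta_disc - eta_disc.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    fine_idx = _sample_categorical(rng, probs)
    fine_cat = np.array(FINE_CATEGORIES)[fine_idx]

    died_before_discharge = (death == 1.0) & (followup <= los)
    discharge = np.array([FINE_TO_GROUP[c] for c in fine_cat], dtype=object)
    sub = np.where(discharge == "other", fine_cat, "")
    eligible = (record_source == "acute") & ~died_before_discharge
    discharge = np.where(eligible, discharge, None)
    sub = np.where(eligible, sub, "")

    cohort = pd.DataFrame(
        {
            "person_id": [f"P{i:06d}" for i in range(n)],
            "sex": sex,
            "age": age,
            "year": year,
            "codes": code_col,
            "adg_score": adg,
            "rurality": rurality,
            "income_quintile": income,
            "los_days": los,
            "severity": severity,
            "mechanism": mechanism,
            "death_within_30d": death,
            "followup_days": followup,
            "discharge_location": discharge,
            "sublocation": sub,
            "record_source": record_source,
        }
    )

    # Missingness applied after outcomes so that truth covariates are intact.
    cohort.loc[rng.random(n) < config.adg_missing_rate, "adg_score"] = np.nan
    cohort.loc[rng.random(n) < config.los_missing_rate, "los_days"] = np.nan
    status_missing = rng.random(n) < config.status_missing_rate
    cohort.loc[status_missing, ["death_within_30d", "followup_days"]] = np.nan
    disc_missing = rng.random(n) < config.discharge_missing_rate
    cohort.loc[disc_missing, "discharge_location"] = None
    cohort.loc[disc_missing, "sublocation"] = ""

    truth = GroundTruth(
        code_classes=dict(zip(codes, classes)),
        per_code_prevalence_by_sex=truth_prev,
        per_code_log_or={c: float(b) for c, b in zip(codes, beta)},
        bayes_optimal_score=score,
        true_mortality_coefficients=coeffs,
        true_discharge_coefficients={
            c: {"intercept": intercepts[c], "score": disc_or[c]} for c in non_ref
        },
        prop_female=config.prop_female,
        covariate_distributions={
            "adg_score": "Poisson(2)",
            "rurality": "Bernoulli(0.155)",
            "income_quintile": "Uniform{1..5}",
            "los_days": "LogNormal(1.1, 0.9) days",
            "severity": f"Categorical{dict(zip(SEVERITY_LEVELS, SEVERITY_PROBS))}",
            "mechanism": f"Categorical{dict(zip(MECHANISMS, MECHANISM_PROBS))}",
        },
    )
    return cohort, lifetable, truth


def _sample_categorical(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """Vectorized draw of one category per row of a probability matrix."""
    u = rng.random(probs.shape[0])
    return (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)


def make_lifetable(
    age_range: tuple[int, int] = (16, 64),
    year_range: tuple[int, int] = (2002, 2019),
) -> LifeTable:
    """Synthetic population life table with Gompertz-like age gradients.

    Male rates start higher and both sexes see a slow secular decline
    (-0.5%/year), mimicking the shape of national life tables without
    reproducing any published one.
    """
    ages = np.arange(age_range[0], age_range[1] + 1)
    years = np.arange(year_range[0], year_range[1] + 1)
    rows = []
    for sex_code, a, b in ((0, 7e-4, 0.055), (1, 3e-4, 0.060)):
        for yr in years:
            drift = math.exp(-0.005 * (yr - years[0]))
            rates = a * np.exp(b * (ages - age_range[0])) * drift
            rows.append(
                pd.DataFrame(
                    {"sex": sex_code, "age": ages, "year": yr, "annual_rate": rates}
                )
            )
    return LifeTable(pd.concat(rows, ignore_index=True))


def _posterior_female(
    indicators: np.ndarray, p_male: np.ndarray, p_female: np.ndarray, prop_female: float
) -> np.ndarray:
    w_present = np.log(p_female / p_male)
    w_absent = np.log((1.0 - p_female) / (1.0 - p_male))
    eta = logit(prop_female) + indicators @ (w_present - w_absent) + w_absent.sum()
    return expit(eta)


def bayes_optimal_gender_score(
    codes: np.ndarray,
    truth: GroundTruth,
    prop_female: float | None = None,
    code_order: list[str] | None = None,
) -> np.ndarray:
    """Posterior P(female | code vector) under conditional independence.

    ``codes`` is a binary vector or matrix whose columns follow
    ``code_order`` (default: the truth's scorable codes).  Codes with a
    prevalence of exactly 0 or 1 in either sex have no finite evidence
    weight and raise :class:`DegenerateCodeError`.
    """
    if prop_female is None:
        prop_female = truth.prop_female
    if code_order is None:
        code_order = truth.scoring_codes()
    p_m = np.array([truth.per_code_prevalence_by_sex[c][0] for c in code_order])
    p_f = np.array([truth.per_code_prevalence_by_sex[c][1] for c in code_order])
    bad = (p_m <= 0.0) | (p_m >= 1.0) | (p_f <= 0.0) | (p_f >= 1.0)
    if bad.any():
        offenders = [c for c, flag in zip(code_order, bad) if flag]
        raise DegenerateCodeError(f"degenerate prevalence for codes: {offenders}")
    x = np.atleast_2d(np.asarray(codes, dtype=float))
    out = _posterior_female(x, p_m, p_f, prop_female)
    return out[0] if np.ndim(codes) == 1 else out


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def config_to_json(config: SimConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=1, default=list)
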