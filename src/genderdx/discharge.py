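"""Discharge-location models: baseline-category multinomial logit with
"discharged home" as reference, plus follow-up binary models for the
sub-locations inside the "other" group.

The analysis set keeps acute-care records of people alive at discharge
with a recorded location and complete covariates.  Each non-reference
category contributes one logit equation against "home", so a model with
k terms has 5k free parameters and single-variable LRTs carry df = 5.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .design import build_design
from .errors import ReferenceMissingError, SchemaError
from .fitting import FitResult, GLMContext, MultinomialContext

logger = logging.getLogger(__name__)

DISCHARGE_CONTROLS = ["age", "los_days", "adg_score", "rurality", "income_quintile"]
DISCHARGE_CATEGORIES = ("home", "home_support", "ltc", "ccc", "rehab", "other")


def build_discharge_set(
    cohort: pd.DataFrame, score_column: str = "gender_score"
) -> pd.DataFrame:
    """Complete-case analysis set for the discharge models.

    Filters: acute-care record; alive at discharge (a death whose
    follow-up time falls within the length of stay is a death in
    facility and is excluded); recorded discharge location; non-missing
    ADG score, LOS, score and remaining covariates.
    """
    required = ["record_source", "discharge_location", score_column]
    missing = [c for c in required + DISCHARGE_CONTROLS if c not in cohort.columns]
    if missing:
        raise SchemaError(f"cohort missing columns for discharge set: {missing}")
    unknown = (
        set(cohort["discharge_location"].dropna().unique()) - set(DISCHARGE_CATEGORIES)
    )
    if unknown:
        raise SchemaError(f"unknown discharge categories: {sorted(unknown)}")
    died_in_facility = (
        (cohort["death_within_30d"] == 1)
        & cohort["followup_days"].notna()
        & cohort["los_days"].notna()
        & (cohort["followup_days"] <= cohort["los_days"])
    )
    steps = [
        ("acute-care record", cohort["record_source"] == "acute"),
        ("alive at discharge", ~died_in_facility),
        ("recorded discharge location", cohort["discharge_location"].notna()),
        (
            "complete covariates",
            cohort[[score_column, "sex"] + DISCHARGE_CONTROLS].notna().all(axis=1),
        ),
    ]
    keep = pd.Series(True, index=cohort.index)
    for name, mask in steps:
        before = int(keep.sum())
        keep &= mask.fillna(False)
        logger.info("discharge filter '%s': %d -> %d rows", name, before, int(keep.sum()))
    data = cohort.loc[keep].copy()
    if (data["discharge_location"] == "home").sum() == 0:
        raise ReferenceMissingError(
            "no 'home' discharges: reference category not estimable"
        )
    return data


def fit_baseline_logit(
    dataset: pd.DataFrame,
    formula_terms: list[str],
    outcome: str = "discharge_location",
    label: str = "discharge",
) -> MultinomialContext:
    """Baseline-category logit of discharge category vs "home".

    Categories with fewer than two observations are dropped (rows
    removed, warning logged, df reduced accordingly).
    """
    counts = dataset[outcome].value_counts()
    if "home" not in counts.index:
        raise ReferenceMissingError("reference category 'home' absent")
    sparse_cats = [c for c in counts.index if counts[c] < 2]
    if sparse_cats:
        logger.warning("dropping sparse discharge categories: %s", sparse_cats)
        dataset = dataset[~dataset[outcome].isin(sparse_cats)]
        counts = dataset[outcome].value_counts()
    categories = ["home"] + [
        c for c in DISCHARGE_CATEGORIES if c != "home" and c in counts.index
    ]
    if len(categories) < 2:
        raise ReferenceMissingError("need at least two observed categories")
    code = dataset[outcome].map({c: i for i, c in enumerate(categories)}).to_numpy()
    design = build_design(dataset, formula_terms)
    return MultinomialContext(code, design, categories, label=label)


def run_discharge_models(
    dataset: pd.DataFrame, score_column: str = "gender_score"
) -> dict[str, MultinomialContext]:
    """Models 1-3: sex / score / both, each plus the control set."""
    specs = {
        "model1": ["sex"] + DISCHARGE_CONTROLS,
        "model2": [score_column] + DISCHARGE_CONTROLS,
        "model3": ["sex", score_column] + DISCHARGE_CONTROLS,
    }
    return {
        name: fit_baseline_logit(dataset, terms, label=f"discharge {name}")
        for name, terms in specs.items()
    }


def fit_other_sublocation_models(
    dataset: pd.DataFrame,
    formula_terms: list[str],
    sublocation_column: str = "sublocation",
) -> dict[str, GLMContext]:
    """Binary logistic fits of each "other" sub-location versus "home".

    Each sub-location with at least two events is compared with the
    "home" records under the same covariates as the main model;
    sub-locations with fewer events are skipped with a warning.
    """
    if sublocation_column not in dataset.columns:
        raise SchemaError(f"missing sub-location column '{sublocation_column}'")
    home = dataset[dataset["discharge_location"] == "home"]
    other = dataset[dataset["discharge_location"] == "other"]
    fits: dict[str, GLMContext] = {}
    subs = sorted(s for s in other[sublocation_column].unique() if s)
    for sub in subs:
        rows = other[other[sublocation_column] == sub]
        if len(rows) < 2:
            logger.warning("skipping sub-location '%s' with <2 events", sub)
            continue
        subset = pd.concat([home, rows])
        y = (subset["discharge_location"] == "other").to_numpy(dtype=float)
        design = build_design(subset, formula_terms)
        fits[sub] = GLMContext(
            endog=y,
            exog=design,
            family=sm.families.Binomial(),
            label=f"sublocation {sub} vs home",
        )
    return fits


def category_or_table(context: MultinomialContext, terms: list[str]) -> pd.DataFrame:
    """Per-category odds ratios with Wald CIs for reporting."""
    rows = []
    res = context.result
    for (cat, term), coef in res.params.items():
        if term not in terms:
            continue
        se = res.se((cat, term))
        rows.append(
            {
                "category": cat,
                "term": term,
                "odds_ratio": float(np.exp(coef)),
                "ci_low": float(np.exp(coef - 1.959964 * se)),
                "ci_high": float(np.exp(coef + 1.959964 * se)),
            }
        )
    return pd.DataFrame(rows)
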