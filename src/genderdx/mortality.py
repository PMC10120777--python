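"""Thirty-day excess-mortality analysis with life-table offsets.

The analysis set is restricted to severe injuries with known 30-day
survival status and complete covariates.  Each person contributes their
follow-up as person-time (deaths on day d contribute d days, survivors
30) and an expected-death mass

    expected_i = annual_rate(sex_i, age_i, year_i) / 365.25 * persontime_i

from the population life table.  The default model is the multiplicative
relative-mortality form: a Poisson regression of the death indicator
with log(expected) as offset, so exp(beta) are excess-mortality rate
ratios and the intercept-only fit is the log standardized mortality
ratio (observed / expected deaths).  An additive excess-hazard variant
(mean = expected + persontime * exp(x'beta)) is available for
sensitivity via ``form="additive"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize

from .design import build_design
from .errors import FitFailureError, MissingRateError, SchemaError
from .fitting import FitResult, GLMContext

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25
MORTALITY_CONTROLS = ["age", "mechanism", "rurality", "income_quintile", "adg_score"]


class LifeTable:
    """(sex, age, year) -> annual population death rate in (0, 1)."""

    COLUMNS = ("sex", "age", "year", "annual_rate")

    def __init__(self, table: pd.DataFrame):
        missing = set(self.COLUMNS) - set(table.columns)
        if missing:
            raise SchemaError(f"life table missing columns: {sorted(missing)}")
        rates = table["annual_rate"].to_numpy(dtype=float)
        if not ((rates > 0.0) & (rates < 1.0)).all():
            raise SchemaError("life-table rates must lie strictly in (0, 1)")
        dup = table.duplicated(subset=["sex", "age", "year"])
        if dup.any():
            raise SchemaError("duplicate (sex, age, year) keys in life table")
        self._series = table.set_index(["sex", "age", "year"])["annual_rate"]

    def rate(self, sex, age, year) -> np.ndarray:
        """Vectorized lookup; an unresolvable key raises MissingRateError."""
        idx = pd.MultiIndex.from_arrays(
            [np.atleast_1d(sex), np.atleast_1d(age), np.atleast_1d(year)]
        )
        out = self._series.reindex(idx)
        if out.isna().any():
            key = idx[int(np.argmax(out.isna().to_numpy()))]
            raise MissingRateError(
                f"no life-table rate for (sex={key[0]}, age={key[1]}, year={key[2]})"
            )
        result = out.to_numpy(dtype=float)
        return result if np.ndim(sex) else float(result[0])

    def to_frame(self) -> pd.DataFrame:
        return self._series.reset_index()

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "LifeTable":
        return cls(pd.read_csv(path))


def build_mortality_set(
    cohort: pd.DataFrame,
    lifetable: LifeTable,
    score_column: str = "gender_score",
) -> pd.DataFrame:
    """Complete-case analysis set for the excess-mortality models.

    Keeps severe injuries with known 30-day status and non-missing
    covariates, and attaches ``event``, ``persontime_days`` and
    ``expected_deaths``.  Row counts in/out are logged per filter.
    """
    required = ["severity", "death_within_30d", "followup_days", score_column]
    missing = [c for c in required + MORTALITY_CONTROLS if c not in cohort.columns]
    if missing:
        raise SchemaError(f"cohort missing columns for mortality set: {missing}")
    steps = [
        ("severe severity", cohort["severity"] == "severe"),
        ("known 30-day status", cohort["death_within_30d"].notna()),
        (
            "complete covariates",
            cohort[[score_column, "sex"] + [c for c in MORTALITY_CONTROLS]]
            .notna()
            .all(axis=1),
        ),
    ]
    keep = pd.Series(True, index=cohort.index)
    for name, mask in steps:
        before = int(keep.sum())
        keep &= mask.fillna(False)
        logger.info("mortality filter '%s': %d -> %d rows", name, before, int(keep.sum()))
    data = cohort.loc[keep].copy()
    event = data["death_within_30d"].astype(int)
    persontime = np.where(event == 1, data["followup_days"].to_numpy(dtype=float), 30.0)
    annual = lifetable.rate(
        data["sex"].to_numpy(), data["age"].to_numpy(), data["year"].to_numpy()
    )
    data["event"] = event
    data["persontime_days"] = persontime
    data["expected_deaths"] = annual / DAYS_PER_YEAR * persontime
    return data


def fit_excess_poisson(
    dataset: pd.DataFrame,
    formula_terms: list[str],
    form: str = "multiplicative",
    label: str = "excess-poisson",
) -> GLMContext | FitResult:
    """Fit the excess-mortality Poisson model.

    Multiplicative form returns a :class:`GLMContext` (supporting LRTs
    and profile CIs); the additive sensitivity form returns a plain
    :class:`FitResult` from direct likelihood maximization.
    """
    if len(dataset) == 0:
        raise FitFailureError("empty mortality analysis set")
    if (dataset["expected_deaths"] <= 0).any():
        raise FitFailureError("expected_deaths must be positive")
    if dataset["event"].sum() == 0:
        raise FitFailureError("no deaths in the analysis set; model not estimable")
    design = build_design(dataset, formula_terms)
    if form == "multiplicative":
        return GLMContext(
            endog=dataset["event"].to_numpy(dtype=float),
            exog=design,
            family=sm.families.Poisson(),
            offset=np.log(dataset["expected_deaths"].to_numpy(dtype=float)),
            label=label,
        )
    if form == "additive":
        return _fit_additive(dataset, design, label)
    raise ValueError(f"unknown model form {form!r}")


def _fit_additive(dataset: pd.DataFrame, design: pd.DataFrame, label: str) -> FitResult:
    y = dataset["event"].to_numpy(dtype=float)
    expected = dataset["expected_deaths"].to_numpy(dtype=float)
    persontime = dataset["persontime_days"].to_numpy(dtype=float)
    x = design.to_numpy()

    def negll(beta):
        mu = expected + persontime * np.exp(x @ beta)
        return -(y * np.log(mu) - mu).sum()

    beta0 = np.zeros(x.shape[1])
    # Start the intercept near the multiplicative SMR scale.
    beta0[0] = np.log(max(y.sum(), 0.5) / persontime.sum())
    res = optimize.minimize(negll, beta0, method="L-BFGS-B")
    if not res.success:
        raise FitFailureError(f"additive excess model failed: {res.message}")
    return FitResult(
        params=pd.Series(res.x, index=design.columns),
        cov=pd.DataFrame(
            np.linalg.pinv(_numeric_hessian(negll, res.x)),
            index=design.columns,
            columns=design.columns,
        ),
        loglik=float(-res.fun),
        model_df=x.shape[1],
        n=len(y),
        model_label=f"{label} (additive)",
    )


def _numeric_hessian(f, x, eps: float = 1e-5) -> np.ndarray:
    k = len(x)
    h = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            pp = x.copy(); pp[i] += eps; pp[j] += eps
            pm = x.copy(); pm[i] += eps; pm[j] -= eps
            mp = x.copy(); mp[i] -= eps; mp[j] += eps
            mm = x.copy(); mm[i] -= eps; mm[j] -= eps
            h[i, j] = h[j, i] = (f(pp) - f(pm) - f(mp) + f(mm)) / (4 * eps**2)
    return h


def run_mortality_models(
    dataset: pd.DataFrame,
    score_column: str = "gender_score",
    form: str = "multiplicative",
) -> dict[str, GLMContext]:
    """Models 1-3: sex / score / both, each plus the control set and offset."""
    specs = {
        "model1": ["sex"] + MORTALITY_CONTROLS,
        "model2": [score_column] + MORTALITY_CONTROLS,
        "model3": ["sex", score_column] + MORTALITY_CONTROLS,
    }
    return {
        name: fit_excess_poisson(dataset, terms, form=form, label=f"mortality {name}")
        for name, terms in specs.items()
    }
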