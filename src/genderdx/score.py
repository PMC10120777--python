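"""Gender-score derivation: univariate screening, multiple-testing
control, multivariable logistic fit, and scoring.

Each code is screened by a univariate logistic regression of sex
(female = 1) on its indicator.  With a single binary predictor the MLE
has a closed form: the slope is the log of the 2x2 cross-product odds
ratio and its Wald standard error is sqrt(1/a + 1/b + 1/c + 1/d) over
the four cell counts, which lets thousands of codes be screened
vectorized.  Codes significant at level alpha after Benjamini-Hochberg
adjustment in BOTH the training and validation sets enter one
multivariable logistic model fitted on training; its coefficients score
held-out persons with a probability-of-female in (0, 1) — the gender
score (0 male-like, 1 female-like).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from .codes import CodeIndicatorMatrix
from .errors import DegenerateCodeError, FitFailureError

logger = logging.getLogger(__name__)

_SCORE_EPS = 1e-12


def univariate_screen(
    matrix: CodeIndicatorMatrix, sex: np.ndarray, method: str = "wald"
) -> pd.DataFrame:
    """Per-code odds ratio and p-value from univariate logistic fits.

    ``method`` selects the test on the code coefficient: "wald"
    (default) or "lrt" (the 2x2 G-statistic).  Requires every code to
    have all four sex-by-presence cells non-empty, which the upstream
    filter guarantees.
    """
    sex = np.asarray(sex, dtype=float)
    n = len(sex)
    n_female_total = sex.sum()
    n_male_total = n - n_female_total
    n_male, n_female = matrix.sex_counts(sex)
    a = n_female  # code present, female
    b = n_male  # code present, male
    c = n_female_total - n_female  # absent, female
    d = n_male_total - n_male  # absent, male
    zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    if zero.any():
        offenders = [v for v, flag in zip(matrix.vocabulary, zero) if flag]
        raise DegenerateCodeError(
            f"zero cell in sex cross-table (perfect separation) for: {offenders[:10]}"
        )
    log_or = np.log(a * d / (b * c))
    if method == "wald":
        se = np.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
        p = 2.0 * stats.norm.sf(np.abs(log_or) / se)
    elif method == "lrt":
        g2 = _g_statistic_2x2(a, b, c, d)
        p = stats.chi2.sf(g2, 1)
    else:
        raise ValueError(f"unknown screening method {method!r}")
    return pd.DataFrame(
        {"code": matrix.vocabulary, "odds_ratio": np.exp(log_or), "p_value": p}
    )


def _g_statistic_2x2(a, b, c, d) -> np.ndarray:
    cells = np.stack([a, b, c, d]).astype(float)
    n = cells.sum(axis=0)
    row1, row0 = a + b, c + d
    col1, col0 = a + c, b + d
    expected = np.stack([row1 * col1, row1 * col0, row0 * col1, row0 * col0]) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(cells > 0, cells * np.log(cells / expected), 0.0)
    return 2.0 * terms.sum(axis=0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    adjusted_(i) = min_{j >= i} min(1, m * p_(j) / j) over the ascending
    order statistics.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    stepped = m * p[order] / np.arange(1, m + 1)
    adjusted_sorted = np.minimum(
        np.minimum.accumulate(stepped[::-1])[::-1], 1.0
    )
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


def bonferroni_adjust(p_values) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    return np.minimum(p * p.size, 1.0)


def select_codes(
    train_screen: pd.DataFrame,
    valid_screen: pd.DataFrame,
    alpha: float = 0.05,
    correction: str = "bh",
) -> pd.DataFrame:
    """Combine both screens into a selection table.

    A code is selected iff its adjusted p-value is below ``alpha`` in the
    training AND validation sets.  Returns one row per code with
    OR/p/adjusted-p for both sets and the ``selected`` flag.
    """
    adjust = {"bh": bh_adjust, "bonferroni": bonferroni_adjust}[correction]
    merged = train_screen.merge(
        valid_screen, on="code", suffixes=("_train", "_valid"), validate="1:1"
    )
    merged = merged.rename(
        columns={
            "odds_ratio_train": "or_train",
            "odds_ratio_valid": "or_valid",
            "p_value_train": "p_train",
            "p_value_valid": "p_valid",
        }
    )
    merged["p_train_adj"] = adjust(merged["p_train"].to_numpy())
    merged["p_valid_adj"] = adjust(merged["p_valid"].to_numpy())
    merged["selected"] = (
        (merged["p_train_adj"] < alpha) & (merged["p_valid_adj"] < alpha)
    ).astype(int)
    if merged["selected"].sum() == 0:
        warnings.warn("no codes passed the both-sets screen; selection is empty")
    return merged


@dataclass
class GenderScoreModel:
    """Selected codes plus logistic coefficients mapping a code vector to
    a probability of female sex."""

    selected_codes: list[str]
    intercept: float
    coefficients: pd.Series  # indexed by selected (non-aliased) codes
    fitted_on: str = "train"
    dropped_codes: list[str] | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "selected_codes": self.selected_codes,
                    "intercept": self.intercept,
                    "coefficients": {k: float(v) for k, v in self.coefficients.items()},
                    "fitted_on": self.fitted_on,
                    "dropped_codes": self.dropped_codes or [],
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "GenderScoreModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            selected_codes=d["selected_codes"],
            intercept=d["intercept"],
            coefficients=pd.Series(d["coefficients"]),
            fitted_on=d.get("fitted_on", "train"),
            dropped_codes=d.get("dropped_codes") or None,
        )


def _independent_columns(x: np.ndarray, tol: float = 1e-9) -> list[int]:
    """Greedy order-respecting selection of linearly independent columns
    via incremental Cholesky on the Gram matrix."""
    gram = x.T @ x
    kept: list[int] = []
    chol = np.zeros((0, 0))
    for j in range(x.shape[1]):
        gjj = gram[j, j]
        if gjj <= tol:
            continue  # empty column
        if kept:
            w = np.linalg.solve(chol, gram[np.ix_(kept, [j])]).ravel()
            resid = gjj - w @ w
        else:
            w = np.empty(0)
            resid = gjj
        if resid > tol * gjj:
            new = np.zeros((len(kept) + 1, len(kept) + 1))
            new[:-1, :-1] = chol
            new[-1, :-1] = w
            new[-1, -1] = np.sqrt(resid)
            chol = new
            kept.append(j)
    return kept


def fit_score_model(
    matrix: CodeIndicatorMatrix,
    sex: np.ndarray,
    selected_codes: list[str],
    fitted_on: str = "train",
) -> GenderScoreModel:
    """Multivariable logistic fit of sex on the selected code indicators.

    Perfectly collinear columns are dropped deterministically (first kept
    in vocabulary order) with a logged warning.  An empty selection
    degrades to the intercept-only model, whose fitted score is the
    training female fraction for everyone.
    """
    sex = np.asarray(sex, dtype=float)
    x = matrix.dense(selected_codes)
    design = np.column_stack([np.ones(len(sex)), x])
    kept_idx = _independent_columns(design)
    if 0 not in kept_idx:  # intercept always estimable for non-empty data
        kept_idx = [0] + kept_idx
    kept_codes = [selected_codes[j - 1] for j in kept_idx if j > 0]
    dropped = [c for c in selected_codes if c not in set(kept_codes)]
    if dropped:
        logger.warning("dropping %d aliased code column(s): %s", len(dropped), dropped)
    model = sm.GLM(sex, design[:, kept_idx], family=sm.families.Binomial())
    res = model.fit(maxiter=200, tol=1e-12)
    if not res.converged:
        raise FitFailureError(
            f"gender-score model did not converge ({len(kept_codes)} codes, "
            f"n={len(sex)})"
        )
    return GenderScoreModel(
        selected_codes=list(selected_codes),
        intercept=float(res.params[0]),
        coefficients=pd.Series(res.params[1:], index=kept_codes),
        fitted_on=fitted_on,
        dropped_codes=dropped or None,
    )


def score_persons(model: GenderScoreModel, matrix: CodeIndicatorMatrix) -> np.ndarray:
    """Gender scores in (0, 1) for every person in the matrix.

    Codes in the model but absent from the matrix vocabulary count as
    absent (zero column); the logistic inverse link is clipped away from
    exactly 0 and 1.
    """
    codes = list(model.coefficients.index)
    x = matrix.dense(codes)
    eta = model.intercept + x @ model.coefficients.to_numpy()
    return np.clip(expit(eta), _SCORE_EPS, 1.0 - _SCORE_EPS)
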