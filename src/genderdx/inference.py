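"""Likelihood-ratio tests, profile-likelihood confidence intervals, and
BIC-approximated Bayes factors with Kass–Raftery interpretation.

The sex-versus-gender comparison rests on an identity for nested model
pairs of equal complexity: if Model 1 (sex + controls) and Model 2
(gender score + controls) have the same degrees of freedom and both nest
inside an encompassing Model 3, then

    BIC_2 - BIC_1 = 2(loglik_1 - loglik_2) = LRT_sex - LRT_gender,

where LRT_sex and LRT_gender are the single-term likelihood-ratio
statistics of the two effects inside Model 3.  Under the Schwarz
approximation 2 log BF(1, 2) ~ BIC_2 - BIC_1, the Bayes factor of the
sex-only model over the gender-only model is exp((LRT_sex - LRT_gender)/2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import InvalidComparisonError
from .fitting import FitResult

__all__ = [
    "lrt",
    "term_lrt",
    "profile_ci",
    "profile_covers",
    "bayes_factor_from_lrt",
    "kass_raftery_label",
    "ComparisonResult",
    "compare_sex_vs_gender",
]

# Kass & Raftery (1995) bin edges on the Bayes-factor scale; a BF falling
# exactly on an edge is assigned to the lower bin.
_KR_EDGES = ((3.0, "negligible"), (20.0, "positive"), (150.0, "strong"))


def lrt(full: FitResult, reduced: FitResult) -> tuple[float, int, float]:
    """Likelihood-ratio test of a reduced model nested in a full model.

    Returns (statistic, df, p).  The statistic is clipped at zero to
    absorb optimizer noise on nested refits.
    """
    df = full.model_df - reduced.model_df
    if df <= 0:
        raise InvalidComparisonError(
            f"reduced model must have fewer parameters (df difference {df})"
        )
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    return stat, df, float(stats.chi2.sf(stat, df))


def term_lrt(context, term: str) -> tuple[float, int, float]:
    """LRT for dropping one term (all its columns) from a fitted context."""
    reduced = context.refit_without(term)
    return lrt(context.result, reduced)


def profile_covers(context, key, value: float, level: float = 0.95) -> bool:
    """Whether ``value`` lies inside the profile-likelihood CI for ``key``.

    Equivalent to tracing the interval and checking membership: the point
    is covered iff the profiled deviance at ``value`` rises by less than
    the chi-square(1) quantile.
    """
    q = stats.chi2.ppf(level, 1)
    rise = 2.0 * (context.result.loglik - context.profile_loglik(key, value))
    return bool(rise <= q)


def profile_ci(
    context,
    key,
    level: float = 0.95,
    xtol: float = 1e-6,
) -> tuple[float, float]:
    """Profile-likelihood confidence interval on the coefficient scale.

    Endpoints solve ``2(loglik_hat - profile_loglik(b)) = chi2_1(level)``
    on either side of the MLE, located by bracket expansion plus Brent
    root finding to ``xtol``.  A side whose profiled deviance never
    crosses the threshold is reported as an open endpoint (+-inf).
    """
    res = context.result
    mle = float(res.params[key]) if not isinstance(key, tuple) else float(res.params[key])
    try:
        se = res.se(key)
        if not np.isfinite(se) or se <= 0:
            se = max(abs(mle), 1.0)
    except Exception:
        se = max(abs(mle), 1.0)
    q = stats.chi2.ppf(level, 1)
    llhat = res.loglik

    def g(b: float) -> float:
        return 2.0 * (llhat - context.profile_loglik(key, b)) - q

    def endpoint(direction: int) -> float:
        step = se
        inner = mle
        for _ in range(60):
            outer = mle + direction * step
            if g(outer) > 0.0:
                lo, hi = sorted((inner, outer))
                return float(optimize.brentq(g, lo, hi, xtol=xtol))
            inner = outer
            step *= 2.0
        warnings.warn(
            f"profile for {key!r} never crossed the {level:.0%} threshold; "
            "reporting an open endpoint"
        )
        return direction * math.inf

    return endpoint(-1), endpoint(+1)


def bayes_factor_from_lrt(lrt_a: float, lrt_b: float, equal_df: bool = True) -> float:
    """Approximate Bayes factor of model A over model B from their
    single-term LRT statistics within a common encompassing model.

    Valid only when A and B have equal degrees of freedom, so the BIC
    complexity penalties cancel and BF = exp((lrt_a - lrt_b) / 2).
    """
    if not equal_df:
        raise InvalidComparisonError(
            "BIC-difference Bayes factor requires models of equal df"
        )
    return math.exp((lrt_a - lrt_b) / 2.0)


def kass_raftery_label(bf: float) -> str:
    """Kass–Raftery qualitative evidence category for a Bayes factor >= 1.

    Bayes factors below 1 describe evidence for the other model; invert
    first and label the favored model.
    """
    if bf <= 0:
        raise InvalidComparisonError("Bayes factor must be positive")
    if bf < 1.0:
        bf = 1.0 / bf
    for edge, label in _KR_EDGES:
        if bf <= edge:
            return label
    return "very strong"


@dataclass
class ComparisonResult:
    """Sex-only vs gender-only model comparison via the encompassing model."""

    lrt_sex: float
    lrt_gender: float
    df: int
    p_sex: float
    p_gender: float
    bayes_factor: float  # favored model over the other (>= 1)
    favored: str  # "sex" or "gender"
    kass_raftery_label: str

    def to_dict(self) -> dict:
        return {
            "lrt_sex": self.lrt_sex,
            "lrt_gender": self.lrt_gender,
            "df": self.df,
            "p_sex": self.p_sex,
            "p_gender": self.p_gender,
            "bayes_factor": self.bayes_factor,
            "favored": self.favored,
            "kass_raftery_label": self.kass_raftery_label,
        }

    def narrative(self) -> str:
        other = "gender" if self.favored == "sex" else "sex"
        return (
            f"LRT (sex) = {self.lrt_sex:.2f} (df {self.df}, p = {self.p_sex:.4g}); "
            f"LRT (gender score) = {self.lrt_gender:.2f} (df {self.df}, "
            f"p = {self.p_gender:.4g}); BF ({self.favored}-only over {other}-only) "
            f"= {self.bayes_factor:.3g} — {self.kass_raftery_label} evidence."
        )


def compare_sex_vs_gender(
    lrt_sex: float, lrt_gender: float, df: int
) -> ComparisonResult:
    """Build a ComparisonResult from the two single-effect LRT statistics
    of the encompassing model (both on the same df)."""
    bf_sex_over_gender = bayes_factor_from_lrt(lrt_sex, lrt_gender)
    favored = "sex" if bf_sex_over_gender >= 1.0 else "gender"
    bf = bf_sex_over_gender if favored == "sex" else 1.0 / bf_sex_over_gender
    return ComparisonResult(
        lrt_sex=lrt_sex,
        lrt_gender=lrt_gender,
        df=df,
        p_sex=float(stats.chi2.sf(lrt_sex, df)),
        p_gender=float(stats.chi2.sf(lrt_gender, df)),
        bayes_factor=bf,
        favored=favored,
        kass_raftery_label=kass_raftery_label(bf),
    )
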