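"""Model-fit containers and profiling contexts.

A *context* owns the data and design of one fitted model and can

* report the fit as a :class:`FitResult`,
* refit without a term (for likelihood-ratio tests), and
* maximize the likelihood with one coefficient pinned to a trial value
  (the profiled log-likelihood used by profile confidence intervals).

Generalized linear models (Poisson with offset, binomial logistic) are
fitted with statsmodels GLM/IRLS; pinning a coefficient is done by
absorbing ``value * x`` into the offset.  The baseline-category
multinomial logit is fitted with statsmodels MNLogit; pinning a single
(category, term) coefficient requires constrained maximization over the
remaining parameters, done with a masked Newton iteration on MNLogit's
own score and Hessian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import FitFailureError


@dataclass
class FitResult:
    """Coefficients and likelihood summary of one fitted model.

    ``params`` is indexed by term name, or by (category, term) pairs for
    multinomial fits.  ``model_df`` counts free parameters.
    """

    params: pd.Series
    cov: pd.DataFrame
    loglik: float
    model_df: int
    n: int
    model_label: str

    def se(self, key) -> float:
        return float(np.sqrt(self.cov.loc[[key], [key]].to_numpy()[0, 0]))

    def to_dict(self) -> dict:
        return {
            "model_label": self.model_label,
            "loglik": self.loglik,
            "model_df": self.model_df,
            "n": self.n,
            "params": {str(k): float(v) for k, v in self.params.items()},
        }


def _masked_newton(
    model,
    theta0: np.ndarray,
    free: np.ndarray,
    max_iter: int = 200,
    grad_tol: float = 1e-6,
) -> tuple[np.ndarray, float, bool]:
    """Maximize ``model.loglike`` over the ``free`` components of theta.

    Damped Newton with backtracking line search on the analytic score and
    Hessian; falls back to a gradient step when the Hessian block is
    singular.  Returns (theta, loglik, gradient_converged).
    """
    theta = np.asarray(theta0, dtype=float).copy()
    ll = model.loglike(theta)
    if not np.isfinite(ll):
        theta[free] = 0.0
        ll = model.loglike(theta)
    grad_ok = False
    for _ in range(max_iter):
        grad = model.score(theta)[free]
        if np.abs(grad).max() < grad_tol:
            grad_ok = True
            break
        hess = model.hessian(theta)[np.ix_(free, free)]
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = grad / max(np.abs(np.diag(hess)).max(), 1.0)
        scale, improved = 1.0, False
        while scale > 1e-10:
            trial = theta.copy()
            trial[free] = theta[free] - scale * step
            ll_new = model.loglike(trial)
            if np.isfinite(ll_new) and ll_new > ll - 1e-12:
                improved = True
                break
            scale /= 2.0
        if not improved:
            break
        theta, ll_prev, ll = trial, ll, ll_new
        if abs(ll - ll_prev) < 1e-11 * (abs(ll) + 1.0):
            grad_ok = np.abs(model.score(theta)[free]).max() < max(grad_tol, 1e-4)
            break
    return theta, float(ll), grad_ok


def _drop_term_columns(exog: pd.DataFrame, term: str) -> pd.DataFrame:
    keep = [c for c in exog.columns if not (c == term or c.startswith(f"{term}["))]
    if len(keep) == len(exog.columns):
        raise KeyError(f"term '{term}' not in design ({list(exog.columns)})")
    return exog[keep]


class GLMContext:
    """Fitted GLM plus refit/profiling capability."""

    def __init__(
        self,
        endog: np.ndarray,
        exog: pd.DataFrame,
        family,
        offset: np.ndarray | None = None,
        label: str = "",
    ):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = exog
        self.family = family
        self.offset = None if offset is None else np.asarray(offset, dtype=float)
        self.label = label
        self._res = self._fit(exog, self.offset)
        self.result = FitResult(
            params=self._res.params,
            cov=self._res.cov_params(),
            loglik=float(self._res.llf),
            model_df=exog.shape[1],
            n=len(self.endog),
            model_label=label,
        )

    def _fit(self, exog: pd.DataFrame, offset):
        model = sm.GLM(self.endog, exog, family=self.family, offset=offset)
        res = model.fit(maxiter=300, tol=1e-10)
        if not res.converged:
            raise FitFailureError(
                f"GLM '{self.label}' did not converge "
                f"(n={len(self.endog)}, k={exog.shape[1]})"
            )
        return res

    def profile_loglik(self, term: str, value: float) -> float:
        """Max log-likelihood with coefficient of ``term`` fixed at ``value``."""
        x = self.exog[term].to_numpy(dtype=float)
        offset = value * x if self.offset is None else self.offset + value * x
        reduced = _drop_term_columns(self.exog, term)
        if reduced.shape[1] == 0:
            model = sm.GLM(
                self.endog,
                np.zeros((len(self.endog), 0)),
                family=self.family,
                offset=offset,
            )
            return float(model.loglike(np.empty(0)))
        return float(self._fit(reduced, offset).llf)

    def refit_without(self, term: str) -> FitResult:
        reduced = _drop_term_columns(self.exog, term)
        res = self._fit(reduced, self.offset)
        return FitResult(
            params=res.params,
            cov=res.cov_params(),
            loglik=float(res.llf),
            model_df=reduced.shape[1],
            n=len(self.endog),
            model_label=f"{self.label} - {term}",
        )


class MultinomialContext:
    """Fitted baseline-category logit plus refit/profiling capability.

    ``endog`` holds integer category codes with 0 = reference;
    ``categories`` names them in code order (reference first).  Parameter
    keys are ``(category, term)`` tuples over the non-reference categories.
    """

    def __init__(
        self,
        endog: np.ndarray,
        exog: pd.DataFrame,
        categories: list[str],
        label: str = "",
    ):
        self.endog = np.asarray(endog, dtype=int)
        self.exog = exog
        self.categories = list(categories)
        self.label = label
        self._model, self._theta, self._ll = self._fit(exog)
        self.result = self._wrap(exog)

    def _fit(self, exog: pd.DataFrame):
        model = sm.MNLogit(self.endog, exog)
        n_params = exog.shape[1] * (len(np.unique(self.endog)) - 1)
        theta = np.zeros(n_params)
        try:
            res = model.fit(method="newton", maxiter=200, tol=1e-10, disp=False)
            cand = res.params.to_numpy().ravel(order="F")
            if np.isfinite(model.loglike(cand)):
                theta = cand
        except Exception:
            pass
        # Damped-Newton polish: plain Newton can overshoot under
        # quasi-separation in sparse categories; the line search enforces
        # monotone likelihood ascent and a strict gradient tolerance.
        theta, ll, grad_ok = _masked_newton(
            model, theta, np.ones(n_params, dtype=bool)
        )
        if not grad_ok:
            raise FitFailureError(f"multinomial fit '{self.label}' did not converge")
        return model, theta, ll

    def _param_index(self, exog: pd.DataFrame) -> pd.MultiIndex:
        # MNLogit flattens parameters category-major (Fortran order over a
        # (k_vars, J-1) array): all terms of category 1, then category 2, ...
        return pd.MultiIndex.from_tuples(
            [
                (cat, term)
                for cat in self.categories[1:]
                for term in exog.columns
            ]
        )

    def _wrap(self, exog: pd.DataFrame) -> FitResult:
        idx = self._param_index(exog)
        hess = self._model.hessian(self._theta)
        cov = pd.DataFrame(np.linalg.inv(-hess), index=idx, columns=idx)
        return FitResult(
            params=pd.Series(self._theta, index=idx),
            cov=cov,
            loglik=float(self._ll),
            model_df=exog.shape[1] * (len(self.categories) - 1),
            n=len(self.endog),
            model_label=self.label,
        )

    def predict_probs(self) -> np.ndarray:
        """Per-person category probabilities in ``categories`` order."""
        params = self._theta.reshape(self.exog.shape[1], -1, order="F")
        return np.asarray(self._model.predict(params, self.exog.to_numpy()))

    def profile_loglik(self, key: tuple[str, str], value: float) -> float:
        """Constrained maximum with one (category, term) coefficient pinned.

        Masked Newton iteration on MNLogit's analytic score and Hessian,
        warm-started at the unconstrained MLE.
        """
        cat, term = key
        k_vars = self.exog.shape[1]
        cat_pos = self.categories[1:].index(cat)
        term_pos = list(self.exog.columns).index(term)
        fixed = cat_pos * k_vars + term_pos

        theta = self._theta.copy()
        theta[fixed] = value
        free = np.ones(theta.size, dtype=bool)
        free[fixed] = False
        _, ll, _ = _masked_newton(self._model, theta, free)
        return float(ll)

    def refit_without(self, term: str) -> FitResult:
        reduced = _drop_term_columns(self.exog, term)
        ctx = MultinomialContext(
            self.endog, reduced, self.categories, label=f"{self.label} - {term}"
        )
        return ctx.result
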