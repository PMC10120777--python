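"""Likelihood-ratio tests, profile CIs, Bayes factors, Kass–Raftery bins."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

import genderdx as gx
from genderdx.errors import InvalidComparisonError
from genderdx.fitting import FitResult, GLMContext


def make_result(loglik, df, label="m"):
    return FitResult(
        params=pd.Series(dtype=float),
        cov=pd.DataFrame(),
        loglik=loglik,
        model_df=df,
        n=100,
        model_label=label,
    )


class TestLRT:
    def test_identical_models_give_zero(self):
        full = make_result(-100.0, 3)
        reduced = make_result(-100.0, 2)
        stat, df, p = gx.lrt(full, reduced)
        assert stat == 0.0 and df == 1 and p == 1.0

    def test_printed_worked_examples(self):
        """Chi-square tails for the two encompassing-model statistics."""
        _, _, p1 = gx.lrt(make_result(-100.0, 2), make_result(-105.75, 1))
        assert p1 == pytest.approx(0.0007, abs=5e-5)  # stat 11.50, df 1
        _, _, p2 = gx.lrt(make_result(-100.0, 2), make_result(-100.59, 1))
        assert p2 == pytest.approx(0.28, abs=5e-3)  # stat 1.18, df 1

    def test_non_nested_rejected(self):
        with pytest.raises(InvalidComparisonError):
            gx.lrt(make_result(-1.0, 2), make_result(-2.0, 2))

    def test_chi_square_tail_matches_closed_forms(self):
        """p-values agree with independent closed forms: erfc for df=1,
        exp(-x/2) for df=2, the Poisson sum for df=4."""
        for x in (0.5, 1.18, 3.84, 11.50, 25.0):
            assert stats.chi2.sf(x, 1) == pytest.approx(
                math.erfc(math.sqrt(x / 2.0)), abs=1e-10
            )
            assert stats.chi2.sf(x, 2) == pytest.approx(math.exp(-x / 2.0), abs=1e-10)
            assert stats.chi2.sf(x, 4) == pytest.approx(
                math.exp(-x / 2.0) * (1.0 + x / 2.0), abs=1e-10
            )


def poisson_context(n_events=10, exposure=10.0, n=10):
    y = np.array([1.0] * n_events + [0.0] * (n - n_events))
    exog = pd.DataFrame({"intercept": np.ones(n)})
    offset = np.log(np.full(n, exposure / n))
    return GLMContext(y, exog, sm.families.Poisson(), offset=offset)


class TestProfileCI:
    def test_poisson_rate_matches_root_scan_oracle(self):
        """Intercept-only Poisson, 10 events on exposure 10: endpoints solve
        2[10 log(10/mu) - (10 - mu)] = 3.8415, located by a brute root scan."""
        ctx = poisson_context()
        lo, hi = gx.profile_ci(ctx, "intercept")
        q = stats.chi2.ppf(0.95, 1)

        def dev(mu):
            return 2.0 * (10.0 * np.log(10.0 / mu) - (10.0 - mu)) - q

        grid = np.linspace(1e-3, 40.0, 2_000_001)
        vals = dev(grid)
        crossings = grid[np.abs(np.diff(np.sign(vals))).astype(bool).nonzero()[0]]
        mu_lo, mu_hi = crossings[0], crossings[-1]
        assert np.exp(lo) == pytest.approx(mu_lo / 10.0, abs=1e-4)
        assert np.exp(hi) == pytest.approx(mu_hi / 10.0, abs=1e-4)

    def test_agrees_with_wald_at_large_n(self):
        rng = np.random.default_rng(2)
        n = 5_000
        z = rng.normal(size=n)
        mu = 0.2 * np.exp(0.3 * z)
        data = pd.DataFrame({"event": rng.poisson(mu).astype(float), "z": z})
        exog = pd.DataFrame({"intercept": np.ones(n), "z": z})
        ctx = GLMContext(
            data["event"].to_numpy(),
            exog,
            sm.families.Poisson(),
            offset=np.zeros(n),
        )
        lo, hi = gx.profile_ci(ctx, "z")
        se = ctx.result.se("z")
        beta = ctx.result.params["z"]
        wald = (beta - 1.959964 * se, beta + 1.959964 * se)
        assert (hi - lo) == pytest.approx(wald[1] - wald[0], rel=0.05)

    def test_duality_with_lrt_across_simulated_fits(self):
        """(LRT p < 0.05) iff (95% profile CI excludes 0 on the coefficient
        scale / 1 on the ratio scale), over 50 simulated Poisson fits."""
        rng = np.random.default_rng(7)
        agree = 0
        for _ in range(50):
            n = 300
            z = (rng.random(n) < 0.5).astype(float)
            mu = 0.1 * np.exp(rng.normal(0.0, 0.25) * z)
            y = rng.poisson(mu).astype(float)
            if y.sum() == 0:
                y[0] = 1.0
            exog = pd.DataFrame({"intercept": np.ones(n), "z": z})
            ctx = GLMContext(y, exog, sm.families.Poisson(), offset=np.zeros(n))
            _, _, p = gx.term_lrt(ctx, "z")
            lo, hi = gx.profile_ci(ctx, "z")
            excludes_null = (lo > 0.0) or (hi < 0.0)
            agree += (p < 0.05) == excludes_null
        assert agree == 50

    def test_coverage_check_equals_membership(self):
        ctx = poisson_context()
        lo, hi = gx.profile_ci(ctx, "intercept")
        inside = 0.5 * (lo + hi)
        assert gx.profile_covers(ctx, "intercept", inside)
        assert not gx.profile_covers(ctx, "intercept", hi + 0.05)
        assert not gx.profile_covers(ctx, "intercept", lo - 0.05)


class TestBayesFactor:
    def test_printed_worked_example(self):
        bf = gx.bayes_factor_from_lrt(11.50, 1.18)
        assert round(bf) == 174
        assert gx.kass_raftery_label(bf) == "very strong"

    def test_symmetry_and_identity(self):
        assert gx.bayes_factor_from_lrt(5.0, 5.0) == pytest.approx(1.0)
        assert gx.bayes_factor_from_lrt(7.0, 3.0) == pytest.approx(
            1.0 / gx.bayes_factor_from_lrt(3.0, 7.0)
        )

    def test_boundary_inversion(self):
        assert gx.bayes_factor_from_lrt(2 * math.log(20.0), 0.0) == pytest.approx(20.0)

    def test_unequal_df_rejected(self):
        with pytest.raises(InvalidComparisonError):
            gx.bayes_factor_from_lrt(5.0, 1.0, equal_df=False)

    def test_matches_bic_difference_on_fitted_models(self):
        """exp((BIC_2 - BIC_1)/2) from log-likelihoods equals the LRT-based
        Bayes factor to 1e-10 for equal-df models."""
        rng = np.random.default_rng(4)
        n = 2_000
        sexv = (rng.random(n) < 0.5).astype(float)
        score = rng.random(n)
        mu = 0.1 * np.exp(0.4 * sexv)
        y = rng.poisson(mu).astype(float)
        base = pd.DataFrame({"intercept": np.ones(n)})
        m1 = GLMContext(
            y, base.assign(sex=sexv), sm.families.Poisson(), offset=np.zeros(n)
        )
        m2 = GLMContext(
            y, base.assign(score=score), sm.families.Poisson(), offset=np.zeros(n)
        )
        m3 = GLMContext(
            y,
            base.assign(sex=sexv, score=score),
            sm.families.Poisson(),
            offset=np.zeros(n),
        )
        lrt_sex, _, _ = gx.lrt(m3.result, m2.result)
        lrt_score, _, _ = gx.lrt(m3.result, m1.result)
        bf = gx.bayes_factor_from_lrt(lrt_sex, lrt_score)
        bic1 = -2 * m1.result.loglik + m1.result.model_df * math.log(n)
        bic2 = -2 * m2.result.loglik + m2.result.model_df * math.log(n)
        assert bf == pytest.approx(math.exp((bic2 - bic1) / 2.0), abs=1e-10)


class TestKassRaftery:
    @pytest.mark.parametrize(
        "bf,label",
        [
            (1.0, "negligible"),
            (3.0, "negligible"),
            (3.0001, "positive"),
            (20.0, "positive"),
            (150.0, "strong"),
            (174.0, "very strong"),
            (0.005, "very strong"),  # inverted: 1/0.005 = 200
        ],
    )
    def test_bins(self, bf, label):
        assert gx.kass_raftery_label(bf) == label

    def test_nonpositive_rejected(self):
        with pytest.raises(InvalidComparisonError):
            gx.kass_raftery_label(0.0)


class TestComparison:
    def test_narrative_fields(self):
        comp = gx.compare_sex_vs_gender(11.50, 1.18, 1)
        assert comp.favored == "sex"
        assert round(comp.bayes_factor) == 174
        assert comp.kass_raftery_label == "very strong"
        text = comp.narrative()
        assert "11.50" in text and "very strong" in text
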