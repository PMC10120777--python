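"""Univariate screening, Benjamini–Hochberg control, and the
multivariable gender-score model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

import genderdx as gx
from genderdx.codes import CodeIndicatorMatrix
from genderdx.errors import DegenerateCodeError
from scipy import sparse

from conftest import spearman


def matrix_from_dense(x):
    x = np.asarray(x)
    return CodeIndicatorMatrix(
        vocabulary=[f"C{j}" for j in range(x.shape[1])],
        matrix=sparse.csr_matrix(x),
        person_index=pd.Index([f"P{i}" for i in range(x.shape[0])]),
    )


def bernoulli_loglik(a, b, x, y):
    eta = a + b * x
    return float((y * eta - np.log1p(np.exp(eta))).sum())


def grid_maximize(x, y, span=6.0, tol=1e-5):
    """Nested-grid maximization of the univariate logistic likelihood,
    independent of any fitting library."""
    center = np.zeros(2)
    width = span
    for _ in range(12):
        grid = np.linspace(-width, width, 21)
        best, arg = -np.inf, None
        for da in grid:
            for db in grid:
                ll = bernoulli_loglik(center[0] + da, center[1] + db, x, y)
                if ll > best:
                    best, arg = ll, (da, db)
        center = center + np.array(arg)
        width *= 0.2
        if width < tol:
            break
    return center


class TestUnivariateScreen:
    def test_or_equals_cross_product_example(self):
        # code present in 10/100 males and 30/100 females
        x = np.r_[np.ones(30), np.zeros(70), np.ones(10), np.zeros(90)]
        sex = np.r_[np.ones(100), np.zeros(100)]
        screen = gx.univariate_screen(matrix_from_dense(x[:, None]), sex)
        assert screen["odds_ratio"][0] == pytest.approx((30 * 90) / (70 * 10))

    def test_null_symmetry(self):
        # identical prevalence in a balanced cohort: OR=1, p ~ 1
        x = np.r_[np.ones(20), np.zeros(80), np.ones(20), np.zeros(80)]
        sex = np.r_[np.ones(100), np.zeros(100)]
        screen = gx.univariate_screen(matrix_from_dense(x[:, None]), sex)
        assert screen["odds_ratio"][0] == pytest.approx(1.0)
        assert screen["p_value"][0] > 0.99

    def test_wald_and_lrt_agree_on_direction(self):
        rng = np.random.default_rng(4)
        x = rng.random((300, 3)) < [0.1, 0.3, 0.5]
        sex = rng.integers(0, 2, 300)
        m = matrix_from_dense(x)
        wald = gx.univariate_screen(m, sex, "wald")
        lrt = gx.univariate_screen(m, sex, "lrt")
        assert np.allclose(wald["odds_ratio"], lrt["odds_ratio"])
        assert spearman(wald["p_value"], lrt["p_value"]) > 0.9

    def test_closed_form_matches_grid_search_oracle(self):
        """The screening (intercept, slope) equal a brute-force grid
        maximization of the Bernoulli log-likelihood on a 40-person fixture."""
        rng = np.random.default_rng(8)
        x = (rng.random(40) < 0.4).astype(float)
        sex = (rng.random(40) < expit(-0.3 + 1.2 * x)).astype(float)
        screen = gx.univariate_screen(matrix_from_dense(x[:, None]), sex)
        a_hat, b_hat = grid_maximize(x, sex)
        assert np.log(screen["odds_ratio"][0]) == pytest.approx(b_hat, abs=1e-4)
        # intercept of the univariate fit is the log odds among non-carriers
        n_f0 = ((sex == 1) & (x == 0)).sum()
        n_m0 = ((sex == 0) & (x == 0)).sum()
        assert np.log(n_f0 / n_m0) == pytest.approx(a_hat, abs=1e-4)

    def test_zero_cell_raises(self):
        x = np.r_[np.ones(5), np.zeros(5)][:, None]
        sex = np.r_[np.ones(5), np.zeros(5)]  # code only in females
        with pytest.raises(DegenerateCodeError):
            gx.univariate_screen(matrix_from_dense(x), sex)


def bh_brute_force(p):
    """Definition-based step-up adjustment: adjusted_i = min_{j: p_j >= p_i}
    of m * p_(j) / rank(j), capped at 1."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        adj[idx] = min(running, 1.0)
    return adj


class TestBHAdjust:
    def test_hand_example(self):
        assert gx.bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones_capped(self):
        assert gx.bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=8,
        )
    )
    def test_matches_brute_force_definition(self, p):
        assert gx.bh_adjust(p) == pytest.approx(bh_brute_force(np.array(p)), abs=1e-12)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=1e-6, max_value=1.0, allow_nan=False),
            min_size=2,
            max_size=8,
        )
    )
    def test_monotone_and_dominates_raw(self, p):
        p = np.array(p)
        adj = gx.bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestSelectCodes:
    def _screen(self, codes, ps):
        return pd.DataFrame(
            {"code": codes, "odds_ratio": np.ones(len(codes)), "p_value": ps}
        )

    def test_engineered_fixture_selects_exactly_three(self):
        codes = [f"C{i}" for i in range(10)]
        strong = [1e-8, 1e-8, 1e-8] + [0.8] * 7
        sel = gx.select_codes(self._screen(codes, strong), self._screen(codes, strong))
        assert sel["selected"].sum() == 3
        assert set(sel.loc[sel["selected"] == 1, "code"]) == {"C0", "C1", "C2"}

    def test_significant_in_one_set_only_excluded(self):
        codes = ["A", "B"]
        train = self._screen(codes, [1e-8, 1e-8])
        valid = self._screen(codes, [1e-8, 0.9])
        sel = gx.select_codes(train, valid)
        assert sel.set_index("code")["selected"].to_dict() == {"A": 1, "B": 0}

    def test_empty_selection_warns(self):
        codes = ["A"]
        with pytest.warns(UserWarning, match="empty"):
            gx.select_codes(self._screen(codes, [0.9]), self._screen(codes, [0.9]))


class TestScoreModel:
    def test_single_code_reproduces_univariate_fit(self):
        rng = np.random.default_rng(2)
        x = (rng.random(200) < 0.3).astype(float)
        sex = (rng.random(200) < expit(0.2 + 0.8 * x)).astype(float)
        m = matrix_from_dense(x[:, None])
        screen = gx.univariate_screen(m, sex)
        model = gx.fit_score_model(m, sex, ["C0"])
        assert model.coefficients["C0"] == pytest.approx(
            np.log(screen["odds_ratio"][0]), abs=1e-6
        )

    def test_intercept_only_scores_female_fraction(self):
        sex = np.r_[np.ones(30), np.zeros(70)]
        m = matrix_from_dense(np.zeros((100, 1)))
        model = gx.fit_score_model(m, sex, [])
        scores = gx.score_persons(model, m)
        assert scores == pytest.approx(np.full(100, 0.3), abs=1e-9)

    def test_aliased_column_dropped_first_kept_wins(self):
        rng = np.random.default_rng(6)
        x = (rng.random(100) < 0.4).astype(float)
        sex = (rng.random(100) < expit(x)).astype(float)
        m = matrix_from_dense(np.column_stack([x, x]))  # C1 duplicates C0
        model = gx.fit_score_model(m, sex, ["C0", "C1"])
        assert list(model.coefficients.index) == ["C0"]
        assert model.dropped_codes == ["C1"]

    def test_mle_beats_random_restarts(self):
        """Fitted log-likelihood dominates 1,000 random coefficient vectors
        on a 3-code fixture."""
        rng = np.random.default_rng(9)
        x = (rng.random((60, 3)) < [0.3, 0.4, 0.2]).astype(float)
        sex = (rng.random(60) < expit(-0.2 + x @ [1.0, -0.8, 0.5])).astype(float)
        m = matrix_from_dense(x)
        model = gx.fit_score_model(m, sex, ["C0", "C1", "C2"])
        design = np.column_stack([np.ones(60), x])
        beta_hat = np.r_[model.intercept, model.coefficients.to_numpy()]

        def ll(beta):
            eta = design @ beta
            return (sex * eta - np.logaddexp(0.0, eta)).sum()

        best_random = max(ll(rng.normal(scale=2.0, size=4)) for _ in range(1000))
        assert ll(beta_hat) >= best_random

    def test_unseen_codes_treated_as_absent(self):
        model = gx.GenderScoreModel(
            selected_codes=["C0", "ZZZ"],
            intercept=-0.5,
            coefficients=pd.Series({"C0": 1.0, "ZZZ": 2.0}),
        )
        m = matrix_from_dense(np.array([[1.0], [0.0]]))
        scores = gx.score_persons(model, m)
        assert scores == pytest.approx([expit(0.5), expit(-0.5)])

    def test_scores_strictly_inside_unit_interval(self):
        model = gx.GenderScoreModel(
            selected_codes=["C0"], intercept=100.0, coefficients=pd.Series({"C0": 100.0})
        )
        m = matrix_from_dense(np.array([[1.0], [0.0]]))
        scores = gx.score_persons(model, m)
        assert (scores > 0).all() and (scores < 1).all()


class TestDerivedScoreProperties:
    """Properties of the full derivation at simulation scale (shared fixture)."""

    def test_mean_training_score_equals_female_fraction(self, score_bundle):
        assert score_bundle["train_scores"].mean() == pytest.approx(
            score_bundle["train_sex"].mean(), abs=1e-8
        )

    def test_female_skewed_codes_recovered_with_or_above_one(self, score_bundle):
        screen = score_bundle["screen_train"]
        truth = score_bundle["truth"]
        female_codes = [c for c, cls in truth.code_classes.items() if cls == "female"]
        ors = screen.set_index("code").loc[
            [c for c in female_codes if c in set(screen["code"])], "odds_ratio"
        ]
        assert (ors > 1).mean() >= 0.95

    def test_score_distribution_skews_toward_male_like(self, score_bundle):
        """With ~80% male-skewed informative codes the test-set score
        distribution is heavier in the left tail."""
        scores = score_bundle["test_scores"]
        assert np.median(scores) < score_bundle["train_sex"].mean()

    def test_model_roundtrips_through_json(self, score_bundle, tmp_path):
        model = score_bundle["model"]
        model.to_json(tmp_path / "m.json")
        back = gx.GenderScoreModel.from_json(tmp_path / "m.json")
        assert back.intercept == pytest.approx(model.intercept)
        assert back.coefficients.to_dict() == pytest.approx(
            model.coefficients.to_dict()
        )
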