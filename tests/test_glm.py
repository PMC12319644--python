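"""Fitting core: closed forms, optimizer oracle, invariances, LR test."""

import math

import numpy as np
import pytest
from scipy import optimize

from relint.glm import (ModelSpec, Term, bic, build_design, fit_logistic,
                        fit_model, fit_multinomial, freeze_knots, lr_test,
                        predict_probs_design, _multinomial_loglik)


def _two_by_two(a, b, c, d):
    """Design/outcome for a 2x2 table: exposed (a yes, b no), unexposed (c, d)."""
    X = np.column_stack([np.ones(a + b + c + d),
                         np.r_[np.ones(a + b), np.zeros(c + d)]])
    y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    return X, y


class TestLogistic:
    def test_two_by_two_closed_form(self):
        X, y = _two_by_two(10, 20, 30, 40)
        f = fit_logistic(X, y)
        assert f.coefficients[1] == pytest.approx(math.log(10 * 40 / (20 * 30)),
                                                  abs=1e-8)
        assert f.coefficients[0] == pytest.approx(math.log(30 / 40), abs=1e-8)
        assert f.converged

    def test_balanced_table_zero_slope(self):
        X, y = _two_by_two(10, 10, 10, 10)
        f = fit_logistic(X, y)
        assert abs(f.coefficients[1]) < 1e-8

    def test_rank_deficiency_rejected(self):
        X = np.column_stack([np.ones(20), np.arange(20.0), np.arange(20.0)])
        y = (np.arange(20) % 2).astype(float)
        with pytest.raises(ValueError):
            fit_logistic(X, y)

    def test_separation_flagged(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = x.copy()
        f = fit_logistic(np.column_stack([np.ones(40), x]), y)
        assert f.separation

    def test_score_at_optimum_small(self, rng):
        X = np.column_stack([np.ones(500), rng.standard_normal((500, 3))])
        y = (rng.random(500) < 0.4).astype(float)
        f = fit_logistic(X, y)
        mu = 1 / (1 + np.exp(-(X @ f.coefficients)))
        assert np.max(np.abs(X.T @ (y - mu))) < 1e-6

    def test_rescaling_column_inversely_rescales_coefficient(self, rng):
        X = np.column_stack([np.ones(400), rng.standard_normal(400)])
        y = (rng.random(400) < 1 / (1 + np.exp(-X[:, 1]))).astype(float)
        f1 = fit_logistic(X, y)
        X2 = X.copy()
        X2[:, 1] *= 10
        f2 = fit_logistic(X2, y)
        assert f2.coefficients[1] == pytest.approx(f1.coefficients[1] / 10,
                                                   rel=1e-6)

    def test_row_permutation_invariance(self, rng):
        X = np.column_stack([np.ones(300), rng.standard_normal((300, 2))])
        y = (rng.random(300) < 0.5).astype(float)
        f1 = fit_logistic(X, y)
        perm = rng.permutation(300)
        f2 = fit_logistic(X[perm], y[perm])
        np.testing.assert_allclose(f1.coefficients, f2.coefficients, atol=1e-9)


class TestMultinomial:
    def test_intercept_only_closed_form(self):
        y = np.array([0] * 10 + [1] * 20 + [2] * 5)
        X = np.ones((35, 1))
        f = fit_multinomial(X, y, n_categories=3)
        assert f.coefficients[0, 0] == pytest.approx(math.log(20 / 10), abs=1e-8)
        assert f.coefficients[1, 0] == pytest.approx(math.log(5 / 10), abs=1e-8)

    def test_loglik_matches_generic_optimizer(self, rng):
        n = 30
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        y = rng.integers(0, 3, size=n)
        f = fit_multinomial(X, y, n_categories=3)

        def negll(theta):
            return -_multinomial_loglik(X, y, theta.reshape(2, 3))

        res = optimize.minimize(negll, np.zeros(6), method="BFGS",
                                options={"gtol": 1e-10, "maxiter": 2000})
        assert f.loglik == pytest.approx(-res.fun, abs=1e-6)

    def test_probabilities_sum_to_one(self, rng):
        X = np.column_stack([np.ones(50), rng.standard_normal(50)])
        y = rng.integers(0, 3, size=50)
        f = fit_multinomial(X, y, n_categories=3)
        P = predict_probs_design(f, X)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_k2_equals_logistic(self, rng):
        X = np.column_stack([np.ones(200), rng.standard_normal(200)])
        y = (rng.random(200) < 0.4).astype(int)
        fm = fit_multinomial(X, y, n_categories=2)
        fl = fit_logistic(X, y.astype(float))
        np.testing.assert_allclose(fm.coefficients[0], fl.coefficients,
                                   atol=1e-8)
        assert fm.loglik == pytest.approx(fl.loglik, abs=1e-8)


class TestInformationCriteria:
    def test_bic_hand_computed_on_2x2(self):
        X, y = _two_by_two(10, 20, 30, 40)
        f = fit_logistic(X, y)
        # closed-form loglik of the saturated-in-x 2x2 fit
        ll = (10 * math.log(1 / 3) + 20 * math.log(2 / 3)
              + 30 * math.log(3 / 7) + 40 * math.log(4 / 7))
        assert f.loglik == pytest.approx(ll, abs=1e-8)
        assert bic(f) == pytest.approx(-2 * ll + 2 * math.log(100), abs=1e-8)

    def test_noise_column_never_lowers_loglik(self, rng):
        X = np.column_stack([np.ones(300), rng.standard_normal(300)])
        y = (rng.random(300) < 0.3).astype(float)
        f1 = fit_logistic(X, y)
        f2 = fit_logistic(np.column_stack([X, rng.standard_normal(300)]), y)
        assert f2.loglik >= f1.loglik - 1e-10


class TestLRTest:
    def test_identical_models_statistic_zero(self, rng):
        X = np.column_stack([np.ones(100), rng.standard_normal(100)])
        y = (rng.random(100) < 0.5).astype(float)
        f = fit_logistic(X, y)
        stat, df, p = lr_test(f, f)
        assert stat == 0 and df == 0 and p == 1.0

    def test_df_equals_columns_dropped(self, rng):
        X = np.column_stack([np.ones(200), rng.standard_normal((200, 4))])
        y = (rng.random(200) < 0.5).astype(float)
        full = fit_logistic(X, y, column_names=["i", "a", "b", "c", "d"])
        red = fit_logistic(X[:, :3], y, column_names=["i", "a", "b"])
        stat, df, p = lr_test(full, red)
        assert df == 2 and stat >= 0

    def test_non_nested_rejected(self, rng):
        X = np.column_stack([np.ones(100), rng.standard_normal((100, 2))])
        y = (rng.random(100) < 0.5).astype(float)
        f1 = fit_logistic(X[:, [0, 1]], y, column_names=["i", "a"])
        f2 = fit_logistic(X[:, [0, 2]], y, column_names=["i", "b"])
        with pytest.raises(ValueError):
            lr_test(f1, f2)


class TestDesign:
    def test_sex_only_single_indicator(self, small_table):
        spec = ModelSpec(outcome="qa", terms=[Term("sex", "categorical")])
        d = build_design(small_table, spec)
        assert d.column_names == ["(Intercept)", "sex[female]"]
        np.testing.assert_array_equal(
            d.X[:, 1],
            (small_table.loc[d.index, "sex"] == "female").to_numpy(float))

    def test_interaction_column_count(self, small_table):
        spec = ModelSpec(outcome="qa",
                         terms=[Term("sex", "categorical"),
                                Term("education", "categorical")],
                         interactions=[("sex", "education")])
        d = build_design(small_table, spec)
        inter = [c for c in d.column_names if ":" in c]
        assert inter == ["sex[female]:education[middle]",
                         "sex[female]:education[high]"]

    def test_spline_interaction_products(self, small_table):
        spec = ModelSpec(outcome="qa",
                         terms=[Term("age", "rcs4"), Term("income", "linear")],
                         interactions=[("age", "income")])
        freeze_knots(small_table, spec)
        d = build_design(small_table, spec)
        # 1 intercept + 3 age + 1 income + 3 products
        assert len(d.column_names) == 8
        age_cols = [d.column_names.index(c) for c in ("age", "age'", "age''")]
        inc = d.X[:, d.column_names.index("income")]
        for k, j in enumerate(age_cols):
            np.testing.assert_allclose(d.X[:, 5 + k], d.X[:, j] * inc,
                                       atol=1e-12)

    def test_unseen_level_raises(self, small_table):
        spec = ModelSpec(outcome="qa", terms=[Term("sex", "categorical")])
        bad = small_table.copy()
        bad.loc[bad.index[0], "sex"] = "other"
        with pytest.raises(ValueError, match="other"):
            build_design(bad, spec)

    def test_hierarchy_enforced(self):
        with pytest.raises(ValueError):
            ModelSpec(outcome="qa", terms=[Term("sex", "categorical")],
                      interactions=[("sex", "education")])

    def test_spec_json_round_trip(self, small_table):
        spec = ModelSpec(outcome="mtss3",
                         terms=[Term("age", "rcs4"), Term("sex", "categorical")],
                         interactions=[])
        freeze_knots(small_table, spec)
        back = ModelSpec.from_json(spec.to_json())
        assert back.to_dict() == spec.to_dict()
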