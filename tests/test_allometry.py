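import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crownagb import allometry as al


class TestReferenceAgb:
    def test_larch_worked_example(self):
        # Independent arithmetic: 0.1179 * exp(0.815 * ln(20^2 * 15))
        expected = 0.1179 * math.exp(0.815 * math.log(20.0 ** 2 * 15.0))
        assert al.reference_agb("larch", 20.0, 15.0) == pytest.approx(expected)
        assert al.reference_agb("larch", 20.0, 15.0) == pytest.approx(141.5, abs=0.1)

    def test_broadleaf_worked_example(self):
        expected = 0.093 * math.exp(0.869 * math.log(12.0 ** 2 * 10.0))
        assert al.reference_agb("ash", 12.0, 10.0) == pytest.approx(expected)
        assert al.reference_agb("sophora", 12.0, 10.0) == pytest.approx(51.7, abs=0.1)

    def test_unit_composite_returns_alpha(self):
        # DBH^2 * H = 1 => W = alpha exactly
        assert al.reference_agb("larch", 1.0, 1.0) == pytest.approx(0.1179)
        assert al.reference_agb("ash", 1.0, 1.0) == pytest.approx(0.093)

    def test_unknown_species_raises(self):
        with pytest.raises(ValueError, match="unknown species"):
            al.reference_agb("oak", 10, 10)

    def test_nonpositive_inputs_raise(self):
        with pytest.raises(ValueError):
            al.reference_agb("larch", -1, 10)
        with pytest.raises(ValueError):
            al.reference_agb("larch", 10, 0)

    def test_monotone_in_both_arguments(self):
        base = al.reference_agb("larch", 15, 12)
        assert al.reference_agb("larch", 16, 12) > base
        assert al.reference_agb("larch", 15, 13) > base

    @given(dbh=st.floats(1, 60), h=st.floats(1, 40),
           k=st.floats(0.5, 2.0))
    def test_composite_predictor_invariance(self, dbh, h, k):
        # (DBH, H) -> (k*DBH, H/k^2) leaves DBH^2*H, hence W, unchanged.
        w1 = al.reference_agb("larch", dbh, h)
        w2 = al.reference_agb("larch", k * dbh, h / k ** 2)
        assert w2 == pytest.approx(w1, rel=1e-9)


class TestModelPredict:
    def test_eq9_trivial(self):
        spec = al.ModelSpec("Eq9", (1.0, 0.0, 0.0))
        assert al.model_predict(spec, 2.0, 1.0) == pytest.approx(9.0)

    def test_eq5_b_zero_is_constant(self):
        spec = al.ModelSpec("Eq5", (4.2, 0.0))
        for h, r in [(1, 1), (10, 3), (25, 0.5)]:
            assert al.model_predict(spec, h, r) == pytest.approx(4.2)

    def test_eq4_product(self):
        spec = al.ModelSpec("Eq4", (2.0, 1.0))
        assert al.model_predict(spec, 3.0, 0.5) == pytest.approx(3.0)

    def test_log_of_nonpositive_predictor_raises(self):
        spec = al.ModelSpec("Eq7", (1.0, 0.0))
        with pytest.raises(ValueError):
            al.model_predict(spec, np.array([-2.0]), np.array([1.0]))

    def test_coefficient_count_enforced(self):
        with pytest.raises(ValueError):
            al.ModelSpec("Eq1", (1.0, 2.0, 3.0))
        with pytest.raises(ValueError):
            al.ModelSpec("Eq9", (1.0, 2.0))

    @pytest.mark.parametrize("code", al.MODEL_CODES)
    def test_all_forms_evaluate(self, code):
        coef = (1.0, 0.5, 0.1) if code == "Eq9" else (1.0, 0.5)
        w = al.model_predict(al.ModelSpec(code, coef),
                             np.array([5.0, 10.0]), np.array([1.0, 2.0]))
        assert np.all(np.isfinite(w))


class TestEvaluate:
    def test_perfect_prediction(self):
        m = al.evaluate([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m.r2 == pytest.approx(1.0)
        assert m.rmse == pytest.approx(0.0)
        assert m.rrmse == pytest.approx(0.0)

    def test_worked_example(self):
        # y=(1,2,3), yhat=(2,2,2): SS_res = SS_tot = 2, y_bar = 2
        m = al.evaluate([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        assert m.r2 == pytest.approx(0.0, abs=1e-12)
        assert m.rmse == pytest.approx(math.sqrt(2.0 / 3.0), rel=1e-9)
        assert m.rmse == pytest.approx(0.8165, abs=5e-5)
        assert m.rrmse == pytest.approx(40.82, abs=5e-3)

    @given(c=st.floats(0.1, 100))
    @settings(max_examples=30)
    def test_scale_invariance(self, c):
        y = np.array([1.0, 2.0, 3.0, 5.0])
        yh = np.array([1.1, 1.8, 3.3, 4.6])
        m1 = al.evaluate(yh, y)
        m2 = al.evaluate(c * yh, c * y)
        assert m2.r2 == pytest.approx(m1.r2, rel=1e-9)
        assert m2.rrmse == pytest.approx(m1.rrmse, rel=1e-9)
        assert m2.rmse == pytest.approx(c * m1.rmse, rel=1e-9)

    def test_zero_variance_with_residuals_is_nan(self):
        m = al.evaluate([1.0, 2.0], [3.0, 3.0])
        assert math.isnan(m.r2)

    def test_zero_mean_rrmse_is_nan(self):
        m = al.evaluate([0.1, -0.1], [1.0, -1.0])
        assert math.isnan(m.rrmse)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            al.evaluate([1.0], [1.0, 2.0])


class TestFitModel:
    def test_eq9_exact_quadratic_recovery(self):
        rng = np.random.default_rng(1)
        h = rng.uniform(5, 20, 10)
        r = rng.uniform(1, 4, 10)
        x = h + r
        w = 2.0 * x ** 2 + 3.0 * x + 1.0
        fit = al.fit_model("Eq9", h, r, w)
        assert fit.converged
        np.testing.assert_allclose(fit.spec.coefficients, (2.0, 3.0, 1.0),
                                   rtol=1e-6)

    def test_eq4_noise_free_recovery(self):
        rng = np.random.default_rng(2)
        h = rng.uniform(5, 20, 50)
        r = rng.uniform(1, 4, 50)
        w = 0.5 * (h * r) ** 1.2
        fit = al.fit_model("Eq4", h, r, w)
        assert fit.converged
        np.testing.assert_allclose(fit.spec.coefficients, (0.5, 1.2),
                                   rtol=1e-4)

    def test_constant_w_eq6_flat_fit(self):
        h = np.array([5.0, 8.0, 11.0, 14.0])
        r = np.array([1.0, 2.0, 1.5, 2.5])
        w = np.full(4, 7.0)
        fit = al.fit_model("Eq6", h, r, w)
        a, b = fit.spec.coefficients
        assert a == pytest.approx(0.0, abs=1e-12)
        assert b == pytest.approx(7.0, rel=1e-12)
        pred = al.model_predict(fit.spec, h, r)
        assert al.evaluate(pred, w).r2 == pytest.approx(0.0)

    def test_too_few_observations_raise(self):
        with pytest.raises(ValueError):
            al.fit_model("Eq9", [1, 2, 3], [1, 1, 1], [1, 2, 3])

    def test_singular_design_raises(self):
        # identical predictor everywhere -> rank-deficient design
        h = np.full(5, 10.0)
        r = np.full(5, 2.0)
        with pytest.raises(np.linalg.LinAlgError):
            al.fit_model("Eq9", h, r, np.arange(5.0) + 1)

    @pytest.mark.parametrize("code", ["Eq6", "Eq7", "Eq9"])
    def test_ols_equals_nls_oracle(self, code):
        """Closed-form OLS vs an independent NLS path agree to 1e-8.

        The NLS oracle is hand-rolled Gauss-Newton in a centred/scaled
        predictor basis (well conditioned; solves normal equations, a
        different numerical path from the SVD-based closed form) whose
        coefficients are mapped back analytically.
        """
        rng = np.random.default_rng(3)
        h = rng.uniform(5, 20, 40)
        r = rng.uniform(1, 4, 40)
        x = h + r
        w = 0.3 * x ** 2 + 1.5 * x + 4 + rng.normal(0, 5, 40)
        fit = al.fit_model(code, h, r, w)

        t = np.log(x) if code == "Eq7" else x
        mu, sd = t.mean(), t.std()
        u = (t - mu) / sd

        if code == "Eq9":
            jac = np.column_stack([u ** 2, u, np.ones_like(u)])
            p = np.array([1.0, 1.0, w.mean()])
        else:
            jac = np.column_stack([u, np.ones_like(u)])
            p = np.array([1.0, w.mean()])
        for _ in range(3):  # GN: exact after one step for a linear model
            resid = jac @ p - w
            p = p - np.linalg.solve(jac.T @ jac, jac.T @ resid)

        if code == "Eq9":
            q2, q1, q0 = p
            back = (q2 / sd ** 2,
                    q1 / sd - 2 * q2 * mu / sd ** 2,
                    q0 - q1 * mu / sd + q2 * mu ** 2 / sd ** 2)
        else:
            q1, q0 = p
            back = (q1 / sd, q0 - q1 * mu / sd)
        np.testing.assert_allclose(back, fit.spec.coefficients, rtol=1e-8)

    def test_train_r2_equals_squared_pearson(self):
        rng = np.random.default_rng(4)
        h = rng.uniform(5, 20, 60)
        r = rng.uniform(1, 4, 60)
        w = 2.0 * (h + r) + 5 + rng.normal(0, 3, 60)
        fit = al.fit_model("Eq6", h, r, w)
        pred = al.model_predict(fit.spec, h, r)
        m = al.evaluate(pred, w)
        rho = np.corrcoef(pred, w)[0, 1]
        assert m.r2 == pytest.approx(rho ** 2, abs=1e-10)

    def test_grid_search_finds_no_lower_sse(self):
        """Dense grid around the NLS optimum: local optimality oracle."""
        rng = np.random.default_rng(5)
        h = rng.uniform(5, 20, 25)
        r = rng.uniform(1, 4, 25)
        w = 0.8 * (h * r) ** 1.1 * np.exp(rng.normal(0, 0.05, 25))
        fit = al.fit_model("Eq4", h, r, w)
        a0, b0 = fit.spec.coefficients
        x = h * r

        def sse(a, b):
            return float(np.sum((a * x ** b - w) ** 2))

        best = sse(a0, b0)
        grid_best = min(
            sse(a, b)
            for a in np.linspace(0.95 * a0, 1.05 * a0, 41)
            for b in np.linspace(0.95 * b0, 1.05 * b0, 41))
        assert best <= grid_best + 1e-9 * max(best, 1.0)
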