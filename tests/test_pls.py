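"""The NIPALS PLSR engine against independent oracles and its invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from osteograft import pls
from osteograft.pls import (
    FittedEquation,
    PLSError,
    ZeroVarianceError,
    backward_eliminate,
    fit_pls,
    loo_predictions,
    loo_rmse,
    pred_obs_correlation,
    predict,
    to_equation,
    vip_scores,
)

# ---------------------------------------------------------------------------
# Independent oracles (kept deliberately naive and separate from the package)
# ---------------------------------------------------------------------------


def ols_equation(X, y):
    """Least squares through the normal equations on the raw design."""
    Xa = np.column_stack([np.ones(len(y)), X])
    beta = np.linalg.solve(Xa.T @ Xa, Xa.T @ y)
    return beta[0], beta[1:]


def nipals_oracle(X, y, A, scale=True):
    """Classic iterative NIPALS with the textbook inner loop."""
    X = np.array(X, dtype=float)
    y = np.array(y, dtype=float)
    xm, ym = X.mean(0), y.mean()
    xs = X.std(0, ddof=1) if scale else np.ones(X.shape[1])
    ys = y.std(ddof=1) if scale else 1.0
    E = (X - xm) / xs
    f = (y - ym) / ys
    W, P, Q = [], [], []
    for _ in range(A):
        u = f.copy()
        for _ in range(100):  # converges immediately for a single response
            w = E.T @ u
            w = w / np.linalg.norm(w)
            t = E @ w
            q = f @ t / (t @ t)
            u_new = f * q / (q * q)
            if np.allclose(u_new, u):
                break
            u = u_new
        p = E.T @ t / (t @ t)
        E = E - np.outer(t, p)
        f = f - q * t
        W.append(w)
        P.append(p)
        Q.append(q)
    W, P, Q = np.array(W).T, np.array(P).T, np.array(Q)
    b = W @ np.linalg.solve(P.T @ W, Q)
    coef = b * ys / xs
    return ym - coef @ xm, coef


def loo_rmse_oracle(X, y, A, scale=True):
    """Naive leave-one-out loop around the oracle fit."""
    errs = []
    for i in range(len(y)):
        mask = np.ones(len(y), dtype=bool)
        mask[i] = False
        b0, b = nipals_oracle(X[mask], y[mask], A, scale)
        errs.append(y[i] - (b0 + X[i] @ b))
    return float(np.sqrt(np.mean(np.square(errs))))


# ---------------------------------------------------------------------------
# fit_pls / to_equation / predict
# ---------------------------------------------------------------------------


class TestFit:
    def test_perfectly_collinear_single_predictor(self):
        m = fit_pls([[1.0], [2.0], [3.0]], [2.0, 4.0, 6.0], 1)
        eq = to_equation(m)
        assert eq.intercept == pytest.approx(0.0, abs=1e-10)
        assert eq.coefficients["x0"] == pytest.approx(2.0)
        assert predict(m, [[1.5]]) == pytest.approx([3.0])

    def test_full_rank_matches_normal_equations(self, rng):
        X = rng.normal(size=(8, 3))
        y = rng.normal(size=8)
        eq = to_equation(fit_pls(X, y, 3))
        b0, b = ols_equation(X, y)
        assert eq.intercept == pytest.approx(b0, abs=1e-8)
        assert list(eq.coefficients.values()) == pytest.approx(b, abs=1e-8)

    @pytest.mark.parametrize("A", [1, 2, 3])
    def test_matches_iterative_nipals_oracle(self, rng, A):
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        eq = to_equation(fit_pls(X, y, A))
        b0, b = nipals_oracle(X, y, A)
        assert eq.intercept == pytest.approx(b0, abs=1e-9)
        assert list(eq.coefficients.values()) == pytest.approx(b, abs=1e-9)

    def test_matches_sklearn_predictions(self, rng):
        sklearn_pls = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(12, 4))
        y = rng.normal(size=12)
        ours = predict(fit_pls(X, y, 2), X)
        ref = sklearn_pls.PLSRegression(n_components=2, scale=True).fit(X, y)
        assert ours == pytest.approx(ref.predict(X).ravel(), abs=1e-8)

    def test_score_orthogonality(self, rng):
        X = rng.normal(size=(15, 5))
        y = rng.normal(size=15)
        m = fit_pls(X, y, 4)
        G = m.scores.T @ m.scores
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() <= 1e-8 * np.diag(G).max()

    def test_zero_variance_column_is_named(self):
        X = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0], [4.0, 5.0]])
        with pytest.raises(ZeroVarianceError, match="const"):
            fit_pls(X, [1.0, 2.0, 3.0, 4.0], 1, labels=["a", "const"])

    def test_inert_constant_column_when_allowed(self):
        X = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0], [4.0, 5.0]])
        m = fit_pls(X, [2.0, 4.0, 6.0, 8.0], 1, labels=["a", "const"],
                    allow_constant=True)
        eq = to_equation(m)
        assert eq.coefficients["const"] == 0.0
        assert eq.coefficients["a"] == pytest.approx(2.0)

    def test_component_cap_and_nonfinite_rejected(self, rng):
        X = rng.normal(size=(5, 2))
        with pytest.raises(PLSError):
            fit_pls(X, rng.normal(size=5), 3)
        X[0, 0] = np.nan
        with pytest.raises(PLSError):
            fit_pls(X, rng.normal(size=5), 1)

    def test_rank_deficient_extraction_truncates(self, rng):
        X = rng.normal(size=(10, 2))
        X = np.column_stack([X, X[:, 0] + X[:, 1]])  # rank 2
        y = rng.normal(size=10)
        m = fit_pls(X, y, 3)
        assert m.n_components == 2

    def test_equation_reproduces_model_predictions_exactly(self, rng):
        X = rng.normal(size=(9, 3))
        y = rng.normal(size=9)
        m = fit_pls(X, y, 2)
        eq = to_equation(m)
        assert predict(eq, X) == pytest.approx(predict(m, X), abs=1e-9)


class TestPredict:
    def test_printed_equation_literals_at_titanium_row(self):
        eq = FittedEquation(
            intercept=58.14,
            coefficients={"caco3_wt": 3.6, "ti_wt": -0.22, "macroporosity": -0.34},
        )
        val = eq.predict({"caco3_wt": 0.0, "ti_wt": 100.0, "macroporosity": 67.12})
        assert val == pytest.approx(13.3192)

    def test_zero_predictors_give_intercept(self):
        eq = FittedEquation(intercept=58.14, coefficients={"a": 3.6, "b": -0.34})
        assert eq.predict({"a": 0.0, "b": 0.0}) == 58.14

    def test_label_mismatch_errors(self):
        eq = FittedEquation(intercept=0.0, coefficients={"a": 1.0})
        with pytest.raises(PLSError):
            eq.predict({"b": 1.0})
        with pytest.raises(PLSError):
            eq.predict([1.0, 2.0])


class TestInvariance:
    def test_column_rescaling_divides_coefficient(self, rng):
        X = rng.normal(size=(9, 3))
        y = rng.normal(size=9)
        c = 4.0
        X2 = X.copy()
        X2[:, 1] *= c
        eq1 = to_equation(fit_pls(X, y, 2))
        eq2 = to_equation(fit_pls(X2, y, 2))
        assert eq2.coefficients["x1"] == pytest.approx(eq1.coefficients["x1"] / c)
        assert predict(eq2, X2) == pytest.approx(predict(eq1, X), abs=1e-9)

    def test_column_shift_leaves_predictions_unchanged(self, rng):
        X = rng.normal(size=(9, 3))
        y = rng.normal(size=9)
        X2 = X.copy()
        X2[:, 2] += 17.0
        eq1 = to_equation(fit_pls(X, y, 2))
        eq2 = to_equation(fit_pls(X2, y, 2))
        assert predict(eq2, X2) == pytest.approx(predict(eq1, X), abs=1e-9)

    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_loo_curve_invariant_to_row_order(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(8, 3))
        y = rng.normal(size=8)
        perm = rng.permutation(8)
        c1 = loo_rmse(X, y, 3)
        c2 = loo_rmse(X[perm], y[perm], 3)
        assert c1.selected_a == c2.selected_a
        for a in c1.rmse_by_components:
            assert c1.rmse_by_components[a] == pytest.approx(
                c2.rmse_by_components[a], abs=1e-10)


class TestLOO:
    def test_exact_collinear_data_has_zero_rmse(self):
        X = np.arange(1.0, 7.0).reshape(-1, 1)
        y = 2.0 * X.ravel()
        curve = loo_rmse(X, y, 1)
        assert curve.rmse_by_components[1] == pytest.approx(0.0, abs=1e-9)

    def test_matches_naive_refit_oracle(self, rng):
        X = rng.normal(size=(9, 3))
        y = rng.normal(size=9)
        curve = loo_rmse(X, y, 3)
        for a in (1, 2, 3):
            assert curve.rmse_by_components[a] == pytest.approx(
                loo_rmse_oracle(X, y, a), abs=1e-10)

    def test_selected_a_is_argmin(self, rng):
        X = rng.normal(size=(10, 4))
        y = X[:, 0] + 0.1 * rng.normal(size=10)
        curve = loo_rmse(X, y, 4)
        best = min(curve.rmse_by_components.values())
        assert curve.rmse_by_components[curve.selected_a] == best

    def test_degenerate_column_in_fold_is_inert(self, scenario_a_design):
        # titanium is non-zero only for Natix; its fold must still predict
        X, y, labels = scenario_a_design
        preds = loo_predictions(X, y, 2, labels=labels)
        assert np.all(np.isfinite(preds))

    def test_needs_at_least_four_rows(self):
        with pytest.raises(PLSError):
            loo_rmse(np.eye(3), np.arange(3.0), 1)


class TestVIP:
    def test_single_predictor_is_unity(self):
        m = fit_pls([[1.0], [2.0], [3.0], [4.0]], [1.0, 3.0, 2.0, 4.0], 1)
        assert vip_scores(m) == pytest.approx([1.0])

    def test_informative_column_ranks_above_noise(self, rng):
        x1 = rng.normal(size=20)
        X = np.column_stack([x1, rng.normal(size=20)])
        m = fit_pls(X, 3.0 * x1, 2)
        v = vip_scores(m)
        assert v[0] > 1.0 > v[1]

    def test_sum_of_squares_equals_p(self, rng):
        X = rng.normal(size=(12, 5))
        y = rng.normal(size=12)
        v = vip_scores(fit_pls(X, y, 3))
        assert float(np.sum(v**2)) == pytest.approx(5.0, abs=1e-9)


class TestEliminate:
    def test_recovers_single_informative_predictor(self, rng):
        x1 = np.linspace(0, 10, 12)
        noise = rng.normal(size=(12, 3))
        X = np.column_stack([x1, noise])
        res = backward_eliminate(X, 2.0 * x1, labels=["x1", "n1", "n2", "n3"])
        assert res.retained == ("x1",)
        assert res.trace[-1].dropped is None

    def test_single_predictor_input_unchanged(self, rng):
        X = rng.normal(size=(8, 1))
        y = X.ravel() + 0.01 * rng.normal(size=8)
        res = backward_eliminate(X, y, labels=["only"])
        assert res.retained == ("only",)

    def test_trace_is_audit_complete(self, rng):
        X = rng.normal(size=(10, 4))
        y = X @ [1.0, 0.5, 0.0, 0.0] + 0.05 * rng.normal(size=10)
        res = backward_eliminate(X, y)
        dropped = [s.dropped for s in res.trace if s.dropped]
        assert len(res.trace[0].labels) == 4
        assert len(res.retained) == 4 - len(dropped)


class TestCorrelation:
    def test_identical_and_anti_ordered(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        assert pred_obs_correlation(v, v) == pytest.approx(1.0)
        assert pred_obs_correlation(v, -v) == pytest.approx(-1.0)

    def test_matches_covariance_definition_oracle(self, rng):
        a = rng.normal(size=30)
        b = 0.5 * a + rng.normal(size=30)
        num = np.mean((a - a.mean()) * (b - b.mean()))
        den = np.sqrt(np.mean((a - a.mean()) ** 2) * np.mean((b - b.mean()) ** 2))
        assert pred_obs_correlation(a, b) == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_and_length_errors(self):
        with pytest.raises(PLSError):
            pred_obs_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(PLSError):
            pred_obs_correlation([1.0, 2.0], [1.0, 2.0])
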