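"""Elastic-net paths, CV lambda rules, extraction policies and prediction links."""

import numpy as np
import pytest

from allsub import (
    extract_model,
    fit_cox_path,
    fit_logistic_path,
    predict_logistic,
    predict_risk,
)
from allsub.enet import FittedModel, RegularizationPath, breslow_loglik
from conftest import make_expr


def _toy_path(nnz_per_lambda, lambdas=None, family="logistic", lam_min=0.1, lam_1se=0.5):
    """Construct a synthetic path with the requested nonzero pattern per lambda."""
    lambdas = np.asarray(lambdas if lambdas is not None else
                         np.geomspace(1.0, 0.01, len(nnz_per_lambda)))
    p = max(max(nnz_per_lambda), 1)
    coefs = np.zeros((p, len(lambdas)))
    for j, k in enumerate(nnz_per_lambda):
        coefs[:k, j] = 1.0
    return RegularizationPath(
        model_family=family, alpha=0.8, gene_ids=[f"g{i}" for i in range(p)],
        lambdas=lambdas, coefficients=coefs,
        cv_mean=np.linspace(2.0, 1.0, len(lambdas)),
        cv_se=np.full(len(lambdas), 0.1),
        lambda_min=lam_min, lambda_1se=lam_1se,
        intercepts=np.zeros(len(lambdas)) if family == "logistic" else None,
    )


class TestLogisticPath:
    def test_separating_gene_selected_with_correct_sign(self, rng):
        n = 60
        x0 = np.concatenate([rng.normal(2, 0.3, n // 2), rng.normal(-2, 0.3, n // 2)])
        X = np.column_stack([x0, rng.normal(size=(n, 4))])
        y = np.concatenate([np.ones(n // 2), np.zeros(n // 2)])
        path = fit_logistic_path(X, y, n_lambda=30, seed=0)
        idx = path.index_of(path.lambdas[-1])
        assert path.coefficients[0, idx] > 0
        assert abs(path.coefficients[0, idx]) == np.abs(path.coefficients[:, idx]).max()

    def test_all_zero_at_lambda_max(self, rng):
        X = rng.normal(size=(50, 8))
        y = (X[:, 0] + rng.normal(size=50) > 0).astype(float)
        path = fit_logistic_path(X, y, n_lambda=25, seed=3)
        assert path.n_nonzero()[0] == 0
        # doubling lambda beyond the grid maximum also yields the null model
        path_hi = fit_logistic_path(X, y, lambdas=[2 * path.lambdas[0]], seed=3)
        assert path_hi.n_nonzero()[0] == 0

    def test_near_zero_lambda_matches_unpenalized_fit(self, rng):
        from sklearn.linear_model import LogisticRegression

        n, p = 400, 3
        X = rng.normal(size=(n, p))
        y = rng.binomial(1, 1 / (1 + np.exp(-(0.8 * X[:, 0] - 0.5 * X[:, 1]))))
        path = fit_logistic_path(X, y, lambdas=[1e-7], seed=0)
        ref = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=10000).fit(X, y)
        np.testing.assert_allclose(path.coefficients[:, 0], ref.coef_.ravel(), atol=1e-3)
        np.testing.assert_allclose(path.intercepts[0], ref.intercept_[0], atol=1e-3)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="both classes"):
            fit_logistic_path(X, np.ones(10))

    def test_cv_deterministic_given_seed(self, rng):
        X = rng.normal(size=(60, 6))
        y = (X[:, 0] + rng.normal(size=60) > 0).astype(float)
        p1 = fit_logistic_path(X, y, n_lambda=20, seed=5)
        p2 = fit_logistic_path(X, y, n_lambda=20, seed=5)
        assert p1.lambda_min == p2.lambda_min and p1.lambda_1se == p2.lambda_1se
        np.testing.assert_array_equal(p1.cv_mean, p2.cv_mean)

    def test_nonzero_count_grows_on_orthogonal_design(self, rng):
        # orthogonal predictors with staggered effect sizes enter one by one
        n = 64
        from scipy.linalg import hadamard

        Q = hadamard(n)[:, 1:5] / np.sqrt(n)
        beta = np.array([3.0, 2.0, 1.0, 0.5])
        y = (Q @ beta + 0.1 * rng.normal(size=n) > 0).astype(float)
        path = fit_logistic_path(Q, y, n_lambda=30, seed=0)
        nnz = path.n_nonzero()
        assert np.all(np.diff(nnz) >= 0)

    def test_lambda_1se_not_below_lambda_min(self, rng):
        X = rng.normal(size=(50, 10))
        y = (X[:, 0] - X[:, 1] + rng.normal(size=50) > 0).astype(float)
        path = fit_logistic_path(X, y, n_lambda=25, seed=2)
        assert path.lambda_1se >= path.lambda_min
        assert np.all(np.diff(path.lambdas) < 0)


class TestCoxPath:
    def test_monotone_hazard_gene_gets_positive_coefficient(self, rng):
        n = 50
        x = np.sort(rng.normal(size=n))  # high x -> short survival, all events
        time = 1000.0 * np.exp(-1.2 * x) * rng.gamma(20, 1 / 20, n)
        X = np.column_stack([x, rng.normal(size=n)])
        path = fit_cox_path(X, time, np.ones(n), n_lambda=25, seed=0)
        mid = len(path.lambdas) // 2
        assert path.coefficients[0, mid] > 0

    def test_all_zero_at_largest_lambda(self, rng):
        n = 60
        X = rng.normal(size=(n, 6))
        time = rng.exponential(100 * np.exp(-0.8 * X[:, 0]))
        event = (rng.random(n) < 0.7).astype(float)
        path = fit_cox_path(X, time, event, n_lambda=20, seed=1)
        assert path.n_nonzero()[0] == 0

    def test_near_zero_lambda_matches_lifelines(self, rng):
        from lifelines import CoxPHFitter
        import pandas as pd

        n, p = 300, 2
        X = rng.normal(size=(n, p))
        time = rng.exponential(100 * np.exp(-(0.7 * X[:, 0] - 0.4 * X[:, 1])))
        event = np.ones(n)
        path = fit_cox_path(X, time, event, lambdas=[1e-6], seed=0)
        df = pd.DataFrame(X, columns=["x0", "x1"])
        df["T"], df["E"] = time, event
        ref = CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(
            path.coefficients[:, 0], ref.params_[["x0", "x1"]].to_numpy(), atol=1e-3)

    def test_no_events_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="events"):
            fit_cox_path(X, np.arange(1.0, 11.0), np.zeros(10))

    def test_breslow_loglik_matches_lifelines(self, rng):
        from lifelines import CoxPHFitter
        import pandas as pd

        n = 40
        X = rng.normal(size=(n, 1))
        time = rng.exponential(50 * np.exp(-0.5 * X[:, 0]))
        event = (rng.random(n) < 0.8).astype(float)
        df = pd.DataFrame({"x": X[:, 0], "T": time, "E": event})
        ref = CoxPHFitter().fit(df, "T", "E")
        beta = float(ref.params_["x"])
        ours = breslow_loglik(beta * X[:, 0], time, event)
        assert ours == pytest.approx(float(ref.log_likelihood_), rel=1e-6)


class TestExtraction:
    def test_1se_model_returned_when_nondegenerate(self):
        path = _toy_path([0, 3, 5, 7], lambdas=[1.0, 0.5, 0.1, 0.01],
                         lam_min=0.1, lam_1se=0.5)
        m = extract_model(path, "1se_fallback_min")
        assert m.k == 3 and m.lambda_used == 0.5 and not m.degenerate

    def test_fallback_to_lambda_min_on_degenerate_1se(self):
        path = _toy_path([0, 0, 5, 7], lambdas=[1.0, 0.5, 0.1, 0.01],
                         lam_min=0.1, lam_1se=0.5)
        m = extract_model(path, "1se_fallback_min")
        assert m.k == 5 and m.lambda_used == 0.1

    def test_fully_degenerate_path_flagged(self):
        path = _toy_path([0, 0, 0, 0], lambdas=[1.0, 0.5, 0.1, 0.01],
                         lam_min=0.1, lam_1se=0.5)
        m = extract_model(path, "1se_fallback_min")
        assert m.degenerate and m.k == 0

    def test_simplest_nondegenerate_takes_largest_lambda_single_gene(self):
        path = _toy_path([0, 1, 2, 6], lambdas=[1.0, 0.5, 0.1, 0.01])
        m = extract_model(path, "simplest_nondegenerate")
        assert m.k == 1 and m.lambda_used == 0.5

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError, match="policy"):
            extract_model(_toy_path([0, 1]), "best_guess")


class TestPrediction:
    def test_null_logistic_model_gives_half(self):
        m = FittedModel("logistic", [], np.array([]), 0.1, 0, intercept=0.0)
        expr = make_expr(np.ones((3, 4)))
        np.testing.assert_allclose(predict_logistic(m, expr), 0.5)

    def test_logistic_link_saturates(self):
        m = FittedModel("logistic", ["g0"], np.array([1.0]), 0.1, 1, intercept=0.0)
        expr = make_expr(np.array([[0.0, 100.0]]))
        p = predict_logistic(m, expr)
        assert p[0] == pytest.approx(0.5) and p[1] > 0.999

    def test_logistic_hand_computed_two_genes(self):
        m = FittedModel("logistic", ["g0", "g1"], np.array([0.3, -0.2]), 0.1, 2,
                        intercept=0.5)
        expr = make_expr(np.array([[1.0, 2.0], [3.0, 4.0]]))
        lin = 0.5 + 0.3 * expr.values[0] - 0.2 * expr.values[1]
        np.testing.assert_allclose(
            predict_logistic(m, expr), 1 / (1 + np.exp(-lin)), atol=1e-12)

    def test_zero_cox_model_gives_zero_scores(self):
        m = FittedModel("cox", [], np.array([]), 0.1, 0)
        expr = make_expr(np.ones((2, 5)))
        np.testing.assert_array_equal(predict_risk(m, expr), np.zeros(5))

    def test_risk_linear_in_expression(self):
        m = FittedModel("cox", ["g0"], np.array([0.5]), 0.1, 1)
        e1 = make_expr(np.array([[2.0]]))
        e2 = make_expr(np.array([[4.0]]))
        assert predict_risk(m, e2)[0] == pytest.approx(2 * predict_risk(m, e1)[0])

    def test_hand_computed_dot_product(self):
        m = FittedModel("cox", ["g0", "g2"], np.array([0.5, -1.0]), 0.1, 2)
        expr = make_expr(np.array([[1.0, 2.0, 3.0], [9.0, 9.0, 9.0], [0.5, 1.0, 2.0]]))
        np.testing.assert_allclose(
            predict_risk(m, expr),
            0.5 * expr.values[0] - 1.0 * expr.values[2], atol=1e-12)

    def test_missing_gene_rejected(self):
        m = FittedModel("cox", ["absent"], np.array([1.0]), 0.1, 1)
        with pytest.raises(ValueError, match="missing"):
            predict_risk(m, make_expr(np.ones((2, 2))))

    def test_family_mismatch_rejected(self):
        m = FittedModel("cox", [], np.array([]), 0.1, 0)
        with pytest.raises(ValueError, match="logistic"):
            predict_logistic(m, make_expr(np.ones((1, 1))))
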