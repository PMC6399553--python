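"""Penalized-lasso solver: penalty factors, KKT, oracles, p_max, ROSE."""
import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression

from ssipre.model import (
    PenaltySpec,
    compute_penalty_factors,
    fit_lasso_path,
    lambda_max,
    predict_proba,
    rose_oversample,
    select_lambda_cv,
)


def simulate(n=200, p=20, seed=0, strong=(1.5, -1.0, 0.8)):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    beta = np.zeros(p)
    beta[: len(strong)] = strong
    y = (rng.random(n) < 1 / (1 + np.exp(-(X @ beta)))).astype(float)
    if len(np.unique(y)) < 2:  # pragma: no cover - not hit for these seeds
        raise RuntimeError("degenerate simulation")
    return X, y


def standardized(X):
    return (X - X.mean(0)) / X.std(0)


class TestPenaltyFactors:
    def test_most_expensive_test_gets_unit_penalty(self, catalog):
        pen = compute_penalty_factors(catalog, ["Leukocytes_mean_S", "age"])
        assert pen.v[0] == 1.0 and pen.v[1] == 1.0

    def test_glucose_ratio(self, catalog):
        pen = compute_penalty_factors(catalog, ["Glucose_mean_S"])
        assert pen.v[0] == pytest.approx(58 / 23)

    def test_all_prices_equal_gives_unit_factors(self, catalog):
        from ssipre.catalog import TestCatalogEntry

        flat = [
            TestCatalogEntry(e.test_name, 40.0, e.ref_low, e.ref_high, e.rate30)
            for e in catalog
        ]
        pen = compute_penalty_factors(flat, [f"{e.test_name}_mean_S" for e in flat])
        assert np.all(pen.v == 1.0)

    def test_unknown_feature_rejected(self, catalog):
        with pytest.raises(KeyError):
            compute_penalty_factors(catalog, ["Ferritin_mean_S"])


class TestLassoPath:
    def test_null_model_at_lambda_max(self):
        X, y = simulate()
        Xs = standardized(X)
        lmax = lambda_max(Xs, y, standardize=False)
        for lam in (lmax, 2 * lmax):
            path = fit_lasso_path(Xs, y, lambdas=np.array([lam]), standardize=False)
            assert path.nnz[0] == 0
            assert path.intercepts[0] == pytest.approx(np.log(y.mean() / (1 - y.mean())))

    def test_kkt_conditions_along_path(self):
        X, y = simulate()
        Xs = standardized(X)
        path = fit_lasso_path(Xs, y, standardize=False, n_lambdas=30, tol=1e-12)
        n = len(y)
        for il, lam in enumerate(path.lambdas):
            b0, b = path.intercepts[il], path.coefs[il]
            pr = 1 / (1 + np.exp(-(b0 + Xs @ b)))
            g = Xs.T @ (pr - y) / n
            zero = b == 0
            if zero.any():
                assert np.max(np.abs(g[zero])) <= lam + 1e-6
            if (~zero).any():
                assert np.max(np.abs(g[~zero] + lam * np.sign(b[~zero]))) <= 1e-6

    def test_penalty_rescaling_equivalence(self):
        """v-penalized fit == unit-penalty fit on columns x_j / v_j, beta / v_j."""
        X, y = simulate(seed=3)
        Xs = standardized(X)
        rng = np.random.default_rng(5)
        v = rng.uniform(0.5, 3.0, X.shape[1])
        pen = PenaltySpec(tuple(f"x{j}" for j in range(X.shape[1])), v)
        lmax = lambda_max(Xs, y, pen, standardize=False)
        lams = np.logspace(np.log10(lmax), np.log10(lmax * 1e-2), 20)
        a = fit_lasso_path(Xs, y, penalty=pen, lambdas=lams, standardize=False, tol=1e-12)
        b = fit_lasso_path(Xs / v[None, :], y, lambdas=lams, standardize=False, tol=1e-12)
        assert np.max(np.abs(a.coefs - b.coefs / v[None, :])) < 1e-6

    def test_matches_saga_oracle_at_fixed_lambda(self):
        X, y = simulate(seed=1)
        Xs = standardized(X)
        lmax = lambda_max(Xs, y, standardize=False)
        lam = lmax / 10
        path = fit_lasso_path(Xs, y, lambdas=np.array([lam]), standardize=False, tol=1e-12)
        n = len(y)
        sk = LogisticRegression(
            l1_ratio=1.0, C=1.0 / (n * lam), solver="saga", max_iter=100000, tol=1e-10
        ).fit(Xs, y)
        assert np.max(np.abs(path.coefs[0] - sk.coef_[0])) < 1e-4
        assert abs(path.intercepts[0] - sk.intercept_[0]) < 1e-4

    def test_small_lambda_matches_unpenalized_mle(self):
        X, y = simulate(n=400, p=5, seed=2, strong=(1.0, -0.5))
        lmax = lambda_max(X, y)
        lams = np.logspace(np.log10(lmax), np.log10(lmax * 1e-8), 40)
        path = fit_lasso_path(X, y, lambdas=lams, tol=1e-13)
        mle = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert np.max(np.abs(path.coefs[-1] - mle.params[1:])) < 1e-4
        assert abs(path.intercepts[-1] - mle.params[0]) < 1e-4

    def test_objective_not_worse_than_null(self):
        X, y = simulate(seed=4)
        path = fit_lasso_path(X, y, n_lambdas=20)
        Xs = (X - path.center) / path.scale
        b0_null = np.log(y.mean() / (1 - y.mean()))

        def objective(b0, b_std, lam):
            eta = b0 + Xs @ b_std
            nll = np.mean(np.log1p(np.exp(-np.abs(eta))) + np.maximum(eta, 0) - y * eta)
            return nll + lam * np.sum(np.abs(b_std))

        for il, lam in enumerate(path.lambdas):
            b_std = path.coefs[il] * path.scale
            assert objective(path.intercepts[il], b_std, lam) <= objective(
                b0_null, np.zeros_like(b_std), lam
            ) + 1e-12

    def test_price_monotonicity_under_vj_rmax_over_rj(self, catalog):
        """v_j = r_max / r_j falls as a test's price rises, so at fixed lambda
        raising the price weakly grows that test's coefficient."""
        X, y = simulate(n=300, p=2, seed=6, strong=(1.0, 1.0))
        names = ("Glucose_mean_S", "Leukocytes_mean_S")
        Xdf = pd.DataFrame(X, columns=names)
        lam = lambda_max(Xdf, y) / 5
        sizes = []
        for glucose_price in (23.0, 58.0):
            v = np.array([58.0 / glucose_price, 1.0])
            pen = PenaltySpec(names, v)
            path = fit_lasso_path(Xdf, y, penalty=pen, lambdas=np.array([lam]), tol=1e-12)
            sizes.append(abs(path.coefs[0, 0]))
        assert sizes[1] > sizes[0]

    def test_input_validation(self):
        X, y = simulate()
        with pytest.raises(ValueError, match="class"):
            fit_lasso_path(X, np.zeros(len(y)))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            fit_lasso_path(X, y)


class TestSelectLambdaCV:
    def test_pmax_inactive_when_large(self):
        X, y = simulate(seed=7)
        a = select_lambda_cv(X, y, folds=4, seed=1)
        b = select_lambda_cv(X, y, folds=4, p_max=X.shape[1], seed=1)
        assert a.lambda_sel == b.lambda_sel
        assert np.array_equal(a.beta, b.beta)

    def test_pmax_zero_gives_prevalence_model(self):
        X, y = simulate(seed=8)
        m = select_lambda_cv(X, y, folds=4, p_max=0, seed=1)
        assert len(m.nonzero) == 0
        assert predict_proba(m, X) == pytest.approx(np.full(len(y), y.mean()), abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_pmax_hard_guarantee_and_support_recovery(self, seed):
        X, y = simulate(n=1000, p=15, seed=seed, strong=(1.5, 1.2, -1.3))
        m = select_lambda_cv(X, y, folds=5, p_max=2, seed=seed)
        nz_idx = [int(n[1:]) for n in m.nonzero]
        assert len(nz_idx) <= 2
        assert set(nz_idx) <= {0, 1, 2}

    def test_deviance_criterion_runs(self):
        X, y = simulate(seed=9)
        m = select_lambda_cv(X, y, folds=3, criterion="deviance", seed=0)
        assert np.isfinite(m.cv_mean_score)

    def test_model_json_round_trip(self, tmp_path):
        from ssipre.model import FittedModel

        X, y = simulate(seed=10)
        m = select_lambda_cv(X, y, folds=3, p_max=5, seed=0)
        path = tmp_path / "model.json"
        m.to_json(path)
        back = FittedModel.from_json(path)
        assert back.feature_names == m.feature_names
        assert back.beta0 == m.beta0
        assert np.array_equal(back.beta, m.beta)
        assert back.p_max == 5


class TestRose:
    def test_exact_balance(self):
        X, y = simulate(seed=11)
        Xb, yb = rose_oversample(X, y, seed=0)
        assert (yb == 1).sum() == (yb == 0).sum()

    def test_zero_bandwidth_duplicates_rows(self):
        X, y = simulate(seed=12)
        Xb, yb = rose_oversample(X, y, seed=0, shrink=0.0)
        rows = {tuple(np.round(r, 12)) for r in np.asarray(Xb)}
        originals = {tuple(np.round(r, 12)) for r in X}
        assert rows <= originals

    def test_class_means_preserved(self):
        X, y = simulate(n=2000, p=4, seed=13, strong=(1.0,))
        Xb, yb = rose_oversample(X, y, seed=1)
        for cls in (0, 1):
            orig = X[y == cls].mean(0)
            boot = np.asarray(Xb)[yb == cls].mean(0)
            sem = X[y == cls].std(0) / np.sqrt((yb == cls).sum())
            assert np.all(np.abs(orig - boot) < 5 * sem)


class TestPredictProba:
    def test_all_half_for_null_model(self):
        from ssipre.model import FittedModel

        m = FittedModel(("a", "b"), 0.0, np.zeros(2), 0.1, PenaltySpec.unit(["a", "b"]))
        assert np.all(predict_proba(m, np.random.default_rng(0).normal(size=(5, 2))) == 0.5)

    def test_hand_computed_two_feature_toy(self):
        from ssipre.model import FittedModel

        m = FittedModel(("a", "b"), 0.5, np.array([1.0, -2.0]), 0.1, PenaltySpec.unit(["a", "b"]))
        x = np.array([[0.2, 0.3]])
        expected = 1 / (1 + np.exp(-(0.5 + 0.2 - 0.6)))
        assert predict_proba(m, x)[0] == pytest.approx(expected)

    def test_monotone_in_positive_coefficient(self):
        X, y = simulate(seed=14)
        m = select_lambda_cv(X, y, folds=3, seed=0)
        j = int(np.argmax(m.beta))
        assert m.beta[j] > 0
        x0 = X[:3].copy()
        x1 = x0.copy()
        x1[:, j] += 0.5
        assert np.all(predict_proba(m, x1) > predict_proba(m, x0))

    def test_column_name_check(self):
        X, y = simulate(seed=15)
        Xdf = pd.DataFrame(X, columns=[f"f{j}" for j in range(X.shape[1])])
        m = select_lambda_cv(Xdf, y, folds=3, seed=0)
        with pytest.raises(ValueError, match="missing feature columns"):
            predict_proba(m, Xdf.rename(columns={"f0": "g0"}))
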