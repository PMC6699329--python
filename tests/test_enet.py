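import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nirsparse.data import standardize_arrays
from nirsparse.enet import (
    ConvergenceError,
    ElasticNet,
    EnetSpec,
    enet_naive_solve,
    enet_objective,
    enet_path,
    enet_solve,
    lambda1_max,
    soft_threshold,
    ust_solution,
)
from nirsparse.metrics import grouping_bound


def brute_force_min(Xs, ys, lambda1, lambda2, radius=6.0, n_grid=61, zooms=3):
    """Independent oracle: refine a dense grid over the coefficient space."""
    p = Xs.shape[1]
    center = np.zeros(p)
    width = radius
    best_obj, best_b = np.inf, center
    for _ in range(zooms):
        axes = [np.linspace(c - width, c + width, n_grid) for c in center]
        mesh = np.meshgrid(*axes, indexing="ij")
        B = np.stack([m.ravel() for m in mesh], axis=1)
        resid = ys[None, :] - B @ Xs.T
        obj = (
            (resid**2).sum(axis=1)
            + lambda2 * (B**2).sum(axis=1)
            + lambda1 * np.abs(B).sum(axis=1)
        )
        i = int(np.argmin(obj))
        best_obj, best_b = float(obj[i]), B[i]
        center = B[i]
        width = 2 * width / (n_grid - 1) * 2  # shrink around the best point
    return best_obj, best_b


def random_standardized(rng, n, p):
    X = rng.standard_normal((n, p))
    y = rng.standard_normal(n)
    Xs, ys, _ = standardize_arrays(X, y)
    return Xs, ys


@pytest.mark.parametrize(
    "z,t,expected", [(5.0, 2.0, 3.0), (-5.0, 2.0, -3.0), (1.0, 2.0, 0.0), (0.0, 0.0, 0.0)]
)
def test_soft_threshold_values(z, t, expected):
    assert soft_threshold(z, t) == expected


def test_soft_threshold_rejects_negative_threshold():
    with pytest.raises(ValueError):
        soft_threshold(1.0, -0.1)


@given(st.floats(-100, 100), st.floats(0, 100))
def test_soft_threshold_is_a_shrinkage(z, t):
    out = soft_threshold(z, t)
    assert abs(out) <= abs(z) + 1e-12
    assert out * z >= 0


class TestNaiveSolver:
    def test_unpenalized_limit_is_ols(self, rng):
        Xs, ys = random_standardized(rng, 30, 5)
        beta = enet_naive_solve(Xs, ys, 0.0, 0.0)
        ols = np.linalg.lstsq(Xs, ys, rcond=None)[0]
        np.testing.assert_allclose(beta, ols, atol=1e-7)

    def test_large_lambda1_gives_zero(self, rng):
        Xs, ys = random_standardized(rng, 20, 4)
        beta = enet_naive_solve(Xs, ys, 1.01 * lambda1_max(Xs, ys), 0.0)
        assert np.all(beta == 0.0)

    def test_matches_brute_force_on_correlated_pair(self, rng):
        base = rng.standard_normal(25)
        X = np.column_stack([base + 0.3 * rng.standard_normal(25), base])
        y = base + 0.5 * rng.standard_normal(25)
        Xs, ys, _ = standardize_arrays(X, y)
        beta = enet_naive_solve(Xs, ys, 0.7, 0.3)
        obj = enet_objective(Xs, ys, beta, 0.7, 0.3)
        oracle_obj, _ = brute_force_min(Xs, ys, 0.7, 0.3)
        assert obj <= oracle_obj + 1e-6

    def test_oracle_equivalence_random_instances(self, rng):
        """Solver objective never exceeds the grid-refined oracle minimum."""
        for trial in range(12):
            p = 1 + trial % 3
            Xs, ys = random_standardized(rng, 12 + trial, p)
            l1 = float(rng.uniform(0.0, 1.0))
            l2 = float(rng.uniform(0.0, 2.0))
            if p >= Xs.shape[0] and l1 == l2 == 0:
                continue
            beta = enet_naive_solve(Xs, ys, l1, l2)
            obj = enet_objective(Xs, ys, beta, l1, l2)
            oracle_obj, _ = brute_force_min(Xs, ys, l1, l2, radius=4.0, n_grid=41)
            assert obj <= oracle_obj + 1e-6

    def test_rejects_doubly_unpenalized_underdetermined(self, rng):
        Xs, ys = random_standardized(rng, 5, 8)
        with pytest.raises(ValueError, match="both"):
            enet_naive_solve(Xs, ys, 0.0, 0.0)

    def test_matches_sklearn_lasso_and_enet(self, rng):
        sklearn_linear = pytest.importorskip("sklearn.linear_model")
        Xs, ys = random_standardized(rng, 40, 8)
        n = 40
        lam1 = 0.8
        lasso = sklearn_linear.Lasso(
            alpha=lam1 / (2 * n), fit_intercept=False, tol=1e-12, max_iter=10**6
        ).fit(Xs, ys)
        np.testing.assert_allclose(
            enet_naive_solve(Xs, ys, lam1, 0.0), lasso.coef_, atol=1e-7
        )
        # general elastic net: lambda1 = 2 n alpha rho, lambda2 = n alpha (1 - rho)
        alpha, l1r = 0.01, 0.6
        sk = sklearn_linear.ElasticNet(
            alpha=alpha, l1_ratio=l1r, fit_intercept=False, tol=1e-12, max_iter=10**6
        ).fit(Xs, ys)
        ours = enet_naive_solve(Xs, ys, 2 * n * alpha * l1r, n * alpha * (1 - l1r))
        np.testing.assert_allclose(ours, sk.coef_, atol=1e-7)


class TestCorrectedEstimate:
    def test_correction_factor_and_active_set(self, rng):
        Xs, ys = random_standardized(rng, 30, 6)
        naive = enet_naive_solve(Xs, ys, 0.5, 2.0)
        fit = enet_solve(Xs, ys, EnetSpec(lambda2=2.0, lambda1=0.5))
        np.testing.assert_allclose(fit.coef.beta, 3.0 * naive, atol=1e-12)
        assert np.array_equal(fit.coef.active_set, np.flatnonzero(naive))

    def test_lambda2_zero_is_lasso(self, rng):
        Xs, ys = random_standardized(rng, 30, 6)
        fit = enet_solve(Xs, ys, EnetSpec(lambda2=0.0, lambda1=0.6))
        np.testing.assert_allclose(
            fit.coef.beta, enet_naive_solve(Xs, ys, 0.6, 0.0), atol=1e-12
        )

    def test_zero_naive_gives_zero_corrected(self, rng):
        Xs, ys = random_standardized(rng, 20, 4)
        fit = enet_solve(
            Xs, ys, EnetSpec(lambda2=5.0, lambda1=1.1 * lambda1_max(Xs, ys))
        )
        assert np.all(fit.coef.beta == 0.0)

    def test_ust_limit_monotone_in_lambda2(self, rng):
        Xs, ys = random_standardized(rng, 30, 6)
        lam1 = 0.4
        u = ust_solution(Xs, ys, lam1)
        scale = np.max(np.abs(u))
        rel = []
        for l2 in (1e2, 1e4, 1e6):
            fit = enet_solve(Xs, ys, EnetSpec(lambda2=l2, lambda1=lam1))
            rel.append(np.max(np.abs(fit.coef.beta - u)) / scale)
        assert rel[0] > rel[1] > rel[2]
        assert rel[2] <= 1e-3


class TestUST:
    def test_plugin_value(self, rng):
        # orthonormal zero-mean design with y' x1 = 0.8
        A = rng.standard_normal((20, 3))
        A -= A.mean(axis=0)
        Q, _ = np.linalg.qr(A)
        ys = 0.8 * Q[:, 0] + 0.3 * Q[:, 1]
        u = ust_solution(Q, ys, 0.4)
        assert u[0] == pytest.approx(0.8 - 0.2, abs=1e-8)

    def test_zero_penalty_returns_covariances(self, rng):
        Xs, ys = random_standardized(rng, 25, 5)
        np.testing.assert_allclose(ust_solution(Xs, ys, 0.0), Xs.T @ ys)

    def test_huge_penalty_returns_zero(self, rng):
        Xs, ys = random_standardized(rng, 25, 5)
        assert np.all(ust_solution(Xs, ys, 1.1 * lambda1_max(Xs, ys)) == 0.0)


class TestGroupingEffect:
    def test_duplicated_predictors_get_identical_coefficients(self, rng):
        base = rng.standard_normal(30)
        X = np.column_stack([base, base, rng.standard_normal(30)])
        y = 2 * base + 0.3 * rng.standard_normal(30)
        Xs, ys, _ = standardize_arrays(X, y)
        for l2 in (0.1, 1.0, 10.0):
            fit = enet_solve(Xs, ys, EnetSpec(lambda2=l2, lambda1=0.2))
            assert fit.coef.beta[0] == pytest.approx(fit.coef.beta[1], abs=1e-6)

    def test_coefficient_gap_bounded_for_correlated_pair(self, rng):
        for trial in range(10):
            base = rng.standard_normal(40)
            X = np.column_stack(
                [base + 0.05 * rng.standard_normal(40), base + 0.05 * rng.standard_normal(40)]
            )
            y = base + 0.2 * rng.standard_normal(40)
            Xs, ys, _ = standardize_arrays(X, y)
            rho = float(Xs[:, 0] @ Xs[:, 1])
            l2 = 0.5
            fit = enet_solve(Xs, ys, EnetSpec(lambda2=l2, lambda1=0.1))
            b = fit.coef.beta
            if b[0] * b[1] > 0:
                assert abs(b[0] - b[1]) <= grouping_bound(ys, l2, rho) + 1e-9


class TestPath:
    def test_endpoints(self, rng):
        Xs, ys = random_standardized(rng, 30, 5)
        fits = enet_path(Xs, ys, 0.5, [0.0, 1.0])
        assert np.all(fits[0].coef.beta == 0.0)
        terminal = enet_naive_solve(Xs, ys, 0.0, 0.5)
        np.testing.assert_allclose(fits[1].beta_naive, terminal, atol=1e-6)

    def test_midpoint_norm_fraction(self, rng):
        Xs, ys = random_standardized(rng, 20, 3)
        fits = enet_path(Xs, ys, 0.2, [0.5, 1.0], refine=True)
        target = 0.5 * np.abs(fits[1].beta_naive).sum()
        assert np.abs(fits[0].beta_naive).sum() == pytest.approx(target, abs=1e-6)

    def test_sparsity_monotone_in_s(self, rng):
        Xs, ys = random_standardized(rng, 40, 8)
        fits = enet_path(Xs, ys, 1.0, np.linspace(0, 1, 21), refine=False)
        nnz = [f.coef.n_selected for f in fits]
        assert all(a <= b for a, b in zip(nnz, nnz[1:]))

    def test_rejects_bad_grid(self, rng):
        Xs, ys = random_standardized(rng, 20, 3)
        with pytest.raises(ValueError):
            enet_path(Xs, ys, 0.0, [0.5, 0.2])
        with pytest.raises(ValueError):
            enet_path(Xs, ys, 0.0, [-0.1])


class TestSpecAndModel:
    def test_spec_validation(self):
        with pytest.raises(ValueError):
            EnetSpec(lambda2=-1.0, s=0.5)
        with pytest.raises(ValueError):
            EnetSpec(s=0.5, lambda1=1.0)
        with pytest.raises(ValueError):
            EnetSpec(s=1.5)
        with pytest.raises(ValueError):
            EnetSpec(lambda1=None, s=None)

    def test_model_predict_and_summary(self, rng):
        X = rng.standard_normal((30, 4)) + 5.0
        y = X[:, 0] * 2.0 + rng.standard_normal(30)
        res = ElasticNet(y, X).fit(lambda2=0.0, s=0.6)
        # prediction path equivalence with the standardized-scale fit
        model = res.model
        manual = model.Xs @ res.coef.beta + model.state.y_mean
        np.testing.assert_allclose(res.predict(X), manual, atol=1e-8)
        text = res.summary()
        assert "Elastic Net" in text and "Selected" in text
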