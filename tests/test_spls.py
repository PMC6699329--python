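import numpy as np
import pytest

from nirsparse._kernels import pls1_beta
from nirsparse.data import CoefficientVector, standardize_arrays
from nirsparse.spls import (
    PLS1,
    SPLS,
    SPLSSpec,
    pls1_nipals,
    predict,
    spls_direction,
    spls_fit,
)


def standardized(rng, n, p, signal_cols=None, noise=0.3):
    X = rng.standard_normal((n, p))
    if signal_cols is None:
        y = rng.standard_normal(n)
    else:
        y = X[:, signal_cols].sum(axis=1) + noise * rng.standard_normal(n)
    return standardize_arrays(X, y)


class TestPLS1:
    def test_single_predictor_is_simple_least_squares(self, rng):
        Xs, ys, _ = standardized(rng, 20, 1, signal_cols=[0])
        model = pls1_nipals(Xs, ys, 1)
        slope = float(Xs[:, 0] @ ys) / float(Xs[:, 0] @ Xs[:, 0])
        np.testing.assert_allclose(model.coef.beta, [slope], atol=1e-10)

    def test_full_rank_K_recovers_ols(self, rng):
        Xs, ys, _ = standardized(rng, 30, 5, signal_cols=[0, 1])
        model = pls1_nipals(Xs, ys, 5)
        ols = np.linalg.lstsq(Xs, ys, rcond=None)[0]
        np.testing.assert_allclose(model.coef.beta, ols, atol=1e-8)

    def test_orthonormal_design_first_weight(self, rng):
        Q, _ = np.linalg.qr(rng.standard_normal((25, 4)))
        Q -= Q.mean(axis=0)
        Q /= np.linalg.norm(Q, axis=0)
        ys = 2.0 * Q[:, 2] + 0.5 * Q[:, 0]
        model = pls1_nipals(Q, ys, 1)
        expected = Q.T @ ys
        expected /= np.linalg.norm(expected)
        np.testing.assert_allclose(np.abs(model.weights[:, 0]), np.abs(expected), atol=1e-10)

    def test_scores_orthogonal_and_residual_orthogonal(self, rng):
        Xs, ys, _ = standardized(rng, 40, 8, signal_cols=[0, 3])
        model = pls1_nipals(Xs, ys, 4)
        gram = model.scores.T @ model.scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8
        resid = ys - model.fitted(Xs)
        assert np.abs(model.scores.T @ resid).max() < 1e-8

    def test_early_stop_when_response_explained(self, rng):
        Xs, ys0, _ = standardized(rng, 20, 3)
        ys = Xs @ np.array([1.0, 0.0, 0.0])  # exactly rank-limited signal
        model = pls1_nipals(Xs, ys, 3)
        assert model.early_stop or model.K == 3
        np.testing.assert_allclose(model.fitted(Xs), ys, atol=1e-8)

    def test_invalid_K(self, rng):
        Xs, ys, _ = standardized(rng, 10, 3)
        with pytest.raises(ValueError):
            pls1_nipals(Xs, ys, 0)
        with pytest.raises(ValueError):
            pls1_nipals(Xs, ys, 4)

    def test_kernel_matches_reference_implementation(self, rng):
        Xs, ys, _ = standardized(rng, 30, 6, signal_cols=[0, 1])
        for K in (1, 3, 6):
            beta, used = pls1_beta(Xs, ys, K, 1e-12)
            ref = pls1_nipals(Xs, ys, K)
            assert used == ref.K
            np.testing.assert_allclose(beta, ref.coef.beta, atol=1e-10)


class TestSPLSDirection:
    def test_plugin_example(self):
        w = spls_direction(np.array([3.0, 1.0, -1.0]), 0.5)
        np.testing.assert_allclose(w, [1.0, 0.0, 0.0])

    def test_eta_zero_keeps_support(self, rng):
        z = rng.standard_normal(6)
        w = spls_direction(z, 0.0)
        assert np.all(w != 0)
        assert np.linalg.norm(w) == pytest.approx(1.0)

    def test_near_one_keeps_only_argmax(self):
        z = np.array([0.5, -2.0, 1.9])
        w = spls_direction(z, 0.99)
        assert np.flatnonzero(w).tolist() == [1]
        assert w[1] > 0  # sign convention: dominant entry positive

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            spls_direction(np.zeros(3), 0.5)
        with pytest.raises(ValueError):
            spls_direction(np.ones(3), 1.0)


class TestSPLSFit:
    def test_eta_zero_reproduces_pls1(self, rng):
        Xs, ys, _ = standardized(rng, 30, 6, signal_cols=[0, 1])
        for K in (1, 2, 4):
            sf = spls_fit(Xs, ys, SPLSSpec(eta=0.0, K=K))
            pm = pls1_nipals(Xs, ys, K)
            assert sf.active_set.size == 6
            np.testing.assert_allclose(Xs @ sf.coef.beta, Xs @ pm.coef.beta, atol=1e-10)

    def test_single_relevant_orthogonal_predictor(self, rng):
        Q, _ = np.linalg.qr(rng.standard_normal((25, 5)))
        Q -= Q.mean(axis=0)
        Q /= np.linalg.norm(Q, axis=0)
        ys = 3.0 * Q[:, 1] + 0.05 * Q[:, 4]
        sf = spls_fit(Q, ys, SPLSSpec(eta=0.9, K=1))
        assert sf.active_set.tolist() == [1]
        slope = float(Q[:, 1] @ ys)
        assert sf.coef.beta[1] == pytest.approx(slope, abs=1e-8)

    def test_correlated_block_selected_together(self, rng):
        """A tight group of correlated drivers enters the support whole."""
        for trial in range(5):
            v = rng.standard_normal(60)
            block = v[:, None] + 0.15 * rng.standard_normal((60, 4))  # rho ~ 0.98
            noise = rng.standard_normal((60, 6))
            X = np.column_stack([block, noise])
            y = v + 0.3 * rng.standard_normal(60)
            Xs, ys, _ = standardize_arrays(X, y)
            for eta in (0.2, 0.5):
                sf = spls_fit(Xs, ys, SPLSSpec(eta=eta, K=1))
                inside = np.isin(np.arange(4), sf.active_set)
                assert inside.all() or not inside.any()
                assert inside.all()  # the block drives y, so it must be in

    def test_coef_supported_on_active_set(self, rng):
        Xs, ys, _ = standardized(rng, 40, 10, signal_cols=[0, 1, 2])
        sf = spls_fit(Xs, ys, SPLSSpec(eta=0.6, K=3))
        outside = np.setdiff1d(np.arange(10), sf.active_set)
        assert np.all(sf.coef.beta[outside] == 0.0)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            SPLSSpec(eta=1.0, K=2)
        with pytest.raises(ValueError):
            SPLSSpec(eta=0.5, K=0)
        with pytest.raises(ValueError):
            SPLSSpec(eta=0.5, K=2, kappa=0.7)


class TestPredict:
    def test_training_fitted_values_for_ols_equivalent_fit(self, rng):
        Xs, ys, state = standardized(rng, 30, 4, signal_cols=[0])
        model = pls1_nipals(Xs, ys, 4)
        np.testing.assert_allclose(predict(model, Xs), Xs @ model.coef.beta)

    def test_zero_fit_predicts_training_mean(self, rng):
        X = rng.standard_normal((20, 3)) + 2.0
        y = rng.standard_normal(20) + 7.0
        Xs, ys, state = standardize_arrays(X, y)

        class Zero:
            coef = CoefficientVector(beta=np.zeros(3))

        np.testing.assert_allclose(predict(Zero(), X, state), np.full(20, y.mean()))

    def test_matches_manual_matrix_product(self, rng):
        X = rng.standard_normal((15, 4)) + 1.0
        y = rng.standard_normal(15)
        Xs, ys, state = standardize_arrays(X, y)
        sf = spls_fit(Xs, ys, SPLSSpec(eta=0.3, K=2))
        Xnew = rng.standard_normal((5, 4))
        manual = state.transform(Xnew) @ sf.coef.beta + state.y_mean
        np.testing.assert_allclose(predict(sf, Xnew, state), manual, atol=1e-10)

    def test_dimension_mismatch(self, rng):
        Xs, ys, state = standardized(rng, 15, 4)
        sf = spls_fit(Xs, ys, SPLSSpec(eta=0.3, K=1))
        with pytest.raises(ValueError):
            predict(sf, np.zeros((3, 5)), state)


def test_model_front_end_agrees_with_functions(rng):
    X = rng.standard_normal((40, 6)) + 3.0
    y = X[:, 0] + 0.5 * X[:, 1] + 0.2 * rng.standard_normal(40)
    res = SPLS(y, X).fit(eta=0.4, K=2)
    Xs, ys, state = standardize_arrays(X, y)
    ref = spls_fit(Xs, ys, SPLSSpec(eta=0.4, K=2))
    np.testing.assert_allclose(res.predict(X), predict(ref, X, state), atol=1e-10)
    assert "Sparse PLS" in res.summary()
    res_pls = PLS1(y, X).fit(K=3)
    assert "PLS1" in res_pls.summary()
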