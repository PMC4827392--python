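"""Latent cross-covariance model: oracle equivalence, algebraic contracts,
parameter recovery and the PCR comparator."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nonlocalpls import center_dataset, sample_cohort
from nonlocalpls.dataset_io import MultimodalDataset
from nonlocalpls.plsr import (
    deflate,
    fit_pcr,
    fit_pls,
    leading_covariance_pair,
    load_model,
    predict,
    project,
    regression_operator,
    save_model,
)

from conftest import noiseless_spec
from oracles import dense_svd_pls, nipals_pls2


def make_dataset(X, Y):
    """Wrap raw matrices in a dataset with a trivially flat 1-D 'grid'."""
    k, n = X.shape
    mask = np.ones((n,), bool)
    if Y.shape[1] != n:
        # pad the mask geometry to the larger block; only used for X geometry
        mask = np.ones((max(n, Y.shape[1]),), bool)
        X = np.pad(X, ((0, 0), (0, mask.size - n)))
        Y = np.pad(Y, ((0, 0), (0, mask.size - Y.shape[1])))
    return MultimodalDataset(
        X, Y, [f"s{i}" for i in range(k)], np.array(["A"] * k), mask, mask.shape
    )


class TestLeadingCovariancePair:
    def test_identical_blocks_reduce_to_pca(self, rng):
        Xc = rng.normal(size=(8, 15))
        Xc -= Xc.mean(axis=0)
        w, c, t, u = leading_covariance_pair(Xc, Xc)
        assert abs(w @ c) == pytest.approx(1.0, abs=1e-8)
        _, _, Vt = np.linalg.svd(Xc)
        assert abs(w @ Vt[0]) == pytest.approx(1.0, abs=1e-8)

    def test_rank_one_factor_model_recovered(self, rng):
        w0 = rng.normal(size=20)
        w0 /= np.linalg.norm(w0)
        c0 = rng.normal(size=30)
        c0 /= np.linalg.norm(c0)
        t0 = rng.normal(size=10)
        w, c, t, u = leading_covariance_pair(np.outer(t0, w0), np.outer(t0, c0))
        assert abs(w @ w0) == pytest.approx(1.0, abs=1e-8)
        assert abs(c @ c0) == pytest.approx(1.0, abs=1e-8)

    def test_matches_dense_svd_oracle(self, rng):
        Xc = rng.normal(size=(6, 20))
        Yc = rng.normal(size=(6, 25))
        Xc -= Xc.mean(axis=0)
        Yc -= Yc.mean(axis=0)
        w, c, t, u = leading_covariance_pair(Xc, Yc)
        U, _, Vt = np.linalg.svd(Xc.T @ Yc)
        assert abs(w @ U[:, 0]) == pytest.approx(1.0, abs=1e-8)
        assert abs(c @ Vt[0]) == pytest.approx(1.0, abs=1e-8)

    def test_scores_are_projections(self, rng):
        Xc = rng.normal(size=(7, 12))
        Yc = rng.normal(size=(7, 9))
        w, c, t, u = leading_covariance_pair(Xc, Yc)
        np.testing.assert_allclose(t, Xc @ w, atol=1e-10)
        np.testing.assert_allclose(u, Yc @ c, atol=1e-10)

    def test_sign_convention(self, rng):
        Xc = rng.normal(size=(6, 10))
        Yc = rng.normal(size=(6, 11))
        w, _, _, _ = leading_covariance_pair(Xc, Yc)
        assert w[np.argmax(np.abs(w))] > 0

    def test_zero_input_rejected(self):
        with pytest.raises(ValueError):
            leading_covariance_pair(np.zeros((4, 5)), np.zeros((4, 6)))


class TestDeflation:
    def test_rank_one_block_fully_deflated(self, rng):
        t0 = rng.normal(size=8)
        w0 = rng.normal(size=12)
        Xc = np.outer(t0, w0 / np.linalg.norm(w0))
        Yc = rng.normal(size=(8, 9))
        w, c, t, u = leading_covariance_pair(Xc, Yc)
        Xd, Yd, p, q = deflate(Xc, Yc, t, w, c)
        np.testing.assert_allclose(Xd, 0.0, atol=1e-10)

    def test_deflated_blocks_orthogonal_to_score(self, rng):
        Xc = rng.normal(size=(9, 14))
        Yc = rng.normal(size=(9, 17))
        w, c, t, u = leading_covariance_pair(Xc, Yc)
        Xd, Yd, _, _ = deflate(Xc, Yc, t, w, c)
        np.testing.assert_allclose(t @ Xd, 0.0, atol=1e-8)
        np.testing.assert_allclose(t @ Yd, 0.0, atol=1e-8)

    def test_successive_scores_orthogonal_and_match_nipals(self, rng):
        X = rng.normal(size=(10, 16))
        Y = rng.normal(size=(10, 13))
        X -= X.mean(axis=0)
        Y -= Y.mean(axis=0)
        model = fit_pls(center_dataset(make_dataset(X + 0.0, Y + 0.0)), 3)
        assert abs(model.T[:, 0] @ model.T[:, 1]) < 1e-8
        ref = nipals_pls2(X, Y, 3)
        for i in range(3):
            cos = abs(model.T[:, i] @ ref["T"][:, i]) / (
                np.linalg.norm(model.T[:, i]) * np.linalg.norm(ref["T"][:, i])
            )
            assert cos == pytest.approx(1.0, abs=1e-6)

    def test_zero_score_rejected(self, rng):
        Xc = rng.normal(size=(5, 6))
        with pytest.raises(ValueError):
            deflate(Xc, Xc, np.zeros(5), None, None)


class TestFitPls:
    def test_m1_equals_single_pair(self, rng):
        X = rng.normal(size=(8, 10))
        Y = rng.normal(size=(8, 12))
        ds = center_dataset(make_dataset(X, Y))
        model = fit_pls(ds, 1)
        w, c, t, u = leading_covariance_pair(ds.X, ds.Y)
        np.testing.assert_allclose(model.W[: 10 + 2, 0], w[: 10 + 2], atol=1e-10)
        np.testing.assert_allclose(model.T[:, 0], t, atol=1e-10)

    def test_noiseless_phantom_reconstructed(self, tiny_spec):
        dataset, _ = sample_cohort(noiseless_spec(tiny_spec))
        ds = center_dataset(dataset)
        model = fit_pls(ds, tiny_spec.n_components)
        Y_hat = predict(model, dataset.X)
        rel = np.linalg.norm(Y_hat - dataset.Y) / np.linalg.norm(dataset.Y)
        assert rel < 1e-6

    def test_matches_reference_nipals_predictions(self, rng):
        X = rng.normal(size=(20, 30))
        Y = rng.normal(size=(20, 30))
        ds = center_dataset(make_dataset(X, Y))
        for m in (1, 3, 5):
            model = fit_pls(ds, m)
            ours = predict(model, X)
            ref = nipals_pls2(ds.X, ds.Y, m)["Y_hat_train"] + ds.y_mean
            rel = np.linalg.norm(ours - ref) / np.linalg.norm(ref)
            assert rel < 1e-6

    def test_matches_sklearn_cross_check(self, rng):
        # structured data keeps the cross-covariance spectrum well separated
        # so sklearn's iterative solver converges to the same factors
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(15, 20))
        Y = rng.normal(size=(15, 18)) + 2.0 * X[:, :18] + X[:, 1:19]
        ds = center_dataset(make_dataset(X.copy(), Y.copy()))
        model = fit_pls(ds, 4)
        ours = predict(model, ds.X + ds.x_mean)
        ref = sklearn.PLSRegression(
            n_components=4, scale=False, tol=1e-12, max_iter=10_000
        ).fit(X, np.pad(Y, ((0, 0), (0, 2)))).predict(X)
        # sklearn's power iteration stops on a weight-change criterion and
        # keeps ~1e-5 residual error; algorithmic disagreement would be O(1)
        np.testing.assert_allclose(ours, ref, atol=1e-4)

    def test_m_out_of_range_rejected(self, rng):
        ds = center_dataset(make_dataset(rng.normal(size=(5, 8)), rng.normal(size=(5, 8))))
        with pytest.raises(ValueError):
            fit_pls(ds, 5)

    def test_uncentered_dataset_rejected(self, rng):
        ds = make_dataset(rng.normal(size=(5, 8)), rng.normal(size=(5, 8)))
        with pytest.raises(ValueError, match="centered"):
            fit_pls(ds, 2)

    def test_degenerate_residual_truncates_with_warning(self, rng):
        t0 = rng.normal(size=6)
        w0 = rng.normal(size=8)
        c0 = rng.normal(size=8)
        ds = center_dataset(make_dataset(np.outer(t0, w0), np.outer(t0, c0)))
        with pytest.warns(UserWarning, match="components"):
            model = fit_pls(ds, 4)
        assert model.m < 4

    def test_weight_columns_unit_norm(self, default_fit):
        _, _, model = default_fit
        np.testing.assert_allclose(np.linalg.norm(model.W, axis=0), 1.0, atol=1e-10)
        np.testing.assert_allclose(np.linalg.norm(model.C, axis=0), 1.0, atol=1e-10)

    def test_score_cross_covariances_non_increasing(self, rng):
        X = rng.normal(size=(12, 25))
        Y = rng.normal(size=(12, 22))
        model = fit_pls(center_dataset(make_dataset(X, Y)), 5)
        covs = [model.T[:, i] @ model.U[:, i] for i in range(5)]
        assert all(covs[i] >= covs[i + 1] - 1e-9 for i in range(4))


class TestRegressionOperator:
    def test_training_scores_reproduced(self, rng):
        X = rng.normal(size=(9, 14))
        Y = rng.normal(size=(9, 11))
        ds = center_dataset(make_dataset(X, Y))
        model = fit_pls(ds, 3)
        scores = project(model, ds.X + ds.x_mean)
        np.testing.assert_allclose(scores, model.T, atol=1e-8)

    def test_factored_equals_dense_coefficient(self, rng):
        X = rng.normal(size=(10, 12))
        Y = rng.normal(size=(10, 12))
        ds = center_dataset(make_dataset(X, Y))
        model = fit_pls(ds, 4)
        dense_B = model.W @ np.linalg.inv(model.P.T @ model.W) @ np.diag(model.b) @ model.C.T
        X_new = rng.normal(size=(5, 12))
        ours = predict(model, X_new)
        explicit = (X_new - ds.x_mean) @ dense_B + ds.y_mean
        np.testing.assert_allclose(ours, explicit, atol=1e-9)

    def test_full_rank_noiseless_interpolates(self, rng):
        # K-1 components on exact factor data of rank K-1
        K = 7
        L = rng.normal(size=(K, K - 1))
        Wt = rng.normal(size=(K - 1, 10))
        Ct = rng.normal(size=(K - 1, 12))
        ds = center_dataset(make_dataset(L @ Wt, L @ Ct))
        model = fit_pls(ds, K - 1)
        resid = predict(model, ds.X + ds.x_mean) - (ds.Y + ds.y_mean)
        assert np.linalg.norm(resid) / np.linalg.norm(ds.Y + ds.y_mean) < 1e-8


class TestPredictProject:
    def test_mean_image_maps_to_mean_target(self, rng):
        X = rng.normal(size=(8, 10)) + 2.0
        Y = rng.normal(size=(8, 10)) - 1.0
        ds = center_dataset(make_dataset(X, Y))
        model = fit_pls(ds, 2)
        np.testing.assert_allclose(predict(model, ds.x_mean), ds.y_mean[None], atol=1e-10)

    @given(a=st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
    @settings(deadline=None, derandomize=True, max_examples=20)
    def test_prediction_is_affine(self, a):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 10))
        Y = rng.normal(size=(8, 10))
        ds = center_dataset(make_dataset(X, Y))
        model = fit_pls(ds, 2)
        x1, x2 = rng.normal(size=(2, 10))
        lhs = predict(model, a * x1 + (1 - a) * x2)
        rhs = a * predict(model, x1) + (1 - a) * predict(model, x2)
        np.testing.assert_allclose(lhs, rhs, atol=1e-8)

    def test_zero_image_projects_negative_mean(self, rng):
        X = rng.normal(size=(8, 10)) + 5.0
        Y = rng.normal(size=(8, 10))
        ds = center_dataset(make_dataset(X, Y))
        model = fit_pls(ds, 2)
        zero_scores = project(model, np.zeros(10))
        ref = project(model, ds.x_mean) - (ds.x_mean @ (
            model.W @ np.linalg.inv(model.P.T @ model.W)))
        np.testing.assert_allclose(zero_scores[0], ref[0], atol=1e-8)
        assert np.linalg.norm(zero_scores) > 0

    def test_column_mismatch_rejected(self, rng):
        ds = center_dataset(make_dataset(rng.normal(size=(6, 8)), rng.normal(size=(6, 8))))
        model = fit_pls(ds, 2)
        with pytest.raises(ValueError, match="voxels"):
            predict(model, np.zeros(9))

    def test_phantom_scores_track_true_loadings(self, default_fit):
        dataset, truth, model = default_fit
        scores = project(model, dataset.X)
        # each planted loading should be tracked by some estimated score
        for j in range(truth.loadings.shape[1]):
            r = max(
                abs(np.corrcoef(truth.loadings[:, j], scores[:, i])[0, 1])
                for i in range(model.m)
            )
            assert r > 0.9


class TestPCR:
    def test_full_rank_equals_ols(self, rng):
        X = rng.normal(size=(10, 6))
        Y = rng.normal(size=(10, 6))
        ds = center_dataset(make_dataset(X, Y))
        pcr = fit_pcr(ds, 6)
        ours = pcr.predict(ds.X + ds.x_mean)
        beta, *_ = np.linalg.lstsq(ds.X, ds.Y, rcond=None)
        ols = ds.X @ beta + ds.y_mean
        np.testing.assert_allclose(ours, ols, atol=1e-8)

    def test_first_axis_is_leading_eigenvector(self, rng):
        X = rng.normal(size=(9, 7))
        Y = rng.normal(size=(9, 7))
        ds = center_dataset(make_dataset(X, Y))
        pcr = fit_pcr(ds, 1)
        evals, evecs = np.linalg.eigh(ds.X.T @ ds.X)
        assert abs(pcr.components[0] @ evecs[:, -1]) == pytest.approx(1.0, abs=1e-8)

    def test_distractor_hurts_pcr_not_pls(self, rng):
        # X carries a high-variance component that is uncorrelated with Y
        # enough training subjects that the weight's finite-sample leak onto
        # the distractor (scale/sqrt(n)) stays well below the signal
        n_train, n_test, nv = 200, 40, 30
        sig_x = np.zeros(nv); sig_x[:5] = 1.0; sig_x /= np.linalg.norm(sig_x)
        dis_x = np.zeros(nv); dis_x[10:20] = 1.0; dis_x /= np.linalg.norm(dis_x)
        sig_y = np.zeros(nv); sig_y[20:] = 1.0; sig_y /= np.linalg.norm(sig_y)
        def draw(n):
            s = rng.normal(size=n)
            d = rng.normal(scale=5.0, size=n)
            X = np.outer(s, sig_x) + np.outer(d, dis_x) + rng.normal(scale=0.05, size=(n, nv))
            Y = np.outer(s, sig_y) + rng.normal(scale=0.05, size=(n, nv))
            return X, Y
        Xtr, Ytr = draw(n_train)
        Xte, Yte = draw(n_test)
        ds = center_dataset(make_dataset(Xtr, Ytr))
        pls_err = np.linalg.norm(predict(fit_pls(ds, 1), Xte) - Yte)
        pcr_err = np.linalg.norm(fit_pcr(ds, 1).predict(Xte) - Yte)
        assert pls_err < pcr_err

    def test_m_exceeding_rank_rejected(self, rng):
        X = rng.normal(size=(4, 10))
        ds = center_dataset(make_dataset(X, X.copy()))
        with pytest.raises(ValueError):
            fit_pcr(ds, 5)


def test_model_roundtrip(tmp_path, rng):
    X = rng.normal(size=(8, 10))
    Y = rng.normal(size=(8, 12))
    ds = center_dataset(make_dataset(X, Y))
    model = fit_pls(ds, 3)
    save_model(model, tmp_path / "model.npz")
    loaded = load_model(tmp_path / "model.npz")
    np.testing.assert_array_equal(loaded.W, model.W)
    np.testing.assert_array_equal(loaded.b, model.b)
    X_new = rng.normal(size=(3, model.W.shape[0]))
    np.testing.assert_allclose(predict(loaded, X_new), predict(model, X_new))
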