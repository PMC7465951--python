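"""PCA/PLS1/PLS-DA engines against independent oracles and identities."""

import numpy as np
import pytest

from milknir import (ConfigurationError, DegenerateDataError, classify,
                     classification_metrics, fit_pca, fit_pls1, fit_plsda,
                     flag_outliers, leverage, load_model, predict, save_model)
from milknir.multivariate import scores


def eigen_pls1(X, y, n_lv):
    """Independent PLS1 oracle: weights from the dominant eigenvector of
    X'yy'X (equivalently the normalised covariance vector), explicit
    deflation, coefficients assembled from scratch."""
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    W, P, Q, T = [], [], [], []
    Xd = Xc.copy()
    for _ in range(n_lv):
        M = Xd.T @ np.outer(yc, yc) @ Xd
        vals, vecs = np.linalg.eigh(M)
        w = vecs[:, -1]
        if w @ (Xd.T @ yc) < 0:
            w = -w
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        q = yc @ t / (t @ t)
        W.append(w); P.append(p); Q.append(q); T.append(t)
        Xd = Xd - np.outer(t, p)
    W, P, Q = np.array(W).T, np.array(P).T, np.array(Q)
    return W @ np.linalg.solve(P.T @ W, Q)


class TestPCA:
    def test_rank_one_matrix_explains_everything(self, rng):
        X = np.outer(rng.normal(size=7), rng.normal(size=5))
        model = fit_pca(X, 1)
        assert model.explained_variance_pct[0] == pytest.approx(100.0)

    def test_orthogonal_design_variance_split(self):
        # two orthogonal directions with variances 4 and 1 -> 80% / 20%
        n = 200
        t = np.linspace(-1, 1, n)
        u1 = t / t.std()
        u2 = np.cos(np.pi * 7 * t)
        u2 = (u2 - u2.mean()) / u2.std()
        X = np.outer(2.0 * u1, [1, 0, 0]) + np.outer(1.0 * u2, [0, 1, 0])
        model = fit_pca(X, 2)
        assert model.explained_variance_pct[0] == pytest.approx(80.0, abs=1.0)
        assert model.explained_variance_pct[1] == pytest.approx(20.0, abs=1.0)

    def test_matches_svd_oracle_up_to_sign(self, rng):
        X = rng.normal(size=(8, 6))
        model = fit_pca(X, 3)
        u, s, vt = np.linalg.svd(X - X.mean(axis=0), full_matrices=False)
        for k in range(3):
            dot = abs(model.loadings[:, k] @ vt[k])
            assert dot == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(np.abs(model.scores),
                                   np.abs(u[:, :3] * s[:3]), atol=1e-10)

    def test_reconstruction_within_discarded_residual(self, rng):
        X = rng.normal(size=(10, 6))
        model = fit_pca(X, 4)
        recon = model.scores @ model.loadings.T + model.mean
        _, s, _ = np.linalg.svd(X - X.mean(axis=0), full_matrices=False)
        residual = np.sqrt(np.sum(s[4:] ** 2))
        assert np.linalg.norm(X - recon) == pytest.approx(residual, rel=1e-8)

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            fit_pca(rng.normal(size=(4, 6)), 4)


class TestPLS1:
    def test_single_direction_noise_free(self, rng):
        direction = rng.normal(size=9)
        t = rng.normal(size=12)
        X = np.outer(t, direction)
        y = 2.0 + 3.0 * t
        model = fit_pls1(X, y, 1)
        assert np.sqrt(np.mean((predict(model, X) - y) ** 2)) < 1e-10

    def test_full_rank_equals_ols(self, rng):
        X = rng.normal(size=(12, 5))
        y = rng.normal(size=12)
        model = fit_pls1(X, y, 5)
        Xd = np.column_stack([np.ones(12), X])
        beta = np.linalg.lstsq(Xd, y, rcond=None)[0]
        np.testing.assert_allclose(predict(model, X), Xd @ beta, atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_eigen_oracle(self, seed):
        r = np.random.default_rng(seed)
        X = r.normal(size=(10, 8))
        y = r.normal(size=10)
        model = fit_pls1(X, y, 3)
        np.testing.assert_allclose(model.b, eigen_pls1(X, y, 3), atol=1e-8)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_sklearn(self, seed):
        from sklearn.cross_decomposition import PLSRegression
        r = np.random.default_rng(100 + seed)
        X = r.normal(size=(11, 7))
        y = r.normal(size=11)
        model = fit_pls1(X, y, 3)
        sk = PLSRegression(n_components=3, scale=False).fit(X, y)
        np.testing.assert_allclose(model.b, sk.coef_.ravel(), atol=1e-8)

    def test_scores_orthogonal(self, rng):
        X = rng.normal(size=(15, 10))
        y = rng.normal(size=15)
        T = fit_pls1(X, y, 5).T
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        norms = np.sqrt(np.diag(G))
        assert np.max(np.abs(off) / np.outer(norms, norms)) < 1e-8

    def test_training_rmse_non_increasing_in_lv(self, rng):
        X = rng.normal(size=(14, 9))
        y = rng.normal(size=14)
        model = fit_pls1(X, y, 6)
        rmses = [np.sqrt(np.mean((predict(model, X, n_lv=k) - y) ** 2))
                 for k in range(1, 7)]
        assert all(a >= b - 1e-12 for a, b in zip(rmses, rmses[1:]))

    def test_y_variance_explained_cumulative(self, rng):
        X = rng.normal(size=(12, 8))
        y = rng.normal(size=12)
        ve = fit_pls1(X, y, 4).y_variance_explained_pct
        assert (ve >= -1e-12).all()
        assert ve.sum() <= 100.0 + 1e-9

    def test_prediction_shift_invariance(self, rng):
        X = rng.normal(size=(10, 6))
        y = rng.normal(size=10)
        base = predict(fit_pls1(X, y, 3), X)
        shifted = predict(fit_pls1(X, y + 7.5, 3), X)
        np.testing.assert_allclose(shifted, base + 7.5, atol=1e-9)

    def test_mean_spectrum_predicts_mean_y(self, rng):
        X = rng.normal(size=(10, 6))
        y = rng.normal(size=10)
        model = fit_pls1(X, y, 2)
        assert predict(model, X.mean(axis=0))[0] == pytest.approx(y.mean())

    def test_degenerate_inputs_rejected(self, rng):
        X = rng.normal(size=(8, 5))
        with pytest.raises(DegenerateDataError):
            fit_pls1(X, np.ones(8), 2)
        with pytest.raises(ConfigurationError):
            fit_pls1(X, rng.normal(size=8), 8)

    def test_save_load_round_trip(self, rng, tmp_path):
        X = rng.normal(size=(9, 6))
        y = rng.normal(size=9)
        model = fit_pls1(X, y, 2)
        save_model(model, tmp_path / "m")
        back = load_model(tmp_path / "m")
        np.testing.assert_allclose(predict(back, X), predict(model, X),
                                   atol=1e-10)


class TestLeverage:
    def test_training_mean_has_zero_leverage(self, rng):
        X = rng.normal(size=(12, 7))
        model = fit_pls1(X, rng.normal(size=12), 3)
        h = leverage(model, X.mean(axis=0))
        assert h[0] == pytest.approx(0.0, abs=1e-12)

    def test_leverage_sum_is_n_lv(self, rng):
        X = rng.normal(size=(12, 7))
        model = fit_pls1(X, rng.normal(size=12), 3)
        assert leverage(model).sum() == pytest.approx(3.0, abs=1e-9)
        assert leverage(model).mean() == pytest.approx(3 / 12, abs=1e-10)

    def test_extreme_sample_has_max_leverage(self, rng):
        X = rng.normal(size=(12, 7))
        model = fit_pls1(X, rng.normal(size=12), 3)
        extreme = X.mean(axis=0) + 10 * (X[0] - X.mean(axis=0))
        assert leverage(model, extreme)[0] > leverage(model).max()

    def test_training_scores_reproduced(self, rng):
        X = rng.normal(size=(10, 6))
        model = fit_pls1(X, rng.normal(size=10), 3)
        np.testing.assert_allclose(scores(model, X), model.T, atol=1e-9)


class TestPLSDA:
    def separable_data(self, rng, n=20):
        X = rng.normal(size=(n, 6))
        labels = np.array(["neg"] * (n // 2) + ["pos"] * (n - n // 2))
        X[labels == "pos", 0] += 10.0
        return X, labels

    def test_separable_classes_perfect_metrics(self, rng):
        X, labels = self.separable_data(rng)
        model = fit_plsda(X, labels, 2)
        metrics = classification_metrics(labels, classify(model, X),
                                         model.classes)
        assert (metrics["sensitivity"] == 1.0).all()
        assert (metrics["specificity"] == 1.0).all()

    def test_degenerate_confusion(self):
        metrics = classification_metrics(
            ["a", "a", "b", "b"], ["b", "b", "b", "b"], ("a", "b"))
        row_a = metrics.set_index("class").loc["a"]
        assert row_a["sensitivity"] == 0.0
        row_b = metrics.set_index("class").loc["b"]
        assert row_b["sensitivity"] == 1.0
        assert row_b["specificity"] == 0.0

    def test_plsda_b_equals_pls1_on_dummy(self, rng):
        X, labels = self.separable_data(rng)
        model = fit_plsda(X, labels, 2)
        dummy = (labels == "pos").astype(float)
        np.testing.assert_allclose(model.pls.b, fit_pls1(X, dummy, 2).b,
                                   atol=1e-12)

    def test_random_labels_near_chance(self):
        r = np.random.default_rng(42)
        X = r.normal(size=(400, 5))
        labels = np.where(r.uniform(size=400) < 0.5, "a", "b")
        model = fit_plsda(X[:200], labels[:200], 2)
        metrics = classification_metrics(labels[200:],
                                         classify(model, X[200:]),
                                         model.classes)
        assert metrics["sensitivity"].mean() == pytest.approx(0.5, abs=0.12)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            fit_plsda(rng.normal(size=(6, 4)), ["a"] * 6, 1)


def test_outlier_flags_planted_sample(rng):
    X = rng.normal(size=(20, 8))
    direction = rng.normal(size=8)
    y = X @ direction * 0.1 + rng.normal(size=20) * 0.01
    y[3] += 5.0                      # gross y outlier
    model = fit_pls1(X, y, 3)
    flags = flag_outliers(model, X, y)
    assert flags.loc[3, "flagged"]
    assert flags["flagged"].sum() <= 4   # no mass flagging
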