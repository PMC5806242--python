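"""NIPALS PCA and OPLS-DA against independent oracles, plus the structural
invariants of the decomposition."""
import numpy as np
import pytest

import chemopls as cp


def eig_pca_oracle(X, a):
    """PCA via eigendecomposition of the covariance-like cross-product."""
    _u, s, vt = np.linalg.svd(X, full_matrices=False)
    P = vt[:a].T
    T = X @ P
    evr = (s[:a] ** 2) / (s**2).sum()
    return T, P, evr


def pls1_oracle(X, y, a):
    """Independent NIPALS PLS1: returns in-sample fitted centred response."""
    Xd, yd = X.copy(), y.copy()
    yhat = np.zeros(len(y))
    for _ in range(a):
        w = Xd.T @ yd
        w = w / np.linalg.norm(w)
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        c = yd @ t / (t @ t)
        yhat += c * t
        Xd = Xd - np.outer(t, p)
        yd = yd - c * t
    return yhat


def centred(rng, n, m):
    X = rng.standard_normal((n, m))
    return X - X.mean(axis=0)


class TestPca:
    def test_rank_one_matrix_first_component_explains_all(self):
        t = np.array([1.0, -2.0, 3.0, 0.5, -2.5])
        p = np.array([0.5, 1.0, -2.0])
        X = np.outer(t - t.mean(), p)
        model = cp.fit_pca(X, 1)
        assert model.explained_variance_ratio[0] >= 0.999999

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_eigendecomposition_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = centred(rng, 10, 6)
        model = cp.fit_pca(X, 4)
        T, P, evr = eig_pca_oracle(X, 4)
        for a in range(4):
            sign = np.sign(P[:, a] @ model.loadings[:, a])
            np.testing.assert_allclose(model.loadings[:, a], sign * P[:, a],
                                       atol=1e-8)
            np.testing.assert_allclose(model.scores[:, a], sign * T[:, a],
                                       atol=1e-8)
        np.testing.assert_allclose(model.explained_variance_ratio, evr, atol=1e-10)

    def test_scores_centred_and_orthogonal_loadings_orthonormal(self):
        rng = np.random.default_rng(3)
        X = centred(rng, 12, 7)
        m = cp.fit_pca(X, 4)
        np.testing.assert_allclose(m.scores.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(m.loadings.T @ m.loadings, np.eye(4), atol=1e-8)
        G = m.scores.T @ m.scores
        np.testing.assert_allclose(G - np.diag(np.diag(G)), 0, atol=1e-6)

    def test_explained_variance_non_increasing(self):
        rng = np.random.default_rng(4)
        m = cp.fit_pca(centred(rng, 15, 9), 5)
        assert np.all(np.diff(m.explained_variance_ratio) <= 1e-12)

    def test_beyond_rank_warns(self):
        rng = np.random.default_rng(5)
        X = centred(rng, 8, 5)
        X[:, 3] = X[:, 0]
        X[:, 4] = X[:, 1]
        with pytest.warns(UserWarning):
            m = cp.fit_pca(X - X.mean(axis=0), 5)
        assert m.explained_variance_ratio[-1] < 1e-10

    def test_hotelling_t2_flags_gross_outlier(self):
        rng = np.random.default_rng(6)
        X = centred(rng, 30, 5)
        X[0] += 25.0
        m = cp.fit_pca(X - X.mean(axis=0), 2)
        assert m.hotelling_t2[0] > m.t2_limit_95
        assert (m.hotelling_t2 > m.t2_limit_95).mean() < 0.2


class TestOplsda:
    labels8 = ["a"] * 4 + ["b"] * 4

    def test_pure_class_structure_gives_r2y_one(self):
        classes, Y = cp.encode_classes(self.labels8)
        yc = (Y - Y.mean(axis=0))[:, 0]
        X = np.outer(yc, np.array([0.3, -1.0, 2.0]))
        m = cp.fit_oplsda(X, self.labels8, n_pred=1, n_ortho=0)
        assert m.r2y > 1 - 1e-10
        E = X - m.T @ m.P.T
        assert np.linalg.norm(E) <= 1e-10

    @pytest.mark.parametrize("seed", range(4))
    @pytest.mark.parametrize("k", [0, 1, 2, 3])
    def test_single_y_equivalence_with_pls1_oracle(self, seed, k):
        """Fitted responses of OPLS(1 predictive, k orthogonal) equal a
        (k+1)-component PLS1 fit."""
        rng = np.random.default_rng(seed)
        X = centred(rng, 8, 5)
        m = cp.fit_oplsda(X, self.labels8, n_pred=1, n_ortho=k)
        _classes, Y = cp.encode_classes(self.labels8)
        yc = (Y - Y.mean(axis=0))[:, 0]
        np.testing.assert_allclose(m.fitted_y()[:, 0] - m.y_mean[0],
                                   pls1_oracle(X, yc, k + 1), atol=1e-8)

    @pytest.mark.parametrize("n_ortho", [1, 2, 3])
    def test_score_and_weight_orthogonality(self, n_ortho):
        rng = np.random.default_rng(10 + n_ortho)
        X = centred(rng, 14, 9)
        m = cp.fit_oplsda(X, ["a"] * 7 + ["b"] * 7, n_pred=1, n_ortho=n_ortho)
        for a in range(m.n_pred):
            for b in range(m.n_ortho):
                t, t_o = m.T[:, a], m.T_o[:, b]
                assert abs(t @ t_o) <= 1e-8 * np.linalg.norm(t) * np.linalg.norm(t_o)
                assert abs(m.W[:, a] @ m.W_o[:, b]) <= 1e-8

    @pytest.mark.parametrize("n_ortho", [0, 1, 2])
    def test_decomposition_identity(self, n_ortho):
        rng = np.random.default_rng(20 + n_ortho)
        X = centred(rng, 12, 8)
        m = cp.fit_oplsda(X, ["a"] * 6 + ["b"] * 6, n_pred=1, n_ortho=n_ortho)
        recon = m.T @ m.P.T + m.T_o @ m.P_o.T
        E = X - recon
        # E is the model residual; the identity X = TP' + T_oP_o' + E is exact
        X2 = recon + E
        assert np.linalg.norm(X - X2) <= 1e-8 * np.linalg.norm(X)
        assert np.linalg.norm(E) < np.linalg.norm(X)

    def test_unit_norm_weights(self):
        rng = np.random.default_rng(30)
        X = centred(rng, 10, 6)
        m = cp.fit_oplsda(X, ["a"] * 5 + ["b"] * 5, n_pred=1, n_ortho=2)
        np.testing.assert_allclose(np.linalg.norm(m.W, axis=0), 1.0, rtol=1e-12)
        np.testing.assert_allclose(np.linalg.norm(m.W_o, axis=0), 1.0, rtol=1e-12)
        np.testing.assert_allclose(np.linalg.norm(m.w_star, axis=0), 1.0, rtol=1e-12)

    def test_class_coding_invariance(self):
        """Renaming classes so the dummy coding flips sign leaves |w*| and the
        fit unchanged and flips score signs."""
        rng = np.random.default_rng(31)
        X = centred(rng, 12, 6)
        la = ["a"] * 6 + ["b"] * 6
        lb = ["b"] * 6 + ["a"] * 6  # swaps which class is coded 1
        ma = cp.fit_oplsda(X, la, n_pred=1, n_ortho=1)
        mb = cp.fit_oplsda(X, lb, n_pred=1, n_ortho=1)
        np.testing.assert_allclose(ma.T, -mb.T, atol=1e-10)
        np.testing.assert_allclose(np.abs(ma.w_star), np.abs(mb.w_star), atol=1e-10)
        assert abs(ma.r2y - mb.r2y) <= 1e-10

    def test_small_class_rejected(self):
        with pytest.raises(cp.DataError):
            cp.fit_oplsda(np.eye(3), ["a", "a", "b"], n_pred=1)

    def test_too_many_orthogonal_components_degenerate(self):
        classes, Y = cp.encode_classes(self.labels8)
        yc = (Y - Y.mean(axis=0))[:, 0]
        X = np.outer(yc, np.array([1.0, 2.0]))  # rank 1, class-only
        with pytest.raises(cp.DegenerateComponentError):
            cp.fit_oplsda(X, self.labels8, n_pred=1, n_ortho=1)

    def test_multiclass_fit_and_dims(self):
        rng = np.random.default_rng(33)
        labels = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        X = centred(rng, 15, 10)
        X[5:10] += 1.5
        X[10:] -= 1.5
        X -= X.mean(axis=0)
        m = cp.fit_oplsda(X, labels, n_pred=2, n_ortho=1)
        assert m.T.shape == (15, 2)
        assert m.C.shape == (2, 2)
        assert m.classes == ["a", "b", "c"]


class TestPredict:
    def _fit(self, seed=40, n=12, m=6, n_ortho=1):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, m))
        X -= X.mean(axis=0)
        labels = ["a"] * (n // 2) + ["b"] * (n - n // 2)
        return X, labels, cp.fit_oplsda(X, labels, n_pred=1, n_ortho=n_ortho)

    def test_training_projection_self_consistent(self):
        X, labels, m = self._fit()
        t_pred, t_ortho, yhat, calls = cp.predict(m, X)
        np.testing.assert_allclose(t_pred, m.T, atol=1e-10)
        np.testing.assert_allclose(t_ortho, m.T_o, atol=1e-10)
        np.testing.assert_allclose(yhat, m.fitted_y(), atol=1e-10)

    def test_duplicated_sample_identical_scores(self):
        X, labels, m = self._fit()
        t1, _, y1, _ = cp.predict(m, X[[3]])
        t2, _, y2, _ = cp.predict(m, np.vstack([X[[3]], X[[3]]]))
        np.testing.assert_array_equal(t2[0], t2[1])
        np.testing.assert_allclose(t2[0], t1[0])

    def test_permutation_equivariance(self):
        """Permuting metabolite columns of training and new data consistently
        leaves scores unchanged."""
        rng = np.random.default_rng(41)
        X, labels, m = self._fit(seed=41)
        perm = rng.permutation(X.shape[1])
        m_perm = cp.fit_oplsda(X[:, perm], labels, n_pred=1, n_ortho=1)
        Xnew = rng.standard_normal((4, X.shape[1]))
        t_a, _, _, _ = cp.predict(m, Xnew)
        t_b, _, _, _ = cp.predict(m_perm, Xnew[:, perm])
        np.testing.assert_allclose(np.abs(t_a), np.abs(t_b), atol=1e-8)

    def test_class_calls_separate_training_classes(self):
        rng = np.random.default_rng(42)
        X = rng.standard_normal((16, 5))
        X[:8] += 4.0
        X -= X.mean(axis=0)
        labels = ["a"] * 8 + ["b"] * 8
        m = cp.fit_oplsda(X, labels, n_pred=1, n_ortho=0)
        _, _, _, calls = cp.predict(m, X)
        assert calls == labels

    def test_column_mismatch_rejected(self):
        X, labels, m = self._fit()
        with pytest.raises(cp.UsageError):
            cp.predict(m, X[:, :3])
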