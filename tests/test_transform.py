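"""Kernel transform machinery: scaling, bandwidth, kernel, eigen steps,
sparsity scoring, and the SSKECA / KECA / KPCA / PCA fit-transform contract."""

import numpy as np
import pytest

from sskeca.transform import (
    DegenerateKernelError,
    EigenSystem,
    KECA,
    KPCA,
    PCATransform,
    SSKECA,
    adaptive_bandwidth,
    baseline_transform,
    center_kernel_apply,
    center_kernel_fit,
    make_transform,
    rbf_kernel,
    select_components,
    sparsity_scores,
    stable_eig,
    zscore_fit,
)


class TestZscore:
    def test_two_point_column(self):
        Xn, params = zscore_fit(np.array([[0.0], [2.0]]))
        assert np.allclose(Xn.ravel(), [-1.0, 1.0])  # population-sd convention

    def test_idempotent(self, rng):
        X = rng.normal(size=(40, 5))
        Xn, _ = zscore_fit(X)
        Xn2, _ = zscore_fit(Xn)
        assert np.allclose(Xn, Xn2, atol=1e-12)

    def test_random_matrix_standardized(self, rng):
        Xn, _ = zscore_fit(rng.normal(2, 3, size=(50, 24)))
        assert np.abs(Xn.mean(axis=0)).max() < 1e-9
        assert np.abs(Xn.std(axis=0) - 1).max() < 1e-9

    def test_constant_column_named(self, rng):
        X = rng.normal(size=(20, 4))
        X[:, 2] = 7.0
        with pytest.raises(ValueError, match=r"\[2\]"):
            zscore_fit(X)


class TestBandwidth:
    def test_formula(self, rng):
        Xn, _ = zscore_fit(rng.normal(size=(30, 24)))
        spec = adaptive_bandwidth(Xn, w=1.0)
        assert spec.bw == pytest.approx(spec.sigma1 / 24)
        assert adaptive_bandwidth(Xn, w=2.0).bw == pytest.approx(2 * spec.bw)

    def test_override_short_circuits(self, rng):
        Xn, _ = zscore_fit(rng.normal(size=(10, 3)))
        assert adaptive_bandwidth(Xn, override=3.948).bw == 3.948

    def test_homogeneity(self, rng):
        Xn, _ = zscore_fit(rng.normal(size=(25, 6)))
        c = 3.7
        assert adaptive_bandwidth(c * Xn).bw == pytest.approx(c * adaptive_bandwidth(Xn).bw)

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            adaptive_bandwidth(np.zeros((5, 3)))


class TestKernel:
    def test_self_similarity_and_closed_form(self):
        x = np.array([[1.0, 2.0]])
        assert rbf_kernel(x, x, 1.0)[0, 0] == 1.0
        bw = 0.7
        y = x + np.array([[bw * np.sqrt(2), 0]])  # squared distance = 2 bw^2
        assert rbf_kernel(x, y, bw)[0, 0] == pytest.approx(np.exp(-1))

    def test_against_bruteforce_loop(self, rng):
        A, B = rng.normal(size=(10, 3)), rng.normal(size=(7, 3))
        K = rbf_kernel(A, B, 1.3)
        for i in range(10):
            for j in range(7):
                expected = np.exp(-np.sum((A[i] - B[j]) ** 2) / (2 * 1.3**2))
                assert K[i, j] == pytest.approx(expected, abs=1e-12)

    def test_properties(self, rng):
        X = rng.normal(size=(20, 4))
        K = rbf_kernel(X, X, 2.0)
        assert np.allclose(K, K.T)
        assert np.allclose(np.diag(K), 1.0)
        assert (K > 0).all() and (K <= 1).all()
        assert np.linalg.eigvalsh(K).min() > -1e-10  # PSD

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            rbf_kernel(np.ones((2, 3)), np.ones((2, 4)), 1.0)


class TestCentering:
    def test_one_by_one(self):
        Kc, _ = center_kernel_fit(np.array([[1.0]]))
        assert Kc[0, 0] == 0.0

    def test_zero_row_col_sums(self, rng):
        X = rng.normal(size=(15, 3))
        Kc, _ = center_kernel_fit(rbf_kernel(X, X, 1.0))
        assert np.abs(Kc.sum(axis=0)).max() < 1e-8
        assert np.abs(Kc.sum(axis=1)).max() < 1e-8

    def test_matches_explicit_H_K_H(self, rng):
        K = rng.normal(size=(8, 8))
        K = K + K.T
        Kc, _ = center_kernel_fit(K)
        H = np.eye(8) - np.ones((8, 8)) / 8
        assert np.allclose(Kc, H @ K @ H, atol=1e-12)

    def test_apply_consistent_with_fit(self, rng):
        X = rng.normal(size=(12, 3))
        K = rbf_kernel(X, X, 1.0)
        Kc, cen = center_kernel_fit(K)
        assert np.allclose(center_kernel_apply(K, cen), Kc, atol=1e-12)


class TestStableEig:
    def test_zero_kernel_degenerate(self):
        with pytest.raises(DegenerateKernelError):
            stable_eig(np.zeros((4, 4)))

    def test_trace_identity(self, rng):
        X = rng.normal(size=(10, 3))
        Kc, _ = center_kernel_fit(rbf_kernel(X, X, 1.0))
        full = np.linalg.eigvalsh(0.5 * (Kc + Kc.T))
        assert full.sum() == pytest.approx(np.trace(Kc), abs=1e-10)

    def test_psd_reconstruction(self, rng):
        A = rng.normal(size=(6, 6))
        Kc = A @ A.T  # PSD
        eig = stable_eig(Kc)
        rec = eig.vectors @ np.diag(eig.values) @ eig.vectors.T
        assert np.allclose(rec, Kc, atol=1e-10)

    def test_descending_and_orthonormal(self, rng):
        X = rng.normal(size=(12, 4))
        Kc, _ = center_kernel_fit(rbf_kernel(X, X, 1.5))
        eig = stable_eig(Kc)
        assert (np.diff(eig.values) <= 1e-12).all()
        gram = eig.vectors.T @ eig.vectors
        assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8)


def toy_eigensystem(rng, n=4):
    """Eigensystem of a small uncentered PSD kernel (alignment with 1 nonzero)."""
    X = rng.normal(size=(n, 2))
    return stable_eig(rbf_kernel(X, X, 1.0) + 1e-6 * np.eye(n))


class TestSparsityScores:
    def test_beta_zero_is_entropy_only(self, rng):
        eig = toy_eigensystem(rng)
        s = sparsity_scores(eig, beta=0.0)
        assert np.allclose(s.scores, s.entropy)

    def test_orthogonal_eigenvector_zero_contribution(self):
        # 2-point symmetric kernel: contrast eigenvector is orthogonal to 1
        K = np.array([[1.0, 0.4], [0.4, 1.0]])
        eig = stable_eig(K)
        s = sparsity_scores(eig, beta=0.0)
        contrast = np.argmin(np.abs(eig.vectors.sum(axis=0)))
        assert s.entropy[contrast] == pytest.approx(0.0, abs=1e-12)

    def test_brute_force_formula_oracle(self, rng):
        eig = toy_eigensystem(rng, n=4)
        beta = 0.37
        s = sparsity_scores(eig, beta=beta)
        for i in range(eig.values.size):
            alpha = eig.vectors[:, i]
            e = alpha / np.linalg.norm(alpha)
            if e.sum() < 0:
                e = -e
            G = eig.values[i] * e.sum()
            expected = G - beta * np.abs(alpha).sum()
            assert s.scores[i] == pytest.approx(expected, abs=1e-12)

    def test_custom_alignment_vector(self, rng):
        eig = toy_eigensystem(rng, n=5)
        v = rng.normal(size=5)
        s = sparsity_scores(eig, beta=0.0, align=v)
        for i in range(eig.values.size):
            assert s.entropy[i] == pytest.approx(
                eig.values[i] * abs(eig.vectors[:, i] @ v), abs=1e-12
            )

    def test_negative_beta_rejected(self, rng):
        with pytest.raises(ValueError):
            sparsity_scores(toy_eigensystem(rng), beta=-0.1)


class TestSelection:
    def _scores(self, values):
        n = len(values)
        eig = EigenSystem(np.linspace(2, 1, n), np.eye(n), 0)
        s = sparsity_scores(eig, beta=0.0)
        return type(s)(s.entropy, s.l1_norms, 0.0, np.asarray(values, float), s.sign_flip)

    def test_topk(self):
        assert select_components(self._scores([3, 1, 2]), 2).tolist() == [0, 2]

    def test_tie_prefers_smaller_eigenrank(self):
        assert select_components(self._scores([2, 2, 1]), 1).tolist() == [0]

    def test_matches_full_sort_oracle(self, rng):
        for _ in range(20):
            vals = rng.normal(size=12)
            k = int(rng.integers(1, 12))
            got = set(select_components(self._scores(vals), k).tolist())
            expected = set(np.argsort(-vals, kind="stable")[:k].tolist())
            assert got == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            select_components(self._scores([1, 2]), 3)


class TestSSKECA:
    def test_full_retention_gram_identity(self, rng):
        X = rng.normal(size=(30, 5))
        model = SSKECA(ncomp=None, ridge=0.0).fit(X)
        Z = model.training_projection_
        Kc = model._Kc
        err = np.linalg.norm(Z @ Z.T - Kc) / np.linalg.norm(Kc)
        assert err < 1e-6

    def test_output_dimensionality(self, small_table):
        from sskeca.features import FEATURE_NAMES

        X = small_table[FEATURE_NAMES].to_numpy(float)
        Z = SSKECA(ncomp=21).fit_transform(X)
        assert Z.shape == (len(X), 21)

    def test_two_point_toy(self):
        Z = SSKECA(ncomp=1).fit_transform(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert Z.shape == (2, 1)
        assert Z.mean(axis=0) == pytest.approx(0.0, abs=1e-9)  # centering consequence

    def test_transform_columns_zero_mean(self, rng):
        Z = SSKECA(ncomp=5).fit_transform(rng.normal(size=(40, 6)))
        assert np.abs(Z.mean(axis=0)).max() < 1e-8

    def test_apply_reproduces_training_projection(self, rng):
        X = rng.normal(size=(35, 6))
        model = SSKECA(ncomp=8).fit(X)
        assert np.abs(model.transform(X) - model.training_projection_).max() < 1e-8

    def test_apply_empty_input(self, rng):
        model = SSKECA(ncomp=4).fit(rng.normal(size=(20, 5)))
        assert model.transform(np.zeros((0, 5))).shape == (0, 4)

    def test_duplicated_training_point_matches(self, rng):
        X = rng.normal(size=(20, 4))
        model = SSKECA(ncomp=6).fit(X)
        out = model.transform(X[3:4].copy())
        assert np.allclose(out, model.training_projection_[3], atol=1e-8)

    def test_dimension_mismatch(self, rng):
        model = SSKECA(ncomp=3).fit(rng.normal(size=(15, 4)))
        with pytest.raises(ValueError):
            model.transform(np.ones((2, 5)))

    def test_beta_zero_selection_is_entropy_order(self, rng):
        X = rng.normal(size=(30, 5))
        model = SSKECA(ncomp=10, beta=0.0).fit(X)
        scores = model.state_.scores
        oracle = np.sort(np.argsort(-scores.entropy, kind="stable")[:10])
        assert model.state_.selected.tolist() == oracle.tolist()

    def test_increasing_beta_penalizes_dense_components(self, rng):
        X = rng.normal(size=(30, 5))
        model = SSKECA(ncomp=None, beta=0.0).fit(X)
        s0 = model.state_.scores
        dense = int(np.argmax(s0.l1_norms))
        # rank position of the densest component never improves as beta grows
        def rank(beta):
            order = np.argsort(-(s0.entropy - beta * s0.l1_norms), kind="stable")
            return int(np.where(order == dense)[0][0])

        ranks = [rank(b) for b in (0.0, 0.05, 0.2, 1.0)]
        assert all(r2 >= r1 for r1, r2 in zip(ranks, ranks[1:]))

    def test_permutation_equivariance(self, rng):
        X = rng.normal(size=(25, 4))
        perm = rng.permutation(25)
        Z = SSKECA(ncomp=5).fit_transform(X)
        Zp = SSKECA(ncomp=5).fit_transform(X[perm])
        assert np.allclose(np.abs(Zp), np.abs(Z[perm]), atol=1e-8)

    def test_lasso_stage_off_by_default(self, rng):
        X = rng.normal(size=(30, 5))
        y = (rng.random(30) > 0.5).astype(int)
        base = SSKECA(ncomp=6).fit_transform(X)
        with_y = SSKECA(ncomp=6).fit_transform(X, y)
        assert np.allclose(base, with_y)

    def test_lasso_stage_zeroes_coordinates(self, rng):
        X = np.vstack([rng.normal(size=(20, 4)), rng.normal(3, 1, size=(20, 4))])
        y = np.repeat([0, 1], 20)
        model = SSKECA(ncomp=10, lasso_penalty=0.05)
        Z = model.fit_transform(X, y)
        mask = model.state_.lasso_mask
        assert mask is not None and (mask == 0).any()
        assert np.allclose(Z[:, mask == 0], 0)


class TestBaselines:
    def test_pca_full_reconstruction(self, rng):
        X = rng.normal(size=(20, 5))
        Z, model = baseline_transform(X, "PCA")
        back = Z @ model._pca.components_ + model._pca.mean_
        assert np.allclose(back, X, atol=1e-10)

    def test_kpca_matches_sklearn(self, rng):
        from sklearn.decomposition import KernelPCA as SkKernelPCA

        X = rng.normal(size=(30, 4))
        Xn, _ = zscore_fit(X)
        bw = 2.0
        ours = KPCA(ncomp=5, bw=bw).fit_transform(Xn)
        ref = SkKernelPCA(n_components=5, kernel="rbf", gamma=1 / (2 * bw**2)).fit_transform(Xn)
        # projections agree up to per-component sign
        for j in range(5):
            assert np.allclose(np.abs(ours[:, j]), np.abs(ref[:, j]), atol=1e-6)

    def test_keca_vs_kpca_ranking_divergence(self):
        # 5-point toy: one tight cluster + one distant point; the cluster-mean
        # component carries the entropy mass, the outlier contrast the variance
        X = np.array([[0.0], [0.1], [0.2], [0.05], [5.0]])
        keca = KECA(ncomp=2, bw=1.0).fit(X)
        kpca = KPCA(ncomp=2, bw=1.0).fit(X)
        assert kpca.state_.selected.tolist() == [0, 1]  # eigenvalue order
        assert keca.state_.selected.tolist() != kpca.state_.selected.tolist() or not np.allclose(
            keca.state_.scores.scores, kpca.state_.scores.scores
        )

    def test_unknown_method(self):
        with pytest.raises(ValueError, match="unknown transform"):
            make_transform("tsne")

    def test_common_contract(self, rng):
        X = rng.normal(size=(25, 6))
        for method in ("SSKECA", "KECA", "KPCA", "PCA"):
            Z, model = baseline_transform(X, method, ncomp=3)
            assert Z.shape == (25, 3)
            assert model.transform(X[:4]).shape == (4, 3)
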