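"""PCA, LDA and SCA against independent eigen/variance oracles."""

import numpy as np
import pytest
import scipy.linalg

from scakit import (
    AUTO,
    PartialLabels,
    SingularConstraintError,
    UNLABELED,
    build_sca_laplacian,
    compute_alpha,
    fit_lda,
    fit_pca,
    fit_sca,
    gaussian_mixture,
    nn_classify,
    remove_labels,
    transform,
)
from scakit.linear_transformers import sca_constraint_matrix

from conftest import principal_angles, random_partial_labels


class TestPCA:
    def test_diagonal_covariance_axis_and_eigenvalue(self, rng):
        # construct data whose sample covariance is exactly diag(4, 1)
        Z = rng.normal(size=(200, 2))
        Z -= Z.mean(axis=0)
        w, U = np.linalg.eigh(np.cov(Z.T, bias=True))
        Z = Z @ (U / np.sqrt(w))  # exact whitening
        X = Z @ np.diag([2.0, 1.0])
        model = fit_pca(X)
        assert abs(model.components[0, 0]) > 1 - 1e-8
        assert model.eigenvalues[0] == pytest.approx(4.0, rel=1e-8)

    def test_spectral_reconstruction(self, rng):
        X = rng.normal(size=(30, 4))
        model = fit_pca(X)
        S = np.cov(X.T, bias=True)
        A, lam = model.components, model.eigenvalues
        np.testing.assert_allclose(A @ np.diag(lam) @ A.T, S, atol=1e-10)
        np.testing.assert_allclose(A.T @ A, np.eye(4), atol=1e-8)

    def test_eigenvalues_are_projection_variances(self, rng):
        X = rng.normal(size=(40, 6))
        model = fit_pca(X)
        Y = transform(model, X)
        for j in range(6):
            col = Y[:, j]
            var = sum((v - col.mean()) ** 2 for v in col) / 40
            assert model.eigenvalues[j] == pytest.approx(var, rel=1e-9)

    def test_insufficient_samples(self):
        with pytest.raises(ValueError, match="at least 2"):
            fit_pca(np.ones((1, 3)))


class TestLDA:
    def test_two_spherical_classes_direction(self):
        X, lab = gaussian_mixture([80, 80], [[3, 0, 0], [-3, 0, 0]],
                                  np.eye(3), seed=7)
        model = fit_lda(X, lab)
        # closed form: Sigma_w^{-1}(mu_1 - mu_2)
        mu1 = X[:80].mean(axis=0)
        mu2 = X[80:].mean(axis=0)
        Sw = (np.cov(X[:80].T, bias=True) + np.cov(X[80:].T, bias=True)) / 2
        direction = np.linalg.solve(Sw, mu1 - mu2)
        cos = np.dot(model.components[:, 0], direction) / (
            np.linalg.norm(model.components[:, 0]) * np.linalg.norm(direction)
        )
        assert abs(cos) > 1 - 1e-6

    def test_identical_class_means_zero_eigenvalues(self, rng):
        X = rng.normal(size=(90, 4))
        lab = PartialLabels(list(rng.integers(0, 3, size=90)))
        model = fit_lda(X, lab)
        # no between-class structure beyond sampling noise of the split
        assert model.eigenvalues[0] < 0.5

    def test_generalized_eigenvalues_match_alternative_factorization(self):
        X, lab = gaussian_mixture(
            [40, 40, 40],
            [[2, 0, 0, 0], [0, 2, 0, 0], [0, 0, 2, 0]],
            np.eye(4), seed=3,
        )
        model = fit_lda(X, lab)
        n = X.shape[0]
        Xc = X - X.mean(axis=0)
        St = Xc.T @ Xc / n
        Sw = np.zeros((4, 4))
        for q in range(3):
            rows = X[np.array(lab.labels) == q]
            Rc = rows - rows.mean(axis=0)
            Sw += Rc.T @ Rc / n
        w = np.sort(np.linalg.eigvals(np.linalg.solve(Sw, St - Sw)).real)[::-1]
        np.testing.assert_allclose(model.eigenvalues, w, rtol=1e-8, atol=1e-10)

    def test_constraint_normalization(self):
        X, lab = gaussian_mixture([30, 30], [[1, 0, 0], [-1, 0, 0]],
                                  np.eye(3), seed=5)
        model = fit_lda(X, lab)
        Sw = np.zeros((3, 3))
        for q in range(2):
            rows = X[np.array(lab.labels) == q]
            Rc = rows - rows.mean(axis=0)
            Sw += Rc.T @ Rc / 60
        A = model.components
        np.testing.assert_allclose(A.T @ Sw @ A, np.eye(3), atol=1e-8)

    def test_rejects_unlabeled(self):
        with pytest.raises(ValueError, match="fully labeled"):
            fit_lda(np.eye(3), PartialLabels([0, 1, UNLABELED]))


class TestComputeAlpha:
    def test_whitened_data_gives_one(self, rng):
        X = rng.normal(size=(50, 4))
        Xc = X - X.mean(axis=0)
        w, U = np.linalg.eigh(Xc.T @ Xc / 50)
        X = Xc @ (U / np.sqrt(w))  # sample covariance exactly I
        assert compute_alpha(X) == pytest.approx(1.0, rel=1e-10)

    @pytest.mark.parametrize("c", [0.5, 3.0])
    def test_quadratic_homogeneity(self, rng, c):
        X = rng.normal(size=(20, 3))
        assert compute_alpha(c * X) == pytest.approx(c**2 * compute_alpha(X),
                                                     rel=1e-12)

    def test_equals_mean_per_dimension_variance(self, rng):
        X = rng.normal(size=(25, 7))
        variances = []
        for j in range(7):
            col = X[:, j]
            variances.append(sum((v - col.mean()) ** 2 for v in col) / 25)
        assert compute_alpha(X) == pytest.approx(np.mean(variances), rel=1e-12)


class TestSCA:
    def test_all_unlabeled_spans_pca_subspace(self, two_class_problem):
        X, lab = two_class_problem
        unl = PartialLabels([UNLABELED] * lab.n, class_ids=lab.class_ids)
        m_sca = fit_sca(X, unl)
        m_pca = fit_pca(X)
        ang = principal_angles(transform(m_sca, X), transform(m_pca, X))
        assert ang.max() < 1e-6

    def test_all_labeled_matches_lda(self, two_class_problem):
        X, lab = two_class_problem
        m_sca = fit_sca(X, lab)
        m_lda = fit_lda(X, lab)
        np.testing.assert_allclose(m_sca.eigenvalues, m_lda.eigenvalues,
                                   rtol=1e-8, atol=1e-10)
        k1 = m_lda.rank_policy["informative"]
        ang = principal_angles(m_sca.components[:, :k1],
                               m_lda.components[:, :k1])
        assert ang.max() < 1e-6

    def test_eigenpair_residuals_against_brute_force(self, rng):
        for _ in range(5):
            lab = random_partial_labels(rng, 60, 3, 25)
            X = rng.normal(size=(60, 5))
            model = fit_sca(X, lab, alpha=AUTO)
            S = build_sca_laplacian(lab).quadratic_form(X)
            M = sca_constraint_matrix(X, lab, model.alpha)
            M = M + model.rank_policy["jitter"] * np.eye(5)
            for lam, a in zip(model.eigenvalues, model.components.T):
                resid = np.linalg.norm(S @ a - lam * (M @ a))
                assert resid < 1e-8 * np.linalg.norm(a) * max(1, abs(lam))

    def test_constraint_satisfied(self, rng):
        lab = random_partial_labels(rng, 40, 2, 15)
        X = rng.normal(size=(40, 4))
        model = fit_sca(X, lab)
        M = sca_constraint_matrix(X, lab, model.alpha)
        M = M + model.rank_policy["jitter"] * np.eye(4)
        A = model.components
        np.testing.assert_allclose(A.T @ M @ A, np.eye(4), atol=1e-8)

    def test_scale_invariance_of_nn_predictions(self):
        for seed in range(10):
            X, lab = gaussian_mixture([25, 25], [[1.5, 0, 0], [-1.5, 0, 0]],
                                      np.eye(3), seed=seed)
            X_test, _ = gaussian_mixture([10, 10], [[1.5, 0, 0], [-1.5, 0, 0]],
                                         np.eye(3), seed=seed + 1000)
            partial = remove_labels(lab, 0.5, seed)
            base = None
            for c in (1e-3, 1.0, 1e3):
                model = fit_sca(c * X, partial, alpha=AUTO)
                pred = nn_classify(transform(model, c * X), lab,
                                   transform(model, c * X_test))
                if base is None:
                    base = pred
                else:
                    assert pred == base

    def test_objective_nonincreasing_under_truncation(self, rng):
        lab = random_partial_labels(rng, 30, 2, 10)
        X = rng.normal(size=(30, 5))
        model = fit_sca(X, lab)
        S = build_sca_laplacian(lab).quadratic_form(X)
        objs = [np.trace(model.components[:, :r].T @ S @ model.components[:, :r])
                for r in range(5, 0, -1)]
        assert all(a >= b - 1e-10 for a, b in zip(objs, objs[1:]))

    def test_illposed_primal_refused(self, rng):
        X = rng.normal(size=(10, 50))
        lab = PartialLabels([0] * 5 + [1] * 5)
        with pytest.raises(SingularConstraintError, match="kernel"):
            fit_sca(X, lab)


class TestTransform:
    def test_identity_components(self, rng):
        X = rng.normal(size=(8, 3))
        from scakit import TransformModel

        model = TransformModel(np.eye(3), np.ones(3), "pca")
        np.testing.assert_array_equal(transform(model, X), X)

    def test_zero_input(self, two_class_problem):
        X, _ = two_class_problem
        model = fit_pca(X)
        assert np.all(transform(model, np.zeros((4, 5))) == 0)

    def test_rowwise_loop_oracle(self, rng, two_class_problem):
        X, _ = two_class_problem
        model = fit_pca(X)
        Z = rng.normal(size=(10, 5))
        Y = transform(model, Z)
        for i in range(10):
            np.testing.assert_allclose(Y[i], model.components.T @ Z[i],
                                       rtol=1e-14, atol=0)

    def test_dimension_mismatch(self, two_class_problem):
        X, _ = two_class_problem
        model = fit_pca(X)
        with pytest.raises(ValueError, match="columns"):
            transform(model, np.ones((3, 4)))

    def test_centering_option_records_mean(self, two_class_problem):
        X, _ = two_class_problem
        model = fit_pca(X, center=True)
        np.testing.assert_allclose(
            transform(model, X), (X - X.mean(axis=0)) @ model.components
        )
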