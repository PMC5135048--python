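"""Dual (kernel) transformers for ill-posed problems.

When the feature dimension m exceeds the sample count n, the primal
generalized eigenproblems are degenerate.  In the dual formulation the
eigenvectors are written as linear combinations of the (implicitly
mapped) training samples, ``a = Phi(X) b``, and everything is expressed
through the Gram matrix ``K_ij = K(x_i, x_j)``.  Kernel SCA solves

    K L K B = { (alpha n_u/n) K + (n_l/n) K L_w K } B Lambda,

where ``L`` is the semi-supervised Laplacian and ``L_w`` the within-class
Laplacian zero-padded over unlabeled samples.  A new sample x is
transformed as ``B^T [K(x, x_1) ... K(x, x_n)]^T``.  The Gram matrix is
used raw (no double-centering); centering is already encoded in the
Laplacians.

Dual versions of the comparison methods (kernel PCA, kernel discriminant
analysis, kernel LPP, kernel SDA) are provided on the same pattern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics.pairwise import pairwise_kernels

from .graph_embedding import (
    PartialLabels,
    build_sca_laplacian,
    build_total_laplacian,
    build_within_laplacian,
)
from .linear_transformers import AUTO, _rank_policy, solve_symmetric_gevp

__all__ = [
    "KernelSpec",
    "KernelModel",
    "gram_matrix",
    "kernel_alpha",
    "fit_ksca",
    "fit_kpca",
    "fit_kda",
    "fit_klpp",
    "fit_ksda",
    "transform_kernel",
]

_PSD_TOL = 1e-8  # Gram eigenvalues below -tol * lambda_max trigger repair


@dataclass(frozen=True)
class KernelSpec:
    """A kernel function K(x, z) = phi(x)^T phi(z).

    kind : {"linear", "rbf", "polynomial"}
    gamma : float, rbf bandwidth (K = exp(-gamma ||x-z||^2)) or polynomial
        scale; must be > 0 for rbf.
    degree : int >= 1, polynomial degree.
    coef0 : float, polynomial offset.
    """

    kind: str = "linear"
    gamma: float | None = None
    degree: int = 3
    coef0: float = 1.0

    def __post_init__(self):
        if self.kind not in ("linear", "rbf", "polynomial"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "rbf" and self.gamma is not None and self.gamma <= 0:
            raise ValueError("rbf kernel requires gamma > 0")
        if self.kind == "polynomial" and (self.degree < 1
                                          or int(self.degree) != self.degree):
            raise ValueError("polynomial kernel requires integer degree >= 1")


@dataclass(frozen=True)
class KernelModel:
    """A fitted dual transformation.

    ``dual_coefficients`` is the n x r matrix B; transforming new data
    requires kernel evaluations against the retained ``training_features``.
    """

    dual_coefficients: np.ndarray
    training_features: np.ndarray
    spec: KernelSpec
    eigenvalues: np.ndarray
    method: str
    alpha: float | None = None
    rank_policy: dict = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.dual_coefficients.shape[1]


def gram_matrix(X: np.ndarray, Z: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Kernel matrix with entries ``K(x_i, z_j)``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if X.shape[1] != Z.shape[1]:
        raise ValueError("X and Z dimensionalities differ")
    if spec.kind == "linear":
        return X @ Z.T
    if spec.kind == "rbf":
        gamma = spec.gamma if spec.gamma is not None else 1.0 / X.shape[1]
        return pairwise_kernels(X, Z, metric="rbf", gamma=gamma)
    gamma = spec.gamma if spec.gamma is not None else 1.0
    return pairwise_kernels(X, Z, metric="polynomial", gamma=gamma,
                            degree=spec.degree, coef0=spec.coef0)


def _repair_psd(K: np.ndarray) -> np.ndarray:
    """Clip negative Gram eigenvalues beyond numerical tolerance."""
    w, V = np.linalg.eigh((K + K.T) / 2)
    lam_max = max(w[-1], 0.0)
    if w[0] < -_PSD_TOL * max(lam_max, 1.0):
        warnings.warn(
            f"Gram matrix has negative eigenvalue {w[0]:.3e}; clipping to 0",
            stacklevel=3,
        )
        K = (V * np.clip(w, 0.0, None)) @ V.T
    return K


def kernel_alpha(K: np.ndarray) -> float:
    """Automatic scaling parameter in kernel space.

    The primal rule ``tr(Sigma)/m`` needs a stand-in for m, the implicit
    feature-space dimension.  With ``K_c`` the doubly-centered Gram
    matrix, ``tr(K_c)/n`` equals the total feature-space variance trace,
    and the numerical rank of ``K_c`` plays the role of the
    dimensionality, preserving the average-per-dimension-variance
    meaning of the primal rule.
    """
    n = K.shape[0]
    H = np.eye(n) - np.full((n, n), 1.0 / n)
    Kc = H @ K @ H
    w = np.linalg.eigvalsh((Kc + Kc.T) / 2)
    lam_max = max(w[-1], 0.0)
    if lam_max <= 0:
        return 0.0
    rank = int(np.sum(w > 1e-10 * lam_max))
    return float(np.trace(Kc) / (n * rank))


def _fit_dual(K, S_lap, M_lap, *, alpha_term, method, spec, X, alpha,
              n_components, ascending=False):
    """Shared dual solve: K S_lap K B = (alpha_term K + K M_lap K) B Lambda."""
    S = K @ S_lap @ K
    M = alpha_term * K + (K @ M_lap @ K if M_lap is not None else 0.0)
    S = (S + S.T) / 2
    M = (M + M.T) / 2
    w, B, jitter = solve_symmetric_gevp(S, M, ascending=ascending)
    if n_components is not None:
        w, B = w[:n_components], B[:, :n_components]
    return KernelModel(
        dual_coefficients=B, training_features=np.asarray(X, dtype=float),
        spec=spec, eigenvalues=w, method=method, alpha=alpha,
        rank_policy=_rank_policy(w, jitter, requested=n_components),
    )


def fit_ksca(X: np.ndarray, labels: PartialLabels,
             spec: KernelSpec = KernelSpec("linear"),
             alpha: float | str = AUTO, *,
             n_components: int | None = None) -> KernelModel:
    """Kernel semi-supervised component analysis.

    Dual of :func:`scakit.linear_transformers.fit_sca`: with a linear
    kernel and m <= n the embedding spans the same subspace as the
    primal solution; with m > n (ill-posed) it remains solvable.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError(f"kernel SCA needs at least 2 samples, got {n}")
    if labels.n != n:
        raise ValueError("labels length does not match X")
    K = _repair_psd(gram_matrix(X, X, spec))
    if alpha == AUTO:
        alpha = kernel_alpha(K)
    alpha = float(alpha)
    L = build_sca_laplacian(labels).in_input_order()
    Lw = (build_within_laplacian(labels).in_input_order()
          if labels.n_l > 0 else None)
    return _fit_dual(
        K, L, None if Lw is None else (labels.n_l / n) * Lw,
        alpha_term=alpha * labels.n_u / n, method="ksca", spec=spec,
        X=X, alpha=alpha, n_components=n_components,
    )


def fit_kpca(X: np.ndarray, spec: KernelSpec = KernelSpec("linear"), *,
             n_components: int | None = None) -> KernelModel:
    """Kernel PCA: ``K L_t K B = K B Lambda`` (constraint ``A^T A = I``)."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("kernel PCA needs at least 2 samples")
    K = _repair_psd(gram_matrix(X, X, spec))
    Lt = build_total_laplacian(n).matrix
    return _fit_dual(K, Lt, None, alpha_term=1.0, method="kpca", spec=spec,
                     X=X, alpha=None, n_components=n_components)


def fit_kda(X: np.ndarray, labels: PartialLabels,
            spec: KernelSpec = KernelSpec("linear"), *,
            n_components: int | None = None) -> KernelModel:
    """Kernel discriminant analysis: ``K L_b K B = K L_w K B Lambda``."""
    X = np.asarray(X, dtype=float)
    if labels.n_u:
        raise ValueError("kernel DA requires fully labeled data")
    n = X.shape[0]
    K = _repair_psd(gram_matrix(X, X, spec))
    Lt = build_total_laplacian(n).matrix
    Lw = build_within_laplacian(labels).in_input_order()
    return _fit_dual(K, Lt - Lw, Lw, alpha_term=0.0, method="kda", spec=spec,
                     X=X, alpha=None, n_components=n_components)


def fit_klpp(X: np.ndarray, graph, spec: KernelSpec = KernelSpec("linear"), *,
             n_components: int | None = None) -> KernelModel:
    """Kernel locality preserving projections (ascending eigenvalues).

    ``graph`` is a :class:`scakit.baselines.SimilarityGraph`.
    """
    X = np.asarray(X, dtype=float)
    K = _repair_psd(gram_matrix(X, X, spec))
    D = np.diag(graph.degree)
    return _fit_dual(K, graph.laplacian, D, alpha_term=0.0, method="klpp",
                     spec=spec, X=X, alpha=None, n_components=n_components,
                     ascending=True)


def fit_ksda(X: np.ndarray, labels: PartialLabels, graph, reg: float,
             spec: KernelSpec = KernelSpec("linear"), *,
             n_components: int | None = None) -> KernelModel:
    """Kernel semi-supervised discriminant analysis.

    Dual of the SDA problem: between-class scatter of the labeled samples
    against total labeled scatter plus a graph-smoothness regularizer
    over all samples.
    """
    from .baselines import _sda_laplacians  # deferred: avoids module cycle

    X = np.asarray(X, dtype=float)
    K = _repair_psd(gram_matrix(X, X, spec))
    Lb, Lreg = _sda_laplacians(labels, graph, reg)
    return _fit_dual(K, Lb, Lreg, alpha_term=0.0, method="ksda", spec=spec,
                     X=X, alpha=None, n_components=n_components)


def transform_kernel(model: KernelModel, X_new: np.ndarray) -> np.ndarray:
    """Transform new samples: ``gram(X_new, X_train) @ B``."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.training_features.shape[1]:
        raise ValueError(
            f"X has {X_new.shape[1]} columns, model expects "
            f"{model.training_features.shape[1]}"
        )
    return gram_matrix(X_new, model.training_features, model.spec) @ model.dual_coefficients
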