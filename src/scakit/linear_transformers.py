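"""Linear feature transformations: PCA, LDA and semi-supervised SCA.

Each transformer estimates an ``m x r`` matrix ``A`` mapping a feature
vector ``x`` to ``y = A^T x``.  All three are solved as (generalized)
symmetric eigenproblems over graph-embedding quadratic forms:

* PCA maximizes ``tr(A^T Sigma A)`` subject to ``A^T A = I``;
* LDA maximizes between- over within-class variance, solving
  ``Sigma_b A = Sigma_w A Lambda`` with ``A^T Sigma_w A = I``;
* SCA maximizes ``tr(A^T X L X^T A)`` with the semi-supervised Laplacian
  ``L``, subject to the mixed constraint
  ``(alpha n_u/n) A^T A + (n_l/n) A^T Sigma_w A = I``,
  which interpolates PCA (no labels) and LDA (all labeled).

The scaling parameter ``alpha`` balances the identity and within-scatter
terms of the constraint; by default it is set automatically to
``tr(Sigma)/m`` (the average per-dimension variance), which makes the
transformation invariant to a global rescaling of the features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .graph_embedding import (
    PartialLabels,
    build_sca_laplacian,
    build_total_laplacian,
    build_within_laplacian,
)

__all__ = [
    "AUTO",
    "TransformModel",
    "SingularConstraintError",
    "solve_symmetric_gevp",
    "fit_pca",
    "fit_lda",
    "compute_alpha",
    "fit_sca",
    "transform",
]

#: Sentinel requesting automatic selection of the scaling parameter.
AUTO = "auto"

# Relative thresholds of the shared generalized-eigenproblem policy.
# The ridge keeps the constraint matrix condition number near 1e8, the
# largest at which float64 can still certify the normalization
# V^T M V = I to ~1e-8; a smaller ridge lets near-null eigenvectors grow
# so large that the constraint product itself loses that many digits.
_JITTER_TRIGGER = 1e-12  # smallest eig of M below this * tr(M)/m -> jitter
_JITTER_SCALE = 1e-8  # ridge added: this * tr(M)/m
_RANK_TOL = 1e-10  # eigenvalue threshold relative to the largest


class SingularConstraintError(np.linalg.LinAlgError):
    """The constraint matrix of a generalized eigenproblem is degenerate.

    Typically the problem is ill-posed (more dimensions than samples);
    the kernel (dual) formulation handles that case.
    """


@dataclass(frozen=True)
class TransformModel:
    """A fitted linear transformation ``y = A^T x``.

    Attributes
    ----------
    components : ndarray, shape (m, r)
        Transformation matrix A, one component per column, eigenvalues
        non-increasing.
    eigenvalues : ndarray, shape (r,)
        (Generalized) eigenvalues, sorted non-increasing.
    method : str
        One of ``pca``, ``lda``, ``sca``, ``lpp``, ``sda``.
    alpha : float or None
        Scaling parameter used (SCA only).
    rank_policy : dict
        How r was chosen: requested components, count above the numerical
        rank threshold, informative-component cap, ridge jitter applied.
    center : bool
        Whether :func:`transform` subtracts the training mean.  Off by
        default: ``y = A^T x`` is applied to raw features, and centering
        happens implicitly inside the Laplacian during fitting.
    mean_ : ndarray or None
        Training mean, stored when ``center`` is requested.
    """

    components: np.ndarray
    eigenvalues: np.ndarray
    method: str
    alpha: float | None = None
    rank_policy: dict = field(default_factory=dict)
    center: bool = False
    mean_: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.components.shape[1]


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Flip columns so the largest-magnitude entry of each is positive."""
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs


def solve_symmetric_gevp(
    S: np.ndarray,
    M: np.ndarray,
    *,
    ascending: bool = False,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Solve ``S v = lambda M v`` for symmetric S and symmetric PSD M.

    Eigenvectors are normalized so ``V^T M V = I`` and signed so each
    column's largest-magnitude entry is positive.  If M is numerically
    singular a small ridge ``eps * I`` with ``eps = 1e-10 tr(M)/m`` is
    added (returned as third element; 0.0 when not needed); if M is
    degenerate outright a :class:`SingularConstraintError` is raised.

    Returns ``(eigenvalues, eigenvectors, jitter)`` with eigenvalues
    sorted non-increasing (or non-decreasing when ``ascending``) by a
    stable sort.
    """
    S = np.asarray(S, dtype=float)
    M = np.asarray(M, dtype=float)
    m = M.shape[0]
    scale = np.trace(M) / m
    if not np.isfinite(scale) or scale <= 0:
        raise SingularConstraintError(
            "constraint matrix has non-positive trace; the problem is "
            "degenerate — consider the kernel (dual) formulation"
        )
    jitter = 0.0
    w_min = scipy.linalg.eigvalsh(M, subset_by_index=(0, 0))[0]
    if w_min < _JITTER_TRIGGER * scale:
        jitter = _JITTER_SCALE * scale
        M = M + jitter * np.eye(m)
    try:
        w, V = scipy.linalg.eigh(S, M)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - safety net
        raise SingularConstraintError(
            "generalized eigenproblem failed; constraint matrix is "
            "numerically singular — consider the kernel (dual) formulation"
        ) from exc
    order = np.argsort(w if ascending else -w, kind="stable")
    w, V = w[order], V[:, order]
    # re-enforce V^T M V = I: eigh loses a few digits of the constraint
    # when M is ill-conditioned after jittering.  The Cholesky correction
    # only mixes near-degenerate columns, so eigen-residuals are preserved.
    C = V.T @ M @ V
    try:
        R = scipy.linalg.cholesky((C + C.T) / 2)
        V = scipy.linalg.solve_triangular(R.T, V.T, lower=True).T
    except scipy.linalg.LinAlgError:
        nrm = np.sqrt(np.abs(np.einsum("ij,ij->j", V, M @ V)))
        good = nrm > 0
        V[:, good] = V[:, good] / nrm[good]
    return w, _fix_signs(V), jitter


def _rank_policy(eigvals: np.ndarray, jitter: float, **extra) -> dict:
    lam_max = float(np.max(np.abs(eigvals))) if eigvals.size else 0.0
    above = int(np.sum(np.abs(eigvals) > _RANK_TOL * lam_max)) if lam_max else 0
    return {"retained": int(eigvals.size), "above_threshold": above,
            "jitter": jitter, **extra}


def _maybe_truncate(w, V, n_components):
    if n_components is not None:
        w, V = w[:n_components], V[:, :n_components]
    return w, V


def fit_pca(X: np.ndarray, *, n_components: int | None = None,
            center: bool = False) -> TransformModel:
    """Principal component analysis via the total-covariance Laplacian.

    Columns of A are the orthonormal eigenvectors of the covariance
    ``X^T L_t X`` in descending eigenvalue order.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError(f"PCA needs at least 2 samples, got {n}")
    S = build_total_laplacian(n).quadratic_form(X)
    w, V = scipy.linalg.eigh(S)
    order = np.argsort(-w, kind="stable")
    w, V = w[order], _fix_signs(V[:, order])
    w, V = _maybe_truncate(w, V, n_components)
    return TransformModel(
        components=V, eigenvalues=w, method="pca",
        rank_policy=_rank_policy(w, 0.0, requested=n_components),
        center=center, mean_=X.mean(axis=0) if center else None,
    )


def fit_lda(X: np.ndarray, labels: PartialLabels, *,
            n_components: int | None = None,
            center: bool = False) -> TransformModel:
    """Fisher discriminant analysis as a generalized eigenproblem.

    Solves ``Sigma_b A = Sigma_w A Lambda`` with ``A^T Sigma_w A = I``.
    At most ``k - 1`` components carry between-class information; by
    default the full rank is retained (nuisance components have
    eigenvalue ~ 0) so downstream comparisons across methods see equal
    dimensionality.  A singular within-class covariance is handled by
    the shared ridge-jitter policy, with a warning.
    """
    X = np.asarray(X, dtype=float)
    if labels.n_u:
        raise ValueError("LDA requires fully labeled data "
                         f"({labels.n_u} unlabeled samples found)")
    if labels.n_classes < 2:
        raise ValueError("LDA needs at least 2 classes")
    n, m = X.shape
    if m > n:
        raise SingularConstraintError(
            f"{m} dimensions > {n} samples: ill-posed primal problem; "
            "use the kernel (dual) formulation"
        )
    Lt = build_total_laplacian(n).quadratic_form(X)
    Sw = build_within_laplacian(labels).quadratic_form(X)
    Sb = Lt - Sw
    w, V, jitter = solve_symmetric_gevp(Sb, Sw)
    if jitter:
        warnings.warn("within-class covariance is singular; "
                      f"ridge jitter {jitter:.3e} applied", stacklevel=2)
    w, V = _maybe_truncate(w, V, n_components)
    informative = min(labels.n_classes - 1, m)
    return TransformModel(
        components=V, eigenvalues=w, method="lda",
        rank_policy=_rank_policy(w, jitter, requested=n_components,
                                 informative=informative),
        center=center, mean_=X.mean(axis=0) if center else None,
    )


def compute_alpha(X: np.ndarray) -> float:
    """Automatic scaling parameter ``alpha = tr(Sigma)/m``.

    The trace of the total covariance divided by the dimensionality,
    i.e. the average per-dimension variance of the full training set.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples to estimate variance")
    d = X - X.mean(axis=0)
    return float(np.sum(d * d) / (X.shape[0] * X.shape[1]))


def sca_constraint_matrix(X: np.ndarray, labels: PartialLabels,
                          alpha: float) -> np.ndarray:
    """The constraint matrix ``(alpha n_u/n) I + (n_l/n) Sigma_w``."""
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    M = (alpha * labels.n_u / n) * np.eye(m)
    if labels.n_l > 0:
        M = M + (labels.n_l / n) * build_within_laplacian(labels).quadratic_form(X)
    return M


def fit_sca(X: np.ndarray, labels: PartialLabels, alpha: float | str = AUTO, *,
            n_components: int | None = None,
            center: bool = False) -> TransformModel:
    """Semi-supervised component analysis.

    Maximizes ``tr(A^T X L X^T A)`` over the semi-supervised Laplacian
    subject to ``(alpha n_u/n) A^T A + (n_l/n) A^T Sigma_w A = I``, where
    ``Sigma_w`` is the within-class covariance of the labeled samples.
    With every sample unlabeled the solution spans the PCA subspace;
    with every sample labeled it coincides with LDA.

    ``alpha=AUTO`` resolves the scaling to ``tr(Sigma)/m`` over the full
    (labeled + unlabeled) training set, making the fitted transformation
    invariant to a global rescaling of the features.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    if n < 2:
        raise ValueError(f"SCA needs at least 2 samples, got {n}")
    if labels.n != n:
        raise ValueError("labels length does not match X")
    if m > n:
        raise SingularConstraintError(
            f"{m} dimensions > {n} samples: ill-posed primal problem; "
            "use the kernel (dual) formulation"
        )
    if alpha == AUTO:
        alpha = compute_alpha(X)
    alpha = float(alpha)
    S = build_sca_laplacian(labels).quadratic_form(X)
    M = sca_constraint_matrix(X, labels, alpha)
    w, V, jitter = solve_symmetric_gevp(S, M)
    w, V = _maybe_truncate(w, V, n_components)
    return TransformModel(
        components=V, eigenvalues=w, method="sca", alpha=alpha,
        rank_policy=_rank_policy(w, jitter, requested=n_components),
        center=center, mean_=X.mean(axis=0) if center else None,
    )


def transform(model: TransformModel, X: np.ndarray) -> np.ndarray:
    """Apply ``y = A^T x`` to each row of X."""
    X = np.asarray(X, dtype=float)
    m = model.components.shape[0]
    if X.ndim != 2 or X.shape[1] != m:
        raise ValueError(f"X has {X.shape[-1] if X.ndim else 0} columns, "
                         f"model expects {m}")
    if model.center and model.mean_ is not None:
        X = X - model.mean_
    return X @ model.components
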