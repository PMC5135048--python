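"""Synthetic feature tables with the structure the transformers assume.

Stands in for real image-feature tables (e.g. GIST or CNN descriptors of
tissue images): class-conditional Gaussian features for the
well-posed regime, and low-rank class structure embedded in a very
high-dimensional ambient space for the ill-posed (m >> n) regime.

All draws derive from a single integer seed through numpy's
``SeedSequence`` spawning, so any example citing "seed 0" is
unambiguous and bit-reproducible.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .graph_embedding import PartialLabels

__all__ = ["gaussian_mixture", "illposed_features", "two_cluster_problem"]


def _check_cov(C: np.ndarray, m: int) -> np.ndarray:
    C = np.asarray(C, dtype=float)
    if C.shape != (m, m):
        raise ValueError(f"covariance must be {m}x{m}, got {C.shape}")
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    w = np.linalg.eigvalsh(C)
    if w[0] < -1e-10 * max(w[-1], 1.0):
        raise ValueError(f"covariance not positive semi-definite (min eig {w[0]:.3e})")
    return C


def gaussian_mixture(
    n_per_class: Sequence[int],
    means: Sequence[np.ndarray],
    covariances,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[np.ndarray, PartialLabels]:
    """Draw a labeled Gaussian-mixture feature table.

    Parameters
    ----------
    n_per_class : sequence of int
        Samples per class, classes labeled ``0..k-1``.
    means : sequence of vectors
        Class mean vectors, shared dimensionality m.
    covariances : matrix or sequence of matrices
        A single m x m covariance shared by all classes, or one per class.
    seed : int or numpy SeedSequence
        Master seed; one child stream per class, so class draws are
        independent and reproducible.

    Returns
    -------
    (X, labels) : feature matrix (rows = samples, class blocks in order)
        and fully labeled :class:`PartialLabels`.
    """
    means = [np.asarray(mu, dtype=float).ravel() for mu in means]
    k = len(means)
    if len(n_per_class) != k:
        raise ValueError("n_per_class and means lengths differ")
    m = means[0].size
    if any(mu.size != m for mu in means):
        raise ValueError("means must share dimensionality")
    covs = (
        [_check_cov(c, m) for c in covariances]
        if isinstance(covariances, (list, tuple))
        else [_check_cov(covariances, m)] * k
    )
    if len(covs) != k:
        raise ValueError("need one covariance per class (or a single shared one)")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = ss.spawn(k)
    blocks, labels = [], []
    for q in range(k):
        rng = np.random.default_rng(streams[q])
        blocks.append(rng.multivariate_normal(
            means[q], covs[q], size=int(n_per_class[q]), method="svd"))
        labels.extend([q] * int(n_per_class[q]))
    return np.vstack(blocks), PartialLabels(labels, class_ids=tuple(range(k)))


def illposed_features(
    n: int,
    intrinsic_dim: int,
    ambient_dim: int,
    noise: float = 0.01,
    n_classes: int = 2,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[np.ndarray, PartialLabels]:
    """High-dimensional features with low-rank class structure (m >> n).

    Emulates deep-network descriptors where the feature dimension
    exceeds the sample count: class-structured points drawn in
    ``intrinsic_dim`` dimensions are embedded by a random linear map
    into ``ambient_dim`` dimensions, plus isotropic Gaussian noise.
    With ``noise = 0`` the centered data have rank <= intrinsic_dim.
    """
    if ambient_dim <= n:
        raise ValueError(f"ambient_dim ({ambient_dim}) must exceed n ({n})")
    if not 1 <= intrinsic_dim <= ambient_dim:
        raise ValueError("intrinsic_dim must be in [1, ambient_dim]")
    if n_classes < 1 or n < n_classes:
        raise ValueError("need at least one sample per class")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_lat, s_map, s_noise = ss.spawn(3)
    per = [n // n_classes + (1 if q < n % n_classes else 0) for q in range(n_classes)]
    rng = np.random.default_rng(s_lat)
    # well-separated class means in the intrinsic space
    mus = rng.normal(scale=3.0, size=(n_classes, intrinsic_dim))
    Z, labels = [], []
    for q in range(n_classes):
        Z.append(mus[q] + rng.normal(size=(per[q], intrinsic_dim)))
        labels.extend([q] * per[q])
    Z = np.vstack(Z)
    P = np.random.default_rng(s_map).normal(
        size=(intrinsic_dim, ambient_dim)) / np.sqrt(intrinsic_dim)
    X = Z @ P
    if noise > 0:
        X = X + noise * np.random.default_rng(s_noise).normal(size=X.shape)
    return X, PartialLabels(labels, class_ids=tuple(range(n_classes)))


def two_cluster_problem(
    n_per_class: int = 60,
    dim: int = 6,
    separation: float = 4.0,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[np.ndarray, PartialLabels]:
    """Convenience two-class benchmark: spherical Gaussians at +-sep/2 on axis 0."""
    delta = np.zeros(dim)
    delta[0] = separation / 2
    return gaussian_mixture(
        [n_per_class, n_per_class], [delta, -delta], np.eye(dim), seed=seed
    )
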