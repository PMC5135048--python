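"""Graph-embedding Laplacians and scatter matrices.

In the graph-embedding view of multivariate analysis, covariance-like
matrices are written as quadratic forms ``X L X^T`` over an n x n sample
Laplacian ``L``.  This module builds every Laplacian used by the
transformers in this package:

* the *total* Laplacian ``L_t = (1/n)(I - ee^T/n)``, whose quadratic form
  is the total covariance;
* the *within-class* Laplacian, a block-diagonal matrix over class blocks
  whose quadratic form is the within-class covariance of the labeled
  samples;
* the *semi-supervised* Laplacian ``L = L_t - [(n_l/n) L_w, 0; 0, 0]``
  combining total variance over unlabeled samples with between-class
  structure over labeled ones.

All Laplacians are built in an *internal* sample order — labeled samples
first, grouped by class, then unlabeled — and carry the permutation back
to the caller's input order, so callers never reorder their data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np

__all__ = [
    "UNLABELED",
    "PartialLabels",
    "GraphLaplacian",
    "ScatterSet",
    "build_total_laplacian",
    "build_within_laplacian",
    "build_sca_laplacian",
    "compute_scatters",
]


class _Unlabeled:
    """Sentinel marking a sample with no class label."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "UNLABELED"


#: Reserved marker for samples whose class is unknown.  Distinct from any
#: user class id; missing labels in file input map to it.
UNLABELED = _Unlabeled()


class EmptyLabelSetError(ValueError):
    """Raised when an operation requires labeled samples but none exist."""


@dataclass(frozen=True)
class PartialLabels:
    """Per-sample class labels where some samples may be unlabeled.

    Parameters
    ----------
    labels : sequence
        One entry per sample: a hashable class id, or :data:`UNLABELED`
        (``None`` and ``float('nan')`` are accepted as aliases).
    class_ids : sequence, optional
        Ordered distinct class ids.  Defaults to first-appearance order of
        the labeled samples.  Classes listed here but absent from
        ``labels`` are allowed only if they never occur.

    Attributes
    ----------
    n, n_l, n_u : int
        Total, labeled and unlabeled sample counts (``n = n_l + n_u``).
    beta : float
        Unlabeled ratio ``n_u / n``.
    class_counts : dict
        Labeled sample count ``n_q`` per class id.
    """

    labels: tuple = field(init=False)
    class_ids: tuple = field(init=False)

    def __init__(self, labels: Sequence, class_ids: Sequence[Hashable] | None = None):
        norm = tuple(self._normalize(v) for v in labels)
        seen: dict = {}
        for v in norm:
            if v is not UNLABELED and v not in seen:
                seen[v] = None
        if class_ids is None:
            cids = tuple(seen)
        else:
            cids = tuple(class_ids)
            if len(set(cids)) != len(cids):
                raise ValueError("class_ids contains duplicates")
            missing = [c for c in seen if c not in cids]
            if missing:
                raise ValueError(f"labels contain class ids not in class_ids: {missing}")
        object.__setattr__(self, "labels", norm)
        object.__setattr__(self, "class_ids", cids)

    @staticmethod
    def _normalize(v):
        if v is None or v is UNLABELED:
            return UNLABELED
        if isinstance(v, float) and np.isnan(v):
            return UNLABELED
        return v

    # -- counts ---------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def n_l(self) -> int:
        return sum(1 for v in self.labels if v is not UNLABELED)

    @property
    def n_u(self) -> int:
        return self.n - self.n_l

    @property
    def beta(self) -> float:
        return self.n_u / self.n if self.n else 0.0

    @property
    def n_classes(self) -> int:
        return len(self.class_ids)

    @property
    def class_counts(self) -> dict:
        counts = {c: 0 for c in self.class_ids}
        for v in self.labels:
            if v is not UNLABELED:
                counts[v] += 1
        return counts

    def is_labeled(self) -> np.ndarray:
        """Boolean mask, True where the sample has a class label."""
        return np.array([v is not UNLABELED for v in self.labels])

    def labeled_classes(self) -> tuple:
        """Class ids with at least one labeled sample, in class_ids order."""
        counts = self.class_counts
        return tuple(c for c in self.class_ids if counts[c] > 0)

    def internal_order(self) -> np.ndarray:
        """Permutation: internal position -> input index.

        Internal order puts labeled samples first, grouped by class in
        ``class_ids`` order (stable within a class), then unlabeled.
        """
        order: list[int] = []
        for c in self.class_ids:
            order.extend(i for i, v in enumerate(self.labels) if v == c)
        order.extend(i for i, v in enumerate(self.labels) if v is UNLABELED)
        return np.asarray(order, dtype=np.intp)

    def labeled_subset(self) -> "PartialLabels":
        """Labels restricted to the labeled samples (fully labeled)."""
        return PartialLabels(
            [v for v in self.labels if v is not UNLABELED],
            class_ids=self.labeled_classes(),
        )

    def to_array(self, unlabeled_value=-1) -> np.ndarray:
        """Integer codes: index into class_ids, ``unlabeled_value`` if none."""
        idx = {c: i for i, c in enumerate(self.class_ids)}
        return np.array(
            [unlabeled_value if v is UNLABELED else idx[v] for v in self.labels]
        )

    @classmethod
    def fully_labeled(cls, labels: Sequence, class_ids=None) -> "PartialLabels":
        out = cls(labels, class_ids=class_ids)
        if out.n_u:
            raise ValueError("labels contain unlabeled samples")
        return out


@dataclass(frozen=True)
class GraphLaplacian:
    """An n x n sample Laplacian plus the ordering it assumes.

    ``matrix`` is expressed in *internal* order (labeled first, grouped by
    class, then unlabeled); ``ordering[i]`` gives the input index of
    internal position ``i``.  :meth:`in_input_order` permutes the matrix
    back so ``X.T @ L @ X`` can be formed with row-sample ``X`` as given.
    """

    matrix: np.ndarray
    ordering: np.ndarray
    kind: str  # {"total", "within", "between", "sca"}

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("Laplacian must be square")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("Laplacian must be symmetric to 1e-10")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "ordering", np.asarray(self.ordering, dtype=np.intp))

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def in_input_order(self) -> np.ndarray:
        """Return the Laplacian permuted to the caller's sample order."""
        inv = np.empty_like(self.ordering)
        inv[self.ordering] = np.arange(self.n)
        return self.matrix[np.ix_(inv, inv)]

    def quadratic_form(self, X: np.ndarray) -> np.ndarray:
        """Compute ``X^T L X`` for row-sample X in input order (m x m)."""
        X = np.asarray(X, dtype=float)
        if X.shape[0] != self.n:
            raise ValueError(f"X has {X.shape[0]} rows, Laplacian expects {self.n}")
        Xi = X[self.ordering]  # internal order
        return Xi.T @ self.matrix @ Xi


@dataclass(frozen=True)
class ScatterSet:
    """Definitional scatter/covariance matrices for a partially labeled set.

    ``total`` is the covariance about the grand mean; ``within`` and
    ``between`` the classical within/between-class covariances of the
    labeled samples; ``sb_labeled``/``su_unlabeled`` are the *unnormalized*
    between-class scatter of labeled class means and total scatter of
    unlabeled samples, both about the grand mean over all n samples.
    """

    total: np.ndarray
    within: np.ndarray
    between: np.ndarray
    sb_labeled: np.ndarray
    su_unlabeled: np.ndarray
    mean: np.ndarray
    class_means: dict


def build_total_laplacian(n: int) -> GraphLaplacian:
    """Laplacian of the total covariance: ``(1/n)(I - ee^T/n)``.

    ``X^T L_t X`` equals the covariance of the rows of X about their mean.
    """
    if n < 1:
        raise ValueError(f"need at least one sample, got n={n}")
    L = (np.eye(n) - np.full((n, n), 1.0 / n)) / n
    return GraphLaplacian(L, np.arange(n), "total")


def _within_block(counts: Sequence[int], n_l: int, n: int) -> np.ndarray:
    """(1/n_l) blockdiag_q (I - e_q e_q^T / n_q), zero-padded to n x n."""
    L = np.zeros((n, n))
    pos = 0
    for n_q in counts:
        blk = (np.eye(n_q) - np.full((n_q, n_q), 1.0 / n_q)) / n_l
        L[pos : pos + n_q, pos : pos + n_q] = blk
        pos += n_q
    return L


def build_within_laplacian(labels: PartialLabels) -> GraphLaplacian:
    """Within-class Laplacian over the labeled samples.

    In internal order the matrix is ``(1/n_l) blockdiag(I - e_q e_q^T/n_q)``
    over the labeled class blocks, with zero rows/columns for unlabeled
    samples; its quadratic form is the within-class covariance of the
    labeled samples.  With every sample labeled this is the classical
    within-class Laplacian of discriminant analysis.
    """
    if labels.n_l == 0:
        raise EmptyLabelSetError("within-class Laplacian needs at least one labeled sample")
    counts = labels.class_counts
    sizes = [counts[c] for c in labels.labeled_classes()]
    L = _within_block(sizes, labels.n_l, labels.n)
    return GraphLaplacian(L, labels.internal_order(), "within")


def build_sca_laplacian(labels: PartialLabels) -> GraphLaplacian:
    """Semi-supervised Laplacian ``L = L_t - [(n_l/n) L_w, 0; 0, 0]``.

    With no unlabeled samples this is the between-class Laplacian
    ``L_t - L_w`` (discriminant analysis); with no labeled samples it is
    the total Laplacian (principal component analysis).
    """
    if labels.n < 1:
        raise ValueError("need at least one sample")
    n = labels.n
    L = (np.eye(n) - np.full((n, n), 1.0 / n)) / n  # L_t in any order
    if labels.n_l > 0:
        counts = labels.class_counts
        sizes = [counts[c] for c in labels.labeled_classes()]
        L -= (labels.n_l / n) * _within_block(sizes, labels.n_l, n)
    return GraphLaplacian(L, labels.internal_order(), "sca")


def compute_scatters(X: np.ndarray, labels: PartialLabels) -> ScatterSet:
    """Scatter matrices by explicit definitional sums (not via Laplacians).

    Serves as the independent reference for the Laplacian quadratic forms:
    ``total = within + between`` when all samples are labeled, and
    ``(1/n)(sb_labeled + su_unlabeled)`` equals the quadratic form of the
    semi-supervised Laplacian for any label pattern.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n == 0:
        raise ValueError("empty input")
    if n != labels.n:
        raise ValueError("X rows and labels length differ")
    m = X.shape[1]
    mu = X.mean(axis=0)

    total = np.zeros((m, m))
    for x in X:
        d = x - mu
        total += np.outer(d, d)
    total /= n

    mask = labels.is_labeled()
    codes = labels.to_array()
    class_means: dict = {}
    within = np.zeros((m, m))
    between = np.zeros((m, m))
    sb = np.zeros((m, m))
    n_l = labels.n_l
    counts = labels.class_counts
    for c in labels.labeled_classes():
        ci = labels.class_ids.index(c)
        rows = X[(codes == ci) & mask]
        mu_q = rows.mean(axis=0)
        class_means[c] = mu_q
        for x in rows:
            d = x - mu_q
            within += np.outer(d, d)
        dq = mu_q - mu
        between += (counts[c] / n) * np.outer(dq, dq)
        sb += counts[c] * np.outer(dq, dq)
    if n_l > 0:
        within /= n_l

    su = np.zeros((m, m))
    for x in X[~mask]:
        d = x - mu
        su += np.outer(d, d)

    return ScatterSet(total, within, between, sb, su, mu, class_means)
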