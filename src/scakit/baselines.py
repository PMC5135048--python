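"""Comparison transformers: locality preserving projections and
semi-supervised discriminant analysis.

Both methods rely on a k-nearest-neighbor similarity graph with
heat-kernel weights ``w_ij = exp(-||x_i - x_j||^2 / t)``.  LPP finds
directions along which graph neighbors stay close, solving

    X^T L_g X a = lambda X^T D X a   (smallest eigenvalues first),

with ``L_g = D - W`` the graph Laplacian and D the degree matrix.  SDA
regularizes Fisher discriminant analysis of the labeled samples with the
same graph-smoothness penalty over all samples:

    S_b a = lambda (S_t + reg * X^T L_g X) a   (largest first),

where S_b and S_t are the between-class and total scatters of the
labeled subset.  Unlike SCA, both need a similarity measure chosen a
priori; the heat bandwidth t (and SDA's reg) are tuned by grid search in
the evaluation protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import pairwise_distances

from .graph_embedding import PartialLabels
from .linear_transformers import (
    TransformModel,
    _rank_policy,
    solve_symmetric_gevp,
)

__all__ = [
    "SimilarityGraph",
    "build_similarity_graph",
    "fit_lpp",
    "fit_sda",
]


@dataclass(frozen=True)
class SimilarityGraph:
    """Symmetric weighted sample graph in input sample order."""

    adjacency: np.ndarray
    heat_bandwidth: float
    neighbors: int

    @property
    def degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    @property
    def laplacian(self) -> np.ndarray:
        return np.diag(self.degree) - self.adjacency

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]


def build_similarity_graph(X: np.ndarray, neighbors: int,
                           heat_bandwidth: float) -> SimilarityGraph:
    """Symmetric k-NN graph with heat-kernel weights.

    An edge exists when either endpoint ranks the other among its k
    nearest (union rule); edge weight is ``exp(-d^2 / t)``.  Neighbor
    ties are broken by sample index.  No self-loops.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 1 <= neighbors < n:
        raise ValueError(f"neighbors must be in [1, {n - 1}], got {neighbors}")
    if heat_bandwidth <= 0:
        raise ValueError("heat_bandwidth must be positive")
    d2 = pairwise_distances(X, metric="sqeuclidean")
    np.fill_diagonal(d2, np.inf)  # exclude self from neighbor ranking
    W = np.zeros((n, n))
    nn_idx = np.argsort(d2, axis=1, kind="stable")[:, :neighbors]
    for i in range(n):
        for j in nn_idx[i]:
            w = np.exp(-d2[i, j] / heat_bandwidth)
            W[i, j] = w
            W[j, i] = w
    return SimilarityGraph(W, float(heat_bandwidth), int(neighbors))


def fit_lpp(X: np.ndarray, graph: SimilarityGraph, *,
            n_components: int | None = None,
            center: bool = False) -> TransformModel:
    """Locality preserving projections (smallest eigenvalues first)."""
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    if n < 2:
        raise ValueError("LPP needs at least 2 samples")
    if graph.n != n:
        raise ValueError("graph size does not match X")
    S = X.T @ graph.laplacian @ X
    M = X.T @ np.diag(graph.degree) @ X
    S = (S + S.T) / 2
    M = (M + M.T) / 2
    w, V, jitter = solve_symmetric_gevp(S, M, ascending=True)
    if n_components is not None:
        w, V = w[:n_components], V[:, :n_components]
    return TransformModel(
        components=V, eigenvalues=w, method="lpp",
        rank_policy=_rank_policy(w, jitter, requested=n_components),
        center=center, mean_=X.mean(axis=0) if center else None,
    )


def _sda_laplacians(labels: PartialLabels, graph: SimilarityGraph,
                    reg: float) -> tuple[np.ndarray, np.ndarray]:
    """n x n Laplacians (input order) of the SDA numerator/denominator.

    Returns ``(L_b, L_t + reg * L_g)`` where the scatter Laplacians act
    on the labeled block only (zero rows/columns elsewhere) and encode
    the unnormalized labeled scatters.
    """
    n = labels.n
    order = labels.internal_order()
    n_l = labels.n_l
    Lt_lab = np.zeros((n, n))
    Lt_lab[:n_l, :n_l] = np.eye(n_l) - np.full((n_l, n_l), 1.0 / n_l)
    Lw_lab = np.zeros((n, n))
    pos = 0
    counts = labels.class_counts
    for c in labels.labeled_classes():
        n_q = counts[c]
        Lw_lab[pos:pos + n_q, pos:pos + n_q] = (
            np.eye(n_q) - np.full((n_q, n_q), 1.0 / n_q)
        )
        pos += n_q
    inv = np.empty(n, dtype=np.intp)
    inv[order] = np.arange(n)
    Lb = (Lt_lab - Lw_lab)[np.ix_(inv, inv)]
    Lt = Lt_lab[np.ix_(inv, inv)]
    return Lb, Lt + reg * graph.laplacian


def fit_sda(X: np.ndarray, labels: PartialLabels, graph: SimilarityGraph,
            reg: float, *, n_components: int | None = None,
            center: bool = False) -> TransformModel:
    """Semi-supervised discriminant analysis.

    With ``reg = 0`` and all samples labeled the solution spans the LDA
    subspace (eigenvalues differ by the total-vs-within normalization of
    the denominator).
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    if labels.n_l < 2:
        raise ValueError("SDA needs at least 2 labeled samples")
    if len(labels.labeled_classes()) < 2:
        raise ValueError("SDA needs at least 2 labeled classes")
    if reg < 0:
        raise ValueError("reg must be non-negative")
    if graph.n != n:
        raise ValueError("graph size does not match X")
    Lb, Lreg = _sda_laplacians(labels, graph, reg)
    S = X.T @ Lb @ X
    M = X.T @ Lreg @ X
    S = (S + S.T) / 2
    M = (M + M.T) / 2
    w, V, jitter = solve_symmetric_gevp(S, M)
    if n_components is not None:
        w, V = w[:n_components], V[:, :n_components]
    informative = min(len(labels.labeled_classes()) - 1, m)
    return TransformModel(
        components=V, eigenvalues=w, method="sda",
        rank_policy=_rank_policy(w, jitter, requested=n_components,
                                 informative=informative),
        center=center, mean_=X.mean(axis=0) if center else None,
    )
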