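"""Evaluation classifiers: 1-nearest-neighbor and nearest-mean.

Deliberately minimal: recognition is always measured in a transformed
feature space, with the classifier kept simple so differences between
transformations dominate.  Ties are broken deterministically (lowest
training index for NN, class order for NM).
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import pairwise_distances

from .graph_embedding import PartialLabels

__all__ = ["nn_classify", "nm_classify", "recognition_rate"]


def _as_partial(train_labels, n) -> PartialLabels:
    if not isinstance(train_labels, PartialLabels):
        train_labels = PartialLabels(train_labels)
    if train_labels.n != n:
        raise ValueError("training labels length does not match training data")
    if train_labels.n_u:
        raise ValueError("classifier requires fully labeled training data")
    return train_labels


def nn_classify(train: np.ndarray, train_labels, test: np.ndarray) -> list:
    """Label each test sample by its Euclidean-nearest training sample.

    Distance ties go to the lowest training index.
    """
    train = np.atleast_2d(np.asarray(train, dtype=float))
    test = np.atleast_2d(np.asarray(test, dtype=float))
    if train.shape[0] == 0:
        raise ValueError("empty training set")
    labels = _as_partial(train_labels, train.shape[0])
    with np.errstate(over="ignore", invalid="ignore"):
        # distances past float range saturate to inf; argmin stays defined
        d = pairwise_distances(test, train, metric="euclidean")
    nearest = np.argmin(d, axis=1)  # argmin returns the first (lowest) index
    return [labels.labels[i] for i in nearest]


def nm_classify(train: np.ndarray, train_labels, test: np.ndarray) -> list:
    """Label each test sample by the Euclidean-nearest class mean.

    Ties go to the class listed first in ``class_ids``.
    """
    train = np.atleast_2d(np.asarray(train, dtype=float))
    test = np.atleast_2d(np.asarray(test, dtype=float))
    if train.shape[0] == 0:
        raise ValueError("empty training set")
    labels = _as_partial(train_labels, train.shape[0])
    counts = labels.class_counts
    empty = [c for c in labels.class_ids if counts[c] == 0]
    if empty:
        raise ValueError(f"classes with no training samples: {empty}")
    codes = labels.to_array()
    means = np.vstack([
        train[codes == i].mean(axis=0) for i in range(labels.n_classes)
    ])
    with np.errstate(over="ignore", invalid="ignore"):
        d = pairwise_distances(test, means, metric="euclidean")
    nearest = np.argmin(d, axis=1)
    return [labels.class_ids[i] for i in nearest]


def recognition_rate(predicted, truth) -> float:
    """Fraction of predictions matching the true labels, in [0, 1]."""
    predicted = list(predicted)
    truth = list(truth)
    if len(predicted) != len(truth):
        raise ValueError(
            f"length mismatch: {len(predicted)} predictions, {len(truth)} truths"
        )
    if not truth:
        raise ValueError("empty label sequences")
    return sum(p == t for p, t in zip(predicted, truth)) / len(truth)
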