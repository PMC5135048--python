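import numpy as np
import pytest

from scakit import PartialLabels, UNLABELED


def principal_angles(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Principal angles (radians) between the column spans of A and B."""
    Qa, _ = np.linalg.qr(np.asarray(A, dtype=float))
    Qb, _ = np.linalg.qr(np.asarray(B, dtype=float))
    s = np.linalg.svd(Qa.T @ Qb, compute_uv=False)
    return np.arccos(np.clip(s, -1.0, 1.0))


def random_partial_labels(rng, n, k, n_unlabeled):
    """Random label pattern with every class represented among the labeled."""
    while True:
        codes = rng.integers(0, k, size=n)
        hide = np.zeros(n, dtype=bool)
        hide[rng.choice(n, size=n_unlabeled, replace=False)] = True
        if len(set(codes[~hide])) == k:
            return PartialLabels(
                [UNLABELED if h else int(c) for c, h in zip(codes, hide)],
                class_ids=tuple(range(k)),
            )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_class_problem():
    """Well-separated two-class Gaussian data, n=60 per class, m=5."""
    from scakit import gaussian_mixture

    mu = np.zeros(5)
    mu[0] = 2.0
    return gaussian_mixture([60, 60], [mu, -mu], np.eye(5), seed=42)
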