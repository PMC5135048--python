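"""Experimental protocols: label removal, beta sweeps, stratified CV and
grid search.

The central experiment varies the unlabeled ratio ``beta = n_u / n`` of
the training set over a grid: at each beta the ground-truth training
labels are randomly hidden from the transformer (repeated several
times), the transformer is fitted on the full training set (labeled +
unlabeled), both sets are projected, and a simple classifier is applied
*with all ground-truth training labels* in the transformed space.
Performance is the mean recognition rate +/- standard deviation over
repetitions.  beta = 0 and beta = 1 involve no randomness and are
computed once.

Supervised methods (LDA and its kernel form) cannot use unlabeled rows;
at 0 < beta < 1 they are fitted on the labeled subset only, mirroring
how a supervised baseline is evaluated alongside semi-supervised ones.

Everything is driven by a single master seed through ``SeedSequence``
spawning, so every reported number is bit-reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import baselines, kernel_transformers as kt, linear_transformers as lt
from .classifiers import nm_classify, nn_classify, recognition_rate
from .graph_embedding import UNLABELED, PartialLabels

__all__ = [
    "MethodSpec",
    "BetaSweepResult",
    "remove_labels",
    "fit_method",
    "beta_sweep",
    "stratified_kfold_eval",
    "grid_search_hyperparam",
    "DEFAULT_GRID",
]

#: Hyperparameter grid used for LPP/SDA tuning: powers of two from 2^-15 to 2^15.
DEFAULT_GRID = tuple(2.0 ** p for p in range(-15, 16))

_SUPERVISED = {"lda", "kda"}
_UNSUPERVISED = {"pca", "lpp", "kpca", "klpp"}


@dataclass(frozen=True)
class MethodSpec:
    """Names a transformer of this library plus its hyperparameters.

    ``name`` is one of pca, lda, sca, lpp, sda (primal) or kpca, kda,
    ksca, klpp, ksda (dual), or "custom" with ``fit_fn(X, labels) ->
    fitted`` supplied, where ``fitted`` has a ``transform(X)`` method or
    is a model understood by :func:`fit_method`'s returned closure.
    """

    name: str
    alpha: float | str = lt.AUTO
    kernel: kt.KernelSpec | None = None
    neighbors: int = 5
    heat_bandwidth: float = 1.0
    reg: float = 1.0
    n_components: int | None = None
    fit_fn: Callable | None = None

    def with_params(self, **kw) -> "MethodSpec":
        return replace(self, **kw)


@dataclass(frozen=True)
class BetaSweepResult:
    """Per-beta mean recognition rates over label-removal repetitions."""

    beta_grid: tuple
    means: np.ndarray
    stds: np.ndarray
    rates: dict  # beta -> list of per-repetition rates (NaN on fit error)
    errors: dict  # (beta, repetition) -> error message
    method: str
    classifier: str
    repetitions: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per (beta, repetition)."""
        rows = [
            {"method": self.method, "classifier": self.classifier,
             "beta": b, "repetition": r, "rate": v}
            for b in self.beta_grid
            for r, v in enumerate(self.rates[b])
        ]
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "method": self.method, "classifier": self.classifier,
            "beta": list(self.beta_grid), "mean_rate": self.means,
            "std_rate": self.stds,
        })

    def plot(self, path=None, ax=None):
        """Rate-vs-beta curve with a +/- one-std band (needs matplotlib)."""
        import matplotlib

        if path is not None:
            matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        b = np.asarray(self.beta_grid, dtype=float)
        ax.plot(b, self.means, marker="o",
                label=f"{self.method} ({self.classifier})")
        ax.fill_between(b, self.means - self.stds, self.means + self.stds,
                        alpha=0.2)
        ax.set_xlabel(r"unlabeled ratio $\beta$")
        ax.set_ylabel("mean recognition rate")
        ax.legend()
        if path is not None:
            ax.figure.savefig(path, bbox_inches="tight")
        return ax


def remove_labels(labels, beta: float, seed) -> PartialLabels:
    """Hide labels of ``round(beta * n)`` samples chosen uniformly.

    ``seed`` may be an int, SeedSequence or Generator.  When beta < 1,
    a draw that would leave some class with no labeled sample is redrawn
    (up to 100 times) so semi-supervised fits keep every class
    represented; beta = 1 hides everything.
    """
    if not isinstance(labels, PartialLabels):
        labels = PartialLabels(labels)
    if labels.n_u:
        raise ValueError("remove_labels expects fully labeled input")
    if not 0 <= beta <= 1:
        raise ValueError(f"beta must be in [0, 1], got {beta}")
    n = labels.n
    n_hide = int(np.floor(beta * n + 0.5))  # half-up rounding
    if n_hide == 0:
        return labels
    if n_hide == n:
        return PartialLabels([UNLABELED] * n, class_ids=labels.class_ids)
    rng = np.random.default_rng(seed)
    for _ in range(100):
        hide = rng.choice(n, size=n_hide, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[hide] = True
        kept = [v for v, h in zip(labels.labels, mask) if not h]
        if all(any(v == c for v in kept) for c in labels.class_ids):
            new = [UNLABELED if h else v for v, h in zip(labels.labels, mask)]
            return PartialLabels(new, class_ids=labels.class_ids)
    raise RuntimeError(
        f"could not hide {n_hide}/{n} labels without emptying a class "
        "(100 redraws exhausted)"
    )


def fit_method(spec: MethodSpec, X: np.ndarray, labels: PartialLabels):
    """Fit the named transformer; returns ``apply(X_new) -> features``.

    Semi-supervised methods see the partial labels; unsupervised methods
    ignore them; supervised methods are fitted on the labeled rows only.
    """
    name = spec.name
    kernel = spec.kernel or kt.KernelSpec("linear")
    if name == "custom":
        fitted = spec.fit_fn(X, labels)
        return fitted.transform if hasattr(fitted, "transform") else fitted
    if name == "pca":
        model = lt.fit_pca(X, n_components=spec.n_components)
        return lambda Z: lt.transform(model, Z)
    if name == "lda":
        mask = labels.is_labeled()
        if not mask.any():
            raise ValueError("LDA requires labeled samples")
        model = lt.fit_lda(X[mask], labels.labeled_subset(),
                           n_components=spec.n_components)
        return lambda Z: lt.transform(model, Z)
    if name == "sca":
        model = lt.fit_sca(X, labels, alpha=spec.alpha,
                           n_components=spec.n_components)
        return lambda Z: lt.transform(model, Z)
    if name == "lpp":
        graph = baselines.build_similarity_graph(
            X, spec.neighbors, spec.heat_bandwidth)
        model = baselines.fit_lpp(X, graph, n_components=spec.n_components)
        return lambda Z: lt.transform(model, Z)
    if name == "sda":
        graph = baselines.build_similarity_graph(
            X, spec.neighbors, spec.heat_bandwidth)
        model = baselines.fit_sda(X, labels, graph, spec.reg,
                                  n_components=spec.n_components)
        return lambda Z: lt.transform(model, Z)
    if name == "kpca":
        model = kt.fit_kpca(X, kernel, n_components=spec.n_components)
        return lambda Z: kt.transform_kernel(model, Z)
    if name == "kda":
        mask = labels.is_labeled()
        if not mask.any():
            raise ValueError("kernel DA requires labeled samples")
        model = kt.fit_kda(X[mask], labels.labeled_subset(), kernel,
                           n_components=spec.n_components)
        return lambda Z: kt.transform_kernel(model, Z)
    if name == "ksca":
        model = kt.fit_ksca(X, labels, kernel, alpha=spec.alpha,
                            n_components=spec.n_components)
        return lambda Z: kt.transform_kernel(model, Z)
    if name == "klpp":
        graph = baselines.build_similarity_graph(
            X, spec.neighbors, spec.heat_bandwidth)
        model = kt.fit_klpp(X, graph, kernel, n_components=spec.n_components)
        return lambda Z: kt.transform_kernel(model, Z)
    if name == "ksda":
        graph = baselines.build_similarity_graph(
            X, spec.neighbors, spec.heat_bandwidth)
        model = kt.fit_ksda(X, labels, graph, spec.reg, kernel,
                            n_components=spec.n_components)
        return lambda Z: kt.transform_kernel(model, Z)
    raise ValueError(f"unknown method {name!r}")


def _classify(kind: str, train, train_labels, test):
    if kind == "nn":
        return nn_classify(train, train_labels, test)
    if kind == "nm":
        return nm_classify(train, train_labels, test)
    raise ValueError(f"unknown classifier {kind!r} (use 'nn' or 'nm')")


def _one_run(spec, X_train, y_train, partial, X_test, y_test, classifier):
    apply = fit_method(spec, X_train, partial)
    T_train = apply(X_train)
    T_test = apply(X_test)
    if not (np.all(np.isfinite(T_train)) and np.all(np.isfinite(T_test))):
        raise ValueError("transformer produced non-finite features")
    pred = _classify(classifier, T_train, y_train, T_test)
    return recognition_rate(pred, list(y_test.labels))


def beta_sweep(
    X_train: np.ndarray,
    y_train,
    X_test: np.ndarray,
    y_test,
    method: MethodSpec,
    beta_grid: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0),
    repetitions: int = 10,
    classifier: str = "nn",
    seed: int = 0,
) -> BetaSweepResult:
    """Recognition rate vs unlabeled ratio on a fixed train/test split.

    At each beta the training labels are randomly hidden (``repetitions``
    independent draws), the transformer is refitted, and classification
    in the transformed space uses all ground-truth training labels.
    beta = 0 and beta = 1 are deterministic and evaluated once.
    Fit failures are recorded per cell as NaN, not raised.
    """
    y_train = y_train if isinstance(y_train, PartialLabels) else PartialLabels(y_train)
    y_test = y_test if isinstance(y_test, PartialLabels) else PartialLabels(y_test)
    if y_train.n_u or y_test.n_u:
        raise ValueError("beta_sweep expects fully labeled train and test sets")
    root = np.random.SeedSequence(seed)
    streams = {b: root.spawn(1)[0].spawn(repetitions)
               for b in beta_grid}  # one substream per (beta, repetition)
    rates: dict = {}
    errors: dict = {}
    for bi, b in enumerate(beta_grid):
        cell = []
        reps = 1 if b in (0.0, 1.0) else repetitions
        for r in range(reps):
            try:
                partial = remove_labels(y_train, b, streams[b][r])
                cell.append(_one_run(method, X_train, y_train, partial,
                                     X_test, y_test, classifier))
            except Exception as exc:  # noqa: BLE001 - recorded per-cell
                errors[(b, r)] = f"{type(exc).__name__}: {exc}"
                cell.append(float("nan"))
        rates[b] = cell
    means = np.array([float(np.nanmean(rates[b])) if not all(np.isnan(rates[b]))
                      else float("nan") for b in beta_grid])
    stds = np.array([float(np.nanstd(rates[b])) if not all(np.isnan(rates[b]))
                     else float("nan") for b in beta_grid])
    return BetaSweepResult(tuple(beta_grid), means, stds, rates, errors,
                           method.name, classifier, repetitions, seed)


def stratified_kfold_eval(
    X: np.ndarray,
    y,
    folds: int,
    method: MethodSpec,
    classifier: str = "nn",
    beta: float = 0.0,
    repetitions: int = 10,
    seed: int = 0,
) -> dict:
    """Stratified k-fold cross-validated recognition rate.

    Within each fold the transformer is fitted on the training rows only
    (with labels partially hidden when 0 < beta < 1, repeated
    ``repetitions`` times) and evaluated on the held-out rows.  Returns
    mean and std over all (fold, repetition) cells plus the tidy record.
    """
    y = y if isinstance(y, PartialLabels) else PartialLabels(y)
    X = np.asarray(X, dtype=float)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    counts = y.class_counts
    small = [c for c, v in counts.items() if v < folds]
    if small:
        raise ValueError(f"classes smaller than fold count {folds}: {small}")
    root = np.random.SeedSequence(seed)
    shuffle_seed, removal_root = root.spawn(2)
    codes = y.to_array()
    skf = StratifiedKFold(n_splits=folds, shuffle=True,
                          random_state=int(shuffle_seed.generate_state(1)[0] % (2**31)))
    records = []
    fold_streams = removal_root.spawn(folds)
    for fold, (tr, te) in enumerate(skf.split(X, codes)):
        y_tr = PartialLabels([y.labels[i] for i in tr], class_ids=y.class_ids)
        y_te = PartialLabels([y.labels[i] for i in te], class_ids=y.class_ids)
        reps = repetitions if 0.0 < beta < 1.0 else 1
        rep_streams = fold_streams[fold].spawn(max(reps, 1))
        for r in range(reps):
            try:
                partial = remove_labels(y_tr, beta, rep_streams[r])
                rate = _one_run(method, X[tr], y_tr, partial, X[te], y_te,
                                classifier)
                err = ""
            except Exception as exc:  # noqa: BLE001
                rate, err = float("nan"), f"{type(exc).__name__}: {exc}"
            records.append({"fold": fold, "repetition": r, "beta": beta,
                            "rate": rate, "error": err})
    frame = pd.DataFrame(records)
    vals = frame["rate"].to_numpy()
    return {
        "mean_rate": float(np.nanmean(vals)) if not np.all(np.isnan(vals)) else float("nan"),
        "std_rate": float(np.nanstd(vals)) if not np.all(np.isnan(vals)) else float("nan"),
        "records": frame,
        "method": method.name,
        "classifier": classifier,
        "folds": folds,
        "beta": beta,
        "seed": seed,
    }


def grid_search_hyperparam(
    X: np.ndarray,
    y,
    method: MethodSpec,
    grid: dict | None = None,
    folds: int = 5,
    classifier: str = "nn",
    seed: int = 0,
) -> dict:
    """Select hyperparameters maximizing mean CV recognition rate.

    ``grid`` maps MethodSpec field names to candidate values, e.g.
    ``{"heat_bandwidth": DEFAULT_GRID}`` for LPP or
    ``{"reg": DEFAULT_GRID}`` for SDA; defaults to the power-of-two grid
    on the method's own tuned parameter.  Ties are resolved toward the
    smallest parameter values (grid points are scanned in sorted order
    and only a strictly better mean replaces the incumbent).
    """
    if grid is None:
        param = "reg" if method.name in ("sda", "ksda") else "heat_bandwidth"
        grid = {param: DEFAULT_GRID}
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("empty hyperparameter grid")
    names = sorted(grid)
    combos = sorted(itertools.product(*(grid[k] for k in names)))
    best, best_rate = None, -np.inf
    scores = {}
    for combo in combos:
        params = dict(zip(names, combo))
        spec = method.with_params(**params)
        try:
            res = stratified_kfold_eval(X, y, folds, spec,
                                        classifier=classifier, seed=seed)
            rate = res["mean_rate"]
        except Exception:  # noqa: BLE001 - a failing grid point scores nothing
            rate = float("nan")
        scores[combo] = rate
        if np.isfinite(rate) and rate > best_rate:
            best, best_rate = params, rate
    if best is None:
        raise RuntimeError("no hyperparameter setting produced a valid fit")
    return {"best_params": best, "best_rate": best_rate, "scores": scores}
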