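"""Spatially aware model evaluation.

Provides random and blocked (k-means) cross-validation folds, the
mean-centered R-squared, cross-validated R-squared, inverse-distance
Moran's I (marginal and conditional, expectation-adjusted), the MSE of
the coefficient estimates and feature-selection metrics (sensitivity,
true discovery proportion, and the spatial share of the selections used
to quantify red-shift).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .datasets import SimulatedDataset, TrueModel
from .design import SpatialDesign

__all__ = [
    "FoldAssignment",
    "random_folds",
    "blocked_folds",
    "r_squared_centered",
    "cv_r_squared",
    "morans_i",
    "adjusted_morans_i",
    "beta_mse",
    "selection_metrics",
]


@dataclass(frozen=True)
class FoldAssignment:
    """Partition of 1..n into k folds (labels 0..k-1)."""

    fold_of: np.ndarray
    scheme: str
    seed: int

    def __post_init__(self):
        labels = np.asarray(self.fold_of, dtype=int)
        object.__setattr__(self, "fold_of", labels)
        k = labels.max() + 1
        sizes = np.bincount(labels, minlength=k)
        if (sizes == 0).any():
            raise ValueError("every fold must be non-empty")

    @property
    def k(self) -> int:
        return int(self.fold_of.max()) + 1

    def split(self):
        """Yield (train_idx, test_idx) per fold."""
        for f in range(self.k):
            test = np.flatnonzero(self.fold_of == f)
            train = np.flatnonzero(self.fold_of != f)
            yield train, test


def random_folds(n: int, k: int, seed: int) -> FoldAssignment:
    """Random folds with sizes differing by at most one."""
    if k > n:
        raise ValueError(f"cannot form k={k} folds from n={n} observations")
    rng = np.random.default_rng(seed)
    labels = np.resize(np.arange(k), n)
    rng.shuffle(labels)
    return FoldAssignment(labels, "random", seed)


def blocked_folds(design: SpatialDesign, k: int, seed: int) -> FoldAssignment:
    """Spatially blocked folds: k-means clusters of the coordinates.

    Runs 10 k-means restarts and keeps the best inertia. Fold sizes are
    whatever the clustering gives — spatial contiguity is the point, not
    balance.
    """
    n = design.n
    if k > n:
        raise ValueError(f"cannot form k={k} folds from n={n} observations")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(design.coords)
    return FoldAssignment(labels, "blocked", seed)


def r_squared_centered(a, a_hat) -> float:
    """Mean-centered R-squared, 1 - sum((a_c - a_hat_c)^2) / sum(a_c^2).

    Both observed and predicted vectors are centered by their own means
    before comparison: within-field relative differences are of
    interest, not the baseline level. Poor models can yield negative
    values.
    """
    a = np.asarray(a, dtype=float).ravel()
    ah = np.asarray(a_hat, dtype=float).ravel()
    if a.size != ah.size or a.size < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    ac = a - a.mean()
    denom = float(ac @ ac)
    if denom == 0.0:
        raise ValueError("observed vector is constant: R^2 undefined")
    ahc = ah - ah.mean()
    return 1.0 - float((ac - ahc) @ (ac - ahc)) / denom


def cv_r_squared(fit_fn, dataset: SimulatedDataset, folds: FoldAssignment) -> float:
    """Mean held-out centered R-squared over the folds.

    ``fit_fn(A, B, design)`` must return a fitted object exposing
    ``predict(B_new)``. A fold whose model fit raises contributes an
    R-squared of 0 (the failed-fit rule); if every fold fails the last
    error propagates.
    """
    if folds.k < 2:
        raise ValueError("need at least two folds")
    scores = []
    n_failed = 0
    last_err = None
    for train, test in folds.split():
        sub = dataset.subset(train)
        try:
            fit = fit_fn(sub.A, sub.B, sub.design)
            pred = fit.predict(dataset.B[test])
            scores.append(r_squared_centered(dataset.A[test], pred))
        except Exception as e:  # noqa: BLE001 - failed fits score 0 by contract
            n_failed += 1
            last_err = e
            scores.append(0.0)
    if n_failed == folds.k:
        raise RuntimeError("model fit failed on every fold") from last_err
    return float(np.mean(scores))


def _inverse_distance_weights(design: SpatialDesign) -> np.ndarray:
    D = design.distance_matrix
    off = ~np.eye(design.n, dtype=bool)
    if np.any(D[off] <= 0):
        raise ValueError("duplicate coordinates give infinite inverse-distance weights")
    W = np.zeros_like(D)
    W[off] = 1.0 / D[off]
    return W


def morans_i(values, design: SpatialDesign, kind: str = "marginal",
             predictions=None) -> float:
    """Moran's I with inverse-distance weights (not row-standardized).

        I = n / s_w * sum_ij w_ij z_i z_j / sum_i z_i^2

    with w_ij = 1/d_ij, w_ii = 0 and s_w the total weight. ``marginal``
    uses deviations from the mean of ``values``; ``conditional`` uses
    the residuals values - predictions of a regression whose predictions
    omit all spatial terms.
    """
    v = np.asarray(values, dtype=float).ravel()
    n = v.size
    if n < 3:
        raise ValueError("Moran's I needs at least three observations")
    if kind == "marginal":
        z = v - v.mean()
    elif kind == "conditional":
        if predictions is None:
            raise ValueError("conditional Moran's I requires predictions")
        z = v - np.asarray(predictions, dtype=float).ravel()
    else:
        raise ValueError("kind must be 'marginal' or 'conditional'")
    denom = float(z @ z)
    if denom == 0.0:
        raise ValueError("constant input: Moran's I undefined")
    W = _inverse_distance_weights(design)
    s_w = float(W.sum())
    return float(n / s_w * (z @ W @ z) / denom)


def adjusted_morans_i(values, design: SpatialDesign, kind: str = "marginal",
                      predictions=None) -> float:
    """Moran's I minus its null expectation -1/(n-1).

    The null expectation depends on the sample size, so raw values from
    full training sets and small left-out folds are not comparable;
    subtracting it centers all of them at zero under exchangeability.
    """
    n = np.asarray(values).size
    return morans_i(values, design, kind, predictions) + 1.0 / (n - 1)


def beta_mse(beta_hat, beta_true) -> float:
    """Mean squared error of the coefficient estimates."""
    bh = np.asarray(beta_hat, dtype=float).ravel()
    bt = np.asarray(beta_true, dtype=float).ravel()
    if bh.size != bt.size:
        raise ValueError(f"length mismatch: {bh.size} vs {bt.size}")
    return float(np.mean((bh - bt) ** 2))


def selection_metrics(selected, truth: TrueModel):
    """(sensitivity, TDP, spatial share) of a selected feature set.

    sensitivity = TP / (TP + FN), TDP = TP / (TP + FP) against the
    nonzero true coefficients; the spatial share is the fraction of
    selections that carry spatial structure (0.5 expected for an
    unbiased selector when half the regressors are spatial; above it is
    red-shift). Empty selections give sensitivity 0 and NaN for the
    undefined ratios.
    """
    sel = np.asarray(sorted(set(int(j) for j in selected)), dtype=int)
    if sel.size and (sel.min() < 0 or sel.max() >= truth.p):
        raise IndexError("selected indices out of range")
    support = set(truth.support.tolist())
    tp = sum(1 for j in sel if j in support)
    fn = len(support) - tp
    fp = sel.size - tp
    sensitivity = tp / (tp + fn) if (tp + fn) > 0 else np.nan
    if sel.size == 0:
        return 0.0 if support else np.nan, np.nan, np.nan
    tdp = tp / (tp + fp)
    spatial_prop = float(np.mean(truth.spatial_flags[sel]))
    return float(sensitivity), float(tdp), spatial_prop
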