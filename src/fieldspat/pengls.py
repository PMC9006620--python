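"""GLS elastic net: penalized regression with spatially correlated errors.

The estimator minimizes the whitened elastic-net criterion

    1/(2n) * (A - b0 - B b)' Sigma^-1 (A - b0 - B b)
        + lambda * (alpha * ||b||_1 + (1 - alpha)/2 * ||b||_2^2)

by alternating between (i) an elastic-net fit on outcome and design
premultiplied by the inverse square-root factor W = Sigma^-1/2 of the
current error covariance and (ii) REML re-estimation of the
Gaussian-decay covariance parameters from the residuals A - b0 - B b.
The covariance starts at the identity, so the first iterate is exactly
the plain elastic net; iteration stops when the mean squared change in
the (unwhitened) predictions b0 + B b drops below 2.5e-4.

The intercept is never penalized. On the whitened scale it multiplies
the whitened constant column c = W 1, which is handled exactly by
projecting (Aw, Bw) onto the orthogonal complement of c, solving the
reduced penalized problem, and recovering b0 in closed form.

Note on the lambda scale: the quadratic term is divided by 2n (the
convention of coordinate-descent elastic-net software). A criterion
stated on the raw residual-sum-of-squares scale with penalty weights
0.5*lambda' and 0.25*lambda' corresponds to alpha = 0.5 and
lambda = lambda' / n here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet as _SkElasticNet

from .covariance import (
    CovarianceEstimationError,
    GaussCovParams,
    fit_cov_params,
    whitening_factor,
)
from .design import SpatialDesign
from .evaluation import FoldAssignment, r_squared_centered

__all__ = [
    "PenGLSFit",
    "SpatialElasticNet",
    "elastic_net",
    "lambda_path",
    "fit_en",
    "fit_pengls",
    "fit_en_eigen",
    "tune_lambda",
    "moran_eigenvectors",
]

logger = logging.getLogger(__name__)

#: outer-loop convergence threshold on the mean squared prediction change
PRED_TOL = 2.5e-4
DEFAULT_ALPHA = 0.5
N_LAMBDA = 100
LAMBDA_MIN_RATIO = 0.01


@dataclass
class PenGLSFit:
    """Fitted (GLS) elastic net."""

    beta0: float
    beta: np.ndarray
    lam: float
    alpha: float
    cov_params: Optional[GaussCovParams]
    n_iter: int
    converged: bool
    method: str
    n_eigenvectors: int = 0
    trace: list = field(default_factory=list, repr=False)

    @property
    def selected(self) -> np.ndarray:
        """Indices of regressors with nonzero coefficients.

        Spatial-eigenvector columns are never part of this set: only the
        substantive regressors count as discoveries.
        """
        return np.flatnonzero(self.beta != 0.0)

    def predict(self, exog_new) -> np.ndarray:
        """Mean-part prediction beta0 + B_new @ beta; spatial terms omitted."""
        B = np.atleast_2d(np.asarray(exog_new, dtype=float))
        if B.shape[1] != self.beta.size:
            raise ValueError(f"expected {self.beta.size} columns, got {B.shape[1]}")
        return self.beta0 + B @ self.beta

    def summary(self) -> str:
        cp = self.cov_params
        cov_line = (
            "  covariance: identity (no spatial whitening)"
            if cp is None
            else f"  covariance: sigma2={cp.sigma2:.4g}  r={cp.r:.4g}  tau={cp.tau:.4g}"
        )
        lines = [
            f"{self.method} elastic net (alpha={self.alpha}, lambda={self.lam:.5g})",
            f"  {self.selected.size} of {self.beta.size} regressors selected; "
            f"{self.n_iter} outer iteration(s), "
            f"{'converged' if self.converged else 'NOT converged'}",
            cov_line,
            f"  intercept: {self.beta0:.5f}",
        ]
        for j in self.selected:
            lines.append(f"  B_{j + 1:<6}{self.beta[j]:>12.5f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "beta0": float(self.beta0),
            "beta": self.beta.tolist(),
            "lambda": float(self.lam),
            "alpha": float(self.alpha),
            "cov_params": None if self.cov_params is None else self.cov_params.to_dict(),
            "n_iter": self.n_iter,
            "converged": self.converged,
            "method": self.method,
            "selected": self.selected.tolist(),
        }


# ------------------------------------------------------------ core solver

def _project_out(c: np.ndarray, aw: np.ndarray, bw: np.ndarray):
    """Remove the span of the unpenalized column c from outcome and design."""
    cn = c / np.linalg.norm(c)
    y = aw - cn * (cn @ aw)
    X = bw - np.outer(cn, cn @ bw)
    return y, X


def _standardize(X: np.ndarray):
    scale = X.std(axis=0)
    scale[scale == 0.0] = 1.0
    return X / scale, scale


def elastic_net(aw, bw, lam: float, alpha: float = DEFAULT_ALPHA,
                intercept_col=None):
    """Elastic net on (whitened) data with an unpenalized intercept.

    Minimizes 1/(2n) ||aw - b0*c - bw b||^2 + lam*(alpha*||b||_1 +
    (1-alpha)/2*||b||_2^2) where c is ``intercept_col`` (the whitened
    constant; defaults to the plain constant vector). Regressors are
    standardized to unit variance on this scale before penalization and
    coefficients returned on the original scale. Returns ``(b0, b)``.
    """
    if lam < 0:
        raise ValueError("penalty lambda must be non-negative")
    aw = np.asarray(aw, dtype=float).ravel()
    bw = np.asarray(bw, dtype=float)
    n = aw.size
    c = np.ones(n) if intercept_col is None else np.asarray(intercept_col, dtype=float)
    y, X = _project_out(c, aw, bw)
    if lam == 0.0:
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        beta = coef
    else:
        Xs, scale = _standardize(X)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            sk = _SkElasticNet(alpha=lam, l1_ratio=alpha, fit_intercept=False,
                               max_iter=10000, tol=1e-8)
            sk.fit(Xs, y)
        beta = sk.coef_ / scale
    beta0 = float(c @ (aw - bw @ beta) / (c @ c))
    return beta0, beta


def en_objective(aw, bw, beta0, beta, lam, alpha, intercept_col=None,
                 standardized: bool = True) -> float:
    """Value of the penalized criterion (used by tests and diagnostics).

    With ``standardized=True`` (the convention the solver follows) the
    penalty applies to the coefficients of the unit-variance rescaled
    regressors, i.e. the L1 term is sum_j s_j |beta_j| with s_j the
    standard deviation of the j-th projected column.
    """
    aw = np.asarray(aw, dtype=float).ravel()
    bw = np.asarray(bw, dtype=float)
    n = aw.size
    c = np.ones(n) if intercept_col is None else np.asarray(intercept_col, dtype=float)
    r = aw - beta0 * c - bw @ beta
    if standardized:
        _, X = _project_out(c, aw, bw)
        _, s = _standardize(X)
    else:
        s = np.ones(bw.shape[1])
    bs = beta * s
    pen = alpha * np.abs(bs).sum() + 0.5 * (1 - alpha) * (bs @ bs)
    return float(r @ r / (2 * n) + lam * pen)


def lambda_path(aw, bw, alpha: float = DEFAULT_ALPHA, intercept_col=None,
                n_lambda: int = N_LAMBDA,
                min_ratio: float = LAMBDA_MIN_RATIO) -> np.ndarray:
    """Decreasing log-spaced penalty path.

    Starts at the smallest lambda that zeroes every coefficient
    (max_j |x_j' y| / (n * alpha) on the standardized projected scale)
    and descends to ``min_ratio`` times it.
    """
    aw = np.asarray(aw, dtype=float).ravel()
    n = aw.size
    c = np.ones(n) if intercept_col is None else np.asarray(intercept_col, dtype=float)
    y, X = _project_out(c, aw, np.asarray(bw, dtype=float))
    Xs, _ = _standardize(X)
    lam_max = float(np.max(np.abs(Xs.T @ y)) / (n * max(alpha, 1e-3)))
    if lam_max <= 0:
        lam_max = 1e-3
    return np.geomspace(lam_max, min_ratio * lam_max, n_lambda)


def _en_path(aw, bw, lams, alpha, intercept_col=None):
    """Warm-started elastic-net fits along a descending lambda path."""
    aw = np.asarray(aw, dtype=float).ravel()
    bw = np.asarray(bw, dtype=float)
    n = aw.size
    c = np.ones(n) if intercept_col is None else np.asarray(intercept_col, dtype=float)
    y, X = _project_out(c, aw, bw)
    Xs, scale = _standardize(X)
    sk = _SkElasticNet(alpha=lams[0], l1_ratio=alpha, fit_intercept=False,
                       max_iter=10000, tol=1e-8, warm_start=True)
    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for lam in lams:
            sk.set_params(alpha=lam)
            sk.fit(Xs, y)
            beta = sk.coef_ / scale
            beta0 = float(c @ (aw - bw @ beta) / (c @ c))
            out.append((beta0, beta.copy()))
    return out


# ------------------------------------------------------------ model fits

def fit_en(A, B, design: SpatialDesign = None, lam: float = None,
           alpha: float = DEFAULT_ALPHA) -> PenGLSFit:
    """Plain elastic net (no spatial correction)."""
    A = np.asarray(A, dtype=float).ravel()
    B = np.asarray(B, dtype=float)
    if lam is None:
        raise ValueError("lam is required; use tune_lambda to choose it")
    beta0, beta = elastic_net(A, B, lam, alpha)
    return PenGLSFit(beta0, beta, lam, alpha, cov_params=None, n_iter=1,
                     converged=True, method="EN")


def fit_pengls(A, B, design: SpatialDesign, lam: float,
               alpha: float = DEFAULT_ALPHA, max_iter: int = 30,
               tol: float = PRED_TOL, method: str = "REML",
               init_cov: GaussCovParams = None) -> PenGLSFit:
    """Iterative GLS elastic net.

    Alternates elastic-net fits on W-whitened data with REML
    re-estimation of the Gaussian-decay covariance from the residuals
    (intercept-only mean model: the selected support changes between
    iterations and conditioning the REML on it would bias sigma2).
    Starts at Sigma = identity unless ``init_cov`` warm-starts the
    covariance (an internal speed-up for path fits). Non-convergence is
    reported via ``converged=False``, never raised; a covariance
    estimation failure is.
    """
    A = np.asarray(A, dtype=float).ravel()
    B = np.asarray(B, dtype=float)
    n = A.size
    ones = np.ones(n)
    cov = init_cov
    if cov is None:
        beta0, beta = elastic_net(A, B, lam, alpha)  # Sigma = I start: plain EN
        start_iter = 1
    else:
        beta0, beta = None, None
        start_iter = 0
    preds = None if beta is None else beta0 + B @ beta
    trace = []
    converged = False
    n_iter = start_iter
    for it in range(start_iter, max_iter):
        if preds is not None:
            resid = A - preds
            cov = fit_cov_params(resid, ones[:, None], design, method=method).params
        # whiten by the correlation factor (unit diagonal): the overall
        # variance scale would only rescale the quadratic term against the
        # fixed penalty, de-calibrating lambda between iterations and
        # against the plain elastic net
        W = whitening_factor(cov.correlation(design))
        beta0, beta = elastic_net(W @ A, W @ B, lam, alpha, intercept_col=W @ ones)
        new_preds = beta0 + B @ beta
        n_iter = it + 1
        if preds is not None:
            delta = float(np.mean((new_preds - preds) ** 2))
            trace.append(delta)
            preds = new_preds
            if delta < tol:
                converged = True
                break
        else:
            preds = new_preds
    else:
        logger.info("pengls reached max_iter=%d without convergence", max_iter)
    return PenGLSFit(beta0, beta, lam, alpha, cov_params=cov, n_iter=n_iter,
                     converged=converged, method="penGLS", trace=trace)


def moran_eigenvectors(design: SpatialDesign, proximity: str = "exp",
                       threshold: float = 0.25) -> np.ndarray:
    """Spatial eigenvectors of the doubly-centered proximity matrix.

    Builds C with c_ij = exp(-d_ij / d_bar) (d_bar the average
    nearest-neighbor distance, c_ii = 0), double-centers it as M C M
    with M = I - 11'/n, and returns the eigenvectors whose eigenvalue
    exceeds ``threshold`` times the largest one. Columns are orthonormal
    and orthogonal to the constant vector; leading columns carry the
    strongest positive spatial autocorrelation.
    """
    n = design.n
    if n < 3:
        raise ValueError("need at least three locations")
    D = design.distance_matrix
    off = ~np.eye(n, dtype=bool)
    if proximity != "exp":
        raise ValueError("only the 'exp' proximity rule is implemented")
    d_nn = np.where(off, D, np.inf).min(axis=1)
    d_bar = float(d_nn.mean())
    C = np.exp(-D / d_bar)
    np.fill_diagonal(C, 0.0)
    M = np.eye(n) - np.full((n, n), 1.0 / n)
    MCM = M @ C @ M
    w, U = np.linalg.eigh((MCM + MCM.T) / 2.0)
    w, U = w[::-1], U[:, ::-1]
    if w[0] <= 0:
        logger.info("no positive eigenvalue in the centered proximity matrix")
        return np.empty((n, 0))
    keep = w > threshold * w[0]
    if not keep.any():
        logger.info("no eigenvalue above threshold %.3g of the maximum", threshold)
    return U[:, keep]


def fit_en_eigen(A, B, design: SpatialDesign, lam: float,
                 alpha: float = DEFAULT_ALPHA,
                 threshold: float = 0.25) -> PenGLSFit:
    """Elastic net with Moran eigenvectors as extra regressors.

    The eigenvectors absorb smooth spatial trends during fitting but are
    excluded from the selected-feature set and from prediction.
    """
    A = np.asarray(A, dtype=float).ravel()
    B = np.asarray(B, dtype=float)
    E = moran_eigenvectors(design, threshold=threshold)
    q = E.shape[1]
    beta0, coefs = elastic_net(A, np.column_stack([B, E]) if q else B, lam, alpha)
    beta = coefs[: B.shape[1]]
    fit = PenGLSFit(beta0, beta, lam, alpha, cov_params=None, n_iter=1,
                    converged=True, method="EN+eigen", n_eigenvectors=q)
    return fit


# ------------------------------------------------------------ tuning

_FITTERS = {"en": fit_en, "pengls": fit_pengls, "en_eigen": fit_en_eigen}


def _path_fits(method, A, B, design, lams, alpha):
    """Per-lambda fits along a descending path for one training set."""
    if method == "en":
        return _en_path(A, B, lams, alpha)
    if method == "en_eigen":
        E = moran_eigenvectors(design)
        q = E.shape[1]
        BE = np.column_stack([B, E]) if q else B
        return [(b0, b[: B.shape[1]]) for b0, b in _en_path(A, BE, lams, alpha)]
    if method == "pengls":
        out = []
        cov = None
        for lam in lams:
            fit = fit_pengls(A, B, design, lam, alpha, init_cov=cov)
            cov = fit.cov_params
            out.append((fit.beta0, fit.beta))
        return out
    raise ValueError(f"unknown method {method!r}")


def tune_lambda(A, B, design: SpatialDesign, folds: FoldAssignment,
                alpha: float = DEFAULT_ALPHA, method: str = "en",
                full_output: bool = False):
    """Choose the penalty by cross-validation and the one-SE rule.

    Computes held-out centered R-squared per lambda on a descending
    path, then returns the largest lambda whose mean CV R-squared is at
    least the best mean minus the standard error at the best lambda.
    """
    if folds.k < 2:
        raise ValueError("need at least two folds")
    A = np.asarray(A, dtype=float).ravel()
    B = np.asarray(B, dtype=float)
    lams = lambda_path(A, B, alpha)
    scores = np.full((folds.k, lams.size), np.nan)
    for f, (train, test) in enumerate(folds.split()):
        sub_design = design.subset(train)
        try:
            fits = _path_fits(method, A[train], B[train], sub_design, lams, alpha)
        except (CovarianceEstimationError, np.linalg.LinAlgError) as e:
            logger.warning("fold %d failed along the whole path: %s", f, e)
            scores[f] = 0.0  # failed fits score 0
            continue
        for i, (b0, b) in enumerate(fits):
            scores[f, i] = r_squared_centered(A[test], b0 + B[test] @ b)
    if np.isnan(scores).all():
        raise RuntimeError("cross-validation failed for every lambda")
    mean = np.nanmean(scores, axis=0)
    se = np.nanstd(scores, axis=0, ddof=1) / np.sqrt(folds.k)
    best = int(np.nanargmax(mean))
    thr = mean[best] - se[best]
    chosen = next(i for i in range(lams.size) if mean[i] >= thr)
    if full_output:
        return float(lams[chosen]), {"lambdas": lams, "mean": mean, "se": se,
                                     "best_index": best, "chosen_index": chosen}
    return float(lams[chosen])


# ------------------------------------------------------------ model class

class SpatialElasticNet:
    """statsmodels-style front end for the penalized spatial fits.

    ``variant`` selects plain ``"en"``, the iterative ``"pengls"`` or
    the Moran-eigenvector ``"en_eigen"`` estimator. ``fit(lam=...)``
    fits at a fixed penalty; ``fit(folds=...)`` tunes it first by the
    one-standard-error CV rule.
    """

    def __init__(self, endog, exog, design: SpatialDesign,
                 alpha: float = DEFAULT_ALPHA, variant: str = "pengls"):
        if variant not in _FITTERS:
            raise ValueError(f"variant must be one of {sorted(_FITTERS)}")
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.asarray(exog, dtype=float)
        self.design = design
        self.alpha = alpha
        self.variant = variant

    @classmethod
    def from_dataframe(cls, df, grid_size=None, outcome: str = "A", **kw):
        coords = df[["x", "y"]].to_numpy()
        G = grid_size or int(coords.max())
        bcols = [c for c in df.columns if c.startswith("B_")]
        return cls(df[outcome].to_numpy(), df[bcols].to_numpy(),
                   SpatialDesign(G, coords), **kw)

    def fit(self, lam: float = None, folds: FoldAssignment = None,
            **kw) -> PenGLSFit:
        if lam is None:
            if folds is None:
                raise ValueError("provide lam or folds for tuning")
            lam = tune_lambda(self.endog, self.exog, self.design, folds,
                              alpha=self.alpha, method=self.variant)
        fitter = _FITTERS[self.variant]
        if self.variant == "en":
            return fitter(self.endog, self.exog, self.design, lam=lam,
                          alpha=self.alpha)
        return fitter(self.endog, self.exog, self.design, lam, alpha=self.alpha, **kw)
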