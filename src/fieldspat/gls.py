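"""OLS baseline and iterative GLS with a Gaussian-decay error covariance.

The GLS estimator alternates between (i) estimating the spatial
covariance structure of the residuals by profiled (RE)ML and (ii) a
least-squares fit on outcome and design premultiplied by the inverse
square-root factor of that covariance (whitening), until the fitted
values stabilize. Predictions on new data use only the mean part
beta0 + B_new @ beta — the spatial error term is a training-field
nuisance and is never extrapolated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .covariance import (
    CovarianceEstimationError,
    GaussCovParams,
    fit_cov_params,
)
from .design import SpatialDesign

__all__ = [
    "SpatialGLS",
    "SpatialGLSResults",
    "fit_ols",
    "fit_gls",
    "wald_test",
    "add_row_col_dummies",
    "RankDeficientError",
]

logger = logging.getLogger(__name__)


class RankDeficientError(ValueError):
    """Design matrix is rank deficient; names the collinear columns."""


def _check_full_rank(X: np.ndarray):
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns incrementally
        bad = []
        kept = np.empty((X.shape[0], 0))
        for j in range(X.shape[1]):
            cand = np.column_stack([kept, X[:, j]])
            if np.linalg.matrix_rank(cand) > kept.shape[1]:
                kept = cand
            else:
                bad.append(j)
        raise RankDeficientError(
            f"design matrix rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns (0-based, incl. intercept): {bad}"
        )


@dataclass
class SpatialGLSResults:
    """Fitted GLS (or OLS) model.

    ``params`` holds the intercept first, then the regressor
    coefficients; ``bse`` the matching standard errors. ``cov_params``
    are the fitted spatial covariance parameters (tau = 1 for OLS).
    """

    params: np.ndarray
    bse: np.ndarray
    cov_params: GaussCovParams
    n_iter: int
    converged: bool
    loglik: float
    df_resid: int
    nobs: int
    method: str
    cov_failed: bool = False
    fittedvalues: np.ndarray = field(default=None, repr=False)
    resid: np.ndarray = field(default=None, repr=False)

    @property
    def tvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.t.sf(np.abs(self.tvalues), self.df_resid)

    def predict(self, exog_new) -> np.ndarray:
        """Mean-part prediction beta0 + B_new @ beta (no spatial term)."""
        B = np.atleast_2d(np.asarray(exog_new, dtype=float))
        p = self.params.size - 1
        if B.shape[1] != p:
            raise ValueError(f"expected {p} regressor columns, got {B.shape[1]}")
        return self.params[0] + B @ self.params[1:]

    def wald_test(self, j: int) -> float:
        """Two-sided p-value for regressor j (0-based, intercept excluded)."""
        p = self.params.size - 1
        if not 0 <= j < p:
            raise IndexError(f"regressor index {j} out of range 0..{p - 1}")
        return float(self.pvalues[j + 1])

    def summary(self) -> str:
        cp = self.cov_params
        lines = [
            f"{'Spatial GLS' if self.method != 'OLS' else 'OLS'} regression results",
            f"  nobs: {self.nobs}   df_resid: {self.df_resid}   "
            f"loglik: {self.loglik:.3f}",
            f"  covariance: sigma2={cp.sigma2:.4g}  "
            f"r={'-' if cp.r is None else format(cp.r, '.4g')}  tau={cp.tau:.4g}"
            f"   ({self.method}, {self.n_iter} iter, "
            f"{'converged' if self.converged else 'NOT converged'})",
            f"  {'':<10}{'coef':>12}{'se':>12}{'t':>10}{'P>|t|':>10}",
        ]
        names = ["intercept"] + [f"B_{j + 1}" for j in range(self.params.size - 1)]
        for name, b, s, t, pv in zip(names, self.params, self.bse, self.tvalues,
                                     self.pvalues):
            lines.append(f"  {name:<10}{b:>12.5f}{s:>12.5f}{t:>10.3f}{pv:>10.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "params": self.params.tolist(),
            "bse": self.bse.tolist(),
            "pvalues": self.pvalues.tolist(),
            "cov_params": self.cov_params.to_dict(),
            "n_iter": self.n_iter,
            "converged": self.converged,
            "loglik": self.loglik,
            "method": self.method,
            "cov_failed": self.cov_failed,
        }


class SpatialGLS:
    """Model object for GLS with Gaussian covariance decay.

    Parameters
    ----------
    endog : (n,) outcome vector A.
    exog : (n, p) regressor matrix B (no intercept column; one is added).
    design : SpatialDesign with the observation coordinates.
    method : "REML" (default) or "ML" for the covariance estimation.
    """

    def __init__(self, endog, exog, design: SpatialDesign, method: str = "REML"):
        self.endog = np.asarray(endog, dtype=float).ravel()
        exog = np.asarray(exog, dtype=float)
        if exog.ndim == 1:
            exog = exog[:, None]
        self.exog = exog
        self.design = design
        self.method = method.upper()
        n, p = exog.shape
        if self.endog.size != n or design.n != n:
            raise ValueError("endog, exog and design are not aligned")
        if n <= p + 1:
            raise ValueError(f"need n > p+1 observations (n={n}, p={p})")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, grid_size: Optional[int] = None,
                       outcome: str = "A", **kw) -> "SpatialGLS":
        """Build from a table with columns x, y, A, B_1..B_p."""
        coords = df[["x", "y"]].to_numpy()
        G = grid_size or int(coords.max())
        bcols = [c for c in df.columns if c.startswith("B_")]
        design = SpatialDesign(G, coords)
        return cls(df[outcome].to_numpy(), df[bcols].to_numpy(), design, **kw)

    def fit(self, tol: float = 1e-6, max_iter: int = 25,
            fallback_to_ols: bool = True) -> SpatialGLSResults:
        """Iterate covariance estimation and whitened least squares.

        Convergence when the mean squared change in fitted values drops
        below ``tol``. On covariance-estimation failure the OLS fit is
        returned with ``cov_failed=True`` (the benchmark layer treats
        such runs as method failures).
        """
        y, B, design = self.endog, self.exog, self.design
        X = np.column_stack([np.ones(len(y)), B])
        _check_full_rank(X)
        ols = sm.OLS(y, X).fit()
        preds = np.asarray(ols.fittedvalues)
        cov_fit = None
        n_iter = 0
        converged = False
        for n_iter in range(1, max_iter + 1):
            try:
                cov_fit = fit_cov_params(y, X, design, method=self.method)
            except (CovarianceEstimationError, np.linalg.LinAlgError) as e:
                if not fallback_to_ols:
                    raise
                logger.warning("covariance estimation failed (%s); falling back to OLS", e)
                res = fit_ols(y, B)
                res.cov_failed = True
                return res
            V = cov_fit.params.correlation(design)
            gls = sm.GLS(y, X, sigma=V).fit()
            new_preds = np.asarray(gls.fittedvalues)
            delta = float(np.mean((new_preds - preds) ** 2))
            preds = new_preds
            if delta < tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"GLS did not converge in {max_iter} iterations", RuntimeWarning
            )
        return SpatialGLSResults(
            params=np.asarray(gls.params),
            bse=np.asarray(gls.bse),
            cov_params=cov_fit.params,
            n_iter=n_iter,
            converged=converged,
            loglik=cov_fit.loglik,
            df_resid=int(gls.df_resid),
            nobs=len(y),
            method=self.method,
            fittedvalues=preds,
            resid=y - preds,
        )


def fit_ols(A, B) -> SpatialGLSResults:
    """Ordinary least squares with classical standard errors.

    Returned as a degenerate spatial fit: pure-nugget covariance
    (tau = 1, no range).
    """
    y = np.asarray(A, dtype=float).ravel()
    Bm = np.asarray(B, dtype=float)
    if Bm.ndim == 1:
        Bm = Bm[:, None]
    X = np.column_stack([np.ones(len(y)), Bm])
    if len(y) <= X.shape[1]:
        raise ValueError(f"need n > p+1 observations (n={len(y)}, p={Bm.shape[1]})")
    _check_full_rank(X)
    res = sm.OLS(y, X).fit()
    return SpatialGLSResults(
        params=np.asarray(res.params),
        bse=np.asarray(res.bse),
        cov_params=GaussCovParams(sigma2=float(res.scale), r=None, tau=1.0),
        n_iter=1,
        converged=True,
        loglik=float(res.llf),
        df_resid=int(res.df_resid),
        nobs=len(y),
        method="OLS",
        fittedvalues=np.asarray(res.fittedvalues),
        resid=np.asarray(res.resid),
    )


def fit_gls(A, B, design: SpatialDesign, method: str = "REML", **fit_kw) -> SpatialGLSResults:
    """Functional wrapper around :class:`SpatialGLS`."""
    return SpatialGLS(A, B, design, method=method).fit(**fit_kw)


def wald_test(fit: SpatialGLSResults, j: int) -> float:
    """Two-sided Wald p-value for regressor j (0-based)."""
    return fit.wald_test(j)


def add_row_col_dummies(B, design: SpatialDesign):
    """Append row/column indicator dummies for checkerboard analyses.

    One indicator per grid row 2..G and column 2..G that is present in
    the sample (row 1 / column 1 are the reference levels; absent levels
    are dropped with a log note). Returns ``(augmented_matrix, names)``.
    """
    Bm = np.asarray(B, dtype=float)
    if Bm.ndim == 1:
        Bm = Bm[:, None]
    x = design.coords[:, 0].astype(int)
    y = design.coords[:, 1].astype(int)
    cols, names = [], []
    for level_values, label in ((x, "row"), (y, "col")):
        present = np.unique(level_values)
        for lev in range(2, design.grid_size + 1):
            if lev not in present:
                logger.info("dropping %s level %d with zero observations", label, lev)
                continue
            cols.append((level_values == lev).astype(float))
            names.append(f"{label}_{lev}")
    if cols:
        return np.column_stack([Bm] + cols), names
    return Bm, names
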