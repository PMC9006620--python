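"""Gaussian-decay spatial covariance: construction, whitening, estimation.

The error covariance model is

    Sigma(sigma2, r, tau) = sigma2 * (tau * I + (1 - tau) * K(r)),
    K(r)_ik = exp(-(d_ik / r)^2),

with residual variance sigma2 > 0, range r > 0 (the distance scale of the
correlation decay) and nugget tau in [0, 1] (the spatially uncorrelated
variance fraction). Parameters are estimated by maximum likelihood or
restricted maximum likelihood (REML, the default) with sigma2 profiled
out analytically.

A key computational identity: for a fixed range r the correlation matrix
V = tau*I + (1-tau)*K(r) shares its eigenvectors with K(r), so a single
eigendecomposition per candidate r makes the profile likelihood in tau a
cheap one-dimensional problem. The optimizer therefore sweeps a grid over
r (each point solving an inner bounded search in tau) and then refines
the best r — a global strategy over the full (r, tau) box, which matters
because the likelihood surface is ill-posed and multimodal: range,
nugget and variance estimates are strongly correlated and individually
very variable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .design import SpatialDesign

__all__ = [
    "GaussCovParams",
    "CovarianceFit",
    "build_sigma",
    "whitening_factor",
    "neg_log_likelihood",
    "fit_cov_params",
    "SingularCovarianceError",
    "CovarianceEstimationError",
]

TAU_BOUNDS = (1e-4, 1.0 - 1e-4)
R_LOWER = 0.1
LOG2PI = np.log(2.0 * np.pi)


class SingularCovarianceError(np.linalg.LinAlgError):
    """Covariance matrix has an eigenvalue below tolerance."""


class CovarianceEstimationError(RuntimeError):
    """Likelihood optimization failed; carries the evaluation trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []


@dataclass(frozen=True)
class GaussCovParams:
    """(sigma2, r, tau) of the Gaussian-decay covariance model.

    ``r=None`` denotes the degenerate pure-nugget model (tau = 1,
    independent errors), used e.g. for OLS fits.
    """

    sigma2: float
    r: Optional[float]
    tau: float

    def __post_init__(self):
        if not self.sigma2 >= 0:
            raise ValueError("sigma2 must be non-negative")
        if self.r is not None and not self.r > 0:
            raise ValueError("range r must be positive")
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError("nugget tau must lie in [0, 1]")

    def correlation(self, design: SpatialDesign) -> np.ndarray:
        """Correlation matrix tau*I + (1-tau)*K(r) (unit diagonal)."""
        n = design.n
        if self.r is None or self.tau == 1.0:
            return np.eye(n)
        K = np.exp(-((design.distance_matrix / self.r) ** 2))
        return self.tau * np.eye(n) + (1.0 - self.tau) * K

    def to_dict(self) -> dict:
        return {"sigma2": float(self.sigma2), "r": None if self.r is None else float(self.r),
                "tau": float(self.tau)}


@dataclass(frozen=True)
class CovarianceFit:
    """Converged covariance parameters plus the achieved log-likelihood."""

    params: GaussCovParams
    loglik: float
    method: str
    n_evals: int


def build_sigma(params: GaussCovParams, design: SpatialDesign) -> np.ndarray:
    """Covariance matrix sigma2 * (tau*I + (1-tau)*K(r)) at the design points."""
    D = design.distance_matrix
    if np.any(D[~np.eye(design.n, dtype=bool)] <= 0):
        raise ValueError("duplicate locations: zero off-diagonal distance")
    return params.sigma2 * params.correlation(design)


def whitening_factor(sigma: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Symmetric inverse square root W with W @ sigma @ W.T = I.

    Raises :class:`SingularCovarianceError` when the smallest eigenvalue
    falls below ``tol`` times the largest.
    """
    sigma = np.asarray(sigma, dtype=float)
    w, U = np.linalg.eigh((sigma + sigma.T) / 2.0)
    if w[0] < tol * w[-1] or w[-1] <= 0:
        raise SingularCovarianceError(
            f"covariance numerically singular (eigenvalue ratio {w[0] / w[-1]:.3e})"
        )
    return (U / np.sqrt(w)) @ U.T


def _as_design_matrix(X, n: int):
    if X is None:
        return None
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != n:
        X = X.T
    if X.shape[0] != n:
        raise ValueError("design matrix not aligned with outcome")
    return X


def neg_log_likelihood(params: GaussCovParams, outcome, design_matrix, design: SpatialDesign,
                       method: str = "ML") -> float:
    """Negative Gaussian (restricted) log-likelihood at the given parameters.

    The mean coefficients are profiled (GLS estimate under ``params``);
    sigma2 is *not* profiled — it is taken from ``params``. With
    ``design_matrix=None`` the mean is fixed at zero and REML reduces to
    ML. Implemented by dense Cholesky, independently of the fast
    eigen-profiled objective used inside :func:`fit_cov_params`.
    """
    y = np.asarray(outcome, dtype=float).ravel()
    n = y.size
    X = _as_design_matrix(design_matrix, n)
    sigma = build_sigma(params, design)
    try:
        c, low = cho_factor(sigma)
    except np.linalg.LinAlgError as e:  # pragma: no cover - guarded upstream
        raise SingularCovarianceError(str(e)) from e
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    if X is not None and X.size:
        Si_X = cho_solve((c, low), X)
        G = X.T @ Si_X
        beta = np.linalg.solve(G, Si_X.T @ y)
        resid = y - X @ beta
    else:
        resid = y
    quad = resid @ cho_solve((c, low), resid)
    nll = 0.5 * (n * LOG2PI + logdet + quad)
    if method.upper() == "REML" and X is not None and X.size:
        q = X.shape[1]
        sign, logdetG = np.linalg.slogdet(G)
        if sign <= 0:
            raise np.linalg.LinAlgError("X' Sigma^-1 X not positive definite")
        nll += 0.5 * (logdetG - q * LOG2PI)
    return float(nll)


#: logit-spaced nugget grid over the admissible interval
_TAU_GRID = 1.0 / (1.0 + np.exp(-np.linspace(np.log(TAU_BOUNDS[0] / (1 - TAU_BOUNDS[0])),
                                             np.log(TAU_BOUNDS[1] / (1 - TAU_BOUNDS[1])),
                                             31)))


def _eig_for_r(design: SpatialDesign, r: float):
    """Eigendecomposition of K(r), cached on the design.

    K(r) and tau*I + (1-tau)*K(r) share eigenvectors, so one
    decomposition per candidate range serves every nugget value; for
    repeated fits on the same design (the lambda path of the penalized
    fits) grid ranges hit the cache.
    """
    cache = design._dist
    key = ("eig", round(float(r), 9))
    if key not in cache:
        K = np.exp(-((design.distance_matrix / r) ** 2))
        cache[key] = np.linalg.eigh(K)
    return cache[key]


def _profile_tau_at_r(r, design, y, X, q, method):
    """min over the tau grid of the profiled objective at range r.

    Returns (objective, tau, sigma2_hat) at the grid optimum after a
    parabolic refinement step on the logit-tau scale. The objective is
    the negative profile log-likelihood minus its dof/2*log(2pi)
    constant.
    """
    n = y.size
    lam, U = _eig_for_r(design, r)
    yt = U.T @ y
    Xt = U.T @ X if q else None
    dof = n - q if method == "REML" else n

    def obj(tau_arr):
        vals = np.full(len(tau_arr), np.inf)
        s2s = np.zeros(len(tau_arr))
        V = np.clip(tau_arr[None, :] + (1.0 - tau_arr[None, :]) * lam[:, None],
                    1e-12, None)  # (n, T)
        logdetV = np.log(V).sum(axis=0)
        if q == 1:
            x = Xt[:, 0]
            a = ((x * x)[:, None] / V).sum(axis=0)
            b = ((x * yt)[:, None] / V).sum(axis=0)
            c = ((yt * yt)[:, None] / V).sum(axis=0)
            quad = c - b * b / a
            ok = (quad > 0) & (a > 0)
            s2s[ok] = quad[ok] / dof
            vals[ok] = dof * np.log(s2s[ok]) + logdetV[ok] + dof
            if method == "REML":
                vals[ok] += np.log(a[ok])
        else:
            for t in range(len(tau_arr)):
                v = V[:, t]
                if q:
                    XtW = Xt / v[:, None]
                    G = Xt.T @ XtW
                    try:
                        beta = np.linalg.solve(G, XtW.T @ yt)
                    except np.linalg.LinAlgError:
                        continue
                    rt = yt - Xt @ beta
                else:
                    rt = yt
                quad = float(rt @ (rt / v))
                if quad <= 0:
                    continue
                s2s[t] = quad / dof
                vals[t] = dof * np.log(s2s[t]) + logdetV[t] + dof
                if method == "REML" and q:
                    sign, logdetG = np.linalg.slogdet(G)
                    if sign <= 0:
                        vals[t] = np.inf
                        continue
                    vals[t] += logdetG
        return vals, s2s

    vals, s2s = obj(_TAU_GRID)
    if not np.isfinite(vals).any():
        return np.inf, np.nan, np.nan
    i = int(np.argmin(vals))
    tau, val, s2 = _TAU_GRID[i], vals[i], s2s[i]
    # parabolic refinement on the (equispaced) logit scale
    if 0 < i < len(_TAU_GRID) - 1 and np.isfinite(vals[i - 1:i + 2]).all():
        f_m, f_0, f_p = vals[i - 1:i + 2]
        denom = f_m - 2 * f_0 + f_p
        if denom > 0:
            logit = np.log(_TAU_GRID / (1 - _TAU_GRID))
            h = logit[1] - logit[0]
            shift = 0.5 * h * (f_m - f_p) / denom
            tau_ref = 1.0 / (1.0 + np.exp(-(logit[i] + shift)))
            v_ref, s_ref = obj(np.array([tau_ref]))
            if v_ref[0] < val:
                tau, val, s2 = tau_ref, v_ref[0], s_ref[0]
    return 0.5 * float(val), float(tau), float(s2)


def fit_cov_params(outcome, design_matrix, design: SpatialDesign, method: str = "REML",
                   n_r_grid: int = 10) -> CovarianceFit:
    """Estimate (sigma2, r, tau) by profiled (RE)ML.

    ``design_matrix`` holds the mean-model columns (typically an
    intercept plus regressors); its coefficients are profiled out of the
    likelihood, as is sigma2. The range r is searched on a log-spaced
    grid over [0.1, 2 * max pairwise distance] (with the nugget
    profiled on a fine grid per candidate, see module docstring) and
    refined by parabolic interpolation on the log scale — a global
    search over the whole (r, tau) box, robust to the multimodality of
    this likelihood.
    """
    method = method.upper()
    if method not in ("ML", "REML"):
        raise ValueError("method must be 'ML' or 'REML'")
    y = np.asarray(outcome, dtype=float).ravel()
    n = y.size
    X = _as_design_matrix(design_matrix, n)
    q = 0 if X is None else X.shape[1]
    if n <= q or n < 2:
        raise CovarianceEstimationError(
            f"need more observations (n={n}) than mean parameters (q={q})"
        )
    D = design.distance_matrix
    r_hi = 2.0 * float(D.max())
    trace = []

    def solve_at_r(r):
        val, tau, s2 = _profile_tau_at_r(float(r), design, y, X, q, method)
        trace.append((float(r), tau, val))
        return val, tau, s2

    r_grid = np.geomspace(R_LOWER, r_hi, n_r_grid)
    sols = [solve_at_r(r) for r in r_grid]
    objs = np.array([s[0] for s in sols])
    if not np.isfinite(objs).any():
        raise CovarianceEstimationError("likelihood not finite anywhere on the r grid",
                                        trace)
    i = int(np.argmin(objs))
    r_hat, (obj, tau_hat, s2_hat) = float(r_grid[i]), sols[i]
    # parabolic refinement of log r between the neighbours of the grid optimum
    if 0 < i < len(r_grid) - 1 and np.isfinite(objs[i - 1:i + 2]).all():
        f_m, f_0, f_p = objs[i - 1:i + 2]
        denom = f_m - 2 * f_0 + f_p
        if denom > 0:
            h = np.log(r_grid[1] / r_grid[0])
            r_ref = float(np.exp(np.log(r_grid[i]) + 0.5 * h * (f_m - f_p) / denom))
            sol_ref = solve_at_r(r_ref)
            if sol_ref[0] < obj:
                r_hat, (obj, tau_hat, s2_hat) = r_ref, sol_ref
    if not np.isfinite(obj) or not np.isfinite(tau_hat):
        raise CovarianceEstimationError("profile likelihood undefined at optimum", trace)
    dof = n - q if method == "REML" else n
    # the profiled objective omits the constant dof/2*log(2pi); restore it so
    # the returned loglik matches -neg_log_likelihood at the fitted parameters
    loglik = -(obj + 0.5 * dof * LOG2PI)
    params = GaussCovParams(sigma2=float(s2_hat), r=r_hat, tau=float(tau_hat))
    return CovarianceFit(params=params, loglik=float(loglik), method=method,
                         n_evals=len(trace))
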