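"""The four spatial structures used to generate field-trial variables.

A variable on the field is drawn from a multivariate normal whose mean
surface and/or covariance carries the spatial structure:

* ``none``     — flat mean, independent errors: f = 0, Sigma = sigma2 * I.
* ``linear``   — a linear gradient in the mean: f(x, y) = x*g1 + y*g2 with
  the gradient components drawn uniformly on [-0.5, 0.5].
* ``edge``     — observations near the field border differ:
  f(x, y) = beta_edge * d_edge(x, y), beta_edge ~ N(0, 50).
* ``gaussCor`` — flat mean but correlation decaying as a bell curve:
  Sigma = sigma2 * (tau * I + (1 - tau) * Sgauss),
  Sgauss_ik = exp(-(d_ik / r)^2), range r and nugget tau.

The linear and edge structures add variance to a variable; gaussCor
redistributes it spatially without increasing the marginal variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .design import SpatialDesign, edge_distance

__all__ = ["ScenarioSpec", "mean_surface", "covariance_matrix", "draw_variable", "STRUCTURES"]

STRUCTURES = ("none", "linear", "edge", "gaussCor")

#: standard deviation of the edge coefficient (variance 50)
EDGE_COEF_SD = np.sqrt(50.0)
#: half-width of the uniform distribution of gradient components
GRADIENT_HALF_WIDTH = 0.5


@dataclass(frozen=True)
class ScenarioSpec:
    """Spatial structure label plus its parameters.

    ``gamma`` (linear) and ``beta_edge`` (edge) may be left as None, in
    which case a fresh value is drawn for every realization — each
    simulated variable gets its own independent gradient / edge
    coefficient.
    """

    structure: str = "none"
    gamma: Optional[tuple] = None
    beta_edge: Optional[float] = None
    r: float = 7.5
    tau: float = 0.25
    sigma2: float = 1.0

    def __post_init__(self):
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}; choose from {STRUCTURES}")
        if self.gamma is not None:
            if self.structure != "linear":
                raise ValueError("gamma is only meaningful for the linear structure")
            object.__setattr__(self, "gamma", tuple(float(g) for g in self.gamma))
            if len(self.gamma) != 2:
                raise ValueError("gamma must have two components")
        if self.beta_edge is not None and self.structure != "edge":
            raise ValueError("beta_edge is only meaningful for the edge structure")
        if not self.r > 0:
            raise ValueError("range r must be positive")
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError("nugget tau must lie in [0, 1]")
        if not self.sigma2 > 0:
            raise ValueError("sigma2 must be positive")

    # -- convenience constructors ------------------------------------
    @classmethod
    def none(cls, sigma2: float = 1.0) -> "ScenarioSpec":
        return cls("none", sigma2=sigma2)

    @classmethod
    def linear(cls, gamma=None, sigma2: float = 1.0) -> "ScenarioSpec":
        return cls("linear", gamma=gamma, sigma2=sigma2)

    @classmethod
    def edge(cls, beta_edge=None, sigma2: float = 1.0) -> "ScenarioSpec":
        return cls("edge", beta_edge=beta_edge, sigma2=sigma2)

    @classmethod
    def gauss_cor(cls, r: float = 7.5, tau: float = 0.25, sigma2: float = 1.0) -> "ScenarioSpec":
        return cls("gaussCor", r=r, tau=tau, sigma2=sigma2)

    def with_structure_none(self) -> "ScenarioSpec":
        """Same residual variance, spatial structure removed."""
        return ScenarioSpec("none", sigma2=self.sigma2)

    def to_dict(self) -> dict:
        return {
            "structure": self.structure,
            "gamma": list(self.gamma) if self.gamma is not None else None,
            "beta_edge": self.beta_edge,
            "r": self.r,
            "tau": self.tau,
            "sigma2": self.sigma2,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        return cls(**d)


def mean_surface(spec: ScenarioSpec, design: SpatialDesign, rng=None) -> np.ndarray:
    """Mean surface f(x, y) evaluated at the design locations.

    For the linear and edge structures with unspecified parameters, the
    gradient / edge coefficient is drawn from ``rng``.
    """
    n = design.n
    if spec.structure == "none":
        return np.zeros(n)
    if spec.structure == "linear":
        gamma = spec.gamma
        if gamma is None:
            if rng is None:
                raise ValueError("gamma unspecified and no rng provided")
            gamma = rng.uniform(-GRADIENT_HALF_WIDTH, GRADIENT_HALF_WIDTH, size=2)
        return design.coords @ np.asarray(gamma, dtype=float)
    if spec.structure == "edge":
        b = spec.beta_edge
        if b is None:
            if rng is None:
                raise ValueError("beta_edge unspecified and no rng provided")
            b = rng.normal(0.0, EDGE_COEF_SD)
        return b * edge_distance(design.coords, design.grid_size)
    raise ValueError(
        "gaussCor has no mean surface: its spatial structure lives in the covariance"
    )


def covariance_matrix(spec: ScenarioSpec, design: SpatialDesign) -> np.ndarray:
    """Covariance of a variable under the scenario, at the design points.

    none/linear/edge carry their structure in the mean, so their
    covariance is sigma2 * I. gaussCor returns
    sigma2 * (tau * I + (1 - tau) * exp(-(D / r)^2)).
    """
    n = design.n
    if spec.structure != "gaussCor":
        return spec.sigma2 * np.eye(n)
    D = design.distance_matrix
    K = np.exp(-((D / spec.r) ** 2))
    return spec.sigma2 * (spec.tau * np.eye(n) + (1.0 - spec.tau) * K)


def draw_variable(spec: ScenarioSpec, design: SpatialDesign, rng) -> np.ndarray:
    """One multivariate-normal realization of a variable under ``spec``.

    Sampling uses a symmetric eigenvalue factorization with a small
    eigenvalue floor (1e-10 * sigma2): Gaussian-decay covariances on
    dense grids are numerically near-singular.
    """
    mean = (
        np.zeros(design.n)
        if spec.structure == "gaussCor"
        else mean_surface(spec, design, rng)
    )
    sigma = covariance_matrix(spec, design)
    if spec.structure != "gaussCor":
        # diagonal covariance: draw directly
        return mean + np.sqrt(spec.sigma2) * rng.standard_normal(design.n)
    w, U = np.linalg.eigh(sigma)
    floor = 1e-10 * spec.sigma2
    if w.min() < -floor * 1e4:
        raise np.linalg.LinAlgError(
            f"covariance not PSD beyond tolerance (min eigenvalue {w.min():.3e})"
        )
    w = np.clip(w, floor, None)
    factor = U * np.sqrt(w)
    return mean + factor @ rng.standard_normal(design.n)
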