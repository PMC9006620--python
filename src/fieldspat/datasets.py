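"""Simulated field-trial datasets.

An outcome A and regressors B_1..B_p are drawn at sampled grid locations
as multivariate normals whose mean surface and/or covariance carry one
of the four spatial structures (none, linear, edge, gaussCor):

    B_j ~ MVN(f_bj(x, y), Sigma_b),      j = 1..p, independently
    A   ~ MVN(f_a(x, y) + B beta, Sigma_a)

Half of the regressors (by default) carry the regressor scenario's
spatial structure, the rest none; within each group 20% of the beta
components are nonzero, drawn N(0, beta_sd^2). Every spatially
structured variable draws its own gradient / edge coefficient / noise
realization, so regressors are mutually independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .design import SpatialDesign, checkerboard_treatment, sample_locations
from .scenarios import ScenarioSpec, draw_variable

__all__ = [
    "TrueModel",
    "SimulatedDataset",
    "simulate_observational",
    "simulate_checkerboard",
    "simulate_test_set",
    "write_dataset",
    "read_dataset",
]

#: grid used for test sets, giving spacing comparable to a size-100
#: sample from the 15x15 training grid
TEST_GRID_SIZE = 5
DEFAULT_TEST_N = 10


@dataclass(frozen=True)
class TrueModel:
    """Ground truth of a simulated dataset."""

    beta: np.ndarray
    spatial_flags: np.ndarray  # True where the regressor carries spatial structure
    outcome_scenario: ScenarioSpec
    regressor_scenario: ScenarioSpec

    def __post_init__(self):
        beta = np.asarray(self.beta, dtype=float).ravel()
        flags = np.asarray(self.spatial_flags, dtype=bool).ravel()
        if beta.size != flags.size:
            raise ValueError("beta and spatial_flags must have equal length")
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "spatial_flags", flags)

    @property
    def p(self) -> int:
        return self.beta.size

    @property
    def support(self) -> np.ndarray:
        """Indices of truly predictive regressors (nonzero beta)."""
        return np.flatnonzero(self.beta != 0.0)

    def to_dict(self) -> dict:
        return {
            "beta": self.beta.tolist(),
            "spatial_flags": self.spatial_flags.astype(int).tolist(),
            "outcome_scenario": self.outcome_scenario.to_dict(),
            "regressor_scenario": self.regressor_scenario.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrueModel":
        return cls(
            beta=np.asarray(d["beta"], dtype=float),
            spatial_flags=np.asarray(d["spatial_flags"], dtype=bool),
            outcome_scenario=ScenarioSpec.from_dict(d["outcome_scenario"]),
            regressor_scenario=ScenarioSpec.from_dict(d["regressor_scenario"]),
        )


@dataclass(frozen=True)
class SimulatedDataset:
    """Outcome, regressors, design and ground truth of one simulation."""

    design: SpatialDesign
    A: np.ndarray
    B: np.ndarray
    truth: TrueModel
    seed: Optional[int] = None

    def __post_init__(self):
        A = np.asarray(self.A, dtype=float).ravel()
        B = np.asarray(self.B, dtype=float)
        if B.ndim == 1:
            B = B[:, None]
        if A.size != self.design.n or B.shape[0] != self.design.n:
            raise ValueError("A/B rows not aligned with design coordinates")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "B", B)

    @property
    def n(self) -> int:
        return self.design.n

    @property
    def p(self) -> int:
        return self.B.shape[1]

    def subset(self, idx) -> "SimulatedDataset":
        idx = np.asarray(idx)
        return SimulatedDataset(self.design.subset(idx), self.A[idx], self.B[idx],
                                self.truth, self.seed)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"x": self.design.coords[:, 0].astype(int),
             "y": self.design.coords[:, 1].astype(int),
             "A": self.A}
        )
        for j in range(self.p):
            df[f"B_{j + 1}"] = self.B[:, j]
        return df


def _spatial_split(p: int, spatial_fraction: float) -> np.ndarray:
    """Boolean flags: the first round(spatial_fraction*p) regressors are spatial."""
    n_spatial = int(round(spatial_fraction * p))
    flags = np.zeros(p, dtype=bool)
    flags[:n_spatial] = True
    return flags


def _draw_beta(flags: np.ndarray, active_fraction: float, beta_sd: float,
               rng) -> np.ndarray:
    """20%-per-group (by default) nonzero beta components, N(0, beta_sd^2).

    The active set is drawn within the spatial and non-spatial groups
    separately, so exactly the same number of predictive regressors sits
    in each group and the expected spatial share of a perfect selector
    is 50%.
    """
    p = flags.size
    beta = np.zeros(p)
    for group in (np.flatnonzero(flags), np.flatnonzero(~flags)):
        if group.size == 0:
            continue
        k = int(round(active_fraction * group.size))
        active = rng.choice(group, size=k, replace=False)
        beta[active] = rng.normal(0.0, beta_sd, size=k)
    return beta


def simulate_observational(
    p: int,
    n: int,
    G: int = 15,
    outcome_spec: ScenarioSpec = ScenarioSpec.none(),
    regressor_spec: ScenarioSpec = ScenarioSpec.none(),
    beta_sd: float = 1.0,
    spatial_fraction: float = 0.5,
    active_fraction: float = 0.2,
    seed=0,
    beta=None,
) -> SimulatedDataset:
    """Simulate an observational dataset on a G x G grid.

    ``spatial_fraction`` of the p regressors follow ``regressor_spec``
    (independent realizations each), the rest are unstructured;
    ``active_fraction`` of each group's beta components are nonzero.
    Passing ``beta`` explicitly (scalar or length-p vector) overrides
    the random draw — used by the univariate null (beta=0) and
    alternative (beta ~ N(0, 0.25)) settings.
    """
    if p < 1:
        raise ValueError("need at least one regressor")
    if not (0.0 <= spatial_fraction <= 1.0 and 0.0 <= active_fraction <= 1.0):
        raise ValueError("spatial_fraction and active_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    design = sample_locations(G, n, rng)
    flags = _spatial_split(p, spatial_fraction)
    if beta is None:
        beta_vec = _draw_beta(flags, active_fraction, beta_sd, rng)
    else:
        beta_vec = np.broadcast_to(np.asarray(beta, dtype=float).ravel(), (p,)).copy()
    none_spec = regressor_spec.with_structure_none()
    B = np.column_stack([
        draw_variable(regressor_spec if flags[j] else none_spec, design, rng)
        for j in range(p)
    ])
    noise = draw_variable(outcome_spec, design, rng)
    A = B @ beta_vec + noise  # noise already includes the outcome mean surface
    truth = TrueModel(beta_vec, flags, outcome_spec, regressor_spec)
    return SimulatedDataset(design, A, B, truth,
                            seed=seed if np.isscalar(seed) else None)


def simulate_checkerboard(
    subplot_size: int,
    outcome_spec: ScenarioSpec = ScenarioSpec.none(),
    beta: float = 0.0,
    n: int = 100,
    G: int = 18,
    seed=0,
) -> SimulatedDataset:
    """Simulate a checkerboard-design experiment on a G x G grid.

    The single binary regressor is the treatment indicator of the
    alternating-subplot design; the outcome's spatial structure follows
    ``outcome_spec``. Sampling of the n observation cells is uniform
    without replacement over the grid.
    """
    rng = np.random.default_rng(seed)
    design = sample_locations(G, n, rng)
    treat = checkerboard_treatment(design.coords, subplot_size, G)
    noise = draw_variable(outcome_spec, design, rng)
    A = beta * treat + noise
    truth = TrueModel(np.array([beta]), np.array([False]), outcome_spec,
                      ScenarioSpec.none())
    return SimulatedDataset(design, A, treat[:, None], truth,
                            seed=seed if np.isscalar(seed) else None)


def simulate_test_set(truth: TrueModel, mode: str = "spatial",
                      n: int = DEFAULT_TEST_N, seed=0) -> SimulatedDataset:
    """Matched test set for a previously simulated training truth.

    ``mode='spatial'`` keeps the training structure types but draws
    fresh gradients / edge coefficients at locations sampled from a
    5x5 grid (similar spacing as the training sample); ``mode='none'``
    replaces every structure by independent noise.
    """
    if mode not in ("spatial", "none"):
        raise ValueError("mode must be 'spatial' or 'none'")
    if n > TEST_GRID_SIZE**2:
        raise ValueError(
            f"test sets live on a {TEST_GRID_SIZE}x{TEST_GRID_SIZE} grid; n={n} > "
            f"{TEST_GRID_SIZE**2}"
        )
    rng = np.random.default_rng(seed)
    design = sample_locations(TEST_GRID_SIZE, n, rng)
    if mode == "spatial":
        out_spec = truth.outcome_scenario
        reg_spec = truth.regressor_scenario
    else:
        out_spec = truth.outcome_scenario.with_structure_none()
        reg_spec = truth.regressor_scenario.with_structure_none()
    none_spec = reg_spec.with_structure_none()
    B = np.column_stack([
        draw_variable(reg_spec if truth.spatial_flags[j] else none_spec, design, rng)
        for j in range(truth.p)
    ])
    noise = draw_variable(out_spec, design, rng)
    A = B @ truth.beta + noise
    return SimulatedDataset(design, A, B, truth,
                            seed=seed if np.isscalar(seed) else None)


# ---------------------------------------------------------------- I/O

def write_dataset(ds: SimulatedDataset, path, sep: str = ",") -> Path:
    """Write the data table (CSV/TSV) plus a sidecar truth JSON.

    The sidecar lands next to the table as ``<stem>.truth.json``.
    """
    path = Path(path)
    ds.to_frame().to_csv(path, sep=sep, index=False)
    sidecar = path.with_suffix(".truth.json")
    meta = {
        "grid_size": ds.design.grid_size,
        "seed": ds.seed,
        "truth": ds.truth.to_dict(),
    }
    sidecar.write_text(json.dumps(meta, indent=1))
    return path


def read_dataset(path, sep: str = ",") -> SimulatedDataset:
    """Read a dataset written by :func:`write_dataset`.

    Without a sidecar file the truth is reconstructed as unknown
    (all-zero beta, no spatial flags) — sufficient for fitting, not for
    selection metrics.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep)
    bcols = sorted((c for c in df.columns if c.startswith("B_")),
                   key=lambda c: int(c.split("_")[1]))
    sidecar = path.with_suffix(".truth.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        G = meta["grid_size"]
        truth = TrueModel.from_dict(meta["truth"])
        seed = meta.get("seed")
    else:
        G = int(df[["x", "y"]].to_numpy().max())
        truth = TrueModel(np.zeros(len(bcols)), np.zeros(len(bcols), dtype=bool),
                          ScenarioSpec.none(), ScenarioSpec.none())
        seed = None
    design = SpatialDesign(G, df[["x", "y"]].to_numpy())
    return SimulatedDataset(design, df["A"].to_numpy(), df[bcols].to_numpy(),
                            truth, seed=seed)
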