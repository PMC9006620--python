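"""Spatial sampling designs on regular grids.

Field observations live on an equispaced square grid with unit interpoint
distance, indexed by integer coordinates (x, y) with 1 <= x, y <= G.
Observation locations are sampled without replacement and with equal
probability from the grid cells, so all pairwise distances are strictly
positive and inverse-distance weight matrices are well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "SpatialDesign",
    "sample_locations",
    "edge_distance",
    "checkerboard_treatment",
    "full_grid",
]


class InvalidDesignError(ValueError):
    """Raised for geometrically impossible design requests."""


@dataclass(frozen=True)
class SpatialDesign:
    """A set of distinct observation locations on a G x G grid.

    Parameters
    ----------
    grid_size : int
        Number of cells per side, G.
    coords : ndarray of shape (n, 2)
        Integer (x, y) pairs, each component in 1..G, all pairs distinct.
    interpoint_distance : float
        Distance between adjacent grid cells; fixed at 1.
    """

    grid_size: int
    coords: np.ndarray
    interpoint_distance: float = 1.0
    _dist: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise InvalidDesignError("coords must be an (n, 2) array")
        object.__setattr__(self, "coords", coords)
        if len(coords) > self.grid_size**2:
            raise InvalidDesignError(
                f"{len(coords)} locations cannot be distinct on a "
                f"{self.grid_size}x{self.grid_size} grid"
            )
        if coords.min() < 1 or coords.max() > self.grid_size:
            raise InvalidDesignError("coordinates must lie in 1..grid_size")
        uniq = {(x, y) for x, y in coords}
        if len(uniq) != len(coords):
            raise InvalidDesignError("duplicate coordinates in design")

    @property
    def n(self) -> int:
        return len(self.coords)

    @property
    def distance_matrix(self) -> np.ndarray:
        """Pairwise Euclidean distances (cached, n x n)."""
        if "D" not in self._dist:
            self._dist["D"] = squareform(pdist(self.coords)) * self.interpoint_distance
        return self._dist["D"]

    def subset(self, idx) -> "SpatialDesign":
        """Design restricted to the given observation indices."""
        return SpatialDesign(self.grid_size, self.coords[np.asarray(idx)])


def full_grid(G: int) -> SpatialDesign:
    """Design containing every cell of the G x G grid."""
    xx, yy = np.meshgrid(np.arange(1, G + 1), np.arange(1, G + 1))
    return SpatialDesign(G, np.column_stack([xx.ravel(), yy.ravel()]))


def sample_locations(G: int, n: int, seed) -> SpatialDesign:
    """Sample n distinct locations uniformly from the G x G grid.

    Deterministic given ``seed`` (an int or a numpy Generator).
    """
    if n < 1:
        raise InvalidDesignError(f"need at least one location, got n={n}")
    if n > G * G:
        raise InvalidDesignError(
            f"cannot place n={n} distinct locations on a {G}x{G} grid ({G * G} cells)"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    idx = rng.choice(G * G, size=n, replace=False)
    coords = np.column_stack([idx // G + 1, idx % G + 1])
    return SpatialDesign(G, coords)


def edge_distance(coords: np.ndarray, G: int) -> np.ndarray:
    """Distance to the closest edge of the field.

    The edge is one unit outside the border rows, so border cells (x=1,
    x=G, y=1 or y=G) have edge distance exactly 1:
    d_edge(x, y) = min(x, y, G+1-x, G+1-y).
    """
    coords = np.asarray(coords, dtype=float)
    x, y = coords[:, 0], coords[:, 1]
    return np.minimum.reduce([x, y, G + 1 - x, G + 1 - y])


def checkerboard_treatment(coords: np.ndarray, subplot_size: int, G: int = 18) -> np.ndarray:
    """Binary treatment indicator of a checkerboard subplot design.

    The G x G grid is partitioned into square subplots of side
    ``subplot_size``; a cell in subplot (bx, by) (0-based block indices)
    is treated iff bx + by is odd, producing alternating treated/control
    subplots. The treatment is a property of the cell: sampled
    observations inherit it.
    """
    if G % subplot_size != 0:
        raise InvalidDesignError(
            f"subplot size {subplot_size} does not divide the grid size {G}"
        )
    coords = np.asarray(coords)
    bx = (coords[:, 0].astype(int) - 1) // subplot_size
    by = (coords[:, 1].astype(int) - 1) // subplot_size
    return ((bx + by) % 2).astype(float)
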