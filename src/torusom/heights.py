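"""U-, P- and U*-matrix heights over a trained SOM lattice.

The U-matrix assigns each unit the average data-space distance from its
prototype to the prototypes of its immediate lattice neighbors; ridges of
large heights separate clusters, valleys of small heights lie inside them.
The P-matrix estimates empirical density as the number of data points inside
a fixed-radius sphere around each prototype.  The U*-matrix damps U-heights
in high-density regions so that distance and density structure combine into
a single landscape.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .som import GridSpec

# Pareto radius: quantile of the pairwise-distance distribution conventionally
# used to size the P-matrix density sphere.
PARETO_QUANTILE = 0.2013

_MOORE = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_VON_NEUMANN = [(-1, 0), (1, 0), (0, -1), (0, 1)]


@dataclasses.dataclass
class HeightMatrix:
    """One scalar height per lattice unit."""

    grid: GridSpec
    heights: np.ndarray  # (rows, cols)
    kind: str  # "U", "P" or "Ustar"
    params: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.shape != (self.grid.rows, self.grid.cols):
            raise ValueError("heights shape does not match grid")
        if self.kind not in {"U", "P", "Ustar"}:
            raise ValueError(f"unknown height-matrix kind {self.kind!r}")

    def save(self, csv_path: str | Path) -> None:
        csv_path = Path(csv_path)
        np.savetxt(csv_path, self.heights, delimiter=",")
        sidecar = csv_path.with_suffix(".json")
        meta = {"kind": self.kind, "rows": self.grid.rows, "cols": self.grid.cols,
                "toroidal": self.grid.toroidal, "params": self.params}
        sidecar.write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, csv_path: str | Path) -> "HeightMatrix":
        csv_path = Path(csv_path)
        meta = json.loads(csv_path.with_suffix(".json").read_text())
        heights = np.loadtxt(csv_path, delimiter=",", ndmin=2)
        grid = GridSpec(meta["rows"], meta["cols"], meta["toroidal"])
        return cls(grid, heights, meta["kind"], meta.get("params", {}))


@dataclasses.dataclass(frozen=True)
class RadiusSpec:
    """How to choose the P-matrix sphere radius ``r``.

    ``fixed`` uses ``r`` as given; ``distance_quantile`` sets r to the stated
    quantile of all pairwise subject-subject distances (Pareto-radius
    convention, default quantile 0.2013).
    """

    method: str = "distance_quantile"
    r: float | None = None
    quantile: float = PARETO_QUANTILE

    def resolve(self, X: np.ndarray) -> float:
        if self.method == "fixed":
            if self.r is None or self.r <= 0:
                raise ValueError("fixed radius requires r > 0")
            return float(self.r)
        if self.method == "distance_quantile":
            if not (0 < self.quantile < 1):
                raise ValueError("quantile must lie in (0, 1)")
            return float(np.quantile(pdist(np.atleast_2d(X)), self.quantile))
        raise ValueError(f"unknown radius method {self.method!r}")


def _neighbor_offsets(connectivity: int) -> list[tuple[int, int]]:
    if connectivity == 8:
        return _MOORE
    if connectivity == 4:
        return _VON_NEUMANN
    raise ValueError("connectivity must be 4 or 8")


def u_matrix(weights: np.ndarray, grid: GridSpec, connectivity: int = 8) -> HeightMatrix:
    """Average data-space distance from each prototype to its lattice neighbors.

    Neighbors are the Moore 8-neighborhood by default, taken with toroidal
    wrap, so every unit has exactly 8 neighbors.
    """
    W = np.asarray(weights, dtype=float).reshape(grid.rows, grid.cols, -1)
    offsets = _neighbor_offsets(connectivity)
    acc = np.zeros((grid.rows, grid.cols))
    count = np.zeros((grid.rows, grid.cols))
    for dr, dc in offsets:
        shifted = np.roll(np.roll(W, -dr, axis=0), -dc, axis=1)
        dist = np.linalg.norm(W - shifted, axis=2)
        if grid.toroidal:
            acc += dist
            count += 1.0
        else:
            rows = np.arange(grid.rows)
            cols = np.arange(grid.cols)
            valid = ((rows[:, None] + dr >= 0) & (rows[:, None] + dr < grid.rows)
                     & (cols[None, :] + dc >= 0) & (cols[None, :] + dc < grid.cols))
            acc += np.where(valid, dist, 0.0)
            count += valid
    return HeightMatrix(grid, acc / count, "U", {"connectivity": connectivity})


def p_matrix(weights: np.ndarray, X: np.ndarray, grid: GridSpec,
             radius: RadiusSpec | float = RadiusSpec()) -> HeightMatrix:
    """Number of data points strictly inside a radius-r sphere around each prototype."""
    if isinstance(radius, (int, float)):
        radius = RadiusSpec(method="fixed", r=float(radius))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    r = radius.resolve(X)
    if r <= 0:
        raise ValueError("sphere radius must be positive")
    counts = (cdist(np.asarray(weights, dtype=float), X) < r).sum(axis=1)
    heights = counts.reshape(grid.rows, grid.cols).astype(float)
    return HeightMatrix(grid, heights, "P", {"r": r, "method": radius.method})


def u_star_matrix(U: HeightMatrix, P: HeightMatrix) -> HeightMatrix:
    """Combine distance (U) and density (P) structure into one landscape.

    U-heights are kept where density is at or below average and damped
    linearly toward zero as density approaches its maximum:
    ``U*(i) = U(i) * s(i)`` with ``s = 1`` for ``P <= mean(P)`` and
    ``s = (max(P) - P) / (max(P) - mean(P))`` otherwise, clipped to [0, 1].
    Constant density leaves U unchanged.
    """
    if U.kind != "U" or P.kind != "P":
        raise ValueError("u_star_matrix expects a U-matrix and a P-matrix")
    if U.grid != P.grid:
        raise ValueError("U- and P-matrix grids differ")
    p = P.heights
    p_mean, p_max = p.mean(), p.max()
    if p_max == p_mean:
        scale = np.ones_like(p)
    else:
        scale = np.where(p <= p_mean, 1.0, (p_max - p) / (p_max - p_mean))
        scale = np.clip(scale, 0.0, 1.0)
    params = {"r": P.params.get("r")}
    return HeightMatrix(U.grid, U.heights * scale, "Ustar", params)
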