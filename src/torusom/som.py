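"""Kohonen-type self-organizing map on a toroidal grid.

An emergent SOM (ESOM) uses a large neuron lattice — here 30 x 48 = 1440
units by default — so that cluster structure shows up in height-matrix
visualizations over the lattice rather than in single neurons.  The lattice
is a torus: opposite edges are identified, which removes border effects.

Each grid unit ``m_i`` carries a prototype (weight vector) ``w(m_i)`` living
in the preprocessed marker space.  Training pulls prototypes toward the data
with a Gaussian neighborhood kernel on the grid; afterwards every subject is
mapped to its best-matching unit (BMU), the unit whose prototype is closest
in Euclidean data-space distance.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted


@dataclasses.dataclass(frozen=True)
class GridSpec:
    """Geometry of the neuron lattice."""

    rows: int = 30
    cols: int = 48
    toroidal: bool = True

    def __post_init__(self) -> None:
        if self.rows < 2 or self.cols < 2:
            raise ValueError("grid needs at least 2 rows and 2 columns")

    @property
    def n_units(self) -> int:
        return self.rows * self.cols

    def unit_index(self, row: int, col: int) -> int:
        """Row-major linear index of a unit."""
        return row * self.cols + col

    def unit_coords(self, index: np.ndarray | int) -> tuple[np.ndarray, np.ndarray]:
        """Inverse of :meth:`unit_index` (vectorized)."""
        return np.divmod(index, self.cols)


def _axis_delta(delta: np.ndarray, size: int, toroidal: bool) -> np.ndarray:
    delta = np.abs(delta)
    if toroidal:
        delta = np.minimum(delta, size - delta)
    return delta


def grid_distance(a: tuple[int, int], b: tuple[int, int], grid: GridSpec) -> float:
    """Euclidean distance between two units on the (possibly wrapped) lattice.

    On a torus each axis offset wraps: delta = min(|Δ|, size − |Δ|), so the
    largest possible distance on a 30 x 48 grid is sqrt(15² + 24²).
    """
    ar, ac = a
    br, bc = b
    for r, c in ((ar, ac), (br, bc)):
        if not (0 <= r < grid.rows and 0 <= c < grid.cols):
            raise IndexError(f"unit ({r}, {c}) outside {grid.rows}x{grid.cols} grid")
    dr = _axis_delta(np.asarray(ar - br), grid.rows, grid.toroidal)
    dc = _axis_delta(np.asarray(ac - bc), grid.cols, grid.toroidal)
    return float(np.hypot(dr, dc))


def squared_grid_distances(grid: GridSpec) -> np.ndarray:
    """(n_units, n_units) matrix of squared lattice distances (exact integers)."""
    rows = np.arange(grid.rows)
    cols = np.arange(grid.cols)
    dr = _axis_delta(rows[:, None] - rows[None, :], grid.rows, grid.toroidal)
    dc = _axis_delta(cols[:, None] - cols[None, :], grid.cols, grid.toroidal)
    # broadcast (R,R) and (C,C) into (R*C, R*C) in row-major unit order
    d2 = (dr[:, None, :, None] ** 2 + dc[None, :, None, :] ** 2)
    return d2.reshape(grid.n_units, grid.n_units)


def init_weights(grid: GridSpec, data: np.ndarray, seed: int | None) -> np.ndarray:
    """Prototypes drawn uniformly from the per-column range of the data."""
    data = np.asarray(data, dtype=float)
    if data.size == 0:
        raise ValueError("cannot initialize from empty data")
    rng = np.random.default_rng(seed)
    lo = data.min(axis=0)
    hi = data.max(axis=0)
    return rng.uniform(lo, hi, size=(grid.n_units, data.shape[1]))


def best_matching_unit(x: np.ndarray, weights: np.ndarray) -> int:
    """Linear index of the unit with the closest prototype.

    Ties are broken toward the lowest row-major index (argmin convention).
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != weights.shape[1]:
        raise ValueError(
            f"subject has {x.shape[-1]} features, prototypes have {weights.shape[1]}"
        )
    d2 = np.einsum("ud,ud->u", weights - x, weights - x)
    return int(np.argmin(d2))


def bmu_indices(X: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Vectorized BMU lookup for a whole data matrix."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != weights.shape[1]:
        raise ValueError("feature dimension mismatch between data and prototypes")
    # ||x - w||^2 = ||w||^2 - 2 x.w + ||x||^2 ; the ||x||^2 term is constant per row
    d2 = (weights**2).sum(axis=1)[None, :] - 2.0 * X @ weights.T
    return np.argmin(d2, axis=1)


def train_online(
    weights: np.ndarray,
    X: np.ndarray,
    grid: GridSpec,
    *,
    epochs: int = 20,
    lr_start: float = 0.5,
    lr_end: float = 0.05,
    radius_start: float = 12.0,
    radius_end: float = 1.0,
    seed: int | None = None,
) -> tuple[np.ndarray, list[float]]:
    """Online SOM learning with a Gaussian lattice neighborhood.

    One epoch is one sweep through the subjects in a seed-shuffled order.
    Learning rate and neighborhood radius decay linearly over the total
    number of presentation steps.  Returns the trained weights and the
    quantization error (mean subject-to-BMU distance) recorded before
    training and after every epoch.

    Parameters follow the usual SOM conventions; with ``epochs=0`` the
    weights are returned unchanged.
    """
    if not (lr_start >= lr_end > 0):
        raise ValueError("need lr_start >= lr_end > 0")
    if not (radius_start >= radius_end >= 0.5):
        raise ValueError("need radius_start >= radius_end >= 0.5")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != weights.shape[1]:
        raise ValueError("feature dimension mismatch between data and prototypes")
    W = np.array(weights, dtype=float, copy=True)
    history = [quantization_error(X, W)]
    if epochs == 0:
        return W, history

    rng = np.random.default_rng(seed)
    d2_grid = squared_grid_distances(grid)
    n = X.shape[0]
    total = epochs * n
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n)
        for i in order:
            frac = step / (total - 1) if total > 1 else 0.0
            lr = lr_start + frac * (lr_end - lr_start)
            radius = radius_start + frac * (radius_end - radius_start)
            x = X[i]
            diff = x - W
            bmu = int(np.argmin(np.einsum("ud,ud->u", diff, diff)))
            h = lr * np.exp(-d2_grid[bmu] / (2.0 * radius * radius))
            W += h[:, None] * diff
            step += 1
        history.append(quantization_error(X, W))
    return W, history


def quantization_error(X: np.ndarray, weights: np.ndarray) -> float:
    """Mean Euclidean distance of each subject to its BMU prototype."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    bmus = bmu_indices(X, weights)
    return float(np.linalg.norm(X - weights[bmus], axis=1).mean())


class ToroidalESOM(BaseEstimator):
    """Emergent self-organizing map on a toroidal lattice (sklearn-style).

    Parameters
    ----------
    rows, cols : int
        Lattice shape; the default 30 x 48 gives u = 1440 units.
    toroidal : bool
        Identify opposite edges (default True).
    epochs : int
        Sweeps through the data during learning (default 20).
    lr_start, lr_end : float
        Linear learning-rate decay endpoints.
    radius_start, radius_end : float
        Linear neighborhood-radius decay endpoints (lattice units).
    random_state : int or None
        Seed for weight initialization and presentation order.

    Attributes
    ----------
    weights_ : ndarray of shape (rows * cols, d)
        Trained prototypes, row-major unit order.
    grid_ : GridSpec
    quantization_errors_ : list of float
        Quantization error before training and after each epoch.
    """

    def __init__(
        self,
        rows: int = 30,
        cols: int = 48,
        toroidal: bool = True,
        epochs: int = 20,
        lr_start: float = 0.5,
        lr_end: float = 0.05,
        radius_start: float = 12.0,
        radius_end: float = 1.0,
        random_state: int | None = None,
    ):
        self.rows = rows
        self.cols = cols
        self.toroidal = toroidal
        self.epochs = epochs
        self.lr_start = lr_start
        self.lr_end = lr_end
        self.radius_start = radius_start
        self.radius_end = radius_end
        self.random_state = random_state

    def fit(self, X, y=None) -> "ToroidalESOM":
        X = check_array(X, dtype=float)
        self.grid_ = GridSpec(self.rows, self.cols, self.toroidal)
        W0 = init_weights(self.grid_, X, self.random_state)
        self.weights_, self.quantization_errors_ = train_online(
            W0,
            X,
            self.grid_,
            epochs=self.epochs,
            lr_start=self.lr_start,
            lr_end=self.lr_end,
            radius_start=self.radius_start,
            radius_end=self.radius_end,
            seed=self.random_state,
        )
        self.n_features_in_ = X.shape[1]
        self.trained_epochs_ = self.epochs
        return self

    def predict(self, X) -> np.ndarray:
        """Linear BMU index for every subject."""
        check_is_fitted(self, "weights_")
        X = check_array(X, dtype=float)
        return bmu_indices(X, self.weights_)

    def bmu_coords(self, X) -> np.ndarray:
        """(n, 2) array of BMU (row, col) lattice coordinates."""
        rows, cols = self.grid_.unit_coords(self.predict(X))
        return np.column_stack([rows, cols])

    def quantization_error(self, X) -> float:
        check_is_fitted(self, "weights_")
        return quantization_error(check_array(X, dtype=float), self.weights_)

    def save(self, csv_path: str | Path) -> None:
        """Weights as CSV (unit row, unit col, weight columns) + JSON sidecar."""
        check_is_fitted(self, "weights_")
        csv_path = Path(csv_path)
        rows, cols = self.grid_.unit_coords(np.arange(self.grid_.n_units))
        df = pd.DataFrame(self.weights_, columns=[f"w{j}" for j in range(self.weights_.shape[1])])
        df.insert(0, "col", cols)
        df.insert(0, "row", rows)
        df.to_csv(csv_path, index=False)
        sidecar = csv_path.with_suffix(".json")
        sidecar.write_text(json.dumps({"params": self.get_params(), "trained_epochs": self.trained_epochs_}, indent=2))

    @classmethod
    def load(cls, csv_path: str | Path) -> "ToroidalESOM":
        csv_path = Path(csv_path)
        meta = json.loads(csv_path.with_suffix(".json").read_text())
        model = cls(**meta["params"])
        df = pd.read_csv(csv_path)
        model.grid_ = GridSpec(model.rows, model.cols, model.toroidal)
        model.weights_ = df.drop(columns=["row", "col"]).to_numpy(dtype=float)
        model.trained_epochs_ = meta["trained_epochs"]
        model.n_features_in_ = model.weights_.shape[1]
        model.quantization_errors_ = []
        return model
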