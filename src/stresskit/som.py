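"""Self-organizing map over epoch feature vectors, with k-means readout.

A batch SOM on a hexagonal grid: each training epoch assigns every input
to its best-matching unit (BMU) and replaces every neuron's weight by
the neighborhood-weighted mean of the inputs, with a Gaussian
neighborhood whose radius decays linearly. Batch updates make training
deterministic given the seed (only the initialization is random). The
U-matrix (mean distance of each neuron to its hex neighbors) visualizes
cluster boundaries, and k-means on the neuron weights (k = 5, one per
stress state) labels the map's regions.

Inputs are z-scored by default: the 24 features span wildly different
scales (bpm, ms, µS, °C) and an unscaled Euclidean BMU rule would be
dominated by the large-magnitude ones.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .errors import InvalidArgumentError


def hex_positions(rows: int, cols: int) -> np.ndarray:
    """Cartesian centers of an odd-r offset hexagonal grid, row-major."""
    pos = np.zeros((rows * cols, 2))
    for r in range(rows):
        for c in range(cols):
            pos[r * cols + c] = (c + 0.5 * (r % 2), r * np.sqrt(3) / 2)
    return pos


# odd-r offset neighbor steps, keyed by row parity
_HEX_STEPS = {
    0: ((-1, -1), (-1, 0), (0, -1), (0, 1), (1, -1), (1, 0)),
    1: ((-1, 0), (-1, 1), (0, -1), (0, 1), (1, 0), (1, 1)),
}


def hex_neighbors(r: int, c: int, rows: int, cols: int):
    """Indices of the existing hex neighbors of neuron (r, c)."""
    out = []
    for dr, dc in _HEX_STEPS[r % 2]:
        rr, cc = r + dr, c + dc
        if 0 <= rr < rows and 0 <= cc < cols:
            out.append(rr * cols + cc)
    return out


@dataclass
class SOMGrid:
    rows: int
    cols: int
    weights: np.ndarray          # (rows*cols, D)
    qe_history: np.ndarray       # mean quantization error per epoch
    seed: int
    mu: np.ndarray | None = None # input standardization, if applied
    sd: np.ndarray | None = None

    @property
    def n_neurons(self) -> int:
        return self.rows * self.cols

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Apply the training-time standardization to new inputs."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.mu is None:
            return X
        return (X - self.mu) / self.sd

    def bmu(self, X: np.ndarray) -> np.ndarray:
        """Best-matching unit index for each (raw-scale) input row."""
        d = cdist(self.transform(X), self.weights)
        return np.argmin(d, axis=1)


def train_som(X: np.ndarray, rows: int = 10, cols: int = 10,
              n_epochs: int = 30, seed: int = 0,
              radius0: float | None = None, radius_final: float = 0.5,
              standardize: bool = True) -> SOMGrid:
    """Train a batch SOM on the rows of X.

    The neighborhood radius decays linearly from ``radius0`` (default:
    half the larger grid dimension) to ``radius_final`` over the training
    epochs; weights are initialized from a seeded random sample of the
    inputs. Quantization error is tracked per epoch and, once the radius
    drops below one grid unit, is non-increasing up to numerical noise.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.size == 0:
        raise InvalidArgumentError("empty input")
    mu = sd = None
    if standardize:
        mu = X.mean(axis=0)
        sd_raw = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.ones(X.shape[1])
        sd = np.where(sd_raw > 0, sd_raw, 1.0)
        X = (X - mu) / sd
    n_neurons = rows * cols
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, X.shape[0], size=n_neurons)
    jitter_scale = np.std(X) if np.std(X) > 0 else 1.0
    weights = X[idx] + 1e-4 * jitter_scale * rng.standard_normal(
        (n_neurons, X.shape[1]))
    pos = hex_positions(rows, cols)
    grid_d2 = cdist(pos, pos) ** 2
    if radius0 is None:
        radius0 = max(rows, cols) / 2.0
    qe = []
    for ep in range(n_epochs):
        frac = ep / max(n_epochs - 1, 1)
        radius = radius0 + frac * (radius_final - radius0)
        d = cdist(X, weights)
        bmu = np.argmin(d, axis=1)
        qe.append(float(np.mean(d[np.arange(X.shape[0]), bmu])))
        h = np.exp(-grid_d2 / (2.0 * radius ** 2))      # (neuron, neuron)
        influence = h[bmu]                               # (n, neuron)
        denom = influence.sum(axis=0)
        num = influence.T @ X
        nz = denom > 0
        weights[nz] = num[nz] / denom[nz, None]
    return SOMGrid(rows, cols, weights, np.asarray(qe), seed, mu, sd)


def u_matrix(grid: SOMGrid) -> np.ndarray:
    """Mean Euclidean distance of each neuron to its hex neighbors.

    Shape (rows, cols); edge and corner neurons average over their
    reduced neighbor sets (interior neurons have six neighbors, corners
    as few as two).
    """
    out = np.zeros((grid.rows, grid.cols))
    W = grid.weights
    for r in range(grid.rows):
        for c in range(grid.cols):
            nbrs = hex_neighbors(r, c, grid.rows, grid.cols)
            w = W[r * grid.cols + c]
            out[r, c] = np.mean(
                [np.linalg.norm(w - W[j]) for j in nbrs])
    return out


def kmeans_neurons(grid: SOMGrid, k: int = 5, seed: int = 0) -> np.ndarray:
    """Cluster neuron weights with k-means (k-means++, 10 restarts).

    Returns a cluster id in [0, k) per neuron, row-major over the grid.
    """
    if k > grid.n_neurons:
        raise InvalidArgumentError("k cannot exceed the neuron count")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(grid.weights)
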