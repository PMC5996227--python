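"""Linear source-mixing models.

Two families are provided:

* a truncated-Gaussian kernel on a regular 2-D grid of point sources —
  mixing between two sources at distance d is exp(-d^2 / (2 d_g^2)) for
  d <= 3 d_g and exactly zero beyond, so a source mixes maximally (weight 1)
  with itself;
* a synthetic cortical source space: random 3-D parcel centroids with a
  modeling operator whose off-diagonal leakage decays with centroid distance,
  has heavy-tailed weights, and whose per-parcel modeling quality is
  heterogeneous (some parcels systematically poorly modeled, via extra
  parcel-specific noise).  This stands in for a forward-plus-inverse MEG
  modeling chain when demonstrating mixing properties on realistic geometry.

Mixing is applied linearly: the measured signal at source v is the original
signal plus the weighted sum over the other sources with non-zero weight,

    X'_v(t) = X_v(t) + sum_{i != v} w(v, i) X_i(t),

i.e. the self term enters once, through the leading X_v.
"""
from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial.distance import cdist, squareform, pdist

from ._util import as_rng, check_square
from .signals import TimeSeriesSet

__all__ = [
    "GridGeometry",
    "MixingModel",
    "truncated_gaussian_kernel",
    "build_grid_mixing",
    "apply_mixing",
    "synthetic_source_space",
    "load_mixing_csv",
]


@dataclasses.dataclass(frozen=True)
class GridGeometry:
    """Open (non-periodic) rectangular grid of point sources, row-major order."""

    n_rows: int
    n_cols: int
    d_g: float = 1.0

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1 or self.d_g <= 0:
            raise ValueError("grid dimensions must be positive")

    @property
    def n_sources(self) -> int:
        return self.n_rows * self.n_cols

    def positions(self) -> np.ndarray:
        """(n_sources, 2) Euclidean coordinates in units of d_g."""
        r, c = np.divmod(np.arange(self.n_sources), self.n_cols)
        return np.column_stack([r, c]).astype(float) * self.d_g

    def node_index(self, row: int, col: int) -> int:
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"({row}, {col}) outside {self.n_rows}x{self.n_cols} grid")
        return row * self.n_cols + col

    def distance_matrix(self) -> np.ndarray:
        p = self.positions()
        return cdist(p, p)


@dataclasses.dataclass
class MixingModel:
    """Paired measurement operator and geometry.

    weights[v, i] is the contribution of original source i to the measured
    signal of source v; the diagonal is the self-weight (1 for grid kernels).
    For synthetic cortical models, `noise_scale[v]` adds parcel-specific
    measurement noise of that standard deviation (relative to unit-variance
    sources) when the model is applied.
    """

    weights: np.ndarray
    distances: np.ndarray | None = None
    kind: str = "user-supplied"
    noise_scale: np.ndarray | None = None

    def __post_init__(self):
        self.weights = check_square(np.asarray(self.weights, dtype=float), "weights")
        if np.any(self.weights < 0):
            raise ValueError("mixing weights must be non-negative")
        if self.distances is not None:
            self.distances = check_square(np.asarray(self.distances, dtype=float))
            if self.distances.shape != self.weights.shape:
                raise ValueError("distances and weights shapes differ")

    @property
    def n_sources(self) -> int:
        return self.weights.shape[0]


def truncated_gaussian_kernel(d, d_g: float):
    """Truncated-Gaussian mixing weight: exp(-d^2/(2 d_g^2)) for d <= 3 d_g, else 0.

    Normalised so the maximum — a source's mixing with itself (d = 0) — is 1.
    Accepts scalars or arrays.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    if d_g <= 0:
        raise ValueError("d_g must be positive")
    w = np.where(d <= 3.0 * d_g, np.exp(-(d**2) / (2.0 * d_g**2)), 0.0)
    return float(w) if w.ndim == 0 else w


def build_grid_mixing(geom: GridGeometry) -> MixingModel:
    """Grid-kernel mixing model: n^2 x n^2 symmetric, diagonal 1, truncated at 3 d_g."""
    d = geom.distance_matrix()
    return MixingModel(
        weights=truncated_gaussian_kernel(d, geom.d_g),
        distances=d,
        kind="grid-kernel",
    )


def apply_mixing(ts: TimeSeriesSet, model: MixingModel, seed=None) -> TimeSeriesSet:
    """Measure `ts` through the model: X'_v = X_v + sum_{i != v} w(v,i) X_i (+ noise).

    Linear in the input.  For models carrying a `noise_scale`, parcel-specific
    complex white noise is added; a seed (or Generator) is then required so
    measurements are reproducible.
    """
    if model.n_sources != ts.n_sources:
        raise ValueError(
            f"model has {model.n_sources} sources, series has {ts.n_sources}"
        )
    op = model.weights.copy()
    np.fill_diagonal(op, 1.0)  # leading X_v term; self excluded from the sum
    mixed = ts.data @ op.T
    if model.noise_scale is not None and np.any(model.noise_scale > 0):
        if seed is None:
            raise ValueError("model adds measurement noise: a seed is required")
        rng = as_rng(seed)
        shape = ts.data.shape
        eta = (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)) / np.sqrt(2)
        mixed = mixed + eta * np.asarray(model.noise_scale)[None, :]
    return ts.copy_with(mixed)


def synthetic_source_space(
    n_parcels: int,
    geometry_seed=0,
    leakage_scale: float = 0.6,
    noise_level: float = 0.6,
    decay_length: float = 0.15,
) -> MixingModel:
    """Random 3-D parcel geometry with distance-decaying, heavy-tailed leakage.

    Parcel centroids are drawn uniformly in the unit cube.  Each parcel gets a
    modeling quality q ~ Beta(4, 2); poorly modeled parcels (low q) receive
    both stronger leakage from their neighbourhood and stronger parcel-specific
    measurement noise, emulating the spatial heterogeneity of source-modeling
    accuracy.  Off-diagonal leakage into parcel v is

        w(v, i)  ∝  h_vi * exp(-d_vi / decay_length),     h_vi ~ LogNormal(0, 1),

    rescaled per row so the total leakage power is (leakage_scale * (1-q_v))^2.
    The self-weight is 1 and the noise scale is noise_level * (1 - q_v).
    With leakage_scale = 0 the weight matrix is the identity.
    """
    if n_parcels < 2:
        raise ValueError("need at least 2 parcels")
    rng = as_rng(geometry_seed)
    centroids = rng.uniform(size=(n_parcels, 3))
    d = squareform(pdist(centroids))
    quality = rng.beta(4.0, 2.0, size=n_parcels)
    heavy = rng.lognormal(mean=0.0, sigma=1.0, size=(n_parcels, n_parcels))
    raw = heavy * np.exp(-d / decay_length)
    np.fill_diagonal(raw, 0.0)
    power = np.sqrt((raw**2).sum(axis=1, keepdims=True))
    power[power == 0] = 1.0
    w = leakage_scale * (1.0 - quality)[:, None] * raw / power
    np.fill_diagonal(w, 1.0)
    return MixingModel(
        weights=w,
        distances=d,
        kind="synthetic-cortex",
        noise_scale=noise_level * (1.0 - quality),
    )


def load_mixing_csv(path, kind: str = "user-supplied") -> MixingModel:
    """Read a square, non-negative numeric CSV matrix as a mixing model."""
    from .io import read_matrix_csv

    w = read_matrix_csv(path)
    if w.shape[0] != w.shape[1]:
        raise ValueError(f"{path}: matrix not square ({w.shape[0]} rows, {w.shape[1]} cols)")
    if np.isnan(w).any():
        r, c = np.argwhere(np.isnan(w))[0]
        raise ValueError(f"{path}: NaN entry at row {r}, col {c}")
    if (w < 0).any():
        r, c = np.argwhere(w < 0)[0]
        raise ValueError(f"{path}: negative entry at row {r}, col {c}")
    return MixingModel(weights=w, kind=kind)
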