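"""All-to-all phase synchrony estimation and graph thresholding.

The complex phase-locking value between sources i and j over n samples is

    cPLV_ij = (1/n) sum_t exp(i (phi_i(t) - phi_j(t))),

with PLV = |cPLV| and iPLV = |Im cPLV|.  iPLV is insensitive to zero- and
±pi-lag coupling, which is exactly the phase signature of instantaneous linear
mixing, hence its use for mixing-robust connectivity graphs.

Significance thresholds are derived from null-hypothesis graphs (uncorrelated
sources measured through the same pipeline): the threshold for a level
L = -log10(p) is the (1 - 10^-L) quantile of the pooled null iPLV values.

The percentile thresholding rule uses midpoint plotting positions
((i - 1/2)/N, the Hazen convention, as in Matlab's ``prctile``) over the
unique upper-triangle values, with a strictly-greater comparison.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from ._util import check_square, unit_phasors, upper_triangle_values
from .signals import TimeSeriesSet

__all__ = [
    "SynchronyGraph",
    "ThresholdSet",
    "cplv_matrix",
    "phase_difference_histogram",
    "null_thresholds",
    "percentile_cutoff",
    "threshold_graph",
]


@dataclasses.dataclass
class SynchronyGraph:
    """Square complex cPLV matrix with PLV / iPLV views."""

    cplv: np.ndarray
    n_samples: int

    def __post_init__(self):
        self.cplv = check_square(np.asarray(self.cplv, dtype=complex), "cplv")
        if not np.allclose(self.cplv, np.conj(self.cplv.T)):
            raise ValueError("cplv must be Hermitian up to conjugation")

    @property
    def n_nodes(self) -> int:
        return self.cplv.shape[0]

    @property
    def plv(self) -> np.ndarray:
        return np.abs(self.cplv)

    @property
    def iplv(self) -> np.ndarray:
        return np.abs(np.imag(self.cplv))


@dataclasses.dataclass
class ThresholdSet:
    """iPLV cutoffs for a set of -log10(p) significance levels."""

    levels: np.ndarray
    thresholds: np.ndarray

    def __post_init__(self):
        self.levels = np.asarray(self.levels, dtype=float)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if self.levels.shape != self.thresholds.shape:
            raise ValueError("levels and thresholds must align")
        order = np.argsort(self.levels)
        if np.any(np.diff(self.thresholds[order]) < 0):
            raise ValueError("thresholds must be non-decreasing with level")

    def threshold_for(self, level: float) -> float:
        idx = np.nonzero(np.isclose(self.levels, level))[0]
        if len(idx) == 0:
            raise KeyError(f"level {level} not in {self.levels.tolist()}")
        return float(self.thresholds[idx[0]])


def cplv_matrix(ts: TimeSeriesSet, allow_dependent: bool = False) -> SynchronyGraph:
    """Complex PLV between all source pairs of an independent-sample series."""
    if not ts.independent and not allow_dependent:
        raise ValueError(
            "series not decimated to independent samples; pass allow_dependent=True "
            "to override"
        )
    if ts.n_samples < 100:
        raise ValueError(f"need >= 100 samples for a stable estimate, got {ts.n_samples}")
    z = unit_phasors(ts.data)
    c = (z.T @ np.conj(z)) / ts.n_samples
    np.fill_diagonal(c, 1.0)
    c = (c + np.conj(c.T)) / 2.0  # enforce exact Hermitian symmetry
    return SynchronyGraph(cplv=c, n_samples=ts.n_samples)


def phase_difference_histogram(phases_a, phases_b, n_bins: int = 50):
    """Histogram of wrapped phase differences over uniform bins on [-pi, pi).

    Returns (counts, bin_edges); counts sum to the number of samples.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    a = np.asarray(phases_a, dtype=float).ravel()
    b = np.asarray(phases_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("phase series must have equal length")
    diff = np.angle(np.exp(1j * (a - b)))  # wrap into [-pi, pi]
    diff[diff == np.pi] = -np.pi
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    counts, edges = np.histogram(diff, bins=edges)
    return counts, edges


def null_thresholds(null_graphs, levels=(1.3, 2.0, 3.0, 4.0, 5.0)) -> ThresholdSet:
    """Pool null iPLV values across graphs and take (1 - 10^-L) quantiles."""
    null_graphs = list(null_graphs)
    if not null_graphs:
        raise ValueError("need at least one null graph")
    pooled = np.concatenate([upper_triangle_values(g.iplv) for g in null_graphs])
    levels = np.asarray(levels, dtype=float)
    strictest = 10.0 ** (np.max(levels) + 1)
    if pooled.size < strictest:
        warnings.warn(
            f"only {pooled.size} pooled null values for strictest level "
            f"{np.max(levels)} (want >= {strictest:.0f}); tail quantile is noisy",
            stacklevel=2,
        )
    qs = 1.0 - 10.0 ** (-levels)
    return ThresholdSet(levels=levels, thresholds=np.quantile(pooled, qs))


def percentile_cutoff(values: np.ndarray, p: float) -> float:
    """Hazen (midpoint plotting position) percentile of `values`."""
    if not 0.0 <= p <= 100.0:
        raise ValueError("percentile must be in [0, 100]")
    return float(np.percentile(values, p, method="hazen"))


def threshold_graph(
    g: SynchronyGraph,
    percentile: float | None = None,
    absolute: float | None = None,
    threshold_set: ThresholdSet | None = None,
    level: float | None = None,
    metric: str = "iplv",
):
    """Unique undirected edges (i < j) whose metric is strictly above a cutoff.

    Exactly one rule must be given: `percentile` (over the unique upper-triangle
    values), `absolute`, or a (`threshold_set`, `level`) pair.

    Returns
    -------
    edges : list of (i, j) tuples, i < j
    cutoff : float
    """
    rules = sum(x is not None for x in (percentile, absolute, threshold_set))
    if rules != 1:
        raise ValueError("give exactly one of percentile, absolute, threshold_set")
    mat = {"iplv": g.iplv, "plv": g.plv}[metric]
    vals = upper_triangle_values(mat)
    if percentile is not None:
        cutoff = percentile_cutoff(vals, percentile)
    elif absolute is not None:
        cutoff = float(absolute)
    else:
        if level is None:
            raise ValueError("a level is required with a threshold_set")
        cutoff = threshold_set.threshold_for(level)
    i, j = np.triu_indices(g.n_nodes, k=1)
    keep = vals > cutoff
    edges = list(zip(i[keep].tolist(), j[keep].tolist()))
    return edges, cutoff
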