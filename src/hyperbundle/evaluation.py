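"""Ground-truth graphs, confusion scoring and graph demographics.

The planted truth is a perfect matching: parcels are split at random into
source and target halves and paired one-to-one, so every node has degree
exactly one and an n-parcel graph has n/2 true edges.  "Other" edges are all
remaining unique pairs (for 400 parcels and 200 true edges: 79,600 of them —
the population whose false-positive rate mixing inflates).

Hyperedge-level scores: a hyperedge is a true positive if it contains at
least one true edge; sensitivity is the fraction of true edges covered by
true-positive hyperedges, specificity is one minus the false-positive
hyperedge fraction, and separability is the fraction of true-positive
hyperedges containing exactly one true edge (ideal bundling puts each true
interaction, with its spurious halo, in its own hyperedge).
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from ._util import as_rng, upper_triangle_values
from .connectivity import SynchronyGraph

__all__ = [
    "GroundTruthGraph",
    "ConfusionSummary",
    "generate_ground_truth",
    "confusion",
    "hyperedge_scores",
    "graph_demographics",
    "fpr_inflation",
]


@dataclasses.dataclass
class GroundTruthGraph:
    """Planted perfect matching: sources[k] -- targets[k] are the true edges."""

    n_parcels: int
    sources: np.ndarray
    targets: np.ndarray

    def __post_init__(self):
        self.sources = np.asarray(self.sources, dtype=int)
        self.targets = np.asarray(self.targets, dtype=int)
        nodes = np.concatenate([self.sources, self.targets])
        if len(nodes) != self.n_parcels or len(np.unique(nodes)) != self.n_parcels:
            raise ValueError("edges must form a perfect matching on the parcels")

    @property
    def edges(self) -> set:
        """Unordered true edges as a set of (i, j) tuples with i < j."""
        return {
            (min(s, t), max(s, t)) for s, t in zip(self.sources, self.targets)
        }

    @property
    def n_edges(self) -> int:
        return len(self.sources)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_parcels, dtype=int)
        for s, t in zip(self.sources, self.targets):
            deg[s] += 1
            deg[t] += 1
        return deg


@dataclasses.dataclass
class ConfusionSummary:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n_true(self) -> int:
        return self.tp + self.fn

    @property
    def n_other(self) -> int:
        return self.fp + self.tn

    @property
    def tpr(self) -> float:
        return self.tp / self.n_true if self.n_true else float("nan")

    @property
    def fpr(self) -> float:
        return self.fp / self.n_other if self.n_other else float("nan")

    @property
    def tnr(self) -> float:
        return self.tn / self.n_other if self.n_other else float("nan")


def generate_ground_truth(n_parcels: int = 400, seed=None) -> GroundTruthGraph:
    """Random equal split into sources/targets, randomly paired one-to-one."""
    if n_parcels < 2 or n_parcels % 2:
        raise ValueError("n_parcels must be even and >= 2")
    rng = as_rng(seed)
    perm = rng.permutation(n_parcels)
    half = n_parcels // 2
    return GroundTruthGraph(
        n_parcels=n_parcels, sources=perm[:half], targets=perm[half:]
    )


def _normalize_edges(edges, n_parcels: int) -> set:
    out = set()
    for i, j in edges:
        if not (0 <= i < n_parcels and 0 <= j < n_parcels) or i == j:
            raise ValueError(f"edge ({i}, {j}) outside parcel range 0..{n_parcels - 1}")
        out.add((min(i, j), max(i, j)))
    return out


def confusion(observed_edges, gt: GroundTruthGraph, mask=None) -> ConfusionSummary:
    """Edge-level confusion counts over unmasked unique pairs.

    `mask` is an optional IntractableEdgeMask (or boolean matrix); masked
    pairs are excluded from both the observed edges and the truth before
    counting, so TP + FN + FP + TN equals the number of unmasked pairs.
    """
    n = gt.n_parcels
    obs = _normalize_edges(observed_edges, n)
    true = gt.edges
    if mask is not None:
        m = mask.mask if hasattr(mask, "mask") else np.asarray(mask, dtype=bool)
        obs = {e for e in obs if not m[e]}
        true = {e for e in true if not m[e]}
        n_pairs = int((~m[np.triu_indices(n, k=1)]).sum())
    else:
        n_pairs = n * (n - 1) // 2
    tp = len(obs & true)
    fp = len(obs - true)
    fn = len(true - obs)
    tn = n_pairs - tp - fp - fn
    return ConfusionSummary(tp=tp, fp=fp, tn=tn, fn=fn)


@dataclasses.dataclass
class HyperedgeScores:
    n_hyperedges: int
    n_true_positive: int
    sensitivity: float
    specificity: float
    separability: float


def hyperedge_scores(partition, gt: GroundTruthGraph, observed_edges) -> HyperedgeScores:
    """Score a hyperedge partition of the observed edges against the truth."""
    observed = [tuple(sorted(e)) for e in observed_edges]
    if partition.n_edges != len(observed):
        raise ValueError("partition does not cover the observed edge list")
    true = gt.edges
    n_true_in_h = []
    for h in partition.hyperedges:
        n_true_in_h.append(sum(1 for e in h if observed[e] in true))
    n_true_in_h = np.asarray(n_true_in_h)
    tp_h = n_true_in_h > 0
    covered_true = int(n_true_in_h.sum())
    sens = covered_true / gt.n_edges if gt.n_edges else float("nan")
    spec = 1.0 - (np.count_nonzero(~tp_h) / len(partition))
    n_tp = int(np.count_nonzero(tp_h))
    sep = (
        float(np.count_nonzero(n_true_in_h == 1)) / n_tp if n_tp else 0.0
    )
    return HyperedgeScores(
        n_hyperedges=len(partition),
        n_true_positive=n_tp,
        sensitivity=min(sens, 1.0),
        specificity=spec,
        separability=sep,
    )


def graph_demographics(graphs_by_condition: dict, gt: GroundTruthGraph, n_bins: int = 50):
    """Mean PLV / iPLV and phase-lag histograms of true vs other edges.

    Parameters
    ----------
    graphs_by_condition : mapping condition name -> SynchronyGraph
    gt : the planted truth shared by all conditions

    Returns
    -------
    table : DataFrame with columns (condition, edge_class, mean_plv, mean_iplv, n_edges)
    histograms : dict (condition, edge_class) -> (counts, bin_edges) of cPLV angles
    """
    iu = np.triu_indices(gt.n_parcels, k=1)
    true_mask = np.zeros((gt.n_parcels, gt.n_parcels), dtype=bool)
    for i, j in gt.edges:
        true_mask[i, j] = True
    is_true = true_mask[iu]
    rows, hists = [], {}
    edges_bins = np.linspace(-np.pi, np.pi, n_bins + 1)
    for cond, g in graphs_by_condition.items():
        if not isinstance(g, SynchronyGraph):
            raise TypeError("graphs_by_condition values must be SynchronyGraph")
        plv = g.plv[iu]
        iplv = g.iplv[iu]
        angles = np.angle(g.cplv[iu])
        for cls, sel in (("true", is_true), ("other", ~is_true)):
            rows.append(
                {
                    "condition": cond,
                    "edge_class": cls,
                    "mean_plv": float(plv[sel].mean()) if sel.any() else float("nan"),
                    "mean_iplv": float(iplv[sel].mean()) if sel.any() else float("nan"),
                    "n_edges": int(sel.sum()),
                }
            )
            counts, _ = np.histogram(angles[sel], bins=edges_bins)
            hists[(cond, cls)] = (counts, edges_bins)
    return pd.DataFrame(rows), hists


def fpr_inflation(fpr_increase: float, n_other: int, n_true: int):
    """False-positive arithmetic: an FPR increase over `n_other` uncorrelated
    pairs implies `fpr_increase * n_other` spurious edges, reported together
    with their ratio to the number of true edges."""
    if n_other <= 0 or n_true <= 0:
        raise ValueError("population sizes must be positive")
    fp = fpr_increase * n_other
    return {"false_positives": fp, "ratio_to_true": fp / n_true}


def n_other_pairs(n_parcels: int, n_true: int) -> int:
    """Exact count of 'other' (non-true) unique pairs."""
    return n_parcels * (n_parcels - 1) // 2 - n_true
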