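"""End-to-end reference experiments composing the pipeline modules.

Three canned experiments mirror the validation platform's study conditions:

* a single phase-lagged interaction on a 13x13 grid, whose mixing halo turns
  one true edge into dozens of spurious suprathreshold edges;
* six interactions on a 20x20 grid, paired by spatial adjacency as "kin"
  (parallel edges two grid units apart), "nearby" (four units apart) and
  "far" (mutually distant and distant from everything else), thresholded at
  the 99.7th percentile of the unique-pair iPLV values;
* a cortical-scale run: a 400-parcel planted perfect matching measured
  through a synthetic source-space operator, with null graphs providing
  -log10(p) significance thresholds.

The grids place true-edge endpoints well beyond the 3 d_g mixing truncation
(the single-interaction pair sits sqrt(72) ~ 8.5 grid units apart), so any
synchrony between the halves of a true edge is genuine, not leaked.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from ._util import as_rng
from .connectivity import SynchronyGraph, cplv_matrix, null_thresholds, threshold_graph
from .evaluation import GroundTruthGraph, generate_ground_truth
from .mixing import (
    GridGeometry,
    MixingModel,
    apply_mixing,
    build_grid_mixing,
    synthetic_source_space,
)
from .signals import (
    couple_pair,
    decimate_independent,
    decimation_step,
    morlet_noise,
    simulate_truth_timeseries,
)

__all__ = [
    "GridExperiment",
    "single_interaction_grid",
    "six_interaction_grid",
    "CorticalExperiment",
    "cortical_experiment",
    "SIX_EDGE_LAYOUT",
]

# (row, col) endpoint pairs on the 20x20 grid; each edge spans >= 5 grid units
# so its endpoints never mix directly (truncation at 3 d_g).
SIX_EDGE_LAYOUT = {
    "kin": [((1, 3), (8, 3)), ((2, 5), (9, 5))],
    "nearby": [((1, 12), (8, 12)), ((3, 16), (10, 16))],
    "far": [((14, 1), (19, 1)), ((14, 18), (19, 18))],
}


@dataclasses.dataclass
class GridExperiment:
    geometry: GridGeometry
    model: MixingModel
    graph: SynchronyGraph
    edges: list
    cutoff: float
    true_edges: list
    edge_groups: dict


def _simulate_grid(
    geom: GridGeometry,
    couplings: list,
    coupling: float,
    lag: int,
    n_independent: int,
    f0: float,
    m: float,
    fs: float,
    seed,
) -> GridExperiment:
    rng = as_rng(seed)
    step = decimation_step(f0, m, fs)
    n_raw = (n_independent - 1) * step + 1 + lag
    ts = morlet_noise(n_raw, geom.n_sources, f0=f0, m=m, fs=fs, seed=rng)
    for src, tgt in couplings:
        ts.data[:, tgt] = couple_pair(
            ts.data[:, src], coupling, lag, noise=ts.data[:, tgt].copy()
        )
    dec = decimate_independent(ts, n_independent, step=step)
    model = build_grid_mixing(geom)
    mixed = apply_mixing(dec, model)
    graph = cplv_matrix(mixed)
    return graph, model, mixed


def single_interaction_grid(
    seed=0,
    n_grid: int = 13,
    coupling: float = 0.9,
    lag: int = 3,
    n_independent: int = 1000,
    f0: float = 10.0,
    m: float = 5.0,
    fs: float = 100.0,
    top_fraction: float = 0.001,
) -> GridExperiment:
    """One true interaction between sources sqrt(72) ~ 8.5 grid units apart;
    returns the strongest `top_fraction` of iPLV edges (default 0.1%)."""
    geom = GridGeometry(n_grid, n_grid)
    v1 = geom.node_index(3, 3)
    v2 = geom.node_index(9, 9)
    graph, model, _ = _simulate_grid(
        geom, [(v1, v2)], coupling, lag, n_independent, f0, m, fs, seed
    )
    edges, cutoff = threshold_graph(graph, percentile=(1.0 - top_fraction) * 100.0)
    return GridExperiment(
        geometry=geom,
        model=model,
        graph=graph,
        edges=edges,
        cutoff=cutoff,
        true_edges=[(min(v1, v2), max(v1, v2))],
        edge_groups={"single": [(min(v1, v2), max(v1, v2))]},
    )


def six_interaction_grid(
    seed=0,
    n_grid: int = 20,
    coupling: float = 0.9,
    lag: int = 3,
    n_independent: int = 1000,
    f0: float = 10.0,
    m: float = 5.0,
    fs: float = 100.0,
    percentile: float = 99.7,
) -> GridExperiment:
    """Six coupled pairs (kin / nearby / far) on a 20x20 grid, mixed and
    thresholded at the 99.7th percentile of the unique-pair iPLV values."""
    geom = GridGeometry(n_grid, n_grid)
    groups, couplings = {}, []
    for name, pairs in SIX_EDGE_LAYOUT.items():
        group_edges = []
        for (r1, c1), (r2, c2) in pairs:
            a, b = geom.node_index(r1, c1), geom.node_index(r2, c2)
            couplings.append((a, b))
            group_edges.append((min(a, b), max(a, b)))
        groups[name] = group_edges
    graph, model, _ = _simulate_grid(
        geom, couplings, coupling, lag, n_independent, f0, m, fs, seed
    )
    edges, cutoff = threshold_graph(graph, percentile=percentile)
    return GridExperiment(
        geometry=geom,
        model=model,
        graph=graph,
        edges=edges,
        cutoff=cutoff,
        true_edges=sorted(e for g in groups.values() for e in g),
        edge_groups=groups,
    )


@dataclasses.dataclass
class CorticalExperiment:
    gt: GroundTruthGraph
    model: MixingModel
    truth_graph: SynchronyGraph  # synchrony of the un-modeled truth series
    modeled_graph: SynchronyGraph  # after the virtual measurement
    thresholds: object
    couplings: np.ndarray


def cortical_experiment(
    seed=0,
    n_parcels: int = 400,
    coupling_pattern=("uniform", 0.9),
    lag: int = 3,
    n_independent: int = 1000,
    f0: float = 10.0,
    m: float = 5.0,
    fs: float = 100.0,
    model: MixingModel | None = None,
    n_null: int = 1,
    levels=(1.3, 2.0, 3.0, 4.0, 5.0),
) -> CorticalExperiment:
    """Planted perfect matching measured through a (synthetic) source space.

    Steps: generate the ground-truth matching; simulate coupled narrowband
    series; decimate to independent samples; measure through the mixing model;
    estimate iPLV graphs of both truth and modeled series; derive -log10(p)
    thresholds from `n_null` null simulations through the same model.
    """
    rng = as_rng(seed)
    if model is None:
        model = synthetic_source_space(n_parcels, geometry_seed=rng)
    gt = generate_ground_truth(n_parcels, seed=rng)
    step = decimation_step(f0, m, fs)
    n_raw = (n_independent - 1) * step + 1 + lag
    ts, couplings = simulate_truth_timeseries(
        gt, n_raw, f0=f0, m=m, fs=fs, coupling_pattern=coupling_pattern, lag=lag, seed=rng
    )
    dec = decimate_independent(ts, n_independent, step=step)
    truth_graph = cplv_matrix(dec)
    modeled_graph = cplv_matrix(apply_mixing(dec, model, seed=rng))
    nulls = []
    for _ in range(n_null):
        null_raw = morlet_noise(n_raw, n_parcels, f0=f0, m=m, fs=fs, seed=rng)
        null_dec = decimate_independent(null_raw, n_independent, step=step)
        nulls.append(cplv_matrix(apply_mixing(null_dec, model, seed=rng)))
    thresholds = null_thresholds(nulls, levels=levels)
    return CorticalExperiment(
        gt=gt,
        model=model,
        truth_graph=truth_graph,
        modeled_graph=modeled_graph,
        thresholds=thresholds,
        couplings=couplings,
    )
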