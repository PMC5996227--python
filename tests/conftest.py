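"""Shared fixtures: reference simulations (computed once per session) and
independent oracles used by the bundling tests."""
from __future__ import annotations

import numpy as np
import pytest

from hyperbundle import experiments, mixing, mixing_properties, signals


# ---------------------------------------------------------------- oracles

def upgma_bruteforce(D: np.ndarray):
    """Independent average-linkage oracle: recompute every cluster-to-cluster
    distance from the original leaf matrix at every step (no incremental
    update), with lexicographic tie-breaking on cluster ids.

    Returns a linkage-table ndarray (child1, child2, height, size).
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    clusters = {i: [i] for i in range(n)}  # id -> leaf members
    linkage = []
    next_id = n
    while len(clusters) > 1:
        ids = sorted(clusters)
        best = None
        for a_pos, p in enumerate(ids):
            for q in ids[a_pos + 1:]:
                d = np.mean([D[x, y] for x in clusters[p] for y in clusters[q]])
                if best is None or d < best[0]:
                    best = (d, p, q)
        d, p, q = best
        linkage.append((p, q, d, len(clusters[p]) + len(clusters[q])))
        clusters[next_id] = clusters.pop(p) + clusters.pop(q)
        next_id += 1
    return np.asarray(linkage)


def random_distance_matrix(n: int, rng) -> np.ndarray:
    d = rng.uniform(0.01, 1.0, size=(n, n))
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return d


def merge_sets(linkage: np.ndarray, n_leaves: int):
    """Set of leaf-member frozensets, one per merge (topology fingerprint)."""
    members = {i: frozenset([i]) for i in range(n_leaves)}
    out = set()
    for k, row in enumerate(linkage):
        m = members[int(row[0])] | members[int(row[1])]
        members[n_leaves + k] = m
        out.add(m)
    return out


@pytest.fixture(scope="session")
def bruteforce_upgma():
    return upgma_bruteforce


# ------------------------------------------------- reference simulations

@pytest.fixture(scope="session")
def grid_exp():
    """Six-interaction 20x20 grid run (study-condition defaults)."""
    return experiments.six_interaction_grid(seed=11)


@pytest.fixture(scope="session")
def grid_props(grid_exp):
    """Mixing properties of the grid kernel from null simulations."""
    return mixing_properties.estimate_mixing_properties(
        grid_exp.model, n_iter=3, n_samples=1000, seed=12
    )


@pytest.fixture(scope="session")
def synth_model():
    """400-parcel synthetic cortical source space."""
    return mixing.synthetic_source_space(400, geometry_seed=7)


@pytest.fixture(scope="session")
def synth_props(synth_model):
    return mixing_properties.estimate_mixing_properties(
        synth_model, n_iter=3, n_samples=1000, seed=8
    )


@pytest.fixture(scope="session")
def cortical_exp(synth_model):
    """400-parcel planted matching measured through the synthetic operator."""
    return experiments.cortical_experiment(seed=5, model=synth_model)


@pytest.fixture(scope="session")
def zero_lag_stats():
    """Per-seed PLV / iPLV of an uncorrelated source pair, before and after
    real-weight mixing (weight = grid kernel at 2 d_g).  100 seeds.

    Returns dict of arrays: null_plv, null_iplv, mixed_plv, mixed_iplv.
    """
    w = mixing.truncated_gaussian_kernel(2.0, 1.0)  # ~0.135
    model = mixing.MixingModel(weights=np.array([[1.0, w], [w, 1.0]]), kind="grid-kernel")
    step = signals.decimation_step(10.0, 5.0, 100.0)
    n_raw = 999 * step + 1
    out = {k: [] for k in ("null_plv", "null_iplv", "mixed_plv", "mixed_iplv")}
    from hyperbundle.connectivity import cplv_matrix

    # 20 simulations of 10 uncorrelated columns give 100 independent pairs
    for sim_seed in range(20):
        ts = signals.morlet_noise(n_raw, 10, seed=1000 + sim_seed)
        dec = signals.decimate_independent(ts, 1000, step=step)
        for k in range(5):
            pair = dec.copy_with(dec.data[:, 2 * k : 2 * k + 2])
            g0 = cplv_matrix(pair)
            g1 = cplv_matrix(mixing.apply_mixing(pair, model))
            out["null_plv"].append(g0.plv[0, 1])
            out["null_iplv"].append(g0.iplv[0, 1])
            out["mixed_plv"].append(g1.plv[0, 1])
            out["mixed_iplv"].append(g1.iplv[0, 1])
    return {k: np.asarray(v) for k, v in out.items()}
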