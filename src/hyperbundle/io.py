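"""CSV interchange: square matrices, edge lists, partitions, linkage tables.

Conventions (also stated in file headers): indices are 0-based; undirected
edges are stored upper-triangle, i < j; complex time series are stored as
paired ``re_<k>`` / ``im_<k>`` columns.  Matrix round-trips preserve values to
better than 1e-12 (17 significant digits are written).
"""
from __future__ import annotations

import os

import numpy as np
import pandas as pd

__all__ = [
    "read_matrix_csv",
    "write_matrix_csv",
    "read_edge_list_csv",
    "write_edge_list_csv",
    "write_partition_csv",
    "write_linkage_csv",
    "write_timeseries_csv",
    "read_timeseries_csv",
]

_FMT = "%.17g"


def _check_nonempty(path):
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if os.path.getsize(path) == 0:
        raise ValueError(f"{path}: empty input file")


def write_matrix_csv(path, matrix: np.ndarray, comment: str | None = None) -> None:
    matrix = np.asarray(matrix, dtype=float)
    header = comment or "square matrix; 0-based row/column indices"
    np.savetxt(path, matrix, delimiter=",", fmt=_FMT, header=header)


def read_matrix_csv(path) -> np.ndarray:
    _check_nonempty(path)
    try:
        mat = np.loadtxt(path, delimiter=",", comments="#", ndmin=2)
    except ValueError as err:
        raise ValueError(f"{path}: malformed numeric CSV ({err})") from err
    return mat


def write_edge_list_csv(path, edges, weights=None) -> None:
    """3-column edge list (i, j, weight); i < j, 0-based."""
    rows = []
    for k, (i, j) in enumerate(edges):
        w = 1.0 if weights is None else float(weights[k])
        rows.append((min(i, j), max(i, j), w))
    df = pd.DataFrame(rows, columns=["i", "j", "weight"])
    with open(path, "w") as fh:
        fh.write("# undirected edge list; 0-based indices; i < j\n")
        df.to_csv(fh, index=False)


def read_edge_list_csv(path):
    """Read an (i, j, weight) edge list; duplicate (i,j)/(j,i) pairs are an error."""
    _check_nonempty(path)
    df = pd.read_csv(path, comment="#")
    required = {"i", "j"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: edge list needs columns i, j (got {list(df.columns)})")
    edges, weights, seen = [], [], set()
    for line, row in enumerate(df.itertuples(index=False), start=2):
        i, j = int(row.i), int(row.j)
        key = (min(i, j), max(i, j))
        if i == j:
            raise ValueError(f"{path} line {line}: self-loop ({i}, {j})")
        if key in seen:
            raise ValueError(f"{path} line {line}: duplicate edge ({i}, {j})")
        seen.add(key)
        edges.append(key)
        weights.append(float(getattr(row, "weight", 1.0)))
    return edges, np.asarray(weights)


def write_partition_csv(path, partition, edges) -> None:
    """(edge_i, edge_j, hyperedge_id) rows for a HyperedgePartition."""
    labels = partition.labels()
    rows = [
        (min(e), max(e), int(labels[k])) for k, e in enumerate(edges)
    ]
    df = pd.DataFrame(rows, columns=["edge_i", "edge_j", "hyperedge_id"])
    with open(path, "w") as fh:
        fh.write("# hyperedge partition; 0-based parcel indices\n")
        df.to_csv(fh, index=False)


def write_linkage_csv(path, tree) -> None:
    """Linkage table (child1, child2, height, size); ids < n_leaves are leaves."""
    df = pd.DataFrame(tree.linkage, columns=["child1", "child2", "height", "size"])
    with open(path, "w") as fh:
        fh.write(f"# UPGMA linkage; n_leaves={tree.n_leaves}; merge k has id n_leaves+k\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def write_timeseries_csv(path, ts) -> None:
    """Wide CSV: paired re_<k>/im_<k> columns; metadata in the header comment."""
    n = ts.n_sources
    cols = {}
    for k in range(n):
        cols[f"re_{k}"] = ts.data[:, k].real
        cols[f"im_{k}"] = ts.data[:, k].imag
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(
            f"# complex time series; fs={ts.fs} f0={ts.f0} m={ts.m} "
            f"independent={int(ts.independent)}\n"
        )
        df.to_csv(fh, index=False, float_format="%.17g")


def read_timeseries_csv(path):
    """Inverse of write_timeseries_csv; returns a TimeSeriesSet."""
    from .signals import TimeSeriesSet

    _check_nonempty(path)
    with open(path) as fh:
        first = fh.readline()
    meta = {}
    if first.startswith("#"):
        for token in first[1:].split():
            if "=" in token:
                k, v = token.split("=")
                meta[k] = float(v)
    df = pd.read_csv(path, comment="#")
    n = sum(1 for c in df.columns if c.startswith("re_"))
    data = np.empty((len(df), n), dtype=complex)
    for k in range(n):
        data[:, k] = df[f"re_{k}"].to_numpy() + 1j * df[f"im_{k}"].to_numpy()
    return TimeSeriesSet(
        data=data,
        fs=meta.get("fs", 100.0),
        f0=meta.get("f0", 10.0),
        m=meta.get("m", 5.0),
        independent=bool(meta.get("independent", 0)),
    )
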