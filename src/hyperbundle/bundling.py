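"""Hyperedge bundling: cluster graph edges by mixing similarity.

A suprathreshold connectivity graph contaminated by linear mixing contains,
around every true interaction, a halo of spurious edges whose endpoints mix
with the true pair.  Bundling groups raw edges into *hyperedges* — ideally one
per true interaction — in four steps:

1. build an edge-to-edge similarity matrix S from the source-space mixing
   properties (default: for edges (a,b) and (c,d), the larger of the two
   endpoint pairings of the geometric mean, max of sqrt(m[a,c] m[b,d]) and
   sqrt(m[a,d] m[b,c]), with m the residual-spread matrix PLV0);
2. agglomerate the distance matrix D = 1 - S with UPGMA (average linkage):
   at every step the globally nearest pair of clusters is merged at a height
   equal to their average inter-cluster distance;
3. score every merge with the inconsistency coefficient
   kappa_theta = (delta - mu_delta) / sigma_delta, where mu and sigma are
   taken over the merge heights within depth theta below and including the
   merge (bottom ties, with a single height, get kappa = 0);
4. split all merges whose kappa exceeds the (1 - CL) * 100 percentile of all
   merge kappas; every maximal subtree containing no split merge becomes one
   hyperedge.  The hyperedges are disjoint and jointly cover all edges.

Ties in the UPGMA minimum are broken toward the lexicographically smallest
pair of cluster ids (leaves 0..n-1, then merges n, n+1, ... in creation
order), making the whole procedure deterministic.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from ._util import check_square
from .mixing_properties import MixingProperties

__all__ = [
    "EdgeSimilarity",
    "HyperedgeTree",
    "HyperedgePartition",
    "edge_similarity",
    "upgma",
    "inconsistency",
    "cut_tree",
    "bundle",
    "bundle_similarity",
]


@dataclasses.dataclass
class EdgeSimilarity:
    """Edge-to-edge similarity S in [0, 1] over an ordered list of graph edges."""

    edges: list
    S: np.ndarray

    def __post_init__(self):
        self.S = check_square(np.asarray(self.S, dtype=float), "S")
        self.edges = [tuple(e) for e in self.edges]
        if len(self.edges) != self.S.shape[0]:
            raise ValueError("edges and S must align")
        if np.any(self.S < 0) or np.any(self.S > 1):
            raise ValueError("similarities must lie in [0, 1]")
        if not np.allclose(self.S, self.S.T):
            raise ValueError("S must be symmetric")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def D(self) -> np.ndarray:
        """Distance matrix 1 - S with an exactly zero diagonal."""
        d = 1.0 - self.S
        np.fill_diagonal(d, 0.0)
        return d


@dataclasses.dataclass
class HyperedgeTree:
    """UPGMA merge history in linkage-table layout.

    linkage row k = (child1, child2, height, size): cluster ids below
    n_leaves are leaves; merge k creates cluster id n_leaves + k.
    """

    linkage: np.ndarray
    n_leaves: int

    def __post_init__(self):
        self.linkage = np.asarray(self.linkage, dtype=float)
        if self.linkage.shape != (self.n_leaves - 1, 4):
            raise ValueError("linkage must have n_leaves - 1 rows of 4")

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def leaves_of(self, cluster_id: int) -> list:
        """Leaf indices under a cluster id (a leaf id returns itself)."""
        stack, out = [int(cluster_id)], []
        while stack:
            c = stack.pop()
            if c < self.n_leaves:
                out.append(c)
            else:
                row = self.linkage[c - self.n_leaves]
                stack.extend([int(row[0]), int(row[1])])
        return sorted(out)


@dataclasses.dataclass
class HyperedgePartition:
    """Disjoint hyperedges (sets of edge indices) jointly covering all edges."""

    hyperedges: list
    cl: float
    theta: int
    n_edges: int

    def __post_init__(self):
        self.hyperedges = [frozenset(h) for h in self.hyperedges]
        if any(len(h) == 0 for h in self.hyperedges):
            raise ValueError("hyperedges must be non-empty")
        all_members = [e for h in self.hyperedges for e in h]
        if len(all_members) != len(set(all_members)):
            raise ValueError("hyperedges must be pairwise disjoint")
        if set(all_members) != set(range(self.n_edges)):
            raise ValueError("hyperedges must jointly cover all edges")

    def __len__(self) -> int:
        return len(self.hyperedges)

    def labels(self) -> np.ndarray:
        """Hyperedge label per edge index."""
        lab = np.empty(self.n_edges, dtype=int)
        for k, h in enumerate(self.hyperedges):
            for e in h:
                lab[e] = k
        return lab


def edge_similarity(
    edges,
    props: MixingProperties,
    method: str = "plv0",
) -> EdgeSimilarity:
    """Similarity between graph edges from source-space mixing properties.

    S[e1, e2] = max over the two endpoint pairings of sqrt(m[a,c] * m[b,d]),
    where m is the chosen mixing measure with its diagonal (self-coupling)
    set to 1 so edges sharing an endpoint score high.

    method : "plv0" (residual spread, default) or "fmix" (mixing function).
    """
    edges = [tuple(e) for e in edges]
    if method == "plv0":
        m = props.plv0.copy()
    elif method == "fmix":
        m = props.f_mix.copy()
    else:
        raise ValueError(f"unknown similarity method {method!r}")
    np.fill_diagonal(m, 1.0)
    m = np.clip(m, 0.0, 1.0)
    n = m.shape[0]
    ea = np.asarray(edges, dtype=int)
    if ea.size and (ea.min() < 0 or ea.max() >= n):
        raise ValueError("edge endpoints outside the parcel range of the properties")
    a, b = ea[:, 0], ea[:, 1]
    s1 = np.sqrt(m[np.ix_(a, a)] * m[np.ix_(b, b)])  # pairing (a,c),(b,d)
    s2 = np.sqrt(m[np.ix_(a, b)] * m[np.ix_(b, a)])  # pairing (a,d),(b,c)
    s = np.maximum(s1, s2)
    s = (s + s.T) / 2.0
    np.fill_diagonal(s, 1.0)
    return EdgeSimilarity(edges=edges, S=s)


def upgma(D: np.ndarray) -> HyperedgeTree:
    """Average-linkage agglomeration of a symmetric zero-diagonal distance matrix.

    At every step the two active clusters with the smallest average-linkage
    distance are merged at that distance; ties go to the lexicographically
    smallest (id, id) pair.  Cluster-to-cluster distances are maintained with
    the exact weighted-average update, equivalent to averaging all leaf-pair
    distances.
    """
    D = check_square(np.asarray(D, dtype=float), "D")
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    if np.any(D < 0):
        raise ValueError("distances must be non-negative")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 leaves")
    total = 2 * n - 1  # cluster ids: leaves 0..n-1, merges n..2n-2
    cur = np.full((total, total), np.inf)
    cur[:n, :n] = D
    np.fill_diagonal(cur, np.inf)
    active = np.zeros(total, dtype=bool)
    active[:n] = True
    sizes = np.ones(total)
    linkage = np.empty((n - 1, 4))
    for step in range(n - 1):
        # row-major argmin over active ids = lexicographically smallest tie
        flat = np.argmin(cur[np.ix_(active, active)])
        act = np.nonzero(active)[0]
        k = len(act)
        p, q = act[flat // k], act[flat % k]
        if p > q:
            p, q = q, p
        d = cur[p, q]
        new = n + step
        linkage[step] = (p, q, d, sizes[p] + sizes[q])
        rest = act[(act != p) & (act != q)]
        upd = (sizes[p] * cur[p, rest] + sizes[q] * cur[q, rest]) / (sizes[p] + sizes[q])
        cur[new, rest] = upd
        cur[rest, new] = upd
        sizes[new] = sizes[p] + sizes[q]
        active[[p, q]] = False
        active[new] = True
    return HyperedgeTree(linkage=linkage, n_leaves=n)


def inconsistency(tree: HyperedgeTree, theta: int = 2) -> np.ndarray:
    """Inconsistency coefficient per merge: z-score of the merge height among
    the merge heights within depth `theta` below and including it.

    Depth 1 is the merge itself, depth 2 adds its direct merge children, and
    so on.  Merges whose depth-theta neighbourhood has a single height or zero
    spread (bottom ties) get kappa = 0.  The SD uses ddof=1 (sample SD).
    """
    if theta < 1:
        raise ValueError("theta must be >= 1")
    n = tree.n_leaves
    kappa = np.zeros(n - 1)
    for k in range(n - 1):
        heights = []
        frontier = [n + k]
        for _ in range(theta):
            nxt = []
            for c in frontier:
                if c >= n:
                    row = tree.linkage[c - n]
                    heights.append(row[2])
                    nxt.extend([int(row[0]), int(row[1])])
            frontier = nxt
        heights = np.asarray(heights)
        if len(heights) < 2:
            continue
        sd = heights.std(ddof=1)
        if sd > 0:
            kappa[k] = (tree.heights[k] - heights.mean()) / sd
    return kappa


def cut_tree(
    tree: HyperedgeTree,
    cl: float = 0.15,
    theta: int = 2,
    kappa: np.ndarray | None = None,
) -> HyperedgePartition:
    """Partition the tree into hyperedges at cutoff limit `cl`.

    The kappa threshold is the (1 - cl) * 100 linear-interpolation percentile
    of kappa over all merges; merges strictly above it are split, and every
    maximal subtree containing no split merge becomes one hyperedge (edges
    not under any un-split merge become singletons).  cl = 1 is the degenerate
    boundary: every merge is split and every edge is its own hyperedge.
    """
    if not 0.0 < cl <= 1.0:
        raise ValueError("CL must be in (0, 1]")
    if kappa is None:
        kappa = inconsistency(tree, theta)
    n = tree.n_leaves
    if cl == 1.0:
        split = np.ones(n - 1, dtype=bool)
    else:
        thr = np.percentile(kappa, (1.0 - cl) * 100.0)
        split = kappa > thr
    # clean[k]: merge k and all merges below it are un-split
    clean = np.zeros(n - 1, dtype=bool)
    for k in range(n - 1):  # children always precede parents
        c1, c2 = int(tree.linkage[k, 0]), int(tree.linkage[k, 1])
        ok = not split[k]
        for c in (c1, c2):
            if c >= n:
                ok = ok and clean[c - n]
        clean[k] = ok
    parent = np.full(2 * n - 1, -1, dtype=int)
    for k in range(n - 1):
        parent[int(tree.linkage[k, 0])] = n + k
        parent[int(tree.linkage[k, 1])] = n + k
    hyperedges = []
    covered = np.zeros(n, dtype=bool)
    for k in range(n - 2, -1, -1):  # top-down: maximal clean subtrees
        if not clean[k]:
            continue
        par = parent[n + k]
        if par != -1 and clean[par - n]:
            continue
        members = tree.leaves_of(n + k)
        hyperedges.append(frozenset(members))
        covered[members] = True
    for leaf in range(n):
        if not covered[leaf]:
            hyperedges.append(frozenset([leaf]))
    return HyperedgePartition(hyperedges=hyperedges, cl=cl, theta=theta, n_edges=n)


def bundle_similarity(
    sim: EdgeSimilarity, cl: float = 0.15, theta: int = 2
) -> HyperedgePartition:
    """UPGMA + inconsistency cut of an existing edge-similarity matrix."""
    if sim.n_edges == 1:
        return HyperedgePartition(
            hyperedges=[frozenset([0])], cl=cl, theta=theta, n_edges=1
        )
    tree = upgma(sim.D)
    return cut_tree(tree, cl=cl, theta=theta)


def bundle(
    edges,
    props: MixingProperties,
    cl: float = 0.15,
    theta: int = 2,
    method: str = "plv0",
) -> HyperedgePartition:
    """End-to-end bundling: edge similarity -> UPGMA -> inconsistency cut."""
    sim = edge_similarity(edges, props, method=method)
    return bundle_similarity(sim, cl=cl, theta=theta)
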