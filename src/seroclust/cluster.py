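"""SNN graph construction, seeded Louvain clustering, cluster dendrograms, and
one-vs-rest Wilcoxon marker statistics.

Cells are joined by the Jaccard overlap of their k-nearest-neighbor sets
(neighbor sets include the cell itself), edges below a prune threshold are
dropped, and communities are found by Louvain modularity maximization with a
resolution parameter scaling the null-model term. Cluster indices are
contiguous from 1, ordered by decreasing size.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist
from sklearn.neighbors import NearestNeighbors

from .preprocess import Embedding, NormMatrix
from .stats import wilcoxon_rank_sum

logger = logging.getLogger("seroclust")

__all__ = [
    "NeighborGraph",
    "ClusterLabels",
    "Dendrogram",
    "build_snn",
    "louvain",
    "cluster_tree",
    "find_markers",
]

DEFAULT_KNN = 20
DEFAULT_PRUNE = 1.0 / 15.0


# ---------------------------------------------------------------------------
# SNN graph
# ---------------------------------------------------------------------------


@dataclass
class NeighborGraph:
    """Shared-nearest-neighbor graph with Jaccard edge weights in (0, 1]."""

    weights: sp.csr_matrix  # symmetric, zero diagonal
    cell_ids: np.ndarray
    k: int
    dims: tuple
    prune: float

    @property
    def n_cells(self) -> int:
        return self.weights.shape[0]

    def to_igraph(self) -> ig.Graph:
        # cached: the same graph is re-clustered at many resolutions
        cached = getattr(self, "_igraph", None)
        if cached is not None:
            return cached
        coo = sp.triu(self.weights, k=1).tocoo()
        g = ig.Graph(
            n=self.n_cells,
            edges=np.column_stack([coo.row, coo.col]).tolist(),
            edge_attrs={"weight": coo.data.tolist()},
        )
        object.__setattr__(self, "_igraph", g)
        return g


def build_snn(
    embedding: Embedding,
    dims=None,
    k: int = DEFAULT_KNN,
    prune: float = DEFAULT_PRUNE,
) -> NeighborGraph:
    """Build the SNN graph from Euclidean k-NN in the selected component subspace.

    ``dims`` are 1-based component indices (default: all components minus the
    embedding's excluded set). Neighbor sets include the cell itself and have
    size k; edge weight is |A n B| / |A u B|; edges with weight < prune are
    dropped.
    """
    if dims is None:
        dims = embedding.dims()
    dims = np.asarray(list(dims), dtype=int)
    if dims.size == 0:
        raise ValueError("empty dims selection")
    if dims.max() > embedding.n_components or dims.min() < 1:
        raise ValueError("dims outside available components")
    n = embedding.coordinates.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")

    coords = np.ascontiguousarray(embedding.coordinates[:, dims - 1])
    nn = NearestNeighbors(n_neighbors=k, algorithm="auto").fit(coords)
    dists, idx = nn.kneighbors(coords)  # self is returned at distance 0
    # coincident points make the k-th neighbor ambiguous; resolve such ties
    # deterministically by stable index order so degenerate inputs reproduce
    tied = dists[:, -1] == 0.0
    if tied.any():
        from sklearn.metrics import pairwise_distances

        D = pairwise_distances(coords[tied], coords)
        idx[tied] = np.argsort(D, axis=1, kind="stable")[:, :k]

    rows = np.repeat(np.arange(n), k)
    adj = sp.csr_matrix(
        (np.ones(n * k, dtype=np.float32), (rows, idx.ravel())), shape=(n, n)
    )
    adj.data[:] = 1.0  # collapse duplicate neighbor entries
    shared = adj @ adj.T  # |A n B|
    shared = shared.tocoo()
    inter = shared.data
    jacc = inter / (2.0 * k - inter)
    keep = (jacc >= prune) & (shared.row != shared.col)
    w = sp.csr_matrix(
        (jacc[keep], (shared.row[keep], shared.col[keep])), shape=(n, n)
    )
    w = w.maximum(w.T)  # enforce symmetry
    return NeighborGraph(
        weights=w,
        cell_ids=embedding.cell_ids,
        k=k,
        dims=tuple(int(d) for d in dims),
        prune=float(prune),
    )


# ---------------------------------------------------------------------------
# Louvain
# ---------------------------------------------------------------------------


@dataclass
class ClusterLabels:
    """Per-cell cluster assignment, 1-based, ordered by decreasing cluster size."""

    labels: np.ndarray
    cell_ids: np.ndarray
    dims: tuple
    resolution: float
    seed: int
    modularity: float

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max())

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels)[1:]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cell_id": self.cell_ids, "cluster": self.labels})


def _relabel_by_size(membership: np.ndarray) -> np.ndarray:
    """Map arbitrary community ids to 1..K ordered by decreasing size
    (ties broken by first appearance)."""
    ids, counts = np.unique(membership, return_counts=True)
    first_seen = {c: np.argmax(membership == c) for c in ids}
    order = sorted(ids, key=lambda c: (-counts[np.flatnonzero(ids == c)[0]],
                                       first_seen[c]))
    mapping = {c: i + 1 for i, c in enumerate(order)}
    return np.array([mapping[c] for c in membership], dtype=int)


def _merge_singletons(membership: np.ndarray, weights: sp.csr_matrix) -> np.ndarray:
    """Reassign single-cell communities to the cluster they are most connected
    to (summed SNN edge weight), as droplet toolkits do by default. Isolated
    vertices (no edges) keep their own label."""
    membership = membership.copy()
    ids, counts = np.unique(membership, return_counts=True)
    for cid in ids[counts == 1]:
        v = int(np.flatnonzero(membership == cid)[0])
        row = weights.getrow(v)
        if row.nnz == 0:
            continue
        neigh_comms = membership[row.indices]
        other = neigh_comms != cid
        if not other.any():
            continue
        totals = {}
        for comm, w in zip(neigh_comms[other], row.data[other]):
            totals[comm] = totals.get(comm, 0.0) + w
        membership[v] = max(sorted(totals), key=lambda c: totals[c])
    return membership


def louvain(
    graph: NeighborGraph,
    resolution: float = 0.9,
    seed: int = 0,
    group_singletons: bool = True,
) -> ClusterLabels:
    """Louvain community detection at the given resolution, deterministic per seed.

    Maximizes Q = (1/2m) sum_ij [w_ij - gamma k_i k_j / (2m)] delta(c_i, c_j).
    Single-cell communities that have edges are merged into their most
    connected cluster when ``group_singletons`` (isolated vertices always keep
    their own label).
    """
    if graph.n_cells == 0:
        raise ValueError("empty graph")
    g = graph.to_igraph()
    ig.set_random_number_generator(random.Random(seed))
    try:
        part = g.community_multilevel(
            weights="weight" if g.ecount() else None, resolution=resolution
        )
        membership = np.asarray(part.membership)
        if group_singletons:
            membership = _merge_singletons(membership, graph.weights)
        mod = g.modularity(
            membership.tolist(),
            weights="weight" if g.ecount() else None,
            resolution=resolution,
        ) if g.ecount() else 0.0
    finally:
        ig.set_random_number_generator(random)
    return ClusterLabels(
        labels=_relabel_by_size(membership),
        cell_ids=graph.cell_ids,
        dims=graph.dims,
        resolution=float(resolution),
        seed=int(seed),
        modularity=float(mod),
    )


# ---------------------------------------------------------------------------
# dendrogram
# ---------------------------------------------------------------------------


@dataclass
class Dendrogram:
    """Average-linkage tree over cluster centroids, serialized as newick."""

    newick: str
    leaf_names: list
    linkage_matrix: np.ndarray


def _linkage_to_newick(Z: np.ndarray, names: list) -> str:
    """Ultrametric newick from a scipy linkage matrix: a node merged at height h
    sits at depth h/2, so a two-leaf cherry has branch lengths d/2."""
    root = to_tree(Z)

    def render(node) -> str:
        if node.is_leaf():
            return names[node.id]
        left, right = node.get_left(), node.get_right()
        parts = []
        for child in (left, right):
            length = (node.dist - child.dist) / 2.0
            parts.append(f"{render(child)}:{length:.6g}")
        return f"({','.join(parts)})"

    return render(root) + ";"


def cluster_tree(embedding: Embedding, labels: ClusterLabels, dims=None) -> Dendrogram:
    """Average-linkage dendrogram of cluster centroids in the selected subspace."""
    if labels.n_clusters < 2:
        raise ValueError("need at least 2 clusters to build a tree")
    if dims is None:
        dims = labels.dims
    dims = np.asarray(list(dims), dtype=int)
    coords = embedding.coordinates[:, dims - 1]
    centroids = np.vstack(
        [coords[labels.labels == c].mean(axis=0)
         for c in range(1, labels.n_clusters + 1)]
    )
    Z = linkage(pdist(centroids), method="average")
    names = [str(c) for c in range(1, labels.n_clusters + 1)]
    return Dendrogram(
        newick=_linkage_to_newick(Z, names),
        leaf_names=names,
        linkage_matrix=Z,
    )


# ---------------------------------------------------------------------------
# marker statistics
# ---------------------------------------------------------------------------


def find_markers(
    norm: NormMatrix,
    labels: ClusterLabels,
    min_pct: float = 0.25,
    logfc_threshold: float = 0.25,
    min_cluster_size: int = 3,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon marker table.

    A gene enters the test for a cluster only if it is expressed in at least
    ``min_pct`` of cells of either group and |logFC| >= ``logfc_threshold``,
    where logFC = ln((mean(expm1(x_in)) + 1) / (mean(expm1(x_out)) + 1)).
    p-values are Bonferroni-adjusted with multiplier = number of genes tested
    for that cluster. Clusters smaller than ``min_cluster_size`` are skipped
    with a warning.
    """
    if labels.n_clusters < 2:
        raise ValueError("need at least 2 clusters")
    mat = sp.csr_matrix(norm.values)
    n_genes, n_cells = mat.shape

    expm1 = mat.copy()
    expm1.data = np.expm1(expm1.data)
    binary = mat.copy()
    binary.data = np.ones_like(binary.data)

    rows = []
    for c in range(1, labels.n_clusters + 1):
        in_mask = labels.labels == c
        n_in = int(in_mask.sum())
        n_out = n_cells - n_in
        if n_in < min_cluster_size:
            logger.warning("cluster %d has %d < %d cells; skipped", c, n_in,
                           min_cluster_size)
            continue
        mean_in = np.asarray(expm1[:, in_mask].mean(axis=1)).ravel()
        mean_out = np.asarray(expm1[:, ~in_mask].mean(axis=1)).ravel()
        pct_in = np.asarray(binary[:, in_mask].mean(axis=1)).ravel()
        pct_out = np.asarray(binary[:, ~in_mask].mean(axis=1)).ravel()
        logfc = np.log((mean_in + 1.0) / (mean_out + 1.0))

        testable = ((pct_in >= min_pct) | (pct_out >= min_pct)) & (
            np.abs(logfc) >= logfc_threshold
        )
        tested = np.flatnonzero(testable)
        m = len(tested)
        for g in tested:
            vals = np.asarray(mat[g, :].todense()).ravel()
            _, p = wilcoxon_rank_sum(vals[in_mask], vals[~in_mask])
            rows.append(
                {
                    "gene": norm.gene_ids[g],
                    "cluster": c,
                    "p_value": p,
                    "p_adjusted": min(p * m, 1.0),
                    "log_fc": logfc[g],
                    "pct_in": pct_in[g],
                    "pct_out": pct_out[g],
                    "direction": "enriched" if logfc[g] > 0 else "de-enriched",
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "cluster", "p_value", "p_adjusted", "log_fc",
            "pct_in", "pct_out", "direction",
        ],
    )
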