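"""SNN graphs, Louvain clustering, dendrograms, and marker statistics."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import seroclust as sc
from seroclust.cluster import NeighborGraph, _linkage_to_newick
from seroclust.preprocess import Embedding, NormMatrix


def embedding_from_coords(coords):
    coords = np.asarray(coords, dtype=float)
    n, k = coords.shape
    return Embedding(
        coordinates=coords,
        loadings=np.eye(k),
        component_variance=coords.var(axis=0, ddof=1),
        total_variance=float(coords.var(axis=0, ddof=1).sum()),
        excluded_components=(),
        gene_ids=np.array([f"g{i}" for i in range(k)], dtype=object),
        cell_ids=np.array([f"c{i}" for i in range(n)], dtype=object),
    )


def clique_graph(sizes):
    """Disjoint unit-weight cliques as a NeighborGraph."""
    n = sum(sizes)
    W = np.zeros((n, n))
    start = 0
    for s in sizes:
        W[start:start + s, start:start + s] = 1.0
        start += s
    np.fill_diagonal(W, 0.0)
    return NeighborGraph(
        weights=sp.csr_matrix(W),
        cell_ids=np.array([f"c{i}" for i in range(n)], dtype=object),
        k=max(sizes), dims=(1,), prune=0.0,
    )


class TestBuildSNN:
    def test_identical_neighbor_sets_weight_one(self):
        # two coincident points with k=2: neighbor sets identical -> weight 1
        coords = np.array([[0.0, 0], [0, 0], [10, 10], [10, 10]])
        emb = embedding_from_coords(coords)
        g = sc.build_snn(emb, dims=[1, 2], k=2, prune=0.0)
        assert g.weights[0, 1] == pytest.approx(1.0)
        assert g.weights[2, 3] == pytest.approx(1.0)

    def test_prune_drops_weak_edges(self):
        # Jaccard below the prune threshold is removed entirely
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(50, 3))
        emb = embedding_from_coords(coords)
        g = sc.build_snn(emb, dims=[1, 2, 3], k=5, prune=1 / 15)
        assert g.weights.nnz > 0
        assert g.weights.data.min() >= 1 / 15
        assert g.weights.data.max() <= 1.0

    def test_no_self_edges_and_symmetric(self):
        rng = np.random.default_rng(1)
        emb = embedding_from_coords(rng.normal(size=(40, 4)))
        g = sc.build_snn(emb, dims=[1, 2, 3, 4], k=6)
        assert g.weights.diagonal().sum() == 0
        assert (abs(g.weights - g.weights.T)).nnz == 0

    def test_two_distant_blobs_no_cross_edges(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(30, 3))
        b = rng.normal(size=(30, 3)) + 40  # ~20 sigma apart
        emb = embedding_from_coords(np.vstack([a, b]))
        g = sc.build_snn(emb, dims=[1, 2, 3], k=5, prune=0.0)
        cross = g.weights[:30, 30:]
        assert cross.nnz == 0

    def test_k_too_large_rejected(self):
        emb = embedding_from_coords(np.zeros((5, 2)))
        with pytest.raises(ValueError, match="k="):
            sc.build_snn(emb, dims=[1, 2], k=5)


class TestLouvain:
    def test_single_clique_one_cluster(self):
        g = clique_graph([5])
        labels = sc.louvain(g, resolution=1.0, seed=0)
        assert labels.n_clusters == 1

    def test_two_cliques_two_clusters_modularity_half(self):
        # exact enumeration: the 2-block partition of two disjoint 5-cliques
        # has modularity 0.5, the optimum
        g = clique_graph([5, 5])
        labels = sc.louvain(g, resolution=1.0, seed=0)
        assert labels.n_clusters == 2
        assert labels.modularity == pytest.approx(0.5, abs=1e-9)
        assert len(set(labels.labels[:5])) == 1
        assert len(set(labels.labels[5:])) == 1

    def test_resolution_monotone_on_planted_blocks(self):
        # 3 planted blobs: cluster count at gamma=0.1 <= count at gamma=2.0
        rng = np.random.default_rng(3)
        blobs = [rng.normal(size=(40, 4)) + off for off in (0, 8, 16)]
        emb = embedding_from_coords(np.vstack(blobs))
        g = sc.build_snn(emb, dims=[1, 2, 3, 4], k=10)
        lo = sc.louvain(g, resolution=0.1, seed=1).n_clusters
        hi = sc.louvain(g, resolution=2.0, seed=1).n_clusters
        assert lo <= hi

    def test_labels_contiguous_and_size_ordered(self):
        g = clique_graph([3, 7, 5])
        labels = sc.louvain(g, resolution=1.0, seed=0)
        sizes = labels.sizes()
        assert labels.labels.min() == 1
        assert labels.labels.max() == len(sizes)
        assert (np.diff(sizes) <= 0).all()

    def test_modularity_at_least_trivial_partitions(self):
        rng = np.random.default_rng(4)
        emb = embedding_from_coords(rng.normal(size=(60, 3)))
        graph = sc.build_snn(emb, dims=[1, 2, 3], k=8)
        labels = sc.louvain(graph, resolution=1.0, seed=0)
        g = graph.to_igraph()
        one = g.modularity([0] * 60, weights="weight", resolution=1.0)
        singles = g.modularity(list(range(60)), weights="weight", resolution=1.0)
        assert labels.modularity >= one - 1e-12
        assert labels.modularity >= singles - 1e-12

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        emb = embedding_from_coords(rng.normal(size=(80, 4)))
        g = sc.build_snn(emb, dims=[1, 2, 3, 4], k=8)
        a = sc.louvain(g, resolution=1.2, seed=9)
        b = sc.louvain(g, resolution=1.2, seed=9)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_empty_graph_rejected(self):
        g = NeighborGraph(sp.csr_matrix((0, 0)), np.array([], dtype=object),
                          1, (1,), 0.0)
        with pytest.raises(ValueError, match="empty"):
            sc.louvain(g)

    def test_cell_permutation_permutes_labels_consistently(self):
        # permuting cell order permutes a well-separated partition with it
        rng = np.random.default_rng(6)
        coords = np.vstack([rng.normal(size=(30, 3)),
                            rng.normal(size=(30, 3)) + 25])
        emb = embedding_from_coords(coords)
        g = sc.build_snn(emb, dims=[1, 2, 3], k=8)
        base = sc.louvain(g, resolution=1.0, seed=0).labels

        perm = rng.permutation(60)
        emb_p = embedding_from_coords(coords[perm])
        g_p = sc.build_snn(emb_p, dims=[1, 2, 3], k=8)
        permuted = sc.louvain(g_p, resolution=1.0, seed=0).labels
        # same partition up to cluster renaming
        pairs = set(zip(base[perm].tolist(), permuted.tolist()))
        assert len(pairs) == len(set(base))

    def test_isolated_vertex_keeps_own_cluster(self):
        W = np.zeros((6, 6))
        W[:5, :5] = 1.0
        np.fill_diagonal(W, 0)
        g = NeighborGraph(sp.csr_matrix(W),
                          np.array([f"c{i}" for i in range(6)], dtype=object),
                          5, (1,), 0.0)
        labels = sc.louvain(g, resolution=1.0, seed=0)
        assert labels.n_clusters == 2
        assert labels.sizes()[-1] == 1


class TestClusterTree:
    def _labels(self, arr, dims=(1, 2)):
        arr = np.asarray(arr)
        from seroclust.cluster import ClusterLabels
        return ClusterLabels(
            labels=arr,
            cell_ids=np.array([f"c{i}" for i in range(len(arr))], dtype=object),
            dims=dims, resolution=1.0, seed=0, modularity=0.0,
        )

    def test_two_clusters_cherry_half_distance(self):
        coords = np.array([[0.0, 0], [0, 0], [6, 0], [6, 0]])
        emb = embedding_from_coords(coords)
        labels = self._labels([1, 1, 2, 2])
        tree = sc.cluster_tree(emb, labels, dims=[1, 2])
        # centroids 6 apart -> each leaf branch d/2 = 3
        assert tree.newick.count(":3") == 2

    def test_three_clusters_close_pair_is_sister(self):
        coords = np.array(
            [[0.0, 0], [0.5, 0], [1.0, 0], [1.5, 0], [20, 0], [20.5, 0]]
        )
        emb = embedding_from_coords(coords)
        labels = self._labels([1, 1, 2, 2, 3, 3])
        tree = sc.cluster_tree(emb, labels, dims=[1, 2])
        # clusters 1 and 2 merge first: newick contains the (1,2) cherry
        assert "(1:" in tree.newick and ",2:" in tree.newick
        cherry = tree.newick[tree.newick.rindex("("):].split(")")[0]
        assert set(c for c in cherry if c.isdigit() and c in "123") <= {"1", "2"}

    def test_single_cluster_rejected(self):
        emb = embedding_from_coords(np.zeros((4, 2)))
        labels = self._labels([1, 1, 1, 1])
        with pytest.raises(ValueError, match="2 clusters"):
            sc.cluster_tree(emb, labels, dims=[1, 2])

    def test_planted_blocks_form_disjoint_subtrees(self, default_clustering,
                                                   default_atlas):
        from conftest import map_clusters_to_truth
        from seroclust.stability import ClusteringParams, preprocess_pipeline

        spec, cm, truth = default_atlas
        filtered, labels = default_clustering
        emb = preprocess_pipeline(filtered, ClusteringParams())
        tree = sc.cluster_tree(emb, labels, dims=emb.dims())
        c2s = map_clusters_to_truth(labels.labels, filtered.cell_ids, truth,
                                    cm.cell_ids)
        gad_subtypes = {f"subtype_{s:02d}" for s in range(2, 7)}
        gad_clusters = {str(c) for c, s in c2s.items() if s in gad_subtypes}

        import re
        # find the smallest newick clade containing all Gad2-block clusters
        # and check it contains no Slc17a8-block cluster
        from io import StringIO
        newick = tree.newick

        def clades(nwk):
            # enumerate leaf sets of all internal nodes by bracket matching
            out = []
            stack = []
            leaves = []
            token = ""
            for ch in nwk:
                if ch == "(":
                    stack.append(len(leaves))
                elif ch in "),;":
                    if token:
                        leaves.append(token.split(":")[0])
                        token = ""
                    if ch == ")":
                        out.append(set(leaves[stack.pop():]))
                elif ch == ",":
                    pass
                else:
                    token += ch
            return out

        best = min((c for c in clades(newick) if gad_clusters <= c), key=len)
        vglut_subtypes = {f"subtype_{s:02d}" for s in range(7, 15)}
        vglut_clusters = {str(c) for c, s in c2s.items() if s in vglut_subtypes}
        assert not (best & vglut_clusters)


class TestFindMarkers:
    def _norm(self, X):
        X = np.asarray(X, dtype=float)
        return NormMatrix(
            values=sp.csr_matrix(X),
            gene_ids=np.array([f"g{i}" for i in range(X.shape[0])], dtype=object),
            cell_ids=np.array([f"c{i}" for i in range(X.shape[1])], dtype=object),
            scale_factor=1e4,
            cell_totals=np.full(X.shape[1], 100.0),
        )

    def _labels(self, arr):
        from seroclust.cluster import ClusterLabels
        arr = np.asarray(arr)
        return ClusterLabels(
            labels=arr,
            cell_ids=np.array([f"c{i}" for i in range(len(arr))], dtype=object),
            dims=(1,), resolution=1.0, seed=0, modularity=0.0,
        )

    def test_exact_p_for_separated_triples(self):
        # values {5,6,7} vs {1,2,3}: U = 9 (maximal), exact two-sided p = 0.10
        X = np.array([[5, 6, 7, 1, 2, 3]], dtype=float)
        table = sc.find_markers(self._norm(X), self._labels([1, 1, 1, 2, 2, 2]),
                                min_pct=0.0, logfc_threshold=0.0)
        row = table[(table.cluster == 1) & (table.gene == "g0")].iloc[0]
        assert row.p_value == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups_p_one(self):
        X = np.array([[1, 2, 3, 1, 2, 3], [9, 9, 9, 9, 9, 9.0]])
        table = sc.find_markers(self._norm(X), self._labels([1, 1, 1, 2, 2, 2]),
                                min_pct=0.0, logfc_threshold=0.0)
        assert (table.p_value == 1.0).all()

    def test_min_pct_gate(self):
        # expressed in 10% of both groups -> not tested at min_pct 0.25
        X = np.zeros((1, 40))
        X[0, 0] = 5.0
        X[0, 20] = 5.0
        labels = self._labels([1] * 20 + [2] * 20)
        table = sc.find_markers(self._norm(X), labels, min_pct=0.25,
                                logfc_threshold=0.0)
        assert len(table) == 0

    def test_logfc_threshold_gate(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(1.0, 1.05, size=(3, 30))  # tiny differences
        labels = self._labels([1] * 15 + [2] * 15)
        table = sc.find_markers(self._norm(X), labels, min_pct=0.0,
                                logfc_threshold=0.25)
        assert len(table) == 0

    def test_bonferroni_multiplier_is_genes_tested(self):
        rng = np.random.default_rng(7)
        X = np.vstack([rng.uniform(0, 4, 30) for _ in range(6)])
        labels = self._labels([1] * 15 + [2] * 15)
        table = sc.find_markers(self._norm(X), labels, min_pct=0.0,
                                logfc_threshold=0.0)
        m = table.groupby("cluster")["gene"].transform("count")
        np.testing.assert_allclose(
            table.p_adjusted, np.minimum(table.p_value * m, 1.0)
        )

    def test_small_cluster_skipped(self):
        X = np.array([[1, 2, 3, 4, 5, 6, 9.0]])
        labels = self._labels([1, 1, 1, 2, 2, 2, 3])
        table = sc.find_markers(self._norm(X), labels, min_pct=0.0,
                                logfc_threshold=0.0)
        assert set(table.cluster) <= {1, 2}

    def test_de_enriched_direction(self):
        X = np.array([[0.1, 0.1, 0.2, 5, 6, 7.0]])
        table = sc.find_markers(self._norm(X), self._labels([1, 1, 1, 2, 2, 2]),
                                min_pct=0.0, logfc_threshold=0.0)
        row = table[table.cluster == 1].iloc[0]
        assert row.direction == "de-enriched"
        assert row.log_fc < 0


def test_linkage_to_newick_ultrametric():
    from scipy.cluster.hierarchy import linkage

    # three points on a line: 0, 1, 10
    Z = linkage(np.array([[0.0], [1.0], [10.0]]), method="average")
    nwk = _linkage_to_newick(Z, ["a", "b", "c"])
    assert nwk.startswith("(") and nwk.endswith(";")
    assert ":0.5" in nwk  # the (a,b) cherry merges at height 1 -> branches 0.5
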