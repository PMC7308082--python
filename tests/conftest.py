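"""Shared fixtures: small synthetic atlases sized for fast unit tests, and the
full default atlas (session-scoped) for the end-to-end recovery tests."""

import numpy as np
import pytest

import seroclust as sc
from seroclust.stability import ClusteringParams


def small_spec(**overrides):
    """A scaled-down atlas recipe for unit tests: 4 subtypes, ~400 cells,
    moderate libraries. QC thresholds must be scaled accordingly (see
    ``small_filter_params``)."""
    defaults = dict(
        n_genes=900,
        n_cells=400,
        n_subtypes=4,
        rare_proportion=0.1,
        markers_per_subtype=10,
        marker_fold=4.0,
        block_genes_each=15,
        n_mito=60,
        n_ribo=40,
        n_glial=6,
        nuisance_genes_each=15,
        n_contaminants=40,
        target_library_size_mean=20_000.0,
    )
    defaults.update(overrides)
    return sc.build_spec(**defaults)


def small_filter_params(**overrides):
    """FilterParams matched to the small spec's scale (900 genes)."""
    defaults = dict(min_genes_per_cell=700, min_cells_per_gene=5)
    defaults.update(overrides)
    return sc.FilterParams(**defaults)


def small_clustering_params(**overrides):
    defaults = dict(n_hvg=300, n_pcs=20, knn_k=10)
    defaults.update(overrides)
    return ClusteringParams(**defaults)


@pytest.fixture(scope="session")
def small_atlas():
    spec = small_spec()
    cm, truth = sc.generate_atlas(spec, seed=7)
    return spec, cm, truth


@pytest.fixture(scope="session")
def small_filtered(small_atlas):
    _, cm, _ = small_atlas
    filtered, report = sc.apply_filters(cm, params=small_filter_params())
    return filtered, report


@pytest.fixture(scope="session")
def default_atlas():
    """One full-size default atlas; shared by the end-to-end recovery tests."""
    spec = sc.default_spec()
    cm, truth = sc.generate_atlas(spec, seed=1)
    return spec, cm, truth


@pytest.fixture(scope="session")
def default_filtered(default_atlas):
    _, cm, _ = default_atlas
    filtered, report = sc.apply_filters(cm)
    return filtered, report


@pytest.fixture(scope="session")
def default_clustering(default_filtered):
    """Cluster labels for the filtered default atlas at resolution 0.9."""
    filtered, _ = default_filtered
    labels = sc.cluster_pipeline(filtered, ClusteringParams(), seed=3)
    return filtered, labels


def map_clusters_to_truth(labels, cell_ids, truth, truth_cell_ids):
    """cluster index -> majority planted label, via aligned cell ids."""
    import pandas as pd

    planted = pd.Series(truth.cell_labels, index=truth_cell_ids).loc[cell_ids]
    ct = pd.crosstab(labels, planted.to_numpy())
    return ct.idxmax(axis=1).to_dict()
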