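"""Cluster-number robustness analyses.

Two complementary experiments probe how stable a cluster count is:

* a PC x resolution sweep — re-cluster over a grid of (number of leading
  principal components, Louvain resolution) and histogram the resulting
  cluster counts into a *frequency landscape*, whose local maxima are the
  candidate cluster numbers least sensitive to parameter tuning;
* cell / UMI subsampling — repeatedly subsample cells without replacement
  and/or thin each cell's UMIs to a cap (multivariate hypergeometric), re-run
  the full pipeline (HVG selection, PCA, SNN graph, Louvain at a fixed
  resolution), and track how many clusters remain discoverable.

Seed policy: every grid point / replicate derives its own seed from the base
seed via a counter-based SeedSequence spawn, so any single point can be
re-run independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .cluster import DEFAULT_KNN, DEFAULT_PRUNE, ClusterLabels, build_snn, louvain
from .io_qc import CountMatrix
from .preprocess import (
    Embedding,
    log_normalize,
    nuisance_components,
    run_pca,
    scale_center,
    select_hvg_vst,
)

logger = logging.getLogger("seroclust")

__all__ = [
    "ClusteringParams",
    "SweepResult",
    "FrequencyLandscape",
    "SubsampleResult",
    "cluster_pipeline",
    "preprocess_pipeline",
    "run_sweep",
    "frequency_landscape",
    "local_maxima",
    "subsample_cells",
    "downsample_umis",
    "thin_counts",
    "joint_subsample",
]

DEFAULT_RESOLUTIONS = tuple(np.round(np.arange(0.1, 2.01, 0.1), 1))
DEFAULT_CELL_GRID = tuple(range(200, 2301, 100))
DEFAULT_UMI_CAPS = (500, 1000, 2500, 4500, 10_000, 25_000, 60_000, 100_000)


def _derive_seed(base: int, *indices: int) -> int:
    """Stable per-grid-point seed below 2**31."""
    ss = np.random.SeedSequence([int(base), *[int(i) for i in indices]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class ClusteringParams:
    """Fixed pipeline parameters used by the sweep and subsampling experiments."""

    n_hvg: int = 2000
    n_pcs: int = 50
    resolution: float = 0.9
    knn_k: int = DEFAULT_KNN
    prune: float = DEFAULT_PRUNE
    scale_clip: float = 10.0
    scale_factor: float = 1e4
    loess_span: float = 0.3
    # nuisance-component policy: exclude components correlated with metadata
    exclude_by_metadata: bool = True
    metadata_columns: tuple = ("batch", "sex")
    metadata_threshold: float = 0.5
    excluded_components: tuple = ()   # explicit exclusions, merged with detected


def preprocess_pipeline(counts: CountMatrix, params: ClusteringParams) -> Embedding:
    """Log-normalize, select HVGs, scale, and run PCA; flag nuisance components."""
    norm = log_normalize(counts, params.scale_factor)
    hvg = select_hvg_vst(counts, n_features=min(params.n_hvg, counts.n_genes - 1),
                         loess_span=params.loess_span, clamp=True)
    genes = hvg.loc[hvg["selected"], "gene"].to_numpy()
    scaled, gene_ids = scale_center(norm, genes, clip_max=params.scale_clip)
    n_comp = min(params.n_pcs, min(scaled.shape) - 1)
    emb = run_pca(scaled, gene_ids, counts.cell_ids, n_components=n_comp)

    excluded = set(params.excluded_components)
    if params.exclude_by_metadata and counts.cell_meta is not None:
        cols = [c for c in params.metadata_columns if c in counts.cell_meta.columns]
        if cols:
            excluded |= set(
                nuisance_components(
                    emb, counts.cell_meta[cols], threshold=params.metadata_threshold
                )
            )
    emb.excluded_components = tuple(sorted(d for d in excluded if d <= n_comp))
    return emb


def cluster_pipeline(
    counts: CountMatrix, params: ClusteringParams, seed: int
) -> ClusterLabels:
    """Full pipeline from a (QC-filtered) count matrix to cluster labels."""
    emb = preprocess_pipeline(counts, params)
    k = min(params.knn_k, counts.n_cells - 1)
    graph = build_snn(emb, dims=emb.dims(), k=k, prune=params.prune)
    return louvain(graph, resolution=params.resolution, seed=seed)


# ---------------------------------------------------------------------------
# PC x resolution sweep
# ---------------------------------------------------------------------------


@dataclass
class SweepResult:
    """Grid of (n_pcs, resolution) -> cluster count."""

    grid: pd.DataFrame  # columns n_pcs, resolution, n_clusters, seed
    pcs_range: tuple
    excluded: tuple
    res_range: tuple
    base_seed: int

    @property
    def n_points(self) -> int:
        return len(self.grid)


def run_sweep(
    embedding: Embedding,
    pcs_range=None,
    excluded: tuple = (),
    res_range=DEFAULT_RESOLUTIONS,
    seed: int = 0,
    knn_k: int = DEFAULT_KNN,
    prune: float = DEFAULT_PRUNE,
) -> SweepResult:
    """Cluster at every (leading-PC count, resolution) grid point.

    For column p the graph uses components {1..p} minus ``excluded``; columns
    whose dim set is empty are skipped with a warning. One graph is built per
    column and Louvain runs at each resolution with a derived seed.
    """
    if pcs_range is None:
        pcs_range = tuple(range(1, embedding.n_components + 1))
    pcs_range = tuple(int(p) for p in pcs_range)
    if max(pcs_range) > embedding.n_components:
        raise ValueError(
            f"pcs_range max {max(pcs_range)} exceeds the "
            f"{embedding.n_components}-component embedding"
        )
    excluded = tuple(sorted(set(int(d) for d in excluded)))

    records = []
    for p in pcs_range:
        dims = [d for d in range(1, p + 1) if d not in excluded]
        if not dims:
            logger.warning("PC column %d excluded entirely; skipped", p)
            continue
        graph = build_snn(embedding, dims=dims, k=knn_k, prune=prune)
        for r in res_range:
            s = _derive_seed(seed, p, int(round(float(r) * 10)))
            labels = louvain(graph, resolution=float(r), seed=s)
            records.append(
                {"n_pcs": p, "resolution": float(r),
                 "n_clusters": labels.n_clusters, "seed": s}
            )
    return SweepResult(
        grid=pd.DataFrame(records),
        pcs_range=pcs_range,
        excluded=excluded,
        res_range=tuple(float(r) for r in res_range),
        base_seed=int(seed),
    )


@dataclass
class FrequencyLandscape:
    """Histogram of cluster counts over a parameter grid, with its maxima."""

    frequencies: dict            # n_clusters -> count of grid points
    support: tuple               # sorted observed cluster counts
    local_maxima: tuple
    global_maxima: tuple         # argmax frequency; ties all reported

    @property
    def global_maximum(self) -> int:
        return self.global_maxima[0]


def local_maxima(frequencies: dict) -> tuple:
    """Support values whose frequency strictly exceeds both neighbors on the
    observed support (endpoints compare to their single neighbor)."""
    support = sorted(frequencies)
    out = []
    for i, v in enumerate(support):
        f = frequencies[v]
        left_ok = i == 0 or f > frequencies[support[i - 1]]
        right_ok = i == len(support) - 1 or f > frequencies[support[i + 1]]
        if left_ok and right_ok:
            out.append(v)
    return tuple(out)


def frequency_landscape(sweep: SweepResult) -> FrequencyLandscape:
    """Frequency of each observed cluster count over the sweep grid."""
    if sweep.n_points == 0:
        raise ValueError("empty sweep")
    counts = sweep.grid["n_clusters"].value_counts().to_dict()
    freqs = {int(k): int(v) for k, v in counts.items()}
    support = tuple(sorted(freqs))
    top = max(freqs.values())
    glob = tuple(v for v in support if freqs[v] == top)
    return FrequencyLandscape(
        frequencies=freqs,
        support=support,
        local_maxima=local_maxima(freqs),
        global_maxima=glob,
    )


# ---------------------------------------------------------------------------
# subsampling experiments
# ---------------------------------------------------------------------------


@dataclass
class SubsampleResult:
    """Cluster counts across subsampling grid values and replicates."""

    axis: str                    # 'cells' | 'umis' | 'joint'
    table: pd.DataFrame          # columns value, replicate, n_clusters, seed
    replicates: int
    params: ClusteringParams
    base_seed: int

    def grid_means(self) -> pd.Series:
        return self.table.groupby("value")["n_clusters"].mean()


def subsample_cells(
    counts: CountMatrix,
    grid=DEFAULT_CELL_GRID,
    replicates: int = 20,
    params: ClusteringParams | None = None,
    seed: int = 0,
) -> SubsampleResult:
    """Subsample cells without replacement and re-run the full pipeline."""
    params = params or ClusteringParams()
    grid = tuple(int(v) for v in grid)
    if max(grid) > counts.n_cells:
        raise ValueError(
            f"grid value {max(grid)} exceeds the {counts.n_cells} available cells"
        )
    records = []
    for gi, n in enumerate(grid):
        for rep in range(replicates):
            s = _derive_seed(seed, 1, gi, rep)
            rng = np.random.default_rng(s)
            idx = rng.choice(counts.n_cells, size=n, replace=False)
            sub = counts.subset(cell_mask=np.sort(idx))
            labels = cluster_pipeline(sub, params, seed=s)
            records.append(
                {"value": n, "replicate": rep, "n_clusters": labels.n_clusters,
                 "seed": s}
            )
    return SubsampleResult(
        axis="cells",
        table=pd.DataFrame(records),
        replicates=replicates,
        params=params,
        base_seed=int(seed),
    )


def thin_counts(counts: CountMatrix, cap: int, rng: np.random.Generator) -> CountMatrix:
    """Cap each cell's total UMIs at ``cap`` by uniform draws without replacement
    from the cell's UMI multiset (multivariate hypergeometric over genes)."""
    if cap <= 0:
        raise ValueError("cap must be positive")
    csc = sp.csc_matrix(counts.counts)
    totals = np.asarray(csc.sum(axis=0)).ravel()
    out = csc.copy()
    # the 'count' sampler is faster for small draws, 'marginals' for deep ones
    method = "count" if cap < 5000 else "marginals"
    for c in np.flatnonzero(totals > cap):
        col = out.data[out.indptr[c]:out.indptr[c + 1]].astype(np.int64)
        thinned = rng.multivariate_hypergeometric(col, cap, method=method)
        out.data[out.indptr[c]:out.indptr[c + 1]] = thinned
    out.eliminate_zeros()
    return CountMatrix(
        sp.csr_matrix(out), counts.gene_ids, counts.cell_ids, counts.cell_meta
    )


def downsample_umis(
    counts: CountMatrix,
    caps=DEFAULT_UMI_CAPS,
    replicates: int = 20,
    params: ClusteringParams | None = None,
    seed: int = 0,
) -> SubsampleResult:
    """Thin each cell's UMIs to a cap and re-run the full pipeline."""
    params = params or ClusteringParams()
    records = []
    for gi, cap in enumerate(caps):
        for rep in range(replicates):
            s = _derive_seed(seed, 2, gi, rep)
            rng = np.random.default_rng(s)
            thinned = thin_counts(counts, int(cap), rng)
            labels = cluster_pipeline(thinned, params, seed=s)
            records.append(
                {"value": int(cap), "replicate": rep,
                 "n_clusters": labels.n_clusters, "seed": s}
            )
    return SubsampleResult(
        axis="umis",
        table=pd.DataFrame(records),
        replicates=replicates,
        params=params,
        base_seed=int(seed),
    )


def joint_subsample(
    counts: CountMatrix,
    n_cells: int,
    cap: int,
    replicates: int = 20,
    params: ClusteringParams | None = None,
    seed: int = 0,
) -> SubsampleResult:
    """Subsample cells, then cap UMIs, then re-cluster (both axes at once)."""
    params = params or ClusteringParams()
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    if n_cells > counts.n_cells:
        raise ValueError(
            f"n_cells={n_cells} exceeds the {counts.n_cells} available cells"
        )
    records = []
    for rep in range(replicates):
        s = _derive_seed(seed, 3, rep)
        rng = np.random.default_rng(s)
        idx = rng.choice(counts.n_cells, size=n_cells, replace=False)
        sub = counts.subset(cell_mask=np.sort(idx))
        thinned = thin_counts(sub, int(cap), rng)
        labels = cluster_pipeline(thinned, params, seed=s)
        records.append(
            {"value": n_cells, "replicate": rep, "n_clusters": labels.n_clusters,
             "seed": s}
        )
    return SubsampleResult(
        axis="joint",
        table=pd.DataFrame(records),
        replicates=replicates,
        params=params,
        base_seed=int(seed),
    )
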