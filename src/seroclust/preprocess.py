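"""Log-normalization, vst highly-variable-gene selection, scaling, and PCA.

The vst HVG procedure standardizes raw counts by the standard deviation
predicted from a local-polynomial (degree-2 loess) fit of log10 variance on
log10 mean, clips the standardized values at sqrt(N_cells), and ranks genes by
the variance of the clipped values. Nuisance components (e.g. principal
components dominated by sex or batch) are identified with inspection helpers
and recorded on the embedding; exclusion is applied downstream at graph
construction, not during decomposition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA

from .io_qc import CountMatrix

logger = logging.getLogger("seroclust")

__all__ = [
    "NormMatrix",
    "Embedding",
    "log_normalize",
    "select_hvg_vst",
    "scale_center",
    "run_pca",
    "variance_explained",
    "nuisance_components",
    "top_loadings",
]


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


@dataclass
class NormMatrix:
    """Log-normalized expression: value = ln(1 + count * scale_factor / cell_total)."""

    values: sp.csr_matrix  # genes x cells
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    scale_factor: float
    cell_totals: np.ndarray

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


def log_normalize(counts: CountMatrix, scale_factor: float = 1e4) -> NormMatrix:
    """Library-size log-normalization with the given scale factor.

    Zero-total cells map to all-zero columns (with a warning); counts must be
    non-negative.
    """
    mat = sp.csr_matrix(counts.counts, dtype=np.float64)
    if mat.nnz and mat.data.min() < 0:
        raise ValueError("counts contain negative entries")
    n_cells = mat.shape[1]
    totals = np.bincount(mat.indices, weights=mat.data, minlength=n_cells)
    zero = totals == 0
    if zero.any():
        logger.warning("%d zero-total cells normalize to all-zero columns",
                       int(zero.sum()))
    safe = np.where(zero, 1.0, totals)
    # scale each entry by its cell's factor then log1p, in place on the csr
    # data (column index = cell; sparsity preserved)
    mat.data *= (scale_factor / safe)[mat.indices]
    np.log1p(mat.data, out=mat.data)
    return NormMatrix(
        values=mat,
        gene_ids=counts.gene_ids,
        cell_ids=counts.cell_ids,
        scale_factor=float(scale_factor),
        cell_totals=totals,
    )


# ---------------------------------------------------------------------------
# vst HVG selection
# ---------------------------------------------------------------------------


def _loess_quadratic(x: np.ndarray, y: np.ndarray, span: float,
                     n_grid: int = 100) -> np.ndarray:
    """Degree-2 loess with tricube weights, evaluated at x via a grid.

    The fit is computed on ``n_grid`` points spanning [min(x), max(x)] and
    linearly interpolated back to x; the window contains ceil(span * n) points.
    """
    n = len(x)
    k = max(int(np.ceil(span * n)), 5)
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    grid = np.linspace(xs[0], xs[-1], min(n_grid, n))
    fitted = np.empty_like(grid)
    for i, g in enumerate(grid):
        # window of the k nearest sorted points around g
        pos = np.searchsorted(xs, g)
        lo = max(0, min(pos - k // 2, n - k))
        hi = lo + k
        xw, yw = xs[lo:hi], ys[lo:hi]
        d = np.abs(xw - g)
        dmax = d.max()
        w = (1 - (d / dmax) ** 3) ** 3 if dmax > 0 else np.ones_like(d)
        X = np.column_stack([np.ones_like(xw), xw - g, (xw - g) ** 2])
        WX = X * w[:, None]
        beta, *_ = np.linalg.lstsq(WX.T @ X, WX.T @ yw, rcond=None)
        fitted[i] = beta[0]
    return np.interp(x, grid, fitted)


def select_hvg_vst(
    counts: CountMatrix,
    n_features: int = 2000,
    loess_span: float = 0.3,
    clamp: bool = False,
) -> pd.DataFrame:
    """vst highly-variable-gene selection on raw counts.

    Returns a per-gene table with columns ``mean``, ``variance``,
    ``expected_sd``, ``standardized_variance``, ``rank`` and ``selected``
    (exactly ``n_features`` genes, ties broken by stable gene order).
    """
    mat = sp.csr_matrix(counts.counts, dtype=np.float64)
    n_genes, n_cells = mat.shape
    if n_cells < 2:
        raise ValueError("vst HVG selection needs at least 2 cells")

    nnz = np.diff(mat.indptr)
    occupied = nnz > 0
    starts = mat.indptr[:-1]
    row_sum = np.zeros(n_genes)
    row_sq = np.zeros(n_genes)
    if mat.nnz:
        sums = np.add.reduceat(mat.data, starts[occupied])
        sqs = np.add.reduceat(mat.data**2, starts[occupied])
        row_sum[occupied] = sums
        row_sq[occupied] = sqs
    mean = row_sum / n_cells
    var = (row_sq - n_cells * mean**2) / (n_cells - 1)
    var = np.maximum(var, 0.0)

    positive = var > 0
    if not positive.any():
        raise ValueError("all genes have zero variance")
    if n_features > int(positive.sum()):
        if clamp:
            logger.warning(
                "n_features=%d clamped to the %d genes with positive variance",
                n_features, int(positive.sum()),
            )
            n_features = int(positive.sum())
        else:
            raise ValueError(
                f"n_features={n_features} exceeds the {int(positive.sum())} genes "
                "with positive variance"
            )

    expected_sd = np.zeros_like(var)
    fit = _loess_quadratic(
        np.log10(mean[positive]), np.log10(var[positive]), span=loess_span
    )
    expected_sd[positive] = np.sqrt(10.0**fit)

    # standardized, clipped variance. Unclipped, the z-scores of gene g are
    # mean-centered, so sum(z) = 0 and sum(z^2) = (N-1) var / sd^2; clipping
    # (upper bound sqrt(N); zeros standardize to -mean/sd, never clipped)
    # touches only entries above mean + clip * sd, which are located per gene
    # and corrected explicitly.
    clip = np.sqrt(n_cells)
    sd_safe = np.where(expected_sd > 0, expected_sd, 1.0)
    s1 = np.zeros(n_genes)
    s2 = (n_cells - 1) * var / sd_safe**2
    row_max = np.zeros(n_genes)
    if mat.nnz:
        row_max[occupied] = np.maximum.reduceat(mat.data, starts[occupied])
    threshold = mean + clip * sd_safe
    for g in np.flatnonzero((row_max > threshold) & positive):
        vals = mat.data[mat.indptr[g]:mat.indptr[g + 1]]
        big = vals[vals > threshold[g]]
        z_big = (big - mean[g]) / sd_safe[g]
        s1[g] += (clip - z_big).sum()
        s2[g] += len(big) * clip**2 - (z_big**2).sum()
    std_var = np.zeros_like(var)
    std_var[positive] = (
        (s2[positive] - s1[positive] ** 2 / n_cells) / (n_cells - 1)
    )

    order = np.argsort(-std_var, kind="stable")
    rank = np.empty(len(order), dtype=int)
    rank[order] = np.arange(1, len(order) + 1)
    selected = rank <= n_features

    return pd.DataFrame(
        {
            "gene": counts.gene_ids,
            "mean": mean,
            "variance": var,
            "expected_sd": expected_sd,
            "standardized_variance": std_var,
            "rank": rank,
            "selected": selected,
        }
    )


# ---------------------------------------------------------------------------
# scaling and PCA
# ---------------------------------------------------------------------------


def scale_center(
    norm: NormMatrix,
    genes: np.ndarray | list,
    clip_max: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene z-scoring of the log-normalized data over the given genes.

    Returns ``(scaled, gene_ids)`` where ``scaled`` is a dense genes x cells
    float32 array with values clipped at +/- clip_max. Zero-variance genes
    scale to all-zero rows (with a warning).
    """
    genes = np.asarray(genes, dtype=object)
    gmap = {g: i for i, g in enumerate(norm.gene_ids)}
    missing = [g for g in genes if g not in gmap]
    if missing:
        raise KeyError(f"genes absent from the matrix: {missing[:5]}")
    idx = np.array([gmap[g] for g in genes])

    dense = np.asarray(norm.values[idx, :].todense(), dtype=np.float64)
    mu = dense.mean(axis=1, keepdims=True)
    sd = dense.std(axis=1, ddof=1, keepdims=True)
    # constant rows can carry sd ~ 1 ulp of the mean; treat those as flat
    flat = sd.ravel() <= 1e-12 * (np.abs(mu).ravel() + 1.0)
    if flat.any():
        logger.warning("%d zero-variance genes scaled to zero rows", int(flat.sum()))
    sd[flat, :] = 1.0
    scaled = (dense - mu) / sd
    np.clip(scaled, -clip_max, clip_max, out=scaled)
    scaled[flat, :] = 0.0
    return scaled.astype(np.float32), genes


@dataclass
class Embedding:
    """PCA embedding: cell coordinates, orthonormal gene loadings, variances.

    Components are 1-based in all public interfaces (``dims=[1, 2, ...]``);
    ``excluded_components`` are recorded here but applied only when graphs are
    built.
    """

    coordinates: np.ndarray        # cells x components
    loadings: np.ndarray           # genes x components, orthonormal columns
    component_variance: np.ndarray
    total_variance: float
    excluded_components: tuple
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    @property
    def n_components(self) -> int:
        return self.coordinates.shape[1]

    def dims(self, n_pcs: int | None = None, excluded: tuple | None = None) -> np.ndarray:
        """1-based component indices 1..n_pcs minus the excluded set."""
        n = self.n_components if n_pcs is None else n_pcs
        excl = set(self.excluded_components if excluded is None else excluded)
        return np.array([d for d in range(1, n + 1) if d not in excl])


def run_pca(
    scaled: np.ndarray,
    gene_ids: np.ndarray,
    cell_ids: np.ndarray,
    n_components: int = 50,
    excluded_components: tuple = (),
) -> Embedding:
    """PCA of cells in the scaled gene space with a deterministic sign convention
    (the largest-magnitude loading of each component is positive)."""
    n_genes, n_cells = scaled.shape
    max_rank = min(n_genes, n_cells) - 1
    if n_components > max_rank:
        raise ValueError(
            f"n_components={n_components} exceeds min(genes, cells) - 1 = {max_rank}"
        )
    X = np.ascontiguousarray(scaled.T, dtype=np.float64)  # cells x genes
    solver = "randomized" if min(X.shape) > 4 * n_components else "full"
    pca = PCA(n_components=n_components, svd_solver=solver, random_state=0,
              iterated_power=4 if solver == "randomized" else "auto")
    coords = pca.fit_transform(X)
    loadings = pca.components_.T  # genes x components

    # sign convention: largest-|loading| gene positive per component
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            coords[:, j] *= -1

    total_var = float(scaled.astype(np.float64).var(axis=1, ddof=1).sum())
    return Embedding(
        coordinates=coords,
        loadings=loadings,
        component_variance=pca.explained_variance_.copy(),
        total_variance=total_var,
        excluded_components=tuple(sorted(excluded_components)),
        gene_ids=np.asarray(gene_ids, dtype=object),
        cell_ids=np.asarray(cell_ids, dtype=object),
    )


def variance_explained(embedding: Embedding, k: int) -> float:
    """Fraction of total variance carried by the first k components."""
    if k > embedding.n_components:
        raise ValueError(f"k={k} exceeds {embedding.n_components} components")
    if k == 0:
        return 0.0
    return float(embedding.component_variance[:k].sum() / embedding.total_variance)


# ---------------------------------------------------------------------------
# nuisance-component inspection helpers
# ---------------------------------------------------------------------------


def top_loadings(embedding: Embedding, component: int, n: int = 20) -> pd.DataFrame:
    """Top-|loading| genes of one (1-based) component, for manual inspection."""
    v = embedding.loadings[:, component - 1]
    order = np.argsort(-np.abs(v))[:n]
    return pd.DataFrame({"gene": embedding.gene_ids[order], "loading": v[order]})


def nuisance_components(
    embedding: Embedding,
    metadata: pd.DataFrame,
    threshold: float = 0.5,
    max_components: int | None = None,
) -> tuple:
    """Components whose coordinates correlate with a metadata factor.

    Each metadata column is integer-coded and the absolute Pearson correlation
    with every component's coordinates computed; components exceeding
    ``threshold`` for any factor are returned (1-based, sorted). This is the
    inspection helper used to flag sex/batch-dominated components; the caller
    decides whether to exclude them.
    """
    k = embedding.n_components if max_components is None else max_components
    flagged = set()
    for col in metadata.columns:
        codes, _ = pd.factorize(metadata[col])
        codes = codes.astype(float)
        if np.std(codes) == 0:
            continue
        for j in range(k):
            c = embedding.coordinates[:, j]
            r = np.corrcoef(c, codes)[0, 1]
            if np.abs(r) >= threshold:
                flagged.add(j + 1)
    return tuple(sorted(flagged))
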