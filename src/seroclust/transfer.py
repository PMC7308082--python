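"""Reference-based label transfer and correspondence tables.

A fitted reference freezes the pipeline state (HVG set, per-gene scaling
statistics, PCA loadings, reference coordinates and labels). Query cells are
log-normalized, z-scored with the *reference* statistics on the shared HVGs
(genes missing from the query enter as zero, i.e. at the reference mean),
projected through the reference loadings, and labeled by a Gaussian-kernel
weighted vote of the nearest reference cells. The projection is affine and
deterministic, so repeated transfers are bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .io_qc import CountMatrix
from .preprocess import log_normalize, run_pca, scale_center, select_hvg_vst

logger = logging.getLogger("seroclust")

__all__ = [
    "ReferenceModel",
    "TransferResult",
    "fit_reference",
    "transfer_labels",
    "correspondence_table",
]


@dataclass
class ReferenceModel:
    """Frozen reference pipeline state for query projection."""

    hvg_ids: np.ndarray           # HVGs in model order
    gene_means: np.ndarray        # per-HVG mean of log-normalized values
    gene_sds: np.ndarray          # per-HVG sd (ddof=1); zero-variance -> 1
    loadings: np.ndarray          # HVGs x components
    center: np.ndarray            # per-component offset (PCA centering term)
    dims: np.ndarray              # 1-based components used for neighbor search
    ref_coords: np.ndarray        # reference cells x |dims|, via project_query
    ref_labels: np.ndarray
    ref_cell_ids: np.ndarray
    k_transfer: int = 30
    scale_factor: float = 1e4
    clip_max: float = 10.0

    @property
    def label_set(self) -> np.ndarray:
        return np.unique(self.ref_labels)


@dataclass
class TransferResult:
    """Per-query-cell predicted label with normalized per-label scores."""

    predicted: np.ndarray
    score: np.ndarray             # score of the predicted label, in [0, 1]
    score_matrix: pd.DataFrame    # query cells x reference labels, rows sum to 1
    query_cell_ids: np.ndarray
    n_missing_genes: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.query_cell_ids,
                "predicted": self.predicted,
                "score": self.score,
            }
        )


def fit_reference(
    counts: CountMatrix,
    labels: np.ndarray,
    n_hvg: int = 2000,
    n_pcs: int = 50,
    excluded_components: tuple = (),
    k_transfer: int = 30,
    scale_factor: float = 1e4,
    clip_max: float = 10.0,
    restrict_genes=None,
) -> ReferenceModel:
    """Fit the reference pipeline state from labeled counts.

    ``restrict_genes`` optionally limits the model to a declared query panel;
    dropped HVGs are logged.
    """
    labels = np.asarray(labels)
    if len(labels) != counts.n_cells:
        raise ValueError(
            f"labels length {len(labels)} != {counts.n_cells} reference cells"
        )

    norm = log_normalize(counts, scale_factor)
    hvg = select_hvg_vst(counts, n_features=min(n_hvg, counts.n_genes - 1),
                         clamp=True)
    genes = hvg.loc[hvg["selected"], "gene"].to_numpy()
    if restrict_genes is not None:
        panel = set(restrict_genes)
        kept = np.array([g in panel for g in genes])
        if (~kept).any():
            logger.info("reference restricted to query panel: %d HVGs dropped",
                        int((~kept).sum()))
        genes = genes[kept]

    gmap = {g: i for i, g in enumerate(norm.gene_ids)}
    idx = np.array([gmap[g] for g in genes])
    dense = np.asarray(norm.values[idx, :].todense(), dtype=np.float64)
    means = dense.mean(axis=1)
    sds = dense.std(axis=1, ddof=1)
    sds[sds <= 1e-12 * (np.abs(means) + 1.0)] = 1.0

    scaled, gene_ids = scale_center(norm, genes, clip_max=clip_max)
    n_comp = min(n_pcs, min(scaled.shape) - 1)
    emb = run_pca(scaled, gene_ids, counts.cell_ids, n_components=n_comp,
                  excluded_components=excluded_components)
    dims = emb.dims()
    # centering offset so query projection reproduces the PCA's convention
    z = np.clip((dense - means[:, None]) / sds[:, None], -clip_max, clip_max)
    center = z.mean(axis=1) @ emb.loadings

    model = ReferenceModel(
        hvg_ids=np.asarray(genes, dtype=object),
        gene_means=means,
        gene_sds=sds,
        loadings=emb.loadings,
        center=center,
        dims=dims,
        ref_coords=np.empty((0, 0)),
        ref_labels=labels,
        ref_cell_ids=counts.cell_ids,
        k_transfer=int(k_transfer),
        scale_factor=float(scale_factor),
        clip_max=float(clip_max),
    )
    # reference coordinates are defined BY the projection operator, so
    # re-projecting the reference is an exact identity (self-transfer maps
    # every cell to itself at distance zero)
    model.ref_coords, _ = project_query(model, counts)
    return model


def project_query(model: ReferenceModel, query: CountMatrix,
                  min_overlap: float = 0.5) -> tuple[np.ndarray, int]:
    """Project query cells into the reference component subspace.

    Returns (coordinates in model.dims, number of model HVGs missing from the
    query). Raises if the HVG overlap fraction falls below ``min_overlap``.
    """
    qmap = {g: i for i, g in enumerate(query.gene_ids)}
    present = np.array([g in qmap for g in model.hvg_ids])
    overlap = present.mean()
    if overlap < min_overlap:
        raise ValueError(
            f"query shares only {overlap:.1%} of the reference HVGs "
            f"(minimum {min_overlap:.0%})"
        )
    if (~present).any():
        logger.info("%d reference HVGs missing from query; imputed at the "
                    "reference mean", int((~present).sum()))

    norm = log_normalize(query, model.scale_factor)
    z = np.zeros((len(model.hvg_ids), query.n_cells), dtype=np.float64)
    idx_model = np.flatnonzero(present)
    idx_query = np.array([qmap[g] for g in model.hvg_ids[idx_model]])
    dense = np.asarray(norm.values[idx_query, :].todense(), dtype=np.float64)
    z[idx_model, :] = (dense - model.gene_means[idx_model, None]) / \
        model.gene_sds[idx_model, None]
    np.clip(z, -model.clip_max, model.clip_max, out=z)

    coords = z.T @ model.loadings - model.center  # query cells x components
    return coords[:, model.dims - 1], int((~present).sum())


def transfer_labels(model: ReferenceModel, query: CountMatrix,
                    min_overlap: float = 0.5) -> TransferResult:
    """Assign reference labels to query cells by kernel-weighted k-NN vote."""
    coords, n_missing = project_query(model, query, min_overlap=min_overlap)

    k = min(model.k_transfer, model.ref_coords.shape[0])
    nn = NearestNeighbors(n_neighbors=k).fit(model.ref_coords)
    dist, idx = nn.kneighbors(coords)

    # Gaussian kernel with a per-query bandwidth (mean neighbor distance)
    sigma = dist.mean(axis=1, keepdims=True)
    sigma[sigma == 0] = 1.0
    w = np.exp(-((dist / sigma) ** 2))

    label_set = model.label_set
    label_pos = {lab: i for i, lab in enumerate(label_set)}
    votes = np.zeros((coords.shape[0], len(label_set)))
    neigh_labels = model.ref_labels[idx]
    for j in range(k):
        cols = np.array([label_pos[lab] for lab in neigh_labels[:, j]])
        np.add.at(votes, (np.arange(coords.shape[0]), cols), w[:, j])
    votes /= votes.sum(axis=1, keepdims=True)

    best = np.argmax(votes, axis=1)
    predicted = label_set[best]
    # a zero-distance neighbor is an identical profile: its label is known
    # exactly, so it overrides the smoothed neighborhood vote (this makes
    # self-transfer of the reference an identity map); tolerance covers the
    # float error of the k-NN distance computation
    exact = dist[:, 0] <= 1e-6 * np.maximum(sigma.ravel(), 1.0)
    predicted[exact] = model.ref_labels[idx[exact, 0]]
    score = votes[np.arange(len(best)),
                  np.array([label_pos[lab] for lab in predicted])]
    return TransferResult(
        predicted=predicted,
        score=score,
        score_matrix=pd.DataFrame(votes, columns=list(label_set)),
        query_cell_ids=query.cell_ids,
        n_missing_genes=n_missing,
    )


def correspondence_table(result: TransferResult, query_groups) -> pd.DataFrame:
    """Row-normalized fractions of each query group assigned to each reference
    label (the dot-plot table). Empty groups are dropped with a warning."""
    groups = np.asarray(query_groups)
    if len(groups) != len(result.predicted):
        raise ValueError("query_groups must cover every query cell")
    df = pd.DataFrame({"group": groups, "predicted": result.predicted})
    table = pd.crosstab(df["group"], df["predicted"], normalize="index")
    empty = set(pd.unique(groups)) - set(table.index)
    for g in sorted(empty):
        logger.warning("query group %r is empty; row dropped", g)
    return table
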