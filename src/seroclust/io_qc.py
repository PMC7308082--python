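"""Count-matrix container, 10X-style Matrix Market I/O, and the QC filter cascade.

The QC cascade mirrors the filtering applied to droplet scRNA-seq libraries of
*Pet1*-lineage dorsal-raphe neurons: a gene-prevalence filter followed by
per-cell filters on library complexity, mitochondrial / ribosomal detected-gene
fractions, glial-marker contamination, lineage-marker (*Fev*) expression, and
robust (median +/- k*MAD) outlier rules on library size and gene detection.
"""

from __future__ import annotations

import gzip
import io
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("seroclust")

__all__ = [
    "CountMatrix",
    "FilterParams",
    "QCTable",
    "QCReport",
    "FormatError",
    "read_counts_10x",
    "write_counts_10x",
    "compute_qc",
    "apply_filters",
]


class FormatError(ValueError):
    """A 10X-dialect input directory is malformed (missing file, bad header, ...)."""


# ---------------------------------------------------------------------------
# CountMatrix
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Sparse genes x cells UMI count matrix with identifiers and metadata.

    Parameters
    ----------
    counts
        Non-negative integer sparse matrix, genes in rows, cells in columns.
    gene_ids
        Unique gene identifiers, one per row.
    cell_ids
        Unique cell barcodes, one per column.
    cell_meta
        Optional per-cell table (batch, sex, ...) indexed like ``cell_ids``.
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    cell_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise FormatError(
                f"gene_ids length {len(self.gene_ids)} != {n_genes} matrix rows"
            )
        if len(self.cell_ids) != n_cells:
            raise FormatError(
                f"cell_ids length {len(self.cell_ids)} != {n_cells} matrix columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise FormatError("gene_ids are not unique")
        if len(set(self.cell_ids)) != n_cells:
            raise FormatError("cell_ids are not unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts contain negative entries")
        if self.counts.nnz and np.any(self.counts.data != np.round(self.counts.data)):
            raise ValueError("counts contain non-integer entries")
        if self.cell_meta is not None and len(self.cell_meta) != n_cells:
            raise FormatError("cell_meta length does not match number of cells")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, gene: str) -> int:
        idx = np.flatnonzero(self.gene_ids == gene)
        if idx.size == 0:
            raise KeyError(f"gene {gene!r} not found")
        return int(idx[0])

    def subset(self, gene_mask=None, cell_mask=None) -> "CountMatrix":
        """Return a new CountMatrix restricted to the given boolean masks."""
        mat = self.counts
        gid, cid, meta = self.gene_ids, self.cell_ids, self.cell_meta
        if gene_mask is not None:
            gene_mask = np.asarray(gene_mask)
            mat = mat[gene_mask, :]
            gid = gid[gene_mask]
        if cell_mask is not None:
            cell_mask = np.asarray(cell_mask)
            mat = mat[:, cell_mask]
            cid = cid[cell_mask]
            if meta is not None:
                meta = meta.iloc[np.flatnonzero(cell_mask)].reset_index(drop=True) \
                    if cell_mask.dtype == bool else meta.iloc[cell_mask].reset_index(drop=True)
        return CountMatrix(sp.csr_matrix(mat), gid, cid, meta)


# ---------------------------------------------------------------------------
# 10X-dialect Matrix Market I/O
# ---------------------------------------------------------------------------


def _open_maybe_gz(path: str, mode: str = "rt"):
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _find_file(directory: str, stem: str) -> str:
    for name in (stem, stem + ".gz"):
        candidate = os.path.join(directory, name)
        if os.path.exists(candidate):
            return candidate
    raise FormatError(f"missing file {stem}[.gz] in {directory}")


def read_counts_10x(path: str) -> CountMatrix:
    """Read a 10X-style directory (matrix.mtx[.gz], features.tsv[.gz], barcodes.tsv[.gz]).

    features.tsv may have 1-3 columns (id, name, type); the first column is used
    as the gene identifier. A ``cell_meta.tsv`` file, if present, is attached.
    """
    mtx_path = _find_file(path, "matrix.mtx")
    feat_path = _find_file(path, "features.tsv")
    bc_path = _find_file(path, "barcodes.tsv")

    with _open_maybe_gz(mtx_path, "rb") as fh:
        try:
            mat = scipy.io.mmread(io.BytesIO(fh.read()))
        except Exception as exc:  # scipy raises bare ValueError on bad headers
            raise FormatError(f"cannot parse {mtx_path}: {exc}") from exc
    mat = sp.csr_matrix(mat)
    if mat.nnz and np.any(mat.data != np.round(mat.data)):
        raise FormatError(f"{mtx_path} contains non-integer entries")
    mat = mat.astype(np.int64)

    with _open_maybe_gz(feat_path) as fh:
        features = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    with _open_maybe_gz(bc_path) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]

    if len(features) != mat.shape[0]:
        raise FormatError(
            f"{feat_path} has {len(features)} lines but matrix declares "
            f"{mat.shape[0]} genes"
        )
    if len(barcodes) != mat.shape[1]:
        raise FormatError(
            f"{bc_path} has {len(barcodes)} lines but matrix declares "
            f"{mat.shape[1]} cells"
        )

    gene_ids = np.array([row[0] for row in features], dtype=object)
    cell_ids = np.array(barcodes, dtype=object)

    meta = None
    meta_path = os.path.join(path, "cell_meta.tsv")
    if os.path.exists(meta_path):
        meta = pd.read_csv(meta_path, sep="\t")

    return CountMatrix(mat, gene_ids, cell_ids, meta)


def write_counts_10x(cm: CountMatrix, path: str, gzipped: bool = False) -> None:
    """Write a CountMatrix as matrix.mtx / features.tsv / barcodes.tsv (optionally .gz)."""
    os.makedirs(path, exist_ok=True)
    suffix = ".gz" if gzipped else ""

    buf = io.BytesIO()
    scipy.io.mmwrite(buf, sp.coo_matrix(cm.counts), field="integer")
    opener = gzip.open if gzipped else open
    with opener(os.path.join(path, "matrix.mtx" + suffix), "wb") as fh:
        fh.write(buf.getvalue())
    with opener(os.path.join(path, "features.tsv" + suffix), "wt") as fh:
        for g in cm.gene_ids:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with opener(os.path.join(path, "barcodes.tsv" + suffix), "wt") as fh:
        for b in cm.cell_ids:
            fh.write(f"{b}\n")
    if cm.cell_meta is not None:
        cm.cell_meta.to_csv(os.path.join(path, "cell_meta.tsv"), sep="\t", index=False)


# ---------------------------------------------------------------------------
# QC metrics and filters
# ---------------------------------------------------------------------------


@dataclass
class FilterParams:
    """Thresholds of the QC cascade.

    Percent thresholds apply to the fraction of a cell's *detected genes*
    belonging to the set (the default interpretation); UMI-fraction variants
    are available via ``fraction_basis='umis'``. Outlier rules are
    median +/- ``outlier_k`` * MAD on log1p scale.
    """

    min_cells_per_gene: int = 10
    min_genes_per_cell: int = 4500
    max_pct_mito: float = 15.0
    min_pct_ribo: float = 2.0
    glial_markers: tuple = ("Plp1", "Olig1", "Aqp4")
    lineage_gene: str = "Fev"
    outlier_k: float = 5.0
    # log1p-scale floor on the MAD of outlier rules: metrics concentrated at a
    # single value (e.g. glial scores near 0) would otherwise collapse the
    # outlier window to zero width and flag any deviation
    mad_floor: float = 0.1
    mito_prefix: tuple = ("mt-",)
    ribo_prefix: tuple = ("Rps", "Rpl")
    mito_genes: tuple | None = None  # explicit override of the prefix rule
    ribo_genes: tuple | None = None
    fraction_basis: str = "detected"  # 'detected' (default) or 'umis'

    def __post_init__(self) -> None:
        for name in ("min_cells_per_gene", "min_genes_per_cell", "max_pct_mito",
                     "min_pct_ribo", "outlier_k"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.fraction_basis not in ("detected", "umis"):
            raise ValueError("fraction_basis must be 'detected' or 'umis'")


@dataclass
class QCTable:
    """Per-cell QC metrics."""

    n_genes_detected: np.ndarray
    n_umis: np.ndarray
    pct_mito: np.ndarray
    pct_ribo: np.ndarray
    glial_score: np.ndarray
    lineage_counts: np.ndarray
    degenerate: np.ndarray  # zero-total cells

    def to_frame(self, cell_ids=None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "n_genes_detected": self.n_genes_detected,
                "n_umis": self.n_umis,
                "pct_mito": self.pct_mito,
                "pct_ribo": self.pct_ribo,
                "glial_score": self.glial_score,
                "lineage_counts": self.lineage_counts,
                "degenerate": self.degenerate,
            }
        )
        if cell_ids is not None:
            df.insert(0, "cell_id", cell_ids)
        return df


@dataclass
class QCReport:
    """Removal bookkeeping for one filter-cascade run."""

    n_input_genes: int
    n_input_cells: int
    n_retained_genes: int
    n_retained_cells: int
    genes_removed_low_prevalence: int
    removal_counts: dict = field(default_factory=dict)
    cell_reasons: pd.DataFrame | None = None  # cell_id x reason boolean flags

    def to_json(self) -> str:
        payload = {
            "n_input_genes": self.n_input_genes,
            "n_input_cells": self.n_input_cells,
            "n_retained_genes": self.n_retained_genes,
            "n_retained_cells": self.n_retained_cells,
            "genes_removed_low_prevalence": self.genes_removed_low_prevalence,
            "removal_counts": self.removal_counts,
        }
        return json.dumps(payload, indent=2)


def _resolve_set(gene_ids: np.ndarray, explicit, prefixes) -> np.ndarray:
    """Boolean gene mask from an explicit list or identifier prefixes."""
    if explicit is not None:
        members = set(explicit)
        mask = np.array([g in members for g in gene_ids])
        missing = members - set(gene_ids)
        if missing:
            logger.warning("gene set members absent from matrix: %s", sorted(missing))
        return mask
    return np.array([any(str(g).startswith(p) for p in prefixes) for g in gene_ids])


def compute_qc(cm: CountMatrix, params: FilterParams | None = None) -> QCTable:
    """Compute per-cell QC metrics.

    ``pct_mito`` / ``pct_ribo`` are, by default, the percent of a cell's
    *detected genes* that belong to the mitochondrial / ribosomal set.
    ``glial_score`` is the mean log-normalized (scale 1e4) expression of the
    glial marker genes. Zero-total cells get all metrics 0 and are flagged
    degenerate.
    """
    params = params or FilterParams()
    counts = sp.csc_matrix(cm.counts)

    mito_mask = _resolve_set(cm.gene_ids, params.mito_genes, params.mito_prefix)
    ribo_mask = _resolve_set(cm.gene_ids, params.ribo_genes, params.ribo_prefix)
    glial_mask = _resolve_set(cm.gene_ids, list(params.glial_markers), ())
    if params.lineage_gene not in set(cm.gene_ids):
        raise KeyError(
            f"lineage gene {params.lineage_gene!r} absent from gene_ids; "
            "the pipeline is lineage-defined"
        )

    detected = counts.copy()
    detected.data = np.ones_like(detected.data)
    n_genes_detected = np.asarray(detected.sum(axis=0)).ravel().astype(int)
    n_umis = np.asarray(counts.sum(axis=0)).ravel().astype(int)

    if params.fraction_basis == "detected":
        mito_num = np.asarray(detected[mito_mask, :].sum(axis=0)).ravel()
        ribo_num = np.asarray(detected[ribo_mask, :].sum(axis=0)).ravel()
        denom = n_genes_detected.astype(float)
    else:
        mito_num = np.asarray(counts[mito_mask, :].sum(axis=0)).ravel()
        ribo_num = np.asarray(counts[ribo_mask, :].sum(axis=0)).ravel()
        denom = n_umis.astype(float)

    degenerate = n_umis == 0
    safe = np.where(denom > 0, denom, 1.0)
    pct_mito = np.where(degenerate, 0.0, 100.0 * mito_num / safe)
    pct_ribo = np.where(degenerate, 0.0, 100.0 * ribo_num / safe)
    if degenerate.any():
        logger.warning("%d zero-total cells flagged degenerate", int(degenerate.sum()))

    # glial score: mean log-normalized expression over resolved glial markers
    size = np.where(n_umis > 0, n_umis, 1).astype(float)
    glial_rows = counts[glial_mask, :].toarray() if glial_mask.any() else np.zeros((0, cm.n_cells))
    if glial_rows.shape[0]:
        norm = np.log1p(glial_rows * (1e4 / size))
        glial_score = norm.mean(axis=0)
    else:
        glial_score = np.zeros(cm.n_cells)

    lineage_counts = np.asarray(
        counts[cm.gene_index(params.lineage_gene), :].todense()
    ).ravel().astype(int)

    return QCTable(
        n_genes_detected=n_genes_detected,
        n_umis=n_umis,
        pct_mito=pct_mito,
        pct_ribo=pct_ribo,
        glial_score=glial_score,
        lineage_counts=lineage_counts,
        degenerate=degenerate,
    )


def _mad_bounds(values: np.ndarray, k: float, mad_floor: float = 0.1
                ) -> tuple[float, float]:
    """(low, high) robust outlier bounds on log1p scale, MAD floored."""
    x = np.log1p(values.astype(float))
    med = np.median(x)
    mad = max(np.median(np.abs(x - med)), mad_floor)
    return med - k * mad, med + k * mad


def apply_filters(
    cm: CountMatrix,
    qc: QCTable | None = None,
    params: FilterParams | None = None,
) -> tuple[CountMatrix, QCReport]:
    """Apply the QC cascade and return (filtered matrix, report).

    Order is fixed: the gene-prevalence filter runs first; all cell filters are
    then evaluated on the gene-filtered matrix. Threshold boundaries are strict
    inequalities ("fewer than", "less than", "greater than"): a cell with
    exactly ``min_genes_per_cell`` detected genes is retained. Because the
    outlier rules are adaptive (median +/- k*MAD of the current cells), the
    cell-filter stage is iterated until no further cell is removed, which
    makes the cascade idempotent by construction.
    """
    params = params or FilterParams()

    # 1. gene-prevalence filter
    detected = cm.counts.copy()
    detected.data = np.ones_like(detected.data)
    cells_per_gene = np.asarray(detected.sum(axis=1)).ravel()
    gene_keep = cells_per_gene >= params.min_cells_per_gene
    filtered = cm.subset(gene_mask=gene_keep)

    # 2. cell filters, iterated to a fixed point
    rule_names = [
        "low_complexity", "high_mito", "low_ribo", "glial", "lineage_low",
        "umi_high_outlier", "genes_high_outlier",
    ]
    all_ids = list(filtered.cell_ids)
    reason_df = pd.DataFrame(
        {name: np.zeros(len(all_ids), dtype=bool) for name in rule_names}
    )
    reason_df.insert(0, "cell_id", all_ids)
    id_pos = {cid: i for i, cid in enumerate(all_ids)}

    current = filtered
    for _ in range(100):
        qc = compute_qc(current, params)

        reasons = {}
        reasons["low_complexity"] = qc.n_genes_detected < params.min_genes_per_cell
        reasons["high_mito"] = qc.pct_mito > params.max_pct_mito
        reasons["low_ribo"] = qc.pct_ribo < params.min_pct_ribo

        _, glial_hi = _mad_bounds(qc.glial_score, params.outlier_k,
                                  params.mad_floor)
        reasons["glial"] = np.log1p(qc.glial_score) > glial_hi

        lin_lo, _ = _mad_bounds(qc.lineage_counts, params.outlier_k,
                                params.mad_floor)
        reasons["lineage_low"] = (qc.lineage_counts == 0) | (
            np.log1p(qc.lineage_counts.astype(float)) < lin_lo
        )

        _, umi_hi = _mad_bounds(qc.n_umis, params.outlier_k, params.mad_floor)
        reasons["umi_high_outlier"] = np.log1p(qc.n_umis.astype(float)) > umi_hi
        _, det_hi = _mad_bounds(qc.n_genes_detected, params.outlier_k,
                                params.mad_floor)
        reasons["genes_high_outlier"] = (
            np.log1p(qc.n_genes_detected.astype(float)) > det_hi
        )

        removed = np.zeros(current.n_cells, dtype=bool)
        for name, mask in reasons.items():
            removed |= mask
            pos = [id_pos[c] for c in current.cell_ids[mask]]
            reason_df.loc[pos, name] = True

        if not removed.any():
            break
        if removed.all():
            raise ValueError("no cells survive the QC cascade")
        current = current.subset(cell_mask=~removed)

    out = current
    counts_by_rule = {
        name: int(reason_df[name].sum()) for name in rule_names
    }
    report = QCReport(
        n_input_genes=cm.n_genes,
        n_input_cells=cm.n_cells,
        n_retained_genes=out.n_genes,
        n_retained_cells=out.n_cells,
        genes_removed_low_prevalence=int((~gene_keep).sum()),
        removal_counts=counts_by_rule,
        cell_reasons=reason_df,
    )
    return out, report
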