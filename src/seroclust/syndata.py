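"""Synthetic UMI-count atlas generator with planted ground truth.

Emulates a deep droplet scRNA-seq atlas of *Pet1*-lineage dorsal-raphe neurons:
~2,500 genuine cells across 14 transcriptomic subtypes (one rare subtype at 4%),
hierarchical marker-block structure (a Gad2-like program shared by subtypes 2-6
and a Slc17a8-like program shared by subtypes 7-14), one bimodal "Tph2-like"
gene whose low mode marks one subtype, batch/sex nuisance expression axes, and
four classes of contaminant cells (glial, debris, high-mitochondrial,
low-ribosomal) that each violate at least one QC rule by construction.

Counts follow a negative-binomial (gamma-Poisson) law: the mean for gene g in
cell c is baseline_g x subtype fold x nuisance fold x cell size factor, with
per-cell size factors lognormal around the target library size. Gene baselines
are drawn from a lognormal whose seed is part of the spec (the simulated
"tissue" is fixed; the sampling seed varies cells and counts), so independent
atlases from one spec share the same gene-expression landscape.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_qc import CountMatrix

logger = logging.getLogger("seroclust")

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "SpecValidationError",
    "default_spec",
    "build_spec",
    "generate_atlas",
]


class SpecValidationError(ValueError):
    """A SyntheticSpec violates one of its invariants."""


@dataclass
class SyntheticSpec:
    """Complete recipe for one synthetic atlas. See :func:`build_spec`."""

    n_genes: int
    n_cells: int
    n_subtypes: int
    proportions: np.ndarray
    markers_per_subtype: int
    marker_fold: float
    subtype_markers: dict          # subtype (1-based) -> list of gene ids
    block_structure: list          # (name, tuple subtypes, list gene ids, fold)
    baseline_mean_log_mu: float
    baseline_mean_log_sigma: float
    dispersion: float
    target_library_size_mean: float
    target_library_size_cv: float
    bimodal_gene: str
    bimodal_high_mean: float
    bimodal_low_mean: float
    bimodal_low_subtype: int       # 1-based subtype index of the low mode
    protein_link_slope: float
    protein_link_center: float
    nuisance_axes: list            # (name, list gene ids, fold)
    contaminants: dict             # class -> cell count
    contaminant_params: dict
    gene_sets: dict                # mitochondrial / ribosomal / glial / lineage
    gene_ids: list
    baseline_multipliers: dict = field(default_factory=dict)
    baseline_seed: int = 1234

    def validate(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if len(p) != self.n_subtypes:
            raise SpecValidationError("proportions length != n_subtypes")
        if abs(p.sum() - 1.0) > 1e-9:
            raise SpecValidationError("proportions do not sum to 1 within 1e-9")
        if (p < 0).any():
            raise SpecValidationError("proportions must be non-negative")
        if self.marker_fold <= 0:
            raise SpecValidationError("marker_fold must be > 0")
        for name, _, _, fold in self.block_structure:
            if fold <= 0:
                raise SpecValidationError(f"block {name!r} fold must be > 0")
        for name, _, fold in self.nuisance_axes:
            if fold <= 0:
                raise SpecValidationError(f"nuisance axis {name!r} fold must be > 0")
        for cls, n in self.contaminants.items():
            if n < 0:
                raise SpecValidationError(f"contaminant count for {cls!r} must be >= 0")
        if len(set(self.gene_ids)) != self.n_genes:
            raise SpecValidationError("gene_ids must be unique and length n_genes")
        marker_genes = {g for gs in self.subtype_markers.values() for g in gs}
        for name, members in self.gene_sets.items():
            if marker_genes & set(members):
                raise SpecValidationError(
                    f"gene set {name!r} overlaps planted subtype markers"
                )
        if not (1 <= self.bimodal_low_subtype <= self.n_subtypes):
            raise SpecValidationError("bimodal_low_subtype out of range")

    def to_json(self) -> str:
        d = asdict(self)
        d["proportions"] = list(np.asarray(self.proportions, dtype=float))
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticSpec":
        d = json.loads(text)
        d["proportions"] = np.asarray(d["proportions"], dtype=float)
        d["subtype_markers"] = {int(k): v for k, v in d["subtype_markers"].items()}
        d["block_structure"] = [
            (n, tuple(s), list(g), f) for n, s, g, f in d["block_structure"]
        ]
        d["nuisance_axes"] = [(n, list(g), f) for n, g, f in d["nuisance_axes"]]
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted annotations for one generated atlas."""

    cell_labels: np.ndarray        # "subtype_01".. or contaminant class name
    marker_map: dict               # subtype (1-based) -> planted marker gene ids
    nuisance_assignments: pd.DataFrame
    protein_positive: np.ndarray   # bool, for the bimodal gene
    size_factors: np.ndarray

    @property
    def is_contaminant(self) -> np.ndarray:
        return ~np.char.startswith(self.cell_labels.astype(str), "subtype_")

    def subtype_index(self) -> np.ndarray:
        """1-based subtype index per cell; 0 for contaminants."""
        out = np.zeros(len(self.cell_labels), dtype=int)
        genuine = ~self.is_contaminant
        out[genuine] = [int(s.split("_")[1]) for s in self.cell_labels[genuine]]
        return out


CONTAMINANT_CLASSES = ("glial", "debris", "high_mito", "low_ribo")


def build_spec(
    n_genes: int = 5000,
    n_cells: int = 2500,
    n_subtypes: int = 14,
    rare_proportion: float = 0.04,
    markers_per_subtype: int = 5,
    marker_fold: float = 4.0,
    block_fold: float = 3.0,
    block_genes_each: int = 40,
    baseline_mean_log_mu: float = 0.0,
    baseline_mean_log_sigma: float = 0.4,
    dispersion: float = 0.1,
    target_library_size_mean: float = 60_000.0,
    target_library_size_cv: float = 0.4,
    n_mito: int = 250,
    n_ribo: int = 150,
    n_glial: int = 20,
    nuisance_genes_each: int = 50,
    sex_fold: float = 2.0,
    batch_fold: float = 1.8,
    n_contaminants: int = 150,
    baseline_seed: int = 1234,
) -> SyntheticSpec:
    """Build a SyntheticSpec; with default arguments this is :func:`default_spec`.

    Subtype 1 is the rare subtype; the remaining mass is split evenly. Two
    hierarchical blocks are planted: "Gad2-like" over subtypes 2-6 and
    "Slc17a8-like" over subtypes 7-14 (clipped to n_subtypes). The bimodal
    "Tph2" gene is low in subtype 13 (or the last subtype if fewer).
    """
    proportions = np.full(n_subtypes, (1.0 - rare_proportion) / (n_subtypes - 1))
    proportions[0] = rare_proportion

    # --- gene layout (deterministic names) ---
    gene_ids: list[str] = ["Fev", "Tph2"]
    glial = ["Plp1", "Olig1", "Aqp4"] + [f"Glial{i:02d}" for i in range(4, n_glial + 1)]
    gene_ids += glial
    mito = [f"mt-{i:04d}" for i in range(1, n_mito + 1)]
    gene_ids += mito
    ribo = [f"Rps{i:04d}" for i in range(1, n_ribo // 2 + 1)]
    ribo += [f"Rpl{i:04d}" for i in range(1, n_ribo - len(ribo) + 1)]
    gene_ids += ribo

    subtype_markers = {
        s: [f"Marker{s:02d}_{j:02d}" for j in range(1, markers_per_subtype + 1)]
        for s in range(1, n_subtypes + 1)
    }
    for genes in subtype_markers.values():
        gene_ids += genes

    gad_members = tuple(s for s in range(2, 7) if s <= n_subtypes)
    vglut_members = tuple(s for s in range(7, 15) if s <= n_subtypes)
    block_structure = []
    if len(gad_members) >= 2:
        genes = [f"BlockGad2_{j:02d}" for j in range(1, block_genes_each + 1)]
        block_structure.append(("Gad2-like", gad_members, genes, block_fold))
        gene_ids += genes
    if len(vglut_members) >= 2:
        genes = [f"BlockVglut3_{j:02d}" for j in range(1, block_genes_each + 1)]
        block_structure.append(("Slc17a8-like", vglut_members, genes, block_fold))
        gene_ids += genes

    sex_genes = [f"SexGene{j:02d}" for j in range(1, nuisance_genes_each + 1)]
    batch_genes = [f"BatchGene{j:02d}" for j in range(1, nuisance_genes_each + 1)]
    gene_ids += sex_genes + batch_genes
    nuisance_axes = [("sex", sex_genes, sex_fold), ("batch", batch_genes, batch_fold)]

    n_filler = n_genes - len(gene_ids)
    if n_filler < 0:
        raise SpecValidationError(
            f"n_genes={n_genes} too small for the requested gene sets "
            f"({len(gene_ids)} structured genes)"
        )
    gene_ids += [f"Gene{j:04d}" for j in range(1, n_filler + 1)]

    # baseline multipliers give the special sets realistic expression levels:
    # the lineage gene and ribosomal genes are strongly expressed (never drop
    # out in genuine cells), glial markers are near-silent in Pet1 neurons,
    # and the shared neurotransmitter-program genes are abundant (as Gad2 /
    # Slc17a8 / Tph2-pathway transcripts are in raphe neurons), so coarse
    # class structure survives aggressive UMI downsampling.
    multipliers: dict[str, float] = {"Fev": 8.0}
    multipliers.update({g: 3.0 for g in ribo})
    multipliers.update({g: 2.0 for g in mito})
    multipliers.update({g: 0.02 for g in glial})
    for _, _, genes, _ in block_structure:
        multipliers.update({g: 3.0 for g in genes})

    base = n_contaminants // len(CONTAMINANT_CLASSES)
    extra = n_contaminants - base * len(CONTAMINANT_CLASSES)
    contaminants = {
        cls: base + (1 if i < extra else 0)
        for i, cls in enumerate(CONTAMINANT_CLASSES)
    }

    spec = SyntheticSpec(
        n_genes=n_genes,
        n_cells=n_cells,
        n_subtypes=n_subtypes,
        proportions=proportions,
        markers_per_subtype=markers_per_subtype,
        marker_fold=marker_fold,
        subtype_markers=subtype_markers,
        block_structure=block_structure,
        baseline_mean_log_mu=baseline_mean_log_mu,
        baseline_mean_log_sigma=baseline_mean_log_sigma,
        dispersion=dispersion,
        target_library_size_mean=target_library_size_mean,
        target_library_size_cv=target_library_size_cv,
        bimodal_gene="Tph2",
        bimodal_high_mean=300.0,
        bimodal_low_mean=2.0,
        bimodal_low_subtype=min(13, n_subtypes),
        protein_link_slope=1.5,
        protein_link_center=float(np.log(25.0)),
        nuisance_axes=nuisance_axes,
        contaminants=contaminants,
        contaminant_params={
            "glial_fold": 100.0,
            "debris_size_scale": 0.03,
            "mito_boost": 40.0,
            "nonmito_scale": 0.005,
            "mito_size_scale": 0.5,
            "ribo_scale": 0.001,
        },
        gene_sets={
            "mitochondrial": mito,
            "ribosomal": ribo,
            "glial": glial,
            "lineage": ["Fev"],
        },
        gene_ids=gene_ids,
        baseline_multipliers=multipliers,
        baseline_seed=baseline_seed,
    )
    spec.validate()
    return spec


def default_spec() -> SyntheticSpec:
    """The default atlas recipe: 5,000 genes, 2,500 cells, 14 subtypes
    (one at 4%), marker fold 4, two hierarchical blocks, one bimodal gene low
    in subtype 13, and 150 contaminant cells across four classes."""
    return build_spec()


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _gene_index_map(spec: SyntheticSpec) -> dict:
    return {g: i for i, g in enumerate(spec.gene_ids)}


def _baseline_rates(spec: SyntheticSpec) -> np.ndarray:
    """Expected baseline counts per gene at size factor 1, calibrated so the
    mixture-averaged expected library size equals the target."""
    rng = np.random.default_rng(spec.baseline_seed)
    rel = np.exp(
        rng.normal(spec.baseline_mean_log_mu, spec.baseline_mean_log_sigma,
                   spec.n_genes)
    )
    gmap = _gene_index_map(spec)
    for g, m in spec.baseline_multipliers.items():
        rel[gmap[g]] *= m

    # expected multiplicative fold per gene under the subtype mixture and
    # half/half nuisance assignment
    p = np.asarray(spec.proportions, dtype=float)
    efold = np.ones(spec.n_genes)
    for s, genes in spec.subtype_markers.items():
        idx = [gmap[g] for g in genes]
        efold[idx] += p[s - 1] * (spec.marker_fold - 1.0)
    for _, members, genes, fold in spec.block_structure:
        mass = p[[s - 1 for s in members]].sum()
        idx = [gmap[g] for g in genes]
        efold[idx] += mass * (fold - 1.0)
    for _, genes, fold in spec.nuisance_axes:
        idx = [gmap[g] for g in genes]
        efold[idx] *= 0.5 + 0.5 * fold

    bi = gmap[spec.bimodal_gene]
    p_low = p[spec.bimodal_low_subtype - 1]
    expected_bimodal = (
        p_low * spec.bimodal_low_mean + (1.0 - p_low) * spec.bimodal_high_mean
    )
    rel[bi] = 0.0
    scale = (spec.target_library_size_mean - expected_bimodal) / float(
        (rel * efold).sum()
    )
    baseline = rel * scale
    baseline[bi] = 1.0  # placeholder; the bimodal gene mean is set per cell
    return baseline


def generate_atlas(spec: SyntheticSpec, seed: int) -> tuple[CountMatrix, GroundTruth]:
    """Draw one atlas from ``spec``; bit-reproducible given (spec, seed)."""
    spec.validate()
    rng = np.random.default_rng(seed)
    gmap = _gene_index_map(spec)
    baseline = _baseline_rates(spec)

    n_cont = int(sum(spec.contaminants.values()))
    n_total = spec.n_cells + n_cont

    # cell identities: genuine subtypes then contaminant classes, shuffled
    subtype = rng.choice(
        np.arange(1, spec.n_subtypes + 1), size=spec.n_cells,
        p=np.asarray(spec.proportions, dtype=float),
    )
    labels = np.array(
        [f"subtype_{s:02d}" for s in subtype]
        + [cls for cls in CONTAMINANT_CLASSES for _ in range(spec.contaminants[cls])],
        dtype=object,
    )
    order = rng.permutation(n_total)
    labels = labels[order]

    sigma = float(np.sqrt(np.log(1.0 + spec.target_library_size_cv**2)))
    size = np.exp(rng.normal(-0.5 * sigma**2, sigma, n_total))
    size[labels == "debris"] *= spec.contaminant_params["debris_size_scale"]
    # dying high-mito cells also have shrunken libraries
    size[labels == "high_mito"] *= spec.contaminant_params.get("mito_size_scale", 1.0)

    # nuisance factor levels (applied to every cell, genuine or not)
    nuis = {}
    for name, _, _ in spec.nuisance_axes:
        nuis[name] = rng.integers(0, 2, n_total)

    # --- mean matrix: genes x cells ---
    mu = baseline[:, None] * size[None, :]
    mu = mu.astype(np.float64)

    for s in range(1, spec.n_subtypes + 1):
        cols = np.flatnonzero(labels == f"subtype_{s:02d}")
        if cols.size == 0:
            continue
        rows = [gmap[g] for g in spec.subtype_markers[s]]
        mu[np.ix_(rows, cols)] *= spec.marker_fold
        for _, members, genes, fold in spec.block_structure:
            if s in members:
                bidx = [gmap[g] for g in genes]
                mu[np.ix_(bidx, cols)] *= fold

    for name, genes, fold in spec.nuisance_axes:
        cols = np.flatnonzero(nuis[name] == 1)
        rows = [gmap[g] for g in genes]
        mu[np.ix_(rows, cols)] *= fold

    # bimodal gene: two-component mixture across subtypes
    bi = gmap[spec.bimodal_gene]
    low_label = f"subtype_{spec.bimodal_low_subtype:02d}"
    bimeans = np.where(
        labels == low_label, spec.bimodal_low_mean, spec.bimodal_high_mean
    )
    bimeans = np.where(labels == "glial", 0.0, bimeans)
    bimeans = np.where(
        np.isin(labels, ["debris", "high_mito", "low_ribo"]),
        spec.bimodal_low_mean, bimeans,
    )
    mu[bi, :] = bimeans * size

    # contaminant class profiles
    cp = spec.contaminant_params
    mito_rows = [gmap[g] for g in spec.gene_sets["mitochondrial"]]
    ribo_rows = [gmap[g] for g in spec.gene_sets["ribosomal"]]
    glial_rows = [gmap[g] for g in spec.gene_sets["glial"]]
    lineage_row = gmap[spec.gene_sets["lineage"][0]]

    cols = np.flatnonzero(labels == "glial")
    if cols.size:
        mu[np.ix_(glial_rows, cols)] *= cp["glial_fold"]
        mu[lineage_row, cols] = 0.0
        mu[bi, cols] = 0.0

    cols = np.flatnonzero(labels == "high_mito")
    if cols.size:
        nonmito = np.setdiff1d(np.arange(spec.n_genes), mito_rows)
        mu[np.ix_(nonmito, cols)] *= cp["nonmito_scale"]
        mu[np.ix_(mito_rows, cols)] *= cp["mito_boost"]

    cols = np.flatnonzero(labels == "low_ribo")
    if cols.size:
        mu[np.ix_(ribo_rows, cols)] *= cp["ribo_scale"]

    # --- gamma-Poisson draw ---
    phi = float(spec.dispersion)
    lam = rng.gamma(1.0 / phi, mu * phi)
    counts = rng.poisson(lam).astype(np.int32)
    del lam, mu

    # bimodal protein state through a logistic link on log1p transcript count
    logit = spec.protein_link_slope * (
        np.log1p(counts[bi, :].astype(float)) - spec.protein_link_center
    )
    protein_positive = rng.random(n_total) < 1.0 / (1.0 + np.exp(-logit))

    cell_ids = np.array([f"Cell{j:05d}" for j in range(1, n_total + 1)], dtype=object)
    meta = pd.DataFrame(
        {name: np.asarray(levels) for name, levels in nuis.items()}
    )
    if "sex" in meta.columns:
        meta["sex"] = np.where(meta["sex"] == 1, "M", "F")
    if "batch" in meta.columns:
        meta["batch"] = np.where(meta["batch"] == 1, "batch1", "batch0")

    cm = CountMatrix(
        sp.csr_matrix(counts), np.array(spec.gene_ids, dtype=object), cell_ids, meta
    )
    truth = GroundTruth(
        cell_labels=labels,
        marker_map=dict(spec.subtype_markers),
        nuisance_assignments=meta.copy(),
        protein_positive=protein_positive,
        size_factors=size,
    )
    return cm, truth


def write_atlas(cm: CountMatrix, truth: GroundTruth, spec: SyntheticSpec,
                path: str) -> None:
    """Write the 10X-dialect matrix plus truth.tsv and spec.json."""
    import os
    from .io_qc import write_counts_10x

    write_counts_10x(cm, path)
    pd.DataFrame(
        {
            "cell_id": cm.cell_ids,
            "label": truth.cell_labels,
            "protein_positive": truth.protein_positive,
            "size_factor": truth.size_factors,
        }
    ).to_csv(os.path.join(path, "truth.tsv"), sep="\t", index=False)
    with open(os.path.join(path, "spec.json"), "w") as fh:
        fh.write(spec.to_json())
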