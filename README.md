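# seroclust

Cluster-number robustness analysis for droplet scRNA-seq atlases of
*Pet1*-lineage dorsal-raphe (serotonergic) neurons — and for any UMI count
matrix with a similar structure.

Deciding *how many* transcriptomic subtypes a single-cell dataset supports is
notoriously sensitive to clustering parameters. This package implements a
workflow that treats that sensitivity as the object of study:

1. **QC cascade** for 10X-style count matrices: gene-prevalence filter, then
   per-cell filters on detected genes, mitochondrial / ribosomal
   detected-gene fractions, glial-marker contamination, lineage-marker
   (*Fev*) expression, and robust (median ± k·MAD) outlier rules.
2. **Preprocessing**: log-normalization (`ln(1 + c·10⁴/total)`),
   variance-stabilizing-transform selection of the top 2,000 highly variable
   genes, per-gene scaling, PCA, and helpers to flag nuisance components
   (sex/batch-correlated PCs) that are excluded at graph construction.
3. **Clustering**: shared-nearest-neighbor graph (Jaccard weights of k=20
   neighbor sets, prune 1/15), Louvain with resolution γ maximizing
   `Q = (1/2m) Σ[w_ij − γ k_i k_j /(2m)] δ(c_i,c_j)`, cluster dendrograms,
   and one-vs-rest Wilcoxon marker tables (min.pct 0.25, |logFC| ≥ 0.25,
   Bonferroni).
4. **Stability analyses** — the heart of the package:
   * a PC × resolution sweep whose **cluster-number frequency landscape**
     (how often each cluster count appears over the grid) nominates candidate
     subtype numbers as its local maxima;
   * **cell subsampling** and **UMI downsampling** (multivariate
     hypergeometric thinning) with full pipeline re-runs, modeling how many
     subtypes a given experimental design can discover.
5. **Label transfer**: project a query through the frozen reference pipeline
   and assign labels by kernel-weighted k-NN vote; correspondence (dot-plot)
   tables between query groups and reference clusters.
6. **Bimodality deciles**: for a gene like *Tph2* with a two-mode transcript
   distribution, decile partition, protein/transcript intermixing per decile
   (index `1 − |2f − 1|`), and grouped Wilcoxon tests with
   Benjamini–Hochberg correction.

Because the real atlases require accession downloads, the package ships a
**synthetic atlas generator** (`seroclust.syndata`) that plants ground truth:
14 negative-binomial subtypes (one at 4%) with hierarchical Gad2-like /
Slc17a8-like marker blocks, a bimodal *Tph2*-like gene with a logistic
protein link, sex/batch nuisance axes, and four contaminant classes that each
violate a QC rule by construction. Every analysis stage is tested against
what was planted. See `docs/methods.md` for the model and its calibration.

## Worked example

```python
import seroclust as sc
from seroclust.stability import ClusteringParams, preprocess_pipeline

spec = sc.default_spec()                       # 5,000 genes, 2,500 cells, K=14
cm, truth = sc.generate_atlas(spec, seed=1)    # counts + planted ground truth
filtered, report = sc.apply_filters(cm)        # QC cascade
print(filtered.n_cells, report.removal_counts["low_complexity"])
# 2650 cells in -> 2491 out; 78 low-complexity libraries removed

emb = preprocess_pipeline(filtered, ClusteringParams())
print(emb.excluded_components)                 # batch/sex-dominated PCs
# (2, 3)

sweep = sc.run_sweep(emb, pcs_range=range(5, 51, 5),
                     excluded=emb.excluded_components, seed=7)
land = sc.frequency_landscape(sweep)
print(land.global_maxima, land.local_maxima)
# (14,) (4, 9, 12, 14, 23)
```

The landscape says: over 200 parameter combinations, 14 clusters is by far
the most frequent outcome (the planted number), flanked by minor local maxima
at coarser and finer partitions — exactly the kind of multi-peaked evidence
the frequency heuristic is designed to surface. Clustering at resolution 0.9 and testing
markers:

```python
labels = sc.cluster_pipeline(filtered, ClusteringParams(), seed=3)
markers = sc.find_markers(sc.log_normalize(filtered), labels)
print(labels.n_clusters, (markers.p_adjusted < 0.05).sum())
# 14 clusters; 1191 significant marker entries
```

A command-line interface mirrors the stages
(`seroclust simulate|qc|preprocess|cluster|sweep|subsample|transfer|bimodality`);
run `seroclust --help`.

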