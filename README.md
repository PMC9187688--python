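# circsc

Downstream analysis of circular RNAs (circRNAs) in full-length single-cell
RNA-seq data. circRNAs are quantified by reads spanning their back-spliced
junction (BSJ); because most circRNAs are sparse, low-count and highly
cell-type-specific, they need their own downstream stack once a detector has
produced per-cell BSJ counts. `circsc` provides that stack for
computational biologists working with Smart-seq-style (full-length) scRNA-seq
cohorts:

- **Count-matrix construction and I/O** — assemble per-cell BSJ tables into a
  sparse circRNA × cell matrix with consistent 0-based half-open coordinates;
  MTX/TSV round trips and BED export.
- **Cell QC** — per-cell library size, detected genes and mitochondrial
  fraction, with median-absolute-deviation (MAD) outlier removal: a cell is
  dropped when a metric falls beyond `median ± 3 × 1.4826 × MAD` on the
  conventional tail.
- **Filtering and normalization** — circRNAs kept at ≥ 2 supporting BSJ reads
  over the whole dataset (≥ 5 flags high confidence); CPM and gene-derived
  size-factor normalization; circular-to-linear ratios; pseudobulk sums.
- **Specificity** — the Tau index over cell-type mean profiles,

      T = Σᵢ (1 − x̂ᵢ) / (n − 1),   x̂ᵢ = xᵢ / max(x),

  together with a five-way detection-pattern classification (lowly expressed /
  cell-type / tissue / group / general enriched) and one-vs-rest Wilcoxon
  rank-sum marker detection with Benjamini–Hochberg control and a ≥ 3-fold
  criterion.
- **Maternal-to-zygotic dynamics** — stage mean profiles over the four embryo
  time points (TB, TE/ICM, EPI/PE, implanted), row standardization, fuzzy
  c-means clustering (c = 5, fuzzifier m = 1.25), maternal/zygotic labeling of
  cluster centroids and per-stage read composition.
- **Cell-composition deconvolution** — build a marker-circRNA signature matrix
  (features detected in ≥ 2 cell types, significant marker of exactly one) and
  estimate cell-type fractions in bulk profiles by non-negative least squares
  (ν-SVR optional), with standardized-RMSE and Pearson-r fit statistics.
- **Synthetic data** — seeded generators for cell populations with planted
  expression-pattern categories, embryo time courses with maternal decay and
  zygotic activation archetypes, and bulk mixtures with known fractions, each
  returning ground-truth tables.

## Worked example

```python
import numpy as np
from circsc import synthetic, qc, quantify, specificity, deconv

genes, circ, ann, truth = synthetic.simulate_cell_population(
    n_cells=2000, n_genes=1000, n_circ=1000, seed=1
)
report = qc.default_cell_filter(genes)
genes, circ = qc.apply_cell_filter([genes, circ], report["keep"].to_numpy())
ann = [a for a in ann if a.cell_id in set(genes.cell_ids)]

circ, high_conf = quantify.dataset_bsj_filter(circ)          # >= 2 BSJ reads
cpm = quantify.normalize(circ, denominators=quantify.cpm_denominators(genes, circ), mode="cpm")

table = specificity.specificity_table(circ, ann, expr=cpm)
print(table["category"].value_counts())
print("median Tau:", round(table["tau"].median(), 3))

cell_types = {a.cell_id: a.cell_type for a in ann}
markers = specificity.find_markers(cpm, cell_types)
sig = deconv.build_signature(cpm, cell_types, markers)
bulk, true_frac = synthetic.simulate_bulk_mixtures(sig.values, n_samples=10, seed=1)
results = deconv.deconvolve(sig, bulk)
est = np.array([r.fractions.to_numpy() for r in results])
print("fraction recovery r:", round(np.corrcoef(est.ravel(), true_frac.to_numpy().ravel())[0, 1], 3))
```

Output:

```
category
general_enriched      200
cell_type_enriched    200
group_enriched        150
lowly_expressed       125
tissue_enriched       100
Name: count, dtype: int64
median Tau: 0.968
fraction recovery r: 1.0
```

The category counts recover the planted mixture of detection patterns (the
2-read dataset filter has removed most single-read sporadic detections, which
is exactly its job); the median Tau of 0.97 reflects that most detected
circRNAs are concentrated in one cell type; and the deconvolution recovers
the known mixture fractions almost exactly from the circRNA signature.

The same stages are available from a shell:

```sh
circsc simulate population --n-cells 2000 --seed 1 --outdir sim/
circsc qc --genes sim/genes --out qc.tsv
circsc run-all --seed 1 --outdir run/
```

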