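# fibrotalk

Spatially resolved fibroblast–CD4⁺ T-cell crosstalk analysis for
single-cell-resolution spatial transcriptomics of nasal mucosa, built for
studies of allergic rhinitis (AR) and other type-2 inflammatory airway
disease. It is aimed at computational immunologists who have a segmented
cell table (coordinates in µm, cell types, QC covariates) plus a genes ×
cells count matrix from a targeted in-situ assay, and who want to quantify
how stromal cells organize and polarize neighboring T cells.

The package also ships a calibrated synthetic tissue generator that
reproduces the statistical structure of an AR-vs-control cohort (cell-type
zonation, fibroblast expansion, biased CD4⁺ T placement, pro-Th2 ligand
upregulation near T cells, ligand-coupled Th2 expression, clinical
coupling), used throughout the validation suite.

## The quantities it computes

For cells with positions $x_i \in \mathbb{R}^2$ (µm) and types $t_i$, two
cells are *neighbors* when $\lVert x_i - x_j \rVert \le 20\,\mu m$ — the
paracrine signaling range of TSLP/IL-33/CCL17 and the OX40L/ICOSL contacts.

- **Proximity score.** For a type pair $(a,b)$, the observed enrichment
  $E_{obs}$ is the fraction of neighbor pairs joining an $a$- and a
  $b$-cell. Cell-type labels are permuted over the fixed positions
  ($K = 1000$ by default), giving a null sample $E_1,\dots,E_K$; the
  proximity score is $E_{obs}/\bar E_{null}$ and the one-tailed p-value is
  $(1 + \#\{E_k \ge E_{obs}\})/(1+K)$, BH-adjusted across type pairs.
- **Fibroblast ligand score.** For each CD4⁺ T cell with a fibroblast
  within 20 µm, $L = \sum_{g \in \{TSLP, ICOSL, OX40L, CCL17, POSTN\}}
  \mathrm{normExpr}_g$ in the *nearest* such fibroblast, where normExpr is
  $\ln(1 + 10^4 \cdot \mathrm{count}/\mathrm{total})$.
- **Crosstalk score.** Per sample, $C = \frac{1}{N}\sum_{j=1}^{N} L_j$
  over the sample's $N$ T–fibroblast pairs; a composite variant is the
  product adjacency × fibroblast-mediator score × T-cell Th2 score.
- **Module scores** (core Th2 = IL4/IL5/IL13/IL9; 42-gene GATA3-target
  set): binned-control mean expression, min–max normalized to [0, 1].
- **Differential expression** (Wilcoxon, min.pct 0.1, log2FC 0.25, BH),
  **hypergeometric pathway enrichment**, a **ligand–receptor permutation
  test** (TSLP–IL7R, OX40L–TNFRSF4, ICOSL–ICOS by default), adjacency-
  stratified expression contrasts, and Pearson correlation of crosstalk
  scores with clinical severity (serum total IgE, SPT wheal diameter).

See `docs/methods.md` for the full model description, parameter defaults
and limitations.

## Worked example

```python
from fibrotalk import synthetic_data as sd, preprocess, spatial_stats, scoring

panel = sd.generate_panel()                     # 412-gene targeted panel
sample = sd.generate_tissue(sd.SimConfig(), panel, "AR_01", "AR", seed=7)

cells, adata, report = preprocess.filter_cells(sample.cells, sample.adata)
preprocess.normalize_expression(adata)
graph = spatial_stats.build_neighbor_graph(cells, radius=20.0)

print(f"QC: {report.n_input} -> {report.n_retained} cells")
print(f"fibroblast occupancy: {spatial_stats.type_area_fraction(cells, 'fibroblast'):.1f}% of cells")
adj = spatial_stats.adjacency_fraction(graph, cells, "CD4_T", "fibroblast")
print(f"CD4 T adjacency to fibroblasts: {100*adj:.1f}%")
enr = spatial_stats.neighborhood_enrichment(graph, cells, "fibroblast", "CD4_T",
                                            n_perm=1000, seed=7)
print(f"proximity score: {enr.proximity_score:.2f} (p = {enr.p_raw:.3f})")
lig = scoring.fibroblast_ligand_score(cells, graph, adata)
cs = scoring.sample_crosstalk_score(lig, "AR_01")
print(f"crosstalk score: {cs.mean_ligand_score:.2f} over {cs.n_pairs} pairs")
```

prints

```
QC: 4800 -> 4473 cells
fibroblast occupancy: 34.7% of cells
CD4 T adjacency to fibroblasts: 57.5%
proximity score: 1.07 (p = 0.033)
crosstalk score: 6.08 over 281 T-fibroblast pairs
```

QC removed the planted debris/high-mito cells; about a third of the cells
are fibroblasts (this is an AR-preset section) and over half the CD4⁺ T
cells sit within paracrine range of a fibroblast. The proximity score > 1
with p < 0.05 says this colocalization exceeds what random label placement
produces on the same architecture. The crosstalk score of ~6 is this
sample's mean pro-Th2 ligand signal delivered to T cells; control-preset
sections land around 3–4.

The same analysis runs from the shell on an on-disk bundle
(`cells.tsv` + MatrixMarket counts + `clinical.tsv` + `panel.tsv`):

```sh
fibrotalk simulate --out cohort/ --seed 1
fibrotalk run --config run.yaml --out results/ --seed 1
```

where `run.yaml` holds the pipeline settings (`inputs: {dir: cohort}`,
QC thresholds, permutation counts…). The pipeline executes
qc → spatial → score → de → lr → associate → report and writes one TSV per
stage plus a JSON manifest with the config hash and seeds; re-running with
the same config reproduces every output bit-identically.

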