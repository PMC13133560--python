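# Methods

`fibrotalk` quantifies spatially resolved fibroblast–CD4⁺ T-cell crosstalk
in single-cell-resolution spatial transcriptomics of nasal mucosa (allergic
rhinitis, AR, vs non-allergic controls), and ships a calibrated synthetic
tissue generator that reproduces the statistical structure such an analysis
assumes. This note documents the models, the parameters that matter, the
numerical choices, and what the synthetic validation does and does not show.

## Analysis model

**Quality control.** Cells are removed iff they have fewer than 50 detected
genes, more than 20% mitochondrial transcripts, or fewer than 100 total
transcripts (strict inequalities; a cell exactly on every threshold is
kept). Samples with fewer than 3,000 retained cells fail sample-level QC.
Filtering is idempotent and criterion-order-independent because the three
predicates are evaluated jointly.

**Normalization.** Counts are library-size scaled and natural-log
transformed: `value = ln(1 + 10_000 · count / cell_total)`. Zero-total
cells stay all-zero (flagged). All downstream "normalized expression" means
this layer; back-transformed means use `expm1`, which returns counts per
10,000 and is exactly linear in the underlying count fraction.

**Neighbor graphs.** Two cells are neighbors when their Euclidean distance
is ≤ 20 µm, the paracrine signaling range for the mediators studied here
(TSLP, IL-33, CCL17 and the OX40L/ICOSL juxtacrine contacts). The graph is
built per sample by an exact k-d-tree radius query; no boundary correction
is applied. "Adjacency" of a cell to a partner type always means ≥ 1
partner-type neighbor within the radius.

**Neighborhood enrichment.** For a type pair (a, b) the observed
enrichment is the number of a–b neighbor pairs divided by the total number
of neighbor pairs (unordered; the choice cancels from the ratio). The null
permutes the full cell-type label vector over the fixed positions, which
preserves tissue architecture exactly and tests only label–position
association. The proximity score is observed / null mean; the one-tailed
p-value is `(1 + #{null ≥ observed}) / (1 + n_perm)` (add-one, so p is
never 0 and the test is valid — super-uniform — under exchangeability).
On sparse tissues the discrete cross-pair count produces ties with the
null and the p-value is mildly conservative; the calibration suite
therefore uses tissues dense enough (~1,400 cells, ≥ 50 expected
cross-pairs) that the null p-distribution is near-uniform. Permutations
are run within each sample; group statistics aggregate per-sample results,
never pooled cells. BH (Benjamini–Hochberg step-up, via statsmodels)
adjusts across the type pairs tested.

**Tissue occupancy** of a cell type is the cell-count fraction, reported
as a percentage. A Voronoi-area variant would be a natural extension; the
count proxy is the default because segmentation areas are not modeled.

**Module scores.** A gene set's per-cell score is the mean normalized
expression of the set genes minus the mean of binned control genes: panel
genes are ranked by mean expression over the scored pool and cut into 25
equal-frequency bins; for each set gene, up to `n_ctrl = 100` controls are
drawn from its bin (the whole bin, deterministically, when the bin is
small; seeded sampling otherwise). Raw scores are min–max rescaled to
[0, 1] over the scored cell pool; an all-equal pool maps to 0. The pool is
always *all* cells being compared in one analysis (both adjacency strata,
both groups), so strata share one scale. Core Th2 set: IL4, IL5, IL13,
IL9. GATA3-target set: the panel's 42-gene stand-in. Fibroblast mediator
set: TSLP, IL33, CCL17, ICOSL, OX40L, POSTN.

**Fibroblast ligand score.** For each CD4⁺ T cell with ≥ 1 fibroblast
within 20 µm, the minimum-distance fibroblast is selected (distance ties
broken by lexicographically smaller cell id, logged) and the score is the
sum of that fibroblast's normalized expression over TSLP, ICOSL, OX40L,
CCL17, POSTN. T cells without a fibroblast in range are excluded and
counted. The score depends only on pairwise distances and expression, so
it is translation/rotation invariant.

**Crosstalk scores.** The sample-level crosstalk score is the arithmetic
mean of the sample's ligand scores over its N T–fibroblast pairs
(undefined and flagged at N = 0). The composite variant is the product of
three sample-level components: CD4-T-to-fibroblast adjacency fraction,
mean fibroblast mediator module norm-score, and mean CD4-T core-Th2
norm-score. Both are computed and reported because the literature is
ambiguous about which one anchors clinical correlation; the mean-ligand
form is the default for clinical association.

**Differential expression.** Per-gene two-sided Wilcoxon rank-sum between
groups within a cell type, on the normalized layer, pooled cells (the
field's convention) with a per-sample-mean variant available to guard
against pseudoreplication. Genes enter testing when detected in ≥ 10% of
either group. `log2FC = log2((mean expm1 + 1e-9)/(mean expm1 + 1e-9))`.
Upregulated calls require BH-adjusted p < 0.05 and log2FC > 0.25. The
Wilcoxon wrapper uses exact enumeration for combined n ≤ 12 without ties,
otherwise the tie-corrected normal approximation with continuity
correction; all-identical pooled values give p = 1.

**Pathway enrichment.** Upper-tail hypergeometric test per pathway with
fold enrichment `(overlap/hits)/(pathway/universe)` and BH across
pathways.

**Ligand–receptor testing.** For a user-supplied pair list (defaults
TSLP–IL7R, OX40L–TNFRSF4, ICOSL–ICOS) the interaction score is the mean of
the sender-type mean ligand expression and the receiver-type mean receptor
expression. The null shuffles sender/receiver labels among the union of
the two populations (10,000 permutations by default), add-one p, BH across
pairs. This is a deliberately self-contained replacement for
database-driven interaction inference; database curation and downstream
target-network modeling are out of scope.

**Associations.** Adjacency-stratified contrasts compare fibroblast-
adjacent (≥ 1 fibroblast ≤ 20 µm) vs fibroblast-poor (none) CD4⁺ T cells:
fold of back-transformed means, cell-level Wilcoxon p, and per-sample
stratum means for group-level testing. An all-zero distant stratum yields
a flagged infinite fold. Pearson correlations use the two-sided
t-distribution p-value and require n ≥ 3 and nonzero variance.

## Synthetic tissue generator

The generator emulates the cohort the analysis was designed for. Each
sample is a 1,000 × 1,000 µm section with 4,800 cells (defaults; all
configurable through `SimConfig`).

**Panel.** 412 genes: ≥ 3 canonical markers for each of 9 cell types
(CD3E shared by the T lineages), the 4 core Th2 cytokines, the 5 pro-Th2
ligands, IL33, GATA3, the receptors IL7R/TNFRSF4/ICOS, a 42-gene
GATA3-target stand-in set (synthetic ids `GATA3-TGT-*`), 5 mitochondrial
genes, and anonymous background genes padding to 412.

**Placement.** Epithelial cells occupy a 150-µm surface band (wide enough
that the band's pair density does not dominate the tissue-wide neighbor-pair
count — the proximity score normalizes against *all* neighbor pairs, so an
over-dense unrelated compartment would dilute stromal colocalization); all other
types live in the stroma below. Fibroblasts form a clustered network
(cluster centers uniform; one cluster per ~120 fibroblasts; Gaussian
spread 60 µm). Per sample, the fibroblast fraction and the CD4-T adjacency
fraction are drawn from Gaussians at the group presets (AR: 34.2 ± 3.1%
occupancy, 62.3 ± 4.5% adjacency; control: 15.6 ± 2.4%, 28.7 ± 3.8%) — the
between-sample SDs are part of the emulated study conditions. The
adjacent CD4-T contingent is placed uniformly inside the 20-µm disc of a
random *niche-hub* fibroblast (hubs are a random 2.2% subset; T cells
aggregate around few stromal cells, as in the immunostaining pattern this
emulates, which keeps the fraction of T-adjacent fibroblasts near 30%);
the distant contingent is rejection-sampled to have no fibroblast within
20 µm, so the planted adjacency fraction is realized exactly. Setting the
adjacency preset to `None` places CD4 T cells uniformly — the bias-zero
null.

**Counts.** Negative binomial around cell-type mean profiles
(`var = m + α·m²`, default dispersion α = 0.10 — in-situ counts are
near-Poisson, and heavier dispersion would bury the planted single-cell
coupling under count noise) with a log-normal per-cell depth factor
(sd 0.16). Background abundances are deterministic per gene id
(heavy-tailed, log-sd 2.1) and identical across types, samples and groups,
so contrasts on them are null by construction. Depth is calibrated so a
default cell averages ≈ 850 transcripts over ≈ 120 detected genes,
matching the targeted-assay regime; the across-cell transcript SD (~240)
is larger than the assay's printed ±150 because of the heavy-tailed
abundance profile — a known cosmetic mismatch. A per-cell Beta(2, 30)
mitochondrial fraction plus a 2% high-mito tail (25–50%) and a 4% "debris"
subpopulation (depth × 0.06) give the QC filters real work.

**Planted effects.** (1) *Fibroblast activation*: each AR fibroblast
enters an activated pro-Th2 state with probability 0.50 if a CD4 T cell is
within 20 µm and 0.01 otherwise; activated cells scale their mediator
means by per-gene activation effects (log2: TSLP 4.3, IL33 4.0, CCL17 3.6,
ICOSL 3.4, OX40L 3.2, POSTN 3.1). Stochastic, adjacency-biased activation
(rather than deterministic upregulation of every T-adjacent fibroblast) is
what makes ligand scores bimodal — the regime in which a marker-positive
adjacency enrichment of ~3×, an adjacent/non-adjacent IL4 fold of ~2.7 and
a single-cell ligand–IL4 correlation of ~0.8 can hold simultaneously. A
separate uniform `ligand_group_log2fc` dial shifts all AR fibroblasts and
is used for DE-recovery validation. Group-level AR-vs-control DE log2FCs
of the six mediators under these defaults come out ~0.2–0.4 log2 units
above the per-gene effects a bulk contrast of the emulated study reports;
ranking, direction and significance are preserved — a known limitation of
compressing a two-state activation model into one group-level number.
(2) *Th2 coupling*: after non-T counts are drawn, each CD4 T cell's
realized nearest-fibroblast ligand score L (computed exactly as the
pipeline computes it) scales the cell's Th2-gene means by
`exp(0.125·L + ε)`, ε ~ N(0, 0.15); GATA3 couples at 0.85× that log-factor
and GATA3-target/receptor genes at 0.5×. Control samples have slope 0.
(3) *Clinical coupling*: per sample,
`IgE = 10 + 60·crosstalk + N(0, 173)` IU/mL and
`SPT = 1.5 + 1.1·crosstalk + N(0, 3.7)` mm, truncated positive; the noise
SDs come from `σ = slope · SD(crosstalk) · sqrt(1/r² − 1)` at the target
correlations (0.71, 0.65) given the cohort crosstalk SD (~2.9).

**Reproducibility.** Every generator entry point takes one integer seed;
per-sample and clinical sub-streams derive from it via `SeedSequence`
spawning. Identical seeds give bit-identical outputs. Background gene
abundances hash the gene id (CRC32), so they are stable across seeds —
group contrasts on background genes stay null for every seed.

**Calibration.** The presets were calibrated once against the emulated
study's printed group statistics (occupancy, adjacency, TSLP⁺ ratio 3.2,
IL4 fold 2.7, ligand–IL4 r 0.79, IgE r 0.71, SPT r 0.65, QC depth) using
held-out calibration seeds, then frozen. The spatial-composition targets
are planted directly and recover trivially; the coupling targets are
*emergent* — none of the ratio, fold, or correlations is a direct
parameter — so their recovery genuinely exercises the estimators.

## What the synthetic validation shows — and what it does not

Passing the validation suite shows that the estimators are unbiased and
correctly calibrated *under the generator's assumptions*: homogeneous
NB counts with type-specific means, exact segmentation, no spatial
expression gradients beyond the planted ones, no batch effects,
no doublets or segmentation spillover, uniform detection efficiency, and
a single fibroblast state axis. Real in-situ data violate several of
these (segmentation errors leak transcripts between adjacent cells, which
can *create* spurious adjacency–expression coupling; detection efficiency
varies across the slide; fibroblast heterogeneity is richer). Results on
real tissue therefore need the orthogonal controls the original study
used (protein co-staining, qPCR on sorted cells); the suite here
establishes software correctness, not biological validity.

## Numerical choices and degenerate inputs

- Radius queries are exact (`cKDTree.query_pairs`); duplicate coordinates
  are allowed (distance-0 edges).
- Permutation p-values use the add-one estimator and are never 0; BH never
  lowers a p below its raw value and caps at 1.
- Ligand-score pairing breaks distance ties by smaller cell id; annotation
  breaks marker-score ties by lexicographic type name (both logged).
- Empty strata, zero-pair samples, zero-variance correlations and
  all-equal module-score pools return flagged NaN/0 results rather than
  raising, except where the quantity is undefined by contract (no source
  cells, missing genes, empty universe), which raises `ValueError`.
- ε = 1e-9 guards the DE fold; an all-zero distant stratum reports
  fold = +inf with a flag.

## Problem sizes in the shipped validation

The validation suite (`tests/`) uses a 10+10-sample cohort at 4,800
cells/sample for composition recovery, five 4-sample AR cohorts at 2,600
cells/sample for coupling recovery, five 30-patient cohorts at 2,000
cells/sample for clinical recovery, and 200 null tissues at 1,400 cells
for calibration. The reproduction script (`scripts/acceptance.py`) scales
up to five 10-sample AR cohorts at 4,800 cells/sample and ten 30-patient
clinical cohorts at 2,400 cells/sample. These sizes hold the Monte-Carlo
error of every seed-averaged statistic well inside its comparison
tolerance; larger cohorts change the estimates by less than their
sampling error.
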