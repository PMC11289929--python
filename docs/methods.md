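# Methods

`synocircuit` implements the computational chain used to localize the in
vivo target of JAK inhibition in inflammatory arthritis to a cell-to-cell
cytokine circuit: macrophage-derived oncostatin M (OSM) acting on the
OSMR/gp130 receptor complex of synovial fibroblasts, whose downstream
target program (IL6-, RANKL/MMP-like genes) is induced by disease and
abrogated by the drug while the upstream ligand is not. Every stage is a
plain function over an AnnData expression object; this note records the
models, the parameters that matter, and the choices made where the design
was genuinely open.

## Quality control and normalization

Genes detected (count > 0) in fewer than 3 cells are removed first; cell
filters are then evaluated on the gene-filtered matrix in a single pass
(the gene filter is not re-run afterwards): a cell is kept when it detects
at least 200 and at most 7,500 genes and its mitochondrial read fraction —
counts on genes whose symbol starts with a configurable prefix, `mt-` by
default (the mouse convention) — is at most 5%. The feature maximum is
inclusive (keep ≤ 7,500). An empty post-QC matrix raises an explicit error
rather than propagating silently.

Normalization is library-size scaling to 10,000 counts per cell followed by
natural `log1p`:

    x[c,g] = log(1 + counts[c,g] · 1e4 / total[c])

This is the single supported dialect; a variance-stabilizing alternative
(SCTransform-style) is deliberately out of scope, since every downstream
operation only assumes a log-scale layer. Normalization is invariant to
rescaling a cell's library and preserves the raw counts layer.

## Clustering and markers

Clustering follows the standard graph pipeline: top-2,000 highly variable
genes (Seurat-flavor dispersion), unit-variance scaling (clipped at 10),
PCA retaining 30 components (ARPACK, seeded), a 15-nearest-neighbor graph,
and Leiden modularity optimization at resolution 1.0. Everything is
deterministic given the seed. A matrix in which no gene varies is assigned
a single cluster by definition. Minor-population removal is an explicit
drop-list in the run config, never an automatic detector.

Markers are one-vs-rest Wilcoxon rank-sum tests on the normalized layer
(tie-corrected normal approximation), Bonferroni-corrected with the total
number of genes as multiplier. The fold change compares
expm1-backtransformed mean normalized expression inside vs outside the
cluster with a pseudocount of 1e-9; rows are kept at adjusted p < 0.05 and
|log2FC| > 0.1. Clusters with fewer than 3 cells are skipped with a
warning.

## Binned-control signature scores

The signature (module) score of a gene set is the mean normalized
expression of its genes minus the mean over expression-matched controls.
All genes are ranked by their average expression over cells and partitioned
into 24 equal-frequency bins (rank binning, ties broken by gene order — the
value-range binning used by some upstream versions behaves badly on skewed
averages); for each signature gene, 100 control genes are sampled uniformly
without replacement from its bin, excluding signature genes, falling back
to sampling with replacement only when a bin is exhausted. The pooled
control list is de-duplicated before averaging, matching the common
upstream implementation. Scores are computed on the normalized layer (not
scaled/centred), are exactly zero on a constant matrix, are invariant to
adding a constant to all values, and are centred at zero for random sets.

Cytokine-program assignment takes, per cell, the argmax module (ties go to
the first module in column order); the threshold is the 0.95 quantile
(linear interpolation) of the per-cell *maximum* score over all cells, and
cells at or above it receive their argmax label, the rest "other". The
sentence defining this rule admits a per-module reading; that variant is
available via `per_module_threshold=True`, with the across-cells maximum as
the documented default. Top-N target sets are built from a differential
table by filtering to significantly upregulated rows, sorting by log2FC
descending with ties broken by gene symbol, and truncating to the first
min(N, available) genes.

A rheumatoid-arthritis score is conventionally built from the KEGG RA
pathway gene list; KEGG licensing prevents shipping it, so the RA list is
a slot the user fills (any GMT works). Tests use the simulator's planted
sets instead.

## Ligand–receptor interaction test

For each ordered cluster pair (source → target) and each curated pair, the
interaction mean is `(ligand complex mean in source + receptor complex mean
in target) / 2` on normalized expression. Heteromeric complexes take the
minimum over subunits, for both the mean and the expressed-cell fraction —
a complex is only as available as its scarcest chain. A test is *defined*
only when all subunit genes are present and both complex fractions reach
`min_fraction` (default 0.1, the convention of the established
cell-communication tools). The null shuffles cluster labels over all
cells of the condition being scored (conditions are scored independently),
recomputing the mean 1,000 times; `p = (1 + #{permuted ≥ observed}) / (1 +
n_perm)`, so p-values live in (0, 1] and are never exactly zero.

Note what this null tests: cluster-specificity of expression, not condition
differences. Under labels that are exchangeable with respect to the pair
genes the test is calibrated (~5% at α = 0.05); cell types whose overall
library composition differs (e.g. through marker blocks) are *not*
exchangeable even for shared genes, because library-size normalization
couples every gene to the type's total — a property of the statistic worth
remembering when interpreting borderline p-values on real data.

## Pseudo-bulk contrasts

`AverageExpression`-style profiles: per (cluster, condition) group, the
mean over cells of `expm1(normalized)` — linear-scale averages. Condition
contrasts use `log2((mean_a + 1) / (mean_b + 1))` and keep genes with
|log2FC| > 0.25. No p-value is attached: with one profile per condition per
cluster there are no replicates to test over, so the fold-change rule is
the criterion for counting drug-affected genes. Empty groups are absent,
not zero-filled; the contrast is antisymmetric in its condition arguments.

## Gene-set enrichment

Genes are ranked by the difference of class means on log-scale data (the
"difference of classes" metric), descending, ties broken by symbol. The
enrichment score is the classic weighted Kolmogorov–Smirnov running sum:
hits add `|metric|^w / Σ_hits |metric|^w` (weight w = 1 by default), misses
subtract `1/(N − n_hits)`; ES is the signed extreme. Because a pseudo-bulk
contrast has no sample replicates, the null permutes gene labels (random
same-size sets from the universe; the desktop tool silently makes the same
switch in this situation), 1,000 draws by default. NES divides ES by the
mean magnitude of same-sign null scores; the nominal p is the
plus-one-corrected same-sign tail; the FDR q is the pooled-null NES tail
fraction divided by the observed-NES tail fraction, clipped to [0, 1]. An
all-zero metric, or a set whose observed sign has no null mass, is flagged
undefined rather than returning NaN silently.

## The simulator

`generate_atlas` draws counts gene-wise from a negative binomial with
shared dispersion θ = 10 (variance μ + μ²/θ), per-cell log-normal library
factors (σ = 0.3), and a per-cell Beta-distributed mitochondrial fraction
(mean 2%, concentration 30) carried by ten dedicated `mt-` genes, so the QC
filter has real work to do. Gene baselines are log-uniform with natural-log
means in (−3, 3), giving ~7–8k counts per cell over the 2,000-gene default
universe — the median depth of a filtered 10x v3 library; cytokine target
programs draw their baselines from a detectably-expressed window (log-mean
in (0.5, 1.5)) because cytokine target genes are expressed genes, and the
pseudo-bulk +1 pseudocount makes fold changes of near-zero genes invisible
by design. Each cell type gets a block of 40 marker genes at 8× its shared
baseline, enough for the graph clustering to recover types exactly.

Two circuits are planted by default, both with disease log2 effect 1.5 and
full drug reversion:

* **OSM analog** — ligand `Osm` expressed by macrophages, induced by
  disease *in both disease and drug conditions* (the drug does not touch
  the upstream ligand); receptor `Osmr`+`Il6st` and a 50-gene target
  program in fibroblasts, induced by disease and multiplied by
  `2^(effect · (1 − reversion))` under drug.
* **IL6 analog** — ligand `Il6` produced by fibroblasts, itself a pathway
  target gene: near-silent at baseline (log-mean −3), induced 8-fold by
  disease, reverted by drug. Its receptor `Il6ra`+`Il6st` sits on
  macrophages; no downstream macrophage program is modelled.

This asymmetry is the discriminating pattern of a JAK-dependent circuit: the
ligand→fibroblast interaction survives the drug while the
fibroblast-derived downstream ligand's interaction loses significance, and
the fibroblast cluster carries the largest count of drug-affected genes.

Ground truth (cell type, condition, per-cytokine responder flags, program
membership, planted per-(gene, type, condition) log2 effects) is returned
alongside the counts. Everything is bit-reproducible from the seed via
independent spawned generator streams for baselines, per-cell factors and
counts, so the analytic means are available independently of the sampled
matrix (`expected_means`).

What the simulator does **not** model: doublets, ambient RNA, batch
effects, UMI-level noise, per-gene dispersion, correlated gene modules
beyond the planted programs, or the full 19-cluster complexity of a real
synovial atlas. Passing tests therefore demonstrate that the chain recovers
what it is designed to recover under clean negative-binomial noise — not
robustness to the artefacts of real droplet data.

## Problem sizes and numerics

The reference study conditions are 3 cell types × 200 cells × 3 conditions
(1,800 cells × ~2,065 genes), with 1,000 permutations for interaction and
GSEA nulls; recovery checks for the condition contrast use 300 cells per
group, and calibration checks use 100 random signatures / ~500 null
interaction tests / 200 null GSEA replicates. These sizes put every
statistical check at its intended operating point while keeping a full run
in seconds to minutes on one core. Tolerances follow from the statistics:
permutation p-values are compared against exhaustive enumeration within
3 Monte-Carlo standard errors; calibration rates within ±0.02–0.05 of the
nominal 5%; oracle equalities are exact to floating point. Degenerate
inputs (constant matrices, all-zero metrics, single cells, empty groups)
are either well-defined by the rules above or raise explicit errors —
never NaN propagation.
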