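# synocircuit

Single-cell RNA-seq analysis of macrophage–fibroblast cytokine circuits
under drug perturbation — the computational chain used to argue that
OSM→OSMR signaling in synovial fibroblasts is the principal in vivo target
of JAK inhibition in inflammatory arthritis, packaged as a reusable, tested
pipeline with a planted-truth simulator.

It is written for computational biologists who want to run (or audit) this
style of argument on their own cells×genes count matrices: QC and
log-normalization, graph clustering and Wilcoxon markers, binned-control
signature scoring with cytokine-program assignment, curated ligand–receptor
interaction tests with a permutation null, pseudo-bulk condition contrasts,
and gene-set enrichment — plus a negative-binomial simulator that plants
known circuits so every stage can be checked against ground truth.

## The statistics at the core

* **Signature (module) score** of a gene set *S* in cell *c*:
  `score(c) = mean_{g∈S} x_cg − mean_{g∈ctrl} x_cg`, where the controls are
  drawn from 24 equal-frequency bins of average expression (100 per
  signature gene, excluding *S*). Cells whose maximum score over modules
  clears the 0.95 quantile of the per-cell maxima are assigned that module;
  the rest are "other".
* **Ligand–receptor interaction mean** for clusters A→B:
  `(min_subunits mean_A(ligand) + min_subunits mean_B(receptor)) / 2`,
  gated on both complexes being expressed in ≥10% of cells, with
  significance from shuffling cluster labels
  (`p = (1 + #{perm ≥ obs}) / (1 + n_perm)`).
* **Pseudo-bulk contrast**: per (cluster, condition) means of
  `expm1(lognorm)`; genes with `|log2((m_a+1)/(m_b+1))| > 0.25` are the
  condition-affected set.
* **GSEA**: weighted Kolmogorov–Smirnov running sum on genes ranked by the
  difference of class means (log scale); NES and FDR from a 1,000-draw
  gene-label permutation null.

Model details, parameter defaults and the design decisions behind them are
in [docs/methods.md](docs/methods.md).

## Worked example

```python
import synocircuit as syn
from synocircuit import preprocess as pp
from synocircuit.pipeline import pairs_from_cytokines
from synocircuit.scoring import score_signatures, assign_program
from synocircuit.interactions import score_interactions
from synocircuit.pseudobulk import average_expression, condition_deg, affected_gene_summary

cfg = syn.default_config(seed=0)              # 3 cell types x 200 cells x 3 conditions
adata, ann, truth = syn.generate_atlas(cfg)   # (1800, 2015) with planted OSM/IL6 circuits
norm = pp.normalize_log(pp.qc_filter(adata))  # QC keeps 1601 cells here

scores = score_signatures(norm, syn.generate_target_gene_sets(cfg), seed=0)
print(assign_program(scores, quantile=0.95)["assigned_program"].value_counts().to_dict())

for cond in ("disease", "disease_drug"):
    sub = norm[(norm.obs["condition"] == cond).to_numpy()].copy()
    res = score_interactions(sub, pairs_from_cytokines(cfg),
                             labels=sub.obs["cell_type"], n_perm=1000, seed=1)
    osm = res.query("pair_name=='OSM_pair' and source_cluster=='macrophage' and target_cluster=='fibroblast'")
    il6 = res.query("pair_name=='IL6_pair' and source_cluster=='fibroblast' and target_cluster=='macrophage'")
    print(f"{cond}: OSM p={osm.p_value.item():.4g}  IL6 p={il6.p_value.item():.4g}")

norm.obs["cluster"] = norm.obs["cell_type"]
deg = condition_deg(average_expression(norm), "disease", "disease_drug")
print("drug-affected genes per cluster:", affected_gene_summary(deg)[0])
```

Output:

```
{'other': 1520, 'OSM_targets': 81}
disease: OSM p=0.000999  IL6 p=0.000999
disease_drug: OSM p=0.000999  IL6 p=nan
drug-affected genes per cluster: {'fibroblast': 65, 'macrophage': 5, 'tcell': 1}
```

Read: the top-scoring 5% of cells are almost all assigned the planted
OSM target program (and they are fibroblasts — check
`truth.cells["responder_OSM"]`); the macrophage→fibroblast OSM interaction
is significant in disease **and under the drug**, while the
fibroblast-derived IL6 interaction disappears under the drug (its ligand is
itself a pathway target gene and falls below the expressed-fraction gate,
hence `p = nan`); and the fibroblast cluster carries by far the most
drug-affected genes. That asymmetry — upstream ligand untouched, downstream
program abrogated, receptor-bearing cluster most affected — is the
circuit-level fingerprint of JAK inhibition this package is built to
detect.

## Command line

Every stage is also a `synocircuit` subcommand operating on MatrixMarket
triplets and CSVs:

```bash
synocircuit simulate --out-dir data --seed 0
synocircuit qc --data-dir data --out-dir data_qc
synocircuit cluster --data-dir data_qc --out-csv clusters.csv --seed 0
synocircuit score --data-dir data_qc --gmt data/target_sets.gmt --out-csv scores.csv --seed 0
synocircuit run --out-dir run0 --seed 0     # the whole chain, one command
```

`run` writes every artifact (matrices, annotations, marker/score/
interaction/DEG/GSEA tables) plus a `summary.json`; two runs with the same
config and seed are byte-identical.

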