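"""QC filtering, log-normalization, graph clustering and marker finding.

Thresholds default to the values used throughout the package's reference
analysis: genes kept when detected in >=3 cells; cells kept with >=200
detected genes, <=5% mitochondrial reads and <=7,500 detected features;
library-size normalization to 1e4 counts followed by natural-log1p; 30
principal components feeding a kNN graph with modularity-optimizing (Leiden)
community detection; one-vs-rest Wilcoxon rank-sum marker tests with
Bonferroni correction, retained at adjusted p < 0.05 and |log2FC| > 0.1.
"""

from __future__ import annotations

import logging

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp
from scipy.stats import mannwhitneyu

from .io import COUNTS_LAYER, LOGNORM_LAYER, DEFAULT_MITO_PREFIX

__all__ = ["qc_filter", "normalize_log", "cluster_cells", "find_markers"]

logger = logging.getLogger(__name__)

LOG2FC_EPS = 1e-9


def _dense(mat) -> np.ndarray:
    return mat.toarray() if sp.issparse(mat) else np.asarray(mat)


def mito_fraction(adata: ad.AnnData, mito_prefix: str | None = None) -> np.ndarray:
    """Per-cell fraction of counts on mitochondrial (prefix-matched) genes."""
    if mito_prefix is None:
        mito_prefix = adata.uns.get("mito_prefix", DEFAULT_MITO_PREFIX)
    counts = adata.layers[COUNTS_LAYER]
    is_mito = adata.var_names.str.startswith(mito_prefix)
    total = np.asarray(counts.sum(axis=1)).ravel()
    mito = np.asarray(counts[:, is_mito].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    return frac


def qc_filter(
    raw: ad.AnnData,
    min_cells_per_gene: int = 3,
    min_genes_per_cell: int = 200,
    max_mito_frac: float = 0.05,
    max_features: int = 7500,
    mito_prefix: str | None = None,
) -> ad.AnnData:
    """Remove low-quality genes then cells, in a single pass.

    Genes detected (count > 0) in fewer than ``min_cells_per_gene`` cells
    are dropped first; cell filters (detected-gene minimum and maximum,
    mitochondrial-fraction maximum) are then evaluated on the gene-filtered
    matrix. The gene filter is not re-run after cells are removed.
    """
    counts = raw.layers[COUNTS_LAYER]
    cells_per_gene = np.asarray((counts > 0).sum(axis=0)).ravel()
    keep_genes = cells_per_gene >= min_cells_per_gene
    sub = raw[:, keep_genes]

    sub_counts = sub.layers[COUNTS_LAYER]
    genes_per_cell = np.asarray((sub_counts > 0).sum(axis=1)).ravel()
    frac = mito_fraction(sub, mito_prefix)
    keep_cells = (
        (genes_per_cell >= min_genes_per_cell)
        & (genes_per_cell <= max_features)
        & (frac <= max_mito_frac)
    )
    if not keep_cells.any():
        raise ValueError(
            "all cells filtered out by QC "
            f"(min_genes={min_genes_per_cell}, max_mito={max_mito_frac}, "
            f"max_features={max_features})"
        )
    out = sub[keep_cells].copy()
    logger.info(
        "qc_filter: kept %d/%d genes, %d/%d cells",
        int(keep_genes.sum()),
        raw.n_vars,
        int(keep_cells.sum()),
        raw.n_obs,
    )
    return out


def normalize_log(filtered: ad.AnnData, scale_factor: float = 1e4) -> ad.AnnData:
    """Library-size normalization to ``scale_factor`` counts/cell + natural log1p.

    normalized[c, g] = log(1 + counts[c, g] * scale_factor / total_counts[c]).
    The counts layer is preserved; the result is stored both in
    ``layers['lognorm']`` and in ``X`` (downstream operations read X).
    """
    adata = filtered.copy()
    counts = adata.layers[COUNTS_LAYER]
    totals = np.asarray(counts.sum(axis=1)).ravel().astype(float)
    if np.any(totals <= 0):
        bad = adata.obs_names[totals <= 0].tolist()
        raise ValueError(f"cells with zero total counts cannot be normalized: {bad[:5]}")
    if sp.issparse(counts):
        norm = counts.astype(float).multiply(scale_factor / totals[:, None]).tocsr()
        norm.data = np.log1p(norm.data)
    else:
        norm = np.log1p(np.asarray(counts, dtype=float) * scale_factor / totals[:, None])
        norm = sp.csr_matrix(norm)
    adata.layers[LOGNORM_LAYER] = norm
    adata.X = norm.copy()
    return adata


def cluster_cells(
    norm: ad.AnnData,
    n_hvg: int = 2000,
    n_pcs: int = 30,
    resolution: float = 1.0,
    n_neighbors: int = 15,
    seed: int = 0,
    key_added: str = "cluster",
) -> pd.DataFrame:
    """Highly-variable genes -> scale -> PCA -> kNN graph -> Leiden communities.

    Returns the annotation frame (existing obs columns plus the new cluster
    label) indexed by cell_id; also records the label in ``norm.obs``.
    Deterministic given ``seed``.
    """
    if LOGNORM_LAYER not in norm.layers:
        raise ValueError("normalized layer required; run normalize_log first")
    if norm.n_obs < n_pcs + 1:
        raise ValueError(f"need at least n_pcs+1={n_pcs + 1} cells, have {norm.n_obs}")
    if norm.n_obs <= n_neighbors:
        raise ValueError(
            f"need more cells ({norm.n_obs}) than neighbors ({n_neighbors})"
        )
    work = ad.AnnData(
        X=norm.layers[LOGNORM_LAYER].copy(), obs=norm.obs[[]].copy(), var=norm.var[[]].copy()
    )
    dense = work.X.toarray() if sp.issparse(work.X) else np.asarray(work.X)
    if float(dense.var(axis=0).max()) == 0.0:
        # no gene varies across cells: a single community by definition
        norm.obs[key_added] = pd.Categorical(["0"] * norm.n_obs)
        ann = norm.obs.copy()
        ann.index.name = "cell_id"
        return ann
    n_top = min(n_hvg, work.n_vars)
    sc.pp.highly_variable_genes(work, n_top_genes=n_top, flavor="seurat")
    work = work[:, work.var["highly_variable"]].copy()
    sc.pp.scale(work, max_value=10)
    n_comps = min(n_pcs, work.n_obs - 1, work.n_vars - 1)
    sc.tl.pca(work, n_comps=n_comps, svd_solver="arpack", random_state=seed)
    sc.pp.neighbors(work, n_neighbors=n_neighbors, n_pcs=n_comps, random_state=seed)
    sc.tl.leiden(
        work,
        resolution=resolution,
        key_added=key_added,
        random_state=seed,
        flavor="leidenalg",
        n_iterations=-1,
    )
    labels = work.obs[key_added].astype(str)
    norm.obs[key_added] = pd.Categorical(labels)
    ann = norm.obs.copy()
    ann.index.name = "cell_id"
    return ann


def _group_log2fc(x_in: np.ndarray, x_out: np.ndarray) -> np.ndarray:
    """log2 fold change on expm1-backtransformed mean normalized expression."""
    mean_in = np.expm1(x_in).mean(axis=0)
    mean_out = np.expm1(x_out).mean(axis=0)
    return np.log2((mean_in + LOG2FC_EPS) / (mean_out + LOG2FC_EPS))


def find_markers(
    norm: ad.AnnData,
    ann: pd.DataFrame | None = None,
    cluster_key: str = "cluster",
    p_adj_max: float = 0.05,
    min_abs_log2fc: float = 0.1,
    min_cells: int = 3,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum markers per cluster, Bonferroni-corrected.

    The Bonferroni multiplier is the total number of genes in the matrix;
    log2FC compares expm1-backtransformed mean normalized expression inside
    vs outside the cluster with a 1e-9 pseudocount. Rows are retained iff
    p_adj < ``p_adj_max`` and |log2FC| > ``min_abs_log2fc``; direction marks
    positive vs negative markers. Clusters with fewer than ``min_cells``
    cells are skipped with a warning.
    """
    obs = norm.obs if ann is None else ann.loc[norm.obs_names]
    if cluster_key not in obs:
        raise ValueError(f"annotation lacks a {cluster_key!r} column")
    labels = obs[cluster_key].astype(str).to_numpy()
    clusters = pd.unique(labels)
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters for marker finding")

    X = _dense(norm.layers[LOGNORM_LAYER])
    n_genes = norm.n_vars
    genes = norm.var_names.to_numpy()
    rows = []
    for cl in clusters:
        mask = labels == cl
        if mask.sum() < min_cells:
            logger.warning("find_markers: cluster %s has <%d cells, skipped", cl, min_cells)
            continue
        x_in, x_out = X[mask], X[~mask]
        res = mannwhitneyu(x_in, x_out, alternative="two-sided", axis=0)
        p_raw = np.asarray(res.pvalue)
        p_raw = np.where(np.isnan(p_raw), 1.0, p_raw)  # constant genes: no evidence
        p_adj = np.minimum(1.0, p_raw * n_genes)
        lfc = _group_log2fc(x_in, x_out)
        keep = (p_adj < p_adj_max) & (np.abs(lfc) > min_abs_log2fc)
        for gi in np.flatnonzero(keep):
            rows.append(
                (
                    cl,
                    genes[gi],
                    float(lfc[gi]),
                    float(p_raw[gi]),
                    float(p_adj[gi]),
                    "up" if lfc[gi] > 0 else "down",
                )
            )
    return pd.DataFrame(
        rows, columns=["cluster", "gene", "log2FC", "p_raw", "p_adj", "direction"]
    )
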