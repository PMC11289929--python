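"""Directional ligand-receptor interaction scoring with a permutation null.

For every ordered cluster pair (source -> target) and every curated
ligand-receptor pair, the interaction mean is the average of the ligand
complex's mean normalized expression in the source cluster and the receptor
complex's mean in the target cluster. Heteromeric complexes take the
minimum over their subunits (a complex is only as available as its scarcest
chain), and the same min rule applies to expressed-cell fractions, which
gate the test: an interaction is only evaluated where both complexes are
expressed in at least ``min_fraction`` of cells. Significance comes from
shuffling cluster labels over all cells and recomputing the mean, with the
plus-one rule so p-values are never exactly zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
import anndata as ad

from .io import InteractionPair, LOGNORM_LAYER

__all__ = ["complex_value", "score_interactions", "count_significant"]


def _lognorm(adata: ad.AnnData) -> np.ndarray:
    if LOGNORM_LAYER not in adata.layers:
        raise ValueError("normalized layer required; run normalize_log first")
    X = adata.layers[LOGNORM_LAYER]
    return X.toarray() if sp.issparse(X) else np.asarray(X)


def complex_value(
    norm: ad.AnnData,
    labels: pd.Series | np.ndarray,
    complex_subunits: list[str] | tuple[str, ...],
    cluster: str,
) -> tuple[float, float, bool]:
    """(mean, fraction, defined) of a (possibly multi-subunit) complex in a cluster.

    Per subunit: mean normalized expression over the cluster's cells and
    fraction of cells with expression > 0; the complex takes the minimum of
    both across subunits. ``defined`` is False when any subunit gene is
    absent from the matrix.
    """
    labels = np.asarray(pd.Series(labels).astype(str))
    mask = labels == str(cluster)
    if not mask.any():
        raise ValueError(f"cluster {cluster!r} has no cells")
    gene_pos = {g: i for i, g in enumerate(norm.var_names)}
    if any(s not in gene_pos for s in complex_subunits):
        return (float("nan"), float("nan"), False)
    X = _lognorm(norm)
    sub = X[np.ix_(mask, [gene_pos[s] for s in complex_subunits])]
    means = sub.mean(axis=0)
    fracs = (sub > 0).mean(axis=0)
    return (float(means.min()), float(fracs.min()), True)


def _cluster_means(E: np.ndarray, codes: np.ndarray, k: int) -> np.ndarray:
    """k x genes matrix of per-cluster column means."""
    order = np.argsort(codes, kind="stable")
    sizes = np.bincount(codes, minlength=k).astype(float)
    starts = np.concatenate(([0], np.cumsum(sizes[:-1]).astype(int)))
    return np.add.reduceat(E[order], starts, axis=0) / sizes[:, None]


def score_interactions(
    norm: ad.AnnData,
    pairs: list[InteractionPair],
    labels: pd.Series | np.ndarray | None = None,
    cluster_key: str = "cluster",
    min_fraction: float = 0.1,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Score every pair over every ordered cluster pair with a permutation test.

    mean_score(A -> B) = (ligand complex mean in A + receptor complex mean
    in B) / 2, defined only when all subunit genes are present and both
    complex expressed-fractions reach ``min_fraction``. The null shuffles
    cluster labels across all cells ``n_perm`` times;
    p = (1 + #{permuted mean >= observed}) / (1 + n_perm). Deterministic
    given ``seed``. Returns a long-format frame with one row per
    (pair, source cluster, target cluster).
    """
    if not pairs:
        raise ValueError("empty interaction pair list")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if labels is None:
        if cluster_key not in norm.obs:
            raise ValueError(f"obs lacks a {cluster_key!r} column")
        labels = norm.obs[cluster_key]
    labels = pd.Series(np.asarray(pd.Series(labels).astype(str)), index=norm.obs_names)
    clusters = pd.unique(labels.to_numpy())
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    codes = pd.Categorical(labels, categories=clusters).codes.astype(np.int64)
    k = len(clusters)

    genes_needed = sorted(
        {s for p in pairs for s in (*p.ligand_subunits, *p.receptor_subunits)}
    )
    gene_pos = {g: i for i, g in enumerate(norm.var_names)}
    present = [g for g in genes_needed if g in gene_pos]
    col_of = {g: i for i, g in enumerate(present)}
    X = _lognorm(norm)
    E = X[:, [gene_pos[g] for g in present]]

    M = _cluster_means(E, codes, k)  # observed cluster x gene means
    F = _cluster_means((E > 0).astype(float), codes, k)

    n_pairs = len(pairs)
    lig_idx, rec_idx, pair_defined = [], [], []
    for p in pairs:
        ok = all(s in col_of for s in (*p.ligand_subunits, *p.receptor_subunits))
        pair_defined.append(ok)
        lig_idx.append([col_of[s] for s in p.ligand_subunits] if ok else [])
        rec_idx.append([col_of[s] for s in p.receptor_subunits] if ok else [])

    def complex_min(mat: np.ndarray, idx_lists: list[list[int]]) -> np.ndarray:
        out = np.full(mat.shape[:-1] + (n_pairs,), np.nan)
        for j, idx in enumerate(idx_lists):
            if idx:
                out[..., j] = mat[..., idx].min(axis=-1)
        return out

    lig_mean = complex_min(M, lig_idx)  # (k, n_pairs)
    rec_mean = complex_min(M, rec_idx)
    lig_frac = complex_min(F, lig_idx)
    rec_frac = complex_min(F, rec_idx)

    obs_score = 0.5 * (lig_mean[:, None, :] + rec_mean[None, :, :])  # (A,B,pair)
    defined = (
        np.asarray(pair_defined)[None, None, :]
        & (lig_frac[:, None, :] >= min_fraction)
        & (rec_frac[None, :, :] >= min_fraction)
    )

    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(obs_score)
    # permuting labels over cells == dealing cells at random into groups of
    # the observed cluster sizes
    sizes = np.bincount(codes, minlength=k).astype(float)
    starts = np.concatenate(([0], np.cumsum(sizes[:-1]).astype(int)))
    n_cells = E.shape[0]
    for _ in range(n_perm):
        deal = rng.permutation(n_cells)
        Mp = np.add.reduceat(E[deal], starts, axis=0) / sizes[:, None]
        lp = complex_min(Mp, lig_idx)
        rp = complex_min(Mp, rec_idx)
        Sp = 0.5 * (lp[:, None, :] + rp[None, :, :])
        with np.errstate(invalid="ignore"):
            exceed += Sp >= obs_score
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    rows = []
    for ai, a in enumerate(clusters):
        for bi, b in enumerate(clusters):
            for j, p in enumerate(pairs):
                ok = bool(defined[ai, bi, j])
                rows.append(
                    (
                        p.name,
                        a,
                        b,
                        float(obs_score[ai, bi, j]) if ok else np.nan,
                        float(pvals[ai, bi, j]) if ok else np.nan,
                        float(lig_frac[ai, j]) if pair_defined[j] else np.nan,
                        float(rec_frac[bi, j]) if pair_defined[j] else np.nan,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "pair_name",
            "source_cluster",
            "target_cluster",
            "mean_score",
            "p_value",
            "ligand_fraction",
            "receptor_fraction",
        ],
    )


def count_significant(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Source x target matrix counting defined pairs with p < alpha."""
    sig = results[results["mean_score"].notna() & (results["p_value"] < alpha)]
    sources = pd.unique(results["source_cluster"])
    targets = pd.unique(results["target_cluster"])
    mat = pd.DataFrame(0, index=sources, columns=targets, dtype=int)
    for (a, b), grp in sig.groupby(["source_cluster", "target_cluster"], sort=False):
        mat.loc[a, b] = len(grp)
    mat.index.name = "source_cluster"
    mat.columns.name = "target_cluster"
    return mat
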