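"""Gene-set enrichment between two conditions: weighted KS score, NES, FDR.

Genes are ranked by the difference of class means on log-scale data (the
"difference of classes" metric appropriate for already-log expression).
The enrichment score walks the ranking: hits increment the running sum in
proportion to |metric|^weight, misses decrement by 1/(N - n_hits); ES is
the signed extreme of the running sum. Because a pseudo-bulk contrast has
one profile per condition, the null is built by gene-label permutation
(random sets of the same size drawn from the ranked universe) rather than
phenotype permutation. NES divides ES by the mean magnitude of same-sign
null scores; the FDR q follows the standard GSEA recipe on pooled
same-sign null NES values.
"""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import GeneSet, LOGNORM_LAYER

__all__ = ["rank_diff_of_classes", "enrichment_score", "gsea"]


def rank_diff_of_classes(
    norm: ad.AnnData,
    cluster: str,
    cond_a: str,
    cond_b: str,
    cluster_key: str = "cluster",
    condition_key: str = "condition",
    ann: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Rank genes by mean log-scale expression in cond_a minus cond_b, per cluster.

    Returns a frame with columns gene, metric, sorted by metric descending
    with ties broken by gene symbol ascending.
    """
    obs = norm.obs if ann is None else ann.reindex(norm.obs_names)
    clusters = obs[cluster_key].astype(str).to_numpy()
    conditions = obs[condition_key].astype(str).to_numpy()
    in_cluster = clusters == str(cluster)
    mask_a = in_cluster & (conditions == str(cond_a))
    mask_b = in_cluster & (conditions == str(cond_b))
    if not mask_a.any() or not mask_b.any():
        raise ValueError(
            f"cluster {cluster!r} lacks cells in condition "
            f"{cond_a if not mask_a.any() else cond_b!r}"
        )
    X = norm.layers[LOGNORM_LAYER]
    X = X.toarray() if sp.issparse(X) else np.asarray(X)
    metric = X[mask_a].mean(axis=0) - X[mask_b].mean(axis=0)
    df = pd.DataFrame({"gene": norm.var_names.to_numpy(), "metric": metric})
    return df.sort_values(
        ["metric", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def enrichment_score(
    ranked: pd.DataFrame, sig: GeneSet, weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score and the full running sum over the ranking."""
    genes = ranked["gene"].to_numpy()
    metric = ranked["metric"].to_numpy(dtype=float)
    in_set = np.isin(genes, np.asarray(sig.genes))
    n_hits = int(in_set.sum())
    if n_hits == 0:
        raise ValueError(f"gene set {sig.name!r} is disjoint from the ranked universe")
    N = len(genes)
    w = np.abs(metric) ** weight
    denom_hit = w[in_set].sum()
    steps = np.zeros(N)
    if denom_hit > 0:
        steps[in_set] = w[in_set] / denom_hit
    else:
        steps[in_set] = 1.0 / n_hits  # all-zero metric: unweighted fallback
    if N > n_hits:
        steps[~in_set] = -1.0 / (N - n_hits)
    running = np.cumsum(steps)
    es = float(running[np.argmax(np.abs(running))])
    return es, running


def _es_from_positions(
    pos: np.ndarray, w_abs: np.ndarray, N: int
) -> float:
    """ES computed from sorted 0-based hit positions only (O(set size))."""
    s = len(pos)
    if N == s:
        return 1.0
    denom = w_abs.sum()
    miss = 1.0 / (N - s)
    idx = np.arange(s)
    if denom > 0:
        H = np.cumsum(w_abs) / denom
    else:
        H = (idx + 1.0) / s
    misses_before = (pos - idx) * miss
    after = H - misses_before
    before = np.concatenate(([0.0], H[:-1])) - misses_before
    cand = np.concatenate((after, before))
    return float(cand[np.argmax(np.abs(cand))])


def gsea(
    ranked: pd.DataFrame,
    sets: list[GeneSet],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Permutation GSEA over several gene sets on one ranked list.

    Null ES per set: ``n_perm`` random same-size gene sets drawn from the
    universe. NES = ES / mean(|null ES| of the same sign); nominal p is the
    plus-one-corrected same-sign tail fraction; FDR q compares the observed
    NES against the pooled same-sign null NES distribution, divided by the
    fraction of observed same-sign NES at least as extreme, clipped to
    [0, 1]. Sets whose observed sign has no null mass (or an all-zero
    metric) are flagged undefined. Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    genes = ranked["gene"].to_numpy()
    metric = ranked["metric"].to_numpy(dtype=float)
    N = len(genes)
    w_all = np.abs(metric) ** weight
    all_zero = bool(np.all(metric == 0))
    rng = np.random.default_rng(seed)

    rows = []
    null_nes_pos, null_nes_neg = [], []
    obs = []
    for sig in sets:
        es, _ = enrichment_score(ranked, sig, weight=weight)
        in_set = np.isin(genes, np.asarray(sig.genes))
        n_hits = int(in_set.sum())
        size_for_null = n_hits
        null_es = np.empty(n_perm)
        for i in range(n_perm):
            pos = np.sort(rng.choice(N, size=size_for_null, replace=False))
            null_es[i] = _es_from_positions(pos, w_all[pos], N)
        pos_null = null_es[null_es > 0]
        neg_null = null_es[null_es < 0]
        if all_zero:
            nes, p_nom, ok = np.nan, np.nan, False
        elif es >= 0:
            ok = len(pos_null) > 0
            nes = es / pos_null.mean() if ok else np.nan
            p_nom = (1.0 + np.sum(pos_null >= es)) / (1.0 + len(pos_null)) if ok else np.nan
        else:
            ok = len(neg_null) > 0
            nes = es / np.abs(neg_null).mean() if ok else np.nan
            p_nom = (1.0 + np.sum(neg_null <= es)) / (1.0 + len(neg_null)) if ok else np.nan
        if ok:
            if len(pos_null):
                null_nes_pos.append(pos_null / pos_null.mean())
            if len(neg_null):
                null_nes_neg.append(-neg_null / np.abs(neg_null).mean())
        obs.append((sig.name, es, nes, p_nom, n_hits, ok))

    pooled_pos = np.concatenate(null_nes_pos) if null_nes_pos else np.array([])
    pooled_neg = np.concatenate(null_nes_neg) if null_nes_neg else np.array([])
    obs_nes = np.array([o[2] for o in obs], dtype=float)

    for name, es, nes, p_nom, n_hits, ok in obs:
        if not ok or not np.isfinite(nes):
            fdr = np.nan
        elif nes >= 0:
            frac_null = np.mean(pooled_pos >= nes) if len(pooled_pos) else 0.0
            same = obs_nes[np.isfinite(obs_nes) & (obs_nes >= 0)]
            frac_obs = np.mean(same >= nes) if len(same) else 1.0
            fdr = float(np.clip(frac_null / max(frac_obs, 1e-12), 0.0, 1.0))
        else:
            frac_null = np.mean(pooled_neg >= -nes) if len(pooled_neg) else 0.0
            same = obs_nes[np.isfinite(obs_nes) & (obs_nes < 0)]
            frac_obs = np.mean(-same >= -nes) if len(same) else 1.0
            fdr = float(np.clip(frac_null / max(frac_obs, 1e-12), 0.0, 1.0))
        rows.append(
            {
                "gene_set": name,
                "es": es,
                "nes": nes,
                "p_nominal": p_nom,
                "fdr_q": fdr,
                "n_hits": n_hits,
                "defined": ok,
            }
        )
    return pd.DataFrame(rows)
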