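"""Binned-control signature scoring and cytokine-program assignment.

A signature (module) score for a cell is the mean normalized expression of
the signature genes minus the mean over expression-matched control genes.
Controls are drawn from equal-frequency bins of each gene's average
expression across cells (``nbin`` bins, ``ctrl_per_bin`` controls sampled
per signature gene from that gene's bin), so the score is centred at zero
for a signature with no coordinated expression. Cells are assigned to the
cytokine program with their highest score, provided that maximum clears a
high quantile of the per-cell maxima; the rest are "other".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import GeneSet, LOGNORM_LAYER

__all__ = [
    "SignatureScoreMatrix",
    "score_signature",
    "score_signatures",
    "build_top_n_set",
    "assign_program",
    "average_scores_by_group",
]

logger = logging.getLogger(__name__)

OTHER_LABEL = "other"


@dataclass
class SignatureScoreMatrix:
    """Cells x modules score table plus the scoring parameters used."""

    scores: pd.DataFrame  # index cell_id, one column per module
    nbin: int
    ctrl_per_bin: int
    seed: int

    @property
    def cell_ids(self) -> pd.Index:
        return self.scores.index

    @property
    def module_names(self) -> list[str]:
        return list(self.scores.columns)


def _lognorm_dense(adata: ad.AnnData) -> np.ndarray:
    if LOGNORM_LAYER not in adata.layers:
        raise ValueError("normalized layer required; run normalize_log first")
    X = adata.layers[LOGNORM_LAYER]
    return X.toarray() if sp.issparse(X) else np.asarray(X)


def _equal_frequency_bins(avg: np.ndarray, nbin: int) -> np.ndarray:
    """Bin index per gene by rank of average expression (ties by gene order)."""
    order = np.argsort(avg, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(len(avg))
    return (ranks * nbin) // len(avg)


def score_signature(
    norm: ad.AnnData,
    sig: GeneSet,
    nbin: int = 24,
    ctrl_per_bin: int = 100,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-cell binned-control score for one gene set.

    Steps: (1) average each gene's normalized expression over cells;
    (2) partition all genes into ``nbin`` equal-frequency bins of that
    average; (3) for each signature gene sample ``ctrl_per_bin`` control
    genes uniformly without replacement from its bin, excluding signature
    genes (falling back to with-replacement only if the bin is exhausted);
    (4) score(cell) = mean normalized expression over signature genes minus
    mean over the pooled (de-duplicated) control genes. Deterministic given
    ``seed``. Signature genes absent from the matrix are dropped with a
    warning; if none remain an error lists the missing genes.
    """
    if norm.n_vars < nbin:
        raise ValueError(f"need >= nbin={nbin} genes, have {norm.n_vars}")
    gene_pos = {g: i for i, g in enumerate(norm.var_names)}
    present = [g for g in sig.genes if g in gene_pos]
    missing = [g for g in sig.genes if g not in gene_pos]
    if not present:
        raise ValueError(
            f"no gene of signature {sig.name!r} present in the matrix; missing: {missing}"
        )
    if missing:
        logger.warning(
            "signature %s: %d/%d genes absent from matrix, dropped",
            sig.name,
            len(missing),
            len(sig.genes),
        )

    X = _lognorm_dense(norm)
    avg = X.mean(axis=0)
    bins = _equal_frequency_bins(avg, nbin)

    if rng is None:
        rng = np.random.default_rng(seed)
    sig_idx = np.array([gene_pos[g] for g in present])
    sig_set = set(sig_idx.tolist())

    ctrl: list[int] = []
    for gi in sig_idx:
        pool = np.flatnonzero(bins == bins[gi])
        pool = pool[~np.isin(pool, sig_idx)]
        if len(pool) == 0:
            continue
        replace = len(pool) < ctrl_per_bin
        picked = rng.choice(pool, size=min(ctrl_per_bin, len(pool)) if not replace else ctrl_per_bin, replace=replace)
        ctrl.extend(int(c) for c in picked)
    ctrl_unique = sorted(set(ctrl) - sig_set)
    if not ctrl_unique:
        raise ValueError(f"signature {sig.name!r}: no control genes available")

    sig_mean = X[:, sig_idx].mean(axis=1)
    ctrl_mean = X[:, ctrl_unique].mean(axis=1)
    return sig_mean - ctrl_mean


def score_signatures(
    norm: ad.AnnData,
    sets: list[GeneSet],
    nbin: int = 24,
    ctrl_per_bin: int = 100,
    seed: int = 0,
) -> SignatureScoreMatrix:
    """Score several gene sets; one independent seeded control draw per module."""
    if not sets:
        raise ValueError("no gene sets given")
    children = np.random.SeedSequence(seed).spawn(len(sets))
    cols = {}
    for s, child in zip(sets, children):
        cols[s.name] = score_signature(
            norm, s, nbin=nbin, ctrl_per_bin=ctrl_per_bin,
            rng=np.random.default_rng(child),
        )
    df = pd.DataFrame(cols, index=norm.obs_names.copy())
    df.index.name = "cell_id"
    return SignatureScoreMatrix(scores=df, nbin=nbin, ctrl_per_bin=ctrl_per_bin, seed=seed)


def build_top_n_set(
    de_table: pd.DataFrame,
    n: int = 50,
    name: str = "top_targets",
    p_adj_max: float = 0.05,
) -> GeneSet:
    """Top-``n`` upregulated genes of a differential table, ranked by fold change.

    Rows with log2FC > 0 and p_adj < ``p_adj_max`` are sorted by log2FC
    descending (ties broken by gene symbol ascending) and truncated to the
    first min(n, available) genes.
    """
    required = {"gene", "log2FC", "p_adj"}
    if not required.issubset(de_table.columns):
        raise ValueError(f"differential table must have columns {sorted(required)}")
    up = de_table[(de_table["log2FC"] > 0) & (de_table["p_adj"] < p_adj_max)]
    if up.empty:
        raise ValueError("no significantly upregulated genes to build a target set from")
    ranked = up.sort_values(["log2FC", "gene"], ascending=[False, True], kind="mergesort")
    genes = ranked["gene"].drop_duplicates().head(n).tolist()
    return GeneSet(name=name, genes=tuple(genes))


def assign_program(
    scores: SignatureScoreMatrix,
    quantile: float = 0.95,
    per_module_threshold: bool = False,
) -> pd.DataFrame:
    """Assign each cell its argmax module if the score clears the quantile cut.

    Default reading: the threshold is the ``quantile`` quantile (linear
    interpolation) of the per-cell maximum score over all cells; cells at
    or above it get their argmax module (ties resolved to the first module
    in column order), the rest are labelled "other". With
    ``per_module_threshold`` each module's own score distribution sets its
    quantile cut instead, and a cell is assigned when its argmax module's
    score clears that module's cut.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    df = scores.scores
    if df.shape[1] < 1:
        raise ValueError("need at least one module")
    vals = df.to_numpy()
    argmax = vals.argmax(axis=1)  # ties -> first column
    max_score = vals[np.arange(len(df)), argmax]
    modules = np.asarray(df.columns)

    if per_module_threshold:
        cuts = np.quantile(vals, quantile, axis=0)
        assigned_mask = max_score >= cuts[argmax]
    else:
        threshold = float(np.quantile(max_score, quantile))
        assigned_mask = max_score >= threshold

    assigned = np.where(assigned_mask, modules[argmax], OTHER_LABEL)
    out = pd.DataFrame(
        {"assigned_program": assigned, "max_score": max_score}, index=df.index.copy()
    )
    out.index.name = "cell_id"
    return out


def average_scores_by_group(
    scores: SignatureScoreMatrix,
    ann: pd.DataFrame,
    by: list[str] = ("cluster", "condition"),
) -> pd.DataFrame:
    """Mean score per (module, group); groups ordered by first appearance.

    ``ann`` must cover every scored cell (indexed by cell_id).
    """
    by = list(by)
    missing_cells = scores.cell_ids.difference(ann.index)
    if len(missing_cells):
        raise ValueError(
            f"{len(missing_cells)} scored cells missing from annotation, "
            f"e.g. {missing_cells[:3].tolist()}"
        )
    joined = scores.scores.join(ann.loc[scores.cell_ids, by].astype(str))
    grouped = joined.groupby(by, sort=False, observed=True).mean()
    return grouped
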