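"""Pseudo-bulk average-expression profiles and condition fold-change contrasts.

Each (cluster, condition) group is collapsed to one profile: the mean over
its cells of expm1-backtransformed normalized expression, i.e. averages on
the linear scale. Condition contrasts use log2((mean_a + 1) / (mean_b + 1))
with genes retained at |log2FC| above a threshold (default 0.25); no
p-value is attached — with one profile per condition there are no
replicates to test over, so the fold-change rule is the criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import LOGNORM_LAYER

__all__ = [
    "PseudobulkProfile",
    "average_expression",
    "condition_deg",
    "affected_gene_summary",
]

logger = logging.getLogger(__name__)


@dataclass
class PseudobulkProfile:
    """Linear-scale mean expression per (cluster, condition) group.

    ``means``: genes x groups frame, columns a MultiIndex of
    (cluster, condition); ``n_cells``: cells per group. Groups with zero
    cells are absent rather than zero-filled.
    """

    means: pd.DataFrame
    n_cells: pd.Series

    @property
    def genes(self) -> pd.Index:
        return self.means.index


def average_expression(
    norm: ad.AnnData,
    ann: pd.DataFrame | None = None,
    cluster_key: str = "cluster",
    condition_key: str = "condition",
) -> PseudobulkProfile:
    """Collapse cells to per-(cluster, condition) linear-scale mean profiles."""
    obs = norm.obs if ann is None else ann.reindex(norm.obs_names)
    for key in (cluster_key, condition_key):
        if key not in obs or obs[key].isna().any():
            bad = norm.obs_names[obs.get(key, pd.Series(index=norm.obs_names)).isna()] \
                if key in obs else norm.obs_names
            raise ValueError(
                f"cells lack a {key!r} annotation, e.g. {list(bad[:5])}"
            )
    X = norm.layers[LOGNORM_LAYER]
    X = X.toarray() if sp.issparse(X) else np.asarray(X)
    linear = np.expm1(X)

    clusters = obs[cluster_key].astype(str).to_numpy()
    conditions = obs[condition_key].astype(str).to_numpy()
    key_df = pd.DataFrame({"cluster": clusters, "condition": conditions})
    groups = key_df.groupby(["cluster", "condition"], sort=True).indices

    cols, names, sizes = [], [], []
    for (cl, cond), idx in groups.items():
        cols.append(linear[idx].mean(axis=0))
        names.append((cl, cond))
        sizes.append(len(idx))
    columns = pd.MultiIndex.from_tuples(names, names=["cluster", "condition"])
    means = pd.DataFrame(
        np.column_stack(cols), index=norm.var_names.copy(), columns=columns
    )
    means.index.name = "gene"
    return PseudobulkProfile(means=means, n_cells=pd.Series(sizes, index=columns))


def condition_deg(
    pb: PseudobulkProfile,
    cond_a: str,
    cond_b: str,
    lfc_threshold: float = 0.25,
) -> pd.DataFrame:
    """Fold-change contrast of two conditions per cluster.

    log2FC = log2((mean_a + 1) / (mean_b + 1)); rows with |log2FC| >
    ``lfc_threshold`` are retained with a direction flag. Clusters present
    in only one of the two conditions are skipped with a warning.
    """
    clusters = pb.means.columns.get_level_values("cluster").unique()
    comparison = f"{cond_a}_vs_{cond_b}"
    frames = []
    for cl in clusters:
        cols = pb.means[cl]
        if cond_a not in cols.columns or cond_b not in cols.columns:
            logger.warning(
                "condition_deg: cluster %s missing condition %s or %s, skipped",
                cl, cond_a, cond_b,
            )
            continue
        lfc = np.log2((cols[cond_a] + 1.0) / (cols[cond_b] + 1.0))
        keep = lfc.abs() > lfc_threshold
        if keep.any():
            frames.append(
                pd.DataFrame(
                    {
                        "cluster": cl,
                        "gene": lfc.index[keep],
                        "log2FC": lfc[keep].to_numpy(),
                        "direction": np.where(lfc[keep] > 0, "up", "down"),
                        "comparison": comparison,
                    }
                )
            )
    if not frames:
        return pd.DataFrame(
            columns=["cluster", "gene", "log2FC", "direction", "comparison"]
        )
    return pd.concat(frames, ignore_index=True)


def affected_gene_summary(deg: pd.DataFrame) -> tuple[dict[str, int], int]:
    """Distinct affected genes per cluster, and the distinct union across clusters."""
    if deg.empty:
        return {}, 0
    per_cluster = {
        str(cl): int(grp["gene"].nunique())
        for cl, grp in deg.groupby("cluster", sort=True)
    }
    union = int(deg["gene"].nunique())
    return per_cluster, union
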