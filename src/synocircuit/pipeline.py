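"""End-to-end orchestration of the cytokine-circuit analysis.

One call wires the stages in analysis order — simulate (optional) -> QC ->
normalize -> cluster -> markers -> signature scores / program assignment ->
per-condition interaction scoring -> pseudo-bulk contrasts -> GSEA — into
an append-only run directory of CSV/MTX/JSON artifacts plus a summary JSON
with per-stage object counts and the headline findings (top NES set per
cluster, interaction significant-count deltas between conditions). Runs are
reproducible bit-for-bit from the resolved config and seed, which are
written beside the outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import interactions, preprocess, pseudobulk, scoring, simulate as sim
from . import enrichment as gsea_mod
from .io import (
    InteractionPair,
    read_annotation_csv,
    read_counts_mtx,
    write_annotation_csv,
    write_counts_mtx,
    write_gmt,
    write_interaction_csv,
)

__all__ = ["RunConfig", "run_pipeline", "pairs_from_cytokines"]

logger = logging.getLogger(__name__)


class RunConfig(BaseModel):
    """Resolved parameters for one pipeline run; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    simulate: bool = True
    sim_overrides: dict[str, Any] = Field(default_factory=dict)
    # used instead of simulation when simulate=False
    matrix_path: Optional[str] = None
    barcodes_path: Optional[str] = None
    features_path: Optional[str] = None
    annotation_path: Optional[str] = None

    min_cells_per_gene: int = 3
    min_genes_per_cell: int = 200
    max_mito_frac: float = 0.05
    max_features: int = 7500
    scale_factor: float = 1e4

    n_hvg: int = 2000
    n_pcs: int = 30
    resolution: float = 1.0
    cluster_drop: list[str] = Field(default_factory=list)

    marker_p_adj_max: float = 0.05
    marker_min_abs_log2fc: float = 0.1

    nbin: int = 24
    ctrl_per_bin: int = 100
    assign_quantile: float = 0.95

    min_fraction: float = 0.1
    interact_n_perm: int = 1000
    alpha: float = 0.05

    deg_lfc_threshold: float = 0.25
    gsea_n_perm: int = 1000
    gsea_weight: float = 1.0

    condition_untreated: str = "untreated"
    condition_disease: str = "disease"
    condition_drug: str = "disease_drug"


def pairs_from_cytokines(config: sim.SimulationConfig) -> list[InteractionPair]:
    """Build the curated ligand-receptor pair list of a simulated circuit."""
    return [
        InteractionPair(
            name=f"{c.name}_pair",
            ligand_subunits=(c.ligand_gene,),
            receptor_subunits=tuple(c.receptor_subunits),
        )
        for c in config.cytokines
    ]


def _sim_config(cfg: RunConfig) -> sim.SimulationConfig:
    overrides = dict(cfg.sim_overrides)
    overrides.setdefault("seed", cfg.seed)
    if "cell_types" in overrides:
        overrides["cell_types"] = tuple(
            sim.CellType(**ct) for ct in overrides["cell_types"]
        )
    if "cytokines" in overrides:
        overrides["cytokines"] = tuple(
            sim.CytokineSpec(
                **{
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in cy.items()
                }
            )
            for cy in overrides["cytokines"]
        )
    return sim.default_config(**overrides)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else round(v, 10)
    return obj


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute the full analysis; returns the run directory.

    Every stage appends its artifacts under ``out_dir``; a failure aborts
    with the stage name while keeping completed artifacts in place.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(config.model_dump(), sort_keys=True))
    summary: dict[str, Any] = {"seed": config.seed, "stages": {}}
    stage = "setup"
    try:
        sim_cfg = None
        target_sets = None
        if config.simulate:
            stage = "simulate"
            sim_cfg = _sim_config(config)
            adata, ann, truth = sim.generate_atlas(sim_cfg)
            target_sets = sim.generate_target_gene_sets(sim_cfg)
            write_counts_mtx(adata, out / "raw")
            write_annotation_csv(ann, out / "raw" / "annotation.csv")
            write_annotation_csv(truth.cells, out / "raw" / "truth_cells.csv")
            truth.genes.to_csv(out / "raw" / "truth_genes.csv", index=False)
            truth.effects.to_csv(out / "raw" / "truth_effects.csv", index=False)
            write_gmt(target_sets, out / "raw" / "target_sets.gmt")
            write_interaction_csv(
                pairs_from_cytokines(sim_cfg), out / "raw" / "pairs.csv"
            )
            summary["stages"]["simulate"] = {
                "n_cells": int(adata.n_obs),
                "n_genes": int(adata.n_vars),
            }
        else:
            stage = "load"
            adata = read_counts_mtx(
                config.matrix_path, config.barcodes_path, config.features_path
            )
            ann = read_annotation_csv(config.annotation_path)
            adata.obs = adata.obs.join(ann)

        stage = "qc"
        filtered = preprocess.qc_filter(
            adata,
            min_cells_per_gene=config.min_cells_per_gene,
            min_genes_per_cell=config.min_genes_per_cell,
            max_mito_frac=config.max_mito_frac,
            max_features=config.max_features,
        )
        summary["stages"]["qc"] = {
            "n_cells": int(filtered.n_obs),
            "n_genes": int(filtered.n_vars),
        }

        stage = "normalize"
        norm = preprocess.normalize_log(filtered, scale_factor=config.scale_factor)

        stage = "cluster"
        ann2 = preprocess.cluster_cells(
            norm,
            n_hvg=config.n_hvg,
            n_pcs=config.n_pcs,
            resolution=config.resolution,
            seed=config.seed,
        )
        if config.cluster_drop:
            keep = ~ann2["cluster"].astype(str).isin(config.cluster_drop)
            norm = norm[keep.to_numpy()].copy()
            ann2 = ann2[keep]
        write_annotation_csv(ann2, out / "annotation.csv")
        summary["stages"]["cluster"] = {
            "n_clusters": int(ann2["cluster"].astype(str).nunique())
        }

        stage = "markers"
        markers = preprocess.find_markers(
            norm,
            p_adj_max=config.marker_p_adj_max,
            min_abs_log2fc=config.marker_min_abs_log2fc,
        )
        markers.to_csv(out / "markers.csv", index=False)
        summary["stages"]["markers"] = {"n_rows": int(len(markers))}

        stage = "score"
        if target_sets is None:
            raise ValueError("scoring stage requires simulated target sets or a GMT")
        score_mat = scoring.score_signatures(
            norm,
            target_sets,
            nbin=config.nbin,
            ctrl_per_bin=config.ctrl_per_bin,
            seed=config.seed,
        )
        score_mat.scores.to_csv(out / "signature_scores.csv")
        assignment = scoring.assign_program(score_mat, quantile=config.assign_quantile)
        assignment.to_csv(out / "program_assignment.csv")
        avg_scores = scoring.average_scores_by_group(
            score_mat, ann2, by=["cluster", "condition"]
        )
        avg_scores.to_csv(out / "signature_scores_by_group.csv")
        summary["stages"]["score"] = {
            "n_modules": len(score_mat.module_names),
            "n_assigned": int((assignment["assigned_program"] != "other").sum()),
        }

        stage = "interact"
        pairs = pairs_from_cytokines(sim_cfg) if sim_cfg else []
        ss = np.random.SeedSequence(config.seed).spawn(2)
        sig_counts = {}
        for cond, child in zip(
            (config.condition_disease, config.condition_drug), ss
        ):
            mask = (ann2["condition"].astype(str) == cond).to_numpy()
            sub = norm[mask].copy()
            res = interactions.score_interactions(
                sub,
                pairs,
                labels=ann2.loc[mask, "cluster"],
                min_fraction=config.min_fraction,
                n_perm=config.interact_n_perm,
                seed=int(child.generate_state(1)[0] % (2**31)),
            )
            res.to_csv(out / f"interactions_{cond}.csv", index=False)
            counts = interactions.count_significant(res, alpha=config.alpha)
            counts.to_csv(out / f"interaction_counts_{cond}.csv")
            sig_counts[cond] = int(counts.to_numpy().sum())
        summary["stages"]["interact"] = {
            "significant_by_condition": sig_counts,
            "delta_disease_minus_drug": sig_counts[config.condition_disease]
            - sig_counts[config.condition_drug],
        }

        stage = "pseudobulk"
        pb = pseudobulk.average_expression(norm, ann=ann2)
        pb.means.to_csv(out / "pseudobulk_means.csv")
        deg = pseudobulk.condition_deg(
            pb,
            config.condition_disease,
            config.condition_drug,
            lfc_threshold=config.deg_lfc_threshold,
        )
        deg.to_csv(out / "deg_disease_vs_drug.csv", index=False)
        per_cluster, union = pseudobulk.affected_gene_summary(deg)
        summary["stages"]["pseudobulk"] = {
            "affected_per_cluster": per_cluster,
            "affected_union": union,
        }

        stage = "gsea"
        top_nes = {}
        gsea_frames = []
        gsea_children = np.random.SeedSequence(config.seed + 1).spawn(
            int(ann2["cluster"].astype(str).nunique())
        )
        for cl, child in zip(
            sorted(ann2["cluster"].astype(str).unique()), gsea_children
        ):
            conds = set(
                ann2.loc[ann2["cluster"].astype(str) == cl, "condition"].astype(str)
            )
            if not {config.condition_disease, config.condition_drug} <= conds:
                continue
            ranked = gsea_mod.rank_diff_of_classes(
                norm,
                cl,
                config.condition_disease,
                config.condition_drug,
                ann=ann2,
            )
            res = gsea_mod.gsea(
                ranked,
                target_sets,
                n_perm=config.gsea_n_perm,
                seed=int(child.generate_state(1)[0] % (2**31)),
                weight=config.gsea_weight,
            )
            res.insert(0, "cluster", cl)
            gsea_frames.append(res)
            defined = res[res["defined"] & res["nes"].notna()]
            if not defined.empty:
                best = defined.loc[defined["nes"].idxmax()]
                top_nes[cl] = {"gene_set": best["gene_set"], "nes": float(best["nes"])}
        if gsea_frames:
            pd.concat(gsea_frames, ignore_index=True).to_csv(
                out / "gsea.csv", index=False
            )
        summary["stages"]["gsea"] = {"top_nes_per_cluster": top_nes}
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "summary.json").write_text(
        json.dumps(_jsonable(summary), sort_keys=True, indent=2) + "\n"
    )
    logger.info("pipeline complete: %s", out)
    return out
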