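"""End-to-end orchestration of the immune-typing / immune-score pipeline."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from . import coexpression, hubs as hubs_mod, nmf, score as score_mod, ssgsea, survival
from .config import RunConfig
from .io import GeneSetCollection

logger = logging.getLogger("immunoscore")


@dataclass
class PipelineResult:
    """Everything the pipeline produces, stage by stage."""

    infiltration: ssgsea.InfiltrationMatrix
    celltype_rho: pd.DataFrame
    assignment: nmf.ClusterAssignment
    cluster_contrasts: pd.DataFrame
    cluster_logrank: tuple[float, int, float]
    modules: coexpression.ModuleResult
    selected_modules: pd.DataFrame
    hub_genes: hubs_mod.HubGeneSet
    immune_score: score_mod.ImmuneScoreTable
    is_logrank: tuple[float, int, float]
    roc_auc: float
    roc_n_used: int
    roc_n_excluded: int


def run_pipeline(
    expr: pd.DataFrame,
    gene_sets: GeneSetCollection,
    clinical: pd.DataFrame,
    config: RunConfig,
    checkpoint_genes: tuple[str, ...] = ("CTLA4", "CD274"),
) -> PipelineResult:
    """Run every stage on one cohort and collect the results.

    Stages: ssGSEA infiltration scoring -> consensus NMF clustering with
    survival-informed rank selection -> A/B labelling -> co-expression module
    analysis against the cluster-B indicator -> hub screening -> immune score
    with optimal cutpoint -> survival statistics of the high/low split.
    """
    clin = clinical.set_index("sample_id") if "sample_id" in clinical.columns else clinical
    clin = clin.loc[expr.columns]

    infil = ssgsea.ssgsea_matrix(
        expr, gene_sets, alpha=config.ssgsea_alpha, normalize=config.ssgsea_normalize
    )
    rho, _ = ssgsea.celltype_spearman(infil)

    X = nmf.nonneg_scale(infil)
    assignment = nmf.select_rank_with_pfs(
        X,
        clin,
        k_range=config.k_range,
        n_restarts=config.n_restarts,
        seed=config.seed,
        stability_floor=config.stability_floor,
        max_iter=config.nmf_max_iter,
        tol=config.nmf_tol,
    )
    if assignment.k != 2:
        raise ValueError(
            f"rank selection chose k={assignment.k}, but the A/B contrast, "
            "module trait and immune score are defined for two clusters; "
            "restrict k_range or inspect assignment diagnostics"
        )
    assignment = nmf.label_clusters(assignment, infil)
    contrasts = nmf.compare_clusters(infil, expr, assignment, list(checkpoint_genes))
    cluster_lr = survival.logrank_test(
        assignment.labels.to_numpy(),
        clin["pfs_time"].to_numpy(float),
        clin["pfs_event"].to_numpy(int),
    )

    trait = assignment.indicator_b()
    modules = coexpression.run_module_analysis(
        expr,
        trait,
        n_top=config.n_top_genes,
        beta_grid=config.beta_grid,
        target_r2=config.scale_free_target,
        min_size=config.min_module_size,
        cut_height=config.cut_height,
        merge_threshold=config.merge_threshold if config.merge_modules else None,
    )
    selected = hubs_mod.select_modules(
        modules.module_trait, r_floor=config.module_r_floor, p_ceiling=config.module_p_ceiling
    )
    hub_genes = hubs_mod.screen_hub_genes(
        modules.mm_gs, selected, config.mm_threshold, config.gs_threshold
    )

    ist = score_mod.score_and_dichotomize(
        expr,
        hub_genes,
        clin,
        q_low=config.cutpoint_q_low,
        q_high=config.cutpoint_q_high,
        pooled=config.pooled_pc1,
    )
    is_lr = survival.logrank_test(
        ist.groups.to_numpy(),
        clin.loc[ist.table.index, "pfs_time"].to_numpy(float),
        clin.loc[ist.table.index, "pfs_event"].to_numpy(int),
    )
    auc, _, n_used, n_excl = survival.roc_horizon(
        ist.scores.to_numpy(),
        clin.loc[ist.table.index, "pfs_time"].to_numpy(float),
        clin.loc[ist.table.index, "pfs_event"].to_numpy(int),
        config.roc_horizon_months,
    )

    return PipelineResult(
        infiltration=infil,
        celltype_rho=rho,
        assignment=assignment,
        cluster_contrasts=contrasts,
        cluster_logrank=cluster_lr,
        modules=modules,
        selected_modules=selected,
        hub_genes=hub_genes,
        immune_score=ist,
        is_logrank=is_lr,
        roc_auc=auc,
        roc_n_used=n_used,
        roc_n_excluded=n_excl,
    )
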