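"""scikit-learn style estimator wrappers over the pipeline stages.

These follow the sklearn conventions (``fit``/``transform``/``predict``,
``get_params``/``set_params``, fitted attributes with a trailing
underscore) so the stages compose with sklearn tooling; they delegate to
the functional modules, which remain the primary API.

Expression/score matrices here follow the transcriptomics layout
(features x samples), so ``X`` is a DataFrame of genes (or cell types) by
samples rather than the sklearn samples-by-features array.
"""

from __future__ import annotations

import pandas as pd
from sklearn.base import BaseEstimator

from . import coexpression, nmf, score as score_mod, ssgsea
from .hubs import HubGeneSet, screen_hub_genes, select_modules
from .io import GeneSetCollection


class SSGSEATransformer(BaseEstimator):
    """Transform a genes x samples matrix into signature scores."""

    def __init__(self, gene_sets: GeneSetCollection = None, alpha: float = 0.25,
                 normalize: bool = True):
        self.gene_sets = gene_sets
        self.alpha = alpha
        self.normalize = normalize

    def fit(self, X: pd.DataFrame, y=None):
        if self.gene_sets is None:
            raise ValueError("gene_sets is required")
        self.n_sets_ = len(self.gene_sets)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self.fit(X)
        infil = ssgsea.ssgsea_matrix(X, self.gene_sets, self.alpha, self.normalize)
        self.infiltration_ = infil
        return infil.scores

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)


class ConsensusNMFClusterer(BaseEstimator):
    """Consensus NMF clustering with survival-informed rank selection.

    ``fit`` expects a cell-types x samples score matrix and the clinical
    table (``y``); fitted attributes expose the labels, chosen rank and
    per-rank diagnostics.
    """

    def __init__(self, k_min: int = 2, k_max: int = 6, n_restarts: int = 50,
                 stability_floor: float = 0.95, max_iter: int = 2000,
                 tol: float = 1e-6, seed: int = 0):
        self.k_min = k_min
        self.k_max = k_max
        self.n_restarts = n_restarts
        self.stability_floor = stability_floor
        self.max_iter = max_iter
        self.tol = tol
        self.seed = seed

    def fit(self, X: pd.DataFrame, y: pd.DataFrame = None):
        if y is None:
            raise ValueError("clinical table (y) is required for rank selection")
        infil = ssgsea.InfiltrationMatrix(scores=X, alpha=float("nan"), normalized=False)
        scaled = nmf.nonneg_scale(infil)
        assignment = nmf.select_rank_with_pfs(
            scaled, y,
            k_range=range(self.k_min, self.k_max + 1),
            n_restarts=self.n_restarts, seed=self.seed,
            stability_floor=self.stability_floor,
            max_iter=self.max_iter, tol=self.tol,
        )
        assignment = nmf.label_clusters(assignment, infil)
        self.assignment_ = assignment
        self.labels_ = assignment.labels
        self.k_ = assignment.k
        self.consensus_ = assignment.consensus
        return self

    def fit_predict(self, X: pd.DataFrame, y: pd.DataFrame = None) -> pd.Series:
        return self.fit(X, y).labels_


class CoexpressionModules(BaseEstimator):
    """Weighted co-expression module detection with MM/GS statistics.

    ``fit`` takes the genes x samples expression matrix and a 0/1 trait
    (``y``, cluster-B indicator); fitted attributes expose labels,
    eigengenes, module-trait correlations and the MM/GS table.
    """

    def __init__(self, n_top: int = 0,
                 beta_grid: tuple = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20),
                 target_r2: float = 0.85, min_size: int = 30,
                 cut_height: float = 0.90, merge_threshold: float = None):
        self.n_top = n_top
        self.beta_grid = beta_grid
        self.target_r2 = target_r2
        self.min_size = min_size
        self.cut_height = cut_height
        self.merge_threshold = merge_threshold

    def fit(self, X: pd.DataFrame, y: pd.Series = None):
        if y is None:
            raise ValueError("trait (y) is required")
        result = coexpression.run_module_analysis(
            X, y, n_top=self.n_top, beta_grid=tuple(self.beta_grid),
            target_r2=self.target_r2, min_size=self.min_size,
            cut_height=self.cut_height, merge_threshold=self.merge_threshold,
        )
        self.result_ = result
        self.labels_ = result.labels
        self.beta_ = result.beta
        self.eigengenes_ = result.eigengenes
        self.module_trait_ = result.module_trait
        self.mm_gs_ = result.mm_gs
        return self


class ImmuneScoreModel(BaseEstimator):
    """Immune score IS = sum PC1(B+) - sum PC1(B-) with optimal cutpoint.

    ``fit`` learns the cutpoint from the training cohort's scores and PFS;
    ``predict`` assigns high/low groups to new scores via the stored
    cutpoint, ``transform`` computes IS for a cohort.
    """

    def __init__(self, module_r_floor: float = 0.5, module_p_ceiling: float = 0.05,
                 mm_threshold: float = 0.8, gs_threshold: float = 0.5,
                 q_low: float = 0.1, q_high: float = 0.9, pooled: bool = False):
        self.module_r_floor = module_r_floor
        self.module_p_ceiling = module_p_ceiling
        self.mm_threshold = mm_threshold
        self.gs_threshold = gs_threshold
        self.q_low = q_low
        self.q_high = q_high
        self.pooled = pooled

    def fit(self, X: pd.DataFrame, y: pd.DataFrame = None, *,
            module_trait: pd.DataFrame = None, mm_gs: pd.DataFrame = None,
            hub_genes: HubGeneSet = None):
        """Fit from expression ``X`` and clinical ``y``.

        Hub genes come either pre-screened (``hub_genes``) or from the
        module statistics (``module_trait`` + ``mm_gs``).
        """
        if y is None:
            raise ValueError("clinical table (y) is required")
        if hub_genes is None:
            if module_trait is None or mm_gs is None:
                raise ValueError("provide hub_genes or (module_trait and mm_gs)")
            selected = select_modules(module_trait, self.module_r_floor, self.module_p_ceiling)
            hub_genes = screen_hub_genes(mm_gs, selected, self.mm_threshold, self.gs_threshold)
        self.hub_genes_ = hub_genes
        ist = score_mod.score_and_dichotomize(
            X, hub_genes, y, q_low=self.q_low, q_high=self.q_high, pooled=self.pooled
        )
        self.score_table_ = ist
        self.cutpoint_ = ist.cutpoint
        return self

    def transform(self, X: pd.DataFrame) -> pd.Series:
        ist = score_mod.compute_immune_score(X, self.hub_genes_, pooled=self.pooled)
        return ist.scores

    def predict(self, X: pd.DataFrame) -> pd.Series:
        scores = self.transform(X)
        return pd.Series(
            ["high" if s > self.cutpoint_ else "low" for s in scores],
            index=scores.index, name="group",
        )
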