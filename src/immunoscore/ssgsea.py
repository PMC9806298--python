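"""Single-sample gene set enrichment (ssGSEA) scoring of immune signatures.

For each sample, genes are ranked by expression (rank 1 = lowest, average
ranks for ties).  The enrichment score of a gene set walks the genes in
decreasing rank order, accumulating a weighted in-set ECDF (weights
``rank^alpha``, normalized over the set) against the unweighted out-of-set
ECDF, and sums the difference over all positions:

    ES = sum_i [ P_in(i) - P_out(i) ]

The score depends only on ranks, set membership and ``alpha``, so it is
invariant under any strictly monotone transformation of a sample's
expression values.  Raw scores are optionally rescaled by the global
(max - min) of the score matrix — an order-preserving affine map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSetCollection

logger = logging.getLogger("immunoscore")


@dataclass
class InfiltrationMatrix:
    """Per-sample abundance scores for each scored signature."""

    scores: pd.DataFrame        # cell types x samples
    alpha: float
    normalized: bool

    @property
    def cell_types(self) -> list[str]:
        return list(self.scores.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)


def rank_transform(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-sample ranks of expression, 1 = lowest, ties averaged."""
    if expr.shape[0] < 2:
        raise ValueError("need >= 2 genes to rank")
    ranks = stats.rankdata(expr.to_numpy(), axis=0, method="average")
    return pd.DataFrame(ranks, index=expr.index, columns=expr.columns)


def enrichment_score(
    sample_ranks: pd.Series, gene_set: list[str] | set[str], alpha: float = 0.25
) -> float:
    """Enrichment score of one gene set in one sample.

    ``sample_ranks`` maps gene id -> rank (1 = lowest expression).  Among
    tied ranks the walk order is fixed by gene id, so the score is invariant
    under reordering of the input.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    genes = sample_ranks.index
    in_set = genes.isin(set(gene_set))
    m = int(in_set.sum())
    n_genes = len(genes)
    if m == 0:
        raise ValueError("gene set has empty intersection with the ranked genes")
    if m == n_genes:
        raise ValueError("gene set covers all genes; out-of-set ECDF undefined")
    ranks = sample_ranks.to_numpy(dtype=float)
    order = np.lexsort((np.asarray(genes), -ranks))
    return float(_es_from_order(ranks[order], in_set[order], alpha))


def _es_from_order(
    ranks_desc: np.ndarray, in_set_desc: np.ndarray, alpha: float
) -> float:
    w = np.where(in_set_desc, ranks_desc**alpha, 0.0)
    cum_in = np.cumsum(w) / w.sum()
    n, m = len(ranks_desc), int(in_set_desc.sum())
    cum_out = np.cumsum(~in_set_desc) / (n - m)
    return float(np.sum(cum_in - cum_out))


def ssgsea_matrix(
    expr: pd.DataFrame,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = True,
) -> InfiltrationMatrix:
    """Score every gene set in every sample.

    Genes absent from the matrix are intersected out per set (effective set
    sizes are logged); a set with empty intersection raises.  When
    ``normalize`` is true, the raw matrix is divided by its global
    ``max - min``, which preserves every within-cell-type sample ordering.
    """
    ranks = rank_transform(expr).to_numpy()
    genes = expr.index.to_numpy()
    n_genes, n_samples = ranks.shape

    # shared descending-rank order per sample, ties broken by gene id
    gene_order_id = np.argsort(np.argsort(genes, kind="stable"), kind="stable")
    orders = np.empty_like(ranks, dtype=np.int64)
    for s in range(n_samples):
        orders[:, s] = np.lexsort((gene_order_id, -ranks[:, s]))

    score = np.empty((len(sets), n_samples))
    gene_index = pd.Index(genes)
    for row, (name, members) in enumerate(sets):
        mask = gene_index.isin(set(members))
        m = int(mask.sum())
        if m == 0:
            raise ValueError(f"gene set {name!r} has no genes in the expression matrix")
        if m == n_genes:
            raise ValueError(f"gene set {name!r} covers all genes")
        if m < len(set(members)):
            logger.debug("set %s: effective size %d of %d", name, m, len(set(members)))
        for s in range(n_samples):
            ord_s = orders[:, s]
            score[row, s] = _es_from_order(ranks[ord_s, s], mask[ord_s], alpha)

    df = pd.DataFrame(score, index=[name for name, _ in sets], columns=expr.columns)
    if normalize:
        span = float(df.to_numpy().max() - df.to_numpy().min())
        if span > 0:
            df = df / span
    return InfiltrationMatrix(scores=df, alpha=alpha, normalized=normalize)


def celltype_spearman(infil: InfiltrationMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman correlation between cell types across samples.

    Returns ``(rho, p)`` DataFrames.  Constant cell-type rows yield missing
    correlations for their pairs (logged).
    """
    scores = infil.scores
    if scores.shape[1] < 3:
        raise ValueError("need >= 3 samples for Spearman correlation")
    constant = scores.std(axis=1) == 0
    if constant.any():
        logger.warning(
            "constant cell-type rows, correlations undefined: %s",
            ", ".join(scores.index[constant]),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        rho, p = stats.spearmanr(scores.to_numpy(), axis=1)
    rho = np.atleast_2d(rho)
    p = np.atleast_2d(p)
    np.fill_diagonal(rho, 1.0)
    idx = scores.index
    return (
        pd.DataFrame(rho, index=idx, columns=idx),
        pd.DataFrame(p, index=idx, columns=idx),
    )
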