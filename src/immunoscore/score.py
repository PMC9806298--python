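"""The immune score IS = sum PC1(B+) - sum PC1(B-) and its optimal cutpoint.

``PC1(B+)`` is the first principal component of the hub genes of each module
positively correlated with cluster B (the low-infiltration, poor-prognosis
cluster); ``PC1(B-)`` the same for negatively correlated modules.  Per-module
PC1 scores are summed within each sign and subtracted.  PCA signs are
arbitrary, so every PC1 is oriented to correlate positively with the mean
standardized expression of its gene group — without this rule the score
would not be reproducible.

Samples are dichotomized at the maximally selected log-rank cutpoint inside
a quantile window of the observed scores; the resulting p-value is
selection-inflated and treated as descriptive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import multivariate_logrank_test

from .hubs import HubGeneSet

logger = logging.getLogger("immunoscore")


@dataclass
class ImmuneScoreTable:
    """Per-sample immune score, high/low group and cutpoint diagnostics."""

    table: pd.DataFrame            # index sample_id; columns IS, group (+ per-module pc1_*)
    cutpoint: float | None = None
    cutpoint_diagnostics: pd.DataFrame | None = None

    @property
    def scores(self) -> pd.Series:
        return self.table["IS"]

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]


def signed_pc1(expr: pd.DataFrame, genes: list[str]) -> pd.Series:
    """Sign-oriented first-principal-component sample scores of a gene subset.

    Genes are z-scored across samples; scores are the raw PC1 projections
    (variance = leading eigenvalue, deliberately not rescaled) oriented so
    they correlate non-negatively with the subset's mean standardized
    profile.
    """
    present = [g for g in genes if g in expr.index]
    if len(present) < 2:
        raise ValueError(f"need >= 2 genes present in the matrix, got {len(present)}")
    sub = expr.loc[present]
    sd = sub.std(axis=1, ddof=1)
    if (sd == 0).any():
        logger.warning("dropping %d zero-variance genes from PC1", int((sd == 0).sum()))
        sub = sub.loc[sd > 0]
        sd = sd.loc[sd > 0]
    if sub.shape[0] < 2:
        raise ValueError("fewer than 2 usable (non-constant) genes")
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0).to_numpy()
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = s[0] * vt[0]
    mean_profile = z.mean(axis=0)
    if np.dot(scores, mean_profile) < 0:
        scores = -scores
    return pd.Series(scores, index=expr.columns, name="pc1")


def compute_immune_score(
    expr: pd.DataFrame, hubs: HubGeneSet, pooled: bool = False
) -> ImmuneScoreTable:
    """IS(sample) = sum of B+ module PC1s minus sum of B- module PC1s.

    With ``pooled=True`` a single PC1 is computed over all hub genes of each
    sign instead of per module (the two coincide when a sign has one
    module).  One empty side contributes 0 with a warning; both sides empty
    is an error.
    """
    pos = hubs.by_sign("positive")
    neg = hubs.by_sign("negative")
    if not pos and not neg:
        raise ValueError("hub gene set has no modules on either side")
    if not pos or not neg:
        logger.warning("one side of the B+/B- partition is empty; its sum is 0")

    def _side(groups: dict[str, list[str]], tag: str) -> tuple[pd.Series, dict]:
        total = pd.Series(0.0, index=expr.columns)
        parts = {}
        if pooled and groups:
            all_genes = sorted({g for gs in groups.values() for g in gs})
            pc = signed_pc1(expr, all_genes)
            parts[f"pc1_{tag}_pooled"] = pc
            return pc, parts
        for mod, genes in groups.items():
            pc = signed_pc1(expr, genes)
            parts[f"pc1_{tag}_{mod}"] = pc
            total = total + pc
        return total, parts

    pos_sum, pos_parts = _side(pos, "pos")
    neg_sum, neg_parts = _side(neg, "neg")
    table = pd.DataFrame({**pos_parts, **neg_parts})
    table["IS"] = pos_sum - neg_sum
    return ImmuneScoreTable(table=table)


def optimal_cutpoint(
    scores: pd.Series,
    clinical: pd.DataFrame,
    q_low: float = 0.1,
    q_high: float = 0.9,
) -> tuple[float, pd.Series, pd.DataFrame]:
    """Maximally selected log-rank cutpoint over observed score values.

    Candidates are the observed scores inside the ``[q_low, q_high]``
    quantile window; each splits samples into high (IS > c) vs low, and the
    candidate maximizing the two-group log-rank statistic wins.  Ties go to
    the more balanced split, then to the lower value.  Returns
    ``(cutpoint, groups, diagnostics)`` with groups in {'high', 'low'}.
    """
    if not (0 <= q_low < q_high <= 1):
        raise ValueError("need 0 <= q_low < q_high <= 1")
    clin = clinical.set_index("sample_id") if "sample_id" in clinical.columns else clinical
    common = scores.index.intersection(clin.index)
    if len(common) < len(scores):
        raise ValueError("clinical table missing scored samples")
    times = clin.loc[scores.index, "pfs_time"].to_numpy(float)
    events = clin.loc[scores.index, "pfs_event"].to_numpy(int)
    vals = scores.to_numpy(float)

    lo, hi = np.quantile(vals, [q_low, q_high])
    candidates = np.unique(vals[(vals >= lo) & (vals <= hi)])
    if len(candidates) == 0:
        # window narrower than the score spacing: nearest observed value
        mid = np.quantile(vals, (q_low + q_high) / 2)
        candidates = np.array([vals[np.argmin(np.abs(vals - mid))]])
    rows = []
    for c in candidates:
        high = vals > c
        if high.all() or (~high).all():
            continue
        if events[high].sum() == 0 or events[~high].sum() == 0:
            continue
        test = multivariate_logrank_test(times, high.astype(int), events)
        rows.append((float(c), float(test.test_statistic), int(high.sum()), int((~high).sum())))
    if not rows:
        raise ValueError("no candidate cutpoint yields two event-bearing groups")
    diag = pd.DataFrame(rows, columns=["cutpoint", "chi2", "n_high", "n_low"])
    balance = (diag["n_high"] - diag["n_low"]).abs()
    order = diag.assign(balance=balance).sort_values(
        ["chi2", "balance", "cutpoint"], ascending=[False, True, True]
    )
    best = order.iloc[0]
    cut = float(best["cutpoint"])
    groups = pd.Series(np.where(vals > cut, "high", "low"), index=scores.index, name="group")
    logger.info(
        "optimal cutpoint %.4f (chi2=%.2f, %d high / %d low); p-value is selection-inflated",
        cut, best["chi2"], best["n_high"], best["n_low"],
    )
    return cut, groups, diag


def score_and_dichotomize(
    expr: pd.DataFrame,
    hubs: HubGeneSet,
    clinical: pd.DataFrame,
    q_low: float = 0.1,
    q_high: float = 0.9,
    pooled: bool = False,
) -> ImmuneScoreTable:
    """Compute IS, find the optimal cutpoint and attach high/low groups."""
    ist = compute_immune_score(expr, hubs, pooled=pooled)
    cut, groups, diag = optimal_cutpoint(ist.scores, clinical, q_low, q_high)
    table = ist.table.copy()
    table["group"] = groups
    return ImmuneScoreTable(table=table, cutpoint=cut, cutpoint_diagnostics=diag)
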