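"""Survival and association statistics shared by all pipeline stages.

Kaplan-Meier estimation and the (multi-group) log-rank test are delegated
to lifelines; the horizon ROC, Wilcoxon rank-sum, Pearson chi-square and
covariate-combined stratification wrap scipy / scikit-learn with the exact
conventions the pipeline needs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

logger = logging.getLogger("immunoscore")


@dataclass
class SurvivalCurve:
    """Product-limit survival curve with its risk table."""

    times: np.ndarray        # event times, sorted
    survival: np.ndarray     # S(t) just after each event time
    n_at_risk: np.ndarray
    n_events: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        s = np.asarray(self.survival)
        if len(s) and (np.any(np.diff(s) > 1e-12) or s.min() < -1e-12 or s.max() > 1 + 1e-12):
            raise ValueError("survival curve must be non-increasing within [0, 1]")


@dataclass
class StratifiedComparison:
    """Joint IS-by-covariate survival comparison."""

    group_sizes: dict[str, int]
    chi2: float
    df: int
    p: float
    curves: dict[str, SurvivalCurve]
    n_excluded: int = 0


def km_estimate(times, events, label: str = "") -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate; steps only at event times."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("empty input")
    if (times <= 0).any():
        raise ValueError("times must be > 0")
    if not np.isin(events, [0, 1]).all():
        raise ValueError("events must be 0 or 1")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    surv = kmf.survival_function_["KM_estimate"]
    return SurvivalCurve(
        times=ev.index.to_numpy(float),
        survival=surv.loc[ev.index].to_numpy(float),
        n_at_risk=ev["at_risk"].to_numpy(int),
        n_events=ev["observed"].to_numpy(int),
        label=label,
    )


def logrank_test(groups, times, events) -> tuple[float, int, float]:
    """Multi-group log-rank test; returns (chi-square, df, p)."""
    groups = np.asarray(groups)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    if (counts == 0).any():
        raise ValueError("every group needs >= 1 subject")
    res = multivariate_logrank_test(times, groups, events)
    df = len(uniq) - 1
    return float(res.test_statistic), df, float(res.p_value)


def roc_horizon(
    scores, times, events, horizon_months: float
) -> tuple[float, pd.DataFrame, int, int]:
    """ROC of a score for progression by a fixed horizon.

    Subjects censored before the horizon carry no outcome and are excluded
    (the count is reported).  Positives progressed by the horizon; negatives
    were still progression-free past it.  AUC is the rank (Mann-Whitney)
    statistic with tie correction.  Returns ``(auc, roc_points, n_used,
    n_excluded)``.
    """
    if horizon_months <= 0:
        raise ValueError("horizon must be > 0")
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    positive = (events == 1) & (times <= horizon_months)
    negative = times > horizon_months
    usable = positive | negative
    n_excluded = int((~usable).sum())
    if n_excluded:
        logger.info("horizon ROC: excluded %d subjects censored before the horizon", n_excluded)
    y = positive[usable].astype(int)
    s = scores[usable]
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("one outcome class is empty after horizon exclusion")
    auc = float(roc_auc_score(y, s))
    fpr, tpr, thr = roc_curve(y, s)
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return auc, points, int(usable.sum()), n_excluded


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney U of ``x``), average-tie ranks.

    Uses exact enumeration when both samples have fewer than 10 values and
    the pooled data are tie-free; otherwise the normal approximation with
    tie and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if min(len(x), len(y)) < 10 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def chi_square_2x2(table, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 count table (Yates optional), df = 1."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be non-negative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("all margins must be positive")
    chi2, p, _, _ = stats.chi2_contingency(t, correction=yates)
    return float(chi2), float(p)


_COVARIATE_LEVELS = {
    "hormone_therapy": (lambda v: v == 1, "treated", "untreated"),
    "radiation_therapy": (lambda v: v == 1, "treated", "untreated"),
    "n_status": (lambda v: v == "N+", "N+", "N-"),
    "gleason_binary": (lambda v: v > 7, "gleason>7", "gleason<=7"),
}


def stratified_survival(
    clinical: pd.DataFrame,
    is_groups: pd.Series,
    covariate: str,
    stage_filter: list[str] | None = None,
) -> StratifiedComparison:
    """Four-group PFS comparison: IS high/low crossed with a binary covariate.

    ``covariate`` is one of hormone_therapy, radiation_therapy, n_status or
    gleason_binary (Gleason dichotomized at <= 7 vs > 7).  An optional
    T-stage subset is applied before grouping; samples with a missing
    covariate are excluded and counted.
    """
    if covariate not in _COVARIATE_LEVELS:
        raise ValueError(f"unknown covariate {covariate!r}")
    pred, level_hi, level_lo = _COVARIATE_LEVELS[covariate]
    source_col = "gleason" if covariate == "gleason_binary" else covariate

    clin = clinical.set_index("sample_id") if "sample_id" in clinical.columns else clinical
    clin = clin.loc[clin.index.intersection(is_groups.index)]
    if stage_filter is not None:
        clin = clin[clin["t_stage"].isin(set(stage_filter))]
        if clin.empty:
            raise ValueError(f"stage filter {stage_filter} excludes all samples")
    n_before = len(clin)
    clin = clin[clin[source_col].notna()]
    n_excluded = n_before - len(clin)
    if n_excluded:
        logger.info("stratified analysis: excluded %d samples missing %s", n_excluded, source_col)

    level = clin[source_col].map(lambda v: level_hi if pred(v) else level_lo)
    combo = is_groups.loc[clin.index].astype(str) + "/" + level.astype(str)
    sizes = combo.value_counts().to_dict()
    expected = {
        f"{g}/{lv}" for g in ("high", "low") for lv in (level_hi, level_lo)
    }
    empty = sorted(expected - set(sizes))
    if empty:
        raise ValueError(f"empty strata: {empty}")

    times = clin["pfs_time"].to_numpy(float)
    events = clin["pfs_event"].to_numpy(int)
    chi2, df, p = logrank_test(combo.to_numpy(), times, events)
    curves = {
        name: km_estimate(
            times[(combo == name).to_numpy()], events[(combo == name).to_numpy()], label=name
        )
        for name in sorted(sizes)
    }
    return StratifiedComparison(
        group_sizes=sizes, chi2=chi2, df=df, p=p, curves=curves, n_excluded=n_excluded
    )
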