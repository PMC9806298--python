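"""Consensus NMF clustering of samples from the infiltration matrix.

Samples are clustered by non-negative matrix factorization of the
(min-max rescaled) cell-type x sample score matrix, stabilized by consensus
over random restarts.  Candidate ranks are screened for factorization
stability (cophenetic coefficient of the consensus matrix) and, among the
stable candidates, the rank whose clustering best separates
progression-free survival (largest log-rank chi-square) is chosen.

Progression-free survival thus enters *model selection only* — the
factorization itself stays unsupervised, which keeps the clustering
reproducible and independent of the outcome it is later evaluated against.

For a two-cluster solution, the cluster with the higher grand-mean
infiltration is labelled ``A`` (good prognosis side) and the other ``B``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.spatial.distance import squareform

from .ssgsea import InfiltrationMatrix

logger = logging.getLogger("immunoscore")

_EPS = 1e-10


@dataclass
class ClusterAssignment:
    """Cluster labels plus the rank-selection diagnostics behind them."""

    labels: pd.Series                  # sample -> label ('A'/'B' or 'C1'..'Ck')
    k: int
    cophenetic: dict[int, float]       # candidate rank -> cophenetic coefficient
    logrank_chi2: dict[int, float]     # candidate rank -> k-group log-rank chi-square
    consensus: pd.DataFrame            # samples x samples, chosen rank
    seed: int
    diagnostics: pd.DataFrame = field(default=None)  # tidy per-rank table
    logrank_p: dict[int, float] = field(default=None)  # candidate rank -> p (df = k-1)

    def indicator_b(self) -> pd.Series:
        """0/1 indicator of membership in cluster B (the trait for modules)."""
        if not set(self.labels.unique()) <= {"A", "B"}:
            raise ValueError("A/B semantics not available for k != 2 labels")
        return (self.labels == "B").astype(int)


def nonneg_scale(infil: InfiltrationMatrix | pd.DataFrame) -> pd.DataFrame:
    """Min-max scale each cell-type row to [0, 1] (NMF needs nonnegativity)."""
    df = infil.scores if isinstance(infil, InfiltrationMatrix) else infil
    lo = df.min(axis=1)
    hi = df.max(axis=1)
    span = hi - lo
    if (span == 0).any():
        name = df.index[(span == 0).to_numpy()][0]
        raise ValueError(f"constant cell-type row {name!r} cannot be min-max scaled")
    return df.sub(lo, axis=0).div(span, axis=0)


def nmf_factorize(
    X: np.ndarray,
    k: int,
    seed: int,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Multiplicative-update NMF for the Frobenius objective ||X - WH||^2.

    Returns ``(W, H, loss_trace)``; the loss trace is non-increasing (the
    classical guarantee of the multiplicative updates) and iteration stops
    when the relative loss change drops below ``tol``.
    """
    X = np.asarray(X, dtype=float)
    if (X < 0).any():
        raise ValueError("X must be nonnegative")
    m, n = X.shape
    if not (2 <= k < min(m, n)):
        raise ValueError(f"rank k={k} outside valid range [2, {min(m, n) - 1}]")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(X.mean() / k) if X.mean() > 0 else 1.0
    W = rng.uniform(0.1, 1.0, size=(m, k)) * scale
    H = rng.uniform(0.1, 1.0, size=(k, n)) * scale

    losses = [float(np.linalg.norm(X - W @ H) ** 2)]
    for _ in range(max_iter):
        H *= (W.T @ X) / (W.T @ W @ H + _EPS)
        W *= (X @ H.T) / (W @ H @ H.T + _EPS)
        loss = float(np.linalg.norm(X - W @ H) ** 2)
        losses.append(loss)
        prev = losses[-2]
        if prev > 0 and (prev - loss) / prev < tol:
            break
    return W, H, np.asarray(losses)


def _restart_labels(
    X: np.ndarray, k: int, seed: int, max_iter: int, tol: float, retry_cap: int = 5
) -> np.ndarray:
    """Hard assignments from one NMF restart (argmax row of H per sample)."""
    rng = np.random.default_rng(seed)
    for attempt in range(retry_cap + 1):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        _, H, _ = nmf_factorize(X, k, sub_seed, max_iter, tol)
        labels = np.argmax(H, axis=0)
        if len(np.unique(labels)) == k:
            return labels
        logger.debug("restart produced an empty cluster (attempt %d), retrying", attempt)
    raise RuntimeError(f"could not obtain {k} non-empty clusters after {retry_cap} retries")


def consensus_cluster(
    X: pd.DataFrame,
    k: int,
    n_restarts: int = 50,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> tuple[pd.Series, pd.DataFrame, float]:
    """Consensus clustering over NMF restarts.

    Returns ``(labels, consensus, cophenetic_coefficient)``.  The consensus
    entry (s, t) is the fraction of restarts co-assigning s and t; final
    labels come from average-linkage clustering of ``1 - consensus`` cut into
    k groups.
    """
    if n_restarts < 2:
        raise ValueError("n_restarts must be >= 2")
    samples = X.columns
    Xv = X.to_numpy(dtype=float)
    n = Xv.shape[1]
    ss = np.random.SeedSequence([seed, k])
    restart_seeds = ss.generate_state(n_restarts) % (2**31 - 1)

    co = np.zeros((n, n))
    for rs in restart_seeds:
        lab = _restart_labels(Xv, k, int(rs), max_iter, tol)
        co += lab[:, None] == lab[None, :]
    consensus = co / n_restarts
    np.fill_diagonal(consensus, 1.0)

    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = linkage(condensed, method="average")
    labels_int = fcluster(Z, t=k, criterion="maxclust")
    if len(condensed) > 1 and np.ptp(condensed) > 0:
        coph, _ = cophenet(Z, condensed)
        coph = float(coph)
    else:
        coph = 1.0  # all restarts agree exactly; trivially stable
    labels = pd.Series([f"C{i}" for i in labels_int], index=samples, name="cluster")
    consensus_df = pd.DataFrame(consensus, index=samples, columns=samples)
    return labels, consensus_df, coph


def select_rank_with_pfs(
    X: pd.DataFrame,
    clinical: pd.DataFrame,
    k_range: range | list[int] = range(2, 7),
    n_restarts: int = 50,
    seed: int = 0,
    stability_floor: float = 0.95,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> ClusterAssignment:
    """Choose the NMF rank by stability, tie-broken by PFS separation.

    For each candidate rank, consensus clustering yields labels, a consensus
    matrix and a cophenetic coefficient; a k-group log-rank test on PFS is
    computed for the labels.  Ranks with cophenetic >= ``stability_floor``
    are eligible (falling back to the max-cophenetic rank if none are), and
    among eligible ranks the one with the most significant PFS separation
    (smallest log-rank p, df = k-1) wins; the raw chi-square is not
    comparable across ranks because it grows with the group count.
    Significance is compared on the log scale (chi-square log-sf, immune to
    underflow), and the smallest rank within two decades of the best p is
    preferred — when every split is overwhelmingly significant the exact
    ordering of vanishing p-values is sampling noise, so parsimony decides.
    """
    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range is empty")
    clin = clinical.set_index("sample_id") if "sample_id" in clinical.columns else clinical
    missing = [s for s in X.columns if s not in clin.index]
    if missing:
        raise ValueError(f"clinical table missing samples: {missing[:5]}")
    clin = clin.loc[X.columns]

    per_rank: dict[int, tuple[pd.Series, pd.DataFrame, float, float]] = {}
    for k in k_range:
        labels, consensus, coph = consensus_cluster(
            X, k, n_restarts=n_restarts, seed=seed, max_iter=max_iter, tol=tol
        )
        test = multivariate_logrank_test(
            clin["pfs_time"].to_numpy(float),
            labels.to_numpy(),
            clin["pfs_event"].to_numpy(int),
        )
        per_rank[k] = (labels, consensus, coph, float(test.test_statistic))
        logger.info(
            "rank k=%d: cophenetic=%.4f, log-rank chi2=%.2f (p=%.3g)",
            k, coph, test.test_statistic, test.p_value,
        )

    cophs = {k: v[2] for k, v in per_rank.items()}
    chi2s = {k: v[3] for k, v in per_rank.items()}
    log10p = {k: float(stats.chi2.logsf(chi2s[k], df=k - 1)) / np.log(10) for k in k_range}
    pvals = {k: float(10.0 ** max(log10p[k], -320)) for k in k_range}
    eligible = [k for k in k_range if cophs[k] >= stability_floor]
    if not eligible:
        best_coph = max(k_range, key=lambda k: (cophs[k], -k))
        logger.warning(
            "no rank reaches cophenetic floor %.2f; falling back to k=%d",
            stability_floor,
            best_coph,
        )
        eligible = [best_coph]
    best_log10p = min(log10p[k] for k in eligible)
    chosen = min(k for k in eligible if log10p[k] <= best_log10p + 2.0)
    labels, consensus, _, _ = per_rank[chosen]
    diag = pd.DataFrame(
        {
            "k": k_range,
            "cophenetic": [cophs[k] for k in k_range],
            "logrank_chi2": [chi2s[k] for k in k_range],
            "logrank_p": [pvals[k] for k in k_range],
            "logrank_log10p": [log10p[k] for k in k_range],
            "eligible": [k in eligible for k in k_range],
            "chosen": [k == chosen for k in k_range],
        }
    )
    return ClusterAssignment(
        labels=labels,
        k=chosen,
        cophenetic=cophs,
        logrank_chi2=chi2s,
        consensus=consensus,
        seed=seed,
        diagnostics=diag,
        logrank_p=pvals,
    )


def label_clusters(
    assignment: ClusterAssignment, infil: InfiltrationMatrix
) -> ClusterAssignment:
    """Name the two clusters A (higher grand-mean infiltration) and B.

    With k != 2 the C1..Ck labels are kept and a warning is emitted.  On an
    exact tie of grand means, A is the cluster containing the
    lexicographically smallest sample id.
    """
    if assignment.k != 2:
        logger.warning("A/B semantics need k=2, got k=%d; labels kept as-is", assignment.k)
        return assignment
    labels = assignment.labels
    scores = infil.scores[labels.index]
    uniq = sorted(labels.unique())
    means = {c: float(scores.loc[:, (labels == c).to_numpy()].to_numpy().mean()) for c in uniq}
    if means[uniq[0]] == means[uniq[1]]:
        logger.warning("grand-mean infiltration tie; labelling A by smallest sample id")
        first = min(labels.index)
        a_cluster = labels.loc[first]
    else:
        a_cluster = max(uniq, key=lambda c: means[c])
    mapping = {c: ("A" if c == a_cluster else "B") for c in uniq}
    new_labels = labels.map(mapping).rename("cluster")
    return ClusterAssignment(
        labels=new_labels,
        k=assignment.k,
        cophenetic=assignment.cophenetic,
        logrank_chi2=assignment.logrank_chi2,
        consensus=assignment.consensus,
        seed=assignment.seed,
        diagnostics=assignment.diagnostics,
    )


def compare_clusters(
    infil: InfiltrationMatrix,
    expr: pd.DataFrame,
    assignment: ClusterAssignment,
    gene_list: list[str] = ("CTLA4", "CD274"),
) -> pd.DataFrame:
    """Wilcoxon rank-sum contrasts of cell-type abundances and named genes.

    Returns a tidy table (feature, kind, statistic, p, higher_in) comparing
    the two clusters; requested genes absent from the matrix are recorded
    with missing statistics.
    """
    labels = assignment.labels
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError("cluster comparison needs exactly two groups")
    g1 = labels.index[(labels == groups[0]).to_numpy()]
    g2 = labels.index[(labels == groups[1]).to_numpy()]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each cluster needs >= 2 samples")

    rows = []

    def _test(name: str, kind: str, values: pd.Series | None) -> None:
        if values is None:
            logger.warning("requested gene %r absent from expression matrix", name)
            rows.append((name, kind, np.nan, np.nan, None))
            return
        x, y = values[g1].to_numpy(float), values[g2].to_numpy(float)
        stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
        higher = groups[0] if np.median(x) > np.median(y) else groups[1]
        rows.append((name, kind, float(stat), float(p), higher))

    for ct in infil.scores.index:
        _test(ct, "cell_type", infil.scores.loc[ct])
    for gene in gene_list:
        _test(gene, "gene", expr.loc[gene] if gene in expr.index else None)

    return pd.DataFrame(rows, columns=["feature", "kind", "statistic", "p", "higher_in"])
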