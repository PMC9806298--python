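"""Weighted co-expression network, modules, eigengenes, MM and GS.

The network follows the unsigned weighted-correlation-network construction:
adjacency ``a_ij = |cor(x_i, x_j)|^beta`` with the soft threshold ``beta``
chosen by approximate scale-free topology, topological overlap

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    L_ij = sum_{u != i,j} a_iu * a_uj,   k_i = sum_{u != i} a_iu,

average-linkage hierarchical clustering of ``1 - TOM``, and a fixed-height
tree cut (a deliberate, deterministic simplification of the dynamic cut).
Modules take standard color-style names by decreasing size; unassigned
genes are "grey".  The module eigengene is the first principal component of
the module's standardized expression, oriented to correlate positively with
the module's mean profile.  Module membership (MM, also called kME) is a
gene's correlation with its module eigengene; gene significance (GS) is the
absolute correlation with the trait (here the 0/1 cluster-B indicator).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger("immunoscore")

MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
)

GREY = "grey"


@dataclass
class ModuleResult:
    """Full output of the module analysis on the analyzed gene subset."""

    labels: pd.Series             # gene -> module color ('grey' = unassigned)
    beta: int
    soft_threshold: pd.DataFrame  # per-beta scale-free fit table
    eigengenes: pd.DataFrame      # modules x samples, unit variance
    module_trait: pd.DataFrame    # per-module r, p vs the trait
    mm_gs: pd.DataFrame           # per-gene module, MM, GS


def filter_genes(expr: pd.DataFrame, n_top: int) -> pd.DataFrame:
    """Keep the ``n_top`` genes with highest median absolute deviation.

    ``n_top = 0`` keeps all genes.
    """
    if n_top < 0 or n_top > expr.shape[0]:
        raise ValueError("n_top must be in [0, n_genes]")
    if n_top == 0:
        return expr
    mad = stats.median_abs_deviation(expr.to_numpy(), axis=1)
    order = np.argsort(-mad, kind="stable")[:n_top]
    return expr.iloc[np.sort(order)]


def _correlation(expr: pd.DataFrame, method: str = "pearson") -> np.ndarray:
    x = expr.to_numpy(dtype=float)
    if (x.std(axis=1) == 0).any():
        gene = expr.index[(x.std(axis=1) == 0)][0]
        raise ValueError(f"constant gene {gene!r}; filter before building the network")
    if method == "spearman":
        x = stats.rankdata(x, axis=1)
    r = np.corrcoef(x)
    return np.clip(r, -1.0, 1.0)


def adjacency(expr: pd.DataFrame, beta: int, method: str = "pearson") -> pd.DataFrame:
    """Unsigned adjacency ``|cor|^beta`` (symmetric, unit diagonal)."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    a = np.abs(_correlation(expr, method)) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def pick_soft_threshold(
    expr: pd.DataFrame,
    beta_grid: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20),
    target_r2: float = 0.85,
    n_bins: int = 10,
    method: str = "pearson",
) -> tuple[int, pd.DataFrame]:
    """Choose the soft-threshold power by approximate scale-free topology.

    For each beta the connectivity distribution is binned (~``n_bins`` bins)
    and log10(frequency) is regressed on log10(mean connectivity); the fit is
    the signed R^2 (sign-flipped when the slope is positive).  The smallest
    beta reaching ``target_r2`` wins; if none does, the conventional default
    power for unsigned networks at this sample size (6 for n >= 40, up to 9
    below 20 samples) is returned with a warning — block-structured data
    with homogeneous connectivity never approximates scale-free topology,
    and chasing the best of a set of poor fits is not informative.
    """
    if not beta_grid:
        raise ValueError("beta_grid is empty")
    abs_r = np.abs(_correlation(expr, method))
    np.fill_diagonal(abs_r, 0.0)
    rows = []
    for beta in beta_grid:
        k = (abs_r**beta).sum(axis=1)
        try:
            fit, slope = _scale_free_fit(k, n_bins)
        except ValueError:
            fit, slope = np.nan, np.nan  # degenerate binning at extreme beta
        rows.append((beta, fit, slope, float(k.mean()), float(np.median(k))))
    table = pd.DataFrame(rows, columns=["beta", "fit", "slope", "mean_k", "median_k"])
    if table["fit"].isna().all():
        raise ValueError("no beta yields >= 3 usable connectivity bins; too few genes")
    reaching = table[table["fit"] >= target_r2]
    if len(reaching):
        beta = int(reaching["beta"].iloc[0])
    else:
        beta = _default_power(expr.shape[1], beta_grid)
        logger.warning(
            "no beta reaches scale-free fit %.2f (best %.3f); "
            "falling back to the default unsigned power beta=%d",
            target_r2,
            table["fit"].max(),
            beta,
        )
    return beta, table


def _default_power(n_samples: int, beta_grid: tuple[int, ...]) -> int:
    """Conventional unsigned-network power by sample count."""
    if n_samples >= 40:
        beta = 6
    elif n_samples >= 30:
        beta = 7
    elif n_samples >= 20:
        beta = 8
    else:
        beta = 9
    return min(beta_grid, key=lambda b: abs(b - beta))


def _scale_free_fit(k: np.ndarray, n_bins: int) -> tuple[float, float]:
    k = k[k > 0]
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        mean_k = k[sel].mean()
        freq = sel.mean()
        if mean_k > 0 and freq > 0:
            xs.append(np.log10(mean_k))
            ys.append(np.log10(freq))
    if len(xs) < 3:
        raise ValueError("fewer than 3 usable connectivity bins; too few genes")
    res = stats.linregress(xs, ys)
    r2 = float(res.rvalue**2)
    fit = r2 if res.slope < 0 else -r2
    return fit, float(res.slope)


def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of an adjacency matrix (unit diagonal)."""
    a = adj.to_numpy(dtype=float)
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    np.fill_diagonal(a, 0.0)  # exclude self terms from L and k
    L = a @ a
    k = a.sum(axis=1)
    min_k = np.minimum.outer(k, k)
    denom = min_k + 1.0 - a
    tom = (L + a) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


def detect_modules(
    diss_tom: pd.DataFrame,
    min_size: int = 30,
    cut_height: float = 0.90,
) -> pd.Series:
    """Modules by average-linkage clustering of ``1 - TOM`` with a height cut.

    The dendrogram is cut at the fixed dissimilarity ``cut_height``
    (within-module merges happen well below it, between-module and noise
    merges essentially at 1); clusters smaller than ``min_size`` become
    "grey".  Surviving modules are named by decreasing size with standard
    color names (exact size ties broken by the smallest member gene index,
    so permuting the gene order permutes nothing but the tie cases).
    """
    if min_size < 3:
        raise ValueError("min_size must be >= 3")
    if not (0 < cut_height < 1):
        raise ValueError("cut_height must be in (0, 1)")
    genes = diss_tom.index
    d = diss_tom.to_numpy(dtype=float).copy()
    np.fill_diagonal(d, 0.0)
    Z = linkage(squareform(d, checks=False), method="average")
    raw = fcluster(Z, t=cut_height, criterion="distance")

    sizes = pd.Series(raw).value_counts()
    keep = sizes[sizes >= min_size]
    if keep.empty:
        logger.warning("no module reaches min_size=%d; all genes grey", min_size)
        return pd.Series(GREY, index=genes, name="module")
    # order by decreasing size, ties by smallest member position
    first_pos = {c: int(np.argmax(raw == c)) for c in keep.index}
    ordered = sorted(keep.index, key=lambda c: (-keep[c], first_pos[c]))
    names = {}
    for i, c in enumerate(ordered):
        names[c] = MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module{i + 1}"
    labels = pd.Series([names.get(c, GREY) for c in raw], index=genes, name="module")
    n_modules = len(ordered)
    logger.info("detected %d modules (+%d grey genes)", n_modules, int((labels == GREY).sum()))
    return labels


def module_eigengenes(expr: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """First principal component of each module's standardized expression.

    Eigengenes are scaled to unit variance across samples and sign-oriented
    so each correlates non-negatively with its module's mean standardized
    profile.  Zero-variance genes are dropped from the PC with a warning.
    """
    modules = [m for m in labels.unique() if m != GREY]
    rows = {}
    for mod in sorted(modules):
        genes = labels.index[(labels == mod).to_numpy()]
        sub = expr.loc[genes]
        sd = sub.std(axis=1, ddof=1)
        if (sd == 0).any():
            logger.warning("module %s: dropping %d zero-variance genes", mod, int((sd == 0).sum()))
            sub = sub.loc[sd > 0]
            sd = sd.loc[sd > 0]
        if sub.shape[0] < 2:
            raise ValueError(f"module {mod!r} has < 2 usable genes")
        z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0).to_numpy()
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        eig = vt[0]
        eig = eig / eig.std(ddof=1)
        mean_profile = z.mean(axis=0)
        if np.dot(eig, mean_profile) < 0:
            eig = -eig
        rows[mod] = eig
    return pd.DataFrame(rows, index=expr.columns).T


def module_trait_correlation(
    eigengenes: pd.DataFrame, trait: pd.Series
) -> pd.DataFrame:
    """Pearson r (and two-sided p) of each eigengene with a 0/1 trait."""
    trait = trait.loc[eigengenes.columns].astype(float)
    if trait.nunique() < 2:
        raise ValueError("trait is constant")
    rows = []
    for mod in eigengenes.index:
        r, p = stats.pearsonr(eigengenes.loc[mod].to_numpy(), trait.to_numpy())
        rows.append((mod, float(r), float(p)))
    return pd.DataFrame(rows, columns=["module", "r", "p"]).set_index("module")


def compute_mm_gs(
    expr: pd.DataFrame,
    eigengenes: pd.DataFrame,
    labels: pd.Series,
    trait: pd.Series,
) -> pd.DataFrame:
    """Per-gene module membership and gene significance.

    MM = cor(gene, its module's eigengene) in [-1, 1] (missing for grey
    genes); GS = |cor(gene, trait)| in [0, 1].
    """
    trait_v = trait.loc[expr.columns].astype(float).to_numpy()
    rows = []
    for gene in labels.index:
        x = expr.loc[gene].to_numpy(dtype=float)
        mod = labels.loc[gene]
        if mod != GREY and mod in eigengenes.index and x.std() > 0:
            mm = float(stats.pearsonr(x, eigengenes.loc[mod].to_numpy())[0])
        else:
            mm = np.nan
        gs = float(abs(stats.pearsonr(x, trait_v)[0])) if x.std() > 0 else np.nan
        rows.append((gene, mod, mm, gs))
    return pd.DataFrame(rows, columns=["gene", "module", "MM", "GS"]).set_index("gene")


def run_module_analysis(
    expr: pd.DataFrame,
    trait: pd.Series,
    n_top: int = 0,
    beta_grid: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20),
    target_r2: float = 0.85,
    min_size: int = 30,
    cut_height: float = 0.90,
    merge_threshold: float | None = None,
    method: str = "pearson",
) -> ModuleResult:
    """End-to-end module analysis: filter, threshold, TOM, cut, MM/GS."""
    sub = filter_genes(expr, n_top)
    sub = sub.loc[sub.std(axis=1) > 0]
    beta, table = pick_soft_threshold(sub, beta_grid, target_r2, method=method)
    adj = adjacency(sub, beta, method=method)
    tom = tom_similarity(adj)
    labels = detect_modules(1.0 - tom, min_size=min_size, cut_height=cut_height)
    if (labels == GREY).all():
        eig = pd.DataFrame(columns=sub.columns)
        mt = pd.DataFrame(columns=["r", "p"])
        mmgs = compute_mm_gs(sub, eig, labels, trait)
        return ModuleResult(labels, beta, table, eig, mt, mmgs)
    eig = module_eigengenes(sub, labels)
    if merge_threshold is not None:
        labels, eig = _merge_modules(sub, labels, eig, merge_threshold)
    mt = module_trait_correlation(eig, trait)
    mmgs = compute_mm_gs(sub, eig, labels, trait)
    return ModuleResult(labels, beta, table, eig, mt, mmgs)


def _merge_modules(
    expr: pd.DataFrame, labels: pd.Series, eig: pd.DataFrame, threshold: float
) -> tuple[pd.Series, pd.DataFrame]:
    """Merge modules whose eigengenes correlate >= threshold (single pass)."""
    mods = list(eig.index)
    parent = {m: m for m in mods}

    def find(m):
        while parent[m] != m:
            m = parent[m]
        return m

    for i, a in enumerate(mods):
        for b in mods[i + 1 :]:
            r = float(np.corrcoef(eig.loc[a], eig.loc[b])[0, 1])
            if r >= threshold:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb, key=mods.index)] = min(ra, rb, key=mods.index)
    mapping = {m: find(m) for m in mods}
    if all(k == v for k, v in mapping.items()):
        return labels, eig
    merged = labels.map(lambda m: mapping.get(m, m))
    new_eig = module_eigengenes(expr, merged)
    return merged, new_eig
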