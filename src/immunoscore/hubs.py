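"""Hub-gene screening and interaction-network hub ranking.

Hub genes are screened inside cluster-associated modules by the strict
criteria MM > 0.8 and GS > 0.5 (both configurable); each hub carries its
module's trait-correlation sign — ``positive`` modules correlate positively
with cluster B (the low-infiltration side), ``negative`` ones negatively.

For a user-supplied undirected interaction network, two hub rankers are
offered: plain degree and maximal clique centrality (MCC), the sum over
maximal cliques C containing a node of ``(|C| - 1)!``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .io import EdgeList

logger = logging.getLogger("immunoscore")


@dataclass
class HubGeneSet:
    """Screened hub genes partitioned by source module and trait sign."""

    table: pd.DataFrame  # index gene; columns: module, sign ('positive'/'negative')

    def __len__(self) -> int:
        return len(self.table)

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def by_sign(self, sign: str) -> dict[str, list[str]]:
        """Map module -> hub genes, restricted to one trait sign."""
        sel = self.table[self.table["sign"] == sign]
        return {m: g.index.tolist() for m, g in sel.groupby("module")}


def select_modules(
    module_trait: pd.DataFrame, r_floor: float = 0.5, p_ceiling: float = 0.05
) -> pd.DataFrame:
    """Modules with |r| >= r_floor and p <= p_ceiling, tagged by sign of r."""
    if module_trait.empty:
        raise ValueError("module_trait table is empty")
    sel = module_trait[
        (module_trait["r"].abs() >= r_floor) & (module_trait["p"] <= p_ceiling)
    ].copy()
    if sel.empty:
        logger.warning("no module passes |r| >= %.2f and p <= %.3g", r_floor, p_ceiling)
    sel["sign"] = sel["r"].map(lambda r: "positive" if r > 0 else "negative")
    return sel


def screen_hub_genes(
    mm_gs: pd.DataFrame,
    selected_modules: pd.DataFrame,
    mm_threshold: float = 0.8,
    gs_threshold: float = 0.5,
) -> HubGeneSet:
    """Genes of selected modules with MM > mm_threshold AND GS > gs_threshold.

    Both inequalities are strict; each retained gene carries its module's
    trait sign.  Counts per module are logged.
    """
    if not (0 < mm_threshold < 1) or not (0 < gs_threshold < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    rows = []
    for mod, info in selected_modules.iterrows():
        sub = mm_gs[mm_gs["module"] == mod]
        hubs = sub[(sub["MM"] > mm_threshold) & (sub["GS"] > gs_threshold)]
        logger.info("module %s: %d hub genes of %d", mod, len(hubs), len(sub))
        for gene in hubs.index:
            rows.append((gene, mod, info["sign"]))
    table = pd.DataFrame(rows, columns=["gene", "module", "sign"]).set_index("gene")
    return HubGeneSet(table=table)


def _graph(edges: EdgeList) -> nx.Graph:
    g = nx.Graph()
    for _, row in edges.edges.iterrows():
        g.add_edge(row["node1"], row["node2"], weight=row["weight"])
    return g


def degree_ranking(edges: EdgeList) -> pd.DataFrame:
    """Undirected degree per node, descending, ties broken by node id."""
    g = _graph(edges)
    rows = sorted(g.degree(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["node", "degree"]).set_index("node")


def mcc_ranking(edges: EdgeList, node_cap: int = 2000) -> pd.DataFrame:
    """Exact maximal clique centrality per node, descending.

    MCC(v) = sum over maximal cliques C containing v of (|C| - 1)!.  When a
    node's only maximal cliques are single edges this equals its degree.
    Maximal cliques are enumerated exactly (Bron-Kerbosch with pivoting), so
    a node cap guards against pathological inputs.
    """
    g = _graph(edges)
    if g.number_of_nodes() > node_cap:
        raise ValueError(
            f"{g.number_of_nodes()} nodes exceed the MCC cap of {node_cap}; "
            "use degree_ranking instead"
        )
    score = {v: 0 for v in g.nodes}
    for clique in nx.find_cliques(g):
        if len(clique) < 2:
            continue
        contrib = math.factorial(len(clique) - 1)
        for v in clique:
            score[v] += contrib
    rows = sorted(score.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["node", "mcc"]).set_index("node")
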