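"""Gene-pair Pearson coexpression network between two gene classes.

The single-gene baseline the set-level screen is compared against: a
bipartite graph whose nodes are disease and metabolic-pathway genes and
whose edges connect pairs correlated above a threshold across the
compendium (r > 0.6 in the signed default).  Connected subnetworks, their
hub genes (maximum degree) and a hypergeometric pathway-enrichment test of
the connected metabolic genes summarise what per-gene correlation alone
can see.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, GeneList, PathwayCollection

logger = logging.getLogger(__name__)

DISEASE = "disease"
METABOLIC = "metabolic"


class CoexpressionNetwork:
    """Bipartite gene graph with Pearson-r edge weights.

    Thin wrapper over a ``networkx.Graph``; nodes carry a ``klass``
    attribute (``"disease"`` or ``"metabolic"``), edges an ``r`` weight
    stored at full precision.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_class(self, gene: str) -> str:
        return self.graph.nodes[gene]["klass"]

    def nodes_of_class(self, klass: str) -> list[str]:
        return sorted(g for g, d in self.graph.nodes(data=True) if d["klass"] == klass)

    def connected_nodes(self) -> list[str]:
        """Nodes with at least one edge, sorted."""
        return sorted(g for g in self.graph.nodes if self.graph.degree[g] > 0)

    def iter_edges(self):
        """Yield (source, target, r, source_class, target_class) with the
        disease gene first for cross-class edges."""
        for u, v, d in self.graph.edges(data=True):
            cu, cv = self.node_class(u), self.node_class(v)
            if (cu, cv) == (METABOLIC, DISEASE) or (cu == cv and v < u):
                u, v, cu, cv = v, u, cv, cu
            yield u, v, d["r"], cu, cv


def bipartite_pearson_network(
    expr: ExpressionMatrix,
    disease: GeneList,
    metabolic: GeneList,
    r_min: float = 0.6,
    mode: str = "signed",
) -> CoexpressionNetwork:
    """Connect disease to metabolic genes whose profiles correlate above r_min.

    ``mode="signed"`` keeps edges with r > r_min; ``mode="absolute"`` with
    |r| > r_min.  Genes absent from the compendium are skipped; genes on
    both lists are dropped from the metabolic side with a warning.
    """
    if mode not in ("signed", "absolute"):
        raise ValueError(f"mode must be 'signed' or 'absolute', got {mode!r}")
    measured = set(expr.gene_ids)
    dis = [g for g in disease if g in measured]
    overlap = set(dis)
    met = [g for g in metabolic if g in measured and g not in overlap]
    n_shared = sum(1 for g in metabolic if g in measured and g in overlap)
    if n_shared:
        logger.warning(
            "%d genes on both lists kept on the disease side only", n_shared
        )
    if not dis or not met:
        raise ValueError("no usable genes on one of the lists")

    D = expr.submatrix(dis)
    P = expr.submatrix(met)
    sd_d = D.std(axis=1, ddof=1)
    sd_p = P.std(axis=1, ddof=1)
    if np.any(sd_d == 0) or np.any(sd_p == 0):
        const = [g for g, s in zip(dis, sd_d) if s == 0]
        const += [g for g, s in zip(met, sd_p) if s == 0]
        logger.warning("constant genes excluded from the network: %s", const)
        dis = [g for g, s in zip(dis, sd_d) if s > 0]
        met = [g for g, s in zip(met, sd_p) if s > 0]
        D, P = expr.submatrix(dis), expr.submatrix(met)

    n = expr.n_experiments
    Dz = (D - D.mean(axis=1, keepdims=True)) / D.std(axis=1, ddof=1, keepdims=True)
    Pz = (P - P.mean(axis=1, keepdims=True)) / P.std(axis=1, ddof=1, keepdims=True)
    R = np.clip(Dz @ Pz.T / (n - 1), -1.0, 1.0)

    g = nx.Graph()
    g.add_nodes_from(dis, klass=DISEASE)
    g.add_nodes_from(met, klass=METABOLIC)
    score = np.abs(R) if mode == "absolute" else R
    for i, j in zip(*np.nonzero(score > r_min)):
        g.add_edge(dis[i], met[j], r=float(R[i, j]))
    return CoexpressionNetwork(g)


def connected_components(net: CoexpressionNetwork) -> list[CoexpressionNetwork]:
    """Maximal connected subgraphs with >= 2 nodes (isolated nodes excluded),
    ordered by descending size, ties by smallest member gene ID."""
    comps = [c for c in nx.connected_components(net.graph) if len(c) > 1]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return [CoexpressionNetwork(net.graph.subgraph(c).copy()) for c in comps]


def hub_nodes(component: CoexpressionNetwork) -> list[str]:
    """All maximum-degree genes of one connected component, ID-ascending."""
    g = component.graph
    if g.number_of_nodes() < 2:
        raise ValueError("component must have at least 2 nodes")
    if not nx.is_connected(g):
        raise ValueError("not a connected component")
    degrees = dict(g.degree)
    top = max(degrees.values())
    return sorted(n for n, d in degrees.items() if d == top)


@dataclass
class EnrichmentRow:
    """One pathway's over-representation test among a query gene set."""

    pathway_id: str
    hit_count: int
    pathway_size: int
    background_size: int
    p_value: float
    q_value: float
    hit_genes: list[str]


def hypergeometric_enrichment(
    query: GeneList,
    pathways: PathwayCollection,
    background: GeneList,
) -> list[EnrichmentRow]:
    """Upper-tail hypergeometric test of each pathway within the query.

    p = P[X >= hits] for X ~ Hypergeom(N=|background|, K=|pathway ∩
    background|, n=|query|); Benjamini-Hochberg q across pathways; rows
    sorted by ascending p (stable in pathway order).
    """
    bg = set(background.gene_ids)
    if not bg:
        raise ValueError("background is empty")
    q_genes = [g for g in query if g in bg]
    n_outside = len(query.gene_ids) - len(q_genes)
    if n_outside:
        logger.warning("%d query genes outside the background were dropped", n_outside)
    qset = set(q_genes)
    N, n_draw = len(bg), len(q_genes)

    rows: list[EnrichmentRow] = []
    for pid, _, members in pathways:
        in_bg = [g for g in members if g in bg]
        hits = [g for g in in_bg if g in qset]
        K, k = len(in_bg), len(hits)
        p = float(stats.hypergeom.sf(k - 1, N, K, n_draw)) if k > 0 else 1.0
        rows.append(EnrichmentRow(pid, k, K, N, min(p, 1.0), np.nan, sorted(hits)))
    if rows:
        qvals = multipletests([r.p_value for r in rows], method="fdr_bh")[1]
        for row, qv in zip(rows, qvals):
            row.q_value = float(qv)
    rows.sort(key=lambda r: r.p_value)
    return rows
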