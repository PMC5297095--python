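"""Gene co-expression network construction and hub calling.

An undirected graph over the positively seed-associated genes: two genes are
connected when their Pearson correlation over case samples reaches ``r_min``
(ties at the threshold included). Topology is unweighted — the correlation is
kept as edge metadata only. Hubs are the intersection of the top-k lists by
degree and by betweenness centrality, both closed under ties at the k-th rank.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)


def build_gcn(matrix: ExpressionMatrix, genes: list[str], r_min: float = 0.7) -> nx.Graph:
    """Build the co-expression graph over ``genes`` from pairwise Pearson r.

    Nodes are the genes incident to at least one edge with r >= r_min;
    candidates with no qualifying partner are excluded, so every node has
    degree >= 1. Fewer than 2 surviving nodes is an error.
    """
    genes = list(dict.fromkeys(genes))
    if len(genes) < 2:
        raise ValueError("need >= 2 candidate genes for network construction")
    missing = [g for g in genes if g not in matrix.values.index]
    if missing:
        raise KeyError(f"genes not in matrix: {missing[:5]}")
    x = matrix.values.loc[genes].to_numpy(dtype=float)
    if x.shape[1] < 3:
        raise ValueError("need >= 3 samples to correlate")
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(x)
    np.fill_diagonal(r, 0.0)
    r = np.nan_to_num(r, nan=0.0)

    g = nx.Graph()
    ii, jj = np.nonzero(np.triu(r >= r_min, k=1))
    for i, j in zip(ii.tolist(), jj.tolist()):
        g.add_edge(genes[i], genes[j], weight=float(r[i, j]))
    if g.number_of_nodes() < 2:
        raise ValueError(
            f"fewer than 2 genes connected at r >= {r_min}: co-expression network is empty"
        )
    logger.info("GCN: %d nodes, %d edges (r_min=%g, %d candidates)",
                g.number_of_nodes(), g.number_of_edges(), r_min, len(genes))
    return g


def centrality(graph: nx.Graph) -> pd.DataFrame:
    """Degree and unnormalised betweenness per node.

    Betweenness uses unweighted shortest paths with fractional credit across
    multiple shortest paths; each unordered pair is counted once.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    deg = dict(graph.degree())
    btw = nx.betweenness_centrality(graph, normalized=False)
    out = pd.DataFrame({
        "degree": pd.Series(deg, dtype=int),
        "betweenness": pd.Series(btw, dtype=float),
    })
    out.index.name = "gene_id"
    return out.sort_values(["degree", "betweenness"], ascending=False)


def _top_k_closed(values: pd.Series, k: int) -> set:
    """Top-k index labels by value, closed under ties at the k-th rank."""
    if k <= 0:
        return set()
    ordered = values.sort_values(ascending=False)
    if k >= len(ordered):
        return set(ordered.index)
    cutoff = ordered.iloc[k - 1]
    return set(ordered.index[ordered >= cutoff])


def select_hubs(cent: pd.DataFrame, k: int = 10) -> dict:
    """Hub genes: intersection of top-k by degree and top-k by betweenness.

    Returns a dict with keys ``top_degree``, ``top_betweenness`` (tie-closed
    sets) and ``hubs`` (sorted list of the intersection; may be empty).
    """
    if k > len(cent):
        raise ValueError(f"k={k} exceeds the {len(cent)} nodes in the network")
    top_deg = _top_k_closed(cent["degree"], k)
    top_btw = _top_k_closed(cent["betweenness"], k)
    hubs = sorted(top_deg & top_btw)
    logger.info("hubs: %d (top-%d degree: %d genes, top-%d betweenness: %d genes)",
                len(hubs), k, len(top_deg), k, len(top_btw))
    return {"top_degree": top_deg, "top_betweenness": top_btw, "hubs": hubs}


def edge_table(graph: nx.Graph) -> pd.DataFrame:
    """Edge list as a DataFrame (gene_a, gene_b, r), lexicographically ordered."""
    rows = [
        {"gene_a": min(u, v), "gene_b": max(u, v), "r": d.get("weight", np.nan)}
        for u, v, d in graph.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "r"]).sort_values(
        ["gene_a", "gene_b"]).reset_index(drop=True)
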