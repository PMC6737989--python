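"""Co-expression graph construction and Markov clustering.

Features whose expression profiles correlate at Pearson r >= 0.90 are
joined by an edge; the resulting graph is partitioned with the Markov
cluster algorithm (MCL) at inflation 2.2, and each cluster is labelled
by the tissue in which its members are on average most expressed.

Edges enter MCL unweighted after thresholding (an optional weighted
mode uses r as the edge weight); self-loops of weight 1 are added
before normalization, the canonical MCL regularization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .quantify import NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CoexpressionGraph",
    "ClusterSet",
    "build_correlation_graph",
    "mcl_cluster",
    "label_clusters",
]


@dataclass
class CoexpressionGraph:
    """Undirected graph of expressed features; edge weight is Pearson r."""

    graph: nx.Graph
    r_min: float

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edge_table(self) -> pd.DataFrame:
        rows = [(a, b, d["r"]) for a, b, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["id_a", "id_b", "r"])


@dataclass
class ClusterSet:
    """Disjoint clusters of graph nodes plus separately-reported singletons."""

    clusters: list[set[str]]
    singletons: set[str] = field(default_factory=set)
    labels: dict[int, str] = field(default_factory=dict)
    inflation: float = 2.2
    converged: bool = True

    def membership(self) -> dict[str, int]:
        out = {}
        for i, c in enumerate(self.clusters):
            for node in c:
                out[node] = i
        return out


def build_correlation_graph(
    expr: NormalizedMatrix | pd.DataFrame, r_min: float = 0.90
) -> CoexpressionGraph:
    """Edge (a, b) present iff Pearson r of the two profiles >= ``r_min``.

    Needs at least 3 samples (r on 2 points is degenerate).  Features
    with zero profile variance are excluded with a logged count.
    """
    v = expr.values if isinstance(expr, NormalizedMatrix) else expr
    if v.shape[1] < 3:
        raise ValueError("correlation graph needs >= 3 samples")
    sd = v.std(axis=1, ddof=1)
    kept = v.loc[sd > 0]
    dropped = len(v) - len(kept)
    if dropped:
        logger.info("excluded %d zero-variance feature(s) from the graph", dropped)
    g = nx.Graph()
    g.add_nodes_from(kept.index)
    if len(kept) >= 2:
        corr = np.corrcoef(kept.to_numpy())
        idx = kept.index.to_numpy()
        ii, jj = np.triu_indices(len(kept), k=1)
        hit = corr[ii, jj] >= r_min
        g.add_edges_from(
            (idx[i], idx[j], {"r": float(corr[i, j])})
            for i, j in zip(ii[hit], jj[hit])
        )
    return CoexpressionGraph(g, r_min)


def mcl_cluster(
    coexpr: CoexpressionGraph | nx.Graph,
    inflation: float = 2.2,
    expansion: int = 2,
    prune_below: float = 1e-5,
    max_iter: int = 200,
    tol: float = 1e-6,
    weighted: bool = False,
) -> ClusterSet:
    """Partition the graph with the Markov cluster algorithm.

    The transition matrix gets self-loops of weight 1 and is made
    column-stochastic; each iteration applies expansion (matrix power),
    inflation (elementwise power, column renormalization) and pruning
    of entries below ``prune_below``, until the largest column change
    falls below ``tol``.  Clusters are the connected components of the
    attractor structure of the limit matrix.  Non-convergence at
    ``max_iter`` returns the current clustering with ``converged=False``.
    """
    g = coexpr.graph if isinstance(coexpr, CoexpressionGraph) else coexpr
    if g.number_of_nodes() == 0:
        raise ValueError("MCL needs a non-empty graph")
    nodes = sorted(g.nodes)  # fixed order: output invariant to insertion order
    n = len(nodes)
    pos = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((n, n))
    for a, b, d in g.edges(data=True):
        w = float(d.get("r", 1.0)) if weighted else 1.0
        m[pos[a], pos[b]] = w
        m[pos[b], pos[a]] = w
    np.fill_diagonal(m, 1.0)
    m /= m.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        m = np.power(m, inflation)
        m[m < prune_below] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        m /= colsum
        if np.abs(m - prev).max() < tol:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not converge in %d iterations", max_iter)

    # attractors: rows with support on the diagonal; a cluster is an
    # attractor system together with every node flowing into it
    support = nx.Graph()
    support.add_nodes_from(range(n))
    rows, cols = np.nonzero(m > 0)
    support.add_edges_from(zip(rows, cols))
    comps = [set(nodes[i] for i in comp) for comp in nx.connected_components(support)]
    clusters = sorted(
        (c for c in comps if len(c) > 1), key=lambda c: sorted(c)[0]
    )
    singletons = set().union(*(c for c in comps if len(c) == 1)) if comps else set()
    return ClusterSet(clusters, singletons, inflation=inflation, converged=converged)


def label_clusters(
    clusters: ClusterSet, expr: NormalizedMatrix | pd.DataFrame
) -> ClusterSet:
    """Label each cluster by the tissue with maximal mean member expression.

    Exact ties go to the alphabetically first tissue with a logged
    warning.
    """
    v = expr.values if isinstance(expr, NormalizedMatrix) else expr
    cols = sorted(v.columns)  # lexicographic tie-break via ordering + idxmax
    for i, members in enumerate(clusters.clusters):
        means = v.loc[sorted(members), cols].mean(axis=0)
        best = means.idxmax()
        if (means == means.max()).sum() > 1:
            logger.warning(
                "cluster %d: tie for top tissue, labelled %r alphabetically", i, best
            )
        clusters.labels[i] = str(best)
    return clusters
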