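"""Centrality measures and top-ten intersection selection.

Five measures are computed on the annotated directed network: in-degree,
out-degree, betweenness (directed, unweighted, unnormalized, endpoints
excluded), and HITS hub/authority scores. Measures driven by outgoing edges
(out-degree, hub, betweenness) are ranked over TF-role nodes only; measures
driven by incoming edges (in-degree, authority) over target-role genes only
(target genes are sinks, so their out-based scores are trivially zero).

Central regulators are the TFs common to the top-ten lists of out-degree,
hub score and betweenness; central targets are the glycolysis genes common
to the top-ten in-degree and authority lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from glyconet.annotation import AnnotatedNetwork
from glyconet.errors import ConvergenceError

logger = logging.getLogger(__name__)

TF_MEASURES = ("out_degree", "hub", "betweenness")
TARGET_MEASURES = ("in_degree", "authority")


def hits_scores(
    graph: nx.DiGraph, tol: float = 1e-10, max_iter: int = 1000
) -> tuple[dict[str, float], dict[str, float]]:
    """Hub and authority scores by normalized power iteration.

    A node's authority is the sum of hub scores of nodes linking into it;
    its hub score is the sum of authority scores of the nodes it links to.
    Iteration starts from the uniform vector and renormalizes to unit
    Euclidean norm each step; convergence is declared when the maximum
    elementwise change of both vectors drops below ``tol``. An edgeless
    graph gets all-zero scores.
    """
    nodes = list(graph.nodes)
    k = len(nodes)
    if k == 0 or graph.number_of_edges() == 0:
        return {n: 0.0 for n in nodes}, {n: 0.0 for n in nodes}
    a = nx.to_numpy_array(graph, nodelist=nodes)  # a[i, j] = 1 iff i -> j
    hub = np.full(k, 1.0 / np.sqrt(k))
    auth = np.full(k, 1.0 / np.sqrt(k))
    residual = np.inf
    for _ in range(max_iter):
        new_auth = a.T @ hub
        norm = np.linalg.norm(new_auth)
        if norm > 0:
            new_auth /= norm
        new_hub = a @ new_auth
        norm = np.linalg.norm(new_hub)
        if norm > 0:
            new_hub /= norm
        residual = max(
            float(np.abs(new_auth - auth).max()), float(np.abs(new_hub - hub).max())
        )
        auth, hub = new_auth, new_hub
        if residual < tol:
            break
    else:
        raise ConvergenceError(
            f"HITS did not converge in {max_iter} iterations", residual=residual
        )
    return dict(zip(nodes, hub)), dict(zip(nodes, auth))


def degree_centrality(net: AnnotatedNetwork) -> pd.DataFrame:
    """Integer in- and out-degree per node."""
    g = net.graph
    return pd.DataFrame(
        {
            "in_degree": pd.Series(dict(g.in_degree()), dtype=int),
            "out_degree": pd.Series(dict(g.out_degree()), dtype=int),
        }
    )


def betweenness_centrality(net: AnnotatedNetwork) -> pd.Series:
    """Directed unweighted shortest-path betweenness, unnormalized."""
    return pd.Series(
        nx.betweenness_centrality(net.graph, normalized=False), dtype=float
    )


def centrality_table(net: AnnotatedNetwork, tol: float = 1e-10, max_iter: int = 1000) -> pd.DataFrame:
    """All five measures plus node role, indexed by node."""
    g = net.graph
    hub, auth = hits_scores(g, tol=tol, max_iter=max_iter)
    table = degree_centrality(net)
    table["betweenness"] = betweenness_centrality(net)
    table["hub"] = pd.Series(hub)
    table["authority"] = pd.Series(auth)
    table["role"] = pd.Series(dict(g.nodes(data="role")))
    return table.fillna(0.0) if len(table) else table


def top_k(
    table: pd.DataFrame, measure: str, role_filter: str, k: int = 10
) -> list[str]:
    """Top-k nodes of one role by one measure, keeping rank-k ties.

    Nodes sharing the k-th distinct value are all included, so the list may
    exceed k; the secondary sort by gene identifier makes output
    deterministic. With fewer than k eligible nodes, all are returned.
    """
    if measure in TF_MEASURES and role_filter != "TF":
        raise ValueError(f"measure {measure!r} is ranked over TF-role nodes")
    if measure in TARGET_MEASURES and role_filter != "target":
        raise ValueError(f"measure {measure!r} is ranked over target-role nodes")
    sub = table[table["role"] == role_filter]
    ordered = (
        sub.assign(_gene=sub.index)
        .sort_values([measure, "_gene"], ascending=[False, True], kind="mergesort")
    )
    if len(ordered) <= k:
        if len(ordered) < k:
            logger.info(
                "top_k(%s): only %d eligible %s nodes (< k=%d)",
                measure, len(ordered), role_filter, k,
            )
        return list(ordered.index)
    cutoff = ordered[measure].iloc[k - 1]
    return list(ordered.index[ordered[measure] >= cutoff])


@dataclass
class SelectionResult:
    """Central genes from the top-ten intersection rule."""

    central_tfs: set[str]
    central_targets: set[str]
    top_lists: dict[str, list[str]] = field(default_factory=dict)


def select_central_genes(table: pd.DataFrame, k: int = 10) -> SelectionResult:
    """Intersect the per-measure top-k lists.

    central_tfs = top_k(out_degree) & top_k(hub) & top_k(betweenness) over
    TF-role nodes; central_targets = top_k(in_degree) & top_k(authority)
    over target-role genes.
    """
    tops = {m: top_k(table, m, "TF", k) for m in TF_MEASURES}
    tops.update({m: top_k(table, m, "target", k) for m in TARGET_MEASURES})
    central_tfs = set(tops["out_degree"]) & set(tops["hub"]) & set(tops["betweenness"])
    central_targets = set(tops["in_degree"]) & set(tops["authority"])
    return SelectionResult(
        central_tfs=central_tfs, central_targets=central_targets, top_lists=tops
    )
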