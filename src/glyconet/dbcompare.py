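"""Promoter-class vs enhancer-class network and binding-site comparison.

Because the enhancer-annotated network has no TF-TF edges, most centrality
measures are not comparable across the two databases; the per-target
in-degree is, since glycolysis genes only ever receive edges. This module
compares target in-degrees and shared directed edges between the two
annotated networks, and binding-site counts per common TF for one target.
"""

from __future__ import annotations

import logging

import pandas as pd

from glyconet.annotation import AnnotatedNetwork, RegulatoryDB
from glyconet.errors import ConsistencyError

logger = logging.getLogger(__name__)


def compare_in_degrees(
    net_promoter: AnnotatedNetwork,
    net_enhancer: AnnotatedNetwork,
    de_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-target in-degrees in both networks plus shared directed edges.

    Rows cover the union of target-role genes across the two networks;
    a gene absent from one network has in-degree 0 there. ``common_edges``
    counts (tf, target) directed edges present in both networks. With a DE
    table supplied, ``de_status`` carries the gene's up/down/ns call. Sorted
    by promoter-network in-degree, descending.
    """
    for net, other in ((net_promoter, net_enhancer), (net_enhancer, net_promoter)):
        shared = set(net.graph.nodes) & set(other.graph.nodes)
        for n in shared:
            if net.graph.nodes[n]["role"] != other.graph.nodes[n]["role"]:
                raise ConsistencyError(f"gene {n!r} has conflicting roles across networks")

    targets = sorted(set(net_promoter.target_nodes) | set(net_enhancer.target_nodes))
    edges_p = set(net_promoter.graph.edges)
    edges_e = set(net_enhancer.graph.edges)
    rows = []
    for gene in targets:
        deg_p = net_promoter.graph.in_degree(gene) if gene in net_promoter.graph else 0
        deg_e = net_enhancer.graph.in_degree(gene) if gene in net_enhancer.graph else 0
        common = sum(1 for tf, tg in edges_p & edges_e if tg == gene)
        status = "-"
        if de_table is not None and gene in de_table.index:
            status = str(de_table.loc[gene, "status"])
        rows.append(
            {
                "gene": gene,
                "de_status": status,
                "in_degree_promoter": deg_p,
                "in_degree_enhancer": deg_e,
                "common_edges": common,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["gene", "de_status", "in_degree_promoter", "in_degree_enhancer", "common_edges"],
    )
    if len(out):
        assert (
            out["common_edges"] <= out[["in_degree_promoter", "in_degree_enhancer"]].min(axis=1)
        ).all(), "common edges exceed an in-degree"
        out = out.sort_values(
            ["in_degree_promoter", "gene"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
    return out


def compare_binding_sites(
    db_promoter: RegulatoryDB, db_enhancer: RegulatoryDB, target: str
) -> tuple[pd.DataFrame, pd.Series]:
    """Binding-site counts per common TF of one target, in both databases.

    Returns ``(rows, summary)``: one row per TF recorded against the target
    in both databases, and tallies of TFs with more enhancer sites, more
    promoter sites, or equal counts. The tallies always sum to the common-TF
    count. A target absent from either database yields an empty result (a
    notice is logged).
    """
    p = db_promoter.records.query("target == @target").set_index("tf")["binding_sites"]
    e = db_enhancer.records.query("target == @target").set_index("tf")["binding_sites"]
    common = sorted(set(p.index) & set(e.index))
    if not common:
        logger.info("compare_binding_sites: target %r has no common TFs", target)
    rows = pd.DataFrame(
        {
            "tf": common,
            "sites_promoter": [int(p[tf]) for tf in common],
            "sites_enhancer": [int(e[tf]) for tf in common],
        }
    )
    summary = pd.Series(
        {
            "n_common_tfs": len(common),
            "n_more_enhancer": int((rows["sites_enhancer"] > rows["sites_promoter"]).sum()) if len(rows) else 0,
            "n_more_promoter": int((rows["sites_promoter"] > rows["sites_enhancer"]).sum()) if len(rows) else 0,
            "n_equal": int((rows["sites_promoter"] == rows["sites_enhancer"]).sum()) if len(rows) else 0,
        },
        name=target,
    )
    return rows, summary
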