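"""Annotation of significant pairs against directed regulatory databases.

A significant undirected pair {a, b} becomes a directed edge a -> b in the
annotated network when the database holds a TF -> target record (a, b), and
b -> a when it holds (b, a); both may fire for a TF-TF pair. Edge sign is
copied from the differential edge-weight contrast (+1: higher in case). The
databases come in two region classes: promoter (binding sites within -1000
to +100 bp of the target's transcription start site) and enhancer (sites
outside that window, linked through enhancer elements).

Target-role (glycolysis) genes are never TFs, so they have only incoming
edges; a network whose annotated target set is too small (fewer than
``min_targets`` glycolysis genes) is excluded from centrality analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from glyconet.errors import ConsistencyError, FormatError

logger = logging.getLogger(__name__)

REGION_CLASSES = ("promoter", "enhancer")


@dataclass
class RegulatoryDB:
    """Directed TF -> target records with binding-site counts."""

    records: pd.DataFrame  # columns: tf, target, binding_sites, region_class
    db_name: str = ""

    def __post_init__(self):
        validate_regulatory_records(self.records)

    def lookup(self) -> dict[tuple[str, str], int]:
        """(tf, target) -> binding_sites map."""
        return {
            (r.tf, r.target): int(r.binding_sites)
            for r in self.records.itertuples(index=False)
        }


def validate_regulatory_records(df: pd.DataFrame) -> None:
    required = ["tf", "target", "binding_sites", "region_class"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"regulatory table missing columns {missing}")
    bad_class = sorted(set(df["region_class"]) - set(REGION_CLASSES))
    if bad_class:
        raise FormatError(f"unknown region_class values {bad_class}")
    selfrec = df.index[df["tf"] == df["target"]].tolist()
    if selfrec:
        raise FormatError(f"self-records (tf == target) at rows {selfrec[:10]}")
    nonpos = df.index[df["binding_sites"] < 1].tolist()
    if nonpos:
        raise FormatError(f"non-positive binding_sites at rows {nonpos[:10]}")
    if df.duplicated(subset=["tf", "target", "region_class"]).any():
        raise FormatError("duplicate (tf, target) records within one region_class")


def load_regulatory_db(path, region_class: str | None = None, db_name: str | None = None) -> RegulatoryDB:
    """Read and validate a regulatory TSV (tf, target, binding_sites[, region_class]).

    Duplicate (tf, target) rows within one region class are collapsed by
    summing their binding-site counts, with a warning.
    """
    df = pd.read_csv(path, sep="\t")
    if "region_class" not in df.columns:
        if region_class is None:
            raise FormatError(f"{path}: no region_class column and none supplied")
        df["region_class"] = region_class
    for col in ("tf", "target", "binding_sites"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    dup = df.duplicated(subset=["tf", "target", "region_class"], keep=False)
    if dup.any():
        warnings.warn(
            f"{path}: {int(dup.sum())} duplicate (tf, target) rows collapsed by summing binding_sites",
            stacklevel=2,
        )
        df = (
            df.groupby(["tf", "target", "region_class"], as_index=False)["binding_sites"]
            .sum()
        )
    df = df[["tf", "target", "binding_sites", "region_class"]].reset_index(drop=True)
    return RegulatoryDB(records=df, db_name=db_name or Path(path).stem)


@dataclass
class AnnotatedNetwork:
    """Signed, directed TF -> target network of database-supported edges."""

    graph: nx.DiGraph
    comparison: str = ""
    db_name: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def tf_nodes(self) -> list[str]:
        return [n for n, r in self.graph.nodes(data="role") if r == "TF"]

    @property
    def target_nodes(self) -> list[str]:
        return [n for n, r in self.graph.nodes(data="role") if r == "target"]


def annotate_network(
    sig_pairs: pd.DataFrame,
    db: RegulatoryDB,
    roles: pd.DataFrame,
    comparison: str = "",
) -> AnnotatedNetwork:
    """Intersect signed significant pairs with a directed regulatory DB.

    ``sig_pairs`` needs columns gene_a, gene_b, sign (and optionally logFC,
    adj_p, carried onto edges). Nodes are restricted to those incident to at
    least one kept edge. Unmatched significant pairs are dropped silently
    (their count is logged and stored in ``meta``).
    """
    role_of = dict(zip(roles["gene_id"], roles["role"]))
    for col in ("gene_a", "gene_b", "sign"):
        if col not in sig_pairs.columns:
            raise FormatError(f"sig_pairs missing column {col!r}")
    unknown = {g for g in pd.concat([sig_pairs["gene_a"], sig_pairs["gene_b"]]) if g not in role_of}
    if unknown:
        raise ConsistencyError(f"genes without a role: {sorted(unknown)[:5]}")

    lut = db.lookup()
    g = nx.DiGraph()
    matched = 0
    for row in sig_pairs.itertuples(index=False):
        a, b = row.gene_a, row.gene_b
        hit = False
        for tf, target in ((a, b), (b, a)):
            if (tf, target) not in lut:
                continue
            if role_of[tf] != "TF":
                raise ConsistencyError(
                    f"database records non-TF gene {tf!r} as a regulator"
                )
            attrs = {"sign": int(row.sign), "binding_sites": lut[(tf, target)]}
            if hasattr(row, "logFC"):
                attrs["logFC"] = float(row.logFC)
            if hasattr(row, "adj_p"):
                attrs["adj_p"] = float(row.adj_p)
            g.add_edge(tf, target, **attrs)
            hit = True
        matched += hit
    for n in g.nodes:
        g.nodes[n]["role"] = role_of[n]
    dropped = len(sig_pairs) - matched
    logger.info(
        "annotation (%s): %d/%d significant pairs matched, %d edges",
        db.db_name, matched, len(sig_pairs), g.number_of_edges(),
    )
    return AnnotatedNetwork(
        graph=g,
        comparison=comparison,
        db_name=db.db_name,
        meta={"n_sig_pairs": len(sig_pairs), "n_matched": matched, "n_dropped": dropped},
    )


def passes_target_filter(net: AnnotatedNetwork, min_targets: int = 20) -> bool:
    """True when the network retains at least ``min_targets`` target-role genes."""
    return len(net.target_nodes) >= min_targets


def write_sif(net: AnnotatedNetwork, path) -> None:
    """Simple interaction format: tf <tab> sign (+/-) <tab> target."""
    with open(path, "w") as fh:
        for tf, target, sign in net.graph.edges(data="sign"):
            fh.write(f"{tf}\t{'+' if sign > 0 else '-'}\t{target}\n")


def write_graphml(net: AnnotatedNetwork, path) -> None:
    nx.write_graphml(net.graph, path)


def write_edge_list(net: AnnotatedNetwork, path) -> None:
    rows = [
        {"tf": tf, "target": target, "sign": data.get("sign"),
         "binding_sites": data.get("binding_sites"), "logFC": data.get("logFC"),
         "adj_p": data.get("adj_p")}
        for tf, target, data in net.graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["tf", "target", "sign", "binding_sites", "logFC", "adj_p"]).to_csv(
        path, sep="\t", index=False
    )
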