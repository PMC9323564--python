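"""End-to-end orchestration of one two-group comparison.

Stage order: differential expression -> count transform -> LIONESS edge
weights over the TF + glycolysis gene list (pooled samples of the two
compared groups only) -> moderated-t differential edge weights -> promoter
database annotation -> minimum-target filter -> centralities and top-ten
selection -> optional enhancer database annotation and promoter/enhancer
comparison. Every stage logs counts in and out; results and a manifest are
written under the configured output directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from glyconet._version import __version__
from glyconet._io import read_counts, read_roles, read_sample_sheet
from glyconet.annotation import (
    annotate_network,
    load_regulatory_db,
    passes_target_filter,
    write_edge_list,
    write_graphml,
    write_sif,
)
from glyconet.centrality import centrality_table, select_central_genes
from glyconet.dbcompare import compare_binding_sites, compare_in_degrees
from glyconet.diffedges import ebayes_moderation, fit_edge_contrasts, significant_edges
from glyconet.errors import InvalidDesignError, StageError
from glyconet.expression import differential_expression, size_factors, transform_counts
from glyconet.lioness import lioness_edge_weights
from glyconet.simulate import CountMatrix

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, comparison labels, thresholds and flags for one run."""

    counts: str
    sample_sheet: str
    roles: str
    promoter_db: str
    out_dir: str
    enhancer_db: str | None = None
    case: str = "case"
    reference: str = "reference"
    de_fdr: float = 0.1
    de_fc: float = 1.5
    edge_fdr: float = 0.1
    min_targets: int = 20
    top_k: int = 10
    transform: str = "log2norm"
    seed: int = 0
    write_edge_matrix: bool = False
    write_graphml_files: bool = False

    def __post_init__(self):
        if self.case == self.reference:
            raise InvalidDesignError("case and reference labels must differ")
        for name in ("de_fdr", "edge_fdr"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise InvalidDesignError(f"{name} must lie in (0, 1]")
        if self.de_fc < 1:
            raise InvalidDesignError("de_fc must be >= 1")
        if self.top_k < 1:
            raise InvalidDesignError("top_k must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload)


def _stage(name: str, manifest: dict):
    """Context wrapper recording stage status in the manifest."""

    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is None:
                manifest["stages"][name] = "OK"
                return False
            manifest["stages"][name] = "FAILED"
            if not isinstance(exc, StageError):
                raise StageError(name, str(exc)) from exc
            return False

    return _Ctx()


def run_comparison(config: PipelineConfig) -> dict:
    """Run the full pipeline for one comparison; returns the result bundle.

    The bundle maps stage names to in-memory results; all tables are also
    written as TSV under ``config.out_dir`` together with ``manifest.json``.
    When the promoter-annotated network keeps fewer than ``min_targets``
    glycolysis genes, the centrality/selection stage is recorded as SKIPPED.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    logging.getLogger("glyconet").addHandler(fh)

    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "stages": {},
        "comparison": f"{config.case}_vs_{config.reference}",
    }
    bundle: dict = {"manifest": manifest}
    try:
        with _stage("load", manifest):
            counts_df = read_counts(config.counts)
            groups = read_sample_sheet(config.sample_sheet)
            roles = read_roles(config.roles)
            keep = [s for s in counts_df.columns if groups.get(s) in (config.case, config.reference)]
            if not keep:
                raise InvalidDesignError(
                    f"no samples labelled {config.case!r} or {config.reference!r}"
                )
            counts = CountMatrix(counts=counts_df[keep], groups=groups[keep])
            n_case = int((counts.groups == config.case).sum())
            n_ref = int((counts.groups == config.reference).sum())
            manifest["n_case"] = n_case
            manifest["n_ref"] = n_ref
            logger.info("loaded %d genes, %d + %d samples", len(counts_df), n_case, n_ref)

        with _stage("differential_expression", manifest):
            de = differential_expression(
                counts, case=config.case, reference=config.reference,
                fdr=config.de_fdr, fc_min=config.de_fc,
            )
            de.to_csv(out / "de_table.tsv", sep="\t", index_label="gene")
            bundle["de_table"] = de

        with _stage("transform", manifest):
            expr = transform_counts(counts, size_factors(counts), mode=config.transform)

        with _stage("lioness", manifest):
            gene_list = [g for g in roles["gene_id"] if g in expr.index]
            ewm = lioness_edge_weights(expr, gene_subset=gene_list)
            ewm.meta["sample_set"] = "pooled_two_groups"
            bundle["edge_weights"] = ewm
            if config.write_edge_matrix:
                ewm.to_frame().to_csv(out / "edge_weights.tsv", sep="\t")

        with _stage("differential_edges", manifest):
            contrasts = fit_edge_contrasts(
                ewm, counts.groups, case=config.case, reference=config.reference
            )
            diff = ebayes_moderation(contrasts)
            sig = significant_edges(diff, fdr=config.edge_fdr)
            manifest["n_edge_tests"] = int(diff.attrs["n_tests"])
            manifest["n_significant_edges"] = int(len(sig))
            manifest["ebayes_d0"] = float(diff.attrs["d0"])
            manifest["ebayes_s0_sq"] = float(diff.attrs["s0_sq"])
            diff_out = diff[["gene_a", "gene_b", "logFC", "t_mod", "p", "adj_p"]]
            diff_out.to_csv(out / "diff_edges.tsv", sep="\t", index=False)
            sig.to_csv(out / "significant_edges.tsv", sep="\t", index=False)
            bundle["diff_edges"] = diff
            bundle["significant_edges"] = sig
            logger.info("%d/%d pairs significant at FDR %.3g",
                        len(sig), len(diff), config.edge_fdr)

        with _stage("annotate_promoter", manifest):
            db_p = load_regulatory_db(config.promoter_db, region_class="promoter")
            net_p = annotate_network(sig, db_p, roles, comparison=manifest["comparison"])
            manifest["promoter_network"] = {
                "nodes": net_p.graph.number_of_nodes(),
                "tfs": len(net_p.tf_nodes),
                "targets": len(net_p.target_nodes),
                "edges": net_p.graph.number_of_edges(),
            }
            write_sif(net_p, out / "network_promoter.sif")
            write_edge_list(net_p, out / "network_promoter_edges.tsv")
            if config.write_graphml_files:
                write_graphml(net_p, out / "network_promoter.graphml")
            bundle["network_promoter"] = net_p

        if passes_target_filter(net_p, min_targets=config.min_targets):
            with _stage("centrality", manifest):
                table = centrality_table(net_p)
                selection = select_central_genes(table, k=config.top_k)
                table.to_csv(out / "centrality.tsv", sep="\t", index_label="node")
                (out / "selection.json").write_text(json.dumps(
                    {
                        "central_tfs": sorted(selection.central_tfs),
                        "central_targets": sorted(selection.central_targets),
                        "top_lists": selection.top_lists,
                    },
                    indent=1,
                ))
                bundle["centrality"] = table
                bundle["selection"] = selection
        else:
            manifest["stages"]["centrality"] = "SKIPPED"
            logger.info(
                "centrality SKIPPED: %d target genes < min_targets=%d",
                len(net_p.target_nodes), config.min_targets,
            )

        if config.enhancer_db:
            with _stage("annotate_enhancer", manifest):
                db_e = load_regulatory_db(config.enhancer_db, region_class="enhancer")
                net_e = annotate_network(sig, db_e, roles, comparison=manifest["comparison"])
                manifest["enhancer_network"] = {
                    "nodes": net_e.graph.number_of_nodes(),
                    "edges": net_e.graph.number_of_edges(),
                }
                write_sif(net_e, out / "network_enhancer.sif")
                write_edge_list(net_e, out / "network_enhancer_edges.tsv")
                if config.write_graphml_files:
                    write_graphml(net_e, out / "network_enhancer.graphml")
                bundle["network_enhancer"] = net_e

            with _stage("db_comparison", manifest):
                indeg = compare_in_degrees(net_p, net_e, de_table=de)
                indeg.to_csv(out / "indegree_comparison.tsv", sep="\t", index=False)
                bundle["indegree_comparison"] = indeg
                summaries = []
                for gene in indeg["gene"]:
                    _, summary = compare_binding_sites(db_p, db_e, gene)
                    summaries.append(summary)
                if summaries:
                    bs = pd.DataFrame(summaries)
                    bs.index.name = "gene"
                    bs.to_csv(out / "binding_site_summary.tsv", sep="\t")
                    bundle["binding_site_summary"] = bs

        manifest["status"] = "OK"
    except StageError:
        manifest["status"] = "FAILED"
        (out / "FAILED").write_text(json.dumps(manifest["stages"], indent=1))
        raise
    finally:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        logging.getLogger("glyconet").removeHandler(fh)
        fh.close()
    return bundle
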