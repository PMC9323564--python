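"""Shared fixtures: planted simulation designs and on-disk fixture bundles."""

from __future__ import annotations

import itertools

import pandas as pd
import pytest

from glyconet import (
    SimDesign,
    generate_gene_roles,
    simulate_counts,
    simulate_regulatory_db,
)
from glyconet._io import (
    write_counts,
    write_roles,
    write_sample_sheet,
)
from glyconet.simulate import tf_names, target_names

HUB_TF = "TF0001"


def hub_block_plan(n_block_targets: int = 9, n_disjoint: int = 5, r_case: float = 0.9, r_ref: float = 0.0):
    """Planted correlation plan: one equicorrelated hub block plus disjoint pairs.

    The hub TF and ``n_block_targets`` targets form an equicorrelated block
    (positive semidefinite at any size), giving C(n_block_targets+1, 2)
    differential pairs, plus ``n_disjoint`` disjoint TF-target pairs.
    """
    tfs, tgs = tf_names(20), target_names(80)
    block = [tfs[0]] + tgs[:n_block_targets]
    plan = [(a, b, r_case, r_ref) for a, b in itertools.combinations(block, 2)]
    plan += [(tfs[1 + k], tgs[n_block_targets + k], r_case, r_ref) for k in range(n_disjoint)]
    return plan


def recovery_design(n_per_group: int, seed: int = 1) -> SimDesign:
    """100-gene design with 50 planted differential pairs and one hub TF."""
    return SimDesign(
        n_tf=20,
        n_target=80,
        n_case=n_per_group,
        n_ref=n_per_group,
        coexpr_plan=hub_block_plan(),
        db_coverage=1.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def powered_simulation():
    """Simulated experiment at a sample size where edge recovery has power."""
    design = recovery_design(n_per_group=60, seed=1)
    cm, truth = simulate_counts(design)
    roles = generate_gene_roles(design.n_tf, design.n_target)
    db_p = simulate_regulatory_db(roles, truth, 1.0, region_class="promoter", seed=2)
    db_e = simulate_regulatory_db(roles, truth, 1.0, extra_edges=10, region_class="enhancer", seed=3)
    return {
        "design": design,
        "counts": cm,
        "truth": truth,
        "roles": roles,
        "db_promoter": db_p,
        "db_enhancer": db_e,
    }


def write_bundle(outdir, sim: dict) -> dict:
    """Write a simulation dict as the pipeline's on-disk input bundle."""
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "sample_sheet": outdir / "samples.tsv",
        "roles": outdir / "roles.tsv",
        "promoter_db": outdir / "regulatory_promoter.tsv",
        "enhancer_db": outdir / "regulatory_enhancer.tsv",
    }
    write_counts(paths["counts"], sim["counts"].counts)
    write_sample_sheet(paths["sample_sheet"], sim["counts"].groups)
    write_roles(paths["roles"], sim["roles"])
    sim["db_promoter"].to_csv(paths["promoter_db"], sep="\t", index=False)
    sim["db_enhancer"].to_csv(paths["enhancer_db"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}


@pytest.fixture(scope="session")
def wide_block_sim(tmp_path_factory):
    """Dense fixture whose network can retain up to 30 target genes.

    One hub TF equicorrelated with 25 targets (plus 5 disjoint pairs) at a
    sample size where essentially every planted pair is detected, so the
    number of target genes entering the annotated network is controlled by
    the regulatory table alone.
    """
    tfs, tgs = tf_names(20), target_names(80)
    block = [tfs[0]] + tgs[:25]
    plan = [(a, b, 0.9, 0.0) for a, b in itertools.combinations(block, 2)]
    plan += [(tfs[1 + k], tgs[25 + k], 0.9, 0.0) for k in range(5)]
    design = SimDesign(
        n_tf=20, n_target=80, n_case=80, n_ref=80, coexpr_plan=plan,
        db_coverage=1.0, seed=7,
    )
    cm, truth = simulate_counts(design)
    roles = generate_gene_roles(20, 80)
    base = tmp_path_factory.mktemp("widesim")
    dummy_db = pd.DataFrame(
        {"tf": [tfs[0]], "target": [tgs[0]], "binding_sites": [1],
         "region_class": ["promoter"]}
    )
    paths = write_bundle(
        base,
        {"counts": cm, "roles": roles, "db_promoter": dummy_db, "db_enhancer": dummy_db},
    )
    return {"base": base, "paths": paths, "tfs": tfs, "tgs": tgs}


@pytest.fixture(scope="session")
def pipeline_bundle(tmp_path_factory, powered_simulation):
    """Full pipeline run on the powered fixture (shared across tests)."""
    from glyconet import PipelineConfig, run_comparison

    base = tmp_path_factory.mktemp("bundle")
    paths = write_bundle(base / "inputs", powered_simulation)
    config = PipelineConfig(
        counts=paths["counts"],
        sample_sheet=paths["sample_sheet"],
        roles=paths["roles"],
        promoter_db=paths["promoter_db"],
        enhancer_db=paths["enhancer_db"],
        out_dir=str(base / "out"),
        min_targets=5,
    )
    bundle = run_comparison(config)
    return {"config": config, "bundle": bundle, "sim": powered_simulation}
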