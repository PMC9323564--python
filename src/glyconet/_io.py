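"""Plain-text readers/writers for the pipeline's tabular formats.

All tables are tab-separated. Counts are genes x samples with a header row of
sample identifiers and the gene identifier in the first column.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from glyconet.errors import FormatError


def write_counts(path, counts: pd.DataFrame) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicate gene identifiers")
    return df


def write_sample_sheet(path, groups: pd.Series) -> None:
    pd.DataFrame({"sample_id": groups.index, "group": groups.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


def read_sample_sheet(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample identifiers")
    return pd.Series(df["group"].to_numpy(), index=df["sample_id"], name="group")


def write_roles(path, roles: pd.DataFrame) -> None:
    roles.to_csv(path, sep="\t", index=False)


def read_roles(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "role"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    bad = sorted(set(df["role"]) - {"TF", "target"})
    if bad:
        raise FormatError(f"{path}: unknown roles {bad}")
    return df


def write_truth(path, truth) -> None:
    payload = {
        "de_genes": truth.de_genes,
        "diff_pairs": sorted(list(p) for p in truth.diff_pairs),
        "hub_tfs": sorted(truth.hub_tfs),
        "db_edges": truth.db_edges,
    }
    Path(path).write_text(json.dumps(payload, indent=1, default=int))


def read_truth(path):
    from glyconet.simulate import SimTruth

    payload = json.loads(Path(path).read_text())
    return SimTruth(
        de_genes=payload["de_genes"],
        diff_pairs={tuple(p) for p in payload["diff_pairs"]},
        hub_tfs=set(payload["hub_tfs"]),
        db_edges=payload["db_edges"],
    )
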