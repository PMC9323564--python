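"""Count normalization, expression transforms, and differential expression.

Normalization follows the median-of-ratios convention: each sample's size
factor is the median, over genes expressed in every sample, of that sample's
count divided by the gene's geometric mean across samples; factors are then
rescaled to geometric mean 1.

The differential expression caller is a simplified per-gene negative-binomial
Wald test (method-of-moments dispersion, delta-method standard error on the
log2 mean ratio, Benjamini-Hochberg correction). It feeds only the up/down
node labels and threshold filters downstream; it does not attempt to
reproduce a full shrinkage-based DE framework.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from glyconet.errors import InvalidDesignError, NormalizationError
from glyconet.simulate import CountMatrix

logger = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-8


def size_factors(counts: pd.DataFrame | CountMatrix) -> pd.Series:
    """Median-of-ratios size factor per sample, rescaled to geometric mean 1.

    Raises
    ------
    NormalizationError
        If no gene has positive counts in every sample.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    x = df.to_numpy(dtype=float)
    expressed = (x > 0).all(axis=1)
    if not expressed.any():
        raise NormalizationError("no gene has positive counts in all samples")
    logx = np.log(x[expressed])
    log_gm = logx.mean(axis=1, keepdims=True)
    # median taken on the ratio scale (matters when the gene count is even)
    factors = np.median(np.exp(logx - log_gm), axis=0)
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=df.columns, name="size_factor")


@np.errstate(divide="ignore")
def transform_counts(
    counts: pd.DataFrame | CountMatrix,
    factors: pd.Series,
    mode: str = "log2norm",
) -> pd.DataFrame:
    """Transform counts for co-expression analysis.

    ``log2norm`` is ``log2(count / factor + 1)``. ``shrunken`` additionally
    shrinks each gene's values toward its cross-sample mean with weight
    ``w = s2 / (s2 + s2_0)`` on the deviation, where ``s2`` is the gene's
    variance and ``s2_0`` the median gene variance — a monotone,
    variance-stabilizing surrogate for regularized-log transforms: genes
    with little genuine variation are flattened, variable genes pass
    through almost unchanged.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    if mode not in ("log2norm", "shrunken"):
        raise ValueError(f"unknown transform mode {mode!r}")
    values = np.log2(df.to_numpy(dtype=float) / factors.reindex(df.columns).to_numpy() + 1.0)
    if mode == "shrunken":
        gene_mean = values.mean(axis=1, keepdims=True)
        s2 = values.var(axis=1, ddof=1, keepdims=True)
        s2_0 = np.median(s2)
        w = np.divide(s2, s2 + s2_0, out=np.zeros_like(s2), where=(s2 + s2_0) > 0)
        values = gene_mean + w * (values - gene_mean)
    out = pd.DataFrame(values, index=df.index, columns=df.columns)
    out.attrs["transform_tag"] = mode
    return out


def linear_fold_change(log2fc: float) -> float:
    """Linear fold change 2**log2fc."""
    return float(2.0 ** np.asarray(log2fc, dtype=float))


def differential_expression(
    counts: CountMatrix,
    case: str = "case",
    reference: str = "reference",
    fdr: float = 0.1,
    fc_min: float = 1.5,
) -> pd.DataFrame:
    """Per-gene NB Wald test of case vs reference group means.

    Returns a table indexed by gene with columns ``log2fc``, ``linear_fc``,
    ``p``, ``adj_p``, ``mean_case``, ``mean_ref`` and ``status`` in
    {up, down, ns, untested}. A gene is ``up`` when ``adj_p <= fdr`` and its
    linear fold change is at least ``fc_min``; ``down`` symmetrically.
    All-zero genes are reported untested and excluded from the BH
    denominator. When exactly one group mean is zero, 0.5 is added to both
    group means for the ratio and its standard error, keeping the fold
    change finite.
    """
    groups = counts.groups
    case_cols = [s for s in counts.counts.columns if groups[s] == case]
    ref_cols = [s for s in counts.counts.columns if groups[s] == reference]
    if len(case_cols) < 2 or len(ref_cols) < 2:
        raise InvalidDesignError("each group needs at least 2 samples")

    factors = size_factors(counts)
    q = counts.counts.to_numpy(dtype=float) / factors.to_numpy()
    idx_case = [counts.counts.columns.get_loc(s) for s in case_cols]
    idx_ref = [counts.counts.columns.get_loc(s) for s in ref_cols]
    qc, qr = q[:, idx_case], q[:, idx_ref]
    n1, n2 = qc.shape[1], qr.shape[1]

    m1, m2 = qc.mean(axis=1), qr.mean(axis=1)
    tested = (m1 > 0) | (m2 > 0)

    # pooled within-group method-of-moments dispersion
    s2 = ((n1 - 1) * qc.var(axis=1, ddof=1) + (n2 - 1) * qr.var(axis=1, ddof=1)) / (n1 + n2 - 2)
    mbar = q[:, idx_case + idx_ref].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(mbar > 0, (s2 - mbar) / np.square(mbar), 0.0)
    phi = np.clip(phi, DISPERSION_FLOOR, None)

    a1, a2 = m1.copy(), m2.copy()
    one_zero = tested & ((m1 == 0) | (m2 == 0))
    a1[one_zero] += 0.5
    a2[one_zero] += 0.5

    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(a1 / a2)
        var1 = (a1 + phi * a1**2) / n1
        var2 = (a2 + phi * a2**2) / n2
        se = np.sqrt(var1 / a1**2 + var2 / a2**2) / math.log(2.0)
        z = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))

    adj_p = np.full(p.shape, np.nan)
    if tested.any():
        adj_p[tested] = multipletests(p[tested], method="fdr_bh")[1]

    lfc_cut = math.log2(fc_min)
    status = np.where(
        ~tested,
        "untested",
        np.where(
            (adj_p <= fdr) & (log2fc >= lfc_cut),
            "up",
            np.where((adj_p <= fdr) & (log2fc <= -lfc_cut), "down", "ns"),
        ),
    )

    table = pd.DataFrame(
        {
            "log2fc": np.where(tested, log2fc, 0.0),
            "linear_fc": np.where(tested, 2.0**log2fc, 1.0),
            "p": np.where(tested, p, np.nan),
            "adj_p": adj_p,
            "mean_case": m1,
            "mean_ref": m2,
            "status": status,
        },
        index=counts.counts.index,
    )
    table.attrs["fdr"] = fdr
    table.attrs["fc_min"] = fc_min
    table.attrs["n_tested"] = int(tested.sum())
    logger.info(
        "differential expression: %d tested, %d up, %d down",
        table.attrs["n_tested"],
        int((status == "up").sum()),
        int((status == "down").sum()),
    )
    return table
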