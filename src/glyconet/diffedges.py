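"""Group-wise differential testing of LIONESS edge weights.

Each gene pair's per-sample edge weights are fit with a two-group linear
model (closed form: group-mean difference and pooled residual variance), and
the per-pair variances are moderated with an empirical-Bayes prior: the s2
are modelled as scaled F draws around a prior variance s0_sq with d0 prior
degrees of freedom, estimated by moment-matching of log(s2) through
digamma/trigamma inversion. The moderated statistic

    t_mod = logFC / sqrt(s2_post * (1/n_case + 1/n_ref)),
    s2_post = (d0 * s0_sq + d * s2) / (d0 + d)

is referred to a t distribution with d + d0 degrees of freedom (standard
normal when d0 is infinite, which happens when the observed variances are
underdispersed relative to chi-square sampling noise).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from glyconet.errors import InvalidDesignError
from glyconet.lioness import EdgeWeightMatrix

logger = logging.getLogger(__name__)


def fit_edge_contrasts(
    ewm: EdgeWeightMatrix,
    groups: pd.Series,
    case: str = "case",
    reference: str = "reference",
) -> pd.DataFrame:
    """Per-pair two-group linear model on edge weights.

    Returns a table with ``logFC`` (mean case - mean reference), ``s2``
    (pooled residual variance) and ``d`` (residual degrees of freedom,
    N - 2), plus the group sizes in ``attrs``.
    """
    labels = np.asarray([groups[s] for s in ewm.sample_ids])
    idx_case = np.flatnonzero(labels == case)
    idx_ref = np.flatnonzero(labels == reference)
    if len(idx_case) < 2 or len(idx_ref) < 2:
        raise InvalidDesignError("each group needs at least 2 samples")
    wc = ewm.weights[:, idx_case]
    wr = ewm.weights[:, idx_ref]
    n1, n2 = wc.shape[1], wr.shape[1]
    logfc = wc.mean(axis=1) - wr.mean(axis=1)
    rss = wc.var(axis=1, ddof=0).astype(float) * n1 + wr.var(axis=1, ddof=0) * n2
    d = n1 + n2 - 2
    s2 = rss / d
    out = pd.DataFrame(
        {"gene_a": [p[0] for p in ewm.pairs], "gene_b": [p[1] for p in ewm.pairs],
         "logFC": logfc, "s2": s2},
    )
    out.attrs.update({"d": d, "n_case": n1, "n_ref": n2})
    return out


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma inverse needs a positive argument")
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_variance_prior(s2: np.ndarray, d: int) -> tuple[float, float]:
    """Moment-match log(s2) to a scaled log-F law; returns (d0, s0_sq).

    ``d0 = inf`` signals that the variances are consistent with a single
    common value (moderation collapses every s2_post to s0_sq).
    """
    s2 = np.asarray(s2, dtype=float)
    if (s2 < 0).any():
        raise ValueError("variances must be nonnegative")
    if d < 1:
        raise ValueError("residual degrees of freedom must be >= 1")
    pos = s2[s2 > 0]
    if len(pos) < 2:
        return math.inf, float(pos.mean()) if len(pos) else 0.0
    if np.ptp(pos) == 0.0:
        # exactly one shared variance: no dispersion to model, t reduces to z
        return math.inf, float(pos[0])
    e = np.log(pos) - special.digamma(d / 2.0) + math.log(d / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1))
    excess = evar - float(special.polygamma(1, d / 2.0))
    if excess <= 0:
        return math.inf, float(math.exp(emean))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = math.exp(emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    return d0, s0_sq


def ebayes_moderation(
    contrasts: pd.DataFrame,
    d: int | None = None,
    n_case: int | None = None,
    n_ref: int | None = None,
) -> pd.DataFrame:
    """Moderated t-statistics and BH-adjusted p-values for every pair.

    ``contrasts`` is the output of :func:`fit_edge_contrasts`; the degrees of
    freedom and group sizes default to its metadata. Returns the table with
    ``s2_post``, ``t_mod``, ``p`` and ``adj_p`` columns added and the prior
    (``d0``, ``s0_sq``) plus the BH denominator in ``attrs``.
    """
    d = d if d is not None else contrasts.attrs["d"]
    n1 = n_case if n_case is not None else contrasts.attrs["n_case"]
    n2 = n_ref if n_ref is not None else contrasts.attrs["n_ref"]
    s2 = contrasts["s2"].to_numpy(dtype=float)
    logfc = contrasts["logFC"].to_numpy(dtype=float)

    d0, s0_sq = estimate_variance_prior(s2, d)
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)

    unit = 1.0 / n1 + 1.0 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(s2_post > 0, logfc / np.sqrt(s2_post * unit), 0.0)
    if math.isinf(d0):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df=d + d0)
    adj_p = multipletests(p, method="fdr_bh")[1]

    out = contrasts.copy()
    out["s2_post"] = s2_post
    out["t_mod"] = t_mod
    out["p"] = p
    out["adj_p"] = adj_p
    out.attrs.update(
        {"d0": d0, "s0_sq": s0_sq, "d": d, "n_case": n1, "n_ref": n2, "n_tests": len(out)}
    )
    logger.info(
        "eBayes moderation: d0=%.3g s0_sq=%.3g over %d pairs", d0, s0_sq, len(out)
    )
    return out


def significant_edges(table: pd.DataFrame, fdr: float = 0.1) -> pd.DataFrame:
    """Pairs with adj_p <= fdr, each carrying the sign of its logFC.

    sign +1 means a higher edge weight in the case group, -1 in the
    reference group.
    """
    sig = table[table["adj_p"] <= fdr].copy()
    sig["sign"] = np.sign(sig["logFC"]).astype(int)
    return sig
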