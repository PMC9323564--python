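"""Aggregate and single-sample (LIONESS) co-expression edge weights.

For each gene pair, the aggregate network statistic is the Pearson
correlation across all N samples, e_alpha. Leaving out sample q gives
e_alpha_minus_q, and the LIONESS edge weight attributed to sample q is the
linear interpolation

    e_q = N * (e_alpha - e_alpha_minus_q) + e_alpha_minus_q,

an estimate of sample q's contribution to the aggregate co-expression.
Although both correlations are bounded by 1, e_q itself is unbounded; no
clipping is applied.

Correlations are computed by N+1 full correlation-matrix evaluations (one
aggregate, one per left-out sample) rather than rank-one updates: at this
scale (~1e3 genes, tens of samples) the direct form is exact and clear.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from glyconet.errors import InsufficientSamplesError

logger = logging.getLogger(__name__)


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Unordered gene pair stored in lexicographic order."""
    if a == b:
        raise ValueError(f"self-pair {a!r}")
    return (a, b) if a <= b else (b, a)


def _pearson_matrix(x: np.ndarray) -> np.ndarray:
    """Pearson correlation between rows, with constant rows mapped to r = 0."""
    sd = x.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant gene(s); their correlations are set to 0",
            stacklevel=3,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.corrcoef(x)
    r[constant, :] = 0.0
    r[:, constant] = 0.0
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def _subset(expr: pd.DataFrame, gene_subset) -> pd.DataFrame:
    if gene_subset is None:
        return expr
    missing = [g for g in gene_subset if g not in expr.index]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing[:5]}")
    return expr.loc[list(gene_subset)]


@dataclass
class EdgeWeightMatrix:
    """LIONESS edge weights for every canonical gene pair and sample.

    Attributes
    ----------
    pairs : list of (gene_a, gene_b)
        Canonical (lexicographically ordered) pairs.
    sample_ids : list of str
    weights : ndarray, pairs x samples
        Single-sample edge weights e_q.
    aggregate : ndarray, pairs
        All-sample Pearson correlation e_alpha.
    loo : ndarray, pairs x samples
        Leave-one-out correlations e_alpha_minus_q.
    n_samples : int
    """

    pairs: list[tuple[str, str]]
    sample_ids: list[str]
    weights: np.ndarray
    aggregate: np.ndarray
    loo: np.ndarray
    n_samples: int
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        idx = pd.Index([f"{a}|{b}" for a, b in self.pairs], name="pair_id")
        return pd.DataFrame(self.weights, index=idx, columns=self.sample_ids)


def aggregate_network(expr: pd.DataFrame, gene_subset=None) -> pd.Series:
    """All-sample Pearson correlation e_alpha for each canonical pair.

    Genes are rows, samples columns. Requires at least 3 samples. Constant
    genes correlate 0 with everything (warning emitted); such pairs can
    never reach significance downstream.
    """
    sub = _subset(expr, gene_subset)
    if sub.shape[1] < 3:
        raise InsufficientSamplesError("aggregate correlation needs >= 3 samples")
    genes = list(sub.index)
    r = _pearson_matrix(sub.to_numpy(dtype=float))
    iu, ju = np.triu_indices(len(genes), k=1)
    pairs = [canonical_pair(genes[i], genes[j]) for i, j in zip(iu, ju)]
    return pd.Series(r[iu, ju], index=pd.MultiIndex.from_tuples(pairs, names=["gene_a", "gene_b"]))


def lioness_edge_weights(expr: pd.DataFrame, gene_subset=None) -> EdgeWeightMatrix:
    """Single-sample edge weights for all canonical pairs.

    The defining identity ``e_q = N (e_alpha - e_loo) + e_loo`` holds exactly
    for every stored entry. Requires N >= 4 so each leave-one-out
    correlation uses at least 3 samples.
    """
    sub = _subset(expr, gene_subset)
    n = sub.shape[1]
    if n < 4:
        raise InsufficientSamplesError("LIONESS needs >= 4 samples (leave-one-out >= 3)")
    genes = list(sub.index)
    x = sub.to_numpy(dtype=float)
    iu, ju = np.triu_indices(len(genes), k=1)
    pairs = [canonical_pair(genes[i], genes[j]) for i, j in zip(iu, ju)]

    agg = _pearson_matrix(x)[iu, ju]
    loo = np.empty((len(pairs), n))
    for q in range(n):
        r = _pearson_matrix(np.delete(x, q, axis=1))
        loo[:, q] = r[iu, ju]
    weights = n * (agg[:, None] - loo) + loo
    logger.info("LIONESS: %d pairs x %d samples", len(pairs), n)
    return EdgeWeightMatrix(
        pairs=pairs,
        sample_ids=list(sub.columns),
        weights=weights,
        aggregate=agg,
        loo=loo,
        n_samples=n,
    )
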