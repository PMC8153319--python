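"""geNorm: expression-stability M values and the pairwise-variation rule.

For genes j and k the pairwise variation V_jk is the standard deviation
over samples of log2(q_j/q_k); a gene's M value is its mean V against all
other candidates.  Ranking proceeds by iterated exclusion of the
highest-M gene until two remain, which are tied at rank 1 (their relative
order is undefined because V is symmetric).  The optimal number of
reference genes follows from V_{n/n+1}, the SD of log-ratios between
normalization factors built from the top n and top n+1 genes: the
smallest n with V_{n/n+1} below the threshold (0.15 by convention)
suffices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .transform import QuantityMatrix

__all__ = [
    "GeNormResult",
    "pairwise_variation",
    "pairwise_variation_matrix",
    "m_values",
    "m_values_from_pairwise",
    "rank_genes",
    "normalization_factor",
    "optimal_gene_count",
    "genorm",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeNormResult:
    """geNorm ranking plus the pairwise-variation series.

    ``ranking`` lists genes from most to least stable (the first two are
    tied).  ``rank_of`` is a dense rank: the surviving pair both get 1,
    then 2, 3, ... in exclusion order.  ``m_trajectory`` holds, per
    exclusion step, the M values of the genes still in play.  ``v_series``
    maps n to V_{n/n+1}; ``optimal_n`` is the recommended gene count and
    ``threshold_met`` records whether any V fell below the threshold.
    """

    ranking: list[str]
    rank_of: dict[str, int]
    m_trajectory: list[pd.Series] = field(default_factory=list)
    v_series: pd.Series | None = None
    optimal_n: int | None = None
    threshold_met: bool = True


def _log2q(q) -> pd.DataFrame:
    if isinstance(q, QuantityMatrix):
        return q.log2()
    return np.log2(pd.DataFrame(q).astype(float))


def pairwise_variation(q, gene_j: str, gene_k: str) -> float:
    """SD (n-1) over samples of log2(q_j / q_k)."""
    if gene_j == gene_k:
        raise ValueError("pairwise variation needs two distinct genes")
    x = _log2q(q)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    return float((x.loc[gene_j] - x.loc[gene_k]).std(ddof=1))


def pairwise_variation_matrix(q) -> pd.DataFrame:
    """Symmetric gene x gene matrix of pairwise variations V_jk."""
    x = _log2q(q)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    a = x.to_numpy()
    d = a[:, None, :] - a[None, :, :]
    v = d.std(axis=2, ddof=1)
    return pd.DataFrame(v, index=x.index, columns=x.index)


def m_values_from_pairwise(v: pd.DataFrame, genes=None) -> pd.Series:
    """M values (mean pairwise variation) from a precomputed V matrix."""
    genes = list(v.index) if genes is None else list(genes)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    sub = v.loc[genes, genes].to_numpy()
    m = sub.sum(axis=1) / (len(genes) - 1)
    return pd.Series(m, index=genes, name="M")


def m_values(q, genes=None) -> pd.Series:
    """geNorm M value per gene over the given subset (default: all genes)."""
    return m_values_from_pairwise(pairwise_variation_matrix(q), genes)


def rank_genes(q) -> GeNormResult:
    """Stability ranking by iterated exclusion of the highest-M gene.

    Ties in the maximum M are broken by removing the lexicographically
    last gene name (logged); exact ties have measure zero on real data.
    """
    v = pairwise_variation_matrix(q)
    genes = list(v.index)
    if len(genes) < 3:
        raise ValueError("need at least 3 genes to rank")
    remaining = list(genes)
    excluded: list[str] = []
    trajectory: list[pd.Series] = []
    while len(remaining) > 2:
        m = m_values_from_pairwise(v, remaining)
        trajectory.append(m)
        top = m.max()
        worst_set = sorted(m.index[m == top])
        if len(worst_set) > 1:
            logger.warning("tie in max M among %s; removing %r", worst_set, worst_set[-1])
        worst = worst_set[-1]
        excluded.append(worst)
        remaining.remove(worst)
    trajectory.append(m_values_from_pairwise(v, remaining))
    ranking = sorted(remaining) + list(reversed(excluded))
    rank_of = {g: 1 for g in remaining}
    for step, g in enumerate(excluded):
        rank_of[g] = len(genes) - 1 - step
    return GeNormResult(ranking=ranking, rank_of=rank_of, m_trajectory=trajectory)


def normalization_factor(q, genes) -> pd.Series:
    """Per-sample normalization factor: geometric mean of the given genes' quantities."""
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("a normalization factor needs at least 2 genes")
    x = _log2q(q)
    nf = np.power(2.0, x.loc[genes].mean(axis=0))
    nf.name = f"NF_{len(genes)}"
    return nf


def optimal_gene_count(q, threshold: float = 0.15, ranking=None):
    """Pairwise-variation series V_{n/n+1} and the optimal gene count.

    Genes enter the normalization factor in geNorm ranking order (computed
    here unless ``ranking`` is supplied).  V_{n/n+1} is the SD over samples
    of log2(NF_n / NF_{n+1}); the optimal count is the smallest n with
    V below ``threshold``.  If no V qualifies the full panel size is
    returned with ``threshold_met`` False.

    Returns ``(v_series, optimal_n, threshold_met)``.
    """
    x = _log2q(q)
    genes = list(x.index)
    k = len(genes)
    if k < 4:
        raise ValueError("pairwise-variation analysis needs at least 4 genes")
    order = list(ranking) if ranking is not None else rank_genes(q).ranking
    vs = {}
    for n in range(2, k):
        nf_n = x.loc[order[:n]].mean(axis=0)
        nf_n1 = x.loc[order[: n + 1]].mean(axis=0)
        vs[n] = float((nf_n - nf_n1).std(ddof=1))
    v_series = pd.Series(vs, name="V_n/n+1")
    below = [n for n, v in vs.items() if v < threshold]
    if below:
        return v_series, min(below), True
    return v_series, k, False


def genorm(q, threshold: float = 0.15) -> GeNormResult:
    """Full geNorm analysis: ranking, M trajectory and optimal gene count."""
    res = rank_genes(q)
    v_series, optimal_n, met = optimal_gene_count(q, threshold=threshold, ranking=res.ranking)
    return GeNormResult(
        ranking=res.ranking,
        rank_of=res.rank_of,
        m_trajectory=res.m_trajectory,
        v_series=v_series,
        optimal_n=optimal_n,
        threshold_met=met,
    )
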