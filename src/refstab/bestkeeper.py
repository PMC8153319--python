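"""BestKeeper: descriptive dispersion statistics on raw Ct and index correlation.

BestKeeper works directly on Ct values.  Its "SD" is the mean absolute
deviation around the arithmetic mean Ct (not the n-1 standard deviation)
and its CV is that SD as a percentage of the arithmetic mean; an SD above
1 cycle marks a gene as unstable.  The BestKeeper index is the per-sample
geometric mean of the candidate genes' Ct values, and each gene's r is its
Pearson correlation with that index.

The composite ranking orders genes with SD <= 1 by descending r, followed
by the SD > 1 genes in order of increasing SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ct_model import CtTable

__all__ = [
    "BestKeeperResult",
    "descriptive_stats",
    "bestkeeper_index",
    "correlate_with_index",
    "rank_genes_bestkeeper",
    "bestkeeper",
]

STAT_COLUMNS = ["geo_mean", "arith_mean", "min_ct", "max_ct", "sd_mad", "cv_percent"]


@dataclass(frozen=True)
class BestKeeperResult:
    """Per-gene BestKeeper statistics (``stats``) and the composite ranking.

    ``stats`` columns: geo_mean, arith_mean, min_ct, max_ct, sd_mad,
    cv_percent, r, p_value.  ``index`` is the per-sample BestKeeper index.
    ``sd_cutoff`` is the instability threshold (cycles) used for ranking.
    """

    stats: pd.DataFrame
    index: pd.Series
    rank_of: dict[str, int]
    sd_cutoff: float = 1.0

    def to_tsv(self, path) -> None:
        out = self.stats.copy()
        out["rank"] = pd.Series(self.rank_of)
        out.to_csv(path, sep="\t")


def _as_matrix(ct) -> pd.DataFrame:
    if isinstance(ct, CtTable):
        return ct.to_matrix(collapse=True)
    mat = pd.DataFrame(ct).astype(float)
    if mat.isna().any().any():
        raise ValueError("incomplete Ct matrix")
    return mat


def descriptive_stats(ct) -> pd.DataFrame:
    """Geometric/arithmetic mean, extremes, SD (mean absolute deviation) and CV%."""
    mat = _as_matrix(ct)
    if (mat.to_numpy() <= 0).any():
        raise ValueError("Ct values must be positive")
    if mat.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    a = mat.to_numpy()
    am = a.mean(axis=1)
    mad = np.abs(a - am[:, None]).mean(axis=1)
    out = pd.DataFrame(
        {
            "geo_mean": np.exp(np.log(a).mean(axis=1)),
            "arith_mean": am,
            "min_ct": a.min(axis=1),
            "max_ct": a.max(axis=1),
            "sd_mad": mad,
            "cv_percent": 100.0 * mad / am,
        },
        index=mat.index,
    )
    return out


def bestkeeper_index(ct, genes=None) -> pd.Series:
    """Per-sample geometric mean of Ct over the given genes (default: all)."""
    mat = _as_matrix(ct)
    if genes is not None:
        genes = list(genes)
        if not genes:
            raise ValueError("empty gene subset")
        mat = mat.loc[genes]
    idx = np.exp(np.log(mat.to_numpy()).mean(axis=0))
    return pd.Series(idx, index=mat.columns, name="bestkeeper_index")


def correlate_with_index(ct, index: pd.Series | None = None) -> pd.DataFrame:
    """Pearson r (and two-sided t-test p, df = n-2) of each gene's Ct vs the index.

    Zero-variance genes get NaN r and p; they are flagged rather than
    erroring so a constant gene does not abort an analysis.
    """
    mat = _as_matrix(ct)
    if index is None:
        index = bestkeeper_index(mat)
    index = index.reindex(mat.columns)
    n = mat.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples for a p-value")
    rows = {}
    for g in mat.index:
        y = mat.loc[g].to_numpy()
        if np.ptp(y) == 0 or np.ptp(index.to_numpy()) == 0:
            rows[g] = (np.nan, np.nan)
            continue
        r, p = stats.pearsonr(y, index.to_numpy())
        rows[g] = (float(r), float(p))
    return pd.DataFrame(rows, index=["r", "p_value"]).T


def rank_genes_bestkeeper(stats_table: pd.DataFrame, sd_cutoff: float = 1.0) -> dict[str, int]:
    """Composite BestKeeper ranking from a stats table with sd_mad and r columns.

    Genes with SD <= cutoff come first, ordered by descending r (ties:
    smaller SD, then name); genes above the cutoff follow in order of
    increasing SD.  Genes with undefined r rank last within the stable
    block.
    """
    df = stats_table
    stable = df.index[df["sd_mad"] <= sd_cutoff]
    unstable = df.index[df["sd_mad"] > sd_cutoff]
    r = df["r"]
    stable_order = sorted(
        stable,
        key=lambda g: (pd.isna(r[g]), -(r[g] if pd.notna(r[g]) else 0.0), df.at[g, "sd_mad"], g),
    )
    unstable_order = sorted(unstable, key=lambda g: (df.at[g, "sd_mad"], g))
    return {g: i + 1 for i, g in enumerate(stable_order + unstable_order)}


def bestkeeper(ct, genes_for_index=None, sd_cutoff: float = 1.0) -> BestKeeperResult:
    """Full BestKeeper analysis on a Ct matrix (or CtTable, collapsed first)."""
    mat = _as_matrix(ct)
    stats_table = descriptive_stats(mat)
    idx = bestkeeper_index(mat, genes_for_index)
    stats_table = stats_table.join(correlate_with_index(mat, idx))
    return BestKeeperResult(
        stats=stats_table,
        index=idx,
        rank_of=rank_genes_bestkeeper(stats_table, sd_cutoff),
        sd_cutoff=sd_cutoff,
    )
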