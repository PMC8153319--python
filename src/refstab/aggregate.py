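"""Consensus ranking across stability methods and tissue-specific selection.

The three stability programs rarely agree exactly, so a comprehensive
ranking takes, per gene, the geometric mean of its per-method ranks and
re-ranks genes by that score.  The best combination for general use is the
top genes of the combined ranking, taken to the optimal count suggested by
geNorm's pairwise-variation rule.

For work confined to a single tissue a simpler empirical rule applies:
restrict to genes with a moderate within-tissue mean Ct (20-25 cycles by
default, i.e. well-detected but not near saturation) and pick the two with
the smallest within-tissue SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ct_model import TissueSummary

__all__ = [
    "ConsensusRanking",
    "TissuePair",
    "geometric_mean_rank",
    "select_combination",
    "select_tissue_pair",
]


@dataclass(frozen=True)
class ConsensusRanking:
    """Per-gene method ranks, geometric-mean score and combined rank.

    ``table`` holds one row per gene: the input method ranks, the
    geo_mean_rank (full precision; display rounding is the caller's
    business) and the integer combined_rank (a permutation of 1..k).
    """

    table: pd.DataFrame
    methods: tuple[str, ...]

    def top(self, n: int) -> list[str]:
        order = self.table.sort_values("combined_rank").index
        return list(order[:n])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")


@dataclass(frozen=True)
class TissuePair:
    """The two genes selected for one tissue plus the evidence behind them."""

    tissue: str
    pair: tuple[str, str]
    window: tuple[float, float]
    criterion: pd.DataFrame  # eligible genes: mean_ct, sd_ct


def geometric_mean_rank(method_ranks: pd.DataFrame) -> ConsensusRanking:
    """Consensus from a gene x method table of ranks.

    geo_mean_rank is the geometric mean of each gene's method ranks (input
    ties, such as geNorm's two rank-1 genes, are used as-is).  The combined
    rank sorts ascending geo_mean_rank, breaking ties by the best single
    method rank and then by gene name.
    """
    ranks = pd.DataFrame(method_ranks).astype(float)
    if ranks.isna().any().any():
        bad = ranks.index[ranks.isna().any(axis=1)].tolist()
        raise ValueError(f"genes missing a method rank: {bad}")
    gm = np.exp(np.log(ranks).mean(axis=1))
    order = sorted(ranks.index, key=lambda g: (gm[g], ranks.loc[g].min(), g))
    combined = pd.Series({g: i + 1 for i, g in enumerate(order)})
    table = ranks.copy()
    table["geo_mean_rank"] = gm
    table["combined_rank"] = combined
    return ConsensusRanking(table=table, methods=tuple(ranks.columns))


def select_combination(consensus: ConsensusRanking, optimal_n: int) -> list[str]:
    """Top ``optimal_n`` genes of the combined ranking."""
    if optimal_n < 1 or optimal_n > len(consensus.table):
        raise ValueError(f"optimal_n must be in 1..{len(consensus.table)}")
    return consensus.top(optimal_n)


def select_tissue_pair(
    summary: TissueSummary,
    tissue: str,
    window: tuple[float, float] = (20.0, 25.0),
) -> TissuePair:
    """Two reference genes for one tissue: moderate Ct, then lowest SD.

    Eligible genes have a within-tissue mean Ct inside the closed
    ``window``; among them the two with the smallest within-tissue SD win
    (ties: smaller distance of the mean to the window midpoint, then
    name).
    """
    lo, hi = window
    if not lo < hi:
        raise ValueError("window low bound must be below high bound")
    sub = summary.per_tissue[summary.per_tissue["tissue"] == tissue]
    if sub.empty:
        raise ValueError(f"unknown tissue: {tissue!r}")
    sub = sub.set_index("gene")
    eligible = sub[(sub["mean_ct"] >= lo) & (sub["mean_ct"] <= hi)]
    if len(eligible) < 2:
        raise ValueError(
            f"fewer than 2 genes with mean Ct in [{lo}, {hi}] for tissue {tissue!r}"
        )
    if eligible["sd_ct"].isna().any():
        raise ValueError("within-tissue SDs unavailable (single replicate per tissue)")
    mid = (lo + hi) / 2.0
    order = sorted(
        eligible.index,
        key=lambda g: (eligible.at[g, "sd_ct"], abs(eligible.at[g, "mean_ct"] - mid), g),
    )
    return TissuePair(
        tissue=tissue,
        pair=(order[0], order[1]),
        window=(lo, hi),
        criterion=eligible[["mean_ct", "sd_ct"]].loc[order],
    )
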