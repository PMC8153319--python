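"""End-to-end stability evaluation: one call from Ct table to consensus."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import aggregate, transform
from .bestkeeper import BestKeeperResult, bestkeeper as _bestkeeper
from .genorm import GeNormResult, genorm as _genorm
from .normfinder import NormFinderResult, stability_ungrouped as _normfinder
from .ct_model import CtTable, TissueSummary, summarize, flag_unstable_by_range

__all__ = ["StabilityReport", "evaluate_stability"]


@dataclass(frozen=True)
class StabilityReport:
    """Everything the stability workflow produces for one dataset."""

    summary: TissueSummary
    range_flagged: set[str]
    genorm: GeNormResult
    normfinder: NormFinderResult
    bestkeeper: BestKeeperResult
    consensus: aggregate.ConsensusRanking
    optimal_n: int
    best_combination: list[str]

    def method_ranks(self) -> pd.DataFrame:
        return self.consensus.table[list(self.consensus.methods)].astype(int)

    def to_json_dict(self) -> dict:
        return {
            "optimal_n": self.optimal_n,
            "genorm_threshold_met": self.genorm.threshold_met,
            "best_combination": self.best_combination,
            "range_flagged": sorted(self.range_flagged),
            "combined_ranking": list(self.consensus.table.sort_values("combined_rank").index),
            "geo_mean_rank": self.consensus.table["geo_mean_rank"].round(4).to_dict(),
            "method_ranks": {
                m: self.consensus.table[m].astype(int).to_dict() for m in self.consensus.methods
            },
        }


def evaluate_stability(
    ct: CtTable,
    base: float = 2.0,
    genorm_threshold: float = 0.15,
    sd_cutoff: float = 1.0,
    range_threshold: float = 4.0,
    collapse: bool = True,
) -> StabilityReport:
    """Run geNorm, NormFinder and BestKeeper and combine their rankings.

    Replicates are collapsed to one value per (gene, tissue) first unless
    ``collapse`` is False.  geNorm and NormFinder score relative
    quantities base^(-dCt); BestKeeper works on the raw Ct matrix.  The
    consensus is the geometric mean of the three rank columns and the best
    combination takes the top genes of the combined ranking up to geNorm's
    optimal count.
    """
    summary = summarize(ct)
    flagged = flag_unstable_by_range(summary, threshold=range_threshold)
    mat = ct.to_matrix(collapse=collapse)
    q = transform.to_quantities(mat, base=base)
    gn = _genorm(q, threshold=genorm_threshold)
    nf = _normfinder(transform.to_log_quantities(mat, base=base))
    bk = _bestkeeper(mat, sd_cutoff=sd_cutoff)
    ranks = pd.DataFrame(
        {
            "genorm": pd.Series(gn.rank_of),
            "normfinder": pd.Series(nf.rank_of),
            "bestkeeper": pd.Series(bk.rank_of),
        }
    ).loc[mat.index]
    consensus = aggregate.geometric_mean_rank(ranks)
    best = aggregate.select_combination(consensus, gn.optimal_n)
    return StabilityReport(
        summary=summary,
        range_flagged=flagged,
        genorm=gn,
        normfinder=nf,
        bestkeeper=bk,
        consensus=consensus,
        optimal_n=gn.optimal_n,
        best_combination=best,
    )
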