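"""Relative expression of target genes by the 2^-ddCt method.

dCt(sample) = Ct_target - mean(Ct of the reference genes); averaging
reference Ct values is equivalent, on the linear scale, to dividing by the
geometric-mean normalization factor of those references.  ddCt subtracts
the calibrator sample's dCt, so the calibrator's fold change is exactly 1.
An efficiency-corrected mode replaces the common base of 2 with per-gene
bases 1 + E.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ct_model import CtTable

__all__ = ["ExpressionResult", "ProfileComparison", "relative_expression", "expression_profile"]


@dataclass(frozen=True)
class ExpressionResult:
    """Fold change per sample for one target / reference-set combination."""

    rel_expr: pd.Series
    delta_ct: pd.Series
    target: str
    references: tuple[str, ...]
    calibrator: str


@dataclass(frozen=True)
class ProfileComparison:
    """Cross-normalization comparison of expression profiles.

    ``concordance`` is the Spearman correlation matrix between the
    per-sample log2 fold-change profiles obtained under each reference
    set; ``consensus_corr`` correlates each profile with the element-wise
    median profile; sets falling below ``threshold`` are ``flagged``.
    """

    results: dict[str, ExpressionResult]
    concordance: pd.DataFrame
    consensus_corr: pd.Series
    flagged: list[str]
    threshold: float


def _as_matrix(ct) -> pd.DataFrame:
    if isinstance(ct, CtTable):
        return ct.to_matrix(collapse=True)
    mat = pd.DataFrame(ct).astype(float)
    if mat.isna().any().any():
        raise ValueError("incomplete Ct matrix")
    return mat


def relative_expression(
    ct,
    target: str,
    references,
    calibrator: str | None = None,
    efficiency: pd.Series | dict | None = None,
) -> ExpressionResult:
    """Fold change of ``target`` across samples, normalized and calibrated.

    ``references`` is one or more reference genes; their per-sample mean
    Ct acts as the normalizer.  ``calibrator`` names the sample whose
    expression defines fold change 1; when omitted, the sample with the
    smallest dCt (highest relative target expression) is used.  When
    ``efficiency`` maps genes to E (fraction, e.g. 0.95), amplification
    bases of 1 + E replace the default 2 gene by gene.
    """
    mat = _as_matrix(ct)
    references = [references] if isinstance(references, str) else list(references)
    if not references:
        raise ValueError("need at least one reference gene")
    if target in references:
        raise ValueError(f"target {target!r} cannot be one of its references")
    missing = [g for g in [target, *references] if g not in mat.index]
    if missing:
        raise ValueError(f"genes absent from the Ct table: {missing}")

    if efficiency is None:
        # log2 expression of a gene (up to a per-gene constant) is -Ct
        logq = -mat
    else:
        eff = pd.Series(efficiency)
        base = (1.0 + eff).reindex(mat.index)
        if base.loc[[target, *references]].isna().any():
            raise ValueError("efficiency missing for target or reference gene(s)")
        logq = -mat.mul(np.log2(base), axis=0)

    dct = -(logq.loc[target] - logq.loc[references].mean(axis=0))
    if calibrator is None:
        calibrator = dct.idxmin()
    if calibrator not in mat.columns:
        raise ValueError(f"calibrator sample {calibrator!r} not present")
    ddct = dct - dct[calibrator]
    rel = np.power(2.0, -ddct)
    rel.name = "rel_expr"
    return ExpressionResult(
        rel_expr=rel,
        delta_ct=dct.rename("delta_ct"),
        target=target,
        references=tuple(references),
        calibrator=str(calibrator),
    )


def expression_profile(
    ct,
    target: str,
    reference_sets,
    calibrator: str | None = None,
    threshold: float = 0.9,
    efficiency=None,
) -> ProfileComparison:
    """Compare the target's expression profile across reference sets.

    ``reference_sets`` maps a label to a list of reference genes (a plain
    sequence of lists gets auto-labelled).  Profiles that rank samples
    differently from the consensus (element-wise median log2 profile)
    betray an unstable normalizer: any set whose Spearman correlation with
    the consensus falls below ``threshold`` is flagged.
    """
    if not isinstance(reference_sets, dict):
        reference_sets = {"+".join(map(str, rs)): list(rs) for rs in reference_sets}
    if len(reference_sets) < 2:
        raise ValueError("need at least 2 reference sets to compare")
    mat = _as_matrix(ct)
    if calibrator is None:
        # shared calibrator so profiles are directly comparable
        first = next(iter(reference_sets.values()))
        calibrator = relative_expression(mat, target, first, efficiency=efficiency).calibrator
    results = {
        label: relative_expression(mat, target, refs, calibrator=calibrator, efficiency=efficiency)
        for label, refs in reference_sets.items()
    }
    profiles = pd.DataFrame({label: np.log2(r.rel_expr) for label, r in results.items()})
    labels = list(profiles.columns)
    conc = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            rho = stats.spearmanr(profiles[a], profiles[b]).statistic
            conc.loc[a, b] = conc.loc[b, a] = rho
    consensus = profiles.median(axis=1)
    consensus_corr = pd.Series(
        {a: float(stats.spearmanr(profiles[a], consensus).statistic) for a in labels},
        name="consensus_spearman",
    )
    flagged = [a for a in labels if consensus_corr[a] < threshold]
    return ProfileComparison(
        results=results,
        concordance=conc,
        consensus_corr=consensus_corr,
        flagged=flagged,
        threshold=threshold,
    )
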