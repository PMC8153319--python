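"""NormFinder: model-based estimation of gene-specific expression variance.

Log-scale expression is modelled additively, x_ij = alpha_i + beta_j +
eps_ij, with gene-specific error variance sigma_i^2.  Double-centered
residuals estimate the error term, but their naive per-gene variance s_i^2
is biased: under the model E[s_i^2] = sigma_i^2 (k-2)/k + S/k^2 with
S = sum of all sigma^2.  Solving this identity yields the bias-corrected
estimator used here,

    sigma_hat_i^2 = (s_i^2 - T / (k (k-1))) * k / (k-2),   T = sum_i s_i^2,

which is exactly unbiased (T estimates S (k-1)/k).  The stability value is
rho_i = sqrt(max(0, sigma_hat_i^2)); smaller is more stable.

The grouped variant adds a gene x group interaction d_ig (how much a gene
deviates from its overall level within a group), shrinks it toward zero in
proportion to how well it is estimated, and scores each gene by the mean
over groups of |d~_ig| + sqrt(sigma_hat^2_ig / n_g).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["NormFinderResult", "stability_ungrouped", "stability_grouped"]


@dataclass(frozen=True)
class NormFinderResult:
    """Per-gene stability values (log2 units, >= 0) and ranks (1 = most stable).

    ``variance_raw`` keeps the bias-corrected variance estimates before
    truncation at zero (they may be slightly negative for very stable
    genes); ``stability`` is the square root of the truncated variance.
    In grouped mode ``group_components`` holds the per-group intergroup
    deviations (raw and shrunken) and intragroup variances.
    """

    stability: pd.Series
    rank_of: dict[str, int]
    mode: str
    variance_raw: pd.Series | None = None
    group_components: dict[str, pd.DataFrame] = field(default_factory=dict)


def _ranks(stability: pd.Series) -> dict[str, int]:
    # ascending stability; ties (e.g. several rho == 0) break by gene name
    order = sorted(stability.index, key=lambda g: (stability[g], g))
    return {g: i + 1 for i, g in enumerate(order)}


def _residual_variances(a: np.ndarray) -> np.ndarray:
    k, n = a.shape
    r = a - a.mean(axis=1, keepdims=True) - a.mean(axis=0, keepdims=True) + a.mean()
    return (r**2).sum(axis=1) / (n - 1)


def stability_ungrouped(x) -> NormFinderResult:
    """NormFinder stability values from a log2-quantity matrix (genes x samples)."""
    x = pd.DataFrame(x).astype(float)
    k, n = x.shape
    if k < 3:
        raise ValueError("bias correction needs at least 3 genes")
    if n < 2:
        raise ValueError("need at least 2 samples")
    a = x.to_numpy()
    s2 = _residual_variances(a)
    t = s2.sum()
    var_raw = (s2 - t / (k * (k - 1))) * k / (k - 2)
    rho = np.sqrt(np.maximum(var_raw, 0.0))
    stability = pd.Series(rho, index=x.index, name="stability")
    return NormFinderResult(
        stability=stability,
        rank_of=_ranks(stability),
        mode="ungrouped",
        variance_raw=pd.Series(var_raw, index=x.index, name="variance_raw"),
    )


def stability_grouped(x, groups) -> NormFinderResult:
    """Grouped NormFinder: intragroup variance plus shrunken intergroup deviation.

    ``groups`` maps each sample (column of ``x``) to a group label; every
    group needs at least 2 samples so the intragroup variance is estimable.
    """
    x = pd.DataFrame(x).astype(float)
    k = x.shape[0]
    if k < 3:
        raise ValueError("bias correction needs at least 3 genes")
    groups = pd.Series(groups).reindex(x.columns)
    if groups.isna().any():
        missing = list(x.columns[groups.isna()])
        raise ValueError(f"samples without a group label: {missing}")
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("grouped mode needs at least 2 groups")
    sizes = groups.value_counts()
    small = sizes.index[sizes < 2].tolist()
    if small:
        raise ValueError(f"groups with fewer than 2 samples: {small}")

    sigma2 = {}
    group_mean = {}
    for g in labels:
        sub = x.loc[:, groups[groups == g].index].to_numpy()
        n_g = sub.shape[1]
        s2 = _residual_variances(sub)
        t = s2.sum()
        var_raw = (s2 - t / (k * (k - 1))) * k / (k - 2)
        sigma2[g] = np.maximum(var_raw, 0.0)
        group_mean[g] = sub.mean(axis=1)
    sigma2 = pd.DataFrame(sigma2, index=x.index)  # gene x group
    gm = pd.DataFrame(group_mean, index=x.index)
    n_per = pd.Series({g: int(sizes[g]) for g in labels})

    # intergroup deviation: double-centered gene x group mean matrix
    d = gm.sub(gm.mean(axis=1), axis=0).sub(gm.mean(axis=0), axis=1) + gm.to_numpy().mean()
    noise = sigma2.div(n_per, axis=1)
    gamma2 = max(0.0, float(d.to_numpy().var(ddof=1)) - float(noise.to_numpy().mean()))
    denom = gamma2 + noise
    # gamma2 == 0 means no evidence of gene x group interaction: shrink fully,
    # also covering the 0/0 cell where a gene's variance estimate truncated to 0
    factor = (gamma2 / denom).where(denom > 0, 0.0)
    d_shrunk = d * factor
    rho = (d_shrunk.abs() + np.sqrt(noise)).mean(axis=1)
    rho.name = "stability"
    return NormFinderResult(
        stability=rho,
        rank_of=_ranks(rho),
        mode="grouped",
        group_components={"d": d, "d_shrunk": d_shrunk, "sigma2": sigma2},
    )
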