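"""Synthetic Ct data with known stability structure.

The generator mirrors the additive structure the stability methods
assume: Ct for gene i in replicate j of tissue g is

    Ct_igj = mu_i + b_gj + delta_ig + eps_igj,

with a gene baseline mu_i (drawn once per dataset from a configurable
window), a sample effect b_gj shared by all genes in a sample (global
loading/RT differences between tubes), a gene x tissue instability term
delta_ig ~ N(0, tau_i^2) (true biological instability of the candidate)
and replicate noise eps_igj ~ N(0, sigma_i^2).  Normal noise on the Ct
scale is multiplicative on expression, matching the log-scale models of
geNorm and NormFinder.  A gene's total instability is
sqrt(tau_i^2 + sigma_i^2); sorting by it gives the ground-truth stability
order used in recovery tests.

The default scenario mimics a multi-tissue reference-gene survey:
19 genes, 6 tissues, 3 replicates, most genes with tissue-effect SDs of
about half a cycle and two planted unstable genes at tau = 2.5 cycles
(comparable to the worst candidates seen in real panels).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ct_model import CtTable, LONG_COLUMNS

__all__ = ["SyntheticTruth", "simulate_ct", "simulate_dilution_series", "default_scenario"]

DEFAULT_TISSUES = ("leaf", "bud", "fruit", "phloem", "root", "xylem")


@dataclass(frozen=True)
class SyntheticTruth:
    """Generator parameters and the true stability ordering."""

    genes: list[str]
    tissues: list[str]
    mu: pd.Series
    sample_effects: pd.Series
    delta: pd.DataFrame  # gene x tissue
    tau: pd.Series
    sigma: pd.Series
    base: float
    seed: int
    true_order: list[str]  # most stable first, by sqrt(tau^2 + sigma^2)

    def total_instability(self) -> pd.Series:
        return np.sqrt(self.tau**2 + self.sigma**2)

    def to_json(self, path) -> None:
        payload = {
            "genes": self.genes,
            "tissues": self.tissues,
            "mu": self.mu.to_dict(),
            "sample_effects": self.sample_effects.to_dict(),
            "delta": {g: self.delta.loc[g].to_dict() for g in self.genes},
            "tau": self.tau.to_dict(),
            "sigma": self.sigma.to_dict(),
            "base": self.base,
            "seed": self.seed,
            "true_order": self.true_order,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _per_gene(values, genes, name) -> pd.Series:
    arr = np.broadcast_to(np.asarray(values, dtype=float), (len(genes),)).copy()
    if (arr < 0).any():
        raise ValueError(f"{name} must be non-negative")
    return pd.Series(arr, index=genes, name=name)


def simulate_ct(
    n_genes: int = 19,
    tissues=DEFAULT_TISSUES,
    replicates: int = 3,
    tau=0.5,
    sigma=0.4,
    sample_effect_sd: float = 1.0,
    baseline_window: tuple[float, float] = (18.0, 26.0),
    base: float = 2.0,
    seed: int = 0,
) -> tuple[CtTable, SyntheticTruth]:
    """Draw a complete Ct dataset with known per-gene instability.

    ``tau`` and ``sigma`` are scalars or per-gene arrays (cycles).  A
    single integer ``seed`` drives one private random stream; the same
    seed reproduces the dataset bit for bit.
    """
    tissues = list(tissues)
    if n_genes < 2 or len(tissues) < 2 or replicates < 1:
        raise ValueError("need >= 2 genes, >= 2 tissues and >= 1 replicate")
    if sample_effect_sd < 0:
        raise ValueError("sample_effect_sd must be non-negative")
    genes = [f"G{i + 1:02d}" for i in range(n_genes)]
    tau = _per_gene(tau, genes, "tau")
    sigma = _per_gene(sigma, genes, "sigma")

    rng = np.random.default_rng(seed)
    lo, hi = baseline_window
    mu = pd.Series(rng.uniform(lo, hi, n_genes), index=genes, name="mu")
    samples = [f"{t}_{r + 1}" for t in tissues for r in range(replicates)]
    b = pd.Series(rng.normal(0.0, sample_effect_sd, len(samples)), index=samples, name="b")
    delta = pd.DataFrame(
        rng.normal(0.0, 1.0, (n_genes, len(tissues))) * tau.to_numpy()[:, None],
        index=genes,
        columns=tissues,
    )
    eps = rng.normal(0.0, 1.0, (n_genes, len(samples))) * sigma.to_numpy()[:, None]

    records = []
    for si, s in enumerate(samples):
        t, r = s.rsplit("_", 1)
        for gi, g in enumerate(genes):
            ct = mu[g] + b[s] + delta.at[g, t] + eps[gi, si]
            records.append((g, s, t, int(r), ct))
    table = CtTable(pd.DataFrame(records, columns=list(LONG_COLUMNS)))

    total = np.sqrt(tau**2 + sigma**2)
    true_order = sorted(genes, key=lambda g: (total[g], g))
    truth = SyntheticTruth(
        genes=genes,
        tissues=tissues,
        mu=mu,
        sample_effects=b,
        delta=delta,
        tau=tau,
        sigma=sigma,
        base=base,
        seed=seed,
        true_order=true_order,
    )
    return table, truth


def default_scenario(seed: int = 0, n_unstable: int = 2, tau_unstable: float = 2.5):
    """The package's reference simulation: 19 genes, 6 tissues, 3 replicates.

    The last ``n_unstable`` genes carry a planted tissue-effect SD of
    ``tau_unstable`` cycles; everything else uses the stable defaults.
    """
    n_genes = 19
    tau = np.full(n_genes, 0.5)
    tau[-n_unstable:] = tau_unstable
    return simulate_ct(n_genes=n_genes, tau=tau, sigma=0.4, seed=seed)


def simulate_dilution_series(
    true_efficiency_percent: float = 100.0,
    intercept: float = 35.0,
    noise_sd: float = 0.0,
    points: int = 5,
    seed: int = 0,
    step: float = -1.0,
) -> pd.DataFrame:
    """Standard-curve data: Ct against log10 input for a serial dilution.

    Ct = intercept + slope * log10(input) with slope = -1/log10(1 + E);
    ``step`` is the log10 spacing between successive dilutions (-1 for a
    tenfold series).  With ``noise_sd`` 0 the fitted efficiency recovers
    the truth exactly.
    """
    if true_efficiency_percent <= 0:
        raise ValueError("efficiency must be positive")
    if points < 3:
        raise ValueError("need at least 3 dilution points")
    rng = np.random.default_rng(seed)
    slope = -1.0 / np.log10(1.0 + true_efficiency_percent / 100.0)
    log10_x = np.arange(points) * step
    ct = intercept + slope * log10_x + rng.normal(0.0, noise_sd, points)
    return pd.DataFrame({"log10_dilution": log10_x, "ct": ct})
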