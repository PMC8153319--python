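"""Ct to relative-quantity transforms.

geNorm and NormFinder both consume relative quantities Q = base^(-dCt),
where dCt anchors each gene at its most expressed (lowest Ct) sample so
that the largest quantity per gene is exactly 1.  The anchor choice is
immaterial downstream: both methods are invariant to per-gene scaling.
The default base of 2 assumes perfect doubling per cycle; an
efficiency-corrected run passes base = 1 + E per gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ct_model import CtTable

__all__ = ["QuantityMatrix", "to_quantities", "to_log_quantities"]


@dataclass(frozen=True)
class QuantityMatrix:
    """Gene x sample matrix of relative quantities in (0, 1].

    ``q`` rows are genes, columns samples; per gene the most expressed
    sample has q = 1.  ``base`` is the per-gene amplification factor used
    (scalar, or a Series aligned to the genes).
    """

    q: pd.DataFrame
    base: float | pd.Series = 2.0

    def __post_init__(self) -> None:
        vals = self.q.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0) or np.any(vals > 1 + 1e-12):
            raise ValueError("quantities must be finite and in (0, 1]")

    @property
    def genes(self) -> list[str]:
        return list(self.q.index)

    @property
    def samples(self) -> list[str]:
        return list(self.q.columns)

    def log2(self) -> pd.DataFrame:
        """Log2 quantities (equal to -dCt when base is 2)."""
        return np.log2(self.q)


def _as_matrix(ct) -> pd.DataFrame:
    if isinstance(ct, CtTable):
        return ct.to_matrix(collapse=True)
    mat = pd.DataFrame(ct).astype(float)
    if mat.isna().any().any():
        raise ValueError("incomplete Ct matrix")
    return mat


def _base_array(base, index: pd.Index) -> np.ndarray:
    if np.isscalar(base):
        arr = np.full(len(index), float(base))
    else:
        arr = pd.Series(base).reindex(index).to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValueError("base missing for some genes")
    if np.any(arr <= 1):
        raise ValueError("amplification base must exceed 1")
    return arr


def to_quantities(ct, base=2.0) -> QuantityMatrix:
    """Relative quantities base^(-dCt), anchored at each gene's minimum Ct.

    ``ct`` may be a :class:`CtTable` (replicates are collapsed to tissue
    means first) or a gene x sample Ct matrix.
    """
    mat = _as_matrix(ct)
    b = _base_array(base, mat.index)
    dct = mat.to_numpy() - mat.to_numpy().min(axis=1, keepdims=True)
    q = np.power(b[:, None], -dct)
    return QuantityMatrix(
        q=pd.DataFrame(q, index=mat.index, columns=mat.columns),
        base=base if np.isscalar(base) else pd.Series(b, index=mat.index),
    )


def to_log_quantities(ct, base=2.0) -> pd.DataFrame:
    """Log2 relative quantities, i.e. -dCt * log2(base).

    With the default base of 2 this is simply -dCt per cell, the scale on
    which NormFinder's additive model operates.
    """
    mat = _as_matrix(ct)
    b = _base_array(base, mat.index)
    dct = mat.to_numpy() - mat.to_numpy().min(axis=1, keepdims=True)
    out = -dct * np.log2(b)[:, None]
    return pd.DataFrame(out, index=mat.index, columns=mat.columns)
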