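"""Ct measurement model: containers, tabular I/O, replicate collapsing and QC.

The central object is :class:`CtTable`, a validated long-format table of
threshold-cycle (Ct) measurements keyed by gene, sample, tissue and
replicate.  Summaries collapse replicates to one value per gene and tissue
(arithmetic mean) before any stability analysis, because the stability
methods downstream all assume a complete gene x sample matrix of
representative Ct values.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CtTable",
    "CtTableError",
    "TissueSummary",
    "DilutionFit",
    "read_ct_table",
    "summarize",
    "flag_unstable_by_range",
    "efficiency_from_dilution",
]

LONG_COLUMNS = ("gene", "sample", "tissue", "replicate", "ct")


class CtTableError(ValueError):
    """Raised when a Ct table violates its contract (bad cells, duplicates...)."""


@dataclass(frozen=True)
class CtTable:
    """Long-format table of Ct measurements.

    ``data`` has columns gene, sample, tissue, replicate, ct.  Every ct is
    finite and positive and (gene, sample) pairs are unique.  Gene and
    sample identifiers are opaque, case-sensitive strings.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise CtTableError(f"missing columns: {missing}")
        ct = pd.to_numeric(df["ct"], errors="coerce")
        bad = df.index[~np.isfinite(ct) | (ct <= 0)]
        if len(bad):
            cells = [
                f"(gene={df.at[i, 'gene']}, sample={df.at[i, 'sample']}, ct={df.at[i, 'ct']!r})"
                for i in bad[:10]
            ]
            raise CtTableError(
                f"{len(bad)} non-finite or non-positive Ct value(s): " + "; ".join(cells)
            )
        dup = df.duplicated(subset=["gene", "sample"], keep=False)
        if dup.any():
            pairs = sorted(set(map(tuple, df.loc[dup, ["gene", "sample"]].values)))
            raise CtTableError(f"duplicate (gene, sample) pairs: {pairs[:10]}")
        object.__setattr__(self, "data", df.assign(ct=ct.astype(float)).reset_index(drop=True))

    # -- introspection -------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return list(pd.unique(self.data["gene"]))

    @property
    def samples(self) -> list[str]:
        return list(pd.unique(self.data["sample"]))

    @property
    def tissues(self) -> list[str]:
        return list(pd.unique(self.data["tissue"]))

    def __len__(self) -> int:
        return len(self.data)

    # -- reshaping -----------------------------------------------------

    def collapse_replicates(self) -> "CtTable":
        """Average replicates to one record per (gene, tissue).

        The collapsed table uses the tissue label as the sample identifier,
        which is the layout the stability methods consume.
        """
        g = (
            self.data.groupby(["gene", "tissue"], sort=False)["ct"]
            .mean()
            .reset_index()
        )
        g["sample"] = g["tissue"]
        g["replicate"] = 1
        return CtTable(g[list(LONG_COLUMNS)])

    def to_matrix(self, collapse: bool = True, on_incomplete: str = "error") -> pd.DataFrame:
        """Gene x sample matrix of Ct values.

        Parameters
        ----------
        collapse
            Average replicates per (gene, tissue) first (default).  When
            False the raw samples become columns.
        on_incomplete
            ``"error"`` (default) raises if any gene misses any sample;
            ``"drop"`` removes offending genes instead.
        """
        tbl = self.collapse_replicates() if collapse else self
        mat = tbl.data.pivot(index="gene", columns="sample", values="ct")
        mat = mat.loc[tbl.genes, tbl.samples]
        if mat.isna().any().any():
            bad = mat.index[mat.isna().any(axis=1)].tolist()
            if on_incomplete == "drop":
                import warnings

                warnings.warn(f"dropping genes with missing samples: {bad}")
                mat = mat.drop(index=bad)
            else:
                raise CtTableError(f"incomplete matrix; genes with missing samples: {bad}")
        mat.columns.name = None
        mat.index.name = "gene"
        return mat


@dataclass(frozen=True)
class TissueSummary:
    """Per-tissue and per-gene descriptive statistics of a Ct table.

    ``per_tissue`` is tidy with columns gene, tissue, mean_ct, sd_ct, n
    (mean and n-1 standard deviation over replicates; sd is NaN when
    n == 1).  ``per_gene`` is indexed by gene with columns overall_mean,
    min_ct, max_ct, range_ct, all computed over the tissue means.
    """

    per_tissue: pd.DataFrame
    per_gene: pd.DataFrame

    def mean_matrix(self) -> pd.DataFrame:
        """Gene x tissue matrix of per-tissue mean Ct."""
        genes = list(pd.unique(self.per_tissue["gene"]))
        tissues = list(pd.unique(self.per_tissue["tissue"]))
        m = self.per_tissue.pivot(index="gene", columns="tissue", values="mean_ct")
        m = m.loc[genes, tissues]
        m.columns.name = None
        m.index.name = "gene"
        return m

    def to_table(self) -> pd.DataFrame:
        """Human-readable wide table: per-tissue mean±SD plus overall columns."""
        tissues = list(pd.unique(self.per_tissue["tissue"]))
        wide = {}
        for t in tissues:
            sub = self.per_tissue[self.per_tissue["tissue"] == t].set_index("gene")
            wide[t] = sub.apply(
                lambda r: f"{r.mean_ct:.3f}"
                + ("" if pd.isna(r.sd_ct) else f" ± {r.sd_ct:.3f}"),
                axis=1,
            )
        out = pd.DataFrame(wide).loc[self.per_gene.index]
        out["Average"] = self.per_gene["overall_mean"].round(3)
        out["Min"] = self.per_gene["min_ct"].round(3)
        out["Max"] = self.per_gene["max_ct"].round(3)
        out["Range"] = self.per_gene["range_ct"].round(3)
        out.index.name = "Gene"
        return out

    def to_tsv(self, path) -> None:
        self.to_table().to_csv(path, sep="\t")


@dataclass(frozen=True)
class DilutionFit:
    """Standard-curve fit: Ct regressed on log10 template input."""

    slope: float
    intercept: float
    efficiency_percent: float
    r_squared: float


def _detect_sep(source, sep: str | None) -> str:
    if sep is not None:
        return sep
    name = getattr(source, "name", source)
    if isinstance(name, (str, Path)) and str(name).endswith(".csv"):
        return ","
    return "\t"


def read_ct_table(
    source,
    layout: str = "long",
    sep: str | None = None,
    samples=None,
) -> CtTable:
    """Read a delimited Ct table.

    Parameters
    ----------
    source
        Path or text stream.  Delimiter is inferred from the extension
        (``.csv`` -> comma, otherwise tab) unless ``sep`` is given.
    layout
        ``"long"``: columns gene, sample, tissue, replicate, ct (tissue
        defaults to the sample label and replicate to 1 when absent).
        ``"wide"``: rows are genes, columns are samples; ``samples`` must
        then provide the sample annotation (path or DataFrame with columns
        sample, tissue, replicate).
    """
    if layout not in ("long", "wide"):
        raise CtTableError(f"unknown layout: {layout!r}")
    sep = _detect_sep(source, sep)
    df = pd.read_csv(source, sep=sep, dtype=str)
    if layout == "long":
        required = {"gene", "sample", "ct"}
        if not required.issubset(df.columns):
            raise CtTableError(f"long layout requires columns {sorted(required)}, got {list(df.columns)}")
        if "tissue" not in df.columns:
            df["tissue"] = df["sample"]
        if "replicate" not in df.columns:
            df["replicate"] = 1
        long = df[list(LONG_COLUMNS)].copy()
    else:
        if samples is None:
            raise CtTableError("wide layout requires a samples annotation table")
        ann = samples if isinstance(samples, pd.DataFrame) else pd.read_csv(samples, sep=sep, dtype=str)
        if "sample" not in ann.columns:
            raise CtTableError("samples annotation must have a 'sample' column")
        if "tissue" not in ann.columns:
            ann = ann.assign(tissue=ann["sample"])
        if "replicate" not in ann.columns:
            ann = ann.assign(replicate=1)
        gene_col = df.columns[0]
        long = df.melt(id_vars=[gene_col], var_name="sample", value_name="ct")
        long = long.rename(columns={gene_col: "gene"})
        unknown = set(long["sample"]) - set(ann["sample"])
        if unknown:
            raise CtTableError(f"samples without annotation: {sorted(unknown)}")
        long = long.merge(ann[["sample", "tissue", "replicate"]], on="sample", how="left")
        long = long[list(LONG_COLUMNS)]
    ct = pd.to_numeric(long["ct"], errors="coerce")
    bad = long.index[ct.isna()]
    if len(bad):
        cells = [f"(row={i + 2}, gene={long.at[i, 'gene']}, sample={long.at[i, 'sample']}, value={long.at[i, 'ct']!r})" for i in bad[:10]]
        raise CtTableError(f"{len(bad)} non-numeric or missing Ct cell(s): " + "; ".join(cells))
    long["replicate"] = pd.to_numeric(long["replicate"]).astype(int)
    long["ct"] = ct
    return CtTable(long)


def summarize(ct: CtTable) -> TissueSummary:
    """Descriptive statistics per (gene, tissue) and per gene.

    Replicates collapse first: the per-tissue mean is the arithmetic mean
    of replicate Ct values and the per-tissue SD uses the n-1 denominator.
    Per-gene overall mean/min/max/range are computed over the tissue means,
    not over raw replicates, so that tissues weigh equally regardless of
    replication depth.
    """
    if len(ct) == 0:
        raise CtTableError("empty Ct table")
    per_tissue = (
        ct.data.groupby(["gene", "tissue"], sort=False)["ct"]
        .agg(mean_ct="mean", sd_ct=lambda x: x.std(ddof=1), n="count")
        .reset_index()
    )
    means = per_tissue.pivot(index="gene", columns="tissue", values="mean_ct")
    means = means.loc[list(pd.unique(per_tissue["gene"]))]
    per_gene = pd.DataFrame(
        {
            "overall_mean": means.mean(axis=1),
            "min_ct": means.min(axis=1),
            "max_ct": means.max(axis=1),
        }
    )
    per_gene["range_ct"] = per_gene["max_ct"] - per_gene["min_ct"]
    per_gene.index.name = "gene"
    return TissueSummary(per_tissue=per_tissue, per_gene=per_gene)


def flag_unstable_by_range(summary: TissueSummary, threshold: float = 4.0) -> set[str]:
    """Genes whose Ct range across tissue means strictly exceeds ``threshold`` cycles.

    A spread of more than ~4 cycles between the most and least expressing
    tissue (a >16-fold abundance swing) marks a candidate as unstable
    before any model-based scoring.
    """
    pg = summary.per_gene
    return set(pg.index[pg["range_ct"] > threshold])


def efficiency_from_dilution(points: Iterable[Sequence[float]] | pd.DataFrame) -> DilutionFit:
    """Amplification efficiency from a dilution series.

    ``points`` are (log10 template input, Ct) pairs from a serial dilution.
    Ct is regressed on log10 input by ordinary least squares; the
    efficiency follows from the slope as E% = (10^(-1/slope) - 1) * 100,
    so a slope of -3.32 (perfect doubling each cycle) gives 100%.
    """
    if isinstance(points, pd.DataFrame):
        arr = points.iloc[:, :2].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(points), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (log10 dilution, Ct) points")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("zero-variance dilution axis")
    fit = stats.linregress(x, y)
    eff = (10.0 ** (-1.0 / fit.slope) - 1.0) * 100.0
    return DilutionFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        efficiency_percent=float(eff),
        r_squared=float(fit.rvalue**2),
    )
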