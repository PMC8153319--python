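"""Packaged datasets: the published Schima superba reference-gene survey.

Three small tables from a published multi-tissue RT-qPCR survey of 19
candidate reference genes in *Schima superba* ship with the package:

* per-tissue mean and SD Ct for each gene over six tissues (leaf, bud,
  fruit, phloem, root, xylem; n = 3 biological replicates per tissue) —
  the input every analysis in this package can be anchored against;
* the study's published BestKeeper statistics table;
* the study's published per-method ranks and consensus ranking.

The raw per-replicate Ct measurements were not deposited, so the
per-tissue means are the finest-grained real data available; the
stability programs in the original study demonstrably ran on these six
tissue means per gene.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .ct_model import CtTable, TissueSummary, LONG_COLUMNS

__all__ = [
    "load_schima_tissue_stats",
    "load_schima_ct",
    "load_schima_summary",
    "load_published_overall",
    "load_published_bestkeeper",
    "load_published_consensus",
]

TISSUES = ("leaf", "bud", "fruit", "phloem", "root", "xylem")


def _read(name: str) -> pd.DataFrame:
    with resources.files("refstab.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_schima_tissue_stats() -> pd.DataFrame:
    """Tidy per (gene, tissue) mean_ct, sd_ct and n (19 genes x 6 tissues)."""
    return _read("schima_tissue_ct.tsv")


def load_schima_ct() -> CtTable:
    """The survey as a CtTable with one record per (gene, tissue).

    Each tissue's mean Ct stands in for the (undeposited) replicate-level
    measurements, with the tissue label doubling as the sample identifier.
    """
    df = load_schima_tissue_stats()
    out = pd.DataFrame(
        {
            "gene": df["gene"],
            "sample": df["tissue"],
            "tissue": df["tissue"],
            "replicate": 1,
            "ct": df["mean_ct"],
        }
    )
    return CtTable(out[list(LONG_COLUMNS)])


def load_schima_summary() -> TissueSummary:
    """TissueSummary carrying the published per-tissue means and SDs (n = 3).

    Unlike :func:`refstab.ct_model.summarize` on :func:`load_schima_ct`
    (which would see a single value per tissue and no within-tissue SD),
    this uses the published replicate SDs, so tissue-specific selection
    rules that need within-tissue dispersion can run on the real data.
    """
    df = load_schima_tissue_stats()
    per_tissue = df.rename(columns={})[["gene", "tissue", "mean_ct", "sd_ct", "n"]].copy()
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


def load_published_overall() -> pd.DataFrame:
    """The survey's published per-gene Average/Min/Max/Range Ct columns, by gene."""
    return _read("schima_overall_published.tsv").set_index("gene")


def load_published_bestkeeper() -> pd.DataFrame:
    """The study's published BestKeeper table, indexed by gene."""
    return _read("schima_bestkeeper_published.tsv").set_index("gene")


def load_published_consensus() -> pd.DataFrame:
    """The study's published per-method ranks and consensus, indexed by gene.

    Columns genorm / normfinder / bestkeeper are the per-method ranks;
    geo_mean_rank and combined_rank are the published consensus columns.
    """
    return _read("schima_consensus_published.tsv").set_index("gene")
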