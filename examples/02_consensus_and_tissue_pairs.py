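"""Consensus arithmetic on published per-method ranks, plus tissue pairs.

The geometric-mean consensus can run on any gene x method rank table.
Here it reruns on the survey's own published geNorm / NormFinder /
BestKeeper rank columns, reproducing the published comprehensive ranking
exactly, and then the per-tissue rule (mean Ct in 20-25, lowest
within-tissue SD) picks a gene pair for each tissue.
"""

from refstab import datasets, geometric_mean_rank, select_combination, select_tissue_pair

pub = datasets.load_published_consensus()
cons = geometric_mean_rank(pub[["genorm", "normfinder", "bestkeeper"]])

agree = int((cons.table["combined_rank"] == pub["combined_rank"]).sum())
print(f"combined ranking matches the published column for {agree}/19 genes")
print(f"SsuACT geometric-mean rank: {cons.table.loc['SsuACT', 'geo_mean_rank']:.2f}")
print(f"best combination of 2: {select_combination(cons, 2)}")

summary = datasets.load_schima_summary()
print("\nper-tissue pairs (moderate Ct window 20-25, lowest SD):")
for tissue in summary.per_tissue["tissue"].unique():
    pair = select_tissue_pair(summary, tissue)
    sds = ", ".join(f"{g} (SD {pair.criterion.at[g, 'sd_ct']:.3f})" for g in pair.pair)
    print(f"  {tissue:7s} -> {sds}")
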