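"""Why the reference choice matters: 2^-ddCt under stable vs unstable genes.

Normalizes one gene's expression across the six survey tissues against
three reference sets.  Stable references (SsuACT, SsuACT+SsuRIB) give
near-identical fold-change profiles.  The unstable SsuCas (its fruit Ct
sits ~10 cycles above its other tissues) inflates the fruit fold change
three orders of magnitude.  Note the concordance score compares sample
*rankings* (Spearman), which is deliberately conservative: here SsuCas
distorts magnitudes while mostly preserving order, so the distortion
shows up in the fold changes themselves rather than in the flag — on
targets whose sample ordering gets scrambled (see the noisy-reference
test in the suite) the flag fires.
"""

import pandas as pd

from refstab import datasets, expression_profile

ct = datasets.load_schima_ct()
comp = expression_profile(
    ct,
    target="SsuMet2",
    reference_sets={
        "SsuACT": ["SsuACT"],
        "SsuACT+SsuRIB": ["SsuACT", "SsuRIB"],
        "SsuCas": ["SsuCas"],
    },
    calibrator="bud",
)

profiles = pd.DataFrame({label: r.rel_expr for label, r in comp.results.items()})
print("relative expression of SsuMet2 (fold change vs bud):")
print(profiles.round(3).to_string())

fruit = profiles.loc["fruit"]
print(f"\nfruit fold change: {fruit['SsuACT+SsuRIB']:.2f} under SsuACT+SsuRIB "
      f"but {fruit['SsuCas']:.0f} under SsuCas — a "
      f"{fruit['SsuCas'] / fruit['SsuACT+SsuRIB']:.0f}-fold normalization artifact")
print("\nSpearman concordance with the consensus profile (rank-based):")
print(comp.consensus_corr.round(3).to_string())
print(f"flagged for rank scrambling (concordance < {comp.threshold}): {comp.flagged or 'none'}")
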