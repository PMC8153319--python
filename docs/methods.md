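# Methods

This note records the models implemented in `refstab`, the estimators and
numerical conventions chosen where the literature leaves room, and what the
synthetic-data tests do and do not establish.

## Data model and replicate collapsing

Ct values are stored long form as (gene, sample, tissue, replicate) → Ct,
validated to be finite, positive and unique per (gene, sample). All three
stability methods assume a complete gene × sample matrix; missing cells are
a hard error by default, with an opt-in `on_incomplete="drop"` that removes
the offending gene with a warning.

Before stability analysis, replicates are averaged to one value per
(gene, tissue) (arithmetic mean on the Ct scale; within-tissue SD uses the
n−1 denominator). This matches how the packaged survey's own published
analyses were run: the per-gene minima, maxima and means in its published
BestKeeper table equal the six per-tissue mean Ct values exactly, showing
the programs received tissue means, not replicates. Per-gene overall
statistics (mean, min, max, range) are computed over the tissue means, so
tissues weigh equally regardless of replication depth. A
`collapse=False` path analyzes replicate-level samples instead.

The Ct-range flag (default threshold 4 cycles, i.e. a >16-fold swing
between the most and least expressing tissue) is a pre-model screen: genes
above it are reported as unstable before any scoring.

## Relative quantities

geNorm and NormFinder operate on relative quantities
`q_ij = base^(−ΔCt_ij)` with `ΔCt_ij = Ct_ij − min_j Ct_ij`, so the most
expressed sample of each gene has q = 1. The anchor is cosmetic: both
methods are exactly invariant to per-gene scaling (a required property
test). The default base is exactly 2 (perfect doubling per cycle); an
efficiency-corrected mode uses per-gene bases 1 + E from standard-curve
fits (`E% = (10^(−1/slope) − 1)·100`, ordinary least squares of Ct on
log10 input, R² = squared Pearson correlation).

## geNorm

`V_jk` is the n−1 standard deviation over samples of `log2(q_j/q_k)`;
`M_j` is the mean of `V_jk` over k ≠ j. Ranking proceeds by repeatedly
removing the gene with the highest M until two remain; the survivors are
tied at dense rank 1 (their relative order is undefined because V is
symmetric), and the exclusion order fills ranks 2, 3, …, k−1. Exact ties
in the maximum M (measure zero on real data) remove the lexicographically
last name and log a warning.

`V_{n/n+1}` is the SD over samples of `log2(NF_n/NF_{n+1})`, where `NF_n`
is the per-sample geometric mean of the top-n genes' quantities in ranking
order. The optimal count is the smallest n with `V < 0.15` (threshold
configurable); if none qualifies the full panel size is returned with a
flag rather than an error. On the packaged survey, V2/3 = 0.101 and only
the final step (adding the worst gene) exceeds 0.15.

The iterative engine is pinned to a brute-force double-loop oracle to
1e−12 on random matrices.

## NormFinder

Log2 quantities follow a two-way additive model
`x_ij = α_i + β_j + ε_ij`, `Var(ε_ij) = σ_i²`. Double-centered residuals
give per-gene naive variances `s_i² = Σ_j r_ij²/(n−1)`. Under the model

    E[s_i²] = σ_i² (k−2)/k + S/k²,   S = Σ_i σ_i²,

an identity verified numerically in the suite before anything else relies
on it. Solving it yields the bias-corrected estimator

    σ̂_i² = (s_i² − T/(k(k−1))) · k/(k−2),   T = Σ_i s_i²,

which is exactly unbiased (Monte-Carlo check: 10 genes × 50 samples ×
500 replicates, planted σ from 0.1 to 1.0, max relative bias of the mean
a few percent). The algebraic identity `Σ σ̂_i² = T·k/(k−1)` holds to
1e−9 pre-truncation and is asserted.

The reported stability is `ρ_i = sqrt(max(0, σ̂_i²))`. Truncation at zero
is necessary for the square root but biases the truncated estimator upward
for genes whose true variance is near zero; the result therefore carries
both `variance_raw` (possibly slightly negative) for calibration work and
the truncated `stability` for ranking. Ties at ρ = 0 rank by gene name
for determinism. The estimator needs k ≥ 3 genes and n ≥ 2 samples.

The grouped variant applies the same machinery within each group to get
`σ̂²_ig`, computes intergroup deviations `d_ig` by double-centering the
gene × group mean matrix, shrinks them by
`d̃_ig = d_ig · γ̂²/(γ̂² + σ̂²_ig/n_g)` with
`γ̂² = max(0, Var(d) − mean(σ̂²/n_g))`, and scores
`ρ_i = mean_g(|d̃_ig| + sqrt(σ̂²_ig/n_g))`. When `γ̂² + σ̂²_ig/n_g = 0`
(no interaction evidence and a truncated variance) the shrinkage factor is
defined as 0, i.e. full shrinkage. Each group needs ≥ 2 samples. The
default analysis mode is ungrouped on the collapsed tissue-mean matrix —
with one representative value per tissue there are no groups to model;
grouped mode is intended for replicate-level runs with tissues (or
treatments) as groups.

## BestKeeper

BestKeeper works on raw Ct. Its "SD" is the mean absolute deviation
around the arithmetic mean and its CV is that SD as a percentage of the
arithmetic mean — not the classical n−1 SD. This convention was
established by recomputation against the packaged survey's published
table: the MAD reproduces every printed SD (e.g. 0.70/3.25% for SsuACT,
0.4625/2.30% for SsuGAPDH, 3.22/13.6% for SsuCas) while the classical SD
does not, and dividing CV by the geometric mean instead of the arithmetic
mean breaks the match in the second decimal. The BestKeeper index is the
per-sample geometric mean of Ct over all candidates (configurable subset;
the historical 10-gene cap of the original spreadsheet tool is not
imposed), and each gene's r is its Pearson correlation with the index,
with a two-sided t-test p at n−2 degrees of freedom. A zero-variance gene
gets an undefined (NaN) r and is ranked last within its SD class rather
than erroring.

The composite ranking — genes with SD ≤ 1 cycle ordered by descending r
(ties: smaller SD, then name), followed by SD > 1 genes ordered by
ascending SD — is reverse-engineered from the packaged survey's published
tables, where a gene with r = 0.926 still ranks 18th because its SD
exceeds 1. Applied to the survey's own published statistics the rule
reproduces its published ranking column for all 19 genes, and applied to
the recomputed statistics it reproduces the five-gene SD > 1 tail exactly.

Unlike geNorm and NormFinder, BestKeeper is *not* invariant to per-sample
Ct shifts: it scores absolute Ct dispersion, so shared run-to-run effects
land in every gene's SD and in the index. That is a property of the
method, not of this implementation; the suite asserts shift invariance
for the two model-based methods and only global-shift invariance for
BestKeeper.

## Consensus and selection

The comprehensive ranking takes, per gene, the geometric mean of its
method ranks (input ties, such as geNorm's two rank-1 genes, enter
as-is) and re-ranks ascending; ties break by the gene's best single-method
rank, then by name. Scores are kept at full precision and rounded only
for display. The best combination for general use is the top genes of the
combined ranking, taken to geNorm's optimal count.

For single-tissue work the selection rule is empirical: restrict to genes
whose within-tissue mean Ct lies in a closed moderate window (20–25 cycles
by default — well detected but far from saturation) and take the two with
the smallest within-tissue SD, breaking ties by distance of the mean to
the window midpoint, then by name. On the packaged survey this reproduces
the published pairs for leaf, bud and xylem. For fruit, phloem and root
the published pairs deviate from this stated rule (one published pick has
a mean of 25.655, outside the window; another passes over a marginally
smaller SD), so for those tissues the implementation follows the rule and
documents the divergence rather than matching the published choice.

## Relative expression and cross-set concordance

`ΔCt(sample) = Ct_target − mean(Ct_references)`; averaging reference Ct
values equals dividing by the geometric-mean normalization factor on the
linear scale (asserted numerically, including the degenerate case of a
duplicated reference). `ΔΔCt` subtracts the calibrator sample's ΔCt, so
the calibrator's fold change is exactly 1; when no calibrator is named,
the sample with the highest relative target expression is used. The
efficiency-corrected mode substitutes per-gene bases 1 + E.

Profiles computed under different reference sets are compared by Spearman
correlation of the per-sample log2 fold changes; each set is also
correlated against the element-wise median profile (the consensus), and
sets below a threshold are flagged. The default threshold is 0.9:
legitimate stable normalizers differ only by small noise, so their
profiles should agree in rank almost perfectly (with six samples, 0.9
tolerates a single adjacent transposition). Rank-based concordance is
deliberately conservative — a distorted normalizer that inflates
magnitudes while preserving sample order (as the packaged survey's worst
gene does on some targets) shows up in the fold changes, not the flag.

## Synthetic data

The generator draws `Ct_igj = μ_i + b_gj + δ_ig + ε_igj` with gene
baselines μ uniform on a window (default 18–26 cycles, the span seen in
real multi-tissue panels), per-sample effects b shared across genes
(default SD 1.0 cycle, comparable to the tissue-level shifts in the
packaged survey), gene × tissue instability `δ_ig ~ N(0, τ_i²)` and
replicate noise `ε ~ N(0, σ_i²)`. Normal noise on the Ct scale is
multiplicative on expression, matching the log-scale models. Ground truth
is the ordering by total instability `sqrt(τ² + σ²)`. One integer seed
drives a single private `numpy` Generator; the same seed reproduces the
dataset bit for bit.

The default scenario mirrors a multi-tissue survey: 19 genes, 6 tissues,
3 replicates, stable genes at τ = 0.5 / σ = 0.4 cycles (consistent with
the residual dispersion of the packaged survey's stable candidates) and
two planted unstable genes at τ = 2.5 cycles. Recovery under this
scenario (200 seeds): the planted pair occupies the two worst ranks in
~96% of runs under geNorm and NormFinder, but only ~89% under BestKeeper,
which cannot remove the shared sample effects and sees just six collapsed
values per gene — an expected consequence of its design, reported as
such.

What the generator does not emulate: amplification-efficiency differences
between genes (unless bases are supplied), plate/position effects, melt
artifacts, heteroscedasticity of Ct noise with abundance, or missingness.
Passing recovery tests therefore demonstrates correct estimation under
the methods' own model class, not robustness to those real-world effects.

Simulation-based tests use scenarios designed for statistical power of
the correctness claim being tested (e.g. the grouped-NormFinder ordering
test uses a well-separated σ ladder of 0.2/0.5/1.0 with 40 samples per
group; the concordance-flagging test uses a 2.5-cycle target span against
2-cycle reference noise) and fixed seed ranges, so they are deterministic.
Problem sizes (200 simulation seeds, 500 Monte-Carlo replicates, panels of
up to 19 genes) were chosen to keep the full suite fast while leaving the
binomial/Monte-Carlo margins comfortable.

## Known limitations

- The packaged survey's published NormFinder rank column cannot be fully
  re-derived from the shipped tissue means: the original program ran on
  replicate-level measurements that were never deposited. The recomputed
  ungrouped ranking agrees at the unstable end (the worst gene matches,
  by a wide margin) but the published top gene differs from the recomputed
  one — with six values per gene, the top of the ranking is simply not
  identifiable to that precision. The same applies to the published
  BestKeeper r column, whose generating index cannot be reconstructed
  (its p-values show it was computed on the six tissue means, but no
  candidate index reproduces the printed correlations); descriptive
  columns reproduce to print precision.
- Dense geNorm ranks leave the top pair unordered by construction.
- BestKeeper's p-values here come from the t distribution; the original
  tool's may not.
- The expression concordance flag compares rankings, not magnitudes (see
  above).
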