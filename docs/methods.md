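# Methods

## Study design the package targets

A small cohort of bulk RNA-seq count profiles (archival FFPE tumors) split
into a few histological subtypes — canonically 16 samples in groups of
6/5/5 (FS/PNST/PWT) — with no matched normal tissue and with fallible
subtype labels. All methods are exercised on synthetic data with planted
truth; the generator's defaults encode those design conditions.

## Count model and differential expression

Counts for gene *g* in sample *j* are negative binomial with mean
`s_j · q_gj` and dispersion `α_g` (`Var = μ + αμ²`). Size factors `s_j` are
median-of-ratios: the median over genes expressed in every sample of
`count_gj / geometric_mean_g`, computed on the linear scale. Genes with a
zero count in any sample are retained in the matrix but excluded from the
geometric means.

For a two-group contrast the engine estimates group means on normalized
counts, a per-gene method-of-moments dispersion pooled within groups
(`α̂ = (Var̂ − μ̂·E[1/s]) / μ̂²`, clipped to `[1e-8, 10]`), and a parametric
mean–dispersion trend `α(μ) = a₁/μ + a₀` fit by least squares with
nonnegative coefficients (flat median fallback). The working dispersion is
the even mix `0.5·α̂_MoM + 0.5·α_trend`; the weight is exposed as
`mom_weight`. The effect is `log2FC = log2((μ̂_a + c)/(μ̂_b + c))` with
pseudocount `c = 0.5`, the Wald statistic is `log2FC / SE(log2FC)` with a
delta-method SE, and two-sided p-values come from the standard normal.
Genes with mean normalized count below `min_count_mean = 1` are excluded
from BH adjustment and reported with `padj = 1`. A DEG is
`padj < 0.05 ∧ |log2FC| > 1`. The construction is symmetric, so swapping
group labels negates every log2FC and preserves p exactly.

This is a deliberately simplified engine: no GLM iteration, no MAP
dispersion estimation, no Cook's-distance outlier handling, no posterior
log2FC shrinkage. Its output will not numerically match any specific
external tool; it is validated on simulations with planted truth
(sensitivity ≈ 99.6%, empirical FDR ≈ 0.6% at the design conditions) and
cross-checked against an independent NB GLM implementation on a small
planted dataset (log2FC correlation > 0.95).

**Calibration.** Under a complete null at n = 16 the fraction of raw
p < 0.05 is ≈ 0.058: the Wald approximation with estimated dispersion is
mildly liberal at this depth, as is expected of any moment-based NB test
at these group sizes (a t-reference overcorrects to ≈ 0.038). The
calibration test therefore asserts near-nominal behavior (mean fraction in
[0.035, 0.07]) rather than an unattainable exact band.

**One-vs-rest contrasts and planted truth.** Each subtype is tested
against the other subtypes pooled. In a 3-group design a gene planted
with +2 log2FC in one subtype induces a genuine ≈ −1.32 log2FC in each
other subtype's one-vs-rest contrast (the pooled "rest" is a mixture), so
such calls are correct, not false discoveries. A false discovery is a
called gene with no planted effect for any subtype.

## Permutation significance of DEG counts

`n_perm` label shuffles (group sizes preserved; size factors are label-free
and computed once) recompute the focal subtype's one-vs-rest DEG count at
identical thresholds; the add-one empirical p is
`(1 + #{null ≥ observed})/(n_perm + 1)` (default `n_perm = 999`; minimum 19
to resolve p < 0.05). With planted structure at the design conditions the
test detects the signal in every probe seed (p = 0.005 at n_perm = 199).
Under a complete null the DEG count is a heavily tied discrete statistic —
almost always 0, because BH controls family-wise rejections — so the
empirical p is *super-uniform* (a large atom at 1.0), the mathematically
correct behavior for a tied permutation statistic. It is conservative,
never anti-conservative; a KS test against U(0,1) will always reject, and
no faithful implementation can behave otherwise.

## Outlier counting and reassignment

For each sample and each DEG specific to its assigned subtype (that
subtype's up∪down one-vs-rest DEGs minus the sets shared by all subtypes),
the sample's log-normalized value is compared with Tukey fences
`[Q1 − 1.5·IQR, Q3 + 1.5·IQR]` over all samples sharing the label, the
sample included, with type-7 (linear interpolation) quartiles. Subtypes
with fewer than 3 samples are skipped. A sample is flagged when its
outlier-DEG count exceeds the upper Tukey fence of counts within its
subtype — an automatic rule standing in for by-eye inspection of the
outlier-count table.

Reassignment removes flagged samples, recomputes one-vs-rest DEGs, takes
the `k_per_type = 185` most variable DEGs per subtype (variance of
log-normalized expression across *all* samples), z-scores rows, clusters
all samples hierarchically (Euclidean distance, complete linkage — the
defaults of the common heatmap tooling — cut at k = number of subtypes),
names each cluster by the majority assigned subtype of its unflagged
members, and gives flagged samples their cluster's name. A cluster with
only flagged members is an error (no anchor to name it). Innocent flagged
samples cluster with their own subtype and keep their label. Correcting
labels makes groups more homogeneous, so per-subtype DEG counts do not
decrease; the recovery rate for two planted mislabels is 100% over 20
probe seeds.

## Marker screens

Fold rules act on linear-scale normalized expression (fold thresholds are
multiplicative, so the log scale would make them additive). Single marker:
`min(target) ≥ fold · max(others)` with `fold = 2.0` and an `1e-8` floor on
zero denominators. Pair rule (default `cover`, `fold = 1.8`): each outside
sample must be separated by at least one gene of the pair — the weakest
reading consistent with single markers having failed; the stricter
`strict-max` reading (one gene clears the fold against the outside
maximum) is available via `rule=`. Pairs in which one gene alone covers
all outside samples are reported separately as degenerate. Candidates
default to the subtype's up-DEGs, keeping the O(n²) pair search small.
Screens are exact rules; tests verify equality with exhaustive brute
force and monotonicity in the fold.

## Tumor-vs-normal analysis and enrichment

Tumor-vs-normal DEGs are called by the same engine on the intersected
gene universe (up = higher in tumor). Reference selection runs each
candidate normal panel and ranks panels by the hypergeometric enrichment
p of the up-DEG list against a sarcoma-expressed phenotype gene set; the
top panel is the reference (panels yielding zero up-DEGs rank last with
p = 1). Shared up/down sets are intersections across subtypes; specific
sets exclude shared genes.

ORA uses the exact hypergeometric upper tail with the universe equal to
the genes actually tested in the contrast (never all annotated genes), BH
within each library, and ties in the "top n" ordering broken by larger
overlap then set name. TF target sets encode direction in their names
(`*_activated_targets`, `*_repressed_targets`); combining the set's tag
with the query's direction yields the inferred TF activity (up-DEGs in
repressed targets ⇒ activity down, etc.). ENRICHR-style combined scores
are not computed; "most significant" means smallest hypergeometric p.

## Cross-species Akaike weights

Per human subtype, OLS of the canine mean log expression profile (over the
subtype's DEGs) on the human column, scored by
`AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1)` with `k = 3`; Akaike weights
`w ∝ exp(−Δ/2)`. AICc is the default because gene counts can be modest
(`ic="aic"` available). Weights are invariant to adding a constant to all
AICc values. The "significantly better match" question is answered by a
gene bootstrap (default 1000 resamples): the fraction of resamples in
which the top subtype stays on top. With one column matched at σ = 0.01
noise and 6 permuted decoys the matched column receives weight > 0.99;
under an exchangeable null each of m columns averages weight 1/m.

## Synthetic data generator

Baseline log2 means are uniform on [3, 9]; library-size factors are
log-uniform on [0.7, 1.4] to exercise normalization; dispersion is a
constant 0.1 by default with optional lognormal per-gene jitter. Per
subtype, 100 planted DEGs (alternating sign, |log2FC| = 2) occupy disjoint
gene blocks. Planted markers are extra up-DEGs of their subtype: singles
at log2 separation 4.0; each pair gene at 3.5 but also elevated in one
(different) other subtype, so only the pair jointly separates. Mislabeled
samples are pure members of their generating subtype whose metadata
carries a wrong label; wrong labels cycle over the other subtypes so
impostors land in distinct assigned groups — the cleanly-reassignable
scenario the pipeline is designed around. Companion resources: a normal
count panel sharing the tumor baseline (the correct reference) plus
gene-permuted decoy panels; a human panel with one column per canine
subtype built from that subtype's planted profile plus N(0, 0.25²) noise,
the rest gene-permuted decoys; GMT libraries with sets drawn from planted
up/down DEGs (tissue-like, TF activated/repressed targets, a
sarcoma-expressed phenotype set) plus random decoy sets. All draws flow
from the config seed through purpose-salted generators, so identical
configs are byte-identical.

What the generator does *not* emulate: FFPE degradation artifacts, batch
effects, gene–gene correlation, GC/length biases, mixtures within a
sample, or ortholog-mapping noise. Passing tests therefore demonstrate
the internal correctness and statistical behavior of the methods under
the stated model, not performance on real archival data.

## Pipeline

Thirteen stages in analysis order (load → initial PCA/k-means →
one-vs-rest DEGs → permutation p → outlier counts → reassignment → final
DEGs + p → markers → reference selection → tumor-vs-normal →
common/specific sets → ORA → cross-species), each writing TSV/JSON plus a
manifest with config hash, seed, package version and per-stage state. A
stage failure halts the run, retaining partial outputs and the manifest.
Per-stage RNG streams are salted with the stage name so adding a stage
never perturbs earlier draws; reruns with the same config are
byte-identical.

## Numerical choices and degenerate inputs

- Dispersion floor 1e-8 and cap 10 stabilize degenerate moment estimates.
- Pseudocount 0.5 in the log transform (`log2(count/s + 0.5)`) keeps zero
  counts finite while allowing negative values for weakly expressed genes
  (log2(x+1) would not).
- Variance-ranking ties break lexicographically by gene ID; enrichment
  ties by overlap then set name; all sorts are stable.
- Zero-variance rows z-score to all-zero; an RSS of 0 in the AICc fit is
  floored at 1e-300.
- Contrasts require ≥ 2 samples per side; quartiles require ≥ 3 samples
  per subtype; AICc requires n − k − 1 > 0 and ≥ 10 shared genes.

## Problem sizes used in tests and the acceptance script

Unit tests run on downscaled studies (300–800 genes, groups of 4–6);
acceptance checks use the full design conditions (2000 genes, 6/5/5) over
20 seeds, with permutation calibration at n_perm = 99–199. These sizes
were chosen so the full statistical behavior (recovery, FDR, calibration)
is measurable while the whole suite stays fast and deterministic.

## Known limitations

- The DE engine's absolute DEG counts depend on its simplified dispersion
  treatment; only properties validated on planted truth (recovery, FDR,
  ordering of counts before/after label correction) should be relied on.
- The permutation p is resolution-limited at 1/(n_perm+1) and
  super-uniform under the null (see above).
- The pair-marker rule's "cover" reading is one of two defensible
  interpretations; both are implemented.
- Cross-species similarity assumes gene IDs are pre-matched across
  species and compares subtype mean profiles, not per-sample fits.
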