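# Methods

## Data model

Input is one tab-delimited table per sample: binned intra-chromosomal
locus pairs (`chr1 start1 end1 chr2 start2 end2 count qvalue`) at a fixed
bin size (default 5 kb), with the loop caller's per-pair FDR in `qvalue`.
Coordinates are treated as 0-based half-open throughout; a loop's key is
`(chrom, start1, start2)` with `start1 < start2` enforced on read, and its
genomic distance is `start2 − start1`. Upstream callers do not document
their coordinate base consistently; the 0-based choice here is a
convention, not an inference. Inter-chromosomal rows are dropped at read
time (the model covers the 10 kb–3 Mb intra-chromosomal range), with the
dropped count logged. A missing `qvalue` column is accepted (q = 0
everywhere) with a warning, because the filtered background and the
per-sample significance filter then degenerate.

The cross-sample count matrix is the union of keys over all samples; a
pair absent from one sample's table gets count 0 and q = 1 there. Two
backgrounds feed the tests: **A** (the full union) and **F** (pairs with
q strictly below `t_bg`, default 0.1, in ≥ 1 sample). Strict `<` is used
at every threshold in the package.

## Negative-binomial engine

Counts are modelled as NB with mean `μ` and dispersion `φ`
(variance `μ + φμ²`); `φ → 0` falls back to dedicated Poisson branches.
Fractional values (pseudo-counts) are supported through the gamma-function
extension of the NB pmf.

**Normalization.** `median_of_ratios` (DESeq-style size factors over rows
nonzero in every sample, rescaled by the geometric-mean library size;
falls back to library size with a warning when no such row exists), `tmm`
(trimmed mean of M-values: 30% trim on M, 5% on A, reference sample by
closest upper quartile, factors renormalized to geometric mean 1), or
plain `libsize`. All downstream formulas consume one vector of effective
library sizes.

**Dispersion.** The two-group NB GLM is saturated per condition, so each
fit reduces to a Newton iteration on the per-group log-mean with offsets
`log(effective libsize)` (score `Σ(y−μ)/(1+φμ)`, observed information
`Σμ(1+φy)/(1+φμ)²`). The common dispersion maximizes the Cox–Reid
adjusted profile likelihood (per-loop likelihood minus
`½ log det(XᵀWX)`, which for this design is `½[log Σ w_A + log Σ w_B]`)
summed over loops, on a log grid over [1e-4, 4] followed by bounded
golden-section refinement to 1e-6. Tagwise dispersions maximize the
weighted likelihood `APL_g(φ) + prior_df · meanAPL(φ)` on the same grid,
shrinking each loop toward the common value.

`prior_df` defaults to 40. This is deliberately strong: with weak
shrinkage, loops whose replicates happen to agree closely within both
groups slide to near-zero dispersion, and a modest between-group
difference then yields a genome-wide-significant p-value. On replicate-
permutation null data this inflated the false-discovery proportion; at
`prior_df = 40` the per-loop estimates track the common value unless the
data clearly demand otherwise, and the null calibration matches what the
Bioconductor reference implementations produce on the same matrices.
Trended (abundance-dependent) dispersion is not implemented; tagwise
shrinkage toward the global common value is the documented simplification.

**Exact test.** Counts are scaled to the common effective library size
(geometric mean), giving fractional pseudo-counts. Under the null the two
group sums follow NB laws with means `n_g·μ₀` and dispersions `φ/n_g`
(`μ₀` = total/total-replicates). Conditioning on the observed total, the
two-sided p-value sums the probabilities of all outcomes on the unit-step
grid through the observed group-A sum whose probability does not exceed
the observed one (ties included), normalized over the grid — for integer
inputs this is the exact conditional enumeration. The reported log2 fold
change uses normalized condition means with a 0.5 prior count per group,
which keeps zero-count groups finite.

**GLM tests.** LRT: deviance difference of nested fits against χ²(1).
QLF: per-loop quasi-dispersion `s² = residual deviance / residual df`,
moderated by a scaled-inverse-χ² empirical-Bayes squeeze whose prior df
and location come from log-scale moment matching (trigamma inversion by
Newton); the moderated F statistic is referred to `F(1, df_resid + d₀)`
(χ²(1) when `d₀ = ∞`). The QLF's NB fits use the **common** dispersion —
loop-wise variability belongs in the quasi-dispersion it squeezes, and
feeding tagwise NB dispersions into it would count that variability
twice. Wald: the fitted condition coefficient over its standard error
from the observed Fisher information, two-sided normal. Non-converged
fits are never dropped: the row is flagged and reported with p = 1.
Designs with one replicate in either condition refuse the GLM tests with
an instructive error; a 1-vs-1 design routes to the exact test with a
fixed dispersion, default φ = 0.16 (biological CV 0.4), configurable.

**Covariates.** `logCPM` (mean over samples of
`log2((y+0.5)/(L+1)·10⁶)`) accompanies the exact and GLM tests; the Wald
mode carries `baseMean` (mean size-factor-normalized count). These are
the inputs to covariate-weighted FDR control.

## Multiple-testing control

`bh_adjust` is the standard step-up adjustment (implemented directly; the
test suite checks it against statsmodels to 1e-12).

`ihw_adjust` re-implements independent hypothesis weighting as
cross-fitted grid-search weighted BH rather than the original
convex-optimization machinery. Hypotheses are split into `n_folds`
(default 5) seeded folds. For each fold, covariate quantile groups
(default 5) are formed on the other folds and per-group weights from the
grid {0, 0.25, …, 3} — renormalized to the budget `Σ w_g n_g = n`, ties
broken toward uniform — are chosen by coordinate ascent to maximize
weighted-BH discoveries at level `alpha` on those training folds. The
held-out fold's p-values are divided by their group's weight and all
hypotheses enter one pooled BH pass. Because each hypothesis's weight is
learned without its own p-value, FDR control is preserved; because the
budget is fixed, a power gain in one covariate stratum is paid for
elsewhere. Small inputs (< `n_folds·n_groups·5`) or constant covariates
fall back to plain BH, bit-identically. Genomic distance itself is
deliberately not used as the covariate; abundance (logCPM/baseMean) is.

`equal_occupancy_bins` sorts loops by distance onto a 10 kb lattice
within [10 kb, 3 Mb] and greedily accumulates contiguous lattice
intervals until each stratum holds at least `C/M` of the total contact
count (`M` = 300 by default); the trailing run forms the final stratum
even if under quota. `stratified_test` re-estimates normalization and
dispersion inside each stratum, applies the chosen test, pools all raw
p-values and BH-adjusts once, globally. Strata too small for the chosen
test fall back to the exact test with a fixed dispersion (logged). IHW on
top of stratification is rejected as a configuration error — the pooled
BH already spends the full error budget. Whether per-stratum models
should share a global dispersion is an open design point; per-stratum
estimation is used here so that long-range strata are not dominated by
the short-range majority.

## Differential calls and 1D anchors

A tested loop is differential iff `padj < f` and `|log2FC| > l` and its
minimum per-sample caller q-value is `< t_sig` (defaults 0.05 / 1 /
0.01; "log fold change" is log2 throughout). The sign of the fold change
(B over A) splits `up-in-B` from `up-in-A`. When per-condition ChIP
coverage is supplied, per-bin coverage is integerized and compared with
the single-replicate exact-test route, BH-adjusted across bins, and bins
with `padj < 0.05` are labelled 1D-differential; a differential loop with
both anchors 1D-non-differential is classed `3D-change`, otherwise
`1D-confounded`. HiChIP's own 1D coverage is never substituted for
missing ChIP data — anchors stay `unknown` instead, because HiChIP 1D
signal is itself contact-weighted.

## Evaluation suite

**KR balancing** finds `x > 0` with `x_i (Mx)_i` constant over nonzero
rows via the damped fixed point `x ← ½(x + 1/(Mx))`, falling back to
symmetric Sinkhorn scaling (`x ← √(x/(Mx))`); failure to reach the
tolerance (default 1e-6 on the max row-sum deviation) under both schemes
raises with the residual. **APA** averages the 11×11 pixel window (10 kb
pixels, center ±50 kb) over loops farther apart than 130 kb, skipping
edge-clipped windows with a logged count; the score is the center pixel
over the mean of the 2×2 corner block at row offsets {+2, +3} and column
offsets {−2, −3} — the in-window realization of "15–30 kb inward of each
anchor" at 10 kb resolution, where the boundary pixel covering 10–20 kb
is excluded (a convention; the region is not exactly derivable at this
pixel size). `d_AB = S_AA − S_AB` for loops up in A; the ideal direction
`S_AA ≥ S_AB` is reported, not enforced. **Overlap** matches two loops
when both anchor starts differ by at most the slack (5 kb = one bin;
slack 0 is exact identity). **Recovery** ranks calls by ascending padj,
then descending |log2FC|, then key, and reports the fraction of a
reference set (exact test, BH < 0.05, |log2FC| > 2) matched within the
top k. **The type-I harness** takes ≥ 4 replicates of one condition,
draws balanced unordered partitions (without replacement across distinct
partitions when there are enough, with replacement otherwise), runs the
full pipeline per partition and records discoveries; since every call is
false, the per-iteration FDP is `D/max(1, D)` and the mean over
iterations is the headline calibration number.

## Synthetic data

The generator emulates a FitHiChIP-style peak-to-all experiment on one
synthetic chromosome (default 20 Mb, 5 kb bins, 200 peak bins with 4×
1D bias plus mild lognormal per-bin wobble). Candidate pairs are all
peak-to-any-bin pairs within 10 kb–3 Mb. The background expectation is
`μ₀ ∝ d^(−α) · bias_i · bias_j` (α = 1), scaled to `depth` expected
contacts per replicate (default 50 000 — a desk-scale stand-in for the
per-region density of a deeply sequenced library). On top of the
background, `n_loops` (default 300) pairs sampled with probability
proportional to `μ₀` form focal loops enriched `loop_strength`-fold
(default 4×): these are the pairs a loop caller would flag, and without
them no pair could earn a small q-value, which would make the
"significant in ≥ 1 sample" filter vacuous. Planted differential effects
(`2^log2fc` multipliers on condition B) sit on loop pairs. Replicate
counts are NB(`μ·libfactor`, φ) with per-replicate library factors drawn
uniformly from [0.7, 1.3] and φ = 0.2 by default; per-sample q-values
are BH-adjusted upper-tail Poisson probabilities of the observed count
against the no-loop expectation — they reproduce the *ordering* a real
caller produces, not its statistics. Zero-count pairs are omitted from a
sample's table, as a caller's output would omit them. Matched
per-condition contact maps aggregate the same model to 10 kb and Poisson-
sample it; coverage tracks Poisson-sample the per-bin bias with optional
per-condition shifts on peak bins. One integer seed makes every artifact
byte-reproducible.

What the generator does **not** emulate: restriction-fragment effects,
TADs and compartment structure, trans contacts, replicate-specific
spatial biases, or the actual FitHiChIP spline background. Passing tests
therefore demonstrate the statistical engine's correctness and
calibration under the assumed NB/power-law model, not performance on any
particular real dataset.

## Problem sizes and test design

The packaged checks run at desk scale, chosen as the package's own study
conditions: the null-calibration harness uses 6 replicates (~100 000
union pairs) and 60 random 3-vs-3 splits; the parameter-recovery scenario
plants |log2FC| = 2 on 40 well-covered loop pairs (per-group mean count
≥ 100, 3 replicates per condition, dispersion 0.05 — a deeply sequenced,
low-variability comparison, since at biological CV ≈ 0.45 no method
recovers 2-fold changes from three replicates at genome-wide FDR); the
long-range power check plants |log2FC| = 3 on loop pairs in every
distance octile (depth 300 000, 3 replicates) and compares, summed over
10 seeds, how many planted loops beyond 400 kb IHW and BH each recover
at the same level. Oracles are independent implementations: scipy pmf
enumeration for the exact test, statsmodels for BH, closed-form Poisson
deviances for the φ = 0 GLM limit.

## Known limitations

* No trended dispersion and no independent filtering of low-count rows;
  extremely shallow data relies on the strong tagwise prior for
  calibration.
* The exact test's fractional-count extension normalizes over a unit-step
  grid; p-values under unequal library sizes are a continuous
  approximation of the integer-case conditional law.
* The IHW re-implementation optimizes discoveries over a coarse weight
  grid; it preserves the FDR-with-budget contract but will not reproduce
  the original's weights numerically.
* KR balancing densifies the map; intended for single-chromosome,
  band-limited matrices at 10 kb, not genome-wide sparse balancing.
* Anchor-level 1D classification assumes coverage on the looping
  resolution grid and integerizes it for the count model.
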