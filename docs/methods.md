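# Methods

## Co-expression scoring

A cell's NP co-expression count is the number of distinct
neuropeptide-list genes with raw count > 0. "Expressed" is strict
presence (any nonzero raw count): presence/absence is more conserved
across sequencing chemistries and depths than exact counts, which is
what makes the count usable as a cross-study proxy for NP transcript
load. The count is therefore invariant under any positive rescaling of
the expression values; by default the accompanying NP transcript sum
is taken on the same layer the caller provides (the normalized/log
layer in the pipeline, with presence still judged on raw counts via
`presence_matrix`).

Cells are stratified at fixed cut points — low [0, 1], mid [2, 5],
high [6, ∞) — exhaustively and mutually exclusively. The cut points
are parameters (`StratumScheme`) but the defaults are the analysis
constants used throughout.

QC keeps cells with 200–2500 expressed genes (inclusive) and a
mitochondrial fraction strictly below 5%. The mitochondrial fraction
comes from metadata when present, otherwise from genes with the `MT-`
prefix. CPM normalization scales each cell to 1e6 total counts;
all-zero cells are left zero and flagged rather than dropped silently.
Log transformation is log2(x + 1) everywhere.

## Rank statistics

**Stratum-proportion comparison.** The observational unit is the
donor: per-donor stratum proportions are compared between conditions
with a Wilcoxon rank-sum test. Pooling cells would pseudoreplicate
(cells within a donor are correlated), so donor-level is the default
and only unit. When both groups have ≤ 10 donors the p-value is
computed by full enumeration of all C(n_a+n_b, n_a) mid-rank splits
(this handles the ties that proportion data produce, which off-the-
shelf exact methods reject); larger groups use the normal
approximation with tie and continuity corrections.

**DGE.** Two-sided Wilcoxon rank-sum per gene on the log layer.
Before testing, genes must be detected in ≥ 10% of at least one group
and carry |ln fold change| ≥ 0.25, where the fold change is
ln((mean(delog A) + 1)/(mean(delog B) + 1)) — the documented defaults
of the standard single-cell toolkits, with every constant
configurable. BH FDR is applied across the genes surviving the
filters within one contrast (filter-then-test order). The exact
rank-sum distribution is used only when both groups have ≤ 50 cells
and the pooled values are tie-free; real cell-level contrasts always
take the corrected normal approximation. Pseudo-bulk aggregation is
deliberately not offered: with few donors it would cost most of the
power the cell-level test has.

**Spearman correlation** uses mid-ranks; p-values come from the t
approximation, or exact permutation for n ≤ 9.

**BH adjustment** delegates to `statsmodels.multipletests` and is
verified in the tests against a literal implementation of the step-up
definition.

## Hypergeometric overlap

P(X ≥ x) is computed via `scipy.stats.hypergeom.logsf` (log-gamma
internals), safe for ~20,000-gene universes. The default tail includes
the observed overlap ("as extreme or more extreme"); a `gt` tail that
excludes it — matching an upper-tail CDF call evaluated at the
observed quantile — is exposed, and for any interesting enrichment the
two agree to well past the decision threshold. Expected overlap is
k·m/(m+n) and fold enrichment x over that.

## Aging association

Bulk samples pass four conjunctive gates: complete age/sex/death
metadata; Hardy death score not 3 or 4; RIN strictly greater than 6
(the boundary at exactly 6 is excluded — the stricter of the two
plausible readings of the inclusion rule, with the gate logged per
criterion); age outside 20–29, since brain development continues into
the third decade. Decade age brackets are mapped to midpoints — rank
methods only need order. Missing values are explicit NA, never
sentinels, and a missing RIN fails the RIN gate.

Cumulative ADNP expression is the sum over ADNP genes of
log2(TPM + 1) (sum of logs; log of the summed TPM is available behind
a flag). Summing logs rewards breadth of expression across the ADNP
panel rather than letting one highly expressed gene dominate, which is
the intended "combined burden" reading.

The partial Spearman correlation is computed by rank residualization:
all variables (response, age, RIN as continuous, Hardy as ordinal) are
mid-rank transformed; response and age ranks are residualized on the
covariate ranks by least squares with intercept; the Pearson
correlation of the residuals is the partial rho, with a t test on
n − 2 − c degrees of freedom. This targets the same estimand as the
probability-scale-residual estimators in the conditional-association
literature but is closed-form and exactly testable (with zero
covariates it reduces to plain Spearman to machine precision). A free
permutation of the age residuals (≥ 10,000 draws) is available as the
robust p-value path. Regions with fewer than 20 retained samples are
skipped (the smallest real region of interest is ~3× that; the floor
is configurable).

## Regional abundance

Atlas clusters are classified AHNP when tagged with ≥ 6 ADNPs and
strictly fewer than 3 non-ADNP NPs (both bounds are parameters; the
defaults encode the published rule, inclusive on 6, exclusive on 3).
Tags outside the declared NP universe are logged and ignored. A
qualifying cluster contributes all its cells: classification operates
on cluster tags, not per-cell expression, so per-cell AHNP calling is
out of scope here.

Cells are attributed to dissections as total_cells × percentage/100.
Percentage sums above 100 (+1e−6) are an error naming the cluster;
shortfalls below 100 are left unattributed — the residual plausibly
lies in dissections the table does not list, and renormalizing would
inflate the listed ones. Estimates stay real-valued through summation
and are rounded half-up only at report time. Rankings are descending
with an alphabetical tie-break, so outputs are deterministic.

## Synthetic cohorts

The generators define the conditions under which the pipeline is
validated; all are pure functions of their parameter objects (seed
included).

**Single-cell.** Per-cell NP count ~ zero-inflated truncated
geometric: P(0) = 0.5, counts ≥ 1 geometric with success probability
0.35 truncated at the panel size. This reproduces a large zero mass
with a long right tail (published brain snRNA-seq sits between ~50%
and >70% zero-NP cells); under these defaults ~5–6% of control cells
are high (6+). The default cohort is 8 donors per condition × 600
cells (≥ 5,000 cells total, the regime for the calibration check),
with a 100-NP panel containing 11 ADNPs. Expressed NPs are chosen
ADNP-weighted (weight 5) for high cells; each draws 1 + NB counts with
mean 2·(1 + np_count) and dispersion 2, so the NP transcript sum grows
superlinearly in the count and the two are rank-correlated at ~0.99 —
comfortably in the >90–96% band reported across real datasets.
Depletion multiplies the probability that a high count survives in
affected conditions by (1 − 0.5), resampling resampled cells from the
conditional low/mid distribution so per-donor cell totals are fixed
and only the proportion signal moves. Ten background genes carry
planted 2-fold condition effects for DGE recovery checks.
`simulate_np_counts` is the count-level fast path (no expression
matrix); stratification and the proportion test depend only on
counts, so the power/type-I simulations use it.

**Aging.** Each region gets 103 samples (ages uniform on 30–79, RIN
uniform on 6.1–9.8, Hardy ∈ {0,1,2}); decline regions lose 0.04
log2-units of cumulative ADNP expression per year (spread evenly over
the 11 ADNPs) against per-gene Gaussian noise of sd 0.45. Those two
numbers put the population partial rho near −0.35, chosen from the
power analysis so a 103-sample region detects the decline ≥ 90% of
the time at α = 0.05 — the magnitude regime of the real per-region
correlations (−0.30 to −0.34). A configurable fraction of extra
samples violates each exclusion gate so the filters are exercised, and
the truth record lists them. RIN can optionally be confounded with
age.

**Annotation.** Planted AHNP clusters (two per region, integer cell
splits over that region's dissections, percentages derived from the
splits) hit each planted region total exactly. Three boundary decoys
probe the classification rule: exactly (6 ADNP, 2 non) → true,
(6, 3) → false, (5, 0) → false. Background clusters are low-tag and
include percentage shortfalls; optional tag noise adds symbols outside
the NP universe.

**What the generators do not emulate:** doublets, ambient RNA, batch
effects, realistic full-transcriptome covariance, donor-level random
effects in expression magnitude, or spatially correlated dissection
sampling. Passing tests show the statistical machinery recovers
planted effects of realistic size under clean sampling assumptions —
not that real datasets will show those effects.

## Numerical choices and degenerate inputs

Gene symbols are trimmed and upper-cased before any matching, because
curated NP lists merge publications with inconsistent casing;
duplicate features are a hard error by default (summing would silently
change co-expression counts), with an explicit keep-first policy flag.
Matrix Market orientation is inferred from sidecar lengths; a square
matrix with equal-length sidecars is refused without an explicit
orientation flag. Zero-variance inputs to correlations and
regressions raise rather than returning NaN. Exact rank-sum ties are
resolved with mid-ranks and an 1e−9 comparison tolerance. Result
tables have deterministic column and row order with floats at 6
significant digits.

## Problem sizes

The default test and simulation sizes — 9,600-cell cohorts, 200
replicates for power/type-I checks, 200,000-draw Monte-Carlo oracles —
were chosen as the smallest sizes at which the quantities being
checked are stable to well within their acceptance bands.

## Known limitations

* The partial Spearman differs in finite samples from
  probability-scale-residual estimators; with heavy ties on few
  distinct levels the two can diverge, and the permutation path is
  the recommended fallback there.
* Cell-level (pooled) alternatives to the donor-level proportion test
  are not offered; with correlated cells they test a different, and
  anti-conservative, null.
* The annotation reader implements one documented schema; real atlas
  files need a mapping step to it.
* Gene-ID harmonization across annotation releases is out of scope;
  matching is case-insensitive exact symbol equality.
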