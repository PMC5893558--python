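# Methods

## Statistical model

`conjfdr` looks for genetic variants shared between two complex traits
using only GWAS summary statistics. For each SNP and trait a Wald Z-score
is formed, `z = beta / se`, with two-sided p-value `p = 2 * Phi(-|z|)`.
After harmonization (SNP intersection, allele alignment to trait 1's
effect-allele orientation, removal of strand-ambiguous A/T and C/G pairs)
the per-trait Z-scores are optionally corrected for genomic inflation and
fed to the enrichment and FDR machinery.

### Conditional FDR

The conditional FDR of trait 1 given trait 2 is the empirical-Bayes
posterior probability that a SNP is null for trait 1 given that both
traits' p-values are at least as small as observed. With the null
proportion pi0 conservatively fixed at 1,

    cFDR(p1 | p2) = min(1, p1 / F_hat(p1 | p2 <= t2)),

where `F_hat` is the empirical CDF of trait-1 p-values among SNPs whose
trait-2 p-value falls below the conditioning threshold. Conditioning uses
cumulative strata (`p2 <= 1, 0.1, 0.01, 0.001` by default): a SNP is
evaluated in the smallest configured stratum that still contains its own
p2, which is what "as small or smaller" implies. Each SNP's cFDR is
computed from exact empirical counts over the observed p-values (a sort
plus binary search), not from grid interpolation; the exported lookup
grid (101 log-spaced p1 points down to the 1e-300 floor) is for
transparency and re-plotting only.

Three guards stabilize the tail behavior:

* **Minimum stratum size** (default 100 SNPs): a conditioning stratum
  smaller than this falls back to the next larger stratum, because an
  empirical CDF from a handful of points is noise.
* **Monotonicity enforcement**: within each stratum the cFDR values are
  replaced by their running minimum scanning from p1 = 1 downward, so a
  smaller observed p1 never receives a larger cFDR.
* **Tail handling**: observed p-values below the smallest grid point
  reuse the deepest available counts; no extrapolation is performed.

Under a fully null panel `F_hat(p1) ~ p1` and the ratio is ~1 for every
SNP — the estimator correctly reports that in an all-null panel any
discovery set is essentially all false. This conservatism is what drives
the zero-discovery behavior on null simulations.

### Conjunction FDR

The conjunction FDR — the posterior probability that a SNP is null for
either trait or both — is conservatively estimated as the maximum of the
two conditional FDRs, an exact identity enforced per SNP. Discoveries are
flagged at conjunction FDR < 0.05 by default. Because the maximum bounds
both conditionals from above, thresholding the conjunction statistic is
conservative relative to either one-directional analysis.

### Fold enrichment and TDR

Cross-trait enrichment is visualized as the ratio of conditional to
unconditional tail proportions of trait-A p-values,

    fold[s, g] = [#(pA<=10^-g, pB<=10^-s) / #(pB<=10^-s)] / [#(pA<=10^-g) / n],

on a -log10 grid from 0 to 7.3 in steps of 0.1 (capped just above the
genome-wide threshold p = 5e-8 to probe sub-threshold polygenic signal)
for conditioning strata -log10(pB) >= 0, 1, 2. The base stratum is
identically 1. The proportion-ratio form was chosen over a Q-Q quantile
shift; the curve's y-axis is labeled accordingly. Enrichment is
interpretable on the true-discovery-rate scale as `TDR ~ 1 - 1/fold`,
an interpretation aid only — thresholding always uses the conjunction FDR.

**Reliable cells.** A fold cell whose joint exceedance count is k has
multiplicative noise of roughly CV = 1/sqrt(k); with k < ~10 the cell is
O(1) noise and with k = 0 it is undefined. Cells with empty strata are
NaN-flagged in the curve, and summaries (`EnrichmentCurve.log2_fold`)
additionally mask cells below a minimum joint count, default 200, which
keeps the CV of the ratio under ~7.5%. Raw fold values and counts are
always emitted so users can apply their own rule. Note that fold
enrichment is a *relative* measure: it is bounded by 1/P(pA <= t), so a
panel in which nearly every SNP carries signal in both traits shows
*small* fold values even though absolute sharing is total — large folds
require sparse sharing against a mostly null background.

### Genomic control

Lambda is the median observed Z^2 divided by the chi-square(1 df) median
(0.4549364..., computed at run time from the quantile function, not
transcribed). Correction divides Z by sqrt(max(lambda, 1)); the clamp
means apparent deflation (lambda < 1) is never reversed into signal
amplification. The original analysis names the inflation-correction step
but delegates the procedure to external references; median-based genomic
control on all analysis SNPs (with an optional user-supplied control
subset mask) is this package's documented stand-in. LD-score-regression
intercepts are out of scope.

### Clumping and annotation

Significant SNPs are collapsed to one lead per LD block (smallest
conjunction FDR; ties by smaller p1, then lexicographic rsID). The
default block definition is a positional window merge (250 kb), chosen
because it needs no external reference panel; connected components of a
user-supplied pairwise r^2 table at r^2 >= 0.2 are available
(`method="r2_graph"`). Leads are annotated with the closest gene by
gene-body distance (not TSS), 0 when inside the gene, ties to the smaller
start coordinate; BED input (0-based half-open) and GFF3 (1-based
inclusive) are normalized internally to 1-based inclusive.

## Synthetic data generator

`simulate_panel` draws each SNP's causal class from a multinomial over
{null, trait1-only, trait2-only, pleiotropic} and adds a latent mean
effect on the Z scale, N(0, sigma^2) per affected trait; pleiotropic
effects are drawn jointly with correlation 0.8 across traits so shared
SNPs tend to be jointly extreme. Observed Z = (latent + noise) *
sqrt(lambda), with block-equicorrelated noise (`sqrt(1-rho)*e_i +
sqrt(rho)*b_block`, giving exact within-block correlation rho) and
per-trait inflation lambda. Defaults — 1e5 SNPs, 0.5% of SNPs in each
non-null class, effect SD 4, no LD, no inflation — are the conditions
under which the calibration properties quoted in the test suite hold.

What the generator does *not* emulate: realistic allele-frequency
spectra and per-study beta/se scales (effects live directly on the Z
scale; beta is emitted as z with se = 1), genotype-level LD structure
beyond block equicorrelation, sample overlap between cohorts, and
population-stratification patterns beyond a scalar lambda. Passing
calibration tests on these panels therefore demonstrates correctness of
the estimator under its own model assumptions, not robustness to the
full messiness of real consortium data — in particular, correlated
effective sample overlap can inflate the conditional CDF in ways the
simulator does not represent.

## Numerical choices

* p-values are floored at 1e-300 so chr17-scale associations (p ~ 1e-41)
  survive text round-trips; -log10(p) is capped correspondingly.
* Rows with p only (no beta/se/z) get |z| from the inverse normal
  survival function with sign +1 and an `unsigned` flag; the FDR
  machinery uses p only, so the sign is cosmetic.
* Duplicate SNP ids within a table keep the smallest-p record
  (deterministic; discovery inflation is handled downstream by clumping).
* Tied p-values are counted inclusively (<=) everywhere.
* Optional LD-aware estimation averages the conditional CDF over R
  random single-SNP-per-block prunings (seeded; default off) while still
  evaluating every SNP.
* All simulations and prunings consume `numpy.random.default_rng` seeds
  threaded through configs; repeated runs are byte-identical, and SVG
  output pins `svg.hashsalt` with date metadata stripped.

## Limitations

* pi0 = 1 makes the cFDR conservative by construction; no mixture-model
  or local-fdr refinement is attempted.
* The empirical CDF ignores LD-induced dependence unless pruning is
  enabled; p-value-level dependence from overlapping controls is not
  modeled.
* The expression module's "repeated measures across ages" is implemented
  as a two-way factorial ANOVA (genotype + age + interaction, Type II
  sums of squares) reporting the genotype main effect, because public
  transgenic-mouse expression series are cross-sectional per age
  (different animals per time point), making a true within-subject age
  factor impossible; with one age level it degenerates to one-way ANOVA.
* Computing r^2/D' from genotype panels, network analyses, and retrieval
  of real cohort data are out of scope.
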