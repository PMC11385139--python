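# Methods

## Scope

`grmpart` implements a genome-partitioned variance-component analysis for
quantitative traits: genomic relationship matrices (GRMs) built from
arbitrary variant subsets, restricted-maximum-likelihood (REML) fits of
one- and two-GRM mixed models for one or two traits, the derived
partitioned heritabilities, genetic correlations and relative
covariances, per-variant summaries that make subsets of very different
sizes comparable, and a six-parameter linkage-disequilibrium (LD)
characterization of each subset. A block-LD genotype/phenotype simulator
provides known-truth inputs for every stage.

## Models

All models use intercept-only fixed effects on de-regressed-proof-like
continuous phenotypes. With `G_s` the GRM of a variant subset and `G_c`
the GRM of the complementary ("chip-tagged") variants:

* **Single-GRM univariate**: `y = mu 1 + g + e`, `g ~ N(0, G sigma2_g)`,
  `e ~ N(0, I sigma2_e)`.
* **Two-GRM univariate**: `y = mu 1 + g_s + g_c + e` with independent
  `g_s ~ N(0, G_s sigma2_s)` and `g_c ~ N(0, G_c sigma2_c)`. The subset
  heritability is `h2_set = sigma2_s / (sigma2_s + sigma2_c + sigma2_e)`
  and `h2_chip` analogously; their sum is the total heritability.
* **Bivariate (one or two GRMs)**: each random term carries a symmetric
  2x2 trait block `[[v1, c12], [c12, v2]]`; the genetic correlation of a
  term is `r = c12 / sqrt(v1 v2)`. The residual covariance applies only
  to individuals observed for both traits.
* **Relative covariances**: each covariance term divided by the sum of
  the absolute values of all three covariance terms, so the three values
  keep their signs and their absolute values add to one.

Per-variant summaries divide subset-level estimates by the subset's
variant count; the across-trait value additionally divides the summed
per-trait `h2_set` by the number of traits. An estimate is flagged
significant when `|estimate| >= 2 SE` (the inclusive reading of a
two-standard-error rule).

## GRM estimator

The per-variant-standardized ("GCTA method 1") estimator:
`G_jk = (1/M) sum_m (x_jm - 2p_m)(x_km - 2p_m) / (2 p_m (1-p_m))`, with
allele frequencies always taken from the analysed sample. Missing
genotypes are mean-imputed per variant at load time (dosage `2p`). GRMs
are float64 in memory and stored in the GCTA binary dialect (float32
lower triangle), which moves REML components by well under 1e-4 on our
fixtures.

## REML algorithm

Record-stacked average-information (AI) REML:

* One record per observed trait value; individuals missing one trait
  contribute their other record (no listwise deletion), so per-trait
  record counts are preserved.
* Start values: each variance gets an equal share of the trait's
  phenotypic variance; each covariance gets half the observed phenotypic
  covariance split equally across terms. A nonzero covariance start
  matters because the EM update is multiplicative and cannot leave an
  exact zero.
* Three EM-REML warm-up iterations, then AI updates with a safeguarded
  line search: the AI system is solved with an escalating
  Levenberg-Marquardt ridge (ending at pure gradient ascent and finally
  single-coordinate ascent), the first trial step is capped at the
  phenotypic-variance scale, and steps are halved until the restricted
  likelihood does not decrease. Coordinate ascent is the only direction
  family that makes progress on the narrow likelihood ridge of boundary
  cases, e.g. two identical traits, where the restricted likelihood is
  unbounded as the genetic correlation approaches 1.
* Candidate parameter vectors whose V has a Cholesky-diagonal ratio
  below 1e-6 are treated as infeasible; this halts boundary cases just
  short of a singular V, after which out-of-range correlations are
  clamped to +/-1 and flagged downstream.
* Variance components dropping below the floor (1e-6 of the phenotypic
  variance) are pinned there but released as soon as their score turns
  positive; permanent pinning demonstrably loses the optimum on small
  two-GRM fixtures.
* Convergence requires both a relative log-likelihood change below 1e-8
  and a small predicted quasi-Newton gain; the AI matrix is not the
  exact Hessian, so the likelihood change alone can look converged while
  the score is still large. Non-convergence within 100 iterations is
  reported via a flag, never raised.
* SEs are square roots of the diagonal of the pseudo-inverse AI matrix
  at the optimum; the full inverse is kept for delta-method SEs of every
  ratio statistic.

The test suite cross-checks the whole fitter against an independent
implementation of the restricted log-likelihood (explicit V, `slogdet`,
explicit projection) maximized by derivative-free Nelder-Mead from
multiple starts, on family-structured fixtures (n <= 20) chosen so the
components are well identified; ill-conditioned random-marker GRMs at
n = 15 can make the restricted likelihood multimodal, which tests the
optimizers' basins rather than their correctness.

## Variant filtering and partitioning

Filters: sample MAF floor (default 0.05 for sequence-density panels,
0.01 for chip-density panels), DR2 imputation-quality floor (default
0.75), and removal of sex chromosomes. LD score of variant i is
`1 + sum r2(i, j)` over variants j within +/-50 kbp on the same
chromosome (inclusive boundary, self term exactly 1); the variant
density (VD) is the variant count in the same window including i. r2 is
the squared Pearson correlation of unphased dosages (composite LD, no
phasing). Quartile subsets are rank-based with genome-order
tie-breaking, giving group sizes differing by at most one; the lowest
MAF quartile is dropped by default, mirroring the practice of excluding
the least informative MAF stratum. Annotation subsets merge raw
annotation labels via a configurable category map; external discovery
subsets (QTL lists, conservation scores, selection signatures and the
like) enter only as variant-id membership lists intersected with the
variant table.

## LD metrics

Every subset variant is paired with every other variant within
+/-500 kbp on its chromosome; pairs are *intern* (both in the subset)
or *extern* (exactly one). The six parameters: mean r2 of extern and of
intern pairs; the decay ratios (mean r2 at 120-500 kbp over mean r2 at
<= 25 kbp, per class; values above 1 are legal and not clamped); the
distribution (intern pairs over all pairs, aggregated over the subset);
and the subset's mean sample MAF. Distance strata are half-open at the
upper end; pairs in (25, 120] kbp contribute to the means but to
neither decay stratum. Empty strata yield an explicit undefined-with-
reason value, never a silent zero. Under uniform variant density, a
subset placed in one consecutive run has a *higher* distribution value
than an equally sized spread-out subset — accumulation in variant-dense
regions, which the field's verbal interpretation targets, only lowers
the value when density varies along the genome. Pearson correlations
between each parameter and the across-trait per-variant h2 are computed
over subsets with complete data and require at least three of them.

## Synthetic data

The simulator is the package's study design, not a fixture generator:

* **Genotypes**: a block-mosaic haplotype model. Blocks of fixed
  physical length (default 25 kbp, variants every 1 kbp) each carry a
  pool of `haplotypes_per_block` haplotypes (default 8); every
  individual draws two per block. This yields strong within-block LD
  (mean r2 roughly 1/pool size), near-zero between-block LD, and a
  controllable MAF spectrum (pool frequencies uniform on
  [maf_floor, 0.5], sample-MAF floor enforced by per-variant pool
  resampling, failing loudly when the pool is too small, e.g. a
  single-haplotype pool). It does not emulate demographic history,
  selection, imputation error or a realistic LD decay curve — passing
  tests show estimator correctness under block LD, not robustness to
  real cattle LD structure.
* **Subsets**: disjoint by construction; "clustered" placement occupies
  one consecutive map run, "uniform" spreads members randomly.
* **Phenotypes**: two genetic components (subset causals drawn from the
  focal subset, chip causals from its complement) with effect pairs
  bivariate normal on standardized dosages, scaled so expected component
  (co)variances equal the configured targets; plus a bivariate normal
  residual. Defaults mirror a dairy-cattle-like design: total h2 0.40
  split 0.30 (chip) / 0.10 (subset), residual variance 0.60, subset
  genetic correlation -0.5, and 20% of individuals missing trait 2
  (routine health records are observed on fewer animals than yield).
  One realized draw of a component's variance fluctuates around its
  target with sd ~ sigma2 sqrt(2/n_causal), so convergence to targets is
  asserted on means over replicates.
* Determinism: a single integer seed fixes genotypes, annotations,
  subset placement, effects, residuals and missingness bitwise.

## Recovery study and problem sizes

The packaged study (`grmpart.study`) runs 20 replicates at n = 1,000
individuals and 5,000 variants (500-variant focal subset, 500 chip and
100 subset causals), refits the single-GRM and two-GRM univariate models
and the two-GRM bivariate model, and summarizes: coverage of the
generating values by +/-2 SE intervals, the mean subset genetic
correlation, and the largest gap of the decomposition identity
(h2_set + h2_chip from the two-GRM fit vs. h2 from the single-GRM fit).
These sizes keep a full study around three minutes on one core while
leaving the per-replicate standard errors small enough for the
calibration checks to be meaningful. The acceptance script reruns the
study from scratch under the given seed; nothing in it is precomputed.

## Known limitations

* At the stated sizes the subset genetic-correlation SE is large
  (~0.2-0.5 per replicate), as is typical for small-subset bivariate
  analyses; conclusions about r_g rest on means over replicates.
* The residual-likelihood surface of boundary cases (duplicated traits,
  components at zero) is handled by clamping-and-flagging rather than by
  formal boundary inference.
* DRP reliability weighting is not modelled: both the simulator and the
  REML assume homoscedastic residuals. Whether reliability weights
  should enter the residual covariance is left open deliberately.
* Only 1-2 GRMs and 1-2 traits; no fixed covariates beyond the
  intercept; no Bayesian alternatives.
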