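# Methods

## The model

Observed expression of gene *g* in individual *s* is treated as the sum of a
cis-genetic component, an environmental component and measurement noise:

    y_sg = GReX_sg + env_sg + e_sg

**GReX** (genetically regulated expression) is imputed as a sparse linear
combination of cis-SNP ALT-allele dosages, `GReX_sg = Σ_v w_gv · d_sv`, the
standard transcriptome-imputation construction.  Weights are either supplied
(a per-tissue weight table) or trained on a reference cohort by elastic-net
regression (mixing parameter 0.5, penalty chosen per gene by inner 5-fold
cross-validation over a 40-point path; all fold assignments derive from the
run seed).  Prediction quality is summarized per gene as the squared Pearson
correlation between tenfold out-of-fold predictions and observed expression
(`cv_r2`), which is compared with a single-component REML estimate of local
heritability: a strong positive correlation across genes indicates the weight
model captures the cis-genetic signal in the cohort at hand.

**EReX** (environmentally regulated expression) is the per-gene residual of
an ordinary least-squares fit of observed expression on GReX, with intercept
and no covariates — covariate adjustment belongs to the association stage.
By construction EReX is orthogonal to centered GReX and
Var(observed) = Var(fitted) + Var(EReX) per gene.  EReX also absorbs any
genetic variance the cis model misses (e.g. trans effects); it is an
environmental component only to the extent the cis model is complete.  Genes
whose GReX is constant cannot be regressed; they keep centered observed
values as EReX and are flagged rather than dropped so downstream analyses
cover all genes.

## Variant QC

Variants enter prediction only if minor allele frequency is strictly above
0.05 and the Hardy–Weinberg exact test p-value is strictly above 0.05.  The
HWE test is the exact conditional test: given the observed minor-allele
count, each compatible heterozygote count is weighted by its conditional
probability and the p-value sums the probabilities of configurations no more
probable than the observed one (no mid-p).  Dosages are harmonized to the
weight's effect allele (flipped to `2 − d` when the effect allele equals
REF); strand-ambiguous A/T and C/G variants are used as-is with a warning.
Missing genotypes are imputed to the variant mean at read time.

## Local heritability (REML)

For each gene, the genomic relationship matrix `GRM = Z Zᵀ / m` is built
from standardized cis dosages and the restricted likelihood of
`y ~ N(μ, σ_g² GRM + σ_e² I)` is maximized over `h² = σ_g²/(σ_g²+σ_e²)` on
the GRM eigenbasis; the total variance is profiled out, leaving a bounded
one-dimensional search (tolerance 1e-6 on h², endpoints checked explicitly,
estimates clamped to [0, 1]).  Tests verify the optimum against a 101-point
grid on the same restricted likelihood.

## Association testing

Case/control status is the outcome of a logistic regression; the
likelihood-ratio statistic compares a null model (covariates only) with a
full model adding one gene variable, `Λ = 2(ℓ_full − ℓ_null)`, floored at 0.
Newton–Raphson with step halving, convergence at relative log-likelihood
change < 1e-10 within 100 iterations; quasi-separated fits are re-run with a
ridge penalty of 1e-6 on the gene coefficient and flagged.

Covariate policy: expression principal components (top 10 scores of the
centered observed matrix by default) are confounders for observed expression
and EReX but not for GReX, which is a function of genotype only; genotype
PCs enter all three components against population stratification; clinical
covariates enter everywhere.

P-values come from Freedman–Lane permutations: the gene variable is
regressed on the null-model covariates, its residuals are permuted with a
seeded RNG and added back to the fitted values, and the LRT is recomputed.
With covariates absent this reduces exactly to permuting the gene variable.
The estimator is `p = b/B` with `b` the number of permutation statistics at
least the observed one; if `b = 0` after the initial 8000 permutations the
count escalates to 1,000,000 total, and a still-empty exceedance set reports
`1/B_max` flagged as an upper bound so ranking stays total.  Per-gene RNG
substreams are derived from (seed, component, gene id), making results
independent of evaluation order.  BH step-up q-values are computed within
component.  The analytic chi-square(1) tail is carried along as a
diagnostic only.

## Enrichment, counting, pi1

Genes are ranked by permutation p-value with ties (common at `b/B`
resolution) broken by larger LRT statistic, then gene id.  Over-
representation of a pathway among the N top-ranked genes is the upper tail
`P(X ≥ x)` of the hypergeometric distribution with the universe defined as
the genes having all three components, summed in log space (the tail is
floored at the smallest positive float; values can legitimately reach
1e-300 at cohort scale).  Threshold counts use strict `p < α`.  The
proportion of true alternatives is `π₁ = 1 − #{p > λ} / ((1−λ) m)` at fixed
λ = 0.5, clamped to [0, 1] — a single-λ uniform-null estimator chosen over
spline-smoothed variants for determinism.

## Synthetic cohorts

The generator emulates a fixed-size case/control blood cohort: 922
individuals (463 cases / 459 controls) by default, biallelic variants drawn
as Binomial(2, f) with f uniform in the configured MAF range (HWE-consistent
by construction, no LD), sparse per-gene causal weights, and per-gene
expression with variance 1 split as h² genetic (default 0.15, inside the
0.10–0.26 range twin studies report for blood), and the non-genetic
remainder split by `env_share` (default 0.7 environmental, 0.3 noise).  The
returned weight table stores the variance-rescaled true weights, so
predicting with them reproduces the true genetic component exactly.
Environmental case/control effects add `effect · σ_env` to cases for the
configured genes; genetic effects generate status from a logistic model on
the summed standardized genetic values in an oversampled pool, then
subsample to exact case/control counts.  One RNG stream with a fixed draw
order (genotypes, causal choice, weights, phenotype, environment, noise,
covariates) gives full determinism per seed.

What the generator does **not** emulate: linkage disequilibrium, trans-eQTL
effects, correlated environmental exposures across genes, count-based
expression noise, or realistic clinical confounders (covariates are
standard normal).  Passing tests therefore demonstrate correctness of the
machinery and calibration under idealized architecture, not performance on
real cohorts.

## Problem sizes and specific analysis choices

Simulation-based checks run at these sizes, chosen to make Monte-Carlo
error small relative to the tested margins: null calibration 500 genes ×
2000 permutations at n = 922 (300 × 1000 in the acceptance script);
decomposition recovery 50 genes at n = 922, h² = 0.3; headline-direction
100 environment-linked + 100 null genes at n = 922, 0.5 SD shift, 1000
permutations; R²–h² relationship 60 genes at n = 600 with h² spread over
[0.05, 0.6]; π₁ recovery m = 5000 with 23% alternatives from Beta(0.05, 1).

In the headline-direction and null-calibration simulations the expression-PC
count is set to 0.  With half of all genes carrying the same simulated
environmental shift, the leading expression PC is nearly collinear with
case/control status, and conditioning on it would both absorb the signal
under test and quasi-separate the null logistic model.  This is a property
of the deliberately extreme synthetic architecture, not a recommendation for
real data, where the default policy (10 expression PCs) stands.

## Known limitations

- Independent variants only; QC and REML behavior under LD is untested.
- The logistic-LRT direction (status as outcome) is a design choice; a
  linear-model direction is not currently implemented.
- EReX inherits any mis-harmonized or missing cis signal as pseudo-
  environmental variance.
- The hypergeometric universe must be supplied consistently by the caller
  when used outside the pipeline (the pipeline uses the shared-gene set).
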