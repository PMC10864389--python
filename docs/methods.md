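# Methods

This note documents the statistical models, numerical choices and known
limitations of `metaprs`. The package implements, end to end on synthetic
cohorts, the construction of risk-factor-informed polygenic meta-scores:
per-variant GWAS, LD score regression, LDpred-infinitesimal reweighting,
a risk-factor-PRS x disease association screen, elastic-net integration of
the selected scores with the disease PRS into a single per-SNP weight
vector, and a validation-set metric battery comparing the meta-score with
the plain disease PRS.

## The synthetic cohort generator

The generator emulates the statistical structure of a biobank-style design
at desk scale; it is first-class, tested code, not a fixture.

**Genotypes.** Diploid dosages x_ij in {0,1,2} are built from two
independent haplotypes per individual. Within an LD block, the haplotype's
allele indicators share a latent Gaussian factor with loading
sqrt(`block_corr`); the allele is carried when the latent value falls below
the normal quantile of the variant's minor-allele frequency (drawn uniformly
from `maf_range`). Marginal frequencies are therefore exact
(Hardy-Weinberg by construction) and the latent correlation within a block
equals `block_corr`, zero across blocks, giving a block-diagonal LD matrix —
the structure the LDpred-infinitesimal solve assumes. Block sizes are drawn
from a multinomial (each block >= 1 variant) rather than made equal: unequal
block sizes spread the LD-score distribution, and that spread is the leverage
LD score regression works with. Dosage-scale correlations are attenuated
relative to the latent correlation (a tetrachoric-style effect); everything
downstream consumes dosage correlations, so this is a property of the data,
not a bug.

**Risk factors.** Each quantitative risk factor is
`sum_j b_j std(x_j) + e`. By default every variant is causal
(`n_causal_per_rf=None`), matching the infinitesimal assumption of both the
LDpred-inf reweighting and the polygenicity assumption of LDSC; sparse
architectures are available through the dial and are deliberately hostile to
both methods at small variant counts. The genetic component is rescaled to
an exact empirical variance of `rf_h2` and the noise is orthogonalized
against it and rescaled to `1 - rf_h2`, so each trait has mean 0, variance 1
and an exact stored variance decomposition — the recovery tests then measure
estimator error, not generator slop. The default `rf_h2` is 0.25, inside
the 0.09-0.44 range typical of heritable anthropometric and blood traits;
the studies use 0.4-0.5 where power matters.

**Diseases.** Liability = `sum_k theta_k RF_k + g_direct + eps`, with
`theta` acting on the standardized *total* risk factor (genetic plus
environmental), so a risk-factor PRS predicts disease only through the
genetic fraction of its risk factor — the premise of integrating RFPRSs.
The direct genetic term is built from dosages and orthogonalized against the
mediated term; the residual is orthogonalized against both; the three
empirical variances partition 1 exactly (tested at 1e-9). A case is
declared when liability exceeds Phi^-1(1 - prevalence). Default prevalence
is 0.1: the real design's 0.1% inclusion floor is implemented in
`prevalence_filter`, but at desk-scale sample sizes a 0.1% disease yields
single-digit case counts and no estimable model, so the simulated diseases
are common by default. Onset ages are not simulated; the cumulative-
incidence stage treats a case's recruitment age as "diagnosed by this age"
and censors controls at their recruitment age.

**Covariates** (age 40-69, sex, genotyping array, 10 PCs as standard
normals) are independent of genotype by default; `confounding > 0` leaks a
genotype axis into PC1 for adjustment tests. Environmental noise is
independent across risk factors by default; `rf_env_corr` introduces an
exchangeable shared factor. The three-way GWAS/PRS/validation split is a
seeded permutation with exact sizes; surplus individuals stay unassigned.
Every stage draws from a dedicated stream of the cohort seed, so cohorts are
bit-reproducible.

## GWAS and variant QC

QC excludes variants by missing call rate > 0.05, MAF < 0.01, exact
Hardy-Weinberg p < 1e-6 (conditional enumeration test on genotype counts),
indel alleles, and strand-ambiguous pairs (A/T, C/G). Filters are pure
per-variant predicates, so the surviving set is order-independent; the
report attributes each exclusion to the first failing filter in a fixed
order.

Linear GWAS residualizes the trait and each dosage on the covariate design
(Frisch-Waugh-Lovell), which is algebraically identical to the full OLS fit
and vectorizes; variants with missing calls fall back to per-variant
complete-case fits. Logistic GWAS fits a maximum-likelihood logit per
variant (statsmodels); non-convergence, separation and degenerate genotypes
produce an omitted row with a logged reason, never a silent zero. P-values
are floored at the smallest positive double so downstream -log10 transforms
stay finite. Disease status is coded 0/1 throughout (logistic estimates are
invariant to the labeling).

## LD score regression

LD scores are `ell_j = 1 + sum_{k != j} [r2 - (1 - r2)/(n - 2)]` over the
variant's block, floored at 1. Heritability comes from the regression
`E[chi2_j] = intercept + (N h2 / M) ell_j`.

Two choices depart from common real-data practice, both forced by desk
scale and documented here deliberately:

* **The intercept is constrained to 1 by default.** The free-intercept
  convention guards against uncorrected stratification in real data. These
  synthetic cohorts have none, so 1 is the true value — and at M ~ 300-500
  variants the LD-score range is so narrow that a free intercept is nearly
  collinear with the slope: with honest standard errors the estimator then
  has no screening power at all (one-sided p ~ 0.1-0.9 for a true h2 of
  0.3). Constrained, the same simulations give accurate estimates and
  p ~ 1e-11-1e-4. `fit_intercept=True` restores the free intercept.
* **Standard errors come from a delete-a-block jackknife** over contiguous
  variant chunks (50 by default), not the i.i.d. OLS covariance: chi-square
  noise is strongly correlated within LD blocks, and the i.i.d. SE is badly
  anti-conservative. Jackknifing contiguous chunks respects the block
  layout of the variant table. Measured coverage of +-3 SE at n=5000,
  m=500 was 19/20 seeds.

The regression is unweighted by default (`weighted=True` applies 1/ell
weights); reported h2 is clipped to [0,1] while the unclipped value feeds
the one-sided Wald test. Screens retain a trait iff p is strictly below
alpha / n_tests.

## PRS construction

The infinitesimal reweighting solves, per LD block,
`(D + (M/(N h2)) I) b = beta_marginal` on the standardized-genotype scale
(marginal betas multiplied by reference dosage SDs), then converts back to
per-allele weights. This makes the identity-LD case an exact scalar
shrinkage `1/(1 + M/(N h2))`, which the tests pin. The h2 plugged in is the
LDSC estimate, clipped below at 0.01 (with a logged warning) because the
ridge term diverges as h2 -> 0. Scoring is the weighted sum of
effect-allele dosages with orientation resolved against the cohort's
variant table; variants absent from the cohort are a hard error.
Standardization uses the PRS-set mean and *population* SD (divide by n),
and those parameters are applied unchanged to every other sample set — the
same sigma_c enters the per-SNP weight conversion, making the meta-score
equivalence exact rather than approximate.

## Screen and integration

Every standardized RFPRS is tested against every disease by logistic
regression with the full covariate set in the PRS sample; selection is
Bonferroni at alpha / (n_rfprs x n_diseases), strict inequality. Diseases
with no selected RFPRS proceed with the disease PRS alone (the elastic net
then degenerates to a reweighted disease PRS).

The integration is a penalized logistic regression of the disease on the
selected RFPRSs plus the disease PRS, covariates unpenalized, with an
L1+L2 mixture (`l1_ratio` default 0.5 — the mixing parameter is a free
choice here, exposed in config and recorded in the output). The solver is
a glmnet-convention coordinate descent (IRLS outer loop, soft-thresholding
inner loop, per-feature penalty factors, warm-started descending penalty
path); no installed Python package supports unpenalized columns inside an
elastic net, so it is implemented here and cross-checked in the tests
against the unpenalized MLE at vanishing penalty, against scikit-learn's
saga at a matched objective, and against R glmnet at fixed lambda
(accounting for glmnet's rescaling of penalty factors to sum to nvars).
Internally, columns are centered and unpenalized columns scaled to unit
variance for conditioning; both transformations leave the optimum invariant
and are undone on output. The penalty grid is geometric from the smallest
all-zero lambda down by a factor 1e-3 (30 points by default). The penalty
is chosen by stratified 10-fold cross-validation maximizing mean held-out
AUC of the linear predictor, ties toward the smaller penalty; the full CV
curve is stored so any alternative rule is recoverable. A single-class
fold triggers one refold with seed+1, then an error. The disease PRS is
penalized like any other column; `force_disease_prs=True` exempts it for
sensitivity analyses.

Per-SNP conversion: combined weight
`w_j = sum_c (gamma_c / sigma_c) alpha_jc` over the components carrying
variant j, after aligning effect-allele orientations. By linearity the
resulting score equals the gamma/sigma-weighted sum of component raw scores
up to an additive constant (absorbed by standardization); the acceptance
suite verifies this per individual at 1e-8 (measured ~1e-15).

The weight ratio reported per disease is |sum of RFPRS coefficients| /
|disease-PRS coefficient| (identical whether one sums ratios or ratios
sums); `mode="per_term_abs"` gives the sum of absolute per-term ratios.
The ratio is undefined (None) when the disease-PRS coefficient is zero.

## Evaluation battery

All metrics are computed in the validation set with PRS-set
standardization parameters. Three nested logistic models share one
covariate design: null (age + sex + array + PC1-10), null + disease PRS,
null + meta-score.

* **Nagelkerke pseudo-R2**: Cox-Snell `1 - exp(2(L0 - L1)/n)` rescaled by
  its maximum `1 - exp(2 L0 / n)`; an augmented model with lower likelihood
  than its null is reported as a fitting bug, not clipped.
* **OR per 1 SD**: exp of the standardized score's coefficient, Wald CI.
* **Continuous NRI** between nested models: case component
  P(up|case) - P(down|case), control component P(down|control) -
  P(up|control); ties count in neither direction. Inference is a seeded
  percentile bootstrap (B configurable). Following the halved-validation
  design, the pipeline fits the models on one random half of the validation
  set and counts reclassification on the other half.
* **Difference of dependent R2** between the two scores' squared outcome
  correlations. The analytic p-value is the Hotelling-Williams t for
  equality of two correlations sharing a variable — chosen over the
  delta-method variance of the difference of *squared* correlations because
  the latter degenerates to zero variance under the global null (both
  correlations ~ 0), where its measured type-I error was 0.000; the
  Hotelling-Williams test measured 0.044-0.061 at alpha = 0.05 over
  1000-replicate null studies. Equality of correlations coincides with
  equality of squared correlations when both share a sign, the normal case
  for two polygenic scores of one disease. The delta-method CI
  (Pearson-Filon covariance) and a seeded paired bootstrap (default
  B = 2000) are both reported; the bootstrap is the headline because it is
  self-validating at desk scale.
* **Top-decile OR**: 2x2 table of top 10% vs rest by stable rank (boundary
  ties logged), Woolf CI, 0.5 continuity correction only when a cell is
  zero; a zero margin reports "undefined" rather than infinity.
* **Cumulative incidence** per risk group: Kaplan-Meier (lifelines) with
  plain Greenwood-variance normal bands on 1 - S(t), clipped to [0,1].

## Pipeline, sizes and runtimes

The `metaprs run` pipeline executes simulate -> qc -> gwas -> h2 ->
reweight -> score -> screen -> integrate -> evaluate from one YAML config
(unknown keys rejected; seed mandatory), writes plain-text artifacts and a
manifest of config hash, per-stage seeds (derived from the global seed by
hashing the stage name), SHA-256 file digests and timings. Re-running a
config reproduces the digests byte-for-byte; the tests assert this.

The replicate studies use deliberately small problem sizes chosen so each
study completes in minutes on one CPU while leaving the estimators
identifiable: heritability recovery at n_gwas = 5000, m = 500, 100 blocks,
50 replicates; logistic-screen calibration on 2000 null variants at
n = 1500; ΔR2 calibration over 1000 replicates at n = 1000; the directional
comparison on 50 replicates of a 5500-individual, 200-variant cohort with
three risk factors, mediated (theta = 0.40/0.30/0.25, direct h2 = 0.05)
versus purely direct (theta = 0, direct h2 = 0.30) architectures, 5-fold CV
over 15 penalties. The directional studies bypass the heritability
*significance* screen (LDSC estimates clipped at 0.05 are used directly):
at these sizes screening power, not integration quality, would otherwise be
the binding constraint, and the comparison targets the latter. The full
pipeline retains the honest screen.

## Limitations

* LD is exchangeable within blocks and zero across; there are no
  recombination-map block boundaries, no MAF-LD coupling beyond the
  threshold model, no population structure (unless `confounding` is set)
  and no relatedness. Passing tests show the estimators work under their
  own assumptions, not that they are robust to real-data violations.
* Real-data use of the PRS stage would need an external LD block map; the
  package uses the simulator's known blocks.
* The liability model has no age structure; cumulative-incidence curves
  order groups correctly but their time axis is recruitment age, not a
  modeled onset process.
* LDSC at a few hundred variants is usable only with the constrained
  intercept; free-intercept behavior at biobank scale is out of reach at
  desk scale.
* The halved-validation NRI and all bootstrap p-values are seeded and
  B-limited; they are calibrated in the package's own studies, not against
  external implementations.
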