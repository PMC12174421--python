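# Methods

`circartp` implements a candidate-gene case-control analysis pipeline of the
kind used to study circadian-gene polymorphisms in differentiated thyroid
cancer: per-SNP log-additive logistic regression, adaptive rank truncated
product (ARTP) tests at the gene and pathway level with permutation nulls, a
gene-environment (GxE) variant of the ARTP permutation scheme, genotype
quality control with an auditable exclusion ledger, Benjamini-Hochberg
multiple-testing correction, and a synthetic cohort generator that stands in
for individual-level study data, which are not publicly deposited.

## Statistical model

**Per-SNP association.** Disease status is modelled by unconditional
logistic regression with the SNP coded as the effect-allele count
g ∈ {0, 1, 2}:

    logit P(case) = β0 + β g + γ' z,

one log-odds ratio β per allele (the log-additive model), with covariates z.
The default adjustment set mirrors a frequency-matched all-female study:
age (11 five-year bands, categorical), department of residence (4 levels),
years of education (4), marital status (4), age at menarche (4), parity (5),
oral-contraceptive use (2), smoking status (never/former/current) and
continuous BMI. Association p-values are Wald by default — the convention
that matches OR + 95% CI reporting — with the likelihood-ratio alternative
also computed; the two agree closely away from boundary cases and the choice
is configurable.

**Stratified odds ratios.** Exposure-stratified ORs (e.g. per smoking
stratum) refit the adjusted log-additive model independently within each
stratum, dropping the stratum variable from the adjustment and entering age
continuously (strata of one to two hundred women cannot afford 10 age-band
dummies). Because strata are small and effect alleles can be rare, the
stratified fits use Firth's bias-reduced logistic regression by default
(Jeffreys-prior penalised likelihood; removes the O(1/n) bias of the MLE
and stays finite under separation; verified against its closed-form 2x2
analogue of adding 1/2 to each cell), with the plain MLE available via
``method="mle"``. A multi-loci variant fits all listed SNPs jointly per
stratum, detecting and reporting rank deficiency among the SNP columns.

**Interaction.** SNP x exposure interaction is tested by the likelihood
ratio: both models carry the SNP and exposure main effects plus the
adjustment; the full model adds dosage x exposure terms. Degrees of freedom
are (levels − 1) for a categorical exposure (2 for smoking, 3 for menarche,
4 for parity, 1 for OC use) and 1 for continuous BMI. Reference-level
invariance of the statistic is asserted in tests.

**ARTP.** For a gene with member p-values p_(1) ≤ … ≤ p_(m), the rank
truncated product at truncation point K is W(K) = Σ_{i≤K} log p_(i).
Truncation points follow "every top 5%": K_j = min(m, max(1, ceil(j·0.05·m)))
for j = 1..5 at the gene level and j = 1..10 at the pathway level,
de-duplicated. For tiny genes the grid collapses (m ≤ 20 gives fewer than
five distinct points; m = 2 or 3 gives just {1}); the fraction and point
counts are configurable. Each W(K)'s significance is its empirical rank
within the permutation null, MinP is the minimum rank over the K grid, and
the single-layer algorithm ranks the observed MinP within the per-permutation
MinP values of the *same* permutation set — the rank-of-rank construction
that makes one layer of permutations sufficient. Counts use closed (≤)
comparisons and include the observed row, so every empirical p lies in
[1/(B+1), 1] and the test is exact under exchangeability. The pathway level
rank-transforms each gene's MinP vector into per-permutation gene p-values
and applies the same machinery with genes as items. The default permutation
count is B = 20,000; examples and tests use B = 199–999.

**Permutation modes.** In main-effect mode only case-control status is
permuted (conditioning on genotypes and covariates; covariate-outcome
associations are re-estimated in every refit). In GxE mode the input
p-values are the interaction LRT p-values and the whole epidemiological
record — status together with all covariates and the exposure — is permuted
as one unit across individuals while genotype rows stay fixed; this
preserves the covariate-outcome structure (the adjustment remains
meaningful under the null) and leaves the SNP-SNP LD structure untouched.

**Permutation backends.** The `refit` backend refits the full logistic
model per SNP per permutation (Wald p in main mode, LRT in GxE mode) using
a dedicated Newton/IRLS fitter with step halving, warm starts and a tiny
Hessian ridge; the user-facing single fits go through statsmodels and the
two are asserted to agree. The `score` backend replaces the per-SNP refit
with Rao score tests (vectorised across SNPs in main mode; a block score
test for the interaction columns in GxE mode), which is the practical choice
for large B; tests assert rank agreement (Spearman ρ > 0.99) with the refit
backend. Fits that fail to converge, separate, or hit collinear designs
record p = 1 with a counter (conservative, keeps the matrix rectangular).
The engine drops individuals with incomplete covariates once up front and
mean-imputes missing dosages with a logged count; the user-facing per-SNP
fits instead drop individuals pairwise per SNP, with full and reduced models
of every LRT sharing one analysis set.

**Multiple testing.** Benjamini-Hochberg step-up q-values
(q_(i) = min_{j≥i} m·p_(j)/j), applied within the families the design
implies: all SNPs for the association scan, the 23 genes for gene-level
ARTP, and each exposure's scan separately. The SNP-level GxE family is all
SNPs within one exposure (the natural reading; noted as a convention).

## Quality control

Filter order is fixed and ledgered with first-failure attribution.
SNPs: call rate < 0.95 → Hardy-Weinberg p < 1e-5 → external reference
concordance (user-supplied ids) → minor-allele frequency < 0.01 in controls
(strict inequality; allele counts over twice the non-missing control
genotypes). Samples: genotyping failure → consent withdrawal → PCA outliers.
The ledger enforces `n_input − Σ excluded = n_remaining` and reproduces the
published accounting (1,010 − 32 − 1 − 32 = 945 participants;
7,021 − 1 − 16 − 143 = 6,861 SNPs) from the printed counts.

The HWE exact test enumerates the conditional distribution of the
heterozygote count given the allele counts (log-gamma weights, normalised;
two-sided by summing configurations no more probable than the observed one)
and is verified against exact rational enumeration to 1e-12 for totals up
to 500. A chi-square variant is provided for parity with older toolchains.
HWE is tested in all individuals by default, with a controls-only option —
both conventions are in use and the original analysis does not specify one.
Note the plain exact p-value is discrete and conservative (it has an atom
of mass ≈ P(modal heterozygote count) at p = 1), which is the right behaviour
for a filter but means it can never pass a literal uniformity test; the
`midp` option applies the standard mid-p correction, and calibration checks
use it.

The PCA outlier rule — mean-impute, standardise, flag individuals beyond 6
SDs on either of the first two principal components — is a reasonable
default for a screen whose exact rule is rarely reported; both the SD
multiplier and the number of components are configurable. PC scores are
returned so they can enter the regression adjustment (`use_pcs`); on a
homogeneous cohort this leaves gene-level p-values within Monte-Carlo noise.
A pairwise identity-by-state screen (IBS fraction > 0.9) stands in for
relatedness checks; external concordance counts are ledger entries supplied
by the user.

## Synthetic cohorts

The generator emulates the study conditions: ~463 cases / 482 controls
drawn from a larger simulated population, a 23-gene panel with the published
per-gene SNP counts (570 SNPs in total, 2–285 per gene), and covariate
distributions taken from the published control-arm tables (e.g. smoking
never/former/current = 266/100/115 of 481). BMI is log-normal with median
23 kg/m² and log-scale SD 0.18 (≈ ±4 kg/m² interquartile-ish spread —
plausible for an adult female population); age is drawn continuously within
its sampled five-year band so both continuous and banded adjustment work.

Genotypes follow a latent-Gaussian haplotype model: per gene, each
individual carries two independent latent AR(1) vectors (correlation
`ld_rho` between adjacent SNPs, independent across genes), thresholded at
the normal quantile of each SNP's allele frequency (drawn uniformly from
`maf_range`, default 0.05–0.45, or pinned per SNP). Because the two
haplotypes are independent, every SNP is in exact HWE at its frequency,
while adjacent-SNP r² rises monotonically with `ld_rho` (default 0.5, a
moderate tag-SNP LD level). A `perfect_ld_pair` helper appends an exact
duplicate column (r² = 1) to exercise the LD-reporting and pruning paths.
What the generator does **not** emulate: the real haplotype structure of the
23 genes, population stratification (except in dedicated two-population
tests), genotyping error, missingness patterns, X-linked effects (the study
is all-female) — so passing tests demonstrate the statistical machinery is
correct under the stated model, not that real-data results are reproduced.

Outcomes are Bernoulli under a logistic model with configurable intercept,
per-SNP log-ORs, covariate-level log-ORs and dosage x exposure interaction
terms; case-control sampling then draws the requested numbers of cases and
controls. All stages are deterministic given their seeds.

## Study-scale checks and problem sizes

The simulation studies in `circartp.experiments` use sizes chosen to keep
each study in the minutes range on one CPU while retaining the study-scale
sample: null calibration runs 200 replicate 463/482 cohorts over the
23-gene panel capped at 5 SNPs per gene (107 SNPs) with B = 199 and the
score backend, checking the pathway type-I error at α = 0.05 and KS
uniformity of pooled gene p-values; the oracle check compares the
single-layer gene p with a nested double-permutation estimate (500 outer ×
500 inner) on a 40-individual, 3-SNP gene; the GxE study runs 100 replicate
945-individual cohorts with one 14-SNP gene whose first SNP (EAF 0.13)
carries smoking-stratum ORs 1.0 / 2.8 / 0.4 — an interaction-only signal
whose marginal main effect is near zero, so the gene's main-effect ARTP
stays at its nominal level while the GxE ARTP should reject in most
replicates and the smoking-stratified CIs should cover the generating ORs
at the nominal rate.

## Numerical choices and limitations

- Natural logs in W(K) (monotone-equivalent to the product statistic).
- Truncation grid arithmetic rounds j·fraction·m to 9 decimals before the
  ceiling so exact-integer grid points survive binary float noise.
- Rank counts use `searchsorted(..., side="right")` on sorted statistic
  columns — O((B+1) log(B+1)) per truncation point, ties handled closed.
- The IRLS fitter flags |β| > 15 as separation; statsmodels-facing fits
  mark non-convergence rather than raising, and monomorphic SNPs return a
  structured result.
- Score-test variances ≤ 1e-12 (collinearity) yield p = 1 with a counter.
- Perfect-LD pruning (report one SNP of an r² = 1 pair) is available but
  off by default.
- Known limitations: no dominant/recessive codings, no haplotype tests, no
  conditional logistic regression for matched sets, no imputation, no
  analytic (non-permutation) ARTP null, no batch-effect correction. The
  permutation engine assumes complete covariates after its single up-front
  drop; heavy covariate missingness should be handled before the ARTP stage.
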