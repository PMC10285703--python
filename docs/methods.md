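# Methods

`bchfkit` re-implements, at workstation scale, the quantitative-genetics
analysis of bovine congestive heart failure (BCHF) heart scores: a synthetic
admixed cattle population with a known liability architecture, genotype QC
and genomic relationships, Bayesian threshold-liability variance components,
GBLUP prediction with cross-validation, mixed-model association, supervised
breed-ancestry estimation, and incidence reporting. This note records the
models, the defaults and why they were chosen, the numerical decisions, and
what the synthetic experiments do and do not demonstrate.

## The liability model

Heart score (1–5) is treated as an ordinal projection of a latent Gaussian
liability. The binary BCHF trait takes scores 1–2 as controls, 4–5 as cases
and excludes score 3. The bivariate threshold–linear animal model is

    [ y_trait ]           ( [ X b_trait + Z u_trait ]          )
    [ I_bchf  ]  ~  N     ( [ X b_bchf  + Z u_bchf  ] ,  I ⊗ R )

with breeding values `u ~ N(0, G0 ⊗ G)`, `G` a genomic relationship matrix,
`G0` the genetic covariance and `R` the residual covariance; the case/control
status is `1(I > t1)` with `t1 = 0`. Heritability on the liability scale is
`h² = σ²g/(σ²g+σ²e)`; the default generating values are `σ²g = 0.554`,
`σ²e = 1.0`, hence `h² = 0.356`.

## Gibbs sampling and the liability-scale gauge

Binary records are invariant under a joint rescaling of liabilities, fixed
effects, breeding values and variances, so the absolute liability scale is a
gauge freedom, not an estimable parameter. Treating it as a free parameter
under flat priors produces an improper posterior: as `σ²g → ∞` the marginal
likelihood tends to a positive orthant-probability constant. At reduced
sample sizes the likelihood barrier around the mode is shallow and a naive
sampler drifts to `h² → 1`; fixing `σ²e = 1` does not help, because a flat
prior on `σ²g` then implies a prior `∝ (1−h²)⁻²` on `h²`, which diverges at
the boundary.

The univariate binary sampler therefore pins the gauge — total liability
variance 1, `σ²g = h²`, `σ²e = 1−h²` — and places a flat prior on
`h² ∈ (0,1)`. Each sweep draws liabilities (truncated normals), fixed
effects, and then `(h², u)` as one block: `h²` by inverse CDF on a 256-point
grid of its conditional with breeding values integrated out (in the GRM
eigenbasis the collapsed covariance is diagonal, `h²(d_i − 1) + 1`), and
`u` from its full conditional given the fresh `h²`. The partial collapse
matters: conditioning `h²` on `u` directly mixes so poorly that chains
stall near `h² ≈ 0`.

The sampler was validated against an independent oracle: for equicorrelated
family blocks the exact flat-prior posterior of `h²` is a two-dimensional
quadrature (Gauss–Hermite over the family intercept, a grid over `h²` and
the threshold offset). Posterior means agree within Monte Carlo error; the
comparison is a permanent unit test.

The bivariate threshold–linear model samples the full 2×2 genetic and
residual covariances from inverse-Wishart full conditionals in the
flat-prior limit (degrees of freedom `n − 3`), matching the published
analysis in which the binary residual variance visibly carries posterior
spread. The binary block is renormalised to total variance 1 after every
sweep; the likelihood is exactly invariant under this renormalisation and
all reported quantities (`h²`, `r_g`, `r_e`) are scale-free ratios, so the
renormalisation only prevents the otherwise unbounded scale random walk
(upward drift ≈ `e^{2·iters/n}`) from accumulating numerically. Missing
continuous records are handled by data augmentation from the conditional
residual distribution, not by imputation ahead of the analysis. Chain
defaults follow the published protocol: 50,000 iterations, 10,000 burn-in,
every post-burn-in sample stored; the thinning default is 1.

Posterior summaries are the mean and empirical 2.5/97.5 percentiles per
parameter, with `h²`, `r_g` and `r_e` summarised from per-iteration ratios.

### Fixed effects at reduced scale

With flat priors on a large dummy design (ranch 8 + harvest date 12 + sex
2 ≈ 20 columns) the location block re-opens a slow inflation ridge in small
binary datasets even when the true effects are zero. The pipeline default
keeps the full design (appropriate at production scale); the recovery
studies fit sex only. This is an analysis-design recommendation, not a
sampler limitation: the continuous-trait model, whose scale is anchored by
data, is stable under the full design.

## Synthetic populations

`simulate_breed_panel` draws per-breed allele frequencies around shared
ancestral frequencies by the Balding–Nichols construction; the divergence
parameter is the expected Hudson-style Fst between breeds (verified by a
brute-force estimator in the tests). `simulate_population` gives each animal
breed fractions Q (Dirichlet by default, or fixed crosses such as 50/50 F1),
draws unlinked genotypes per locus from the Q-mixed frequencies, and builds
additive breeding values from Gaussian marker effects rescaled so the
realised genetic (co)variance equals the target exactly — replicate-to-
replicate variation then reflects the analysis, not the generator. Small
categorical ranch/harvest-date/sex effects (one N(0, 0.2²) draw per level)
and a multivariate residual complete the phenotypes. Heart scores follow
from four ordered cutpoints; the defaults sit at the empirical liability
quantiles reproducing the observed score distribution
60.46/26.37/9.03/2.48/1.66 %.

An optional paternal half-sib mode (`n_sires`) draws sire genotypes and
transmits one gamete per offspring, producing progeny groups with expected
genomic relationship 0.25. Commercial fed cattle descend from a limited
pool of AI sires, and this relatedness is what identifies liability-scale
variance from binary records: with fully unrelated linkage-equilibrium
genotypes the binary-data likelihood for `σ²g` is nearly flat and no
estimator behaves. A single-causal-locus mode (`n_causal`) exists for
association power studies only.

What the generator does not emulate: linkage disequilibrium within breeds,
genotyping or imputation error, maternal environment, and selection over
time. Passing recovery tests therefore demonstrate correctness of the
estimators under the stated architecture, not robustness to those real-data
features.

## Recovery studies (the headline checks)

`bchfkit.recovery` freezes the reduced-scale study conditions: 1,500
animals, 5,000 loci, 60 half-sib sire families, binary status at the
genotyped-cohort case fraction 555/5,001 ≈ 0.111 with a single threshold
(the genotyped cohort contained only binary-classified animals), sex as the
fixed effect, chains of 10,000 iterations with 2,000 burn-in, ten replicate
datasets. The univariate study checks the posterior-mean `h²` against the
generating 0.356; the bivariate study adds a carcass-weight-like trait
(h² = 0.40, residual correlation −0.261) or a daily-gain-like trait
(h² = 0.35, −0.127) and checks the genetic correlation (0.460 / 0.289).
Quadrature calculations show the flat-prior posterior mean at this scale
carries a small upward skew (≈ +0.02 to +0.06 on `h²`) that vanishes at the
real study's cohort size; the replicate-mean tolerance (±0.08) accommodates
it.

## Genotype QC and the GRM

QC follows the published order: minor-allele-frequency filter (default
0.10) first, then down-sampling to one randomly chosen locus per
equal-width genomic bin. Bins are laid per chromosome with the bin budget
apportioned by spanned length, so no bin crosses a chromosome junction.
Dosages are recoded from 0/1/2 alternative-allele counts to −1/0/+1 with
missing values mean-imputed at `2p − 1`; recoding a recoded matrix is an
error. The GRM is VanRaden method 1, `G = WW'/c` with frequency-centred
dosages and `c = 2Σp(1−p)` from observed frequencies. Panel intersection
(for array-overlap filtering) matches on chromosome and position with
complement-base strand flips allowed and ambiguous A/T, C/G sites dropped.
Positions are 1-based throughout; PLINK bed/bim/fam and VCF round-trips are
exact.

## GBLUP and cross-validation

The binary response is fitted on the observed 0/1 scale with a linear
GBLUP, as in the published protocol (the threshold model is the
liability-correct alternative). REML runs in the GRM eigenbasis: for a
candidate heritability the covariance is diagonal, the total variance
profiles out, and a bounded 1-D optimisation maximises the restricted
likelihood (verified against a dense-matrix grid search). EPDs are BLUPs of
the genomic effect; masked animals are predicted through the GRM
cross-block, which is exactly how the forward (season-out) and k-fold
schemes mask test splits. Default fixed effect: intercept only; k-fold
splits are unstratified by default with a stratified option; a fold whose
test response is single-class yields an undefined correlation, recorded as
missing and excluded from the mean with a warning. The GBLUP/SNP-BLUP ridge
identity is asserted to 1e−6 in the tests.

## GWAS

Per-SNP association uses the EMMAX/P3D approximation: variance components
estimated once under the null, data whitened in the GRM eigenbasis,
covariates projected out, then per-SNP GLS effect, SE and Wald p (t
reference, n − p − 1 df). Population structure is handled with leading GRM
principal components (default 4) and/or contemporary-group covariates.
λ_GC is the median-χ² ratio and is reported without applying genomic
control. An exact per-SNP REML mode exists for small panels. Monomorphic
SNPs get missing p-values. No significance threshold is hard-coded;
Bonferroni at 0.05/n_SNPs is reported alongside raw p-values.

## Supervised admixture and breed risk

Per animal, breed fractions Q maximise the binomial likelihood over the
simplex with reference frequencies fixed (clamped to [0.001, 0.999]); the
classic admixture EM (block relaxation) is vectorised over animals, with
monotonicity of the log-likelihood asserted every iteration, convergence at
relative change < 1e−7 or 2,000 iterations, and a flat-likelihood
(non-identifiability) warning when the fitted likelihood barely improves on
uniform fractions. Breed risk is a per-breed univariate binary logistic
regression of case status on that breed's fraction (IRLS via statsmodels);
complete separation falls back to a lightly ridge-penalised fit and is
flagged.

## Reporting conventions

Incidence tables keep full precision internally and display half-even
two-decimal percentages. The headline incidence uses all scored animals as
denominator; the case rate among binary-classified animals is reported
separately. Where a published percentage disagrees with its own printed
count, the recomputed value from counts is authoritative.

## Known limitations

* Loci are in linkage equilibrium; no LD-aware simulation or pruning.
* The threshold model supports at most two traits and GRM relationships
  only (no pedigree matrices).
* Bivariate genetic-correlation chains mix slowly at reduced scale
  (effective sample sizes of a few dozen per 10,000 sweeps); replicate
  averaging carries the recovery studies.
* The scale gauge makes absolute liability-scale variances reporting
  conventions, not estimates; only ratios are inferentially meaningful for
  the binary trait.
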