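# bchfkit

Quantitative genetics of bovine congestive heart failure (BCHF) heart
scores, for animal breeders and quantitative geneticists who want a tested,
self-contained rendition of the full analysis chain on simulated data:

* a synthetic-population generator for admixed, half-sib-structured cattle
  with a latent cardiac-liability trait and correlated production traits;
* genotype QC (MAF filtering, equal-bin down-sampling, −1/0/+1 recoding),
  PLINK/VCF I/O and a VanRaden genomic relationship matrix (GRM);
* a Bayesian threshold-liability animal model (univariate binary and
  bivariate threshold–linear) fitted by Gibbs sampling with genomic
  relationships;
* GBLUP with spectral REML, EPD prediction, and forward / k-fold
  cross-validation;
* EMMAX-style linear mixed-model GWAS with GRM principal components;
* supervised admixture (genomic breed percentage) and per-breed logistic
  risk curves;
* heart-score incidence reporting.

## The model

Heart score (an ordinal 1–5 grade of cardiac remodeling recorded at
harvest) is modeled through a latent liability: scores 1–2 are controls,
4–5 are BCHF cases, score 3 is excluded, and the binary status is
`1(I > t₁)` for a liability

    I = Xβ + Zu + e,   u ~ N(0, σ²g G),   e ~ N(0, σ²e I)

with `G` a genomic relationship matrix. Heritability on the liability scale
is `h² = σ²g/(σ²g + σ²e)`; with the component values `σ²g = 0.554` and
`σ²e = 1.003` this is 0.356. The bivariate threshold–linear model couples
the liability with a continuous production trait through 2×2 genetic and
residual covariances, yielding genetic correlations `r_g` (e.g. 0.460 with
carcass weight, 0.289 with average daily gain). Because binary records
cannot identify the absolute liability scale, the samplers gauge-fix total
binary variance to 1 and report the scale-free ratios `h²`, `r_g`, `r_e`
(see `docs/methods.md`).

## Worked example

Simulate a cohort of 1,500 fed cattle in 60 paternal half-sib families
(5,000 unlinked loci, liability h² = 0.356, cases enriched to the genotyped
cohort's 11.1%), build the GRM, and fit the univariate threshold model:

```python
from bchfkit.recovery import recovery_dataset
from bchfkit.threshold import ThresholdModelSpec, run_gibbs, summarize_posterior

pheno, grm, truth = recovery_dataset(seed=7)
spec = ThresholdModelSpec(fixed_effects=("sex",), n_iterations=10_000,
                          burn_in=2_000, seed=0)
samples = run_gibbs(pheno, grm, spec)
print(summarize_posterior(samples).round(3))
```

```
               mean   q2.5  q97.5
parameter
var_g_binary  0.358  0.163  0.575
var_e_binary  0.642  0.425  0.837
h2_binary     0.358  0.163  0.575
```

The posterior mean heritability (0.358) recovers the generating 0.356; the
variance rows are the gauge-fixed components `h²` and `1 − h²`, so only
their ratio is inferentially meaningful. Incidence arithmetic from
per-category counts:

```python
from bchfkit.report import incidence_from_counts
print(incidence_from_counts([19_809, 8_640, 2_957, 812, 545]).to_markdown())
```

```
| Heart score | N | % of total |
| --- | --- | --- |
| 1 | 19,809 | 60.46% |
| 2 | 8,640 | 26.37% |
| 3 | 2,957 | 9.03% |
| 4 | 812 | 2.48% |
| 5 | 545 | 1.66% |
| overall score >=4 incidence | | 4.14% |
```

A score ≥ 4 incidence of 4.14% means roughly one fed animal in 24 reaches
end-stage cardiac remodeling by harvest.

## Command line

The `bchf` entry point wraps the same library:

```bash
bchf simulate --out run/ --n 1000 --loci 5000 --seed 1
bchf grm --bfile run/genotypes --maf 0.10 --out run/grm.tsv
bchf threshold-fit --pheno run/phenotypes.tsv --grm run/grm.tsv \
     --iters 50000 --burnin 10000 --seed 1 --out run/threshold/
bchf gblup-cv --pheno run/phenotypes.tsv --grm run/grm.tsv --k 5 --seed 1 \
     --out run/cv.json
bchf gwas --bfile run/genotypes --pheno run/phenotypes.tsv --pcs 4 \
     --out run/gwas.tsv
bchf incidence --pheno run/phenotypes.tsv
bchf run --out run/   # full pipeline with a JSON manifest
```

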