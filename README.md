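# latentpgs

Polygenic scores, confirmatory factor models, and genomic-SEM latent
polygenic scores for studying the meta-structure of psychopathology in
genotyped cohorts.

Psychiatric phenotypes co-occur far more than diagnostic boundaries
suggest, and both the phenotypes and their polygenic scores (PGSs) may be
organized by a small number of latent dimensions — correlated
internalizing and externalizing factors, or a single general factor of
psychopathology (the *p*-factor). `latentpgs` is for researchers who want
to run that entire analysis on their own cohort: quality-control the
genotypes, build PGSs from published GWAS summary statistics, fit and
compare phenotypic factor models with measurement-invariance testing,
model the *genetic* covariance of the GWAS traits with LD-score regression
and genomic SEM, derive per-SNP weights for the latent genetic factors,
and ask whether those latent PGSs predict the phenotypic factors better
than any single-trait PGS.

## The models

**Phenotypic side.** Indicators x follow a common-factor model
x = ν + Λf + e, fitted by maximum likelihood (full-information ML under
missingness) with robust (sandwich) standard errors and a mean-scaled
chi-square. Fit is summarized by χ², CFI, TLI, RMSEA (90% CI), SRMR and
AIC; nested models are compared on ΔCFI > −0.01 / ΔRMSEA < 0.015 rather
than Δχ², and invariance across groups is tested as the configural →
metric → scalar → residual ladder.

**Genetic side.** For each pair of traits, LD-score regression separates
polygenic signal from confounding and sample overlap:
E[z₁ⱼz₂ⱼ] = intercept + (√(N₁N₂)·σ_g12/m)·ℓⱼ. The resulting genetic
covariance matrix S (with block-jackknife sampling covariance V) is
modelled by diagonally weighted least squares — genomic SEM — giving
factor models of genetic liability with full-V test statistics. Each SNP is
then regressed on the latent factor(s), holding the measurement model
fixed, to produce latent SNP weights that feed back into the ordinary PGS
machinery.

A synthetic-data module generates genotypes with block LD, phenotype
panels, and multi-trait GWAS summary statistics from known factor-model
truth — including mechanistic sample overlap — so the whole chain is
testable without restricted data.

## Worked example

Simulate a small study with a one-factor genetic truth over four traits,
run the full pipeline, and look at the decisions it makes:

```python
import numpy as np
from latentpgs import (SnpPanelSpec, GeneticTruth, PhenoTruth,
                       StudyConfig, SyntheticStudy, run_study)

panel = SnpPanelSpec(n_snps=800, n_blocks=80, within_block_corr=0.5)
genetic = GeneticTruth(
    trait_names=("neu", "anx", "mdd", "alc"),
    loadings=np.array([[0.85], [0.80], [0.75], [0.70]]),
    total_h2=[0.3] * 4, n_per_trait=[6000] * 4)
pheno = PhenoTruth.single_group(
    (0.85, 0.80, 0.70, 0.60, 0.50),
    indicator_names=("negaff", "anxsx", "depsx", "impuls", "anger"))

cfg = StudyConfig(
    synthetic=SyntheticStudy(pheno=pheno, n_individuals=2000,
                             panel=panel, genetic=genetic, h2_factor=0.3),
    seed=11, split_seed=12, run_invariance=False,
    two_factor_pattern={"negaff": "INT", "anxsx": "INT", "depsx": "INT",
                        "impuls": "EXT", "anger": "EXT"},
    ldsc={"window_snps": 60, "n_blocks": 100})
report = run_study(cfg)
d = report.to_dict()
print(d["cfa"]["accepted_model"], round(d["cfa"]["interfactor_corr"], 2))
for row in d["associations"]:
    print(f"{row['predictor']:>12}  b = {row['b']:+.3f}  "
          f"incremental R2 = {row['r2_incremental']:.4f}")
```

Output from this exact configuration:

```
one_factor 1.06
         neu  b = +0.359  incremental R2 = 0.1131
         anx  b = +0.235  incremental R2 = 0.0461
         mdd  b = +0.232  incremental R2 = 0.0394
         alc  b = +0.157  incremental R2 = 0.0232
    latent:G  b = +0.303  incremental R2 = 0.0768
```

Reading it: the generating phenotypic model has one factor, so the
two-factor fit's inter-factor correlation comes out ≈ 1 and the pipeline
keeps the parsimonious one-factor model. Each PGS is then regressed on the
holdout half's general-factor scores with 10 ancestry PCs as covariates;
`b` is the per-SD effect of the score and incremental R² the variance it
explains beyond the PCs. (At this deliberately over-powered toy scale the
single-trait scores are precision-saturated; the calibration studies in
`latentpgs.benchmarks` run the noise-dominated regime where the latent
score's pooling advantage appears.)

Fitting pieces individually is just as direct: `CFAModel(df, spec).fit()`
returns a results object with `summary()`, `factor_scores()`, and
`compare()`; `build_genetic_cov(tables, ld_scores)` feeds
`GenomicSEM(gcov, spec).fit()`; `latent_snp_weights(...)` produces weight
tables that `compute_pgs` scores like any other trait.

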