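# Methods

`latentpgs` implements a complete inference chain for studying the
phenotypic and polygenic meta-structure of psychopathology in a genotyped
cohort: genotype quality control and ancestry PCA, direct-weight polygenic
scores, confirmatory factor analysis (CFA) with measurement-invariance
testing, LD-score regression (LDSC) and genomic structural equation
modelling (genomic SEM) of GWAS summary statistics, latent-factor SNP
weights, and PGS–factor association. Because the motivating data (cohort
genotypes and consortium GWAS) are access-restricted in general, the package
carries a synthetic-data generator whose known ground truth makes every
stage testable end-to-end. This note records the models, the defaults and
why, the numerical choices, and what the desk-scale simulations do and do
not establish.

## Phenotypic factor model

The CFA engine fits the linear common-factor model

    x_i = nu + Lambda f_i + e_i,    f_i ~ N(alpha, Psi),   e_i ~ N(0, Theta)

by maximum likelihood: minimising
F = log|Sigma(theta)| + tr(S Sigma(theta)^-1) − log|S| − p over the free
parameters, with Sigma = Lambda Psi Lambda' + Theta. Identification fixes
factor variances to 1 (loadings are then standardized-factor effects); the
alternative first-loading-fixed convention is available via
`identification="loading"`.

Conventions, stated because reported chi-squares cannot disambiguate them:

* complete-data groups use the unbiased sample covariance and a chi-square
  multiplier of (n_g − 1) per group (Wishart form);
* rows with missing entries are handled by full-information ML over
  missingness patterns; such groups contribute a casewise likelihood-ratio
  against an EM-fitted saturated model (multiplier effectively n). A
  listwise-deletion flag exists for testing. FIML requires a mean structure,
  which is enabled automatically when holes are present;
* `estimator="ml_robust"` (default) adds sandwich standard errors computed
  from casewise scores and a mean-scaled (Satorra–Bentler-type) chi-square.
  The scaling factor is computed from fourth moments of complete rows; with
  missing data this is an approximation using complete cases only. On
  multivariate-normal data the scaling factor is ≈ 1.

Optimisation is L-BFGS with analytic gradients (the adjoint
Sigma^{-1}(Sigma−S)Sigma^{-1} chained through Lambda, Psi, Theta, and the
mean structure), with up to four restarts from perturbed start values.
Just-identified single-group models get a Newton polish on the moment
residuals, which reproduces the sample covariance to machine precision —
this is what makes closed-form checks exact to 1e−8 and beyond. Heywood
cases (negative residual-variance estimates) are flagged on the results
object, never silently truncated; the genomic-SEM engine (below) is the one
place a zero-residual refit happens, because inadmissible genetic residuals
there are expected and have an established handling convention.

Fit indices follow the standard definitions: CFI and TLI against the
independence model fitted to the same data; RMSEA = sqrt(max(chi2−df,0) /
(df·n_eff)) with a 90% CI by inverting the noncentral chi-square CDF
(Brent root-finding on the noncentrality); SRMR as the RMS standardized
covariance residual (group-weighted); AIC = −2·loglik + 2·k from the
casewise likelihood. At df = 0, TLI and RMSEA are reported as undefined
(`None`), not NaN. Acceptability cutoffs are RMSEA < 0.06 and CFI, TLI >
0.90. Multi-group RMSEA uses n_eff = sum of group multipliers with no
group-count factor.

Nested models are compared on ΔCFI and ΔRMSEA rather than Δchi-square,
which is oversensitive at large n: a restriction "depreciates" fit when CFI
drops by more than 0.01 or RMSEA rises by more than 0.015 (both
configurable). Measurement invariance across groups is the standard
four-level ladder — configural (same pattern, all parameters free), metric
(equal loadings; factor variances freed in non-reference groups), scalar
(plus equal intercepts; factor means freed), residual (plus equal
uniquenesses) — each level compared with its predecessor by the same
Δ-criteria. The age bands used for grouping are 51–64, 65–74 and 75–83
years. Factor scores use the regression method,
f̂ = Psi Lambda' Sigma^{-1}(x − mu), computed patternwise under
missingness and z-standardized.

A screening diagnostic flags any indicator with a negative standardized
loading; `drop_negative_indicators` removes the worst offender and refits
until clean — the rule that removes, e.g., a drinking-frequency measure
that correlates negatively with the other indicators.

## Polygenic scores

Scores are direct genotyped-SNP weighted allele sums: no LD clumping, no
p-value threshold, weights taken as published (log-odds for binary traits).
Harmonization intersects panel and GWAS by SNP id, reconciles allele pairs
(dropping irreconcilable ones with a count), and re-orients every weight to
the risk-increasing allele, so weight tables always have non-negative
weights. Strand-ambiguous (A/T, C/G) SNPs are kept by default — matching is
by id on a fixed array — with a `drop_palindromic` option. Missing dosages
are mean-imputed at twice the counted-allele frequency (the PLINK
convention) or the SNP is omitted for that individual; scores are
z-standardized within the analysis sample. The scoring core is exact: it is
tested against a brute-force double loop and is invariant to allele
re-orientation, SNP order, and weight-table splitting.

## Genotype QC and ancestry PCA

QC runs in a fixed order — individuals with missing call rate > 2%, then
SNPs with call rate < 98%, then SNPs with Hardy–Weinberg exact-test
p < 1e−4 — because the SNP statistics depend on the retained individuals.
The HWE test enumerates heterozygote counts exactly (chi-square
approximations are unreliable at the 1e−4 tail). Ancestry selection is
two-stage: PCA on all individuals; retain the labelled subgroup whose PC1
and PC2 scores fall within ±1 SD of the overall mean; PCA again within the
retained set to produce the 10 ancestry-specific PCs used as covariates.
PCA standardizes mean-imputed dosages and excludes monomorphic SNPs; no LD
pruning is applied (fidelity to the stated procedure; a pruned variant can
be composed from the primitives). The ±1 SD window is interpreted on PC
*scores*, with the reference mean/SD computed over all individuals — both
choices are configurable because the source procedures are often ambiguous
on exactly these points.

## LDSC and genomic SEM

LD scores are within-window sums of bias-adjusted squared correlations,
r²_adj = r² − (1 − r²)/(n − 2), computed from a reference panel sharing the
cohort's allele frequencies. Univariate LDSC regresses chi-square on LD
scores, E[chi2_j] = intercept + (N h²/m) l_j; the bivariate form regresses
z-score products with an intercept that absorbs sample overlap
(≈ N_shared·rho_phenotypic/sqrt(N1 N2)). Weights are iterated
inverse-variance weights recomputed once from a first 1/l pass (a plain
1/l fallback exists). Standard errors come from a delete-a-block jackknife
(default 200 contiguous blocks, the published convention); the blocks must
be at least as long as the LD correlation range or adjacent blocks stay
dependent and SEs are underestimated — the calibration studies therefore
align jackknife blocks with the generator's LD blocks; `build_genetic_cov` runs all t(t+1)/2 regressions
on one shared SNP universe with the same blocks, so the sampling covariance
V of vech(S) (lower-triangle row-major order) captures cross-element
dependence. S is eigenvalue-clipped to PSD when needed and the perturbation
norm recorded.

The genomic-SEM core fits a factor model to (S, V) by diagonally weighted
least squares, W = diag(V)^-1, with sandwich parameter covariance
(Δ'WΔ)^-1 Δ'W V W Δ (Δ'WΔ)^-1. The model chi-square is Browne's
residual-based statistic e'[(I−P)V(I−P)']^+ e with pseudo-inverse rank df —
the full-V statistic; CFI is computed against the independence model on the
same (S, V), SRMR on the correlation metric, and AIC = chi2 + 2k (the
summary-statistic convention; there is no casewise likelihood). A negative
residual-variance estimate triggers a refit with that residual fixed to 0
and is recorded on the results — under unit-variance identification this is
equivalent to fixing the offending standardized loading to 1.

Latent SNP weights hold the measurement model at its no-SNP estimates and
solve, per SNP, the weighted least-squares problem implied by appending the
SNP to S: observed per-allele trait effects beta_k against the model
prediction sum_f lambda_kf b_f, with per-SNP error covariance
Omega_kl = intercept_kl·se_k·se_l built from the LDSC intercept matrix (so
overlap-induced dependence between trait estimates is weighted correctly).
Because estimated cross-trait intercepts are noisy at modest SNP counts —
and slope–intercept leakage can make a disjoint pair's intercept look
large — off-diagonal intercepts enter Omega only under strong evidence
(beyond four jackknife SEs), diagonals are bounded to [0.5, 2] around their
theoretical value of ~1, and a normalized magnitude above 0.9 is treated
as a broken estimate and dropped rather than clipped.
One-at-a-time SNP models keep the step deterministic and O(m); joint
re-estimation per SNP is out of scope. The resulting per-allele factor
weights convert losslessly to the PGS weight-table format, so latent PGSs
are computed by exactly the same scoring code as observed-trait PGSs.

## Association and power

Associations are OLS of an outcome (phenotype or factor score) on one PGS
plus the top 10 ancestry PCs, on complete cases aligned by sample id.
Reports include the unstandardized coefficient with its SE, the
standardized coefficient, full-model R², covariates-only R², incremental R²
(the PGS performance metric, highlighted), and adjusted R². Rank-deficient
designs are rejected with the offending columns named. No multiple-testing
correction is applied; instead a power gate is computed:
`min_detectable_r2` inverts the noncentral-F power function (noncentrality
λ = f²·n; df1 = k_tested, df2 = n − k_total − 1) to the smallest f² reaching
the requested power, and converts to R² and adjusted R². Note that at small
effects the adjusted threshold can be negative (the adjustment term
−k/(n−k−1) dominates), in which case any non-negative adjusted R² is
detectable; the raw R² threshold is the strictly n-monotone quantity. At the
configuration n = 3003, alpha = 0.05, power = 0.80, one tested of 11
predictors, the machinery gives raw R² ≈ 0.0026 (adjusted ≈ −0.001); the
function exposes the full configuration space rather than asserting any one
published gate value.

## Pipeline and the model-acceptance rule

`run_study` executes QC → ancestry PCA → phenotype screening → split-half
(ceil/floor halves, seed-deterministic; a 6003-row sample splits 3002/3001)
→ one- vs two-factor CFA in the test half → holdout replication of the
accepted structure → invariance ladders → observed-trait PGSs → LDSC /
genomic SEM → latent PGSs → associations, logging every stage and seed,
and writes a JSON-serializable report validated for completeness. Stage
failures raise with the stage named and the partial report attached.

Model acceptance is an explicit rule: accept the two-factor model only when
the one-factor restriction depreciates fit (Δ-criteria) AND the inter-factor
correlation stays at or below an alert level (default 0.80); otherwise the
parsimonious one-factor model is kept. The alert formalizes the judgement
that two near-collinear factors do not measure distinct constructs. The
holdout half refits only the accepted structure.

## The synthetic-data generator

Genotypes use a Gaussian copula: per individual, two latent standard
normals per SNP with block-constant correlation (sqrt(rho)·shared +
sqrt(1−rho)·idiosyncratic), thresholded at the MAF quantile and summed to a
0/1/2 dosage. This gives exact MAF control and approximate LD control;
realized dosage correlations are attenuated relative to the latent rho
(more so at extreme MAF), which is fine because LD enters the downstream
methods only through estimated LD scores. MAFs are a deterministic
low-discrepancy property of the `SnpPanelSpec`, so every cohort simulated
from the same panel shares allele frequencies, exactly as cohorts genotyped
on the same array do — the LD reference panel must share frequencies with
the GWAS cohorts for LD scores to transfer. Missingness is MCAR.

GWAS summary statistics are produced mechanistically: per-SNP
standardized-scale effects are drawn from the latent genetic factor model
(factor effects ~ N(0, Psi/m) through the loadings, plus trait residuals),
individual-level cohorts are simulated with exact pairwise sample overlap
(pairwise-exclusive shared blocks; triple-wise overlap is not
representable), optional environmental correlation among shared
individuals, and each SNP is regressed marginally on each phenotype. LDSC
intercepts therefore arise from the data, not by construction. All traits
are continuous (liability-scale conversion is out of scope). Default scales
are desk-sized: cohorts of 5,000–20,000 and panels of 1,000–5,000 SNPs —
orders of magnitude below consortium GWAS, which is acceptable because
LDSC/genomic-SEM estimands are scale-free; what desk scale costs is
precision, which the calibration studies quantify rather than hide.

Phenotype panels follow the common-factor model with group-specific
intercepts and factor SDs (the shapes probed by the invariance ladder) and
MCAR missingness; the latent factor can be supplied externally, which is how
the pipeline couples the phenotypic general factor to the simulated genetic
factor (factor = sqrt(h2_factor)·standardized genetic value + noise,
h2_factor default 0.30). A second correlated phenotypic factor is expressed
by a second indicator block plus the generating inter-factor correlation.

## Calibration studies and their scales

`latentpgs.benchmarks` holds the package's verification suite; the test
suite asserts thresholds on its outputs and `scripts/acceptance.py` reports
them. The study designs, chosen once as the package's desk-scale analogues
of the motivating full-scale analyses:

* closed-form CFA recovery: 100 random just-identified 3-indicator models;
  agreement with lambda_1 = sqrt(s12·s13/s23) to 1e−8.
* invariance calibration: two groups of 1,000; 100 null replicates (expect
  residual invariance ≥ 90%) and 100 replicates with a 0.5-SD intercept
  shift (expect scalar rejection ≥ 90%).
* PGS exactness: 100×50 panel against a brute-force double loop, exact.
* LDSC recovery: 5,000 SNPs (100 LD blocks, latent rho 0.7, MAF
  0.02–0.5), three traits of n = 10,000 — two fully overlapping with
  environmental correlation 0.4, one disjoint; h² = 0.15–0.20, like
  observed-scale psychiatric traits. 20 replicates; jackknife-CI coverage
  of h² and genetic covariance, and intercept separation between the
  overlapping and disjoint pairs, asserted on replicate means.
* genomic-SEM recovery: 7 traits, two-factor truth with factor correlation
  0.64 and standardized loadings 0.55–0.93; h² = 0.30; n = 10,000 per
  cohort with adjacent cohorts sharing half their samples (consortium-style
  overlap); 3,000 SNPs; 20 replicates. Recovery within sandwich CIs and the
  one- vs two-factor decision pattern (Δchi², ΔCFI, AIC) are asserted. The
  sandwich CIs are mildly anticonservative at this scale (observed coverage
  ≈ 85–100% against the nominal 95%), consistent with noisy V estimation
  from 200 jackknife blocks.
* latent-PGS study: end-to-end `run_study` with a pleiotropic one-factor
  genetic truth over seven traits (GWAS n = 4,000 each, 1,500 SNPs, target
  cohort 2,400), 50 replicates; the latent one-factor PGS's mean
  incremental R² for the general phenotypic factor must exceed every
  single-trait PGS's. The scale puts per-SNP GWAS noise above per-SNP
  signal — the noise-dominated regime real polygenic scores live in, and
  the regime in which pooling GWAS through the factor model helps; at
  over-powered scales single-trait weights saturate the LD-smear ceiling
  and no ordering is predicted. Absolute R² values are far larger than
  consortium analyses report because the simulated panel is small and dense
  in causal SNPs; only the ordering is the claim.
* model-selection study: phenotypic two-factor truth with inter-factor
  correlation 0.82 (internalizing loadings 0.78–0.88; externalizing
  indicators loading 0.55–0.65 on their own factor), n = 6,003 with the
  3002/3001 split; 50 replicates; the pipeline must keep the one-factor
  model ≥ 90% of the time. At these loadings the estimated inter-factor
  correlation has SD ≈ 0.01, so the 0.80 alert separates reliably from the
  generating 0.82.

What passing these studies shows: the algebraic cores are exact; the
statistical machinery is calibrated and recovers truth at desk scale under
the generator's assumptions (normal indicators, MCAR holes, block LD,
infinitesimal effects, continuous traits). What they do not show: behaviour
under real LD maps, ascertained case/control traits, liability-scale
effects, population structure confounding beyond a displaced-cluster toy,
or item-level measurement artefacts.

## Known limitations

Bifactor and categorical-indicator models are out of scope, as are LD-aware
scoring methods, annotation-stratified LDSC, and imputation. The
Satorra–Bentler scaling under FIML uses complete cases. The generator's
pairwise-exclusive overlap blocks cannot express three-way sample sharing.
Duplicate SNP ids are dropped with a warning rather than resolved by
position. The two-step factor-score regression (PGS → factor scores) is the
default realization of PGS–factor association; a one-step structural
variant is not implemented beyond what composing the primitives provides.
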