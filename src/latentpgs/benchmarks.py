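"""Calibration studies: the package's own end-to-end verification suite.

Each function runs a self-contained simulation study against known ground
truth and returns the resulting summary quantities (recovery errors,
calibration rates, CI coverages, decision rates). The test suite asserts
thresholds on these quantities; ``scripts/acceptance.py`` reports them.

Problem sizes are desk-scale: cohort sizes in the thousands-to-tens-of-
thousands and SNP panels of 1,000-5,000, chosen so the scale-free estimands
(LDSC slopes and intercepts, factor loadings and correlations, incremental
R-squared orderings) remain recoverable with meaningful power. The methods
note discusses what these scales do and do not establish about
consortium-scale data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import simulate as sim
from .association import regress_with_pcs
from .cfa import CFAModel, invariance_ladder
from .genotype import GenotypeData
from .gsem import fit_gsem
from .ldsc import build_genetic_cov, compute_ld_scores, ldsc_bivariate, \
    ldsc_univariate
from .model_spec import FactorModelSpec
from .pgs import compute_pgs, harmonize_weights
from .pipeline import StudyConfig, SyntheticStudy, run_study

__all__ = [
    "data_with_exact_cov", "cfa_closed_form_study", "invariance_calibration",
    "pgs_exactness_study", "ldsc_recovery_study", "gsem_recovery_study",
    "latent_pgs_study", "pipeline_decision_study",
]


def data_with_exact_cov(S, n, rng):
    """A sample whose unbiased sample covariance equals S exactly."""
    S = np.asarray(S, dtype=float)
    Z = rng.standard_normal((n, S.shape[0]))
    Z -= Z.mean(0)
    C = np.cov(Z, rowvar=False, ddof=1)
    return Z @ np.linalg.inv(np.linalg.cholesky(C)).T @ np.linalg.cholesky(S).T


# ---------------------------------------------------------------------------

def cfa_closed_form_study(seed: int, n_matrices: int = 100) -> dict:
    """Just-identified 3-indicator fits vs the closed form
    lambda_1 = sqrt(s12*s13/s23) on random one-factor covariance matrices."""
    rng = np.random.default_rng(seed)
    spec = FactorModelSpec.one_factor(list("abc"))
    max_lam_err = 0.0
    max_chi2 = 0.0
    for _ in range(n_matrices):
        lam = rng.uniform(0.4, 0.95, 3)
        S = np.outer(lam, lam) + np.diag(1 - lam ** 2)
        X = data_with_exact_cov(S, 150, rng)
        res = CFAModel(X, spec).fit(estimator="ml")
        s12, s13, s23 = S[0, 1], S[0, 2], S[1, 2]
        closed = np.array([np.sqrt(s12 * s13 / s23),
                           np.sqrt(s12 * s23 / s13),
                           np.sqrt(s13 * s23 / s12)])
        est = np.abs(res.loadings.to_numpy().ravel())
        max_lam_err = max(max_lam_err, float(np.max(np.abs(est - closed))))
        max_chi2 = max(max_chi2, abs(res.chi2))
    return {"n_matrices": n_matrices,
            "max_loading_abs_error": max_lam_err,
            "max_chi2": max_chi2}


# ---------------------------------------------------------------------------

_INV_LOADINGS = np.array([0.88, 0.80, 0.70, 0.60, 0.50, 0.40])


def invariance_calibration(seed: int, n_reps: int = 100,
                           n_per_group: int = 1000,
                           shift: float = 0.5) -> dict:
    """Invariance-ladder calibration.

    Null arm: two groups simulated from identical parameters — how often is
    full residual invariance attained? Violation arm: group 2's intercepts
    shifted by ``shift`` indicator-SDs — how often is scalar invariance
    rejected?
    """
    rng = np.random.default_rng(seed)
    spec = FactorModelSpec.one_factor(list("abcdef"))
    lam = _INV_LOADINGS
    g = np.repeat(["g1", "g2"], n_per_group)

    def draw(delta):
        X = np.empty((2 * n_per_group, 6))
        for k, off in enumerate((0.0, delta)):
            sl = slice(k * n_per_group, (k + 1) * n_per_group)
            F = rng.standard_normal(n_per_group)
            X[sl] = (F[:, None] * lam
                     + rng.standard_normal((n_per_group, 6))
                     * np.sqrt(1 - lam ** 2) + off)
        return X

    null_resid = 0
    for _ in range(n_reps):
        rep = invariance_ladder(draw(0.0), spec, g)
        null_resid += rep.highest_level_attained == "residual"
    scalar_rej = 0
    for _ in range(n_reps):
        rep = invariance_ladder(draw(shift), spec, g)
        scalar_rej += rep.comparisons["scalar"].verdict == "depreciated"
    return {"n_reps": n_reps,
            "null_residual_attained_pct": 100.0 * null_resid / n_reps,
            "shift_scalar_rejected_pct": 100.0 * scalar_rej / n_reps}


# ---------------------------------------------------------------------------

def pgs_exactness_study(seed: int, n_ind: int = 100, n_snps: int = 50) -> dict:
    """compute_pgs vs an independent brute-force double loop, plus
    allele-orientation-flip invariance of the z-scores."""
    rng = np.random.default_rng(seed)
    panel = sim.SnpPanelSpec(n_snps=n_snps, n_blocks=5, within_block_corr=0.3)
    g = sim.simulate_genotypes(n_ind, panel, seed=seed)
    beta = rng.standard_normal(n_snps)
    ss = pd.DataFrame({"SNP": g.snp_meta["snp"], "A1": g.snp_meta["a1"],
                       "A2": g.snp_meta["a2"], "BETA": beta,
                       "SE": 0.1, "P": 0.5, "N": 1000})
    w = harmonize_weights(ss, g)
    res = compute_pgs(g, w)
    brute = np.zeros(n_ind)
    wmap = {s: (c, wt) for s, c, wt in
            zip(w["snp"], w["counted_allele"], w["weight"])}
    for i in range(n_ind):
        for j in range(n_snps):
            counted, wt = wmap[g.snp_meta["snp"][j]]
            d = g.dosages[i, j]
            if counted != g.snp_meta["a1"][j]:
                d = 2 - d
            brute[i] += wt * d
    max_err = float(np.max(np.abs(res["raw_score"].to_numpy() - brute)))
    # orientation flips
    flip = rng.random(n_snps) < 0.5
    ss2 = ss.copy()
    ss2.loc[flip, ["A1", "A2"]] = ss.loc[flip, ["A2", "A1"]].to_numpy()
    ss2.loc[flip, "BETA"] = -ss.loc[flip, "BETA"]
    z2 = compute_pgs(g, harmonize_weights(ss2, g))["z_score"]
    flip_err = float(np.max(np.abs(res["z_score"].to_numpy() - z2.to_numpy())))
    return {"n": n_ind * n_snps,
            "brute_force_max_abs_error": max_err,
            "orientation_flip_max_abs_z_diff": flip_err}


# ---------------------------------------------------------------------------

LDSC_PANEL = sim.SnpPanelSpec(n_snps=5000, n_blocks=100,
                              within_block_corr=0.7, maf_range=(0.02, 0.5))


def _ldsc_truth(n: int):
    # traits: x and y share one fully overlapping cohort; z is disjoint
    return sim.GeneticTruth(
        trait_names=("x", "y", "z"),
        loadings=np.array([[0.9], [0.7], [0.8]]),
        total_h2=[0.20, 0.15, 0.20],
        n_per_trait=[n, n, n],
        pairwise_overlap=np.array([[0, n, 0], [n, 0, 0], [0, 0, 0]]),
        env_corr=np.array([[1.0, 0.4, 0.0], [0.4, 1.0, 0.0],
                           [0.0, 0.0, 1.0]]))


def ldsc_recovery_study(seed: int, n_reps: int = 20, n_per_trait: int = 10000,
                        n_ref: int = 2500) -> dict:
    """LDSC calibration: jackknife-CI coverage of h2 and genetic covariance,
    and cross-trait intercepts with and without sample overlap."""
    truth = _ldsc_truth(n_per_trait)
    gref = sim.simulate_genotypes(n_ref, LDSC_PANEL, seed=seed + 901)
    ld = compute_ld_scores(gref, window_snps=60)
    cov_h2 = cov_rg = 0
    int_overlap, int_disjoint = [], []
    for rep in range(n_reps):
        tabs, S = sim.simulate_multitrait_gwas(truth, LDSC_PANEL,
                                               seed=seed + rep)
        uni = ldsc_univariate(tabs[0], ld, n_blocks=100)
        lo, hi = uni.h2_ci()
        cov_h2 += lo <= S[0, 0] <= hi
        bo = ldsc_bivariate(tabs[0], tabs[1], ld, n_blocks=100)
        lo, hi = bo.h2_ci()
        cov_rg += lo <= S[0, 1] <= hi
        bd = ldsc_bivariate(tabs[0], tabs[2], ld, n_blocks=100)
        int_overlap.append(bo.intercept)
        int_disjoint.append(bd.intercept)
    io, idj = np.asarray(int_overlap), np.asarray(int_disjoint)
    return {
        "n_reps": n_reps,
        "h2_ci_coverage_pct": 100.0 * cov_h2 / n_reps,
        "rg_ci_coverage_pct": 100.0 * cov_rg / n_reps,
        "overlap_intercept_mean": float(io.mean()),
        "overlap_intercept_tstat": float(
            io.mean() / (io.std(ddof=1) / np.sqrt(n_reps))),
        "disjoint_intercept_mean": float(idj.mean()),
        "disjoint_intercept_tstat": float(
            idj.mean() / (idj.std(ddof=1) / np.sqrt(n_reps))),
        "true_h2": 0.20,
    }


# ---------------------------------------------------------------------------

GSEM_FACTOR_CORR = 0.64
GSEM_TRAITS = ("neu", "anx", "mdd", "alc", "adhd", "can", "asb")
GSEM_PATTERN = {"neu": "INT", "anx": "INT", "mdd": "INT",
                "alc": "EXT", "adhd": "EXT", "can": "EXT", "asb": "EXT"}
_GSEM_LOADINGS = {"neu": 0.80, "anx": 0.88, "mdd": 0.93,
                  "alc": 0.81, "adhd": 0.65, "can": 0.55, "asb": 0.79}

GSEM_PANEL = sim.SnpPanelSpec(n_snps=3000, n_blocks=100,
                              within_block_corr=0.7, maf_range=(0.02, 0.5))


def _gsem_truth(n: int):
    L = np.zeros((7, 2))
    for i, t in enumerate(GSEM_TRAITS):
        L[i, 0 if GSEM_PATTERN[t] == "INT" else 1] = _GSEM_LOADINGS[t]
    # adjacent cohorts share half their samples (consortium-style overlap,
    # absorbed by the cross-trait LDSC intercepts)
    O = np.zeros((7, 7), dtype=int)
    for i in range(6):
        O[i, i + 1] = O[i + 1, i] = n // 2
    return sim.GeneticTruth(
        trait_names=GSEM_TRAITS, loadings=L,
        factor_corr=np.array([[1.0, GSEM_FACTOR_CORR],
                              [GSEM_FACTOR_CORR, 1.0]]),
        total_h2=[0.30] * 7, n_per_trait=[n] * 7,
        pairwise_overlap=O)


def gsem_recovery_study(seed: int, n_reps: int = 20,
                        n_per_trait: int = 10000, n_ref: int = 2000) -> dict:
    """Seven traits from a two-factor genetic truth (factor correlation
    0.64): loading/factor-correlation recovery within jackknife CIs and the
    one- vs two-factor decision pattern."""
    truth = _gsem_truth(n_per_trait)
    gref = sim.simulate_genotypes(n_ref, GSEM_PANEL, seed=seed + 901)
    ld = compute_ld_scores(gref, window_snps=60)
    spec1 = FactorModelSpec.one_factor(list(GSEM_TRAITS), "G")
    spec2 = FactorModelSpec.two_factor(dict(GSEM_PATTERN),
                                       factor_names=["INT", "EXT"])
    true_load_std = np.array([_GSEM_LOADINGS[t] for t in GSEM_TRAITS])
    corr_cover = 0
    load_cover = load_total = 0
    prefer = 0
    corrs = []
    for rep in range(n_reps):
        tabs, S = sim.simulate_multitrait_gwas(truth, GSEM_PANEL,
                                               seed=seed + rep)
        gcov = build_genetic_cov(tabs, ld, n_blocks=100,
                                 trait_names=list(GSEM_TRAITS))
        f2 = fit_gsem(gcov, spec2)
        f1 = fit_gsem(gcov, spec1)
        # factor correlation CI from the sandwich SE of psi[INT,EXT]
        prow = f2.params.set_index("param")
        est = prow.loc["psi[INT,EXT]", "estimate"]
        se = prow.loc["psi[INT,EXT]", "se"]
        corrs.append(est)
        corr_cover += abs(est - GSEM_FACTOR_CORR) <= 1.96 * se
        # unstandardized truth: loading on covariance scale
        lam_true = true_load_std * np.sqrt(0.30)
        for i, t in enumerate(GSEM_TRAITS):
            fac = GSEM_PATTERN[t]
            lam_est = prow.loc[f"lambda[{t},{fac}]", "estimate"]
            lam_se = prow.loc[f"lambda[{t},{fac}]", "se"]
            load_total += 1
            load_cover += abs(abs(lam_est) - lam_true[i]) <= 1.96 * lam_se
        dchi = f1.chi2 - f2.chi2
        prefer += (f2.aic < f1.aic) and (f2.cfi - f1.cfi > 0.0) and (dchi > 0)
    return {
        "n_reps": n_reps,
        "factor_corr_mean": float(np.mean(corrs)),
        "true_factor_corr": GSEM_FACTOR_CORR,
        "factor_corr_ci_coverage_pct": 100.0 * corr_cover / n_reps,
        "loading_ci_coverage_pct": 100.0 * load_cover / load_total,
        "two_factor_preferred_pct": 100.0 * prefer / n_reps,
    }


# ---------------------------------------------------------------------------

LATENT_TRAITS = ("neu", "anx", "mdd", "alc", "adhd", "can", "asb")
# low-MAF SNPs anchor the LDSC intercept (see LDSC_PANEL)
LATENT_PANEL = sim.SnpPanelSpec(n_snps=1500, n_blocks=100,
                                within_block_corr=0.7, maf_range=(0.02, 0.5))


def _latent_config(seed: int, n_gwas: int, n_target: int):
    gen = sim.GeneticTruth(
        trait_names=LATENT_TRAITS,
        loadings=np.array([[0.85], [0.80], [0.78], [0.75],
                           [0.72], [0.70], [0.68]]),
        total_h2=[0.30] * 7, n_per_trait=[n_gwas] * 7)
    ph = sim.PhenoTruth.single_group(
        (0.85, 0.80, 0.70, 0.60, 0.50),
        indicator_names=("na", "anxs", "dep", "imp", "ang"))
    syn = SyntheticStudy(pheno=ph, n_individuals=n_target, panel=LATENT_PANEL,
                         genetic=gen, h2_factor=0.30)
    return StudyConfig(synthetic=syn, seed=seed, split_seed=seed + 1,
                       run_invariance=False,
                       ldsc={"window_snps": 40, "n_blocks": 100})


def latent_pgs_study(seed: int, n_reps: int = 50, n_gwas: int = 4000,
                     n_target: int = 2400) -> dict:
    """End-to-end: pleiotropic one-factor genetic truth, seven trait GWAS in
    the noise-dominated regime (per-SNP GWAS noise exceeds per-SNP signal,
    as in consortium-scale polygenic scores), latent one-factor PGS vs each
    single-trait PGS as predictors of the general phenotypic factor
    (incremental R-squared over 10 ancestry PCs)."""
    inc = {}
    for rep in range(n_reps):
        report = run_study(_latent_config(seed + 37 * rep, n_gwas, n_target))
        for row in report.associations:
            inc.setdefault(row["predictor"], []).append(row["r2_incremental"])
    means = {k: float(np.mean(v)) for k, v in inc.items()}
    latent = means["latent:G"]
    singles = {k: v for k, v in means.items() if not k.startswith("latent")}
    best_single = max(singles, key=singles.get)
    return {
        "n_reps": n_reps,
        "latent_pgs_incremental_r2_pct": 100.0 * latent,
        "best_single_pgs_incremental_r2_pct": 100.0 * singles[best_single],
        "best_single_pgs": best_single,
        "single_pgs_incremental_r2_pct": {k: 100.0 * v
                                          for k, v in singles.items()},
        "latent_beats_every_single": bool(
            all(latent > v for v in singles.values())),
    }


# ---------------------------------------------------------------------------

PIPELINE_INTERFACTOR_CORR = 0.82


def _decision_config(seed: int, n_individuals: int = 6003):
    ph_int = sim.PhenoTruth.single_group(
        (0.88, 0.80, 0.78), indicator_names=("na", "anxs", "dep"))
    ph_ext = sim.PhenoTruth.single_group(
        (0.65, 0.60, 0.55), indicator_names=("imp", "tang", "sang"))
    syn = SyntheticStudy(pheno=ph_int, pheno2=ph_ext,
                         pheno_factor_corr=PIPELINE_INTERFACTOR_CORR,
                         n_individuals=n_individuals)
    pattern = {"na": "INT", "anxs": "INT", "dep": "INT",
               "imp": "EXT", "tang": "EXT", "sang": "EXT"}
    return StudyConfig(synthetic=syn, seed=seed, split_seed=seed + 1,
                       two_factor_pattern=pattern, run_invariance=False)


def pipeline_decision_study(seed: int, n_reps: int = 50,
                            n_individuals: int = 6003) -> dict:
    """Phenotypic truth with inter-factor correlation 0.82: how often does
    the full pipeline accept the parsimonious one-factor model?"""
    one_factor = 0
    corrs = []
    alerts = 0
    for rep in range(n_reps):
        report = run_study(_decision_config(seed + 101 * rep, n_individuals))
        d = report.cfa
        one_factor += d["accepted_model"] == "one_factor"
        if d["interfactor_corr"] is not None:
            corrs.append(d["interfactor_corr"])
        alerts += bool(d["corr_alert_triggered"])
    return {
        "n_reps": n_reps,
        "one_factor_selected_pct": 100.0 * one_factor / n_reps,
        "interfactor_corr_mean": float(np.mean(corrs)) if corrs else None,
        "true_interfactor_corr": PIPELINE_INTERFACTOR_CORR,
        "corr_alert_triggered_pct": 100.0 * alerts / n_reps,
    }
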