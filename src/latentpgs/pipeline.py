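"""Config-driven orchestration of the full study workflow.

``run_study`` executes, in order: genotype QC, two-stage ancestry PCA,
phenotype screening (indicators loading negatively on the general factor are
dropped and the model refitted), a split-half design (one- and two-factor
models estimated in the test half, the accepted structure replicated in the
holdout half), measurement-invariance ladders, per-trait polygenic scores,
LD-score regression and genomic SEM on the GWAS summary statistics, latent
polygenic scores, and PGS-factor associations with ancestry-PC covariates.

Model acceptance is an explicit rule: the two-factor phenotypic model is
accepted only when the comparison verdict says the one-factor restriction
really deteriorates fit AND the inter-factor correlation stays below a
configurable alert level (default 0.80); otherwise the parsimonious
one-factor model is kept. The alert formalizes the judgement that two
near-collinear factors do not represent distinct constructs.

Every stage is logged with its seed; a stage failure raises
:class:`StageError` carrying the partial report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import cfa as _cfa
from . import simulate as _sim
from .association import PowerSpec, min_detectable_r2, regress_with_pcs
from .cfa import CFAModel, compare_models, invariance_ladder, split_half
from .genotype import ancestry_pca_select, qc_filter, read_genotypes
from .gsem import fit_gsem, latent_snp_weights, latent_weights_to_pgs_table
from .ldsc import build_genetic_cov, compute_ld_scores
from .model_spec import FactorModelSpec
from .pgs import compute_pgs, harmonize_weights, read_sumstats

__all__ = ["StudyConfig", "SyntheticStudy", "StudyReport", "StageError",
           "run_study", "validate_report"]

log = logging.getLogger("latentpgs.pipeline")

DEFAULT_THRESHOLDS = {
    "delta_cfi": 0.01,
    "delta_rmsea": 0.015,
    "corr_alert": 0.80,
    "power_alpha": 0.05,
    "power_target": 0.80,
}


@dataclass
class SyntheticStudy:
    """Synthetic-truth block: what to generate instead of reading data.

    ``pheno`` defines the (first) phenotypic factor's indicators. A second,
    correlated factor is expressed by giving ``pheno2`` (its indicators) and
    ``pheno_factor_corr`` — the generating inter-factor correlation; any
    genetic coupling applies to the first factor.
    """
    pheno: _sim.PhenoTruth
    n_individuals: int = 3000
    panel: _sim.SnpPanelSpec = None
    genetic: _sim.GeneticTruth = None
    h2_factor: float = 0.30        # genetic share of the phenotypic factor
    group_probs: dict = None       # label -> probability (defaults: pheno groups, equal)
    pheno2: _sim.PhenoTruth = None
    pheno_factor_corr: float = 0.0

    def __post_init__(self):
        if self.group_probs is None:
            labs = list(self.pheno.intercepts_by_group)
            self.group_probs = {g: 1.0 / len(labs) for g in labs}
        if self.pheno2 is not None:
            dup = set(self.pheno.indicator_names) & set(self.pheno2.indicator_names)
            if dup:
                raise ValueError(f"indicator names shared across factors: {dup}")
            if not (-1.0 <= self.pheno_factor_corr <= 1.0):
                raise ValueError("pheno_factor_corr must lie in [-1, 1]")


@dataclass
class StudyConfig:
    """Exactly one of ``paths`` / ``synthetic`` selects the data source."""
    synthetic: SyntheticStudy = None
    paths: dict = None             # genotypes (plink prefix), sumstats (list), phenotypes (tsv)
    indicators: tuple = None       # phenotype columns (user-data path)
    two_factor_pattern: dict = None        # indicator -> factor name
    gsem_two_factor_pattern: dict = None   # trait -> factor name
    seed: int = 0
    split_seed: int = 0
    group_columns: tuple = ("group",)
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    run_invariance: bool = True
    run_genetics: bool = True
    estimator: str = "ml_robust"
    qc: dict = field(default_factory=dict)
    pca: dict = field(default_factory=lambda: {"label": "EUR", "sd_window": 1.0,
                                               "n_pcs_out": 10})
    ldsc: dict = field(default_factory=lambda: {"window_snps": 100,
                                                "n_blocks": 200})

    def __post_init__(self):
        if (self.synthetic is None) == (self.paths is None):
            raise ValueError("provide exactly one of synthetic= or paths=")
        thr = dict(DEFAULT_THRESHOLDS)
        thr.update(self.thresholds or {})
        self.thresholds = thr

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        syn = None
        if "synthetic" in d:
            s = d["synthetic"]
            panel = _sim.SnpPanelSpec(**s["panel"]) if "panel" in s else None
            gen = None
            if s.get("genetic"):
                gkw = dict(s["genetic"])
                for key in ("loadings", "factor_corr", "pairwise_overlap",
                            "env_corr"):
                    if key in gkw and gkw[key] is not None:
                        gkw[key] = np.asarray(gkw[key], dtype=float)
                gen = _sim.GeneticTruth(**gkw)
            pk = dict(s["pheno"])
            if "intercepts_by_group" in pk:
                pheno = _sim.PhenoTruth(**pk)
            else:
                pheno = _sim.PhenoTruth.single_group(**pk)
            syn = SyntheticStudy(
                pheno=pheno, n_individuals=s.get("n_individuals", 3000),
                panel=panel, genetic=gen,
                h2_factor=s.get("h2_factor", 0.30),
                group_probs=s.get("group_probs"))
        kw = {k: v for k, v in d.items() if k != "synthetic"}
        if "two_factor_pattern" in kw and kw["two_factor_pattern"]:
            kw["two_factor_pattern"] = dict(kw["two_factor_pattern"])
        return cls(synthetic=syn, **kw)


@dataclass
class StudyReport:
    seeds: dict = field(default_factory=dict)
    qc: dict = None
    pca: dict = None
    screening: dict = None
    split: dict = None
    cfa: dict = None
    holdout: dict = None
    invariance: dict = None
    pgs: dict = None
    ldsc: dict = None
    gsem: dict = None
    latent_pgs: dict = None
    associations: list = None
    power_gate: dict = None
    skipped: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    partial: bool = False
    error: str = None

    def to_dict(self) -> dict:
        return _jsonable(asdict(self))

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    def text_summary(self) -> str:
        d = self.to_dict()
        lines = ["Study report", "=" * 60]
        for k, v in d.items():
            if v in (None, {}, []):
                continue
            lines.append(f"[{k}]")
            lines.append(json.dumps(v, indent=2)[:2000])
        return "\n".join(lines)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception, report: StudyReport):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
        self.report = report


def _jsonable(x):
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (pd.Series,)):
        return x.to_dict()
    if isinstance(x, pd.DataFrame):
        return x.to_dict(orient="list")
    return x


def _fit_summary(fit) -> dict:
    d = {"chi2": fit.chi2, "df": fit.df, "cfi": fit.cfi, "tli": getattr(fit, "tli", None),
         "rmsea": getattr(fit, "rmsea", None), "srmr": fit.srmr, "aic": fit.aic,
         "n": getattr(fit, "n_obs", None), "converged": fit.converged,
         "std_loadings": fit.std_loadings.to_dict()}
    if len(fit.spec.factors) > 1:
        d["factor_corr"] = fit.factor_cov.to_dict()
    return d


def _verdict_dict(v) -> dict:
    return {"delta_chi2": v.delta_chi2, "delta_df": v.delta_df,
            "delta_cfi": v.delta_cfi, "delta_rmsea": v.delta_rmsea,
            "delta_aic": v.delta_aic, "verdict": v.verdict}


def run_study(cfg: StudyConfig, out_json=None) -> StudyReport:
    """Execute the full workflow; returns a structured report."""
    report = StudyReport(seeds={"seed": cfg.seed, "split_seed": cfg.split_seed})
    stage = "setup"
    t_start = time.time()

    def tick(name):
        report.timings[name] = round(time.time() - t_start, 3)
        log.info("stage %s done (%.2fs)", name, report.timings[name])

    try:
        # ------------------------------------------------------------ inputs
        stage = "inputs"
        sumstats = []
        trait_names = []
        genetic_truth = None
        extras = None
        if cfg.synthetic is not None:
            syn = cfg.synthetic
            if syn.genetic is not None and syn.panel is not None and cfg.run_genetics:
                genetic_truth = syn.genetic
                sumstats, _, extras = _sim.simulate_multitrait_gwas(
                    genetic_truth, syn.panel, seed=cfg.seed,
                    return_effects=True)
                trait_names = list(genetic_truth.trait_names)
            g = None
            if syn.panel is not None:
                g = _sim.simulate_genotypes(syn.n_individuals, syn.panel,
                                            seed=cfg.seed + 1,
                                            missing_rate=0.005)
        else:
            paths = cfg.paths
            g = read_genotypes(paths["genotypes"]) if paths.get("genotypes") else None
            for p in paths.get("sumstats", []):
                ss = read_sumstats(p)
                sumstats.append(ss)
                trait_names.append(ss.attrs.get("trait", str(p)))
        tick("inputs")

        # ---------------------------------------------------------- qc + pca
        pcs_frame = None
        if g is not None:
            stage = "qc"
            g, qc_rep = qc_filter(g, **cfg.qc)
            report.qc = _jsonable(qc_rep.__dict__)
            tick("qc")
            stage = "pca"
            g = ancestry_pca_select(g, **cfg.pca)
            k = cfg.pca.get("n_pcs_out", 10)
            pcs_frame = g.sample_meta[["iid"] + [f"PC{j + 1}" for j in range(k)]]
            report.pca = {"n_retained": g.n_samples, "n_pcs": k}
            tick("pca")
        else:
            report.skipped["qc"] = report.skipped["pca"] = "no genotype data"

        # -------------------------------------------------------- phenotypes
        stage = "phenotypes"
        if cfg.synthetic is not None:
            syn = cfg.synthetic
            n = g.n_samples if g is not None else syn.n_individuals
            rng = np.random.default_rng(cfg.seed + 2)
            labs = list(syn.group_probs)
            groups = rng.choice(labs, size=n, p=[syn.group_probs[l] for l in labs])
            factor = None
            if extras is not None and g is not None:
                # couple the phenotypic factor to the latent genetic factor;
                # QC may have dropped SNPs, so map ids back to panel rows
                panel_pos = pd.Series(
                    np.arange(syn.panel.n_snps),
                    index=_sim._panel_meta(syn.panel)["snp"])
                rows = panel_pos[g.snp_meta["snp"]].to_numpy()
                Z = g.dosages.astype(np.float32)
                Z[Z < 0] = np.nan
                freq = np.nanmean(Z, axis=0) / 2
                freq = np.clip(freq, 1e-6, 1 - 1e-6)
                Z = np.where(np.isnan(Z), 2 * freq, Z)
                Z = (Z - 2 * freq) / np.sqrt(2 * freq * (1 - freq))
                gf = Z @ extras["factor_effects"][rows, 0]
                gf = (gf - gf.mean()) / gf.std(ddof=1)
                h2f = syn.h2_factor
                factor = (np.sqrt(h2f) * gf
                          + np.sqrt(1 - h2f) * rng.standard_normal(n))
            pheno, f1 = _sim.simulate_phenotype_panel(
                n, syn.pheno, groups, seed=cfg.seed + 3,
                factor_values=factor, return_factor=True)
            indicators = list(syn.pheno.indicator_names)
            if syn.pheno2 is not None:
                rho = syn.pheno_factor_corr
                f2 = rho * f1 + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)
                pheno2 = _sim.simulate_phenotype_panel(
                    n, syn.pheno2, groups, seed=cfg.seed + 4, factor_values=f2)
                ind2 = list(syn.pheno2.indicator_names)
                pheno = pd.concat([pheno, pheno2[ind2]], axis=1)
                indicators += ind2
            if g is not None:
                pheno["iid"] = g.sample_meta["iid"].to_numpy()
        else:
            pheno = pd.read_csv(cfg.paths["phenotypes"], sep="\t")
            indicators = list(cfg.indicators)
            if g is not None:
                pheno = pheno[pheno["iid"].isin(g.sample_meta["iid"])]
        tick("phenotypes")

        # ------------------------------------------------------------- split
        stage = "split"
        test, holdout = split_half(pheno, seed=cfg.split_seed)
        report.split = {"n_test": len(test), "n_holdout": len(holdout)}
        tick("split")

        # --------------------------------------------------------- screening
        stage = "screening"
        spec1 = FactorModelSpec.one_factor(indicators)
        res_screen, dropped = _cfa.drop_negative_indicators(
            test, spec1, estimator=cfg.estimator)
        indicators = [i for i in indicators if i not in dropped]
        spec1 = res_screen.spec
        report.screening = {"dropped_negative_loading": dropped,
                            "indicators_kept": indicators}
        tick("screening")

        # ------------------------------------------------------ cfa compare
        stage = "cfa_compare"
        thr = cfg.thresholds
        fit1 = res_screen
        fit2 = None
        verdict = None
        inter_corr = None
        accepted = "one_factor"
        if cfg.two_factor_pattern:
            pat = {i: cfg.two_factor_pattern[i] for i in indicators
                   if i in cfg.two_factor_pattern}
            fac_counts = pd.Series(list(pat.values())).value_counts()
            if len(fac_counts) >= 2 and (fac_counts >= 2).all():
                spec2 = FactorModelSpec.two_factor(pat)
                fit2 = CFAModel(test, spec2).fit(estimator=cfg.estimator)
                verdict = compare_models(fit2, fit1,
                                         delta_cfi_max=thr["delta_cfi"],
                                         delta_rmsea_max=thr["delta_rmsea"])
                off = fit2.factor_cov.to_numpy()[np.triu_indices(len(spec2.factors), 1)]
                inter_corr = float(np.max(np.abs(off)))
                if verdict.verdict == "depreciated" and inter_corr <= thr["corr_alert"]:
                    accepted = "two_factor"
        report.cfa = {
            "one_factor": _fit_summary(fit1),
            "two_factor": _fit_summary(fit2) if fit2 is not None else None,
            "comparison": _verdict_dict(verdict) if verdict else None,
            "interfactor_corr": inter_corr,
            "corr_alert_level": thr["corr_alert"],
            "corr_alert_triggered": (inter_corr is not None
                                     and inter_corr > thr["corr_alert"]),
            "accepted_model": accepted,
        }
        tick("cfa_compare")

        # ----------------------------------------------------------- holdout
        stage = "holdout"
        acc_spec = fit1.spec if accepted == "one_factor" else fit2.spec
        hold_fit = CFAModel(holdout, acc_spec).fit(estimator=cfg.estimator)
        report.holdout = _fit_summary(hold_fit)
        tick("holdout")

        # -------------------------------------------------------- invariance
        if cfg.run_invariance:
            stage = "invariance"
            report.invariance = {}
            for col in cfg.group_columns:
                if col not in pheno.columns:
                    report.skipped[f"invariance:{col}"] = "column absent"
                    continue
                labels = pheno[col]
                if labels.nunique() < 2:
                    report.skipped[f"invariance:{col}"] = "fewer than 2 groups"
                    continue
                ladder = invariance_ladder(
                    pheno, acc_spec.with_(group_constraints="none"), labels,
                    estimator=cfg.estimator,
                    delta_cfi_max=thr["delta_cfi"],
                    delta_rmsea_max=thr["delta_rmsea"])
                report.invariance[col] = {
                    "highest_level_attained": ladder.highest_level_attained,
                    "levels": {k: _fit_summary(v) for k, v in ladder.levels.items()},
                    "comparisons": {k: _verdict_dict(v)
                                    for k, v in ladder.comparisons.items()},
                }
            tick("invariance")
        else:
            report.skipped["invariance"] = "disabled in config"

        # --------------------------------------------------- genetics branch
        scores = {}
        if sumstats and g is not None and cfg.run_genetics:
            stage = "pgs"
            for name, ss in zip(trait_names, sumstats):
                w = harmonize_weights(ss, g, source=name)
                scores[name] = compute_pgs(g, w)
            report.pgs = {name: {
                "n_snps_used": int(s["n_snps_used"].iloc[0]),
                "raw_mean": float(s["raw_score"].mean()),
                "raw_sd": float(s["raw_score"].std(ddof=1)),
            } for name, s in scores.items()}
            tick("pgs")

            stage = "ldsc_gsem"
            ld = compute_ld_scores(g, window_snps=cfg.ldsc["window_snps"])
            gcov = build_genetic_cov(sumstats, ld,
                                     n_blocks=cfg.ldsc["n_blocks"],
                                     trait_names=trait_names)
            report.ldsc = {
                "S": gcov.S, "intercepts": gcov.intercepts,
                "m_snps": gcov.m_snps, "n_blocks": gcov.n_blocks,
                "smoothing_applied": gcov.smoothing_applied,
            }
            gspec1 = FactorModelSpec.one_factor(trait_names, "G")
            gfit1 = fit_gsem(gcov, gspec1)
            gfit2 = None
            gverdict = None
            g_accepted = "one_factor"
            if cfg.gsem_two_factor_pattern:
                gspec2 = FactorModelSpec.two_factor(
                    {t: cfg.gsem_two_factor_pattern[t] for t in trait_names})
                gfit2 = fit_gsem(gcov, gspec2)
                d_chi2 = gfit1.chi2 - gfit2.chi2
                d_cfi = gfit2.cfi - gfit1.cfi
                if (gfit2.aic < gfit1.aic and d_cfi > thr["delta_cfi"]):
                    g_accepted = "two_factor"
                gverdict = {"delta_chi2": d_chi2, "delta_df": gfit1.df - gfit2.df,
                            "delta_cfi": d_cfi,
                            "delta_aic": gfit2.aic - gfit1.aic,
                            "accepted": g_accepted}
            report.gsem = {
                "one_factor": {"chi2": gfit1.chi2, "df": gfit1.df,
                               "cfi": gfit1.cfi, "srmr": gfit1.srmr,
                               "aic": gfit1.aic,
                               "heywood_fixed": gfit1.heywood_fixed,
                               "std_loadings": gfit1.std_loadings.to_dict()},
                "two_factor": None if gfit2 is None else
                              {"chi2": gfit2.chi2, "df": gfit2.df,
                               "cfi": gfit2.cfi, "srmr": gfit2.srmr,
                               "aic": gfit2.aic,
                               "heywood_fixed": gfit2.heywood_fixed,
                               "factor_corr": gfit2.factor_cov.to_dict(),
                               "std_loadings": gfit2.std_loadings.to_dict()},
                "comparison": gverdict,
            }
            tick("ldsc_gsem")

            stage = "latent_pgs"
            panel_snps = set(g.snp_meta["snp"])
            for gfit in filter(None, [gfit1, gfit2]):
                lw = latent_snp_weights(gcov, gfit, sumstats)
                for fac, tab in lw.items():
                    wt = latent_weights_to_pgs_table(tab)
                    wt = wt[wt["snp"].isin(panel_snps)].reset_index(drop=True)
                    scores[f"latent:{fac}"] = compute_pgs(g, wt)
            report.latent_pgs = {k: {"n_snps_used": int(v["n_snps_used"].iloc[0])}
                                 for k, v in scores.items() if k.startswith("latent:")}
            tick("latent_pgs")
        else:
            reason = ("no summary statistics" if not sumstats
                      else "no genotype data" if g is None
                      else "disabled in config")
            for s in ("pgs", "ldsc", "gsem", "latent_pgs"):
                report.skipped[s] = reason

        # ------------------------------------------------------ associations
        if scores:
            stage = "associations"
            hold_ids = holdout["iid"]
            fscores = hold_fit.factor_scores(holdout)
            rows = []
            k = cfg.pca.get("n_pcs_out", 10)
            pcs_hold = pcs_frame.set_index("iid").loc[hold_ids].to_numpy()
            gate = min_detectable_r2(PowerSpec(
                n=len(holdout), alpha=thr["power_alpha"],
                power=thr["power_target"], k_total=k + 1, k_tested=1))
            for fac in fscores.columns:
                out = pd.Series(fscores[fac].to_numpy(), dtype=float,
                                index=hold_ids.to_numpy())
                for name, sc in scores.items():
                    res = regress_with_pcs(out, sc, pcs_hold,
                                           predictor_name=name,
                                           outcome_name=f"factor:{fac}")
                    rows.append(res.to_row())
            report.associations = rows
            report.power_gate = {"adj_r2_threshold": gate,
                                 "n": len(holdout), "k_total": k + 1}
            tick("associations")
        else:
            report.skipped["associations"] = "no polygenic scores computed"

    except Exception as exc:                      # noqa: BLE001
        report.partial = True
        report.error = f"{stage}: {exc}"
        if out_json:
            report.to_json(out_json)
        raise StageError(stage, exc, report) from exc

    if out_json:
        report.to_json(out_json)
    return report


def validate_report(report: StudyReport, expect_genetics: bool = True,
                    expect_invariance: bool = True) -> list:
    """Check that every module invoked contributed a section; returns the
    list of problems (empty when the report is complete)."""
    problems = []
    base = ["split", "screening", "cfa", "holdout"]
    for s in base:
        if getattr(report, s) in (None, {}):
            problems.append(f"missing section: {s}")
    if expect_invariance and report.invariance in (None, {}) \
            and not any(k.startswith("invariance") for k in report.skipped):
        problems.append("missing section: invariance")
    genetic = ["qc", "pca", "pgs", "ldsc", "gsem", "latent_pgs", "associations"]
    for s in genetic:
        present = getattr(report, s) not in (None, {}, [])
        skipped = s in report.skipped or any(
            k.split(":")[0] == s for k in report.skipped)
        if expect_genetics and not present and not skipped:
            problems.append(f"missing section: {s}")
        if not expect_genetics and not present and not skipped:
            problems.append(f"section neither present nor skipped: {s}")
    return problems
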