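"""Genomic SEM: factor models of genetic covariance, and latent SNP weights.

:class:`GenomicSEM` fits a confirmatory factor model to an LDSC-estimated
genetic covariance matrix S by diagonally weighted least squares (weights =
inverse sampling variances from V), with sandwich-corrected standard errors
and a model chi-square that uses the full sampling covariance V (Browne's
residual-based statistic). A negative residual-variance estimate (Heywood
case) triggers a refit with that residual fixed to zero, and the fix is
recorded on the results.

:func:`latent_snp_weights` integrates per-SNP effects into the fitted model:
holding the measurement model at its estimates, each SNP's regression on the
latent factor(s) is solved by the same weighted-least-squares criterion, with
the per-SNP error covariance across traits built from the LDSC intercept
matrix (so overlapping-sample dependence is accounted for). The resulting
weights convert directly to polygenic-score weight tables, so latent-factor
PGSs are computed exactly like observed-trait PGSs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import _sem
from .ldsc import GeneticCov, align_sumstats
from .model_spec import FactorModelSpec
from .pgs import validate_sumstats

__all__ = ["GenomicSEM", "GsemResults", "fit_gsem", "latent_snp_weights",
           "latent_weights_to_pgs_table"]


@dataclass
class GsemResults:
    """Fitted genetic factor model with DWLS fit statistics."""

    spec: FactorModelSpec
    gcov: GeneticCov
    loadings: pd.DataFrame
    std_loadings: pd.DataFrame
    factor_cov: pd.DataFrame
    residual_var: pd.Series
    params: pd.DataFrame
    chi2: float
    df: int
    cfi: float
    srmr: float
    aic: float
    converged: bool
    heywood_fixed: list
    fit_fun: float
    meta: dict = field(default_factory=dict)
    _theta: np.ndarray = field(default=None, repr=False)
    _layout: _sem.ParamLayout = field(default=None, repr=False)

    @property
    def p_value(self) -> float:
        if self.df <= 0:
            return np.nan
        return float(stats.chi2.sf(self.chi2, self.df))

    def implied_cov(self) -> np.ndarray:
        Sigma, _ = self._layout.implied(self._theta, 0)
        return Sigma

    def summary(self) -> str:
        lines = [
            "Genomic SEM (DWLS on LDSC genetic covariance)",
            "=" * 60,
            f"traits: {', '.join(self.gcov.trait_names)}",
            f"chi2({self.df}) = {self.chi2:.3f}  p = {self.p_value:.3g}",
            f"CFI = {self.cfi:.3f}  SRMR = {self.srmr:.3f}  AIC = {self.aic:.3f}",
            "",
            "standardized loadings:",
            self.std_loadings.round(3).to_string(),
        ]
        if len(self.spec.factors) > 1:
            lines += ["", "factor correlations:",
                      self.factor_cov.round(3).to_string()]
        if self.heywood_fixed:
            lines += ["", "Heywood handling: residual variance fixed to 0 "
                      f"for {self.heywood_fixed}"]
        return "\n".join(lines)


class GenomicSEM:
    """Factor model for a genetic covariance matrix (S, V).

    Parameters
    ----------
    gcov : GeneticCov from :func:`latentpgs.ldsc.build_genetic_cov`.
    spec : FactorModelSpec whose indicators are gcov's trait names.
    """

    def __init__(self, gcov: GeneticCov, spec: FactorModelSpec):
        if tuple(spec.indicators) != tuple(gcov.trait_names):
            missing = set(spec.indicators) - set(gcov.trait_names)
            if missing:
                raise ValueError(f"spec indicators not in gcov: {sorted(missing)}")
            raise ValueError("spec indicators must match gcov trait order")
        if spec.mean_structure:
            raise ValueError("genetic covariance models have no mean structure")
        self.gcov = gcov
        self.spec = spec

    def fit(self, estimator: str = "dwls", fix_heywood: bool = True) -> GsemResults:
        if estimator != "dwls":
            raise ValueError("only the DWLS estimator is supported")
        gcov, spec = self.gcov, self.spec
        dV = np.diag(gcov.V)
        if np.any(dV <= 0):
            raise ValueError("V has non-positive diagonal entries; W singular")
        res = _fit_dwls(spec, gcov)
        heywood_fixed = []
        if fix_heywood:
            for _ in range(spec.n_indicators):
                layout = res["layout"]
                _, _, Th, _, _ = layout.unpack(res["theta"], 0)
                i_free, _, _, _ = layout.free[("theta", 0)]
                neg = [a for a in i_free if Th[a] < 0]
                if not neg:
                    break
                worst = min(neg, key=lambda a: Th[a])
                name = spec.indicators[worst]
                heywood_fixed.append(name)
                spec = spec.with_(fixed_params=tuple(spec.fixed_params)
                                  + ((f"theta[{name}]", 0.0),))
                res = _fit_dwls(spec, gcov)
        return _build_gsem_results(spec, gcov, res, heywood_fixed)


def fit_gsem(gcov: GeneticCov, spec: FactorModelSpec,
             estimator: str = "dwls") -> GsemResults:
    return GenomicSEM(gcov, spec).fit(estimator=estimator)


def _dwls_objective(theta, layout, s_obs, w):
    Sigma, _ = layout.implied(theta, 0)
    r_, c_ = _sem.vech_indices(layout.p)
    resid = s_obs - Sigma[r_, c_]
    F = float(resid @ (w * resid))
    dS, _ = layout.dsigma_dmu(theta, 0)
    Delta = dS[:, r_, c_]
    grad = -2.0 * Delta @ (w * resid)
    return F, grad


def _fit_dwls(spec: FactorModelSpec, gcov: GeneticCov):
    layout = _sem.ParamLayout(spec, 1)
    t = layout.p
    s_obs = gcov.s_vech()
    w = 1.0 / np.diag(gcov.V)
    theta0 = np.zeros(layout.n_free)
    dS = np.clip(np.diag(gcov.S), 1e-4, None)
    i, j, k, _ = layout.free[("lambda", 0)]
    theta0[k] = 0.7 * np.sqrt(dS[i])
    i, j, k, _ = layout.free[("psi", 0)]
    theta0[k] = np.where(i == j, 1.0, 0.3)
    i, _, k, _ = layout.free[("theta", 0)]
    theta0[k] = 0.5 * dS[i]
    best = None
    rng = np.random.default_rng(0)
    for attempt in range(4):
        x0 = theta0 if attempt == 0 else theta0 * (1 + 0.3 * rng.standard_normal(theta0.shape))
        r = optimize.minimize(_dwls_objective, x0, args=(layout, s_obs, w),
                              jac=True, method="L-BFGS-B",
                              options={"maxiter": 2000, "ftol": 1e-16,
                                       "gtol": 1e-10})
        if best is None or r.fun < best.fun - 1e-14:
            best = r
        if np.linalg.norm(best.jac, np.inf) < 1e-7:
            break
    q = t * (t + 1) // 2
    df = q - layout.n_free
    if df < 0:
        raise ValueError("model not identified on the genetic covariance")
    return {"theta": best.x, "layout": layout, "F": float(best.fun),
            "df": df, "q": q, "w": w, "s_obs": s_obs,
            "converged": bool(np.isfinite(best.fun)
                              and np.linalg.norm(best.jac, np.inf) < 1e-4)}


def _browne_chi2(layout, theta, s_obs, w, V, df):
    """Residual-based test statistic using the full sampling covariance."""
    if df <= 0:
        return 0.0
    r_, c_ = _sem.vech_indices(layout.p)
    Sigma, _ = layout.implied(theta, 0)
    e = s_obs - Sigma[r_, c_]
    dS, _ = layout.dsigma_dmu(theta, 0)
    Delta = dS[:, r_, c_].T                       # (q, K)
    WD = Delta * w[:, None]
    P = Delta @ np.linalg.solve(Delta.T @ WD, WD.T)
    IP = np.eye(len(e)) - P
    Ve = IP @ V @ IP.T
    # pseudo-inverse restricted to the residual space (rank = df)
    ev, U = np.linalg.eigh(Ve)
    order = np.argsort(ev)[::-1]
    ev, U = ev[order[:df]], U[:, order[:df]]
    ev = np.clip(ev, 1e-14, None)
    return float(e @ (U @ np.diag(1.0 / ev) @ U.T) @ e)


def _sandwich_cov(layout, theta, w, V):
    r_, c_ = _sem.vech_indices(layout.p)
    dS, _ = layout.dsigma_dmu(theta, 0)
    Delta = dS[:, r_, c_].T
    WD = Delta * w[:, None]
    bread = np.linalg.inv(Delta.T @ WD)
    meat = WD.T @ V @ WD
    return bread @ meat @ bread


def _build_gsem_results(spec, gcov, res, heywood_fixed) -> GsemResults:
    layout, theta = res["layout"], res["theta"]
    t = layout.p
    chi2 = _browne_chi2(layout, theta, res["s_obs"], res["w"], gcov.V, res["df"])
    # independence baseline on the same (S, V)
    bspec = spec.baseline_spec()
    bres = _fit_dwls(bspec, gcov)
    chi2_b = _browne_chi2(bres["layout"], bres["theta"], bres["s_obs"],
                          bres["w"], gcov.V, bres["df"])
    d = max(chi2 - res["df"], 0.0)
    db = max(chi2_b - bres["df"], 0.0)
    cfi = 1.0 - d / max(db, d) if max(db, d) > 0 else 1.0
    # SRMR on the correlation metric
    Sigma, _ = layout.implied(theta, 0)
    sd = np.sqrt(np.clip(np.diag(gcov.S), 1e-12, None))
    resid = (gcov.S - Sigma) / np.outer(sd, sd)
    r_, c_ = _sem.vech_indices(t)
    srmr = float(np.sqrt(np.mean(resid[r_, c_] ** 2)))
    aic = chi2 + 2.0 * layout.n_free
    cov = _sandwich_cov(layout, theta, res["w"], gcov.V)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    params = pd.DataFrame({"param": layout.names, "estimate": theta, "se": se})
    params["z"] = params["estimate"] / params["se"].replace(0, np.nan)
    Lam, Psi, Th, _, _ = layout.unpack(theta, 0)
    gsd = np.sqrt(np.clip(np.diag(Sigma), 1e-12, None))
    fsd = np.sqrt(np.clip(np.diag(Psi), 0, None)) if layout.m else np.zeros(0)
    std_lam = Lam * fsd[None, :] / gsd[:, None] if layout.m else Lam.copy()
    psi_corr = Psi / np.outer(fsd, fsd) if layout.m else Psi
    inds, facs = list(spec.indicators), list(spec.factors)
    return GsemResults(
        spec=spec, gcov=gcov,
        loadings=pd.DataFrame(Lam, index=inds, columns=facs),
        std_loadings=pd.DataFrame(std_lam, index=inds, columns=facs),
        factor_cov=pd.DataFrame(psi_corr, index=facs, columns=facs),
        residual_var=pd.Series(Th, index=inds),
        params=params,
        chi2=float(chi2), df=res["df"], cfi=float(cfi), srmr=srmr,
        aic=float(aic), converged=res["converged"],
        heywood_fixed=heywood_fixed, fit_fun=res["F"],
        meta={"estimator": "dwls", "chi2": "Browne residual-based (full V)",
              "aic": "chi2 + 2*n_free", "srmr_metric": "correlation"},
        _theta=theta, _layout=layout,
    )


# ---------------------------------------------------------------------------
# per-SNP latent-factor weights

def latent_snp_weights(gcov: GeneticCov, fitted: GsemResults, all_ss: list,
                       ld=None) -> dict:
    """Estimate each SNP's effect on the latent factor(s).

    Holding the measurement model at the fitted estimates, the per-allele
    trait effects beta-hat of a SNP imply beta_k = sum_f lambda_kf b_f; b is
    solved by weighted least squares with the per-SNP error covariance
    Omega_kl = intercept_kl * se_k * se_l (the LDSC intercept matrix encodes
    cross-trait sampling dependence from overlapping samples).

    Returns {factor_name: DataFrame(snp, counted_allele, weight, se, source)}.
    SNPs absent from any trait's table are dropped and counted in
    ``.attrs["n_dropped"]``.
    """
    if not fitted.converged:
        raise ValueError("latent weights need a converged genomic SEM fit")
    spec = fitted.spec
    if len(all_ss) != len(gcov.trait_names):
        raise ValueError("one summary-statistics table per trait is required")
    tables = [validate_sumstats(ss) for ss in all_ss]
    n_total = len(set().union(*(set(t["SNP"]) for t in tables)))
    merged = tables[0][["SNP", "A1", "A2", "BETA", "SE"]].rename(
        columns={"BETA": "BETA_0", "SE": "SE_0"})
    for k, ss in enumerate(tables[1:], start=1):
        mg = align_sumstats(tables[0], ss)
        add = mg[["SNP", "BETA_2", "SE_2"]].rename(
            columns={"BETA_2": f"BETA_{k}", "SE_2": f"SE_{k}"})
        merged = merged.merge(add, on="SNP", how="inner")
    n_dropped = n_total - len(merged)
    if len(merged) == 0:
        raise ValueError("no SNPs shared by every trait's summary statistics")
    t = len(tables)
    Lam = fitted.loadings.to_numpy()               # (t, f)
    f = Lam.shape[1]
    betas = merged[[f"BETA_{k}" for k in range(t)]].to_numpy()   # (m, t)
    ses = merged[[f"SE_{k}" for k in range(t)]].to_numpy()
    # per-SNP GLS with Omega = R * se se', R from the LDSC intercept matrix.
    # Cross-trait intercepts carry large sampling noise at modest SNP counts,
    # so off-diagonals are used only when estimated away from zero (> 2 SE);
    # diagonals are floored near their theoretical value of ~1.
    R = gcov.intercepts.copy()
    offd = ~np.eye(t, dtype=bool)
    if gcov.intercept_ses is not None:
        # demand strong evidence before treating trait estimates as
        # correlated: intercept noise easily mimics overlap at modest m
        keep = np.abs(R) > 4.0 * gcov.intercept_ses
        R[offd & ~keep] = 0.0
    # diagonal intercepts sit near 1 in theory; bound them so noisy
    # estimates cannot blow up the normalized off-diagonals
    dR = np.sqrt(np.clip(np.diag(R), 0.5, 2.0))
    R = R / np.outer(dR, dR)                       # correlation-like, diag 1
    np.fill_diagonal(R, 1.0)
    # a normalized magnitude near/above 1 marks a broken estimate, not a
    # strong correlation: drop it rather than clip it
    R[offd & (np.abs(R) > 0.9)] = 0.0
    ev = np.linalg.eigvalsh(R)
    if ev.min() < 1e-3:
        R = R + (1e-3 - ev.min()) * np.eye(t)
    m_snps = len(merged)
    Omega = R[None, :, :] * ses[:, :, None] * ses[:, None, :]
    Oi = np.linalg.inv(Omega)                      # (m, t, t)
    XtOi = np.einsum("tf,mtu->mfu", Lam, Oi)       # (m, f, t)
    A = np.einsum("mfu,ug->mfg", XtOi, Lam)        # (m, f, f)
    rhs = np.einsum("mfu,mu->mf", XtOi, betas)     # (m, f)
    b = np.linalg.solve(A, rhs[:, :, None])[:, :, 0]
    covb = np.linalg.inv(A)
    se_b = np.sqrt(np.einsum("mff->mf", covb).clip(0))
    out = {}
    for j, fac in enumerate(spec.factors):
        df = pd.DataFrame({
            "snp": merged["SNP"].to_numpy(),
            "counted_allele": merged["A1"].to_numpy(),
            "other_allele": merged["A2"].to_numpy(),
            "weight": b[:, j],
            "se": se_b[:, j],
            "source": f"latent:{fac}",
        })
        df.attrs["n_dropped"] = int(n_dropped)
        df.attrs["model_hash"] = hash((spec.indicators, spec.factors,
                                       tuple(sorted(map(str, spec.fixed_params)))))
        out[fac] = df
    return out


def latent_weights_to_pgs_table(lw: pd.DataFrame) -> pd.DataFrame:
    """Orient latent weights to the risk-increasing allele (pgs convention)."""
    w = lw["weight"].to_numpy(dtype=float).copy()
    counted = lw["counted_allele"].to_numpy(dtype=object).copy()
    other = lw["other_allele"].to_numpy(dtype=object).copy()
    neg = w < 0
    counted[neg], other[neg] = other[neg], counted[neg]
    w = np.abs(w)
    return pd.DataFrame({"snp": lw["snp"], "counted_allele": counted,
                         "weight": w, "source": lw["source"]})
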