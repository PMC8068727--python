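"""Confirmatory factor analysis of phenotype panels.

The entry point is :class:`CFAModel`, a statsmodels-style model object built
from a data frame of continuous indicators; ``fit()`` returns a
:class:`CFAResults` carrying parameter estimates with robust (sandwich)
standard errors, the chi-square and absolute/incremental fit indices
(CFI, TLI, RMSEA with 90% CI, SRMR, AIC), and diagnostics such as Heywood
cases and negative-loading indicators.

Model-comparison and invariance machinery follows common practice for large
samples: nested models are compared on change in CFI and RMSEA rather than the
chi-square difference alone (a CFI drop greater than 0.01 or an RMSEA rise
greater than 0.015 marks a real deterioration), and measurement invariance
across groups is tested as the usual four-level ladder (configural, metric,
scalar, residual).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import _sem
from .model_spec import FactorModelSpec, INVARIANCE_LEVELS, LEVEL_CONSTRAINTS

__all__ = [
    "CFAModel", "CFAResults", "ComparisonVerdict", "InvarianceReport",
    "fit_indices", "fit_indices_from_stats", "rmsea_ci", "compare_models",
    "invariance_ladder", "factor_scores", "split_half", "age_group_labels",
    "drop_negative_indicators",
]

#: fit-acceptability cutoffs: RMSEA below, CFI/TLI above
FIT_ACCEPTABLE = {"rmsea": 0.06, "cfi": 0.90, "tli": 0.90}

#: age bands used for invariance grouping: middle age, young-old, old-old
AGE_BANDS = ((51, 64), (65, 74), (75, 83))
AGE_LABELS = ("middle", "young-old", "old-old")


# ---------------------------------------------------------------------------
# fit indices

def rmsea_ci(chi2, df, n_eff, level=0.90):
    """RMSEA confidence interval by inverting the noncentral chi-square.

    ``n_eff`` is the chi-square multiplier (n - 1 for a single group).
    """
    if df <= 0 or n_eff <= 0:
        return (None, None)
    lo_p, hi_p = (1 + level) / 2, (1 - level) / 2

    def _bound(target):
        f = lambda nc: stats.ncx2.cdf(chi2, df, nc) - target
        if f(0.0) < 0:
            return 0.0
        hi = max(chi2, 1.0)
        while f(hi) > 0 and hi < 1e8:
            hi *= 2
        if f(hi) > 0:
            return hi
        return optimize.brentq(f, 0.0, hi, xtol=1e-12)

    lam_lo = _bound(lo_p)
    lam_hi = _bound(hi_p)
    return (np.sqrt(lam_lo / (df * n_eff)), np.sqrt(lam_hi / (df * n_eff)))


def fit_indices_from_stats(chi2, df, chi2_baseline, df_baseline, n_eff):
    """CFI/TLI/RMSEA (with 90% CI) recomputed from stored statistics.

    A pure function of (chi2, df, baseline chi2/df, effective n); undefined
    quantities (TLI/RMSEA at df = 0) are returned as None.
    """
    d = max(chi2 - df, 0.0)
    db = max(chi2_baseline - df_baseline, 0.0)
    cfi = 1.0 - d / max(db, d, np.finfo(float).tiny) if max(db, d) > 0 else 1.0
    tli = None
    if df > 0 and df_baseline > 0:
        denom = chi2_baseline / df_baseline - 1.0
        if abs(denom) > 1e-12:
            tli = (chi2_baseline / df_baseline - chi2 / df) / denom
    rmsea = rmsea_lo = rmsea_hi = None
    if df > 0:
        rmsea = float(np.sqrt(d / (df * n_eff)))
        rmsea_lo, rmsea_hi = rmsea_ci(chi2, df, n_eff)
    return {"cfi": float(cfi), "tli": None if tli is None else float(tli),
            "rmsea": rmsea, "rmsea_ci": (rmsea_lo, rmsea_hi)}


def fit_indices(fit: "CFAResults", baseline: "CFAResults") -> dict:
    """Incremental/absolute fit indices of ``fit`` against an explicit
    independence-model ``baseline`` fitted to the same data."""
    if baseline.df != fit._raw.pstar - len(fit.spec.indicators) * (
            1 + int(fit.spec.mean_structure)) * len(fit.group_ns):
        # baseline must be the independence model: p variances (+p means) free
        raise ValueError("baseline is not the independence model on this data")
    if baseline.n_obs != fit.n_obs:
        raise ValueError("baseline fitted to different data")
    out = fit_indices_from_stats(fit.chi2, fit.df, baseline.chi2, baseline.df,
                                 fit.n_eff)
    out["srmr"] = fit.srmr
    out["aic"] = fit.aic
    return out


def _srmr(raw: _sem.RawFit) -> float:
    """Root mean squared standardized covariance residual, group-weighted."""
    vals, weights = [], []
    r, c = np.tril_indices(raw.layout.p)
    for g, gd in enumerate(raw.groups):
        Sigma, _ = raw.layout.implied(raw.theta, g)
        if gd.complete:
            S = gd.S_full
        else:
            _, S = _sem._em_saturated(gd.rows)
        sd = np.sqrt(np.diag(S))
        resid = (S - Sigma) / np.outer(sd, sd)
        vals.append(np.mean(resid[r, c] ** 2))
        weights.append(gd.n)
    return float(np.sqrt(np.average(vals, weights=weights)))


# ---------------------------------------------------------------------------
# results object

@dataclass
class CFAResults:
    """Estimated factor model plus its full fit-statistic block."""

    spec: FactorModelSpec
    estimator: str
    params: pd.DataFrame              # name, estimate, se, z
    loadings: pd.DataFrame            # group-1 unstandardized loadings
    std_loadings: pd.DataFrame        # group-1 standardized loadings
    factor_cov: pd.DataFrame          # group-1 factor covariance (std = corr)
    residual_var: pd.Series
    intercepts: pd.Series
    chi2: float                       # chi-square used for indices (scaled if robust)
    chi2_ml: float                    # unscaled normal-theory chi-square
    scaling_factor: float
    df: int
    n_obs: int
    group_ns: tuple
    cfi: float
    tli: float
    rmsea: float
    rmsea_ci90: tuple
    srmr: float
    aic: float
    loglik: float
    n_free: int
    converged: bool
    heywood: list
    baseline_chi2: float
    baseline_df: int
    meta: dict = field(default_factory=dict)
    _raw: _sem.RawFit = field(default=None, repr=False)

    @property
    def n_eff(self) -> float:
        return float(sum(g.mult for g in self._raw.groups))

    def acceptable_fit(self) -> bool:
        ok = self.cfi is None or self.cfi > FIT_ACCEPTABLE["cfi"]
        if self.tli is not None:
            ok = ok and self.tli > FIT_ACCEPTABLE["tli"]
        if self.rmsea is not None:
            ok = ok and self.rmsea < FIT_ACCEPTABLE["rmsea"]
        return bool(ok)

    def group_matrices(self, g=0):
        return self._raw.layout.unpack(self._raw.theta, g)

    def implied_moments(self, g=0):
        return self._raw.layout.implied(self._raw.theta, g)

    def negative_loading_indicators(self) -> list:
        """Indicators whose standardized loading is negative on any factor
        (flagged for exclusion, mirroring the drinking-frequency screen)."""
        out = []
        for ind in self.std_loadings.index:
            row = self.std_loadings.loc[ind]
            lo = [v for v in row if v != 0.0]
            if lo and min(lo) < 0:
                out.append(ind)
        return out

    def factor_scores(self, data=None, standardize=True) -> pd.DataFrame:
        return factor_scores(self, data=data, standardize=standardize)

    def summary(self) -> str:
        lines = [
            "Confirmatory factor analysis",
            "=" * 60,
            f"estimator: {self.estimator}   n = {self.n_obs}"
            + (f"   groups: {len(self.group_ns)}" if len(self.group_ns) > 1 else ""),
            f"chi2({self.df}) = {self.chi2:.3f}"
            + (f"  (scaling factor {self.scaling_factor:.3f})"
               if self.estimator == "ml_robust" else ""),
            f"CFI = {_fmt(self.cfi)}  TLI = {_fmt(self.tli)}  "
            f"RMSEA = {_fmt(self.rmsea)} 90% CI [{_fmt(self.rmsea_ci90[0])}, "
            f"{_fmt(self.rmsea_ci90[1])}]  SRMR = {_fmt(self.srmr)}",
            f"AIC = {self.aic:.2f}   loglik = {self.loglik:.2f}",
            "",
            "standardized loadings (group 1):",
            self.std_loadings.round(3).to_string(),
        ]
        if len(self.spec.factors) > 1:
            lines += ["", "factor correlations:",
                      self.factor_cov.round(3).to_string()]
        if self.heywood:
            lines += ["", f"Heywood cases (negative residual variance): {self.heywood}"]
        lines += ["", "parameter estimates:",
                  self.params.round(4).to_string(index=False)]
        return "\n".join(lines)

    def compare(self, restricted: "CFAResults") -> "ComparisonVerdict":
        return compare_models(self, restricted)


def _fmt(x):
    return "NA" if x is None else f"{x:.3f}"


# ---------------------------------------------------------------------------
# model object

class CFAModel:
    """Confirmatory factor model on raw indicator data.

    Parameters
    ----------
    data : DataFrame (or array) holding the indicator columns.
    spec : FactorModelSpec
    groups : optional per-row group labels for multi-group estimation.
    """

    def __init__(self, data, spec: FactorModelSpec, groups=None):
        self.spec = spec
        if isinstance(data, pd.DataFrame):
            missing_cols = [c for c in spec.indicators if c not in data.columns]
            if missing_cols:
                raise ValueError(f"indicators absent from data: {missing_cols}")
            X = data.loc[:, list(spec.indicators)].to_numpy(dtype=float)
        else:
            X = np.asarray(data, dtype=float)
            if X.shape[1] != spec.n_indicators:
                raise ValueError("column count does not match indicators")
        if groups is not None:
            groups = np.asarray(groups)
            if len(groups) != len(X):
                raise ValueError("groups length does not match data")
            if pd.isna(groups).any():
                raise ValueError("group labels contain missing values")
            self.group_labels = tuple(pd.unique(groups))
            self.rows_by_group = [X[groups == lab] for lab in self.group_labels]
        else:
            self.group_labels = ("all",)
            self.rows_by_group = [X]
        p = spec.n_indicators
        for lab, rows in zip(self.group_labels, self.rows_by_group):
            n_complete = int((~np.isnan(rows).any(axis=1)).sum())
            if n_complete < p + 1:
                raise ValueError(
                    f"group {lab!r} has {n_complete} complete rows; "
                    f"need at least {p + 1}")

    @classmethod
    def from_dataframe(cls, df, indicators, factors=("G",), groups=None, **kw):
        spec = FactorModelSpec(indicators=tuple(indicators),
                               factors=tuple(factors), **kw)
        glab = df[groups] if isinstance(groups, str) else groups
        return cls(df, spec, groups=glab)

    def fit(self, estimator="ml_robust", missing="fiml", start=None) -> CFAResults:
        if estimator not in ("ml", "ml_robust"):
            raise ValueError("estimator must be 'ml' or 'ml_robust'")
        spec = self.spec
        rows_by_group = self.rows_by_group
        if missing == "listwise":
            rows_by_group = [r[~np.isnan(r).any(axis=1)] for r in rows_by_group]
        has_missing = any(np.isnan(r).any() for r in rows_by_group)
        if has_missing and not spec.mean_structure:
            # FIML needs a mean structure; saturated means leave df unchanged
            spec = spec.with_(mean_structure=True)
        groups = [_sem.prepare_group(r, spec.mean_structure) for r in rows_by_group]
        raw = _sem.fit_ml(spec, groups, start=start)
        if not raw.converged:
            raise RuntimeError(
                f"CFA did not converge (gradient norm {raw.grad_norm:.2e})")
        base_raw = _fit_baseline(spec, groups)
        return _build_results(self, spec, raw, base_raw, estimator,
                              missing="fiml" if has_missing else "complete")


def _fit_baseline(spec, groups) -> _sem.RawFit:
    bspec = spec.baseline_spec()
    layout = _sem.ParamLayout(bspec, len(groups))
    # exact start: residual variances at the sample variances
    theta0 = np.zeros(layout.n_free)
    for g, gd in enumerate(groups):
        if gd.complete:
            s, mn = np.diag(gd.S_full), gd.mean_full
        else:
            s = np.nanvar(gd.rows, axis=0, ddof=1)
            mn = np.nanmean(gd.rows, axis=0)
        i, _, k, _ = layout.free[("theta", g)]
        theta0[k] = s[i]
        i, _, k, _ = layout.free[("nu", g)]
        if len(k):
            theta0[k] = mn[i]
    return _sem.fit_ml(bspec, groups, start=theta0)


def _build_results(model, spec, raw, base_raw, estimator, missing):
    layout = raw.layout
    n_groups = len(raw.groups)
    robust = estimator == "ml_robust"
    scale = _sem.satorra_bentler_scale(raw) if robust else 1.0
    scale_b = _sem.satorra_bentler_scale(base_raw) if robust else 1.0
    chi2 = raw.chi2 / scale
    chi2_b = base_raw.chi2 / scale_b
    n_eff = sum(g.mult for g in raw.groups)
    idx = fit_indices_from_stats(chi2, raw.df, chi2_b, base_raw.df, n_eff)
    aic = -2.0 * raw.loglik + 2.0 * raw.n_free

    cov = _sem.parameter_covariance(raw, robust=robust)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    params = pd.DataFrame({
        "param": layout.names,
        "estimate": raw.theta,
        "se": se,
    })
    params["z"] = params["estimate"] / params["se"].replace(0, np.nan)

    Lam, Psi, Th, nu, al = layout.unpack(raw.theta, 0)
    Sigma, _ = layout.implied(raw.theta, 0)
    sd = np.sqrt(np.diag(Sigma))
    fsd = np.sqrt(np.clip(np.diag(Psi), 0, None)) if layout.m else np.zeros(0)
    std_lam = Lam * fsd[None, :] / sd[:, None] if layout.m else Lam.copy()
    psi_corr = Psi / np.outer(fsd, fsd) if layout.m else Psi
    inds = list(spec.indicators)
    facs = list(spec.factors)
    res = CFAResults(
        spec=spec, estimator=estimator,
        params=params,
        loadings=pd.DataFrame(Lam, index=inds, columns=facs),
        std_loadings=pd.DataFrame(std_lam, index=inds, columns=facs),
        factor_cov=pd.DataFrame(psi_corr, index=facs, columns=facs),
        residual_var=pd.Series(Th, index=inds),
        intercepts=pd.Series(nu, index=inds),
        chi2=float(chi2), chi2_ml=float(raw.chi2), scaling_factor=float(scale),
        df=raw.df, n_obs=int(sum(g.n for g in raw.groups)),
        group_ns=tuple(g.n for g in raw.groups),
        cfi=idx["cfi"], tli=idx["tli"], rmsea=idx["rmsea"],
        rmsea_ci90=idx["rmsea_ci"], srmr=_srmr(raw), aic=float(aic),
        loglik=float(raw.loglik), n_free=raw.n_free,
        converged=raw.converged, heywood=raw.heywood,
        baseline_chi2=float(chi2_b), baseline_df=base_raw.df,
        meta={
            "chi2_multiplier": "(n_g - 1) per complete group; n for FIML groups",
            "missing": missing,
            "robust": "sandwich SEs + mean-scaled chi-square" if robust else "none",
            "n_groups": n_groups,
        },
        _raw=raw,
    )
    return res


# ---------------------------------------------------------------------------
# model comparison

@dataclass
class ComparisonVerdict:
    """Deltas between a freer and a restricted nested model.

    The verdict is "depreciated" when the restriction drops CFI by more than
    ``delta_cfi_max`` or raises RMSEA by more than ``delta_rmsea_max``.
    """
    delta_chi2: float
    delta_df: int
    delta_cfi: float
    delta_rmsea: float
    delta_aic: float
    verdict: str
    delta_cfi_max: float = 0.01
    delta_rmsea_max: float = 0.015

    @property
    def p_value(self) -> float:
        if self.delta_df <= 0:
            return np.nan
        return float(stats.chi2.sf(max(self.delta_chi2, 0.0), self.delta_df))


def compare_models(free, restricted, delta_cfi_max=0.01,
                   delta_rmsea_max=0.015) -> ComparisonVerdict:
    """Compare nested fits on the same data (restricted minus free deltas)."""
    if restricted.df < free.df:
        raise ValueError(
            "restricted model has fewer df than the free model; not nested")
    if free.n_obs != restricted.n_obs:
        raise ValueError("models were fitted to different data")
    r_free = 0.0 if free.rmsea is None else free.rmsea
    r_res = 0.0 if restricted.rmsea is None else restricted.rmsea
    d_cfi = restricted.cfi - free.cfi
    d_rmsea = r_res - r_free
    depreciated = (d_cfi < -delta_cfi_max) or (d_rmsea > delta_rmsea_max)
    return ComparisonVerdict(
        delta_chi2=float(restricted.chi2 - free.chi2),
        delta_df=int(restricted.df - free.df),
        delta_cfi=float(d_cfi),
        delta_rmsea=float(d_rmsea),
        delta_aic=float(restricted.aic - free.aic),
        verdict="depreciated" if depreciated else "equivalent",
        delta_cfi_max=delta_cfi_max, delta_rmsea_max=delta_rmsea_max,
    )


# ---------------------------------------------------------------------------
# measurement invariance

@dataclass
class InvarianceReport:
    levels: dict                     # level -> CFAResults
    comparisons: dict                # level -> ComparisonVerdict (vs previous)
    highest_level_attained: str

    def summary(self) -> str:
        lines = ["Measurement invariance ladder", "=" * 60]
        for lvl in INVARIANCE_LEVELS:
            if lvl not in self.levels:
                continue
            f = self.levels[lvl]
            line = (f"{lvl:<11} chi2({f.df}) = {f.chi2:9.2f}  "
                    f"CFI = {_fmt(f.cfi)}  RMSEA = {_fmt(f.rmsea)}")
            if lvl in self.comparisons:
                c = self.comparisons[lvl]
                line += (f"  dCFI = {c.delta_cfi:+.4f}  "
                         f"dRMSEA = {c.delta_rmsea:+.4f}  [{c.verdict}]")
            lines.append(line)
        lines.append(f"highest level attained: {self.highest_level_attained}")
        return "\n".join(lines)


def invariance_ladder(data, spec: FactorModelSpec, grouping,
                      estimator="ml_robust", delta_cfi_max=0.01,
                      delta_rmsea_max=0.015) -> InvarianceReport:
    """Fit the configural/metric/scalar/residual ladder across groups."""
    grouping = np.asarray(grouping)
    labels = pd.unique(grouping[~pd.isna(grouping)])
    if len(labels) < 2:
        raise ValueError("invariance testing needs at least 2 groups")
    levels = {}
    comparisons = {}
    attained = None
    prev = None
    for lvl in INVARIANCE_LEVELS:
        lspec = spec.with_(group_constraints=LEVEL_CONSTRAINTS[lvl],
                           mean_structure=True)
        model = CFAModel(data, lspec, groups=grouping)
        fit = model.fit(estimator=estimator)
        levels[lvl] = fit
        if prev is not None:
            cmp_ = compare_models(prev, fit, delta_cfi_max=delta_cfi_max,
                                  delta_rmsea_max=delta_rmsea_max)
            comparisons[lvl] = cmp_
            if cmp_.verdict == "depreciated" and attained is None:
                attained = prev_lvl
        prev, prev_lvl = fit, lvl
    if attained is None:
        attained = INVARIANCE_LEVELS[-1]
    return InvarianceReport(levels=levels, comparisons=comparisons,
                            highest_level_attained=attained)


def age_group_labels(ages) -> pd.Series:
    """Map ages to the middle-age / young-old / old-old bands (NaN outside)."""
    ages = pd.Series(np.asarray(ages, dtype=float))
    out = pd.Series([np.nan] * len(ages), dtype=object)
    for (lo, hi), lab in zip(AGE_BANDS, AGE_LABELS):
        out[(ages >= lo) & (ages <= hi)] = lab
    return out


# ---------------------------------------------------------------------------
# factor scores and utilities

def factor_scores(results: CFAResults, data=None, standardize=True) -> pd.DataFrame:
    """Regression-method factor scores: f = Psi Lambda' Sigma^{-1} (x - mu).

    Rows with partially missing indicators are scored from their observed
    subvector. Single-group fits only.
    """
    raw = results._raw
    if len(raw.groups) != 1:
        raise ValueError("factor scores are computed from single-group fits")
    layout = raw.layout
    if data is None:
        X = raw.groups[0].rows
        index = pd.RangeIndex(len(X))
    elif isinstance(data, pd.DataFrame):
        X = data.loc[:, list(results.spec.indicators)].to_numpy(dtype=float)
        index = data.index
    else:
        X = np.asarray(data, dtype=float)
        index = pd.RangeIndex(len(X))
    Lam, Psi, Th, nu, al = layout.unpack(raw.theta, 0)
    Sigma, mu = layout.implied(raw.theta, 0)
    if not results.spec.mean_structure:
        mu = np.nanmean(X, axis=0)
    cond = np.linalg.cond(Sigma)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError("model-implied covariance is singular")
    scores = np.full((len(X), layout.m), np.nan)
    obs_mask = ~np.isnan(X)
    for key, idx in _sem._pattern_groups(obs_mask).items():
        o = np.flatnonzero(np.array(key))
        if len(o) == 0:
            continue
        So = Sigma[np.ix_(o, o)]
        B = Psi @ Lam[o].T @ np.linalg.inv(So)   # (m, p_o)
        scores[idx] = (X[np.ix_(idx, o)] - mu[o]) @ B.T
    if standardize:
        sd = np.nanstd(scores, axis=0, ddof=1)
        sd[sd == 0] = 1.0
        scores = (scores - np.nanmean(scores, axis=0)) / sd
    return pd.DataFrame(scores, index=index, columns=list(results.spec.factors))


def split_half(data, seed: int):
    """Random disjoint split into ceil(n/2) and floor(n/2) rows.

    Returns (test, holdout); a 6003-row sample yields 3002 / 3001.
    """
    n = len(data)
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    k = (n + 1) // 2
    a, b = np.sort(perm[:k]), np.sort(perm[k:])
    if isinstance(data, pd.DataFrame):
        return data.iloc[a], data.iloc[b]
    arr = np.asarray(data)
    return arr[a], arr[b]


def drop_negative_indicators(data, spec: FactorModelSpec, estimator="ml_robust",
                             max_rounds=None):
    """Screen indicators with negative standardized loadings and refit.

    Returns (results, dropped) where ``dropped`` lists excluded indicators in
    removal order (the drinking-frequency rule applied iteratively).
    """
    dropped = []
    cur = spec
    rounds = max_rounds if max_rounds is not None else len(spec.indicators) - 3
    for _ in range(max(rounds, 1)):
        res = CFAModel(data, cur).fit(estimator=estimator)
        bad = res.negative_loading_indicators()
        if not bad:
            return res, dropped
        worst = min(bad, key=lambda i: res.std_loadings.loc[i].min())
        dropped.append(worst)
        keep = [i for i in cur.indicators if i != worst]
        pattern = {i: cur.loading_pattern[i] for i in keep}
        cur = cur.with_(indicators=tuple(keep), loading_pattern=pattern)
    res = CFAModel(data, cur).fit(estimator=estimator)
    return res, dropped
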