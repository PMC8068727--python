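"""PGS-outcome association with ancestry-PC covariates, and power analysis.

Each association is an OLS of the outcome (a phenotype or latent factor
score) on one polygenic score plus the top ancestry principal components.
Reported alongside the unstandardized coefficient are the standardized
coefficient, the full-model R-squared, the covariates-only R-squared, their
difference (incremental R-squared — the standard measure of PGS predictive
power), and the adjusted R-squared.

:func:`min_detectable_r2` inverts the noncentral-F power function of the
multiple-regression F test to find the smallest effect detectable at a given
sample size, alpha and power — the gate used to decide which associations
are worth interpreting in large samples where almost everything is
"significant".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
import statsmodels.api as sm

__all__ = ["AssocResult", "PowerSpec", "regress_with_pcs",
           "min_detectable_r2", "min_detectable_effect"]


@dataclass
class AssocResult:
    predictor: str
    outcome: str
    b: float
    se: float
    p: float
    beta_std: float
    r2_full: float
    r2_covariates_only: float
    r2_incremental: float
    adj_r2: float
    n: int

    def to_row(self) -> dict:
        return self.__dict__.copy()


def _align(outcome, pgs, pcs):
    """Complete-case alignment by sample id when available, else position."""
    def ids_of(x):
        if isinstance(x, pd.DataFrame) and "iid" in x.columns:
            return x["iid"].to_numpy()
        if isinstance(x, pd.Series):
            return x.index.to_numpy()
        return None

    def values_of(x, col=None):
        if isinstance(x, pd.DataFrame):
            if col and col in x.columns:
                return x[col].to_numpy(dtype=float)
            return x.select_dtypes("number").to_numpy(dtype=float)
        return np.asarray(x, dtype=float)

    y = values_of(outcome)
    if y.ndim > 1:
        y = y[:, 0]
    x = values_of(pgs, col="z_score")
    if x.ndim > 1:
        x = x[:, 0]
    C = values_of(pcs)
    if C.ndim == 1:
        C = C[:, None]
    iy, ix = ids_of(outcome), ids_of(pgs)
    if iy is not None and ix is not None:
        common = pd.Index(iy).intersection(pd.Index(ix))
        y = pd.Series(y, index=iy).loc[common].to_numpy()
        x = pd.Series(x, index=ix).loc[common].to_numpy()
        ic = ids_of(pcs)
        if ic is not None:
            C = pd.DataFrame(C, index=ic).loc[common].to_numpy()
        elif len(C) != len(common):
            raise ValueError("PC rows cannot be aligned by sample id")
    if not (len(y) == len(x) == len(C)):
        raise ValueError("outcome, PGS and PCs have mismatched lengths")
    ok = np.isfinite(y) & np.isfinite(x) & np.all(np.isfinite(C), axis=1)
    return y[ok], x[ok], C[ok]


def regress_with_pcs(outcome, pgs, pcs, predictor_name: str = None,
                     outcome_name: str = "outcome") -> AssocResult:
    """OLS of outcome on [PGS, PCs]; reports effect sizes and R-squared
    decomposition (full, covariates-only, incremental, adjusted)."""
    y, x, C = _align(outcome, pgs, pcs)
    k_cov = C.shape[1]
    n = len(y)
    if n <= k_cov + 2:
        raise ValueError(f"n = {n} too small for {k_cov + 1} predictors")
    X_full = sm.add_constant(np.column_stack([x, C]))
    rank = np.linalg.matrix_rank(X_full)
    if rank < X_full.shape[1]:
        # locate offending columns via QR diagnostics
        _, R = np.linalg.qr(X_full)
        diag = np.abs(np.diag(R))
        bad = np.flatnonzero(diag < 1e-8 * diag.max())
        names = ["const", "PGS"] + [f"PC{j + 1}" for j in range(k_cov)]
        raise ValueError(
            f"design matrix is rank deficient (collinear columns: "
            f"{[names[j] for j in bad]})")
    full = sm.OLS(y, X_full).fit()
    cov_only = sm.OLS(y, sm.add_constant(C)).fit()
    b = float(full.params[1])
    se = float(full.bse[1])
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    name = predictor_name or (pgs.attrs.get("trait", "PGS")
                              if isinstance(pgs, pd.DataFrame) else "PGS")
    return AssocResult(
        predictor=name, outcome=outcome_name,
        b=b, se=se, p=float(full.pvalues[1]),
        beta_std=float(b * sx / sy) if sy > 0 else np.nan,
        r2_full=float(full.rsquared),
        r2_covariates_only=float(cov_only.rsquared),
        r2_incremental=float(full.rsquared - cov_only.rsquared),
        adj_r2=float(full.rsquared_adj),
        n=n,
    )


@dataclass(frozen=True)
class PowerSpec:
    """Configuration of the regression power analysis."""
    n: int
    alpha: float = 0.05
    power: float = 0.80
    k_total: int = 11
    k_tested: int = 1

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0 < self.power < 1):
            raise ValueError("power must lie in (0, 1)")
        if not (1 <= self.k_tested <= self.k_total):
            raise ValueError("need 1 <= k_tested <= k_total")
        if self.n <= self.k_total + 1:
            raise ValueError("n must exceed k_total + 1")


def min_detectable_effect(spec: PowerSpec) -> dict:
    """Smallest effect size f2 whose noncentral-F test reaches the requested
    power, with its R-squared and adjusted-R-squared equivalents.

    The noncentrality parameter is lambda = f2 * n (the common power-software
    convention); df1 = k_tested, df2 = n - k_total - 1.
    """
    df1 = spec.k_tested
    df2 = spec.n - spec.k_total - 1
    fcrit = stats.f.ppf(1 - spec.alpha, df1, df2)

    def power_at(f2):
        nc = f2 * spec.n
        if nc <= 0:
            return stats.f.sf(fcrit, df1, df2)   # ncf.sf is unstable at nc=0
        return stats.ncf.sf(fcrit, df1, df2, nc)

    if power_at(0.0) >= spec.power:
        f2 = 0.0          # requested power at or below the test size
    else:
        hi = 1.0
        while power_at(hi) < spec.power:
            hi *= 2
            if hi > 1e6:
                raise ValueError("requested power unreachable")
        f2 = optimize.brentq(lambda v: power_at(v) - spec.power, 0.0, hi,
                             xtol=1e-14, rtol=1e-13)
    r2 = f2 / (1.0 + f2)
    adj = 1.0 - (1.0 - r2) * (spec.n - 1) / (spec.n - spec.k_total - 1)
    return {"f2": f2, "r2": r2, "adj_r2": adj, "ncp": f2 * spec.n,
            "df1": df1, "df2": df2}


def min_detectable_r2(spec: PowerSpec) -> float:
    """Adjusted-R-squared detection threshold for the given configuration."""
    return float(min_detectable_effect(spec)["adj_r2"])
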