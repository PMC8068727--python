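"""LD scores and LD-score regression (univariate and cross-trait).

Univariate LDSC regresses per-SNP association chi-square on LD scores,
E[chi2_j] = intercept + (N h2 / m) l_j, separating polygenic signal (slope)
from confounding/cryptic relatedness (intercept). The bivariate form
regresses z-score products, E[z1 z2] = intercept + (sqrt(N1 N2) sigma_g12 / m)
l_j, whose intercept absorbs phenotypic correlation among overlapping
samples. Standard errors come from a delete-a-block jackknife over contiguous
genome blocks; :func:`build_genetic_cov` reuses the same blocks for every
element of the genetic covariance matrix S so that its sampling covariance V
captures cross-element dependence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype import GenotypeData
from .pgs import validate_sumstats
from ._sem import vech_indices

__all__ = [
    "compute_ld_scores", "ldsc_univariate", "ldsc_bivariate",
    "build_genetic_cov", "LdscResult", "GeneticCov", "align_sumstats",
]


def compute_ld_scores(g: GenotypeData, window_snps: int = 100) -> pd.DataFrame:
    """LD score per SNP: sum of bias-adjusted squared correlations with all
    SNPs within ``window_snps`` positions (self term included).

    The adjustment r2_adj = r2 - (1 - r2)/(n - 2) removes the upward
    finite-sample bias of squared sample correlations.
    """
    if window_snps < 1:
        raise ValueError("window_snps must be >= 1")
    if g.n_samples < 3:
        raise ValueError("need at least 3 individuals for LD scores")
    d = g.dosages.astype(np.float32)
    d[d < 0] = np.nan
    mean = np.nanmean(d, axis=0)
    inds = np.where(np.isnan(d))
    d[inds] = np.take(mean, inds[1])
    sd = d.std(axis=0, ddof=0)
    sd[sd == 0] = np.inf        # monomorphic SNPs correlate with nothing
    Z = (d - d.mean(0)) / sd
    n, m = Z.shape
    w = window_snps
    ell = np.zeros(m)
    chunk = 512
    for a in range(0, m, chunk):
        b = min(a + chunk, m)
        lo, hi = max(0, a - w), min(m, b + w)
        R = Z[:, a:b].T @ Z[:, lo:hi] / n
        r2 = R ** 2
        r2adj = r2 - (1.0 - r2) / (n - 2)
        jj = np.arange(a, b)[:, None]
        kk = np.arange(lo, hi)[None, :]
        mask = np.abs(jj - kk) <= w
        ell[a:b] = np.where(mask, r2adj, 0.0).sum(axis=1)
    out = pd.DataFrame({"SNP": g.snp_meta["snp"].to_numpy(), "L2": ell})
    out.attrs["n_ref"] = n
    out.attrs["window_snps"] = window_snps
    return out


@dataclass
class LdscResult:
    """One LD-score regression: slope-derived (co)heritability + intercept."""
    h2: float                 # heritability (or genetic covariance, bivariate)
    h2_se: float
    intercept: float
    intercept_se: float
    m_snps: int
    n_snps_used: int
    delete_values: np.ndarray = field(repr=False, default=None)  # (B, 2) jackknife

    def h2_ci(self, level=0.95):
        from scipy import stats
        zq = stats.norm.ppf((1 + level) / 2)
        return (self.h2 - zq * self.h2_se, self.h2 + zq * self.h2_se)

    def intercept_ci(self, level=0.95):
        from scipy import stats
        zq = stats.norm.ppf((1 + level) / 2)
        return (self.intercept - zq * self.intercept_se,
                self.intercept + zq * self.intercept_se)


def _block_wls(X, y, w, n_blocks):
    """WLS plus delete-a-block jackknife via block-sum arithmetic.

    Returns (coef, jackknife covariance, delete-value coefs (B, k)).
    """
    n, k = X.shape
    B = min(n_blocks, n)
    edges = np.linspace(0, n, B + 1).astype(int)
    Xw = X * w[:, None]
    XtX_b = np.zeros((B, k, k))
    Xty_b = np.zeros((B, k))
    for b in range(B):
        s = slice(edges[b], edges[b + 1])
        XtX_b[b] = Xw[s].T @ X[s]
        Xty_b[b] = Xw[s].T @ y[s]
    XtX = XtX_b.sum(0)
    Xty = Xty_b.sum(0)
    coef = np.linalg.solve(XtX, Xty)
    deletes = np.empty((B, k))
    for b in range(B):
        deletes[b] = np.linalg.solve(XtX - XtX_b[b], Xty - Xty_b[b])
    dbar = deletes.mean(0)
    dev = deletes - dbar
    cov = (B - 1) / B * (dev.T @ dev)
    return coef, cov, deletes


def _regression_frame(ss: pd.DataFrame, ld: pd.DataFrame) -> pd.DataFrame:
    ss = validate_sumstats(ss)
    df = ss.merge(ld, on="SNP", how="inner")
    if len(df) < 200:
        raise ValueError(
            f"only {len(df)} SNPs overlap the LD-score table; need >= 200")
    return df


def ldsc_univariate(ss: pd.DataFrame, ld: pd.DataFrame, m: int | None = None,
                    n_blocks: int = 200,
                    weights: str = "iterated") -> LdscResult:
    """Heritability and intercept from a chi-square-on-LD-score regression."""
    df = _regression_frame(ss, ld)
    m = int(m if m is not None else len(df))
    chi2 = (df["BETA"] / df["SE"]) ** 2
    ell = df["L2"].to_numpy()
    if np.var(ell) < 1e-12:
        raise ValueError("LD scores are (near-)constant; slope unidentified")
    N = df["N"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(df)), N * ell / m])
    y = chi2.to_numpy()
    ell_c = np.clip(ell, 1.0, None)
    w = 1.0 / ell_c
    coef, cov, dels = _block_wls(X, y, w, n_blocks)
    if weights == "iterated":
        h2_0 = np.clip(coef[1], 0.0, 1.0)
        i0 = max(coef[0], 0.1)
        w = 1.0 / (ell_c * (i0 + N * h2_0 * ell / m) ** 2)
        coef, cov, dels = _block_wls(X, y, w, n_blocks)
    elif weights != "inverse_ld":
        raise ValueError("weights must be 'iterated' or 'inverse_ld'")
    se = np.sqrt(np.diag(cov))
    return LdscResult(h2=float(coef[1]), h2_se=float(se[1]),
                      intercept=float(coef[0]), intercept_se=float(se[0]),
                      m_snps=m, n_snps_used=len(df),
                      delete_values=dels[:, ::-1])


def align_sumstats(ss1: pd.DataFrame, ss2: pd.DataFrame):
    """Inner-join two tables on SNP id, flipping the second table's effect
    sign where its allele pair is swapped; irreconcilable SNPs are dropped."""
    a = validate_sumstats(ss1)
    b = validate_sumstats(ss2)
    mg = a.merge(b, on="SNP", suffixes=("_1", "_2"))
    same = (mg["A1_1"] == mg["A1_2"]) & (mg["A2_1"] == mg["A2_2"])
    swap = (mg["A1_1"] == mg["A2_2"]) & (mg["A2_1"] == mg["A1_2"])
    mg = mg[same | swap].copy()
    sign = np.where(same[same | swap], 1.0, -1.0)
    mg["BETA_2"] = mg["BETA_2"] * sign
    return mg


def ldsc_bivariate(ss1: pd.DataFrame, ss2: pd.DataFrame, ld: pd.DataFrame,
                   m: int | None = None, n_blocks: int = 200,
                   weights: str = "iterated") -> LdscResult:
    """Genetic covariance and sample-overlap intercept from a z1*z2
    regression on LD scores. Symmetric in its two arguments."""
    mg = align_sumstats(ss1, ss2).merge(ld, on="SNP", how="inner")
    if len(mg) < 200:
        raise ValueError(
            f"only {len(mg)} SNPs overlap across both tables and the LD "
            "scores; need >= 200")
    m = int(m if m is not None else len(mg))
    z1 = (mg["BETA_1"] / mg["SE_1"]).to_numpy()
    z2 = (mg["BETA_2"] / mg["SE_2"]).to_numpy()
    ell = mg["L2"].to_numpy()
    if np.var(ell) < 1e-12:
        raise ValueError("LD scores are (near-)constant; slope unidentified")
    N1 = mg["N_1"].to_numpy(dtype=float)
    N2 = mg["N_2"].to_numpy(dtype=float)
    rootN = np.sqrt(N1 * N2)
    X = np.column_stack([np.ones(len(mg)), rootN * ell / m])
    y = z1 * z2
    ell_c = np.clip(ell, 1.0, None)
    w = 1.0 / ell_c
    coef, cov, dels = _block_wls(X, y, w, n_blocks)
    if weights == "iterated":
        h1 = np.clip(np.average(z1 ** 2 - 1) * m / (np.mean(N1) * np.mean(ell)), 0, 1)
        h2_ = np.clip(np.average(z2 ** 2 - 1) * m / (np.mean(N2) * np.mean(ell)), 0, 1)
        a1 = 1.0 + N1 * h1 * ell / m
        a2 = 1.0 + N2 * h2_ * ell / m
        c = coef[0] + rootN * np.clip(coef[1], -1, 1) * ell / m
        w = 1.0 / (ell_c * (a1 * a2 + c ** 2))
        coef, cov, dels = _block_wls(X, y, w, n_blocks)
    elif weights != "inverse_ld":
        raise ValueError("weights must be 'iterated' or 'inverse_ld'")
    se = np.sqrt(np.diag(cov))
    return LdscResult(h2=float(coef[1]), h2_se=float(se[1]),
                      intercept=float(coef[0]), intercept_se=float(se[0]),
                      m_snps=m, n_snps_used=len(mg),
                      delete_values=dels[:, ::-1])


# ---------------------------------------------------------------------------
# genetic covariance assembly

@dataclass
class GeneticCov:
    """Genetic covariance matrix S with jackknife sampling covariance V.

    V covers the unique elements of S in lower-triangle row-major
    (half-vectorized) order: (0,0), (1,0), (1,1), (2,0), ... The intercept
    matrix carries univariate LDSC intercepts on the diagonal and cross-trait
    (sample-overlap) intercepts off it.
    """
    trait_names: tuple
    S: np.ndarray
    V: np.ndarray
    intercepts: np.ndarray
    m_snps: int
    n_blocks: int
    smoothing_applied: float = 0.0      # spectral-norm change from PSD clipping
    intercept_ses: np.ndarray = None    # jackknife SEs of the intercepts

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    def s_vech(self) -> np.ndarray:
        r, c = vech_indices(self.n_traits)
        return self.S[r, c]

    def genetic_corr(self) -> np.ndarray:
        d = np.sqrt(np.clip(np.diag(self.S), 1e-12, None))
        return self.S / np.outer(d, d)

    def save(self, path):
        """YAML bundle: trait names, S, V (vech order documented), intercepts."""
        import yaml
        d = {
            "trait_names": list(self.trait_names),
            "vech_order": "lower-triangle row-major: (0,0),(1,0),(1,1),...",
            "S": self.S.tolist(),
            "V": self.V.tolist(),
            "intercepts": self.intercepts.tolist(),
            "intercept_ses": None if self.intercept_ses is None
                             else self.intercept_ses.tolist(),
            "m_snps": int(self.m_snps),
            "n_blocks": int(self.n_blocks),
            "smoothing_applied": float(self.smoothing_applied),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "GeneticCov":
        import yaml
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(trait_names=tuple(d["trait_names"]),
                   S=np.asarray(d["S"]), V=np.asarray(d["V"]),
                   intercepts=np.asarray(d["intercepts"]),
                   m_snps=d["m_snps"], n_blocks=d["n_blocks"],
                   smoothing_applied=d.get("smoothing_applied", 0.0),
                   intercept_ses=None if d.get("intercept_ses") is None
                                 else np.asarray(d["intercept_ses"]))


def build_genetic_cov(all_ss: list, ld: pd.DataFrame, m: int | None = None,
                      n_blocks: int = 200, trait_names=None,
                      weights: str = "iterated") -> GeneticCov:
    """Assemble (S, V, intercepts) from pairwise LD-score regressions.

    All pairwise regressions run on the shared SNP universe with one common
    set of contiguous jackknife blocks, so V reflects the joint sampling
    distribution of every element of S. S is smoothed to the nearest PSD
    matrix by eigenvalue clipping when needed (the perturbation is recorded).
    """
    t = len(all_ss)
    if t < 2:
        raise ValueError("need at least 2 traits")
    names = tuple(trait_names) if trait_names else tuple(
        ss.attrs.get("trait", f"trait{k + 1}") for k, ss in enumerate(all_ss))
    tables = [validate_sumstats(ss) for ss in all_ss]
    # common SNP universe, aligned to the first trait's allele orientation
    ref = tables[0][["SNP", "A1", "A2"]]
    universe = set(ref["SNP"])
    aligned = [tables[0]]
    for ss in tables[1:]:
        mg = align_sumstats(tables[0], ss)
        keep = mg[["SNP"]].copy()
        keep["A1"] = mg["A1_1"]
        keep["A2"] = mg["A2_1"]
        keep["BETA"] = mg["BETA_2"]
        keep["SE"] = mg["SE_2"]
        keep["P"] = mg["P_2"]
        keep["N"] = mg["N_2"]
        aligned.append(keep)
        universe &= set(keep["SNP"])
    universe &= set(ld["SNP"])
    if len(universe) < 200:
        raise ValueError(f"shared SNP universe has {len(universe)} SNPs; "
                         "need >= 200")
    order = [s for s in ld["SNP"] if s in universe]
    aligned = [ss.set_index("SNP").loc[order].reset_index() for ss in aligned]
    ld_use = ld.set_index("SNP").loc[order].reset_index()
    m = int(m if m is not None else len(order))

    r, c = vech_indices(t)
    q = len(r)
    S = np.zeros((t, t))
    intercepts = np.zeros((t, t))
    intercept_ses = np.zeros((t, t))
    deletes = np.zeros((min(n_blocks, len(order)), q))
    for k, (i, j) in enumerate(zip(r, c)):
        try:
            if i == j:
                res = ldsc_univariate(aligned[i], ld_use, m=m,
                                      n_blocks=n_blocks, weights=weights)
            else:
                res = ldsc_bivariate(aligned[i], aligned[j], ld_use, m=m,
                                     n_blocks=n_blocks, weights=weights)
        except Exception as exc:
            raise RuntimeError(
                f"LD-score regression failed for trait pair "
                f"({names[i]}, {names[j]}): {exc}") from exc
        S[i, j] = S[j, i] = res.h2
        intercepts[i, j] = intercepts[j, i] = res.intercept
        intercept_ses[i, j] = intercept_ses[j, i] = res.intercept_se
        deletes[:, k] = res.delete_values[:, 0]
    B = deletes.shape[0]
    dev = deletes - deletes.mean(0)
    V = (B - 1) / B * (dev.T @ dev)
    # PSD smoothing
    smoothing = 0.0
    ev, U = np.linalg.eigh(S)
    if ev.min() < 0:
        S_new = (U * np.clip(ev, 1e-10, None)) @ U.T
        smoothing = float(np.linalg.norm(S_new - S, 2))
        S = S_new
    evV = np.linalg.eigvalsh(V)
    if evV.min() < 0:
        eV, UV = np.linalg.eigh(V)
        V = (UV * np.clip(eV, 1e-12, None)) @ UV.T
    return GeneticCov(trait_names=names, S=S, V=V, intercepts=intercepts,
                      m_snps=m, n_blocks=B, smoothing_applied=smoothing,
                      intercept_ses=intercept_ses)
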