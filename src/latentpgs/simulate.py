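"""Synthetic genotypes, multi-trait GWAS summary statistics, and phenotype
panels with known ground truth.

The generator stands in for restricted cohort data so every downstream stage
(QC, scoring, CFA, LD-score regression, genomic SEM) can be tested against a
known generating model:

* genotypes: diploid 0/1/2 dosages with block LD, via a Gaussian copula —
  two latent standard normals per individual with block correlation, each
  thresholded at the MAF quantile and summed;
* GWAS summary statistics: individual-level cohorts are simulated and each
  SNP is regressed on the phenotype, so LD-score-regression intercepts and
  sample-overlap effects arise mechanistically rather than by construction.
  Per-SNP true effects follow a latent genetic factor model (factor-mediated
  plus trait-residual components) under the infinitesimal regime;
* phenotype panels: a common-factor model with group-specific intercept and
  factor-scale shifts, and MCAR missingness.

All simulated traits are continuous; cohort sizes of 5,000-20,000 and SNP
panels of 2,000-10,000 give desk-scale runs on which LD-score-regression
estimands (which are scale-free) remain recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .genotype import GenotypeData

__all__ = [
    "SnpPanelSpec", "GeneticTruth", "PhenoTruth",
    "simulate_genotypes", "simulate_multitrait_gwas",
    "simulate_phenotype_panel", "write_sumstats", "write_truth_yaml",
]

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("C", "T"), ("G", "A")]


def panel_alleles(panel: "SnpPanelSpec"):
    """Deterministic allele pair per SNP, shared by genotype and sumstats
    simulation so that tables simulated from the same panel harmonize."""
    pair_ix = np.arange(panel.n_snps) % len(_ALLELE_PAIRS)
    a1 = np.array([_ALLELE_PAIRS[i][0] for i in pair_ix])
    a2 = np.array([_ALLELE_PAIRS[i][1] for i in pair_ix])
    return a1, a2


@dataclass(frozen=True)
class SnpPanelSpec:
    """Layout of a genotyped SNP panel: size, LD blocks, allele frequencies."""

    n_snps: int
    n_blocks: int = 1
    within_block_corr: float = 0.0
    maf_range: tuple = (0.05, 0.5)

    def __post_init__(self):
        if self.n_snps < 1 or self.n_blocks < 1:
            raise ValueError("n_snps and n_blocks must be positive")
        if self.n_snps < self.n_blocks:
            raise ValueError("need n_snps >= n_blocks")
        if not (0.0 <= self.within_block_corr < 1.0):
            raise ValueError("within_block_corr must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 <= lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 <= lower <= upper <= 0.5")

    def block_of(self) -> np.ndarray:
        """Block index per SNP (contiguous, near-equal blocks)."""
        return np.repeat(np.arange(self.n_blocks),
                         np.diff(np.linspace(0, self.n_snps,
                                             self.n_blocks + 1).astype(int)))


def panel_mafs(panel: SnpPanelSpec) -> np.ndarray:
    """Deterministic per-SNP MAFs for a panel.

    MAF is a property of the SNP panel, not of any one simulated cohort:
    every cohort drawn from the same panel shares allele frequencies (as real
    cohorts genotyped on the same array do). A low-discrepancy sequence
    spreads frequencies over ``maf_range``.
    """
    lo, hi = panel.maf_range
    phi = (np.sqrt(5) - 1) / 2
    u = np.mod((np.arange(panel.n_snps) + 1) * phi, 1.0)
    return lo + (hi - lo) * u


def _simulate_dosage_array(n: int, panel: SnpPanelSpec, rng,
                           mafs=None) -> tuple:
    """Raw dosage matrix (n x m, int8) and the MAF vector used."""
    if mafs is None:
        mafs = panel_mafs(panel)
    m = panel.n_snps
    blocks = panel.block_of()
    rho = panel.within_block_corr
    thr = stats.norm.ppf(mafs).astype(np.float32)
    edges = np.flatnonzero(np.r_[1, np.diff(blocks), 1])
    dos = np.zeros((n, m), dtype=np.int8)
    for _copy in range(2):
        z = rng.standard_normal((n, m), dtype=np.float32)
        if rho > 0:
            z *= np.float32(np.sqrt(1.0 - rho))
            shared = rng.standard_normal((n, panel.n_blocks), dtype=np.float32)
            a = np.float32(np.sqrt(rho))
            for b in range(panel.n_blocks):
                z[:, edges[b]:edges[b + 1]] += a * shared[:, [b]]
        dos += z < thr[None, :]
    return dos, mafs


def simulate_genotypes(n_individuals: int, panel: SnpPanelSpec, seed: int,
                       missing_rate: float = 0.0, mafs=None,
                       group_label: str = "EUR") -> GenotypeData:
    """Diploid genotype panel with block LD and known MAFs.

    SNPs in different blocks are generated independently; the per-SNP
    counted-allele (A1) frequency equals the drawn MAF in expectation.
    Pass ``mafs`` to reuse the frequencies of a previously simulated cohort.
    """
    if n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    dos, mafs = _simulate_dosage_array(n_individuals, panel, rng, mafs=mafs)
    if missing_rate > 0:
        mask = rng.random(dos.shape) < missing_rate
        dos[mask] = -1
    m = panel.n_snps
    a1, a2 = panel_alleles(panel)
    snp_meta = pd.DataFrame({
        "snp": [f"rs{j + 1:06d}" for j in range(m)],
        "chrom": np.ones(m, dtype=int),
        "pos": (np.arange(m) + 1) * 1000,
        "a1": a1, "a2": a2,
        "maf": mafs, "block": panel.block_of(),
    })
    sample_meta = pd.DataFrame({
        "iid": [f"id{i + 1:06d}" for i in range(n_individuals)],
        "group": group_label,
    })
    return GenotypeData(dosages=dos, snp_meta=snp_meta, sample_meta=sample_meta)


# ---------------------------------------------------------------------------
# phenotype panels

@dataclass(frozen=True)
class PhenoTruth:
    """Generating common-factor model for a panel of continuous indicators.

    ``intercepts_by_group`` and ``factor_sd_by_group`` map group label to the
    group's indicator intercepts / latent-factor SD, emulating the kind of
    group shifts probed by measurement-invariance testing.
    """

    loadings: tuple
    intercepts_by_group: dict
    residual_sd: tuple
    factor_sd_by_group: dict
    missing_rate: float = 0.0
    indicator_names: tuple = None

    def __post_init__(self):
        object.__setattr__(self, "loadings", tuple(float(x) for x in self.loadings))
        object.__setattr__(self, "residual_sd", tuple(float(x) for x in self.residual_sd))
        p = len(self.loadings)
        if len(self.residual_sd) != p:
            raise ValueError("residual_sd length must match loadings")
        if any(s <= 0 for s in self.residual_sd):
            raise ValueError("residual_sd must be positive")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        ig = {k: np.asarray(v, dtype=float) for k, v in self.intercepts_by_group.items()}
        for k, v in ig.items():
            if v.shape != (p,):
                raise ValueError(f"intercepts for group {k!r} have wrong length")
        object.__setattr__(self, "intercepts_by_group", ig)
        fg = {k: float(v) for k, v in self.factor_sd_by_group.items()}
        if set(fg) != set(ig):
            raise ValueError("factor_sd_by_group and intercepts_by_group "
                             "must cover the same groups")
        object.__setattr__(self, "factor_sd_by_group", fg)
        names = self.indicator_names or tuple(f"y{j + 1}" for j in range(p))
        if len(names) != p:
            raise ValueError("indicator_names length must match loadings")
        object.__setattr__(self, "indicator_names", tuple(names))

    @classmethod
    def single_group(cls, loadings, residual_sd=None, missing_rate=0.0,
                     indicator_names=None, group="all"):
        """Standardized one-group truth: unit factor, intercepts 0; residual
        SDs default to sqrt(1 - loading^2) so indicators have unit variance."""
        loadings = tuple(loadings)
        if residual_sd is None:
            residual_sd = tuple(np.sqrt(1.0 - np.square(loadings)))
        p = len(loadings)
        return cls(loadings=loadings,
                   intercepts_by_group={group: np.zeros(p)},
                   residual_sd=residual_sd,
                   factor_sd_by_group={group: 1.0},
                   missing_rate=missing_rate,
                   indicator_names=indicator_names)


def simulate_phenotype_panel(n_individuals: int, truth: PhenoTruth,
                             groups, seed: int,
                             return_factor: bool = False,
                             factor_values=None) -> pd.DataFrame:
    """Indicator panel: y_ij = intercept_g(j) + loading_j * f_i + e_ij.

    ``factor_values`` (optional, length n) supplies the latent factor draws,
    which lets a caller couple the phenotypic factor to a genetic value.
    Missing entries are inserted completely at random.
    """
    groups = np.asarray(groups)
    if len(groups) != n_individuals:
        raise ValueError("groups length must equal n_individuals")
    unknown = set(pd.unique(groups)) - set(truth.intercepts_by_group)
    if unknown:
        raise ValueError(f"groups without truth parameters: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    p = len(truth.loadings)
    lam = np.asarray(truth.loadings)
    f = np.asarray(factor_values, dtype=float) if factor_values is not None \
        else rng.standard_normal(n_individuals)
    if len(f) != n_individuals:
        raise ValueError("factor_values length must equal n_individuals")
    fsd = np.array([truth.factor_sd_by_group[g] for g in groups])
    icpt = np.vstack([truth.intercepts_by_group[g] for g in groups])
    Y = icpt + (fsd * f)[:, None] * lam[None, :] \
        + rng.standard_normal((n_individuals, p)) * np.asarray(truth.residual_sd)[None, :]
    if truth.missing_rate > 0:
        Y[rng.random(Y.shape) < truth.missing_rate] = np.nan
    df = pd.DataFrame(Y, columns=list(truth.indicator_names))
    df.insert(0, "iid", [f"id{i + 1:06d}" for i in range(n_individuals)])
    df.insert(1, "group", groups)
    if return_factor:
        return df, f
    return df


# ---------------------------------------------------------------------------
# multi-trait GWAS

@dataclass(frozen=True)
class GeneticTruth:
    """Generating latent genetic factor model for a set of GWAS traits.

    ``loadings`` are standardized (genetic-correlation-scale) factor loadings;
    the implied genetic correlation matrix is loadings @ factor_corr @
    loadings' plus a diagonal residual, and the genetic covariance S scales it
    by sqrt(h2_i h2_j). ``pairwise_overlap[i, j]`` individuals are shared
    between cohorts i and j (realized as pairwise-exclusive blocks, so
    sum_j overlap[i, j] must not exceed n_i). ``env_corr`` optionally
    correlates the environmental residuals of shared individuals.
    """

    trait_names: tuple
    loadings: np.ndarray            # traits x factors, standardized
    factor_corr: np.ndarray = None
    total_h2: np.ndarray = None
    residual_h2: np.ndarray = None  # derived unless supplied
    n_per_trait: np.ndarray = None
    pairwise_overlap: np.ndarray = None
    env_corr: np.ndarray = None

    def __post_init__(self):
        L = np.atleast_2d(np.asarray(self.loadings, dtype=float))
        t, f = L.shape
        names = tuple(self.trait_names)
        if len(names) != t:
            raise ValueError("trait_names length must match loadings rows")
        P = np.eye(f) if self.factor_corr is None \
            else np.asarray(self.factor_corr, dtype=float)
        if P.shape != (f, f) or not np.allclose(P, P.T):
            raise ValueError("factor_corr must be a symmetric f x f matrix")
        h2 = np.full(t, 0.3) if self.total_h2 is None \
            else np.asarray(self.total_h2, dtype=float)
        if np.any(h2 < 0) or np.any(h2 > 1):
            raise ValueError("total_h2 must lie in [0, 1]")
        comm = np.einsum("ij,jk,ik->i", L, P, L)
        if np.any(comm > 1 + 1e-9):
            raise ValueError("standardized communalities exceed 1")
        resid_corr = np.clip(1.0 - comm, 0.0, None)
        rh2 = h2 * resid_corr
        if self.residual_h2 is not None:
            given = np.asarray(self.residual_h2, dtype=float)
            if not np.allclose(given, rh2, atol=1e-8):
                raise ValueError(
                    "residual_h2 inconsistent with loadings and total_h2")
            rh2 = given
        R = L @ P @ L.T + np.diag(resid_corr)
        ev = np.linalg.eigvalsh(R)
        if ev.min() < -1e-8:
            raise ValueError(
                "implied genetic correlation matrix is not positive "
                f"semi-definite (min eigenvalue {ev.min():.3e}); adjust "
                "loadings/factor_corr")
        n = np.full(t, 10000) if self.n_per_trait is None \
            else np.asarray(self.n_per_trait, dtype=int)
        O = np.zeros((t, t), dtype=int) if self.pairwise_overlap is None \
            else np.asarray(self.pairwise_overlap, dtype=int)
        if not np.array_equal(O, O.T):
            raise ValueError("pairwise_overlap must be symmetric")
        for i in range(t):
            for j in range(t):
                if i != j and O[i, j] > min(n[i], n[j]):
                    raise ValueError("overlap exceeds cohort size")
            if O[i].sum() - O[i, i] > n[i]:
                raise ValueError(
                    f"total pairwise overlap for trait {names[i]} exceeds n")
        E = np.eye(t) if self.env_corr is None \
            else np.asarray(self.env_corr, dtype=float)
        object.__setattr__(self, "trait_names", names)
        object.__setattr__(self, "loadings", L)
        object.__setattr__(self, "factor_corr", P)
        object.__setattr__(self, "total_h2", h2)
        object.__setattr__(self, "residual_h2", rh2)
        object.__setattr__(self, "n_per_trait", n)
        object.__setattr__(self, "pairwise_overlap", O)
        object.__setattr__(self, "env_corr", E)

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    @property
    def genetic_corr(self) -> np.ndarray:
        comm = np.einsum("ij,jk,ik->i", self.loadings, self.factor_corr,
                         self.loadings)
        return self.loadings @ self.factor_corr @ self.loadings.T \
            + np.diag(np.clip(1 - comm, 0, None))

    @property
    def genetic_cov(self) -> np.ndarray:
        s = np.sqrt(self.total_h2)
        return self.genetic_corr * np.outer(s, s)


def _allocate_cohorts(truth: GeneticTruth):
    """Pool row indices per trait realizing exact pairwise overlaps."""
    t = truth.n_traits
    n = truth.n_per_trait
    O = truth.pairwise_overlap
    rows = [[] for _ in range(t)]
    cursor = 0
    for i in range(t):
        for j in range(i + 1, t):
            if O[i, j] > 0:
                blk = np.arange(cursor, cursor + O[i, j])
                rows[i].append(blk)
                rows[j].append(blk)
                cursor += O[i, j]
    out = []
    for i in range(t):
        used = sum(len(b) for b in rows[i])
        extra = np.arange(cursor, cursor + (n[i] - used))
        cursor += n[i] - used
        out.append(np.concatenate(rows[i] + [extra]) if rows[i] else extra)
    return out, cursor


def _draw_snp_effects(truth: GeneticTruth, m: int, rng):
    """Per-SNP standardized-genotype effects (m x t) under the factor model."""
    t, f = truth.loadings.shape
    cholP = np.linalg.cholesky(truth.factor_corr + 1e-12 * np.eye(f))
    u = rng.standard_normal((m, f)) @ cholP.T / np.sqrt(m)
    comm = np.einsum("ij,jk,ik->i", truth.loadings, truth.factor_corr,
                     truth.loadings)
    resid_corr = np.clip(1.0 - comm, 0.0, None)
    r = rng.standard_normal((m, t)) * np.sqrt(resid_corr / m)[None, :]
    beta_corr = u @ truth.loadings.T + r         # unit-variance genetic scale
    beta_std = beta_corr * np.sqrt(truth.total_h2)[None, :]
    return beta_std, u


def _marginal_gwas(X_int8, Y, snp_meta):
    """Per-SNP simple linear regression of each column of Y on raw dosage.

    One pass over the dosage matrix serves every trait measured on the
    cohort. Returns one table per column of Y.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=np.float64).T).T   # (n, k)
    n, k = Y.shape
    Yc = (Y - Y.mean(0)).astype(np.float32)
    Syy = np.einsum("ik,ik->k", Yc, Yc).astype(float)
    cols = X_int8.shape[1]
    beta = np.empty((cols, k))
    se = np.empty((cols, k))
    chunk = 2048
    for a in range(0, cols, chunk):
        Xc = X_int8[:, a:a + chunk].astype(np.float32)
        Xc -= Xc.mean(0)
        Sxx = np.einsum("ij,ij->j", Xc, Xc).astype(float)
        Sxy = (Xc.T @ Yc).astype(float)                      # (chunk, k)
        Sxx[Sxx == 0] = np.nan
        b = Sxy / Sxx[:, None]
        sigma2 = np.clip(Syy[None, :] - b * Sxy, 0, None) / (n - 2)
        beta[a:a + chunk] = b
        se[a:a + chunk] = np.sqrt(sigma2 / Sxx[:, None])
    tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    out = []
    for j in range(k):
        out.append(pd.DataFrame({
            "SNP": snp_meta["snp"].to_numpy(),
            "A1": snp_meta["a1"].to_numpy(),
            "A2": snp_meta["a2"].to_numpy(),
            "BETA": beta[:, j], "SE": se[:, j], "P": p[:, j], "N": n,
        }))
    return out


def simulate_multitrait_gwas(truth: GeneticTruth, panel: SnpPanelSpec,
                             seed: int, return_effects: bool = False):
    """One summary-statistics table per trait plus the generating genetic
    covariance matrix.

    Cohorts are simulated at the individual level; shared individuals across
    cohorts implement ``pairwise_overlap`` (they share genotypes and,
    under ``env_corr``, environmental residuals), so cross-trait LDSC
    intercepts arise mechanistically.
    """
    rng = np.random.default_rng(seed)
    t = truth.n_traits
    m = panel.n_snps
    rows_by_trait, pool_n = _allocate_cohorts(truth)
    dos, mafs = _simulate_dosage_array(pool_n, panel, rng)
    freq = dos.mean(0) / 2.0
    freq = np.clip(freq, 1e-6, 1 - 1e-6)
    sd = np.sqrt(2 * freq * (1 - freq)).astype(np.float32)

    beta_std, factor_effects = _draw_snp_effects(truth, m, rng)

    # genetic values on the standardized-genotype scale, chunked over SNPs
    G = np.zeros((pool_n, t), dtype=np.float64)
    Fg = np.zeros((pool_n, truth.loadings.shape[1]))
    chunk = 1024
    for a in range(0, m, chunk):
        Z = dos[:, a:a + chunk].astype(np.float32)
        Z -= 2 * freq[a:a + chunk].astype(np.float32)
        Z /= sd[a:a + chunk]
        G += Z @ beta_std[a:a + chunk].astype(np.float32)
        if return_effects:
            Fg += Z @ factor_effects[a:a + chunk].astype(np.float32)

    ev = np.linalg.eigvalsh(truth.env_corr)
    if ev.min() < -1e-8:
        raise ValueError("env_corr is not positive semi-definite")
    cholE = np.linalg.cholesky(truth.env_corr + 1e-10 * np.eye(t))
    env = rng.standard_normal((pool_n, t)) @ cholE.T
    env *= np.sqrt(np.clip(1.0 - truth.total_h2, 0, None))[None, :]
    Y = G + env

    meta = _panel_meta(panel)
    tables = [None] * t
    # traits sharing a cohort (identical row sets) share one GWAS pass
    by_rows: dict = {}
    for k in range(t):
        by_rows.setdefault(rows_by_trait[k].tobytes(), []).append(k)
    for traits in by_rows.values():
        rows = rows_by_trait[traits[0]]
        tabs = _marginal_gwas(dos[rows], Y[np.ix_(rows, traits)], meta)
        for tab, k in zip(tabs, traits):
            tab.attrs["trait"] = truth.trait_names[k]
            tables[k] = tab
    if return_effects:
        return tables, truth.genetic_cov, {
            "beta_std": beta_std, "factor_effects": factor_effects,
            "mafs": mafs, "dosages": dos, "rows_by_trait": rows_by_trait,
            "genetic_values": G, "factor_genetic_values": Fg, "freq": freq,
        }
    return tables, truth.genetic_cov


def _panel_meta(panel: SnpPanelSpec) -> pd.DataFrame:
    m = panel.n_snps
    a1, a2 = panel_alleles(panel)
    return pd.DataFrame({
        "snp": [f"rs{j + 1:06d}" for j in range(m)],
        "chrom": 1, "pos": (np.arange(m) + 1) * 1000,
        "a1": a1, "a2": a2,
    })


# ---------------------------------------------------------------------------
# sidecar output

def write_sumstats(df: pd.DataFrame, path):
    df.to_csv(path, sep="\t", index=False)


def write_truth_yaml(path, panel: SnpPanelSpec = None,
                     genetic: GeneticTruth = None, pheno: PhenoTruth = None,
                     seed: int = None):
    """Record every generating parameter next to the simulated data."""
    d = {}
    if seed is not None:
        d["seed"] = int(seed)
    if panel is not None:
        d["panel"] = {"n_snps": panel.n_snps, "n_blocks": panel.n_blocks,
                      "within_block_corr": panel.within_block_corr,
                      "maf_range": list(panel.maf_range)}
    if genetic is not None:
        d["genetic"] = {
            "trait_names": list(genetic.trait_names),
            "loadings": genetic.loadings.tolist(),
            "factor_corr": genetic.factor_corr.tolist(),
            "total_h2": genetic.total_h2.tolist(),
            "residual_h2": genetic.residual_h2.tolist(),
            "n_per_trait": genetic.n_per_trait.tolist(),
            "pairwise_overlap": genetic.pairwise_overlap.tolist(),
            "env_corr": genetic.env_corr.tolist(),
        }
    if pheno is not None:
        d["phenotype"] = {
            "indicator_names": list(pheno.indicator_names),
            "loadings": list(pheno.loadings),
            "intercepts_by_group": {k: v.tolist() for k, v
                                    in pheno.intercepts_by_group.items()},
            "residual_sd": list(pheno.residual_sd),
            "factor_sd_by_group": dict(pheno.factor_sd_by_group),
            "missing_rate": pheno.missing_rate,
        }
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
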