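"""Genotype data: PLINK/VCF input, quality control, and ancestry PCA.

QC applies the standard array-data filters in a fixed order — individuals
with missing call rate above 2%, then SNPs with call rate below 98%, then
SNPs failing the Hardy-Weinberg exact test at p < 1e-4. The exact test uses
Wigginton-style enumeration of heterozygote counts rather than the chi-square
approximation, which is poor in the tail at moderate counts.

Ancestry selection is the two-stage procedure used for array cohorts: PCA on
all individuals, retention of the labelled subgroup whose scores on the first
two PCs fall within +/- 1 SD of the overall mean, then a second PCA within
the retained sample to produce the top 10 "ancestry-specific" PCs used as
regression covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "GenotypeData", "QcReport", "read_genotypes", "read_plink", "read_vcf",
    "write_plink", "qc_filter", "hwe_exact_pvalue", "ancestry_pca_select",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# PLINK 1 2-bit codes -> dosage of the A1 allele (-1 = missing)
_CODE_TO_DOSAGE = np.array([2, -1, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0, -1: 1, 1: 2, 0: 3}


@dataclass
class GenotypeData:
    """Individuals x SNPs dosage matrix plus SNP and sample metadata.

    ``dosages`` counts copies of the per-SNP A1 allele (int8; -1 = missing).
    ``snp_meta`` has columns snp, chrom, pos, a1, a2; ``sample_meta`` has
    iid, group and, after :func:`ancestry_pca_select`, PC1..PCk columns.
    """

    dosages: np.ndarray
    snp_meta: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self):
        d = np.asarray(self.dosages)
        if d.dtype != np.int8:
            d = d.astype(np.int8)
        vals = np.unique(d)
        if not np.isin(vals, [-1, 0, 1, 2]).all():
            raise ValueError("dosages must be 0/1/2 or -1 for missing")
        if d.shape != (len(self.sample_meta), len(self.snp_meta)):
            raise ValueError("dosage matrix shape does not match metadata")
        if self.snp_meta["snp"].duplicated().any():
            dup = self.snp_meta["snp"][self.snp_meta["snp"].duplicated()]
            raise ValueError(f"duplicate SNP ids: {list(dup[:5])}")
        if self.sample_meta["iid"].duplicated().any():
            raise ValueError("duplicate sample ids")
        self.dosages = d
        self.snp_meta = self.snp_meta.reset_index(drop=True)
        self.sample_meta = self.sample_meta.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.dosages == -1

    def allele_freqs(self) -> np.ndarray:
        """Observed A1 allele frequency per SNP (missing excluded)."""
        d = self.dosages
        obs = d >= 0
        with np.errstate(invalid="ignore"):
            return np.where(obs, d, 0).sum(0) / (2.0 * obs.sum(0))

    def take(self, sample_idx=None, snp_idx=None) -> "GenotypeData":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        vi = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeData(
            dosages=self.dosages[np.ix_(si, vi)],
            snp_meta=self.snp_meta.iloc[vi].reset_index(drop=True),
            sample_meta=self.sample_meta.iloc[si].reset_index(drop=True),
        )

    def pcs(self, k=10) -> np.ndarray:
        cols = [f"PC{i + 1}" for i in range(k)]
        missing = [c for c in cols if c not in self.sample_meta.columns]
        if missing:
            raise ValueError(f"PC columns not present: {missing}; "
                             "run ancestry_pca_select first")
        return self.sample_meta[cols].to_numpy(dtype=float)


@dataclass
class QcReport:
    n_individuals_removed: int
    n_snps_removed_callrate: int
    n_snps_removed_hwe: int
    ind_missing_max: float
    snp_callrate_min: float
    hwe_alpha: float

    def summary(self) -> str:
        return (f"QC: removed {self.n_individuals_removed} individuals "
                f"(missing > {self.ind_missing_max:.0%}), "
                f"{self.n_snps_removed_callrate} SNPs "
                f"(call rate < {self.snp_callrate_min:.0%}), "
                f"{self.n_snps_removed_hwe} SNPs "
                f"(HWE p < {self.hwe_alpha:g})")


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam

def write_plink(g: GenotypeData, prefix):
    """PLINK 1 binary triplet (v1.00, SNP-major). Group label goes to FID."""
    prefix = Path(prefix)
    n, m = g.n_samples, g.n_snps
    dos = g.dosages
    nbytes = (n + 3) // 4
    out = np.zeros((m, nbytes), dtype=np.uint8)
    codes = np.empty((m, n), dtype=np.uint8)
    for dosage, code in _DOSAGE_TO_CODE.items():
        codes[(dos == dosage).T] = code
    padded = np.zeros((m, nbytes * 4), dtype=np.uint8)
    padded[:, :n] = codes
    # 0-dosage pad encodes as code 3? pad with 0b00 per PLINK convention
    padded[:, n:] = 0
    for k in range(4):
        out |= (padded[:, k::4] << (2 * k)).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(out.tobytes())
    bim = pd.DataFrame({
        "chrom": g.snp_meta["chrom"], "snp": g.snp_meta["snp"],
        "cm": 0, "pos": g.snp_meta["pos"],
        "a1": g.snp_meta["a1"], "a2": g.snp_meta["a2"],
    })
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    group = g.sample_meta.get("group", pd.Series(["0"] * n))
    fam = pd.DataFrame({
        "fid": group, "iid": g.sample_meta["iid"],
        "pat": 0, "mat": 0, "sex": 0, "pheno": -9,
    })
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


def read_plink(prefix) -> GenotypeData:
    prefix = Path(prefix)
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=["chrom", "snp", "cm", "pos", "a1", "a2"],
                      dtype={"snp": str, "a1": str, "a2": str})
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"],
                      dtype={"fid": str, "iid": str})
    n, m = len(fam), len(bim)
    if n == 0 or m == 0:
        raise ValueError("empty .fam or .bim file")
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if len(raw) < 3 or bytes(raw[:3]) != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed is not a SNP-major PLINK 1 file")
    nbytes = (n + 3) // 4
    body = raw[3:]
    if len(body) != m * nbytes:
        raise ValueError(
            f".bed payload is {len(body)} bytes; expected {m * nbytes} for "
            f"{n} samples x {m} SNPs — bed/bim/fam are inconsistent")
    lut = np.empty((256, 4), dtype=np.int8)
    for b in range(256):
        for k in range(4):
            lut[b, k] = _CODE_TO_DOSAGE[(b >> (2 * k)) & 3]
    decoded = lut[body.reshape(m, nbytes)]           # (m, nbytes, 4)
    dos = decoded.reshape(m, nbytes * 4)[:, :n].T.copy()
    snp_meta = bim[["snp", "chrom", "pos", "a1", "a2"]].copy()
    sample_meta = pd.DataFrame({"iid": fam["iid"], "group": fam["fid"]})
    return GenotypeData(dosages=dos, snp_meta=snp_meta, sample_meta=sample_meta)


def read_vcf(path) -> GenotypeData:
    """Hard-called GT field of a VCF; records without a hard call are missing."""
    from cyvcf2 import VCF
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError("VCF contains no samples")
    rows, meta = [], []
    for var in vcf:
        if var.ID is None or not var.ALT:
            continue
        # gts012: 0/1/2 = copies of ALT; 3 = unknown
        gt = np.asarray(var.gt_types, dtype=np.int8)
        gt[gt == 3] = -1
        rows.append(gt)
        meta.append((var.ID, var.CHROM, var.POS, var.ALT[0], var.REF))
    if not rows:
        raise ValueError("VCF contains no usable variant records")
    snp_meta = pd.DataFrame(meta, columns=["snp", "chrom", "pos", "a1", "a2"])
    dos = np.vstack(rows).T.copy()
    sample_meta = pd.DataFrame({"iid": samples, "group": "0"})
    return GenotypeData(dosages=dos, snp_meta=snp_meta, sample_meta=sample_meta)


def read_genotypes(path, format: str = "plink") -> GenotypeData:
    """Read genotypes from a PLINK prefix or a VCF path.

    The counted allele is recorded explicitly per SNP: PLINK A1 or VCF ALT.
    """
    if format == "plink":
        return read_plink(path)
    if format == "vcf":
        return read_vcf(path)
    raise ValueError("format must be 'plink' or 'vcf'")


# ---------------------------------------------------------------------------
# quality control

def hwe_exact_pvalue(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg test p-value by heterozygote-count enumeration."""
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    # log-probability of each possible heterozygote count with same parity
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    homr = (n_rare - hets) // 2
    homc = n - hets - homr
    logp = (gammaln(n + 1) - gammaln(hets + 1) - gammaln(homr + 1)
            - gammaln(homc + 1) + hets * np.log(2.0)
            + gammaln(n_rare + 1) + gammaln(2 * n - n_rare + 1)
            - gammaln(2 * n + 1))
    p = np.exp(logp - logp.max())
    p /= p.sum()
    p_obs = p[hets == n_het][0]
    return float(min(p[p <= p_obs * (1 + 1e-12)].sum(), 1.0))


def qc_filter(g: GenotypeData, ind_missing_max: float = 0.02,
              snp_callrate_min: float = 0.98,
              hwe_alpha: float = 1e-4):
    """Apply the three QC stages in order; returns (filtered, QcReport).

    Stage order — individuals by missing rate, then SNP call rate, then the
    HWE exact test — is fixed because the SNP statistics depend on the
    retained individual set.
    """
    if g.n_samples == 0 or g.n_snps == 0:
        raise ValueError("empty genotype data")
    miss = g.missing_mask()
    ind_rate = miss.mean(axis=1)
    keep_ind = np.flatnonzero(ind_rate <= ind_missing_max)
    if len(keep_ind) == 0:
        raise ValueError("QC individual-missingness stage removed all individuals")
    g1 = g.take(sample_idx=keep_ind)

    call = 1.0 - g1.missing_mask().mean(axis=0)
    keep_call = call >= snp_callrate_min
    n_callrate_removed = int((~keep_call).sum())
    if not keep_call.any():
        raise ValueError("QC SNP call-rate stage removed all SNPs")
    g2 = g1.take(snp_idx=np.flatnonzero(keep_call))

    d = g2.dosages
    n_het = (d == 1).sum(0)
    n_hom_a1 = (d == 2).sum(0)
    n_hom_a2 = (d == 0).sum(0)
    pvals = np.array([hwe_exact_pvalue(h, r, c)
                      for h, r, c in zip(n_het, n_hom_a1, n_hom_a2)])
    keep_hwe = pvals >= hwe_alpha
    n_hwe_removed = int((~keep_hwe).sum())
    if not keep_hwe.any():
        raise ValueError("QC HWE stage removed all SNPs")
    g3 = g2.take(snp_idx=np.flatnonzero(keep_hwe))

    report = QcReport(
        n_individuals_removed=g.n_samples - len(keep_ind),
        n_snps_removed_callrate=n_callrate_removed,
        n_snps_removed_hwe=n_hwe_removed,
        ind_missing_max=ind_missing_max,
        snp_callrate_min=snp_callrate_min,
        hwe_alpha=hwe_alpha,
    )
    return g3, report


# ---------------------------------------------------------------------------
# ancestry PCA

def _pca_scores(g: GenotypeData, k: int) -> np.ndarray:
    """PC scores of mean-imputed, variance-standardized dosages.

    Monomorphic SNPs are excluded rather than standardized (no division by
    zero); no LD pruning by default.
    """
    d = g.dosages.astype(np.float32)
    d[d < 0] = np.nan
    mean = np.nanmean(d, axis=0)
    inds = np.where(np.isnan(d))
    d[inds] = np.take(mean, inds[1])
    sd = d.std(axis=0, ddof=1)
    poly = sd > 0
    X = (d[:, poly] - mean[poly]) / sd[poly]
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    return U[:, :k] * s[:k]


def ancestry_pca_select(g: GenotypeData, label: str, sd_window: float = 1.0,
                        n_pcs_out: int = 10) -> GenotypeData:
    """Two-stage ancestry PCA selection.

    Stage 1: PCA over all individuals; individuals carrying ``label`` whose
    scores on PCs 1 and 2 both lie within mean +/- sd_window*SD (mean and SD
    over all individuals) are retained. Stage 2: PCA within the retained
    sample; the top ``n_pcs_out`` PC scores are attached to sample_meta.
    """
    if g.n_samples <= n_pcs_out:
        raise ValueError(
            f"{g.n_samples} individuals cannot support {n_pcs_out} PCs")
    scores = _pca_scores(g, 2)
    mean = scores.mean(0)
    sd = scores.std(0, ddof=1)
    in_window = np.all(np.abs(scores - mean) <= sd_window * sd, axis=1)
    is_label = (g.sample_meta["group"].to_numpy() == label)
    keep = np.flatnonzero(in_window & is_label)
    if len(keep) < n_pcs_out + 1:
        raise ValueError(
            f"only {len(keep)} individuals retained; need at least "
            f"{n_pcs_out + 1} for {n_pcs_out} PCs")
    sub = g.take(sample_idx=keep)
    pcs = _pca_scores(sub, n_pcs_out)
    if pcs.shape[1] < n_pcs_out:
        raise ValueError("retained panel has too few polymorphic SNPs for "
                         f"{n_pcs_out} PCs")
    sm = sub.sample_meta.copy()
    for j in range(n_pcs_out):
        sm[f"PC{j + 1}"] = pcs[:, j] - pcs[:, j].mean()
    return GenotypeData(dosages=sub.dosages, snp_meta=sub.snp_meta,
                        sample_meta=sm)
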