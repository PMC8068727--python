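"""Polygenic scores from GWAS summary statistics.

Scores follow the direct genotyped-SNP recipe: match array SNPs to GWAS
results by id, orient every weight to the risk-increasing allele, form the
weighted allele-count sum over ALL matched SNPs — no LD trimming and no GWAS
p-value threshold — and normalize the scores within the analysis sample.

Summary-statistics tables and weight tables are plain pandas DataFrames with
canonical columns (SNP, A1, A2, BETA, SE, P, N and snp, counted_allele,
weight, source respectively).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .genotype import GenotypeData

__all__ = [
    "read_sumstats", "validate_sumstats", "harmonize_weights",
    "compute_pgs", "normalize_pgs", "write_weights",
]

_VALID_ALLELES = {"A", "C", "G", "T"}
_PALINDROMIC = {frozenset({"A", "T"}), frozenset({"C", "G"})}

DEFAULT_COLUMNS = {"SNP": "SNP", "A1": "A1", "A2": "A2", "BETA": "BETA",
                   "SE": "SE", "P": "P", "N": "N"}


def read_sumstats(path, column_map: dict | None = None,
                  or_column: str | None = None) -> pd.DataFrame:
    """Read a tab-separated GWAS summary-statistics table.

    ``column_map`` renames source columns onto the canonical names; pass
    ``or_column`` when effects are odds ratios (log-transformed on read).
    Duplicate SNP ids are dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t")
    cmap = dict(DEFAULT_COLUMNS)
    if column_map:
        cmap.update(column_map)
    rename = {v: k for k, v in cmap.items() if v in df.columns}
    df = df.rename(columns=rename)
    if or_column:
        if or_column in df.columns:
            df["BETA"] = np.log(df[or_column].astype(float))
        elif "BETA" not in df.columns:
            raise ValueError(f"odds-ratio column {or_column!r} not found")
    elif "BETA" not in df.columns and "OR" in df.columns:
        df["BETA"] = np.log(df["OR"].astype(float))
    return validate_sumstats(df)


def validate_sumstats(df: pd.DataFrame) -> pd.DataFrame:
    need = ["SNP", "A1", "A2", "BETA", "SE", "P", "N"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"summary statistics lack columns: {missing}")
    df = df[need].copy()
    df["A1"] = df["A1"].str.upper()
    df["A2"] = df["A2"].str.upper()
    bad_alleles = ~(df["A1"].isin(_VALID_ALLELES) & df["A2"].isin(_VALID_ALLELES))
    if bad_alleles.any():
        raise ValueError(f"{int(bad_alleles.sum())} rows with non-ACGT alleles")
    if (df["A1"] == df["A2"]).any():
        raise ValueError("rows with identical effect and other allele")
    if (df["SE"] <= 0).any():
        raise ValueError("standard errors must be positive")
    if ((df["P"] <= 0) | (df["P"] > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    dup = df["SNP"].duplicated()
    if dup.any():
        warnings.warn(f"dropping {int(dup.sum())} duplicate SNP ids")
        df = df[~dup]
    return df.reset_index(drop=True)


def harmonize_weights(ss: pd.DataFrame, g: GenotypeData,
                      drop_palindromic: bool = False,
                      source: str | None = None) -> pd.DataFrame:
    """Match sumstats to the genotype panel and orient weights to risk alleles.

    Returns a weight table (snp, counted_allele, weight, source) whose
    weights are all non-negative: each SNP is expressed in terms of its
    risk-increasing allele. SNPs whose allele pairs cannot be reconciled are
    dropped and tallied in ``.attrs["n_mismatch"]``.
    """
    if len(ss) == 0 or g.n_snps == 0:
        raise ValueError("empty sumstats or genotype panel")
    ss = validate_sumstats(ss)
    panel = g.snp_meta[["snp", "a1", "a2"]]
    merged = ss.merge(panel, left_on="SNP", right_on="snp", how="inner")
    if len(merged) == 0:
        raise ValueError(
            "no SNP ids shared between the summary statistics and the "
            f"genotype panel ({len(ss)} vs {g.n_snps} SNPs)")
    if drop_palindromic:
        pal = merged.apply(
            lambda r: frozenset({r["A1"], r["A2"]}) in _PALINDROMIC, axis=1)
        merged = merged[~pal]
    same = (merged["A1"] == merged["a1"]) & (merged["A2"] == merged["a2"])
    flipped = (merged["A1"] == merged["a2"]) & (merged["A2"] == merged["a1"])
    n_mismatch = int((~(same | flipped)).sum())
    merged = merged[same | flipped].copy()
    if len(merged) == 0:
        raise ValueError("no SNPs with reconcilable allele pairs remain")
    # express the effect for the panel's counted (A1) allele ...
    w = np.where(merged["A1"] == merged["a1"], merged["BETA"], -merged["BETA"])
    counted = merged["a1"].to_numpy(dtype=object)
    other = merged["a2"].to_numpy(dtype=object)
    # ... then re-orient every entry to the risk-increasing allele
    neg = w < 0
    counted[neg], other[neg] = other[neg], counted[neg]
    w = np.abs(w)
    out = pd.DataFrame({
        "snp": merged["snp"].to_numpy(),
        "counted_allele": counted,
        "weight": w,
        "source": source or ss.attrs.get("trait", "trait"),
    })
    out.attrs["n_mismatch"] = n_mismatch
    out.attrs["n_matched"] = len(out)
    return out


def _dosage_of(g: GenotypeData, weights: pd.DataFrame) -> np.ndarray:
    """Dosage matrix counted on the weight table's counted allele (float,
    NaN for missing)."""
    pos = pd.Series(np.arange(g.n_snps), index=g.snp_meta["snp"])
    absent = ~weights["snp"].isin(pos.index)
    if absent.any():
        raise ValueError(
            f"{int(absent.sum())} weight SNPs absent from the genotype panel")
    cols = pos[weights["snp"]].to_numpy()
    d = g.dosages[:, cols].astype(float)
    d[d < 0] = np.nan
    a1 = g.snp_meta["a1"].to_numpy()[cols]
    a2 = g.snp_meta["a2"].to_numpy()[cols]
    counted = weights["counted_allele"].to_numpy()
    if not np.all((counted == a1) | (counted == a2)):
        raise ValueError("counted alleles not present in the genotype panel; "
                         "harmonize weights against this panel first")
    flip = counted == a2
    d[:, flip] = 2.0 - d[:, flip]
    return d


def compute_pgs(g: GenotypeData, weights: pd.DataFrame,
                missing_policy: str = "mean_impute") -> pd.DataFrame:
    """Weighted allele-count scores: raw_i = sum_j weight_j * dosage_ij.

    Missing dosages are replaced by twice the counted-allele frequency
    (``mean_impute``, the PLINK convention) or the SNP is skipped for that
    individual (``omit``). Scores are z-standardized within the sample.
    """
    if missing_policy not in ("mean_impute", "omit"):
        raise ValueError("missing_policy must be 'mean_impute' or 'omit'")
    d = _dosage_of(g, weights)
    w = weights["weight"].to_numpy(dtype=float)
    obs = ~np.isnan(d)
    n_used = obs.sum(axis=1)
    if missing_policy == "mean_impute":
        freq = np.nanmean(d, axis=0) / 2.0
        fill = np.broadcast_to(2.0 * freq, d.shape)
        d = np.where(obs, d, fill)
        raw = d @ w
        n_used = np.full(len(d), len(w))
    else:
        if (n_used == 0).any():
            bad = g.sample_meta["iid"][n_used == 0].tolist()[:5]
            raise ValueError(f"individuals with zero usable SNPs under "
                             f"'omit' policy: {bad}")
        raw = np.where(obs, d, 0.0) @ w
    out = pd.DataFrame({
        "iid": g.sample_meta["iid"].to_numpy(),
        "raw_score": raw,
        "z_score": normalize_pgs(raw),
        "n_snps_used": n_used,
    })
    out.attrs["trait"] = str(weights["source"].iloc[0])
    out.attrs["missing_policy"] = missing_policy
    return out


def normalize_pgs(raw) -> np.ndarray:
    """Within-sample standardization (mean 0, SD 1; sample SD with n-1)."""
    raw = np.asarray(raw, dtype=float)
    if len(raw) < 2:
        raise ValueError("need at least 2 individuals to normalize")
    sd = raw.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("scores have zero variance; cannot normalize")
    return (raw - raw.mean()) / sd


def write_weights(weights: pd.DataFrame, path):
    weights.to_csv(path, sep="\t", index=False)
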