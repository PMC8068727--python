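"""Genotype IO (PLINK codec, VCF), QC filters, HWE exact test, ancestry PCA."""

import math
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from latentpgs import (
    GenotypeData, SnpPanelSpec, ancestry_pca_select, hwe_exact_pvalue,
    qc_filter, read_genotypes, simulate_genotypes, write_plink,
)


def _tiny_genotypes(dosages, groups=None):
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    return GenotypeData(
        dosages=dosages,
        snp_meta=pd.DataFrame({
            "snp": [f"rs{j}" for j in range(m)], "chrom": 1,
            "pos": np.arange(m) + 1, "a1": "A", "a2": "G"}),
        sample_meta=pd.DataFrame({
            "iid": [f"s{i}" for i in range(n)],
            "group": groups if groups is not None else "EUR"}),
    )


class TestPlinkCodec:
    def test_hand_decoded_bed_fixture(self, tmp_path):
        """A 3-sample, 2-SNP .bed written byte-by-byte from the PLINK spec:
        codes 00=hom A1 (dosage 2), 01=missing, 10=het, 11=hom A2."""
        # SNP1: s1 hom A1 (00), s2 het (10), s3 missing (01)
        byte1 = 0b00_01_10_00   # bits: s1 in 0-1, s2 in 2-3, s3 in 4-5
        # SNP2: s1 hom A2 (11), s2 hom A1 (00), s3 het (10)
        byte2 = 0b00_10_00_11
        (tmp_path / "toy.bed").write_bytes(bytes([0x6C, 0x1B, 0x01,
                                                  byte1, byte2]))
        (tmp_path / "toy.bim").write_text(
            "1\trs1\t0\t100\tA\tG\n1\trs2\t0\t200\tC\tT\n")
        (tmp_path / "toy.fam").write_text(
            "f1\ts1\t0\t0\t0\t-9\nf1\ts2\t0\t0\t0\t-9\nf1\ts3\t0\t0\t0\t-9\n")
        g = read_genotypes(tmp_path / "toy", format="plink")
        expected = np.array([[2, 0], [1, 2], [-1, 1]], dtype=np.int8)
        assert np.array_equal(g.dosages, expected)
        assert list(g.snp_meta["a1"]) == ["A", "C"]
        assert list(g.sample_meta["iid"]) == ["s1", "s2", "s3"]

    def test_roundtrip_identity(self, tmp_path):
        panel = SnpPanelSpec(n_snps=37, n_blocks=4, within_block_corr=0.3)
        g = simulate_genotypes(53, panel, seed=1, missing_rate=0.05)
        write_plink(g, tmp_path / "rt")
        g2 = read_genotypes(tmp_path / "rt", format="plink")
        assert np.array_equal(g.dosages, g2.dosages)
        assert list(g.snp_meta["snp"]) == list(g2.snp_meta["snp"])
        assert list(g.snp_meta["a1"]) == list(g2.snp_meta["a1"])
        assert list(g.sample_meta["iid"]) == list(g2.sample_meta["iid"])

    def test_empty_variant_set_errors(self, tmp_path):
        (tmp_path / "e.bed").write_bytes(bytes([0x6C, 0x1B, 0x01]))
        (tmp_path / "e.bim").write_text("")
        (tmp_path / "e.fam").write_text("f\ts1\t0\t0\t0\t-9\n")
        with pytest.raises((ValueError, pd.errors.EmptyDataError)):
            read_genotypes(tmp_path / "e", format="plink")

    def test_inconsistent_triplet_errors(self, tmp_path):
        panel = SnpPanelSpec(n_snps=10)
        g = simulate_genotypes(20, panel, seed=2)
        write_plink(g, tmp_path / "bad")
        # truncate the fam to 10 samples -> payload mismatch
        fam = (tmp_path / "bad.fam").read_text().splitlines()
        (tmp_path / "bad.fam").write_text("\n".join(fam[:10]) + "\n")
        with pytest.raises(ValueError, match="inconsistent"):
            read_genotypes(tmp_path / "bad", format="plink")

    def test_duplicate_snp_ids_rejected(self):
        d = np.zeros((3, 2), dtype=np.int8)
        meta = pd.DataFrame({"snp": ["rs1", "rs1"], "chrom": 1,
                             "pos": [1, 2], "a1": "A", "a2": "G"})
        sm = pd.DataFrame({"iid": list("abc"), "group": "x"})
        with pytest.raises(ValueError, match="duplicate SNP"):
            GenotypeData(dosages=d, snp_meta=meta, sample_meta=sm)


class TestVcf:
    def test_vcf_gt_parsing(self, tmp_path):
        vcf = tmp_path / "toy.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\n"
            "1\t100\trs1\tG\tA\t.\t.\t.\tGT\t1/1\t0/1\t./.\n"
            "1\t200\trs2\tT\tC\t.\t.\t.\tGT\t0/0\t1/0\t1/1\n")
        g = read_genotypes(vcf, format="vcf")
        # dosage counts the ALT allele
        expected = np.array([[2, 0], [1, 1], [-1, 2]], dtype=np.int8)
        assert np.array_equal(g.dosages, expected)
        assert list(g.snp_meta["a1"]) == ["A", "C"]
        assert list(g.snp_meta["a2"]) == ["G", "T"]


class TestHwe:
    def _oracle(self, het, hom1, hom2):
        """Exact-integer enumeration of the conditional distribution of the
        heterozygote count, independent of the gammaln implementation."""
        n = het + hom1 + hom2
        nr = 2 * min(hom1, hom2) + het
        # exact: P(h) proportional to n!/(h! r! c!) 2^h
        probs = {}
        for h in range(nr % 2, nr + 1, 2):
            r = (nr - h) // 2
            c = n - h - r
            num = (math.factorial(n) * 2 ** h)
            den = (math.factorial(h) * math.factorial(r) * math.factorial(c))
            probs[h] = num / den
        tot = sum(probs.values())
        p_obs = probs[het]
        return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12)) / tot

    @pytest.mark.parametrize("het,hom1,hom2", [
        (0, 50, 50), (50, 25, 25), (10, 5, 85), (3, 0, 97), (20, 40, 40),
        (1, 1, 1), (0, 0, 10),
    ])
    def test_matches_exact_integer_oracle(self, het, hom1, hom2):
        assert hwe_exact_pvalue(het, hom1, hom2) == pytest.approx(
            self._oracle(het, hom1, hom2), rel=1e-10)

    def test_extreme_disequilibrium_tiny_p(self):
        assert hwe_exact_pvalue(0, 50, 50) < 1e-20

    def test_perfect_hwe_p_one(self):
        assert hwe_exact_pvalue(50, 25, 25) == pytest.approx(1.0)


class TestQc:
    def test_hwe_stage_removes_het_deficient_snp(self):
        rng = np.random.default_rng(0)
        good = rng.binomial(2, 0.5, size=(100, 3)).astype(np.int8)
        bad = np.array([2] * 50 + [0] * 50, dtype=np.int8)[:, None]
        g = _tiny_genotypes(np.hstack([good, bad]))
        out, rep = qc_filter(g)
        assert rep.n_snps_removed_hwe == 1
        assert "rs3" not in list(out.snp_meta["snp"])

    def test_perfect_hwe_nothing_removed(self):
        col = np.array([2] * 25 + [1] * 50 + [0] * 25, dtype=np.int8)
        g = _tiny_genotypes(np.column_stack([col, col[::-1]]))
        out, rep = qc_filter(g)
        assert (rep.n_individuals_removed, rep.n_snps_removed_callrate,
                rep.n_snps_removed_hwe) == (0, 0, 0)
        assert out.n_snps == 2

    def test_individual_removed_before_snp_callrate(self):
        rng = np.random.default_rng(1)
        d = rng.binomial(2, 0.5, size=(50, 100)).astype(np.int8)
        d[0, :3] = -1          # individual 0 missing 3% > 2%
        g = _tiny_genotypes(d)
        out, rep = qc_filter(g)
        assert rep.n_individuals_removed == 1
        # once the individual is gone the three SNPs are complete again
        assert rep.n_snps_removed_callrate == 0

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        d = rng.binomial(2, 0.4, size=(80, 40)).astype(np.int8)
        d[rng.random(d.shape) < 0.01] = -1
        g = _tiny_genotypes(d)
        once, _ = qc_filter(g)
        twice, rep2 = qc_filter(once)
        assert (rep2.n_individuals_removed, rep2.n_snps_removed_callrate,
                rep2.n_snps_removed_hwe) == (0, 0, 0)
        assert np.array_equal(once.dosages, twice.dosages)

    def test_all_removed_names_stage(self):
        d = np.full((4, 3), -1, dtype=np.int8)
        with pytest.raises(ValueError, match="individual"):
            qc_filter(_tiny_genotypes(d))


class TestAncestryPca:
    def test_homogeneous_retention_fraction(self):
        panel = SnpPanelSpec(n_snps=300, maf_range=(0.1, 0.5))
        g = simulate_genotypes(1500, panel, seed=3)
        out = ancestry_pca_select(g, "EUR", sd_window=1.0, n_pcs_out=10)
        frac = out.n_samples / g.n_samples
        # two roughly normal PC margins: P(|z|<1)^2 ~ 0.466
        assert 0.38 < frac < 0.55

    def test_displaced_cluster_excluded(self):
        panel = SnpPanelSpec(n_snps=400, maf_range=(0.2, 0.5))
        g1 = simulate_genotypes(900, panel, seed=4)
        # second cluster: systematically different allele frequencies
        from latentpgs.simulate import panel_mafs
        g2 = simulate_genotypes(100, panel, seed=5,
                                mafs=np.clip(panel_mafs(panel) + 0.3, 0, 0.5))
        d = np.vstack([g1.dosages, g2.dosages])
        sm = pd.DataFrame({"iid": [f"i{k}" for k in range(1000)],
                           "group": "EUR"})
        g = GenotypeData(dosages=d, snp_meta=g1.snp_meta, sample_meta=sm)
        out = ancestry_pca_select(g, "EUR", sd_window=1.0, n_pcs_out=5)
        kept = set(out.sample_meta["iid"])
        displaced_kept = sum(f"i{k}" in kept for k in range(900, 1000))
        assert displaced_kept <= 2

    def test_label_filter_applies(self):
        panel = SnpPanelSpec(n_snps=200)
        g = simulate_genotypes(400, panel, seed=6)
        g.sample_meta.loc[:99, "group"] = "OTHER"
        out = ancestry_pca_select(g, "EUR", n_pcs_out=5)
        assert (out.sample_meta["group"] == "EUR").all()

    def test_rank_bound_error(self):
        panel = SnpPanelSpec(n_snps=50)
        g = simulate_genotypes(5, panel, seed=7)
        with pytest.raises(ValueError):
            ancestry_pca_select(g, "EUR", n_pcs_out=10)

    def test_pcs_orthogonal_and_ordered(self):
        panel = SnpPanelSpec(n_snps=300, maf_range=(0.1, 0.5))
        g = simulate_genotypes(800, panel, seed=8)
        out = ancestry_pca_select(g, "EUR", n_pcs_out=6)
        P = out.pcs(6)
        G = P.T @ P
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-3 * np.max(np.diag(G))
        assert np.all(np.diff(np.diag(G)) <= 1e-6)
        assert np.allclose(P.mean(0), 0.0, atol=1e-6)

    def test_monomorphic_snps_excluded_not_divided(self):
        d = np.hstack([
            np.random.default_rng(9).binomial(2, 0.4, (60, 20)).astype(np.int8),
            np.zeros((60, 5), dtype=np.int8)])
        g = _tiny_genotypes(d)
        out = ancestry_pca_select(g, "EUR", n_pcs_out=3)
        assert np.all(np.isfinite(out.pcs(3)))
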