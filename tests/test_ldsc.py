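"""LD scores and LD-score regression: oracles, nulls, symmetry, and the
genetic-covariance assembly with its shared-block jackknife."""

import numpy as np
import pandas as pd
import pytest

from latentpgs import (
    GeneticTruth, GenotypeData, SnpPanelSpec, build_genetic_cov,
    compute_ld_scores, ldsc_bivariate, ldsc_univariate, simulate_genotypes,
    simulate_multitrait_gwas,
)

# low-MAF SNPs give near-unit LD scores, anchoring the intercept
PANEL = SnpPanelSpec(n_snps=1200, n_blocks=60, within_block_corr=0.7,
                     maf_range=(0.02, 0.5))


@pytest.fixture(scope="module")
def ld_ref():
    g = simulate_genotypes(1200, PANEL, seed=77)
    return compute_ld_scores(g, window_snps=40)


def _flat_sumstats(n_snps, n=10000):
    """Summary statistics with chi-square identically 1 for every SNP."""
    a = ["A"] * n_snps
    g = ["G"] * n_snps
    return pd.DataFrame({"SNP": [f"rs{j + 1:06d}" for j in range(n_snps)],
                         "A1": a, "A2": g, "BETA": [0.01] * n_snps,
                         "SE": [0.01] * n_snps, "P": [0.5] * n_snps,
                         "N": [n] * n_snps})


class TestLdScores:
    def test_linkage_equilibrium_scores_near_one(self):
        panel = SnpPanelSpec(n_snps=60, maf_range=(0.2, 0.5))
        g = simulate_genotypes(4000, panel, seed=1)
        ld = compute_ld_scores(g, window_snps=10)
        assert np.all(np.abs(ld["L2"] - 1.0) < 0.15)
        assert abs(ld["L2"].mean() - 1.0) < 0.02

    def test_duplicated_snp_adds_one(self):
        panel = SnpPanelSpec(n_snps=30, maf_range=(0.2, 0.5))
        g = simulate_genotypes(3000, panel, seed=2)
        d2 = np.hstack([g.dosages, g.dosages[:, [0]]])
        meta2 = pd.concat([g.snp_meta, g.snp_meta.iloc[[0]].assign(snp="dup")],
                          ignore_index=True)
        g2 = GenotypeData(dosages=d2, snp_meta=meta2,
                          sample_meta=g.sample_meta)
        ld1 = compute_ld_scores(g, window_snps=40)
        ld2 = compute_ld_scores(g2, window_snps=40)
        assert ld2["L2"].iloc[0] == pytest.approx(ld1["L2"].iloc[0] + 1.0,
                                                  abs=0.05)

    def test_brute_force_all_pairs_oracle(self):
        panel = SnpPanelSpec(n_snps=25, n_blocks=5, within_block_corr=0.6,
                             maf_range=(0.2, 0.5))
        g = simulate_genotypes(500, panel, seed=3)
        ld = compute_ld_scores(g, window_snps=25)
        X = g.dosages.astype(float)
        n = len(X)
        R = np.corrcoef(X, rowvar=False)
        r2adj = R ** 2 - (1 - R ** 2) / (n - 2)
        assert np.allclose(ld["L2"], r2adj.sum(axis=1), atol=1e-8)

    def test_window_restricts_pairs(self):
        panel = SnpPanelSpec(n_snps=100, n_blocks=1, within_block_corr=0.9)
        g = simulate_genotypes(800, panel, seed=4)
        wide = compute_ld_scores(g, window_snps=99)["L2"]
        narrow = compute_ld_scores(g, window_snps=5)["L2"]
        assert (wide > narrow + 1).mean() > 0.9

    def test_bad_window(self):
        g = simulate_genotypes(50, SnpPanelSpec(n_snps=10), seed=5)
        with pytest.raises(ValueError):
            compute_ld_scores(g, window_snps=0)


class TestUnivariate:
    def test_flat_chi2_gives_zero_slope(self, ld_ref):
        res = ldsc_univariate(_flat_sumstats(PANEL.n_snps), ld_ref,
                              n_blocks=50)
        assert res.h2 == pytest.approx(0.0, abs=1e-10)
        assert res.intercept == pytest.approx(1.0, abs=1e-10)

    def test_null_heritability_calibration(self, ld_ref):
        truth = GeneticTruth(trait_names=["t"], loadings=np.zeros((1, 1)),
                             total_h2=[0.0], n_per_trait=[8000])
        covered_h2 = covered_int = 0
        for rep in range(4):
            tabs, _ = simulate_multitrait_gwas(truth, PANEL, seed=30 + rep)
            res = ldsc_univariate(tabs[0], ld_ref, n_blocks=60)
            lo, hi = res.h2_ci()
            covered_h2 += lo <= 0.0 <= hi
            lo, hi = res.intercept_ci()
            covered_int += lo <= 1.0 <= hi
        assert covered_h2 >= 3
        assert covered_int >= 3

    def test_recovers_generating_h2(self, ld_ref):
        truth = GeneticTruth(trait_names=["t"], loadings=np.array([[1.0]]),
                             total_h2=[0.4], n_per_trait=[10000])
        covered = 0
        for rep in range(4):
            tabs, _ = simulate_multitrait_gwas(truth, PANEL, seed=40 + rep)
            res = ldsc_univariate(tabs[0], ld_ref, n_blocks=60)
            lo, hi = res.h2_ci()
            covered += lo <= 0.4 <= hi
        assert covered >= 3

    def test_too_few_snps(self, ld_ref):
        with pytest.raises(ValueError, match="200"):
            ldsc_univariate(_flat_sumstats(50), ld_ref)


class TestBivariate:
    def test_exact_symmetry(self, ld_ref):
        truth = GeneticTruth(trait_names=["a", "b"],
                             loadings=np.array([[0.9], [0.7]]),
                             total_h2=[0.4, 0.3], n_per_trait=[6000, 6000])
        tabs, _ = simulate_multitrait_gwas(truth, PANEL, seed=50)
        r1 = ldsc_bivariate(tabs[0], tabs[1], ld_ref, n_blocks=60)
        r2 = ldsc_bivariate(tabs[1], tabs[0], ld_ref, n_blocks=60)
        assert r1.h2 == pytest.approx(r2.h2, abs=1e-12)
        assert r1.intercept == pytest.approx(r2.intercept, abs=1e-12)

    def test_self_pairing_matches_univariate(self, ld_ref):
        truth = GeneticTruth(trait_names=["t"], loadings=np.array([[1.0]]),
                             total_h2=[0.35], n_per_trait=[9000])
        tabs, _ = simulate_multitrait_gwas(truth, PANEL, seed=51)
        uni = ldsc_univariate(tabs[0], ld_ref, n_blocks=60)
        biv = ldsc_bivariate(tabs[0], tabs[0], ld_ref, n_blocks=60)
        assert biv.h2 == pytest.approx(uni.h2, rel=0.15, abs=0.03)
        assert biv.intercept == pytest.approx(uni.intercept, abs=0.3)

    def test_disjoint_uncorrelated_null(self, ld_ref):
        truth = GeneticTruth(trait_names=["a", "b"],
                             loadings=np.array([[1.0, 0.0], [0.0, 1.0]]),
                             factor_corr=np.eye(2),
                             total_h2=[0.3, 0.3], n_per_trait=[8000, 8000])
        cov_cov = cov_int = 0
        for rep in range(3):
            tabs, S = simulate_multitrait_gwas(truth, PANEL, seed=60 + rep)
            assert S[0, 1] == 0.0
            res = ldsc_bivariate(tabs[0], tabs[1], ld_ref, n_blocks=60)
            lo, hi = res.h2_ci()
            cov_cov += lo <= 0.0 <= hi
            lo, hi = res.intercept_ci()
            cov_int += lo <= 0.0 <= hi
        assert cov_cov >= 2 and cov_int >= 2

    def test_duplicated_trait_full_overlap(self, ld_ref):
        """Two copies of the same cohort and phenotype: genetic correlation 1
        and a cross-trait intercept like the univariate one (near 1)."""
        n = 9000
        truth = GeneticTruth(
            trait_names=["t", "t2"], loadings=np.array([[1.0], [1.0]]),
            total_h2=[0.05, 0.05], n_per_trait=[n, n],
            pairwise_overlap=np.array([[0, n], [n, 0]]),
            env_corr=np.array([[1.0, 1.0], [1.0, 1.0]]))
        intercepts = []
        for rep in range(5):
            tabs, _ = simulate_multitrait_gwas(truth, PANEL, seed=70 + rep)
            # identical cohorts and phenotypes -> near-identical statistics
            assert np.allclose(tabs[0]["BETA"], tabs[1]["BETA"], atol=1e-4)
            biv = ldsc_bivariate(tabs[0], tabs[1], ld_ref, n_blocks=60)
            intercepts.append(biv.intercept)
            if rep == 0:
                h11 = ldsc_bivariate(tabs[0], tabs[0], ld_ref, n_blocks=60)
                h22 = ldsc_bivariate(tabs[1], tabs[1], ld_ref, n_blocks=60)
                rg = biv.h2 / np.sqrt(h11.h2 * h22.h2)
                assert rg == pytest.approx(1.0, abs=1e-3)
                assert biv.intercept == pytest.approx(h11.intercept, abs=1e-3)
        # chi2-regression intercept for a fully shared cohort is ~1: the
        # replicate mean must be bounded away from 0
        mean = np.mean(intercepts)
        se = np.std(intercepts, ddof=1) / np.sqrt(len(intercepts))
        assert mean - 2 * se > 0.0
        assert mean == pytest.approx(1.0, abs=0.6)


class TestGeneticCovAssembly:
    def test_identical_traits_give_equal_entries(self, ld_ref):
        n = 8000
        truth = GeneticTruth(
            trait_names=["t", "t2"], loadings=np.array([[1.0], [1.0]]),
            total_h2=[0.3, 0.3], n_per_trait=[n, n],
            pairwise_overlap=np.array([[0, n], [n, 0]]),
            env_corr=np.ones((2, 2)))
        tabs, _ = simulate_multitrait_gwas(truth, PANEL, seed=80)
        gc = build_genetic_cov(tabs, ld_ref, n_blocks=60)
        assert gc.S[0, 0] == pytest.approx(gc.S[1, 1], abs=1e-3)
        assert gc.S[0, 1] == pytest.approx(gc.S[0, 0], abs=1e-3)

    def test_independent_traits_offdiagonal_null(self, ld_ref):
        truth = GeneticTruth(trait_names=["a", "b"],
                             loadings=np.array([[1.0, 0.0], [0.0, 1.0]]),
                             total_h2=[0.3, 0.3], n_per_trait=[8000, 8000])
        tabs, _ = simulate_multitrait_gwas(truth, PANEL, seed=81)
        gc = build_genetic_cov(tabs, ld_ref, n_blocks=60)
        # vech order (0,0),(1,0),(1,1): off-diagonal is element 1
        se = np.sqrt(gc.V[1, 1])
        assert abs(gc.S[0, 1]) < 3 * se

    def test_v_symmetric_psd_and_dimensions(self, ld_ref):
        truth = GeneticTruth(trait_names=["a", "b", "c"],
                             loadings=np.array([[0.9], [0.7], [0.5]]),
                             total_h2=[0.3, 0.3, 0.3],
                             n_per_trait=[6000, 6000, 6000])
        tabs, _ = simulate_multitrait_gwas(truth, PANEL, seed=82)
        gc = build_genetic_cov(tabs, ld_ref, n_blocks=60)
        q = 3 * 4 // 2
        assert gc.V.shape == (q, q)
        assert np.allclose(gc.V, gc.V.T)
        assert np.linalg.eigvalsh(gc.V).min() >= -1e-12
        assert np.allclose(gc.S, gc.S.T)
        assert gc.smoothing_applied >= 0.0

    def test_yaml_bundle_roundtrip(self, ld_ref, tmp_path):
        from latentpgs import GeneticCov
        truth = GeneticTruth(trait_names=["a", "b"],
                             loadings=np.array([[0.9], [0.7]]),
                             total_h2=[0.3, 0.3], n_per_trait=[6000, 6000])
        tabs, _ = simulate_multitrait_gwas(truth, PANEL, seed=84)
        gc = build_genetic_cov(tabs, ld_ref, n_blocks=60)
        gc.save(tmp_path / "gc.yaml")
        back = GeneticCov.load(tmp_path / "gc.yaml")
        assert back.trait_names == gc.trait_names
        assert np.allclose(back.S, gc.S)
        assert np.allclose(back.V, gc.V)
        assert np.allclose(back.intercepts, gc.intercepts)

    def test_failure_names_trait_pair(self, ld_ref, monkeypatch):
        truth = GeneticTruth(trait_names=["a", "b"],
                             loadings=np.array([[0.9], [0.7]]),
                             total_h2=[0.3, 0.3], n_per_trait=[5000, 5000])
        tabs, _ = simulate_multitrait_gwas(truth, PANEL, seed=83)
        import latentpgs.ldsc as ldsc_mod

        def boom(*a, **kw):
            raise np.linalg.LinAlgError("singular")

        monkeypatch.setattr(ldsc_mod, "ldsc_bivariate", boom)
        with pytest.raises(RuntimeError, match=r"trait pair \(b, a\)"):
            build_genetic_cov(tabs, ld_ref, n_blocks=60)
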