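"""Confirmatory factor analysis engine: closed forms, fit indices,
model comparison, invariance, factor scores and the split-half utility."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from latentpgs import (
    CFAModel, FactorModelSpec, age_group_labels, compare_models,
    drop_negative_indicators, fit_indices_from_stats, invariance_ladder,
    rmsea_ci, split_half,
)
from tests.conftest import data_with_exact_cov, one_factor_sample


def _corr3(s12, s13, s23):
    return np.array([[1.0, s12, s13], [s12, 1.0, s23], [s13, s23, 1.0]])


class TestClosedForm:
    """A just-identified 3-indicator one-factor model has the closed-form
    solution lambda_1 = sqrt(s12*s13/s23) (and permutations)."""

    @pytest.mark.parametrize("s12,s13,s23", [
        (0.72, 0.63, 0.56),          # loadings 0.9, 0.8, 0.7
        (0.35, 0.30, 0.42),
        (0.12, 0.20, 0.15),
    ])
    def test_matches_formula(self, s12, s13, s23):
        S = _corr3(s12, s13, s23)
        X = data_with_exact_cov(S, 400, seed=3)
        res = CFAModel(X, FactorModelSpec.one_factor(list("abc"))).fit(
            estimator="ml")
        lam = np.abs(res.loadings.to_numpy().ravel())
        expected = np.array([
            np.sqrt(s12 * s13 / s23),
            np.sqrt(s12 * s23 / s13),
            np.sqrt(s13 * s23 / s12),
        ])
        assert np.allclose(lam, expected, atol=1e-8)
        assert res.chi2 == pytest.approx(0.0, abs=1e-8)
        assert res.df == 0

    def test_just_identified_reproduces_sample_cov(self):
        S = _corr3(0.5, 0.4, 0.45)
        X = data_with_exact_cov(S, 250, seed=8)
        res = CFAModel(X, FactorModelSpec.one_factor(list("abc"))).fit(
            estimator="ml")
        Sigma, _ = res.implied_moments()
        assert np.allclose(Sigma, np.cov(X, rowvar=False, ddof=1), atol=1e-10)


class TestFitIndices:
    def test_arithmetic_on_reference_example(self):
        # one-factor phenotypic fit block: chi2(9)=70.37 at n=3002, with an
        # illustrative independence baseline chi2(15)=3000
        idx = fit_indices_from_stats(70.37, 9, 3000.0, 15, 3001)
        assert idx["cfi"] == pytest.approx(1 - 61.37 / 2985, abs=1e-9)
        assert idx["tli"] == pytest.approx(
            ((3000 / 15) - (70.37 / 9)) / ((3000 / 15) - 1), abs=1e-9)
        assert idx["rmsea"] == pytest.approx(
            np.sqrt(61.37 / (9 * 3001)), abs=1e-9)

    def test_noncentrality_floor(self):
        idx = fit_indices_from_stats(5.0, 9, 300.0, 15, 999)
        assert idx["rmsea"] == 0.0
        assert idx["cfi"] == 1.0

    def test_independence_model_as_own_baseline(self):
        idx = fit_indices_from_stats(3000.0, 15, 3000.0, 15, 3001)
        assert idx["cfi"] == 0.0

    def test_df_zero_reported_as_undefined(self):
        idx = fit_indices_from_stats(0.0, 0, 100.0, 3, 500)
        assert idx["tli"] is None and idx["rmsea"] is None
        assert idx["cfi"] == 1.0

    def test_rmsea_ci_against_independent_rootfinder(self):
        # oracle: plain bisection on the noncentral chi-square CDF
        def oracle(chi2, df, n, target):
            def f(nc):
                return stats.ncx2.cdf(chi2, df, nc) - target
            if f(0.0) < 0:
                return 0.0
            lo, hi = 0.0, 1e6
            for _ in range(200):
                mid = (lo + hi) / 2
                if f(mid) > 0:
                    lo = mid
                else:
                    hi = mid
            return np.sqrt((lo + hi) / 2 / (df * n))

        for chi2, df, n in [(70.37, 9, 3001), (46.71, 8, 3001),
                            (15.0, 9, 499), (200.0, 20, 999)]:
            lo, hi = rmsea_ci(chi2, df, n)
            assert lo == pytest.approx(oracle(chi2, df, n, 0.95), abs=1e-6)
            assert hi == pytest.approx(oracle(chi2, df, n, 0.05), abs=1e-6)

    def test_indices_are_pure_functions_of_stored_stats(self):
        rng = np.random.default_rng(4)
        X = one_factor_sample([0.8, 0.7, 0.6, 0.5], 600, rng)
        res = CFAModel(X, FactorModelSpec.one_factor(list("abcd"))).fit()
        idx = fit_indices_from_stats(res.chi2, res.df, res.baseline_chi2,
                                     res.baseline_df, res.n_eff)
        assert idx["cfi"] == res.cfi
        assert idx["tli"] == res.tli
        assert idx["rmsea"] == res.rmsea

    def test_explicit_baseline_wrapper(self):
        from latentpgs import fit_indices
        rng = np.random.default_rng(14)
        X = one_factor_sample([0.8, 0.7, 0.6, 0.5], 500, rng)
        spec = FactorModelSpec.one_factor(list("abcd"))
        fit = CFAModel(X, spec).fit(estimator="ml")
        baseline = CFAModel(X, spec.baseline_spec()).fit(estimator="ml")
        out = fit_indices(fit, baseline)
        assert out["cfi"] == pytest.approx(fit.cfi, abs=1e-9)
        with pytest.raises(ValueError, match="independence"):
            fit_indices(fit, fit)


class _Stub:
    def __init__(self, chi2, df, cfi, rmsea, aic=0.0, n_obs=3002):
        self.chi2, self.df, self.cfi = chi2, df, cfi
        self.rmsea, self.aic, self.n_obs = rmsea, aic, n_obs


class TestModelComparison:
    def test_small_deltas_are_equivalent(self):
        # two-factor CFI 0.988 / RMSEA 0.044 vs one-factor 0.980 / 0.052:
        # drop 0.008 <= 0.01 and rise 0.008 <= 0.015
        free = _Stub(46.71, 8, 0.988, 0.044)
        restricted = _Stub(70.37, 9, 0.980, 0.052)
        v = compare_models(free, restricted)
        assert v.verdict == "equivalent"
        assert v.delta_cfi == pytest.approx(-0.008)
        assert v.delta_rmsea == pytest.approx(0.008)

    def test_identical_fits(self):
        a = _Stub(50.0, 9, 0.98, 0.05)
        v = compare_models(a, _Stub(50.0, 9, 0.98, 0.05))
        assert v.verdict == "equivalent"
        assert v.delta_chi2 == v.delta_cfi == v.delta_rmsea == 0.0

    def test_cfi_threshold_crossing(self):
        v = compare_models(_Stub(40.0, 8, 0.98, 0.05),
                           _Stub(90.0, 9, 0.95, 0.05))
        assert v.verdict == "depreciated"

    def test_non_nested_rejected(self):
        with pytest.raises(ValueError, match="not nested"):
            compare_models(_Stub(40.0, 9, 0.98, 0.05),
                           _Stub(50.0, 8, 0.97, 0.05))


class TestRecoveryAndRobust:
    LAM = np.array([0.88, 0.80, 0.70, 0.60, 0.50, 0.40])

    def test_parameter_recovery_and_ci_coverage(self):
        spec = FactorModelSpec.one_factor(list("abcdef"))
        hits = 0
        total = 0
        rng = np.random.default_rng(11)
        for rep in range(40):
            X = one_factor_sample(self.LAM, 1500, rng)
            res = CFAModel(X, spec).fit()
            est = res.loadings.to_numpy().ravel()
            se = res.params.set_index("param").loc[
                [f"lambda[{i},G]" for i in "abcdef"], "se"].to_numpy()
            hits += int(np.sum(np.abs(est - self.LAM) <= 1.96 * se))
            total += len(self.LAM)
        coverage = hits / total
        assert 0.90 <= coverage <= 0.99

    def test_scaled_chi2_near_unscaled_for_normal_data(self):
        rng = np.random.default_rng(5)
        X = one_factor_sample(self.LAM, 2000, rng)
        res = CFAModel(X, FactorModelSpec.one_factor(list("abcdef"))).fit()
        assert 0.8 <= res.scaling_factor <= 1.25

    def test_constraint_monotonicity(self):
        """Adding cross-group equality constraints never decreases chi2."""
        rng = np.random.default_rng(6)
        X = np.vstack([one_factor_sample(self.LAM, 700, rng),
                       one_factor_sample(self.LAM, 700, rng, shift=0.2)])
        g = np.repeat(["a", "b"], 700)
        spec = FactorModelSpec.one_factor(list("abcdef"), mean_structure=True)
        chi2s = []
        for lvl in ("none", "loadings", "loadings+intercepts",
                    "loadings+intercepts+residuals"):
            fit = CFAModel(X, spec.with_(group_constraints=lvl),
                           groups=g).fit(estimator="ml")
            chi2s.append(fit.chi2)
        assert all(b >= a - 1e-6 for a, b in zip(chi2s, chi2s[1:]))

    def test_rescaling_invariance_of_standardized_solution(self):
        rng = np.random.default_rng(7)
        X = one_factor_sample(self.LAM, 1200, rng)
        spec = FactorModelSpec.one_factor(list("abcdef"))
        a = CFAModel(X, spec).fit(estimator="ml")
        X2 = X * np.array([5.0, 1.0, 0.2, 3.0, 1.0, 10.0])
        b = CFAModel(X2, spec).fit(estimator="ml")
        assert np.allclose(a.std_loadings.to_numpy(),
                           b.std_loadings.to_numpy(), atol=1e-6)
        assert a.chi2 == pytest.approx(b.chi2, abs=1e-6)

    def test_indicator_reordering_invariance(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(one_factor_sample(self.LAM, 1000, rng),
                         columns=list("abcdef"))
        a = CFAModel(X, FactorModelSpec.one_factor(list("abcdef"))).fit(
            estimator="ml")
        b = CFAModel(X, FactorModelSpec.one_factor(list("fedcba"))).fit(
            estimator="ml")
        assert a.chi2 == pytest.approx(b.chi2, abs=1e-6)
        for ind in "abcdef":
            assert a.std_loadings.loc[ind, "G"] == pytest.approx(
                b.std_loadings.loc[ind, "G"], abs=1e-6)

    def test_fiml_handles_missing_data(self):
        rng = np.random.default_rng(9)
        X = one_factor_sample(self.LAM, 1200, rng, missing_rate=0.05)
        res = CFAModel(X, FactorModelSpec.one_factor(list("abcdef"))).fit()
        assert res.converged
        assert np.all(np.abs(res.std_loadings.to_numpy().ravel() - self.LAM) < 0.12)

    def test_heywood_case_flagged_not_fixed(self):
        # a sample covariance implying negative residual variance for 'a'
        S = np.array([[1.0, 0.95, 0.90],
                      [0.95, 1.0, 0.80],
                      [0.90, 0.80, 1.0]])
        X = data_with_exact_cov(S, 300, seed=10)
        res = CFAModel(X, FactorModelSpec.one_factor(list("abc"))).fit(
            estimator="ml")
        assert any(ind == "a" for _, ind in res.heywood)
        assert res.residual_var["a"] < 0


class TestNegativeLoadingScreen:
    def test_drinking_frequency_rule(self):
        rng = np.random.default_rng(12)
        lam = np.array([0.8, 0.7, 0.6, 0.5, -0.4])
        X = pd.DataFrame(one_factor_sample(lam, 2000, rng),
                         columns=["na", "dep", "anx", "imp", "drinkfreq"])
        spec = FactorModelSpec.one_factor(list(X.columns))
        res, dropped = drop_negative_indicators(X, spec, estimator="ml")
        assert dropped == ["drinkfreq"]
        assert "drinkfreq" not in res.spec.indicators
        assert res.negative_loading_indicators() == []


class TestInvariance:
    LAM = np.array([0.85, 0.75, 0.65, 0.55, 0.45])

    def test_identical_groups_attain_residual(self):
        rng = np.random.default_rng(13)
        X = np.vstack([one_factor_sample(self.LAM, 900, rng),
                       one_factor_sample(self.LAM, 900, rng)])
        g = np.repeat(["m", "f"], 900)
        rep = invariance_ladder(X, FactorModelSpec.one_factor(list("abcde")), g)
        assert rep.highest_level_attained == "residual"

    def test_intercept_shift_fails_scalar_passes_metric(self):
        rng = np.random.default_rng(14)
        shift = np.array([0.5, -0.5, 0.5, 0.0, -0.5])  # not loading-collinear
        X = np.vstack([one_factor_sample(self.LAM, 1500, rng),
                       one_factor_sample(self.LAM, 1500, rng) + shift])
        g = np.repeat(["y", "o"], 1500)
        rep = invariance_ladder(X, FactorModelSpec.one_factor(list("abcde")), g)
        assert rep.highest_level_attained == "metric"
        assert rep.comparisons["scalar"].verdict == "depreciated"

    def test_single_group_rejected(self):
        X = np.random.default_rng(0).standard_normal((50, 3))
        with pytest.raises(ValueError, match="2 groups"):
            invariance_ladder(X, FactorModelSpec.one_factor(list("abc")),
                              np.repeat("only", 50))

    def test_age_bands(self):
        labs = age_group_labels([51, 64, 65, 74, 75, 83, 50, 90])
        assert list(labs[:6]) == ["middle", "middle", "young-old",
                                  "young-old", "old-old", "old-old"]
        assert labs[6:].isna().all()


class TestFactorScores:
    def test_deterministic_limit_single_indicator(self):
        rng = np.random.default_rng(15)
        x = rng.standard_normal((200, 1))
        spec = FactorModelSpec.one_factor(["a"],
                                          fixed_params=(("lambda[a,G]", 1.0),
                                                        ("theta[a]", 0.0)))
        res = CFAModel(x, spec).fit(estimator="ml")
        scores = res.factor_scores(x)
        z = (x[:, 0] - x.mean()) / x.std(ddof=1)
        assert np.allclose(scores["G"], z, atol=1e-8)

    def test_mean_row_scores_zero(self):
        rng = np.random.default_rng(16)
        X = one_factor_sample([0.8, 0.7, 0.6], 800, rng)
        res = CFAModel(X, FactorModelSpec.one_factor(list("abc"))).fit(
            estimator="ml")
        row = np.nanmean(X, axis=0)[None, :]
        sc = res.factor_scores(np.vstack([X, row]), standardize=False)
        assert sc["G"].iloc[-1] == pytest.approx(0.0, abs=1e-10)

    def test_score_reliability_matches_theory(self):
        lam = np.array([0.8, 0.75, 0.7, 0.65, 0.6, 0.55])
        rng = np.random.default_rng(17)
        n = 4000
        F = rng.standard_normal(n)
        X = F[:, None] * lam + rng.standard_normal((n, 6)) * np.sqrt(1 - lam ** 2)
        res = CFAModel(X, FactorModelSpec.one_factor(list("abcdef"))).fit(
            estimator="ml")
        sc = res.factor_scores(X)["G"]
        Sigma = lam[:, None] * lam[None, :] + np.diag(1 - lam ** 2)
        rho = np.sqrt(lam @ np.linalg.solve(Sigma, lam))   # score validity
        assert np.corrcoef(sc, F)[0, 1] == pytest.approx(rho, abs=0.03)


class TestSplitHalf:
    def test_odd_sample_split_sizes(self):
        df = pd.DataFrame({"x": np.arange(6003)})
        a, b = split_half(df, seed=1)
        assert (len(a), len(b)) == (3002, 3001)

    @pytest.mark.parametrize("n", [2, 4, 5, 11])
    def test_disjoint_exhaustive(self, n):
        arr = np.arange(n)
        a, b = split_half(arr, seed=7)
        assert sorted(np.concatenate([a, b])) == list(range(n))
        assert set(a).isdisjoint(b)
        assert (len(a), len(b)) == ((n + 1) // 2, n // 2)

    def test_seed_determinism(self):
        arr = np.arange(100)
        assert np.array_equal(split_half(arr, 5)[0], split_half(arr, 5)[0])
        assert not np.array_equal(split_half(arr, 5)[0], split_half(arr, 6)[0])

    def test_too_small(self):
        with pytest.raises(ValueError):
            split_half(np.arange(1), seed=0)
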