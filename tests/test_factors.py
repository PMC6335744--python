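import numpy as np
import pandas as pd
import pytest

from dabold.exceptions import InvalidSpecError
from dabold.factors import (composite_da, factor_scores, fit_hierarchical_cfa,
                            fit_hierarchical_cfa_cov, rmsea_ci)
from dabold.regions import REGIONS, default_structure


def simulate_from_model(n, seed=0, uniqueness=0.25, lam1_val=0.9, lam2_val=0.8):
    """Data from a known hierarchical model; returns (df, free loading truth)."""
    rng = np.random.default_rng(seed)
    structure = default_structure()
    phi = np.array([[1.0, 0.5, 0.45], [0.5, 1.0, 0.7], [0.45, 0.7, 1.0]])
    lam2 = {f: lam2_val for f in structure.first_order_factors}
    lam1 = {ind: lam1_val for ind in structure.indicators}
    eta2 = rng.multivariate_normal(np.zeros(3), phi, size=n)
    cols = {}
    for gi, (g, kids) in enumerate(structure.second_order.items()):
        for f in kids:
            e1 = lam2[f] * eta2[:, gi] + rng.normal(0, np.sqrt(1 - lam2[f] ** 2), n)
            for ind in structure.first_order[f]:
                cols[ind] = lam1[ind] * e1 + rng.normal(0, np.sqrt(uniqueness), n)
    return pd.DataFrame(cols)[list(REGIONS)], lam1, lam2


class TestHierarchicalCfa:
    def test_exact_model_covariance_fits_perfectly(self):
        """Feeding the model-implied covariance itself: chi2=0, CFI=1, RMSEA=0."""
        df, _, _ = simulate_from_model(2000, seed=1)
        m0 = fit_hierarchical_cfa(df, seed=0)
        m = fit_hierarchical_cfa_cov(m0.implied_cov(), n=2000, seed=0)
        assert m.chi2 == pytest.approx(0.0, abs=1e-4)
        assert m.cfi == pytest.approx(1.0, abs=1e-6)
        assert m.rmsea == pytest.approx(0.0, abs=1e-4)

    def test_degrees_of_freedom_census(self):
        """df = p(p+1)/2 - free parameters, counted independently:
        8 free first-order + 5 free second-order loadings, 16 uniquenesses,
        8 disturbances, 6 (co)variances of 3 factors -> 43 free, df = 136 - 43."""
        df, _, _ = simulate_from_model(300, seed=2)
        m = fit_hierarchical_cfa(df, seed=0)
        assert m.n_free == 8 + 5 + 16 + 8 + 6
        assert m.df == 16 * 17 // 2 - m.n_free == 93

    def test_loading_recovery_large_n(self):
        """Free standardized loadings recovered within 2% at n=10^4."""
        df, lam1, lam2 = simulate_from_model(10_000, seed=3, uniqueness=0.1,
                                             lam1_val=0.95, lam2_val=0.85)
        m = fit_hierarchical_cfa(df, seed=0)
        structure = m.structure
        # standardize the fitted solution back: compare loading ratios, which are
        # metric-free: free/fixed indicator loadings of one factor
        for f in structure.first_order_factors:
            fixed, free = structure.first_order[f]
            ratio = m.lambda1.loc[free, f] / m.lambda1.loc[fixed, f]
            truth = lam1[free] / lam1[fixed]
            assert ratio == pytest.approx(truth, rel=0.02)
        for g in structure.second_order_factors:
            kids = structure.second_order[g]
            for free in kids[1:]:
                ratio = m.lambda2.loc[free, g] / m.lambda2.loc[kids[0], g]
                assert ratio == pytest.approx(1.0, rel=0.02)   # equal true loadings

    def test_subject_order_invariance(self):
        df, _, _ = simulate_from_model(400, seed=4)
        m1 = fit_hierarchical_cfa(df, seed=0)
        m2 = fit_hierarchical_cfa(df.sample(frac=1.0, random_state=9), seed=0)
        assert m1.chi2 == pytest.approx(m2.chi2, abs=1e-6)
        assert m1.cfi == pytest.approx(m2.cfi, abs=1e-8)

    def test_fit_index_ranges(self, default_cohort):
        m = fit_hierarchical_cfa(default_cohort.bp_regional, seed=0)
        assert m.chi2 >= 0 and m.rmsea >= 0 and 0 <= m.cfi <= 1
        assert (m.theta >= 0).all() and (m.psi >= 0).all()
        sigma = m.implied_cov().to_numpy()
        assert np.allclose(sigma, sigma.T)
        assert np.linalg.eigvalsh(sigma).min() > -1e-10

    def test_too_small_sample_rejected(self):
        df, _, _ = simulate_from_model(30, seed=5)
        with pytest.raises(InvalidSpecError):
            fit_hierarchical_cfa(df)

    def test_rmsea_ci_brackets_point_estimate(self):
        lo, hi = rmsea_ci(chi2=147.2, df=77, n=176)
        point = np.sqrt((147.2 - 77) / (77 * 175))
        assert lo <= point <= hi


class TestFactorScores:
    def test_mean_subject_scores_zero(self, default_cohort):
        m = fit_hierarchical_cfa(default_cohort.bp_regional, seed=0)
        sc = factor_scores(m, default_cohort.bp_regional)
        assert np.allclose(sc.scores.mean(axis=0), 0.0, atol=1e-10)

    def test_scores_track_generating_factors(self, default_cohort):
        m = fit_hierarchical_cfa(default_cohort.bp_regional, seed=0)
        sc = factor_scores(m, default_cohort.bp_regional)
        truth = default_cohort.truth["factor_scores"]
        for col in sc.scores.columns:
            r = np.corrcoef(sc.scores[col], truth[col])[0, 1]
            assert r > 0.85

    def test_unit_rescaling_leaves_truth_correlation_unchanged(self, default_cohort):
        bp = default_cohort.bp_regional
        m1 = fit_hierarchical_cfa(bp, seed=0)
        s1 = factor_scores(m1, bp)
        m2 = fit_hierarchical_cfa(bp * 2.0, seed=0)
        s2 = factor_scores(m2, bp * 2.0)
        for col in s1.scores.columns:
            r = np.corrcoef(s1.scores[col], s2.scores[col])[0, 1]
            assert abs(r) == pytest.approx(1.0, abs=1e-3)


class TestComposite:
    def test_identical_columns_give_equal_loadings(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=100)
        df = pd.DataFrame({"a": col, "b": col, "c": col})
        out = composite_da(df)
        assert np.allclose(out.composite_loadings, out.composite_loadings.iloc[0])
        r = np.corrcoef(out.composite, df.mean(axis=1))[0, 1]
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_loadings_match_bruteforce_eigendecomposition(self, default_cohort):
        m = fit_hierarchical_cfa(default_cohort.bp_regional, seed=0)
        sc = composite_da(factor_scores(m, default_cohort.bp_regional))
        z = (sc.scores - sc.scores.mean()) / sc.scores.std(ddof=1)
        corr = np.corrcoef(z.to_numpy(), rowvar=False)
        # brute-force leading eigenvector by power iteration
        v = np.ones(3)
        for _ in range(500):
            v = corr @ v
            v /= np.linalg.norm(v)
        lam = float(v @ corr @ v)
        expect = np.abs(v * np.sqrt(lam))
        assert np.allclose(np.abs(sc.composite_loadings), expect, atol=1e-8)

    def test_composite_explains_at_least_third_of_variance(self, default_cohort):
        m = fit_hierarchical_cfa(default_cohort.bp_regional, seed=0)
        sc = composite_da(factor_scores(m, default_cohort.bp_regional))
        assert sc.explained_variance_ratio >= 1 / 3

    def test_default_cohort_loading_ordering(self, default_cohort):
        """Calibrated generator reproduces the limbic > neocortical > striatal
        ordering of composite loadings."""
        m = fit_hierarchical_cfa(default_cohort.bp_regional, seed=0)
        sc = composite_da(factor_scores(m, default_cohort.bp_regional))
        l = sc.composite_loadings
        assert l["limbic"] > l["neocortical"] > l["striatal"]

    def test_zero_variance_column_rejected(self):
        df = pd.DataFrame({"a": np.ones(50), "b": np.arange(50.0), "c": np.arange(50.0)})
        with pytest.raises(InvalidSpecError):
            composite_da(df)
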