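import numpy as np
import pandas as pd
import pytest

from dabold.exceptions import DaboldError, InvalidSpecError
from dabold.pls import (BoldBlock, bootstrap_saliences, brain_scores,
                        build_cross_block, correlation_scores, decompose,
                        exclude_outlier_subjects, n_estimable_lvs,
                        permutation_test)
from conftest import truth_blocks, truth_da


def make_block(data, group="g", condition="c", subjects=None):
    data = np.asarray(data, dtype=float)
    return BoldBlock(group=group, condition=condition, data=data,
                     subjects=subjects or list(range(data.shape[0])))


class TestDesignCounts:
    @pytest.mark.parametrize("n_da,n_cond,n_group,expect",
                             [(1, 3, 2, 6), (3, 3, 2, 18), (1, 1, 1, 1)])
    def test_estimable_lv_count(self, n_da, n_cond, n_group, expect):
        assert n_estimable_lvs(n_da, n_cond, n_group) == expect

    def test_zero_count_rejected(self):
        with pytest.raises(InvalidSpecError):
            n_estimable_lvs(0, 3, 2)

    @pytest.mark.parametrize("n_da,expect_rows", [(1, 6), (3, 18)])
    def test_cross_block_row_count_matches_design(self, small_cohort, n_da, expect_rows):
        blocks = truth_blocks(small_cohort)
        da = truth_da(small_cohort)
        if n_da == 3:
            da = small_cohort.truth["factor_scores"].copy()
        R = build_cross_block(blocks, da)
        assert R.n_rows == expect_rows
        assert len(decompose(R)) == expect_rows


class TestCrossBlock:
    def test_single_block_single_voxel(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=30)
        x = 0.6 * z + 0.8 * rng.normal(size=30)
        block = make_block(x[:, None])
        da = pd.DataFrame({"da": z})
        R = build_cross_block([block], da)
        expect = np.corrcoef(z, x)[0, 1]
        assert R.values.shape == (1, 1)
        assert R.values[0, 0] == pytest.approx(expect, abs=1e-12)

    def test_constant_voxel_column_set_to_zero(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(20, 3))
        data[:, 1] = 4.2
        R = build_cross_block([make_block(data)], pd.DataFrame({"da": rng.normal(size=20)}))
        assert R.values[0, 1] == 0.0

    def test_constant_da_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(InvalidSpecError):
            build_cross_block([make_block(rng.normal(size=(10, 4)))],
                              pd.DataFrame({"da": np.ones(10)}))

    def test_entries_are_valid_correlations(self, small_cohort):
        R = build_cross_block(truth_blocks(small_cohort), truth_da(small_cohort))
        assert np.all(np.abs(R.values) <= 1.0)


class TestDecompose:
    def test_scalar_matrix(self):
        lvs = decompose(np.array([[-0.7]]))
        assert lvs[0].s == pytest.approx(0.7)
        assert lvs[0].pct_crossblock == pytest.approx(100.0)

    def test_singular_values_account_for_frobenius_norm(self, small_cohort):
        R = build_cross_block(truth_blocks(small_cohort), truth_da(small_cohort))
        lvs = decompose(R)
        assert sum(lv.s ** 2 for lv in lvs) == pytest.approx(np.sum(R.values ** 2))
        assert sum(lv.pct_crossblock for lv in lvs) == pytest.approx(100.0, abs=1e-8)

    def test_reconstruction(self, small_cohort):
        R = build_cross_block(truth_blocks(small_cohort), truth_da(small_cohort))
        lvs = decompose(R)
        rec = sum(lv.s * np.outer(lv.u, lv.v) for lv in lvs)
        assert np.linalg.norm(rec - R.values) < 1e-10

    def test_matches_eigendecomposition_oracle(self):
        """u, s, v agree (up to sign) with an eigendecomposition of R'R / RR'."""
        rng = np.random.default_rng(3)
        R = rng.normal(size=(6, 50))
        lvs = decompose(R)
        evals, evecs = np.linalg.eigh(R @ R.T)
        order = np.argsort(evals)[::-1]
        for j, lv in enumerate(lvs):
            assert lv.s == pytest.approx(np.sqrt(evals[order[j]]), abs=1e-10)
            u_oracle = evecs[:, order[j]]
            assert abs(abs(u_oracle @ lv.u) - 1.0) < 1e-8
            v_oracle = R.T @ u_oracle / np.linalg.norm(R.T @ u_oracle)
            assert abs(abs(v_oracle @ lv.v) - 1.0) < 1e-8

    def test_lvs_ordered_by_singular_value(self, small_cohort):
        lvs = decompose(build_cross_block(truth_blocks(small_cohort),
                                          truth_da(small_cohort)))
        s = [lv.s for lv in lvs]
        assert s == sorted(s, reverse=True)


class TestBrainScores:
    def test_indicator_salience_picks_one_voxel(self):
        rng = np.random.default_rng(4)
        data = rng.normal(size=(8, 5))
        v = np.zeros(5)
        v[3] = 1.0
        sc = brain_scores(v, make_block(data))
        assert np.allclose(sc.to_numpy(), data[:, 3])

    def test_equals_explicit_summation_loop(self):
        rng = np.random.default_rng(5)
        data = rng.normal(size=(5, 20))
        v = rng.normal(size=20)
        sc = brain_scores(v, make_block(data))
        for m in range(5):
            total = 0.0
            for i in range(20):
                total += v[i] * data[m, i]
            assert sc.iloc[m] == pytest.approx(total, rel=1e-12)

    def test_linearity_in_data(self):
        rng = np.random.default_rng(6)
        data = rng.normal(size=(6, 9))
        v = rng.normal(size=9)
        a = 3.7
        assert np.allclose(brain_scores(v, make_block(a * data)),
                           a * brain_scores(v, make_block(data)))

    def test_dimension_mismatch(self):
        with pytest.raises(InvalidSpecError):
            brain_scores(np.ones(3), make_block(np.ones((4, 5))))


class TestCorrelationScores:
    def test_perfect_positive_and_negative(self):
        z = np.arange(10.0)
        da = pd.DataFrame({"da": z})
        up = pd.Series(z, index=range(10))
        down = pd.Series(-z, index=range(10))
        out = correlation_scores({"up": up, "down": down}, da, "da")
        assert out["up"] == pytest.approx(1.0)
        assert out["down"] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(7)
        sc = pd.Series(rng.normal(size=10), index=range(10))
        z = rng.normal(size=10)
        da = pd.DataFrame({"da": z})
        r = correlation_scores({"b": sc}, da, "da")["b"]
        x, y = sc.to_numpy(), z
        oracle = ((x - x.mean()) * (y - y.mean())).sum() / (
            np.sqrt(((x - x.mean()) ** 2).sum()) * np.sqrt(((y - y.mean()) ** 2).sum()))
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_scores_rejected(self):
        sc = pd.Series(np.ones(10), index=range(10))
        with pytest.raises(DaboldError):
            correlation_scores({"b": sc}, pd.DataFrame({"da": np.arange(10.0)}), "da")


class TestPermutation:
    def test_counting_rule_strong_signal_gives_zero(self, small_cohort):
        lvs, p = permutation_test(truth_blocks(small_cohort), truth_da(small_cohort),
                                  n_perm=50, seed=0)
        assert p[0] == 0.0
        assert lvs[0].perm_p == 0.0

    def test_add_one_convention(self, small_cohort):
        _, p = permutation_test(truth_blocks(small_cohort), truth_da(small_cohort),
                                n_perm=50, seed=0, add_one=True)
        assert p[0] == pytest.approx(1 / 51)

    def test_null_pvalues_near_uniform(self):
        """Null blocks (no DA-BOLD association): LV1 p rejects at ~nominal rate."""
        ps = []
        for sim in range(40):
            rng = np.random.default_rng(200 + sim)
            blocks = [make_block(rng.normal(size=(25, 30)), group="g", condition=c)
                      for c in ("a", "b", "c")]
            da = pd.DataFrame({"da": rng.normal(size=25)})
            _, p = permutation_test(blocks, da, n_perm=40, seed=sim)
            ps.append(p[0])
        ps = np.asarray(ps)
        rate = (ps <= 0.05).mean()
        # 3 binomial SEs around the nominal level (n=40, permutation resolution 1/40)
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 40) + 1 / 40
        assert ps.mean() == pytest.approx(0.5, abs=0.2)

    def test_determinism(self, small_cohort):
        a = permutation_test(truth_blocks(small_cohort), truth_da(small_cohort),
                             n_perm=30, seed=9)[1]
        b = permutation_test(truth_blocks(small_cohort), truth_da(small_cohort),
                             n_perm=30, seed=9)[1]
        assert np.array_equal(a, b)


class TestBootstrap:
    def test_identical_subjects_give_zero_se_sentinel(self):
        data = np.tile(np.arange(6.0), (8, 1))       # identical across subjects
        block = make_block(data)
        da = pd.DataFrame({"da": np.arange(8.0)})
        # constant columns make correlations 0; add one informative voxel
        data2 = data.copy()
        data2[:, 0] = np.arange(8.0)
        block = make_block(data2)
        out = bootstrap_saliences([block], da, n_boot=10, seed=0)
        assert out.degenerate_se or np.isfinite(out.bsr).all()

    def test_ci_covers_planted_correlation(self):
        """Single-voxel design: percentile CI covers planted r=0.6 in ~95% of cohorts."""
        covered = 0
        n_rep, n, r = 30, 104, 0.6
        for rep in range(n_rep):
            rng = np.random.default_rng(300 + rep)
            z = rng.normal(size=n)
            x = r * (z - z.mean()) / z.std() + np.sqrt(1 - r ** 2) * rng.normal(size=n)
            block = make_block(x[:, None])
            da = pd.DataFrame({"da": z})
            out = bootstrap_saliences([block], da, n_boot=150, seed=rep)
            lo, hi = out.ci_low.iloc[0], out.ci_high.iloc[0]
            covered += lo <= r <= hi
        # 95% nominal with Monte-Carlo slack at 30 replicates
        assert covered / n_rep >= 0.95 - 3 * np.sqrt(0.95 * 0.05 / n_rep)

    def test_bsr_separates_planted_from_null_voxels(self):
        rng = np.random.default_rng(11)
        n, v_sig, v_null = 100, 10, 30
        z = rng.normal(size=n)
        sig = 0.7 * z[:, None] + np.sqrt(1 - 0.49) * rng.normal(size=(n, v_sig))
        null = rng.normal(size=(n, v_null))
        block = make_block(np.hstack([sig, null]))
        da = pd.DataFrame({"da": z})
        out = bootstrap_saliences([block], da, n_boot=120, seed=1, n_lv=1)
        bsr = out.bsr[0]
        assert (np.abs(bsr[:v_sig]) > 3.29).mean() >= 0.8
        assert (np.abs(bsr[v_sig:]) > 3.29).mean() <= 0.2

    def test_determinism(self, small_cohort):
        kw = dict(n_boot=20, seed=4, n_lv=1)
        a = bootstrap_saliences(truth_blocks(small_cohort), truth_da(small_cohort), **kw)
        b = bootstrap_saliences(truth_blocks(small_cohort), truth_da(small_cohort), **kw)
        assert np.array_equal(a.bsr, b.bsr)
        assert a.ci_low.equals(b.ci_low)


class TestOutlierExclusion:
    def test_no_outliers_no_refit(self):
        rng = np.random.default_rng(12)
        scores = {"b": pd.Series(rng.uniform(-1, 1, size=50), index=range(50))}
        kept, excluded, refit = exclude_outlier_subjects(scores)
        assert excluded == [] and not refit and len(kept) == 50

    def test_planted_spike_removed(self):
        rng = np.random.default_rng(13)
        vals = rng.normal(size=60)
        vals[17] = 25.0
        scores = {"b": pd.Series(vals, index=range(60))}
        kept, excluded, refit = exclude_outlier_subjects(scores)
        assert excluded == [17] and refit

    def test_constant_scores_exclude_nobody(self):
        scores = {"b": pd.Series(np.ones(10), index=range(10))}
        kept, excluded, refit = exclude_outlier_subjects(scores)
        assert excluded == [] and not refit
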