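import numpy as np
import pytest

import dabold
from dabold.exceptions import InvalidSpecError
from dabold.synth import (CONDITIONS, GROUPS, CohortConfig, _signal_mask,
                          generate_cohort, write_cohort)


class TestConfigValidation:
    def test_empty_cohort_rejected(self):
        with pytest.raises(InvalidSpecError):
            CohortConfig(n_subjects=0)

    def test_proportions_must_sum_to_one(self):
        with pytest.raises(InvalidSpecError):
            CohortConfig(class_proportions=(0.6, 0.6))

    def test_planted_r_bounds(self):
        with pytest.raises(InvalidSpecError):
            CohortConfig(planted_r={(g, c): 1.0 for g in GROUPS for c in CONDITIONS})

    def test_negative_tac_noise_rejected(self):
        with pytest.raises(InvalidSpecError):
            CohortConfig(tac_noise_sd=-1.0)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = CohortConfig(seed=21, grid_shape=(5, 5, 5))
        a = generate_cohort(cfg)
        b = generate_cohort(CohortConfig(seed=21, grid_shape=(5, 5, 5)))
        assert a.accuracy.equals(b.accuracy)
        assert a.bp_regional.equals(b.bp_regional)
        for c in CONDITIONS:
            assert np.array_equal(a.bold[c], b.bold[c])
        assert np.array_equal(a.tacs["putamen"], b.tacs["putamen"])

    def test_different_seed_differs(self):
        a = generate_cohort(CohortConfig(seed=1, grid_shape=(5, 5, 5)))
        b = generate_cohort(CohortConfig(seed=2, grid_shape=(5, 5, 5)))
        assert not a.accuracy.equals(b.accuracy)


class TestAccuracyMarginals:
    def test_interior_means_and_sds_match_config(self):
        """With means far from the truncation bounds, sample moments match."""
        cfg = CohortConfig(
            n_subjects=4000, seed=3, grid_shape=(2, 2, 2),
            class_proportions=(1.0,), class_means=((50.0, 45.0, 40.0),),
            class_sds=((6.0, 6.0, 6.0),),
            planted_r={(g, c): 0.0 for g in GROUPS for c in CONDITIONS},
        )
        coh = generate_cohort(cfg)
        x = coh.accuracy.to_numpy(dtype=float)
        assert np.allclose(x.mean(axis=0), [50, 45, 40], atol=3 * 6 / np.sqrt(4000) + 0.5)
        assert np.allclose(x.std(axis=0), 6.0, atol=0.4)

    def test_values_within_score_range(self, default_cohort):
        x = default_cohort.accuracy.to_numpy()
        assert x.min() >= 0 and x.max() <= 90
        assert np.issubdtype(x.dtype, np.integer)

    def test_class_shares_within_binomial_error(self):
        """n=168 at 0.67/0.33: empirical shares stay within 3 binomial SEs."""
        shares = []
        for seed in range(20):
            coh = generate_cohort(CohortConfig(seed=seed, grid_shape=(2, 2, 2)))
            shares.append(np.mean(np.array(coh.truth["group"]) == "normal"))
        p = 113 / 168
        se = np.sqrt(p * (1 - p) / 168)
        assert np.mean(shares) == pytest.approx(p, abs=3 * se / np.sqrt(20))


class TestPlantedCorrelations:
    def test_null_cohort_mean_voxel_correlation_near_zero(self):
        """planted_r = 0 everywhere: mean DA-BOLD correlation ~ 3/sqrt(n) of 0."""
        rs = []
        for seed in range(10):
            cfg = CohortConfig(seed=seed, grid_shape=(4, 4, 4),
                               planted_r={(g, c): 0.0 for g in GROUPS for c in CONDITIONS})
            coh = generate_cohort(cfg)
            z = coh.truth["composite"]
            groups = np.asarray(coh.truth["group"])
            for g in GROUPS:
                rows = np.flatnonzero(groups == g)
                for c in CONDITIONS:
                    x = coh.bold[c][rows]
                    zc = z[rows] - z[rows].mean()
                    r = (zc @ (x - x.mean(0))) / (
                        len(rows) * zc.std() * x.std(0))
                    rs.append(r.mean())
        n_eff = 55
        assert abs(np.mean(rs)) < 3 / np.sqrt(n_eff * len(rs))

    def test_planted_r_recovered_within_sampling_error(self):
        """Mean signal-voxel sample r per block tracks planted_r across seeds."""
        acc = {}
        n_seeds = 25
        for seed in range(n_seeds):
            coh = generate_cohort(CohortConfig(seed=seed, grid_shape=(6, 6, 6),
                                               signal_radius_vox=2.0))
            mask = coh.truth["signal_mask"]
            z = coh.truth["composite"]
            groups = np.asarray(coh.truth["group"])
            for (g, c), r_target in coh.truth["planted_r"].items():
                rows = np.flatnonzero(groups == g)
                x = coh.bold[c][np.ix_(rows, np.flatnonzero(mask))]
                zz = (z[rows] - z[rows].mean()) / z[rows].std()
                r = (zz @ (x - x.mean(0))) / (len(rows) * x.std(0))
                acc.setdefault((g, c), []).append(r.mean())
        for (g, c), vals in acc.items():
            r_target = coh.truth["planted_r"][(g, c)]
            # 3 empirical SEs of the across-seed mean
            se_mean = np.std(vals, ddof=1) / np.sqrt(n_seeds)
            assert np.mean(vals) == pytest.approx(r_target, abs=max(3 * se_mean, 0.01))

    def test_strong_single_block_r(self):
        """planted r=0.5 in one block, n~104: sample r within 2(1-r^2)/sqrt(n)."""
        planted = {(g, c): 0.0 for g in GROUPS for c in CONDITIONS}
        planted[("normal", "back2")] = 0.5
        coh = generate_cohort(CohortConfig(seed=9, grid_shape=(6, 6, 6),
                                           signal_radius_vox=2.0, planted_r=planted))
        mask = coh.truth["signal_mask"]
        groups = np.asarray(coh.truth["group"])
        rows = np.flatnonzero(groups == "normal")
        z = coh.truth["composite"][rows]
        x = coh.bold["back2"][np.ix_(rows, np.flatnonzero(mask))]
        zz = (z - z.mean()) / z.std()
        r = ((zz @ (x - x.mean(0))) / (len(rows) * x.std(0))).mean()
        assert r == pytest.approx(0.5, abs=2 * (1 - 0.25) / np.sqrt(len(rows)))


class TestStructure:
    def test_signal_blob_is_contiguous_and_sized(self):
        cfg = CohortConfig(seed=0)
        mask = _signal_mask(cfg).reshape(cfg.grid_shape)
        from scipy import ndimage

        labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3)))
        assert n == 1
        assert mask.sum() >= 50    # large enough to survive the cluster extent rule

    def test_components_share_subject_index(self, default_cohort):
        assert list(default_cohort.accuracy.index) == list(default_cohort.bp_regional.index)
        n = len(default_cohort.accuracy)
        for c in CONDITIONS:
            assert default_cohort.bold[c].shape[0] == n
        assert len(default_cohort.truth["group"]) == n
        assert len(default_cohort.truth["composite"]) == n

    def test_bp_table_covers_region_vocabulary(self, default_cohort):
        assert list(default_cohort.bp_regional.columns) == list(dabold.REGIONS)
        assert np.isfinite(default_cohort.bp_regional.to_numpy()).all()


def test_write_and_reload_roundtrip(tmp_path):
    cfg = CohortConfig(seed=17, grid_shape=(5, 5, 5), signal_radius_vox=1.6)
    coh = generate_cohort(cfg)
    write_cohort(coh, tmp_path)
    loaded = dabold.load_cohort(tmp_path)
    assert loaded.accuracy.reset_index(drop=True).equals(
        coh.accuracy.reset_index(drop=True))
    assert np.allclose(loaded.bp_regional.to_numpy(), coh.bp_regional.to_numpy())
    for c in CONDITIONS:
        assert np.allclose(loaded.bold[c], coh.bold[c], atol=1e-6)   # float32 volumes
    assert loaded.truth["group"] == coh.truth["group"]
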