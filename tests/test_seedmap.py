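"""Seed-to-voxel mapping and the r -> z -> t -> binary thresholding chain."""

import numpy as np
import pytest
from scipy import stats

from dbsnet import (NetworkSpec, PhantomSpec, RegionSpec, SeedMask, StatMap,
                    SubjectScan, bonferroni_t_threshold,
                    extract_seed_timecourse, fisher_z, group_tmap,
                    seed_to_voxel_rmap, simulate_bold, threshold_binarize)
from dbsnet.seedmap import GridMismatchError

AFFINE = np.diag([3.0, 3.0, 3.0, 1.0])


def make_scan(data):
    return SubjectScan(data=np.asarray(data, float), affine=AFFINE)


def make_mask(shape, voxels):
    m = np.zeros(shape, dtype=bool)
    for v in voxels:
        m[v] = True
    return m


class TestExtractSeedTimecourse:
    def test_single_voxel_identity(self, rng):
        data = rng.standard_normal((4, 4, 4, 16))
        scan = make_scan(data)
        seed = SeedMask("s", make_mask((4, 4, 4), [(1, 2, 3)]), AFFINE)
        assert np.array_equal(extract_seed_timecourse(scan, seed),
                              data[1, 2, 3])

    def test_antiphase_voxels_cancel(self, rng):
        data = np.zeros((4, 4, 4, 16))
        s = rng.standard_normal(16)
        data[0, 0, 0], data[0, 0, 1] = s, -s
        scan = make_scan(data)
        seed = SeedMask("s", make_mask((4, 4, 4), [(0, 0, 0), (0, 0, 1)]), AFFINE)
        assert np.allclose(extract_seed_timecourse(scan, seed), 0.0)

    def test_noise_averaging_shrinks_variance(self):
        """Mean of m independent noise voxels has variance ~ sigma^2 / m."""
        rng = np.random.default_rng(0)
        m, sigma, reps = 16, 2.0, 400
        variances = []
        for _ in range(reps):
            data = sigma * rng.standard_normal((m, 1, 1, 32))
            scan = make_scan(data)
            seed = SeedMask("s", np.ones((m, 1, 1), bool), AFFINE)
            variances.append(extract_seed_timecourse(scan, seed).var(ddof=1))
        assert np.isclose(np.mean(variances), sigma**2 / m, rtol=0.1)

    def test_grid_mismatch_rejected(self, rng):
        scan = make_scan(rng.standard_normal((4, 4, 4, 16)))
        seed = SeedMask("s", np.ones((5, 5, 5), bool), AFFINE)
        with pytest.raises(GridMismatchError):
            extract_seed_timecourse(scan, seed)


class TestSeedToVoxelRmap:
    def test_identical_and_negated_series(self, rng):
        tc = rng.standard_normal(16)
        data = np.zeros((2, 1, 1, 16))
        data[0, 0, 0], data[1, 0, 0] = tc, -tc
        rmap = seed_to_voxel_rmap(make_scan(data), tc)
        assert np.isclose(rmap.data[0, 0, 0], 1.0)
        assert np.isclose(rmap.data[1, 0, 0], -1.0)

    def test_zero_variance_voxel_flagged_as_zero(self, rng):
        data = rng.standard_normal((2, 1, 1, 16))
        data[1, 0, 0] = 5.0
        rmap = seed_to_voxel_rmap(make_scan(data), data[0, 0, 0])
        assert rmap.data[1, 0, 0] == 0.0
        assert rmap.qc["zero_variance_voxels"] == 1
        assert np.all(np.isfinite(rmap.data))

    def test_planted_loading_gives_closed_form_r(self):
        """a = 1, sd_s = sd = 1 -> population r = 1/sqrt(2) ~ 0.707."""
        spec = PhantomSpec(
            grid_shape=(3, 3, 3), n_subjects=100, n_timepoints=124,
            regions=[RegionSpec("v", [(1, 1, 1)], {"n": 1.0})],
            networks=[NetworkSpec("n")], rng_seed=5,
        )
        scans, latents = simulate_bold(spec, return_latents=True)
        rs = [seed_to_voxel_rmap(scan, lat["n"]).data[1, 1, 1]
              for scan, lat in zip(scans, latents)]
        assert abs(np.mean(rs) - 1 / np.sqrt(2)) < 0.03


class TestFisherZ:
    def test_values_and_antisymmetry(self):
        r = np.array([[[0.0, 0.5, -0.5, 0.9]]])
        z = fisher_z(StatMap("r", r, AFFINE))
        assert np.isclose(z.data[0, 0, 0], 0.0)
        assert np.isclose(z.data[0, 0, 1], 0.5493, atol=1e-4)
        assert np.isclose(z.data[0, 0, 1], -z.data[0, 0, 2])

    def test_perfect_correlation_clamped(self):
        z = fisher_z(StatMap("r", np.array([[[1.0, -1.0]]]), AFFINE))
        assert np.all(np.isfinite(z.data))
        assert z.qc["clamped_voxels"] == 2


class TestGroupTmap:
    def zmaps(self, values):
        return [StatMap("z", np.full((1, 1, 1), v), AFFINE) for v in values]

    def test_all_zero_and_symmetric_pairs(self):
        assert group_tmap(self.zmaps([0.0, 0.0, 0.0])).data[0, 0, 0] == 0.0
        assert group_tmap(self.zmaps([1.0, -1.0])).data[0, 0, 0] == 0.0

    def test_df_recorded(self):
        assert group_tmap(self.zmaps([0.1, 0.2, 0.3])).df == 2

    def test_large_sample_matches_analytic_t(self):
        """n = 1000 draws from N(0.3, 0.1^2) -> t ~ 0.3/(0.1/sqrt(1000)) ~ 94.9."""
        rng = np.random.default_rng(2)
        zs = self.zmaps(0.3 + 0.1 * rng.standard_normal(1000))
        t = group_tmap(zs).data[0, 0, 0]
        assert np.isclose(t, 94.9, rtol=0.07)

    def test_zero_variance_sentinels(self):
        t = group_tmap(self.zmaps([0.5, 0.5]))
        assert np.isposinf(t.data[0, 0, 0])
        assert t.qc["zero_variance_voxels"] == 1


class TestBonferroniThreshold:
    def test_single_test_is_plain_quantile(self):
        assert np.isclose(bonferroni_t_threshold(0.05, 1, 999),
                          stats.t.isf(0.025, 999), atol=1e-9)
        assert np.isclose(bonferroni_t_threshold(0.05, 1, 999), 1.962, atol=1e-3)

    def test_whole_brain_cutoff_near_published_value(self):
        """67 000 voxel tests at df = 999 give a cutoff consistent with 5.1."""
        t_star = bonferroni_t_threshold(0.05, 67_000, 999)
        assert 4.9 <= t_star <= 5.2

    def test_alpha_to_one_limit(self):
        assert bonferroni_t_threshold(0.999999, 1, 50) < 1e-4

    def test_more_tests_raise_cutoff(self):
        ts = [bonferroni_t_threshold(0.05, n, 99) for n in (1, 10, 1000, 67000)]
        assert np.all(np.diff(ts) > 0)


class TestThresholdBinarize:
    def test_toy_count_and_monotonicity(self, rng):
        data = np.zeros((3, 3, 3))
        data.flat[[0, 5, 9, 13]] = [5.2, -6.0, 7.7, 5.1]
        data.flat[[1, 2]] = [4.9, -5.0]
        tmap = StatMap("t", data, AFFINE, df=99)
        b = threshold_binarize(tmap, 5.1)
        assert b.qc["suprathreshold_voxels"] == 4
        assert set(np.unique(b.data)) <= {0.0, 1.0}
        counts = [threshold_binarize(tmap, c).qc["suprathreshold_voxels"]
                  for c in np.linspace(0.5, 9.0, 20)]
        assert np.all(np.diff(counts) <= 0)

    def test_chain_preserves_grid_and_affine(self, rng):
        data = rng.standard_normal((4, 5, 6, 20))
        scan = make_scan(data)
        tc = data[0, 0, 0]
        rmap = seed_to_voxel_rmap(scan, tc)
        zmap = fisher_z(rmap)
        for m in (rmap, zmap):
            assert m.grid_shape == (4, 5, 6)
            assert np.array_equal(m.affine, AFFINE)
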