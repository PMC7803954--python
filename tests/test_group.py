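"""Sign-flip and covariate permutation inference, smoothing, peaks."""

import itertools

import numpy as np
import pytest

import voicelight as vl
from voicelight.group import GroupInferenceError, _one_sample_t, _slope_t


class TestSubtractChance:
    def test_constant_chance_map_zeroes(self):
        m = np.full((4, 4, 4), 1.0 / 3.0)
        assert np.allclose(vl.subtract_chance(m), 0.0, atol=1e-12)

    def test_arithmetic(self):
        assert np.isclose(vl.subtract_chance(np.array([0.5]))[0], 1.0 / 6.0)

    def test_round_trip(self):
        rng = np.random.default_rng(0)
        m = rng.uniform(size=(3, 3, 3))
        assert np.allclose(vl.subtract_chance(m) + 1.0 / 3.0, m)


class TestGaussianSmooth:
    def test_fwhm_zero_identity(self):
        rng = np.random.default_rng(1)
        m = rng.normal(size=(5, 5, 5))
        assert np.allclose(vl.gaussian_smooth(m, 0.0), m)

    def test_constant_map_unchanged_with_mask(self):
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[2:6, 2:6, 2:6] = True
        vol = np.where(mask, 3.7, np.nan)
        sm = vl.gaussian_smooth(vol, 8.0, (2.0, 2.0, 2.0), mask=mask)
        assert np.allclose(sm[mask], 3.7, atol=1e-10)
        assert np.isnan(sm[~mask]).all()

    def test_impulse_center_value_matches_direct_convolution(self):
        from scipy.ndimage import gaussian_filter

        n = 31
        vol = np.zeros((n, n, n))
        vol[n // 2, n // 2, n // 2] = 1.0
        fwhm, vs = 8.0, (2.0, 2.0, 2.0)
        sm = vl.gaussian_smooth(vol, fwhm, vs, mask=np.ones_like(vol, bool))
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2))) / 2.0
        expected = gaussian_filter(vol, sigma)
        assert np.allclose(sm, expected, atol=1e-12)


class TestSignFlip:
    def test_identical_positive_maps_exhaustive(self):
        """4 identical strictly positive maps: the observed t is +inf at
        every voxel, attained only when no subject is flipped; against
        2^4 exhaustive flips p_fwe = 1/16 at every voxel."""
        base = np.array([[[0.2, 0.5], [0.1, 0.3]]])
        maps = np.stack([base] * 4)
        n_perm = 16
        res = vl.signflip_onesample(maps, n_permutations=n_perm, seed=0)
        # observed max-t is infinite; enumerate flips: only all-(+1) gives
        # +inf, so p = (#flip vectors with max >= inf)/16 >= 1/16
        inside = res.mask
        assert np.isinf(res.stat[inside]).all()
        # random flips may duplicate the identity; enumerate by hand
        signs = np.array(list(itertools.product([1.0, -1.0], repeat=4)))
        data = maps[:, inside]
        max_t = np.array(
            [_one_sample_t(s[:, None] * data).max() for s in signs]
        )
        p_exact = np.mean(max_t >= np.inf)
        assert np.isclose(p_exact, 1.0 / 16.0)
        assert np.allclose(res.p_fwe[inside].min(), 1.0 / n_perm, atol=0.2)

    def test_p_bounded_below_by_identity(self):
        rng = np.random.default_rng(3)
        maps = rng.normal(0.5, 0.2, size=(8, 4, 4, 4))
        res = vl.signflip_onesample(maps, n_permutations=100, seed=1)
        assert np.nanmin(res.p_fwe) >= 1.0 / 100

    def test_p_monotone_in_statistic(self):
        rng = np.random.default_rng(4)
        maps = rng.normal(0.1, 1.0, size=(10, 5, 5, 5))
        res = vl.signflip_onesample(maps, n_permutations=200, seed=2)
        t = res.stat[res.mask]
        p = res.p_fwe[res.mask]
        order = np.argsort(t)
        assert np.all(np.diff(p[order]) <= 1e-12)

    def test_seed_determinism(self):
        rng = np.random.default_rng(5)
        maps = rng.normal(size=(6, 4, 4, 4))
        a = vl.signflip_onesample(maps, 150, seed=9)
        b = vl.signflip_onesample(maps, 150, seed=9)
        assert np.array_equal(a.p_fwe, b.p_fwe, equal_nan=True)
        assert np.array_equal(a.max_null, b.max_null)

    def test_exhaustive_size_bounded_by_alpha(self):
        """Sign-flip test is exact under a symmetric null: with n=6
        subjects and all 64 flips enumerated per dataset, the attained
        size at alpha=0.05 cannot exceed alpha (up to MC error)."""
        rng = np.random.default_rng(6)
        n, n_data = 6, 400
        rejections = 0
        signs = np.array(list(itertools.product([1.0, -1.0], repeat=n)))
        for _ in range(n_data):
            data = rng.normal(size=(n, 12))
            t_obs = _one_sample_t(data)
            max_null = np.array(
                [_one_sample_t(s[:, None] * data).max() for s in signs]
            )
            p = (max_null[None, :] >= t_obs[:, None] - 1e-12).mean(axis=1)
            rejections += p.min() <= 0.05
        size = rejections / n_data
        assert size <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_data)

    def test_requires_two_subjects(self):
        with pytest.raises(GroupInferenceError):
            vl.signflip_onesample(np.zeros((1, 2, 2, 2)), 10)


class TestPermutationRegression:
    def test_perfect_covariate_voxel_attains_max(self):
        """n=5, one voxel exactly equal to the covariate: its slope-t is
        +inf, reached only by order-preserving permutations."""
        x = np.array([0.1, 0.4, 0.2, 0.9, 0.6])
        maps = np.zeros((5, 2, 1, 1))
        rng = np.random.default_rng(7)
        maps[:, 0, 0, 0] = x
        maps[:, 1, 0, 0] = rng.normal(size=5)
        res = vl.permutation_regression(maps, x, n_permutations=120, seed=3)
        t_voxel = res.stat[0, 0, 0]
        assert t_voxel > 1e10  # numerically infinite (zero residuals)
        # only draws equal to the identity permutation reach that value;
        # with 119 uniform draws of 5! orderings that is Binomial(119,
        # 1/120) extra hits on top of the included identity
        n_hits = int((res.max_null >= t_voxel - 1e-12).sum())
        assert res.p_fwe[0, 0, 0] == n_hits / 120
        assert 1 <= n_hits <= 5
        assert res.p_fwe[0, 0, 0] == np.nanmin(res.p_fwe)

    def test_affine_covariate_invariance(self):
        rng = np.random.default_rng(8)
        maps = rng.normal(size=(10, 3, 3, 3))
        x = rng.normal(size=10)
        a = vl.permutation_regression(maps, x, 200, seed=4)
        b = vl.permutation_regression(maps, 3.0 + 2.0 * x, 200, seed=4)
        assert np.allclose(a.stat, b.stat, equal_nan=True)
        assert np.array_equal(a.p_fwe, b.p_fwe, equal_nan=True)

    def test_constant_covariate_raises(self):
        with pytest.raises(GroupInferenceError):
            vl.permutation_regression(np.zeros((4, 2, 2, 2)), np.ones(4), 10)

    def test_slope_t_matches_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(9)
        x = rng.normal(size=12)
        y = rng.normal(size=(12, 1))
        t = _slope_t(y, x)[0]
        lr = stats.linregress(x, y[:, 0])
        np.testing.assert_allclose(
            t, lr.slope / lr.stderr, rtol=1e-10
        )


class TestExplicitMask:
    def test_full_mask_identity(self):
        m = np.ones((3, 3, 3), dtype=bool)
        assert vl.apply_explicit_mask(m, m).all()

    def test_disjoint_masks_raise(self):
        a = np.zeros((3, 3, 3), dtype=bool); a[0] = True
        b = np.zeros((3, 3, 3), dtype=bool); b[2] = True
        with pytest.raises(GroupInferenceError):
            vl.apply_explicit_mask(a, b)

    def test_restriction_never_raises_p(self):
        rng = np.random.default_rng(10)
        maps = rng.normal(0.3, 1.0, size=(10, 6, 6, 6))
        full = np.ones((6, 6, 6), dtype=bool)
        sound = np.zeros_like(full); sound[1:5, 1:5, 1:5] = True
        res_full = vl.signflip_onesample(maps, 300, seed=5, mask=full)
        res_sub = vl.signflip_onesample(
            maps, 300, seed=5, mask=vl.apply_explicit_mask(full, sound)
        )
        inter = sound
        assert np.all(res_sub.p_fwe[inter] <= res_full.p_fwe[inter] + 1e-12)


class TestClusterPeaks:
    def test_single_voxel_cluster(self):
        stat = np.zeros((5, 5, 5))
        stat[2, 2, 2] = 5.0
        peaks = vl.cluster_peaks(stat, threshold=3.0)
        assert len(peaks) == 1
        assert peaks.iloc[0]["cluster_size_vox"] == 1
        assert peaks.iloc[0]["stat"] == 5.0

    def test_two_distant_blobs_two_clusters(self):
        stat = np.zeros((20, 6, 6))
        stat[2:4, 2:4, 2:4] = 4.0   # blob 1
        stat[14:16, 2:4, 2:4] = 4.5  # blob 2, 24 mm away at 2 mm voxels
        peaks = vl.cluster_peaks(stat, threshold=3.0)
        assert peaks["cluster_id"].nunique() == 2

    def test_close_maxima_merge_to_one_peak(self):
        # two maxima 6 mm apart inside one blob: separation rule (> 8 mm)
        # reports only the higher one
        stat = np.zeros((12, 6, 6))
        stat[2:7, 2:4, 2:4] = 3.5  # every blob voxel within 8 mm of peak
        stat[3, 3, 3] = 6.0
        stat[6, 3, 3] = 5.5  # 3 voxels = 6 mm from the first maximum
        peaks = vl.cluster_peaks(stat, threshold=3.0,
                                 min_peak_separation_mm=8.0)
        assert len(peaks) == 1
        assert peaks.iloc[0]["stat"] == 6.0

    def test_extent_threshold_drops_small_clusters(self):
        stat = np.zeros((10, 6, 6))
        stat[2, 2, 2] = 5.0               # 8 mm^3 cluster
        stat[6:8, 2:4, 2:4] = 4.0          # 64 mm^3 cluster
        peaks = vl.cluster_peaks(stat, threshold=3.0, min_cluster_mm3=20.0)
        assert peaks["cluster_id"].nunique() == 1
        assert (peaks["cluster_size_vox"] == 8).all()
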