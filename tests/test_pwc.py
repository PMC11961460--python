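"""PWC curve construction, candidate thresholds, feature scoring, segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pkdvol.phantom import PhantomSpec, generate_phantom
from pkdvol.pwc import (
    GrayHistogram,
    ObjectFeatures,
    apply_threshold,
    build_histogram,
    compute_pwc,
    compute_tcv,
    find_candidate_thresholds,
    object_features,
    score_thresholds,
    segment_cysts,
)
from pkdvol.volume import IntensityVolume


def vol_of(arr, spacing=(1.0, 1.0, 1.0)):
    return IntensityVolume(grid=np.asarray(arr), spacing=spacing)


def hist_of(counts, levels):
    counts = np.asarray(counts)
    levels = np.asarray(levels, dtype=float)
    edges = np.concatenate([levels - 0.5, [levels[-1] + 0.5]])
    return GrayHistogram(counts, levels, edges)


class TestBuildHistogram:
    def test_counts_conserve_masked_voxels(self):
        rng = np.random.default_rng(0)
        grid = rng.integers(0, 200, size=(10, 10, 10))
        mask = np.zeros_like(grid, dtype=bool)
        mask.ravel()[:500] = True
        h = build_histogram(vol_of(grid), mask, 64)
        assert h.n_voxels == 500

    def test_constant_image_single_bin_flagged(self):
        grid = np.full((6, 6, 6), 42)
        h = build_histogram(vol_of(grid), np.ones_like(grid), 256)
        assert h.constant_image
        assert (h.counts > 0).sum() == 1
        assert h.counts.sum() == 216

    def test_two_value_image_two_bins(self):
        grid = np.full((10, 10, 10), 10)
        grid.ravel()[:50] = 200
        mask = np.zeros_like(grid, dtype=bool)
        mask.ravel()[:150] = True  # 50 voxels at 200, 100 at 10
        h = build_histogram(vol_of(grid), mask, 256)
        nz = h.counts[h.counts > 0]
        assert list(nz) == [100, 50]

    def test_empty_mask_rejected(self):
        grid = np.ones((4, 4, 4))
        with pytest.raises(ValueError, match="empty"):
            build_histogram(vol_of(grid), np.zeros_like(grid), 16)


class TestComputePWC:
    def test_delta_histogram_is_constant_at_level(self):
        h = hist_of([0, 0, 7, 0, 0], [0, 1, 2, 3, 4])
        c = compute_pwc(h)
        assert np.allclose(c.values[2:], 2.0)
        assert c.defined_from == 2

    def test_uniform_histogram_endpoint_is_mean(self):
        c = compute_pwc(hist_of([1, 1, 1, 1], [0, 1, 2, 3]))
        assert c.values[-1] == pytest.approx(1.5)

    def test_hand_evaluated_curve(self):
        c = compute_pwc(hist_of([2, 1, 1], [0, 1, 2]))
        assert np.allclose(c.values, [0.0, 1.0 / 3.0, 3.0 / 4.0])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            compute_pwc(hist_of([0, 0, 0], [0, 1, 2]))

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        counts=st.lists(st.integers(min_value=0, max_value=1000), min_size=5, max_size=64).filter(
            lambda c: sum(c) > 0
        )
    )
    def test_monotone_and_endpoint_mean(self, counts):
        """PWC never decreases and ends at the count-weighted mean level."""
        levels = np.arange(len(counts), dtype=float)
        c = compute_pwc(hist_of(counts, levels))
        assert np.all(np.diff(c.values) >= -1e-9)
        w = np.asarray(counts, dtype=float)
        assert c.values[-1] == pytest.approx(np.average(levels, weights=w))


class TestCandidateThresholds:
    def test_linear_curve_no_inflections(self):
        curve = compute_pwc(hist_of(np.ones(32), np.arange(32)))
        # PWC of a uniform histogram is exactly linear (mean of 0..k = k/2)
        assert find_candidate_thresholds(curve, smoothing_sigma=0.0) == []

    def test_bimodal_histogram_candidate_in_valley_window(self):
        levels = np.arange(256, dtype=float)
        counts = (
            1000 * np.exp(-0.5 * ((levels - 60) / 15) ** 2)
            + 800 * np.exp(-0.5 * ((levels - 180) / 20) ** 2)
        ).astype(int)
        curve = compute_pwc(hist_of(counts, levels))
        cand = find_candidate_thresholds(curve, smoothing_sigma=1.0)
        assert any(100 <= levels[i] <= 140 for i in cand)

    def test_short_curve_returns_empty(self):
        curve = compute_pwc(hist_of([1, 1, 1], [0, 1, 2]))
        assert find_candidate_thresholds(curve) == []


class TestApplyThreshold:
    @staticmethod
    def three_spheres():
        grid = np.full((40, 40, 20), 100.0)
        xx, yy, zz = np.mgrid[:40, :40, :20]
        for cx, cy in [(8, 8), (8, 30), (30, 20)]:
            grid[(xx - cx) ** 2 + (yy - cy) ** 2 + (zz - 10) ** 2 <= 25] = 200.0
        return vol_of(grid)

    def test_three_disjoint_objects(self):
        vol = self.three_spheres()
        labels, n = apply_threshold(vol, np.ones_like(vol.grid), 150.0)
        assert n == 3

    def test_level_above_max_empty(self):
        vol = self.three_spheres()
        _, n = apply_threshold(vol, np.ones_like(vol.grid), 250.0)
        assert n == 0

    def test_level_below_min_whole_mask(self):
        vol = self.three_spheres()
        mask = np.ones_like(vol.grid)
        labels, n = apply_threshold(vol, mask, 50.0)
        assert n == 1
        assert (labels > 0).sum() == mask.sum()

    def test_small_objects_removed(self):
        grid = np.zeros((10, 10, 10))
        grid[0, 0, 0] = 10  # single bright voxel
        _, n = apply_threshold(vol_of(grid), np.ones_like(grid), 5.0, min_object_voxels=5)
        assert n == 0


class TestObjectFeatures:
    def test_digital_disc_is_circular(self):
        xx, yy = np.mgrid[:50, :50]
        disc = (xx - 25) ** 2 + (yy - 25) ** 2 <= 20**2
        obj = np.repeat(disc[:, :, None], 3, axis=2)
        grid = np.where(obj, 200.0, 100.0)
        f = object_features(obj, vol_of(grid))
        assert f.circularity >= 0.9

    def test_constant_object_zero_sd(self):
        obj = np.zeros((8, 8, 8), dtype=bool)
        obj[2:6, 2:6, 2:6] = True
        f = object_features(obj, vol_of(np.full((8, 8, 8), 7.0)))
        assert f.internal_sd == 0.0

    def test_single_voxel_convention(self):
        obj = np.zeros((5, 5, 5), dtype=bool)
        obj[2, 2, 2] = True
        f = object_features(obj, vol_of(np.random.default_rng(0).normal(size=(5, 5, 5))))
        assert f.circularity == 1.0
        assert f.internal_sd == 0.0

    def test_border_gradient_grows_with_step_height(self):
        def grad_for(h):
            grid = np.zeros((20, 20, 20))
            obj = np.zeros_like(grid, dtype=bool)
            obj[5:15, 5:15, 5:15] = True
            grid[obj] = h
            return object_features(obj, vol_of(grid)).border_gradient

        assert grad_for(50) < grad_for(100) < grad_for(200)

    def test_empty_object_rejected(self):
        with pytest.raises(ValueError):
            object_features(np.zeros((4, 4, 4), dtype=bool), vol_of(np.zeros((4, 4, 4))))


class TestScoreThresholds:
    def test_empty_candidate_scores_zero(self):
        assert score_thresholds([[]])[0] == 0.0

    def test_identical_feature_sets_tie(self):
        objs = [ObjectFeatures(0.8, 5.0, 30.0, 100, 180.0)]
        s = score_thresholds([objs, list(objs)])
        assert s[0] == pytest.approx(s[1])

    def test_compact_sharp_object_beats_ragged_noisy_ones(self):
        good = [ObjectFeatures(0.95, 4.0, 40.0, 500, 200.0)]
        ragged = [
            ObjectFeatures(0.25, 30.0, 8.0, 80, 120.0),
            ObjectFeatures(0.30, 28.0, 10.0, 60, 125.0),
            ObjectFeatures(0.20, 35.0, 7.0, 90, 118.0),
        ]
        s = score_thresholds([good, ragged])
        assert s[0] > s[1]

    def test_scores_bounded(self):
        rng = np.random.default_rng(3)
        cands = [
            [
                ObjectFeatures(
                    rng.uniform(0, 1), rng.uniform(0, 40), rng.uniform(0, 50),
                    int(rng.integers(5, 500)), 150.0,
                )
                for _ in range(int(rng.integers(1, 6)))
            ]
            for _ in range(8)
        ]
        s = score_thresholds(cands)
        assert np.all((s >= 0) & (s <= 1))


class TestSegmentCysts:
    def test_noisefree_level_between_modes(self, noisefree_phantom):
        vol, truth = noisefree_phantom
        res = segment_cysts(vol, truth.kidney_mask)
        vals = vol.grid[truth.kidney_mask > 0]
        counts = np.bincount(vals.ravel(), minlength=256)
        parenchyma_mode = int(np.argmax(counts[:150]))
        cyst_mode = 150 + int(np.argmax(counts[150:]))
        assert parenchyma_mode < res.chosen_level < cyst_mode

    def test_zero_cyst_phantom_near_empty(self):
        vol, truth = generate_phantom(
            PhantomSpec(pattern="typical_bilateral", n_cysts=0, seed=3)
        )
        res = segment_cysts(vol, truth.kidney_mask)
        assert res.tcv_ml <= 0.01 * truth.true_tkv

    def test_lopsided_recovery_within_ten_percent(self, lopsided_phantom):
        vol, truth = lopsided_phantom
        res = segment_cysts(vol, truth.kidney_mask)
        assert res.tcv_ml == pytest.approx(truth.true_tcv, rel=0.10)

    def test_cyst_mask_inside_kidney_and_tcv_below_tkv(self, lopsided_phantom):
        vol, truth = lopsided_phantom
        res = segment_cysts(vol, truth.kidney_mask)
        assert not (res.cyst_mask & (truth.kidney_mask == 0)).any()
        assert res.tcv_ml <= truth.true_tkv

    def test_affine_intensity_rescaling_same_chosen_bin(self, lopsided_phantom):
        """Gain/offset changes of the scanner must not move the threshold bin."""
        vol, truth = lopsided_phantom
        res1 = segment_cysts(vol, truth.kidney_mask)
        rescaled = IntensityVolume(
            grid=2.5 * vol.grid.astype(float) + 37.0, spacing=vol.spacing
        )
        res2 = segment_cysts(rescaled, truth.kidney_mask)
        assert res2.chosen_index == res1.chosen_index
        assert np.array_equal(res2.cyst_mask, res1.cyst_mask)

    def test_empty_mask_rejected(self):
        vol = vol_of(np.zeros((6, 6, 6)))
        with pytest.raises(ValueError, match="mask"):
            segment_cysts(vol, np.zeros((6, 6, 6)))

    def test_constant_image_reports_no_cysts(self):
        vol = vol_of(np.full((16, 16, 16), 9.0))
        res = segment_cysts(vol, np.ones((16, 16, 16)))
        assert res.tcv_ml == 0.0
        assert res.no_valid_candidate


class TestComputeTCV:
    def test_unit_conversion(self):
        mask = np.zeros((20, 20, 20), dtype=bool)
        mask.ravel()[:1000] = True
        assert compute_tcv(mask, (1.0, 1.0, 1.0)) == pytest.approx(1.0)

    def test_empty_mask(self):
        assert compute_tcv(np.zeros((4, 4, 4), dtype=bool), (1, 1, 1)) == 0.0

    def test_truth_sphere_volume(self):
        spec = PhantomSpec(
            grid_shape=(96, 48, 48),
            voxel_spacing=(1.0, 1.0, 1.0),
            kidney_semiaxes=(18.0, 18.0, 20.0),
            pattern="unilateral",
            n_cysts=1,
            cyst_radius_range=(10.0, 10.0),
            seed=2,
        )
        _, truth = generate_phantom(spec)
        tcv = compute_tcv(truth.cyst_mask, spec.voxel_spacing)
        assert tcv == pytest.approx(4.0 / 3.0 * np.pi, rel=0.02)  # 4.19 mL
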