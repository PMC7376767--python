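import numpy as np
import pytest

from batquant import (SegmentationMask, SegmentationParams, Volume3D,
                      body_mask, intersect, place_paired_spheres,
                      segment_bat_active, segment_scat_ct, segment_scat_mr,
                      shrink, sphere_mask, threshold_mask, uniform_grid)
from batquant.dixon import FatFractionMap
from batquant.volumes import GridMismatchError
from conftest import make_volume
from oracle_utils import (brute_erode, brute_intersect, brute_label_sizes,
                          brute_threshold)


def mask_of(values, grid=None):
    values = np.asarray(values, dtype=bool)
    return SegmentationMask(values=values,
                            grid=grid or uniform_grid(values.shape))


class TestThresholdMask:
    def test_ff_window_bounds_are_inclusive(self):
        vals = np.full((3, 3, 3), 500.0)
        vals[0, 0, 0] = 400.0   # exactly at the lower bound
        vals[0, 0, 1] = 1000.0  # exactly at the upper bound
        vals[0, 0, 2] = 399.9
        m = threshold_mask(make_volume(vals, units="per_mille"), 400, 1000)
        assert m.values[0, 0, 0] and m.values[0, 0, 1]
        assert not m.values[0, 0, 2]

    def test_suv_threshold_inclusive_at_1p5(self):
        vals = np.zeros((2, 2, 2))
        vals[0, 0, 0] = 1.5
        m = threshold_mask(make_volume(vals, units="g_per_ml"), 1.5)
        assert m.values[0, 0, 0] and m.voxel_count == 1

    def test_all_below_gives_empty(self):
        m = threshold_mask(make_volume(np.zeros((3, 3, 3))), 1.0, 2.0)
        assert m.is_empty()

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            threshold_mask(make_volume(np.zeros((2, 2, 2))), 2.0, 1.0)


class TestIntersect:
    def test_idempotent(self, rng):
        m = mask_of(rng.random((4, 4, 4)) < 0.5)
        out = intersect([m, m])
        np.testing.assert_array_equal(out.values, m.values)

    def test_with_empty_is_empty(self, rng):
        m = mask_of(rng.random((4, 4, 4)) < 0.5)
        empty = mask_of(np.zeros((4, 4, 4)), grid=m.grid)
        assert intersect([m, empty]).is_empty()

    def test_grid_mismatch_rejected(self):
        a = mask_of(np.ones((3, 3, 3)))
        b = SegmentationMask(values=np.ones((3, 3, 3), bool),
                             grid=uniform_grid((3, 3, 3), spacing=(2, 2, 2)))
        with pytest.raises(GridMismatchError):
            intersect([a, b])


class TestShrink:
    def test_single_voxel_erodes_to_empty(self):
        vals = np.zeros((3, 3, 3), bool)
        vals[1, 1, 1] = True
        assert shrink(mask_of(vals), 1).is_empty()

    def test_cube_erodes_to_center(self):
        vals = np.zeros((5, 5, 5), bool)
        vals[1:4, 1:4, 1:4] = True
        out = shrink(mask_of(vals), 1)
        expected = np.zeros((5, 5, 5), bool)
        expected[2, 2, 2] = True
        np.testing.assert_array_equal(out.values, expected)

    def test_zero_iterations_is_identity(self, rng):
        m = mask_of(rng.random((4, 4, 4)) < 0.5)
        np.testing.assert_array_equal(shrink(m, 0).values, m.values)

    def test_anti_extensive_and_decreasing(self, rng):
        m = mask_of(rng.random((8, 8, 8)) < 0.7)
        s1 = shrink(m, 1)
        s2 = shrink(m, 2)
        assert not (s1.values & ~m.values).any()
        assert not (s2.values & ~s1.values).any()


class TestMorphologyOracles:
    """Primitives agree with pure-Python voxel-loop implementations."""

    @pytest.mark.parametrize("seed", range(8))
    def test_threshold_intersect_shrink_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(4, 10, size=3))
        vals = rng.uniform(0, 10, size=shape)
        lo, hi = sorted(rng.uniform(0, 10, size=2))
        thr = threshold_mask(make_volume(vals), lo, hi)
        np.testing.assert_array_equal(thr.values,
                                      brute_threshold(vals, lo, hi))

        masks = [rng.random(shape) < 0.6 for _ in range(3)]
        out = intersect([mask_of(m, grid=thr.grid) for m in masks])
        np.testing.assert_array_equal(out.values, brute_intersect(masks))

        dense = rng.random(shape) < 0.8
        n_erode = int(rng.integers(1, 3))
        np.testing.assert_array_equal(
            shrink(mask_of(dense), n_erode).values,
            brute_erode(dense, n_erode))


class TestBodyMask:
    def test_recovers_high_signal_ellipsoid(self):
        idx = np.indices((16, 16, 16), dtype=float)
        ell = (((idx[0] - 8) / 6) ** 2 + ((idx[1] - 8) / 5) ** 2
               + ((idx[2] - 8) / 5) ** 2) <= 1
        vol = make_volume(np.where(ell, 100.0, 0.0))
        m = body_mask(vol, quantile=0.2)
        np.testing.assert_array_equal(m.values, ell)

    def test_zero_volume_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            body_mask(make_volume(np.zeros((4, 4, 4))))

    def test_keeps_largest_component_only(self):
        vals = np.zeros((12, 12, 12))
        vals[1:8, 1:8, 1:8] = 100.0   # 343 voxels
        vals[10:12, 10:12, 10:12] = 100.0  # 8 voxels
        m = body_mask(make_volume(vals), quantile=0.2)
        sizes = brute_label_sizes(m.values)
        assert sizes == [343]
        assert m.values[2, 2, 2] and not m.values[11, 11, 11]


def _ff_map(vals, grid=None, valid=None):
    vol = make_volume(vals, units="per_mille") if grid is None else \
        Volume3D(values=vals, grid=grid, units="per_mille")
    v = np.ones(vol.shape, bool) if valid is None else valid
    return FatFractionMap(ff=vol, valid_mask=SegmentationMask(values=v,
                                                              grid=vol.grid))


class TestComposedSegmentations:
    def _inputs(self):
        shape = (16, 16, 16)
        idx = np.indices(shape, dtype=float)
        body = (((idx[0] - 8) / 7) ** 2 + ((idx[1] - 8) / 7) ** 2
                + ((idx[2] - 8) / 7) ** 2) <= 1
        depot = (((idx[0] - 8) / 4) ** 2 + ((idx[1] - 8) / 3.5) ** 2
                 + ((idx[2] - 8) / 3) ** 2) <= 1
        ff = np.where(depot, 700.0, np.where(body, 80.0, 0.0))
        ip = np.where(body, 100.0, 0.0)
        return shape, body, depot, ff, ip

    def test_mr_path_matches_composed_brute_force(self):
        shape, body, depot, ff, ip = self._inputs()
        anat = mask_of(depot)
        out = segment_scat_mr(anat, _ff_map(ff), make_volume(ip),
                              SegmentationParams(shrink_voxels=1))
        expected = brute_erode(brute_intersect(
            [depot, brute_threshold(ff, 400, 1000), body]), 1)
        np.testing.assert_array_equal(out.values, expected)

    def test_empty_ff_window_is_an_error(self):
        shape, body, depot, ff, ip = self._inputs()
        with pytest.raises(ValueError, match="no supraclavicular"):
            segment_scat_mr(mask_of(depot), _ff_map(ff), make_volume(ip),
                            SegmentationParams(ff_window=(0.0, 0.0)))

    def test_no_shrink_reduces_to_intersection(self):
        shape, body, depot, ff, ip = self._inputs()
        out = segment_scat_mr(mask_of(depot), _ff_map(ff), make_volume(ip),
                              SegmentationParams(shrink_voxels=0))
        expected = brute_intersect([depot, brute_threshold(ff, 400, 1000), body])
        np.testing.assert_array_equal(out.values, expected)

    def test_active_bat_empty_for_cold_subject(self):
        shape, body, depot, ff, ip = self._inputs()
        scat = segment_scat_mr(mask_of(depot), _ff_map(ff), make_volume(ip))
        suv = make_volume(np.zeros(shape), units="g_per_ml")
        active = segment_bat_active(scat, suv)
        assert active.is_empty()  # a BAT-negative participant, not an error

    def test_active_bat_equals_scat_when_uniformly_hot(self):
        shape, body, depot, ff, ip = self._inputs()
        scat = segment_scat_mr(mask_of(depot), _ff_map(ff), make_volume(ip))
        suv = make_volume(np.full(shape, 2.0), units="g_per_ml")
        active = segment_bat_active(scat, suv)
        np.testing.assert_array_equal(active.values, scat.values)

    def test_hot_spot_count_matches_voxel_loop(self):
        shape, body, depot, ff, ip = self._inputs()
        scat = segment_scat_mr(mask_of(depot), _ff_map(ff), make_volume(ip),
                               SegmentationParams(shrink_voxels=0))
        rng = np.random.default_rng(5)
        suv_vals = rng.uniform(0, 3, size=shape)
        active = segment_bat_active(scat, make_volume(suv_vals, units="g_per_ml"))
        count = sum(1 for i in np.ndindex(shape)
                    if scat.values[i] and suv_vals[i] >= 1.5)
        assert active.voxel_count == count

    def test_raising_suv_threshold_never_enlarges(self):
        shape, body, depot, ff, ip = self._inputs()
        scat = segment_scat_mr(mask_of(depot), _ff_map(ff), make_volume(ip))
        rng = np.random.default_rng(6)
        suv = make_volume(rng.uniform(0, 3, size=shape), units="g_per_ml")
        prev = None
        for thr in (0.5, 1.0, 1.5, 2.0, 2.5):
            cur = segment_bat_active(scat, suv,
                                     SegmentationParams(suv_threshold=thr))
            if prev is not None:
                assert not (cur.values & ~prev).any()
            prev = cur.values

    def test_outputs_subset_of_anatomical_input(self):
        shape, body, depot, ff, ip = self._inputs()
        anat = mask_of(depot)
        scat = segment_scat_mr(anat, _ff_map(ff), make_volume(ip))
        rng = np.random.default_rng(7)
        suv = make_volume(rng.uniform(0, 3, size=shape), units="g_per_ml")
        active = segment_bat_active(scat, suv)
        assert not (scat.values & ~anat.values).any()
        assert not (active.values & ~anat.values).any()


class TestCtPath:
    def _inputs(self):
        shape = (12, 12, 12)
        ct = np.full(shape, 40.0)
        ct[2:9, 2:9, 2:9] = -100.0  # adipose block
        ct[2, 2, 2] = -200.0        # below the adipose window
        suv = np.zeros(shape)
        suv[4:7, 4:7, 4:7] = 2.0
        anat = np.zeros(shape, bool)
        anat[1:10, 1:10, 1:10] = True
        return (make_volume(ct, units="HU"),
                make_volume(suv, units="g_per_ml"), mask_of(anat))

    def test_fat_voxel_with_uptake_included(self):
        ct, suv, anat = self._inputs()
        out = segment_scat_ct(anat, ct, suv, SegmentationParams(shrink_voxels=0))
        assert out.values[5, 5, 5]

    def test_below_hu_window_excluded(self):
        ct, suv, anat = self._inputs()
        suv2 = make_volume(np.full((12, 12, 12), 2.0), units="g_per_ml")
        out = segment_scat_ct(anat, ct, suv2, SegmentationParams(shrink_voxels=0))
        assert not out.values[2, 2, 2]    # -200 HU: outside [-190, -10]
        assert out.values[3, 3, 3]

    def test_matches_composed_brute_force(self):
        ct, suv, anat = self._inputs()
        out = segment_scat_ct(anat, ct, suv, SegmentationParams(shrink_voxels=1))
        expected = brute_erode(brute_intersect([
            anat.values,
            brute_threshold(ct.values, -190, -10),
            brute_threshold(suv.values, 1.5, np.inf),
        ]), 1)
        np.testing.assert_array_equal(out.values, expected)


class TestPairedSpheres:
    def _phantom(self):
        """Two-lobe depot: one hot low-FF lobe, one cold high-FF lobe."""
        shape = (32, 32, 16)
        grid = uniform_grid(shape, spacing=(2, 2, 2))
        idx = np.indices(shape, dtype=float)
        left = (((idx[0] - 8) / 5) ** 2 + ((idx[1] - 16) / 5) ** 2
                + ((idx[2] - 8) / 5) ** 2) <= 1
        right = (((idx[0] - 24) / 5) ** 2 + ((idx[1] - 16) / 5) ** 2
                 + ((idx[2] - 8) / 5) ** 2) <= 1
        scat = mask_of(left | right, grid=grid)
        suv = np.full(shape, 0.3)
        suv[left] = 2.5
        suv[8, 16, 8] = 3.0  # unique global maximum
        ff = np.full(shape, 700.0)
        ff[left] = 600.0
        return (grid, scat,
                Volume3D(values=suv, grid=grid, units="g_per_ml"),
                Volume3D(values=ff, grid=grid, units="per_mille"),
                left, right)

    def test_positive_center_at_global_max(self):
        grid, scat, suv, ff, left, right = self._phantom()
        active = intersect([scat, threshold_mask(suv, 1.5)])
        pos, neg = place_paired_spheres(suv, scat, active)
        assert pos.values[8, 16, 8]
        # sphere world diameter is 5% of the 64 mm in-plane extent
        r_vox = 0.05 * 64 / 2 / 2
        assert pos.voxel_count <= 4 / 3 * np.pi * (r_vox + 1) ** 3

    def test_negative_sphere_in_cold_lobe(self):
        grid, scat, suv, ff, left, right = self._phantom()
        active = intersect([scat, threshold_mask(suv, 1.5)])
        pos, neg = place_paired_spheres(suv, scat, active)
        assert (neg.values & right).sum() == neg.voxel_count
        mean_pos = suv.values[pos.values].mean()
        mean_neg = suv.values[neg.values].mean()
        assert mean_neg < mean_pos
        assert ff.values[neg.values].mean() > ff.values[pos.values].mean()

    def test_all_cold_raises_from_empty_active(self):
        grid, scat, suv, ff, left, right = self._phantom()
        cold = Volume3D(values=np.full(suv.shape, 0.2), grid=grid,
                        units="g_per_ml")
        active = intersect([scat, threshold_mask(cold, 1.5)])
        with pytest.raises(ValueError, match="active"):
            place_paired_spheres(cold, scat, active)

    def test_no_quiet_zone_raises(self):
        grid, scat, suv, ff, left, right = self._phantom()
        hot = Volume3D(values=np.full(suv.shape, 2.0), grid=grid,
                       units="g_per_ml")
        active = intersect([scat, threshold_mask(hot, 1.5)])
        with pytest.raises(ValueError, match="PET-negative"):
            place_paired_spheres(hot, scat, active)

    def test_sphere_mask_is_world_distance_ball(self):
        grid = uniform_grid((9, 9, 9), spacing=(1, 2, 1))
        m = sphere_mask(grid, (4, 4, 4), radius_mm=2.0)
        # anisotropic spacing: +/-2 voxels along x/z but only +/-1 along y
        assert m.values[6, 4, 4] and m.values[4, 5, 4] and m.values[4, 4, 6]
        assert not m.values[4, 6, 4]
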