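"""WMH partition, intensity grading, WM correction and distance rings."""

import numpy as np
import pytest
from scipy import ndimage

from svdquant.errors import ValidationError
from svdquant.wmh import (
    contour_rings,
    correct_wm_mask,
    grade_wmh_by_intensity,
    partition_wmh,
)

from conftest import dice, make_mask, make_volume


class TestCorrectWM:
    def test_no_probmaps_leaves_wm_unchanged(self):
        wm = make_mask(np.ones((10, 10, 4)))
        out = correct_wm_mask(wm, {})
        assert np.array_equal(out.data, wm.data)

    def test_cube_diamond_erosion_removes_27_core_voxels(self):
        shape = (11, 11, 11)
        wm = make_mask(np.ones(shape))
        p = np.zeros(shape)
        p[3:8, 3:8, 3:8] = 1.0          # 5x5x5 cube of probability 1
        out = correct_wm_mask(wm, {"putamen_l": make_volume(p)})
        removed = wm.n_voxels - out.n_voxels
        assert removed == 27            # (5-2)^3 under the 6-connected diamond
        # and the removed voxels are the eroded core
        assert not out.data[4:7, 4:7, 4:7].any()

    def test_thalamus_keeps_only_max_probability_level(self):
        shape = (9, 9, 3)
        wm = make_mask(np.ones(shape))
        p = np.zeros(shape)
        p[0:6, :, 1] = 0.2
        p[0:4, :, 1] = 0.6
        p[0:2, :, 1] = 1.0
        out = correct_wm_mask(wm, {"thalamus_l": make_volume(p)})
        removed = wm.data & ~out.data
        assert np.array_equal(removed, p == 1.0)

    def test_hippocampus_used_as_given(self):
        shape = (7, 7, 3)
        wm = make_mask(np.ones(shape))
        p = np.zeros(shape)
        p[2:5, 2:5, 1] = 0.4
        out = correct_wm_mask(wm, {"hippocampus_r": make_volume(p)})
        assert wm.n_voxels - out.n_voxels == 9

    def test_probability_outside_unit_interval_raises(self):
        wm = make_mask(np.ones((5, 5, 2)))
        with pytest.raises(ValidationError):
            correct_wm_mask(wm, {"putamen_l": make_volume(
                np.full((5, 5, 2), 1.5))})


class TestPartition:
    def test_wmh_inside_wm_is_all_less_intense(self):
        wm = make_mask(np.ones((8, 8, 2)))
        w = np.zeros((8, 8, 2), bool)
        w[2:5, 2:5, 0] = True
        wmh = make_mask(w)
        part = partition_wmh(wmh, wm)
        assert part.intense.is_empty()
        assert np.array_equal(part.less_intense.data, wmh.data)

    def test_wmh_disjoint_from_wm_is_all_intense(self):
        shape = (8, 8, 2)
        wm_arr = np.zeros(shape, bool)
        wm_arr[:4] = True
        wmh_arr = np.zeros(shape, bool)
        wmh_arr[5:7, :, :] = True
        part = partition_wmh(make_mask(wmh_arr), make_mask(wm_arr))
        assert np.array_equal(part.intense.data, wmh_arr)
        assert part.less_intense.is_empty()

    def test_phantom_grades(self, phantom_noisy):
        t = phantom_noisy.truth
        part = partition_wmh(t["wmh"], t["wm_gross"])
        assert dice(part.less_intense, t["wmh_less_intense"]) >= 0.9
        assert dice(part.intense, t["wmh_intense"]) >= 0.9

    def test_partition_invariants_enforced(self, phantom_noisy):
        t = phantom_noisy.truth
        part = partition_wmh(t["wmh"], t["wm_gross"])
        assert not (part.intense.data & part.less_intense.data).any()
        assert np.array_equal(part.intense.data | part.less_intense.data,
                              part.wmh.data)
        assert not (part.nawm.data & part.wmh.data).any()


class TestGradeByIntensity:
    def test_constructed_lesion_grades(self):
        """Parenchyma N(100, 5); lesion A at 127 (z = 5.4) grades
        less-intense, lesion B at 200 >= 1.5 x 127 grades intense."""
        rng = np.random.default_rng(0)
        shape = (24, 24, 4)
        flair = rng.normal(100, 5, shape)
        brain = np.ones(shape, bool)
        wmh = np.zeros(shape, bool)
        a = np.zeros(shape, bool)
        a[2:7, 2:7, 1] = True
        b = np.zeros(shape, bool)
        b[12:17, 12:17, 2] = True
        flair[a] = 127.0
        flair[b] = 200.0
        wmh = a | b
        out = grade_wmh_by_intensity(make_volume(flair), make_mask(brain),
                                     make_mask(wmh))
        assert np.array_equal(out["less_intense"].data, a)
        assert np.array_equal(out["intense"].data, b)

    def test_no_wmh_gives_empty_grades(self):
        rng = np.random.default_rng(1)
        shape = (10, 10, 3)
        out = grade_wmh_by_intensity(
            make_volume(rng.normal(100, 5, shape)),
            make_mask(np.ones(shape)), make_mask(np.zeros(shape)))
        assert out["intense"].is_empty() and out["less_intense"].is_empty()

    def test_subthreshold_wmh_warns(self):
        rng = np.random.default_rng(2)
        shape = (10, 10, 3)
        flair = rng.normal(100, 5, shape)
        wmh = np.zeros(shape, bool)
        wmh[4:6, 4:6, 1] = True
        flair[wmh] = 104.0              # well under 5 SD
        with pytest.warns(UserWarning, match="subthreshold"):
            out = grade_wmh_by_intensity(make_volume(flair),
                                         make_mask(np.ones(shape)),
                                         make_mask(wmh))
        assert out["intense"].is_empty() and out["less_intense"].is_empty()

    def test_agrees_with_wm_coincidence_partition(self, phantom_noisy):
        """The two grade definitions coincide on a phantom built to
        satisfy both simultaneously (Dice >= 0.8 per grade)."""
        ph = phantom_noisy
        t = ph.truth
        part = partition_wmh(t["wmh"], t["wm_gross"])
        graded = grade_wmh_by_intensity(
            ph.volumes["flair"], t["brain_tissue"], t["wmh"],
            exclusions=t["index_stroke"])
        assert dice(graded["less_intense"], part.less_intense) >= 0.8
        assert dice(graded["intense"], part.intense) >= 0.8


def brute_force_rings(wmh, nawm, width, n_rings):
    """Oracle: rings from the Chebyshev distance transform (in-plane)."""
    labels = np.zeros(wmh.shape, np.int16)
    for z in range(wmh.shape[2]):
        if not wmh[:, :, z].any():
            continue
        dist = ndimage.distance_transform_cdt(~wmh[:, :, z],
                                              metric="chessboard")
        for k in range(1, n_rings + 1):
            ring = (dist > (k - 1) * width) & (dist <= k * width)
            labels[:, :, z][ring & nawm[:, :, z]] = k
    return labels


class TestContourRings:
    def test_single_voxel_first_ring_is_24_voxels(self):
        shape = (21, 21, 1)
        wmh = np.zeros(shape, bool)
        wmh[10, 10, 0] = True
        nawm = np.ones(shape, bool)
        nawm[10, 10, 0] = False
        rm = contour_rings(make_mask(wmh), make_mask(nawm), ring_width_vox=2,
                           max_dist_mm=10.0)
        # Chebyshev distances {1, 2} around one voxel: 5^2 - 1 = 24
        assert int((rm.labels.data == 1).sum()) == 24

    def test_wmh_filling_nawm_gives_empty_rings(self):
        shape = (8, 8, 2)
        full = make_mask(np.ones(shape))
        empty_nawm = make_mask(np.zeros(shape))
        with pytest.warns(UserWarning):
            rm = contour_rings(full, empty_nawm)
        assert not (rm.labels.data > 0).any()

    def test_default_protocol_geometry_gives_five_rings(self):
        shape = (31, 31, 2)
        wmh = np.zeros(shape, bool)
        wmh[15, 15, :] = True
        nawm = ~wmh
        rm = contour_rings(
            make_mask(wmh, spacing=(0.9375, 0.9375, 6.0)),
            make_mask(nawm, spacing=(0.9375, 0.9375, 6.0)),
            ring_width_vox=2, max_dist_mm=10.0)
        assert rm.n_rings == 5

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_distance_transform_oracle(self, seed):
        rng = np.random.default_rng(seed)
        shape = (24, 24, 3)
        wmh = ndimage.binary_dilation(rng.random(shape) > 0.97)
        nawm = (rng.random(shape) > 0.2) & ~wmh
        if not wmh.any():
            wmh[10, 10, 1] = True
        rm = contour_rings(make_mask(wmh), make_mask(nawm), ring_width_vox=2,
                           max_dist_mm=10.0)
        oracle = brute_force_rings(wmh, nawm, 2, rm.n_rings)
        np.testing.assert_array_equal(rm.labels.data, oracle)

    def test_rings_disjoint_and_inside_nawm(self, phantom_noisy):
        t = phantom_noisy.truth
        rm = contour_rings(t["wmh"], t["nawm"])
        for k in range(1, rm.n_rings + 1):
            ring = rm.ring_mask(k)
            assert not (ring.data & ~t["nawm"].data).any()
            assert not (ring.data & t["wmh"].data).any()
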