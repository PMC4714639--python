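"""Iron deposit detection, artifact filtering and microbleed counting."""

import numpy as np
import pytest
from scipy import stats

from svdquant.errors import ParameterError
from svdquant.iron import (
    component_sphericity,
    count_microbleeds,
    detect_iron_global,
    detect_iron_subcortical,
    filter_artifacts,
)
from svdquant.volumes import BinaryMask

from conftest import dice, make_grid, make_mask, make_volume


def gaussian_structure(seed, shape=(20, 20, 20), implant=None,
                       implant_t1_dark=False):
    """One structure with Gaussian T2*/T1W intensities and an optional
    implanted iron cluster at a depth of -6 SD."""
    rng = np.random.default_rng(seed)
    t2 = rng.normal(100.0, 5.0, shape)
    t1 = rng.normal(120.0, 5.0, shape)
    mask = np.ones(shape, bool)
    cluster = np.zeros(shape, bool)
    if implant:
        idx = np.indices(shape) - np.array(implant["center"])[:, None, None, None]
        cluster = (idx ** 2).sum(axis=0) <= implant["radius"] ** 2
        t2[cluster] = rng.normal(100.0 - 6 * 5.0, 5.0, int(cluster.sum()))
        if implant_t1_dark:
            t1[cluster] = rng.normal(120.0 - 8 * 5.0, 5.0, int(cluster.sum()))
        else:
            t1[cluster] = rng.normal(122.0, 5.0, int(cluster.sum()))
    return (make_volume(t2), make_volume(t1),
            {"structure": make_mask(mask)}, make_mask(cluster))


class TestSubcorticalIron:
    def test_implanted_cluster_detected(self):
        t2, t1, structs, truth = gaussian_structure(
            0, implant={"center": (10, 10, 10), "radius": 4})
        seg = detect_iron_subcortical(t2, t1, structs)
        assert dice(seg.global_mask, truth) >= 0.9

    def test_null_false_positive_rate_matches_fence_expectation(self):
        """Pure-Gaussian structure: the flagged fraction agrees with the
        joint fence rule's binomial expectation."""
        t2, t1, structs, _ = gaussian_structure(1, shape=(30, 30, 30))
        seg = detect_iron_subcortical(t2, t1, structs)
        n = structs["structure"].n_voxels
        flagged = seg.global_mask.n_voxels
        p_low = stats.norm.cdf(-(0.6745 + 1.5 * 1.349))  # below Q1 - 1.5 IQR
        expect = p_low * (1 - p_low) * n
        tol = 4 * np.sqrt(n * p_low)                     # ~4 binomial SDs
        assert abs(flagged - expect) <= tol
        assert flagged < 0.01 * n

    def test_t1_dark_vessel_like_cluster_rejected(self):
        t2, t1, structs, truth = gaussian_structure(
            2, implant={"center": (10, 10, 10), "radius": 4},
            implant_t1_dark=True)
        seg = detect_iron_subcortical(t2, t1, structs)
        # the dark-on-both cluster must not be picked up
        assert (seg.global_mask.data & truth.data).sum() == 0

    def test_small_structure_skipped_with_warning(self):
        t2, t1, structs, _ = gaussian_structure(3)
        tiny = np.zeros(t2.shape, bool)
        tiny[0, 0, :5] = True
        structs["tiny"] = make_mask(tiny)
        with pytest.warns(UserWarning, match="tiny"):
            seg = detect_iron_subcortical(t2, t1, structs)
        assert seg.structure_masks["tiny"].is_empty()

    def test_phantom_pallidal_iron(self, phantom_noisy):
        ph = phantom_noisy
        structs = {k[len("struct_"):]: v for k, v in ph.truth.items()
                   if k.startswith("struct_")}
        seg = detect_iron_subcortical(ph.volumes["t2s"], ph.volumes["t1w"],
                                      structs)
        seg = filter_artifacts(seg, ph.volumes["t2s"])
        assert dice(seg.global_mask, ph.truth["iron"]) >= 0.8


class TestArtifactFilter:
    def _seg_with_components(self, comps):
        """Build an IronSegmentation-like input from explicit components."""
        shape = (30, 12, 4)
        t2 = np.random.default_rng(4).normal(100, 5, shape)
        mask = np.ones(shape, bool)
        for sl, value in comps:
            t2[sl] = value if np.isscalar(value) else value
        vol = make_volume(t2)
        return vol, make_mask(mask)

    def test_high_variance_streak_removed_compact_focus_kept(self):
        shape = (40, 15, 4)
        rng = np.random.default_rng(5)
        t2 = rng.normal(100, 5, shape)
        t1 = rng.normal(120, 5, shape)
        # compact low-variance focus
        t2[5:8, 5:8, 1] = 60.0
        # smooth gradient streak spanning the fence down to far below it
        t2[20:36, 6, 2] = np.linspace(80, 30, 16)
        structs = {"s": make_mask(np.ones(shape, bool))}
        seg = detect_iron_subcortical(make_volume(t2), make_volume(t1), structs)
        kinds = dict(zip(seg.components["component"],
                         seg.components["std_t2s_variance"]))
        filtered = filter_artifacts(seg, make_volume(t2), var_bound=2.5)
        # the focus survives, the streak does not
        assert filtered.global_mask.data[5:8, 5:8, 1].any()
        assert not filtered.global_mask.data[20:36, 6, 2].any()

    def test_empty_input_passes_through(self, phantom_noisy):
        ph = phantom_noisy
        structs = {"thalamus_l": ph.truth["struct_thalamus_l"]}
        seg = detect_iron_subcortical(ph.volumes["t2s"], ph.volumes["t1w"],
                                      structs)
        out = filter_artifacts(seg, ph.volumes["t2s"])
        assert out.global_mask.n_voxels <= seg.global_mask.n_voxels


class TestGlobalIron:
    def test_excluded_zone_focus_dropped(self):
        shape = (30, 30, 4)
        rng = np.random.default_rng(6)
        img = rng.normal(160, 3, shape)
        foci = [(5, 5), (15, 15), (25, 25)]
        for cx, cy in foci:
            img[cx - 1:cx + 2, cy - 1:cy + 2, 1:3] = 30.0
        vol = make_volume(img)
        brain = make_mask(np.ones(shape))
        nawm = make_mask(rng.random(shape) > 0.5)
        excl = np.zeros(shape, bool)
        excl[24:27, 24:27, :] = True     # third-ventricle-style exclusion
        out = detect_iron_global(vol, nawm, (2, 100), brain,
                                 exclusions=make_mask(excl))
        import scipy.ndimage as ndi
        _, n = ndi.label(out.data, np.ones((3, 3, 3), bool))
        assert n == 2

    def test_empty_brain_gives_empty(self, phantom_noisy):
        ph = phantom_noisy
        empty = BinaryMask(np.zeros(ph.grid.shape, bool), ph.grid)
        out = detect_iron_global(ph.volumes["t2s"], ph.truth["nawm"],
                                 (1, 1000), empty)
        assert out.is_empty()

    def test_half_median_fraction_rejected(self, phantom_noisy):
        ph = phantom_noisy
        with pytest.raises(ParameterError):
            detect_iron_global(ph.volumes["t2s"], ph.truth["nawm"], (1, 100),
                               ph.truth["brain_tissue"],
                               threshold_fraction=0.5)

    def test_count_nonincreasing_in_threshold_fraction(self, phantom_noisy):
        ph = phantom_noisy
        counts = []
        for f in (0.45, 0.35, 0.25, 0.15):
            out = detect_iron_global(ph.volumes["t2s"], ph.truth["nawm"],
                                     (1, 10000), ph.truth["brain_tissue"],
                                     threshold_fraction=f)
            counts.append(out.n_voxels)
        assert counts == sorted(counts, reverse=True)


def digital_ball(r):
    n = int(np.ceil(r)) * 2 + 5
    idx = np.indices((n, n, n)) - n // 2
    return (idx ** 2).sum(axis=0) <= r * r


def analytic_cylinder_psi(radius, length):
    v = np.pi * radius ** 2 * length
    a = 2 * np.pi * radius * length + 2 * np.pi * radius ** 2
    return np.pi ** (1 / 3) * (6 * v) ** (2 / 3) / a


def analytic_prolate_psi(a_semi, c_semi):
    """Surface area of a prolate spheroid (c > a) in closed form."""
    e = np.sqrt(1 - a_semi ** 2 / c_semi ** 2)
    area = 2 * np.pi * a_semi ** 2 * (1 + c_semi / (a_semi * e) * np.arcsin(e))
    v = 4 / 3 * np.pi * a_semi ** 2 * c_semi
    return np.pi ** (1 / 3) * (6 * v) ** (2 / 3) / area


class TestSphericity:
    @pytest.mark.parametrize("r", [3, 4, 5, 6, 7, 8])
    def test_digital_sphere_within_5_percent_of_unity(self, r):
        psi, eq = component_sphericity(digital_ball(r), (1, 1, 1))
        assert abs(psi - 1.0) <= 0.05
        assert eq == pytest.approx(2 * r, rel=0.1)

    def test_thin_cylinder_classified_below_threshold(self):
        assert analytic_cylinder_psi(1.0, 12.0) == pytest.approx(0.665,
                                                                 abs=0.005)
        assert analytic_cylinder_psi(1.0, 12.0) < 0.7

    def test_prolate_spheroid_classified_above_threshold(self):
        psi_analytic = analytic_prolate_psi(4.0, 12.0)
        assert psi_analytic > 0.7
        n = 33
        idx = np.indices((n, n, n)) - 16
        spheroid = ((idx[0] / 4) ** 2 + (idx[1] / 4) ** 2
                    + (idx[2] / 12) ** 2) <= 1
        psi_mesh, _ = component_sphericity(spheroid, (1, 1, 1))
        assert psi_mesh > 0.7
        assert psi_mesh == pytest.approx(psi_analytic, rel=0.06)


class TestCountMicrobleeds:
    def test_sphere_counted_vessel_tube_excluded(self):
        shape = (40, 44, 20)
        arr = np.zeros(shape, bool)
        idx = np.indices(shape)
        arr |= ((idx[0] - 10) ** 2 + (idx[1] - 10) ** 2
                + (idx[2] - 10) ** 2) <= 16
        # vessel-like tube: radius ~1, length 30
        arr |= (((idx[0] - 30) ** 2 + (idx[2] - 10) ** 2) <= 1.2) \
            & (idx[1] >= 7) & (idx[1] < 37)
        finds, tally = count_microbleeds(make_mask(arr))
        assert len(finds) == 1
        assert finds[0].sphericity > 0.9
        assert int(tally.values.sum()) == 1

    def test_phantom_microbleeds_with_vessel(self, phantom_noisy):
        """Three implanted microbleeds count; the vein tube does not."""
        ph = phantom_noisy
        mask = ph.truth["microbleeds"] | ph.truth["vessel"]
        finds, _ = count_microbleeds(mask)
        assert len(finds) == 3

    def test_empty_mask_gives_no_findings(self):
        finds, tally = count_microbleeds(make_mask(np.zeros((8, 8, 4))))
        assert finds == []
        assert int(tally.values.sum()) == 0

    def test_boundary_component_flagged_and_excluded(self):
        arr = np.zeros((12, 12, 6), bool)
        arr[0:4, 4:8, 2:5] = True        # touches the x = 0 face
        with pytest.warns(UserWarning, match="boundary"):
            finds, _ = count_microbleeds(make_mask(arr))
        assert finds == []

    def test_hemisphere_assignment(self, phantom_noisy):
        finds, _ = count_microbleeds(phantom_noisy.truth["microbleeds"])
        hemis = sorted(f.hemisphere for f in finds)
        assert hemis == ["left", "right", "right"]
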