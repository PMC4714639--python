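"""Multispectral fusion: ICV extraction, normalization, quantization, rules."""

import itertools

import numpy as np
import pytest

from svdquant.errors import (
    ConfigurationError,
    DegenerateContrastError,
    InclusionError,
    SegmentationError,
)
from svdquant.fusion import (
    ClusterRule,
    FusedColorVolume,
    assign_clusters,
    derive_tissue_masks,
    fuse_channels,
    normalize_channel,
    quantize_min_variance,
    segment_icv,
)
from svdquant.volumes import BinaryMask

from conftest import dice, make_grid, make_mask, make_volume


class TestSegmentICV:
    def test_phantom_head_recovery(self, phantom_noisy):
        icv = segment_icv(phantom_noisy.volumes["t2s"])
        assert dice(icv, phantom_noisy.truth["icv"]) >= 0.95

    def test_all_zero_volume_raises(self):
        with pytest.raises(SegmentationError):
            segment_icv(make_volume(np.zeros((16, 16, 8))))

    def test_idempotent_on_binary_truth(self, phantom_clean):
        truth = phantom_clean.truth["icv"]
        vol = make_volume(truth.data.astype(float),
                          spacing=truth.grid.spacing)
        out = segment_icv(vol, threshold_fraction=0.5)
        assert np.array_equal(out.data, truth.data)


class TestNormalizeChannel:
    def test_full_range_image_unchanged(self):
        rng = np.random.default_rng(0)
        data = rng.random((10, 10, 4))
        data.flat[0], data.flat[1] = 0.0, 1.0
        vol = make_volume(data)
        domain = make_mask(np.ones(data.shape))
        out = normalize_channel(vol, domain, lo_pct=0, hi_pct=100)
        np.testing.assert_allclose(out.data, data, atol=1e-12)

    def test_percentiles_map_to_unit_interval(self):
        rng = np.random.default_rng(1)
        data = rng.normal(50, 10, (12, 12, 6))
        vol = make_volume(data)
        domain = make_mask(np.ones(data.shape))
        out = normalize_channel(vol, domain)   # defaults 1-99
        p1, p99 = np.percentile(data, [1, 99])
        scaled = out.data[(data > p1 + 1e-9) & (data < p99 - 1e-9)]
        orig = data[(data > p1 + 1e-9) & (data < p99 - 1e-9)]
        np.testing.assert_allclose(scaled, (orig - p1) / (p99 - p1), atol=1e-9)
        assert out.data.min() == 0.0 and out.data.max() == 1.0

    def test_constant_image_raises(self):
        vol = make_volume(np.full((8, 8, 4), 3.0))
        with pytest.raises(DegenerateContrastError):
            normalize_channel(vol, make_mask(np.ones((8, 8, 4))))


def _three_color_fusion():
    """Domain with exactly three well-separated colors."""
    shape = (12, 12, 3)
    red = np.zeros(shape)
    green = np.zeros(shape)
    labels = np.zeros(shape, int)
    labels[:4] = 0
    labels[4:8] = 1
    labels[8:] = 2
    colors = [(0.1, 0.1), (0.5, 0.9), (0.9, 0.2)]
    for k, (r, g) in enumerate(colors):
        red[labels == k] = r
        green[labels == k] = g
    domain = make_mask(np.ones(shape))
    fused = FusedColorVolume(
        {"red": make_volume(red), "green": make_volume(green)}, domain)
    return fused, labels, colors


class TestQuantization:
    def test_three_colors_exact_partition(self):
        fused, labels, colors = _three_color_fusion()
        q = quantize_min_variance(fused, 3)
        assert q.n_levels == 3
        # each cluster must hold exactly one color (brute-force check of
        # every voxel's palette entry against its true color)
        for k, (r, g) in enumerate(colors):
            sel = labels == k
            cluster_ids = np.unique(q.labels.data[sel])
            assert len(cluster_ids) == 1
            np.testing.assert_allclose(q.palette[cluster_ids[0] - 1], (r, g),
                                       atol=1e-12)

    def test_uniform_color_warns_and_collapses(self):
        shape = (6, 6, 2)
        fused = FusedColorVolume(
            {"red": make_volume(np.full(shape, 0.5)),
             "green": make_volume(np.full(shape, 0.5))},
            make_mask(np.ones(shape)))
        with pytest.warns(UserWarning, match="distinct"):
            q = quantize_min_variance(fused, 2)
        assert q.n_levels == 1

    def test_deterministic(self, phantom_noisy):
        brain = phantom_noisy.truth["brain_tissue"]
        fused = fuse_channels(brain, red=phantom_noisy.volumes["t2s"],
                              green=phantom_noisy.volumes["flair"])
        q1 = quantize_min_variance(fused, 8)
        q2 = quantize_min_variance(fused, 8)
        assert np.array_equal(q1.labels.data, q2.labels.data)
        np.testing.assert_array_equal(q1.palette, q2.palette)

    def test_phantom_wmh_recovery_16_levels(self, phantom_noisy):
        """Criterion: the yellow clusters of the FLAIR/T2*W fusion recover
        the WMH truth at the 2%-of-range noise level."""
        ph = phantom_noisy
        fused = fuse_channels(ph.truth["brain_tissue"],
                              red=ph.volumes["t2s"], green=ph.volumes["flair"])
        q = quantize_min_variance(fused, 16)
        masks, _ = assign_clusters(
            q, [ClusterRule("wmh", {"green": (0.62, 1.0), "red": (0.30, 1.0)})])
        est = masks["wmh"] - ph.truth["index_stroke"]
        assert dice(est, ph.truth["wmh"]) >= 0.9

    def test_objective_beats_random_partition_and_near_optimal(self):
        """Total within-cluster variance is below a size-matched random
        partition and within 10% of the exhaustive optimum on a 3-color
        fixture."""
        rng = np.random.default_rng(5)
        n = 30
        colors = np.concatenate([
            rng.normal(0.2, 0.01, (n, 2)),
            rng.normal(0.5, 0.01, (n, 2)) + [0.2, -0.1],
            rng.normal(0.8, 0.01, (n, 2))])
        shape = (colors.shape[0], 1, 1)
        fused = FusedColorVolume(
            {"red": make_volume(colors[:, 0].reshape(shape)),
             "green": make_volume(colors[:, 1].reshape(shape))},
            make_mask(np.ones(shape)))
        q = quantize_min_variance(fused, 3)

        def sse_of(assign):
            tot = 0.0
            for k in np.unique(assign):
                sub = colors[assign == k]
                tot += ((sub - sub.mean(axis=0)) ** 2).sum()
            return tot

        ours = sse_of(q.labels.data.ravel())
        sizes = [int((q.labels.data == k).sum()) for k in (1, 2, 3)]
        perm = rng.permutation(len(colors))
        random_assign = np.empty(len(colors), int)
        start = 0
        for k, s in enumerate(sizes, start=1):
            random_assign[perm[start:start + s]] = k
            start += s
        assert ours <= sse_of(random_assign)
        # exhaustive optimum over contiguous splits of the 1D projection
        # (clusters this separated are linearly ordered along red)
        order = np.argsort(colors[:, 0])
        best = np.inf
        m = len(colors)
        for i, j in itertools.combinations(range(1, m), 2):
            assign = np.zeros(m, int)
            assign[order[i:j]] = 1
            assign[order[j:]] = 2
            best = min(best, sse_of(assign))
        assert ours <= 1.1 * best


class TestAssignClusters:
    def test_yellow_rule_selects_yellow_cluster(self):
        fused, labels, colors = _three_color_fusion()
        q = quantize_min_variance(fused, 3)
        rule = ClusterRule("wmh", {"red": (0.4, 1.0), "green": (0.5, 1.0)})
        masks, unassigned = assign_clusters(q, [rule])
        assert np.array_equal(masks["wmh"].data, labels == 1)
        assert len(unassigned) == 2

    def test_no_match_gives_empty_mask(self):
        fused, _, _ = _three_color_fusion()
        q = quantize_min_variance(fused, 3)
        masks, _ = assign_clusters(
            q, [ClusterRule("none", {"red": (0.99, 1.0)})])
        assert masks["none"].is_empty()

    def test_zero_thresholds_select_whole_domain(self):
        fused, _, _ = _three_color_fusion()
        q = quantize_min_variance(fused, 3)
        masks, unassigned = assign_clusters(
            q, [ClusterRule("all", {"red": (0.0, 1.0)})])
        assert np.array_equal(masks["all"].data, fused.domain_mask.data)
        assert unassigned == []

    def test_strict_overlapping_rules_raise(self):
        fused, _, _ = _three_color_fusion()
        q = quantize_min_variance(fused, 3)
        rules = [ClusterRule("a", {"red": (0.0, 1.0)}),
                 ClusterRule("b", {"green": (0.0, 1.0)})]
        with pytest.raises(ConfigurationError):
            assign_clusters(q, rules, strict=True)

    def test_rule_referencing_absent_channel_raises(self):
        fused, _, _ = _three_color_fusion()
        q = quantize_min_variance(fused, 3)
        with pytest.raises(ConfigurationError):
            assign_clusters(q, [ClusterRule("x", {"blue": (0.0, 1.0)})])


class TestDeriveTissueMasks:
    def test_liquid_equals_nonbrain(self, phantom_clean):
        t = phantom_clean.truth
        out = derive_tissue_masks(t["icv"], t["nonbrain"], t["nonbrain"])
        assert np.array_equal(out["csf"].data, t["nonbrain"].data)
        assert np.array_equal(out["brain_tissue"].data,
                              t["icv"].data & ~t["nonbrain"].data)

    def test_dural_rim_excluded_from_csf(self, phantom_clean):
        t = phantom_clean.truth
        liquid = t["csf"]          # liquid fusion finds CSF but not dura
        out = derive_tissue_masks(t["icv"], t["nonbrain"], liquid)
        assert not (out["csf"].data & t["dura"].data).any()
        assert np.array_equal(out["csf"].data, t["csf"].data)

    def test_empty_nonbrain(self, phantom_clean):
        t = phantom_clean.truth
        empty = BinaryMask(np.zeros(t["icv"].grid.shape, bool), t["icv"].grid)
        out = derive_tissue_masks(t["icv"], empty, empty)
        assert np.array_equal(out["brain_tissue"].data, t["icv"].data)
        assert out["csf"].is_empty()

    def test_nonbrain_outside_icv_raises(self, phantom_clean):
        t = phantom_clean.truth
        outside = BinaryMask(~t["icv"].data, t["icv"].grid)
        with pytest.raises(InclusionError):
            derive_tissue_masks(t["icv"], outside, outside)

    def test_brain_nonbrain_partition_of_icv(self, phantom_clean):
        t = phantom_clean.truth
        out = derive_tissue_masks(t["icv"], t["nonbrain"], t["csf"])
        brain = out["brain_tissue"]
        assert not (brain.data & t["nonbrain"].data).any()
        assert np.array_equal(brain.data | t["nonbrain"].data, t["icv"].data)
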