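"""Hotspot segmentation, connected components, volumetric metrics."""

from collections import deque

import numpy as np
import pytest

import orthospect as osp
from orthospect.frames import AnatomicFrame
from orthospect.normalization import IntensityStats

from test_normalization import make_vol


def brute_force_mask(vol, region, threshold, frame=None):
    lo, hi = region.bounds
    out = np.zeros(vol.shape, dtype=bool)
    for i in range(vol.shape[0]):
        for j in range(vol.shape[1]):
            for k in range(vol.shape[2]):
                p = vol.index_to_world([i, j, k])
                if frame is not None:
                    p = osp.world_to_anatomic(p, frame)
                inside = all(lo[d] <= p[d] < hi[d] for d in range(3))
                out[i, j, k] = inside and vol.voxels[i, j, k] >= threshold
    return out


def bfs_components(bits):
    """Independent 26-connectivity flood fill."""
    seen = np.zeros_like(bits, dtype=bool)
    sizes = []
    nbrs = [
        (di, dj, dk)
        for di in (-1, 0, 1)
        for dj in (-1, 0, 1)
        for dk in (-1, 0, 1)
        if (di, dj, dk) != (0, 0, 0)
    ]
    for start in zip(*np.nonzero(bits)):
        if seen[start]:
            continue
        q = deque([start])
        seen[start] = True
        size = 0
        while q:
            i, j, k = q.popleft()
            size += 1
            for di, dj, dk in nbrs:
                n = (i + di, j + dj, k + dk)
                if all(0 <= n[d] < bits.shape[d] for d in range(3)):
                    if bits[n] and not seen[n]:
                        seen[n] = True
                        q.append(n)
        sizes.append(size)
    return sorted(sizes, reverse=True)


class TestSelectBox:
    def test_whole_volume_box(self):
        vol = make_vol(np.ones((5, 5, 5)))
        region = osp.select_box(((-1, -1, -1), (6, 6, 6)))
        mask = osp.hotspot_mask(vol, region, 0.5)
        assert mask.count == 125

    def test_degenerate_axis_rejected(self):
        with pytest.raises(ValueError):
            osp.select_box(((0, 0, 0), (5, 0, 5)))


class TestHotspotMask:
    def test_single_hot_voxel(self):
        data = np.ones((3, 3, 3))
        data[1, 1, 1] = 10.0
        vol = make_vol(data)
        region = osp.select_box(((-1, -1, -1), (4, 4, 4)))
        mask = osp.hotspot_mask(vol, region, 5.0)
        assert mask.count == 1
        assert mask.bits[1, 1, 1]

    def test_threshold_above_max_gives_empty_mask(self):
        vol = make_vol(np.ones((3, 3, 3)))
        region = osp.select_box(((-1, -1, -1), (4, 4, 4)))
        assert osp.hotspot_mask(vol, region, 2.0).count == 0

    def test_matches_brute_force_oracle(self, rng):
        for trial in range(10):
            shape = tuple(rng.integers(3, 11, 3))
            vol = make_vol(rng.poisson(20, shape), spacing=rng.uniform(0.5, 2, 3))
            frame = None
            tag = "world"
            if trial % 2:
                frame = AnatomicFrame(
                    rng.normal(0, 2, 3), osp.rotation_about(rng.normal(size=3), 40.0)
                )
                tag = "femoral"
            lo = rng.normal(-1, 1, 3)
            region = osp.ReferenceRegion((lo, lo + rng.uniform(3, 10, 3)), frame_tag=tag)
            thr = float(rng.uniform(10, 30))
            expected = brute_force_mask(vol, region, thr, frame)
            if not expected.any() and not brute_force_mask(vol, region, -1e9, frame).any():
                with pytest.raises(ValueError):
                    osp.hotspot_mask(vol, region, thr, frame)
                continue
            got = osp.hotspot_mask(vol, region, thr, frame)
            assert np.array_equal(got.bits, expected)

    def test_monotone_in_threshold(self, rng):
        vol = make_vol(rng.poisson(20, (8, 8, 8)))
        region = osp.select_box(((-1, -1, -1), (9, 9, 9)))
        counts = [osp.hotspot_mask(vol, region, t).count for t in (0, 10, 20, 30, 50)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestMaxFractionThreshold:
    @pytest.mark.parametrize("fraction, expected", [(0.9, 900.0), (0.6, 600.0)])
    def test_fraction_of_max(self, fraction, expected):
        data = np.ones((4, 4, 4))
        data[0, 0, 0] = 1000.0
        assert osp.max_fraction_threshold(make_vol(data), fraction) == expected

    def test_fraction_one_keeps_only_max_voxels(self):
        data = np.ones((4, 4, 4))
        data[2, 2, 2] = 500.0
        vol = make_vol(data)
        thr = osp.max_fraction_threshold(vol, 1.0)
        region = osp.select_box(((-1, -1, -1), (5, 5, 5)))
        mask = osp.hotspot_mask(vol, region, thr)
        assert mask.count == 1

    @pytest.mark.parametrize("fraction", [0.0, 1.5, -0.2])
    def test_invalid_fraction_rejected(self, fraction):
        with pytest.raises(ValueError):
            osp.max_fraction_threshold(make_vol(np.ones((2, 2, 2))), fraction)


class TestConnectedComponents:
    def test_two_disjoint_blocks(self):
        bits = np.zeros((8, 8, 8), dtype=bool)
        bits[0:2, 0:2, 0:2] = True
        bits[5:7, 5:7, 5:7] = True
        labels, sizes = osp.connected_components(osp.VoxelMask(bits, np.eye(4)))
        assert sizes == [8, 8]
        assert labels.max() == 2
        assert labels[0, 0, 0] == 1  # tie broken by smallest linear index

    def test_empty_mask(self):
        labels, sizes = osp.connected_components(
            osp.VoxelMask(np.zeros((4, 4, 4), dtype=bool), np.eye(4))
        )
        assert sizes == []
        assert labels.max() == 0

    def test_matches_flood_fill_oracle(self, rng):
        for _ in range(10):
            bits = rng.random((9, 9, 9)) < 0.18
            _, sizes = osp.connected_components(osp.VoxelMask(bits, np.eye(4)))
            assert sizes == bfs_components(bits)


class TestHotspotMetrics:
    def _model(self, mean=1.0):
        ref = IntensityStats(n=100, mean=mean, sd=0.1 * mean, min=0, max=2 * mean)
        return osp.NormalizationModel("scale_by_mean", ref), ref

    def test_volume_from_count_and_spacing(self):
        data = np.zeros((5, 5, 5))
        data[0, 0, :5] = 9.0
        data[1, 1, :5] = 9.0
        vol = make_vol(data, spacing=(2, 2, 2))
        region = osp.select_box(((-2, -2, -2), (20, 20, 20)))
        mask = osp.hotspot_mask(vol, region, 5.0)
        model, ref = self._model()
        m = osp.hotspot_metrics(vol, mask, model, AnatomicFrame.identity(), ref)
        assert m.voxel_count == 10
        assert m.volume_mm3 == pytest.approx(80.0)
        assert m.volume_ml == pytest.approx(0.08)

    def test_symmetric_mask_centroid_at_origin(self):
        data = np.zeros((5, 5, 5))
        data[1:4, 1:4, 1:4] = 7.0
        vol = make_vol(data, origin=(-2, -2, -2))  # symmetric about world 0
        region = osp.select_box(((-3, -3, -3), (3, 3, 3)))
        mask = osp.hotspot_mask(vol, region, 5.0)
        model, ref = self._model()
        m = osp.hotspot_metrics(vol, mask, model, AnatomicFrame.identity(), ref)
        assert np.allclose(m.centroid_anatomic, (0, 0, 0), atol=1e-9)

    def test_empty_mask_flagged_undefined(self):
        vol = make_vol(np.ones((3, 3, 3)))
        mask = osp.VoxelMask(np.zeros((3, 3, 3), dtype=bool), vol.affine)
        model, ref = self._model()
        m = osp.hotspot_metrics(vol, mask, model, AnatomicFrame.identity(), ref)
        assert not m.defined
        assert m.voxel_count == 0
        assert m.max_ratio is None and m.mean_ratio is None

    def test_max_ratio_bounds_mean_ratio(self, rng):
        vol = make_vol(rng.poisson(40, (8, 8, 8)))
        region = osp.select_box(((-1, -1, -1), (9, 9, 9)))
        mask = osp.hotspot_mask(vol, region, 35.0)
        model, ref = self._model(mean=40.0)
        m = osp.hotspot_metrics(vol, mask, model, AnatomicFrame.identity(), ref)
        assert m.max_ratio >= m.mean_ratio

    def test_phantom_ratio_and_volume_recovery(self, noiseless_phantom, ref_region, roi_region):
        """On a noiseless ratio-4 phantom, the mean ratio lies in [3, 4] and
        the segmented volume is within a surface shell of the true ellipsoid."""
        ph, spec = noiseless_phantom
        fem = ph["truth"].femoral_frame
        ref = osp.region_stats(ph["spect"], ref_region, fem)
        model = osp.NormalizationModel("scale_by_mean", ref)
        thr = osp.threshold_from_model(model, {"k_times_mean": 3.0})
        mask = osp.hotspot_mask(ph["spect"], roi_region, thr, fem)
        m = osp.hotspot_metrics(ph["spect"], mask, model, fem, ref, threshold_raw=thr)
        assert 3.0 <= m.mean_ratio <= 4.0
        true_vol = spec.hotspots[0].true_volume_mm3
        a, b, c = spec.hotspots[0].semi_axes
        p = 1.6075  # Thomsen ellipsoid surface approximation
        area = 4 * np.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3) ** (1 / p)
        shell = area * max(ph["spect"].spacing)
        assert abs(m.volume_mm3 - true_vol) < shell
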