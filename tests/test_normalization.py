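"""Reference-region statistics, normalisation modes, thresholds, Welch test."""

import numpy as np
import pytest

import orthospect as osp
from orthospect.frames import AnatomicFrame
from orthospect.normalization import IntensityStats


def brute_force_region_stats(vol, region, frame=None):
    """Per-voxel loop oracle for region membership and statistics."""
    values = []
    lo, hi = region.bounds
    for i in range(vol.shape[0]):
        for j in range(vol.shape[1]):
            for k in range(vol.shape[2]):
                p = vol.index_to_world([i, j, k])
                if frame is not None:
                    p = osp.world_to_anatomic(p, frame)
                if all(lo[d] <= p[d] < hi[d] for d in range(3)):
                    values.append(float(vol.voxels[i, j, k]))
    return values


def make_vol(data, spacing=(1, 1, 1), origin=(0, 0, 0), modality="SPECT"):
    A = np.diag([*spacing, 1.0]).astype(float)
    A[:3, 3] = origin
    return osp.ImageVolume(np.asarray(data, dtype=float), A, modality=modality)


class TestRegionStats:
    def test_constant_field(self):
        vol = make_vol(np.full((12, 12, 12), 7.0))
        region = osp.ReferenceRegion(((0, 0, 0), (10, 10, 10)))
        s = osp.region_stats(vol, region)
        assert (s.n, s.mean, s.sd) == (1000, 7.0, 0.0)

    def test_eight_voxel_box(self):
        vol = make_vol(np.arange(1.0, 9.0).reshape(2, 2, 2))
        region = osp.ReferenceRegion(((-0.5, -0.5, -0.5), (1.5, 1.5, 1.5)))
        s = osp.region_stats(vol, region)
        assert s.n == 8
        assert s.mean == 4.5
        assert s.sd == pytest.approx(np.sqrt(6.0), abs=1e-12)
        assert int(s.hist_counts.sum()) == 8

    def test_box_outside_volume_rejected(self):
        vol = make_vol(np.ones((4, 4, 4)))
        region = osp.ReferenceRegion(((100, 100, 100), (110, 110, 110)))
        with pytest.raises(ValueError):
            osp.region_stats(vol, region)

    def test_missing_frame_rejected(self):
        vol = make_vol(np.ones((4, 4, 4)))
        region = osp.ReferenceRegion(((0, 0, 0), (2, 2, 2)), frame_tag="femoral")
        with pytest.raises(ValueError):
            osp.region_stats(vol, region, frame=None)

    def test_matches_brute_force_oracle(self, rng):
        """Vectorised membership equals a triple loop, including under an
        oblique frame."""
        for trial in range(10):
            shape = tuple(rng.integers(3, 12, 3))
            vol = make_vol(rng.poisson(50, shape), spacing=rng.uniform(0.5, 3, 3),
                           origin=rng.normal(0, 5, 3))
            frame = None
            tag = "world"
            if trial % 2:
                frame = AnatomicFrame(rng.normal(0, 3, 3), osp.rotation_about(rng.normal(size=3), 25.0))
                tag = "femoral"
            lo = rng.normal(0, 2, 3)
            region = osp.ReferenceRegion((lo, lo + rng.uniform(2, 12, 3)), frame_tag=tag)
            expected = brute_force_region_stats(vol, region, frame)
            if not expected:
                with pytest.raises(ValueError):
                    osp.region_stats(vol, region, frame)
                continue
            s = osp.region_stats(vol, region, frame)
            assert s.n == len(expected)
            assert s.mean == pytest.approx(np.mean(expected), abs=1e-12)
            if s.n >= 2:
                assert s.sd == pytest.approx(np.std(expected, ddof=1), abs=1e-12)


class TestNormalize:
    def ref(self, mean, sd=1.0, n=100):
        return IntensityStats(n=n, mean=mean, sd=sd, min=0.0, max=mean * 2)

    def test_scale_by_mean_gives_uptake_ratio(self):
        model = osp.NormalizationModel("scale_by_mean", self.ref(200.0))
        assert osp.normalize(910.0, model) == pytest.approx(4.55)

    @pytest.mark.parametrize(
        "mode, expected", [("scale_by_mean", 1.0), ("offset_by_mean", 0.0), ("zscore", 0.0)]
    )
    def test_reference_mean_maps_to_identity_value(self, mode, expected):
        model = osp.NormalizationModel(mode, self.ref(150.0, sd=10.0))
        assert osp.normalize(150.0, model) == expected

    def test_self_normalisation_property(self, rng):
        """After scale-by-mean normalising a volume, the reference region's
        mean is exactly 1."""
        vol = make_vol(rng.poisson(80, (10, 10, 10)).astype(float))
        region = osp.ReferenceRegion(((0, 0, 0), (8, 8, 8)))
        ref = osp.region_stats(vol, region)
        model = osp.NormalizationModel("scale_by_mean", ref)
        normed = osp.normalize(vol, model)
        assert osp.region_stats(normed, region).mean == pytest.approx(1.0, abs=1e-12)

    def test_invalid_models_rejected(self):
        with pytest.raises(ValueError):
            osp.NormalizationModel("scale_by_mean", self.ref(0.0))
        with pytest.raises(ValueError):
            osp.NormalizationModel("zscore", self.ref(10.0, sd=0.0))


class TestThresholdRules:
    def ref(self, mean, sd):
        return IntensityStats(n=50, mean=mean, sd=sd, min=0, max=mean * 2)

    @pytest.mark.parametrize(
        "rule, mean, sd, expected",
        [
            ({"k_times_mean": 3.0}, 200.0, 5.0, 600.0),
            ({"k_times_mean": 4.0}, 200.0, 5.0, 800.0),
            ({"n_sd": 2.0}, 100.0, 20.0, 140.0),
        ],
    )
    def test_rules(self, rule, mean, sd, expected):
        model = osp.NormalizationModel("scale_by_mean", self.ref(mean, sd))
        assert osp.threshold_from_model(model, rule) == expected

    def test_monotone_in_k_and_n(self):
        model = osp.NormalizationModel("scale_by_mean", self.ref(120.0, 30.0))
        ks = [osp.threshold_from_model(model, {"k_times_mean": k}) for k in (1, 2, 3, 4, 6)]
        ns = [osp.threshold_from_model(model, {"n_sd": n}) for n in (0, 1, 2, 5)]
        assert all(a < b for a, b in zip(ks, ks[1:]))
        assert all(a < b for a, b in zip(ns, ns[1:]))

    def test_bad_rule_rejected(self):
        model = osp.NormalizationModel("scale_by_mean", self.ref(100.0, 10.0))
        with pytest.raises(ValueError):
            osp.threshold_from_model(model, {"k_times_mean": -1})
        with pytest.raises(ValueError):
            osp.threshold_from_model(model, {"quantile": 0.9})


class TestWelchTest:
    def test_identical_samples_null(self):
        s = IntensityStats(n=10, mean=5.0, sd=1.0, min=3, max=7)
        r = osp.hotspot_vs_reference_test(s, s)
        assert r["t"] == 0.0
        assert r["p"] == pytest.approx(1.0)

    def test_hand_computed_welch_value(self):
        hot = IntensityStats(n=4, mean=10.0, sd=2.0, min=7, max=13)
        ref = IntensityStats(n=100, mean=2.0, sd=1.0, min=0, max=5)
        r = osp.hotspot_vs_reference_test(hot, ref)
        assert r["t"] == pytest.approx(8.0 / np.sqrt(4.0 / 4.0 + 1.0 / 100.0), abs=1e-9)
        assert 0 < r["p"] < 0.05

    def test_matches_scipy_on_raw_samples(self, rng):
        from scipy import stats as sps

        a = rng.normal(10, 2, 40)
        b = rng.normal(8, 3, 60)
        r = osp.hotspot_vs_reference_test(
            IntensityStats.from_values(a), IntensityStats.from_values(b)
        )
        t_ref, p_ref = sps.ttest_ind(a, b, equal_var=False)
        assert r["t"] == pytest.approx(t_ref, abs=1e-9)
        assert r["p"] == pytest.approx(p_ref, abs=1e-9)

    def test_tiny_samples_rejected(self):
        good = IntensityStats(n=10, mean=2.0, sd=1.0, min=0, max=4)
        bad = IntensityStats(n=1, mean=9.0, sd=0.0, min=9, max=9)
        with pytest.raises(ValueError):
            osp.hotspot_vs_reference_test(bad, good)


class TestHistogramTriplet:
    def test_equal_regions_give_equal_histograms(self, rng):
        vol = make_vol(rng.poisson(30, (10, 10, 10)).astype(float))
        region = osp.ReferenceRegion(((1, 1, 1), (6, 6, 6)))
        h = osp.histogram_triplet(vol, region, region)
        assert np.array_equal(h["saved"], h["local"])

    def test_roi_covering_volume_equals_global(self, rng):
        vol = make_vol(rng.poisson(30, (8, 8, 8)).astype(float))
        whole = osp.ReferenceRegion(((-1, -1, -1), (9, 9, 9)))
        small = osp.ReferenceRegion(((2, 2, 2), (5, 5, 5)))
        h = osp.histogram_triplet(vol, small, whole)
        assert np.array_equal(h["local"], h["global"])
        assert int(h["global"].sum()) == vol.voxels.size

    def test_hotspot_mass_above_threshold(self, noiseless_phantom, ref_region, roi_region):
        """With a ratio-4 hotspot, the ROI histogram has mass above 3x the
        reference mean; the reference histogram has none."""
        ph, _ = noiseless_phantom
        fem = ph["truth"].femoral_frame
        h = osp.histogram_triplet(ph["spect"], ref_region, roi_region, fem)
        edges = h["edges"]
        cut = 3.0 * 100.0
        above = edges[:-1] >= cut
        assert h["local"][above].sum() > h["saved"][above].sum()
        assert h["saved"][above].sum() == 0
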