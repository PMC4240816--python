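"""Contour pairing, profile sampling, and the 20-80% transition metric."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvmra import (
    ContourPair,
    ImageVolume,
    PlaneRef,
    SegmentRejected,
    SharpnessError,
    make_pv_phantom,
    pair_contours,
    pv_sharpness,
    sample_profile,
    transition_length,
)
from pvmra.sharpness import ProfileSegment, Segment
from conftest import coarse_tube_spec


def _circle(r, n=360, center=(0.0, 0.0)):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.stack([center[0] + r * np.cos(t), center[1] + r * np.sin(t)], axis=1)


def _profile(samples, step=0.1):
    seg = Segment(np.array([0.0, 0.0]), np.array([1.0, 0.0]), PlaneRef(0, 0))
    return ProfileSegment(seg, np.asarray(samples, float), step_mm=step)


class TestPairContours:
    def test_concentric_circles_give_radial_segments(self):
        pair = ContourPair("pv", _circle(8.0), _circle(10.0), PlaneRef(0, 0))
        segments = pair_contours(pair)
        lengths = np.array([s.length_mm for s in segments])
        assert len(segments) == 360
        np.testing.assert_allclose(lengths, 2.0, atol=0.01)

    def test_identical_polylines_all_discarded(self):
        poly = _circle(5.0, n=12)
        pair = ContourPair("pv", poly, poly.copy(), PlaneRef(0, 0))
        assert pair_contours(pair) == []

    def test_square_pairs_to_nearest_of_three_inner_vertices(self):
        outer = np.array([[-5, -5], [5, -5], [5, 5], [-5, 5]], float)
        inner = np.array([[0.0, 0.5], [-0.5, -0.5], [0.5, -0.5]])
        pair = ContourPair("pv", inner, outer, PlaneRef(0, 0))
        segments = pair_contours(pair)
        inner_pts = {tuple(s.inner_mm) for s in segments}
        assert inner_pts <= set(map(tuple, inner))

    def test_fewer_than_three_vertices_rejected(self):
        with pytest.raises(ValueError, match="3 vertices"):
            ContourPair("pv", _circle(1.0, n=2), _circle(2.0), PlaneRef(0, 0))


class TestSampleProfile:
    @pytest.fixture()
    def flat_volume(self):
        return ImageVolume(np.full((8, 32, 32), 7.0), spacing_mm=1.0)

    def test_constant_image_gives_constant_profile(self, flat_volume):
        seg = Segment(np.array([5.0, 5.0]), np.array([15.0, 15.0]), PlaneRef(0, 4))
        prof = sample_profile(flat_volume, seg, extension_mm=1.0)
        np.testing.assert_allclose(prof.samples, 7.0)

    def test_two_mm_segment_has_21_samples(self, flat_volume):
        seg = Segment(np.array([5.0, 5.0]), np.array([7.0, 5.0]), PlaneRef(0, 4))
        prof = sample_profile(flat_volume, seg, extension_mm=0.0)
        assert prof.samples.size == 21

    def test_samples_at_voxel_centers_equal_voxel_values(self):
        rng = np.random.default_rng(0)
        data = rng.random((8, 32, 32))
        vol = ImageVolume(data, spacing_mm=1.0)
        # voxel centers along row y-index 10: y = 10.5 mm, z = (k + 0.5) mm
        seg = Segment(np.array([10.5, 20.5]), np.array([10.5, 10.5]), PlaneRef(0, 3))
        prof = sample_profile(vol, seg, extension_mm=0.0)
        sampled = prof.samples[::10]  # every 1 mm = every voxel center
        expect = data[3, 10, 20:9:-1]
        np.testing.assert_allclose(sampled, expect, atol=1e-12)

    def test_out_of_bounds_segment_is_an_error(self, flat_volume):
        seg = Segment(np.array([-10.0, 5.0]), np.array([5.0, 5.0]), PlaneRef(0, 4), "pv", 3)
        with pytest.raises(ValueError, match="pv#3"):
            sample_profile(flat_volume, seg, extension_mm=1.0)


class TestTransitionLength:
    @pytest.mark.parametrize("w", [1.0, 2.0, 3.0])
    def test_linear_ramp_transition_is_point6_w(self, w):
        """A linear edge of width w has 20-80% transition length 0.6 w."""
        x = np.arange(0, w + 2.0001, 0.1)  # outer -> inner, rising
        samples = np.clip((x - 1.0) / w, 0, 1) * 100.0
        L = transition_length(_profile(samples))
        assert L == pytest.approx(0.6 * w, rel=1e-9)

    def test_ideal_step_transition_below_sample_spacing(self):
        samples = np.array([0.0] * 10 + [100.0] * 10)  # outer->inner step
        L = transition_length(_profile(samples))
        assert L <= 0.1
        assert 1.0 / L >= 10.0

    def test_threshold_definitions(self):
        prof = _profile(np.linspace(100.0, 0.0, 41)[::-1])
        transition_length(prof)
        assert prof.I_min == 0.0 and prof.I_max == 100.0
        assert prof.T_min == pytest.approx(20.0)
        assert prof.T_max == pytest.approx(80.0)

    def test_flat_profile_rejected(self):
        with pytest.raises(SegmentRejected, match="flat"):
            transition_length(_profile(np.full(30, 5.0)), min_range=1.0)

    def test_profile_without_outward_decay_rejected(self):
        # intensity rises walking outward: no falling 80->20 transition
        samples = np.linspace(100.0, 0.0, 41)  # outer high, inner low
        with pytest.raises(SegmentRejected, match="no_transition"):
            transition_length(_profile(samples))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        scale=st.floats(0.01, 100.0),
        offset=st.floats(-50.0, 50.0),
        seed=st.integers(0, 1000),
    )
    def test_invariant_under_affine_intensity_rescaling(self, scale, offset, seed):
        rng = np.random.default_rng(seed)
        base = np.clip(np.linspace(-0.5, 1.5, 41), 0, 1) * 100.0
        base = base + rng.normal(0, 3.0, base.size)
        try:
            L0 = transition_length(_profile(base))
        except SegmentRejected:
            return
        L1 = transition_length(_profile(scale * base + offset))
        assert L1 == pytest.approx(L0, rel=1e-9)


class TestPvSharpness:
    def test_wider_edge_is_less_sharp(self):
        means = {}
        for w in (2.0, 3.0):
            vol, contours = make_pv_phantom(coarse_tube_spec(edge_width_mm=w))
            means[w] = pv_sharpness(vol, contours)[0].mean
        assert means[3.0] < means[2.0]

    def test_identical_vessels_identical_means(self, slab_phantom):
        vol, contours = slab_phantom
        # left_superior and right_superior share radius and edge width
        res = {r.vessel: r.mean for r in pv_sharpness(vol, contours)}
        assert res["left_superior"] == pytest.approx(res["right_superior"], rel=1e-6)

    def test_gaussian_blur_monotonically_degrades_sharpness(self):
        from pvmra import directional_gaussian_blur

        vol, contours = make_pv_phantom(coarse_tube_spec(edge_width_mm=2.0))
        values = []
        for fwhm in (0.0, 3.0, 6.0):
            data = directional_gaussian_blur(vol.data, 1.5, (0, 1, 0), fwhm)
            values.append(pv_sharpness(ImageVolume(data, 1.5), contours)[0].mean)
        assert values[0] >= values[1] >= values[2]
        assert values[2] < values[0]

    def test_constant_image_rejects_vessel(self, slab_phantom):
        _, contours = slab_phantom
        flat = ImageVolume(np.full((8, 128, 48), 5.0), spacing_mm=1.5)
        with pytest.raises(SharpnessError):
            pv_sharpness(flat, contours)

    def test_csv_report_round_trip(self, slab_phantom, tmp_path):
        import pandas as pd

        vol, contours = slab_phantom
        from pvmra.sharpness import results_to_csv

        results = pv_sharpness(vol, contours)
        results_to_csv(results, tmp_path / "sharp.csv")
        df = pd.read_csv(tmp_path / "sharp.csv")
        assert list(df["vessel"]) == [r.vessel for r in results]
        np.testing.assert_allclose(
            df["mean_sharpness_mm^-1"], [r.mean for r in results]
        )
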