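"""Detection pipeline: MIP, tracking, bb' geometry, xbar, classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spinsense import detection as det, phantom as ph
from spinsense.optics import IntensityImage
from spinsense.stack_io import MultiPlaneStack


def _stack(arrs):
    arrs = np.asarray(arrs, dtype=float)
    return MultiPlaneStack(intensities=arrs, z_positions=np.arange(len(arrs), dtype=float),
                           t_start=0.0, stack_index=0)


class TestMip:
    def test_single_plane_is_identity(self):
        a = np.random.default_rng(1).random((5, 5))
        assert np.array_equal(det.mip(_stack([a])).values, a)

    def test_elementwise_maximum(self):
        a = [[1, 5], [3, 0]]
        b = [[4, 2], [1, 7]]
        assert np.array_equal(det.mip(_stack([a, b])).values, [[4, 5], [3, 7]])

    def test_constant_planes(self):
        planes = [np.full((3, 3), c) for c in (0.2, 0.9, 0.5)]
        assert np.allclose(det.mip(_stack(planes)).values, 0.9)


class TestTrackHead:
    @staticmethod
    def _ellipse(cx, cy, phi, a=10.0, b=4.0, shape=(80, 80)):
        yy, xx = np.mgrid[: shape[0], : shape[1]]
        c, s = np.cos(phi), np.sin(phi)
        u = (xx - cx) * c + (yy - cy) * s
        v = -(xx - cx) * s + (yy - cy) * c
        img = np.ones(shape)
        img[(u / a) ** 2 + (v / b) ** 2 <= 1.0] = 1.5
        return IntensityImage(img)

    @pytest.mark.parametrize("cx,cy,phi", [(40.0, 40.0, 0.0), (30.0, 50.0, 0.7),
                                           (45.0, 35.0, 2.4)])
    def test_recovers_centre_and_orientation(self, cx, cy, phi):
        pose = det.track_head(self._ellipse(cx, cy, phi))
        assert abs(pose.a[0] - cx) < 0.5 and abs(pose.a[1] - cy) < 0.5
        d = abs((pose.phi - phi + np.pi / 2) % np.pi - np.pi / 2)
        assert np.degrees(d) < 2.0

    def test_rotating_image_rotates_phi(self):
        img = self._ellipse(40.0, 40.0, 0.3)
        pose = det.track_head(img)
        rot = det.track_head(IntensityImage(np.rot90(img.values).copy()))
        d = abs((rot.phi - pose.phi - np.pi / 2 + np.pi / 2) % np.pi - np.pi / 2)
        assert np.degrees(d) < 2.0

    def test_blank_image_raises_tracking_lost(self):
        with pytest.raises(det.TrackingLostError):
            det.track_head(IntensityImage(np.ones((40, 40))), frame_index=7)


class TestProfileGeometry:
    def test_hand_constructed_case(self):
        # centre at origin, tip toward +x, L=3, w=2, 1 um/px:
        # intersection at (1, 0); b/b' at (1, +-2) with b' on the tip-to-tail
        # observer's right
        pose = det.HeadPose2D(a=(0.0, 0.0), phi=0.0, tip_sign=1)
        geom = det.build_profile_geometry(pose, 3.0, 2.0, 16, 1.0)
        assert np.allclose(geom.intersection, [1.0, 0.0])
        assert np.allclose(geom.b, [1.0, 2.0])
        assert np.allclose(geom.bprime, [1.0, -2.0])

    def test_rotation_preserves_distances(self):
        for ang in (0.0, 0.9, 2.2, 4.0):
            pose = det.HeadPose2D(a=(5.0, 5.0), phi=ang % np.pi,
                                  tip_sign=1 if ang < np.pi else -1)
            geom = det.build_profile_geometry(pose, 3.0, 2.0, 16, 1.0)
            assert np.linalg.norm(geom.b - geom.bprime) == pytest.approx(4.0)
            assert np.linalg.norm(geom.intersection - np.array([5.0, 5.0])) == pytest.approx(1.0)

    def test_flipping_tip_sign_swaps_b_and_bprime(self):
        p1 = det.HeadPose2D(a=(0.0, 0.0), phi=0.3, tip_sign=1)
        p2 = det.HeadPose2D(a=(0.0, 0.0), phi=0.3, tip_sign=-1)
        g1 = det.build_profile_geometry(p1, 3.0, 2.0, 8, 1.0)
        g2 = det.build_profile_geometry(p2, 3.0, 2.0, 8, 1.0)
        assert np.allclose(g1.b - g1.intersection, -(g2.b - g2.intersection))

    def test_invalid_lengths_rejected(self):
        pose = det.HeadPose2D(a=(0.0, 0.0), phi=0.0, tip_sign=1)
        with pytest.raises(ValueError):
            det.build_profile_geometry(pose, -1.0, 2.0, 8, 1.0)
        with pytest.raises(ValueError):
            det.build_profile_geometry(pose, 3.0, 0.0, 8, 1.0)


class TestSampleProfile:
    def test_constant_image_gives_constant_profile(self):
        img = IntensityImage(np.full((40, 40), 0.7))
        pose = det.HeadPose2D(a=(20.0, 20.0), phi=0.0, tip_sign=1)
        geom = det.build_profile_geometry(pose, 6.0, 3.0, 32, 1.0)
        prof = det.sample_profile(img, geom)
        assert np.allclose(prof.values, 0.7)

    def test_linear_ramp_samples_linearly(self):
        yy = np.mgrid[0:40, 0:40][0].astype(float)
        img = IntensityImage(yy)
        pose = det.HeadPose2D(a=(20.0, 20.0), phi=0.0, tip_sign=1)  # bb' along y
        geom = det.build_profile_geometry(pose, 6.0, 5.0, 21, 1.0)
        prof = det.sample_profile(img, geom)
        assert np.allclose(np.diff(prof.values), np.diff(prof.values)[0], atol=1e-9)

    def test_bright_spot_lands_at_expected_position(self):
        img = np.ones((40, 40))
        img[26, 22] = 3.0
        pose = det.HeadPose2D(a=(20.0, 20.0), phi=0.0, tip_sign=1)
        geom = det.build_profile_geometry(pose, 6.0, 6.0, 25, 1.0)
        # tip at +x: segment runs from b=(22, 26) to b'=(22, 14); the spot
        # sits exactly at the b end
        assert np.allclose(geom.b, [22.0, 26.0])
        prof = det.sample_profile(IntensityImage(img), geom)
        s_star = np.argmax(prof.values) / 24.0
        assert s_star <= 1.0 / 24.0 + 1e-9

    def test_fully_outside_segment_rejected(self):
        img = IntensityImage(np.ones((20, 20)))
        pose = det.HeadPose2D(a=(100.0, 100.0), phi=0.0, tip_sign=1)
        geom = det.build_profile_geometry(pose, 6.0, 3.0, 8, 1.0)
        with pytest.raises(ValueError):
            det.sample_profile(img, geom)


class TestWeightedAverage:
    def test_uniform_profile_is_centred(self):
        prof = det.IntensityProfile(np.ones(32), np.linspace(0, 1, 32))
        assert det.weighted_average_position(prof) == pytest.approx(0.5)

    def test_delta_at_bprime(self):
        v = np.zeros(16)
        v[-1] = 2.0
        prof = det.IntensityProfile(v, np.linspace(0, 1, 16))
        assert det.weighted_average_position(prof) == pytest.approx(1.0)

    def test_hand_computed_four_samples(self):
        prof = det.IntensityProfile(np.array([1.0, 2.0, 3.0, 4.0]), np.linspace(0, 1, 4))
        assert det.weighted_average_position(prof) == pytest.approx(2.0 / 3.0, abs=1e-4)

    def test_all_zero_profile_is_undefined(self):
        prof = det.IntensityProfile(np.zeros(8), np.linspace(0, 1, 8))
        with pytest.raises(det.UndefinedProfileError):
            det.weighted_average_position(prof)

    @given(st.lists(st.floats(0.01, 10.0), min_size=4, max_size=32),
           st.floats(0.1, 50.0))
    @settings(max_examples=40, deadline=None)
    def test_offset_pulls_xbar_toward_centre(self, values, offset):
        v = np.asarray(values)
        prof = det.IntensityProfile(v, np.linspace(0, 1, len(v)))
        x0 = det.weighted_average_position(prof)
        x1 = det.weighted_average_position(
            det.IntensityProfile(v + offset, np.linspace(0, 1, len(v)))
        )
        assert 0.0 <= x1 <= 1.0
        assert abs(x1 - 0.5) <= abs(x0 - 0.5) + 1e-12


class TestClassifyRotation:
    @staticmethod
    def _sawtooth(n_cycles=5, n_per=10, lo=0.2, hi=0.8, rising=True):
        ramp = np.linspace(lo, hi, n_per)
        x = np.tile(ramp if rising else ramp[::-1], n_cycles)
        t = np.arange(len(x)) / 80.0
        return det.RotationTrace(x, t)

    def test_rising_sawtooth_is_ccw(self):
        call = det.classify_rotation(self._sawtooth(rising=True))
        assert call.direction == "ccw"
        assert call.confidence > 0.9
        assert call.n_halfcycles >= 4

    def test_falling_sawtooth_is_cw(self):
        call = det.classify_rotation(self._sawtooth(rising=False))
        assert call.direction == "cw"
        assert call.confidence > 0.9

    def test_flat_noisy_trace_is_non_rotating(self, rng):
        x = 0.5 + 0.01 * rng.standard_normal(60)
        call = det.classify_rotation(det.RotationTrace(np.clip(x, 0, 1), np.arange(60) / 80.0))
        assert call.direction == "non-rotating"

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            det.classify_rotation(det.RotationTrace(np.full(3, 0.5), np.arange(3) / 80.0))

    def test_frequency_estimate_matches_cycle_count(self):
        call = det.classify_rotation(self._sawtooth(n_cycles=6, n_per=10))
        duration = 60 / 80.0
        assert call.frequency_hz == pytest.approx(6 / (2 * duration), rel=0.35)


class TestProfileDriftLag:
    def test_moving_pattern_gives_signed_lag(self):
        base = np.zeros(64)
        base[20:26] = 1.0
        fwd = [det.IntensityProfile(np.roll(base, 3 * k), np.linspace(0, 1, 64))
               for k in range(5)]
        bwd = [det.IntensityProfile(np.roll(base, -3 * k), np.linspace(0, 1, 64))
               for k in range(5)]
        assert det.profile_drift_lag(fwd) == pytest.approx(3.0)
        assert det.profile_drift_lag(bwd) == pytest.approx(-3.0)

    def test_static_pattern_has_zero_lag(self):
        profs = [det.IntensityProfile(np.linspace(0, 1, 64) ** 2, np.linspace(0, 1, 64))
                 for _ in range(4)]
        assert det.profile_drift_lag(profs) == 0.0


class TestKymograph:
    def test_shape_and_orientation(self):
        profiles = [det.IntensityProfile(np.arange(8, dtype=float),
                                         np.linspace(0, 1, 8), t=i) for i in range(5)]
        kym = det.kymograph(profiles)
        assert kym.shape == (8, 5)
        # b (position 0) at the bottom row
        assert kym[-1, 0] == 0.0 and kym[0, 0] == 7.0

    def test_ragged_profiles_rejected(self):
        profiles = [det.IntensityProfile(np.ones(8), np.linspace(0, 1, 8)),
                    det.IntensityProfile(np.ones(9), np.linspace(0, 1, 9))]
        with pytest.raises(ValueError):
            det.kymograph(profiles)


class TestEndToEnd:
    def test_ccw_phantom_is_called_ccw(self, ccw_series):
        series, gt = ccw_series
        res = det.analyze_series(series)
        assert res.call.direction == "ccw"
        assert res.call.confidence > 0.6
        assert np.all((res.trace.xbar >= 0) & (res.trace.xbar <= 1))

    def test_mirrored_series_flips_the_call(self, ccw_series):
        series, _ = ccw_series
        from spinsense.stack_io import MultiPlaneStack, StackSeries

        mirrored = StackSeries(
            stacks=[MultiPlaneStack(s.intensities[:, :, ::-1].copy(), s.z_positions,
                                    s.t_start, s.stack_index) for s in series.stacks],
            config=series.config, provenance=dict(series.provenance),
        )
        assert det.analyze_series(mirrored).call.direction == "cw"
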