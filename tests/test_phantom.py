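"""Synthetic acquisition: scan timing, kinematics, rendering, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spinsense import phantom as ph


class TestAcquisitionConfig:
    def test_canonical_plane_arithmetic(self):
        cfg = ph.AcquisitionConfig()
        assert cfg.planes_per_rising_slope == 50
        assert cfg.plane_spacing_um == pytest.approx(0.4)

    def test_non_integer_plane_count_rejected(self):
        with pytest.raises(ph.ConfigError):
            ph.AcquisitionConfig(fps=8000.0, scan_hz=75.0)

    def test_frame_and_stack_counts(self):
        cfg = ph.AcquisitionConfig(duration_s=0.5)
        assert cfg.n_frames == 4000
        assert cfg.n_stacks == 40


class TestTriangularScan:
    def test_origin_is_rising_plane_zero(self):
        cfg = ph.AcquisitionConfig()
        z, phase, plane = ph.triangular_scan_z(0.0, cfg)
        assert (z, phase, plane) == (0.0, "rising", 0)

    @given(st.integers(0, 7999))
    @settings(max_examples=60, deadline=None)
    def test_plane_index_matches_frame_position(self, k):
        cfg = ph.AcquisitionConfig()
        t = k / cfg.fps
        z, phase, plane = ph.triangular_scan_z(t, cfg)
        in_cycle = k % 100
        if in_cycle < 50:
            assert phase == "rising" and plane == in_cycle
            assert z == pytest.approx(in_cycle * 0.4)
        else:
            assert phase == "falling" and plane == -1
        assert 0.0 <= z <= cfg.scan_amplitude_um + 1e-9

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            ph.triangular_scan_z(-0.1, ph.AcquisitionConfig())


class TestMotion:
    def test_initial_pose(self):
        mot = ph.MotionModel(direction="ccw", rotation_hz=5.0)
        pose = ph.pose_at(0.0, mot)
        assert np.allclose(pose.centre, mot.initial_position)
        assert pose.roll == 0.0

    def test_half_turn_in_a_tenth_second_at_5hz(self):
        mot = ph.MotionModel(direction="ccw", rotation_hz=5.0, z_wobble_amp_um=0.0)
        assert abs(ph.pose_at(0.1, mot).roll) == pytest.approx(np.pi)

    def test_no_rotation_means_zero_roll(self):
        mot = ph.MotionModel(direction="none", rotation_hz=0.0)
        for t in (0.0, 0.3, 1.7):
            assert ph.pose_at(t, mot).roll == 0.0

    def test_direction_and_rate_must_agree(self):
        with pytest.raises(ph.ConfigError):
            ph.MotionModel(direction="none", rotation_hz=3.0)
        with pytest.raises(ph.ConfigError):
            ph.MotionModel(direction="ccw", rotation_hz=0.0)

    def test_roll_sign_follows_direction(self):
        assert ph.MotionModel(direction="ccw", rotation_hz=2.0).roll_rate > 0
        assert ph.MotionModel(direction="cw", rotation_hz=2.0).roll_rate < 0

    def test_head_axes_stay_orthonormal(self):
        mot = ph.MotionModel(direction="cw", rotation_hz=4.0, initial_heading=0.8)
        r = ph.pose_at(0.123, mot).rotation()
        assert np.allclose(r @ r.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(r) == pytest.approx(1.0)


class TestRenderFrame:
    def test_head_parallel_at_focus_has_no_lateral_asymmetry(self, small_cfg):
        head = ph.HeadPhantom()
        model = ph.default_optics(small_cfg)
        pose = ph.HeadPose(centre=np.array([10.0, 10.0, 10.0]), heading=0.0, roll=0.0)
        img = ph.render_frame(pose, head, 10.0, model, small_cfg).values
        # flat side up, centred on the focal plane: top and bottom halves match
        assert np.allclose(img, img[::-1], atol=1e-7)

    def test_head_across_focus_inverts_contrast(self, small_cfg):
        head = ph.HeadPhantom()
        model = ph.default_optics(small_cfg)
        pose = ph.HeadPose(centre=np.array([10.0, 10.0, 10.0]), heading=0.0, roll=0.0)
        hi = ph.render_frame(pose, head, 8.5, model, small_cfg).values  # head behind
        lo = ph.render_frame(pose, head, 11.5, model, small_cfg).values  # head in front
        centre = (slice(36, 44), slice(32, 48))
        assert hi[centre].mean() > 1.005
        assert lo[centre].mean() < 0.995

    def test_far_from_focus_is_background(self, small_cfg):
        head = ph.HeadPhantom()
        model = ph.default_optics(small_cfg)
        pose = ph.HeadPose(centre=np.array([10.0, 10.0, 18.0]), heading=0.0, roll=0.0)
        img = ph.render_frame(pose, head, 2.0, model, small_cfg).values
        assert np.allclose(img, 1.0)


class TestGenerateSeries:
    def test_series_structure_and_ground_truth(self, ccw_series, small_cfg):
        series, gt = ccw_series
        assert len(series) == small_cfg.n_stacks
        assert all(s.n_planes == 50 for s in series.stacks)
        # constant roll rate with the sign of the label (logged frames are
        # the rising-slope ticks, so increments are uniform per tick)
        rate = 2 * np.pi * 5.0
        assert np.allclose(gt.roll, rate * gt.t, atol=1e-12)
        within = np.diff(gt.roll)[np.diff(gt.stack_index) == 0]
        assert np.allclose(within, within[0], atol=1e-12)
        assert within[0] > 0  # ccw
        # focal z log equals the triangular scan at each frame time
        for t, z in zip(gt.t[:200], gt.focal_z[:200]):
            assert z == pytest.approx(ph.triangular_scan_z(t, small_cfg)[0])

    def test_same_seed_is_byte_identical(self):
        cfg = ph.AcquisitionConfig(duration_s=0.05, noise_sd=0.01, seed=9)
        mot = ph.MotionModel(direction="cw", rotation_hz=5.0)
        s1, _ = ph.generate_stack_series(ph.HeadPhantom(), mot, cfg)
        s2, _ = ph.generate_stack_series(ph.HeadPhantom(), mot, cfg)
        for a, b in zip(s1.stacks, s2.stacks):
            assert np.array_equal(a.intensities, b.intensities)

    def test_mirrored_scene_gives_mirrored_frames(self):
        cfg = ph.AcquisitionConfig(duration_s=0.05, noise_sd=0.0, seed=0)
        fov = cfg.frame_shape[1] * cfg.pixel_size_um
        head = ph.HeadPhantom()
        mot = ph.MotionModel(direction="ccw", rotation_hz=5.0, initial_heading=0.4,
                             initial_position=(8.0, 10.0, 10.0))
        mirrored = ph.MotionModel(
            direction="cw", rotation_hz=5.0, initial_heading=np.pi - 0.4,
            initial_position=(fov - 8.0, 10.0, 10.0),
            z_wobble_phase=mot.z_wobble_phase,
        )
        s1, _ = ph.generate_stack_series(head, mot, cfg)
        s2, _ = ph.generate_stack_series(head, mirrored, cfg)
        for a, b in zip(s1.stacks, s2.stacks):
            assert np.allclose(a.intensities, b.intensities[:, :, ::-1], atol=1e-7)

    def test_particle_brightness_follows_its_side_of_focus(self):
        cfg = ph.AcquisitionConfig(duration_s=0.0125, noise_sd=0.0, seed=0,
                                   frame_shape=(96, 96))
        head = ph.HeadPhantom(particle=ph.ParticleSpec())
        mot = ph.MotionModel(direction="ccw", rotation_hz=5.0,
                             initial_position=(12.0, 12.0, 10.0), z_wobble_amp_um=0.0)
        model = ph.default_optics(cfg)
        checked = 0
        for theta, focal_off in [(0.6, -1.0), (-0.6, 1.0), (2.2, -0.8)]:
            t = theta / mot.roll_rate
            if t < 0:
                t += 1.0 / mot.rotation_hz
            pose = ph.pose_at(t, mot)
            rot = pose.rotation()
            p = head.particle
            p_centre = pose.centre - p.axial_offset_um * rot[:, 0] + p.radial_offset_um * rot[:, 1]
            focal_z = p_centre[2] + focal_off
            img = ph.render_frame(pose, head, focal_z, model, cfg).values
            col = int(p_centre[0] / cfg.pixel_size_um)
            row = int(cfg.frame_shape[0] - p_centre[1] / cfg.pixel_size_um)
            patch = img[row - 2 : row + 3, col - 2 : col + 3]
            if focal_off < 0:  # particle above the focal plane: behind -> bright
                assert patch.max() > 1.01
            else:
                assert patch.min() < 0.99
            checked += 1
        assert checked == 3


class TestCohortScenarios:
    def test_cohort_mixes_directions_and_quadrants(self):
        scen = ph.cohort_scenarios(12, seed=5)
        directions = [m.direction for _, m, _ in scen]
        assert set(directions) == {"ccw", "cw", "none"}
        quadrants = {int((m.initial_heading % (2 * np.pi)) // (np.pi / 2)) for _, m, _ in scen}
        assert quadrants == {0, 1, 2, 3}
        rates = [m.rotation_hz for _, m, _ in scen if m.direction != "none"]
        assert all(3.0 <= r <= 8.0 for r in rates)

    def test_cohort_is_seed_deterministic(self):
        a = ph.cohort_scenarios(6, seed=2)
        b = ph.cohort_scenarios(6, seed=2)
        assert [m for _, m, _ in a] == [m for _, m, _ in b]
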