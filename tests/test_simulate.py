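"""Simulator correctness: raycasting against analytic intersections,
occlusion, walker kinematics, and the ground-truth identities."""

import numpy as np
import pytest

from gaitlidar import simulate
from gaitlidar.geometry import SHIN, SensorPose, SensorSpec
from gaitlidar.simulate import (
    PolylinePath,
    WalkSpec,
    preset_walk,
    ray_circle_ranges,
    ray_segment_ranges,
    synthesize_background,
    synthesize_static_legs,
    synthesize_walk,
    walker_trajectory,
)


class TestRaycast:
    def test_circle_intersection_matches_analytic(self):
        dirs = np.array([[1.0, 0.0]])
        r = ray_circle_ranges(np.zeros(2), dirs, np.array([[2.0, 0.0]]), 0.05)
        np.testing.assert_allclose(r, [1.95], atol=1e-9)

    def test_offset_ray_circle_chord(self):
        # ray passing 0.03 off-centre through a 0.05-radius circle at x=2
        dirs = np.array([[1.0, 0.0]])
        r = ray_circle_ranges(np.array([0.0, 0.03]), dirs, np.array([[2.0, 0.0]]), 0.05)
        np.testing.assert_allclose(r, [2.0 - np.sqrt(0.05**2 - 0.03**2)], atol=1e-9)

    def test_miss_returns_inf(self):
        dirs = np.array([[0.0, 1.0]])
        assert np.isinf(ray_circle_ranges(np.zeros(2), dirs, np.array([[2.0, 0.0]]), 0.05))
        assert np.isinf(ray_segment_ranges(np.zeros(2), dirs,
                                           np.array([[[1, -1], [1, 1]]])))

    def test_segment_intersection(self):
        dirs = np.array([[1.0, 0.0], [np.cos(np.pi / 4), np.sin(np.pi / 4)]])
        segs = np.array([[[3.0, -5.0], [3.0, 5.0]]])
        r = ray_segment_ranges(np.zeros(2), dirs, segs)
        np.testing.assert_allclose(r, [3.0, 3.0 * np.sqrt(2)], atol=1e-9)

    def test_occluded_circle_contributes_nothing(self):
        # two circles collinear with the sensor: nearest-hit ranges with and
        # without the hidden one are identical
        dirs = np.column_stack([np.cos(np.linspace(-0.5, 0.5, 201)),
                                np.sin(np.linspace(-0.5, 0.5, 201))])
        near = np.array([[1.0, 0.0]])
        both = np.array([[1.0, 0.0], [2.0, 0.0]])
        r_near = ray_circle_ranges(np.zeros(2), dirs, near, 0.05)
        r_both = ray_circle_ranges(np.zeros(2), dirs, both, 0.05)
        np.testing.assert_array_equal(r_near, r_both)


class TestGroundTruthIdentities:
    @pytest.mark.parametrize("step, cadence, vel", [(0.60, 60.0, 60.0), (0.30, 120.0, 60.0)])
    def test_identities_hold_exactly(self, room, poses, spec, step, cadence, vel):
        walk = WalkSpec(step_length_m=step, cadence_spm=cadence, range_noise_sd_m=0.0)
        _, truth = synthesize_walk(walk, room, poses, spec)
        assert truth.stride_length_m == 2 * step
        assert truth.step_time_s == 60.0 / cadence
        assert truth.cycle_time_s == 2 * truth.step_time_s
        assert truth.mean_velocity_ms * 100 == pytest.approx(vel)

    def test_stance_foot_is_stationary_half_the_cycle(self):
        walk = WalkSpec(step_length_m=0.6, cadence_spm=60.0)
        path = PolylinePath([[0.0, 0.0], [6.0, 0.0]])
        times = np.arange(0.0, 5.0, 0.025)
        left, right, torso, heading, events, K = walker_trajectory(walk, path, times)
        # left holds site 0 during the first swing period
        first = times < walk.step_time_s
        assert np.allclose(left[first], left[0], atol=1e-12)
        # and the right shin travels two step lengths during that swing
        moved = np.linalg.norm(right[np.searchsorted(times, walk.step_time_s) - 1] - right[0])
        assert moved == pytest.approx(2 * walk.step_length_m, abs=0.01)

    def test_torso_moves_at_mean_speed(self):
        walk = WalkSpec(step_length_m=0.6, cadence_spm=60.0)
        path = PolylinePath([[0.0, 0.0], [6.0, 0.0]])
        times = np.arange(0.0, 4.0, 0.025)
        *_, torso, _, _, _ = walker_trajectory(walk, path, times)[:7]
        v = np.diff(torso[:, 0]) / np.diff(times)
        np.testing.assert_allclose(v, walk.mean_velocity_ms, atol=1e-9)


class TestBackgroundSynthesis:
    def test_2000_frames_at_40hz_span_50_seconds(self, room, poses, spec):
        scans = synthesize_background(room, poses, spec, n_frames=2000,
                                      noise_sd=0.0, seed=0)
        for seq in scans.values():
            assert len(seq) == 2000
            duration = seq[-1].timestamp - seq[0].timestamp + spec.scan_period_s
            assert duration == pytest.approx(50.0)

    def test_zero_noise_frames_identical(self, room, poses, spec):
        scans = synthesize_background(room, poses, spec, n_frames=5, noise_sd=0.0, seed=0)
        for seq in scans.values():
            for s in seq[1:]:
                np.testing.assert_array_equal(s.ranges, seq[0].ranges)

    def test_sample_mean_concentrates_on_true_range(self, room, poses, spec):
        sd = 0.01
        scans = synthesize_background(room, poses, spec, n_frames=2000, noise_sd=sd, seed=5)
        clean = synthesize_background(room, poses, spec, n_frames=1, noise_sd=0.0, seed=0)
        for sid, seq in scans.items():
            block = np.stack([s.ranges for s in seq])
            truth = clean[sid][0].ranges
            valid = truth > 0
            err = np.abs(block[:, valid].mean(axis=0) - truth[valid])
            # CLT: 4 sigma of the mean over 2000 draws
            assert (err < 4 * sd / np.sqrt(2000)).mean() > 0.999

    def test_empty_scene_walk_frame_equals_background(self, room, poses, spec):
        # a walk raycast with no walker is just the static scene: compare a
        # noiseless background frame with the noiseless static ranges
        scene = synthesize_static_legs(room, poses, spec, duration_h=0.001,
                                       noise_sd=0.0, sample_rate_hz=1.0)
        bg = synthesize_background(room, poses, spec, n_frames=2, noise_sd=0.0, seed=0)
        static = {sid: np.where(np.isfinite(r) & (r <= spec.max_range_m), r, 0.0)
                  for sid, r in
                  simulate._static_scene_ranges(room, poses, spec).items()}
        for sid in poses:
            np.testing.assert_array_equal(bg[sid][0].ranges, static[sid])
        assert scene.n_frames == int(round(0.001 * 3600))


class TestStaticLegScene:
    def test_frame_count_and_downsampling(self, room, poses, spec):
        scene = synthesize_static_legs(room, poses, spec, duration_h=12.0)
        assert scene.n_frames == 12 * 3600 * 40  # 1,728,000 at the native rate
        scene1 = synthesize_static_legs(room, poses, spec, duration_h=12.0,
                                        sample_rate_hz=1.0)
        assert scene1.n_frames == 43200

    def test_zero_noise_chunks_identical(self, room, poses, spec):
        scene = synthesize_static_legs(room, poses, spec, duration_h=0.01,
                                       noise_sd=0.0, sample_rate_hz=2.0)
        times, block = next(scene.iter_chunks(50))
        for arr in block.values():
            assert (arr == arr[0]).all()

    def test_pipe_separation_matches_configuration(self, room, poses, spec):
        scene = synthesize_static_legs(room, poses, spec, duration_h=0.01,
                                       pipe_spacing_m=0.25)
        sep = np.linalg.norm(scene.pipe_centers[1] - scene.pipe_centers[0])
        assert sep == pytest.approx(0.25)


class TestPresets:
    def test_fixed_presets_cover_study_conditions(self):
        for name, (step, cad) in {"30-100": (0.30, 100), "30-120": (0.30, 120),
                                  "60-60": (0.60, 60), "60-120": (0.60, 120)}.items():
            w = preset_walk(name)
            assert w.step_length_m == step and w.cadence_spm == cad

    def test_uturn_preset_has_turnaround_path(self):
        w = preset_walk("uturn")
        assert w.path is not None
        # the path comes back: net displacement much shorter than its length
        net = np.linalg.norm(w.path.pts[-1] - w.path.pts[0])
        assert net < 0.5 * w.path.length

    def test_unknown_preset_rejected(self):
        with pytest.raises(KeyError):
            preset_walk("sprint")

    def test_path_outside_room_rejected(self, room, poses, spec):
        walk = WalkSpec(path=PolylinePath([[-5.0, 2.0], [2.0, 2.0]]))
        with pytest.raises(ValueError, match="extent"):
            synthesize_walk(walk, room, poses, spec)
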