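"""Head tracking: detection, angle extraction, corrections, events, sync."""

import numpy as np
import pytest

from agdep import synth, tracking
from agdep.geometry import circular_difference, tuft_axis
from agdep.tracking import (
    AngleSeries,
    apply_corrections,
    build_angle_series,
    detect_head,
    detect_sync,
    detect_turns,
    detect_tufts,
    head_direction,
    summarize_trial,
)


def _series(angles, fps=100.0, valid=None, initial=0.0):
    angles = np.asarray(angles, dtype=float)
    if valid is None:
        valid = np.ones(len(angles), dtype=bool)
    return AngleSeries(angles, np.asarray(valid), fps, initial)


class TestDetectHead:
    def test_position_accuracy(self, geometry, template):
        frame = synth.render_frame(0.0, (70.0, 90.0), geometry)
        det = detect_head(frame, template)
        assert det.found
        assert abs(det.center_rc[0] - 70) <= 10 and abs(det.center_rc[1] - 90) <= 10

    def test_translation_equivariance(self, geometry, template):
        d1 = detect_head(synth.render_frame(30.0, (60.0, 70.0), geometry), template)
        d2 = detect_head(synth.render_frame(30.0, (66.0, 61.0), geometry), template)
        assert d1.found and d2.found
        assert abs((d2.center_rc[0] - d1.center_rc[0]) - 6.0) <= 2.0
        assert abs((d2.center_rc[1] - d1.center_rc[1]) + 9.0) <= 2.0

    def test_black_frame_yields_no_detection(self, template):
        det = detect_head(np.zeros((120, 160)), template)
        assert not det.found

    def test_template_must_fit_in_frame(self, template):
        with pytest.raises(ValueError):
            detect_head(np.zeros((10, 10)), template)


class TestDetectTufts:
    def test_centroids_near_ground_truth(self, geometry, template):
        angle, centre = 40.0, (70.0, 90.0)
        frame = synth.render_frame(angle, centre, geometry)
        det = detect_head(frame, template)
        tufts = detect_tufts(frame, det.box)
        assert tufts.valid
        p = tuft_axis(angle)
        truth = sorted(
            [
                (centre[0] - geometry.tuft_offset_px * p[1],
                 centre[1] - geometry.tuft_offset_px * p[0]),
                (centre[0] + geometry.tuft_offset_px * p[1],
                 centre[1] + geometry.tuft_offset_px * p[0]),
            ],
            key=lambda rc: rc[1],
        )
        for got, exp in zip((tufts.left_centroid_rc, tufts.right_centroid_rc), truth):
            assert abs(got[0] - exp[0]) <= 3 and abs(got[1] - exp[1]) <= 3

    def test_occluded_tuft_invalid(self, geometry, template):
        frame = synth.render_frame(0.0, (70.0, 90.0), geometry, occlude="left")
        det = detect_head(frame, template)
        assert not detect_tufts(frame, det.box).valid

    def test_ordering_by_image_x(self, geometry, template):
        frame = synth.render_frame(0.0, (70.0, 90.0), geometry)
        det = detect_head(frame, template)
        tufts = detect_tufts(frame, det.box)
        assert tufts.left_centroid_rc[1] < tufts.right_centroid_rc[1]


class TestHeadDirection:
    def test_front_facing_symmetric_tufts(self):
        tufts = tracking.TuftPair(True, (50.0, 30.0), (50.0, 62.0))
        assert head_direction(tufts, previous_angle=0.0) == pytest.approx(0.0)

    def test_continuity_picks_flipped_branch(self):
        tufts = tracking.TuftPair(True, (50.0, 30.0), (50.0, 62.0))
        assert head_direction(tufts, previous_angle=170.0) == pytest.approx(180.0)

    def test_invalid_tufts_rejected(self):
        with pytest.raises(ValueError):
            head_direction(tracking.TuftPair(False), 0.0)

    def test_pose_sweep_recovery(self, geometry, template):
        for angle in range(-175, 181, 15):
            frame = synth.render_frame(float(angle), (70.0, 90.0), geometry)
            det = detect_head(frame, template)
            tufts = detect_tufts(frame, det.box)
            rec = head_direction(tufts, previous_angle=float(angle))
            assert abs(circular_difference(rec, angle)) <= 5.0


class TestBuildAngleSeries:
    def test_constant_pose_clip(self, geometry, template):
        frames = [synth.render_frame(25.0, (70.0, 90.0), geometry)] * 10
        series = build_angle_series(frames, template, initial_direction=0.0)
        assert series.valid.all()
        assert np.ptp(series.angles_deg) < 1.0

    def test_occluded_frames_marked_invalid(self, geometry, template):
        traj = synth.make_trajectory(0.0, [], 0.5, occlusions=[(10, 20)])
        frames, _ = synth.render_trial_video(traj, geometry)
        series = build_angle_series(frames, template, 0.0)
        assert (~series.valid).sum() == 10
        assert not series.valid[10:20].any()

    def test_smooth_sweep_recovered(self, geometry, template):
        traj = synth.make_trajectory(0.0, [(0.1, 180.0, 1.0)], 1.3)
        frames, _ = synth.render_trial_video(traj, geometry)
        series = apply_corrections(build_angle_series(frames, template, 0.0))
        err = np.abs(
            [circular_difference(a, b) for a, b in zip(series.angles_deg, traj.angles_deg)]
        )
        assert err.max() <= 5.0
        # continuity resolves the 180-degree ambiguity on nearly all frames
        assert (err <= 5.0).mean() >= 0.99

    def test_no_detection_anywhere_is_an_error(self, template):
        with pytest.raises(ValueError):
            build_angle_series([np.zeros((120, 160))] * 3, template, 0.0)


class TestApplyCorrections:
    def test_carry_forward_fills_invalid(self):
        s = _series([10.0, 0.0, 0.0, 12.0], valid=[True, False, False, True])
        out = apply_corrections(s)
        np.testing.assert_allclose(out.angles_deg, [10.0, 10.0, 10.0, 12.0])
        assert out.carried_frames == (1, 2)

    def test_isolated_misflip_corrected(self):
        out = apply_corrections(_series([10.0, -170.0, 12.0]))
        np.testing.assert_allclose(out.angles_deg, [10.0, 10.0, 12.0])
        assert out.flipped_frames == (1,)

    def test_identity_on_valid_smooth_series(self):
        angles = np.linspace(0, 80, 30)
        out = apply_corrections(_series(angles))
        np.testing.assert_array_equal(out.angles_deg, angles)
        assert out.flipped_frames == () and out.carried_frames == ()

    def test_correction_never_touches_valid_samples(self):
        rng = np.random.default_rng(0)
        angles = np.cumsum(rng.normal(0, 3, 50))
        valid = rng.random(50) > 0.3
        valid[0] = True
        out = apply_corrections(_series(angles, valid=valid))
        np.testing.assert_array_equal(out.angles_deg[valid], angles[valid])

    def test_leading_invalid_uses_entry_direction(self):
        s = _series([0.0, 0.0, 20.0], valid=[False, False, True], initial=90.0)
        out = apply_corrections(s)
        np.testing.assert_allclose(out.angles_deg, [90.0, 90.0, 20.0])


class TestDetectTurns:
    def test_single_crossing_time_and_latency(self):
        t = np.arange(0, 6.0, 0.01)
        angles = np.clip(100.0 * t / 1.2 * 0.9, 0, 120)  # crosses 90 at 1.2 s
        events = detect_turns(_series(angles), onset_time_s=0.0)
        assert len(events) == 1
        assert events[0].crossing_time_s == pytest.approx(1.2, abs=0.02)
        assert events[0].sign == 90

    def test_negative_crossing_sign(self):
        angles = np.linspace(0, -120, 300)  # reaches -90 deg at 2.24 s
        events = detect_turns(_series(angles), 0.0, window_s=2.9)
        assert len(events) == 1 and events[0].sign == -90

    def test_window_boundary_excludes_late_crossing(self):
        angles = np.zeros(700)
        angles[488:492] = 95.0  # crossing at 4.88-4.92 s
        angles[509:513] = 95.0  # second crossing at 5.09 s, outside window
        events = detect_turns(_series(angles), 0.0, window_s=5.0)
        assert len(events) == 1

    def test_rearm_counts_every_scheduled_crossing(self):
        traj = synth.make_trajectory(
            0.0,
            [(0.5, 120.0, 0.5), (1.5, 0.0, 0.5), (2.5, -130.0, 0.5), (3.5, 20.0, 0.5)],
            duration_s=5.01,
        )
        events = detect_turns(_series(traj.angles_deg), 0.0, window_s=5.0)
        assert len(events) == len(traj.turn_schedule)

    def test_window_past_series_end_is_an_error(self):
        with pytest.raises(ValueError):
            detect_turns(_series(np.zeros(100)), 0.0, window_s=5.0)

    def test_already_oriented_at_onset_counts_no_turn(self):
        summary = summarize_trial(_series(np.full(600, 100.0)), 0.0)
        assert summary.n_turns == 0
        assert summary.max_rotation == pytest.approx(100.0)
        assert summary.latency_s is None


class TestSummarizeTrial:
    def test_constant_zero(self):
        s = summarize_trial(_series(np.zeros(600)), 0.0)
        assert s == tracking.TrialSummary(0.0, 0.0, 0, None)

    def test_matches_analytic_ramp(self):
        # |angle| rises linearly 0 -> 100 over the 5 s window: mean 50, max 100
        angles = np.linspace(0.0, 100.0, 501)
        s = summarize_trial(_series(angles), 0.0)
        assert s.mean_orientation == pytest.approx(50.0, abs=0.5)
        assert s.max_rotation == pytest.approx(100.0)
        assert s.n_turns == 1


class TestDetectSync:
    def test_id_code_and_stimulus_flashes(self):
        sched = synth.make_flash_schedule(19, 100, 400)
        lit = np.zeros(500)
        for a, b in sched.flash_intervals():
            lit[a:b] = 1.0
        res = detect_sync(lit)
        assert res.session_id == 19
        kinds = {e.kind: e.frame_index for e in res.events}
        assert kinds["stimulus_on"] == 100 and kinds["stimulus_off"] == 400
        assert not res.incomplete
        assert kinds["stimulus_on"] / 100.0 == pytest.approx(1.0)  # onset at 100 fps

    def test_flat_brightness_no_events(self):
        res = detect_sync(np.full(100, 0.2))
        assert res.events == () and res.session_id is None

    def test_odd_flash_count_flags_incomplete(self):
        sched = synth.make_flash_schedule(5, 100, 400)
        lit = np.zeros(500)
        for a, b in sched.flash_intervals()[:-1]:  # drop the offset flash
            lit[a:b] = 1.0
        assert detect_sync(lit).incomplete


def test_overlay_frames_written_for_review(geometry, template, tmp_path):
    traj = synth.make_trajectory(20.0, [], 0.05)
    frames, _ = synth.render_trial_video(traj, geometry)
    series = apply_corrections(build_angle_series(frames, template, 0.0))
    paths = tracking.write_overlay_frames(frames, series, template, tmp_path)
    assert len(paths) == 5 and all(p.exists() for p in paths)


def test_summaries_invariant_to_brightness_scaling(geometry, template):
    traj = synth.make_trajectory(0.0, [(0.2, 110.0, 0.5)], 1.2)
    frames, _ = synth.render_trial_video(traj, geometry)
    run = lambda stack: summarize_trial(
        apply_corrections(build_angle_series(stack, template, 0.0)), 0.0, window_s=1.0
    )
    bright = run(frames)
    dim = run([0.4 * f for f in frames])
    assert dim.n_turns == bright.n_turns
    assert dim.mean_orientation == pytest.approx(bright.mean_orientation, abs=1.0)
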