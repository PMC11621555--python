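"""Kinematics, the switch detector, and cohort statistics."""

import numpy as np
import pytest

from chemolane import synthetic, trajectory
from chemolane.tracks import Track, TrajectorySet, WaveformState
from chemolane.trajectory import (
    TOWARD_SINK,
    TOWARD_SOURCE,
    DetectorParams,
    classify_orientation,
    compute_kinematics,
    detect_waveform_switches,
    event_detection_scores,
    photoshock_metrics,
    switch_rate,
    symmetric_asymmetric_ratio,
)

from conftest import reversal_track, straight_track


class TestKinematics:
    def test_straight_constant_velocity(self):
        t = straight_track(speed=80.0, heading=0.3)
        kin = compute_kinematics(t)
        np.testing.assert_allclose(kin.speeds, 80.0, rtol=1e-9)
        np.testing.assert_allclose(kin.turn_angles, 0.0, atol=1e-9)
        np.testing.assert_allclose(kin.headings, 0.3, rtol=1e-9)

    def test_exact_reversal_turn_angle_is_pi(self):
        fps = 30.0
        times = np.arange(6) / fps
        x = np.array([0.0, 1, 2, 1, 0, -1])
        tr = Track(0, times, np.column_stack([x, np.zeros(6)]))
        kin = compute_kinematics(tr)
        assert abs(kin.turn_angles[1]) == pytest.approx(np.pi)

    def test_circular_track_constant_turn_angle(self):
        r, v, fps = 50.0, 60.0, 30.0
        omega = v / r
        t = np.arange(120) / fps
        pos = np.column_stack([r * np.cos(omega * t), r * np.sin(omega * t)])
        kin = compute_kinematics(Track(0, t, pos))
        expected = v / (r * fps)
        np.testing.assert_allclose(kin.turn_angles, expected, rtol=1e-3)
        # chord speed slightly below arc speed; matches to first order
        np.testing.assert_allclose(kin.speeds, v, rtol=1e-3)


class TestDetector:
    def test_single_half_second_reversal_detected(self):
        tr, (start, end) = reversal_track()
        ann = detect_waveform_switches(tr)
        assert len(ann.events) == 1
        ev = ann.events[0]
        assert ev.start_s == pytest.approx(start, abs=2 / 30)
        assert ev.end_s == pytest.approx(end, abs=2 / 30)

    def test_straight_track_has_no_events(self):
        ann = detect_waveform_switches(straight_track())
        assert ann.events == []
        assert np.all(ann.states == WaveformState.ASYMMETRIC.value)

    def test_detected_duration_bounded_by_max_event(self, wt_cohort, wt_annotations):
        params = DetectorParams()
        for ann in wt_annotations.values():
            for ev in ann.events:
                assert params.min_event - 1e-9 <= ev.duration_s <= params.max_event + 1e-9

    def test_states_partition_all_frames(self, wt_cohort, wt_annotations):
        _, ts = wt_cohort
        valid = {s.value for s in WaveformState}
        for t in ts:
            ann = wt_annotations[t.track_id]
            assert len(ann.states) == t.n_frames
            assert set(np.unique(ann.states)) <= valid

    def test_event_f1_against_truth(self, wt_cohort, wt_annotations):
        _, ts = wt_cohort
        detected = [ev for ann in wt_annotations.values() for ev in ann.events]
        scores = event_detection_scores(ts.truth_events, detected)
        assert scores["f1"] >= 0.90

    def test_short_track_excluded_not_raised(self):
        tr = straight_track(n=60)  # 2 s
        ann = detect_waveform_switches(tr)
        assert not ann.eligible
        assert "duration" in ann.reason


class TestSwitchRate:
    def test_duration_filter_boundary_inclusive(self):
        fps = 30.0
        tracks = []
        for i, dur in enumerate((3.9, 4.0, 4.1)):
            n = int(round(dur * fps)) + 1
            tracks.append(straight_track(track_id=i, n=n))
        ts = TrajectorySet(tracks=tracks, fps=fps)
        res = switch_rate(ts)
        assert res.n_tracks == 2  # exactly the >= 4 s tracks survive
        assert res.n_excluded == 1

    def test_zero_rate_cohort_measures_zero(self):
        cfg = synthetic.SwimConfig(n_cells=30, duration=10.0, switch_rate_base=0.0, rng_seed=6)
        ts = synthetic.simulate_tracks(cfg)
        res = switch_rate(ts)
        assert res.mean == 0.0

    def test_unbiased_across_rate_grid(self):
        # detector rate estimate tracks the true rate over the working range
        for lam, seed in ((0.02, 21), (0.05, 22), (0.085, 23), (0.15, 24)):
            cfg = synthetic.SwimConfig(
                n_cells=200, duration=20.0, switch_rate_base=lam, rng_seed=seed
            )
            ts = synthetic.simulate_tracks(cfg)
            res = switch_rate(ts)
            se = max(res.sem, 1e-6)
            assert abs(res.mean - lam) < 2 * se, f"lambda0={lam}: {res.mean} +- {se}"

    def test_empty_cohort_explicit_empty_result(self):
        ts = TrajectorySet(tracks=[straight_track(n=30)], fps=30.0)  # all too short
        res = switch_rate(ts)
        assert res.n_tracks == 0 and np.isnan(res.mean)


class TestRotationInvariance:
    def test_statistics_invariant_under_common_rotation(self):
        cfg = synthetic.SwimConfig(
            n_cells=40, duration=10.0, switch_rate_base=0.085, bias=0.4, rng_seed=12
        )
        ts = synthetic.simulate_tracks(cfg)
        phi = 1.234
        R = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        rot = TrajectorySet(
            tracks=[Track(t.track_id, t.times, t.positions @ R.T) for t in ts],
            fps=ts.fps,
        )
        r1 = switch_rate(ts)
        r2 = switch_rate(rot)
        assert r1.mean == pytest.approx(r2.mean, abs=1e-12)
        src = np.array([1.0, 0.0])
        a = symmetric_asymmetric_ratio(ts, src)
        b = symmetric_asymmetric_ratio(rot, R @ src)
        assert a.toward_source_mean == pytest.approx(b.toward_source_mean, rel=1e-9)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-9)


class TestOrientation:
    def test_straight_at_source_single_toward_segment(self):
        tr = straight_track(heading=0.1)
        segs = classify_orientation(tr, (1.0, 0.0))
        assert [s.label for s in segs] == [TOWARD_SOURCE]

    def test_perpendicular_heading_is_toward_sink(self):
        tr = straight_track(heading=np.pi / 2)
        segs = classify_orientation(tr, (1.0, 0.0))
        assert [s.label for s in segs] == [TOWARD_SINK]  # strict < pi/2 rule

    def test_mid_track_reversal_gives_two_labeled_segments(self):
        tr, _ = reversal_track(post_heading=np.pi)  # leaves toward the sink
        segs = classify_orientation(tr, (1.0, 0.0))
        assert [s.label for s in segs] == [TOWARD_SOURCE, TOWARD_SINK]


class TestRatio:
    def test_zero_rate_cohort_has_zero_ratio(self):
        cfg = synthetic.SwimConfig(n_cells=24, duration=10.0, switch_rate_base=0.0, rng_seed=7)
        ts = synthetic.simulate_tracks(cfg)
        r = symmetric_asymmetric_ratio(ts, (1.0, 0.0))
        assert r.toward_source_mean == 0.0 and r.toward_sink_mean == 0.0

    def test_event_count_mode_runs(self):
        cfg = synthetic.SwimConfig(n_cells=40, duration=10.0, switch_rate_base=0.1, rng_seed=8)
        ts = synthetic.simulate_tracks(cfg)
        r = symmetric_asymmetric_ratio(ts, (1.0, 0.0), mode="events")
        assert r.n_replicates == 4 and np.isfinite(r.p_value)


class TestPhotoshock:
    def test_forced_cohort_responds(self):
        cfg = synthetic.SwimConfig(n_cells=60, duration=6.0, switch_rate_base=0.0, rng_seed=12)
        ts = synthetic.simulate_photoshock(cfg, flash_time=2.0)
        res = photoshock_metrics(ts, 2.0)
        assert res.responding_fraction >= 0.95
        assert res.rayleigh_p > 0.05  # recovery headings are randomized

    def test_unflashed_zero_rate_cohort_does_not_respond(self):
        cfg = synthetic.SwimConfig(n_cells=30, duration=6.0, switch_rate_base=0.0, rng_seed=14)
        ts = synthetic.simulate_tracks(cfg)
        res = photoshock_metrics(ts, 2.0)
        assert res.responding_fraction == 0.0

    def test_no_spanning_tracks_rejected(self):
        cfg = synthetic.SwimConfig(n_cells=5, duration=6.0, switch_rate_base=0.0, rng_seed=1)
        ts = synthetic.simulate_tracks(cfg)
        with pytest.raises(ValueError, match="span"):
            photoshock_metrics(ts, 100.0)
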