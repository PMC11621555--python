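"""Ground-truthed generators: swimmers, photoshock, profiles, lane stacks."""

import dataclasses

import numpy as np
import pingouin as pg
import pytest

from chemolane import synthetic
from chemolane.synthetic import LaneImageConfig, SwimConfig, render_lane_stack
from chemolane.tracks import WaveformState, read_trackmate, write_trackmate


class TestSimulateTracks:
    def test_zero_rate_produces_no_events(self):
        for seed in (0, 1, 99):
            cfg = SwimConfig(n_cells=20, duration=5.0, switch_rate_base=0.0, rng_seed=seed)
            ts = synthetic.simulate_tracks(cfg)
            assert ts.truth_events == []
            for lab in ts.truth_labels.values():
                assert np.all(lab == WaveformState.ASYMMETRIC.value)

    def test_truth_event_rate_matches_configured_rate(self, wt_cohort):
        # closed-form Poisson check on the labels, before any detector runs:
        # 200 tracks x 20 s at 0.085 events per track-second
        cfg, ts = wt_cohort
        total_time = sum(t.duration_s for t in ts)
        rate = len(ts.truth_events) / total_time
        se = np.sqrt(cfg.switch_rate_base / total_time)
        assert abs(rate - cfg.switch_rate_base) < 3 * se

    def test_gradient_bias_modulates_event_rate(self):
        # frames with heading nearly up-gradient switch less often than
        # frames nearly down-gradient, in the ratio the hazard predicts
        beta = 0.5
        cfg = SwimConfig(
            n_cells=500, duration=30.0, switch_rate_base=0.085, bias=beta, rng_seed=5
        )
        ts = synthetic.simulate_tracks(cfg)
        up = down = up_n = down_n = 0
        cos_up, cos_down = [], []
        for t in ts:
            lab = ts.truth_labels[t.track_id]
            steps = np.diff(t.positions, axis=0)
            cos = np.cos(np.arctan2(steps[:, 1], steps[:, 0]))  # gradient = +x
            asym = lab[:-1] == WaveformState.ASYMMETRIC.value
            sw = (lab[:-1] == 0) & (lab[1:] == 1)
            sel_up = asym & (cos > 0.9)
            sel_down = asym & (cos < -0.9)
            up_n += np.sum(sel_up)
            down_n += np.sum(sel_down)
            up += np.sum(sw & (cos > 0.9))
            down += np.sum(sw & (cos < -0.9))
            cos_up.append(cos[sel_up])
            cos_down.append(cos[sel_down])
        ratio = (up / up_n) / (down / down_n)
        # hazard-formula oracle at the actual bin-mean orientations,
        # tolerance propagated from the Poisson error of both counts
        mu_up = np.concatenate(cos_up).mean()
        mu_down = np.concatenate(cos_down).mean()
        expected = (1 - beta * mu_up) / (1 - beta * mu_down)
        rel_se = np.sqrt(1 / up + 1 / down)
        assert ratio < 1.0  # switching suppressed while swimming up-gradient
        assert abs(ratio / expected - 1) < 3 * rel_se

    def test_per_frame_hazard_matches_model_in_cosine_deciles(self):
        cfg = SwimConfig(
            n_cells=300, duration=20.0, switch_rate_base=0.085, bias=0.5, rng_seed=8
        )
        ts = synthetic.simulate_tracks(cfg)
        dt = 1.0 / cfg.fps
        lam0 = cfg.switch_rate_base * cfg.hazard_scale()
        cos_all, sw_all = [], []
        for t in ts:
            lab = ts.truth_labels[t.track_id]
            steps = np.diff(t.positions, axis=0)
            cos = np.cos(np.arctan2(steps[:, 1], steps[:, 0]))
            asym = lab[:-1] == WaveformState.ASYMMETRIC.value
            sw = (lab[:-1] == 0) & (lab[1:] == 1)
            cos_all.append(cos[asym])
            sw_all.append(sw[asym])
        cos_all = np.concatenate(cos_all)
        sw_all = np.concatenate(sw_all)
        edges = np.quantile(cos_all, np.linspace(0, 1, 11))
        for lo, hi in zip(edges[:-1], edges[1:]):
            sel = (cos_all >= lo) & (cos_all <= hi)
            n = sel.sum()
            p_obs = sw_all[sel].mean()
            p_mod = lam0 * (1 - cfg.bias * cos_all[sel].mean()) * dt
            se = np.sqrt(p_mod * (1 - p_mod) / n)
            assert abs(p_obs - p_mod) < 4 * se

    def test_bit_reproducible_given_seed(self):
        cfg = SwimConfig(n_cells=10, duration=5.0, rng_seed=42)
        a = synthetic.simulate_tracks(cfg)
        b = synthetic.simulate_tracks(cfg)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.positions, tb.positions)
        assert [(e.start_s, e.end_s) for e in a.truth_events] == [
            (e.start_s, e.end_s) for e in b.truth_events
        ]

    def test_no_symmetric_event_exceeds_one_second(self, wt_cohort):
        _, ts = wt_cohort
        assert ts.truth_events  # non-vacuous
        for ev in ts.truth_events:
            assert ev.duration_s < 1.0 + 1e-9

    def test_positions_stay_inside_arena(self):
        cfg = SwimConfig(n_cells=30, duration=10.0, arena=(300.0, 300.0), rng_seed=2)
        ts = synthetic.simulate_tracks(cfg)
        for t in ts:
            assert np.all(t.positions >= -1e-9)
            assert np.all(t.positions[:, 0] <= 300.0 + 1e-9)
            assert np.all(t.positions[:, 1] <= 300.0 + 1e-9)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(fps=0.0),
            dict(switch_rate_base=-0.1),
            dict(bias=1.0),
            dict(bias=-0.2),
            dict(base_speed_mean=float("nan")),
            dict(gradient_direction=(0.0, 0.0)),
        ],
    )
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            SwimConfig(**bad)


class TestSimulatePhotoshock:
    def test_all_cells_event_at_flash(self):
        cfg = SwimConfig(n_cells=50, duration=6.0, switch_rate_base=0.0, rng_seed=1)
        ts = synthetic.simulate_photoshock(cfg, flash_time=2.0)
        per_track = {ev.track_id for ev in ts.truth_events}
        assert len(per_track) == 50
        for ev in ts.truth_events:
            assert ev.start_s <= 2.0 <= ev.end_s

    def test_exactly_one_event_when_spontaneous_rate_zero(self):
        cfg = SwimConfig(n_cells=40, duration=6.0, switch_rate_base=0.0, rng_seed=4)
        ts = synthetic.simulate_photoshock(cfg, flash_time=3.0)
        counts = {}
        for ev in ts.truth_events:
            counts[ev.track_id] = counts.get(ev.track_id, 0) + 1
        assert all(c == 1 for c in counts.values()) and len(counts) == 40

    def test_post_event_headings_circularly_uniform(self):
        cfg = SwimConfig(n_cells=500, duration=4.0, switch_rate_base=0.0, rng_seed=9)
        ts = synthetic.simulate_photoshock(cfg, flash_time=1.0)
        post = np.array(
            [ev.post_heading for ev in ts.truth_events if np.isfinite(ev.post_heading)]
        )
        assert len(post) > 450
        _, p = pg.circ_rayleigh(post)
        assert p > 0.05

    @pytest.mark.parametrize("flash", [-1.0, 0.0, 6.0, 9.0])
    def test_flash_outside_recording_rejected(self, flash):
        cfg = SwimConfig(n_cells=5, duration=6.0)
        with pytest.raises(ValueError):
            synthetic.simulate_photoshock(cfg, flash)


class TestSimulateDiffusionProfiles:
    def test_zero_noise_equals_closed_form(self):
        from chemolane.diffusion import fick_concentration

        x = np.arange(0.0, 20.0, 0.5)
        t = np.array([1.0, 4.0])
        prof = synthetic.simulate_diffusion_profiles(5e-5, 2.0, t, x, noise_frac=0.0)
        xg, tg = np.meshgrid(x, t * 3600.0, indexing="ij")
        np.testing.assert_allclose(prof.values, fick_concentration(xg, tg, 5e-5, 2.0))

    def test_source_boundary_value(self):
        prof = synthetic.simulate_diffusion_profiles(
            5e-5, 7.0, [1.0, 24.0], [0.0, 1.0, 2.0, 3.0, 4.0], noise_frac=0.0
        )
        np.testing.assert_allclose(prof.values[0], 7.0)

    def test_profile_monotone_in_position(self):
        prof = synthetic.simulate_diffusion_profiles(
            7.497e-5, 1.0, [24.0], np.arange(0.0, 60.0, 1.0), noise_frac=0.0
        )
        assert np.all(np.diff(prof.values[:, 0]) <= 1e-15)

    def test_negative_d_rejected(self):
        with pytest.raises(ValueError):
            synthetic.simulate_diffusion_profiles(-1e-5, 1.0, [1.0], [0.0, 1.0])


class TestRenderLaneStack:
    def test_static_when_no_drift_no_noise(self):
        cfg = LaneImageConfig(drift_velocity=0.0, noise_sd=0.0)
        stack = render_lane_stack(cfg)
        for frame in stack[1:]:
            np.testing.assert_array_equal(frame, stack[0])

    def test_center_of_mass_moves_toward_source(self):
        cfg = LaneImageConfig(noise_sd=0.0, source_end="high")
        stack = render_lane_stack(cfg).astype(float)
        x = np.arange(stack.shape[2])
        com = [(f.mean(axis=0) * x).sum() / f.mean(axis=0).sum() for f in stack]
        assert com[-1] > com[0] + 10  # clearly displaced toward high-x source
        assert np.all(np.diff(com) > -1e-9)

    def test_total_intensity_conserved(self):
        cfg = LaneImageConfig(rng_seed=3)
        stack = render_lane_stack(cfg).astype(float)
        s0, s1 = stack[0].sum(), stack[-1].sum()
        assert abs(s1 - s0) / s0 < 0.01
        assert stack.max() < 255  # no clipping at defaults

    def test_reproducible_and_8bit(self):
        cfg = LaneImageConfig(rng_seed=5)
        a, b = render_lane_stack(cfg), render_lane_stack(cfg)
        np.testing.assert_array_equal(a, b)
        assert a.dtype == np.uint8


def test_tiff_roundtrip(tmp_path):
    cfg = LaneImageConfig(rng_seed=1, timepoints=np.array([0.0, 1.0, 2.0]))
    stack = render_lane_stack(cfg)
    path = tmp_path / "stack.tif"
    synthetic.write_tiff(stack, path)
    np.testing.assert_array_equal(synthetic.read_tiff(path), stack)


def test_trackmate_roundtrip(tmp_path):
    cfg = SwimConfig(n_cells=5, duration=5.0, switch_rate_base=0.1, rng_seed=3)
    ts = synthetic.simulate_tracks(cfg)
    path = tmp_path / "spots.csv"
    write_trackmate(ts, path, truth=True)
    back = read_trackmate(path)
    assert back.fps == pytest.approx(cfg.fps)
    for t in ts:
        np.testing.assert_allclose(back.track(t.track_id).positions, t.positions, atol=1e-5)
        np.testing.assert_array_equal(back.truth_labels[t.track_id], ts.truth_labels[t.track_id])
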