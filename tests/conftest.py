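import numpy as np
import pytest

from chemolane import synthetic, trajectory


@pytest.fixture(scope="session")
def detector_params():
    return trajectory.DetectorParams()


@pytest.fixture(scope="session")
def wt_cohort():
    """Wild-type-like cohort at the spontaneous switch rate: 200 tracks x 20 s."""
    cfg = synthetic.SwimConfig(
        n_cells=200, duration=20.0, switch_rate_base=0.085, bias=0.0, rng_seed=0
    )
    return cfg, synthetic.simulate_tracks(cfg)


@pytest.fixture(scope="session")
def wt_annotations(wt_cohort, detector_params):
    _, tset = wt_cohort
    return trajectory.annotate_set(tset, detector_params)


def straight_track(track_id=0, n=241, fps=30.0, speed=100.0, heading=0.0, start=(0.0, 0.0)):
    """Constant-velocity straight track (8 s at defaults)."""
    t = np.arange(n) / fps
    d = speed * t
    pos = np.column_stack(
        [start[0] + d * np.cos(heading), start[1] + d * np.sin(heading)]
    )
    from chemolane.tracks import Track

    return Track(track_id, t, pos)


def reversal_track(
    track_id=0,
    fps=30.0,
    speed=100.0,
    run_s=3.0,
    event_s=0.5,
    reverse_factor=0.8,
    post_heading=np.pi / 3,
    total_s=8.0,
):
    """Toy track: forward run, one backward episode, brief pause, new course."""
    from chemolane.tracks import Track

    dt = 1.0 / fps
    pts = [np.zeros(2)]
    heading = 0.0

    def walk(n, h, v):
        for _ in range(n):
            pts.append(pts[-1] + v * dt * np.array([np.cos(h), np.sin(h)]))

    n_run = int(round(run_s * fps))
    n_ev = int(round(event_s * fps))
    walk(n_run, heading, speed)
    walk(n_ev, heading + np.pi, reverse_factor * speed)  # backward
    walk(2, heading + 1.0, 0.1 * speed)                  # uncoordinated
    n_rest = int(round(total_s * fps)) - len(pts) + 1
    walk(n_rest, post_heading, speed)
    pos = np.array(pts)
    t = np.arange(len(pos)) / fps
    return Track(track_id, t, pos), (n_run / fps, (n_run + n_ev) / fps)
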