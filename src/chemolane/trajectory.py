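"""Trajectory kinematics and symmetric-waveform switch detection.

A cell that switches from the forward (asymmetric) to the backward
(symmetric) ciliary waveform leaves a characteristic signature in its
track: a near-180 degree reversal of the step heading, a sub-second stretch
of backward motion, and then either a second large heading change (the cell
leaves on a fresh course) or a transient collapse of speed while the cilia
are uncoordinated.  The detector here is a state machine over step headings
and speeds that turns that signature into discrete events, labels every
frame ASYMMETRIC / SYMMETRIC / UNCOORDINATED, and feeds the cohort-level
statistics: spontaneous switch rates, photoshock response metrics,
orientation of travel relative to the attractant source, and the
symmetric:asymmetric residence ratio compared between source-ward and
sink-ward movement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tracks import SwitchEvent, Track, TrajectorySet, WaveformState, read_trackmate  # noqa: F401

__all__ = [
    "DetectorParams",
    "Kinematics",
    "WaveformAnnotation",
    "GroupRateResult",
    "compute_kinematics",
    "detect_waveform_switches",
    "annotate_set",
    "switch_rate",
    "photoshock_metrics",
    "classify_orientation",
    "symmetric_asymmetric_ratio",
    "event_detection_scores",
    "read_trackmate",
]

TOWARD_SOURCE = "TOWARD_SOURCE"
TOWARD_SINK = "TOWARD_SINK"


def _wrap(a):
    return -((-np.asarray(a) + np.pi) % (2 * np.pi) - np.pi)


@dataclass
class DetectorParams:
    """Thresholds of the reversal-plus-speed-disruption detector.

    smooth_window: boxcar width (frames) for the smoothed speed trace.
    reversal_threshold: minimum wrapped heading change (rad) to call a
        reversal; default 2*pi/3 sits well between run wobble and the
        near-pi flip of a true waveform switch.
    speed_drop_ratio: speed below this fraction of the local reference —
        the preceding step at candidate entry, the entry step within an
        episode — counts as a disruption (uncoordinated cilia).
    min_event / max_event: admissible event durations (s); symmetric
        episodes last under a second.
    refractory: events separated by less than this (s) are merged.
    min_track_duration: tracks shorter than this (s) are excluded from
        cohort statistics (boundary inclusive).
    """

    smooth_window: int = 3
    reversal_threshold: float = 2.0 * np.pi / 3.0
    speed_drop_ratio: float = 0.5
    min_event: float = 2.0 / 30.0
    max_event: float = 1.0
    refractory: float = 0.2
    min_track_duration: float = 4.0

    def __post_init__(self) -> None:
        if not (0.0 < self.reversal_threshold <= np.pi):
            raise ValueError("reversal_threshold must lie in (0, pi]")
        if not (0.0 < self.min_event <= self.max_event <= 1.0):
            raise ValueError("need 0 < min_event <= max_event <= 1 s")
        if self.smooth_window < 1:
            raise ValueError("smooth_window must be >= 1")


@dataclass
class Kinematics:
    """Per-step speeds and headings of one track.

    ``speeds``/``headings`` have length n_frames - 1 (one per step),
    ``turn_angles`` length n_frames - 2, wrapped to (-pi, pi].
    """

    speeds: np.ndarray
    headings: np.ndarray
    turn_angles: np.ndarray
    smoothed_speeds: np.ndarray
    fps: float


@dataclass
class WaveformAnnotation:
    """Frame labels plus discrete switch events for one track."""

    track_id: int
    states: np.ndarray            # per-frame WaveformState values
    events: list[SwitchEvent]
    eligible: bool = True         # False when the track was too short
    reason: str = ""

    @property
    def n_events(self) -> int:
        return len(self.events)


@dataclass
class GroupRateResult:
    """Cohort symmetric-switch incidence: events per track per second."""

    rates: np.ndarray
    mean: float
    sd: float
    n_tracks: int
    n_excluded: int = 0

    @property
    def sem(self) -> float:
        return float(self.sd / math.sqrt(self.n_tracks)) if self.n_tracks else float("nan")


def compute_kinematics(track: Track, params: DetectorParams | None = None) -> Kinematics:
    """Step speeds (displacement x fps), headings (atan2), wrapped turn
    angles, and a boxcar-smoothed speed trace."""
    params = params or DetectorParams()
    dt = np.diff(track.times)
    fps = 1.0 / float(np.median(dt))
    steps = np.diff(track.positions, axis=0)
    speeds = np.hypot(steps[:, 0], steps[:, 1]) * fps
    headings = np.arctan2(steps[:, 1], steps[:, 0])
    turns = _wrap(np.diff(headings))
    w = min(params.smooth_window, len(speeds))
    kernel = np.ones(w) / w
    smoothed = np.convolve(speeds, kernel, mode="same")
    return Kinematics(speeds, headings, np.atleast_1d(turns), smoothed, fps)


def detect_waveform_switches(
    track: Track, params: DetectorParams | None = None
) -> WaveformAnnotation:
    """Detect symmetric-waveform episodes in one track.

    A candidate event opens at a step whose heading reverses by at least
    ``reversal_threshold`` relative to the preceding step (checked over
    lags up to ``smooth_window`` so a flip spread over two frames still
    triggers), provided the step is taken at swimming speed.  It closes at
    the next reversal — the cell flipping back or leaving on a new course —
    or, failing that, at a collapse of speed below ``speed_drop_ratio`` x
    the speed the episode was entered at (uncoordinated cilia).
    Candidates lasting between ``min_event`` and ``max_event``
    become events; trailing frames are labeled UNCOORDINATED until the
    heading stabilizes (turn < reversal_threshold/4 on two consecutive
    steps); events closer than ``refractory`` merge.

    Tracks shorter than ``min_track_duration`` are returned un-annotated
    with ``eligible=False`` rather than raising.
    """
    params = params or DetectorParams()
    n = track.n_frames
    states = np.full(n, WaveformState.ASYMMETRIC.value, dtype=np.int8)
    if track.duration_s < params.min_track_duration:
        return WaveformAnnotation(
            track.track_id, states, [], eligible=False,
            reason=f"duration {track.duration_s:.2f}s < {params.min_track_duration}s",
        )
    kin = compute_kinematics(track, params)
    fps = kin.fps
    h = kin.headings
    n_steps = len(h)
    max_f = int(round(params.max_event * fps))
    min_f = max(1, int(round(params.min_event * fps)))

    # reversal score: largest wrapped heading change over lags 1..smooth_window
    rev = np.zeros(n_steps, dtype=bool)
    for lag in range(1, params.smooth_window + 1):
        if lag < n_steps:
            d = np.abs(_wrap(h[lag:] - h[:-lag]))
            rev[lag:] |= d >= params.reversal_threshold

    events: list[SwitchEvent] = []
    i = 1
    while i < n_steps:
        # a candidate opens at a reversal taken at swimming speed — a large
        # heading change entered at a fraction of the preceding step's speed
        # is uncoordinated jitter, not backward swimming
        if not rev[i] or kin.speeds[i] < params.speed_drop_ratio * kin.speeds[i - 1]:
            i += 1
            continue
        # step i is the first backward step; find the event end.  The speed
        # disruption is judged against the speed the episode was entered at:
        # swimming speed varies run to run, so a global (track-median)
        # reference would mistake a slow run's backward segment for the
        # uncoordinated phase
        drop = params.speed_drop_ratio * kin.speeds[i]
        back = h[i]  # the episode's backward course
        end = None
        j = i + 1
        while j < n_steps and j - i <= max_f:
            if abs(float(_wrap(h[j] - back))) >= params.reversal_threshold:
                end = j  # heading departs the backward course: cell flipped
                break    # back or left on a new course
            if kin.speeds[j] < drop:
                end = j  # speed collapse: uncoordinated cilia
                break
            j += 1
        if end is None:
            i += 1
            continue
        dur_f = end - i
        if min_f <= dur_f <= max_f:
            pre = h[i - 1]
            events.append(
                SwitchEvent(
                    track_id=track.track_id,
                    start_s=float(track.times[i]),
                    end_s=float(track.times[end]),
                    pre_heading=float(pre),
                    post_heading=np.nan,
                )
            )
            states[i:end] = WaveformState.SYMMETRIC.value
            # trailing uncoordinated frames until heading stabilizes
            k = end
            calm = 0
            while k < n_steps - 1 and k - end < max_f:
                if abs(_wrap(h[k + 1] - h[k])) < params.reversal_threshold / 4.0:
                    calm += 1
                    if calm >= 2:
                        break
                else:
                    calm = 0
                if kin.speeds[k] < drop:
                    states[k] = WaveformState.UNCOORDINATED.value
                k += 1
            post_idx = min(k + 1, n_steps - 1)
            events[-1].post_heading = float(h[post_idx])
            # resume at the closing step: if the event ended on a reversal,
            # that same step may open the next episode
            i = end
        else:
            i = end if dur_f > max_f else i + 1

    events = _merge_refractory(events, params.refractory, params.max_event, states)
    return WaveformAnnotation(track.track_id, states, events)


def _merge_refractory(events, refractory, max_event, states):
    # merge only when the combined episode still fits max_event, so event
    # durations never exceed the physical bound
    if not events:
        return events
    merged = [events[0]]
    for ev in events[1:]:
        prev = merged[-1]
        if (
            ev.start_s - prev.end_s < refractory
            and ev.end_s - prev.start_s <= max_event
        ):
            prev.end_s = ev.end_s
            prev.post_heading = ev.post_heading
        else:
            merged.append(ev)
    return merged


def annotate_set(
    tset: TrajectorySet, params: DetectorParams | None = None
) -> dict[int, WaveformAnnotation]:
    """Run the detector over every track; returns annotations by track id."""
    params = params or DetectorParams()
    return {t.track_id: detect_waveform_switches(t, params) for t in tset}


def switch_rate(
    tset: TrajectorySet,
    params: DetectorParams | None = None,
    annotations: dict[int, WaveformAnnotation] | None = None,
) -> GroupRateResult:
    """Symmetric-waveform incidences per track per second across a cohort.

    Per eligible track (duration >= min_track_duration), rate = detected
    event count / track duration; the cohort mean and sample sd summarize
    the group.
    """
    params = params or DetectorParams()
    annotations = annotations or annotate_set(tset, params)
    rates = []
    excluded = 0
    for t in tset:
        ann = annotations[t.track_id]
        if not ann.eligible:
            excluded += 1
            continue
        rates.append(ann.n_events / t.duration_s)
    if not rates:
        return GroupRateResult(np.array([]), float("nan"), float("nan"), 0, excluded)
    rates = np.asarray(rates)
    sd = float(rates.std(ddof=1)) if len(rates) > 1 else 0.0
    return GroupRateResult(rates, float(rates.mean()), sd, len(rates), excluded)


@dataclass
class PhotoshockResult:
    """Population response to a light flash."""

    responding_fraction: float
    mean_latency_s: float       # event end - flash time, among responders
    latency_sd_s: float
    n_responders: int
    n_tracks: int
    rayleigh_z: float           # uniformity of post-pre heading change
    rayleigh_p: float


def photoshock_metrics(
    tset: TrajectorySet,
    flash_time: float,
    params: DetectorParams | None = None,
    response_window: float = 1.0,
) -> PhotoshockResult:
    """Quantify the population photoshock response.

    Responders are tracks with a detected event starting within
    ``response_window`` seconds after the flash.  Recovery latency is the
    event end minus the flash time (the cell is forward-swimming again);
    heading randomization is tested with a Rayleigh circular-uniformity
    test on post-minus-pre heading changes among responders.
    """
    import pingouin as pg

    params = params or DetectorParams()
    spanning = [
        t for t in tset if t.times[0] <= flash_time <= t.times[-1]
    ]
    if not spanning:
        raise ValueError("no tracks span the flash time")
    latencies, dheads = [], []
    n_resp = 0
    for t in spanning:
        ann = detect_waveform_switches(t, params)
        hit = None
        for ev in ann.events:
            if flash_time <= ev.start_s <= flash_time + response_window:
                hit = ev
                break
        if hit is not None:
            n_resp += 1
            latencies.append(hit.end_s - flash_time)
            if np.isfinite(hit.pre_heading) and np.isfinite(hit.post_heading):
                dheads.append(_wrap(hit.post_heading - hit.pre_heading))
    if n_resp == 0:
        return PhotoshockResult(0.0, float("nan"), float("nan"), 0, len(spanning),
                                float("nan"), float("nan"))
    lat = np.asarray(latencies)
    if len(dheads) >= 5:
        z, p = pg.circ_rayleigh(np.asarray(dheads, dtype=float))
    else:
        z, p = float("nan"), float("nan")
    return PhotoshockResult(
        responding_fraction=n_resp / len(spanning),
        mean_latency_s=float(lat.mean()),
        latency_sd_s=float(lat.std(ddof=1)) if len(lat) > 1 else 0.0,
        n_responders=n_resp,
        n_tracks=len(spanning),
        rayleigh_z=float(z),
        rayleigh_p=float(p),
    )


@dataclass
class OrientedSegment:
    """A between-event stretch of a track with its travel orientation."""

    start_frame: int
    end_frame: int              # half-open
    label: str                  # TOWARD_SOURCE or TOWARD_SINK
    mean_heading: float


def classify_orientation(
    track: Track,
    source_direction,
    params: DetectorParams | None = None,
    annotation: WaveformAnnotation | None = None,
) -> list[OrientedSegment]:
    """Split a track at detected events and label each segment by whether
    its circular-mean heading points within 90 degrees of the source
    (TOWARD_SOURCE, strict) or not (TOWARD_SINK)."""
    params = params or DetectorParams()
    annotation = annotation or detect_waveform_switches(track, params)
    kin = compute_kinematics(track, params)
    src = np.asarray(source_direction, dtype=float)
    nrm = np.hypot(*src)
    if nrm == 0:
        raise ValueError("source_direction must be nonzero")
    src_angle = math.atan2(src[1], src[0])
    fps = kin.fps
    bounds = [0]
    for ev in annotation.events:
        s = int(round((ev.start_s - track.times[0]) * fps))
        e = int(round((ev.end_s - track.times[0]) * fps))
        bounds.extend([s, e])
    bounds.append(len(kin.headings))
    segments = []
    for a, b in zip(bounds[::2], bounds[1::2]):
        if b - a < 1:
            continue
        hs = kin.headings[a:b]
        mean_h = math.atan2(np.sin(hs).sum(), np.cos(hs).sum())
        dev = abs(float(_wrap(mean_h - src_angle)))
        label = TOWARD_SOURCE if dev < np.pi / 2 else TOWARD_SINK
        segments.append(OrientedSegment(a, b, label, mean_h))
    return segments


@dataclass
class RatioResult:
    """Symmetric:asymmetric residence ratio, split by travel orientation."""

    toward_source_mean: float
    toward_source_sd: float
    toward_sink_mean: float
    toward_sink_sd: float
    n_replicates: int
    t_statistic: float
    p_value: float
    per_replicate: pd.DataFrame = field(repr=False, default=None)


def symmetric_asymmetric_ratio(
    tset: TrajectorySet,
    source_direction,
    params: DetectorParams | None = None,
    n_replicates: int = 4,
    mode: str = "frames",
    equal_var: bool = True,
) -> RatioResult:
    """Ratio of symmetric to asymmetric waveform residence, by orientation.

    Tracks are assigned round-robin to ``n_replicates`` replicate subsets.
    Within each replicate, frames are attributed to TOWARD_SOURCE or
    TOWARD_SINK by the detected segment they fall in (event frames inherit
    the orientation of the segment that preceded the switch), and the
    ratio symmetric/asymmetric frame counts is computed per group
    (``mode="events"`` counts events against asymmetric frames instead).
    Group means are compared with a two-sample Student's t-test
    (equal-variance by default; set ``equal_var=False`` for Welch).
    """
    params = params or DetectorParams()
    if mode not in ("frames", "events"):
        raise ValueError("mode must be 'frames' or 'events'")
    eligible = [t for t in tset if t.duration_s >= params.min_track_duration]
    if len(eligible) < n_replicates:
        raise ValueError("fewer eligible tracks than replicates")
    counts = [
        {TOWARD_SOURCE: [0.0, 0.0], TOWARD_SINK: [0.0, 0.0]} for _ in range(n_replicates)
    ]  # [symmetric measure, asymmetric frames]
    fps = tset.fps
    for k, t in enumerate(eligible):
        rep = counts[k % n_replicates]
        ann = detect_waveform_switches(t, params)
        segs = classify_orientation(t, source_direction, params, annotation=ann)
        for seg in segs:
            asym = int(
                np.sum(
                    ann.states[seg.start_frame : seg.end_frame]
                    == WaveformState.ASYMMETRIC.value
                )
            )
            rep[seg.label][1] += asym
        for ev in ann.events:
            s = int(round((ev.start_s - t.times[0]) * fps))
            owner = None
            for seg in segs:
                if seg.end_frame <= s:
                    owner = seg
                else:
                    break
            if owner is None and segs:
                owner = segs[0]
            if owner is None:
                continue
            if mode == "frames":
                rep[owner.label][0] += (ev.end_s - ev.start_s) * fps
            else:
                rep[owner.label][0] += 1.0
    rows = []
    for r, rep in enumerate(counts):
        row = {"replicate": r}
        for g in (TOWARD_SOURCE, TOWARD_SINK):
            sym, asym = rep[g]
            if asym == 0:
                raise ValueError(f"replicate {r}: no asymmetric frames in group {g}")
            row[g] = sym / asym
        rows.append(row)
    df = pd.DataFrame(rows)
    a = df[TOWARD_SOURCE].to_numpy()
    b = df[TOWARD_SINK].to_numpy()
    tt = stats.ttest_ind(a, b, equal_var=equal_var)
    return RatioResult(
        toward_source_mean=float(a.mean()),
        toward_source_sd=float(a.std(ddof=1)),
        toward_sink_mean=float(b.mean()),
        toward_sink_sd=float(b.std(ddof=1)),
        n_replicates=n_replicates,
        t_statistic=float(tt.statistic),
        p_value=float(tt.pvalue),
        per_replicate=df,
    )


def event_detection_scores(
    truth: list[SwitchEvent],
    detected: list[SwitchEvent],
) -> dict:
    """Precision/recall/F1 of detected events against ground truth.

    Events match when they belong to the same track and overlap in time;
    matching is greedy one-to-one in chronological order.
    """
    by_track_truth: dict[int, list[SwitchEvent]] = {}
    for ev in truth:
        by_track_truth.setdefault(ev.track_id, []).append(ev)
    matched_t = 0
    used: dict[int, set[int]] = {}
    for ev in detected:
        cands = by_track_truth.get(ev.track_id, [])
        taken = used.setdefault(ev.track_id, set())
        for i, tv in enumerate(cands):
            if i in taken:
                continue
            if ev.start_s < tv.end_s and tv.start_s < ev.end_s:
                taken.add(i)
                matched_t += 1
                break
    n_truth, n_det = len(truth), len(detected)
    precision = matched_t / n_det if n_det else 1.0
    recall = matched_t / n_truth if n_truth else 1.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "n_truth": n_truth,
        "n_detected": n_det,
    }


def annotations_to_frames(ann: WaveformAnnotation) -> pd.DataFrame:
    """Per-frame (frame, state) table for one track's annotation."""
    return pd.DataFrame(
        {
            "frame": np.arange(len(ann.states)),
            "state": [WaveformState(int(s)).name for s in ann.states],
        }
    )


def events_table(annotations: dict[int, WaveformAnnotation]) -> pd.DataFrame:
    """Cohort event table (track_id, start_s, end_s, duration_s)."""
    rows = [
        {
            "track_id": ev.track_id,
            "start_s": ev.start_s,
            "end_s": ev.end_s,
            "duration_s": ev.duration_s,
        }
        for ann in annotations.values()
        for ev in ann.events
    ]
    return pd.DataFrame(rows, columns=["track_id", "start_s", "end_s", "duration_s"])
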