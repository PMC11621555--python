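"""Track containers and TrackMate-dialect I/O.

Single-cell trajectories are the common currency between the swimmer
simulator and the waveform-switch analysis: a :class:`Track` is a uniformly
sampled (x, y) path in micrometres, a :class:`TrajectorySet` a cohort of
tracks sharing a frame rate.  Synthetic sets may carry ground-truth
per-frame waveform labels and event intervals, which downstream detector
benchmarks consume.

Tables are read and written in the spot-table dialect exported by the
TrackMate particle-tracking plugin (columns ``TRACK_ID``, ``POSITION_X``,
``POSITION_Y``, ``POSITION_T``, ``FRAME``), including the three extra
sub-header rows newer TrackMate versions emit.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WaveformState",
    "Track",
    "SwitchEvent",
    "TrajectorySet",
    "read_trackmate",
    "write_trackmate",
]


class WaveformState(enum.IntEnum):
    """Per-frame ciliary beat state.

    ASYMMETRIC: breaststroke-like beat pulling the cell forward.
    SYMMETRIC: undulatory beat pushing the cell backward (transient, < 1 s).
    UNCOORDINATED: brief post-reversal phase with little net displacement,
    after which the cell leaves in a randomized direction.
    """

    ASYMMETRIC = 0
    SYMMETRIC = 1
    UNCOORDINATED = 2


@dataclass
class SwitchEvent:
    """One symmetric-waveform (backward swimming) episode within a track."""

    track_id: int
    start_s: float
    end_s: float
    pre_heading: float = np.nan   # rad, heading just before the reversal
    post_heading: float = np.nan  # rad, heading once swimming re-stabilizes

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class Track:
    """A uniformly sampled single-cell trajectory.

    ``times`` are seconds with strict 1/fps spacing; ``positions`` is an
    (n, 2) float array in micrometres.
    """

    track_id: int
    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 2:
            raise ValueError(f"track {self.track_id}: need >= 2 points")
        if self.positions.shape != (len(self.times), 2):
            raise ValueError(f"track {self.track_id}: positions must be (n, 2)")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError(f"track {self.track_id}: times must strictly increase")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError(f"track {self.track_id}: non-finite positions")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def duration_s(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass
class TrajectorySet:
    """A cohort of tracks at a common frame rate, with optional ground truth.

    ``truth_labels`` maps track_id -> per-frame :class:`WaveformState` array
    (same length as the track); ``truth_events`` lists the true symmetric
    episodes.  Both are populated only by the synthetic generator.
    """

    tracks: list[Track]
    fps: float
    truth_labels: dict[int, np.ndarray] = field(default_factory=dict)
    truth_events: list[SwitchEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        for t in self.tracks:
            lab = self.truth_labels.get(t.track_id)
            if lab is not None and len(lab) != t.n_frames:
                raise ValueError(f"track {t.track_id}: label length mismatch")

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)

    def track(self, track_id: int) -> Track:
        for t in self.tracks:
            if t.track_id == track_id:
                return t
        raise KeyError(track_id)


_REQUIRED = ("TRACK_ID", "POSITION_X", "POSITION_Y")


def write_trackmate(tset: TrajectorySet, path, truth: bool = False) -> None:
    """Write a cohort as a TrackMate-style spots CSV.

    One row per spot with TRACK_ID, POSITION_X, POSITION_Y, POSITION_T and
    FRAME; with ``truth=True`` an extra TRUTH_STATE column carries the
    generator's per-frame waveform labels (fixture use only).
    """
    rows = []
    for t in tset.tracks:
        frames = np.round(t.times * tset.fps).astype(int)
        rec = {
            "TRACK_ID": np.full(t.n_frames, t.track_id),
            "POSITION_X": t.positions[:, 0],
            "POSITION_Y": t.positions[:, 1],
            "POSITION_T": t.times,
            "FRAME": frames,
        }
        if truth:
            lab = tset.truth_labels.get(t.track_id)
            if lab is None:
                lab = np.zeros(t.n_frames, dtype=int)
            rec["TRUTH_STATE"] = [WaveformState(int(s)).name for s in lab]
        rows.append(pd.DataFrame(rec))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format="%.6f")


def _strip_subheaders(df: pd.DataFrame) -> pd.DataFrame:
    # TrackMate >= 7 emits 3 extra non-numeric sub-header rows (human-readable
    # names, units, a blank-ish row) directly under the column names.
    head = df.head(4)
    drop = []
    for i, (_, row) in enumerate(head.iterrows()):
        try:
            float(row["TRACK_ID"])
        except (TypeError, ValueError):
            drop.append(df.index[i])
    return df.drop(index=drop)


def read_trackmate(
    path,
    fps: float | None = None,
    max_gap_frames: int = 2,
) -> TrajectorySet:
    """Read a TrackMate spots CSV into a :class:`TrajectorySet`.

    fps is inferred from POSITION_T spacing when not supplied.  Missing
    detections (gaps in FRAME) of at most ``max_gap_frames`` are filled by
    linear interpolation; longer gaps split the track in two (the fragment
    keeps a derived id).  TRUTH_STATE columns written by
    :func:`write_trackmate` round-trip into ``truth_labels``.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    if "FRAME" not in df.columns and "POSITION_T" not in df.columns:
        raise ValueError("missing required column(s): FRAME or POSITION_T")
    df = _strip_subheaders(df)
    for c in ("TRACK_ID", "POSITION_X", "POSITION_Y", "POSITION_T", "FRAME"):
        if c in df.columns:
            df[c] = pd.to_numeric(df[c])

    if "FRAME" not in df.columns:
        if fps is None:
            fps = _infer_fps(df["POSITION_T"].to_numpy())
        df = df.assign(FRAME=np.round(df["POSITION_T"] * fps).astype(int))
    if fps is None:
        if "POSITION_T" in df.columns:
            fps = _infer_fps(df["POSITION_T"].to_numpy(), df["FRAME"].to_numpy())
        else:
            raise ValueError("fps not supplied and no POSITION_T column to infer it")

    has_truth = "TRUTH_STATE" in df.columns
    tracks: list[Track] = []
    labels: dict[int, np.ndarray] = {}
    for tid, g in df.groupby("TRACK_ID", sort=True):
        g = g.sort_values("FRAME")
        frames = g["FRAME"].to_numpy(dtype=int)
        if len(np.unique(frames)) != len(frames):
            raise ValueError(f"track {int(tid)}: duplicate frames")
        xy = g[["POSITION_X", "POSITION_Y"]].to_numpy(dtype=float)
        states = (
            np.array([WaveformState[s].value for s in g["TRUTH_STATE"]])
            if has_truth
            else None
        )
        for sub_id, fr, pos, lab in _split_and_fill(
            int(tid), frames, xy, states, max_gap_frames
        ):
            if len(fr) < 2:
                continue
            tracks.append(Track(sub_id, fr / fps, pos))
            if lab is not None:
                labels[sub_id] = lab
    return TrajectorySet(tracks=tracks, fps=float(fps), truth_labels=labels)


def _infer_fps(times: np.ndarray, frames: np.ndarray | None = None) -> float:
    times = np.asarray(times, dtype=float)
    if frames is not None:
        span = frames.max() - frames.min()
        if span > 0:
            return float(span / (times.max() - times.min()))
    dt = np.diff(np.unique(times))
    dt = dt[dt > 0]
    if len(dt) == 0:
        raise ValueError("cannot infer fps from POSITION_T")
    step = float(np.median(dt))
    rel = np.abs(dt - step) / step
    if np.any(rel > 0.01):
        raise ValueError("non-uniform frame spacing in POSITION_T")
    return 1.0 / step


def _split_and_fill(tid, frames, xy, states, max_gap):
    """Yield (track_id, frames, positions, labels) pieces after gap handling."""
    gaps = np.diff(frames)
    cut = np.where(gaps > max_gap + 1)[0] + 1
    pieces = np.split(np.arange(len(frames)), cut)
    for k, idx in enumerate(pieces):
        sub_id = tid if len(pieces) == 1 else tid * 1000 + k
        fr = frames[idx]
        full = np.arange(fr[0], fr[-1] + 1)
        pos = np.empty((len(full), 2))
        for d in range(2):
            pos[:, d] = np.interp(full, fr, xy[idx, d])
        lab = None
        if states is not None:
            # nearest-neighbour fill for categorical labels
            nearest = np.searchsorted(fr, full).clip(0, len(fr) - 1)
            lab = states[idx][nearest]
        yield sub_id, full.astype(float), pos, lab
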