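"""Chemotaxis Lane Assay (CLA) quantification.

The lane assay reads chemotaxis from time-lapse images of cells in long
narrow lanes connecting a chemical source to a sink.  The chain is:

1. extract a 1-D intensity profile per lane and frame (average across the
   lane width, bin along the length);
2. express each profile as the percent change from its spatial mean,
   PCM(x, t) = 100 * (I(x, t) - mean_x I(x, t)) / mean_x I(x, t);
3. fit an ordinary least-squares line of PCM against position at each
   timepoint; the slope scaled to the full lane length is the Slope Index
   (percent per lane), positive when cells accumulate at the source;
4. the maximum Slope Index over the time course is the Chemotaxis Index.

Assay quality over positive/negative control replicates is summarized by
the Z-factor, Z' = 1 - 3(sigma_p + sigma_n)/|mu_p - mu_n|; Z' > 0.5 marks
an excellent screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LaneGeometry",
    "IntensityProfile",
    "ChemotaxisResult",
    "extract_profiles",
    "compute_pcm",
    "slope_index",
    "chemotaxis_index",
    "analyze_profile",
    "z_factor",
    "ZFactorUndefined",
]


@dataclass
class LaneGeometry:
    """Pixel layout of the lanes within an image stack.

    ``lane_bounds`` lists one (row0, row1, col0, col1) half-open pixel
    rectangle per lane; columns run along the lane length.  ``source_end``
    says which column end abuts the source reservoir.
    """

    lane_bounds: list[tuple[int, int, int, int]]
    px_per_mm: float
    source_end: str = "high"
    lane_length_mm: float = 60.0
    lane_width_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.px_per_mm <= 0 or self.lane_length_mm <= 0 or self.lane_width_mm <= 0:
            raise ValueError("geometry dimensions must be positive")
        if self.source_end not in ("low", "high"):
            raise ValueError("source_end must be 'low' or 'high'")
        for b in self.lane_bounds:
            r0, r1, c0, c1 = b
            if r1 <= r0 or c1 <= c0:
                raise ValueError(f"degenerate lane bounds {b}")


@dataclass
class IntensityProfile:
    """Lane intensity as a position x time matrix on a physical grid.

    Positions (mm) are oriented so they increase toward the source end;
    times in hours.  Values are on the 8-bit scale (after any inversion).
    """

    positions_mm: np.ndarray
    times_h: np.ndarray
    intensity: np.ndarray
    lane_id: int = 0
    oriented_toward_source: bool = True

    def __post_init__(self) -> None:
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (len(self.positions_mm), len(self.times_h)):
            raise ValueError("intensity must have shape (n_positions, n_times)")


@dataclass
class ChemotaxisResult:
    """PCM matrix, Slope Index series, and the Chemotaxis Index of one lane."""

    pcm: np.ndarray                # percent, positions x times
    slope_index: np.ndarray        # percent per lane, per timepoint
    times_h: np.ndarray
    chemotaxis_index: float
    t_max: float
    lane_id: int = 0

    def summary(self) -> dict:
        return {
            "lane": self.lane_id,
            "chemotaxis_index": self.chemotaxis_index,
            "t_max_h": self.t_max,
        }


def extract_profiles(
    stack: np.ndarray,
    geometry: LaneGeometry,
    times_h,
    bin_mm: float = 1.0,
    invert: bool = False,
) -> list[IntensityProfile]:
    """Reduce an aligned image stack to one intensity profile per lane.

    For each lane and frame, pixel rows across the lane width are averaged
    into a 1-D profile along the length, then mean-binned onto a regular
    ``bin_mm`` grid.  Profiles are oriented so position increases toward
    the source.  ``invert`` applies the 8-bit inversion (255 - I) for
    stacks where dense cells image dark.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be (n_frames, height, width)")
    n_t, H, W = stack.shape
    times_h = np.asarray(times_h, dtype=float)
    if len(times_h) != n_t:
        raise ValueError("times_h length must match number of frames")
    out = []
    for lane_id, (r0, r1, c0, c1) in enumerate(geometry.lane_bounds):
        if not (0 <= r0 < r1 <= H and 0 <= c0 < c1 <= W):
            raise ValueError(f"lane {lane_id}: bounds outside image")
        sub = stack[:, r0:r1, c0:c1].astype(float)
        if invert:
            sub = 255.0 - sub
        prof_px = sub.mean(axis=1)  # (n_t, n_cols)
        n_cols = c1 - c0
        px_mm = (np.arange(n_cols) + 0.5) / geometry.px_per_mm
        edges = np.arange(0.0, px_mm[-1] + bin_mm, bin_mm)
        if len(edges) < 3:
            raise ValueError(f"lane {lane_id}: fewer than 2 position bins")
        which = np.clip(np.digitize(px_mm, edges) - 1, 0, len(edges) - 2)
        centers = 0.5 * (edges[:-1] + edges[1:])
        binned = np.empty((len(centers), n_t))
        for b in range(len(centers)):
            sel = which == b
            binned[b] = prof_px[:, sel].mean(axis=1) if sel.any() else np.nan
        keep = ~np.isnan(binned[:, 0])
        binned, centers = binned[keep], centers[keep]
        if geometry.source_end == "low":
            binned = binned[::-1]
            centers = centers[-1] - centers[::-1]
        out.append(
            IntensityProfile(
                positions_mm=centers,
                times_h=times_h,
                intensity=binned,
                lane_id=lane_id,
                oriented_toward_source=True,
            )
        )
    return out


def compute_pcm(profile: IntensityProfile) -> np.ndarray:
    """Percent change from the lane's spatial mean, per position and time.

    PCM(x, t) = 100 * (I(x, t) - mean_x I(., t)) / mean_x I(., t).  Using
    the same-timepoint spatial mean makes the metric invariant to global
    illumination scaling; it is zero-mean in x at every t.
    """
    I = profile.intensity
    if I.shape[0] < 2:
        raise ValueError("need at least 2 positions")
    mean_t = I.mean(axis=0, keepdims=True)
    if np.any(mean_t == 0):
        raise ValueError("empty lane: zero mean intensity at some timepoint")
    return 100.0 * (I - mean_t) / mean_t


def slope_index(
    pcm: np.ndarray,
    positions_mm: np.ndarray,
    lane_length_mm: float = 60.0,
) -> np.ndarray:
    """OLS slope of PCM against position, scaled to percent per lane.

    The fit runs over the full lane at each timepoint; multiplying the
    per-mm slope by the lane length reports the index on a binning-
    independent scale.  Positive means accumulation toward the source.
    """
    positions_mm = np.asarray(positions_mm, dtype=float)
    if pcm.shape[0] < 2:
        raise ValueError("need at least 2 positions")
    x = positions_mm - positions_mm.mean()
    denom = float(np.sum(x**2))
    slopes = (x[None, :] @ pcm).ravel() / denom  # percent per mm
    return slopes * lane_length_mm


def chemotaxis_index(slopes: np.ndarray, times_h: np.ndarray) -> tuple[float, float]:
    """Maximum of the Slope Index series and the hour it occurs.

    Ties break toward the earliest time.
    """
    slopes = np.asarray(slopes, dtype=float)
    times_h = np.asarray(times_h, dtype=float)
    if slopes.size == 0:
        raise ValueError("empty slope series")
    i = int(np.argmax(slopes))  # argmax returns the first maximum
    return float(slopes[i]), float(times_h[i])


def analyze_profile(
    profile: IntensityProfile, lane_length_mm: float = 60.0
) -> ChemotaxisResult:
    """Full per-lane chain: PCM -> Slope Index series -> Chemotaxis Index."""
    pcm = compute_pcm(profile)
    slopes = slope_index(pcm, profile.positions_mm, lane_length_mm)
    ci, t_max = chemotaxis_index(slopes, profile.times_h)
    return ChemotaxisResult(
        pcm=pcm,
        slope_index=slopes,
        times_h=profile.times_h,
        chemotaxis_index=ci,
        t_max=t_max,
        lane_id=profile.lane_id,
    )


class ZFactorUndefined(ValueError):
    """Positive and negative control means coincide; Z' is undefined."""


def z_factor(positive, negative) -> float:
    """Z' = 1 - 3(sigma_p + sigma_n) / |mu_p - mu_n| over control replicates.

    Sample standard deviations (ddof=1).  1 is an ideal assay; values above
    0.5 denote an excellent screen; <= 0 means no separation.
    """
    p = np.asarray(positive, dtype=float)
    n = np.asarray(negative, dtype=float)
    if len(p) < 2 or len(n) < 2:
        raise ValueError("need at least 2 replicates per control group")
    sep = abs(p.mean() - n.mean())
    if sep == 0:
        raise ZFactorUndefined("control group means are equal")
    return float(1.0 - 3.0 * (p.std(ddof=1) + n.std(ddof=1)) / sep)


def results_table(results: list[ChemotaxisResult]) -> pd.DataFrame:
    """Summary table (lane, chemotaxis_index, t_max_h) across lanes."""
    return pd.DataFrame([r.summary() for r in results])
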