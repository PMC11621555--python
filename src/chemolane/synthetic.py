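"""Synthetic swimmers, lane-image stacks, and diffusion profiles.

Every downstream stage of the pipeline — the switch detector, the lane
quantification chain, the diffusion fit — is validated against data with
known ground truth produced here.

The swimmer model is a 2-D run-and-reverse walk mimicking *Chlamydomonas*:
cells swim forward in runs (asymmetric ciliary waveform, heading subject to
rotational diffusion) and stochastically switch to a sub-second backward
episode (symmetric waveform), after which the cilia are briefly
uncoordinated and the cell leaves in a fresh, uniformly random direction.
The per-second switch hazard is modulated by the swimming direction
relative to an attractant gradient,

    lambda(theta) = lambda0 * (1 - beta * cos(theta)),

theta being the angle between the heading and the gradient direction: cells
swimming up-gradient reverse less often, which alone produces net drift
toward the source (a biased random walk — no gradient steering within a
run).  beta = 0 recovers unbiased spontaneous switching.

``lambda0`` is specified as the *observable* statistic the tracking
analysis estimates — symmetric-waveform events per track per second.
Because the hazard is only active while a cell swims forward, the
instantaneous hazard is internally scaled by 1/(1 - lambda0 * tau_dead),
where tau_dead is the mean time an event plus recovery consumes, so the
realized event rate per total second equals lambda0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .diffusion import DiffusionProfile, fick_concentration
from .tracks import SwitchEvent, Track, TrajectorySet, WaveformState

__all__ = [
    "SwimConfig",
    "LaneImageConfig",
    "simulate_tracks",
    "simulate_photoshock",
    "simulate_diffusion_profiles",
    "render_lane_stack",
    "write_tiff",
    "read_tiff",
]


@dataclass
class SwimConfig:
    """Parameters of the run-and-reverse swimmer simulation.

    Speeds are µm·s⁻¹, the arena is a width x height rectangle in µm with
    reflecting walls, ``rot_diffusion`` (rad²·s⁻¹) sets heading wobble
    during runs, ``switch_rate_base`` is the spontaneous event rate λ₀
    (events per track-second), ``bias`` the dimensionless gradient coupling
    β ∈ [0, 1), and symmetric-event durations are Normal(mean, sd) truncated
    to (0, 1) s.  ``base_speed_mean`` defaults to 100 µm·s⁻¹, a typical
    order of magnitude for a swimming alga; treat it as a free parameter.
    """

    n_cells: int = 100
    duration: float = 20.0
    fps: float = 30.0
    arena: tuple[float, float] = (2000.0, 2000.0)
    base_speed_mean: float = 100.0
    base_speed_sd: float = 20.0
    rot_diffusion: float = 0.1
    switch_rate_base: float = 0.085
    bias: float = 0.0
    gradient_direction: tuple[float, float] = (1.0, 0.0)
    sym_duration_mean: float = 0.5
    sym_duration_sd: float = 0.15
    reverse_speed_factor: float = 0.8
    uncoordinated_speed_factor: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        vals = [
            self.n_cells, self.duration, self.fps, *self.arena,
            self.base_speed_mean, self.base_speed_sd, self.rot_diffusion,
            self.switch_rate_base, self.bias, *self.gradient_direction,
            self.sym_duration_mean, self.sym_duration_sd,
            self.reverse_speed_factor, self.uncoordinated_speed_factor,
        ]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("SwimConfig values must be finite")
        if self.fps <= 0 or self.duration <= 0 or self.n_cells < 1:
            raise ValueError("fps, duration and n_cells must be positive")
        if self.switch_rate_base < 0:
            raise ValueError("switch_rate_base must be >= 0")
        if not (0.0 <= self.bias < 1.0):
            raise ValueError("bias must lie in [0, 1)")
        if self.arena[0] <= 0 or self.arena[1] <= 0:
            raise ValueError("arena dimensions must be positive")
        n = math.hypot(*self.gradient_direction)
        if n == 0:
            raise ValueError("gradient_direction must be a nonzero vector")
        self.gradient_direction = (
            self.gradient_direction[0] / n,
            self.gradient_direction[1] / n,
        )

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.fps)) + 1

    def mean_dead_time(self) -> float:
        """Mean seconds a symmetric event plus uncoordinated recovery lasts."""
        return self.sym_duration_mean + 2.0 / self.fps  # 1-3 frames, mean 2

    def hazard_scale(self) -> float:
        """Factor converting λ₀ (events per track-second) to the
        instantaneous in-run hazard, compensating event dead time."""
        c = 1.0 - self.switch_rate_base * self.mean_dead_time()
        if c <= 0.1:
            raise ValueError("switch_rate_base too high for the event duration")
        return 1.0 / c


@dataclass
class LaneImageConfig:
    """Parameters of the rendered lane-image time series.

    The lane is ``lane_length`` x ``lane_width`` mm imaged at ``px_per_mm``;
    frames are taken at ``timepoints`` (hours).  The cell-density field
    starts uniform at ``density_baseline`` (8-bit intensity after the usual
    greyscale inversion, so brighter = denser) and is advected toward the
    source end at ``drift_velocity`` mm·h⁻¹, conserving total density;
    ``noise_sd`` adds per-pixel Gaussian noise.
    """

    lane_length: float = 60.0
    lane_width: float = 3.0
    px_per_mm: float = 5.0
    timepoints: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 24.0 + 1e-9, 0.5)
    )
    drift_velocity: float = 1.0
    cell_diffusivity: float = 50.0  # mm^2/h, dispersal from motility
    density_baseline: float = 60.0
    noise_sd: float = 2.0
    source_end: str = "high"  # which x end abuts the source reservoir
    n_lanes: int = 1
    lane_gap_px: int = 4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        if self.lane_length <= 0 or self.lane_width <= 0 or self.px_per_mm <= 0:
            raise ValueError("lane dimensions and px_per_mm must be positive")
        if self.source_end not in ("low", "high"):
            raise ValueError("source_end must be 'low' or 'high'")
        if self.n_lanes < 1:
            raise ValueError("n_lanes must be >= 1")
        if np.any(self.timepoints < 0) or np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be non-negative and increasing")

    @property
    def n_px_length(self) -> int:
        return int(round(self.lane_length * self.px_per_mm))

    @property
    def n_px_width(self) -> int:
        return max(1, int(round(self.lane_width * self.px_per_mm)))


def _wrap(a):
    """Wrap angle(s) to (-pi, pi]."""
    return -((-np.asarray(a) + np.pi) % (2 * np.pi) - np.pi)


def simulate_tracks(config: SwimConfig) -> TrajectorySet:
    """Simulate a cohort of run-and-reverse swimmers with ground truth.

    Returns a :class:`TrajectorySet` whose ``truth_labels`` give the
    per-frame waveform state and ``truth_events`` the symmetric episodes
    (start/end seconds).  Bit-reproducible for a given ``rng_seed``: each
    cell consumes an independent child stream of the seed sequence.
    """
    return _simulate(config, flash_time=None)


def simulate_photoshock(config: SwimConfig, flash_time: float) -> TrajectorySet:
    """Simulate a cohort subjected to a light flash at ``flash_time``.

    Identical to :func:`simulate_tracks` except that every cell
    deterministically enters a symmetric (backward-swimming) event at the
    flash, with duration drawn from the configured distribution — the
    population-wide photoshock response used to characterize the symmetric
    waveform.
    """
    if not (0.0 < flash_time < config.duration):
        raise ValueError("flash_time must lie strictly inside the recording")
    return _simulate(config, flash_time=flash_time)


def _simulate(config: SwimConfig, flash_time: float | None) -> TrajectorySet:
    dt = 1.0 / config.fps
    n_frames = config.n_frames
    scale = config.hazard_scale()
    grad_angle = math.atan2(config.gradient_direction[1], config.gradient_direction[0])
    flash_frame = None if flash_time is None else int(round(flash_time * config.fps))
    max_event_frames = int(math.floor(config.fps * 0.999))  # events stay < 1 s

    seeds = np.random.SeedSequence(config.rng_seed).spawn(config.n_cells)
    tracks: list[Track] = []
    labels: dict[int, np.ndarray] = {}
    events: list[SwitchEvent] = []

    for cid in range(config.n_cells):
        rng = np.random.default_rng(seeds[cid])
        pos = np.empty((n_frames, 2))
        lab = np.full(n_frames, WaveformState.ASYMMETRIC.value, dtype=np.int8)
        pos[0] = rng.uniform([0, 0], config.arena)
        heading = rng.uniform(0.0, 2 * np.pi)
        run_speed = _draw_speed(rng, config)

        state = WaveformState.ASYMMETRIC
        frames_left = 0          # countdown within SYM / UNC phases
        event_start_frame = 0
        pre_heading = heading

        f = 0
        while f < n_frames - 1:
            forced = flash_frame is not None and f == flash_frame
            if state == WaveformState.ASYMMETRIC:
                lam = (
                    scale
                    * config.switch_rate_base
                    * (1.0 - config.bias * math.cos(heading - grad_angle))
                )
                spontaneous = lam > 0 and rng.random() < -math.expm1(-lam * dt)
                if forced or spontaneous:
                    dur = _draw_sym_duration(rng, config)
                    frames_left = min(
                        max(2, int(round(dur * config.fps))), max_event_frames
                    )
                    pre_heading = heading
                    heading = _wrap(heading + np.pi)
                    state = WaveformState.SYMMETRIC
                    event_start_frame = f
            elif forced:
                # flash during an ongoing event: restart it from here
                if state == WaveformState.SYMMETRIC:
                    events.append(
                        _event(cid, event_start_frame, f, config.fps, pre_heading, heading)
                    )
                dur = _draw_sym_duration(rng, config)
                frames_left = min(max(2, int(round(dur * config.fps))), max_event_frames)
                heading = _wrap(heading + np.pi) if state != WaveformState.SYMMETRIC else heading
                state = WaveformState.SYMMETRIC
                event_start_frame = f

            if state == WaveformState.ASYMMETRIC:
                lab[f] = WaveformState.ASYMMETRIC.value
                step = run_speed * dt
                heading += math.sqrt(2.0 * config.rot_diffusion * dt) * rng.standard_normal()
                heading = float(_wrap(heading))
            elif state == WaveformState.SYMMETRIC:
                lab[f] = WaveformState.SYMMETRIC.value
                step = config.reverse_speed_factor * run_speed * dt
                frames_left -= 1
                if frames_left == 0:
                    events.append(
                        _event(cid, event_start_frame, f + 1, config.fps, pre_heading, np.nan)
                    )
                    state = WaveformState.UNCOORDINATED
                    frames_left = int(rng.integers(1, 4))  # 1-3 frames
            else:  # UNCOORDINATED: low displacement, incoherent direction
                lab[f] = WaveformState.UNCOORDINATED.value
                step = config.uncoordinated_speed_factor * run_speed * dt
                heading = rng.uniform(0.0, 2 * np.pi)
                frames_left -= 1
                if frames_left == 0:
                    state = WaveformState.ASYMMETRIC
                    heading = rng.uniform(0.0, 2 * np.pi)  # randomized new course
                    run_speed = _draw_speed(rng, config)
                    if events and events[-1].track_id == cid:
                        events[-1].post_heading = float(_wrap(heading))

            new = pos[f] + step * np.array([math.cos(heading), math.sin(heading)])
            new, heading = _reflect(new, heading, config.arena)
            pos[f + 1] = new
            f += 1

        if state == WaveformState.SYMMETRIC:  # event truncated by track end
            events.append(
                _event(cid, event_start_frame, n_frames - 1, config.fps, pre_heading, heading)
            )
            lab[n_frames - 1] = WaveformState.SYMMETRIC.value
        else:
            lab[n_frames - 1] = state.value

        times = np.arange(n_frames) / config.fps
        tracks.append(Track(cid, times, pos))
        labels[cid] = lab

    return TrajectorySet(
        tracks=tracks, fps=config.fps, truth_labels=labels, truth_events=events
    )


def _event(cid, f0, f1, fps, pre, post):
    return SwitchEvent(
        track_id=cid,
        start_s=f0 / fps,
        end_s=f1 / fps,
        pre_heading=float(_wrap(pre)),
        post_heading=float(_wrap(post)),
    )


def _draw_speed(rng, config):
    s = rng.normal(config.base_speed_mean, config.base_speed_sd)
    return max(s, 0.1 * config.base_speed_mean)


def _draw_sym_duration(rng, config):
    # truncated to (0, 1) s by rejection; symmetric events never reach 1 s
    for _ in range(100):
        d = rng.normal(config.sym_duration_mean, config.sym_duration_sd)
        if 0.0 < d < 1.0:
            return d
    return min(max(config.sym_duration_mean, 0.05), 0.95)


def _reflect(p, heading, arena):
    """Reflect a position (and heading) at the arena walls."""
    x, y = p
    hx, hy = math.cos(heading), math.sin(heading)
    if x < 0:
        x, hx = -x, -hx
    elif x > arena[0]:
        x, hx = 2 * arena[0] - x, -hx
    if y < 0:
        y, hy = -y, -hy
    elif y > arena[1]:
        y, hy = 2 * arena[1] - y, -hy
    return np.array([x, y]), math.atan2(hy, hx)


def simulate_diffusion_profiles(
    D: float,
    c0: float,
    times_h,
    positions_mm,
    noise_frac: float = 0.0,
    rng_seed: int = 0,
) -> DiffusionProfile:
    """Noisy erfc-shaped concentration profiles at the given grid.

    Evaluates the semi-infinite constant-source solution at ``positions_mm``
    x ``times_h`` and applies multiplicative Gaussian noise of relative
    standard deviation ``noise_frac`` (0 reproduces the closed form
    exactly), emulating repeated dye-intensity measurements along a lane.
    """
    if not np.isfinite(D) or D <= 0:
        raise ValueError("D must be positive")
    times_h = np.asarray(times_h, dtype=float)
    positions_mm = np.asarray(positions_mm, dtype=float)
    xg, tg = np.meshgrid(positions_mm, times_h * 3600.0, indexing="ij")
    clean = fick_concentration(xg, tg, D, c0)
    if noise_frac > 0:
        rng = np.random.default_rng(rng_seed)
        clean = clean * (1.0 + noise_frac * rng.standard_normal(clean.shape))
    return DiffusionProfile(positions_mm, times_h, clean, c0=c0)


def _advect_density(
    n_cells: int,
    drift_px_per_h: float,
    times_h: np.ndarray,
    diff_px2_per_h: float = 0.0,
) -> np.ndarray:
    """Conservative advection-diffusion of an initially uniform 1-D density.

    Density drifts toward the high-index end with zero-flux walls while
    motility-driven dispersal (``diff_px2_per_h``) spreads it, so mass
    accumulates in a bounded boundary layer at the source instead of a
    single-pixel pile; returns shape (n_times, n_cells) with mean 1.
    Finite-volume upwind advection + explicit diffusion, both conservative.
    """
    rho = np.ones(n_cells)
    out = np.empty((len(times_h), n_cells))
    t_prev = 0.0
    for i, t in enumerate(times_h):
        span = t - t_prev
        if span > 0 and (drift_px_per_h != 0 or diff_px2_per_h != 0):
            # substeps satisfying CFL (advection) and r <= 0.4 (diffusion)
            n_adv = abs(drift_px_per_h) * span / 0.9
            n_dif = diff_px2_per_h * span / 0.4
            n_sub = max(1, int(math.ceil(max(n_adv, n_dif))))
            dt = span / n_sub
            c = drift_px_per_h * dt
            r = diff_px2_per_h * dt
            for _ in range(n_sub):
                if c != 0:
                    flux = c * rho[:-1]  # toward the high-index (source) end
                    rho[:-1] -= flux
                    rho[1:] += flux
                if r != 0:
                    dflux = r * np.diff(rho)  # Fickian, zero-flux walls
                    rho[:-1] += dflux
                    rho[1:] -= dflux
        out[i] = rho
        t_prev = t
    return out


def render_lane_stack(config: LaneImageConfig) -> np.ndarray:
    """Render an 8-bit grayscale image stack of drifting lane density.

    Returns an array (n_timepoints, height, width).  Intensity encodes cell
    density (inverted greyscale convention): each frame is the advected 1-D
    density profile times ``density_baseline``, broadcast across the lane
    width, plus Gaussian pixel noise, clipped to [0, 255].  Total lane
    intensity is conserved up to clipping because cells relocate rather
    than appear.
    """
    nx, ny = config.n_px_length, config.n_px_width
    drift_px = config.drift_velocity * config.px_per_mm
    diff_px2 = config.cell_diffusivity * config.px_per_mm**2
    dens = _advect_density(nx, drift_px, config.timepoints, diff_px2)
    if config.source_end == "low":
        dens = dens[:, ::-1]
    rng = np.random.default_rng(config.rng_seed)
    height = config.n_lanes * ny + (config.n_lanes - 1) * config.lane_gap_px
    stack = np.zeros((len(config.timepoints), height, nx), dtype=np.uint8)
    for lane in range(config.n_lanes):
        r0 = lane * (ny + config.lane_gap_px)
        base = dens * config.density_baseline  # (T, nx)
        frames = np.repeat(base[:, None, :], ny, axis=1)
        if config.noise_sd > 0:
            frames = frames + config.noise_sd * rng.standard_normal(frames.shape)
        stack[:, r0 : r0 + ny, :] = np.clip(np.round(frames), 0, 255).astype(np.uint8)
    return stack


def write_tiff(stack: np.ndarray, path) -> None:
    """Write an image stack as a multi-page 8-bit grayscale TIFF."""
    import tifffile

    tifffile.imwrite(path, np.asarray(stack, dtype=np.uint8), photometric="minisblack")


def read_tiff(path) -> np.ndarray:
    """Read a multi-page TIFF stack as (n_frames, height, width)."""
    import tifffile

    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def config_to_dict(config) -> dict:
    """Serializable echo of any generator config (for run logs)."""
    d = asdict(config)
    for k, v in d.items():
        if isinstance(v, np.ndarray):
            d[k] = v.tolist()
    return d
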