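# Methods

`chemolane` implements the quantitative chain used to study ammonium
chemotaxis in a swimming microalga (*Chlamydomonas*-like): how a chemical
gradient forms in a lane assay, how cell accumulation in that assay is
turned into a Chemotaxis Index, and how single-cell tracks reveal the
steering mechanism — transient switches from the forward (asymmetric) to
the backward (symmetric) ciliary waveform whose rate depends on swimming
direction relative to the gradient.  Because the study's raw videos and
plate images are available only on request, the package pairs every
analysis stage with a ground-truthed synthetic generator; all quantitative
claims made by the test suite are claims about recovery of known inputs.

## Gradient model (`chemolane.diffusion`)

The source reservoir is treated as an infinite reservoir of constant
concentration C0 feeding a semi-infinite lane, so Fick's second law gives

    C(x, t) = C0 · erfc( x / (2·√(D·t)) ),

with x the distance from the source barrier and D the diffusion
coefficient (cm²·s⁻¹; inputs in mm and hours are converted at the
boundary).  At t = 0 the limit convention C(0,0) = C0, C(x>0, 0) = 0
applies.  `fit_diffusion_coefficient` minimizes squared residuals of this
form over all samples with t > 0 (t = 0 columns only restate the initial
condition and are excluded).  D — and C0, when it is fit jointly — are
optimized in log space: positivity is enforced structurally and
convergence becomes insensitive to the numerical scale of D (initial value
1 × 10⁻⁵ cm²·s⁻¹).  Whether C0 should be fixed (it is nominally known
from the loaded source) or fit jointly is genuinely open; both modes are
provided and agree to well under a percent on clean data.  The closed form
is validated in the tests against an explicit finite-difference
integration of the PDE with a fixed-concentration boundary on a long
domain (< 0.5% relative disagreement).

## Lane-assay quantification (`chemolane.cla`)

Per lane and frame, pixel rows across the 3 mm lane width are averaged
into a 1-D intensity profile along the 60 mm length, binned to a 1 mm
grid, and oriented so position increases toward the source.  The chain is

    PCM(x, t) = 100 · (I(x,t) − Ī(t)) / Ī(t),      Ī(t) = spatial mean,
    Slope Index(t) = OLS slope of PCM vs x · lane length   [% per lane],
    Chemotaxis Index = max_t Slope Index(t)   (ties → earliest t).

Design choices: the PCM baseline is the *same-timepoint* spatial mean, not
the t = 0 profile — this makes the whole chain exactly invariant to global
illumination scaling, which the tests check end to end.  The slope is
reported × lane length so it does not depend on the binning grid.
Accumulation at the source is positive by convention; flipping the
declared source end negates the series exactly.  Registration of raw
frames is out of scope: the pipeline assumes aligned stacks and validates
frame-shape consistency only.

Assay quality over control replicates is summarized by the Z-factor,
Z' = 1 − 3(σ₊ + σ₋)/|μ₊ − μ₋| with sample standard deviations; values
above 0.5 denote an excellent screen.  `chemolane.datasets` ships a
*synthetic* control-replicate table whose separation sits in that regime
(Z' ≈ 0.69) for examples and worked checks — it is constructed, not
measured.

## Swimmer model (`chemolane.synthetic`)

2-D point swimmers alternate forward runs and backward episodes:

- **Runs** (asymmetric waveform): speed drawn per run from
  Normal(100, 20) µm·s⁻¹ (a typical magnitude for a swimming alga, and a
  free parameter — no measured value is assumed), heading subject to
  rotational diffusion with D_r = 0.1 rad²·s⁻¹.  D_r sets the heading
  decorrelation time 1/D_r ≈ 10 s, comparable to the 10–20 s records the
  trajectory statistics are designed for; substantially larger D_r would
  make the between-reversal segments directionally meaningless, which is
  not what tracks of this organism look like.
- **Switches**: per frame, a run ends with probability 1 − e^(−λ·Δt),
  where λ = s·λ₀·(1 − β·cos θ), θ the angle between heading and gradient.
  λ₀ is defined as the *observable* event rate per track-second (the
  statistic the tracking analysis estimates); since the hazard only runs
  during forward swimming, the scale factor s = 1/(1 − λ₀·τ_dead)
  (τ_dead = mean event + recovery time ≈ 0.57 s) makes the realized
  per-track-second truth rate equal λ₀.  β ∈ [0, 1) is the gradient
  coupling; the linear-in-cosine form is the minimal smooth model that
  keeps λ ≥ 0.
- **Symmetric episodes**: the cell moves along the reversed heading at
  0.8× run speed for a duration Normal(0.5, 0.15) s truncated to (0, 1) s
  — backward excursions are sub-second by construction.
- **Recovery**: 1–3 frames of uncoordinated motion (0.1× speed, incoherent
  direction), then a fresh heading uniform on [0, 2π) and a fresh run
  speed.  This is the heading-randomization step that makes the walk a
  biased random walk: there is no steering *within* a run.

Boundaries reflect (position and heading).  Each cell consumes an
independent child stream of the seed sequence, so cohorts are
bit-reproducible and insensitive to cell count changes elsewhere.
`simulate_photoshock` is identical except every cell deterministically
enters an episode at the flash time.

The lane-image generator advects an initially uniform 1-D density toward
the source at `drift_velocity` (mm·h⁻¹) while a dispersal term
(`cell_diffusivity`, default 50 mm²·h⁻¹ ≈ v²τ/2 for a 100 µm·s⁻¹ swimmer
with ~3 s persistence) spreads it.  Both terms are conservative
finite-volume updates (upwind advection under CFL, explicit diffusion),
so cells relocate rather than appear: total intensity is conserved to
within 8-bit rounding, and the accumulation layer at the source stays
bounded instead of piling into a single saturated pixel.  Frames are the
density times an 8-bit baseline plus Gaussian pixel noise, clipped to
[0, 255].

## Switch detector (`chemolane.trajectory`)

The detector is a state machine over step headings and speeds:

1. **Entry**: a candidate opens at step *i* when the heading change over
   any lag up to `smooth_window` (3 frames) reaches
   `reversal_threshold` = 2π/3, *and* the step is taken at swimming speed
   (≥ `speed_drop_ratio` = 0.5 of the preceding step) — large angle
   changes during low-displacement stretches are uncoordinated jitter,
   not backward swimming.
2. **Exit**: the episode closes at the first later step whose heading
   departs the episode's backward course by ≥ 2π/3 (the cell flips back
   or leaves on a new course) or whose speed falls below 0.5× the entry
   speed (uncoordinated cilia).  Speed references are *local* (entry
   step), not the track median: swimming speed varies run to run, and a
   global reference misreads a slow run's backward segment as the
   uncoordinated phase (switching to the local reference raised measured
   recall from ~0.75 to ~0.95 on ground-truthed cohorts).
3. **Acceptance**: candidates lasting 2 frames to 1.0 s become events;
   trailing frames are labeled UNCOORDINATED until the heading is stable
   (turn < θ_rev/4 twice in a row); events closer than 0.2 s merge, but
   only while the merged episode still fits the 1 s physical bound.
   Scanning resumes at the closing step so an exit flip can open the next
   episode.

Every threshold lives in `DetectorParams`.  The detector is validated
against generator truth rather than against any published
parameterization: on 200-track × 20 s cohorts at λ₀ = 0.085 s⁻¹ it
reaches event-level F1 ≈ 0.95 with approximately balanced misses and
false alarms, so cohort rate estimates are unbiased to within sampling
error across λ₀ ∈ {0.02, 0.05, 0.085, 0.15} s⁻¹.  Tracks shorter than
4 s (boundary inclusive: ≥ 4 s survive) are excluded from cohort
statistics with a recorded reason, not an exception.

Cohort statistics built on the annotations:

- **Switch rate**: events / duration per eligible track; cohort mean ± sd.
- **Photoshock**: responding fraction (event starting within 1 s of the
  flash), mean recovery latency (event end − flash), and a Rayleigh
  circular-uniformity test (via `pingouin`) on post-minus-pre heading
  changes among responders.
- **Orientation**: tracks split at events; each segment labeled
  TOWARD_SOURCE when its circular-mean heading is strictly within π/2 of
  the source direction, else TOWARD_SINK (the strict inequality decides
  the perpendicular tie toward the sink).  Per-segment classification is
  used rather than whole-track, since segments between reversals are the
  natural units of directed travel.
- **Symmetric:asymmetric ratio**: tracks assigned round-robin to 4
  replicate subsets; within each, symmetric residence (event frames,
  attributed to the orientation of the segment preceding the switch) over
  asymmetric frames, per orientation group; groups compared with a
  two-sample equal-variance Student's t-test (Welch behind a flag).
  Frame counts (time in state) are the default numerator; an event-count
  mode exists because the published captions do not pin the denominator
  down.

## Phenotype clustering and statistics (`chemolane.pipeline`)

Strain-by-phenotype tables are z-scored per column (constant columns
dropped with a warning — mixed-unit phenotypes would otherwise let one
column dominate), clustered hierarchically with Ward linkage on Euclidean
distances, and labeled with k-means on the same standardized matrix.
Group comparisons use the two-sided equal-variance t-test with the
figure-style star convention (* p < 0.1, ** p < 0.01, *** p < 0.001); no
multiple-testing correction is applied by default, matching the practice
the assays' figures follow (a Holm option exists).  `run_end_to_end`
executes generation → quantification → statistics from a single
serializable `RunConfig`; identical config + seed yields byte-identical
summary CSVs.

## Problem sizes and numerical checks

The test suite and the acceptance script size their simulations so each
statistic is measured with precision well inside its tolerance: rate
recovery uses 200 tracks × 20 s (≈ 340 events); the fold-change uses
three replicate pairs of 200 tracks × 60 s so the ratio's standard error
(≈ 3%) is small against the 10% band; the gradient-bias contrast uses 600
tracks × 10 s (the null check uses 10 × 100 tracks); photoshock uses 100
flashed tracks; lane-assay properties use 49-frame stacks at 5 px/mm.
Degenerate inputs are rejected with named errors (non-finite configs,
zero-mean lanes, all-zero profiles, equal control means for Z', missing
CSV columns); the only silent exclusions are sub-4 s tracks, which carry
a logged reason.

## What the synthetic data do and do not show

The generators emulate the statistical structure the analyses rely on —
erfc-shaped gradients with multiplicative noise, drifting conserved lane
density, run-and-reverse kinematics with direction-dependent hazard —
but not microscopy reality: no cell–cell interaction or crowding, no
gliding on surfaces, no 3-D swimming or helical wobble, no localization
noise or missed detections in tracks, no illumination vignetting or
misregistration in stacks, and no biology behind the drift velocity (so
the demo Slope Index saturates rather than peaking at any particular
hour).  Passing tests therefore demonstrate that the estimators recover
known ground truth under the stated noise models — not that any specific
biological value is reproduced from real recordings.
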