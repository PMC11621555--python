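# chemolane

Quantitative analysis of microalgal ammonium chemotaxis: gradient
characterization, lane-assay image quantification, and detection of
ciliary waveform switching from single-cell tracks.

Swimming microalgae such as *Chlamydomonas* steer toward ammonium not by
turning smoothly up the gradient but by modulating how often they
transiently reverse: the cilia switch from the forward-driving
*asymmetric* waveform to a sub-second backward-driving *symmetric*
waveform, after which the cell leaves in a random new direction.
Suppressing these reversals while swimming up-gradient yields a biased
random walk and net drift toward the source.  `chemolane` provides the
analysis chain for studying this — for experimentalists quantifying lane
assays and track tables, and for modelers who need a ground-truthed
simulation of the whole measurement process.

## What it computes

- **Gradient formation** (`chemolane.diffusion`): the constant-source
  solution of Fick's second law, C(x,t) = C0·erfc(x/2√(Dt)), and
  nonlinear least-squares estimation of D (cm²·s⁻¹) from dye profiles.
- **Lane assay** (`chemolane.cla`): lane images → percent change from
  mean, PCM(x,t) = 100·(I − Ī)/Ī → per-timepoint OLS slope × lane length
  (*Slope Index*, % per lane) → its time-course maximum (*Chemotaxis
  Index*); assay quality via the Z-factor
  Z' = 1 − 3(σ₊+σ₋)/|μ₊−μ₋|.
- **Trajectories** (`chemolane.trajectory`): TrackMate-dialect spot
  tables → kinematics → a reversal-plus-speed-disruption detector for
  symmetric-waveform events → spontaneous switch rates
  (events·track⁻¹·s⁻¹), photoshock response (responding fraction,
  recovery latency, heading-randomization test), and the
  symmetric:asymmetric residence ratio compared between source-ward and
  sink-ward travel with λ(θ) = λ₀(1 − β·cos θ) as the underlying hazard
  model.
- **Synthetic data** (`chemolane.synthetic`): run-and-reverse swimmer
  cohorts with per-frame truth labels, photoshocked cohorts, noisy
  diffusion profiles, and drifting conserved lane-image stacks — every
  downstream stage is testable without external data.
- **Pipeline** (`chemolane.pipeline`): Ward-linkage/k-means phenotype
  clustering, Student's t-tests, and a reproducible end-to-end demo run.

## Worked example

Detect waveform switches in a simulated wild-type-like cohort and a
switching-deficient mutant-like cohort (`examples/03_switch_detection.py`):

```sh
$ python examples/03_switch_detection.py
wild-type-like  true rate 0.0850/s -> detected 0.0843 +- 0.0619/s  (n=200 tracks, event F1 0.958)
mutant-like     true rate 0.0531/s -> detected 0.0505 +- 0.0501/s  (n=200 tracks, event F1 0.953)
```

Each line reports the cohort's symmetric-waveform incidence per track per
second as estimated from the raw (x, y) tracks alone, against the rate
the generator actually used; F1 scores the detected events against the
generator's per-frame truth labels.  The detected 0.084/0.051 s⁻¹ against
true 0.085/0.053 s⁻¹ shows the detector recovers both the rates and their
~1.6-fold separation.  The other examples cover the diffusion fit
(`01`), the lane-assay chain and Z-factor (`02`), photoshock latency
(`04`), gradient-biased switching (`05`), and phenotype clustering
(`06`).

A thin CLI wraps the same functions:

```sh
chemolane simulate --n-cells 100 --duration 20 --out spots.csv
chemolane tracks --tracks spots.csv --out results/
chemolane cla --stack stack.tif --geometry geom.json --out results/
chemolane demo --seed 1 --out demo/
```

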