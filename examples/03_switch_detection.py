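"""Detect symmetric-waveform switches and estimate spontaneous rates.

Simulates a wild-type-like cohort (spontaneous backward-swimming episodes
at 0.085 per track-second) and a mutant-like cohort switching 1.6-fold
less, runs the detector on the raw tracks, and compares detected rates to
the generator's ground truth.
"""

from chemolane import synthetic, trajectory

params = trajectory.DetectorParams()

for name, rate, seed in (("wild-type-like", 0.085, 0), ("mutant-like", 0.085 / 1.6, 1)):
    cfg = synthetic.SwimConfig(
        n_cells=200, duration=20.0, switch_rate_base=rate, rng_seed=seed
    )
    tset = synthetic.simulate_tracks(cfg)
    annotations = trajectory.annotate_set(tset, params)
    result = trajectory.switch_rate(tset, params, annotations)
    detected = [ev for ann in annotations.values() for ev in ann.events]
    scores = trajectory.event_detection_scores(tset.truth_events, detected)
    print(
        f"{name:15s} true rate {rate:.4f}/s -> detected "
        f"{result.mean:.4f} +- {result.sd:.4f}/s  "
        f"(n={result.n_tracks} tracks, event F1 {scores['f1']:.3f})"
    )

print()
print("Rates are symmetric-waveform incidences per track per second; F1")
print("scores the detector's events against the generator's truth labels.")
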