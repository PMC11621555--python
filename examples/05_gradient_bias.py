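"""Gradient-biased switching: the steering statistic behind chemotaxis.

Cells steer by modulating how often they reverse: swimming up-gradient
suppresses switching (hazard lambda0*(1 - beta*cos(theta))), so reversals
are rarer on source-ward stretches.  This example compares the
symmetric:asymmetric residence ratio between cells moving toward the
source and toward the sink, for a biased and an unbiased cohort.
"""

from chemolane import synthetic, trajectory
from chemolane.pipeline import significance_stars

SOURCE = (1.0, 0.0)  # gradient points along +x

for name, beta, seed in (("unbiased (beta=0)", 0.0, 4), ("biased (beta=0.5)", 0.5, 2)):
    cfg = synthetic.SwimConfig(
        n_cells=600, duration=10.0, switch_rate_base=0.085, bias=beta, rng_seed=seed
    )
    tset = synthetic.simulate_tracks(cfg)
    r = trajectory.symmetric_asymmetric_ratio(tset, SOURCE)
    print(
        f"{name:18s} toward-source {r.toward_source_mean:.4f} +- {r.toward_source_sd:.4f} | "
        f"toward-sink {r.toward_sink_mean:.4f} +- {r.toward_sink_sd:.4f} | "
        f"t-test p = {r.p_value:.4f} [{significance_stars(r.p_value)}]"
    )

print()
print("With beta > 0 the toward-source ratio drops below the toward-sink")
print("ratio: suppressed reversals up-gradient produce the biased random")
print("walk that drifts the population toward the attractant.")
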