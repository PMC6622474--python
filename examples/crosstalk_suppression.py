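"""Cross-talk elimination by independent sensor noise.

Both microzone pairs read the same undifferentiated parallel-fibre bus, so
each acquires "cross-talk" weights on the other sensor's channels.  Small
independent Gaussian sensor noise makes orienting errors correlated only
with the responsible sensor's signals, and the covariance rule then slowly
drives cross-talk weights toward silence -- but only when gating also breaks
the symmetry between sensors.
"""

from mapcalib.experiments import default_config, run_experiment

res = run_experiment(default_config("task2-m3"), seed=0)
ct = res.crosstalk
for i in (1, 2):
    series = ct[f"crosstalk_rms_{i}"].to_numpy()
    print(
        f"microzone pair {i}: cross-talk weight RMS peak {series.max():.4f}"
        f" -> final {series[-1]:.4f}"
    )
s1, s2 = res.summary["probe_sensor_rms"]
print(f"per-sensor probe RMS with noise + gating: {s1:.4f}, {s2:.4f}")

control = default_config("task2-m3")
control.gating_mode = "none"
ctrl = run_experiment(control, seed=0)
c1, c2 = ctrl.summary["probe_sensor_rms"]
print(f"per-sensor probe RMS with noise, NO gating: {c1:.4f}, {c2:.4f}")
print()
print(
    "With gating the cross-talk weights decay after their early peak and"
    " both maps calibrate individually; noise alone (no gating) leaves both"
    " unimodal maps badly miscalibrated even though the combined response"
    " is accurate."
)
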