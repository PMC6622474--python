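"""Predictive recalibration of a delayed, distorted moving target.

The map only sees the target's position 5 samples (250 ms) in the past, and
through a curvilinear distortion.  Coarse-coded map activity is passed
through a bank of three leaky integrators and a fixed decorrelation matrix
Q, giving the parallel fibres a temporal basis; the delayed error teaches
the microzones to aim the orienting response at the target's future
position.
"""

from mapcalib.experiments import default_config, run_experiment

res = run_experiment(default_config("task3"), seed=0)
s = res.summary
print(f"zero-weight baseline RMS (last 1000 samples): {s['tail_rms_nobias']:.4f}")
print(f"learnt tracking RMS       (last 1000 samples): {s['tail_rms']:.4f}")
print(f"ratio: {s['tail_ratio']:.3f}")
print()
print(
    "The baseline is the error an uncalibrated map makes from delayed,"
    " distorted input; after learning along a 10,000-sample coloured-noise"
    " trajectory, the tracking error falls to a fraction of it.  The target"
    " motion is predictable only through its low-frequency structure, which"
    " the leaky-integrator basis captures."
)
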