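# Methods

## Model overview

`mapcalib` simulates closed-loop calibration of topographic sensorimotor
maps by an adaptive-filter model of the cerebellar microcircuit.  All
quantities live in dimensionless "map units" except in the 1-D
constant-velocity experiment, where target space is metres.

A trial proceeds: target → sensor → (distortion) → map write → population
readout → cerebellar bias → orienting response → error → weight update.

* **Sensor**: s = K·x_d, optionally plus independent zero-mean Gaussian
  noise of standard deviation σ per component.  K must be invertible; this
  is checked at construction.
* **Distortion**: s_g = A·s + a + B·s^∘2 + C·s^∘3 (element-wise powers).
  The identity distortion is an exact bit-level no-op.
* **Map write**: the map is an n_g×n_g grid of neurons with centres evenly
  spanning [−x_max, x_max] per axis; activity is the unnormalised Gaussian
  exp(−½ (r − K⁻¹s_g)ᵀ Σ⁻¹ (r − K⁻¹s_g)), peak ≤ 1.
* **Readout**: population vector — the activity-weighted mean of neuron
  centres, normalised by total activity.  The raw weighted sum would scale
  with total activity and could not return a single active neuron's centre;
  normalisation makes the calibrated round trip x̂ ≈ K⁻¹s exact up to grid
  discretisation.  A map with zero total activity raises a degenerate-map
  error (it cannot arise from a Gaussian write, which is strictly positive).
* **Coarse coding**: a k×k grid of broad Gaussians with covariance gp_cov,
  centres evenly spanning the full map extent, evaluated at the map-neuron
  centres and precomputed once as a (k², n_g²) operator; the raw outputs q
  are normalised to the parallel-fibre vector P with Σ P_n = 1.
* **Microzones**: per map, one weight vector per axis over the
  parallel-fibre bus; bias z = (w_x·P, w_y·P); adjusted estimate
  x_a = x_g + z; error e = x_d − x_a; update w ← w + β e P (sign-only
  variant: e replaced component-wise by its sign, with sign(0) = 0).  The
  update sign is fixed by requiring negative feedback — zero error is a
  fixed point and the bias moves the estimate toward the target.  Under the
  convention that Purkinje output inhibits the deep nuclei the same rule
  reads Δw = −β e P with w the synaptic weights, so either sign convention
  describes the same observable system.
* **Trial ordering**: the bias is computed from pre-update weights, the
  error from the biased estimate, and the weights are updated once per
  target presentation.  The parallel fibres are driven by the *unshifted*
  distorted map (the bias acts on the readout, not on the filter input).

## Published parameter sets

Defaults reproduce the printed configurations and are audited by a test:

| task | key parameters |
|---|---|
| task1(-sign) | n_g=100, x_max=1.5, targets uniform ±0.75, K=[[0.8944,0],[0.2739,0.7906]], Σ=[[0.0125,−0.0043],[−0.0043,0.0175]], A=[[1.1,0.1],[−0.2,0.9]], a=(0,−0.2), B=[[0,−0.05],[0.05,0.1]], C=[[0.1,0.7],[−0.8,0]], k=8, gp_cov=0.0352·I, β=1, 3000 trials |
| task2-m1/m2 | K₁=K₂=I, Σ=0.0225·I, gated Σ=4.5·I, β₁=β₂=0.25, 10,000 trials; cancelling pair A₁=[[0.8,0.2],[−0.4,1.1]], A₂=[[1.15,−0.21],[0.42,0.83]]; one-accurate condition A₁=[[0.75,0.2],[−0.4,1.1]], B₁=[[0.01,0.02],[0.05,−0.05]] |
| task2-m3 | as above with σ=0.005 noise, A₁=[[0.7,−0.2],[−0.3,0.9]], a₁=(0.1,0.25), A₂=[[0.8,−0.2],[−0.1,1.1]], a₂=(−0.5,0), 15,000 trials |
| task3 | Task-1 K and Σ, A=[[1.2,0.2],[−0.3,0.9]], B=[[0,−0.05],[0.05,0.01]], Δ=5 samples at 20 Hz, τ=(0.05,0.0707,0.1) s, β=5, 10,000 samples |
| velocity-1d | K=0.1094, Σ=0.7559 m², Δ=100 samples, dt=5 ms, 8 coarse Gaussians, 24 PF signals, β=25, speeds ±{0.125,0.5,1,2} m/s |

## Metrics

Two error scalars are used and named consistently:

* **Per-trial RMS error** (`rms_e`, summarised as `final_window_rms`): the
  root-mean-square over the error components, √((e_x²+e_y²)/2).  This is the
  statistic quoted for the headline recalibration numbers; the final window
  is the last 500 of 3000 trials, averaged over 5 seeds in the acceptance
  script.
* **Probe RMS** (`probe_rms`, `probe_sensor_rms`, ...): the RMS of the
  Euclidean error *norm* over a deterministic 10×10 target lattice,
  evaluated with frozen weights and no noise.  Probing a single sensor in
  the fused architecture sets the other sensor's bus channels to zero.

The per-trial `err` column of trial logs is the plain Euclidean norm (the
orienting miss distance), kept alongside `rms_e`.

## Multisensory fusion

Unimodal maps are combined by element-wise product, which implements Bayes'
rule for Gaussian likelihoods with a unit prior: the fused bump has
precision Σ₁⁻¹+Σ₂⁻¹ and precision-weighted mean (tested against the closed
form to 1e-3).  Each sensor's bias shifts its *own* map before fusion,
implemented by re-writing the bump at the shifted centre — exact for
Gaussians and free of interpolation artefacts.  Both microzone pairs share
the concatenated parallel-fibre bus (each map's block normalised to sum 1)
and learn from the same combined-map error.

**Gating.**  On a random third of trials sensor 1 "fails to detect" the
target, on another third sensor 2 does.  A failed sensor (i) writes its map
with the near-flat covariance 4.5·I (so the fused estimate is carried by the
detecting sensor), (ii) has its climbing-fibre teaching signal suppressed
(its weights are frozen that trial), and (iii) contributes silent (zero)
channels to the parallel-fibre bus.  Choice (iii) is the package's reading
of "detection failure": a modality that saw nothing provides no
target-locked granular-layer drive.  It matters quantitatively: if the
near-flat map's coarse code is kept on the bus, its roughly constant
channel pattern acquires weight offsets that are present on gated trials
but absent whenever the other configuration occurs, and the per-sensor
calibration that gating should produce never sharpens, while cross-talk
weights saturate instead of decaying.  With silent channels, the trials on
which a pair learns alone are statistically identical to the single-sensor
probe, and both the per-sensor calibration and the noise-driven cross-talk
decay emerge.

**Sensor noise and cross-talk.**  With independent per-sensor noise
(σ = 0.005) each pair's weights on the *other* sensor's channels
("cross-talk", reported as the RMS of those weights) acquire a decay
pressure: noise fluctuations pass through cross-talk weights into the
response and generate self-inflicted error correlated with those channels.
The decay rate scales with the noise variance and is slow at σ = 0.005 —
over 15,000 trials the cross-talk RMS falls well below its early peak but
not to a small fraction of it; the no-noise control stalls entirely, and the
no-gating control leaves both maps individually miscalibrated.  This
time-scale separation (behavioural error fast, synaptic clean-up slow) is a
property of the mechanism, not a numerical artefact.

## Temporal basis and decorrelation

Each coarse channel's normalised signal is filtered by three leaky
integrators, discretised as y[t] = α y[t−1] + (1−α) u[t] with
α = exp(−dt/τ) — exact pole placement and unit DC gain.  Filter states are
initialised at steady state for the first sample (the target is already
present when a run begins); zero initialisation injects a large charging
transient into the decorrelated difference signals that can destroy the
weights at high learning rates.

The three outputs per channel are nearly collinear.  They are decorrelated
by a fixed 3×3 matrix Q — symmetric whitening of the filter-output
covariance pooled over channels and time, estimated once on a held-out
calibration trajectory and frozen before learning.  Rank-deficient
covariances (e.g. a stationary calibration target) are regularised by a
small diagonal jitter.  Pooling leaves some per-channel residual
correlation (channels differ slightly in spectra); per-channel whitening
blocks were evaluated and converge more slowly, so pooling is kept.

A whitening matrix is defined only up to scale, and the learning rate β is
only meaningful relative to that scale (the per-step update gain is
β·‖Qy‖²; LMS requires it below 2).  The free scale is fixed by a loop-gain
criterion: on the calibration series, β·E‖Qy‖² = 0.4.  The value 0.4 (20%
of the stability limit) leaves margin for the heavy-tailed instantaneous
bus norm and the delayed error; gains near 1 diverge in practice and gains
below ~0.1 visibly underfit within a 10,000-sample run.  With this
normalisation the printed learning rates for both temporal tasks run
stably; note that it makes the closed-loop dynamics invariant to the
numerical value of β, which is the only reading we found under which the
two printed rates (5 and 25) are simultaneously usable.

## Trajectories

The 2-D tracking target is coloured noise: per axis, uniform samples on
[−0.75, 0.75] at 20 Hz, spectral components above 0.5 Hz removed by
zero-phase frequency-domain truncation, then a tanh rescale
x' = L·tanh(gx/L) with the gain g fitted so the 99.9th-percentile amplitude
maps to 0.98·L.  The rescale restores the full target range (so the map is
exercised out to its limits) at the cost of a small amount of harmonic
power above the cutoff; the band limit is exact before rescaling and the
leak is below a few percent of total power after it.

## 1-D constant-velocity experiment

Geometry not fixed by the published parameters (recorded as this package's
choices): the sensed axis spans ±1.5 units so the map spans
±1.5/K ≈ ±13.7 m with 100 neurons; the sweep crosses the central half of
the map; the 8 coarse Gaussians span the full extent with width
0.4377 × spacing, mirroring the 2-D overlap ratio √0.0352/(3/7).  Q is
fitted on a pass over the same (deterministic) sweep and frozen.

The reported receptive-field shift is the bias expressed *during* the
single learning sweep, as a function of the delayed input position, with
the mean taken over the central 80% to exclude the onset ramp.  A
frozen-weight replay is deliberately not used: with a one-pass,
non-recurring input, LMS keeps adjusting the response at positions the
target has already left (they are never corrected afterwards), so a replay
over-reports the shift at earlier positions by up to a factor of ~2.  The
analytic optimum is the constant shift v·Δ·dt; a brute-force oracle (the
error-minimising constant offset over the sweep) confirms it, and the
learnt mean shift matches it to within a few percent, odd in velocity and
monotone in speed.

## What the synthetic data do and do not emulate

All inputs are generated internally: random uniform targets, parametric
distortions, coloured-noise and constant-velocity trajectories.  They
emulate the *structure* of the calibration problems — curvilinear sensor
miscalibration, cancelling multi-sensor errors, detection failure, sensory
delay — under exactly the published parameter values.  They do not emulate
real collicular physiology: no spiking, no trial-to-trial neural
variability beyond the modelled sensor noise, a single target per trial, a
global (not regional) bias signal, and fixed map-to-motor wiring.  Passing
tests therefore demonstrate properties of the model, not of biological
tissue; the owl-experiment comparison is qualitative (the simulated and
experimental time scales differ).

## Known limitations

* **Sign-only error floor.**  With β kept at 1 (no published value exists
  for the sign-only variant), sign-error LMS dithers with step size
  β·‖P‖² ≈ 0.25–0.35 per trial, giving an equilibrium error floor near
  0.16 (component-RMS) — an order of magnitude above the full-error floor,
  and above the historically reported value for this variant, which would
  require an effective sign-mode step of ~0.01 (β ≈ 0.03–0.05).  The
  qualitative claim (sign-only strictly worse but bounded, map still
  largely restored in shape) holds.  The acceptance suite keeps the strict
  numeric band and the corresponding test is expected to fail under β = 1.
* **Cross-talk decay rate.**  At σ = 0.005 the noise-driven purge of
  cross-talk weights is much slower than 15,000 trials (estimated time
  constant ~10⁵ trials); the direction and noise-dependence of the decay
  reproduce, the "final ≪ peak" end state within 15k trials does not.
* Probe errors concentrate at the corners of the target region, where the
  distorted bump approaches the map boundary and targets are sparse.
* The fused architecture is implemented and tested for exactly two sensors.
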