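"""Multisensory map fusion with gated credit assignment.

Two unimodal maps (e.g. visual and somatosensory) are combined by
element-wise multiplication into a multimodal map; for Gaussian bumps this
implements Bayes' rule, so with equal receptive-field covariances the
combined estimate is the mean of the unimodal estimates.  Both maps are
calibrated by their own microzone pairs, which share a single undifferentiated
parallel-fibre bus (the concatenated coarse codes of both maps) and a single
climbing-fibre error derived from the combined readout.

Because one error trains every map, miscalibrations that cancel between the
maps are invisible to learning (a credit-assignment failure).  Two mechanisms
from the model resolve it:

* **gating** -- on trials where a sensor fails to detect the target
  (simulated by a near-flat write covariance), the climbing-fibre teaching
  signal to that sensor's microzones is suppressed, while the other sensor
  still learns from the combined error (which that sensor then dominates);
* **independent sensor noise** -- small per-sensor Gaussian noise makes the
  error correlated only with the responsible sensor's signals, so the
  covariance rule drives cross-talk weights (a microzone's weights onto the
  *other* sensor's parallel fibres) to silence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cerebellum import MicrozonePair, bias_output, update_weights
from .map_core import (
    CoarseGridSpec,
    DistortionModel,
    SensorModel,
    TopographicMapSpec,
    build_coarse_weights,
    coarse_code,
    distort,
    encode_location,
    normalize_pf,
    read_map,
    sense,
    write_activity,
)

__all__ = [
    "GATE_PATTERNS",
    "draw_gate_pattern",
    "combine_maps",
    "TwoSensorCalibrator",
    "crosstalk_weight_rms",
]

#: The three equally likely per-trial patterns under random-thirds gating:
#: both sensors detect the target / sensor 1 fails / sensor 2 fails.
GATE_PATTERNS = ((False, False), (True, False), (False, True))


def draw_gate_pattern(
    rng: np.random.Generator, gating_mode: str = "random-thirds"
) -> tuple[bool, bool]:
    """Draw one per-trial gate pattern.

    ``random-thirds`` returns each of ``GATE_PATTERNS`` with probability 1/3;
    ``none`` always returns (False, False).
    """
    if gating_mode == "none":
        return (False, False)
    if gating_mode == "random-thirds":
        return GATE_PATTERNS[rng.integers(3)]
    raise ValueError(f"unknown gating_mode {gating_mode!r}")


def combine_maps(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """Multimodal map: element-wise product of two unimodal activity maps."""
    if g1.shape != g2.shape:
        raise ValueError(f"map shapes differ: {g1.shape} vs {g2.shape}")
    return g1 * g2


def crosstalk_weight_rms(mz: MicrozonePair, other_slice: slice) -> float:
    """RMS of a microzone pair's weights onto the other sensor's PF channels."""
    w = mz.w[:, other_slice]
    return float(np.sqrt(np.mean(w * w)))


@dataclass
class FusionTrialRecord:
    x_d: np.ndarray
    x_enc: tuple[np.ndarray, np.ndarray]  # per-sensor encoded (distorted) locations
    z: tuple[np.ndarray, np.ndarray]  # per-sensor biases
    x_a: np.ndarray  # combined, bias-adjusted readout
    e: np.ndarray
    gates: tuple[bool, bool]


class TwoSensorCalibrator:
    """Closed-loop calibration of two fused unimodal maps.

    Each trial: draw a gate pattern; sense (with optional per-sensor noise)
    and distort each sensor; write each unimodal map (a gated sensor writes
    with the near-flat covariance); coarse-code each detected map and
    concatenate into one parallel-fibre bus, a sensor that failed to detect
    the target contributing silent (zero) channels; compute each sensor's
    bias from its own microzone pair over the full bus; slide each unimodal
    map by its own bias (re-writing the bump at the shifted centre, exact
    for Gaussians); combine the shifted maps; read the combined map; and
    train both microzone pairs with the same combined error, skipping any
    gated pair.
    """

    def __init__(
        self,
        map_spec: TopographicMapSpec,
        sensors: tuple[SensorModel, SensorModel],
        distortions: tuple[DistortionModel, DistortionModel],
        coarse: CoarseGridSpec,
        betas: tuple[float, float] = (0.25, 0.25),
        gating_mode: str = "none",
        sign_only: bool = False,
    ):
        self.map_spec = map_spec
        self.sensors = tuple(sensors)
        self.distortions = tuple(distortions)
        self.coarse = coarse
        self.coarse_weights = build_coarse_weights(coarse, map_spec)
        self.gating_mode = gating_mode
        n = coarse.n_channels
        self.n_per_sensor = n
        self.bus_slices = (slice(0, n), slice(n, 2 * n))
        self.microzones = tuple(
            MicrozonePair.zeros(2 * n, beta=b, dim=map_spec.dim, sign_only=sign_only)
            for b in betas
        )

    # -- training ---------------------------------------------------------

    def trial(
        self,
        x_d,
        rng: np.random.Generator | None = None,
        gates: tuple[bool, bool] | None = None,
        learn: bool = True,
    ) -> FusionTrialRecord:
        x_d = np.asarray(x_d, dtype=float)
        if gates is None:
            gates = (
                draw_gate_pattern(rng if not isinstance(rng, (tuple, list)) else rng[0],
                                  self.gating_mode)
                if self.gating_mode != "none"
                else (False, False)
            )
        # rng may be a single generator shared by both sensors or one
        # independent, seedable stream per sensor
        rngs = rng if isinstance(rng, (tuple, list)) else (rng, rng)
        x_enc, P_parts, acts = [], [], []
        for sensor, dist, gated, rng_i in zip(
            self.sensors, self.distortions, gates, rngs
        ):
            s_g = distort(sense(x_d, sensor, rng_i), dist)
            x = encode_location(s_g, sensor)
            sig_inv = sensor.gated_sigma_rf_inv if gated else sensor.sigma_rf_inv
            x_enc.append(x)
            acts.append((x, sig_inv))
            if gated:
                # detection failure: no target-locked mossy-fibre drive from
                # this modality, so its channels of the shared bus are silent
                P_parts.append(np.zeros(self.n_per_sensor))
            else:
                act = write_activity(x, self.map_spec, sig_inv)
                P_parts.append(normalize_pf(coarse_code(act, self.coarse_weights)))
        P = np.concatenate(P_parts)
        z = tuple(bias_output(P, mz) for mz in self.microzones)
        shifted = [
            write_activity(x + zi, self.map_spec, sig_inv)
            for (x, sig_inv), zi in zip(acts, z)
        ]
        combined = combine_maps(shifted[0], shifted[1])
        x_a = read_map(combined, self.map_spec)
        e = x_d - x_a
        if learn:
            for mz, gated in zip(self.microzones, gates):
                update_weights(P, e, mz, gate=gated)
        return FusionTrialRecord(
            x_d=x_d, x_enc=tuple(x_enc), z=z, x_a=x_a, e=e, gates=gates
        )

    def run(
        self,
        n_trials: int,
        rng: np.random.Generator,
        target_limit: float = 0.75,
        targets: np.ndarray | None = None,
        gate_patterns: np.ndarray | None = None,
        noise_rngs: tuple[np.random.Generator, np.random.Generator] | None = None,
        gate_rng: np.random.Generator | None = None,
    ) -> list[FusionTrialRecord]:
        """Run trials on uniform random targets.

        ``targets`` and ``gate_patterns`` (an (n, 2) boolean array) can be
        supplied explicitly for full reproducibility control; ``noise_rngs``
        gives each sensor its own stream so noise is independent across
        sensors, and ``gate_rng`` separates the gating draws from the rest.
        """
        if targets is None:
            targets = rng.uniform(
                -target_limit, target_limit, size=(n_trials, self.map_spec.dim)
            )
        gate_rng = gate_rng if gate_rng is not None else rng
        trial_rng = noise_rngs if noise_rngs is not None else rng
        records = []
        for i, t in enumerate(targets):
            if gate_patterns is not None:
                g = tuple(bool(b) for b in gate_patterns[i])
            elif self.gating_mode != "none":
                g = draw_gate_pattern(gate_rng, self.gating_mode)
            else:
                g = (False, False)
            records.append(self.trial(t, trial_rng, gates=g))
        return records

    # -- probes (no learning, no noise, no gating) ------------------------

    def _noiseless(self, i: int) -> SensorModel:
        s = self.sensors[i]
        if s.noise_sd == 0:
            return s
        return SensorModel(s.K, s.sigma_rf, 0.0, s.gated_sigma_rf)

    def probe_sensor(self, i: int, targets: np.ndarray) -> np.ndarray:
        """Per-target errors of unimodal map ``i`` evaluated alone.

        The other sensor's input is set to zero: its channels of the
        parallel-fibre bus are zeroed, so each sensor's own channels (which
        are normalised per map) carry the whole signal.  The sensor's bias is
        applied to its own readout.
        """
        sensor = self._noiseless(i)
        dist = self.distortions[i]
        mz = self.microzones[i]
        errs = np.empty((len(targets), self.map_spec.dim))
        for j, t in enumerate(np.asarray(targets, dtype=float)):
            s_g = distort(sense(t, sensor), dist)
            act = write_activity(
                encode_location(s_g, sensor), self.map_spec, sensor.sigma_rf_inv
            )
            x_g = read_map(act, self.map_spec)
            P = np.zeros(2 * self.n_per_sensor)
            P[self.bus_slices[i]] = normalize_pf(
                coarse_code(act, self.coarse_weights)
            )
            x_a = x_g + bias_output(P, mz)
            errs[j] = t - x_a
        return errs

    def probe_combined(self, targets: np.ndarray) -> np.ndarray:
        """Per-target errors of the full fused pipeline (no gates, no noise)."""
        saved = self.sensors
        self.sensors = tuple(self._noiseless(i) for i in range(2))
        try:
            return np.array(
                [
                    self.trial(t, rng=None, gates=(False, False), learn=False).e
                    for t in np.asarray(targets, dtype=float)
                ]
            )
        finally:
            self.sensors = saved

    def crosstalk_rms(self) -> tuple[float, float]:
        """Cross-talk weight RMS for each microzone pair."""
        return (
            crosstalk_weight_rms(self.microzones[0], self.bus_slices[1]),
            crosstalk_weight_rms(self.microzones[1], self.bus_slices[0]),
        )
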