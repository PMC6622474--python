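"""The adaptive-filter cerebellar microcircuit.

Each sensory map is calibrated by a pair of microzones, one biasing the map
along each axis.  A microzone output is a plain weighted sum of the
parallel-fibre signals, z = w . P, and the weights follow the covariance
(LMS / decorrelation) learning rule driven by the climbing-fibre error
e = x_d - x_a: weights change by beta * e * P per trial, with the sign
arranged so that the closed loop is negative feedback (the update stops
exactly when the orienting error is zero).  An optional low-quality-error
variant uses only the sign of each error component.

`SingleMapCalibrator` wires one sensor, one distorted map and one microzone
pair into the full closed loop (sense -> distort -> write -> coarse-code ->
bias -> error -> learn) used for unimodal recalibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .map_core import (
    CoarseGridSpec,
    DistortionModel,
    SensorModel,
    TopographicMapSpec,
    apply_bias,
    build_coarse_weights,
    coarse_code,
    distort,
    normalize_pf,
    read_map,
    sense,
    write_map,
)

__all__ = ["MicrozonePair", "bias_output", "update_weights", "SingleMapCalibrator"]


@dataclass
class MicrozonePair:
    """Adaptive-filter weights biasing one map (one row of weights per axis).

    ``w`` has shape (dim, N) where N is the parallel-fibre bus length.
    Weights start at zero; ``beta`` is the learning rate; ``sign_only``
    replaces the error by its sign in the update (sign(0) = 0).
    """

    w: np.ndarray
    beta: float
    sign_only: bool = False

    @classmethod
    def zeros(cls, n_channels: int, beta: float, dim: int = 2, sign_only: bool = False):
        return cls(w=np.zeros((dim, n_channels)), beta=beta, sign_only=sign_only)

    @property
    def w_x(self) -> np.ndarray:
        return self.w[0]

    @property
    def w_y(self) -> np.ndarray:
        if self.w.shape[0] < 2:
            raise AttributeError("1-D microzone pair has no y channel")
        return self.w[1]

    @property
    def n_channels(self) -> int:
        return self.w.shape[1]


def bias_output(P: np.ndarray, mz: MicrozonePair) -> np.ndarray:
    """Cerebellar bias z = (w_x . P, w_y . P)."""
    P = np.asarray(P, dtype=float)
    if P.shape[0] != mz.n_channels:
        raise ValueError(
            f"parallel-fibre vector length {P.shape[0]} != weight length {mz.n_channels}"
        )
    return mz.w @ P


def update_weights(
    P: np.ndarray, e: np.ndarray, mz: MicrozonePair, gate: bool = False
) -> MicrozonePair:
    """One covariance-rule update; in place.  A gated trial changes nothing.

    The update is w += beta * e * P per axis (sign chosen so that the bias
    moves the adjusted estimate toward the target; zero error is a fixed
    point).  With ``sign_only`` the error components are replaced by their
    signs.
    """
    if gate:
        return mz
    P = np.asarray(P, dtype=float)
    if P.shape[0] != mz.n_channels:
        raise ValueError("parallel-fibre / weight dimension mismatch")
    err = np.sign(e) if mz.sign_only else np.asarray(e, dtype=float)
    mz.w += mz.beta * np.outer(err, P)
    return mz


class SingleMapCalibrator:
    """Closed-loop recalibration of one distorted unimodal map.

    Parameters mirror the simulation defaults: a 100x100 map spanning
    +/-1.5 map units, an 8x8 coarse grid, and zero-initialised weights.
    """

    def __init__(
        self,
        map_spec: TopographicMapSpec,
        sensor: SensorModel,
        distortion: DistortionModel,
        coarse: CoarseGridSpec,
        beta: float = 1.0,
        sign_only: bool = False,
    ):
        self.map_spec = map_spec
        self.sensor = sensor
        self.distortion = distortion
        self.coarse = coarse
        self.coarse_weights = build_coarse_weights(coarse, map_spec)
        self.mz = MicrozonePair.zeros(
            coarse.n_channels, beta=beta, dim=map_spec.dim, sign_only=sign_only
        )

    def trial(
        self, x_d, rng: np.random.Generator | None = None, learn: bool = True
    ) -> dict:
        """Run one target presentation; learn (unless disabled) and log it.

        Order of operations: the bias is computed from the pre-update
        weights, the error from the biased estimate, and the weights are
        then updated once.
        """
        x_d = np.asarray(x_d, dtype=float)
        s_d = sense(x_d, self.sensor, rng)
        s_g = distort(s_d, self.distortion)
        act = write_map(s_g, self.map_spec, self.sensor)
        x_g = read_map(act, self.map_spec)
        P = normalize_pf(coarse_code(act, self.coarse_weights))
        z = bias_output(P, self.mz)
        x_a = apply_bias(x_g, z)
        e = x_d - x_a
        if learn:
            update_weights(P, e, self.mz)
        return {"x_d": x_d, "x_g": x_g, "x_a": x_a, "z": z, "e": e}

    def run(
        self,
        n_trials: int,
        rng: np.random.Generator,
        target_limit: float = 0.75,
        targets: np.ndarray | None = None,
    ) -> list[dict]:
        """Run a sequence of trials on uniform random targets (or given ones)."""
        if targets is None:
            targets = rng.uniform(
                -target_limit, target_limit, size=(n_trials, self.map_spec.dim)
            )
        return [self.trial(t, rng) for t in targets]

    def probe(self, targets: np.ndarray) -> np.ndarray:
        """Closed-loop errors on a deterministic target set, without learning
        and without sensor noise."""
        errs = np.empty((len(targets), self.map_spec.dim))
        noiseless = (
            self.sensor
            if self.sensor.noise_sd == 0
            else SensorModel(
                self.sensor.K, self.sensor.sigma_rf, 0.0, self.sensor.gated_sigma_rf
            )
        )
        saved = self.sensor
        self.sensor = noiseless
        try:
            for i, t in enumerate(targets):
                errs[i] = self.trial(t, rng=None, learn=False)["e"]
        finally:
            self.sensor = saved
        return errs
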