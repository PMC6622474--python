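"""Reproducible task runners, published parameter sets, metrics and logs.

Task ids
--------
``task1``      single distorted unimodal map, full signed error
``task1-sign`` same, sign-only error
``task2-m1``   two fused maps, shared error, no gating (credit-assignment demo)
``task2-m2``   two fused maps with climbing-fibre gating
``task2-m3``   gating plus independent sensor noise (cross-talk suppression)
``task3``      predictive tracking of a delayed, distorted moving target
``velocity-1d`` 1-D constant-velocity receptive-field-shift experiment

``default_config(task)`` returns the published parameter set for a task;
``run_experiment(cfg, seed)`` executes it with fully seeded randomness and
returns a trial log (DataFrame), a summary dict, and the trained calibrator.
Every output is a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cerebellum import SingleMapCalibrator
from .fusion import TwoSensorCalibrator, draw_gate_pattern
from .map_core import (
    CoarseGridSpec,
    DistortionModel,
    SensorModel,
    TopographicMapSpec,
)
from .prediction import (
    FilterBank,
    PredictiveCalibrator,
    TrajectorySpec,
    Velocity1DConfig,
    generate_coloured_trajectory,
    run_constant_velocity_1d,
)

__all__ = [
    "Task1Config",
    "Task2Config",
    "Task3Config",
    "VelocityStudyConfig",
    "default_config",
    "run_experiment",
    "probe_lattice",
    "summarize",
    "save_run",
    "TASK_IDS",
]

TASK_IDS = (
    "task1",
    "task1-sign",
    "task2-m1",
    "task2-m2",
    "task2-m3",
    "task3",
    "velocity-1d",
)

# --------------------------------------------------------------------------
# Published parameter sets
# --------------------------------------------------------------------------

MAP_SPEC = TopographicMapSpec(n_g=100, extent=1.5, dim=2)
COARSE = CoarseGridSpec(k=8, gp_cov=0.0352, dim=2)
TARGET_LIMIT = 0.75

TASK1_K = np.array([[0.8944, 0.0], [0.2739, 0.7906]])
TASK1_SIGMA = np.array([[0.0125, -0.0043], [-0.0043, 0.0175]])
TASK1_DISTORTION = DistortionModel(
    A=np.array([[1.1, 0.1], [-0.2, 0.9]]),
    a=np.array([0.0, -0.2]),
    B=np.array([[0.0, -0.05], [0.05, 0.1]]),
    C=np.array([[0.1, 0.7], [-0.8, 0.0]]),
)

TASK2_SIGMA = np.array([[0.0225, 0.0], [0.0, 0.0225]])
#: Pair of affine distortions arranged so the two estimates average to the
#: target: x_g1 + x_g2 ~= 2 x_d (errors cancel in the combined map).
TASK2_CANCELLING = (
    DistortionModel(
        A=np.array([[0.8, 0.2], [-0.4, 1.1]]),
        a=np.zeros(2), B=np.zeros((2, 2)), C=np.zeros((2, 2)),
    ),
    DistortionModel(
        A=np.array([[1.15, -0.21], [0.42, 0.83]]),
        a=np.zeros(2), B=np.zeros((2, 2)), C=np.zeros((2, 2)),
    ),
)
#: Sensor 1 distorted, sensor 2 accurate.
TASK2_ONE_ACCURATE = (
    DistortionModel(
        A=np.array([[0.75, 0.2], [-0.4, 1.1]]),
        a=np.zeros(2),
        B=np.array([[0.01, 0.02], [0.05, -0.05]]),
        C=np.zeros((2, 2)),
    ),
    DistortionModel.identity(2),
)
#: Non-cancelling affine distortions used with independent sensor noise.
TASK2_M3_DISTORTIONS = (
    DistortionModel(
        A=np.array([[0.7, -0.2], [-0.3, 0.9]]),
        a=np.array([0.1, 0.25]), B=np.zeros((2, 2)), C=np.zeros((2, 2)),
    ),
    DistortionModel(
        A=np.array([[0.8, -0.2], [-0.1, 1.1]]),
        a=np.array([-0.5, 0.0]), B=np.zeros((2, 2)), C=np.zeros((2, 2)),
    ),
)
TASK2_NOISE_SD = 0.005

TASK3_DISTORTION = DistortionModel(
    A=np.array([[1.2, 0.2], [-0.3, 0.9]]),
    a=np.zeros(2),
    B=np.array([[0.0, -0.05], [0.05, 0.01]]),
    C=np.zeros((2, 2)),
)


@dataclass
class Task1Config:
    task: str = "task1"
    map_spec: TopographicMapSpec = MAP_SPEC
    sensor: SensorModel = field(
        default_factory=lambda: SensorModel(K=TASK1_K, sigma_rf=TASK1_SIGMA)
    )
    distortion: DistortionModel = TASK1_DISTORTION
    coarse: CoarseGridSpec = COARSE
    beta: float = 1.0
    sign_only: bool = False
    n_trials: int = 3000
    target_limit: float = TARGET_LIMIT
    probe_n: int = 10


@dataclass
class Task2Config:
    task: str = "task2-m1"
    condition: str = "cancelling"  # or "one-accurate"
    map_spec: TopographicMapSpec = MAP_SPEC
    sensors: tuple = field(
        default_factory=lambda: (
            SensorModel(K=np.eye(2), sigma_rf=TASK2_SIGMA),
            SensorModel(K=np.eye(2), sigma_rf=TASK2_SIGMA),
        )
    )
    distortions: tuple = TASK2_CANCELLING
    coarse: CoarseGridSpec = COARSE
    betas: tuple = (0.25, 0.25)
    gating_mode: str = "none"
    n_trials: int = 10_000
    target_limit: float = TARGET_LIMIT
    probe_n: int = 10
    #: log the cross-talk weight RMS every this many trials
    crosstalk_every: int = 10


@dataclass
class Task3Config:
    task: str = "task3"
    map_spec: TopographicMapSpec = MAP_SPEC
    sensor: SensorModel = field(
        default_factory=lambda: SensorModel(K=TASK1_K, sigma_rf=TASK1_SIGMA)
    )
    distortion: DistortionModel = TASK3_DISTORTION
    coarse: CoarseGridSpec = COARSE
    trajectory: TrajectorySpec = TrajectorySpec(
        n_samples=10_000, fs=20.0, cutoff_hz=0.5, limit=TARGET_LIMIT, dim=2
    )
    bank: FilterBank = FilterBank(taus=(0.0500, 0.0707, 0.1000), dt=0.05)
    delay: int = 5
    beta: float = 5.0


@dataclass
class VelocityStudyConfig:
    task: str = "velocity-1d"
    base: Velocity1DConfig = Velocity1DConfig()
    velocities: tuple = (0.125, 0.5, 1.0, 2.0, -0.125, -0.5, -1.0, -2.0)


def default_config(task: str, condition: str = "cancelling"):
    """The published parameter set for a task id."""
    if task == "task1":
        return Task1Config()
    if task == "task1-sign":
        return Task1Config(task=task, sign_only=True)
    if task in ("task2-m1", "task2-m2", "task2-m3"):
        cfg = Task2Config(task=task, condition=condition)
        if task != "task2-m1":
            cfg.gating_mode = "random-thirds"
        if task == "task2-m3":
            cfg.n_trials = 15_000
            cfg.sensors = tuple(
                SensorModel(K=np.eye(2), sigma_rf=TASK2_SIGMA, noise_sd=TASK2_NOISE_SD)
                for _ in range(2)
            )
            cfg.distortions = TASK2_M3_DISTORTIONS
        elif condition == "one-accurate":
            cfg.distortions = TASK2_ONE_ACCURATE
        return cfg
    if task == "task3":
        return Task3Config()
    if task == "velocity-1d":
        return VelocityStudyConfig()
    raise ValueError(f"unknown task {task!r}; expected one of {TASK_IDS}")


# --------------------------------------------------------------------------
# Runners
# --------------------------------------------------------------------------


def probe_lattice(n: int, limit: float = TARGET_LIMIT, dim: int = 2) -> np.ndarray:
    """Deterministic n-per-axis lattice of probe targets."""
    axis = np.linspace(-limit, limit, n)
    if dim == 1:
        return axis[:, None]
    gx, gy = np.meshgrid(axis, axis, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel()])


@dataclass
class RunResult:
    log: pd.DataFrame
    summary: dict
    calibrator: object


def _rms(a: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.asarray(a) ** 2)))


def _norms(e: np.ndarray) -> np.ndarray:
    return np.linalg.norm(np.atleast_2d(e), axis=-1)


def _run_task1(cfg: Task1Config, seed: int, resume=None) -> RunResult:
    rng = np.random.default_rng(seed)
    calib = SingleMapCalibrator(
        cfg.map_spec, cfg.sensor, cfg.distortion, cfg.coarse,
        beta=cfg.beta, sign_only=cfg.sign_only,
    )
    if resume is not None:
        calib.mz.w = _load_snapshot(resume)["w"].copy()
    records = calib.run(cfg.n_trials, rng, target_limit=cfg.target_limit)
    log = pd.DataFrame(
        {
            "trial": np.arange(cfg.n_trials),
            "x_d": [r["x_d"][0] for r in records],
            "y_d": [r["x_d"][1] for r in records],
            "x_g": [r["x_g"][0] for r in records],
            "y_g": [r["x_g"][1] for r in records],
            "x_a": [r["x_a"][0] for r in records],
            "y_a": [r["x_a"][1] for r in records],
            "e_x": [r["e"][0] for r in records],
            "e_y": [r["e"][1] for r in records],
        }
    )
    log["err"] = np.hypot(log["e_x"], log["e_y"])
    log["rms_e"] = log["err"] / np.sqrt(2.0)
    summary = summarize(log)
    probe_err = calib.probe(probe_lattice(cfg.probe_n, cfg.target_limit))
    summary["probe_rms"] = _rms(_norms(probe_err))
    return RunResult(log=log, summary=summary, calibrator=calib)


def _run_task2(cfg: Task2Config, seed: int, resume=None) -> RunResult:
    ss = np.random.SeedSequence(seed)
    rng_t, rng_gate, rng_n1, rng_n2 = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    calib = TwoSensorCalibrator(
        cfg.map_spec, cfg.sensors, cfg.distortions, cfg.coarse,
        betas=cfg.betas, gating_mode=cfg.gating_mode,
    )
    if resume is not None:
        snap = _load_snapshot(resume)
        for i, mz in enumerate(calib.microzones):
            mz.w = snap[f"w{i + 1}"].copy()
    targets = rng_t.uniform(
        -cfg.target_limit, cfg.target_limit, size=(cfg.n_trials, 2)
    )
    rows = []
    ct_trials, ct1s, ct2s = [], [], []
    records = []
    for i, t in enumerate(targets):
        if cfg.gating_mode != "none":
            gates = draw_gate_pattern(rng_gate, cfg.gating_mode)
        else:
            gates = (False, False)
        rec = calib.trial(t, (rng_n1, rng_n2), gates=gates)
        records.append(rec)
        if (i + 1) % cfg.crosstalk_every == 0 or i == cfg.n_trials - 1:
            c1, c2 = calib.crosstalk_rms()
            ct_trials.append(i)
            ct1s.append(c1)
            ct2s.append(c2)
    log = pd.DataFrame(
        {
            "trial": np.arange(cfg.n_trials),
            "x_d": [r.x_d[0] for r in records],
            "y_d": [r.x_d[1] for r in records],
            "x_a": [r.x_a[0] for r in records],
            "y_a": [r.x_a[1] for r in records],
            "e_x": [r.e[0] for r in records],
            "e_y": [r.e[1] for r in records],
            "gate_s1": [r.gates[0] for r in records],
            "gate_s2": [r.gates[1] for r in records],
            "x_g1": [r.x_enc[0][0] for r in records],
            "y_g1": [r.x_enc[0][1] for r in records],
            "x_g2": [r.x_enc[1][0] for r in records],
            "y_g2": [r.x_enc[1][1] for r in records],
            "z1_x": [r.z[0][0] for r in records],
            "z1_y": [r.z[0][1] for r in records],
            "z2_x": [r.z[1][0] for r in records],
            "z2_y": [r.z[1][1] for r in records],
        }
    )
    log["err"] = np.hypot(log["e_x"], log["e_y"])
    log["rms_e"] = log["err"] / np.sqrt(2.0)
    crosstalk = pd.DataFrame(
        {"trial": ct_trials, "crosstalk_rms_1": ct1s, "crosstalk_rms_2": ct2s}
    )
    summary = summarize(log)
    lattice = probe_lattice(cfg.probe_n, cfg.target_limit)
    summary["probe_combined_rms"] = _rms(_norms(calib.probe_combined(lattice)))
    summary["probe_sensor_rms"] = [
        _rms(_norms(calib.probe_sensor(i, lattice))) for i in range(2)
    ]
    for i in (0, 1):
        series = crosstalk[f"crosstalk_rms_{i + 1}"].to_numpy()
        summary[f"crosstalk_final_{i + 1}"] = float(series[-1])
        summary[f"crosstalk_peak_{i + 1}"] = float(series.max())
    res = RunResult(log=log, summary=summary, calibrator=calib)
    res.crosstalk = crosstalk
    return res


def _run_task3(cfg: Task3Config, seed: int, resume=None) -> RunResult:
    ss = np.random.SeedSequence(seed)
    rng_calib, rng_train = (np.random.default_rng(s) for s in ss.spawn(2))
    calib = PredictiveCalibrator(
        cfg.map_spec, cfg.sensor, cfg.distortion, cfg.coarse,
        cfg.bank, cfg.delay, beta=cfg.beta,
    )
    snap = _load_snapshot(resume) if resume is not None else {}
    if "Q" in snap:
        calib.bank = calib.bank.with_Q(snap["Q"])
    else:
        # held-out trajectory fixes the decorrelation matrix Q before learning
        calib.calibrate_decorrelation(
            generate_coloured_trajectory(cfg.trajectory, rng_calib)
        )
    if "w" in snap:
        calib.mz.w = snap["w"].copy()
    traj = generate_coloured_trajectory(cfg.trajectory, rng_train)
    out = calib.run(traj, learn=True)
    n = len(out["e"])
    log = pd.DataFrame(
        {
            "trial": np.arange(n),
            "x_d": traj[cfg.delay : cfg.delay + n, 0],
            "y_d": traj[cfg.delay : cfg.delay + n, 1],
            "x_g": out["x_g"][:, 0],
            "y_g": out["x_g"][:, 1],
            "x_a": out["x_a"][:, 0],
            "y_a": out["x_a"][:, 1],
            "e_x": out["e"][:, 0],
            "e_y": out["e"][:, 1],
        }
    )
    log["err"] = _norms(out["e"])
    log["rms_e"] = log["err"] / np.sqrt(2.0)
    log["err_nobias"] = _norms(out["e_nobias"])
    summary = summarize(log)
    tail = slice(-1000, None)
    summary["tail_rms"] = _rms(log["err"].to_numpy()[tail])
    summary["tail_rms_nobias"] = _rms(log["err_nobias"].to_numpy()[tail])
    summary["tail_ratio"] = summary["tail_rms"] / summary["tail_rms_nobias"]
    return RunResult(log=log, summary=summary, calibrator=calib)


def _run_velocity(cfg: VelocityStudyConfig, seed: int) -> RunResult:
    # fully deterministic; seed kept for interface uniformity
    profiles = [run_constant_velocity_1d(v, cfg.base) for v in cfg.velocities]
    log = pd.DataFrame(
        {
            "velocity": [p.velocity for p in profiles],
            "mean_shift": [p.mean_shift for p in profiles],
            "optimal_shift": [p.optimal_shift for p in profiles],
        }
    )
    summary = {
        "velocities": list(cfg.velocities),
        "mean_shifts": [p.mean_shift for p in profiles],
        "optimal_shifts": [p.optimal_shift for p in profiles],
    }
    res = RunResult(log=log, summary=summary, calibrator=None)
    res.profiles = profiles
    return res


def run_experiment(cfg, seed: int = 0, resume: str | Path | None = None) -> RunResult:
    """Execute a configured task end-to-end with seeded randomness.

    ``resume`` points at a ``weights.npz`` snapshot (or the run directory
    containing one) written by :func:`save_run`; learning continues from the
    stored weights instead of zero.
    """
    if isinstance(cfg, Task1Config):
        return _run_task1(cfg, seed, resume)
    if isinstance(cfg, Task2Config):
        return _run_task2(cfg, seed, resume)
    if isinstance(cfg, Task3Config):
        return _run_task3(cfg, seed, resume)
    if isinstance(cfg, VelocityStudyConfig):
        return _run_velocity(cfg, seed)
    raise TypeError(f"unrecognised config type {type(cfg).__name__}")


def _load_snapshot(resume) -> dict:
    path = Path(resume)
    if path.is_dir():
        path = path / "weights.npz"
    with np.load(path) as npz:
        return {k: npz[k] for k in npz.files}


# --------------------------------------------------------------------------
# Metrics and persistence
# --------------------------------------------------------------------------


def summarize(
    log: pd.DataFrame, window: int = 500, threshold: float = 0.02
) -> dict:
    """Windowed error statistics of a trial log.

    The per-trial scalar is the RMS over error components,
    sqrt((e_x^2 + e_y^2) / 2) (column ``rms_e``; the plain Euclidean norm
    ``err`` is used if absent).  ``final_window_rms`` is its mean over the
    last ``window`` trials; ``convergence_trial`` is the first trial at
    which the trailing-``window`` mean drops below ``threshold`` (None if
    never).
    """
    if len(log) == 0:
        raise ValueError("empty trial log")
    err = log["rms_e" if "rms_e" in log else "err"].to_numpy()
    n = len(err)
    w = min(window, n)
    trailing = pd.Series(err).rolling(w).mean().to_numpy()
    below = np.flatnonzero(trailing < threshold)
    return {
        "n_trials": n,
        "final_window_rms": float(err[-w:].mean()),
        "window": w,
        "convergence_trial": int(below[0]) if below.size else None,
    }


def save_run(result: RunResult, out_dir: str | Path, cfg=None) -> Path:
    """Write the trial log (CSV), summary (JSON) and weights (NPZ) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.log.to_csv(out / "trial_log.csv", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2, default=_json_default)
    if hasattr(result, "crosstalk"):
        result.crosstalk.to_csv(out / "crosstalk.csv", index=False)
    calib = result.calibrator
    weights = {}
    if hasattr(calib, "mz"):
        weights["w"] = calib.mz.w
        weights["beta"] = calib.mz.beta
    elif hasattr(calib, "microzones"):
        for i, mz in enumerate(calib.microzones):
            weights[f"w{i + 1}"] = mz.w
            weights[f"beta{i + 1}"] = mz.beta
    if hasattr(calib, "bank") and calib.bank.Q is not None:
        weights["Q"] = calib.bank.Q
    if weights:
        np.savez(out / "weights.npz", **weights)
    if cfg is not None:
        from .config import dump_config

        dump_config(cfg, out / "config.yaml")
    return out


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"cannot serialise {type(o)}")
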