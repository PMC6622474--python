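"""Plain-text (YAML) configuration round-tripping for experiment configs.

The schema mirrors the config dataclasses field-for-field, with matrices as
nested lists: e.g. a single-map run is

.. code-block:: yaml

    task: task1
    sensor: {K: [[0.8944, 0.0], [0.2739, 0.7906]], sigma_rf: [[0.0125, ...]]}
    distortion: {A: ..., a: ..., B: ..., C: ...}
    coarse: {k: 8, gp_cov: [[0.0352, 0.0], [0.0, 0.0352]], dim: 2}
    beta: 1.0
    n_trials: 3000
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import yaml

from .map_core import (
    CoarseGridSpec,
    DistortionModel,
    SensorModel,
    TopographicMapSpec,
)
from .prediction import FilterBank, TrajectorySpec, Velocity1DConfig

__all__ = ["dump_config", "load_config", "config_to_dict", "config_from_dict"]


def _encode(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        out = {}
        for f in dataclasses.fields(obj):
            if not f.init:  # skip derived caches (K_inv, axis_centres, ...)
                continue
            out[f.name] = _encode(getattr(obj, f.name))
        return out
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (tuple, list)):
        return [_encode(v) for v in obj]
    return obj


def config_to_dict(cfg) -> dict:
    return _encode(cfg)


def _maybe(d: dict, key: str, fn, default=None):
    return fn(d[key]) if key in d and d[key] is not None else default


def _sensor(d: dict) -> SensorModel:
    return SensorModel(
        K=np.asarray(d["K"]),
        sigma_rf=np.asarray(d["sigma_rf"]),
        noise_sd=d.get("noise_sd", 0.0),
        gated_sigma_rf=_maybe(d, "gated_sigma_rf", np.asarray),
    )


def _distortion(d: dict) -> DistortionModel:
    return DistortionModel(
        A=np.asarray(d["A"]), a=np.asarray(d["a"]),
        B=np.asarray(d["B"]), C=np.asarray(d["C"]),
    )


def _map_spec(d: dict) -> TopographicMapSpec:
    return TopographicMapSpec(**d)


def _coarse(d: dict) -> CoarseGridSpec:
    return CoarseGridSpec(
        k=d["k"], gp_cov=np.asarray(d["gp_cov"]), dim=d.get("dim", 2)
    )


def config_from_dict(d: dict):
    from .experiments import (
        Task1Config,
        Task2Config,
        Task3Config,
        VelocityStudyConfig,
    )

    task = d["task"]
    if task in ("task1", "task1-sign"):
        return Task1Config(
            task=task,
            map_spec=_map_spec(d["map_spec"]),
            sensor=_sensor(d["sensor"]),
            distortion=_distortion(d["distortion"]),
            coarse=_coarse(d["coarse"]),
            beta=d["beta"],
            sign_only=d.get("sign_only", task == "task1-sign"),
            n_trials=d["n_trials"],
            target_limit=d.get("target_limit", 0.75),
            probe_n=d.get("probe_n", 10),
        )
    if task.startswith("task2"):
        return Task2Config(
            task=task,
            condition=d.get("condition", "cancelling"),
            map_spec=_map_spec(d["map_spec"]),
            sensors=tuple(_sensor(s) for s in d["sensors"]),
            distortions=tuple(_distortion(x) for x in d["distortions"]),
            coarse=_coarse(d["coarse"]),
            betas=tuple(d["betas"]),
            gating_mode=d.get("gating_mode", "none"),
            n_trials=d["n_trials"],
            target_limit=d.get("target_limit", 0.75),
            probe_n=d.get("probe_n", 10),
            crosstalk_every=d.get("crosstalk_every", 10),
        )
    if task == "task3":
        return Task3Config(
            map_spec=_map_spec(d["map_spec"]),
            sensor=_sensor(d["sensor"]),
            distortion=_distortion(d["distortion"]),
            coarse=_coarse(d["coarse"]),
            trajectory=TrajectorySpec(**d["trajectory"]),
            bank=FilterBank(
                taus=tuple(d["bank"]["taus"]), dt=d["bank"]["dt"],
                Q=_maybe(d["bank"], "Q", np.asarray),
            ),
            delay=d["delay"],
            beta=d["beta"],
        )
    if task == "velocity-1d":
        base = dict(d.get("base", {}))
        if "taus" in base:
            base["taus"] = tuple(base["taus"])
        return VelocityStudyConfig(
            base=Velocity1DConfig(**base),
            velocities=tuple(d.get("velocities", (0.125, 0.5, 1.0, 2.0))),
        )
    raise ValueError(f"unknown task {task!r}")


def dump_config(cfg, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)


def load_config(path: str | Path):
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))
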