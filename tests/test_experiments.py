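"""Task runners: determinism, published defaults, summaries, config I/O."""

import numpy as np
import pandas as pd
import pytest

from mapcalib.config import config_from_dict, config_to_dict
from mapcalib.experiments import (
    default_config,
    probe_lattice,
    run_experiment,
    summarize,
)


class TestDefaultsAudit:
    """The default configs must equal the published parameter sets."""

    def test_task1(self):
        cfg = default_config("task1")
        assert cfg.map_spec.n_g == 100 and cfg.map_spec.extent == 1.5
        np.testing.assert_array_equal(
            cfg.sensor.K, [[0.8944, 0.0], [0.2739, 0.7906]]
        )
        np.testing.assert_array_equal(
            cfg.sensor.sigma_rf, [[0.0125, -0.0043], [-0.0043, 0.0175]]
        )
        d = cfg.distortion
        np.testing.assert_array_equal(d.A, [[1.1, 0.1], [-0.2, 0.9]])
        np.testing.assert_array_equal(d.a, [0.0, -0.2])
        np.testing.assert_array_equal(d.B, [[0.0, -0.05], [0.05, 0.1]])
        np.testing.assert_array_equal(d.C, [[0.1, 0.7], [-0.8, 0.0]])
        assert cfg.coarse.k == 8
        np.testing.assert_array_equal(cfg.coarse.gp_cov, 0.0352 * np.eye(2))
        assert cfg.beta == 1.0 and cfg.n_trials == 3000
        assert cfg.target_limit == 0.75
        assert default_config("task1-sign").sign_only

    def test_task2(self):
        cfg = default_config("task2-m1")
        for s in cfg.sensors:
            np.testing.assert_array_equal(s.K, np.eye(2))
            np.testing.assert_array_equal(s.sigma_rf, 0.0225 * np.eye(2))
            np.testing.assert_array_equal(s.gated_sigma_rf, 4.5 * np.eye(2))
        a1, a2 = cfg.distortions
        np.testing.assert_array_equal(a1.A, [[0.8, 0.2], [-0.4, 1.1]])
        np.testing.assert_array_equal(a2.A, [[1.15, -0.21], [0.42, 0.83]])
        assert cfg.betas == (0.25, 0.25)
        assert cfg.gating_mode == "none" and cfg.n_trials == 10_000
        assert default_config("task2-m2").gating_mode == "random-thirds"
        one = default_config("task2-m2", condition="one-accurate")
        np.testing.assert_array_equal(
            one.distortions[0].A, [[0.75, 0.2], [-0.4, 1.1]]
        )
        np.testing.assert_array_equal(
            one.distortions[0].B, [[0.01, 0.02], [0.05, -0.05]]
        )
        np.testing.assert_array_equal(one.distortions[1].A, np.eye(2))
        m3 = default_config("task2-m3")
        assert m3.n_trials == 15_000
        assert all(s.noise_sd == 0.005 for s in m3.sensors)
        np.testing.assert_array_equal(m3.distortions[0].A, [[0.7, -0.2], [-0.3, 0.9]])
        np.testing.assert_array_equal(m3.distortions[0].a, [0.1, 0.25])
        np.testing.assert_array_equal(m3.distortions[1].A, [[0.8, -0.2], [-0.1, 1.1]])
        np.testing.assert_array_equal(m3.distortions[1].a, [-0.5, 0.0])

    def test_task3(self):
        cfg = default_config("task3")
        np.testing.assert_array_equal(cfg.distortion.A, [[1.2, 0.2], [-0.3, 0.9]])
        np.testing.assert_array_equal(cfg.distortion.B, [[0.0, -0.05], [0.05, 0.01]])
        assert cfg.delay == 5 and cfg.beta == 5.0
        assert cfg.trajectory.n_samples == 10_000
        assert cfg.trajectory.fs == 20.0 and cfg.trajectory.cutoff_hz == 0.5
        assert cfg.bank.taus == (0.0500, 0.0707, 0.1000)

    def test_velocity_1d(self):
        cfg = default_config("velocity-1d")
        b = cfg.base
        assert (b.K, b.sigma_rf, b.beta) == (0.1094, 0.7559, 25.0)
        assert (b.delay, b.dt, b.k) == (100, 0.005, 8)
        assert b.taus == (0.0500, 0.0707, 0.1000)
        assert set(abs(v) for v in cfg.velocities) == {0.125, 0.5, 1.0, 2.0}


class TestDeterminism:
    def test_task1_logs_bit_identical(self):
        cfg = default_config("task1")
        cfg.n_trials = 150
        a = run_experiment(cfg, seed=7)
        b = run_experiment(cfg, seed=7)
        pd.testing.assert_frame_equal(a.log, b.log)
        assert a.summary == b.summary

    def test_task2_logs_bit_identical(self):
        cfg = default_config("task2-m3")
        cfg.n_trials = 80
        a = run_experiment(cfg, seed=3)
        b = run_experiment(cfg, seed=3)
        pd.testing.assert_frame_equal(a.log, b.log)
        pd.testing.assert_frame_equal(a.crosstalk, b.crosstalk)

    def test_different_seeds_differ(self):
        cfg = default_config("task1")
        cfg.n_trials = 20
        a = run_experiment(cfg, seed=1)
        b = run_experiment(cfg, seed=2)
        assert not a.log.equals(b.log)


class TestSummarize:
    def test_constant_error_series(self):
        log = pd.DataFrame({"err": np.full(800, 0.3)})
        s = summarize(log, window=500, threshold=0.02)
        assert s["final_window_rms"] == pytest.approx(0.3)
        assert s["convergence_trial"] is None

    def test_convergence_trial_unique_for_decreasing_series(self):
        err = np.geomspace(1.0, 1e-4, 2000)
        s = summarize(pd.DataFrame({"err": err}), window=100, threshold=0.02)
        trailing = pd.Series(err).rolling(100).mean().to_numpy()
        assert trailing[s["convergence_trial"]] < 0.02
        assert trailing[s["convergence_trial"] - 1] >= 0.02

    def test_empty_log_raises(self):
        with pytest.raises(ValueError):
            summarize(pd.DataFrame({"err": []}))


def test_zero_weight_probe_without_distortion_is_round_trip_bound(
    map_spec, task1_sensor, coarse
):
    from mapcalib import DistortionModel, SingleMapCalibrator

    calib = SingleMapCalibrator(
        map_spec, task1_sensor, DistortionModel.identity(2), coarse
    )
    errs = calib.probe(probe_lattice(10))
    assert np.sqrt(np.mean(np.linalg.norm(errs, axis=1) ** 2)) < 0.02


def test_zero_weight_probe_matches_raw_distortion_error(
    map_spec, task1_sensor, coarse, task1_distortion
):
    from mapcalib import SingleMapCalibrator, distort, encode_location, sense
    calib = SingleMapCalibrator(map_spec, task1_sensor, task1_distortion, coarse)
    lattice = probe_lattice(6)
    errs = calib.probe(lattice)
    expected = np.array(
        [
            t - encode_location(distort(sense(t, task1_sensor), task1_distortion), task1_sensor)
            for t in lattice
        ]
    )
    # population-vector readout differs from the analytic encoding only by
    # discretisation / truncation
    assert np.abs(np.linalg.norm(errs, axis=1) - np.linalg.norm(expected, axis=1)).max() < 0.05


class TestConfigRoundTrip:
    @pytest.mark.parametrize("task", ["task1", "task2-m3", "task3", "velocity-1d"])
    def test_yaml_dict_round_trip(self, task):
        cfg = default_config(task)
        d = config_to_dict(cfg)
        back = config_from_dict(d)
        assert config_to_dict(back) == d

    def test_round_trip_through_file(self, tmp_path):
        import yaml

        from mapcalib.config import dump_config, load_config

        cfg = default_config("task1")
        path = tmp_path / "cfg.yaml"
        dump_config(cfg, path)
        loaded = load_config(path)
        assert config_to_dict(loaded) == config_to_dict(cfg)
        # plain-text, human-editable
        raw = yaml.safe_load(path.read_text())
        assert raw["task"] == "task1" and raw["beta"] == 1.0


def test_resume_from_weight_snapshot(tmp_path):
    from mapcalib.experiments import save_run

    cfg = default_config("task1")
    cfg.n_trials = 60
    first = run_experiment(cfg, seed=11)
    out = save_run(first, tmp_path / "run")
    resumed = run_experiment(cfg, seed=12, resume=out)
    # resumed learning starts from the stored weights: the very first trial
    # already applies a non-zero bias
    assert abs(resumed.log.loc[0, "x_a"] - resumed.log.loc[0, "x_g"]) > 0
    fresh = run_experiment(cfg, seed=12)
    assert resumed.log.loc[0, "x_a"] != fresh.log.loc[0, "x_a"]


def test_cli_run_smoke(tmp_path):
    from click.testing import CliRunner

    from mapcalib.cli import main

    res = CliRunner().invoke(
        main, ["run", "task1", "--trials", "40", "--seed", "0",
               "--out", str(tmp_path / "run")]
    )
    assert res.exit_code == 0, res.output
    assert (tmp_path / "run" / "trial_log.csv").exists()
    assert (tmp_path / "run" / "summary.json").exists()
    assert (tmp_path / "run" / "config.yaml").exists()
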