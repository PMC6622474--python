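"""Sensor model, distortion, map write/read and coarse coding."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from mapcalib import (
    ConfigurationError,
    CoarseGridSpec,
    DegenerateMapError,
    DistortionModel,
    SensorModel,
    TopographicMapSpec,
    apply_bias,
    build_coarse_weights,
    coarse_code,
    distort,
    encode_location,
    normalize_pf,
    read_map,
    sense,
    write_activity,
    write_map,
)
from mapcalib.experiments import TASK1_K, TASK1_SIGMA


@pytest.mark.parametrize(
    "x_d, K, expected",
    [
        ((0.0, 0.0), TASK1_K, (0.0, 0.0)),
        ((1.0, 0.0), TASK1_K, (0.8944, 0.2739)),
        ((0.5, 0.5), np.eye(2), (0.5, 0.5)),
    ],
)
def test_noiseless_sensor_is_linear_map(x_d, K, expected):
    m = SensorModel(K=K, sigma_rf=TASK1_SIGMA)
    np.testing.assert_allclose(sense(x_d, m), expected, atol=1e-12)


def test_sensor_noise_is_zero_mean_gaussian(rng):
    m = SensorModel(K=np.eye(2), sigma_rf=TASK1_SIGMA, noise_sd=0.01)
    draws = np.array([sense((0.2, -0.1), m, rng) for _ in range(4000)])
    resid = draws - np.array([0.2, -0.1])
    np.testing.assert_allclose(resid.mean(axis=0), 0.0, atol=6e-4)
    np.testing.assert_allclose(resid.std(axis=0), 0.01, rtol=0.1)


def test_singular_sensor_matrix_rejected_at_construction():
    with pytest.raises(ConfigurationError):
        SensorModel(K=np.array([[1.0, 2.0], [2.0, 4.0]]), sigma_rf=TASK1_SIGMA)


def test_nonpositive_receptive_field_rejected():
    with pytest.raises(ConfigurationError):
        SensorModel(K=np.eye(2), sigma_rf=-np.eye(2))


class TestDistortion:
    def test_offset_only_at_origin(self, task1_distortion):
        np.testing.assert_array_equal(
            distort((0.0, 0.0), task1_distortion), (0.0, -0.2)
        )

    def test_hand_evaluated_quadratic_term(self):
        d = DistortionModel(
            A=np.eye(2), a=np.zeros(2),
            B=np.array([[0.0, -0.05], [0.05, 0.1]]), C=np.zeros((2, 2)),
        )
        np.testing.assert_allclose(distort((1.0, 1.0), d), (0.95, 1.15))

    @given(arrays(float, (2,), elements=st.floats(-2, 2)))
    def test_identity_distortion_is_exact_noop(self, s):
        out = distort(s, DistortionModel.identity(2))
        assert np.array_equal(out, s)


class TestMapWriteRead:
    def test_peak_at_encoded_location(self, map_spec, task1_sensor):
        act = write_map(task1_sensor.K @ np.zeros(2), map_spec, task1_sensor)
        i, j = np.unravel_index(act.argmax(), act.shape)
        c = map_spec.axis_centres
        # centre-most neurons of an even grid straddle the origin
        assert abs(c[i]) <= map_spec.spacing and abs(c[j]) <= map_spec.spacing
        assert act.max() <= 1.0

    def test_gated_write_is_near_flat(self, map_spec, task1_sensor):
        s = task1_sensor.K @ np.array([0.0, 0.0])
        sharp = write_map(s, map_spec, task1_sensor)
        flat = write_map(s, map_spec, task1_sensor, gated=True)
        assert flat.max() / flat.min() < 3
        assert sharp.max() / sharp.min() > 1e6

    def test_activity_decays_away_from_bump(self, map_spec, task1_sensor):
        s = task1_sensor.K @ np.array([0.75, 0.75])
        act = write_map(s, map_spec, task1_sensor)
        c = map_spec.axis_centres
        x = encode_location(s, task1_sensor)
        d2 = (c[:, None] - x[0]) ** 2 + (c[None, :] - x[1]) ** 2
        near = act[np.unravel_index(d2.argmin(), d2.shape)]
        assert near > act[d2 >= 0.3**2].max()

    def test_single_neuron_readout_returns_its_centre(self, map_spec):
        act = np.zeros((100, 100))
        act[12, 87] = 0.7
        c = map_spec.axis_centres
        np.testing.assert_allclose(read_map(act, map_spec), (c[12], c[87]))

    def test_symmetric_bump_reads_as_origin(self, map_spec, task1_sensor):
        act = write_activity((0.0, 0.0), map_spec, np.linalg.inv(np.eye(2) * 0.02))
        np.testing.assert_allclose(read_map(act, map_spec), (0.0, 0.0), atol=1e-12)

    def test_round_trip_single_target(self, map_spec, task1_sensor):
        x_d = np.array([0.3, -0.4])
        est = read_map(write_map(sense(x_d, task1_sensor), map_spec, task1_sensor), map_spec)
        assert np.linalg.norm(est - x_d) < 0.01

    def test_round_trip_fidelity_over_target_lattice(self, map_spec, task1_sensor):
        axis = np.linspace(-0.75, 0.75, 20)
        worst = 0.0
        for x in axis:
            for y in axis:
                x_d = np.array([x, y])
                est = read_map(
                    write_map(sense(x_d, task1_sensor), map_spec, task1_sensor),
                    map_spec,
                )
                worst = max(worst, np.linalg.norm(est - x_d))
        assert worst < 0.02

    def test_translation_covariance_by_one_grid_spacing(self, map_spec, task1_sensor):
        h = map_spec.spacing
        inv = task1_sensor.sigma_rf_inv
        a = read_map(write_activity((0.2, -0.1), map_spec, inv), map_spec)
        b = read_map(write_activity((0.2 + h, -0.1), map_spec, inv), map_spec)
        np.testing.assert_allclose(b - a, (h, 0.0), atol=1e-9)

    def test_empty_map_raises(self, map_spec):
        with pytest.raises(DegenerateMapError):
            read_map(np.zeros((100, 100)), map_spec)


class TestCoarseCoding:
    def test_zero_map_gives_zero_vector(self, map_spec, coarse):
        w = build_coarse_weights(coarse, map_spec)
        assert not coarse_code(np.zeros((100, 100)), w).any()

    def test_bump_on_coarse_centre_dominates(self, map_spec, coarse):
        w = build_coarse_weights(coarse, map_spec)
        centres = np.linspace(-map_spec.extent, map_spec.extent, coarse.k)
        n = 3 * coarse.k + 4  # coarse cell (3, 4)
        act = write_activity(
            (centres[3], centres[4]), map_spec, np.linalg.inv(TASK1_SIGMA)
        )
        assert coarse_code(act, w).argmax() == n

    def test_translated_bump_moves_argmax(self, map_spec, coarse):
        w = build_coarse_weights(coarse, map_spec)
        inv = np.linalg.inv(TASK1_SIGMA)
        q0 = coarse_code(write_activity((-0.8, 0.0), map_spec, inv), w)
        q1 = coarse_code(write_activity((0.8, 0.0), map_spec, inv), w)
        assert q0.argmax() != q1.argmax()
        centres = np.linspace(-map_spec.extent, map_spec.extent, coarse.k)
        assert centres[q1.argmax() // coarse.k] > centres[q0.argmax() // coarse.k]

    def test_gaussian_write_keeps_pf_well_defined(self, map_spec, coarse, task1_sensor):
        # strictly positive activity everywhere -> normalisation never degenerate
        w = build_coarse_weights(coarse, map_spec)
        act = write_map(sense((0.75, -0.75), task1_sensor), map_spec, task1_sensor)
        assert act.min() > 0
        P = normalize_pf(coarse_code(act, w))
        assert P.min() >= 0


class TestPFNormalisation:
    def test_uniform_vector(self):
        np.testing.assert_allclose(normalize_pf(np.full(64, 2.0)), np.full(64, 1 / 64))

    def test_one_hot(self):
        q = np.zeros(64)
        q[17] = 3.5
        P = normalize_pf(q)
        assert P[17] == 1.0 and P.sum() == 1.0

    @given(
        arrays(float, st.integers(1, 100), elements=st.floats(0, 1e6)).filter(
            lambda q: q.sum() > 0
        )
    )
    def test_sums_to_one(self, q):
        assert abs(normalize_pf(q).sum() - 1.0) < 1e-12

    def test_all_zero_raises(self):
        with pytest.raises(DegenerateMapError):
            normalize_pf(np.zeros(64))


def test_apply_bias():
    np.testing.assert_array_equal(apply_bias((0.1, 0.2), (0.0, 0.0)), (0.1, 0.2))
    np.testing.assert_allclose(apply_bias((0.1, 0.2), (-0.1, -0.2)), (0.0, 0.0))
    x_g, x_d = np.array([0.4, -0.2]), np.array([0.5, 0.1])
    np.testing.assert_allclose(apply_bias(x_g, x_d - x_g), x_d)


def test_one_dimensional_write_and_read():
    spec = TopographicMapSpec(n_g=100, extent=10.0, dim=1)
    m = SensorModel(K=0.1094, sigma_rf=0.7559)
    est = read_map(write_map(sense([3.0], m), spec, m), spec)
    np.testing.assert_allclose(est, [3.0], atol=0.01)
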