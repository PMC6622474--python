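"""Sensor simulation, distortion, and the topographic (collicular) map.

The superior colliculus is modelled as a square grid of neurons whose
receptive-field centres tile a 2-D (or 1-D) workspace in dimensionless map
units.  A target at ``x_d`` is sensed through a linear sensor model
``s = K @ x_d`` (optionally with additive Gaussian noise), possibly corrupted
by an element-wise cubic polynomial distortion, and written into the map as a
Gaussian bump centred on the encoded location ``K^-1 @ s``.  The map is read
out with a population vector (activity-weighted mean of receptive-field
centres), and re-represented for the cerebellum by a small grid of broad
Gaussian receptive fields ("coarse coding") whose normalised outputs are the
parallel-fibre signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfigurationError",
    "DegenerateMapError",
    "SensorModel",
    "DistortionModel",
    "TopographicMapSpec",
    "CoarseGridSpec",
    "sense",
    "distort",
    "encode_location",
    "write_activity",
    "write_map",
    "read_map",
    "build_coarse_weights",
    "coarse_code",
    "normalize_pf",
    "apply_bias",
]

#: Receptive-field covariance used on trials where a sensor fails to detect
#: the target: the written bump becomes near-flat over the whole map.
GATED_VARIANCE = 4.5


class ConfigurationError(ValueError):
    """Raised at model construction for invalid parameters (e.g. singular K)."""


class DegenerateMapError(ValueError):
    """Raised when a map or parallel-fibre vector has no activity to read."""


def _as_matrix(m, dim: int, name: str) -> np.ndarray:
    a = np.asarray(m, dtype=float)
    if a.ndim == 0:
        a = a.reshape(1, 1)
    if a.shape != (dim, dim):
        raise ConfigurationError(f"{name} must be {dim}x{dim}, got shape {a.shape}")
    return a


def _check_spd(m: np.ndarray, name: str) -> None:
    if not np.allclose(m, m.T):
        raise ConfigurationError(f"{name} must be symmetric")
    if np.any(np.linalg.eigvalsh(m) <= 0):
        raise ConfigurationError(f"{name} must be positive definite")


@dataclass(frozen=True)
class SensorModel:
    """Linear sensor ``s = K @ x`` with a Gaussian receptive-field spread.

    Parameters
    ----------
    K : (d, d) array_like or scalar
        Invertible sensor matrix mapping target location to sensor data.
    sigma_rf : (d, d) array_like or scalar
        Positive-definite receptive-field covariance of the written bump,
        in map units squared.
    noise_sd : float
        Standard deviation of independent additive Gaussian sensor noise
        (0 gives the noiseless linear sensor exactly).
    gated_sigma_rf : optional covariance used when the sensor fails to
        detect the target; defaults to ``GATED_VARIANCE * I``.
    """

    K: np.ndarray
    sigma_rf: np.ndarray
    noise_sd: float = 0.0
    gated_sigma_rf: np.ndarray | None = None
    # caches, filled in __post_init__
    K_inv: np.ndarray = field(init=False, repr=False)
    sigma_rf_inv: np.ndarray = field(init=False, repr=False)
    gated_sigma_rf_inv: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        K = np.asarray(self.K, dtype=float)
        if K.ndim == 0:
            K = K.reshape(1, 1)
        dim = K.shape[0]
        K = _as_matrix(K, dim, "K")
        if abs(np.linalg.det(K)) < 1e-12:
            raise ConfigurationError("sensor matrix K is singular")
        sigma = _as_matrix(self.sigma_rf, dim, "sigma_rf")
        _check_spd(sigma, "sigma_rf")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        gated = self.gated_sigma_rf
        gated = GATED_VARIANCE * np.eye(dim) if gated is None else _as_matrix(gated, dim, "gated_sigma_rf")
        _check_spd(gated, "gated_sigma_rf")
        object.__setattr__(self, "K", K)
        object.__setattr__(self, "sigma_rf", sigma)
        object.__setattr__(self, "gated_sigma_rf", gated)
        object.__setattr__(self, "K_inv", np.linalg.inv(K))
        object.__setattr__(self, "sigma_rf_inv", np.linalg.inv(sigma))
        object.__setattr__(self, "gated_sigma_rf_inv", np.linalg.inv(gated))

    @property
    def dim(self) -> int:
        return self.K.shape[0]


@dataclass(frozen=True)
class DistortionModel:
    """Element-wise cubic polynomial distortion of sensor data.

    ``s_g = A @ s + a + B @ (s*s) + C @ (s*s*s)`` where the squares and cubes
    are taken component-wise before the matrix products.
    """

    A: np.ndarray
    a: np.ndarray
    B: np.ndarray
    C: np.ndarray

    def __post_init__(self):
        A = np.asarray(self.A, dtype=float)
        if A.ndim == 0:
            A = A.reshape(1, 1)
        dim = A.shape[0]
        object.__setattr__(self, "A", _as_matrix(A, dim, "A"))
        object.__setattr__(self, "a", np.asarray(self.a, dtype=float).reshape(dim))
        object.__setattr__(self, "B", _as_matrix(self.B, dim, "B"))
        object.__setattr__(self, "C", _as_matrix(self.C, dim, "C"))

    @classmethod
    def identity(cls, dim: int = 2) -> "DistortionModel":
        z = np.zeros((dim, dim))
        return cls(A=np.eye(dim), a=np.zeros(dim), B=z, C=z)

    @property
    def dim(self) -> int:
        return self.A.shape[0]


@dataclass(frozen=True)
class TopographicMapSpec:
    """Square grid of map neurons spanning ``[-extent, extent]`` per axis."""

    n_g: int = 100
    extent: float = 1.5
    dim: int = 2
    axis_centres: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if self.n_g < 2:
            raise ConfigurationError("n_g must be >= 2")
        if self.extent <= 0:
            raise ConfigurationError("extent must be > 0")
        if self.dim not in (1, 2):
            raise ConfigurationError("dim must be 1 or 2")
        object.__setattr__(
            self, "axis_centres", np.linspace(-self.extent, self.extent, self.n_g)
        )

    @property
    def spacing(self) -> float:
        return 2 * self.extent / (self.n_g - 1)


@dataclass(frozen=True)
class CoarseGridSpec:
    """Evenly spaced k-per-axis grid of broad Gaussian receptive fields."""

    k: int = 8
    gp_cov: np.ndarray = 0.0352  # variance (scalar) or full covariance matrix
    dim: int = 2

    def __post_init__(self):
        cov = np.asarray(self.gp_cov, dtype=float)
        if cov.ndim == 0:
            cov = float(cov) * np.eye(self.dim)
        cov = _as_matrix(cov, self.dim, "gp_cov")
        _check_spd(cov, "gp_cov")
        object.__setattr__(self, "gp_cov", cov)

    @property
    def n_channels(self) -> int:
        return self.k ** self.dim


def sense(x_d, model: SensorModel, rng: np.random.Generator | None = None) -> np.ndarray:
    """Sensor data for target ``x_d``: ``K @ x_d`` plus optional Gaussian noise."""
    x = np.asarray(x_d, dtype=float).reshape(model.dim)
    s = model.K @ x
    if model.noise_sd > 0:
        if rng is None:
            raise ValueError("sensor has noise_sd > 0 but no rng was supplied")
        s = s + rng.normal(0.0, model.noise_sd, size=model.dim)
    return s


def distort(s, d: DistortionModel) -> np.ndarray:
    """Apply the element-wise cubic distortion to sensor data ``s``."""
    s = np.asarray(s, dtype=float).reshape(d.dim)
    s2 = s * s
    return d.A @ s + d.a + d.B @ s2 + d.C @ (s2 * s)


def encode_location(s, model: SensorModel) -> np.ndarray:
    """Location the map encodes for sensor data ``s``: ``K^-1 @ s``."""
    return model.K_inv @ np.asarray(s, dtype=float).reshape(model.dim)


def write_activity(x, spec: TopographicMapSpec, sigma_inv: np.ndarray) -> np.ndarray:
    """Unnormalised Gaussian activity pattern centred at map location ``x``.

    ``sigma_inv`` is the inverse receptive-field covariance.  Returns an
    (n_g, n_g) array for 2-D maps (axis 0 = x centres, axis 1 = y centres)
    or an (n_g,) array in 1-D.  Values are in (0, 1], peak 1 exactly when a
    centre coincides with ``x``.
    """
    c = spec.axis_centres
    x = np.asarray(x, dtype=float).reshape(spec.dim)
    if spec.dim == 1:
        d = c - x[0]
        return np.exp(-0.5 * sigma_inv[0, 0] * d * d)
    dx = c - x[0]
    dy = c - x[1]
    quad = (
        sigma_inv[0, 0] * (dx * dx)[:, None]
        + 2.0 * sigma_inv[0, 1] * np.outer(dx, dy)
        + sigma_inv[1, 1] * (dy * dy)[None, :]
    )
    return np.exp(-0.5 * quad)


def write_map(
    s,
    spec: TopographicMapSpec,
    model: SensorModel,
    gated: bool = False,
) -> np.ndarray:
    """Write sensor data into the map: Gaussian bump at ``K^-1 @ s``.

    On gated trials the bump uses the (huge) gated covariance, simulating a
    sensor that failed to detect the target.
    """
    sig_inv = model.gated_sigma_rf_inv if gated else model.sigma_rf_inv
    return write_activity(encode_location(s, model), spec, sig_inv)


def read_map(act: np.ndarray, spec: TopographicMapSpec) -> np.ndarray:
    """Population-vector readout: activity-weighted mean of neuron centres."""
    total = act.sum()
    if not total > 0:
        raise DegenerateMapError("map has no activity to read")
    c = spec.axis_centres
    if spec.dim == 1:
        return np.array([float(act @ c) / total])
    return np.array(
        [float(act.sum(axis=1) @ c) / total, float(act.sum(axis=0) @ c) / total]
    )


def build_coarse_weights(cg: CoarseGridSpec, spec: TopographicMapSpec) -> np.ndarray:
    """Fixed coarse-coding operator: (k^dim, n_g^dim) matrix of GP values.

    Row ``n`` holds the n-th coarse Gaussian evaluated at every map-neuron
    centre, so coarse coding a written map is a single matrix-vector product
    with the flattened activity.
    """
    if cg.dim != spec.dim:
        raise ConfigurationError("coarse grid and map dimensionality differ")
    centres = np.linspace(-spec.extent, spec.extent, cg.k)
    inv = np.linalg.inv(cg.gp_cov)
    c = spec.axis_centres
    if spec.dim == 1:
        d = centres[:, None] - c[None, :]
        return np.exp(-0.5 * inv[0, 0] * d * d)
    if abs(cg.gp_cov[0, 1]) < 1e-15:
        # separable case: kron of the two 1-D profiles
        dx = centres[:, None] - c[None, :]
        gx = np.exp(-0.5 * inv[0, 0] * dx * dx)
        gy = np.exp(-0.5 * inv[1, 1] * dx * dx)  # square grid: same centres
        return np.kron(gx, gy)
    w = np.empty((cg.k * cg.k, spec.n_g * spec.n_g))
    for n, (cx, cy) in enumerate(
        (cx, cy) for cx in centres for cy in centres
    ):
        dx = c - cx
        dy = c - cy
        quad = (
            inv[0, 0] * (dx * dx)[:, None]
            + 2 * inv[0, 1] * np.outer(dx, dy)
            + inv[1, 1] * (dy * dy)[None, :]
        )
        w[n] = np.exp(-0.5 * quad).ravel()
    return w


def coarse_code(act: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Raw coarse-coded vector q: overlap of each coarse Gaussian with the map."""
    return weights @ act.ravel()


def normalize_pf(q: np.ndarray) -> np.ndarray:
    """Parallel-fibre vector: q normalised to sum to one."""
    total = q.sum()
    if not total > 0:
        raise DegenerateMapError("coarse-coded vector sums to zero")
    return q / total


def apply_bias(x_g, z) -> np.ndarray:
    """Shift an estimated location by the cerebellar bias z."""
    return np.asarray(x_g, dtype=float) + np.asarray(z, dtype=float)
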