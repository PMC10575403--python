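"""Complementary-filter estimation of the sagittal thigh flexion angle.

The accelerometer gives a drift-free but noisy inclination (gravity
direction); the gyroscope gives a clean but drifting angular rate.  A
first-order complementary filter blends the two: gyro integration above the
crossover frequency 1/(2*pi*tau), accelerometer inclination below it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ImuSample",
    "ThighState",
    "FusionConfig",
    "accel_inclination",
    "complementary_step",
    "fuse_stream",
]

#: Minimum accelerometer magnitude (m/s^2) accepted by the inclination math.
_ACCEL_EPS = 1e-9


@dataclass(frozen=True)
class ImuSample:
    """One timestamped 6-axis IMU measurement.

    Attributes
    ----------
    t : float
        Timestamp in seconds.
    accel : tuple of float
        3-axis specific force in m/s^2.
    gyro : tuple of float
        3-axis angular rate in rad/s.
    """

    t: float
    accel: tuple[float, float, float]
    gyro: tuple[float, float, float]


@dataclass(frozen=True)
class ThighState:
    """Sagittal thigh flexion angle and angular velocity at one instant.

    ``theta`` is measured from the ground's vertical, flexion positive.
    """

    t: float
    theta: float
    theta_dot: float


@dataclass
class FusionConfig:
    """Complementary-filter gains and sensor axis mapping.

    The axis mapping is configuration because the module can be mounted in
    any orientation; the defaults assume x = longitudinal (toward the hip),
    y = anterior, z = sagittal rotation axis (flexion positive).
    """

    tau: float = 1.0
    fs: float = 1000.0
    gyro_axis: int = 2
    gyro_sign: float = 1.0
    accel_long_axis: int = 0
    accel_long_sign: float = 1.0
    accel_ant_axis: int = 1
    accel_ant_sign: float = 1.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")

    def sagittal_gyro(self, gyro) -> float:
        return self.gyro_sign * gyro[self.gyro_axis]


def accel_inclination(accel, config: FusionConfig | None = None) -> float:
    """Thigh angle implied by the gravity direction in the accelerometer.

    Projects the measured specific-force vector onto the sagittal plane and
    returns its four-quadrant angle relative to the longitudinal axis,
    mapped to the flexion-positive thigh-angle convention.

    Raises
    ------
    ValueError
        If the sagittal projection of the acceleration vector is (near) zero.
    """
    if config is None:
        config = FusionConfig()
    a_long = config.accel_long_sign * accel[config.accel_long_axis]
    a_ant = config.accel_ant_sign * accel[config.accel_ant_axis]
    if math.hypot(a_long, a_ant) < _ACCEL_EPS:
        raise ValueError("acceleration vector has no sagittal component")
    return math.atan2(a_ant, a_long)


def complementary_step(
    prev: ThighState, sample: ImuSample, config: FusionConfig
) -> ThighState:
    """One update of the complementary filter.

    theta = lam * (theta_prev + gyro * dt) + (1 - lam) * accel_inclination,
    with lam = tau / (tau + dt).

    Raises
    ------
    ValueError
        If ``sample.t`` does not advance past ``prev.t``.
    """
    dt = sample.t - prev.t
    if dt <= 0:
        raise ValueError(f"non-monotone timestamps: {prev.t} -> {sample.t}")
    lam = config.tau / (config.tau + dt)
    gyro_s = config.sagittal_gyro(sample.gyro)
    incl = accel_inclination(sample.accel, config)
    theta = lam * (prev.theta + gyro_s * dt) + (1.0 - lam) * incl
    return ThighState(t=sample.t, theta=theta, theta_dot=gyro_s)


def fuse_stream(
    t: np.ndarray,
    accel: np.ndarray,
    gyro: np.ndarray,
    config: FusionConfig | None = None,
) -> np.ndarray:
    """Run the complementary filter over a whole recording.

    Parameters
    ----------
    t : (N,) array of timestamps in seconds, strictly increasing.
    accel : (N, 3) array in m/s^2.
    gyro : (N, 3) array in rad/s.

    Returns
    -------
    (N,) array of fused thigh angles in rad.  The filter is seeded with the
    accelerometer inclination of the first sample.
    """
    if config is None:
        config = FusionConfig()
    t = np.asarray(t, dtype=float)
    accel = np.asarray(accel, dtype=float)
    gyro = np.asarray(gyro, dtype=float)
    n = t.shape[0]
    if accel.shape != (n, 3) or gyro.shape != (n, 3):
        raise ValueError("accel and gyro must be (N, 3) arrays matching t")
    dts = np.diff(t)
    if n > 1 and np.any(dts <= 0):
        raise ValueError("timestamps must be strictly increasing")

    a_long = config.accel_long_sign * accel[:, config.accel_long_axis]
    a_ant = config.accel_ant_sign * accel[:, config.accel_ant_axis]
    if np.any(np.hypot(a_long, a_ant) < _ACCEL_EPS):
        raise ValueError("acceleration vector has no sagittal component")
    incl = np.arctan2(a_ant, a_long)
    gyro_s = config.gyro_sign * gyro[:, config.gyro_axis]

    theta = np.empty(n)
    theta[0] = incl[0]
    tau = config.tau
    for k in range(1, n):
        dt = dts[k - 1]
        lam = tau / (tau + dt)
        theta[k] = lam * (theta[k - 1] + gyro_s[k] * dt) + (1.0 - lam) * incl[k]
    return theta
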