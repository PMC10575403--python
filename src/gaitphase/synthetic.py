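"""Synthetic gait generator with exact ground truth.

Produces multi-speed thigh kinematics, raw IMU signals, and a vertical
ground-reaction-force (vGRF) trace, together with the exact gait phase and
event times used as ground truth by the evaluation code.  The thigh angle is
modelled as a two-harmonic oscillation (the thigh spectrum shows a dominant
fundamental plus a second harmonic) whose instantaneous frequency follows a
speed profile, with optional per-stride period jitter, sensor noise, and an
exponentially decaying impact burst on the accelerometer at each heel
strike.

Conventions: phase 0 % at maximum flexion; heel strike and toe-off placed
at fixed fractions of the cycle (defaults 17.24 % and 55.14 %).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "SpeedProfile",
    "GaitModelParams",
    "ThighTruth",
    "SyntheticTrial",
    "make_speed_profile",
    "default_stride_freq",
    "thigh_trajectory",
    "synth_imu",
    "synth_grf",
    "simulate_trial",
]

TWO_PI = 2.0 * math.pi
GRAVITY = 9.81
SPEED_RANGE = (0.3, 2.5)

#: Fraction of body weight whose crossing defines heel strike / toe-off.
GRF_THRESHOLD_FRACTION = 0.1


@dataclass(frozen=True)
class SpeedProfile:
    """Piecewise-linear walking-speed profile.

    ``breakpoints`` is a sequence of ``(time_s, speed_m_per_s)`` pairs with
    strictly increasing times; speed is held constant outside the span.
    """

    breakpoints: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.breakpoints) < 1:
            raise ValueError("profile needs at least one breakpoint")
        times = [b[0] for b in self.breakpoints]
        speeds = [b[1] for b in self.breakpoints]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("breakpoint times must be strictly increasing")
        lo, hi = SPEED_RANGE
        if any(not (lo <= v <= hi) for v in speeds):
            raise ValueError(f"speeds must lie in [{lo}, {hi}] m/s")

    @property
    def duration(self) -> float:
        return self.breakpoints[-1][0]

    def speed(self, t) -> np.ndarray:
        """Speed (m/s) at time(s) ``t``, linearly interpolated."""
        times = np.array([b[0] for b in self.breakpoints])
        speeds = np.array([b[1] for b in self.breakpoints])
        return np.interp(np.asarray(t, dtype=float), times, speeds)


def default_stride_freq(speed) -> np.ndarray:
    """Stride frequency (Hz) vs speed: linear, 0.6 m/s -> 0.75 Hz, 1.6 -> 1.05."""
    return 0.75 + 0.3 * (np.asarray(speed, dtype=float) - 0.6)


@dataclass
class GaitModelParams:
    """Parameters of the synthetic thigh-kinematics and sensor model.

    ``harmonic_amplitudes``/``harmonic_phases`` are (fundamental, 2nd
    harmonic); both amplitudes scale by ``1 + amplitude_speed_gain*(v - 1)``
    so faster walking swings the thigh further.  ``period_jitter_std`` adds
    a fresh multiplicative frequency perturbation each stride.
    """

    angle_offset: float = 0.0
    harmonic_amplitudes: tuple[float, float] = (0.35, 0.08)
    harmonic_phases: tuple[float, float] = (0.0, 0.0)
    stride_freq_fn: Callable[[np.ndarray], np.ndarray] | None = None
    hs_fraction: float = 17.24
    to_fraction: float = 55.14
    noise_std_gyro: float = 0.0
    noise_std_accel: float = 0.0
    impact_amplitude: float = 0.0
    impact_decay: float = 0.02
    impact_carrier_hz: float = 60.0
    amplitude_speed_gain: float = 0.2
    period_jitter_std: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stride_freq_fn is None:
            self.stride_freq_fn = default_stride_freq
        if any(a <= 0 for a in self.harmonic_amplitudes):
            raise ValueError("harmonic amplitudes must be positive")
        if not (0.0 < self.hs_fraction < self.to_fraction < 100.0):
            raise ValueError("need 0 < hs_fraction < to_fraction < 100")
        # spot-check monotonicity of the stride-frequency map
        probe = np.array([0.4, 0.8, 1.2, 1.6, 2.0])
        f = np.asarray(self.stride_freq_fn(probe), dtype=float)
        if np.any(np.diff(f) <= 0) or np.any(f <= 0):
            raise ValueError("stride_freq_fn must be positive and increasing")


@dataclass
class ThighTruth:
    """Ground-truth thigh kinematics, phase, and event times."""

    t: np.ndarray
    theta: np.ndarray
    theta_dot: np.ndarray
    phase_pct: np.ndarray
    hs_times: np.ndarray
    to_times: np.ndarray
    max_flexion_times: np.ndarray


@dataclass
class SyntheticTrial:
    """One generated walking trial: IMU + truth + vGRF."""

    t: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    theta_true: np.ndarray
    theta_dot_true: np.ndarray
    phase_true_pct: np.ndarray
    hs_times: np.ndarray
    to_times: np.ndarray
    max_flexion_times: np.ndarray
    vgrf: np.ndarray
    body_weight: float
    speed: np.ndarray
    fs: float


def make_speed_profile(kind: str, **params) -> SpeedProfile:
    """Build a speed profile.

    ``kind='constant'`` takes ``speed`` (m/s) and ``duration`` (s).
    ``kind='ramp_profile'`` holds ``v_low`` (default 0.6 m/s), ramps at
    ``accel`` (default 0.1 m/s^2) to ``v_high`` (default 1.2 m/s), holds,
    and ramps back down at ``-accel``; ``hold`` (default 20 s) sets each
    constant-speed segment, including a trailing hold at ``v_low``.
    """
    if kind == "constant":
        speed = float(params.get("speed", 1.0))
        duration = float(params.get("duration", 60.0))
        if duration <= 0:
            raise ValueError("duration must be positive")
        return SpeedProfile(((0.0, speed), (duration, speed)))
    if kind == "ramp_profile":
        v_low = float(params.get("v_low", 0.6))
        v_high = float(params.get("v_high", 1.2))
        accel = float(params.get("accel", 0.1))
        hold = float(params.get("hold", 20.0))
        if v_high <= v_low or accel <= 0 or hold <= 0:
            raise ValueError("need v_high > v_low, accel > 0, hold > 0")
        ramp = (v_high - v_low) / accel
        pts = [
            (0.0, v_low),
            (hold, v_low),
            (hold + ramp, v_high),
            (2 * hold + ramp, v_high),
            (2 * hold + 2 * ramp, v_low),
            (3 * hold + 2 * ramp, v_low),
        ]
        return SpeedProfile(tuple(pts))
    raise ValueError(f"unknown speed-profile kind: {kind!r}")


def _max_flexion_offset(params: GaitModelParams) -> float:
    """Cycle angle psi (rad) at which the two-harmonic shape is maximal.

    The maximizer does not depend on the common speed-scaling of the two
    amplitudes, so it is a single constant per parameter set.
    """
    a1, a2 = params.harmonic_amplitudes
    p1, p2 = params.harmonic_phases

    def neg_theta(psi: float) -> float:
        return -(a1 * math.cos(psi + p1) + a2 * math.cos(2 * psi + p2))

    grid = np.linspace(0.0, TWO_PI, 4096, endpoint=False)
    vals = a1 * np.cos(grid + p1) + a2 * np.cos(2 * grid + p2)
    psi0 = float(grid[np.argmax(vals)])
    step = TWO_PI / 4096
    res = minimize_scalar(
        neg_theta, bounds=(psi0 - step, psi0 + step), method="bounded",
        options={"xatol": 1e-12},
    )
    return float(res.x) % TWO_PI


def thigh_trajectory(
    profile: SpeedProfile, params: GaitModelParams, fs: float
) -> ThighTruth:
    """Generate the ground-truth thigh trajectory for a speed profile.

    theta(t) = offset + A1(t) cos(psi + p1) + A2(t) cos(2 psi + p2) where
    psi integrates 2*pi*stride_freq(speed(t)) (optionally jittered per
    stride).  Phase truth is (psi - psi_at_max_flexion) mod 2*pi in percent;
    heel-strike / toe-off times sit at the configured cycle fractions.
    """
    if fs < 100:
        raise ValueError(f"fs must be >= 100 Hz, got {fs}")
    dt = 1.0 / fs
    t = np.arange(0.0, profile.duration, dt)
    v = profile.speed(t)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite speed in profile")
    f_stride = np.asarray(params.stride_freq_fn(v), dtype=float)

    psi_max = _max_flexion_offset(params)
    omega = TWO_PI * f_stride
    if params.period_jitter_std > 0.0:
        rng = np.random.Generator(
            np.random.PCG64(np.random.SeedSequence(params.seed).spawn(3)[0])
        )
        psi = np.empty_like(t)
        psi[0] = psi_max  # start the trial at maximum flexion
        jit = 1.0 + params.period_jitter_std * rng.standard_normal()
        cycles_done = 0
        for k in range(1, t.size):
            psi[k] = psi[k - 1] + omega[k - 1] * jit * dt
            if psi[k] - psi_max >= TWO_PI * (cycles_done + 1):
                cycles_done += 1
                jit = max(
                    1.0 + params.period_jitter_std * rng.standard_normal(), 0.2
                )
    else:
        # trapezoidal accumulation of the instantaneous angular rate
        psi = psi_max + np.concatenate(
            ([0.0], np.cumsum(0.5 * (omega[1:] + omega[:-1]) * dt))
        )

    scale = 1.0 + params.amplitude_speed_gain * (v - 1.0)
    if np.any(scale <= 0):
        raise ValueError("amplitude speed scaling became non-positive")
    a1 = params.harmonic_amplitudes[0] * scale
    a2 = params.harmonic_amplitudes[1] * scale
    p1, p2 = params.harmonic_phases
    theta = params.angle_offset + a1 * np.cos(psi + p1) + a2 * np.cos(2 * psi + p2)
    theta_dot = np.gradient(theta, dt)

    big_psi = psi - psi_max  # unwrapped phase, 0 at the first max flexion
    phase_pct = (big_psi % TWO_PI) * (100.0 / TWO_PI)

    def _times_at(fraction_pct: float) -> np.ndarray:
        target0 = TWO_PI * fraction_pct / 100.0
        k_min = math.ceil((big_psi[0] - target0) / TWO_PI)
        k_max = math.floor((big_psi[-1] - target0) / TWO_PI)
        targets = target0 + TWO_PI * np.arange(k_min, k_max + 1)
        return np.interp(targets, big_psi, t)

    return ThighTruth(
        t=t,
        theta=theta,
        theta_dot=theta_dot,
        phase_pct=phase_pct,
        hs_times=_times_at(params.hs_fraction),
        to_times=_times_at(params.to_fraction),
        max_flexion_times=_times_at(0.0),
    )


def synth_imu(
    truth: ThighTruth, params: GaitModelParams, fs: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Raw IMU streams consistent with the ground-truth trajectory.

    Returns ``(t, accel, gyro)`` with accel/gyro of shape (N, 3).  The
    sagittal gyro channel is theta_dot plus noise; the accelerometer
    measures gravity decomposed by theta, plus noise and a decaying
    high-frequency burst after each heel strike.  Fully determined by
    ``params.seed``, with an independent sub-stream per channel.
    """
    t = truth.t
    n = t.size
    dt = 1.0 / fs
    children = np.random.SeedSequence(params.seed).spawn(3)
    rng_gyro = np.random.Generator(np.random.PCG64(children[1]))
    rng_accel = np.random.Generator(np.random.PCG64(children[2]))

    gyro = rng_gyro.standard_normal((n, 3)) * params.noise_std_gyro
    gyro[:, 2] += truth.theta_dot

    accel = rng_accel.standard_normal((n, 3)) * params.noise_std_accel
    accel[:, 0] += GRAVITY * np.cos(truth.theta)
    accel[:, 1] += GRAVITY * np.sin(truth.theta)

    if params.impact_amplitude > 0.0:
        span = int(round(5.0 * params.impact_decay * fs))
        for t_hs in truth.hs_times:
            k0 = int(math.ceil(t_hs * fs))
            if k0 >= n:
                continue
            k1 = min(k0 + span, n)
            tau = t[k0:k1] - t_hs
            burst = (
                params.impact_amplitude
                * np.exp(-tau / params.impact_decay)
                * np.sin(TWO_PI * params.impact_carrier_hz * tau)
            )
            accel[k0:k1, 0] += 0.5 * burst
            accel[k0:k1, 1] += burst
    return t, accel, gyro


def synth_grf(
    hs_times: Sequence[float],
    to_times: Sequence[float],
    body_weight: float,
    fs: float,
    t: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Smooth vertical GRF that crosses 10 % BW exactly at the event times.

    Each stance is a half-sine lobe stretched slightly beyond [hs, to] so
    that the rising 0.1*BW crossing lands exactly on the heel strike and the
    falling crossing on the toe-off; swing is zero force.

    Returns ``(t, vgrf)``.  Raises on overlapping stance intervals.
    """
    if body_weight <= 0:
        raise ValueError("body weight must be positive")
    hs_times = np.sort(np.asarray(hs_times, dtype=float))
    to_times = np.sort(np.asarray(to_times, dtype=float))
    if t is None:
        end = 0.2 + (
            max(
                hs_times[-1] if hs_times.size else 0.0,
                to_times[-1] if to_times.size else 0.0,
            )
        )
        t = np.arange(0.0, end, 1.0 / fs)
    vgrf = np.zeros_like(t)
    if hs_times.size == 0:
        return t, vgrf

    thr = GRF_THRESHOLD_FRACTION
    asin_thr = math.asin(thr)
    prev_end = -math.inf
    for t_hs in hs_times:
        later = to_times[to_times > t_hs]
        if later.size == 0:
            break  # trailing stance without a toe-off: skip
        t_to = later[0]
        d = t_to - t_hs
        period = d / (1.0 - 2.0 * asin_thr / math.pi)
        margin = period * asin_thr / math.pi
        t0 = t_hs - margin
        if t0 < prev_end:
            raise ValueError("overlapping stance intervals")
        prev_end = t0 + period
        mask = (t >= t0) & (t <= t0 + period)
        vgrf[mask] = body_weight * np.sin(math.pi * (t[mask] - t0) / period)
    np.clip(vgrf, 0.0, None, out=vgrf)
    return t, vgrf


def simulate_trial(
    profile: SpeedProfile,
    params: GaitModelParams | None = None,
    fs: float = 1000.0,
    body_weight: float = 700.0,
) -> SyntheticTrial:
    """Generate a complete trial: truth, IMU streams, and vGRF."""
    if params is None:
        params = GaitModelParams()
    truth = thigh_trajectory(profile, params, fs)
    t, accel, gyro = synth_imu(truth, params, fs)
    _, vgrf = synth_grf(truth.hs_times, truth.to_times, body_weight, fs, t=t)
    return SyntheticTrial(
        t=t,
        accel=accel,
        gyro=gyro,
        theta_true=truth.theta,
        theta_dot_true=truth.theta_dot,
        phase_true_pct=truth.phase_pct,
        hs_times=truth.hs_times,
        to_times=truth.to_times,
        max_flexion_times=truth.max_flexion_times,
        vgrf=vgrf,
        body_weight=body_weight,
        speed=profile.speed(t),
        fs=fs,
    )
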