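"""End-to-end online gait phase estimator.

Chains, strictly causally (sample k uses only samples <= k):

    sensor fusion -> adaptive low-pass (angle) -> backward-difference
    derivative -> stride segmentation at maximum flexion -> per-stride
    normalization parameters with IIR smoothing -> phase-portrait phase ->
    constant delay compensation -> percent conversion.

Stride boundaries are detected at maximum thigh flexion (zero crossing of
the filtered angular velocity while the angle is above its smoothed center)
because that instant is free of ground-impact disturbance.  The per-stride
normalization parameters (centers and amplitudes of angle and velocity) are
updated there and low-pass smoothed with a one-pole IIR so the phase
portrait — and hence the phase — stays continuous across updates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from gaitphase.fusion import FusionConfig, _ACCEL_EPS
from gaitphase.gfaf import CUTOFF_BOUNDS, GfafCascade, gait_frequency

__all__ = [
    "SmootherConfig",
    "StrideState",
    "PhaseSample",
    "EstimatorConfig",
    "PhaseEstimator",
    "PhaseStreamResult",
    "update_stride_params",
    "smooth_param_step",
    "normalize",
    "portrait_phase",
    "compensate",
    "to_percent",
    "process_stream",
]

TWO_PI = 2.0 * math.pi

#: Amplitudes at or below this are treated as a degenerate (non-walking) stride.
DEGENERATE_AMPLITUDE = 1e-6

#: Stride-period clamp (s), i.e. the plausible cadence band.
T_STRIDE_BOUNDS = (0.4, 2.5)


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def update_stride_params(
    theta_max: float, theta_min: float, dtheta_max: float, dtheta_min: float
) -> tuple[float, float, float, float]:
    """Centers and amplitudes from per-stride extrema.

    Returns ``(theta_o, dtheta_o, A_theta, A_dtheta)`` where each center is
    (max+min)/2 and each amplitude (max-min)/2.

    Raises
    ------
    ValueError
        If an extrema pair is inverted, or if an amplitude is at or below
        ``DEGENERATE_AMPLITUDE`` (non-walking stride; caller should retain
        the previous parameters).
    """
    if theta_max < theta_min or dtheta_max < dtheta_min:
        raise ValueError("extrema inverted: max < min")
    a_theta = 0.5 * (theta_max - theta_min)
    a_dtheta = 0.5 * (dtheta_max - dtheta_min)
    if a_theta <= DEGENERATE_AMPLITUDE or a_dtheta <= DEGENERATE_AMPLITUDE:
        raise ValueError("degenerate stride: amplitude ~ 0")
    theta_o = 0.5 * (theta_max + theta_min)
    dtheta_o = 0.5 * (dtheta_max + dtheta_min)
    return theta_o, dtheta_o, a_theta, a_dtheta


@dataclass
class SmootherConfig:
    """One-pole IIR smoother applied per sample to normalization parameters.

    ``y[k] = a*y[k-1] + (1-a)*target``; the target is the raw per-stride
    value, held constant between stride updates.
    """

    a: float = 0.98
    fs: float = 1000.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.a < 1.0):
            raise ValueError(f"pole must lie in [0, 1), got {self.a}")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")


def smooth_param_step(current: float, target: float, config: SmootherConfig) -> float:
    """One step of the parameter smoother."""
    return config.a * current + (1.0 - config.a) * target


def normalize(
    theta: float, theta_dot: float, params: tuple[float, float, float, float]
) -> tuple[float, float]:
    """Map (theta, theta_dot) onto the unit-circle portrait coordinates.

    ``params`` is ``(theta_o, dtheta_o, A_theta, A_dtheta)``.
    """
    theta_o, dtheta_o, a_theta, a_dtheta = params
    if a_theta <= 0 or a_dtheta <= 0:
        raise ValueError("normalization amplitudes must be positive")
    return (theta - theta_o) / a_theta, (theta_dot - dtheta_o) / a_dtheta


def portrait_phase(theta_n: float, theta_dot_n: float) -> float:
    """Clockwise portrait angle in [0, 2*pi); 0 at maximum flexion.

    Implemented as ``atan2(-theta_dot_n, theta_n) mod 2*pi``, which is
    algebraically identical to the three-branch arctangent form but is
    well-defined on the axes.
    """
    if theta_n == 0.0 and theta_dot_n == 0.0:
        raise ValueError("portrait phase undefined at the origin")
    phi = math.atan2(-theta_dot_n, theta_n) % TWO_PI
    return 0.0 if phi >= TWO_PI else phi  # fold float rounding at the wrap


def compensate(phi: float, n: int, alpha: float) -> float:
    """Add the constant filter lag n*arctan(1/alpha) back, modulo 2*pi."""
    out = (phi + n * math.atan(1.0 / alpha)) % TWO_PI
    return 0.0 if out >= TWO_PI else out


def to_percent(phi: float) -> float:
    """Convert a phase in [0, 2*pi) rad to percent of cycle: 50*phi/pi."""
    return 50.0 * phi / math.pi


# ---------------------------------------------------------------------------
# Stride tracking
# ---------------------------------------------------------------------------


@dataclass
class StrideState:
    """Per-stride bookkeeping: extrema, period, and normalization params."""

    t_last_max_flexion: float | None = None
    t_stride: float = 1.1
    omega_gait: float = field(default=None)  # type: ignore[assignment]
    theta_max: float = -math.inf
    theta_min: float = math.inf
    dtheta_max: float = -math.inf
    dtheta_min: float = math.inf
    raw_params: tuple[float, float, float, float] = (0.0, 0.0, 0.35, 2.0)
    stride_count: int = 0

    def __post_init__(self) -> None:
        if self.omega_gait is None:
            self.omega_gait = gait_frequency(self.t_stride)


class StrideTracker:
    """Online maximum-flexion event detector with per-stride extrema.

    An event fires when the angular velocity crosses from positive to
    non-positive while the angle exceeds ``center``, subject to a refractory
    period of ``refractory_frac * t_stride`` since the previous event.  On
    each event the current stride's extrema are frozen into the raw
    normalization parameters, the stride period and gait frequency are
    updated (clamped to ``t_stride_bounds``), and the extrema reset.
    """

    def __init__(
        self,
        bootstrap_t_stride: float = 1.1,
        prior_params: tuple[float, float, float, float] | None = None,
        refractory_frac: float = 0.4,
        t_stride_bounds: tuple[float, float] = T_STRIDE_BOUNDS,
    ) -> None:
        if prior_params is None:
            a_theta = 0.35
            prior_params = (0.0, 0.0, a_theta, TWO_PI * a_theta / bootstrap_t_stride)
        self.state = StrideState(t_stride=bootstrap_t_stride, raw_params=prior_params)
        self.refractory_frac = refractory_frac
        self.t_stride_bounds = t_stride_bounds
        self._prev_dtheta: float | None = None

    def step(self, t: float, theta: float, theta_dot: float, center: float) -> bool:
        """Feed one sample; returns True if a maximum-flexion event fired."""
        s = self.state
        s.theta_max = max(s.theta_max, theta)
        s.theta_min = min(s.theta_min, theta)
        s.dtheta_max = max(s.dtheta_max, theta_dot)
        s.dtheta_min = min(s.dtheta_min, theta_dot)

        fired = False
        prev = self._prev_dtheta
        if prev is not None and prev > 0.0 and theta_dot <= 0.0 and theta > center:
            refractory_ok = (
                s.t_last_max_flexion is None
                or (t - s.t_last_max_flexion) >= self.refractory_frac * s.t_stride
            )
            if refractory_ok:
                fired = True
                self._on_event(t, theta, theta_dot)
        self._prev_dtheta = theta_dot
        return fired

    def _on_event(self, t: float, theta: float, theta_dot: float) -> None:
        s = self.state
        if s.t_last_max_flexion is not None:
            lo, hi = self.t_stride_bounds
            s.t_stride = min(max(t - s.t_last_max_flexion, lo), hi)
            s.omega_gait = gait_frequency(s.t_stride)
            try:
                s.raw_params = update_stride_params(
                    s.theta_max, s.theta_min, s.dtheta_max, s.dtheta_min
                )
            except ValueError:
                pass  # degenerate stride: keep previous parameters
            s.stride_count += 1
        s.t_last_max_flexion = t
        s.theta_max = s.theta_min = theta
        s.dtheta_max = s.dtheta_min = theta_dot


# ---------------------------------------------------------------------------
# Full estimator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhaseSample:
    """Estimator output at one instant."""

    t: float
    phi: float
    phi_filtered: float
    phi_pct: float
    stride_id: int
    converged: bool


@dataclass
class PhaseStreamResult:
    """Column-wise estimator output for a whole recording."""

    t: np.ndarray
    phi_rad: np.ndarray
    phi_comp_rad: np.ndarray
    phi_pct: np.ndarray
    stride_id: np.ndarray
    converged: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t": self.t,
                "phi_rad": self.phi_rad,
                "phi_comp_rad": self.phi_comp_rad,
                "phi_pct": self.phi_pct,
                "stride_id": self.stride_id,
                "converged": self.converged.astype(int),
            }
        )


@dataclass
class EstimatorConfig:
    """Everything the end-to-end estimator needs.

    ``adaptive=False`` freezes the cutoff at ``fixed_cutoff_hz`` (the
    fixed-filter baseline); ``compensate_delay=False`` skips the constant
    lag compensation (meaningless for a fixed cutoff, whose lag varies with
    gait frequency).
    """

    fs: float = 1000.0
    fusion: FusionConfig = field(default_factory=FusionConfig)
    order: int = 2
    alpha: float = 2.5
    pole: float = 0.98
    adaptive: bool = True
    fixed_cutoff_hz: float = 1.5
    compensate_delay: bool = True
    bootstrap_t_stride: float = 1.1
    prior_a_theta: float = 0.35
    prior_theta_o: float = 0.0
    refractory_frac: float = 0.4
    converged_after_strides: int = 2

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.order < 1:
            raise ValueError(f"order must be >= 1, got {self.order}")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if not (0.0 <= self.pole < 1.0):
            raise ValueError(f"pole must lie in [0, 1), got {self.pole}")
        self.fusion.fs = self.fs


class PhaseEstimator:
    """Strictly causal streaming gait phase estimator.

    Call :meth:`step` with one raw IMU sample at a time, or use
    :func:`process_stream` for array input.
    """

    def __init__(self, config: EstimatorConfig | None = None) -> None:
        self.config = config or EstimatorConfig()
        cfg = self.config
        a0 = cfg.prior_a_theta
        priors = (
            cfg.prior_theta_o,
            0.0,
            a0,
            TWO_PI * a0 / cfg.bootstrap_t_stride,
        )
        self.tracker = StrideTracker(
            bootstrap_t_stride=cfg.bootstrap_t_stride,
            prior_params=priors,
            refractory_frac=cfg.refractory_frac,
        )
        self.cascade = GfafCascade(n=cfg.order)
        self.smoother = SmootherConfig(a=cfg.pole, fs=cfg.fs)
        # smoothed params start at the priors so there is no initial transient
        self._smoothed = list(priors)
        self._omega_gait_smoothed = gait_frequency(cfg.bootstrap_t_stride)
        self._t_prev: float | None = None
        self._theta_fused: float | None = None
        self._theta_f_prev: float | None = None
        self._comp_offset = (
            cfg.order * math.atan(1.0 / cfg.alpha) if cfg.compensate_delay else 0.0
        )

    # -- internals ----------------------------------------------------------

    def _fuse(self, t: float, accel, gyro) -> float:
        cfg = self.config.fusion
        a_long = cfg.accel_long_sign * accel[cfg.accel_long_axis]
        a_ant = cfg.accel_ant_sign * accel[cfg.accel_ant_axis]
        gyro_s = cfg.gyro_sign * gyro[cfg.gyro_axis]
        degenerate = math.hypot(a_long, a_ant) < _ACCEL_EPS
        if self._theta_fused is None:
            # seed with the accelerometer inclination (0 if degenerate)
            theta = 0.0 if degenerate else math.atan2(a_ant, a_long)
        else:
            dt = t - self._t_prev
            if dt <= 0:
                raise ValueError(f"non-monotone timestamps at t={t}")
            if degenerate:
                theta = self._theta_fused + gyro_s * dt  # gravity unusable
            else:
                lam = cfg.tau / (cfg.tau + dt)
                incl = math.atan2(a_ant, a_long)
                theta = lam * (self._theta_fused + gyro_s * dt) + (1 - lam) * incl
        self._theta_fused = theta
        return theta

    def _cutoff(self) -> float:
        cfg = self.config
        if cfg.adaptive:
            wc = cfg.alpha * self._omega_gait_smoothed
        else:
            wc = TWO_PI * cfg.fixed_cutoff_hz
        lo, hi = CUTOFF_BOUNDS
        return min(max(wc, lo), hi)

    # -- public API ---------------------------------------------------------

    def step(self, t: float, accel, gyro) -> PhaseSample:
        """Consume one IMU sample and emit one phase sample."""
        cfg = self.config
        first = self._t_prev is None
        ts = (1.0 / cfg.fs) if first else (t - self._t_prev)
        theta_raw = self._fuse(t, accel, gyro)
        if first:
            self.cascade.reset(theta_raw)

        theta_f = self.cascade.step(theta_raw, self._cutoff(), ts)
        theta_dot_f = 0.0 if first else (theta_f - self._theta_f_prev) / ts
        self._theta_f_prev = theta_f
        self._t_prev = t

        self.tracker.step(t, theta_f, theta_dot_f, center=self._smoothed[0])

        # per-sample smoothing toward the held per-stride targets
        targets = self.tracker.state.raw_params
        a = cfg.pole
        sm = self._smoothed
        for i in range(4):
            sm[i] = a * sm[i] + (1.0 - a) * targets[i]
        self._omega_gait_smoothed = (
            a * self._omega_gait_smoothed + (1.0 - a) * self.tracker.state.omega_gait
        )

        theta_n = (theta_f - sm[0]) / sm[2]
        dtheta_n = (theta_dot_f - sm[1]) / sm[3]
        if theta_n == 0.0 and dtheta_n == 0.0:
            phi = phi_c = phi_pct = math.nan
            converged = False
        else:
            phi = math.atan2(-dtheta_n, theta_n) % TWO_PI
            if phi >= TWO_PI:
                phi = 0.0
            phi_c = (phi + self._comp_offset) % TWO_PI
            if phi_c >= TWO_PI:
                phi_c = 0.0
            phi_pct = 50.0 * phi_c / math.pi
            converged = self.tracker.state.stride_count >= cfg.converged_after_strides
        return PhaseSample(
            t=t,
            phi=phi,
            phi_filtered=phi_c,
            phi_pct=phi_pct,
            stride_id=self.tracker.state.stride_count,
            converged=converged,
        )


def process_stream(
    t: np.ndarray,
    accel: np.ndarray,
    gyro: np.ndarray,
    config: EstimatorConfig | None = None,
) -> PhaseStreamResult:
    """Run the full estimator over arrays of raw IMU data.

    Parameters
    ----------
    t : (N,) timestamps in s, strictly increasing.
    accel : (N, 3) accelerometer stream in m/s^2.
    gyro : (N, 3) gyroscope stream in rad/s.
    """
    t = np.asarray(t, dtype=float)
    accel = np.asarray(accel, dtype=float)
    gyro = np.asarray(gyro, dtype=float)
    n = t.shape[0]
    if accel.shape != (n, 3) or gyro.shape != (n, 3):
        raise ValueError("accel and gyro must be (N, 3) arrays matching t")
    est = PhaseEstimator(config)
    phi = np.empty(n)
    phi_c = np.empty(n)
    phi_pct = np.empty(n)
    stride_id = np.empty(n, dtype=int)
    converged = np.empty(n, dtype=bool)
    for k in range(n):
        try:
            s = est.step(float(t[k]), accel[k], gyro[k])
        except ValueError as exc:
            raise ValueError(f"estimation failed at sample {k}: {exc}") from exc
        phi[k] = s.phi
        phi_c[k] = s.phi_filtered
        phi_pct[k] = s.phi_pct
        stride_id[k] = s.stride_id
        converged[k] = s.converged
    return PhaseStreamResult(
        t=t,
        phi_rad=phi,
        phi_comp_rad=phi_c,
        phi_pct=phi_pct,
        stride_id=stride_id,
        converged=converged,
    )
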