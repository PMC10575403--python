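"""Comparison methods: fixed-cutoff portrait (LPF) and time-based estimation.

The LPF baseline is the same portrait pipeline with the cutoff frozen at a
fixed frequency; its lag varies with gait frequency, so no constant
compensation is applied.  Time-based estimation (TBE) ramps the phase
linearly with the time elapsed since the last maximum-flexion event,
scaled by the previous stride period, saturating just below 100 % when the
current stride runs long.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from gaitphase.engine import (
    EstimatorConfig,
    PhaseStreamResult,
    SmootherConfig,
    StrideTracker,
    process_stream,
)
from gaitphase.fusion import FusionConfig, fuse_stream
from gaitphase.gfaf import differentiate

__all__ = ["LpfConfig", "lpf_portrait_pipeline", "tbe_phase"]

TWO_PI = 2.0 * math.pi

#: Saturation margin: TBE reports at most 100 - this (percent).
_TBE_EPS = 1e-6


@dataclass
class LpfConfig:
    """Fixed low-pass filter for the baseline portrait pipeline."""

    cutoff_hz: float = 1.5
    n: int = 2
    fs: float = 1000.0

    def __post_init__(self) -> None:
        if self.cutoff_hz <= 0:
            raise ValueError(f"cutoff must be positive, got {self.cutoff_hz}")
        if self.n < 1:
            raise ValueError(f"order must be >= 1, got {self.n}")


def lpf_portrait_pipeline(
    t: np.ndarray,
    accel: np.ndarray,
    gyro: np.ndarray,
    config: LpfConfig | None = None,
    pole: float = 0.98,
) -> PhaseStreamResult:
    """Portrait pipeline with a fixed cutoff and no delay compensation."""
    if config is None:
        config = LpfConfig()
    est_cfg = EstimatorConfig(
        fs=config.fs,
        order=config.n,
        pole=pole,
        adaptive=False,
        fixed_cutoff_hz=config.cutoff_hz,
        compensate_delay=False,
    )
    return process_stream(t, accel, gyro, est_cfg)


def tbe_phase(
    t: np.ndarray,
    accel: np.ndarray,
    gyro: np.ndarray,
    fusion: FusionConfig | None = None,
    pole: float = 0.98,
) -> PhaseStreamResult:
    """Time-based phase estimate from raw (unfiltered) thigh kinematics.

    Maximum-flexion events are detected on the raw complementary-filter
    angle; between events the phase is 100*(t - t_event)/T_prev percent,
    clipped just below 100, where T_prev is the previous inter-event
    interval.  Samples before the first completed stride are flagged
    invalid (``converged`` False, phase NaN).
    """
    t = np.asarray(t, dtype=float)
    if fusion is None:
        fusion = FusionConfig()
    theta = fuse_stream(t, accel, gyro, fusion)
    dt = float(np.median(np.diff(t))) if t.size > 1 else 1.0 / fusion.fs
    theta_dot = differentiate(theta, dt)

    tracker = StrideTracker()
    smoother = SmootherConfig(a=pole, fs=fusion.fs)
    center = tracker.state.raw_params[0]

    n = t.size
    phi_pct = np.full(n, math.nan)
    stride_id = np.zeros(n, dtype=int)
    valid = np.zeros(n, dtype=bool)
    t_event: float | None = None
    t_prev_period: float | None = None
    for k in range(n):
        fired = tracker.step(float(t[k]), float(theta[k]), float(theta_dot[k]), center)
        if fired:
            if t_event is not None:
                t_prev_period = tracker.state.t_stride
            t_event = float(t[k])
        center = smoother.a * center + (1.0 - smoother.a) * tracker.state.raw_params[0]
        stride_id[k] = tracker.state.stride_count
        if t_event is not None and t_prev_period is not None:
            phi_pct[k] = min(
                100.0 * (t[k] - t_event) / t_prev_period, 100.0 - _TBE_EPS
            )
            valid[k] = True
    phi_rad = np.where(np.isnan(phi_pct), math.nan, phi_pct * math.pi / 50.0)
    return PhaseStreamResult(
        t=t,
        phi_rad=phi_rad,
        phi_comp_rad=phi_rad.copy(),
        phi_pct=phi_pct,
        stride_id=stride_id,
        converged=valid,
    )
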