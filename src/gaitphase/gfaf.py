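"""Gait-frequency-adaptive low-pass filter (GFAF) and its phase-lag algebra.

The filter is an n-stage cascade of identical first-order low-pass sections
whose common cutoff is a fixed multiple alpha of the current gait frequency.
Its steady-state phase lag at the gait frequency is therefore

    n * arctan(1 / alpha)

independent of the gait frequency itself, which makes the lag compensable
by a constant.  Each stage is discretized with the backward-Euler rule

    y[k] = (y[k-1] + wc*Ts*x[k]) / (1 + wc*Ts)

with the cutoff ``wc`` re-read every sample, so cutoff changes during speed
ramps are bumpless (state carries over).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "GfafConfig",
    "GfafCascade",
    "gait_frequency",
    "cutoff",
    "lpf_phase_lag",
    "gfaf_lag",
    "filter_stream",
    "differentiate",
    "CUTOFF_BOUNDS",
]

#: Clamp on the adaptive cutoff (rad/s) to survive degenerate stride periods.
CUTOFF_BOUNDS = (0.5, 50.0)


@dataclass
class GfafConfig:
    """Order, proportional factor and sample rate of the adaptive filter."""

    n: int = 2
    alpha: float = 2.5
    fs: float = 1000.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"filter order must be >= 1, got {self.n}")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")


def gait_frequency(t_stride: float) -> float:
    """Angular gait frequency (rad/s) from the stride period (s)."""
    if t_stride <= 0:
        raise ValueError(f"stride period must be positive, got {t_stride}")
    return 2.0 * math.pi / t_stride


def cutoff(omega_gait: float, alpha: float) -> float:
    """Adaptive cutoff: alpha times the gait frequency (both rad/s)."""
    if omega_gait <= 0:
        raise ValueError(f"gait frequency must be positive, got {omega_gait}")
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    return alpha * omega_gait


def lpf_phase_lag(omega: float, omega_c: float, n: int) -> float:
    """Phase response (rad, negative = lag) of the n-stage cascade at omega."""
    if omega_c <= 0:
        raise ValueError(f"cutoff must be positive, got {omega_c}")
    return -n * math.atan(omega / omega_c)


def gfaf_lag(n: int, alpha: float) -> float:
    """Magnitude of the cascade's lag at the gait frequency: n*arctan(1/alpha).

    Because the cutoff is alpha times the gait frequency, the ratio
    omega/omega_c is always 1/alpha and the lag is the same at every gait
    frequency — the property that makes constant compensation possible.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    return n * math.atan(1.0 / alpha)


@dataclass
class GfafCascade:
    """Streaming state of the n-stage backward-Euler cascade.

    ``stage_outputs[i]`` is the last output of stage i; the final stage's
    output is the filtered signal.
    """

    n: int = 2
    stage_outputs: np.ndarray = field(default=None)  # type: ignore[assignment]
    omega_c: float = math.nan

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"filter order must be >= 1, got {self.n}")
        if self.stage_outputs is None:
            self.stage_outputs = np.zeros(self.n)
        else:
            self.stage_outputs = np.asarray(self.stage_outputs, dtype=float)
            if self.stage_outputs.shape != (self.n,):
                raise ValueError("stage_outputs must have length n")

    def reset(self, value: float = 0.0) -> None:
        """Preload every stage with ``value`` (avoids a startup transient)."""
        self.stage_outputs[:] = value

    def step(self, x: float, omega_c: float, ts: float) -> float:
        """Advance the cascade one sample and return the filtered value.

        A non-finite input raises and leaves the state untouched.
        """
        if not math.isfinite(x):
            raise ValueError(f"non-finite filter input: {x}")
        if ts <= 0:
            raise ValueError(f"sample period must be positive, got {ts}")
        if omega_c <= 0:
            raise ValueError(f"cutoff must be positive, got {omega_c}")
        c = omega_c * ts
        gain = 1.0 / (1.0 + c)
        y = x
        for i in range(self.n):
            y = (self.stage_outputs[i] + c * y) * gain
            self.stage_outputs[i] = y
        self.omega_c = omega_c
        return y


def filter_stream(
    x: np.ndarray,
    omega_c,
    ts: float,
    n: int = 2,
    initial: float | None = None,
) -> np.ndarray:
    """Offline application of the cascade to a whole signal.

    ``omega_c`` may be a scalar (fast path via ``scipy.signal.lfilter``) or a
    per-sample array (the streaming update is replayed sample by sample).
    ``initial`` preloads all stages; default is the first input sample.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("input must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite filter input")
    if ts <= 0:
        raise ValueError(f"sample period must be positive, got {ts}")
    y0 = float(x[0]) if initial is None and x.size else (initial or 0.0)

    if np.ndim(omega_c) == 0:
        c = float(omega_c) * ts
        if c <= 0:
            raise ValueError("cutoff must be positive")
        b = [c / (1.0 + c)]
        a = [1.0, -1.0 / (1.0 + c)]
        y = x
        for _ in range(n):
            # zi chosen so a constant preload y0 is a fixed point
            zi = np.array([y0 / (1.0 + c)])
            y, _ = lfilter(b, a, y, zi=zi)
        return y

    omega_c = np.asarray(omega_c, dtype=float)
    if omega_c.shape != x.shape:
        raise ValueError("per-sample omega_c must match the input length")
    casc = GfafCascade(n=n)
    casc.reset(y0)
    out = np.empty_like(x)
    for k in range(x.size):
        out[k] = casc.step(float(x[k]), float(omega_c[k]), ts)
    return out


def differentiate(theta: np.ndarray, ts: float) -> np.ndarray:
    """Backward-difference derivative; the first sample's derivative is 0."""
    theta = np.asarray(theta, dtype=float)
    if theta.size < 2:
        raise ValueError("need at least 2 samples to differentiate")
    if ts <= 0:
        raise ValueError(f"sample period must be positive, got {ts}")
    out = np.empty_like(theta)
    out[0] = 0.0
    out[1:] = np.diff(theta) / ts
    return out
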