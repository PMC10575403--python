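"""Evaluation: GRF event detection, event-phase statistics, delay and
spectral measurements, and method comparison tables.

Phases live on a 0-100 % circle, so all event-phase statistics are circular:
values are unwrapped about the circular mean before taking the sample
standard deviation, which keeps events near the 0/100 wrap from exploding
the spread.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import welch

__all__ = [
    "EventPhaseStats",
    "DelayMeasurement",
    "DominantFrequency",
    "detect_events_grf",
    "circular_mean_pct",
    "circular_std_pct",
    "phase_at_events",
    "event_phase_stats",
    "measure_phase_delay",
    "dominant_frequency",
    "frequency_rmse",
    "compare_report",
]

TWO_PI = 2.0 * math.pi

#: Fraction of body weight defining the event threshold.
GRF_THRESHOLD_FRACTION = 0.1

#: Peak-to-median spectral ratio below which a dominant peak is untrusted.
SPECTRAL_CONFIDENCE_RATIO = 5.0


@dataclass(frozen=True)
class EventPhaseStats:
    """Circular mean/std of the estimated phase at one gait event."""

    event: str  # "heel_strike" | "toe_off"
    speed: float | None
    mean_phase: float
    std_phase: float
    n_strides: int


@dataclass(frozen=True)
class DelayMeasurement:
    """Measured filter lag at one gait frequency."""

    gait_freq: float
    lag: float  # rad, magnitude
    method: str  # "gfaf" | "lpf"


@dataclass(frozen=True)
class DominantFrequency:
    """Dominant spectral peak with a confidence flag."""

    freq_hz: float
    peak_ratio: float
    confident: bool


def detect_events_grf(
    t: np.ndarray, vgrf: np.ndarray, body_weight: float
) -> tuple[np.ndarray, np.ndarray]:
    """Heel-strike / toe-off times from the 10 %-body-weight crossings.

    Upward crossings of 0.1*BW are heel strikes, downward crossings are
    toe-offs; crossing times are linearly interpolated between the
    bracketing samples.
    """
    t = np.asarray(t, dtype=float)
    vgrf = np.asarray(vgrf, dtype=float)
    if t.size == 0:
        raise ValueError("empty GRF stream")
    if body_weight <= 0:
        raise ValueError("body weight must be positive")
    thr = GRF_THRESHOLD_FRACTION * body_weight

    lo, hi = vgrf[:-1], vgrf[1:]
    up = np.flatnonzero((lo < thr) & (hi >= thr))
    down = np.flatnonzero((lo >= thr) & (hi < thr))

    def _interp(idx: np.ndarray) -> np.ndarray:
        frac = (thr - vgrf[idx]) / (vgrf[idx + 1] - vgrf[idx])
        return t[idx] + frac * (t[idx + 1] - t[idx])

    return _interp(up), _interp(down)


def circular_mean_pct(phases_pct: np.ndarray) -> float:
    """Circular mean of phases on the 0-100 % circle, in [0, 100)."""
    ang = np.asarray(phases_pct, dtype=float) * (TWO_PI / 100.0)
    mean_ang = math.atan2(np.mean(np.sin(ang)), np.mean(np.cos(ang))) % TWO_PI
    return mean_ang * (100.0 / TWO_PI)


def circular_std_pct(phases_pct: np.ndarray) -> float:
    """Sample std (ddof=1) of phases unwrapped about their circular mean."""
    phases_pct = np.asarray(phases_pct, dtype=float)
    if phases_pct.size < 2:
        return 0.0
    mean = circular_mean_pct(phases_pct)
    dev = (phases_pct - mean + 50.0) % 100.0 - 50.0
    return float(np.std(dev, ddof=1))


def phase_at_events(
    t: np.ndarray,
    phi_pct: np.ndarray,
    event_times: np.ndarray,
    valid: np.ndarray | None = None,
) -> np.ndarray:
    """Phase sampled at the nearest stream sample to each event time.

    Events outside the stream span raise; events landing on an invalid
    (NaN or not-converged) sample are dropped.
    """
    t = np.asarray(t, dtype=float)
    phi_pct = np.asarray(phi_pct, dtype=float)
    event_times = np.asarray(event_times, dtype=float)
    if event_times.size and (
        event_times.min() < t[0] or event_times.max() > t[-1]
    ):
        raise ValueError("event time outside the phase stream span")
    idx = np.searchsorted(t, event_times)
    idx = np.clip(idx, 1, t.size - 1)
    idx = np.where(
        np.abs(event_times - t[idx - 1]) <= np.abs(t[idx] - event_times),
        idx - 1,
        idx,
    )
    vals = phi_pct[idx]
    keep = np.isfinite(vals)
    if valid is not None:
        keep &= np.asarray(valid, dtype=bool)[idx]
    return vals[keep]


def event_phase_stats(
    t: np.ndarray,
    phi_pct: np.ndarray,
    event_times: np.ndarray,
    event: str = "heel_strike",
    speed: float | None = None,
    valid: np.ndarray | None = None,
) -> EventPhaseStats:
    """Circular mean/std of the estimated phase at the given event times."""
    vals = phase_at_events(t, phi_pct, event_times, valid=valid)
    if vals.size == 0:
        raise ValueError("no valid events in the phase stream")
    return EventPhaseStats(
        event=event,
        speed=speed,
        mean_phase=circular_mean_pct(vals),
        std_phase=circular_std_pct(vals),
        n_strides=int(vals.size),
    )


def measure_phase_delay(
    x_in: np.ndarray,
    x_out: np.ndarray,
    fundamental: float,
    fs: float,
    signed: bool = False,
) -> float:
    """Input-to-output lag (rad) from the cross-spectrum at the fundamental.

    Both streams must already be trimmed of transients and have equal
    length.  Positive signed values mean the output lags the input; by
    default the magnitude is returned.
    """
    x_in = np.asarray(x_in, dtype=float)
    x_out = np.asarray(x_out, dtype=float)
    if x_in.shape != x_out.shape or x_in.ndim != 1:
        raise ValueError("streams must be 1-D and of equal length")
    n = x_in.size
    df = fs / n
    if fundamental < df:
        raise ValueError(
            f"fundamental {fundamental} Hz below frequency resolution {df} Hz"
        )
    k = int(round(fundamental / df))
    xi = np.fft.rfft(x_in - np.mean(x_in))
    xo = np.fft.rfft(x_out - np.mean(x_out))
    lag = float(np.angle(xi[k] * np.conj(xo[k])))
    return lag if signed else abs(lag)


def dominant_frequency(
    theta: np.ndarray, fs: float, min_duration: float = 10.0
) -> DominantFrequency:
    """Largest non-DC spectral peak of the (detrended) signal.

    Welch spectrum with 4 Hann segments at 50 % overlap; the peak location
    is refined by quadratic interpolation of the log-magnitude.  The result
    is flagged unconfident when the peak-to-median power ratio is below
    ``SPECTRAL_CONFIDENCE_RATIO`` (e.g. for white noise).
    """
    theta = np.asarray(theta, dtype=float)
    if theta.size / fs < min_duration:
        raise ValueError(f"need at least {min_duration} s of data")
    if np.ptp(theta) == 0.0:
        raise ValueError("constant signal has no dominant frequency")
    nperseg = int(2 * theta.size / 5)  # 4 segments, 50 % overlap
    freqs, pxx = welch(
        theta,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="linear",
    )
    pxx = pxx.copy()
    pxx[0] = 0.0  # ignore DC
    k = int(np.argmax(pxx))
    freq = freqs[k]
    if 1 <= k < pxx.size - 1 and pxx[k - 1] > 0 and pxx[k + 1] > 0:
        # quadratic interpolation on log power
        ym, y0, yp = np.log(pxx[k - 1 : k + 2])
        denom = ym - 2 * y0 + yp
        if denom < 0:
            freq = freqs[k] + 0.5 * (ym - yp) / denom * (freqs[1] - freqs[0])
    ratio = float(pxx[k] / np.median(pxx[1:])) if np.median(pxx[1:]) > 0 else math.inf
    return DominantFrequency(
        freq_hz=float(freq),
        peak_ratio=ratio,
        confident=ratio >= SPECTRAL_CONFIDENCE_RATIO,
    )


def frequency_rmse(estimated: Sequence[float], measured: Sequence[float]) -> float:
    """RMSE of relative frequency errors, in percent."""
    est = np.asarray(estimated, dtype=float)
    meas = np.asarray(measured, dtype=float)
    if est.shape != meas.shape:
        raise ValueError("estimated and measured lists differ in length")
    if np.any(meas == 0):
        raise ValueError("measured frequencies must be nonzero")
    rel = (est - meas) / meas
    return 100.0 * float(np.sqrt(np.mean(rel**2)))


def compare_report(
    trials: Sequence,
    methods: Mapping[str, Callable],
    reference: str = "gfaf",
    settle_strides: int = 3,
) -> pd.DataFrame:
    """Per-method event-phase statistics pooled over trials, plus std
    reductions of the reference method relative to each baseline.

    Parameters
    ----------
    trials : sequence of SyntheticTrial (or anything with t/accel/gyro,
        vgrf, body_weight attributes).
    methods : mapping name -> callable(t, accel, gyro) -> PhaseStreamResult.
    reference : method whose std reduction vs the others is reported.
    settle_strides : events in the first N strides of each trial are
        dropped as convergence transient.

    Returns a DataFrame with one row per (method, event) and columns
    ``mean``, ``std``, ``n``, and ``reduction_vs_<baseline>`` (percent, on
    the reference rows only).
    """
    if len(methods) < 2:
        raise ValueError("need at least two methods to compare")
    pooled: dict[tuple[str, str], list[np.ndarray]] = {}
    for trial in trials:
        hs, to = detect_events_grf(trial.t, trial.vgrf, trial.body_weight)
        hs, to = hs[settle_strides:], to[settle_strides:]
        for name, fn in methods.items():
            res = fn(trial.t, trial.accel, trial.gyro)
            for event, times in (("heel_strike", hs), ("toe_off", to)):
                vals = phase_at_events(
                    res.t, res.phi_pct, times, valid=res.converged
                )
                pooled.setdefault((name, event), []).append(vals)

    rows = []
    stds: dict[tuple[str, str], float] = {}
    for (name, event), chunks in pooled.items():
        vals = np.concatenate(chunks)
        if vals.size == 0:
            raise ValueError(f"method {name!r} produced no valid events")
        mean = circular_mean_pct(vals)
        std = circular_std_pct(vals)
        stds[(name, event)] = std
        rows.append(
            {"method": name, "event": event, "mean": mean, "std": std,
             "n": int(vals.size)}
        )
    df = pd.DataFrame(rows).set_index(["method", "event"]).sort_index()
    if reference in methods:
        for name in methods:
            if name == reference:
                continue
            col = f"reduction_vs_{name}"
            df[col] = np.nan
            for event in ("heel_strike", "toe_off"):
                base = stds.get((name, event))
                ref = stds.get((reference, event))
                if base and ref is not None:
                    df.loc[(reference, event), col] = 100.0 * (base - ref) / base
    return df.reset_index()
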