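import numpy as np
import pytest

from gaitphase.baselines import LpfConfig, lpf_portrait_pipeline, tbe_phase
from gaitphase.engine import EstimatorConfig, process_stream
from gaitphase.synthetic import (
    GaitModelParams,
    make_speed_profile,
    simulate_trial,
)

FS = 200.0
SPEEDS = (0.6, 0.8, 1.0, 1.2, 1.4, 1.6)


@pytest.fixture(scope="session")
def pure_trial():
    """Noise-free constant-speed trial with a (numerically) pure fundamental.

    With a single harmonic the portrait phase is exactly the oscillator
    phase, so the full pipeline can be checked against truth everywhere.
    """
    profile = make_speed_profile("constant", speed=1.0, duration=30.0)
    params = GaitModelParams(seed=1, harmonic_amplitudes=(0.35, 1e-9))
    return simulate_trial(profile, params, fs=FS)


@pytest.fixture(scope="session")
def default_trial():
    """Noise-free constant-speed trial with the default two-harmonic shape."""
    profile = make_speed_profile("constant", speed=1.0, duration=30.0)
    params = GaitModelParams(seed=1)
    return simulate_trial(profile, params, fs=FS)


@pytest.fixture(scope="session")
def multi_speed_trials():
    """Seeded noisy trials across the walking-speed range (one per speed)."""
    trials = {}
    for i, v in enumerate(SPEEDS):
        params = GaitModelParams(
            seed=10 + i,
            noise_std_gyro=0.02,
            noise_std_accel=0.3,
            impact_amplitude=30.0,
            period_jitter_std=0.02,
        )
        profile = make_speed_profile("constant", speed=v, duration=40.0)
        trials[v] = simulate_trial(profile, params, fs=FS)
    return trials


@pytest.fixture(scope="session")
def method_runners():
    est_cfg = EstimatorConfig(fs=FS)
    lpf_cfg = LpfConfig(cutoff_hz=1.5, n=2, fs=FS)
    return {
        "gfaf": lambda t, a, g: process_stream(t, a, g, est_cfg),
        "lpf": lambda t, a, g: lpf_portrait_pipeline(t, a, g, lpf_cfg),
        "tbe": lambda t, a, g: tbe_phase(t, a, g),
    }


@pytest.fixture(scope="session")
def multi_speed_results(multi_speed_trials, method_runners):
    """Phase streams of every method on every multi-speed trial."""
    out = {}
    for name, fn in method_runners.items():
        out[name] = {
            v: fn(tr.t, tr.accel, tr.gyro)
            for v, tr in multi_speed_trials.items()
        }
    return out
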