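# gaitphase

Speed-adaptive online gait phase estimation from a thigh-mounted 6-axis IMU.

The estimator outputs the position within the gait cycle (0–100 %, anchored
at maximum hip flexion) continuously and monotonically across walking speeds
and speed ramps. The pipeline is strictly causal:

1. **Sensor fusion** (`gaitphase.fusion`) — complementary filter blending
   accelerometer inclination (low frequency) with gyroscope integration
   (high frequency) into the sagittal thigh flexion angle.
2. **Adaptive low-pass filter** (`gaitphase.gfaf`) — an n-stage cascade of
   identical first-order sections whose cutoff is α times the current gait
   frequency (2π/T_stride). Its lag at the gait frequency is
   `n·arctan(1/α)` regardless of speed (0.761 rad for n=2, α=2.5), so it is
   compensated by a constant.
3. **Phase engine** (`gaitphase.engine`) — online stride segmentation at
   maximum flexion, per-stride normalization parameters (centers/amplitudes
   of angle and angular velocity) smoothed by a one-pole IIR (pole 0.98) so
   the phase portrait stays continuous across updates, phase-portrait angle,
   delay compensation, percent conversion.
4. **Baselines** (`gaitphase.baselines`) — fixed-cutoff portrait pipeline
   (LPF, uncompensable speed-dependent lag) and time-based estimation (TBE).
5. **Evaluation** (`gaitphase.evaluation`) — ground-truth heel-strike /
   toe-off detection from vertical GRF (10 % body-weight crossings),
   circular event-phase statistics, cross-spectral lag measurement, FFT
   dominant-frequency analysis, and method comparison tables.
6. **Synthetic gait** (`gaitphase.synthetic`) — seeded multi-speed
   two-harmonic thigh trajectories with exact ground-truth phase/events,
   IMU noise, heel-strike impact bursts, and a matching vGRF trace.

## CLI

```sh
# generate a synthetic trial (IMU + GRF + truth CSVs)
gaitphase simulate --kind constant --speed 1.0 --duration 60 --fs 1000 \
    --seed 0 --out data/

# estimate the phase from an IMU CSV (t, ax, ay, az, gx, gy, gz)
gaitphase run --input data/trial_imu.csv --method gfaf \
    --alpha 2.5 --order 2 --pole 0.98 --fs 1000 --out phase.csv

# run all three methods on seeded multi-speed trials and tabulate
# event-phase statistics (means, stds, std reductions)
gaitphase compare --speeds 0.6,0.8,1.0,1.2,1.4,1.6 --out compare.csv

# summarize / plot a comparison table
gaitphase report --table compare.csv --out report/ --plots
```

## Library example

```python
import numpy as np
from gaitphase import (EstimatorConfig, GaitModelParams, make_speed_profile,
                       process_stream, simulate_trial)

trial = simulate_trial(make_speed_profile("constant", speed=1.2, duration=30.0),
                       GaitModelParams(seed=0, noise_std_gyro=0.02),
                       fs=1000.0)
result = process_stream(trial.t, trial.accel, trial.gyro,
                        EstimatorConfig(fs=1000.0, order=2, alpha=2.5, pole=0.98))
print(result.to_frame().head())
```
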