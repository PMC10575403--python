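import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gaitphase.engine import (
    EstimatorConfig,
    SmootherConfig,
    StrideTracker,
    compensate,
    normalize,
    portrait_phase,
    process_stream,
    smooth_param_step,
    to_percent,
    update_stride_params,
)
from gaitphase.evaluation import phase_at_events

TWO_PI = 2 * math.pi


def printed_three_branch_phase(theta_n, theta_dot_n):
    """Independent oracle: the three-branch arctangent form as printed."""
    base = -math.atan(theta_dot_n / theta_n)
    if theta_n >= 0 and theta_dot_n <= 0:
        return base
    if theta_n < 0:
        return base + math.pi
    return base + TWO_PI


class TestUpdateStrideParams:
    def test_arithmetic(self):
        theta_o, _, a_theta, _ = update_stride_params(0.5, -0.3, 1.0, -1.0)
        assert theta_o == pytest.approx(0.1)
        assert a_theta == pytest.approx(0.4)

    def test_symmetric_extrema(self):
        theta_o, dtheta_o, a_theta, a_dtheta = update_stride_params(
            0.7, -0.7, 2.0, -2.0
        )
        assert theta_o == 0.0 and dtheta_o == 0.0
        assert a_theta == pytest.approx(0.7)
        assert a_dtheta == pytest.approx(2.0)

    def test_degenerate_stride_raises(self):
        with pytest.raises(ValueError):
            update_stride_params(0.5, 0.5, 1.0, -1.0)

    def test_inverted_extrema_raise(self):
        with pytest.raises(ValueError):
            update_stride_params(-0.5, 0.5, 1.0, -1.0)

    @given(
        center=st.floats(-1.0, 1.0),
        amp=st.floats(0.01, 2.0),
        dcenter=st.floats(-3.0, 3.0),
        damp=st.floats(0.01, 8.0),
    )
    def test_roundtrip(self, center, amp, dcenter, damp):
        got = update_stride_params(
            center + amp, center - amp, dcenter + damp, dcenter - damp
        )
        assert got == pytest.approx((center, dcenter, amp, damp))


class TestSmoother:
    def test_step_response_first_samples(self):
        cfg = SmootherConfig(a=0.98)
        y = smooth_param_step(0.0, 1.0, cfg)
        assert y == pytest.approx(0.02)
        assert smooth_param_step(y, 1.0, cfg) == pytest.approx(0.0396)

    def test_pole_zero_is_passthrough(self):
        cfg = SmootherConfig(a=0.0)
        assert smooth_param_step(0.3, 7.0, cfg) == 7.0

    def test_geometric_decay(self):
        cfg = SmootherConfig(a=0.9)
        y, target = 5.0, 1.0
        for k in range(1, 40):
            y = smooth_param_step(y, target, cfg)
            assert abs(y - target) == pytest.approx(0.9**k * 4.0, rel=1e-9)

    def test_invalid_pole_rejected(self):
        with pytest.raises(ValueError):
            SmootherConfig(a=1.0)


class TestNormalize:
    def test_arithmetic(self):
        tn, _ = normalize(0.3, 0.0, (0.1, 0.0, 0.4, 1.0))
        assert tn == pytest.approx(0.5)

    def test_center_maps_to_origin(self):
        assert normalize(0.1, -0.5, (0.1, -0.5, 0.4, 1.0)) == (0.0, 0.0)

    def test_unit_circle_for_sinusoid(self):
        t = np.linspace(0, 1, 500)
        omega, amp, bias = TWO_PI, 0.4, 0.1
        theta = bias + amp * np.cos(omega * t)
        theta_dot = -amp * omega * np.sin(omega * t)
        for th, thd in zip(theta, theta_dot):
            tn, tdn = normalize(th, thd, (bias, 0.0, amp, amp * omega))
            assert tn**2 + tdn**2 == pytest.approx(1.0, abs=1e-9)

    def test_zero_amplitude_raises(self):
        with pytest.raises(ValueError):
            normalize(0.1, 0.0, (0.0, 0.0, 0.0, 1.0))


class TestPortraitPhase:
    @pytest.mark.parametrize(
        "point, expected_pct",
        [((1.0, 0.0), 0.0), ((0.0, -1.0), 25.0), ((-1.0, 0.0), 50.0),
         ((0.0, 1.0), 75.0)],
    )
    def test_axis_points(self, point, expected_pct):
        assert to_percent(portrait_phase(*point)) == pytest.approx(expected_pct)

    def test_45_degree_point(self):
        s = math.sqrt(2) / 2
        assert portrait_phase(s, -s) == pytest.approx(math.pi / 4)

    def test_origin_raises(self):
        with pytest.raises(ValueError):
            portrait_phase(0.0, 0.0)

    @given(
        r=st.floats(0.05, 3.0),
        ang=st.floats(0.0, TWO_PI, exclude_max=True),
    )
    def test_matches_three_branch_form(self, r, ang):
        tn, tdn = r * math.cos(ang), r * math.sin(ang)
        if abs(tn) < 1e-12:
            tn = 0.0
        if tn == 0.0:
            return  # printed form divides by theta_n; atan2 form extends it
        expected = printed_three_branch_phase(tn, tdn) % TWO_PI
        got = portrait_phase(tn, tdn)
        circ_diff = (got - expected + math.pi) % TWO_PI - math.pi
        assert abs(circ_diff) < 1e-9

    def test_oracle_equivalence_sinusoid(self):
        # exact params, no filtering: estimated phase equals omega*t mod 2pi
        omega, amp, bias = 5.0, 0.35, 0.05
        t = np.linspace(0.0, 3.0, 2000, endpoint=False)
        theta = bias + amp * np.cos(omega * t)
        theta_dot = -amp * omega * np.sin(omega * t)
        for ti, th, thd in zip(t, theta, theta_dot):
            tn, tdn = normalize(th, thd, (bias, 0.0, amp, amp * omega))
            assert portrait_phase(tn, tdn) == pytest.approx(
                (omega * ti) % TWO_PI, abs=1e-6
            )


class TestCompensate:
    def test_paper_offset(self):
        assert compensate(0.0, 2, 2.5) == pytest.approx(0.761, abs=5e-4)

    def test_large_alpha_identity(self):
        assert compensate(1.0, 2, 1e12) == pytest.approx(1.0, abs=1e-9)

    def test_wraps(self):
        assert compensate(6.0, 2, 2.5) == pytest.approx(0.4778, abs=1e-3)

    @given(phi=st.floats(0.0, TWO_PI, exclude_max=True))
    def test_range(self, phi):
        assert 0.0 <= compensate(phi, 2, 2.5) < TWO_PI


class TestToPercent:
    @pytest.mark.parametrize(
        "phi, pct", [(math.pi, 50.0), (0.0, 0.0), (1.5 * math.pi, 75.0)]
    )
    def test_values(self, phi, pct):
        assert to_percent(phi) == pytest.approx(pct)


class TestStrideTracker:
    def test_cosine_events_once_per_period(self):
        fs = 200.0
        t = np.arange(0.0, 10.0, 1.0 / fs)
        theta = 0.35 * np.cos(TWO_PI * t)
        theta_dot = -0.35 * TWO_PI * np.sin(TWO_PI * t)
        tracker = StrideTracker()
        events = [
            ti
            for ti, th, thd in zip(t, theta, theta_dot)
            if tracker.step(ti, th, thd, center=0.0)
        ]
        # maxima at t = 0(not detectable), 1, 2, ... 9
        assert len(events) == 9
        assert np.allclose(np.asarray(events), np.arange(1, 10), atol=1.5 / fs)
        assert tracker.state.t_stride == pytest.approx(1.0, abs=2.0 / fs)

    def test_monotone_stream_no_events(self):
        tracker = StrideTracker()
        fired = [
            tracker.step(k * 0.01, 0.01 * k, 1.0, center=-10.0) for k in range(500)
        ]
        assert not any(fired)

    def test_two_harmonic_one_event_per_cycle(self, default_trial):
        # refractory window must reject the secondary hump
        from gaitphase.gfaf import differentiate

        tr = default_trial
        dt = 1.0 / tr.fs
        theta_dot = differentiate(tr.theta_true, dt)
        tracker = StrideTracker()
        events = [
            ti
            for ti, th, thd in zip(tr.t, tr.theta_true, theta_dot)
            if tracker.step(ti, th, thd, center=0.0)
        ]
        true_cycles = tr.max_flexion_times
        # offline truth: one maximum per cycle
        assert abs(len(events) - len(true_cycles)) <= 1
        matched = np.asarray(events)
        offline = true_cycles[
            np.searchsorted(true_cycles, matched[0] - 0.1) :
        ][: matched.size]
        assert np.allclose(matched, offline, atol=2.0 * dt)


class TestProcessStream:
    def test_phase_zero_at_true_max_flexion(self, pure_trial):
        tr = pure_trial
        res = process_stream(
            tr.t, tr.accel, tr.gyro, EstimatorConfig(fs=tr.fs)
        )
        events = tr.max_flexion_times[tr.max_flexion_times > 5.0]
        vals = phase_at_events(res.t, res.phi_pct, events, valid=res.converged)
        dev = (vals + 50.0) % 100.0 - 50.0
        assert np.abs(dev).max() < 1.5

    def test_round_trip_recovers_truth(self, pure_trial):
        # noise-free single-harmonic trial: compensated phase tracks the
        # generator truth to within the compensation residual
        tr = pure_trial
        res = process_stream(tr.t, tr.accel, tr.gyro, EstimatorConfig(fs=tr.fs))
        mask = res.converged & (tr.t > 10.0)
        err = (res.phi_pct[mask] - tr.phase_true_pct[mask] + 50.0) % 100.0 - 50.0
        assert np.abs(err).max() < 1.0

    def test_output_range_and_monotonicity(self, default_trial):
        tr = default_trial
        res = process_stream(tr.t, tr.accel, tr.gyro, EstimatorConfig(fs=tr.fs))
        ok = np.isfinite(res.phi_pct)
        assert np.all((res.phi_pct[ok] >= 0.0) & (res.phi_pct[ok] < 100.0))
        mask = res.converged & (tr.t > 5.0)
        unwrapped = np.unwrap(res.phi_pct[mask], period=100.0)
        assert np.all(np.diff(unwrapped) > -1e-9)

    def test_continuity_smooth_input(self, default_trial):
        tr = default_trial
        res = process_stream(tr.t, tr.accel, tr.gyro, EstimatorConfig(fs=tr.fs))
        mask = res.converged & (tr.t > 5.0)
        d = np.diff(np.unwrap(res.phi_pct[mask], period=100.0))
        nominal = np.median(d)
        assert d.max() < 5.0 * nominal

    def test_unsmoothed_params_reintroduce_jumps(self):
        # negative control: pole 0 (no smoothing) produces larger phase
        # jumps at stride updates than pole 0.98 on the same jittery trial
        from gaitphase.synthetic import (
            GaitModelParams,
            make_speed_profile,
            simulate_trial,
        )

        profile = make_speed_profile("ramp_profile", hold=10.0)
        params = GaitModelParams(
            seed=3, period_jitter_std=0.05,
            noise_std_gyro=0.02, noise_std_accel=0.3,
        )
        tr = simulate_trial(profile, params, fs=200.0)
        jumps = {}
        for pole in (0.98, 0.0):
            res = process_stream(
                tr.t, tr.accel, tr.gyro, EstimatorConfig(fs=tr.fs, pole=pole)
            )
            mask = res.converged & (tr.t > 8.0)
            d = np.diff(np.unwrap(res.phi_pct[mask], period=100.0))
            jumps[pole] = d.max()
        assert jumps[0.0] > jumps[0.98]

    def test_all_zero_imu_flagged_invalid(self):
        n = 2000
        t = np.arange(n) / 200.0
        res = process_stream(
            t, np.zeros((n, 3)), np.zeros((n, 3)), EstimatorConfig(fs=200.0)
        )
        assert not res.converged.any()
        assert np.isnan(res.phi_pct).all()

    def test_deterministic(self, default_trial):
        tr = default_trial
        r1 = process_stream(tr.t, tr.accel, tr.gyro, EstimatorConfig(fs=tr.fs))
        r2 = process_stream(tr.t, tr.accel, tr.gyro, EstimatorConfig(fs=tr.fs))
        assert np.array_equal(r1.phi_pct, r2.phi_pct, equal_nan=True)
        assert np.array_equal(r1.stride_id, r2.stride_id)

    def test_parameter_recovery(self, pure_trial):
        # smoothed center converges to generator truth; the amplitude
        # converges to the *filtered* signal's amplitude (the extrema are
        # tracked after the adaptive filter, whose gain at the gait
        # frequency is (1 + 1/alpha^2)^(-n/2))
        from gaitphase.engine import PhaseEstimator

        tr = pure_trial
        est = PhaseEstimator(EstimatorConfig(fs=tr.fs))
        n_five_strides = int(5 * 1.15 * tr.fs) + int(2 * tr.fs)
        for k in range(n_five_strides):
            est.step(float(tr.t[k]), tr.accel[k], tr.gyro[k])
        theta_o, _, a_theta, _ = est._smoothed
        gen_amp = 0.35  # at 1.0 m/s the speed scaling is unity
        filt_gain = (1.0 + 1.0 / 2.5**2) ** -1.0  # two-stage cascade
        assert a_theta == pytest.approx(gen_amp * filt_gain, rel=0.02)
        assert abs(theta_o - 0.0) < 0.02 * gen_amp

    def test_non_monotone_timestamps_raise(self):
        t = np.array([0.0, 0.01, 0.01])
        accel = np.tile([9.81, 0.0, 0.0], (3, 1))
        with pytest.raises(ValueError, match="sample"):
            process_stream(t, accel, np.zeros((3, 3)), EstimatorConfig(fs=100.0))
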