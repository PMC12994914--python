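import numpy as np
import pytest
from scipy.signal import find_peaks

from insom.model import (
    IH,
    IM,
    IntegrationError,
    ModelParams,
    derivatives,
    entrain,
    integrate,
    kss,
    vpvtrt,
)
from insom.units import MelanopicIrradianceSeries

from conftest import square_day_series


def _state_at(traj, day, clock_h):
    i = np.argmin(np.abs(traj.t - (day * 24.0 + clock_h) * 3600.0))
    return traj.states[i]


class TestDerivatives:
    def test_h_rises_during_wake(self, params, week_trajectory):
        s = _state_at(week_trajectory, 3, 14.0)  # mid-afternoon, awake
        for light in (0.0, 0.5, 5.0):
            d = derivatives(s, light, awake=True, p=params)
            assert d[IH] > 0.0

    def test_h_falls_during_sleep(self, params, week_trajectory):
        s = _state_at(week_trajectory, 3, 3.0)  # deep night, asleep
        d = derivatives(s, 0.0, awake=False, p=params)
        assert d[IH] < 0.0

    def test_light_inhibits_melatonin_synthesis(self, params, week_trajectory):
        s = _state_at(week_trajectory, 3, 23.5).copy()  # secretion active
        IP = 6
        d_dark = derivatives(s, 0.0, awake=True, p=params)
        d_dim = derivatives(s, 0.05, awake=True, p=params)
        d_bright = derivatives(s, 1.0, awake=True, p=params)
        assert d_bright[IP] <= d_dim[IP] <= d_dark[IP]

    def test_sleep_gates_light_out(self, params, week_trajectory):
        s = _state_at(week_trajectory, 3, 3.0)
        d_dark = derivatives(s, 0.0, awake=False, p=params)
        d_lit = derivatives(s, 10.0, awake=False, p=params)
        assert np.array_equal(d_dark, d_lit)

    def test_nonfinite_state_rejected(self, params):
        bad = np.full(8, np.nan)
        with pytest.raises(IntegrationError):
            derivatives(bad, 0.0, True, params)


class TestAlertnessOutputs:
    def test_kss_bounded(self, params, week_trajectory):
        awake = week_trajectory.awake
        vals = week_trajectory.kss[awake]
        assert np.all((vals >= 1.0) & (vals <= 9.0))
        # extreme synthetic states still clamp
        hot = week_trajectory.states[0].copy()
        hot[IH] = 200.0
        assert kss(hot, 0.0, params) == 9.0
        hot[IH] = -200.0
        assert kss(hot, 10.0, params) == 1.0

    def test_kss_light_term_saturates_above_0p075(self, params, week_trajectory):
        s = _state_at(week_trajectory, 3, 10.0)
        span = params.kss_light_range
        assert abs(kss(s, 0.075, params) - kss(s, 10.0, params)) < 0.05 * span

    def test_kss_strictly_lower_under_light(self, params, week_trajectory):
        s = _state_at(week_trajectory, 3, 10.0)
        assert kss(s, 0.075, params) < kss(s, 0.0, params)

    def test_vpvtrt_independent_of_instantaneous_light(self, params,
                                                       scheduled,
                                                       entrained_state):
        """Two runs differing only in light level give identical vPVTRT
        wherever H and C agree (initial instants before divergence)."""
        a = integrate(square_day_series(1, 0.1), scheduled, params,
                      initial_state=entrained_state)
        b = integrate(square_day_series(1, 5.0), scheduled, params,
                      initial_state=entrained_state)
        # states at the first lit step are still equal (light acts forward):
        # identical (H, C) → identical reaction time despite 50× the light
        i0 = int(6 * 3600 / a.dt)
        assert a.vpvtrt[i0] == b.vpvtrt[i0]
        assert a.kss[i0] != b.kss[i0]  # KSS does react instantaneously

    def test_vpvtrt_monotone_in_h_and_positive(self, params, week_trajectory):
        s = _state_at(week_trajectory, 3, 10.0).copy()
        lo = vpvtrt(s, params)
        s[IH] += 2.0
        assert vpvtrt(s, params) >= lo > 0.0


class TestIntegration:
    def test_deterministic(self, params, scheduled, entrained_state):
        ser = square_day_series(2, 0.5)
        a = integrate(ser, scheduled, params, initial_state=entrained_state)
        b = integrate(ser, scheduled, params, initial_state=entrained_state)
        assert np.array_equal(a.states, b.states)
        assert np.array_equal(a.kss[a.awake], b.kss[b.awake])

    def test_light_during_sleep_is_ignored(self, params, scheduled,
                                           entrained_state):
        """Forced mode: arbitrary light inside scheduled sleep intervals
        changes nothing — eyes closed."""
        ser = square_day_series(3, 0.5)
        leaky = ser.values.copy()
        h = ser.clock_hours()
        leaky[h < 6.0] = 7.7  # blast light into the sleep window
        ser_leaky = MelanopicIrradianceSeries(ser.t, leaky)
        a = integrate(ser, scheduled, params, initial_state=entrained_state)
        b = integrate(ser_leaky, scheduled, params,
                      initial_state=entrained_state)
        assert np.array_equal(a.states, b.states)

    def test_afternoon_melatonin_near_zero(self, week_trajectory):
        h = week_trajectory.clock_hours()
        aft = week_trajectory.melatonin[(h >= 13.0) & (h < 16.0)]
        assert aft.max() < 0.02 * week_trajectory.melatonin.max()

    def test_validity_mask_blocks_two_hours_after_main_wake(self,
                                                            week_trajectory):
        h = week_trajectory.clock_hours()
        valid = week_trajectory.alertness_valid
        awake = week_trajectory.awake
        sel = (h >= 6.0) & (h < 8.0) & awake
        assert not valid[sel].any()
        assert valid[(h >= 8.5) & (h < 12.0) & awake].all()

    def test_step_refinement_converges(self, params, scheduled,
                                       entrained_state):
        """Halving dt from 20 s to 10 s changes each state component by
        less than 1e-3 of its trajectory amplitude over 7 days."""
        ser = square_day_series(7, 0.5)
        a = integrate(ser, scheduled, params, dt=20.0,
                      initial_state=entrained_state)
        b = integrate(ser, scheduled, params, dt=10.0,
                      initial_state=entrained_state)
        for j in range(8):
            scale = np.max(np.abs(b.states[:, j]))
            diff = np.max(np.abs(a.states[:, j] - b.states[::2, j]))
            assert diff / scale < 1e-3

    def test_divergence_reported_with_step(self, params, scheduled):
        # a microsecond plasma-clearance time makes the melatonin equation
        # violently stiff: the fixed-step integrator must fail loudly,
        # naming the step and the state component
        wild = params.replace(tau_clear=1e-7)
        with pytest.raises(IntegrationError, match="step"):
            with np.errstate(all="ignore"):
                integrate(square_day_series(1, 0.5), scheduled, wild)

    def test_invalid_mode_rejected(self, params, scheduled):
        with pytest.raises(ValueError):
            integrate(square_day_series(1, 0.5), scheduled, params,
                      mode="lucid")


class TestEntrainment:
    def test_deterministic(self, params, scheduled):
        ser = square_day_series(1, 0.5)
        a = entrain(scheduled, params, days=2, exposure=ser)
        b = entrain(scheduled, params, days=2, exposure=ser)
        assert np.array_equal(a, b)

    def test_zero_days_returns_initial_condition(self, params, scheduled):
        out = entrain(scheduled, params, days=0)
        assert np.array_equal(out, np.array(params.initial_state))

    def test_disrupted_h_exceeds_scheduled_at_6am(self, params, scheduled,
                                                  disrupted):
        """Fragmented, circadian-inopportune sleep restores less: the
        disrupted sleeper carries more homeostatic pressure at 06:00."""
        ser = square_day_series(1, 0.5)
        run = square_day_series(2, 0.5)
        h_at_6 = {}
        for name, sched in (("scheduled", scheduled), ("disrupted", disrupted)):
            s0 = entrain(sched, params, days=7, exposure=ser)
            traj = integrate(run, sched, params, initial_state=s0)
            i = np.argmin(np.abs(traj.t - (24.0 + 6.0) * 3600.0))
            h_at_6[name] = traj.states[i, IH]
        assert h_at_6["disrupted"] > h_at_6["scheduled"]

    def test_melatonin_peak_stable_after_entrainment(self, params, scheduled,
                                                     entrained_state):
        """Under a regular 16:8 photoperiod the entrained melatonin peak
        drifts by less than 2 min/day."""
        traj = integrate(square_day_series(10, 0.5), scheduled, params,
                         initial_state=entrained_state)
        peaks = []
        for d in range(1, 10):
            sel = (traj.t >= (d - 1) * 86400 + 15 * 3600) & \
                  (traj.t < d * 86400 + 15 * 3600)
            i = np.argmax(traj.melatonin[sel])
            peaks.append(traj.t[sel][i] / 3600.0 % 24.0)
        drift_min = (np.diff(peaks) + 12.0) % 24.0 - 12.0
        assert np.max(np.abs(drift_min)) * 60.0 < 2.0


class TestFreeRun:
    def test_period_matches_intrinsic_in_darkness(self, params, scheduled):
        """Natural-mode constant darkness: the circadian peak-to-peak
        interval equals the intrinsic period within ±5 min/day."""
        dark = square_day_series(32, 0.0)
        traj = integrate(dark, scheduled, params, mode="natural",
                         initial_state=np.array(params.initial_state))
        x = traj.states[:, 3]
        pk, _ = find_peaks(x, distance=int(20 * 3600 / traj.dt))
        periods = np.diff(traj.t[pk] / 3600.0)[2:]  # skip initial transient
        assert abs(np.mean(periods) - params.tau_c) * 60.0 < 5.0

    def test_natural_mode_produces_sleep_and_wake(self, params, scheduled):
        dark = square_day_series(10, 0.0)
        traj = integrate(dark, scheduled, params, mode="natural",
                         initial_state=np.array(params.initial_state))
        frac_asleep = 1.0 - traj.awake.mean()
        assert 0.15 < frac_asleep < 0.6


class TestParams:
    def test_intrinsic_period_bounds_enforced(self):
        with pytest.raises(ValueError):
            ModelParams(tau_c=30.0)

    def test_positive_rates_enforced(self):
        with pytest.raises(ValueError):
            ModelParams(chi=-1.0)
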