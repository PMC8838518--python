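"""Ground-truth simulator: temperature step rule, HR walk, PPG waveform."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neophantom import (
    HRProfile,
    HRTrace,
    PulseShape,
    RegionId,
    TemperaturePhase,
    TemperatureProfile,
    generate_ppg,
    plan_temperature_steps,
    simulate_hr,
    simulate_temperature,
    skin_temperature,
)

R = RegionId.TORSO_MID


def one_region_profile(initial, phases_spec, **kw):
    phases = [TemperaturePhase({R: tgt}, dur) for tgt, dur in phases_spec]
    return TemperatureProfile(phases=phases, initial_set={r: initial for r in RegionId}, **kw)


class TestStepPlanning:
    @pytest.mark.parametrize(
        "current,target,interval,rate,expected",
        [
            (30.0, 33.0, 30.0, 1.0, 0.5),  # ceil(3/0.5)=6 equal steps
            (36.0, 36.0, 30.0, 1.0, 0.0),  # already at target
            (38.0, 34.0, 30.0, 1.0, -4.0),  # decrease: single jump
            (30.0, 30.3, 30.0, 1.0, 0.3),  # below one max step: one step
        ],
    )
    def test_step_width(self, current, target, interval, rate, expected):
        assert plan_temperature_steps(current, target, interval, rate) == pytest.approx(expected)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            plan_temperature_steps(math.nan, 33.0)
        with pytest.raises(ValueError):
            plan_temperature_steps(30.0, math.inf)

    @given(
        current=st.floats(20, 45),
        target=st.floats(20, 45),
        interval=st.floats(5, 120),
        rate=st.floats(0.1, 5),
    )
    @settings(derandomize=True, max_examples=200)
    def test_step_bounded_and_target_exact(self, current, target, interval, rate):
        """Each heat-up step respects the rate cap and divides the gap evenly."""
        step = plan_temperature_steps(current, target, interval, rate)
        if target > current:
            assert 0 < step <= rate * interval / 60.0 + 1e-12
            n = (target - current) / step
            assert n == pytest.approx(round(n))
        else:
            assert step == pytest.approx(target - current)


class TestTemperatureSimulation:
    def test_single_heatup_series(self):
        profile = one_region_profile(30.0, [(33.0, 300.0)])
        times, series = simulate_temperature(profile)
        expected = [30, 30.5, 31, 31.5, 32, 32.5, 33, 33, 33, 33, 33]
        np.testing.assert_allclose(series[R], expected)
        np.testing.assert_allclose(times, np.arange(11) * 30.0)

    def test_constant_when_target_equals_initial(self):
        profile = one_region_profile(34.0, [(34.0, 120.0)])
        _, series = simulate_temperature(profile)
        assert np.all(series[R] == 34.0)

    def test_heat_then_cool_composition(self):
        profile = one_region_profile(30.0, [(32.0, 180.0), (31.0, 120.0)])
        _, series = simulate_temperature(profile)
        s = series[R]
        rise = s[:7]
        assert np.all(np.diff(rise) >= 0) and rise[-1] == 32.0
        # cool-down: single jump to target at the first update of phase 2
        assert s[7] == 31.0 and np.all(s[7:] == 31.0)

    def test_rate_bound_over_any_60s_window(self):
        """Positive change over any 60 s window never exceeds 1 degC."""
        profile = one_region_profile(30.0, [(40.0, 900.0)])
        times, series = simulate_temperature(profile)
        s = series[R]
        lag = int(round(60.0 / 30.0))
        window_rise = s[lag:] - s[:-lag]
        assert window_rise.max() <= 1.0 + 1e-12

    def test_every_phase_reaches_target_exactly(self):
        profile = one_region_profile(
            31.3, [(36.7, 600.0), (33.1, 300.0), (39.9, 900.0)]
        )
        times, series = simulate_temperature(profile)
        s = series[R]
        bounds = np.cumsum([0, 600, 300, 900]) / 30
        for tgt, end in zip([36.7, 33.1, 39.9], bounds[1:]):
            assert s[int(end)] == pytest.approx(tgt)

    def test_rejects_empty_phases(self):
        with pytest.raises(ValueError):
            TemperatureProfile(phases=[], initial_set={})
        with pytest.raises(ValueError):
            TemperaturePhase({R: 33.0}, 0.0)


class TestSkinLag:
    def test_tau_zero_is_identity(self):
        s = np.array([30.0, 31.0, 32.0])
        np.testing.assert_array_equal(skin_temperature(s, 0.0), s)

    def test_first_order_step_response(self):
        """Closed form: skin(60 s) = 30 + 4 (1 - e^-1) for a 30->34 step, tau 60."""
        set_series = np.array([34.0, 34.0, 34.0])  # step applied at t=0
        skin = skin_temperature(set_series, tau=60.0, update_interval=30.0, initial=30.0)
        expected_60 = 30.0 + 4.0 * (1 - math.exp(-1.0))
        assert skin[2] == pytest.approx(expected_60)

    def test_constant_input_stays_constant(self):
        s = np.full(10, 33.0)
        np.testing.assert_allclose(skin_temperature(s, tau=45.0), 33.0)

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            skin_temperature(np.array([30.0]), tau=-1.0)


class TestHRWalk:
    def test_rmax_zero_constant(self):
        trace = simulate_hr(HRProfile(hrt=140.0, rmax=0), 600.0, seed=0)
        assert np.all(trace.values == 140.0)

    def test_confinement_one_hour(self):
        trace = simulate_hr(HRProfile(hrt=140.0), 3600.0, seed=7)
        assert np.max(np.abs(trace.values - 140.0)) <= 10.0
        assert trace.values[0] == 140.0
        assert trace.times[1] - trace.times[0] == 5.0

    def test_steps_are_integers(self):
        trace = simulate_hr(HRProfile(hrt=140.0), 300.0, seed=3)
        unclipped = np.abs(trace.values - 140.0) < 10.0
        steps = np.diff(trace.values)[unclipped[1:]]
        assert np.all(steps == np.round(steps))
        assert np.all(np.abs(steps) <= 10)

    def test_seed_determinism(self):
        a = simulate_hr(HRProfile(hrt=120.0), 1200.0, seed=42)
        b = simulate_hr(HRProfile(hrt=120.0), 1200.0, seed=42)
        np.testing.assert_array_equal(a.values, b.values)

    def test_hrv_disabled_forces_constant(self):
        trace = simulate_hr(HRProfile(hrt=140.0, rmax=10, hrv_enabled=False), 600.0, seed=1)
        assert np.all(trace.values == 140.0)


def constant_trace(bpm):
    return HRTrace(times=np.array([0.0]), values=np.array([float(bpm)]))


class TestPPG:
    def test_beat_count_60bpm(self):
        ppg = generate_ppg(constant_trace(60), duration=10.0, sample_rate=30.0)
        assert len(ppg.beat_times) == 10
        np.testing.assert_allclose(np.diff(ppg.beat_times), 1.0)

    def test_onset_spacing_140bpm(self):
        ppg = generate_ppg(constant_trace(140), duration=10.0, sample_rate=30.0)
        np.testing.assert_allclose(np.diff(ppg.beat_times), 60.0 / 140.0)

    def test_bounded_samples_and_unimodal_option(self):
        shape = PulseShape(secondary_amplitude=0.0)
        ppg = generate_ppg(constant_trace(120), duration=5.0, sample_rate=60.0, pulse_shape=shape)
        assert ppg.samples.min() >= 0 and ppg.samples.max() <= 1
        # unimodal: one local max per beat
        v = ppg.samples
        n_max = np.sum((v[1:-1] > v[:-2]) & (v[1:-1] > v[2:]))
        assert n_max == len(ppg.beat_times)

    def test_sample_rate_too_low_rejected(self):
        with pytest.raises(ValueError):
            generate_ppg(constant_trace(240), duration=5.0, sample_rate=6.0)

    def test_pulse_count_conserved_under_varying_rate(self):
        trace = simulate_hr(HRProfile(hrt=140.0), 60.0, seed=5)
        ppg = generate_ppg(trace, duration=60.0, sample_rate=60.0)
        # onsets spaced by 60/HRS at each onset
        hrs = trace.at(ppg.beat_times[:-1])
        np.testing.assert_allclose(np.diff(ppg.beat_times), 60.0 / hrs)
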