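"""Integrator semantics: fixed points, closed-form limits, reset/refractory."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from adexscape import (
    AdExParameters,
    IntegrationError,
    StimulusProtocol,
    simulate,
    v_nullcline,
    w_nullcline,
)

PASSIVE = AdExParameters(
    C=200.0, g_L=10.0, E_L=-70.0, Delta_T=2.0, V_th=-50.0,
    a=0.0, b=0.0, tau_w=100.0, V_reset=-58.0, V_peak=20.0, t_ref=0.0,
)

TONIC = AdExParameters(
    C=200.0, g_L=10.0, E_L=-70.0, Delta_T=2.0, V_th=-50.0,
    a=2.0, b=3.0, tau_w=40.0, V_reset=-58.0, V_peak=20.0, t_ref=2.0,
)


def step_protocol(step, v0=-70.0, delay=100.0, end=600.0, duration=700.0, hold=0.0):
    return StimulusProtocol(
        step_amplitude=step, stim_delay=delay, stim_end=end,
        duration=duration, initial_voltage=v0, holding_current=hold,
    )


class TestSimulate:
    def test_rest_is_a_fixed_point(self):
        """Without input, at V=E_L with a=0 both derivatives vanish exactly."""
        res = simulate(PASSIVE, step_protocol(0.0), dt=0.01)
        assert np.allclose(res.voltages, PASSIVE.E_L)
        assert np.allclose(res.adaptation, 0.0)
        assert res.n_spikes == 0

    def test_matches_linear_membrane_closed_form(self):
        """With a=0 and V well below V_th the response is the RC charging
        curve E_L + (I/g_L)(1 - exp(-t/tau_m)) to within 0.1 mV."""
        I = 100.0
        proto = step_protocol(I, delay=0.0, end=600.0, duration=600.0)
        res = simulate(PASSIVE, proto, dt=0.01)
        tau_m = PASSIVE.C / PASSIVE.g_L
        expected = PASSIVE.E_L + (I / PASSIVE.g_L) * (1 - np.exp(-res.times / tau_m))
        assert np.max(np.abs(res.voltages - expected)) < 0.1
        # the derived spot value at 20 ms
        idx = int(round(20.0 / 0.01))
        assert res.voltages[idx] == pytest.approx(-63.68, abs=0.1)

    def test_reset_and_refractory_semantics(self):
        """Each spike stores a V_peak sample, then V_reset; w jumps by exactly
        b across the reset and both stay clamped for t_ref."""
        res = simulate(TONIC, step_protocol(352.6), dt=0.01)
        assert res.n_spikes > 3
        dt = res.dt
        ref_steps = int(round(TONIC.t_ref / dt))
        spike_idx = np.rint(res.spike_times / dt).astype(int)
        for k in spike_idx:
            assert res.voltages[k] == TONIC.V_peak
            assert res.voltages[k + 1] == TONIC.V_reset
            # w at the spike sample = euler update of previous w, plus b
            w_prev = res.adaptation[k - 1]
            v_prev = res.voltages[k - 1]
            w_euler = w_prev + dt * (TONIC.a * (v_prev - TONIC.E_L) - w_prev) / TONIC.tau_w
            assert res.adaptation[k] == pytest.approx(w_euler + TONIC.b, rel=1e-12)
            # clamp: V and w constant over the refractory window
            assert np.all(res.voltages[k + 1 : k + 1 + ref_steps] == TONIC.V_reset)
            assert np.all(res.adaptation[k : k + 1 + ref_steps] == res.adaptation[k])

    def test_no_two_spikes_within_refractory(self):
        res = simulate(TONIC, step_protocol(352.6), dt=0.01)
        assert np.all(np.diff(res.spike_times) > TONIC.t_ref)

    def test_recorded_voltage_never_exceeds_peak(self):
        res = simulate(TONIC, step_protocol(352.6), dt=0.01)
        assert np.all(res.voltages <= TONIC.V_peak)

    @pytest.mark.parametrize("fine", [0.005, 0.001])
    def test_spike_time_step_convergence(self, fine):
        """Refining the step preserves the spike count and moves the first
        spike and every interspike interval by < 0.5 ms.  (Absolute spike
        times accumulate first-order phase drift along long trains, so the
        bound applies to the quantities that do not accumulate.)"""
        res_c = simulate(TONIC, step_protocol(352.6), dt=0.01)
        res_f = simulate(TONIC, step_protocol(352.6), dt=fine)
        assert res_c.n_spikes == res_f.n_spikes > 0
        assert abs(res_c.spike_times[0] - res_f.spike_times[0]) < 0.5
        isi_c = np.diff(res_c.spike_times)
        isi_f = np.diff(res_f.spike_times)
        assert np.max(np.abs(isi_c - isi_f)) < 0.5

    def test_spike_times_converge_on_short_train(self):
        """On the near-rheobase tonic step (5 spikes) every spike time moves
        by < 0.5 ms between dt = 0.01 and dt = 0.001 ms."""
        res_c = simulate(TONIC, step_protocol(231.4), dt=0.01)
        res_f = simulate(TONIC, step_protocol(231.4), dt=0.001)
        assert res_c.n_spikes == res_f.n_spikes > 0
        assert np.max(np.abs(res_c.spike_times - res_f.spike_times)) < 0.5

    def test_phase_drift_shrinks_first_order_with_dt(self):
        """The accumulated spike-time drift along the strong-step train is
        roughly halved when dt is halved (explicit Euler is first order)."""
        ref = simulate(TONIC, step_protocol(352.6), dt=0.00125)
        drift = []
        for dt in (0.01, 0.005, 0.0025):
            res = simulate(TONIC, step_protocol(352.6), dt=dt)
            n = min(res.n_spikes, ref.n_spikes)
            drift.append(np.max(np.abs(res.spike_times[:n] - ref.spike_times[:n])))
        assert drift[0] > drift[1] > drift[2]

    def test_initial_adaptation_defaults_to_steady_state(self):
        params = TONIC.replace(t_ref=0.0)
        proto = step_protocol(0.0, v0=-60.0)
        res = simulate(params, proto, dt=0.01)
        assert res.adaptation[0] == params.a * (-60.0 - params.E_L)
        res0 = simulate(params, proto, dt=0.01, w0=0.0)
        assert res0.adaptation[0] == 0.0

    def test_invalid_dt_rejected(self):
        with pytest.raises(ValueError):
            simulate(TONIC, step_protocol(0.0), dt=0.0)
        with pytest.raises(ValueError):
            simulate(TONIC, step_protocol(0.0), dt=-0.01)
        # refractory clamp must be representable
        with pytest.raises(ValueError):
            simulate(TONIC, step_protocol(0.0), dt=5.0)

    def test_divergent_adaptation_raises_integration_error(self):
        """An Euler-unstable adaptation variable (dt >> tau_w with strong
        coupling) must be reported as an integration failure, not returned."""
        bad = TONIC.replace(tau_w=0.001, a=50.0, t_ref=0.0)
        with pytest.raises(IntegrationError) as exc:
            simulate(bad, step_protocol(300.0), dt=0.01)
        assert exc.value.time_ms >= 0.0


class TestProtocol:
    def test_invalid_windows_rejected(self):
        with pytest.raises(ValueError):
            StimulusProtocol(step_amplitude=0, stim_delay=100, stim_end=50,
                             duration=700, initial_voltage=-70)
        with pytest.raises(ValueError):
            StimulusProtocol(step_amplitude=0, stim_delay=100, stim_end=800,
                             duration=700, initial_voltage=-70)

    def test_current_step_window(self):
        p = step_protocol(100.0, hold=-30.0)
        assert p.current_at(0.0) == -30.0
        assert p.current_at(100.0) == 70.0  # half-open [delay, end)
        assert p.current_at(600.0) == -30.0
        assert p.stim_duration == 500.0


class TestParameters:
    @pytest.mark.parametrize(
        "changes",
        [
            {"C": 0.0},
            {"g_L": -1.0},
            {"Delta_T": 0.0},
            {"tau_w": 0.0},
            {"t_ref": -1.0},
            {"V_reset": 30.0},
            {"V_th": 25.0},
        ],
    )
    def test_invariants_enforced(self, changes):
        with pytest.raises(ValueError):
            TONIC.replace(**changes)

    def test_array_round_trip(self):
        assert AdExParameters.from_array(TONIC.as_array()) == TONIC
        assert AdExParameters.from_dict(TONIC.to_dict()) == TONIC


class TestNullclines:
    def test_v_nullcline_at_leak_reversal(self):
        expected = TONIC.g_L * TONIC.Delta_T * math.exp(
            (TONIC.E_L - TONIC.V_th) / TONIC.Delta_T
        )
        assert v_nullcline(TONIC, 0.0, TONIC.E_L) == pytest.approx(expected)

    def test_v_nullcline_minimum_at_threshold(self):
        """The minimum over V sits at V_th with value I - g_L(V_th-E_L) + g_L*Delta_T
        (dense-grid check)."""
        I = 50.0
        grid = np.linspace(TONIC.E_L - 30, TONIC.V_th + 10, 20001)
        vals = v_nullcline(TONIC, I, grid)
        i_min = int(np.argmin(vals))
        assert grid[i_min] == pytest.approx(TONIC.V_th, abs=5e-3)
        expected_min = I - TONIC.g_L * (TONIC.V_th - TONIC.E_L) + TONIC.g_L * TONIC.Delta_T
        assert vals[i_min] == pytest.approx(expected_min, abs=1e-3)

    def test_current_shifts_v_nullcline_additively(self):
        grid = np.linspace(-90.0, 0.0, 101)
        shift = v_nullcline(TONIC, 37.5, grid) - v_nullcline(TONIC, 0.0, grid)
        assert np.allclose(shift, 37.5)

    def test_w_nullcline_is_linear_in_v(self):
        assert w_nullcline(TONIC, TONIC.E_L) == 0.0
        assert w_nullcline(TONIC, TONIC.E_L + 1.0) == pytest.approx(TONIC.a)
        flat = PASSIVE  # a = 0
        assert np.allclose(w_nullcline(flat, np.linspace(-90, 0, 11)), 0.0)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        I=st.floats(-500, 500),
        V=st.floats(-120, 10),
        g_L=st.floats(1, 30),
        a=st.floats(-5, 15),
    )
    def test_current_additivity_holds_for_any_parameters(self, I, V, g_L, a):
        """v_nullcline(I)(V) - v_nullcline(0)(V) == I for every V and model."""
        p = PASSIVE.replace(g_L=g_L, a=a)
        base = v_nullcline(p, 0.0, V)
        # tolerance scales with the nullcline magnitude: the exponential term
        # dominates at depolarised V and the subtraction cancels
        tol = 1e-12 * max(1.0, abs(base), abs(I))
        assert v_nullcline(p, I, V) - base == pytest.approx(I, abs=tol)

    def test_quiescent_samples_lie_on_both_nullclines(self):
        """Late samples of a subthreshold relaxation satisfy both nullcline
        equations to within a small tolerance."""
        proto = step_protocol(50.0, delay=0.0, end=700.0)
        res = simulate(TONIC.replace(t_ref=0.0), proto, dt=0.01)
        V_end, w_end = res.voltages[-1], res.adaptation[-1]
        I = proto.current_at(res.times[-1] - res.dt)
        assert abs(v_nullcline(TONIC, 50.0, V_end) - w_end) < 0.05
        assert abs(w_nullcline(TONIC, V_end) - w_end) < 0.05
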