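"""Excitatory/inhibitory rate-network dynamics and closed-form steady states."""

import numpy as np
import pytest

from divnorm.basis import FeatureBasis, topographic_pair_basis
from divnorm.ei_network import (
    NetworkParams,
    NetworkState,
    TraceRecord,
    network_step,
    simulate,
    simulate_to_steady_state,
    steady_exc_given_inh,
    steady_state_simple,
    steady_state_two_unit,
    subtractive_network_step,
    time_to_fraction,
    time_to_peak,
    wavefront_latency,
)
from divnorm.estimators import EstimatorConfig, run_to_convergence, subtractive_closed_form
from conftest import random_basis

FAST_DT = 1e-3 * 0.08  # coarser Euler step for tests, ~50x under stability bound


class TestDivisiveNetwork:
    def test_quiescent_without_input(self, two_input_basis):
        p = NetworkParams(two_input_basis)
        st = NetworkState(np.zeros(2), np.zeros(1))
        out = network_step(p, st, np.zeros(2))
        assert np.all(out.r_exc == 0) and np.all(out.r_inh == 0)
        assert out.t == pytest.approx(p.dt)

    def test_fixed_point_is_stationary(self, two_input_basis):
        # r_exc = s / (w0 + W r_inh), balanced inhibition drive
        p = NetworkParams(two_input_basis)
        st = NetworkState(np.array([1.5, 0.5]), np.array([2.475]))
        out = network_step(p, st, np.array([150.0, 50.0]))
        assert np.allclose(out.r_exc, st.r_exc, atol=1e-9)
        assert np.allclose(out.r_inh, st.r_inh, atol=1e-9)

    def test_two_unit_steady_state_values(self, two_input_basis):
        p = NetworkParams(two_input_basis, dt=FAST_DT)
        st, conv = simulate_to_steady_state(p, np.array([150.0, 50.0]))
        assert conv
        assert np.allclose(st.r_exc, [1.5, 0.5], atol=1e-4)
        assert st.r_inh[0] == pytest.approx(2.475, abs=1e-4)

    def test_perfectly_predicted_input_drives_unit_rates(self, two_input_basis):
        b = two_input_basis
        s = b.mean_input(np.array([2.0]))
        p = NetworkParams(b, dt=FAST_DT)
        st, _ = simulate_to_steady_state(p, s)
        assert np.allclose(st.r_exc, 1.0, atol=1e-4)
        # closed form is exactly one
        assert np.all(steady_exc_given_inh(b, s, np.array([2.0])) == 1.0)

    def test_inhibitory_steady_state_equals_divisive_estimate(self, rng):
        for _ in range(3):
            b = random_basis(rng, 6, 2, background=1.0)
            s = rng.poisson(b.mean_input(rng.uniform(0.5, 2, 2))).astype(float)
            p = NetworkParams(b, dt=FAST_DT)
            st, conv = simulate_to_steady_state(p, s, tol=1e-9)
            assert conv
            est = run_to_convergence(b, s, EstimatorConfig(tol=1e-11,
                                                           max_iters=300_000))
            assert np.abs(st.r_inh - est.x_hat).max() < 1e-3

    def test_contrast_invariance_of_excitatory_steady_state(self, rng):
        # negligible background: scaling s leaves r_exc, scales r_inh
        b = random_basis(rng, 6, 2, background=1e-3)
        s = b.mean_input(rng.uniform(0.5, 2, 2))
        p = NetworkParams(b, dt=1e-4 * 0.08)
        st1, c1 = simulate_to_steady_state(p, s, tol=1e-9, max_time=400)
        st3, c3 = simulate_to_steady_state(p, 3 * s, tol=1e-9, max_time=400)
        assert c1 and c3
        assert np.allclose(st3.r_exc, st1.r_exc, rtol=1e-2, atol=1e-3)
        assert np.allclose(st3.r_inh, 3 * st1.r_inh, rtol=1e-2)

    def test_transient_peak_exceeds_steady_state(self, two_input_basis):
        p = NetworkParams(two_input_basis, dt=1e-5 * 0.08)
        tr = simulate(p, np.array([100.0, 0.0]), duration=1.5, record_every=1e-3)
        y = tr.r_exc[:, 0]
        assert y.max() > 1.5 * y[-1]

    def test_instability_error_names_dt(self, two_input_basis):
        p = NetworkParams(two_input_basis, dt=10.0)
        with pytest.raises(RuntimeError, match="dt"):
            simulate(p, np.array([100.0, 0.0]), duration=50.0)


class TestSubtractiveNetwork:
    def test_predicted_background_is_stationary(self, two_input_basis):
        # at s = w0 the signed error is zero and nothing moves
        p = NetworkParams(two_input_basis)
        st = NetworkState(np.zeros(2), np.zeros(1))
        out = subtractive_network_step(p, st, np.full(2, two_input_basis.background))
        assert np.all(out.r_exc == 0) and np.all(out.r_inh == 0)

    def test_steady_state_matches_least_squares_closed_form(self, rng):
        for _ in range(3):
            b = random_basis(rng, 6, 2, background=1.0)
            s = rng.uniform(20, 150, 6)
            p = NetworkParams(b, dt=FAST_DT)
            st, conv = simulate_to_steady_state(p, s, mode="subtractive", tol=1e-9)
            assert conv
            cf = subtractive_closed_form(b, s, clamp=False)
            assert np.abs(st.r_inh - cf).max() < 1e-3

    def test_error_units_vanish_for_representable_input(self, two_input_basis):
        # classical predictive coding: for an input the generative model can
        # produce, prediction errors decay to zero (in general the error
        # units carry the least-squares residual / w0)
        p = NetworkParams(two_input_basis, dt=FAST_DT)
        s = two_input_basis.mean_input(np.array([2.0]))
        st, _ = simulate_to_steady_state(p, s, mode="subtractive", tol=1e-9)
        assert np.abs(st.r_exc).max() < 1e-3

    def test_time_to_peak_invariant_across_amplitudes(self, two_input_basis):
        p = NetworkParams(two_input_basis, dt=1e-4 * 0.08)
        tts = []
        for amp in (50.0, 200.0):
            tr = simulate(p, np.array([amp, 0.0]), duration=1.0,
                          record_every=1e-3, mode="subtractive")
            tts.append(time_to_peak(tr, 0, "exc"))
        assert tts[0] == pytest.approx(tts[1], rel=5e-3)


class TestClosedForms:
    def test_two_unit_formula_values(self):
        assert steady_state_two_unit(100.0, 100.0, 1.0) == pytest.approx(0.5)
        assert steady_state_two_unit(0.0, 0.0, 1.0) == 0.0
        # weak-input limit: linear with slope 1/s2
        s2 = 100.0
        r1 = steady_state_two_unit(1e-3, s2, 1.0)
        r2 = steady_state_two_unit(2e-3, s2, 1.0)
        assert r2 / r1 == pytest.approx(2.0, rel=1e-3)

    def test_simple_input_formula_reduces_to_two_unit(self, two_input_basis):
        s = np.array([80.0, 0.0])
        full = steady_state_simple(two_input_basis, s)
        assert full[0] == pytest.approx(steady_state_two_unit(80.0, 0.0, 1.0))

    def test_below_threshold_responses_are_linear(self, two_input_basis):
        # rectification floor: pooled input below w0 leaves responses ~ s/w0
        r = steady_state_simple(two_input_basis, np.array([3e-4, 1e-4]))
        assert np.allclose(r, np.array([3e-4, 1e-4]) / 1.0)

    def test_two_unit_simulation_matches_formula_ratios(self, two_input_basis):
        p = NetworkParams(two_input_basis, dt=FAST_DT)
        ratios = []
        for s1, s2 in [(150.0, 50.0), (60.0, 90.0), (200.0, 10.0)]:
            st, _ = simulate_to_steady_state(p, np.array([s1, s2]), tol=1e-9)
            ratios.append(st.r_exc[0] / steady_state_two_unit(s1, s2, 1.0))
        assert np.ptp(ratios) / np.mean(ratios) < 1e-3


class TestTemporalMetrics:
    def _ramp_trace(self):
        t = np.linspace(0, 1, 101)
        y = t.copy()
        return TraceRecord(t, y[:, None], np.zeros((101, 1)))

    def test_half_rise_of_linear_ramp(self):
        assert time_to_fraction(self._ramp_trace(), 0, 0.5) == pytest.approx(0.5)

    def test_fraction_one_returns_time_of_max(self):
        assert time_to_fraction(self._ramp_trace(), 0, 1.0) == pytest.approx(1.0)

    def test_never_crossing_flagged_as_nan(self):
        tr = TraceRecord(np.arange(3.0), np.zeros((3, 1)), np.zeros((3, 1)))
        assert np.isnan(time_to_fraction(tr, 0, 0.7))

    def test_divisive_peak_latency_decreases_with_amplitude(self, two_input_basis):
        p = NetworkParams(two_input_basis, dt=1e-4 * 0.08)
        tts = []
        for amp in (50.0, 100.0, 200.0):
            tr = simulate(p, np.array([amp, 0.0]), duration=1.0, record_every=1e-3)
            tts.append(time_to_peak(tr, 0, "exc"))
        assert tts[0] > tts[1] > tts[2]

    def test_wavefront_uses_first_substantial_peak(self):
        t = np.linspace(0, 1, 201)
        # front peak at 0.2 (height 1), late slow hump at 0.8 (height 2)
        y = np.exp(-((t - 0.2) / 0.05) ** 2) + 2 * np.exp(-((t - 0.8) / 0.1) ** 2)
        tr = TraceRecord(t, y[:, None], np.zeros((201, 1)))
        assert wavefront_latency(tr, 0, 0.7) < 0.2
        assert time_to_fraction(tr, 0, 0.7) > 0.7


class TestBookkeeping:
    def test_record_every_equal_to_duration_gives_one_row_plus_initial(self,
                                                                       two_input_basis):
        p = NetworkParams(two_input_basis, dt=FAST_DT)
        tr = simulate(p, np.array([100.0, 0.0]), duration=0.2, record_every=0.2)
        assert tr.r_exc.shape[0] == 2
        assert tr.times[0] == 0.0

    def test_simulation_is_deterministic(self, two_input_basis):
        p = NetworkParams(two_input_basis, dt=FAST_DT)
        a = simulate(p, np.array([120.0, 30.0]), duration=0.3, record_every=1e-2)
        b = simulate(p, np.array([120.0, 30.0]), duration=0.3, record_every=1e-2)
        assert np.array_equal(a.r_exc, b.r_exc)
        assert np.array_equal(a.r_inh, b.r_inh)

    def test_callable_input_matches_constant_fast_path(self, two_input_basis):
        p = NetworkParams(two_input_basis, dt=1e-3 * 0.08)
        s = np.array([100.0, 20.0])
        a = simulate(p, s, duration=0.05, record_every=1e-2)
        b = simulate(p, lambda t: s, duration=0.05, record_every=1e-2)
        assert np.allclose(a.r_exc, b.r_exc, atol=1e-10)
        assert np.allclose(a.r_inh, b.r_inh, atol=1e-10)

    def test_divisive_rates_stay_nonnegative(self, rng):
        b = random_basis(rng, 5, 2, background=1.0)
        p = NetworkParams(b, dt=FAST_DT)
        tr = simulate(p, rng.uniform(0, 150, 5), duration=0.5, record_every=1e-2)
        assert np.all(tr.r_exc >= 0) and np.all(tr.r_inh >= 0)

    def test_trace_validation(self):
        with pytest.raises(ValueError, match="monotone"):
            TraceRecord(np.array([0.0, 1.0, 0.5]), np.zeros((3, 1)), np.zeros((3, 1)))
        with pytest.raises(ValueError, match="row"):
            TraceRecord(np.arange(2.0), np.zeros((3, 1)), np.zeros((3, 1)))
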