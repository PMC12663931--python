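"""Efficacy models and the Tsodyks-Markram state recursions."""

import numpy as np
import pytest

from tempostp.neuron import NeuronConfig, simulate_response
from tempostp.patterns import SpikePattern, expand_to_ordered_single_spike
from tempostp.synapses import (
    OrdinalParams,
    SignConstrainedParams,
    StaticParams,
    TMParams,
    instantaneous_efficacies,
    tm_state_sequence,
)

from helpers import voltage_at


def tm_reference(ts, U, tr, tf):
    """Plain-Python reference recursion (complex-capable for derivative checks)."""
    u, x = [1.0 + 0j], [1.0 + 0j]
    for j in range(1, len(ts)):
        dt = ts[j] - ts[j - 1]
        ef, er = np.exp(-dt / tf), np.exp(-dt / tr)
        u.append(u[-1] * (1 - U) * ef + 1)
        x.append(x[-1] * (1 - U * u[-2]) * er + 1 - er)
    return np.array(u), np.array(x)


class TestTMStateSequence:
    def test_first_spike_baseline_and_zero_partials(self):
        st = tm_state_sequence(np.array([0.123]), 0.3, 0.2, 0.1,
                               with_partials=True)
        assert st.u[0] == 1.0 and st.x[0] == 1.0
        for p in (st.du_dU, st.dx_dU, st.dx_dtau_rec, st.du_dtau_fac,
                  st.dx_dtau_fac):
            assert p[0] == 0.0

    def test_full_utilization_kills_facilitation(self):
        ts = np.arange(5) * 0.02
        st = tm_state_sequence(ts, 1.0, 0.1, 0.1)
        np.testing.assert_allclose(st.u, 1.0)

    def test_worked_two_spike_values(self):
        st = tm_state_sequence(np.array([0.0, 0.02]), 0.5, 0.1, 0.1)
        assert st.u[1] == pytest.approx(1.409365, abs=1e-5)
        assert st.x[1] == pytest.approx(0.590634, abs=1e-5)
        # product of the hand-derived factors: 1.409365 * 0.590634
        assert st.u[1] * st.x[1] == pytest.approx(0.832419, abs=1e-5)

    def test_long_interval_recovers_baseline(self):
        st = tm_state_sequence(np.array([0.0, 50.0]), 0.7, 0.2, 0.3)
        assert st.u[1] == pytest.approx(1.0, abs=1e-12)
        assert st.x[1] == pytest.approx(1.0, abs=1e-12)

    def test_matches_reference_recursion(self, rng):
        ts = np.sort(rng.uniform(0, 0.5, 8))
        st = tm_state_sequence(ts, 0.4, 0.15, 0.08)
        u_ref, x_ref = tm_reference(ts, 0.4, 0.15, 0.08)
        np.testing.assert_allclose(st.u, u_ref.real, rtol=1e-12)
        np.testing.assert_allclose(st.x, x_ref.real, rtol=1e-12)

    @pytest.mark.parametrize("param", ["U", "tau_rec", "tau_fac"])
    def test_partials_match_complex_step(self, rng, param):
        ts = np.sort(rng.uniform(0, 0.4, 6))
        U, tr, tf = 0.6, 0.07, 0.04
        st = tm_state_sequence(ts, U, tr, tf, with_partials=True)
        h = 1e-25
        args = {"U": U, "tau_rec": tr, "tau_fac": tf}
        args[param] = args[param] + 1j * h
        u_c, x_c = tm_reference(ts, args["U"], args["tau_rec"], args["tau_fac"])
        if param == "U":
            np.testing.assert_allclose(st.du_dU, u_c.imag / h, rtol=1e-9, atol=1e-12)
            np.testing.assert_allclose(st.dx_dU, x_c.imag / h, rtol=1e-9, atol=1e-12)
        elif param == "tau_rec":
            np.testing.assert_allclose(st.dx_dtau_rec, x_c.imag / h, rtol=1e-9,
                                       atol=1e-12)
        else:
            np.testing.assert_allclose(st.du_dtau_fac, u_c.imag / h, rtol=1e-9,
                                       atol=1e-12)
            np.testing.assert_allclose(st.dx_dtau_fac, x_c.imag / h, rtol=1e-9,
                                       atol=1e-12)

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValueError):
            tm_state_sequence(np.array([0.2, 0.1]), 0.5, 0.1, 0.1)

    def test_facilitation_bound_on_periodic_train(self):
        # on a fixed-interval train u converges to a geometric fixed point
        U, tf, dt = 0.3, 0.2, 0.02
        ts = np.arange(50) * dt
        st = tm_state_sequence(ts, U, 1.0, tf)
        q = (1 - U) * np.exp(-dt / tf)
        u_max = 1.0 / (1.0 - q)
        assert np.all(st.u <= u_max + 1e-12)
        assert st.u[-1] == pytest.approx(u_max, rel=1e-6)

    def test_pure_depression_monotone_to_small_steady_state(self):
        ts = np.arange(30) * 0.02  # 50 Hz
        st = tm_state_sequence(ts, 0.99, 2.0, 0.001)
        ux = st.u * st.x
        assert np.all(np.diff(ux) < 1e-12)
        assert ux[-1] < 0.1 * ux[0]


class TestEfficacyModels:
    def test_static_ignores_rank_and_time(self, small_pattern):
        params = StaticParams(np.arange(6, dtype=float))
        eff = instantaneous_efficacies(small_pattern, "static", params)
        for i, e in enumerate(eff):
            np.testing.assert_array_equal(e, np.full(4, float(i)))

    def test_sign_constrained_uniform_z(self, small_pattern, rng):
        omega = rng.normal(0, 1, 6)
        params = SignConstrainedParams(omega, np.ones((6, 4)))
        eff = instantaneous_efficacies(small_pattern, "sign_constrained", params)
        for i, e in enumerate(eff):
            np.testing.assert_allclose(e, omega[i] / 4)

    def test_tm_single_spike_equals_static(self, rng):
        pat = SpikePattern(0.5, [rng.uniform(0, 0.5, 1) for _ in range(5)], 1)
        omega = rng.normal(0, 1, 5)
        tm = TMParams(omega, rng.uniform(0.1, 0.9, 5),
                      rng.uniform(0.05, 1, 5), rng.uniform(0.05, 1, 5))
        eff = instantaneous_efficacies(pat, "tm", tm)
        for i, e in enumerate(eff):
            assert e[0] == pytest.approx(omega[i])

    def test_ordinal_equals_static_on_expanded_pattern(self, neuron_cfg, kernel, rng):
        # the rank-order expansion maps ordinal synapses exactly onto static ones
        for trial in range(5):
            pat = SpikePattern(
                0.5, [np.sort(rng.uniform(0, 0.5, 3)) for _ in range(4)], 3)
            w = rng.normal(0, 1, (4, 3))
            exp = expand_to_ordered_single_spike(pat)
            eff_ord = instantaneous_efficacies(pat, "ordinal", OrdinalParams(w))
            eff_static = instantaneous_efficacies(
                exp, "static", StaticParams(w.reshape(-1)))
            tt = np.linspace(0, 0.6, 500)
            v_ord = voltage_at(pat, eff_ord, kernel, tt)
            v_static = voltage_at(exp, eff_static, kernel, tt)
            np.testing.assert_allclose(v_ord, v_static, rtol=1e-10, atol=1e-12)

    def test_rank_overflow_rejected(self, small_pattern):
        with pytest.raises(ValueError):
            instantaneous_efficacies(small_pattern, "ordinal",
                                     OrdinalParams(np.zeros((6, 2))))

    def test_all_zero_z_rejected(self):
        with pytest.raises(ValueError):
            SignConstrainedParams(np.ones(2), np.zeros((2, 3)))

    def test_mismatched_params_rejected(self, small_pattern):
        with pytest.raises(ValueError):
            instantaneous_efficacies(small_pattern, "static",
                                     StaticParams(np.zeros(3)))
        with pytest.raises(ValueError):
            instantaneous_efficacies(small_pattern, "nope", None)
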