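"""Voltage gradients, momentum rules and batch training."""

import numpy as np
import pytest

from tempostp.learning import (
    LearnConfig,
    UpdateState,
    apply_update,
    init_params,
    train_until_convergence,
    voltage_gradient_sign_constrained,
    voltage_gradient_static,
    voltage_gradient_tm,
)
from tempostp.neuron import NeuronConfig, simulate_response
from tempostp.patterns import PatternBatch, SpikePattern, gen_latency_batch
from tempostp.synapses import (
    OrdinalParams,
    SignConstrainedParams,
    StaticParams,
    TMParams,
    instantaneous_efficacies,
)

from helpers import voltage_at


def random_pattern(rng, n_aff=6, n_spk=4, T=0.5):
    return SpikePattern(T, [np.sort(rng.uniform(0, T, n_spk))
                            for _ in range(n_aff)], n_spk)


def random_tm(rng, n_aff=6):
    return TMParams(rng.normal(0, 2, n_aff), rng.uniform(0.1, 0.95, n_aff),
                    np.exp(rng.uniform(np.log(0.02), 0, n_aff)),
                    np.exp(rng.uniform(np.log(0.02), 0, n_aff)))


def fd_check(value_fn, arr, analytic, h_rel=1e-5, tol=1e-4):
    """Central finite differences vs analytic gradient, mixed rel/abs criterion."""
    fd = np.zeros_like(np.asarray(arr, float))
    it = np.nditer(fd, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        h = h_rel * max(abs(arr[idx]), 1.0)
        orig = arr[idx]
        arr[idx] = orig + h
        vp = value_fn()
        arr[idx] = orig - h
        vm = value_fn()
        arr[idx] = orig
        fd[idx] = (vp - vm) / (2 * h)
    denom = np.maximum(np.maximum(np.abs(fd), np.abs(analytic)), 1e-6)
    assert np.max(np.abs(fd - analytic) / denom) < tol


class TestGradientOracle:
    """Finite-difference equivalence: the load-bearing correctness gate."""

    def test_static_gradient_matches_fd(self, kernel, neuron_cfg):
        rng = np.random.default_rng(0)
        for _ in range(10):
            pat = random_pattern(rng)
            params = StaticParams(rng.normal(0, 2, 6))
            eff = instantaneous_efficacies(pat, "static", params)
            tmax = simulate_response(pat, eff, neuron_cfg, with_reset=False).t_max
            g = voltage_gradient_static(pat, params, tmax, kernel)

            def V():
                eff = instantaneous_efficacies(pat, "static", params)
                return voltage_at(pat, eff, kernel, tmax)

            fd_check(V, params.omega, g)

    def test_ordinal_gradient_matches_fd(self, kernel, neuron_cfg):
        rng = np.random.default_rng(1)
        for _ in range(5):
            pat = random_pattern(rng)
            params = OrdinalParams(rng.normal(0, 2, (6, 4)))
            eff = instantaneous_efficacies(pat, "ordinal", params)
            tmax = simulate_response(pat, eff, neuron_cfg, with_reset=False).t_max
            g = voltage_gradient_static(pat, params, tmax, kernel)

            def V():
                eff = instantaneous_efficacies(pat, "ordinal", params)
                return voltage_at(pat, eff, kernel, tmax)

            fd_check(V, params.omega, g)

    def test_sign_constrained_gradients_match_fd(self, kernel, neuron_cfg):
        rng = np.random.default_rng(2)
        for _ in range(10):
            pat = random_pattern(rng)
            params = SignConstrainedParams(rng.normal(0, 2, 6),
                                           rng.uniform(0.2, 1.5, (6, 4)))
            eff = instantaneous_efficacies(pat, "sign_constrained", params)
            tmax = simulate_response(pat, eff, neuron_cfg, with_reset=False).t_max
            g_w, g_z, _ = voltage_gradient_sign_constrained(pat, params, tmax,
                                                            kernel)

            def V():
                eff = instantaneous_efficacies(pat, "sign_constrained", params)
                return voltage_at(pat, eff, kernel, tmax)

            fd_check(V, params.omega, g_w)
            fd_check(V, params.z, g_z)

    @pytest.mark.parametrize("component", ["omega", "U", "tau_rec", "tau_fac"])
    def test_tm_gradients_match_fd(self, kernel, neuron_cfg, component):
        rng = np.random.default_rng(3)
        for _ in range(10):
            pat = random_pattern(rng)
            params = random_tm(rng)
            eff = instantaneous_efficacies(pat, "tm", params)
            tmax = simulate_response(pat, eff, neuron_cfg, with_reset=False).t_max
            g_w, g_U, g_r, g_f, _ = voltage_gradient_tm(pat, params, tmax, kernel)
            g = {"omega": g_w, "U": g_U, "tau_rec": g_r, "tau_fac": g_f}[component]

            def V():
                eff = instantaneous_efficacies(pat, "tm", params)
                return voltage_at(pat, eff, kernel, tmax)

            fd_check(V, getattr(params, component), g)

    def test_uniform_z_equal_kernel_values_cancel(self, kernel):
        # all spikes at equal kernel value and uniform z: dV/dz vanishes exactly
        d = 0.05
        pat = SpikePattern(0.5, [np.array([0.1, 0.1]), np.array([0.2, 0.2])], 2)
        params = SignConstrainedParams(np.array([1.5, -2.0]), np.ones((2, 2)))
        tmax = 0.25
        g_w, g_z, _ = voltage_gradient_sign_constrained(pat, params, tmax, kernel)
        np.testing.assert_allclose(g_z, 0.0, atol=1e-12)

    def test_single_spike_special_cases(self, kernel):
        rng = np.random.default_rng(4)
        pat = SpikePattern(0.5, [rng.uniform(0.0, 0.3, 1) for _ in range(3)], 1)
        tmax = 0.45
        sc = SignConstrainedParams(rng.normal(0, 1, 3), np.ones((3, 1)))
        g_w, g_z, _ = voltage_gradient_sign_constrained(pat, sc, tmax, kernel)
        from tempostp.neuron import psp_kernel
        expected = [psp_kernel(tmax - pat.times[i][0], kernel) for i in range(3)]
        np.testing.assert_allclose(g_w, expected, rtol=1e-12)
        np.testing.assert_allclose(g_z, 0.0, atol=1e-12)
        tm = random_tm(rng, 3)
        g_w, g_U, g_r, g_f, _ = voltage_gradient_tm(pat, tm, tmax, kernel)
        np.testing.assert_allclose(g_w, expected, rtol=1e-12)
        for g in (g_U, g_r, g_f):
            np.testing.assert_allclose(g, 0.0, atol=1e-12)

    def test_afferent_silent_before_tmax_has_zero_gradient(self, kernel):
        pat = SpikePattern(0.5, [np.array([0.1]), np.array([0.4])], 1)
        params = StaticParams(np.array([1.0, 1.0]))
        g = voltage_gradient_static(pat, params, 0.2, kernel)
        assert g[1] == 0.0 and g[0] > 0.0


class TestMomentumRules:
    def test_static_zero_gradient_leaves_weight_and_memory(self):
        params = StaticParams(np.array([0.5, -0.5]))
        state = UpdateState.zeros_like(params)
        state.prev["omega"][:] = [0.1, 0.2]
        g = np.array([0.3, 0.0])
        cfg = LearnConfig(eta_omega=0.01, mu=0.5)
        apply_update(params, g, +1, cfg, state)
        assert params.omega[0] == pytest.approx(0.5 + 0.01 * 0.3 + 0.5 * 0.1)
        assert state.prev["omega"][0] == pytest.approx(0.01 * 0.3 + 0.5 * 0.1)
        # zero-gradient entry: weight and previous update untouched
        assert params.omega[1] == -0.5
        assert state.prev["omega"][1] == 0.2

    def test_zero_momentum_is_pure_gradient_step(self):
        params = StaticParams(np.array([1.0]))
        state = UpdateState.zeros_like(params)
        cfg = LearnConfig(eta_omega=0.02, mu=0.0)
        apply_update(params, np.array([2.0]), -1, cfg, state)
        assert params.omega[0] == pytest.approx(1.0 - 0.02 * 2.0)

    def test_tm_momentum_fires_on_active_afferent_with_zero_gradient(self):
        params = TMParams(np.ones(2), np.full(2, 0.5), np.full(2, 0.1),
                          np.full(2, 0.1))
        state = UpdateState.zeros_like(params)
        state.prev["U"][:] = [0.01, 0.01]
        # afferent 0 active with zero dV/dU this trial; afferent 1 inactive
        grads = (np.array([0.5, 0.4]), np.zeros(2), np.zeros(2), np.zeros(2))
        cfg = LearnConfig(eta_omega=0.0, eta_u=0.0, eta_tau=0.0, mu=0.5)
        apply_update(params, grads, +1, cfg, state,
                     active_mask=np.array([True, False]))
        assert params.U[0] == pytest.approx(0.5 + 0.5 * 0.01)
        assert params.U[1] == 0.5
        assert state.prev["U"][1] == 0.01

    def test_tm_projection_bounds(self):
        params = TMParams(np.ones(1), np.array([0.99]), np.array([0.002]),
                          np.array([9.5]))
        state = UpdateState.zeros_like(params)
        grads = (np.zeros(1), np.ones(1), -np.ones(1), np.ones(1))
        cfg = LearnConfig(eta_omega=0.0, eta_u=1.0, eta_tau=1.0, mu=0.0)
        apply_update(params, grads, +1, cfg, state, active_mask=np.ones(1, bool))
        assert params.U[0] == 1.0
        assert params.tau_rec[0] == pytest.approx(1e-3)
        assert params.tau_fac[0] == pytest.approx(10.0)

    def test_single_step_improves_missed_target(self, kernel, neuron_cfg):
        rng = np.random.default_rng(5)
        for model in ("static", "tm"):
            pat = random_pattern(rng)
            params = (StaticParams(rng.normal(0, 0.05, 6)) if model == "static"
                      else random_tm(rng))
            eff = instantaneous_efficacies(pat, model, params)
            resp = simulate_response(pat, eff, neuron_cfg, with_reset=False)
            v_before = voltage_at(pat, eff, kernel, resp.t_max)
            state = UpdateState.zeros_like(params)
            cfg = LearnConfig(eta_omega=1e-4, eta_u=1e-5, eta_tau=1e-5, mu=0.0)
            if model == "static":
                g = voltage_gradient_static(pat, params, resp.t_max, kernel)
                apply_update(params, g, +1, cfg, state)
            else:
                g_w, g_U, g_r, g_f, act = voltage_gradient_tm(
                    pat, params, resp.t_max, kernel)
                apply_update(params, (g_w, g_U, g_r, g_f), +1, cfg, state,
                             active_mask=act)
            eff2 = instantaneous_efficacies(pat, model, params)
            v_after = voltage_at(pat, eff2, kernel, resp.t_max)
            assert v_after > v_before


class TestTraining:
    def test_all_null_silent_start_is_presolved(self):
        batch = gen_latency_batch(8, 1, 0.5, 1.0, seed=6)
        batch = PatternBatch(batch.patterns, np.zeros(len(batch), dtype=np.int8))
        params = StaticParams(np.zeros(8))
        res = train_until_convergence(batch, "static", params,
                                      LearnConfig(max_epochs=50, seed=0))
        assert res.convergence_epochs == 0
        assert res.converged

    def test_single_target_pattern_converges_fast(self):
        batch = gen_latency_batch(10, 1, 0.5, 0.1, seed=7)
        batch = PatternBatch(batch.patterns, np.ones(len(batch), dtype=np.int8))
        params = init_params("static", 10, 1, seed=8)
        # adequate learning rate for a single stored pattern
        res = train_until_convergence(batch, "static", params,
                                      LearnConfig(eta_omega=5e-3,
                                                  max_epochs=200, seed=1))
        assert res.converged and res.convergence_epochs < 50

    @pytest.mark.parametrize("model", ["static", "ordinal", "sign_constrained",
                                       "tm"])
    def test_all_models_converge_below_capacity(self, model):
        batch = gen_latency_batch(20, 2, 0.5, 0.5, seed=9)
        params = init_params(model, 20, 2, seed=10)
        res = train_until_convergence(batch, model, params,
                                      LearnConfig(max_epochs=2000, seed=2))
        assert res.converged, f"{model} failed to converge at load 0.5"
        assert res.error_history[-1] == 0

    def test_far_above_capacity_hits_cutoff(self):
        batch = gen_latency_batch(20, 1, 0.5, 20.0, seed=11)
        params = init_params("static", 20, 1, seed=12)
        res = train_until_convergence(batch, "static", params,
                                      LearnConfig(max_epochs=30, seed=3))
        assert not res.converged
        assert res.convergence_epochs == 30

    def test_ordinal_and_expanded_static_trajectories_identical(self):
        """Ordinal training on multi-spike patterns == static training on the
        rank-expanded patterns: identical final weights and error history."""
        from tempostp.patterns import expand_to_ordered_single_spike

        batch = gen_latency_batch(8, 3, 0.5, 1.0, seed=13)
        w0 = np.random.default_rng(14).normal(0, 0.02, (8, 3))
        cfg = LearnConfig(max_epochs=500, seed=4, eta_omega=1e-3)
        res_ord = train_until_convergence(batch, "ordinal", OrdinalParams(w0),
                                          cfg)
        expanded = PatternBatch(
            [expand_to_ordered_single_spike(p) for p in batch.patterns],
            batch.labels)
        # same kernel: the expanded task must keep the original integration
        # scale (N*nspikes spikes in both representations)
        from tempostp.learning import default_neuron_config
        ncfg = default_neuron_config(8, 3, 0.5)
        res_sta = train_until_convergence(expanded, "static",
                                          StaticParams(w0.reshape(-1)), cfg,
                                          neuron_config=ncfg)
        np.testing.assert_allclose(res_ord.params.omega.reshape(-1),
                                   res_sta.params.omega, rtol=1e-10)
        np.testing.assert_array_equal(res_ord.error_history,
                                      res_sta.error_history)

    def test_identical_seed_identical_trajectory(self):
        batch = gen_latency_batch(10, 2, 0.5, 1.0, seed=15)
        outs = []
        for _ in range(2):
            params = init_params("tm", 10, 2, seed=16)
            res = train_until_convergence(batch, "tm", params,
                                          LearnConfig(max_epochs=300, seed=5))
            outs.append(res)
        np.testing.assert_array_equal(outs[0].params.omega, outs[1].params.omega)
        np.testing.assert_array_equal(outs[0].error_history,
                                      outs[1].error_history)

    def test_frozen_parameters_stay_put(self):
        batch = gen_latency_batch(10, 3, 0.5, 1.0, seed=17)
        params = init_params("tm", 10, 3, seed=18)
        U0 = params.U.copy()
        tr0 = params.tau_rec.copy()
        cfg = LearnConfig(max_epochs=300, seed=6, train=("omega", "tau_fac"))
        res = train_until_convergence(batch, "tm", params, cfg)
        np.testing.assert_array_equal(res.params.U, U0)
        np.testing.assert_array_equal(res.params.tau_rec, tr0)
        assert not np.array_equal(res.params.omega, params.omega)
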