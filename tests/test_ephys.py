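"""12-pulse STP protocol statistics, quality control and TM fitting."""

import numpy as np
import pytest

from tempostp.ephys import (
    PROTOCOL_TIMES,
    ConnectionRecording,
    QCRejection,
    compare_distributions,
    fit_tm_to_connection,
    population_stp,
    qc_and_amplitudes,
    simulate_protocol_amplitudes,
    stp_measures,
    synth_connection_generator,
)
from tempostp.synapses import TMParams


class TestProtocol:
    def test_pulse_times(self):
        np.testing.assert_allclose(
            PROTOCOL_TIMES,
            [0.0, 0.02, 0.04, 0.06, 0.08, 0.10, 0.12, 0.14,
             0.39, 0.41, 0.43, 0.45])

    def test_strong_depression_collapses_second_pulse(self):
        A = simulate_protocol_amplitudes((1.0, 1.0, 10.0, 1e-3))
        assert A[1] < 0.05 * A[0]

    def test_instant_recovery_restores_baseline(self):
        A = simulate_protocol_amplitudes((2.0, 0.5, 1e-3, 1e-3))
        np.testing.assert_allclose(A, 2.0, rtol=1e-6)

    def test_worked_paired_pulse_ratio(self):
        # U=0.5, tau_rec=tau_fac=0.1 s at 20 ms spacing
        A = simulate_protocol_amplitudes((1.0, 0.5, 0.1, 0.1))
        assert A[1] / A[0] == pytest.approx(0.832419, abs=1e-5)


class TestSTPMeasures:
    def test_constant_amplitudes_give_zero(self):
        ind, rec = stp_measures(np.full(12, 3.0))
        assert ind == 0.0 and rec == 0.0

    def test_worked_example(self):
        A = [1.0, .8, .6, .5, .45, .4, .4, .4, .9, .85, .8, .75]
        ind, rec = stp_measures(A)
        assert ind == pytest.approx(-0.6)
        assert rec == pytest.approx(0.1)

    def test_full_depression_reaches_lower_bound(self):
        A = np.zeros(12)
        A[0] = 1.0
        ind, rec = stp_measures(A)
        assert ind == pytest.approx(-1.0)

    def test_rescaling_invariance(self):
        rng = np.random.default_rng(0)
        A = rng.uniform(0.1, 1.0, 12)
        base = stp_measures(A)
        for s in (0.3, 7.0):
            assert stp_measures(s * A) == pytest.approx(base)

    @pytest.mark.parametrize("sign", [1.0, -1.0])
    def test_bounded_for_both_polarities(self, sign):
        rng = np.random.default_rng(1)
        for _ in range(200):
            A = sign * rng.uniform(0.01, 1.0, 12)
            ind, rec = stp_measures(A)
            assert -1.0 <= ind <= 1.0
            assert -1.0 <= rec <= 1.0

    def test_zero_amax_rejected(self):
        with pytest.raises(ValueError):
            stp_measures(np.zeros(12))


class TestQC:
    def make_rec(self, A, n_trials=6, polarity="excitatory"):
        return ConnectionRecording(np.tile(A, (n_trials, 1)), polarity)

    def test_clean_excitatory_accepted(self):
        A = np.linspace(1.0, 0.4, 12)
        meas = qc_and_amplitudes(self.make_rec(A))
        np.testing.assert_allclose(meas.A, A)
        assert meas.A_max == pytest.approx(1.0)

    def test_sign_inconsistent_rejected(self):
        A = -np.linspace(1.0, 0.4, 12)
        with pytest.raises(QCRejection, match="negative mean"):
            qc_and_amplitudes(self.make_rec(A, polarity="excitatory"))
        with pytest.raises(QCRejection, match="positive mean"):
            qc_and_amplitudes(self.make_rec(-A, polarity="inhibitory"))

    def test_too_few_trials_rejected(self):
        A = np.linspace(1.0, 0.4, 12)
        trials = np.tile(A, (5, 1))
        trials[0:2, 3] = np.nan  # pulse 4 left with 3 valid trials
        rec = ConnectionRecording(trials, "excitatory")
        with pytest.raises(QCRejection, match="pulse 4"):
            qc_and_amplitudes(rec, min_trials=4)

    def test_qc_flag_respected(self):
        A = np.linspace(1.0, 0.4, 12)
        rec = self.make_rec(A)
        rec.qc_pass = False
        with pytest.raises(QCRejection):
            qc_and_amplitudes(rec)


class TestFit:
    def test_recovers_generating_parameters(self):
        truth = (3.0, 0.4, 0.3, 0.08)
        A = simulate_protocol_amplitudes(truth)
        fit = fit_tm_to_connection(A)
        assert fit.n_starts == 378
        assert fit.params.omega[0] == pytest.approx(truth[0], rel=0.01)
        assert fit.params.U[0] == pytest.approx(truth[1], abs=0.02)
        assert fit.params.tau_rec[0] == pytest.approx(truth[2], rel=0.10)
        assert fit.params.tau_fac[0] == pytest.approx(truth[3], rel=0.10)
        # composed forward model reproduces the STP statistics
        ind, rec = stp_measures(A)
        assert fit.stp_ind == pytest.approx(ind, abs=1e-3)
        assert fit.stp_rec == pytest.approx(rec, abs=1e-3)

    def test_constant_amplitudes_fit_with_no_stp(self):
        fit = fit_tm_to_connection(np.full(12, 1.5))
        assert fit.mse < 1e-8
        assert abs(fit.stp_ind) < 1e-3 and abs(fit.stp_rec) < 1e-3

    def test_nonfinite_amplitudes_rejected(self):
        A = np.full(12, 1.0)
        A[3] = np.nan
        with pytest.raises(ValueError):
            fit_tm_to_connection(A)


class TestKS:
    def test_identical_samples_zero(self):
        a = np.arange(50.0)
        assert compare_distributions(a, a.copy()) == 0.0

    def test_disjoint_supports_one(self):
        assert compare_distributions([1.0, 2.0], [10.0, 11.0]) == 1.0

    def test_matches_ecdf_sweep(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 1000)
        b = rng.normal(0.5, 1, 1000)
        grid = np.sort(np.concatenate([a, b]))
        ecdf_a = np.searchsorted(np.sort(a), grid, side="right") / a.size
        ecdf_b = np.searchsorted(np.sort(b), grid, side="right") / b.size
        d_brute = np.max(np.abs(ecdf_a - ecdf_b))
        assert compare_distributions(a, b) == pytest.approx(d_brute, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_distributions([], [1.0])


class TestSynthetic:
    def test_zero_noise_medians_exact(self):
        truth = TMParams([2.0], [0.5], [0.2], [0.05])
        rec = synth_connection_generator(truth, n_trials=8, trial_noise_sd=0.0,
                                         seed=3)
        meas = qc_and_amplitudes(rec)
        np.testing.assert_allclose(meas.A, simulate_protocol_amplitudes(truth))

    def test_inhibitory_polarity_and_qc(self):
        truth = TMParams([-2.5], [0.6], [0.15], [0.05])
        rec = synth_connection_generator(truth, n_trials=10,
                                         trial_noise_sd=0.0, seed=4)
        assert rec.polarity == "inhibitory"
        meas = qc_and_amplitudes(rec)
        assert np.all(meas.A < 0)

    def test_end_to_end_noisy_recovery(self):
        truth = (4.0, 0.35, 0.25, 0.06)
        A_true = simulate_protocol_amplitudes(truth)
        rec = synth_connection_generator(
            TMParams([truth[0]], [truth[1]], [truth[2]], [truth[3]]),
            n_trials=50, trial_noise_sd=0.1 * abs(A_true[0]), seed=5)
        meas = qc_and_amplitudes(rec)
        fit = fit_tm_to_connection(meas.A)
        assert fit.params.omega[0] == pytest.approx(truth[0], rel=0.1)
        assert fit.params.U[0] == pytest.approx(truth[1], abs=0.1)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            synth_connection_generator(TMParams([1.0], [0.5], [0.1], [0.1]),
                                       n_trials=3)


class TestPopulationPipeline:
    def test_polarity_split_and_stp_signs(self):
        # strongly depressing excitatory + facilitating inhibitory synapses
        params = TMParams([3.0, -3.0], [0.95, 0.1], [1.5, 0.05],
                          [1e-3, 0.5])
        df = population_stp(params)
        assert set(df["polarity"]) == {"excitatory", "inhibitory"}
        dep = df[df["omega"] > 0].iloc[0]
        fac = df[df["omega"] < 0].iloc[0]
        assert dep["stp_ind"] <= 0
        assert fac["stp_ind"] >= 0
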