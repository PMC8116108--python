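"""System identification: harmonic extraction, fitting, delay estimation."""

import numpy as np
import pytest

from soundpursuit import APSParameters
from soundpursuit.identify import (
    estimate_subject_delay,
    fit_session,
    fit_trial,
    fitted_transfer_at_harmonics,
    goodness_of_fit,
    harmonic_transfer,
    predict_response,
)
from soundpursuit.lti import step_response, transfer_function
from soundpursuit.simulate import TrialRecord, simulate_trial
from soundpursuit.stimulus import TrajectoryTrace, generate_stimulus, trial_set
from soundpursuit.simulate import SyntheticSubjectConfig, simulate_session


def _record(stimulus, head_pos, spec):
    head = stimulus.with_position(head_pos, role="head")
    return TrialRecord("S1", 1, stimulus, head, spec=spec)


class TestHarmonicTransfer:
    def test_identity_response(self, spec, stimulus):
        rec = _record(stimulus, stimulus.position.copy(), spec)
        ht = harmonic_transfer(rec, spec)
        np.testing.assert_allclose(ht.gain, 1.0, rtol=1e-12)
        np.testing.assert_allclose(ht.phase, 0.0, atol=1e-9)

    def test_pure_delay_phase(self, spec, stimulus):
        # shift theorem: integer-sample circular delay of a periodic trace
        k = 33  # 0.3 s at 110 Hz
        tau = k * stimulus.dt
        rec = _record(stimulus, np.roll(stimulus.position, k), spec)
        ht = harmonic_transfer(rec, spec)
        np.testing.assert_allclose(ht.gain, 1.0, rtol=1e-10)
        expected = -np.mod(360.0 * spec.frequencies * tau, 360.0)
        np.testing.assert_allclose(ht.phase, expected, atol=1e-6)

    def test_noise_free_trial_matches_model_transfer(self, spec, stimulus):
        params = APSParameters(0.6, 0.5, t_d=0.05)
        rec = simulate_trial(stimulus, params, noise_sd=0.0, spec=spec, warmup_periods=1)
        ht = harmonic_transfer(rec, spec)
        h = transfer_function(params, spec.frequencies)
        np.testing.assert_allclose(ht.gain, np.abs(h), rtol=5e-3)

    def test_unusable_harmonic_flagged(self, spec):
        # stimulus missing one harmonic: that bin is flagged, not divided by ~0
        weak = generate_stimulus(spec, seed=3)
        fft = np.fft.rfft(weak.position)
        fft[7] = 0.0  # multiplier 7 -> 0.35 Hz
        pos = np.fft.irfft(fft, weak.position.size)
        stim = weak.with_position(pos)
        rec = _record(stim, pos.copy(), spec)
        ht = harmonic_transfer(rec, spec)
        assert not ht.usable[2]
        assert np.isnan(ht.gain[2])
        assert ht.usable[[0, 1, 3, 4]].all()


class TestPredictResponse:
    def test_wideband_allpass_limit(self, spec, stimulus):
        params = APSParameters(12.0, 1.0, t_d=0.0)
        pred = predict_response(params, stimulus)
        interior = slice(110, None)  # onset catch-up from rest excluded
        assert np.max(np.abs(pred.position - stimulus.position)[interior]) < 0.1 * 30

    def test_unit_step_matches_step_response(self, spec):
        # two independent code paths: discrete convolution vs cumulative integral
        dt = 1 / 110.0
        n = 2200
        t = np.arange(n) * dt
        step = TrajectoryTrace(t, np.full(n, 1.0), role="command")
        params = APSParameters(0.6, 0.4, t_d=0.0)
        pred = predict_response(params, step)
        analytic = step_response(params, t)
        assert np.max(np.abs(pred.position - analytic)) < 5e-3 * analytic.max()

    def test_rejects_nyquist_violation(self, spec, stimulus):
        with pytest.raises(ValueError):
            predict_response(APSParameters(60.0, 0.5), stimulus)


class TestGoodnessOfFit:
    def test_identical_traces(self):
        x = np.sin(np.linspace(0, 10, 500))
        r, r2, mse = goodness_of_fit(x, x.copy())
        assert (r, r2, mse) == (pytest.approx(1.0), pytest.approx(1.0), pytest.approx(0.0))

    def test_anticorrelated(self):
        x = np.sin(np.linspace(0, 10, 500))
        r, _, _ = goodness_of_fit(x, -x)
        assert r == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning):
            r, r2, _ = goodness_of_fit(np.zeros(10), np.arange(10.0))
        assert np.isnan(r)


class TestFitTrial:
    def test_noise_free_recovery(self, spec, noise_free_trial):
        fit = fit_trial(noise_free_trial, t_d_clamped=0.050, spec=spec)
        assert fit.params.f_c == pytest.approx(0.600, abs=0.006)
        assert fit.params.zeta == pytest.approx(0.500, abs=0.005)
        assert fit.r2 > 0.999
        assert not fit.at_boundary

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_random_parameter_recovery(self, spec, seed):
        # noise-free trials over the operating range: < 2% relative error
        rng = np.random.default_rng(seed)
        f_c = float(rng.uniform(0.3, 1.2))
        zeta = float(rng.uniform(0.2, 2.0))
        stim = generate_stimulus(spec, seed=rng, trial_id=1)
        rec = simulate_trial(stim, APSParameters(f_c, zeta, t_d=0.03), noise_sd=0.0, spec=spec)
        fit = fit_trial(rec, t_d_clamped=0.03, spec=spec)
        assert fit.params.f_c == pytest.approx(f_c, rel=0.02)
        assert fit.params.zeta == pytest.approx(zeta, rel=0.02)

    def test_pure_noise_flagged_low_r2(self, spec, stimulus):
        rng = np.random.default_rng(11)
        rec = _record(stimulus, rng.normal(0, 1, stimulus.position.size), spec)
        fit = fit_trial(rec, t_d_clamped=0.0, spec=spec, grid_shape=(12, 12))
        assert fit.r2 < 0.1

    def test_fitted_model_consistent_across_domains(self, spec, noise_free_trial):
        # transfer function of the fitted model vs FFT of its own prediction
        fit = fit_trial(noise_free_trial, t_d_clamped=0.050, spec=spec)
        pred = predict_response(fit.params, noise_free_trial.stimulus)
        settled = simulate_trial(
            noise_free_trial.stimulus, fit.params, noise_sd=0.0, spec=spec, warmup_periods=1
        )
        ht = harmonic_transfer(settled, spec)
        model = fitted_transfer_at_harmonics(fit, spec)
        np.testing.assert_allclose(ht.gain, model.gain, rtol=5e-3)
        np.testing.assert_allclose(ht.phase, model.phase, atol=0.5)
        # and the measured trace agrees up to the (zero) noise
        assert fit.r2 > 0.999
        assert pred.position.shape == noise_free_trial.head.position.shape


class TestDelayEstimation:
    def test_noise_free_recovery(self, noise_free_session):
        t_d = estimate_subject_delay(noise_free_session[:5])
        assert abs(t_d - 0.050) <= 0.002

    def test_zero_delay_session(self, spec):
        stims = trial_set(3, spec, seed=21)
        cfg = SyntheticSubjectConfig(t_d=0.0, noise_sd=0.0, q_jitter_sd=0.0)
        recs = simulate_session(cfg, stims, seed=22, spec=spec)
        assert estimate_subject_delay(recs) == pytest.approx(0.0, abs=1e-12)

    def test_invariant_to_stimulus_realization(self, spec):
        cfg = SyntheticSubjectConfig(t_d=0.064, noise_sd=0.0, q_jitter_sd=0.0)
        estimates = []
        for seed in (31, 32):
            stims = trial_set(3, spec, seed=seed)
            recs = simulate_session(cfg, stims, seed=seed + 100, spec=spec)
            estimates.append(estimate_subject_delay(recs))
        assert abs(estimates[0] - estimates[1]) <= 0.002
        assert abs(estimates[0] - 0.064) <= 0.002


class TestFitSession:
    def test_matches_fit_trial(self, spec, noise_free_session):
        fits = fit_session(noise_free_session[:2], 0.050, spec=spec)
        solo = fit_trial(noise_free_session[0], 0.050, spec=spec)
        assert fits[0].params.f_c == pytest.approx(solo.params.f_c, rel=1e-6)
        assert fits[0].params.zeta == pytest.approx(solo.params.zeta, rel=1e-6)

    def test_noisy_session_median_r2(self, spec, noisy_session):
        fits = fit_session(noisy_session, 0.030, spec=spec)
        assert np.median([f.r2 for f in fits]) > 0.8
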