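"""Analytic second-order-plus-delay model: responses, peaks, effort."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soundpursuit.lti import (
    APSParameters,
    frequency_response,
    impulse_response,
    kinetic_energy,
    peak_gain,
    q_to_zeta,
    spectral_effort,
    step_response,
    transfer_function,
    zeta_to_q,
)


class TestTransferFunction:
    def test_dc_gain_is_clamped_to_one(self):
        for q in (0.3, 0.5, 1.5):
            h = transfer_function(APSParameters.from_quality(0.6, q, t_d=0.05), 0.0)
            assert h == pytest.approx(1.0)

    def test_gain_at_resonance_equals_q(self):
        # |H(i w_C)| = G0 * Q exactly, independent of the delay
        p = APSParameters.from_quality(0.6, 1.5, t_d=0.02)
        assert abs(transfer_function(p, 0.6)) == pytest.approx(1.5, rel=1e-12)

    def test_critically_damped_max_gain_at_zero(self):
        p = APSParameters.from_quality(0.6, 0.5)
        f = np.linspace(0, 5, 20001)
        gains = np.abs(transfer_function(p, f))
        assert gains.max() == pytest.approx(1.0)
        assert np.argmax(gains) == 0

    def test_rejects_nonfinite_and_negative_frequency(self):
        p = APSParameters(0.6, 0.5)
        with pytest.raises(ValueError):
            transfer_function(p, np.nan)
        with pytest.raises(ValueError):
            transfer_function(p, -0.1)

    def test_delay_only_affects_phase(self):
        p0 = APSParameters(0.6, 0.5, t_d=0.0)
        p1 = APSParameters(0.6, 0.5, t_d=0.080)
        f = np.linspace(0.05, 2, 50)
        np.testing.assert_allclose(
            np.abs(transfer_function(p0, f)), np.abs(transfer_function(p1, f)), rtol=1e-12
        )
        dphi = np.angle(transfer_function(p1, f) / transfer_function(p0, f))
        np.testing.assert_allclose(dphi, -2 * np.pi * f * 0.080, atol=1e-9)


class TestImpulseResponse:
    @pytest.mark.parametrize("zeta", [0.3, 0.5, 1.0, 1.2, 2.0])
    def test_unit_area(self, zeta):
        # DC normalization: integral of h equals G0 = 1; the window covers
        # 50 time constants of the slowest pole (zeta - sqrt(zeta^2-1) for
        # overdamped systems, much slower than zeta itself)
        p = APSParameters(0.6, zeta)
        slow = zeta - np.sqrt(zeta**2 - 1.0) if zeta > 1 else zeta
        t_max = 50.0 / (slow * p.omega_c)
        t = np.linspace(0, t_max, 200001)
        assert np.trapezoid(impulse_response(p, t), t) == pytest.approx(1.0, abs=1e-3)

    @pytest.mark.parametrize("zeta", [0.3, 0.5, 0.83])
    def test_energy_closed_form(self, zeta):
        # integral of h^2 over [0, inf) = w_C / (4 zeta) for underdamped systems
        p = APSParameters(0.6, zeta)
        t = np.linspace(0, 100.0 / (zeta * p.omega_c), 400001)
        quad = np.trapezoid(impulse_response(p, t) ** 2, t)
        assert quad == pytest.approx(p.omega_c / (4 * zeta), rel=5e-3)

    def test_zero_before_delay(self):
        p = APSParameters(0.6, 0.5, t_d=0.1)
        t = np.linspace(0, 0.0999, 50)
        assert np.all(impulse_response(p, t) == 0)

    def test_overdamped_nonnegative_single_peak(self):
        p = APSParameters(0.6, 1.2)
        t = np.linspace(0, 20, 20001)
        h = impulse_response(p, t)
        assert np.all(h >= 0)
        sign_changes = np.sum(np.diff(np.sign(np.diff(h[h > 1e-12]))) != 0)
        assert sign_changes == 1  # one interior maximum

    def test_continuity_at_critical_damping(self):
        p_crit = APSParameters(0.6, 1.0)
        t = np.linspace(0, 10, 2001)
        h_crit = impulse_response(p_crit, t)
        peak = h_crit.max()
        for zeta in (1.0 - 1e-4, 1.0 + 1e-4):
            h = impulse_response(APSParameters(0.6, zeta), t)
            assert np.max(np.abs(h - h_crit)) < 1e-3 * peak

    def test_rejects_negative_time(self):
        with pytest.raises(ValueError):
            impulse_response(APSParameters(0.6, 0.5), [-0.1, 0.0])


class TestStepResponse:
    def test_final_value(self):
        t = np.linspace(0, 10, 4001)
        s = step_response(APSParameters.from_quality(0.6, 0.6), t)
        assert s[-1] == pytest.approx(1.0, abs=1e-3)

    def test_underdamped_overshoot(self):
        # peak overshoot of a 2nd-order step response: 1 + exp(-pi zeta / beta)
        zeta = q_to_zeta(1.5)
        t = np.linspace(0, 15, 8001)
        s = step_response(APSParameters(0.6, zeta), t)
        expected = 1.0 + np.exp(-np.pi * zeta / np.sqrt(1 - zeta**2))
        assert s.max() == pytest.approx(expected, rel=1e-3)
        assert s.max() > 1

    def test_critically_damped_monotone(self):
        t = np.linspace(0, 15, 8001)
        s = step_response(APSParameters.from_quality(0.6, 0.5), t)
        assert np.all(np.diff(s) >= -1e-12)


class TestPeakGain:
    def test_critical_damping_peak_at_dc(self):
        w, g = peak_gain(APSParameters.from_quality(0.6, 0.5))
        assert (w, g) == (0.0, 1.0)

    @pytest.mark.parametrize("q", [0.6, 0.75, 1.0, 1.5, 3.0])
    def test_agrees_with_grid_search(self, q):
        p = APSParameters.from_quality(0.6, q)
        w_max, g_max = peak_gain(p)
        w = np.linspace(0, 5 * p.omega_c, 10001)
        gains = np.abs(transfer_function(p, w / (2 * np.pi)))
        i = int(np.argmax(gains))
        assert abs(w_max - w[i]) <= w[1] - w[0]
        assert g_max == pytest.approx(gains[i], rel=1e-4)

    def test_high_q_limit(self):
        p = APSParameters.from_quality(0.6, 50.0)
        w_max, g_max = peak_gain(p)
        assert w_max == pytest.approx(p.omega_c, rel=1e-3)
        assert g_max == pytest.approx(50.0, rel=1e-3)


class TestEffort:
    def test_kinetic_energy_long_window_matches_closed_form(self):
        for q in (1.5, 0.8):
            p = APSParameters.from_quality(0.6, q)
            d = 100.0 / (p.zeta * p.omega_c)
            assert kinetic_energy(p, d) == pytest.approx(p.omega_c / (4 * p.zeta), rel=5e-3)

    def test_kinetic_energy_rejects_bad_duration(self):
        with pytest.raises(ValueError):
            kinetic_energy(APSParameters(0.6, 0.5), 0.0)

    def test_spectral_effort_monotone_in_q(self):
        efforts = [
            spectral_effort(APSParameters.from_quality(0.6, q), (0.05, 1.05))
            for q in np.arange(1.5, 0.55, -0.1)
        ]
        assert all(a > b for a, b in zip(efforts, efforts[1:]))

    def test_spectral_effort_constant_gain_limit(self):
        # wideband system: gain ~ 1 across the band, effort ~ 1
        p = APSParameters(50.0, 0.7)
        assert spectral_effort(p, (0.05, 1.05)) == pytest.approx(1.0, rel=1e-4)

    def test_spectral_effort_rejects_empty_band(self):
        with pytest.raises(ValueError):
            spectral_effort(APSParameters(0.6, 0.5), (1.0, 1.0))


class TestQZeta:
    def test_known_values(self):
        assert zeta_to_q(0.5) == pytest.approx(1.0)
        assert q_to_zeta(0.5) == pytest.approx(1.0)  # critical damping

    @given(st.floats(min_value=1e-3, max_value=1e3))
    @settings(deadline=None, max_examples=50)
    def test_round_trip(self, value):
        assert q_to_zeta(zeta_to_q(value)) == pytest.approx(value, rel=1e-12)

    def test_rejects_nonpositive(self):
        for bad in (0.0, -1.0, np.nan):
            with pytest.raises(ValueError):
                q_to_zeta(bad)


class TestFrequencyTimeEquivalence:
    def test_fft_of_impulse_matches_transfer(self, spec):
        # long fine grid: FFT of the sampled impulse response vs analytic H
        p = APSParameters(0.6, 0.45, t_d=0.03)
        dt, n = 1 / 440.0, 2**17
        h = impulse_response(p, np.arange(n) * dt) * dt
        hf = np.fft.rfft(h)
        f = np.fft.rfftfreq(n, dt)
        idx = [int(round(fk / f[1])) for fk in spec.frequencies]
        analytic = transfer_function(p, f[idx])
        np.testing.assert_allclose(np.abs(hf[idx]), np.abs(analytic), rtol=0.01)
        np.testing.assert_allclose(np.angle(hf[idx]), np.angle(analytic), atol=0.01)

    def test_frequency_response_container(self):
        fr = frequency_response(APSParameters(0.6, 0.5, t_d=0.05), np.linspace(0, 2, 100))
        assert fr.gain[0] == pytest.approx(1.0)
        assert fr.phase[0] == pytest.approx(0.0)
        assert np.all(fr.phase[1:] < 0)  # causal lag
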