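"""Cross-peak extraction protocol and kinetics tests.

The synthetic exchange series provides the closed-form oracle: in
phenomenological mode the normalized, reference-subtracted cross-peak
trace is proportional to 1 - exp(-T_w/tau_forward).
"""

import numpy as np
import pytest

from chex2dir import (ExchangeGenParams, R, SpectralWindow, arrhenius_fit,
                      cross_peak_trace, extract_forward_kinetics, fit_exchange,
                      normalize_series, reverse_rate, simulate_2dir_series,
                      subtract_reference, window_integral)
from chex2dir.types import Spectrum2DSeries
from conftest import (DG_KJMOL, KINETIC_TEMPS_C, TAU_FORWARD_23C,
                      TAU_FORWARD_PS)


def _scaled(series, c):
    return Spectrum2DSeries(
        omega_tau=series.omega_tau, omega_t=series.omega_t,
        waiting_times=series.waiting_times,
        matrices=[c * m for m in series.matrices],
        temperature=series.temperature)


class TestNormalizeSeries:
    def test_scale_invariance(self, exchange_series_23, norm_window):
        a = normalize_series(exchange_series_23, norm_window)
        b = normalize_series(_scaled(exchange_series_23, 7.3), norm_window)
        for ma, mb in zip(a.matrices, b.matrices):
            np.testing.assert_allclose(ma, mb, atol=1e-12)

    def test_window_integral_is_unity_after_normalization(
            self, exchange_series_23, norm_window):
        normed = normalize_series(exchange_series_23, norm_window)
        axes = (normed.omega_tau, normed.omega_t)
        for m in normed.matrices:
            assert abs(window_integral(axes, m, norm_window)) == pytest.approx(
                1.0, abs=1e-12)

    def test_normalized_diagonal_constant_without_exchange(self, norm_window):
        """With exchange switched off, only lifetime decay remains and
        the normalization divides it out: the diagonal 1->2 magnitude is
        constant in T_w to 1%."""
        params = ExchangeGenParams(tau_forward=1e6, tau_reverse=1e6)
        series = simulate_2dir_series(params)
        normed = normalize_series(series, norm_window)
        axes = (normed.omega_tau, normed.omega_t)
        vals = [window_integral(axes, m, norm_window) for m in normed.matrices]
        vals = np.abs(np.array(vals))
        assert vals.max() / vals.min() < 1.01

    def test_vanishing_window_integral_raises_with_waiting_time(
            self, exchange_series_23):
        empty = SpectralWindow(1561.0, 1566.0, 1561.0, 1566.0)
        with pytest.raises(ValueError, match="T_w"):
            normalize_series(exchange_series_23, empty)


class TestSubtractReference:
    def test_zero_waiting_time_becomes_identically_zero(
            self, exchange_series_23, norm_window):
        diff = subtract_reference(normalize_series(exchange_series_23,
                                                   norm_window))
        np.testing.assert_array_equal(diff.matrix_at(0.0), 0.0)

    def test_static_series_differences_vanish(self, exchange_series_23):
        static = Spectrum2DSeries(
            omega_tau=exchange_series_23.omega_tau,
            omega_t=exchange_series_23.omega_t,
            waiting_times=exchange_series_23.waiting_times,
            matrices=[exchange_series_23.matrices[0]]
            * len(exchange_series_23.matrices))
        diff = subtract_reference(static)
        for m in diff.matrices:
            np.testing.assert_array_equal(m, 0.0)

    def test_missing_reference_rejected(self, exchange_series_23):
        with pytest.raises(ValueError, match="T_w = 0"):
            Spectrum2DSeries(
                omega_tau=exchange_series_23.omega_tau,
                omega_t=exchange_series_23.omega_t,
                waiting_times=exchange_series_23.waiting_times[1:],
                matrices=exchange_series_23.matrices[1:])


class TestCrossPeakTrace:
    def test_monotone_growth_of_cross_difference(
            self, exchange_series_23, norm_window, cross_window):
        diff = subtract_reference(normalize_series(exchange_series_23,
                                                   norm_window))
        trace = cross_peak_trace(diff, cross_window)
        assert np.all(trace[1:, 1] >= trace[:-1, 1] - 1e-12)
        assert trace[-1, 1] > 0

    def test_trace_follows_generator_closed_form(
            self, exchange_series_23, norm_window, cross_window):
        """Noise-free phenomenological trace is proportional to
        1 - exp(-T_w/0.53) with R^2 > 0.999."""
        diff = subtract_reference(normalize_series(exchange_series_23,
                                                   norm_window))
        trace = cross_peak_trace(diff, cross_window)
        tw, m = trace[:, 0], trace[:, 1]
        model = 1.0 - np.exp(-tw / TAU_FORWARD_23C)
        slope = np.dot(model, m) / np.dot(model, model)
        ss_res = np.sum((m - slope * model) ** 2)
        ss_tot = np.sum((m - m.mean()) ** 2)
        assert 1.0 - ss_res / ss_tot > 0.999

    def test_window_size_changes_magnitude_not_tau(self):
        """On a well-separated test geometry doubling the cross window
        grows the integral but moves the fitted tau by < 1%."""
        params = ExchangeGenParams(
            freq_shb_01=1580.0, freq_whb_01=1640.0,
            grid_tau=np.arange(1530.0, 1700.0, 0.5),
            grid_t=np.arange(1530.0, 1700.0, 0.5))
        series = simulate_2dir_series(params)
        nw = SpectralWindow(1577.5, 1582.5, 1564.5, 1569.5)
        diff = subtract_reference(normalize_series(series, nw))
        taus, mags = [], []
        for size in (5.0, 10.0):
            cw = SpectralWindow.centered(1580.0, 1640.0, size)
            trace = cross_peak_trace(diff, cw)
            kin = fit_exchange(trace)
            taus.append(kin.tau_forward)
            mags.append(trace[-1, 1])
        assert mags[1] > mags[0]
        assert taus[1] == pytest.approx(taus[0], rel=0.01)

    def test_all_zero_differences_give_zero_trace(
            self, exchange_series_23, cross_window):
        zero = Spectrum2DSeries(
            omega_tau=exchange_series_23.omega_tau,
            omega_t=exchange_series_23.omega_t,
            waiting_times=exchange_series_23.waiting_times,
            matrices=[np.zeros_like(m) for m in exchange_series_23.matrices])
        trace = cross_peak_trace(zero, cross_window)
        np.testing.assert_array_equal(trace[:, 1], 0.0)

    def test_window_outside_grid_rejected(self, exchange_series_23):
        with pytest.raises(ValueError, match="outside"):
            cross_peak_trace(exchange_series_23,
                             SpectralWindow(1900.0, 1905.0, 1600.0, 1605.0))


class TestFitExchange:
    def test_exact_exponential_machine_precision(self):
        tw = np.arange(0.0, 3.01, 0.2)
        trace = np.column_stack([tw, 2.0 * (1.0 - np.exp(-tw / 1.0))])
        kin = fit_exchange(trace)
        assert kin.tau_forward == pytest.approx(1.0, rel=1e-8)
        assert kin.amplitude == pytest.approx(2.0, rel=1e-8)

    def test_constant_nonzero_trace_raises(self):
        tw = np.arange(0.0, 3.01, 0.2)
        trace = np.column_stack([tw, np.full_like(tw, 0.7)])
        with pytest.raises(RuntimeError, match="bound"):
            fit_exchange(trace)

    def test_too_few_waiting_times_rejected(self):
        trace = np.column_stack([[0.0, 0.5, 1.0], [0.0, 0.3, 0.5]])
        with pytest.raises(ValueError, match="4"):
            fit_exchange(trace)


class TestEndToEnd:
    def test_room_temperature_tau_recovery(
            self, exchange_series_23, norm_window, cross_window):
        """The full protocol recovers the generating 0.53 ps within 5%."""
        kin = extract_forward_kinetics(exchange_series_23, norm_window,
                                       cross_window)
        assert kin.tau_forward == pytest.approx(TAU_FORWARD_23C, rel=0.05)

    def test_lifetime_independence(self, norm_window, cross_window):
        """Changing both vibrational lifetimes changes raw amplitudes but
        the fitted tau by < 2% - the point of the normalization step."""
        taus = []
        for t1s, t1w in [(0.67, 0.72), (0.4, 1.2), (1.0, 0.5)]:
            series = simulate_2dir_series(ExchangeGenParams(
                t1_shb=t1s, t1_whb=t1w))
            kin = extract_forward_kinetics(series, norm_window, cross_window)
            taus.append(kin.tau_forward)
        assert max(taus) / min(taus) < 1.02

    def test_pipeline_scale_invariance(self, exchange_series_23, norm_window,
                                       cross_window):
        kin1 = extract_forward_kinetics(exchange_series_23, norm_window,
                                        cross_window)
        kin2 = extract_forward_kinetics(_scaled(exchange_series_23, 123.4),
                                        norm_window, cross_window)
        assert kin2.tau_forward == pytest.approx(kin1.tau_forward, rel=1e-9)

    def test_detailed_balance_identity_in_kinetics_record(
            self, exchange_series_23, norm_window, cross_window):
        kin = extract_forward_kinetics(exchange_series_23, norm_window,
                                       cross_window, dG=1.68)
        T = 23.0 + 273.15
        lhs = kin.k_forward / kin.k_reverse
        rhs = np.exp(-1.68 * 1000.0 / (R * T))
        assert lhs == pytest.approx(rhs, abs=1e-9)


class TestArrhenius:
    def test_printed_forward_rates_give_printed_activation_energy(self):
        T = np.array(KINETIC_TEMPS_C) + 273.15
        k = 1.0 / np.array(TAU_FORWARD_PS)
        res = arrhenius_fit(np.column_stack([T, k]))
        assert res.Ea == pytest.approx(13.25, abs=0.15)

    def test_temperature_independent_rates_give_zero(self):
        T = np.array([300.0, 320.0, 340.0, 360.0])
        res = arrhenius_fit(np.column_stack([T, np.full(4, 2.0)]))
        assert res.Ea == pytest.approx(0.0, abs=1e-12)

    def test_noise_free_inversion_is_exact(self):
        T = np.array([296.15, 323.15, 333.15, 358.15])
        Ea, lnA = 10.0, 1.3
        k = np.exp(lnA - Ea * 1000.0 / (R * T))
        res = arrhenius_fit(np.column_stack([T, k]))
        assert res.Ea == pytest.approx(Ea, abs=1e-10)
        assert res.ln_prefactor == pytest.approx(lnA, abs=1e-10)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3"):
            arrhenius_fit([[300.0, 1.0], [320.0, 2.0]])


class TestReverseRate:
    def test_room_temperature_reverse_time_constant(self):
        k_rev = reverse_rate(1.0 / TAU_FORWARD_23C, DG_KJMOL[0], 296.15)
        assert 1.0 / k_rev == pytest.approx(0.27, abs=0.005)

    def test_all_printed_reverse_time_constants(self):
        """The detailed-balance reverse times at the four temperatures
        round to the printed 0.27/0.21/0.19/0.16 ps."""
        printed = (0.27, 0.21, 0.19, 0.16)
        for t_c, tau_f, dG, expected in zip(KINETIC_TEMPS_C, TAU_FORWARD_PS,
                                            DG_KJMOL, printed):
            k_rev = reverse_rate(1.0 / tau_f, dG, t_c + 273.15)
            assert round(1.0 / k_rev, 2) == expected

    def test_zero_free_energy_gives_equal_rates(self):
        assert reverse_rate(1.9, 0.0, 296.15) == pytest.approx(1.9, rel=1e-14)

    def test_round_trip_free_energy(self):
        """Inverting the detailed-balance relation returns the input dG
        to 1e-12."""
        kf, dG, T = 1.0 / 0.53, 1.68, 296.15
        kr = reverse_rate(kf, dG, T)
        dG_back = -R * T * np.log(kf / kr) / 1000.0
        assert dG_back == pytest.approx(dG, abs=1e-12)

    def test_reverse_arrhenius_from_printed_values(self):
        """Arrhenius on the reverse rates at the printed two-decimal
        precision reproduces the printed reverse activation energy."""
        printed_tau_rev = (0.27, 0.21, 0.19, 0.16)
        T = np.array(KINETIC_TEMPS_C) + 273.15
        k = 1.0 / np.array(printed_tau_rev)
        res = arrhenius_fit(np.column_stack([T, k]))
        assert res.Ea == pytest.approx(7.48, abs=0.15)
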