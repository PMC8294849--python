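"""Electrophysiology: spectra, γ metrics, PSC detection, intrinsic properties."""

import numpy as np
import pytest

from mitonet import ephys, synthetic
from mitonet.containers import LFPRecording, VCTrace
from mitonet.errors import FitError, InputError, UndefinedResultError
from mitonet.ephys import (
    FWHM_PER_SIGMA,
    PowerSpectrum,
    autocorrelogram,
    detect_pscs,
    fepsp_slope,
    gamma_metrics,
    intrinsic_properties,
    io_curve,
    power_spectrum,
    spectrum_width50,
    train_recovery,
)


def sinusoid_lfp(freq, amp=0.1, duration=300.0, fs=5000.0, noise=0.0, seed=0):
    return synthetic.gen_lfp(
        synthetic.LFPGroundTruth(freq, amp, noise, duration, fs), seed=seed
    )


class TestPowerSpectrum:
    def test_pure_sinusoid_peak_at_frequency(self):
        spec = power_spectrum(sinusoid_lfp(40.0))
        gm = gamma_metrics(spec)
        assert gm.peak_frequency == pytest.approx(40.0, abs=0.5)

    def test_mains_band_excluded_from_statistics(self):
        spec = power_spectrum(sinusoid_lfp(50.0))
        gm = gamma_metrics(spec)
        # the 50 Hz mains bin is notched out, so the peak must sit elsewhere
        assert not 49.0 <= gm.peak_frequency <= 51.0

    def test_parseval_white_noise(self):
        lfp = sinusoid_lfp(40.0, amp=0.0, noise=1.0, duration=300.0, seed=4)
        spec = power_spectrum(lfp)
        assert spec.power.sum() == pytest.approx(lfp.samples.var(), rel=0.02)

    def test_amplitude_equivariance_c_squared(self):
        lfp = sinusoid_lfp(35.0, amp=0.1, noise=0.01, seed=5)
        scaled = LFPRecording(3.0 * lfp.samples, lfp.sample_rate)
        p1 = gamma_metrics(power_spectrum(lfp)).peak_power
        p2 = gamma_metrics(power_spectrum(scaled)).peak_power
        assert p2 == pytest.approx(9.0 * p1, rel=1e-6)

    def test_single_fft_mode_same_peak(self):
        spec = power_spectrum(sinusoid_lfp(40.0), single_fft=True)
        assert gamma_metrics(spec).peak_frequency == pytest.approx(40.0, abs=0.1)

    def test_short_recording_rejected(self):
        with pytest.raises(InputError):
            power_spectrum(sinusoid_lfp(40.0, duration=10.0))


class TestGammaMetrics:
    def test_flat_spectrum_area(self):
        f = np.arange(0.0, 100.0, 0.5)
        p = np.full(f.size, 2.0)
        spec = PowerSpectrum(f, p, excluded_bands=[])
        gm = gamma_metrics(spec, (20.0, 80.0))
        assert gm.power_area == pytest.approx(2.0 * 60.0)

    def test_all_zero_spectrum_undefined(self):
        spec = PowerSpectrum(np.arange(0.0, 100.0), np.zeros(100))
        with pytest.raises(UndefinedResultError):
            gamma_metrics(spec)


class TestWidth50:
    def test_exact_gaussian_bump(self):
        f = np.arange(20.0, 80.5, 0.5)
        sigma = 2.123
        p = 5.0 * np.exp(-0.5 * ((f - 40.0) / sigma) ** 2) + 0.1
        w = spectrum_width50(PowerSpectrum(f, p))
        assert w == pytest.approx(FWHM_PER_SIGMA * sigma, rel=1e-4)
        assert w == pytest.approx(5.0, abs=0.01)

    def test_monotone_in_sigma(self):
        f = np.arange(20.0, 80.5, 0.5)
        widths = []
        for sigma in (1.0, 2.0, 4.0):
            p = np.exp(-0.5 * ((f - 45.0) / sigma) ** 2)
            widths.append(spectrum_width50(PowerSpectrum(f, p)))
        assert widths == sorted(widths)

    def test_noisy_bump_recovered_within_10pct(self):
        f = np.arange(20.0, 80.5, 0.5)
        sigma_true = 3.0
        errs = []
        rng = np.random.default_rng(99)
        for _ in range(100):
            p = np.exp(-0.5 * ((f - 38.0) / sigma_true) ** 2)
            noisy = p + rng.normal(0, 0.1 * p.max() / 10, size=f.size)
            w = spectrum_width50(PowerSpectrum(f, np.clip(noisy, 0, None)))
            errs.append(abs(w - FWHM_PER_SIGMA * sigma_true) / (FWHM_PER_SIGMA * sigma_true))
        assert np.mean(errs) < 0.1

    def test_flat_spectrum_fails_explicitly(self):
        f = np.arange(20.0, 80.5, 0.5)
        with pytest.raises((FitError, UndefinedResultError)):
            spectrum_width50(PowerSpectrum(f, np.full(f.size, 1.0)))


class TestAutocorrelogram:
    def test_unity_at_zero_lag(self):
        lfp = sinusoid_lfp(40.0, noise=0.05, duration=5.0, seed=2)
        lags, acf = autocorrelogram(lfp, 0.1)
        assert acf[lags == 0][0] == pytest.approx(1.0)

    def test_sinusoid_first_peak_at_period(self):
        lfp = sinusoid_lfp(40.0, duration=5.0)
        lags, acf = autocorrelogram(lfp, 0.1)
        pos = (lags > 0.005)
        first_peak = lags[pos][np.argmax(acf[pos])]
        assert first_peak == pytest.approx(1.0 / 40.0, abs=1e-3)

    def test_symmetry(self):
        lfp = sinusoid_lfp(33.0, noise=0.02, duration=5.0, seed=3)
        lags, acf = autocorrelogram(lfp, 0.05)
        assert np.allclose(acf, acf[::-1], atol=1e-10)

    def test_white_noise_decorrelates(self):
        lfp = sinusoid_lfp(40.0, amp=0.0, noise=1.0, duration=20.0, seed=6)
        lags, acf = autocorrelogram(lfp, 0.02)
        nonzero = acf[lags != 0]
        bound = 3.0 / np.sqrt(lfp.samples.size)
        assert (np.abs(nonzero) < bound).mean() > 0.98


class TestPSCDetection:
    def test_three_large_events_detected(self):
        truth = synthetic.PSCGroundTruth(
            np.array([0.1, 0.3, 0.5]), np.array([50.0, 50.0, 50.0]), 0.5, 5.0, 2.0
        )
        trace, _ = synthetic.gen_psc_trace(truth, 1.0, seed=7)
        ev = detect_pscs(trace)
        assert ev.n == 3
        assert np.allclose(ev.amplitudes, 50.0, rtol=0.05)

    def test_event_below_5x_noise_excluded(self):
        # The noise SD refers to the low-pass-filtered trace (detection runs
        # after filtering): generator noise of 5 pA leaves ~2.2 pA after the
        # 1 kHz filter, so the exclusion floor is ~11 pA.  An 8 pA event is
        # above the 3 pA initial threshold but below 5×SD, and is dropped.
        truth = synthetic.PSCGroundTruth(
            np.array([0.25, 0.5]), np.array([50.0, 8.0]), 0.5, 5.0, 5.0
        )
        trace, _ = synthetic.gen_psc_trace(truth, 1.0, seed=8)
        ev = detect_pscs(trace)
        assert 5.0 * ev.noise_sd > 8.0  # construction is in the exclusion regime
        assert ev.n == 1
        assert abs(ev.event_times[0] - 0.25) < 0.01

    def test_event_below_initial_threshold_not_detected(self):
        truth = synthetic.PSCGroundTruth(
            np.array([0.3]), np.array([2.0]), 0.5, 5.0, 0.001
        )
        trace, _ = synthetic.gen_psc_trace(truth, 1.0, seed=9)
        ev = detect_pscs(trace)
        assert ev.n == 0

    def test_output_floors_always_hold(self):
        for seed in range(5):
            truth = synthetic.gen_poisson_psc_truth(8.0, 10.0, seed=seed)
            trace, _ = synthetic.gen_psc_trace(truth, 10.0, seed=seed)
            ev = detect_pscs(trace)
            assert np.all(ev.amplitudes >= 3.0)
            assert np.all(ev.amplitudes >= 5.0 * ev.noise_sd)

    def test_precision_recall_high_snr(self):
        """Recall and precision ≥ 0.95 on trains with amplitudes ≥ 10× noise."""
        tp = fp = fn = 0
        for seed in range(100):
            truth = synthetic.gen_poisson_psc_truth(
                10.0, 5.0, mean_amp=50.0, noise_sd=2.0, seed=seed
            )
            trace, truth = synthetic.gen_psc_trace(truth, 5.0, seed=seed)
            ev = detect_pscs(trace)
            matched = np.zeros(truth.event_times.size, dtype=bool)
            for t in ev.event_times:
                d = np.abs(truth.event_times - t)
                i = int(np.argmin(d)) if d.size else -1
                if i >= 0 and d[i] < 0.005 and not matched[i]:
                    matched[i] = True
                    tp += 1
                else:
                    fp += 1
            fn += int((~matched).sum())
        recall = tp / (tp + fn)
        precision = tp / (tp + fp)
        assert recall >= 0.95
        assert precision >= 0.95

    def test_median_statistics(self):
        truth = synthetic.PSCGroundTruth(
            np.array([0.1, 0.3, 0.6]), np.array([30.0, 50.0, 40.0]), 0.5, 5.0, 1.0
        )
        trace, _ = synthetic.gen_psc_trace(truth, 1.0, seed=10)
        ev = detect_pscs(trace)
        assert ev.median_amplitude == pytest.approx(40.0, rel=0.05)
        assert ev.median_iei == pytest.approx(0.25, abs=0.01)


class TestTrainRecovery:
    def test_known_recovery_fractions_within_3pct(self):
        trace, tt, pt, truth = synthetic.gen_train_trace(
            recovery_fracs=(0.5, 0.7, 0.9), n_trains=10, seed=11
        )
        rec = train_recovery(trace, tt, pt)
        assert np.allclose(rec, truth, rtol=0.03)

    def test_probe_equal_first_peak_is_100pct(self):
        trace, tt, pt, _ = synthetic.gen_train_trace(
            recovery_fracs=(1.0,), probe_delays_s=(0.5,), n_trains=3,
            noise_sd=0.0, seed=12,
        )
        rec = train_recovery(trace, tt, pt)
        assert rec[0] == pytest.approx(100.0, abs=1.0)


class TestIntrinsicProperties:
    @pytest.fixture()
    def sweeps(self):
        return synthetic.gen_cc_sweeps(
            [-100, -50, -25, 50, 100, 120, 140],
            r_in_mohm=100.0, tau_ms=10.0, threshold_mv=-40.0,
            rheobase_pA=100.0, seed=13,
        )

    def test_rc_parameters_recovered(self, sweeps):
        p = intrinsic_properties(sweeps)
        assert p.input_resistance == pytest.approx(100.0, rel=0.02)
        assert p.tau_m == pytest.approx(10.0, rel=0.05)

    def test_threshold_within_1mv(self, sweeps):
        p = intrinsic_properties(sweeps)
        assert p.ap_threshold == pytest.approx(-40.0, abs=1.0)

    def test_rheobase_and_rate(self, sweeps):
        p = intrinsic_properties(sweeps)
        assert p.rheobase == 100.0
        # at rheobase + 40 pA: 0.5 Hz/pA · 40 + 10 = 30 Hz
        assert p.spike_rate_rheo40 == pytest.approx(30.0, rel=0.1)

    def test_no_spikes_returns_undefined_rheobase(self):
        sweeps = synthetic.gen_cc_sweeps([-100, -50, 20, 40], rheobase_pA=1000.0, seed=1)
        p = intrinsic_properties(sweeps)
        assert p.rheobase is None
        assert p.ap_amplitude is None

    def test_ohms_law_single_step(self):
        # −50 pA step with −5 mV deflection -> 100 MΩ
        sweeps = synthetic.gen_cc_sweeps([-50, -25], r_in_mohm=100.0, seed=2)
        p = intrinsic_properties(sweeps)
        assert p.input_resistance == pytest.approx(100.0, rel=0.02)


class TestFEPSP:
    def test_alpha_function_matches_analytic_chord(self):
        from scipy.optimize import brentq

        A, tau_ms = 0.5, 5.0
        lfp = synthetic.gen_fepsp(A, tau_ms, sample_rate=50000.0)
        slope, ok = fepsp_slope(lfp, 0.05)
        assert ok
        f = lambda x: x * np.exp(1 - x)
        x20 = brentq(lambda x: f(x) - 0.2, 1e-9, 1.0)
        x80 = brentq(lambda x: f(x) - 0.8, 1e-9, 1.0)
        chord = -A * 0.6 / ((x80 - x20) * tau_ms)
        assert slope == pytest.approx(chord, rel=0.02)

    def test_doubling_amplitude_doubles_slope(self):
        s1, _ = fepsp_slope(synthetic.gen_fepsp(0.3), 0.05)
        s2, _ = fepsp_slope(synthetic.gen_fepsp(0.6), 0.05)
        assert s2 == pytest.approx(2.0 * s1, rel=0.01)

    def test_flat_trace_flagged_invalid(self):
        flat = LFPRecording(np.zeros(3000), 10000.0)
        slope, ok = fepsp_slope(flat, 0.05)
        assert slope == 0.0 and not ok

    def test_io_curve_monotone_with_intensity(self):
        traces = [synthetic.gen_fepsp(a) for a in (0.1, 0.3, 0.5)]
        curve = io_curve(traces, [10, 20, 30], 0.05)
        slopes = [abs(s) for _, s in curve]
        assert slopes == sorted(slopes)
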