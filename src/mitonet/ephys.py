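"""Slice electrophysiology analysis.

γ-oscillation (20–80 Hz) spectral metrics from local field potentials,
autocorrelogram, Gaussian 50%-width of the spectral peak, spontaneous
postsynaptic-current (sPSC) detection with the 3-pA initial threshold and
5×noise-SD exclusion, train-recovery normalisation, intrinsic membrane
properties from current-clamp step families, and fEPSP slope / input–output
curves.

Spectral estimation uses Welch averaging with 2-s Hann segments at 50%
overlap (0.5 Hz resolution) and is normalised so the summed per-bin power
equals the signal variance (Parseval); a single-FFT mode is available.  The
49–51 Hz band is flagged as mains and ignored by all band statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

from .containers import LFPRecording, VCTrace
from .errors import FitError, InputError, UndefinedResultError

GAMMA_BAND = (20.0, 80.0)     # Hz
MAINS_BAND = (49.0, 51.0)     # Hz, notch-out of band statistics
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ≈ 2.3548


# ---------------------------------------------------------------------------
# Power spectra and γ metrics

@dataclass
class PowerSpectrum:
    frequencies: np.ndarray              # Hz
    power: np.ndarray                    # per-bin power; sums to variance
    excluded_bands: list = field(default_factory=list)  # [(lo, hi)] Hz

    def band_mask(self, band: tuple[float, float]) -> np.ndarray:
        """In-band bins, with excluded (mains) bins removed."""
        m = (self.frequencies >= band[0]) & (self.frequencies <= band[1])
        for lo, hi in self.excluded_bands:
            m &= ~((self.frequencies >= lo) & (self.frequencies <= hi))
        return m


@dataclass
class GammaMetrics:
    peak_frequency: float  # Hz
    peak_power: float
    power_area: float
    width50: float | None = None  # Hz, filled by spectrum_width50


def power_spectrum(
    lfp: LFPRecording,
    window: float = 300.0,
    mains_exclusion: tuple[float, float] = MAINS_BAND,
    segment_s: float = 2.0,
    single_fft: bool = False,
) -> PowerSpectrum:
    """Normalised magnitude-squared spectrum of the last ``window`` seconds.

    Welch averaging (2-s Hann, 50% overlap) by default; ``single_fft``
    computes one periodogram over the whole window instead.  In both modes
    the per-bin power sums to the analysed signal's variance.
    """
    if lfp.duration < window:
        raise InputError(
            f"recording {lfp.duration:.1f} s shorter than analysis window {window} s"
        )
    n = int(round(window * lfp.sample_rate))
    x = lfp.samples[-n:]
    if single_fft:
        freqs, psd = signal.periodogram(x, fs=lfp.sample_rate, detrend="constant")
    else:
        nper = int(round(segment_s * lfp.sample_rate))
        freqs, psd = signal.welch(
            x, fs=lfp.sample_rate, window="hann", nperseg=nper,
            noverlap=nper // 2, detrend="constant",
        )
    df = freqs[1] - freqs[0]
    power = psd * df  # per-bin power; Parseval: sum(power) ≈ var(x)
    excluded = [tuple(mains_exclusion)] if mains_exclusion is not None else []
    return PowerSpectrum(freqs, power, excluded)


def gamma_metrics(
    spec: PowerSpectrum, band: tuple[float, float] = GAMMA_BAND
) -> GammaMetrics:
    """Peak frequency/power and area under the spectrum within the band."""
    m = spec.band_mask(band)
    if not np.any(m):
        raise InputError("spectrum does not cover the requested band")
    f, p = spec.frequencies[m], spec.power[m]
    if np.all(p == 0):
        raise UndefinedResultError("all-zero spectrum in band; peak undefined")
    i = int(np.argmax(p))
    return GammaMetrics(
        peak_frequency=float(f[i]),
        peak_power=float(p[i]),
        power_area=float(np.trapezoid(p, f)),
    )


def spectrum_width50(
    spec: PowerSpectrum, band: tuple[float, float] = GAMMA_BAND
) -> float:
    """Full width at half maximum (Hz) of a Gaussian fit to the in-band peak.

    Fits amplitude, center, σ and baseline by least squares and returns
    2·sqrt(2 ln 2)·σ.  Raises FitError on non-convergence rather than
    substituting a default.
    """
    m = spec.band_mask(band)
    f, p = spec.frequencies[m], spec.power[m]
    if f.size < 5:
        raise InputError("too few in-band bins for a Gaussian fit")

    def gauss(x, a, mu, sigma, b):
        return a * np.exp(-0.5 * ((x - mu) / sigma) ** 2) + b

    i = int(np.argmax(p))
    p0 = [float(p[i] - p.min()), float(f[i]), 2.0, float(p.min())]
    try:
        popt, _ = optimize.curve_fit(gauss, f, p, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"Gaussian fit did not converge: {exc}") from None
    a, mu, sigma, b = popt
    sigma = abs(float(sigma))
    if a <= 0 or not (band[0] - 10 <= mu <= band[1] + 10) or sigma > (band[1] - band[0]):
        raise FitError("Gaussian fit converged to a non-physical peak")
    return FWHM_PER_SIGMA * sigma


def autocorrelogram(lfp: LFPRecording, max_lag: float) -> tuple[np.ndarray, np.ndarray]:
    """Normalised autocorrelation (1 at lag 0), symmetric over ±max_lag."""
    if max_lag >= lfp.duration:
        raise InputError("max_lag must be shorter than the recording")
    x = lfp.samples - lfp.samples.mean()
    n = x.size
    k = int(round(max_lag * lfp.sample_rate))
    full = signal.correlate(x, x, mode="full")
    mid = n - 1
    acf = full[mid - k: mid + k + 1] / full[mid]
    lags = np.arange(-k, k + 1) / lfp.sample_rate
    return lags, acf


# ---------------------------------------------------------------------------
# Spontaneous PSC detection

@dataclass
class PSCEventSeries:
    event_times: np.ndarray       # s, at the event peak
    amplitudes: np.ndarray        # pA, positive magnitudes
    noise_sd: float               # pA, robust estimate from the filtered trace
    median_iei: float             # s (NaN for < 2 events)
    median_amplitude: float       # pA (NaN for 0 events)

    @property
    def n(self) -> int:
        return self.event_times.size


def _lowpass(x: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    sos = signal.butter(4, cutoff, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def detect_pscs(
    trace: VCTrace,
    polarity: str = "inward",
    init_threshold: float = 3.0,   # pA
    noise_mult: float = 5.0,       # × noise SD exclusion
    lp_cutoff: float = 1000.0,     # Hz
    baseline_window: float = 0.005,  # s, pre-event median baseline
) -> PSCEventSeries:
    """Threshold-based spontaneous PSC detection.

    The trace is zero-phase low-pass filtered (4th-order Butterworth at
    ``lp_cutoff``), baseline-subtracted (global median), and scanned for
    excursions beyond ``init_threshold`` pA in the requested polarity.  Each
    contiguous excursion yields one candidate event at its extremum, with
    amplitude measured from the median of the preceding ``baseline_window``.
    Candidates below ``noise_mult`` × noise SD are excluded; the noise SD is
    1.4826·MAD of the filtered trace with event regions masked out.
    """
    if trace.sample_rate <= 2 * lp_cutoff:
        raise InputError("sample rate must exceed twice the low-pass cutoff")
    if trace.samples.size < 10 * int(trace.sample_rate / lp_cutoff):
        raise InputError("trace too short for filter warm-up")
    if polarity not in ("inward", "outward"):
        raise InputError("polarity must be 'inward' or 'outward'")
    x = _lowpass(trace.samples, trace.sample_rate, lp_cutoff)
    x = x - np.median(x)
    sgn = -1.0 if polarity == "inward" else 1.0
    y = sgn * x  # events are positive excursions of y
    event_mask = y > init_threshold
    mad = np.median(np.abs(x[~event_mask] - np.median(x[~event_mask]))) if np.any(~event_mask) \
        else np.median(np.abs(x - np.median(x)))
    noise_sd = float(1.4826 * mad)
    nbase = max(int(round(baseline_window * trace.sample_rate)), 1)
    # peaks above threshold; prominence splits events riding a decay shoulder
    peaks, props = signal.find_peaks(
        y, height=init_threshold, prominence=init_threshold / 2.0
    )
    times, amps = [], []
    for peak_i, prom, lb in zip(peaks, props["prominences"], props["left_bases"]):
        b0 = max(lb - nbase, 0)
        baseline = np.median(y[b0:lb]) if lb > b0 else 0.0
        # isolated events: height above the pre-event baseline; events on a
        # shoulder (left base still above threshold): prominence, the rise
        # from the inter-event valley
        amp = float(y[peak_i] - baseline) if y[lb] <= init_threshold else float(prom)
        if amp < init_threshold or amp < noise_mult * noise_sd:
            continue
        times.append(peak_i / trace.sample_rate)
        amps.append(amp)
    times = np.asarray(times)
    amps = np.asarray(amps)
    return PSCEventSeries(
        event_times=times,
        amplitudes=amps,
        noise_sd=noise_sd,
        median_iei=float(np.median(np.diff(times))) if times.size >= 2 else float("nan"),
        median_amplitude=float(np.median(amps)) if amps.size else float("nan"),
    )


# ---------------------------------------------------------------------------
# Train recovery

def _response_amplitude(y: np.ndarray, fs: float, t: float, window: float) -> float:
    """Peak excursion (positive y) within ``window`` s after time t."""
    i0 = int(round(t * fs))
    i1 = min(int(round((t + window) * fs)), y.size)
    if i1 <= i0:
        raise InputError("response window outside trace")
    base = np.median(y[max(i0 - int(0.005 * fs), 0):i0]) if i0 > 0 else 0.0
    return float(np.max(y[i0:i1]) - base)


def train_recovery(
    trace: VCTrace,
    train_times: list,
    probe_times: list,
    polarity: str = "inward",
    response_window: float = 0.02,
    lp_cutoff: float = 1000.0,
    min_first_peak: float = 3.0,
) -> np.ndarray:
    """Percent recovery per probe interval, averaged across trains.

    ``train_times[i]`` holds the stimulus times of train i (the first entry
    is the reference peak); ``probe_times[i]`` holds that train's probe
    stimulus times.  Each probe's response amplitude is normalised to the
    first-peak amplitude of its own train; trains with an undetectable
    first peak are excluded with a warning.
    """
    import warnings

    if len(train_times) != len(probe_times):
        raise InputError("need probe times for every train")
    y = _lowpass(trace.samples, trace.sample_rate, lp_cutoff)
    y = (-1.0 if polarity == "inward" else 1.0) * (y - np.median(y))
    per_train = []
    for stims, probes in zip(train_times, probe_times):
        first = _response_amplitude(y, trace.sample_rate, stims[0], response_window)
        if first < min_first_peak:
            warnings.warn("train excluded: undetectable first peak", stacklevel=2)
            continue
        per_train.append([
            100.0 * _response_amplitude(y, trace.sample_rate, t, response_window) / first
            for t in probes
        ])
    if not per_train:
        raise UndefinedResultError("no train had a detectable first peak")
    return np.mean(np.asarray(per_train), axis=0)


# ---------------------------------------------------------------------------
# Intrinsic membrane properties

@dataclass
class CCSweep:
    """One current-clamp sweep: step current (pA) and voltage trace (mV)."""

    current_pA: float
    voltage: np.ndarray
    sample_rate: float
    step_on: float   # s
    step_off: float  # s


@dataclass
class IntrinsicProperties:
    ap_amplitude: float | None    # mV, threshold to peak
    ap_halfwidth: float | None    # ms
    ap_threshold: float | None    # mV
    input_resistance: float       # MΩ
    tau_m: float                  # ms
    rheobase: float | None        # pA
    spike_rate_rheo40: float | None  # Hz at rheobase + 40 pA


def _detect_spikes(v: np.ndarray, fs: float, dvdt_crit: float = 20.0) -> list[int]:
    """Spike peak indices via dV/dt threshold crossings (V/s)."""
    dvdt = np.gradient(v) * fs / 1000.0  # mV/sample -> V/s
    crossing = (dvdt[:-1] < dvdt_crit) & (dvdt[1:] >= dvdt_crit)
    idx = np.flatnonzero(crossing)
    peaks = []
    for i in idx:
        j = i
        while j + 1 < v.size and v[j + 1] > v[j]:
            j += 1
        if v[j] > -10.0 and (not peaks or j - peaks[-1] > int(0.001 * fs)):
            peaks.append(j)
    return peaks


def intrinsic_properties(
    sweeps: list[CCSweep], dvdt_crit: float = 20.0
) -> IntrinsicProperties:
    """Membrane properties from a hyper/depolarising step family.

    Input resistance: slope of steady-state ΔV vs ΔI over hyperpolarising
    steps.  τm: single-exponential fit to the onset of the largest
    hyperpolarising step.  Rheobase: smallest depolarising step evoking ≥ 1
    spike; spiking metrics come from the first spike of the rheobase sweep,
    and the spike rate is read from the sweep nearest rheobase + 40 pA.
    """
    if not sweeps:
        raise InputError("no sweeps")
    fs = sweeps[0].sample_rate
    hyper = [s for s in sweeps if s.current_pA < 0]
    if len(hyper) < 2:
        raise InputError("need >= 2 hyperpolarising steps for input resistance")

    def baseline(s):
        return float(np.mean(s.voltage[: int(s.step_on * fs)]))

    def steady(s):
        i1 = int(s.step_off * fs)
        i0 = max(int((s.step_off - 0.05) * fs), int(s.step_on * fs))
        return float(np.mean(s.voltage[i0:i1]))

    dI = np.array([s.current_pA for s in hyper])
    dV = np.array([steady(s) - baseline(s) for s in hyper])
    rin = float(np.polyfit(dI, dV, 1)[0] * 1000.0)  # mV/pA -> MΩ

    big = min(hyper, key=lambda s: s.current_pA)
    i0, i1 = int(big.step_on * fs), int(big.step_off * fs)
    seg = big.voltage[i0:i1] - steady(big)
    t = np.arange(seg.size) / fs
    v0 = baseline(big) - steady(big)

    def expdec(t, tau):
        return v0 * np.exp(-t / tau)

    try:
        popt, _ = optimize.curve_fit(expdec, t, seg, p0=[0.01], maxfev=10000)
        tau_m = float(abs(popt[0]) * 1000.0)  # ms
    except RuntimeError:
        raise FitError("membrane time-constant fit did not converge") from None

    depol = sorted((s for s in sweeps if s.current_pA > 0), key=lambda s: s.current_pA)
    rheo_sweep = None
    for s in depol:
        if _detect_spikes(s.voltage, fs, dvdt_crit):
            rheo_sweep = s
            break
    if rheo_sweep is None:
        return IntrinsicProperties(None, None, None, rin, tau_m, None, None)

    v = rheo_sweep.voltage
    peaks = _detect_spikes(v, fs, dvdt_crit)
    pk = peaks[0]
    dvdt = np.gradient(v) * fs / 1000.0
    # walk back to the start of the upstroke, then take the first sample
    # where dV/dt reaches the criterion
    j = pk
    while j > 0 and v[j - 1] < v[j]:
        j -= 1
    th_i = pk
    for i in range(j, pk + 1):
        if dvdt[i] >= dvdt_crit:
            th_i = i
            break
    threshold = float(v[th_i])
    amplitude = float(v[pk] - threshold)
    half = threshold + amplitude / 2.0
    l = pk
    while l > th_i and v[l] > half:
        l -= 1
    r = pk
    while r < v.size - 1 and v[r] > half:
        r += 1
    halfwidth = (r - l) / fs * 1000.0  # ms

    target = rheo_sweep.current_pA + 40.0
    rate_sweep = min(depol, key=lambda s: abs(s.current_pA - target))
    n_spk = len(_detect_spikes(rate_sweep.voltage, fs, dvdt_crit))
    rate = n_spk / (rate_sweep.step_off - rate_sweep.step_on)
    return IntrinsicProperties(
        ap_amplitude=amplitude,
        ap_halfwidth=halfwidth,
        ap_threshold=threshold,
        input_resistance=rin,
        tau_m=tau_m,
        rheobase=float(rheo_sweep.current_pA),
        spike_rate_rheo40=float(rate),
    )


# ---------------------------------------------------------------------------
# fEPSP slope

def fepsp_slope(
    trace,
    stim_time: float,
    sample_rate: float | None = None,
    blank: float = 0.002,
    search_window: float = 0.05,
    noise_floor: float = 0.02,
) -> tuple[float, bool]:
    """Initial slope (mV/ms) of a field EPSP.

    The stimulus artifact is blanked for ``blank`` s; the response extremum
    is located within ``search_window`` s and a line is fitted over the
    20–80% span of the initial phase.  Returns (slope, valid); responses
    smaller than ``noise_floor`` mV return (0.0, False).
    """
    if sample_rate is None:
        v, fs = trace.samples, trace.sample_rate
    else:
        v, fs = np.asarray(trace, dtype=float), float(sample_rate)
    i0 = int(round((stim_time + blank) * fs))
    i1 = min(int(round((stim_time + blank + search_window) * fs)), v.size)
    if i1 - i0 < 5:
        raise InputError("search window outside trace")
    seg = v[i0:i1]
    base = np.median(v[max(i0 - int(0.005 * fs), 0):i0]) if i0 > 0 else seg[0]
    dev = seg - base
    pk = int(np.argmax(np.abs(dev)))
    peak_dev = dev[pk]
    if abs(peak_dev) < noise_floor:
        return 0.0, False
    sgn = np.sign(peak_dev)
    mag = sgn * dev  # positive-going response
    lo, hi = 0.2 * mag[pk], 0.8 * mag[pk]
    rise = np.flatnonzero((mag[: pk + 1] >= lo) & (mag[: pk + 1] <= hi))
    if rise.size < 2:
        return 0.0, False
    t_ms = rise / fs * 1000.0
    slope = float(np.polyfit(t_ms, seg[rise], 1)[0])
    return slope, True


def io_curve(traces, intensities, stim_time: float, **kwargs) -> list[tuple[float, float]]:
    """Input–output relation: (stimulation intensity, fEPSP slope) pairs."""
    out = []
    for trace, inten in zip(traces, intensities):
        slope, _ = fepsp_slope(trace, stim_time, **kwargs)
        out.append((float(inten), slope))
    return out
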