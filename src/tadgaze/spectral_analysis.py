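"""Wavelet spectral decomposition of eye and nerve traces.

The frequency content of a motor trace — locomotor (swim) versus
vestibular-stimulus components — is extracted in two steps: an FFT scan
identifies candidate oscillation frequencies, then a continuous Morlet
wavelet transform resolves them in time.  Spectrograms show the wavelet
power over time × frequency (0.5–16 Hz by default); periodograms show its
time average per frequency.  Significance of power is assessed against
seeded white-noise surrogates matched in length and variance, with the
cone of influence excluded from peak calls.

The Morlet centre frequency is ω₀ = 6 with 20 voices per octave, the
conventional defaults for this analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.signal import detrend, find_peaks

#: Morlet ω0 = 6 expressed as the pywt "cmorB-C" centre frequency C = ω0/2π
_MORLET_C = 6.0 / (2.0 * np.pi)
_WAVELET = f"cmor2.0-{_MORLET_C:.6f}"


@dataclass
class Spectrogram:
    """Time × frequency wavelet power with optional significance mask."""

    freqs: np.ndarray            # Hz, ascending
    times: np.ndarray            # s
    power: np.ndarray            # (n_freq, n_time), >= 0
    coi_mask: np.ndarray         # True where inside the cone of influence (valid)
    rate: float
    trace_std: float
    mask: np.ndarray | None = None            # significance, set by significance_mask
    _null_row_means: np.ndarray | None = None  # surrogate time-averaged power


@dataclass
class Periodogram:
    """Time-averaged wavelet power per frequency with significant peaks."""

    freqs: np.ndarray
    mean_power: np.ndarray
    peak_freqs: np.ndarray       # significant local maxima, descending power
    threshold: np.ndarray | None = None


def principal_frequencies_fft(trace, rate: float, fmin: float = 0.5,
                              fmax: float = 16.0, min_snr: float = 5.0) -> np.ndarray:
    """Candidate oscillation frequencies from the FFT amplitude spectrum.

    The trace is linearly detrended; local maxima of the amplitude
    spectrum within [fmin, fmax] whose amplitude exceeds ``min_snr`` × the
    in-band median are returned ranked by amplitude (strongest first).
    White noise yields an empty list.
    """
    x = np.asarray(trace, dtype=float)
    if x.size < 2 * rate / fmin:
        raise ValueError(f"trace too short to resolve {fmin} Hz (need {2 / fmin} s)")
    x = detrend(x)
    amp = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(x.size, d=1.0 / rate)
    band = (freqs >= fmin) & (freqs <= fmax)
    a, f = amp[band], freqs[band]
    floor = float(np.median(a))
    idx, _ = find_peaks(a, height=min_snr * floor)
    order = np.argsort(a[idx])[::-1]
    return f[idx][order]


def cwt_spectrogram(trace, rate: float, fmin: float = 0.5, fmax: float = 16.0,
                    voices_per_octave: int = 20) -> Spectrogram:
    """Continuous Morlet wavelet power of a uniformly sampled trace.

    Frequencies are log-spaced at ``1/voices_per_octave`` octave steps;
    the ridge of a pure tone falls at its frequency within one scale step.
    The rate must satisfy rate ≥ 2 fmax (down-sample first if not).
    """
    x = np.asarray(trace, dtype=float)
    if fmin >= fmax:
        raise ValueError("fmin must be below fmax")
    if rate < 2 * fmax:
        raise ValueError(f"rate {rate} Hz below 2*fmax = {2 * fmax} Hz; down-sample first")
    x = detrend(x)
    n_oct = np.log2(fmax / fmin)
    n_freq = int(np.floor(n_oct * voices_per_octave)) + 1
    freqs = fmax * 2.0 ** (-np.arange(n_freq) / voices_per_octave)
    scales = _MORLET_C * rate / freqs
    coefs, _ = pywt.cwt(x, scales, _WAVELET, sampling_period=1.0 / rate, method="fft")
    power = np.abs(coefs) ** 2
    # ascending frequency order
    freqs, power = freqs[::-1], power[::-1]
    times = np.arange(x.size) / rate
    # cone of influence: e-folding time sqrt(2)*s with s = C/f (seconds)
    coi_t = np.sqrt(2.0) * _MORLET_C / freqs
    edge = np.minimum(times[None, :], times[-1] - times[None, :])
    coi_mask = edge >= coi_t[:, None]
    return Spectrogram(freqs, times, power, coi_mask, rate, float(np.std(x)))


def _surrogate_row_stats(spec: Spectrogram, n_surrogates: int, seed: int,
                         time_stride: int):
    """Pointwise power samples and time-averaged power rows under the null.

    The null is seeded white noise matched to the analyzed trace in length
    and variance, transformed exactly as the data.
    """
    rng = np.random.default_rng(seed)
    n = spec.times.size
    scales = (_MORLET_C * spec.rate / spec.freqs)[::-1]
    cells = []
    row_means = []
    for _ in range(n_surrogates):
        surro = rng.normal(0.0, spec.trace_std if spec.trace_std > 0 else 1.0, size=n)
        coefs, _ = pywt.cwt(surro, scales, _WAVELET,
                            sampling_period=1.0 / spec.rate, method="fft")
        p = (np.abs(coefs) ** 2)[::-1]
        cells.append(p[:, ::time_stride])
        row_means.append(np.where(spec.coi_mask, p, np.nan))
    row_means = np.asarray([np.nanmean(rm, axis=1) for rm in row_means])
    return np.concatenate(cells, axis=1), row_means


def significance_mask(spec: Spectrogram, n_surrogates: int = 100,
                      alpha: float = 0.05, seed: int = 0) -> np.ndarray:
    """Pointwise significance of wavelet power against white-noise surrogates.

    Each power cell is compared with the (1 − alpha) quantile of surrogate
    power at the same frequency (pooled over time, the null being
    stationary).  The mask is stored on the spectrogram and returned;
    identical seeds give identical masks.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_surrogates < 30:
        raise ValueError("need at least 30 surrogates for a stable quantile")
    stride = max(1, spec.times.size // 256)
    cells, row_means = _surrogate_row_stats(spec, n_surrogates, seed, stride)
    thresh = np.quantile(cells, 1.0 - alpha, axis=1)
    spec.mask = spec.power > thresh[:, None]
    spec._null_row_means = row_means
    return spec.mask


def periodogram(spec: Spectrogram, n_surrogates: int = 100, alpha: float = 0.05,
                seed: int = 0, prominence_frac: float = 0.05) -> Periodogram:
    """Time-averaged wavelet power per frequency with significant peaks.

    Mean power is taken over cells inside the cone of influence.  A peak
    is a local maximum of the mean-power profile that exceeds the
    (1 − alpha) quantile of the surrogate time-averaged power at its
    frequency and whose prominence is at least ``prominence_frac`` of its
    own height (wavelet power falls with frequency, so an absolute
    prominence floor would hide weak high-frequency components).  Peaks
    are returned strongest first.
    """
    valid = np.where(spec.coi_mask, spec.power, np.nan)
    mean_power = np.nanmean(valid, axis=1)
    if spec._null_row_means is None:
        stride = max(1, spec.times.size // 256)
        _, row_means = _surrogate_row_stats(spec, n_surrogates, seed, stride)
        spec._null_row_means = row_means
    thresh = np.quantile(spec._null_row_means, 1.0 - alpha, axis=0)
    idx, props = find_peaks(mean_power, height=thresh, prominence=0.0)
    keep = props["prominences"] >= prominence_frac * mean_power[idx]
    idx = idx[keep]
    order = np.argsort(mean_power[idx])[::-1]
    return Periodogram(spec.freqs, mean_power, spec.freqs[idx][order], thresh)
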