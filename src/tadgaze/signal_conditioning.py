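"""Envelope integration and burst metrics for nerve/motoneuron discharge.

Raw spike discharge (extracellular nerve recordings or simulated membrane
potential) is rectified and smoothed with a repeated moving average to give
the integral of spike activity; burst peaks detected on that envelope carry
the rhythm timing, and peak/baseline amplitudes quantify the intra-burst
firing intensity.  Conventions follow common electrophysiology practice:
a 25 ms moving average (one iteration) for nerve recordings, 15 ms with two
iterations for model motoneuron output, and interpolation-based
down-sampling to 500 Hz ahead of spectral analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, find_peaks, sosfiltfilt

#: integration defaults: (window ms, iterations)
NERVE_INTEGRATION = (25.0, 1)
MODEL_INTEGRATION = (15.0, 2)


@dataclass
class Envelope:
    """Non-negative integrated activity envelope.

    ``window_ms`` and ``iterations`` record the smoothing provenance;
    ``baseline_fallback`` is set by :func:`burst_metrics` when a burst had
    no flanking trough and the global minimum was used instead.
    """

    values: np.ndarray
    rate: float
    window_ms: float
    iterations: int
    baseline_fallback: bool = False

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.rate


@dataclass
class BurstTable:
    """Per-burst timing and amplitude metrics (times in seconds)."""

    onset_s: np.ndarray
    peak_s: np.ndarray
    peak_value: np.ndarray
    baseline: np.ndarray
    amplitude: np.ndarray

    @property
    def n(self) -> int:
        return self.peak_s.size


def rectify_integrate(trace, rate: float, window_ms: float = 25.0,
                      iterations: int = 1) -> Envelope:
    """Rectify and repeatedly boxcar-smooth a discharge trace.

    The moving-average "time constant" is read as the boxcar window
    width (not an RC constant).  Edges are reflect-padded so short episodes
    do not acquire onset artifacts.  The operation is positively
    homogeneous (scaling the input by k > 0 scales the envelope by k) and
    leaves a constant input at its absolute value.
    """
    x = np.abs(np.asarray(trace, dtype=float))
    if x.ndim != 1 or x.size == 0:
        raise ValueError("trace must be a non-empty 1-D array")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    win = max(1, int(round(window_ms * rate / 1000.0)))
    if win > x.size:
        raise ValueError(f"window of {win} samples exceeds trace length {x.size}")
    for _ in range(int(iterations)):
        x = uniform_filter1d(x, size=win, mode="reflect")
    return Envelope(x, rate, window_ms, int(iterations))


def detect_burst_peaks(env: Envelope, threshold: float | None = None,
                       min_separation_ms: float = 20.0) -> np.ndarray:
    """Times (s) of supra-threshold local maxima of the envelope.

    The default threshold rule is mean + 1 SD of the envelope; an empty
    result (silent trace) is valid.
    """
    x = env.values
    if x.size == 0:
        raise ValueError("empty envelope")
    if threshold is None:
        threshold = float(np.mean(x) + np.std(x))
    dist = max(1, int(round(min_separation_ms * env.rate / 1000.0)))
    if np.ptp(x) == 0:  # flat trace: every sample ties, no discrete peaks
        return np.empty(0)
    # silence rule: a bursty envelope swings far relative to its mean,
    # a stationary noise envelope does not — treat the latter as silent
    # rather than marking its noise maxima
    if np.std(x) < 0.25 * np.mean(x):
        return np.empty(0)
    idx, _ = find_peaks(x, height=threshold, distance=dist,
                        prominence=float(np.std(x)))
    return idx / env.rate


def burst_metrics(env: Envelope, events: np.ndarray) -> BurstTable:
    """Peak, baseline and amplitude of each detected burst.

    The baseline of a burst is the mean envelope over the inter-burst
    windows flanking it (central half of each inter-event interval, where
    the envelope has returned toward its trough).  A lone burst with no
    flanking interval falls back to the global envelope minimum; the
    fallback is recorded on the envelope provenance.
    """
    events = np.asarray(events, dtype=float)
    x, rate = env.values, env.rate
    if events.size == 0:
        z = np.empty(0)
        return BurstTable(z, z, z, z, z)
    pk_idx = np.clip(np.round(events * rate).astype(int), 0, x.size - 1)

    # mean envelope over the central half of each inter-event gap
    gap_means = []
    for a, b in zip(pk_idx[:-1], pk_idx[1:]):
        lo = a + (b - a) // 4
        hi = b - (b - a) // 4
        gap_means.append(float(np.mean(x[lo:hi + 1])))
    gap_means = np.asarray(gap_means)

    n = pk_idx.size
    baseline = np.empty(n)
    if n == 1:
        baseline[0] = float(np.min(x))
        env.baseline_fallback = True
    else:
        for i in range(n):
            flank = gap_means[max(0, i - 1):i + 1]  # gaps i-1 and i where they exist
            baseline[i] = float(np.mean(flank))

    peak_value = x[pk_idx]
    amplitude = np.maximum(peak_value - baseline, 0.0)

    # onset: last sub-half-amplitude sample before the peak
    onset = np.empty(n)
    for i, p in enumerate(pk_idx):
        level = baseline[i] + 0.5 * amplitude[i]
        start = pk_idx[i - 1] if i else 0
        below = np.nonzero(x[start:p] < level)[0]
        onset[i] = (start + below[-1]) / rate if below.size else start / rate
    return BurstTable(onset, pk_idx / rate, peak_value, baseline, amplitude)


def rhythm_frequency(events: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean and instantaneous (1/inter-event-interval) frequency in Hz."""
    events = np.sort(np.asarray(events, dtype=float))
    if events.size < 2:
        raise ValueError("at least two events are needed to define a frequency")
    inst = 1.0 / np.diff(events)
    return float(np.mean(inst)), inst


def downsample(trace, rate: float, target_rate: float = 500.0):
    """Interpolation-based down-sampling.

    A zero-phase low-pass guard at 0.45 × target rate is applied first so
    components below the new Nyquist frequency keep their identity.
    Returns ``(values, target_rate)``.
    """
    x = np.asarray(trace, dtype=float)
    if target_rate > rate:
        raise ValueError(f"cannot up-sample: target {target_rate} Hz > source {rate} Hz")
    if target_rate == rate:
        return x.copy(), rate
    sos = butter(8, 0.45 * target_rate / (rate / 2.0), output="sos")
    x = sosfiltfilt(sos, x)
    n_out = int(round(x.size * target_rate / rate))
    t_src = np.arange(x.size) / rate
    t_out = np.arange(n_out) / target_rate
    return np.interp(t_out, t_src, x), target_rate
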