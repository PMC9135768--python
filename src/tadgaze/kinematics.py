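"""Swim-cycle kinematics of eye and tail traces.

Tail traces are segmented into swim cycles (onset = hysteresis-qualified
departure from the null angle after a full excursion); per-cycle
peak-to-peak amplitudes give the spino-ocular gain, and a cross-correlation
within one cycle gives the eye-re-tail phase.  Slow, vestibular-frequency
structure is separated from the fast per-cycle oscillation by interpolating
between cycle-mean eye positions (the eccentricity trace); the ranges of
the per-cycle amplitude and of the slow component over ≥ 4 stimulus cycles
are the Δ-magnitude and Δ-eccentricity modulation metrics.

Angle convention: positive = leftward deviation from the longitudinal head
axis viewed from above.  Phase convention for sinusoid fits: a perfectly
compensatory response has phase 0°, leads are positive, wrapped to
(−180°, 180°].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.signal import butter, correlate, correlation_lags, sosfiltfilt, welch

from tadgaze.traces import AngleTrace


@dataclass
class SwimCycleTable:
    """Per-swim-cycle kinematic summary."""

    frame: pd.DataFrame  # onset_s, tail_ptp_deg, eye_ptp_deg, inst_freq_hz, eye_mean_deg

    @property
    def n(self) -> int:
        return len(self.frame)

    def __getitem__(self, col: str) -> np.ndarray:
        return self.frame[col].to_numpy()


@dataclass(frozen=True)
class ResponseFit:
    gain: float
    phase_deg: float     # (−180, 180], positive = lead re stimulus
    freq_hz: float


@dataclass(frozen=True)
class ModulationMetrics:
    delta_magnitude_deg: float
    delta_eccentricity_deg: float
    n_vestibular_cycles: int


def lowpass_20(trace: np.ndarray, rate: float, cutoff_hz: float = 20.0) -> np.ndarray:
    """Zero-phase 20 Hz low-pass (4th-order Butterworth, filtfilt)."""
    if rate <= 2 * cutoff_hz:
        raise ValueError(f"sampling rate {rate} Hz too low for a {cutoff_hz} Hz low-pass")
    sos = butter(4, cutoff_hz / (rate / 2.0), output="sos")
    return sosfiltfilt(sos, np.asarray(trace, dtype=float))


def segment_swim_cycles(tail: np.ndarray, rate: float,
                        hysteresis_deg: float = 1.0) -> np.ndarray:
    """Cycle onset times (s) of a tail oscillation.

    An onset is an upward crossing of +hysteresis that follows an excursion
    below −hysteresis (so each onset marks one full left-right
    oscillation); quiescent traces yield no cycles.
    """
    x = np.asarray(tail, dtype=float)
    h = float(hysteresis_deg)
    onsets = []
    armed = False          # saw the negative half-excursion since last onset
    started = False        # saw any supra-hysteresis activity at all
    for i in range(1, x.size):
        if x[i] < -h:
            armed = True
            started = True
        if (armed or not started) and x[i - 1] < h <= x[i]:
            if not started:
                started = True
                armed = False
                onsets.append(i)
            elif armed:
                armed = False
                onsets.append(i)
    return np.asarray(onsets, dtype=float) / rate


def _cycle_spans(onsets_s: np.ndarray, rate: float, n_samples: int) -> list[tuple[int, int]]:
    """Sample-index spans per cycle; the last cycle reuses the median period."""
    idx = np.round(onsets_s * rate).astype(int)
    spans = [(a, b) for a, b in zip(idx[:-1], idx[1:])]
    if idx.size >= 2:
        period = int(round(np.median(np.diff(idx))))
    else:
        period = n_samples - idx[-1] if idx.size else 0
    if idx.size:
        spans.append((idx[-1], min(idx[-1] + max(period, 1), n_samples)))
    return spans


def per_cycle_amplitudes(eye: np.ndarray, tail: np.ndarray, onsets_s: np.ndarray,
                         rate: float) -> SwimCycleTable:
    """Peak-to-peak eye/tail amplitude and mean eye position per swim cycle."""
    eye = np.asarray(eye, dtype=float)
    tail = np.asarray(tail, dtype=float)
    if eye.size != tail.size:
        raise ValueError("eye and tail traces must share the time base")
    onsets_s = np.asarray(onsets_s, dtype=float)
    if onsets_s.size and (onsets_s[0] < 0 or onsets_s[-1] * rate >= eye.size):
        raise ValueError("cycle onsets fall outside the trace span")
    rows = []
    spans = _cycle_spans(onsets_s, rate, eye.size)
    for k, (a, b) in enumerate(spans):
        seg_e, seg_t = eye[a:b], tail[a:b]
        dur = (b - a) / rate
        rows.append({
            "onset_s": onsets_s[k],
            "tail_ptp_deg": float(np.ptp(seg_t)) if seg_t.size else 0.0,
            "eye_ptp_deg": float(np.ptp(seg_e)) if seg_e.size else 0.0,
            "inst_freq_hz": 1.0 / dur if dur > 0 else np.nan,
            "eye_mean_deg": float(np.mean(seg_e)) if seg_e.size else np.nan,
        })
    cols = ["onset_s", "tail_ptp_deg", "eye_ptp_deg", "inst_freq_hz", "eye_mean_deg"]
    return SwimCycleTable(pd.DataFrame(rows, columns=cols))


def spino_ocular_gain_phase(table: SwimCycleTable, eye: np.ndarray, tail: np.ndarray,
                            rate: float) -> tuple[np.ndarray, float]:
    """Per-cycle eye/tail gain and the eye-re-tail phase in swim-cycle degrees.

    Gain is the per-cycle peak-to-peak ratio (cycles with zero tail
    amplitude are dropped).  Phase is taken from the cross-correlation peak
    within ± half a cycle; positive values are phase lags of the eye re the
    (rostral) tail.
    """
    if table.n < 5:
        raise ValueError("gain/phase estimation needs at least 5 swim cycles")
    tail_ptp = table["tail_ptp_deg"]
    eye_ptp = table["eye_ptp_deg"]
    ok = tail_ptp > 0
    gains = eye_ptp[ok] / tail_ptp[ok]

    period = 1.0 / float(np.nanmedian(table["inst_freq_hz"]))
    a = int(round(table["onset_s"][0] * rate))
    b = min(int(round((table["onset_s"][-1] + period) * rate)), len(eye))
    e = np.asarray(eye[a:b], dtype=float) - np.mean(eye[a:b])
    t = np.asarray(tail[a:b], dtype=float) - np.mean(tail[a:b])
    cc = correlate(e, t, mode="full")
    lags = correlation_lags(e.size, t.size, mode="full") / rate
    half = period / 2.0
    win = (lags >= -half) & (lags <= half)
    lag = float(lags[win][np.argmax(cc[win])])
    phase_deg = (lag / period) * 360.0
    return gains, phase_deg


def sinusoid_response_fit(response: np.ndarray, stimulus: np.ndarray,
                          freq_hz: float, rate: float) -> ResponseFit:
    """Least-squares single-frequency fit of a response against its stimulus.

    Both traces are projected on sin/cos at the stimulus frequency;
    gain = fitted response amplitude / fitted stimulus amplitude and
    phase = response phase − stimulus phase (0° = perfectly compensatory,
    leads positive).  At least 4 stimulus cycles must be present.
    """
    r = np.asarray(response, dtype=float)
    s = np.asarray(stimulus, dtype=float)
    if r.size != s.size:
        raise ValueError("response and stimulus must share the time base")
    if r.size / rate * freq_hz < 4:
        raise ValueError("sinusoid fit requires at least 4 stimulus cycles")
    t = np.arange(r.size) / rate
    X = np.column_stack([np.sin(2 * np.pi * freq_hz * t),
                         np.cos(2 * np.pi * freq_hz * t),
                         np.ones_like(t)])
    br, *_ = np.linalg.lstsq(X, r, rcond=None)
    bs, *_ = np.linalg.lstsq(X, s, rcond=None)
    amp_r = float(np.hypot(br[0], br[1]))
    amp_s = float(np.hypot(bs[0], bs[1]))
    if amp_s <= 0:
        raise ValueError("stimulus amplitude is zero")
    phase = np.rad2deg(np.arctan2(br[1], br[0]) - np.arctan2(bs[1], bs[0]))
    phase = (phase + 180.0) % 360.0 - 180.0
    if phase == -180.0:
        phase = 180.0
    return ResponseFit(amp_r / amp_s, float(phase), freq_hz)


def eccentricity_trace(eye: np.ndarray, table: SwimCycleTable, rate: float) -> np.ndarray:
    """Slow eye-position component by interpolation between cycle means.

    Cycle-mean eye positions anchored at cycle mid-times are joined by a
    monotone cubic (PCHIP) and held constant beyond the first/last anchor.
    Subtracting the result from the eye trace leaves the fast per-cycle
    oscillation.
    """
    eye = np.asarray(eye, dtype=float)
    if table.n < 2:
        raise ValueError("eccentricity trace needs at least 2 swim cycles")
    onset = table["onset_s"]
    dur = 1.0 / table["inst_freq_hz"]
    mid = onset + 0.5 * dur
    mean_pos = table["eye_mean_deg"]
    f = PchipInterpolator(mid, mean_pos, extrapolate=False)
    t = np.arange(eye.size) / rate
    out = f(t)
    out[t <= mid[0]] = mean_pos[0]
    out[t >= mid[-1]] = mean_pos[-1]
    return out


def modulation_metrics(table: SwimCycleTable, slow_trace: np.ndarray,
                       vest_freq_hz: float, rate: float,
                       window_s: tuple | None = None) -> ModulationMetrics:
    """Δ-magnitude and Δ-eccentricity of eye motion during head rotation.

    Δ-magnitude is the range (max − min) of the per-cycle eye peak-to-peak
    amplitude, Δ-eccentricity the range of the slow eye-position component,
    both evaluated over the analyzed window, which must contain at least
    four vestibular stimulus cycles.  ``window_s`` restricts the analysis
    to steady swimming (cycles with onset inside the window and the
    matching stretch of the slow trace); episode on/off ramps otherwise
    masquerade as amplitude modulation.
    """
    slow = np.asarray(slow_trace, dtype=float)
    amps = table["eye_ptp_deg"]
    if window_s is not None:
        lo, hi = window_s
        keep = (table["onset_s"] >= lo) & (table["onset_s"] <= hi)
        amps = amps[keep]
        slow = slow[int(lo * rate):int(hi * rate)]
    n_vest = int(np.floor(slow.size / rate * vest_freq_hz))
    if n_vest < 4:
        raise ValueError(
            f"modulation metrics require >= 4 vestibular stimulus cycles, got {n_vest}")
    if amps.size < 2:
        raise ValueError("modulation metrics require a populated swim-cycle table")
    dmag = float(np.ptp(amps))
    decc = float(np.ptp(slow[np.isfinite(slow)]))
    return ModulationMetrics(dmag, decc, n_vest)


def drift_screen(trace: np.ndarray, rate: float, stim_freq_hz: float,
                 slope_threshold_deg_s: float = 0.1,
                 power_ratio_threshold: float = 0.5) -> tuple[bool, float]:
    """Screen for stimulus-unrelated slow positional drift.

    Fails (returns ``(False, slope)``) when the linear trend exceeds the
    slope threshold or when spectral power below stimulus-frequency/4
    exceeds ``power_ratio_threshold`` × the power at the stimulus band.
    Both thresholds are configuration, and the outcome is deterministic.
    """
    x = np.asarray(trace, dtype=float)
    if x.size / rate * stim_freq_hz < 4:
        raise ValueError("drift screen needs at least 4 stimulus cycles")
    t = np.arange(x.size) / rate
    # trend taken on the sub-stimulus band: a raw regression would pick up
    # the stimulus sinusoid itself (integral of t*sin over full cycles is
    # not zero)
    sos = butter(2, (stim_freq_hz / 4.0) / (rate / 2.0), output="sos")
    trend = sosfiltfilt(sos, x)
    slope = float(np.polyfit(t, trend, 1)[0])
    if abs(slope) > slope_threshold_deg_s:
        return False, slope

    detr = x - np.polyval(np.polyfit(t, x, 1), t)
    nper = min(x.size, int(rate * max(8.0 / stim_freq_hz, 4.0)))
    f, p = welch(detr, fs=rate, nperseg=nper)
    lo = (f > 0) & (f <= stim_freq_hz / 4.0)
    band = (f >= 0.5 * stim_freq_hz) & (f <= 1.5 * stim_freq_hz)
    p_lo = float(np.sum(p[lo]))
    p_band = float(np.sum(p[band]))
    if p_band > 0 and p_lo / p_band > power_ratio_threshold:
        return False, slope
    return True, slope
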