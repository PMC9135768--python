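"""Seeded generators of eye/tail/stimulus traces and nerve-like discharge.

Every analysis stage of the package is exercised on synthetic traces whose
statistical structure matches the recordings the pipeline was designed
for: episodic tail undulation at a stage-dependent swim frequency
(6–15 Hz across larval stages), eye movements coupled to the tail with a
configurable gain and phase lag, slow vestibular-frequency modulation of
eye magnitude and eccentricity during simulated head rotation, and
Poisson-burst nerve discharge.

Stage presets encode the published stage-typical quantities (swim
frequency, spino-ocular gain, modulation depths); envelope shape and noise
level are synthetic-only choices.  All randomness flows from the explicit
seed of each generator call.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from tadgaze.traces import AngleTrace


@dataclass(frozen=True)
class StagePreset:
    """Generator parameters for one developmental-stage archetype."""

    name: str
    swim_freq_hz: float
    tail_amp_deg: float              # half-range of tail deflection
    gain: float                      # eye/tail peak-to-peak ratio
    phase_lag_deg: float             # eye lag re tail, in swim-cycle degrees
    eye_amplitude_mode: str          # "invariant" | "proportional"
    invariant_eye_ptp_deg: float     # used in invariant mode
    vest_freq_hz: float | None       # None = no head rotation
    vest_amp_deg: float
    magnitude_mod_depth_deg: float   # range of per-cycle eye ptp over vest cycles
    eccentricity_mod_depth_deg: float
    noise_sigma_deg: float = 0.5

    def __post_init__(self) -> None:
        if self.eye_amplitude_mode not in ("invariant", "proportional"):
            raise ValueError("eye_amplitude_mode must be 'invariant' or 'proportional'")
        if self.magnitude_mod_depth_deg < 0 or self.eccentricity_mod_depth_deg < 0:
            raise ValueError("modulation depths must be >= 0")


#: Stage archetypes.  Swim frequencies, gains, amplitudes and the stage-58
#: eccentricity depth are the published stage-typical values; the
#: remaining numbers (noise, tail amplitude, stage-52 depths) are
#: synthetic-only defaults.
STAGE_PRESETS: dict[str, StagePreset] = {
    # young larva: fast swimming, no angular VOR yet -> single spectral peak
    "48": StagePreset("48", swim_freq_hz=13.0, tail_amp_deg=12.0, gain=0.74,
                      phase_lag_deg=15.0, eye_amplitude_mode="invariant",
                      invariant_eye_ptp_deg=6.0, vest_freq_hz=1.0,
                      vest_amp_deg=10.0, magnitude_mod_depth_deg=0.0,
                      eccentricity_mod_depth_deg=0.0),
    # amplitude-invariant eye coupling (~5-7 deg) with gain 0.74 at ~10 deg tail
    "49": StagePreset("49", swim_freq_hz=10.0, tail_amp_deg=10.0, gain=0.74,
                      phase_lag_deg=15.0, eye_amplitude_mode="invariant",
                      invariant_eye_ptp_deg=6.0, vest_freq_hz=None,
                      vest_amp_deg=0.0, magnitude_mod_depth_deg=0.0,
                      eccentricity_mod_depth_deg=0.0),
    # aVOR emerged: swim (~6 Hz) + vestibular (1 Hz) components coexist
    "52": StagePreset("52", swim_freq_hz=6.0, tail_amp_deg=10.0, gain=0.5,
                      phase_lag_deg=20.0, eye_amplitude_mode="proportional",
                      invariant_eye_ptp_deg=0.0, vest_freq_hz=1.0,
                      vest_amp_deg=10.0, magnitude_mod_depth_deg=4.0,
                      eccentricity_mod_depth_deg=6.0),
    # late larva: proportional coupling with invariant gain ~0.4, strong modulation
    "58": StagePreset("58", swim_freq_hz=6.0, tail_amp_deg=15.0, gain=0.4,
                      phase_lag_deg=30.0, eye_amplitude_mode="proportional",
                      invariant_eye_ptp_deg=0.0, vest_freq_hz=1.0,
                      vest_amp_deg=10.0, magnitude_mod_depth_deg=8.0,
                      eccentricity_mod_depth_deg=12.0),
}


def get_preset(stage: str, **overrides) -> StagePreset:
    """Look up a stage preset, optionally overriding fields."""
    try:
        preset = STAGE_PRESETS[str(stage)]
    except KeyError:
        raise KeyError(f"unknown stage {stage!r}; available: {sorted(STAGE_PRESETS)}")
    return replace(preset, **overrides) if overrides else preset


def _episode_envelope(n: int, rate: float, ramp_s: float = 0.2) -> np.ndarray:
    """Raised-cosine on/off ramps so episodes start and end smoothly."""
    env = np.ones(n)
    k = min(int(round(ramp_s * rate)), n // 2)
    if k > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(k) / k))
        env[:k] = ramp
        env[n - k:] = ramp[::-1]
    return env


def make_tail_trace(preset: StagePreset, duration_s: float, rate: float = 500.0,
                    seed: int = 0) -> AngleTrace:
    """Episodic tail undulation at the preset swim frequency.

    A sinusoid at the swim frequency under a raised-cosine episode
    envelope, plus white angular noise.  Reproducible for a fixed seed.
    """
    if rate < 2 * preset.swim_freq_hz:
        raise ValueError(f"rate {rate} Hz below Nyquist for {preset.swim_freq_hz} Hz swim")
    if preset.vest_freq_hz is not None and duration_s * preset.vest_freq_hz < 4:
        raise ValueError("duration must cover >= 4 vestibular cycles for this preset")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate
    x = preset.tail_amp_deg * np.sin(2 * np.pi * preset.swim_freq_hz * t)
    x *= _episode_envelope(n, rate)
    x += rng.normal(0.0, preset.noise_sigma_deg, size=n)
    return AngleTrace(x, rate, role="tail")


def make_eye_traces(tail: AngleTrace, preset: StagePreset,
                    seed: int = 1) -> tuple[AngleTrace, AngleTrace]:
    """Conjugate left/right eye traces coupled to a tail trace.

    The fast component is the tail oscillation scaled by the spino-ocular
    gain (or clamped to the invariant eye amplitude) and delayed by the
    preset phase lag.  On top ride the two vestibular-frequency
    modulations: a multiplicative magnitude envelope whose per-cycle
    peak-to-peak range equals the magnitude depth, and an additive
    eccentricity carrier whose range equals the eccentricity depth.
    """
    if tail.role != "tail":
        raise ValueError("make_eye_traces expects a tail trace")
    rng = np.random.default_rng(seed)
    rate, n = tail.rate, tail.n
    t = tail.times
    lag_s = (preset.phase_lag_deg / 360.0) / preset.swim_freq_hz
    shift = int(round(lag_s * rate))
    lagged = np.roll(tail.values, shift)
    lagged[:shift] = 0.0

    if preset.eye_amplitude_mode == "invariant":
        # eye excursion clamped to the preset amplitude no matter how far
        # the tail swings: normalize by the tail's instantaneous amplitude
        from scipy.signal import hilbert
        inst_amp = np.abs(hilbert(lagged))
        win = max(1, int(round(rate / preset.swim_freq_hz)))
        from scipy.ndimage import uniform_filter1d
        inst_amp = uniform_filter1d(inst_amp, size=win, mode="nearest")
        floor = 0.1 * float(np.max(inst_amp)) or 1.0
        base = (lagged / np.maximum(inst_amp, floor)
                * (preset.invariant_eye_ptp_deg / 2.0)
                * np.clip(inst_amp / floor, 0.0, 1.0))
        base_ptp = preset.invariant_eye_ptp_deg
    else:
        base = preset.gain * lagged
        base_ptp = preset.gain * 2.0 * preset.tail_amp_deg

    fast = base
    slow = np.zeros(n)
    if preset.vest_freq_hz is not None:
        w = 2 * np.pi * preset.vest_freq_hz * t
        if preset.magnitude_mod_depth_deg > 0 and base_ptp > 0:
            fast = base * (1.0 + preset.magnitude_mod_depth_deg / (2.0 * base_ptp)
                           * np.sin(w))
        slow = 0.5 * preset.eccentricity_mod_depth_deg * np.sin(w)

    def one_eye() -> np.ndarray:
        return fast + slow + rng.normal(0.0, preset.noise_sigma_deg, size=n)

    left = AngleTrace(one_eye(), rate, role="left_eye")
    right = AngleTrace(one_eye(), rate, role="right_eye")
    return left, right


def make_stimulus_trace(freq_hz: float, amplitude_deg: float, duration_s: float,
                        rate: float = 500.0) -> AngleTrace:
    """Pure sinusoidal turntable-position trace (amplitude = half-range)."""
    if freq_hz <= 0:
        raise ValueError("stimulus frequency must be positive")
    t = np.arange(int(round(duration_s * rate))) / rate
    return AngleTrace(amplitude_deg * np.sin(2 * np.pi * freq_hz * t), rate,
                      role="stimulus")


def make_nerve_trace(rate_envelope_hz: np.ndarray, rate: float, seed: int = 0,
                     noise_sigma: float = 0.02) -> np.ndarray:
    """Nerve-like voltage trace from an instantaneous firing-rate envelope.

    Spikes are drawn as an inhomogeneous Poisson process driven by the
    envelope (Hz), convolved with a biphasic ~1.5 ms extracellular
    waveform, plus Gaussian noise.  Rectify-and-integrate recovers the
    envelope shape.
    """
    lam = np.asarray(rate_envelope_hz, dtype=float)
    if np.any(lam < 0):
        raise ValueError("rate envelope must be non-negative")
    rng = np.random.default_rng(seed)
    spikes = rng.random(lam.size) < lam / rate
    tw = np.arange(int(round(0.0015 * rate)))
    sigma = max(len(tw) / 6.0, 1.0)
    center = len(tw) / 2.0
    wave = -(tw - center) / sigma * np.exp(-0.5 * ((tw - center) / sigma) ** 2)
    v = np.convolve(spikes.astype(float), wave, mode="same")
    return v + rng.normal(0.0, noise_sigma, size=lam.size)


def make_stage_bundle(stage: str, duration_s: float, rate: float = 500.0,
                      seed: int = 0) -> dict[str, AngleTrace]:
    """Full synthetic recording: tail, both eyes and (if any) the stimulus."""
    preset = get_preset(stage)
    tail = make_tail_trace(preset, duration_s, rate, seed=seed)
    left, right = make_eye_traces(tail, preset, seed=seed + 1)
    out = {"tail": tail, "left_eye": left, "right_eye": right}
    if preset.vest_freq_hz is not None:
        out["stimulus"] = make_stimulus_trace(preset.vest_freq_hz,
                                              preset.vest_amp_deg, duration_s, rate)
    return out
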