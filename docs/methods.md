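# Methods

`tadgaze` couples two things: a 14-neuron conductance-based model of how a
larval swim central pattern generator (CPG) interacts with vestibulo-ocular
signalling, and the trace-analysis pipeline used to quantify
gaze-stabilizing eye movements in swimming Xenopus larvae.  This note
records the model, its assumptions, the tunable parameters, what the
synthetic-data generators do and do not emulate, the numerical choices,
and the known limitations.

## The circuit model

### Architecture

Seven cell roles per side, fourteen neurons in total, built from three
membrane templates:

| role   | template    | function |
|--------|-------------|----------|
| dIN    | `dIN`       | descending excitatory interneuron; the CPG kernel |
| cIN    | `MN`        | commissural inhibitory interneuron |
| sp MN  | `MN`        | spinal motoneuron (fictive swim readout) |
| EC     | `MN`        | efference-copy interneuron, sp MN → contralateral Abd MN |
| VO     | `vest_spin` | vestibulo-ocular neuron → contralateral Abd MN |
| VS     | `vest_spin` | vestibulo-spinal neuron → ipsilateral sp MN and EC |
| Abd MN | `MN`        | abducens motoneuron (ocular readout) |

Wiring per side: dIN excites the ipsilateral cIN and sp MN and itself
(recurrent AMPA + NMDA); cIN inhibits the contralateral cIN, dIN and
sp MN; sp MN excites the ipsilateral EC; EC excites the contralateral
Abd MN; VO excites the contralateral Abd MN; VS excites the ipsilateral
sp MN and EC.  Each VO additionally receives a strictly periodic 10 Hz
inhibitory synaptic drive whose maximal conductance is

    gGABA_Max = num_syn_Inh · Unitary_gGABA · sigmCoeff
    sigmCoeff = sigmAmp · logistic(sigmSteep · (iCPG − iTrans))

where iCPG is the mean step current injected into the two dINs.  With the
defaults (iTrans = 0.16 nA, sigmSteep = 200 /nA, sigmAmp = 1,
num_syn_Inh = 10, Unitary_gGABA = 1 nS, two-exponential events with
τ₁ = 0.5 ms and τ₂ = 100 ms) the gate is effectively open below
≈0.15 nA and closed above ≈0.17 nA, silencing the angular VOR at high
swim rates without touching VS.

### Membrane and synapse dynamics

All neurons are single-compartment Hodgkin–Huxley cells with the
classical squid Na/K/leak kinetics (gNa = 1200 nS, gK = 360 nS,
gL = 3 nS, C = 10 pF, ENa = +50 mV, EK = −77 mV; resting potential
≈ −65 mV).  These are type-II neurons: they need a fast-rising input to
fire and do not respond to slow current ramps, which matters twice below.
Synapses are linear two-exponential conductances normalized so one event
peaks at g_max; NMDA carries the standard sigmoidal magnesium-block
factor 1/(1 + 0.28·exp(−0.062·V)) for 1 mM Mg²⁺.  A uniform 1 ms
axonal/synaptic delay applies.

Two deviations from the plain template:

* **dIN adaptation.**  dIN carries a spike-triggered, K-like adaptation
  conductance (increment b = 1.105 per spike on g_a = 53.7 nS, decay
  τ_a = 29.4 ms).  One dIN spike per cycle plus this adaptation turns
  each dIN into a relaxation oscillator whose period shortens with
  injected current; the two sides are held in alternation by the
  commissural inhibition (25 nS, decay 12.75 ms).  This is the mechanism
  that produces the drive-dependent swim rhythm.
* **dIN leak reversal −51 mV** (vs −54.4 mV elsewhere).  This small
  depolarizing bias places the current→frequency curve on the branch
  that reproduces the published anchors (below).

The motor relay synapses (dIN→spMN, spMN→EC, EC→AbdMN, VS→*, VO→AbdMN)
decay with τ = 25 ms so motoneurons fire short graded bursts rather than
1:1 spike copies; cIN→spMN inhibition decays more slowly (40 ms) so the
motoneuron is shielded through the whole contralateral half-cycle.

### Calibration

The membrane/synaptic parameter values are not published for this
circuit; they were calibrated in-repo (`scripts/calibrate_model.py`,
Nelder–Mead on five parameters) against the published current→frequency
anchors, each measured by the same procedure used to report it
(5 s step with 50 ms left–right onset offset; integrate the motoneuron
trace with a 15 ms moving average, two iterations; detect burst peaks;
average the instantaneous burst frequency after discarding the first
0.5 s):

| drive (nA) | measured neuron | calibrated model (Hz) | published anchor (Hz) |
|-----------:|-----------------|----------------------:|----------------------:|
| 0.0  | sp MN | 0 (no rhythm) | 0 |
| 0.13 + 1 Hz VO/VS sinusoid | sp MN | 6.41 | 6 |
| 0.15 | sp MN | 7.32 | 7 |
| 0.16 + 1 Hz VO/VS sinusoid | Abd MN | 7.98 | 8 |
| 0.30 | sp MN | 11.83 | ~12 |

The frequency map is monotone over 0.12–0.3 nA.  The 0.3 nA endpoint is
mode-locked: nearby parameter sets jump between ≈11.8 and ≈13 Hz, so it
is treated as approximate (asserted at ±1.5 Hz in the invariant tests).

### Stimulation conventions

* `step_into_dins(I)` injects a constant current into both dINs, the
  right side delayed by 50 ms.
* `sinusoid_into(roles, A, f)` injects A·sin(2πft) into the named
  vestibular neurons.  The default amplitude is **0.2 nA**: being type-II,
  the vest_spin cells ignore a 0.1 nA, 1 Hz sinusoid entirely
  (accommodation), while 0.5 nA recruits spiking through the whole cycle
  via rebound.  At 0.2 nA VO fires only during the depolarizing
  half-cycle, the regime the model is meant to reproduce.

### Integration

Fixed-step exponential Euler at dt = 0.025 ms for the voltage and all
gating variables, compiled with numba; spike detection is the upward
crossing of 0 mV with a 2 ms refractory window.  Non-finite state aborts
the run with an error naming the step size.  Identical parameters,
stimuli and seed give bit-identical spike times (the seed only matters if
gate-event jitter is enabled; it is off by default).

## Trace analysis

* **Envelope integration** (`rectify_integrate`): rectification followed
  by a repeated boxcar average; the moving-average "time constant" is
  read as the boxcar width.  Nerve traces use 25 ms × 1, model
  motoneuron traces 15 ms × 2 on the membrane potential referenced to
  −50 mV and half-wave rectified.  Edges are reflect-padded.
* **Burst detection**: supra-threshold local maxima of the envelope with
  a minimum separation; the default height rule is mean + 1 SD, with a
  matching prominence requirement and a silence rule (an envelope whose
  SD is below 25 % of its mean is stationary noise, not bursting).
* **Burst metrics**: per burst, peak value, baseline (mean envelope over
  the central half of the flanking inter-burst gaps) and amplitude
  (peak − baseline).  A lone burst falls back to the global minimum and
  flags the envelope.
* **Cycle kinematics**: tail traces are low-passed at 20 Hz (4th-order
  zero-phase Butterworth); a swim cycle starts at an upward crossing of
  +1° (hysteresis) following an excursion below −1°.  Per cycle the
  peak-to-peak tail and eye amplitudes, instantaneous frequency and mean
  eye position are tabulated.  Spino-ocular gain is the per-cycle
  peak-to-peak ratio; phase comes from the cross-correlation peak within
  ± half a cycle, in swim-cycle degrees (lags positive).
* **Eccentricity decomposition**: cycle-mean eye positions at cycle
  mid-times are joined by a monotone cubic (PCHIP) to give the slow
  component; Δ-eccentricity is its range, Δ-magnitude the range of the
  per-cycle eye amplitude, both over ≥ 4 vestibular stimulus cycles and,
  when a window is given, restricted to steady swimming — the raised
  on/off ramps of an episode otherwise masquerade as amplitude
  modulation.
* **Drift screen**: the slow trend is estimated on the sub-stimulus band
  (below f_stim/4; a raw regression would absorb the stimulus sinusoid
  itself, whose time-integral over whole cycles is not zero).  Traces
  fail on |slope| > 0.1 °/s or on sub-band/stimulus-band power ratio
  > 0.5.  Both thresholds are configuration.
* **Spectral decomposition**: linear detrend, FFT candidate scan
  (in-band maxima above 5 × the in-band median amplitude), then a
  continuous Morlet transform (ω₀ = 6, 20 voices per octave, 0.5–16 Hz)
  computed by FFT convolution.  Significance is assessed against seeded
  white-noise surrogates matched in length and variance: pointwise cells
  against the per-frequency (1−α) quantile of surrogate power, and
  periodogram peaks against the quantile of surrogate *time-averaged*
  power.  A periodogram peak must also have prominence ≥ 5 % of its own
  height (not of the global maximum — wavelet power falls with
  frequency, so an absolute floor would hide weak fast components).  The
  cone of influence (e-folding time √2·ω₀/2πf) is excluded from means
  and peak calls.
* **Circular statistics**: mean vector (μ, r); Rayleigh uniformity test
  with Z = n r² and the standard series approximation for p; Moore's
  rank-weighted second-order test with a seeded Monte-Carlo null (the
  classical large-n 5 % critical value ≈ 1.05 is reproduced by that null
  and cross-checked in the tests); Hotelling's two-sample T² on the
  Cartesian components of per-animal mean vectors, F-distributed with
  (2, n₁+n₂−3) degrees of freedom.  Degenerate covariance is reported,
  never silently passed.  Degrees at the API, radians internally.

## Synthetic data

Stage presets encode published, stage-typical quantities as generator
inputs: swim frequency (13, 10, 6, 6 Hz for stages 48/49/52/58),
spino-ocular gain (0.74 invariant-amplitude at young stages, 0.4
proportional at stage 58), vestibular stimulus (1 Hz, ±10°) and the
stage-58 eccentricity-modulation depth (12°).  Everything else — noise
σ (0.5°), tail amplitudes, the 200 ms raised-cosine episode ramps, the
stage-52 modulation depths — is a synthetic-only choice.  Eye traces are
a gain-scaled, phase-lagged copy of the tail drive (in invariant mode
normalized by the tail's instantaneous Hilbert amplitude so the eye
excursion really is clamped), plus a multiplicative magnitude envelope
and an additive eccentricity carrier at the vestibular frequency, plus
white angular noise.  Nerve traces are inhomogeneous Poisson spike
trains convolved with a biphasic ~1.5 ms waveform.

What the generators do **not** emulate: saccade-like quick phases,
torsional components, tracking noise with temporal correlation,
amplitude asymmetries between eyes, episode-to-episode variability of
swim frequency.  Passing the recovery tests therefore shows that the
estimators are unbiased at realistic noise levels on well-formed traces,
not that they are robust to every artifact of real video tracking — the
drift screen exists precisely because real traces are not always
well-formed.

## Known limitations

* **Burst-amplitude vs baseline modulation.**  In the real circuit (and
  the claim this model mirrors), sinusoidal vestibular drive modulates
  the Abd MN burst *amplitude* through the ungated VS pathway at every
  swim frequency, while the *baseline* modulation through VO collapses
  once the gate closes.  In this implementation the baseline half is
  reproduced cleanly (below the gate the 1 Hz-locked baseline depth is
  ≈4–5 envelope units, above it < 0.25; Pearson r ≈ −0.86 against swim
  frequency), but the amplitude-flatness half is not: envelope peaks of
  a single-compartment HH motoneuron are refractory-saturated, so
  peak − baseline mirrors the baseline series almost exactly
  (r ≈ 0.99 between the two depth series) and inherits its downward
  trend.  Graded multi-spike bursts, motoneuron adaptation, slower relay
  kinetics, rebalanced VS/VO weights and several alternative estimators
  (swim-locked windows, area-based amplitudes, subthreshold-inclusive
  envelopes) all fail for the same reason.  The corresponding acceptance
  test is left failing deliberately; removing the saturation would need
  a motoneuron with a graded firing-rate range well above the CPG's
  spike rates (e.g. a multi-compartment or rate-coded readout), which is
  outside this model's scope.
* **Half-center phase.**  Alternation is stable and never synchronous,
  but the locked phase is exactly 180° only at low drive (≤ 0.13 nA);
  at mid drives it sits at 139–160° because the 50 ms onset offset falls
  in the phase-response dead zone of the brief commissural inhibition,
  and at 0.3 nA at 260°.  Longer inhibition restores global antiphase
  but destroys the calibrated frequency map; the frequencies were
  prioritized.
* The model covers one spinal segment; there is no rostro-caudal wave,
  no multi-segment coordination, and no claim of biophysical realism
  beyond the printed input–output mapping.
* `run_protocol_grid` reports modulation depths as twice the fitted
  amplitude of the stimulus-frequency component of the per-burst series
  (not the raw range), which rejects burst-to-burst jitter.
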