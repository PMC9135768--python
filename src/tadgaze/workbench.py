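"""Scripted end-to-end analyses and run manifests.

Two workflows are wired here: the model frequency map / gating scan of the
spiking network, and the trace-analysis pipeline (drift screen, swim-cycle
table, gains and phases, modulation metrics, spectral decomposition) that
turns a CSV of angle traces into a metrics bundle.  Every run writes a
manifest (config snapshot, seed, package version, per-step timing, output
registry) sufficient to re-run bit-identically.
"""

from __future__ import annotations

import json
import pathlib
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

import tadgaze
from tadgaze import circuit_model as cm
from tadgaze import kinematics as kin
from tadgaze import signal_conditioning as sc
from tadgaze import spectral_analysis as sa
from tadgaze.traces import ROLES, read_trace_csv


@dataclass
class RunManifest:
    """Record of one workbench run; serializes to manifest.json."""

    command: str
    seed: int
    config: dict = field(default_factory=dict)
    version: str = tadgaze.__version__
    timings_s: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def register(self, name: str, path) -> None:
        self.outputs[name] = str(path)

    def write(self, out_dir) -> pathlib.Path:
        path = pathlib.Path(out_dir) / "manifest.json"
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, default=str)
        self.register("manifest", path)
        return path


class ConfigurationError(RuntimeError):
    pass


class SchemaError(ValueError):
    pass


def reproduce_model_map(out_dir, istim_values=None, duration_s: float = 5.0,
                        vest_freq_hz: float = 1.0, vest_amp_nA: float = 0.2,
                        seed: int = 0, config: dict | None = None) -> pd.DataFrame:
    """Sweep dIN drive and write the frequency map + gating scan.

    Produces ``model_map.csv`` with one row per iStim (swim frequency,
    Abd MN modulation depths, VO spike count and the gate coefficient) and
    a manifest.  The network must carry calibrated parameters; a missing or
    incomplete configuration is an explicit error pointing at
    ``scripts/calibrate_model.py``.
    """
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        net = cm.build_default_network(config)
    except (KeyError, FileNotFoundError) as exc:
        raise ConfigurationError(
            "model configuration incomplete; re-run scripts/calibrate_model.py "
            f"to regenerate the calibrated defaults ({exc})") from exc
    if istim_values is None:
        istim_values = [0.0, 0.1, 0.12, 0.13, 0.14, 0.15, 0.16, 0.17, 0.18,
                        0.2, 0.22, 0.26, 0.3]
    man = RunManifest("reproduce-model-map", seed, net.config)
    t0 = time.time()
    grid = cm.run_protocol_grid(net, istim_values, vest_freq_hz, vest_amp_nA,
                                duration_s, seed=seed)
    grid["gate_coeff"] = [cm.gating_coefficient(i, net.gating)
                          for i in grid["istim_nA"]]
    man.timings_s["grid"] = round(time.time() - t0, 3)
    path = out / "model_map.csv"
    grid.to_csv(path, index=False)
    man.register("model_map", path)
    man.write(out)
    return grid


def analyze_trace_pipeline(trace_csv, out_dir, vest_freq_hz: float = 1.0,
                           min_cycles: int = 4, swim_hysteresis_deg: float = 1.0,
                           n_surrogates: int = 100, seed: int = 0,
                           eye_channel: str = "left_eye") -> dict:
    """Full behavioural analysis of an angle-trace CSV.

    Runs, in order: schema validation, the 20 Hz low-pass, the drift
    screen, swim-cycle segmentation with per-cycle amplitudes, the
    spino-ocular gain/phase, eccentricity extraction with modulation
    metrics (when a vestibular stimulus is present), and the wavelet
    spectrogram/periodogram of the analyzed eye trace.  Writes
    ``cycles.csv``, ``metrics.json``, ``periodogram.csv``,
    ``spectrogram_power.csv`` and a manifest; returns the metrics dict.
    """
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    man = RunManifest("analyze", seed)
    t0 = time.time()
    try:
        traces = read_trace_csv(trace_csv)
    except Exception as exc:
        raise SchemaError(f"{trace_csv}: {exc}") from exc
    if "tail" not in traces or eye_channel not in traces:
        raise SchemaError(
            f"{trace_csv}: need columns tail_deg and {eye_channel}_deg; "
            f"found {[f'{r}_deg' for r in ROLES if r in traces]}")
    rate = traces["tail"].rate
    tail = kin.lowpass_20(traces["tail"].values, rate)
    eye = kin.lowpass_20(traces[eye_channel].values, rate)
    man.timings_s["load_filter"] = round(time.time() - t0, 3)

    metrics: dict = {"rate_hz": rate, "eye_channel": eye_channel,
                     "duration_s": len(tail) / rate}
    has_stim = "stimulus" in traces
    if has_stim:
        ok, slope = kin.drift_screen(eye, rate, vest_freq_hz)
        metrics["drift_screen"] = {"pass": bool(ok), "slope_deg_s": slope}

    onsets = kin.segment_swim_cycles(tail, rate, swim_hysteresis_deg)
    table = kin.per_cycle_amplitudes(eye, tail, onsets, rate)
    cyc_path = out / "cycles.csv"
    table.frame.to_csv(cyc_path, index=False)
    man.register("cycles", cyc_path)
    metrics["n_cycles"] = table.n
    if table.n >= 2:
        metrics["swim_freq_hz"] = float(np.nanmedian(table["inst_freq_hz"]))
    if table.n >= 5:
        gains, phase = kin.spino_ocular_gain_phase(table, eye, tail, rate)
        metrics["gain_mean"] = float(np.mean(gains))
        metrics["gain_sd"] = float(np.std(gains))
        metrics["phase_deg"] = phase
    if has_stim and table.n >= 2:
        slow = kin.eccentricity_trace(eye, table, rate)
        duration = len(tail) / rate
        steady = (0.4, duration - 0.4) if duration > 2.0 else None
        mod = kin.modulation_metrics(table, slow, vest_freq_hz, rate,
                                     window_s=steady)
        metrics["delta_magnitude_deg"] = mod.delta_magnitude_deg
        metrics["delta_eccentricity_deg"] = mod.delta_eccentricity_deg
        metrics["n_vestibular_cycles"] = mod.n_vestibular_cycles
    man.timings_s["kinematics"] = round(time.time() - t0, 3)

    x, r500 = sc.downsample(eye, rate, min(rate, 100.0))
    spec = sa.cwt_spectrogram(x, r500)
    sa.significance_mask(spec, n_surrogates=n_surrogates, seed=seed)
    pgram = sa.periodogram(spec, n_surrogates=n_surrogates, seed=seed)
    metrics["periodogram_peaks_hz"] = [float(f) for f in pgram.peak_freqs]
    pd.DataFrame({"freq_hz": pgram.freqs, "mean_power": pgram.mean_power,
                  "threshold": pgram.threshold}).to_csv(
        out / "periodogram.csv", index=False)
    man.register("periodogram", out / "periodogram.csv")
    np.savetxt(out / "spectrogram_power.csv", spec.power, delimiter=",")
    man.register("spectrogram_power", out / "spectrogram_power.csv")
    man.timings_s["spectral"] = round(time.time() - t0, 3)

    mpath = out / "metrics.json"
    with open(mpath, "w") as fh:
        json.dump(metrics, fh, indent=1)
    man.register("metrics", mpath)
    man.write(out)
    return metrics
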