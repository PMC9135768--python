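"""Angular-position time series and their CSV round-trip.

All behavioural quantities in this package are uniformly sampled angle
traces in degrees: eye-in-head angle (left/right), tail deflection re the
longitudinal body axis, and turntable/stimulus position.  The nominal
sampling rate of the video pipeline is 500 frames per second.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: canonical CSV column names, in writing order
CSV_COLUMNS = ("time_s", "left_eye_deg", "right_eye_deg", "tail_deg", "stimulus_deg")

#: channel roles an AngleTrace may carry
ROLES = ("left_eye", "right_eye", "tail", "stimulus")


@dataclass
class AngleTrace:
    """A uniformly sampled angular position series.

    Parameters
    ----------
    values : array of float
        Angle in degrees at each sample.
    rate : float
        Sampling rate in Hz.
    role : str
        One of ``left_eye``, ``right_eye``, ``tail``, ``stimulus``.
    t0 : float
        Time of the first sample in seconds.
    """

    values: np.ndarray
    rate: float
    role: str = "tail"
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("AngleTrace values must be one-dimensional")
        if not np.isfinite(self.rate) or self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        if self.role not in ROLES:
            raise ValueError(f"unknown channel role {self.role!r}; expected one of {ROLES}")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Trace span in seconds (n samples at 1/rate spacing)."""
        return self.n / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.rate

    def copy_with(self, values: np.ndarray, role: str | None = None) -> "AngleTrace":
        return AngleTrace(np.asarray(values, dtype=float), self.rate,
                          role or self.role, self.t0)


def traces_to_frame(traces: dict[str, AngleTrace]) -> pd.DataFrame:
    """Assemble role-keyed traces into the canonical CSV frame.

    All traces must share rate, length and origin.
    """
    if not traces:
        raise ValueError("no traces given")
    ref = next(iter(traces.values()))
    for name, tr in traces.items():
        if tr.rate != ref.rate or tr.n != ref.n or tr.t0 != ref.t0:
            raise ValueError(f"trace {name!r} does not share the common time base")
    out = pd.DataFrame({"time_s": ref.times})
    for role in ROLES:
        if role in traces:
            out[f"{role.replace('_eye', '_eye')}_deg" if role.endswith("eye")
                else f"{role}_deg"] = traces[role].values
    return out


def read_trace_csv(path) -> dict[str, AngleTrace]:
    """Read a trace CSV (columns: time_s plus any of the *_deg channels).

    Returns a dict keyed by channel role.  The sampling rate is inferred
    from the median time step and checked for uniformity (1% tolerance).
    """
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError("trace CSV must contain a time_s column")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("trace CSV must contain at least two samples")
    dt = np.diff(t)
    if np.any(dt <= 0) or np.max(np.abs(dt - np.median(dt))) > 0.01 * np.median(dt):
        raise ValueError("time_s must be uniformly increasing")
    rate = 1.0 / float(np.median(dt))
    out: dict[str, AngleTrace] = {}
    for role in ROLES:
        col = f"{role}_deg"
        if col in df.columns:
            out[role] = AngleTrace(df[col].to_numpy(dtype=float), rate, role, t0=float(t[0]))
    if not out:
        raise ValueError(f"no angle columns found; expected some of "
                         f"{[f'{r}_deg' for r in ROLES]}")
    return out


def write_trace_csv(path, traces: dict[str, AngleTrace]) -> None:
    traces_to_frame(traces).to_csv(path, index=False)
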