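"""Uniformly sampled membrane-potential time series and their text/HDF5 I/O.

A :class:`VoltageTrace` is the package's exchange currency: model output,
fitting objectives, and CTC-converted APs are all traces.  Samples are in mV
on a uniform grid (ms); the times at which stimulus pulses began are carried
as annotations so that resting potential ("the sample before stimulus onset")
and beat segmentation are well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import TraceFormatError

__all__ = ["VoltageTrace", "read_trace", "write_trace", "save_traces_h5", "load_traces_h5"]


@dataclass(frozen=True)
class VoltageTrace:
    """Uniformly sampled voltage time series with stimulus annotations.

    Parameters
    ----------
    t0 : float
        Time of the first sample (ms).
    dt : float
        Sample interval (ms), > 0.
    v : numpy.ndarray
        Voltage samples (mV), at least two.
    stim_onsets : numpy.ndarray
        Times (ms) at which stimulus pulses started, ascending.
    """

    t0: float
    dt: float
    v: np.ndarray
    stim_onsets: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        v = np.asarray(self.v, dtype=float)
        onsets = np.asarray(self.stim_onsets, dtype=float)
        object.__setattr__(self, "v", v)
        object.__setattr__(self, "stim_onsets", onsets)
        if self.dt <= 0:
            raise ValueError("sample interval must be positive")
        if v.ndim != 1 or v.size < 2:
            raise ValueError("need a 1-D trace with at least 2 samples")

    @property
    def t(self) -> np.ndarray:
        """Sample times (ms)."""
        return self.t0 + self.dt * np.arange(self.v.size)

    @property
    def t_end(self) -> float:
        return self.t0 + self.dt * (self.v.size - 1)

    def value_at(self, times: np.ndarray | float) -> np.ndarray | float:
        """Linear interpolation of the trace at arbitrary times inside its span."""
        return np.interp(times, self.t, self.v)

    def index_before(self, time: float) -> int:
        """Index of the last sample strictly before ``time``."""
        i = int(np.ceil((time - self.t0) / self.dt)) - 1
        if i < 0 or i >= self.v.size:
            raise ValueError(f"time {time} ms has no preceding sample in trace")
        return i

    def shifted(self, offset: float) -> "VoltageTrace":
        """The same trace with all times (including onsets) shifted by ``offset`` ms."""
        return VoltageTrace(self.t0 + offset, self.dt, self.v.copy(), self.stim_onsets + offset)

    def beat(self, k: int, period: float | None = None) -> "VoltageTrace":
        """Extract the ``k``-th beat (0-based) as its own trace.

        The beat spans from just after onset ``k`` minus a short pre-stimulus
        margin up to the next onset (or trace end).  The pre-stimulus margin is
        whatever data precede the onset, capped at one pacing period.
        """
        onsets = self.stim_onsets
        if k < 0 or k >= onsets.size:
            raise IndexError(f"beat {k} not annotated (only {onsets.size} onsets)")
        start = self.t0 if k == 0 else onsets[k - 1]
        if period is not None:
            start = max(start, onsets[k] - period)
        end = onsets[k + 1] if k + 1 < onsets.size else self.t_end
        i0 = max(0, int(np.ceil((start - self.t0) / self.dt)))
        i1 = min(self.v.size, int(np.floor((end - self.t0) / self.dt)) + 1)
        return VoltageTrace(self.t0 + i0 * self.dt, self.dt, self.v[i0:i1].copy(),
                            np.array([onsets[k]]))


_HEADER = "# ctclab voltage trace"


def write_trace(path, trace: VoltageTrace) -> None:
    """Write a trace as 2-column delimited text (time_ms, voltage_mV).

    The comment header carries the sample interval and stimulus-onset times so
    that :func:`read_trace` round-trips the full object.
    """
    onsets = ",".join(repr(float(x)) for x in trace.stim_onsets)
    header = (f"{_HEADER}\n# dt_ms = {trace.dt!r}\n# t0_ms = {trace.t0!r}\n"
              f"# stim_onsets_ms = {onsets}\n# time_ms\tvoltage_mV")
    with open(path, "w") as fh:
        fh.write(header + "\n")
        t = trace.t
        for i in range(trace.v.size):
            fh.write(f"{float(t[i])!r}\t{float(trace.v[i])!r}\n")


def read_trace(path) -> VoltageTrace:
    """Read a trace written by :func:`write_trace`.

    Raises
    ------
    TraceFormatError
        On malformed rows (with the 1-based row index) or a non-uniform time
        column.
    """
    dt = None
    t0 = None
    onsets: np.ndarray = np.empty(0)
    times: list[float] = []
    volts: list[float] = []
    with open(path) as fh:
        for row, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("dt_ms"):
                    dt = float(body.split("=", 1)[1])
                elif body.startswith("t0_ms"):
                    t0 = float(body.split("=", 1)[1])
                elif body.startswith("stim_onsets_ms"):
                    payload = body.split("=", 1)[1].strip()
                    onsets = (np.array([float(x) for x in payload.split(",")])
                              if payload else np.empty(0))
                continue
            parts = line.split()
            if len(parts) != 2:
                raise TraceFormatError(f"row {row}: expected 2 columns, got {len(parts)}", row)
            try:
                times.append(float(parts[0]))
                volts.append(float(parts[1]))
            except ValueError as exc:
                raise TraceFormatError(f"row {row}: non-numeric entry", row) from exc
    if dt is None or t0 is None:
        raise TraceFormatError("missing dt_ms/t0_ms header")
    t_arr = np.asarray(times)
    if t_arr.size < 2:
        raise TraceFormatError("need at least 2 samples")
    steps = np.diff(t_arr)
    if not np.allclose(steps, dt, rtol=0, atol=1e-6 * dt):
        bad = int(np.argmax(np.abs(steps - dt))) + 2
        raise TraceFormatError(f"row {bad}: non-uniform time column", bad)
    return VoltageTrace(t0, dt, np.asarray(volts), onsets)


def save_traces_h5(path, traces: dict[str, VoltageTrace]) -> None:
    """Store a batch of traces in one HDF5 container (binary, runtime only)."""
    import h5py

    with h5py.File(path, "w") as fh:
        for name, tr in traces.items():
            grp = fh.create_group(name)
            grp.create_dataset("v", data=tr.v)
            grp.create_dataset("stim_onsets", data=tr.stim_onsets)
            grp.attrs["t0"] = tr.t0
            grp.attrs["dt"] = tr.dt


def load_traces_h5(path) -> dict[str, VoltageTrace]:
    import h5py

    out = {}
    with h5py.File(path, "r") as fh:
        for name, grp in fh.items():
            out[name] = VoltageTrace(float(grp.attrs["t0"]), float(grp.attrs["dt"]),
                                     grp["v"][:], grp["stim_onsets"][:])
    return out
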