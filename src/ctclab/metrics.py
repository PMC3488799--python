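"""Action-potential morphology metrics and the sum-of-squared-differences
fitting error.

Conventions
-----------
* Upstroke onset is the interpolated time of the first upward crossing of
  -40 mV (the same alignment rule the SSD uses, chosen to avoid the stimulus
  foot artifact); all APD measures are referenced to it.
* APD80 uses the murine convention: return 80% of the way from 0 mV to the
  resting potential, i.e. a downward crossing of ``0.8 * V_rest``.
* APD30/50/90 use the amplitude convention: downward crossing of
  ``V_peak - (level/100) * (V_peak - V_rest)``.
* Crossings are linearly interpolated; a sample exactly at threshold counts
  as the crossing.
* The SSD aligns both traces at their own -40 mV upstroke crossing and sums
  squared differences on a common 300 ms grid at the coarser sample interval
  (inclusive endpoints).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import AlignmentError, UndefinedAPDError
from .trace import VoltageTrace

__all__ = ["ErrorWindow", "APDReport", "resting_potential", "align_upstroke",
           "apd_mouse80", "apd_amplitude", "ssd", "average_aps", "apd_report"]


@dataclass(frozen=True)
class ErrorWindow:
    """Alignment threshold and window of the SSD error (defaults: -40 mV, 300 ms)."""

    threshold: float = -40.0
    t_max: float = 300.0

    def __post_init__(self) -> None:
        if self.t_max <= 0:
            raise ValueError("window length must be positive")
        if not (-80.0 <= self.threshold <= 0.0):
            raise ValueError("alignment threshold must lie in [-80, 0] mV")


@dataclass(frozen=True)
class APDReport:
    """Per-beat AP morphology summary (all durations in ms, potentials in mV)."""

    apd80_mouse: float
    apd30: float
    apd50: float
    apd90: float
    resting_potential: float
    peak: float


def resting_potential(trace: VoltageTrace, beat: int = 0) -> float:
    """Membrane potential at the sample immediately preceding stimulus onset."""
    if trace.stim_onsets.size == 0:
        raise ValueError("trace carries no stimulus-onset annotation")
    onset = float(trace.stim_onsets[beat])
    return float(trace.v[trace.index_before(onset)])


def align_upstroke(trace: VoltageTrace, threshold: float = -40.0,
                   start: float | None = None) -> float:
    """Interpolated time of the first upward crossing of ``threshold``.

    ``start`` restricts the search to times >= start.  A sample exactly at
    threshold counts as the crossing.
    """
    v = trace.v
    t = trace.t
    i0 = 0 if start is None else int(np.searchsorted(t, start))
    for i in range(i0, v.size):
        if v[i] == threshold:
            if i + 1 < v.size and v[i + 1] > v[i]:
                return float(t[i])
            if i > i0 and v[i - 1] < threshold:
                return float(t[i])
        if i + 1 < v.size and v[i] < threshold < v[i + 1]:
            frac = (threshold - v[i]) / (v[i + 1] - v[i])
            return float(t[i] + frac * trace.dt)
    raise AlignmentError(f"trace never crosses {threshold} mV upward")


def _downward_crossing(trace: VoltageTrace, threshold: float, t_from: float) -> float:
    """Interpolated time of the first downward crossing of ``threshold`` after t_from."""
    v = trace.v
    t = trace.t
    i0 = int(np.searchsorted(t, t_from))
    for i in range(max(i0, 1), v.size):
        if v[i] == threshold and v[i - 1] > threshold:
            return float(t[i])
        if v[i - 1] > threshold > v[i]:
            frac = (v[i - 1] - threshold) / (v[i - 1] - v[i])
            return float(t[i - 1] + frac * trace.dt)
    raise UndefinedAPDError(
        f"no downward crossing of {threshold:.2f} mV within the beat")


def apd_mouse80(trace: VoltageTrace, beat: int = 0) -> float:
    """APD80, murine definition: onset to return 80% of the way from 0 mV to rest."""
    v_rest = resting_potential(trace, beat)
    t_on = align_upstroke(trace, -40.0, start=float(trace.stim_onsets[beat]))
    thr = 0.8 * v_rest
    return _downward_crossing(trace, thr, t_on) - t_on


def apd_amplitude(trace: VoltageTrace, level: float, beat: int = 0) -> float:
    """APD at ``level`` percent repolarization of the AP amplitude."""
    if not (0.0 < level < 100.0):
        raise ValueError("level must be in (0, 100) percent")
    v_rest = resting_potential(trace, beat)
    onset = float(trace.stim_onsets[beat])
    t_on = align_upstroke(trace, -40.0, start=onset)
    if beat + 1 < trace.stim_onsets.size:
        i_end = trace.index_before(float(trace.stim_onsets[beat + 1]))
    else:
        i_end = trace.v.size
    i_on = int(np.searchsorted(trace.t, t_on))
    v_peak = float(trace.v[i_on:i_end].max())
    thr = v_peak - (level / 100.0) * (v_peak - v_rest)
    return _downward_crossing(trace, thr, t_on) - t_on


def apd_report(trace: VoltageTrace, beat: int = 0) -> APDReport:
    """All APD measures plus resting and peak potential for one beat."""
    v_rest = resting_potential(trace, beat)
    t_on = align_upstroke(trace, -40.0, start=float(trace.stim_onsets[beat]))
    i_on = int(np.searchsorted(trace.t, t_on))
    return APDReport(
        apd80_mouse=apd_mouse80(trace, beat),
        apd30=apd_amplitude(trace, 30, beat),
        apd50=apd_amplitude(trace, 50, beat),
        apd90=apd_amplitude(trace, 90, beat),
        resting_potential=v_rest,
        peak=float(trace.v[i_on:].max()),
    )


def ssd(trace1: VoltageTrace, trace2: VoltageTrace,
        window: ErrorWindow = ErrorWindow()) -> float:
    """Sum of squared voltage differences over the aligned error window (mV^2).

    Both traces are aligned at their own upstroke crossing of the window
    threshold, resampled by linear interpolation onto a common grid at the
    coarser of the two sample intervals, and differenced over ``t_max`` ms.
    """
    t01 = align_upstroke(trace1, window.threshold)
    t02 = align_upstroke(trace2, window.threshold)
    dt = max(trace1.dt, trace2.dt)
    n = int(round(window.t_max / dt))
    tau = dt * np.arange(n + 1)
    if t01 + window.t_max > trace1.t_end + 1e-9 or t02 + window.t_max > trace2.t_end + 1e-9:
        raise ValueError("trace does not cover the full error window after alignment")
    v1 = trace1.value_at(t01 + tau)
    v2 = trace2.value_at(t02 + tau)
    return float(np.sum((v1 - v2) ** 2))


def average_aps(traces: list[VoltageTrace]) -> VoltageTrace:
    """Average beats aligned at their stimulus onsets (pointwise mean).

    All traces must share the sample interval and carry a stimulus-onset
    annotation.  The result spans the common support around the onset and is
    annotated with a single onset.
    """
    if not traces:
        raise ValueError("need at least one trace")
    dt = traces[0].dt
    for k, tr in enumerate(traces):
        if abs(tr.dt - dt) > 1e-12:
            raise ValueError(f"trace {k}: sample interval {tr.dt} != {dt}")
        if tr.stim_onsets.size == 0:
            raise ValueError(f"trace {k}: no stimulus-onset annotation")
    # common support relative to each trace's own first onset
    pre = min(float(tr.stim_onsets[0]) - tr.t0 for tr in traces)
    post = min(tr.t_end - float(tr.stim_onsets[0]) for tr in traces)
    n_pre = int(np.floor(pre / dt + 1e-9))
    n_post = int(np.floor(post / dt + 1e-9))
    tau = dt * np.arange(-n_pre, n_post + 1)
    stack = np.stack([tr.value_at(float(tr.stim_onsets[0]) + tau) for tr in traces])
    onset0 = float(traces[0].stim_onsets[0])
    return VoltageTrace(onset0 - n_pre * dt, dt, stack.mean(axis=0), np.array([onset0]))
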