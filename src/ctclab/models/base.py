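"""Shared model contract: parameter sets, stimulus/simulation settings, and
the :class:`CellModel` wrapper exposing free-running and voltage-clamped
stepping over the compiled kernels.

Sign convention (package-wide): ionic and applied currents are
capacitance-normalized (pA/pF) and outward positive; the membrane equation is
``dV/dt = -(i_ion + i_applied)`` so a depolarizing stimulus enters as a
negative applied current.  :class:`StimulusProtocol` stores the depolarizing
magnitude as a positive number.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from numba import njit

from ..exceptions import BoundsError, SimulationBlowupError
from ..trace import VoltageTrace

__all__ = ["ParameterSet", "StimulusProtocol", "SimSettings", "CellModel",
           "make_paced_loop"]


_UNITS = {"g_": "uS", "G_": "nS/pF", "i_": "nA", "P_": "pA/pF", "k_": "nA/mM^4",
          "C_m": "pF", "T": "K"}


@dataclass
class ParameterSet:
    """Named parameter vector of a cell model.

    Conductance entries must be non-negative, concentrations positive and the
    membrane capacitance positive; :meth:`validate` enforces this.
    """

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.size:
            raise ValueError("names/values length mismatch")
        self._index = {n: i for i, n in enumerate(self.names)}

    def __getitem__(self, name: str) -> float:
        return float(self.values[self._index[name]])

    def __setitem__(self, name: str, value: float) -> None:
        self.values[self._index[name]] = value

    def copy(self) -> "ParameterSet":
        return ParameterSet(self.names, self.values.copy())

    @property
    def capacitance_pf(self) -> float:
        return self["C_m"]

    def validate(self) -> None:
        for name in self.names:
            v = self[name]
            if not np.isfinite(v):
                raise BoundsError(f"{name} is not finite")
            if (name.startswith("g_") or name.startswith("G_")) and v < 0:
                raise BoundsError(f"conductance {name} < 0")
            if name in ("C_m", "T") and v <= 0:
                raise BoundsError(f"{name} must be positive")
            if name[-2:] in ("_o", "_i") and name[:2] in ("Na", "K_", "Ca") and v <= 0:
                raise BoundsError(f"concentration {name} must be positive")

    def unit_of(self, name: str) -> str:
        if name[-2:] in ("_o", "_i") and name[:2] in ("Na", "K_", "Ca"):
            return "mM"
        for prefix, unit in _UNITS.items():
            if name.startswith(prefix):
                return unit
        return ""

    def to_json(self) -> str:
        payload = {n: {"value": self[n], "unit": self.unit_of(n)} for n in self.names}
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ParameterSet":
        payload = json.loads(text)
        names = tuple(payload)
        values = np.array([payload[n]["value"] for n in names])
        return cls(names, values)


@dataclass(frozen=True)
class StimulusProtocol:
    """Periodic current-pulse pacing.

    ``amplitude`` is the depolarizing pulse magnitude in pA/pF (> 0); pulses
    of ``duration`` ms start at ``onset`` and repeat every ``period`` ms.
    """

    period: float = 1000.0
    duration: float = 1.0
    amplitude: float = 30.0
    onset: float = 50.0

    def __post_init__(self) -> None:
        if not (self.period > self.duration > 0):
            raise ValueError("need period > duration > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude is a depolarizing magnitude, >= 0")
        if self.onset < 0:
            raise ValueError("onset must be >= 0")


@dataclass(frozen=True)
class SimSettings:
    """Integration settings: Euler step, number of beats, fast-exp flag."""

    dt: float = 0.1
    beats: int = 1
    use_fast_exp: bool = False
    prepace_beats: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.beats < 0 or self.prepace_beats < 0:
            raise ValueError("beat counts must be >= 0")


def make_paced_loop(current_fn: Callable, gates_fn: Callable):
    """Compile a free-running pacing loop specialized to one model's kernels.

    Step ordering (package-wide convention): gates advance at the pre-step
    voltage, the total current is evaluated at the updated gates, then V is
    updated.  The same ordering is used by the CTC loop, which makes the
    ideal-conversion cancellation of target and canceling currents exact.

    The loop records V at every step and returns the failing step index on
    numerical blow-up (-1 on success).
    """

    @njit
    def paced_loop(p, y, dt, n_steps, onset, period, dur, amp, fast, out_v):
        out_v[0] = y[0]
        for k in range(n_steps):
            t = k * dt
            V = y[0]
            i_app = 0.0
            if t >= onset and (t - onset) % period < dur:
                i_app = -amp
            gates_fn(p, y, V, dt, fast)
            i_tot = current_fn(p, y, V, fast)
            v_new = V - dt * (i_tot + i_app)
            if not np.isfinite(v_new) or v_new < -200.0 or v_new > 200.0:
                return k
            y[0] = v_new
            out_v[k + 1] = v_new
        return -1

    return paced_loop


@dataclass
class CellModel:
    """Uniform contract over an explicit-Euler ionic model.

    Wraps the compiled per-model kernels with free-running and clamped
    stepping, total-current evaluation and 1 Hz paced simulation.  State
    vectors are plain float arrays (``state_names`` gives the layout, V
    first); instances are cheap views over a parameter vector.
    """

    name: str
    params: ParameterSet
    initial_state: np.ndarray
    state_names: tuple[str, ...]
    default_dt: float
    current_fn: Callable
    gates_fn: Callable
    paced_loop: Callable
    protocol_factory: Callable[[], StimulusProtocol]
    use_fast_exp: bool = False

    @property
    def capacitance_pf(self) -> float:
        return self.params.capacitance_pf

    def default_protocol(self) -> StimulusProtocol:
        return self.protocol_factory()

    def _check_state(self, state: np.ndarray) -> None:
        if not np.all(np.isfinite(state)):
            raise SimulationBlowupError(
                f"{self.name}: non-finite state: {np.array2string(state, precision=6)}")

    def ionic_current(self, state: np.ndarray, V: float | None = None) -> float:
        """Total membrane current at imposed V (pA/pF, outward positive)."""
        self._check_state(state)
        if V is None:
            V = float(state[0])
        return float(self.current_fn(self.params.values, state, V, self.use_fast_exp))

    def step_clamped(self, state: np.ndarray, V: float, dt: float) -> np.ndarray:
        """Advance gates/concentrations one Euler step with V held fixed."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        self._check_state(state)
        out = state.copy()
        self.gates_fn(self.params.values, out, V, dt, self.use_fast_exp)
        out[0] = V
        return out

    def step_free(self, state: np.ndarray, i_applied: float, dt: float) -> np.ndarray:
        """One free-running Euler step with an applied (outward-positive) current."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        self._check_state(state)
        V = float(state[0])
        out = state.copy()
        self.gates_fn(self.params.values, out, V, dt, self.use_fast_exp)
        i_tot = float(self.current_fn(self.params.values, out, V, self.use_fast_exp))
        out[0] = V - dt * (i_tot + i_applied)
        if not np.isfinite(out[0]) or abs(out[0]) > 200.0:
            raise SimulationBlowupError(f"{self.name}: V blow-up in step_free", 0.0)
        return out

    def simulate_paced(self, protocol: StimulusProtocol | None = None,
                       settings: SimSettings | None = None,
                       state: np.ndarray | None = None) -> VoltageTrace:
        """Free-running paced simulation from the stored resting state.

        Returns the voltage trace with stimulus onsets annotated.  Raises
        :class:`SimulationBlowupError` naming the failing time on numerical
        runaway.
        """
        if protocol is None:
            protocol = self.default_protocol()
        if settings is None:
            settings = SimSettings(dt=self.default_dt)
        y = (self.initial_state if state is None else state).astype(float).copy()
        dt = settings.dt
        total_beats = settings.beats + settings.prepace_beats
        n_steps = int(round((protocol.onset + total_beats * protocol.period) / dt))
        out = np.empty(n_steps + 1)
        status = self.paced_loop(self.params.values, y, dt, n_steps,
                                 protocol.onset, protocol.period,
                                 protocol.duration, protocol.amplitude,
                                 self.use_fast_exp, out)
        if status >= 0:
            raise SimulationBlowupError(
                f"{self.name}: numerical blow-up at t = {status * dt:.3f} ms",
                status * dt)
        onsets = protocol.onset + protocol.period * np.arange(total_beats)
        if settings.prepace_beats:
            skip = int(round(settings.prepace_beats * protocol.period / dt))
            out = out[skip:]
            onsets = onsets[settings.prepace_beats:] - skip * dt
        return VoltageTrace(0.0, dt, out, onsets)

    def with_settings(self, use_fast_exp: bool) -> "CellModel":
        return replace(self, use_fast_exp=use_fast_exp)
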