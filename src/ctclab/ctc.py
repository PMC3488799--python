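"""In silico cell-type transforming clamp (CTC).

The CTC couples a target myocyte (here: a simulated neonatal-mouse model) to
two computational cells in a closed loop.  Each loop cycle:

1. the target voltage is measured (optionally offset by the liquid-junction
   potential),
2. the target-canceling and recipient models are advanced one loop step
   clamped at that voltage (the recipient sub-stepped at its finer dt),
3. both total currents are computed and scaled by the capacitance ratios
   K_c = C_target / C_cancel and K_r = C_target / C_recipient,
4. the difference current I_diff = scaled recipient - scaled canceling is
   formed (in capacitance-normalized terms simply i_rec - i_cancel),
5. the stimulus and the seal-leak compensation are added to produce the
   injected current,
6. the target model advances one free-running step under the injection.

When the canceling model reproduces the target's currents exactly, the
injection reduces the target's membrane equation to the recipient's, so the
target expresses the recipient AP (ideal conversion).  All currents are
capacitance-normalized (pA/pF) and outward positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .exceptions import SimulationBlowupError
from .metrics import apd_amplitude, resting_potential
from .models import CellModel, StimulusProtocol
from .models.human import human_current, human_gates
from .models.mouse import mouse_current, mouse_gates
from .trace import VoltageTrace

__all__ = ["CTCConfig", "CTCRecord", "seal_leak", "ctc_step", "run_ctc",
           "recipient_reference", "apd_comparison", "plot_record"]


@dataclass(frozen=True)
class CTCConfig:
    """CTC circuit configuration.

    Capacitances default to the models' own values (pF); ``r_seal_gohm`` is
    the patch seal resistance (GOhm, ``inf`` disables the leak and its
    compensation); ``ljp_mv`` is the liquid-junction-potential offset added
    to the measured voltage (0 in silico; -3 mV experimentally).  The loop
    runs at ``loop_dt`` with the recipient sub-stepped ``substeps`` times.
    """

    c_target_pf: float = 100.0
    c_cancel_pf: float = 100.0
    c_recipient_pf: float = 185.0
    r_seal_gohm: float = math.inf
    ljp_mv: float = 0.0
    loop_dt: float = 0.1
    substeps: int = 10
    protocol: StimulusProtocol = field(
        default_factory=lambda: StimulusProtocol(period=1000.0, duration=1.0,
                                                 amplitude=52.0, onset=50.0))

    def __post_init__(self) -> None:
        if min(self.c_target_pf, self.c_cancel_pf, self.c_recipient_pf) <= 0:
            raise ValueError("capacitances must be positive")
        if not (self.r_seal_gohm > 0):
            raise ValueError("seal resistance must be positive (inf allowed)")
        if self.loop_dt <= 0 or self.substeps < 1:
            raise ValueError("need loop_dt > 0 and substeps >= 1")

    @property
    def k_c(self) -> float:
        return self.c_target_pf / self.c_cancel_pf

    @property
    def k_r(self) -> float:
        return self.c_target_pf / self.c_recipient_pf


def seal_leak(v_mv: float, r_seal_gohm: float, c_target_pf: float = 1.0) -> float:
    """Ohmic seal-leak current toward 0 mV: V / R_seal.

    Returns pA for ``c_target_pf = 1`` (mV/GOhm = pA), or a
    capacitance-normalized pA/pF when the target capacitance is supplied.
    ``r_seal_gohm = inf`` gives 0.
    """
    if math.isinf(r_seal_gohm):
        return 0.0
    return v_mv / (r_seal_gohm * c_target_pf)


@dataclass
class CTCRecord:
    """Synchronized CTC traces; currents capacitance-normalized, outward positive."""

    t: np.ndarray
    v_target: np.ndarray
    i_cancel: np.ndarray
    i_recipient: np.ndarray
    i_diff: np.ndarray
    i_seal: np.ndarray
    i_inject: np.ndarray
    config: CTCConfig
    stim_onsets: np.ndarray
    v_recipient_ref: np.ndarray | None = None

    def target_trace(self) -> VoltageTrace:
        return VoltageTrace(float(self.t[0]), self.config.loop_dt,
                            self.v_target, self.stim_onsets)

    def reference_trace(self) -> VoltageTrace:
        if self.v_recipient_ref is None:
            raise ValueError("record was built without the recipient reference")
        return VoltageTrace(float(self.t[0]), self.config.loop_dt,
                            self.v_recipient_ref, self.stim_onsets)

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"time_ms": self.t, "v_target_mV": self.v_target,
                "i_cancel": self.i_cancel, "i_recipient": self.i_recipient,
                "i_diff": self.i_diff, "i_seal": self.i_seal,
                "i_inject": self.i_inject}
        if self.v_recipient_ref is not None:
            cols["v_recipient_ref_mV"] = self.v_recipient_ref
        return pd.DataFrame(cols)

    def export_text(self, path) -> None:
        """Multi-column delimited text export of the full current decomposition."""
        df = self.to_dataframe()
        with open(path, "w") as fh:
            fh.write("# ctclab CTC record; currents in pA/pF, outward positive\n")
            onsets = ",".join(repr(float(x)) for x in self.stim_onsets)
            fh.write(f"# stim_onsets_ms = {onsets}\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.9g")


def _make_ctc_loop(tgt_cur, tgt_gates, can_cur, can_gates, rec_cur, rec_gates):
    @njit
    def loop(pt, yt, pc, yc, pr, yr, n_steps, dt, sub, onset, period, dur, amp,
             ljp, g_seal, fast, out):
        # out rows: v_target, i_cancel, i_recipient, i_diff, i_seal, i_inject
        sub_dt = dt / sub
        for k in range(n_steps):
            t = k * dt
            v_true = yt[0]
            v_meas = v_true + ljp                      # step 1
            can_gates(pc, yc, v_meas, dt, fast)        # step 2
            for _ in range(sub):
                rec_gates(pr, yr, v_meas, sub_dt, fast)
            i_can = can_cur(pc, yc, v_meas, fast)      # step 3
            i_rec = rec_cur(pr, yr, v_meas, fast)
            i_diff = i_rec - i_can                     # step 4
            i_stim = 0.0
            if t >= onset and (t - onset) % period < dur:
                i_stim = -amp
            i_leak = v_true * g_seal                   # physical seal leak
            i_comp = -v_meas * g_seal                  # its compensation
            i_inj = i_diff + i_stim + i_comp           # step 5
            tgt_gates(pt, yt, v_true, dt, fast)        # step 6
            i_ion = tgt_cur(pt, yt, v_true, fast)
            v_new = v_true - dt * (i_ion + i_inj + i_leak)
            out[0, k] = v_true
            out[1, k] = i_can
            out[2, k] = i_rec
            out[3, k] = i_diff
            out[4, k] = i_leak
            out[5, k] = i_inj
            if not np.isfinite(v_new) or v_new < -250.0 or v_new > 250.0:
                return k
            yt[0] = v_new
        return -1

    return loop


def _make_reference_loop(rec_cur, rec_gates):
    @njit
    def loop(pr, yr, n_steps, dt, sub, onset, period, dur, amp, fast, out_v):
        sub_dt = dt / sub
        for k in range(n_steps):
            t = k * dt
            V = yr[0]
            for _ in range(sub):
                rec_gates(pr, yr, V, sub_dt, fast)
            i_rec = rec_cur(pr, yr, V, fast)
            i_stim = 0.0
            if t >= onset and (t - onset) % period < dur:
                i_stim = -amp
            v_new = V - dt * (i_rec + i_stim)
            out_v[k] = V
            if not np.isfinite(v_new) or v_new < -250.0 or v_new > 250.0:
                return k
            yr[0] = v_new
        return -1

    return loop


_CTC_LOOP_MMH = _make_ctc_loop(mouse_current, mouse_gates,
                               mouse_current, mouse_gates,
                               human_current, human_gates)
_REFERENCE_LOOP_H = _make_reference_loop(human_current, human_gates)

_LOOP_CACHE = {}


def _ctc_loop_for(target: CellModel, canceling: CellModel, recipient: CellModel):
    key = (target.current_fn, canceling.current_fn, recipient.current_fn)
    if key == (mouse_current, mouse_current, human_current):
        return _CTC_LOOP_MMH
    if key not in _LOOP_CACHE:  # pluggable-model slot (e.g. other recipients)
        _LOOP_CACHE[key] = _make_ctc_loop(target.current_fn, target.gates_fn,
                                          canceling.current_fn, canceling.gates_fn,
                                          recipient.current_fn, recipient.gates_fn)
    return _LOOP_CACHE[key]


def ctc_step(target: CellModel, canceling: CellModel, recipient: CellModel,
             yt: np.ndarray, yc: np.ndarray, yr: np.ndarray,
             cfg: CTCConfig, t: float) -> dict[str, float]:
    """Advance one loop cycle in place; returns the record row.

    Thin single-step wrapper over the compiled loop, mainly for inspection
    and tests; :func:`run_ctc` drives the same kernel over whole beats.
    """
    loop = _ctc_loop_for(target, canceling, recipient)
    out = np.empty((6, 1))
    g_seal = 0.0 if math.isinf(cfg.r_seal_gohm) else 1.0 / (cfg.r_seal_gohm * cfg.c_target_pf)
    proto = cfg.protocol
    # offset the stimulus clock so that absolute time t is honoured
    status = loop(target.params.values, yt, canceling.params.values, yc,
                  recipient.params.values, yr, 1, cfg.loop_dt, cfg.substeps,
                  proto.onset - t, proto.period, proto.duration, proto.amplitude,
                  cfg.ljp_mv, g_seal, target.use_fast_exp, out)
    if status >= 0:
        raise SimulationBlowupError(f"CTC blow-up at t = {t:.3f} ms", t)
    names = ("v_target", "i_cancel", "i_recipient", "i_diff", "i_seal", "i_inject")
    return {n: float(out[i, 0]) for i, n in enumerate(names)}


def run_ctc(target: CellModel, canceling: CellModel, recipient: CellModel,
            cfg: CTCConfig | None = None, beats: int = 1,
            with_reference: bool = True) -> CTCRecord:
    """Run the closed-loop CTC for the requested number of beats.

    Initial states are each model's stored resting state.  Returns the full
    current decomposition; with ``with_reference`` the recipient model's
    free-running AP (same multirate discretization, same stimulus) is
    recorded alongside for comparison.
    """
    if cfg is None:
        cfg = CTCConfig(c_target_pf=target.capacitance_pf,
                        c_cancel_pf=canceling.capacitance_pf,
                        c_recipient_pf=recipient.capacitance_pf)
    loop = _ctc_loop_for(target, canceling, recipient)
    proto = cfg.protocol
    n_steps = int(round((proto.onset + beats * proto.period) / cfg.loop_dt))
    yt = target.initial_state.copy()
    yc = canceling.initial_state.copy()
    yr = recipient.initial_state.copy()
    out = np.empty((6, n_steps))
    g_seal = 0.0 if math.isinf(cfg.r_seal_gohm) else 1.0 / (cfg.r_seal_gohm * cfg.c_target_pf)
    status = loop(target.params.values, yt, canceling.params.values, yc,
                  recipient.params.values, yr, n_steps, cfg.loop_dt,
                  cfg.substeps, proto.onset, proto.period, proto.duration,
                  proto.amplitude, cfg.ljp_mv, g_seal,
                  target.use_fast_exp, out)
    if status >= 0:
        raise SimulationBlowupError(
            f"CTC blow-up at t = {status * cfg.loop_dt:.3f} ms", status * cfg.loop_dt)
    onsets = proto.onset + proto.period * np.arange(beats)
    ref = None
    if with_reference:
        ref = recipient_reference(recipient, cfg, beats).v
    return CTCRecord(
        t=cfg.loop_dt * np.arange(n_steps),
        v_target=out[0], i_cancel=out[1], i_recipient=out[2],
        i_diff=out[3], i_seal=out[4], i_inject=out[5],
        config=cfg, stim_onsets=onsets, v_recipient_ref=ref,
    )


def recipient_reference(recipient: CellModel, cfg: CTCConfig,
                        beats: int = 1) -> VoltageTrace:
    """Free-running recipient AP under the CTC discretization.

    Integrates the recipient with the same multirate scheme the loop uses
    (V updated at ``loop_dt``, gates sub-stepped), so it is the exact
    waveform an ideal conversion reproduces.
    """
    if recipient.current_fn is human_current:
        loop = _REFERENCE_LOOP_H
    else:
        loop = _make_reference_loop(recipient.current_fn, recipient.gates_fn)
    proto = cfg.protocol
    n_steps = int(round((proto.onset + beats * proto.period) / cfg.loop_dt))
    yr = recipient.initial_state.copy()
    out_v = np.empty(n_steps)
    status = loop(recipient.params.values, yr, n_steps, cfg.loop_dt,
                  cfg.substeps, proto.onset, proto.period, proto.duration,
                  proto.amplitude, recipient.use_fast_exp, out_v)
    if status >= 0:
        raise SimulationBlowupError(
            f"recipient reference blow-up at t = {status * cfg.loop_dt:.3f} ms",
            status * cfg.loop_dt)
    onsets = proto.onset + proto.period * np.arange(beats)
    return VoltageTrace(0.0, cfg.loop_dt, out_v, onsets)


def apd_comparison(record: CTCRecord,
                   reference: VoltageTrace | None = None) -> pd.DataFrame:
    """Per-beat amplitude-based APDs of the converted AP vs the recipient AP.

    Undefined APDs (no crossing within the beat) propagate as NaN.
    """
    if reference is None:
        reference = record.reference_trace()
    converted = record.target_trace()
    rows = []
    for beat in range(record.stim_onsets.size):
        row: dict[str, float] = {"beat": beat}
        for name, tr in (("converted", converted), ("recipient", reference)):
            for level in (30, 50, 90):
                try:
                    val = apd_amplitude(tr, level, beat)
                except Exception:
                    val = float("nan")
                row[f"{name}_apd{level}"] = val
            try:
                row[f"{name}_rest"] = resting_potential(tr, beat)
            except Exception:
                row[f"{name}_rest"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows, columns=[
        "beat", "converted_apd30", "converted_apd50", "converted_apd90",
        "converted_rest", "recipient_apd30", "recipient_apd50",
        "recipient_apd90", "recipient_rest"])


def plot_record(record: CTCRecord, path=None):
    """Four stacked panels: converted AP (with recipient reference), canceling
    current, recipient current and difference current."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(4, 1, sharex=True, figsize=(6, 9))
    axes[0].plot(record.t, record.v_target, "r", label="converted AP")
    if record.v_recipient_ref is not None:
        axes[0].plot(record.t, record.v_recipient_ref, "k--",
                     label="recipient model")
    axes[0].set_ylabel("V (mV)")
    axes[0].legend(loc="upper right", fontsize=8)
    for ax, ser, lab in ((axes[1], record.i_cancel, "I_cancel"),
                         (axes[2], record.i_recipient, "I_recipient"),
                         (axes[3], record.i_diff, "I_diff")):
        ax.plot(record.t, ser)
        ax.set_ylabel(f"{lab} (pA/pF)")
    axes[3].set_xlabel("time (ms)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
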