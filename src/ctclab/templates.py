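"""Nine-member APD80 template suite for baseline target-canceling selection.

The pre-GA approach to matching a recorded myocyte is to pick, from a suite
of nine neonatal-mouse model variants with APD80 of 40, 50, ..., 120 ms, the
member whose APD80 is closest to the measured one.  Suite members differ only
in the steady-state (g_ss) and slowly inactivating (g_Kslow) K+ conductances.

Calibration path: both conductances are scaled by a common factor ``s``
relative to the baseline model and ``s`` is bisected against the APD80 of a
fresh 1 Hz paced beat (the APD80-s relation is monotone decreasing on the
usable range, which is verified at run time).  Any (g_ss, g_Kslow) pair
achieving the labelled APD80 serves the selection role.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

from .exceptions import CalibrationError
from .metrics import apd_mouse80
from .models import SimSettings
from .models.mouse import make_neonatal_mouse_model

__all__ = ["TemplateMember", "TemplateSuite", "calibrate_template",
           "build_suite", "select_template", "LABELS"]

LABELS = tuple(range(40, 121, 10))

_S_MIN, _S_MAX = 0.085, 30.0  # usable scale range of the calibration path


@dataclass(frozen=True)
class TemplateMember:
    """One suite entry: APD80 label, its conductances and the re-measured APD80."""

    label: float
    g_ss: float
    g_Kslow: float
    apd80: float
    scale: float


@dataclass(frozen=True)
class TemplateSuite:
    members: tuple[TemplateMember, ...]

    def __post_init__(self) -> None:
        labels = [m.label for m in self.members]
        if labels != sorted(labels) or len(set(labels)) != len(labels):
            raise ValueError("labels must be strictly increasing")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __getitem__(self, i: int) -> TemplateMember:
        return self.members[i]


def _apd80_at_scale(s: float, dt: float = 0.1) -> float:
    """APD80 of one fresh paced beat with g_ss, g_Kslow scaled by ``s``.

    Returns NaN when the AP fails to repolarize within the beat.
    """
    model, params = make_neonatal_mouse_model()
    params["g_ss"] = params["g_ss"] * s
    params["g_Kslow"] = params["g_Kslow"] * s
    trace = model.simulate_paced(settings=SimSettings(dt=dt, beats=1))
    try:
        return apd_mouse80(trace)
    except Exception:
        return float("nan")


def calibrate_template(target_apd80: float, tol: float = 1.0,
                       dt: float = 0.1) -> tuple[float, float]:
    """Find (g_ss, g_Kslow) whose paced APD80 is within ``tol`` of the target.

    Bisects the common scale factor on a log grid.  Raises
    :class:`CalibrationError` if the target cannot be bracketed on the path.
    """
    lo, hi = _S_MIN, _S_MAX
    a_lo, a_hi = _apd80_at_scale(lo, dt), _apd80_at_scale(hi, dt)
    if math.isnan(a_lo) or math.isnan(a_hi):
        raise CalibrationError(
            f"calibration endpoints undefined: APD80({lo})={a_lo}, APD80({hi})={a_hi}")
    if not (a_hi <= target_apd80 <= a_lo):
        raise CalibrationError(
            f"target {target_apd80} ms outside achievable range "
            f"[{a_hi:.1f}, {a_lo:.1f}] ms on the g_ss/g_Kslow path")
    if a_lo <= a_hi:
        raise CalibrationError("APD80 is not decreasing along the scale path")
    s = lo
    for _ in range(60):
        s = math.sqrt(lo * hi)
        a = _apd80_at_scale(s, dt)
        if math.isnan(a) or a > target_apd80:
            lo = s
        else:
            hi = s
        if not math.isnan(a) and abs(a - target_apd80) <= 0.25 * tol:
            break
    a = _apd80_at_scale(s, dt)
    if math.isnan(a) or abs(a - target_apd80) > tol:
        raise CalibrationError(
            f"bisection failed to reach {target_apd80} +/- {tol} ms (got {a})")
    _, params = make_neonatal_mouse_model()
    return params["g_ss"] * s, params["g_Kslow"] * s


@lru_cache(maxsize=None)
def _build_suite_cached(dt: float) -> TemplateSuite:
    _, base = make_neonatal_mouse_model()
    members = []
    for label in LABELS:
        g_ss, g_kslow = calibrate_template(float(label), tol=1.0, dt=dt)
        # verify with a fresh simulation
        s = g_ss / base["g_ss"]
        apd = _apd80_at_scale(s, dt)
        if abs(apd - label) > 1.0:
            raise CalibrationError(f"member {label}: verification gave {apd:.2f} ms")
        members.append(TemplateMember(float(label), g_ss, g_kslow, apd, s))
    return TemplateSuite(tuple(members))


def build_suite(dt: float = 0.1) -> TemplateSuite:
    """Calibrate all nine members (cached per process) and verify each."""
    return _build_suite_cached(dt)


def select_template(suite: TemplateSuite, measured_apd80: float) -> TemplateMember:
    """Suite member with APD80 label closest to the measurement.

    Ties (measurement equidistant from two labels) resolve to the
    shorter-APD member.
    """
    if not math.isfinite(measured_apd80):
        raise ValueError("measured APD80 must be finite")
    return min(suite, key=lambda mem: (abs(mem.label - measured_apd80), mem.label))


def starting_point_params():
    """Parameter set of the GA starting-point model (the 60 ms suite member)."""
    member = select_template(build_suite(), 60.0)
    _, params = make_neonatal_mouse_model()
    params["g_ss"] = member.g_ss
    params["g_Kslow"] = member.g_Kslow
    return params
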