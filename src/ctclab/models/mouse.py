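"""Neonatal-mouse ventricular myocyte model (modified Pandit formulation).

The target-canceling cell is a rat ventricular epicardial formulation (Pandit
and colleagues' Hodgkin-Huxley style model) adapted to the neonatal mouse:

* the fast sodium conductance is 0.8 uS;
* all ionic concentrations are held fixed ([K+]o = 5.4, [Na+]o = 140,
  [Ca2+]o = 1.2, [Na+]i = 8.6, [K+]i = 142 mM, [Ca2+]i = 0.079 uM), so the
  state reduces to V plus thirteen gating variables;
* the Ca2+-independent transient outward current is split into a fast
  component I_t (gates r, s) and a slowly inactivating component I_Kslow
  (gates r, s_slow), giving the six independently scalable conductances used
  throughout the package (g_Na, g_ss, g_Kslow, g_CaL, g_K1, g_t).  The
  baseline magnitudes of g_t, g_Kslow and g_ss were calibrated once so that
  scaling g_ss and g_Kslow spans action-potential durations (APD80) from
  under 40 ms to over 120 ms, the range the template suite requires.

Membrane currents are in nA (conductances in uS, V in mV); the kernel
returns the total current normalized by the 100 pF membrane capacitance
(pA/pF), outward positive, so that dV/dt = -(i_ion + i_applied) in mV/ms.
Integration: V advances by forward Euler at dt = 0.1 ms; gating variables
advance by exact exponential (Rush-Larsen) relaxation toward their
voltage-dependent steady state over the step, which preserves the [0, 1]
bounds and the resting fixed point at this step size.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from ._fastmath import exp_
from .base import CellModel, ParameterSet, SimSettings, StimulusProtocol, make_paced_loop

__all__ = ["make_neonatal_mouse_model", "PARAM_NAMES", "STATE_NAMES",
           "BASELINE_PARAMS", "default_protocol", "stimulus_amplitude"]

R = 8314.5      # mJ mol^-1 K^-1
FARADAY = 96487.0  # C mol^-1

PARAM_NAMES = (
    "g_Na", "g_CaL", "g_t", "g_Kslow", "g_ss", "g_K1", "g_f",
    "g_B_Na", "g_B_Ca", "g_B_K",
    "i_NaK_max", "k_NaCa", "d_NaCa", "i_CaP_max",
    "C_m", "Na_o", "K_o", "Ca_o", "Na_i", "K_i", "Ca_i", "T",
)

# Baseline neonatal parameter vector.  Conductances in uS, pump/exchanger
# magnitudes in nA (k_NaCa in nA mM^-4), C_m in pF, concentrations in mM,
# temperature in K.
BASELINE_PARAMS = np.array([
    0.8,        # g_Na (0.8 uS)
    0.020,      # g_CaL (neonatal density, calibrated)
    0.0080,     # g_t        (fast transient outward, calibrated)
    0.0150,     # g_Kslow    (slowly inactivating K+, calibrated)
    0.0140,     # g_ss       (steady-state K+, calibrated)
    0.024,      # g_K1
    0.00145,    # g_f
    8.015e-5,   # g_B_Na
    3.24e-5,    # g_B_Ca
    1.38e-4,    # g_B_K
    0.08,       # i_NaK_max
    0.9984e-5,  # k_NaCa
    1e-4,       # d_NaCa
    0.004,      # i_CaP_max
    100.0,      # C_m (pF)
    140.0,      # Na_o
    5.4,        # K_o
    1.2,        # Ca_o
    8.6,        # Na_i
    142.0,      # K_i
    7.9e-5,     # Ca_i (0.079 uM)
    295.0,      # T
])

STATE_NAMES = ("V", "m", "h", "j", "d", "f11", "f12", "ca_inact",
               "r", "s", "s_slow", "r_ss", "s_ss", "y")

# Quiescent steady state of the baseline parameter vector (20 s free run,
# no stimulus); frozen so single-beat evaluations start from rest.
RESTING_STATE = np.array([
    -80.36992542781366,
    0.004314169284491078, 0.6689516508717064, 0.6689516508683204,
    2.2289335524093237e-06, 0.999951740764516, 0.9999517407645161,
    0.9921619208254837,
    0.002216845876801623, 0.9939059942957824, 0.9939057268967213,
    0.002939538442768963, 0.3335347070818065, 0.0038481590294258093,
])


@njit(cache=True)
def mouse_current(p, y, V, fast):
    """Total sarcolemmal current at imposed V (pA/pF, outward positive)."""
    rt_f = R * p[21] / FARADAY
    e_na = rt_f * np.log(p[15] / p[18])
    e_k = rt_f * np.log(p[16] / p[19])
    e_ca = 0.5 * rt_f * np.log(p[17] / p[20])

    i_na = p[0] * y[1] ** 3 * y[2] * y[3] * (V - e_na)
    i_cal = p[1] * y[4] * ((0.9 + y[7] / 10.0) * y[5] +
                           (0.1 - y[7] / 10.0) * y[6]) * (V - 65.0)
    i_t = p[2] * y[8] * y[9] * (V - e_k)
    i_kslow = p[3] * y[8] * y[10] * (V - e_k)
    i_ss = p[4] * y[11] * y[12] * (V - e_k)
    i_f = p[6] * y[13] * (0.2 * (V - e_na) + 0.8 * (V - e_k))

    dvk = V - e_k
    i_k1 = ((0.048 / (exp_((V + 37.0) / 25.0, fast) + exp_(-(V + 37.0) / 25.0, fast))
             + 0.01) * 0.001 / (1.0 + exp_(-(dvk - 76.77) / 17.0, fast))
            + p[5] * (dvk - 1.73)
            / ((1.0 + exp_(1.613 * (dvk - 1.73) / rt_f, fast))
               * (1.0 + exp_(-(p[16] - 0.9988) / 0.124, fast))))

    i_bna = p[7] * (V - e_na)
    i_bca = p[8] * (V - e_ca)
    i_bk = p[9] * (V - e_k)

    i_nak = (p[10] * (1.0 / (1.0 + (10.0 / p[18]) ** 1.5))
             * (p[16] / (p[16] + 1.5))
             * 1.6 / (1.5 + exp_(-(V + 60.0) / 40.0, fast)))

    vfrt = V / rt_f
    na_i3 = p[18] ** 3
    na_o3 = p[15] ** 3
    i_naca = (p[11] * (na_i3 * p[17] * exp_(0.5 * vfrt, fast)
                       - na_o3 * p[20] * exp_(-0.5 * vfrt, fast))
              / (1.0 + p[12] * (na_i3 * p[17] + na_o3 * p[20])))

    i_cap = p[13] * p[20] / (p[20] + 4e-4)

    total = (i_na + i_cal + i_t + i_kslow + i_ss + i_f + i_k1
             + i_bna + i_bca + i_bk + i_nak + i_naca + i_cap)
    return total / (p[14] * 1e-3)  # nA / nF -> pA/pF


@njit(cache=True)
def mouse_gates(p, y, V, dt, fast):
    """One Rush-Larsen step of the thirteen gates at clamped V (in place)."""
    # I_Na activation/inactivation (Lindblad/Luo-Rudy rate structure)
    m_inf = 1.0 / (1.0 + exp_(-(V + 45.0) / 6.5, fast))
    den = 1.0 - exp_(-0.1 * (V + 47.13), fast)
    if abs(den) < 1e-12:
        alpha_lin = 3.2  # limit of 0.32*x/(1-exp(-0.1 x)) as x -> 0
    else:
        alpha_lin = 0.32 * (V + 47.13) / den
    tau_m = 1.36 / (alpha_lin + 0.08 * exp_(-V / 11.0, fast))

    h_inf = 1.0 / (1.0 + exp_((V + 76.1) / 6.07, fast))
    if V >= -40.0:
        tau_h = 0.4537 * (1.0 + exp_(-(V + 10.66) / 11.1, fast))
        tau_j = (11.63 * (1.0 + exp_(-0.1 * (V + 32.0), fast))
                 / exp_(-2.535e-7 * V, fast))
    else:
        tau_h = 3.49 / (0.135 * exp_(-(V + 80.0) / 6.8, fast)
                        + 3.56 * exp_(0.079 * V, fast)
                        + 3.1e5 * exp_(0.35 * V, fast))
        aj = ((-1.2714e5 * exp_(0.2444 * V, fast)
               - 3.474e-5 * exp_(-0.04391 * V, fast)) * (V + 37.78)
              / (1.0 + exp_(0.311 * (V + 79.23), fast)))
        bj = (0.1212 * exp_(-0.01052 * V, fast)
              / (1.0 + exp_(-0.1378 * (V + 40.14), fast)))
        tau_j = 3.49 / (aj + bj)

    # I_CaL
    d_inf = 1.0 / (1.0 + exp_(-(V + 15.3) / 5.0, fast))
    tau_d = (3.05 * exp_(-0.0045 * (V + 7.0) ** 2, fast)
             + 1.05 * exp_(-0.002 * (V - 18.0) ** 2, fast) + 0.25)
    f_inf = 1.0 / (1.0 + exp_((V + 26.7) / 5.4, fast))
    tau_f11 = (105.0 * exp_(-((V + 45.0) / 12.0) ** 2, fast)
               + 40.0 / (1.0 + exp_((-V + 25.0) / 25.0, fast))
               + 15.0 / (1.0 + exp_((V + 75.0) / 25.0, fast)) + 1.7)
    tau_f12 = (41.0 * exp_(-((V + 47.0) / 12.0) ** 2, fast)
               + 80.0 / (1.0 + exp_(-(V + 55.0) / 5.0, fast))
               + 15.0 / (1.0 + exp_((V + 75.0) / 25.0, fast)) + 1.7)
    ca_inact_inf = 1.0 / (1.0 + p[20] / 0.01)
    tau_ca_inact = 9.0

    # I_t / I_Kslow (shared activation r; fast s, slow s_slow inactivation)
    r_inf = 1.0 / (1.0 + exp_(-(V + 10.6) / 11.42, fast))
    rate_sum = (45.16 * exp_(0.03577 * (V + 50.0), fast)
                + 98.9 * exp_(-0.1 * (V + 38.0), fast))
    tau_r = 1000.0 / rate_sum
    s_inf = 1.0 / (1.0 + exp_((V + 45.3) / 6.8841, fast))
    tau_s = 350.0 * exp_(-((V + 70.0) / 15.0) ** 2, fast) + 35.0
    tau_s_slow = 3700.0 * exp_(-((V + 70.0) / 30.0) ** 2, fast) + 35.0

    # I_ss
    r_ss_inf = 1.0 / (1.0 + exp_(-(V + 11.5) / 11.82, fast))
    tau_r_ss = 10000.0 / rate_sum
    s_ss_inf = 1.0 / (1.0 + exp_((V + 87.5) / 10.3, fast))
    tau_s_ss = 2100.0

    # I_f
    y_inf = 1.0 / (1.0 + exp_((V + 138.6) / 10.48, fast))
    tau_y = 1000.0 / (0.11885 * exp_((V + 80.0) / 28.37, fast)
                      + 0.56236 * exp_(-(V + 80.0) / 14.19, fast))

    # exponential (Rush-Larsen) relaxation toward the steady state: exact for
    # the linear gate ODE over the step, unconditionally stable, stays in [0,1]
    y[1] += (m_inf - y[1]) * (1.0 - exp_(-dt / tau_m, fast))
    y[2] += (h_inf - y[2]) * (1.0 - exp_(-dt / tau_h, fast))
    y[3] += (h_inf - y[3]) * (1.0 - exp_(-dt / tau_j, fast))
    y[4] += (d_inf - y[4]) * (1.0 - exp_(-dt / tau_d, fast))
    y[5] += (f_inf - y[5]) * (1.0 - exp_(-dt / tau_f11, fast))
    y[6] += (f_inf - y[6]) * (1.0 - exp_(-dt / tau_f12, fast))
    y[7] += (ca_inact_inf - y[7]) * (1.0 - exp_(-dt / tau_ca_inact, fast))
    y[8] += (r_inf - y[8]) * (1.0 - exp_(-dt / tau_r, fast))
    y[9] += (s_inf - y[9]) * (1.0 - exp_(-dt / tau_s, fast))
    y[10] += (s_inf - y[10]) * (1.0 - exp_(-dt / tau_s_slow, fast))
    y[11] += (r_ss_inf - y[11]) * (1.0 - exp_(-dt / tau_r_ss, fast))
    y[12] += (s_ss_inf - y[12]) * (1.0 - exp_(-dt / tau_s_ss, fast))
    y[13] += (y_inf - y[13]) * (1.0 - exp_(-dt / tau_y, fast))
    for i in range(1, 14):
        if y[i] < 0.0:
            y[i] = 0.0
        elif y[i] > 1.0:
            y[i] = 1.0


_MOUSE_PACED_LOOP = make_paced_loop(mouse_current, mouse_gates)

# amplitude cache: baseline 1.5x-diastolic-threshold stimulus (pA/pF)
_STIM_CACHE: dict[str, float] = {}


def stimulus_amplitude() -> float:
    """Depolarizing stimulus amplitude for in silico pacing (pA/pF).

    Defined as 1.5x the diastolic threshold of the baseline model for a 1 ms
    pulse, located by bisection once per process and cached.
    """
    if "amp" not in _STIM_CACHE:
        p = BASELINE_PARAMS
        lo, hi = 0.5, 200.0

        def _fires(amp: float) -> bool:
            y = RESTING_STATE.copy()
            n = int(round(100.0 / 0.1))
            out = np.empty(n + 1)
            status = _MOUSE_PACED_LOOP(p, y, 0.1, n, 10.0, 1000.0, 1.0, amp,
                                       False, out)
            return status != -1 or out.max() > 0.0

        if not _fires(hi):  # pragma: no cover - defensive
            raise RuntimeError("baseline model refuses to fire")
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if _fires(mid):
                hi = mid
            else:
                lo = mid
        _STIM_CACHE["amp"] = 1.5 * hi
    return _STIM_CACHE["amp"]


def default_protocol() -> StimulusProtocol:
    """1 Hz pacing with a 1 ms pulse at the cached in silico amplitude."""
    return StimulusProtocol(period=1000.0, duration=1.0,
                            amplitude=stimulus_amplitude(), onset=50.0)


def make_neonatal_mouse_model(genotype=None, base_params: ParameterSet | None = None):
    """Build the neonatal-mouse cell model.

    Parameters
    ----------
    genotype : Genotype or None
        Optional six-gene conductance scaling (fractional changes applied
        multiplicatively as ``(1 + s)``); validated against the GA bounds.
    base_params : ParameterSet, optional
        Conductance set the genotype scales (defaults to the baseline
        neonatal parameters; the GA passes its 60 ms starting-point model).

    Returns
    -------
    (CellModel, ParameterSet)
    """
    if base_params is None:
        params = ParameterSet(PARAM_NAMES, BASELINE_PARAMS.copy())
    else:
        params = base_params.copy()
    if genotype is not None:
        from ..ga import Genotype  # late import: ga builds on models

        if not isinstance(genotype, Genotype):
            genotype = Genotype(np.asarray(genotype, dtype=float))
        genotype.validate()
        for gene, scale in zip(genotype.GENE_NAMES, genotype.values):
            params[gene] = params[gene] * (1.0 + scale)
    params.validate()
    model = CellModel(
        name="neonatal_mouse",
        params=params,
        initial_state=RESTING_STATE.copy(),
        state_names=STATE_NAMES,
        default_dt=0.1,
        current_fn=mouse_current,
        gates_fn=mouse_gates,
        paced_loop=_MOUSE_PACED_LOOP,
        protocol_factory=default_protocol,
    )
    return model, params
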