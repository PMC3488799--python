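"""Reduced ten Tusscher-Panfilov human ventricular myocyte model (recipient).

Epicardial formulation with the standard current set (I_Na, I_CaL, I_to,
I_Ks, I_Kr, I_K1, Na+/Ca2+ exchange, Na+/K+ pump, plateau and background
currents) and a single-pool sarcoplasmic-reticulum calcium subsystem with
steady-state buffering.  The reduction holds intracellular Na+ and K+ fixed,
leaving 15 states: V, twelve gates and the two calcium pools.

Currents are capacitance-normalized (pA/pF, outward positive); the membrane
capacitance is 185 pF.  V and the calcium pools advance by forward Euler at
dt = 0.01 ms; gates advance by exact exponential (Rush-Larsen) relaxation.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from ._fastmath import exp_
from .base import CellModel, ParameterSet, StimulusProtocol, make_paced_loop

__all__ = ["make_human_recipient_model", "PARAM_NAMES", "STATE_NAMES",
           "BASELINE_PARAMS", "default_protocol"]

R = 8314.472
FARADAY = 96485.3415

PARAM_NAMES = (
    "G_Na", "G_CaL", "G_to", "G_Ks", "G_Kr", "G_K1",
    "G_bNa", "G_bCa", "G_pK", "G_pCa", "P_NaK", "k_NaCa",
    "C_m", "Na_o", "K_o", "Ca_o", "Na_i", "K_i", "T",
)

BASELINE_PARAMS = np.array([
    14.838,     # G_Na (nS/pF)
    1.75e-4,    # G_CaL (cm^3 uF^-1 s^-1)
    0.294,      # G_to (epicardial)
    0.245,      # G_Ks (epicardial)
    0.096,      # G_Kr
    5.405,      # G_K1
    2.9e-4,     # G_bNa
    5.92e-4,    # G_bCa
    0.0146,     # G_pK
    0.825,      # G_pCa
    1.362,      # P_NaK (pA/pF)
    1000.0,     # k_NaCa (pA/pF)
    185.0,      # C_m (pF)
    140.0,      # Na_o
    5.4,        # K_o
    2.0,        # Ca_o
    11.6,       # Na_i (fixed in the reduction)
    138.3,      # K_i  (fixed in the reduction)
    310.0,      # T
])

STATE_NAMES = ("V", "m", "h", "j", "d", "f", "f_Ca", "r", "s",
               "x_s", "x_r1", "x_r2", "g_rel", "Ca_i", "Ca_SR")

# Quiescent steady state of the baseline vector (20 s free run), frozen.
RESTING_STATE = np.array([
    -86.40179918297048,
    0.0013367324861585288, 0.7755990920984955, 0.775597368410703,
    1.9335021866270764e-05, 0.9999240955011628, 1.0,
    1.987839162761541e-08, 0.9999982922941794,
    0.0029753492169452243, 0.0001788432735321356, 0.48335821597901846,
    0.9999968049671876, 4.2475830510718244e-05, 0.18272662325937347,
])

# fixed cell geometry / buffering constants
_VC = 0.016404
_VSR = 0.001094
_CAP = 0.185
_BUFC = 0.15
_KBUFC = 1e-3
_BUFSR = 10.0
_KBUFSR = 0.3
_VMAXUP = 4.25e-4
_KUP = 2.5e-4
_VLEAK = 8e-5
_AREL = 0.016464
_BREL = 0.25
_CREL = 0.008232


@njit(cache=True)
def human_current(p, y, V, fast):
    """Total sarcolemmal current at imposed V (pA/pF, outward positive)."""
    rt_f = R * p[18] / FARADAY
    e_na = rt_f * np.log(p[13] / p[16])
    e_k = rt_f * np.log(p[14] / p[17])
    e_ks = rt_f * np.log((p[14] + 0.03 * p[13]) / (p[17] + 0.03 * p[16]))
    e_ca = 0.5 * rt_f * np.log(p[15] / y[13])

    i_na = p[0] * y[1] ** 3 * y[2] * y[3] * (V - e_na)

    x = 2.0 * (V - 0.0) / rt_f  # 2VF/RT
    if abs(V) < 1e-4:
        i_cal_drv = 2.0 * FARADAY * (0.25 * y[13] - p[15])
    else:
        ex = exp_(x, fast)
        i_cal_drv = (4.0 * V * FARADAY / rt_f) * (0.25 * y[13] * ex - p[15]) / (ex - 1.0)
    i_cal = p[1] * y[4] * y[5] * y[6] * i_cal_drv

    i_to = p[2] * y[7] * y[8] * (V - e_k)
    i_ks = p[3] * y[9] ** 2 * (V - e_ks)
    i_kr = p[4] * np.sqrt(p[14] / 5.4) * y[10] * y[11] * (V - e_k)

    dvk = V - e_k
    a_k1 = 0.1 / (1.0 + exp_(0.06 * (dvk - 200.0), fast))
    b_k1 = ((3.0 * exp_(2e-4 * (dvk + 100.0), fast) + exp_(0.1 * (dvk - 10.0), fast))
            / (1.0 + exp_(-0.5 * dvk, fast)))
    i_k1 = p[5] * np.sqrt(p[14] / 5.4) * a_k1 / (a_k1 + b_k1) * dvk

    i_naca = (p[11] * (exp_(0.35 * V / rt_f, fast) * p[16] ** 3 * p[15]
                       - exp_(-0.65 * V / rt_f, fast) * p[13] ** 3 * y[13] * 2.5)
              / ((87.5 ** 3 + p[13] ** 3) * (1.38 + p[15])
                 * (1.0 + 0.1 * exp_(-0.65 * V / rt_f, fast))))

    i_nak = (p[10] * p[14] * p[16]
             / ((p[14] + 1.0) * (p[16] + 40.0)
                * (1.0 + 0.1245 * exp_(-0.1 * V / rt_f, fast)
                   + 0.0353 * exp_(-V / rt_f, fast))))

    i_pca = p[9] * y[13] / (y[13] + 5e-4)
    i_pk = p[8] * dvk / (1.0 + exp_((25.0 - V) / 5.98, fast))
    i_bna = p[6] * (V - e_na)
    i_bca = p[7] * (V - e_ca)

    return (i_na + i_cal + i_to + i_ks + i_kr + i_k1 + i_naca + i_nak
            + i_pca + i_pk + i_bna + i_bca)


@njit(cache=True)
def human_gates(p, y, V, dt, fast):
    """One step of gates (Rush-Larsen) and calcium pools (Euler) at clamped V."""
    rt_f = R * p[18] / FARADAY
    e_ca = 0.5 * rt_f * np.log(p[15] / y[13])

    # currents feeding the calcium balance (at current state)
    x = 2.0 * V / rt_f
    if abs(V) < 1e-4:
        i_cal_drv = 2.0 * FARADAY * (0.25 * y[13] - p[15])
    else:
        ex = exp_(x, fast)
        i_cal_drv = (4.0 * V * FARADAY / rt_f) * (0.25 * y[13] * ex - p[15]) / (ex - 1.0)
    i_cal = p[1] * y[4] * y[5] * y[6] * i_cal_drv
    i_bca = p[7] * (V - e_ca)
    i_pca = p[9] * y[13] / (y[13] + 5e-4)
    i_naca = (p[11] * (exp_(0.35 * V / rt_f, fast) * p[16] ** 3 * p[15]
                       - exp_(-0.65 * V / rt_f, fast) * p[13] ** 3 * y[13] * 2.5)
              / ((87.5 ** 3 + p[13] ** 3) * (1.38 + p[15])
                 * (1.0 + 0.1 * exp_(-0.65 * V / rt_f, fast))))

    # I_Na gates (Luo-Rudy rate structure)
    m_inf = 1.0 / (1.0 + exp_((-56.86 - V) / 9.03, fast)) ** 2
    a_m = 1.0 / (1.0 + exp_((-60.0 - V) / 5.0, fast))
    b_m = (0.1 / (1.0 + exp_((V + 35.0) / 5.0, fast))
           + 0.1 / (1.0 + exp_((V - 50.0) / 200.0, fast)))
    tau_m = a_m * b_m
    h_inf = 1.0 / (1.0 + exp_((V + 71.55) / 7.43, fast)) ** 2
    if V < -40.0:
        a_h = 0.057 * exp_(-(V + 80.0) / 6.8, fast)
        b_h = 2.7 * exp_(0.079 * V, fast) + 3.1e5 * exp_(0.3485 * V, fast)
        a_j = ((-2.5428e4 * exp_(0.2444 * V, fast)
                - 6.948e-6 * exp_(-0.04391 * V, fast)) * (V + 37.78)
               / (1.0 + exp_(0.311 * (V + 79.23), fast)))
        b_j = (0.02424 * exp_(-0.01052 * V, fast)
               / (1.0 + exp_(-0.1378 * (V + 40.14), fast)))
    else:
        a_h = 0.0
        b_h = 0.77 / (0.13 * (1.0 + exp_(-(V + 10.66) / 11.1, fast)))
        a_j = 0.0
        b_j = (0.6 * exp_(0.057 * V, fast)
               / (1.0 + exp_(-0.1 * (V + 32.0), fast)))
    tau_h = 1.0 / (a_h + b_h)
    tau_j = 1.0 / (a_j + b_j)
    j_inf = h_inf

    # I_CaL gates
    d_inf = 1.0 / (1.0 + exp_((-5.0 - V) / 7.5, fast))
    a_d = 1.4 / (1.0 + exp_((-35.0 - V) / 13.0, fast)) + 0.25
    b_d = 1.4 / (1.0 + exp_((V + 5.0) / 5.0, fast))
    g_d = 1.0 / (1.0 + exp_((50.0 - V) / 20.0, fast))
    tau_d = a_d * b_d + g_d
    f_inf = 1.0 / (1.0 + exp_((V + 20.0) / 7.0, fast))
    tau_f = (1125.0 * exp_(-((V + 27.0) ** 2) / 240.0, fast) + 80.0
             + 165.0 / (1.0 + exp_((25.0 - V) / 10.0, fast)))
    ca = y[13]
    a_fca = 1.0 / (1.0 + (ca / 3.25e-4) ** 8)
    b_fca = 0.1 / (1.0 + exp_((ca - 5e-4) / 1e-4, fast))
    g_fca = 0.2 / (1.0 + exp_((ca - 7.5e-4) / 8e-4, fast))
    fca_inf = (a_fca + b_fca + g_fca + 0.23) / 1.46

    # I_to gates (epicardial)
    r_inf = 1.0 / (1.0 + exp_((20.0 - V) / 6.0, fast))
    tau_r = 9.5 * exp_(-((V + 40.0) ** 2) / 1800.0, fast) + 0.8
    s_inf = 1.0 / (1.0 + exp_((V + 20.0) / 5.0, fast))
    tau_s = (85.0 * exp_(-((V + 45.0) ** 2) / 320.0, fast)
             + 5.0 / (1.0 + exp_((V - 20.0) / 5.0, fast)) + 3.0)

    # I_Ks / I_Kr gates
    xs_inf = 1.0 / (1.0 + exp_((-5.0 - V) / 14.0, fast))
    a_xs = 1100.0 / np.sqrt(1.0 + exp_((-10.0 - V) / 6.0, fast))
    b_xs = 1.0 / (1.0 + exp_((V - 60.0) / 20.0, fast))
    tau_xs = a_xs * b_xs
    xr1_inf = 1.0 / (1.0 + exp_((-26.0 - V) / 7.0, fast))
    a_xr1 = 450.0 / (1.0 + exp_((-45.0 - V) / 10.0, fast))
    b_xr1 = 6.0 / (1.0 + exp_((V + 30.0) / 11.5, fast))
    tau_xr1 = a_xr1 * b_xr1
    xr2_inf = 1.0 / (1.0 + exp_((V + 88.0) / 24.0, fast))
    a_xr2 = 3.0 / (1.0 + exp_((-60.0 - V) / 20.0, fast))
    b_xr2 = 1.12 / (1.0 + exp_((V - 60.0) / 20.0, fast))
    tau_xr2 = a_xr2 * b_xr2

    # SR release gate g
    if ca <= 3.5e-4:
        g_inf = 1.0 / (1.0 + (ca / 3.5e-4) ** 6)
    else:
        g_inf = 1.0 / (1.0 + (ca / 3.5e-4) ** 16)

    # calcium fluxes (mM/ms)
    i_leak = _VLEAK * (y[14] - ca)
    i_up = _VMAXUP / (1.0 + (_KUP / ca) ** 2)
    i_rel = (_AREL * y[14] ** 2 / (_BREL ** 2 + y[14] ** 2) + _CREL) * y[4] * y[12]

    csqn = 1.0 / (1.0 + _BUFSR * _KBUFSR / (y[14] + _KBUFSR) ** 2)
    d_casr = csqn * (i_up - i_rel - i_leak) * _VC / _VSR
    bufc = 1.0 / (1.0 + _BUFC * _KBUFC / (ca + _KBUFC) ** 2)
    d_cai = bufc * (-(i_cal + i_bca + i_pca - 2.0 * i_naca)
                    / (2.0 * _VC * FARADAY) * _CAP + i_leak - i_up + i_rel)

    # exponential (Rush-Larsen) gate relaxation; calcium pools stay Euler
    y[1] += (m_inf - y[1]) * (1.0 - exp_(-dt / tau_m, fast))
    y[2] += (h_inf - y[2]) * (1.0 - exp_(-dt / tau_h, fast))
    y[3] += (j_inf - y[3]) * (1.0 - exp_(-dt / tau_j, fast))
    y[4] += (d_inf - y[4]) * (1.0 - exp_(-dt / tau_d, fast))
    y[5] += (f_inf - y[5]) * (1.0 - exp_(-dt / tau_f, fast))
    fca_new = y[6] + (fca_inf - y[6]) * (1.0 - exp_(-dt / 2.0, fast))
    if not (fca_new > y[6] and V > -60.0):  # inactivation locked while depolarized
        y[6] = fca_new
    y[7] += (r_inf - y[7]) * (1.0 - exp_(-dt / tau_r, fast))
    y[8] += (s_inf - y[8]) * (1.0 - exp_(-dt / tau_s, fast))
    y[9] += (xs_inf - y[9]) * (1.0 - exp_(-dt / tau_xs, fast))
    y[10] += (xr1_inf - y[10]) * (1.0 - exp_(-dt / tau_xr1, fast))
    y[11] += (xr2_inf - y[11]) * (1.0 - exp_(-dt / tau_xr2, fast))
    g_new = y[12] + (g_inf - y[12]) * (1.0 - exp_(-dt / 2.0, fast))
    if not (g_new > y[12] and V > -60.0):
        y[12] = g_new
    y[13] = max(ca + dt * d_cai, 1e-9)
    y[14] = max(y[14] + dt * d_casr, 1e-9)
    for i in range(1, 13):
        if y[i] < 0.0:
            y[i] = 0.0
        elif y[i] > 1.0:
            y[i] = 1.0


_HUMAN_PACED_LOOP = make_paced_loop(human_current, human_gates)


def default_protocol() -> StimulusProtocol:
    """1 Hz pacing, 1 ms / 52 pA/pF depolarizing pulse."""
    return StimulusProtocol(period=1000.0, duration=1.0, amplitude=52.0, onset=50.0)


def make_human_recipient_model():
    """Build the reduced human ventricular recipient model.

    Returns
    -------
    (CellModel, ParameterSet)
    """
    params = ParameterSet(PARAM_NAMES, BASELINE_PARAMS.copy())
    model = CellModel(
        name="human_reduced",
        params=params,
        initial_state=RESTING_STATE.copy(),
        state_names=STATE_NAMES,
        default_dt=0.01,
        current_fn=human_current,
        gates_fn=human_gates,
        paced_loop=_HUMAN_PACED_LOOP,
        protocol_factory=default_protocol,
    )
    return model, params
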