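"""Independent scalar re-implementations of both cell models.

Written separately from the package kernels (plain ``math`` on named
locals, no arrays, no numba) as the reference-equivalence oracle: the
production kernels must reproduce these equations' currents and voltage
trajectories to floating-point agreement.
"""

from math import exp, inf, isfinite, log, sqrt


# ---------------------------------------------------------------- mouse ----

def mouse_reference_current(p: dict, s: dict, v: float) -> float:
    """Total membrane current of the neonatal-mouse model, pA/pF outward."""
    rtf = 8314.5 * p["T"] / 96487.0
    ena = rtf * log(p["Na_o"] / p["Na_i"])
    ek = rtf * log(p["K_o"] / p["K_i"])
    eca = rtf / 2.0 * log(p["Ca_o"] / p["Ca_i"])

    ina = p["g_Na"] * s["m"] ** 3 * s["h"] * s["j"] * (v - ena)
    ical = p["g_CaL"] * s["d"] * (
        (0.9 + s["ca_inact"] / 10.0) * s["f11"]
        + (0.1 - s["ca_inact"] / 10.0) * s["f12"]) * (v - 65.0)
    it = p["g_t"] * s["r"] * s["s"] * (v - ek)
    ikslow = p["g_Kslow"] * s["r"] * s["s_slow"] * (v - ek)
    iss = p["g_ss"] * s["r_ss"] * s["s_ss"] * (v - ek)
    i_f = p["g_f"] * s["y"] * (0.2 * (v - ena) + 0.8 * (v - ek))
    ik1 = ((0.048 / (exp((v + 37.0) / 25.0) + exp((v + 37.0) / -25.0)) + 0.01)
           * 0.001 / (1.0 + exp((v - ek - 76.77) / -17.0))
           + p["g_K1"] * (v - ek - 1.73)
           / ((1.0 + exp(1.613 * 96487.0 * (v - ek - 1.73) / (8314.5 * p["T"])))
              * (1.0 + exp((p["K_o"] - 0.9988) / -0.124))))
    ibna = p["g_B_Na"] * (v - ena)
    ibca = p["g_B_Ca"] * (v - eca)
    ibk = p["g_B_K"] * (v - ek)
    inak = (p["i_NaK_max"] / (1.0 + (10.0 / p["Na_i"]) ** 1.5)
            * p["K_o"] / (p["K_o"] + 1.5)
            * 1.6 / (1.5 + exp((v + 60.0) / -40.0)))
    inaca = (p["k_NaCa"]
             * (p["Na_i"] ** 3 * p["Ca_o"] * exp(0.5 * v / rtf)
                - p["Na_o"] ** 3 * p["Ca_i"] * exp(-0.5 * v / rtf))
             / (1.0 + p["d_NaCa"] * (p["Na_i"] ** 3 * p["Ca_o"]
                                     + p["Na_o"] ** 3 * p["Ca_i"])))
    icap = p["i_CaP_max"] * p["Ca_i"] / (p["Ca_i"] + 0.0004)

    total_na = (ina + ical + it + ikslow + iss + i_f + ik1 + ibna + ibca + ibk
                + inak + inaca + icap)
    return total_na / (p["C_m"] / 1000.0)


def _mouse_rates(p: dict, v: float) -> dict:
    out = {}
    out["m"] = (1.0 / (1.0 + exp((v + 45.0) / -6.5)),
                1.36 / (0.32 * (v + 47.13) / (1.0 - exp(-0.1 * (v + 47.13)))
                        + 0.08 * exp(v / -11.0)))
    hinf = 1.0 / (1.0 + exp((v + 76.1) / 6.07))
    if v < -40.0:
        tauh = 3.49 / (0.135 * exp((v + 80.0) / -6.8) + 3.56 * exp(0.079 * v)
                       + 310000.0 * exp(0.35 * v))
        aj = ((v + 37.78) / (1.0 + exp(0.311 * (v + 79.23)))
              * (-127140.0 * exp(0.2444 * v) - 3.474e-5 * exp(-0.04391 * v)))
        bj = 0.1212 * exp(-0.01052 * v) / (1.0 + exp(-0.1378 * (v + 40.14)))
        tauj = 3.49 / (aj + bj)
    else:
        tauh = 0.4537 * (1.0 + exp((v + 10.66) / -11.1))
        tauj = 11.63 * (1.0 + exp(-0.1 * (v + 32.0))) * exp(2.535e-7 * v)
    out["h"] = (hinf, tauh)
    out["j"] = (hinf, tauj)
    out["d"] = (1.0 / (1.0 + exp((v + 15.3) / -5.0)),
                3.05 * exp(-0.0045 * (v + 7.0) ** 2)
                + 1.05 * exp(-0.002 * (v - 18.0) ** 2) + 0.25)
    finf = 1.0 / (1.0 + exp((v + 26.7) / 5.4))
    out["f11"] = (finf, 105.0 * exp(-((v + 45.0) / 12.0) ** 2)
                  + 40.0 / (1.0 + exp((-v + 25.0) / 25.0))
                  + 15.0 / (1.0 + exp((v + 75.0) / 25.0)) + 1.7)
    out["f12"] = (finf, 41.0 * exp(-((v + 47.0) / 12.0) ** 2)
                  + 80.0 / (1.0 + exp((v + 55.0) / -5.0))
                  + 15.0 / (1.0 + exp((v + 75.0) / 25.0)) + 1.7)
    denom = (45.16 * exp(0.03577 * (v + 50.0)) + 98.9 * exp(-0.1 * (v + 38.0)))
    out["r"] = (1.0 / (1.0 + exp((v + 10.6) / -11.42)), 1000.0 / denom)
    sinf = 1.0 / (1.0 + exp((v + 45.3) / 6.8841))
    out["s"] = (sinf, 350.0 * exp(-((v + 70.0) / 15.0) ** 2) + 35.0)
    out["s_slow"] = (sinf, 3700.0 * exp(-((v + 70.0) / 30.0) ** 2) + 35.0)
    out["r_ss"] = (1.0 / (1.0 + exp((v + 11.5) / -11.82)), 10000.0 / denom)
    out["s_ss"] = (1.0 / (1.0 + exp((v + 87.5) / 10.3)), 2100.0)
    out["y"] = (1.0 / (1.0 + exp((v + 138.6) / 10.48)),
                1000.0 / (0.11885 * exp((v + 80.0) / 28.37)
                          + 0.56236 * exp((v + 80.0) / -14.19)))
    return out


def mouse_reference_gates(p: dict, s: dict, v: float, dt: float) -> dict:
    rates = _mouse_rates(p, v)
    rates["ca_inact"] = (1.0 / (1.0 + p["Ca_i"] / 0.01), 9.0)
    out = dict(s)
    for name, (y_inf, tau) in rates.items():
        val = s[name] + (y_inf - s[name]) * (1.0 - exp(-dt / tau))
        out[name] = min(1.0, max(0.0, val))
    return out


def mouse_reference_run(p: dict, s0: dict, v0: float, dt: float, n_steps: int,
                        onset: float, duration: float, amplitude: float):
    """Forward-Euler paced run; returns the V trajectory (list, n_steps + 1)."""
    s = dict(s0)
    v = v0
    vs = [v]
    for k in range(n_steps):
        t = k * dt
        iapp = -amplitude if (onset <= t < onset + duration) else 0.0
        s = mouse_reference_gates(p, s, v, dt)
        v = v - dt * (mouse_reference_current(p, s, v) + iapp)
        if not isfinite(v):
            raise ArithmeticError(f"reference blow-up at t={t}")
        vs.append(v)
    return vs, s


# ---------------------------------------------------------------- human ----

def human_reference_current(p: dict, s: dict, v: float) -> float:
    """Total membrane current of the reduced human model, pA/pF outward."""
    rtf = 8314.472 * p["T"] / 96485.3415
    ena = rtf * log(p["Na_o"] / p["Na_i"])
    ek = rtf * log(p["K_o"] / p["K_i"])
    eks = rtf * log((p["K_o"] + 0.03 * p["Na_o"]) / (p["K_i"] + 0.03 * p["Na_i"]))
    eca = rtf / 2.0 * log(p["Ca_o"] / s["Ca_i"])

    ina = p["G_Na"] * s["m"] ** 3 * s["h"] * s["j"] * (v - ena)
    if abs(v) < 1e-4:
        drive = 2.0 * 96485.3415 * (0.25 * s["Ca_i"] - p["Ca_o"])
    else:
        e2 = exp(2.0 * v / rtf)
        drive = (4.0 * v * 96485.3415 / rtf
                 * (0.25 * s["Ca_i"] * e2 - p["Ca_o"]) / (e2 - 1.0))
    ical = p["G_CaL"] * s["d"] * s["f"] * s["f_Ca"] * drive
    ito = p["G_to"] * s["r"] * s["s"] * (v - ek)
    iks = p["G_Ks"] * s["x_s"] ** 2 * (v - eks)
    ikr = p["G_Kr"] * sqrt(p["K_o"] / 5.4) * s["x_r1"] * s["x_r2"] * (v - ek)
    ak1 = 0.1 / (1.0 + exp(0.06 * (v - ek - 200.0)))
    bk1 = ((3.0 * exp(0.0002 * (v - ek + 100.0)) + exp(0.1 * (v - ek - 10.0)))
           / (1.0 + exp(-0.5 * (v - ek))))
    ik1 = p["G_K1"] * sqrt(p["K_o"] / 5.4) * ak1 / (ak1 + bk1) * (v - ek)
    inaca = (p["k_NaCa"]
             * (exp(0.35 * v / rtf) * p["Na_i"] ** 3 * p["Ca_o"]
                - exp(-0.65 * v / rtf) * p["Na_o"] ** 3 * s["Ca_i"] * 2.5)
             / ((87.5 ** 3 + p["Na_o"] ** 3) * (1.38 + p["Ca_o"])
                * (1.0 + 0.1 * exp(-0.65 * v / rtf))))
    inak = (p["P_NaK"] * p["K_o"] * p["Na_i"]
            / ((p["K_o"] + 1.0) * (p["Na_i"] + 40.0)
               * (1.0 + 0.1245 * exp(-0.1 * v / rtf) + 0.0353 * exp(-v / rtf))))
    ipca = p["G_pCa"] * s["Ca_i"] / (s["Ca_i"] + 0.0005)
    ipk = p["G_pK"] * (v - ek) / (1.0 + exp((25.0 - v) / 5.98))
    ibna = p["G_bNa"] * (v - ena)
    ibca = p["G_bCa"] * (v - eca)
    return (ina + ical + ito + iks + ikr + ik1 + inaca + inak + ipca + ipk
            + ibna + ibca)


def human_reference_gates(p: dict, s: dict, v: float, dt: float) -> dict:
    rtf = 8314.472 * p["T"] / 96485.3415
    ca = s["Ca_i"]
    eca = rtf / 2.0 * log(p["Ca_o"] / ca)
    if abs(v) < 1e-4:
        drive = 2.0 * 96485.3415 * (0.25 * ca - p["Ca_o"])
    else:
        e2 = exp(2.0 * v / rtf)
        drive = (4.0 * v * 96485.3415 / rtf
                 * (0.25 * ca * e2 - p["Ca_o"]) / (e2 - 1.0))
    ical = p["G_CaL"] * s["d"] * s["f"] * s["f_Ca"] * drive
    ibca = p["G_bCa"] * (v - eca)
    ipca = p["G_pCa"] * ca / (ca + 0.0005)
    inaca = (p["k_NaCa"]
             * (exp(0.35 * v / rtf) * p["Na_i"] ** 3 * p["Ca_o"]
                - exp(-0.65 * v / rtf) * p["Na_o"] ** 3 * ca * 2.5)
             / ((87.5 ** 3 + p["Na_o"] ** 3) * (1.38 + p["Ca_o"])
                * (1.0 + 0.1 * exp(-0.65 * v / rtf))))

    minf = (1.0 + exp((-56.86 - v) / 9.03)) ** -2
    taum = (1.0 / (1.0 + exp((-60.0 - v) / 5.0))
            * (0.1 / (1.0 + exp((v + 35.0) / 5.0))
               + 0.1 / (1.0 + exp((v - 50.0) / 200.0))))
    hinf = (1.0 + exp((v + 71.55) / 7.43)) ** -2
    if v < -40.0:
        tauh = 1.0 / (0.057 * exp(-(v + 80.0) / 6.8)
                      + 2.7 * exp(0.079 * v) + 310000.0 * exp(0.3485 * v))
        aj = ((-25428.0 * exp(0.2444 * v) - 6.948e-6 * exp(-0.04391 * v))
              * (v + 37.78) / (1.0 + exp(0.311 * (v + 79.23))))
        bj = 0.02424 * exp(-0.01052 * v) / (1.0 + exp(-0.1378 * (v + 40.14)))
        tauj = 1.0 / (aj + bj)
    else:
        tauh = 0.13 * (1.0 + exp(-(v + 10.66) / 11.1)) / 0.77
        tauj = (1.0 + exp(-0.1 * (v + 32.0))) / (0.6 * exp(0.057 * v))
    dinf = 1.0 / (1.0 + exp((-5.0 - v) / 7.5))
    taud = ((1.4 / (1.0 + exp((-35.0 - v) / 13.0)) + 0.25)
            * 1.4 / (1.0 + exp((v + 5.0) / 5.0))
            + 1.0 / (1.0 + exp((50.0 - v) / 20.0)))
    finf = 1.0 / (1.0 + exp((v + 20.0) / 7.0))
    tauf = (1125.0 * exp(-(v + 27.0) ** 2 / 240.0) + 80.0
            + 165.0 / (1.0 + exp((25.0 - v) / 10.0)))
    fcainf = (1.0 / (1.0 + (ca / 0.000325) ** 8)
              + 0.1 / (1.0 + exp((ca - 0.0005) / 0.0001))
              + 0.2 / (1.0 + exp((ca - 0.00075) / 0.0008)) + 0.23) / 1.46
    rinf = 1.0 / (1.0 + exp((20.0 - v) / 6.0))
    taur = 9.5 * exp(-(v + 40.0) ** 2 / 1800.0) + 0.8
    sinf = 1.0 / (1.0 + exp((v + 20.0) / 5.0))
    taus = (85.0 * exp(-(v + 45.0) ** 2 / 320.0)
            + 5.0 / (1.0 + exp((v - 20.0) / 5.0)) + 3.0)
    xsinf = 1.0 / (1.0 + exp((-5.0 - v) / 14.0))
    tauxs = (1100.0 / sqrt(1.0 + exp((-10.0 - v) / 6.0))
             / (1.0 + exp((v - 60.0) / 20.0)))
    xr1inf = 1.0 / (1.0 + exp((-26.0 - v) / 7.0))
    tauxr1 = (450.0 / (1.0 + exp((-45.0 - v) / 10.0))
              * 6.0 / (1.0 + exp((v + 30.0) / 11.5)))
    xr2inf = 1.0 / (1.0 + exp((v + 88.0) / 24.0))
    tauxr2 = (3.0 / (1.0 + exp((-60.0 - v) / 20.0))
              * 1.12 / (1.0 + exp((v - 60.0) / 20.0)))
    if ca <= 0.00035:
        ginf = 1.0 / (1.0 + (ca / 0.00035) ** 6)
    else:
        ginf = 1.0 / (1.0 + (ca / 0.00035) ** 16)

    ileak = 0.00008 * (s["Ca_SR"] - ca)
    iup = 0.000425 / (1.0 + (0.00025 / ca) ** 2)
    irel = ((0.016464 * s["Ca_SR"] ** 2 / (0.0625 + s["Ca_SR"] ** 2) + 0.008232)
            * s["d"] * s["g_rel"])
    bsr = 1.0 / (1.0 + 10.0 * 0.3 / (s["Ca_SR"] + 0.3) ** 2)
    bc = 1.0 / (1.0 + 0.15 * 0.001 / (ca + 0.001) ** 2)
    dcasr = bsr * (iup - irel - ileak) * 0.016404 / 0.001094
    dcai = bc * (-(ical + ibca + ipca - 2.0 * inaca)
                 / (2.0 * 0.016404 * 96485.3415) * 0.185 + ileak - iup + irel)

    out = dict(s)

    def gate(name, y_inf, tau):
        out[name] = min(1.0, max(0.0, s[name]
                                 + (y_inf - s[name]) * (1.0 - exp(-dt / tau))))

    gate("m", minf, taum)
    gate("h", hinf, tauh)
    gate("j", hinf, tauj)
    gate("d", dinf, taud)
    gate("f", finf, tauf)
    fca_next = s["f_Ca"] + (fcainf - s["f_Ca"]) * (1.0 - exp(-dt / 2.0))
    if not (fca_next > s["f_Ca"] and v > -60.0):
        out["f_Ca"] = min(1.0, max(0.0, fca_next))
    gate("r", rinf, taur)
    gate("s", sinf, taus)
    gate("x_s", xsinf, tauxs)
    gate("x_r1", xr1inf, tauxr1)
    gate("x_r2", xr2inf, tauxr2)
    g_next = s["g_rel"] + (ginf - s["g_rel"]) * (1.0 - exp(-dt / 2.0))
    if not (g_next > s["g_rel"] and v > -60.0):
        out["g_rel"] = min(1.0, max(0.0, g_next))
    out["Ca_i"] = max(ca + dt * dcai, 1e-9)
    out["Ca_SR"] = max(s["Ca_SR"] + dt * dcasr, 1e-9)
    return out


def human_reference_run(p: dict, s0: dict, v0: float, dt: float, n_steps: int,
                        onset: float, duration: float, amplitude: float):
    s = dict(s0)
    v = v0
    vs = [v]
    for k in range(n_steps):
        t = k * dt
        iapp = -amplitude if (onset <= t < onset + duration) else 0.0
        s = human_reference_gates(p, s, v, dt)
        v = v - dt * (human_reference_current(p, s, v) + iapp)
        if not isfinite(v):
            raise ArithmeticError(f"reference blow-up at t={t}")
        vs.append(v)
    return vs, s
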