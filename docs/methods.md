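# Methods

## Cell models

**Neonatal-mouse target/canceling model.** A Pandit-type rat ventricular
epicardial formulation adapted to the neonatal mouse. Currents: fast Na⁺
(I_Na; m³hj), L-type Ca²⁺ (I_CaL; d, two voltage-inactivation gates f11/f12
and a Ca²⁺-inactivation gate held near unity by the fixed Ca²⁺ level),
Ca²⁺-independent transient outward (I_t; r·s), slowly inactivating delayed
rectifier (I_Kslow; r·s_slow), non-inactivating steady-state K⁺
(I_ss; r_ss·s_ss), inward rectifier (I_K1), hyperpolarization-activated
(I_f), Na⁺/K⁺ pump, Na⁺/Ca²⁺ exchange, sarcolemmal Ca²⁺ pump and three
ohmic backgrounds. All ionic concentrations are fixed
([K⁺]ₒ 5.4, [Na⁺]ₒ 140, [Ca²⁺]ₒ 1.2, [Na⁺]ᵢ 8.6, [K⁺]ᵢ 142 mM,
[Ca²⁺]ᵢ 0.079 µM), so the state is V plus thirteen gates. Conductances are
in µS on a 100 pF cell; g_Na = 0.8 µS.

Two modelling choices define the neonatal variant and are deliberate:

* Pandit's single transient-outward current (fast s plus slow s_slow
  inactivation components) is split into separately scalable I_t and
  I_Kslow, matching the current systems reported in neonatal mouse ventricle
  and giving the six named conductances the fitting and the template suite
  need.
* The baseline magnitudes g_CaL = 0.020, g_t = 0.008, g_Kslow = 0.015,
  g_ss = 0.014 µS were calibrated once, before any test was frozen, against
  two structural requirements and not revisited: (i) the APD₈₀ obtained by
  scaling (g_ss, g_Kslow) by a common factor must be smooth and monotone
  from below 40 ms to above 120 ms, and (ii) the six-gene search box must
  reach APD₈₀ ≥ 160 ms. With fixed [Ca²⁺]ᵢ the I_CaL window component is
  never quenched by Ca²⁺-dependent inactivation, and for larger g_CaL a
  stable depolarized equilibrium (a never-repolarizing AP) appears once the
  K⁺ reserve is scaled low; the chosen values keep that bistability outside
  the calibration corridor. APs that do hit it are treated as having an
  undefined APD (they are excluded from the reach search and receive the
  sentinel fitness in the GA).

**Human recipient model.** A reduced ten Tusscher–Panfilov epicardial
ventricular myocyte: the standard current set (I_Na, I_CaL, I_to, I_Ks,
I_Kr, I_K1, NCX, NaK, plateau and background currents), a single-pool SR
calcium subsystem (leak, uptake, gated release; steady-state cytosolic and
SR buffering) and gates fCa and g with the usual depolarization locks.
The reduction fixes [Na⁺]ᵢ = 11.6 and [K⁺]ᵢ = 138.3 mM, leaving 15 states.
Currents are in pA/pF on a 185 pF cell.

**Sign convention (package-wide).** All currents are capacitance-normalized
(pA/pF) and outward positive; dV/dt = −(i_ion + i_applied). A depolarizing
stimulus is a negative applied current; `StimulusProtocol` stores its
magnitude as a positive number.

## Numerics

V (and the calcium pools of the human model) advance by forward Euler —
dt = 0.1 ms for the mouse model, 0.01 ms for the recipient. Gating variables
advance by Rush–Larsen exponential relaxation,
y ← y∞ + (y − y∞)·exp(−dt/τ), which is exact for the per-step linear gate
ODE. This choice is load-bearing: the mouse m-gate time constant is
≈ 0.01 ms near rest, so explicit Euler at dt = 0.1 ms is a clipped
oscillation that destroys the resting fixed point; Rush–Larsen is
unconditionally stable and keeps gates in [0, 1] by construction. Gate
values are additionally clipped to [0, 1] and calcium floored at 10⁻⁹ mM as
a belt-and-braces guard. Step ordering is uniform everywhere: gates advance
at the pre-step voltage, the total current is evaluated at the updated
gates, then V updates. Integration aborts with a time-stamped error when V
leaves ±200 mV (±250 mV in the clamp loop) or becomes non-finite.

Each model stores the quiescent steady state of its baseline parameters
(frozen from a 20 s unstimulated run); single-beat evaluations start there
with no pre-pacing. Under sustained 1 Hz pacing the mouse APD₈₀ lengthens
for a few beats while the slow s_ss gate (τ = 2.1 s) settles; the package
consistently uses the first beat from rest for phenotypes, objectives and
calibration, so this adaptation cancels out of every comparison.

The in silico stimulus for the mouse model is a 1 ms pulse at 1.5× the
baseline model's diastolic threshold (bisected once per process and cached,
≈ 36 pA/pF); the recipient uses 52 pA/pF for 1 ms. An opt-in fast
exponential (2ⁿ·eʳ range reduction with a 5th-order polynomial, relative
error < 2·10⁻⁷) can replace `exp` in the kernels for speed; every
correctness test runs exact.

## Morphology metrics

Upstroke onset is the linearly interpolated time of the first upward
crossing of −40 mV (a sample exactly at threshold counts as the crossing) —
the same rule aligns the SSD window, so one convention serves both.
APD₈₀ uses the murine definition (downward crossing of 0.8 × V_rest, with
V_rest the sample immediately before stimulus onset); APD₃₀/₅₀/₉₀ use the
amplitude definition (V_peak − level% of the amplitude). The SSD aligns
both traces at their own −40 mV crossing, resamples them by linear
interpolation onto a common 300 ms grid at the coarser of the two sample
intervals (inclusive endpoints: 3001 points at 0.1 ms) and sums squared
differences. Beat averaging aligns traces at their stimulus onsets and takes
the pointwise mean over the common support.

## Template suite and GA

The suite calibrates nine members (APD₈₀ labels 40…120 ms) by bisecting a
common scale factor applied to (g_ss, g_Kslow) on a log grid against the
APD₈₀ of a fresh paced beat; monotonicity of the APD–scale relation is
checked at run time and each member is verified by re-simulation to ±1 ms.
Selection picks the member with the label closest to the measured APD₈₀;
exact ties resolve to the shorter-APD member. Any (g_ss, g_Kslow) pair
achieving the labelled APD₈₀ serves the selection role, so the common-factor
path replaces per-member hand-tuned pairs.

The GA's starting point is the 60 ms member. Genotypes are fractional
changes applied as g·(1+s); bounds: ±0.9 for g_Na, g_K1, g_t; ±0.1 for
g_CaL; −0.9…+2.0 for g_ss, g_Kslow. Operators (defaults throughout):

* tournament selection without replacement — two independent random
  pairings of the population; each pair's lower-error member enters the
  mating pool in win order (ties: first drawn); pool size = population;
* SBX with distribution index 10: per pair with probability 0.9, per gene
  with probability 0.5, spread β from u ~ U(0,1); children clipped to
  bounds; non-crossover pairs become their own children;
* polynomial mutation, index 20, probability 0.1 per gene, centred on the
  current value, offset δ·(upper − lower), clipped;
* elitism: after the children are evaluated the previous generation's best
  (with its cached error) replaces the worst child.

A run records 15 generations of 40 individuals; the random initial
population is generation 1, so a fit costs exactly 600 single-beat
evaluations (≈ 3 s here). Failed or unmeasurable phenotypes receive a
finite sentinel error (10⁹ mV²) so selection continues. One RNG stream per
run (seeded from the config) feeds initialization, pairing shuffles and all
operator draws in a fixed order; runs are bit-reproducible.

The claim being tested is waveform recovery, not parameter recovery:
distinct genotypes routinely produce near-identical APs (the model is
sloppy in this basis), so all recovery tests assert SSD/APD closeness only.

## CTC simulator

The loop runs at 0.1 ms; per cycle: (1) read target V (plus the
liquid-junction-potential offset, default 0); (2) advance the canceling
model one loop step and the recipient ten sub-steps of 0.01 ms, both
clamped at the measured V; (3) evaluate both total currents; (4) form the
capacitance-normalized difference î_rec − î_can (the raw-current statement
I_diff = K_r·I_rec − K_c·I_can, with K_c and K_r the target/model
capacitance ratios, is the same identity multiplied by C_target); (5) add
the stimulus and the seal-leak compensation −V/(R_seal·C_target); (6) step
the target free-running under the injected current. The physical seal leak
V/(R_seal·C_target) acts on the target membrane; with exact in silico
voltage measurement the compensation cancels it identically, and
R_seal = ∞ (default) disables both. The stimulus is delivered through the
injection path and uses the recipient's protocol, so an ideal conversion
reduces the target's membrane equation exactly to the recipient's.

The free-running recipient reference for conversion comparisons is
integrated under the *same* multirate discretization as the loop (V updated
at 0.1 ms, gates sub-stepped at 0.01 ms). This is deliberate: it is the
waveform an ideal conversion can reproduce; against a pure 0.01 ms
reference the Euler phase shift of the ~1 ms upstroke alone would dominate
the sup-norm. Conversion accuracy is assessed over the beat (from stimulus
onset): before the stimulus the target necessarily relaxes from the mouse
resting potential (≈ −80 mV) to the recipient's (≈ −86 mV), a start-up
transient that is not part of the conversion claim. With identical target
and canceling models the over-beat deviation is ≈ 0.45 mV at default steps
and shrinks as the loop step is refined; with a 70 ms canceling model
against a 60 ms target the converted APD₉₀ falls tens of ms short of ideal
— too little canceling (outward) current leaves uncompensated repolarizing
current in the target, the failure mechanism the current decomposition
(`CTCRecord`, `plot_record`) makes visible.

## Pseudo-cells: what they emulate and what they do not

A pseudo-cell is a hidden genotype (uniform within the GA bounds unless
supplied; redrawn if its AP is unmeasurable) paced for ten 1 Hz beats, each
with independent log-normal multiplicative jitter (CV 3%, unit median) on
the six key conductances and additive white Gaussian voltage noise
(SD 0.5 mV); the averaged beat is the objective. This emulates the
beat-to-beat and cell-to-cell variability and the averaging workflow of
real recordings. It does **not** emulate: model-structure error (the target
lies exactly on the model manifold, unlike a real myocyte), correlated or
drifting noise, electrode artifacts (access resistance, imperfect
capacitance measurement), temperature mismatch, or calcium-transient
dynamics. Passing recovery tests therefore demonstrates that the fitting
machinery recovers waveforms through realistic observation noise — not that
the mouse model can fit any real cell.

The recovery experiment fits each pseudo-cell (GA seeds decorrelated from
cell seeds via a seed sequence) and compares the final best SSD to the
cell's noise floor — the median SSD between its individual beats and their
average. At default noise the measured floor is ≈ 700–800 mV²; the median
fit lands well below it. On noise-free cells the pilot run used to freeze
the test threshold gave a median final/first-generation best-SSD ratio of
5.4% (10 seeded cells); the suite asserts ≤ 7.5%.

## Known limitations

* The mouse model's fixed-concentration reduction removes Ca²⁺-transient
  feedback; I_CaL inactivation is purely voltage-dependent, which both
  lengthens plateaus and creates the non-repolarizing regime described
  above at low repolarization reserve.
* Model kinetics are formulated at their native temperatures; no
  temperature correction is applied.
* The template/GA machinery and the clamp are wired for the
  mouse-target/human-recipient pair; other recipients plug in through the
  same kernel contract (`CellModel`) but none is implemented.
* Real-time behaviour (hard deadlines, amplifier artifacts, bridge
  balance) is out of scope; the loop is an idealized simulation of the
  circuit.

## Problem sizes used by the test suite and acceptance script

Template calibration bisects ≈ 40 single-beat simulations per member
(seconds for the full suite). The reach search evaluates 64 corners plus
108 line-scan points. A GA fit is 600 evaluations; the recovery experiment
fits 10 cells. The full test suite runs in about a minute after kernel
compilation.
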