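# ctclab

Rapid genetic-algorithm fitting of a neonatal-mouse ventricular
action-potential model, and an in silico **cell-type transforming clamp
(CTC)** that uses the fitted model to convert mouse-like action potentials
(APs) into human-like ones.

## The problem

Murine ventricular APs are short and triangular; human APs have a long
plateau. Many drug and mutation effects act on that plateau, so testing them
only in mouse myocytes is hard to interpret. The CTC is a dynamic-clamp
variant that fixes this in current clamp: a real (here: simulated) mouse
myocyte is coupled in a closed loop to two computational cells, a
*target-canceling* model of the mouse cell and a *recipient* model of the
desired cell type. Each cycle the measured voltage V is fed to both models,
their total membrane currents are capacitance-scaled and differenced,

&nbsp;&nbsp;&nbsp;&nbsp; Î<sub>diff</sub> = Î<sub>recipient</sub> − Î<sub>cancel</sub> ,

and Î<sub>diff</sub> (plus stimulus and seal-leak compensation) is injected
back into the cell. If the canceling model reproduces the cell's currents
exactly, the cell's membrane equation collapses to the recipient's and the
myocyte expresses a human-like AP. CTC quality therefore hinges on how well
the canceling model matches *this particular cell*.

Two matching strategies are implemented:

* **Template selection** — pick from a suite of nine mouse-model variants
  with APD₈₀ = 40…120 ms (10 ms steps, obtained by scaling the steady-state
  and slowly inactivating K⁺ conductances g_ss and g_Kslow) the member whose
  APD₈₀ is closest to the cell's.
* **Genetic-algorithm fitting** — tune six conductance scale factors
  (g_Na, g_ss, g_Kslow ∈ −90…+200%, g_CaL ∈ ±10%, g_K1, g_t ∈ ±90% around
  the 60 ms template model) to minimize the fitting error

  &nbsp;&nbsp;&nbsp;&nbsp; SSD = Σ<sub>t₀</sub><sup>t₀+300 ms</sup> [V₁(t) − V₂(t)]² ,

  the sum of squared differences over a 300 ms window aligned at the −40 mV
  upstroke crossing. The GA is small and fast by design: 40 individuals,
  15 generations, tournament selection without replacement, simulated binary
  crossover (index 10, pair probability 0.9, gene-wise probability 0.5),
  bounded polynomial mutation (index 20, probability 0.1/gene), and elitism.
  An individual's phenotype is a single 1 Hz-paced AP.

The models are explicit-Euler ODE systems: a Pandit-type neonatal-mouse
ventricular myocyte with fixed ionic concentrations (dt = 0.1 ms) and a
reduced ten Tusscher–Panfilov human ventricular myocyte (dt = 0.01 ms).
Since no patch-clamp data ship with the package, a **pseudo-cell generator**
synthesizes "recordings": ten consecutive 1 Hz beats of a hidden genotype
with per-beat conductance jitter (CV 3%) and additive voltage noise
(SD 0.5 mV), averaged into the fitting objective.

## Worked example

Generate a pseudo-cell, fit it with the GA, and run the ideal-conversion
clamp:

```sh
ctclab pseudo --seed 7 -o demo_pseudo
ctclab fit demo_pseudo/objective.tsv --seed 7 -o demo_fit
ctclab ctc -o demo_ctc
```

The fit prints

```
final best SSD: 42.283 mV^2 (2.9 s)
```

and `demo_fit/ga_log.tsv` shows the population converging from a mean SSD of
6.1·10⁵ mV² in the random first generation to a best of 42.3 mV² by
generation 14 — i.e. the fitted AP deviates from the ten-beat average by
about 0.12 mV RMS over the 300 ms error window, well inside that cell's
beat-to-beat spread. `demo_fit/genotype.json` holds the six fitted scale
factors and `demo_fit/phenotype.tsv` the fitted AP.

The clamp run prints

```
scenario: ideal
sup-norm deviation from recipient AP (over the beat): 0.454 mV
 beat  converted_apd30  converted_apd50  converted_apd90 ...
    0       306.845062       353.411114       382.299031 ...
```

meaning that with a perfectly matched canceling model the converted mouse AP
tracks the free-running human AP to half a millivolt, and its APD₃₀/₅₀/₉₀
match the recipient's to ≲ 0.4 ms. Running the `mismatch` scenario instead
(70 ms canceling model against a 60 ms target) shortens the converted APD₉₀
by tens of milliseconds — the insufficient-prolongation failure mode that
motivates cell-specific fitting.

`ctclab template` prints the calibrated suite, e.g.

```
APD80    60 ms -> g_ss 0.00482 uS, g_Kslow 0.00516 uS (measured 59.99 ms)
...
APD80   120 ms -> g_ss 0.00127 uS, g_Kslow 0.00137 uS (measured 120.06 ms)
```

`ctclab pseudo --recovery` runs the full fitting experiment over many
pseudo-cells and reports each cell's final SSD against its beat-to-beat
noise floor. `ctclab validate --schema` prints the JSON schema for the run
configuration.

## Layout

| module | contents |
| --- | --- |
| `ctclab.models` | mouse and human ODE models, shared stepping contract |
| `ctclab.metrics` | APD measures, upstroke alignment, SSD, beat averaging |
| `ctclab.templates` | nine-member APD₈₀ suite: calibration and selection |
| `ctclab.ga` | genotype bounds, GA operators, `fit_cell`, reach search |
| `ctclab.ctc` | closed-loop CTC simulator, current decomposition, plots |
| `ctclab.pseudo` | pseudo-cell generator and recovery experiment |
| `ctclab.cli` / `ctclab.config` | `ctclab` command-line workbench |

See `docs/methods.md` for the modelling and numerical details.
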