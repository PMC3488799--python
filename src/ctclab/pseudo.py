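"""Synthetic "recorded myocyte" generator.

Fitting and CTC are exercised without patch-clamp data by simulating a
pseudo-cell: a hidden true genotype (within the GA bounds, around the 60 ms
starting-point model) paced for ten consecutive 1 Hz beats with two noise
sources emulating a recording:

* per-beat multiplicative log-normal jitter on the six key conductances
  (default CV 3%), emulating beat-to-beat variability of the cell, and
* additive Gaussian observation noise on the voltage samples
  (default SD 0.5 mV).

The averaged beat is the fitting objective, exactly as averaged experimental
APs are.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ga import GENE_NAMES, LOWER, UPPER, GAConfig, Genotype, fit_cell
from .metrics import apd_mouse80, average_aps, ssd
from .models import SimSettings
from .models.mouse import make_neonatal_mouse_model
from .trace import VoltageTrace

__all__ = ["NoiseSettings", "PseudoCell", "generate_pseudo_cell",
           "recovery_experiment"]


@dataclass(frozen=True)
class NoiseSettings:
    """Beat-to-beat conductance jitter (CV) and additive voltage noise (mV)."""

    conductance_cv: float = 0.03
    voltage_sd_mv: float = 0.5

    def __post_init__(self) -> None:
        if self.conductance_cv < 0 or self.voltage_sd_mv < 0:
            raise ValueError("noise settings must be non-negative")


@dataclass
class PseudoCell:
    """Synthetic recording: hidden genotype, ten noisy beats and their average."""

    true_genotype: Genotype
    beats: list[VoltageTrace]
    objective: VoltageTrace
    noise: NoiseSettings
    seed: int


def generate_pseudo_cell(seed: int, noise: NoiseSettings | None = None,
                         genotype: Genotype | None = None,
                         n_beats: int = 10,
                         sim: SimSettings | None = None) -> PseudoCell:
    """Simulate ``n_beats`` noisy 1 Hz beats of a hidden genotype and average them.

    The genotype is drawn uniformly within the GA bounds when not supplied
    (redrawn if its AP is unmeasurable, e.g. fails to repolarize).
    """
    from .templates import starting_point_params

    if noise is None:
        noise = NoiseSettings()
    if sim is None:
        sim = SimSettings(dt=0.1, beats=1)
    rng = np.random.default_rng(seed)
    base = starting_point_params()

    def _beat(geno_values: np.ndarray) -> VoltageTrace:
        model, _ = make_neonatal_mouse_model(Genotype(geno_values), base)
        return model.simulate_paced(settings=sim)

    if genotype is None:
        for _ in range(100):
            candidate = rng.uniform(LOWER, UPPER)
            try:
                apd_mouse80(_beat(candidate))
            except Exception:
                continue
            genotype = Genotype(candidate)
            break
        else:  # pragma: no cover - bounds always contain measurable APs
            raise RuntimeError("could not draw a measurable genotype")
    genotype.validate()

    # per-beat conductance jitter: lognormal, unit median, stated CV
    sigma = np.sqrt(np.log(1.0 + noise.conductance_cv ** 2))
    beats = []
    for _ in range(n_beats):
        jitter = np.exp(rng.normal(0.0, sigma, size=6)) if sigma > 0 else np.ones(6)
        scales = np.clip((1.0 + genotype.values) * jitter - 1.0, LOWER, UPPER)
        trace = _beat(scales)
        if noise.voltage_sd_mv > 0:
            v = trace.v + rng.normal(0.0, noise.voltage_sd_mv, size=trace.v.size)
            trace = VoltageTrace(trace.t0, trace.dt, v, trace.stim_onsets)
        beats.append(trace)
    objective = average_aps(beats)
    return PseudoCell(genotype, beats, objective, noise, seed)


def noise_floor_ssd(cell: PseudoCell) -> float:
    """Median SSD between the individual beats and their average.

    This is the intrinsic beat-to-beat variability of the recording; a model
    fit below this floor matches the cell as well as its own beats do.
    """
    return float(np.median([ssd(b, cell.objective) for b in cell.beats]))


def recovery_experiment(n_cells: int, ga_cfg: GAConfig | None = None,
                        seeds: list[int] | None = None,
                        noise: NoiseSettings | None = None) -> pd.DataFrame:
    """Fit GA models to ``n_cells`` pseudo-cells and score the recovery.

    Per cell: the final best SSD, the first-generation best SSD, the
    beat-to-beat noise-floor SSD, and the APD80 error of the fit against the
    objective.  Acceptance is phrased on the phenotype (SSD/APD), not the
    genotype: distinct genotypes can produce near-identical APs.
    """
    if n_cells < 1:
        raise ValueError("need at least one cell")
    if seeds is None:
        seeds = list(range(n_cells))
    if len(seeds) != n_cells:
        raise ValueError("need one seed per cell")
    if ga_cfg is None:
        ga_cfg = GAConfig()
    rows = []
    for seed in seeds:
        cell = generate_pseudo_cell(seed, noise)
        # decorrelate the GA stream from the cell-generation stream
        ga_seed = int(np.random.SeedSequence([int(seed), int(ga_cfg.seed), 1]
                                             ).generate_state(1)[0] % (2 ** 31))
        result = fit_cell(cell.objective,
                          ga_cfg.__class__(**{**ga_cfg.__dict__, "seed": ga_seed}))
        fit_trace = result.best_individual.phenotype
        try:
            apd_err = abs(apd_mouse80(fit_trace) - apd_mouse80(cell.objective))
        except Exception:
            apd_err = float("nan")
        rows.append({
            "seed": seed,
            "final_ssd": float(result.best_errors[-1]),
            "gen1_ssd": float(result.best_errors[0]),
            "noise_floor_ssd": noise_floor_ssd(cell),
            "apd80_error_ms": apd_err,
        })
    return pd.DataFrame(rows)
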