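"""Rapid genetic-algorithm tuning of the six mouse-model conductances.

An individual's genotype is a vector of six fractional conductance changes
applied multiplicatively (``g -> g * (1 + s)``) to the starting-point model
(the 60 ms template member); its phenotype is a single 1 Hz paced AP; its
fitness is the sum-of-squared-differences error against the objective AP over
a 300 ms window aligned at the -40 mV upstroke crossing (lower is fitter).

Operators follow the classic real-coded toolbox: pairwise tournament
selection without replacement (two passes, pool size = population),
simulated binary crossover (SBX, distribution index 10, pair probability
0.9, gene-wise swap probability 0.5), bounded polynomial mutation
(index 20, probability 0.1 per gene) and single-individual elitism.
Defaults: 40 individuals, 15 generations.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import BoundsError
from .metrics import ErrorWindow, ssd
from .models import SimSettings
from .models.mouse import make_neonatal_mouse_model
from .trace import VoltageTrace

__all__ = ["Genotype", "GAConfig", "Individual", "GARunResult",
           "initialize_population", "evaluate", "tournament_pool",
           "sbx_crossover", "polynomial_mutation", "next_generation",
           "fit_cell", "search_range_reach"]

# Sentinel fitness for individuals whose simulation blows up; finite so that
# selection and elitism remain well defined.
WORST_ERROR = 1e9

GENE_NAMES = ("g_Na", "g_ss", "g_Kslow", "g_CaL", "g_K1", "g_t")
LOWER = np.array([-0.9, -0.9, -0.9, -0.1, -0.9, -0.9])
UPPER = np.array([0.9, 2.0, 2.0, 0.1, 0.9, 0.9])


@dataclass(frozen=True)
class Genotype:
    """Six conductance scale factors (fractional change from the start model)."""

    values: np.ndarray

    GENE_NAMES = GENE_NAMES
    LOWER = LOWER
    UPPER = UPPER

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.shape != (6,):
            raise ValueError("genotype has exactly six genes")

    def validate(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise BoundsError("genotype contains non-finite genes")
        if np.any(self.values < LOWER - 1e-12) or np.any(self.values > UPPER + 1e-12):
            raise BoundsError(
                f"genotype {self.values} outside bounds [{LOWER}, {UPPER}]")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(GENE_NAMES, map(float, self.values)))

    @classmethod
    def zeros(cls) -> "Genotype":
        return cls(np.zeros(6))


@dataclass(frozen=True)
class GAConfig:
    """GA settings; the defaults are the production configuration."""

    population_size: int = 40
    generations: int = 15
    crossover_probability: float = 0.9
    sbx_eta: float = 10.0
    swap_probability: float = 0.5
    mutation_probability: float = 0.1
    mutation_eta: float = 20.0
    elitism: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.crossover_probability, self.swap_probability,
                  self.mutation_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.population_size < 2 or self.population_size % 2:
            raise ValueError("population size must be even and >= 2")
        if self.generations < 1:
            raise ValueError("need at least one generation")
        if self.sbx_eta <= 0 or self.mutation_eta <= 0:
            raise ValueError("distribution indices must be positive")


@dataclass
class Individual:
    genotype: Genotype
    phenotype: VoltageTrace | None = None
    error: float | None = None

    @property
    def evaluated(self) -> bool:
        return self.error is not None


@dataclass
class GARunResult:
    """Full optimization history plus the final lowest-error individual."""

    error_history: np.ndarray       # (generations, population)
    best_errors: np.ndarray         # (generations,)
    best_individual: Individual
    seed: int
    wall_time_s: float
    config: GAConfig = field(repr=False, default=None)


def initialize_population(n: int, rng: np.random.Generator) -> list[Individual]:
    """n genotypes sampled i.i.d. uniformly within the per-gene bounds."""
    if n < 2 or n % 2:
        raise ValueError("population size must be even and >= 2")
    genes = rng.uniform(LOWER, UPPER, size=(n, 6))
    return [Individual(Genotype(g)) for g in genes]


def evaluate(individual: Individual, objective: VoltageTrace,
             sim: SimSettings | None = None,
             base_params=None, window: ErrorWindow = ErrorWindow()) -> float:
    """Simulate the phenotype (one paced AP) and score it against the objective.

    A simulation blow-up or an unmeasurable phenotype is assigned the finite
    sentinel error so selection can proceed.  The phenotype trace and error
    are cached on the individual.
    """
    if sim is None:
        sim = SimSettings(dt=0.1, beats=1)
    if base_params is None:
        from .templates import starting_point_params

        base_params = starting_point_params()
    try:
        model, _ = make_neonatal_mouse_model(individual.genotype, base_params)
        trace = model.simulate_paced(settings=sim)
        err = ssd(trace, objective, window)
        individual.phenotype = trace
    except BoundsError:
        raise
    except Exception:
        individual.phenotype = None
        err = WORST_ERROR
    individual.error = float(err)
    return individual.error


def tournament_pool(population: list[Individual],
                    rng: np.random.Generator) -> list[Individual]:
    """Mating pool via pairwise tournament selection without replacement.

    The population is randomly partitioned into pairs and each pair's
    lower-error member enters the pool in win order; a second independent
    pass doubles the pool to the population size.  Equal errors resolve to
    the first-drawn individual.
    """
    n = len(population)
    if n < 2 or n % 2:
        raise ValueError("population size must be even and >= 2")
    for ind in population:
        if not ind.evaluated:
            raise ValueError("tournament selection requires an evaluated population")
    pool: list[Individual] = []
    for _ in range(2):
        order = rng.permutation(n)
        for k in range(0, n, 2):
            a, b = population[order[k]], population[order[k + 1]]
            pool.append(a if a.error <= b.error else b)
    return pool


def _sbx_pair(x1: float, x2: float, eta: float, u: float) -> tuple[float, float]:
    if u <= 0.5:
        beta = (2.0 * u) ** (1.0 / (eta + 1.0))
    else:
        beta = (2.0 * (1.0 - u)) ** (-1.0 / (eta + 1.0))
    c1 = 0.5 * ((1.0 + beta) * x1 + (1.0 - beta) * x2)
    c2 = 0.5 * ((1.0 - beta) * x1 + (1.0 + beta) * x2)
    return c1, c2


def sbx_crossover(parent1: Genotype, parent2: Genotype, cfg: GAConfig,
                  rng: np.random.Generator) -> tuple[Genotype, Genotype]:
    """Simulated binary crossover with gene-wise application and clipping.

    With probability ``crossover_probability`` the pair recombines: each gene
    independently undergoes the SBX spread with probability
    ``swap_probability`` (otherwise it is copied).  Non-crossover pairs become
    their own children.
    """
    g1 = parent1.values.copy()
    g2 = parent2.values.copy()
    if rng.random() < cfg.crossover_probability:
        for i in range(6):
            if rng.random() < cfg.swap_probability:
                u = rng.random()
                g1[i], g2[i] = _sbx_pair(g1[i], g2[i], cfg.sbx_eta, u)
    np.clip(g1, LOWER, UPPER, out=g1)
    np.clip(g2, LOWER, UPPER, out=g2)
    return Genotype(g1), Genotype(g2)


def polynomial_mutation(genotype: Genotype, cfg: GAConfig,
                        rng: np.random.Generator) -> Genotype:
    """Bounded polynomial mutation centred on the current gene values."""
    g = genotype.values.copy()
    for i in range(6):
        if rng.random() < cfg.mutation_probability:
            u = rng.random()
            if u < 0.5:
                delta = (2.0 * u) ** (1.0 / (cfg.mutation_eta + 1.0)) - 1.0
            else:
                delta = 1.0 - (2.0 * (1.0 - u)) ** (1.0 / (cfg.mutation_eta + 1.0))
            g[i] += delta * (UPPER[i] - LOWER[i])
    np.clip(g, LOWER, UPPER, out=g)
    return Genotype(g)


def next_generation(population: list[Individual], objective: VoltageTrace,
                    cfg: GAConfig, rng: np.random.Generator,
                    sim: SimSettings | None = None,
                    base_params=None) -> list[Individual]:
    """One full GA cycle: selection, crossover, mutation, evaluation, elitism.

    Parents are paired sequentially in the order they won their tournaments;
    each pair yields two children.  With elitism on, the previous
    generation's best individual (with its cached error, not re-evaluated)
    replaces the worst child.
    """
    pool = tournament_pool(population, rng)
    children: list[Individual] = []
    for k in range(0, len(pool), 2):
        c1, c2 = sbx_crossover(pool[k].genotype, pool[k + 1].genotype, cfg, rng)
        children.append(Individual(polynomial_mutation(c1, cfg, rng)))
        children.append(Individual(polynomial_mutation(c2, cfg, rng)))
    for child in children:
        evaluate(child, objective, sim, base_params)
    if cfg.elitism:
        elite = min(population, key=lambda ind: ind.error)
        worst = int(np.argmax([c.error for c in children]))
        children[worst] = Individual(elite.genotype, elite.phenotype, elite.error)
    return children


def fit_cell(objective: VoltageTrace, cfg: GAConfig | None = None,
             sim: SimSettings | None = None, base_params=None) -> GARunResult:
    """Run the full GA and return the history and final best individual."""
    if cfg is None:
        cfg = GAConfig()
    if base_params is None:
        from .templates import starting_point_params

        base_params = starting_point_params()
    rng = np.random.default_rng(cfg.seed)
    t_start = time.perf_counter()
    population = initialize_population(cfg.population_size, rng)
    for ind in population:
        evaluate(ind, objective, sim, base_params)
    history = np.empty((cfg.generations, cfg.population_size))
    for gen in range(cfg.generations):
        if gen > 0:
            population = next_generation(population, objective, cfg, rng,
                                         sim, base_params)
        history[gen] = [ind.error for ind in population]
    best = min(population, key=lambda ind: ind.error)
    return GARunResult(
        error_history=history,
        best_errors=history.min(axis=1),
        best_individual=best,
        seed=cfg.seed,
        wall_time_s=time.perf_counter() - t_start,
        config=cfg,
    )


def _apd80_of_genotype(genes: np.ndarray, base_params, dt: float = 0.1) -> float:
    from .metrics import apd_mouse80

    try:
        model, _ = make_neonatal_mouse_model(Genotype(genes), base_params)
        trace = model.simulate_paced(settings=SimSettings(dt=dt, beats=1))
        return apd_mouse80(trace)
    except Exception:
        return float("nan")


def search_range_reach(direction: str = "max", n_refine: int = 9,
                       sweeps: int = 2) -> tuple[float, Genotype]:
    """Extreme APD80 reachable inside the six-gene search bounds.

    Deterministic coarse directed search: evaluate the 64 corners of the
    bound box around the starting-point model, keep the extreme corner with a
    measurable APD80, then refine by cyclic per-gene line scans (``n_refine``
    points per gene, ``sweeps`` passes).  Genotypes whose AP fails to
    repolarize within the beat are excluded (their APD80 is undefined).

    Returns the extreme APD80 (ms) and the genotype achieving it.
    """
    from itertools import product

    from .templates import starting_point_params

    if direction not in ("max", "min"):
        raise ValueError("direction must be 'max' or 'min'")
    sign = 1.0 if direction == "max" else -1.0
    base = starting_point_params()

    best_val = -np.inf
    best_genes = np.zeros(6)
    for corner in product(*[(lo, hi) for lo, hi in zip(LOWER, UPPER)]):
        genes = np.array(corner)
        apd = _apd80_of_genotype(genes, base)
        if np.isfinite(apd) and sign * apd > best_val:
            best_val = sign * apd
            best_genes = genes
    for _ in range(sweeps):
        for i in range(6):
            grid = np.linspace(LOWER[i], UPPER[i], n_refine)
            for x in grid:
                genes = best_genes.copy()
                genes[i] = x
                apd = _apd80_of_genotype(genes, base)
                if np.isfinite(apd) and sign * apd > best_val:
                    best_val = sign * apd
                    best_genes = genes
    return sign * best_val, Genotype(best_genes)
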