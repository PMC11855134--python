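"""Real-coded genetic algorithm over the (concentration, exposure) rectangle.

Operator suite: uniform initialization within box bounds, rank-scaled
stochastic universal sampling (SUS) for parent selection, scattered
crossover (independent fair per-gene mask), success-adaptive bounded
Gaussian mutation, and elitism.  Each generation carries the elites
unchanged, fills a crossover fraction of the remaining slots with
scattered-crossover children, and the rest with mutants; the best-so-far
trace is therefore non-decreasing.  The run executes exactly the
configured number of generations — no early stopping.

The fitness is any callable mapping a gene vector to a finite scalar;
``make_fitness`` builds the one used in the pipeline, the PNN posterior
probability of the tetraploid class at the standardized query point.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .classifiers.pnn import PNNModel, pnn_posterior
from .errors import DomainError
from .preprocess import StandardizationParams, apply_standardizer

#: Mutation-scale dynamics: initial sd as a fraction of each gene's range,
#: and the contraction factor applied after a generation without improvement
#: (expansion is the reciprocal, capped at the initial scale).
INITIAL_SCALE_FRACTION = 0.10
SCALE_CONTRACTION = 0.95


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 200
    generations: int = 1000
    mutation_rate: float = 0.05  # per-gene probability within mutant offspring
    crossover_fraction: float = 0.6  # share of non-elite offspring from crossover
    bounds: tuple[tuple[float, float], ...] = ((0.0, 100.0), (0.0, 36.0))
    elite_count: int | None = None  # default ceil(0.05 * population)
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 2:
            raise DomainError("population_size must be >= 2")
        if self.generations < 1:
            raise DomainError("generations must be >= 1")
        for name in ("mutation_rate", "crossover_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DomainError(f"{name} must be in [0, 1]")
        for lo, hi in self.bounds:
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise DomainError("bounds must be finite with lower < upper")
        if self.elite_count is None:
            object.__setattr__(
                self, "elite_count", math.ceil(0.05 * self.population_size)
            )
        if not 0 <= self.elite_count < self.population_size:
            raise DomainError("elite_count must be < population_size")

    @property
    def n_genes(self) -> int:
        return len(self.bounds)

    @property
    def lower(self) -> np.ndarray:
        return np.array([b[0] for b in self.bounds])

    @property
    def upper(self) -> np.ndarray:
        return np.array([b[1] for b in self.bounds])


@dataclass(frozen=True)
class Individual:
    genes: np.ndarray
    fitness: float


@dataclass(frozen=True)
class GAResult:
    best: Individual
    trace: np.ndarray = field(repr=False)  # best-so-far fitness per generation
    generations: int = 0
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "best_genes": [float(g) for g in self.best.genes],
            "best_fitness": float(self.best.fitness),
            "generations": int(self.generations),
            "seed": int(self.seed),
            "trace": [float(v) for v in self.trace],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


def make_fitness(model: PNNModel, standardizer: StandardizationParams):
    """Tetraploid-posterior fitness over raw (concentration, exposure) genes.

    Returns a callable accepting a single gene vector (returns a float in
    [0, 1]) or an (n, 2) batch (returns an (n,) array).
    """
    if model.X.size == 0:
        raise DomainError("PNN model holds no training patterns")
    tet_idx = list(model.classes).index("tetraploid")

    def fitness(x):
        x = np.asarray(x, dtype=float)
        z = apply_standardizer(standardizer, x)
        post = np.atleast_2d(pnn_posterior(model, z))
        out = post[:, tet_idx]
        return float(out[0]) if x.ndim == 1 else out

    return fitness


def init_population(cfg: GAConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Population-size individuals i.i.d. uniform over the bounds rectangle."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    return rng.uniform(cfg.lower, cfg.upper, size=(cfg.population_size, cfg.n_genes))


def _rank_scaled_weights(fitnesses: np.ndarray) -> np.ndarray:
    """Scaled fitness 1/rank with ties sharing their average rank.

    Rank scaling makes selection depend only on fitness order, never on raw
    fitness magnitudes; the harmonic (1/rank) profile concentrates parent
    mass on the current leaders, which the success-adaptive mutation needs
    in order to polish the optimum.  Equal fitnesses receive equal weight
    (uniform selection in the all-equal case).
    """
    from scipy.stats import rankdata

    ranks = rankdata(-np.asarray(fitnesses, dtype=float), method="average")
    return 1.0 / ranks


def select_parents(
    population: np.ndarray,
    fitnesses: np.ndarray,
    count: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Stochastic universal sampling over the rank-scaled fitness line.

    `count` evenly spaced pointers share a single random phase, so each
    individual's expected selection count is proportional to its scaled
    fitness while the variance stays minimal.
    """
    if count < 1:
        raise DomainError("count must be >= 1")
    population = np.asarray(population, dtype=float)
    weights = _rank_scaled_weights(fitnesses)
    cum = np.cumsum(weights)
    step = cum[-1] / count
    phase = rng.uniform(0.0, step)
    points = phase + step * np.arange(count)
    idx = np.searchsorted(cum, points, side="right")
    idx = np.minimum(idx, len(population) - 1)
    return population[idx]


def scattered_crossover(
    parent1: np.ndarray, parent2: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Child takes each gene from parent1 or parent2 by an independent fair coin."""
    p1 = np.asarray(parent1, dtype=float)
    p2 = np.asarray(parent2, dtype=float)
    if p1.shape != p2.shape:
        raise DomainError("parents must have equal gene counts")
    mask = rng.random(p1.shape) < 0.5
    return np.where(mask, p1, p2)


def adaptive_feasible_mutation(
    ind: np.ndarray,
    cfg: GAConfig,
    scale: np.ndarray,
    rng: np.random.Generator,
    ensure_change: bool = False,
) -> np.ndarray:
    """Mutate each gene with cfg.mutation_rate by a Gaussian step of sd `scale`.

    `scale` is the current per-gene standard deviation (the generation
    state); results are clipped to the box bounds.  With ``ensure_change``
    (used for the mutation offspring inside :func:`evolve`) a uniformly
    chosen gene is forced to mutate when every per-gene draw misses, so a
    mutation child is never a clone of its parent.
    """
    ind = np.asarray(ind, dtype=float)
    scale = np.broadcast_to(np.asarray(scale, dtype=float), ind.shape)
    mask = rng.random(ind.shape) < cfg.mutation_rate
    if ensure_change and not mask.any():
        mask = mask.copy()
        mask[rng.integers(ind.size)] = True
    steps = rng.normal(0.0, 1.0, size=ind.shape) * scale
    mutant = np.where(mask, ind + steps, ind)
    return np.clip(mutant, cfg.lower, cfg.upper)


def _evaluate(fitness, population: np.ndarray) -> np.ndarray:
    """Evaluate fitness on a population, batched when the callable supports it."""
    try:
        vals = np.asarray(fitness(population), dtype=float)
        if vals.shape == (len(population),):
            # guard against a scalar fitness that happens to broadcast
            try:
                v0 = float(fitness(population[0]))
            except Exception:
                return vals
            if np.isclose(v0, vals[0], rtol=1e-12, atol=0, equal_nan=True) or not np.isfinite(v0):
                return vals
    except Exception:
        pass
    return np.array([float(fitness(ind)) for ind in population])


def evolve(fitness, cfg: GAConfig) -> GAResult:
    """Run the GA for exactly cfg.generations generations.

    Per generation: carry elites unchanged, fill the crossover fraction of
    the remaining slots with scattered-crossover children of SUS-selected
    parents, the rest with adaptive-Gaussian mutants of selected parents;
    the mutation scale contracts by 0.95 after a generation without
    best-fitness improvement and expands by 1/0.95 (capped at the initial
    scale) after one with improvement.
    """
    rng = np.random.default_rng(cfg.seed)
    pop = init_population(cfg, rng)
    fit = _evaluate(fitness, pop)
    _check_finite(fit, pop)

    init_scale = INITIAL_SCALE_FRACTION * (cfg.upper - cfg.lower)
    scale = init_scale.copy()

    best_i = int(np.argmax(fit))
    best_genes, best_fit = pop[best_i].copy(), float(fit[best_i])
    trace = np.empty(cfg.generations)

    n_rest = cfg.population_size - cfg.elite_count
    n_cross = int(round(cfg.crossover_fraction * n_rest))
    n_mut = n_rest - n_cross

    for gen in range(cfg.generations):
        order = np.argsort(-fit, kind="stable")
        elites = pop[order[: cfg.elite_count]].copy()
        parents = select_parents(pop, fit, 2 * n_cross + n_mut, rng)
        children = np.array(
            [
                scattered_crossover(parents[2 * i], parents[2 * i + 1], rng)
                for i in range(n_cross)
            ]
        ).reshape(n_cross, cfg.n_genes)
        mutants = np.array(
            [
                adaptive_feasible_mutation(
                    parents[2 * n_cross + i], cfg, scale, rng, ensure_change=True
                )
                for i in range(n_mut)
            ]
        ).reshape(n_mut, cfg.n_genes)
        pop = np.vstack([elites, children, mutants])
        fit = _evaluate(fitness, pop)
        _check_finite(fit, pop)
        gen_best = int(np.argmax(fit))
        if fit[gen_best] > best_fit:
            best_genes, best_fit = pop[gen_best].copy(), float(fit[gen_best])
            scale = np.minimum(scale / SCALE_CONTRACTION, init_scale)
        else:
            scale = scale * SCALE_CONTRACTION
        trace[gen] = best_fit

    return GAResult(
        best=Individual(genes=best_genes, fitness=best_fit),
        trace=trace,
        generations=cfg.generations,
        seed=cfg.seed,
    )


def _check_finite(fit: np.ndarray, pop: np.ndarray) -> None:
    bad = np.flatnonzero(~np.isfinite(fit))
    if len(bad):
        raise DomainError(
            f"non-finite fitness at gene vector {pop[bad[0]].tolist()}"
        )


def grid_argmax(fitness, cfg: GAConfig, resolution: int = 200):
    """Exhaustive grid argmax of the fitness surface (oracle for the GA)."""
    axes = [
        np.linspace(lo, hi, resolution) for lo, hi in cfg.bounds
    ]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([m.ravel() for m in mesh])
    vals = _evaluate(fitness, pts)
    i = int(np.argmax(vals))
    return pts[i], float(vals[i])
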