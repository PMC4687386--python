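"""Genetic algorithm over keep/kill partitions of the EFM set.

Each individual is a binary vector S over the n EFMs: bit j = 1 keeps mode
E_j (desired set D(S)), bit j = 0 targets it for elimination (T(S)).  An
individual therefore codes an intervention problem

    I(S) = I[T(S), D(S), k(S)],   k(S) = ceil(w_k · |D(S)|),

whose constrained minimal cut sets are enumerated exactly.  Every cut set
leaves some survivor *pattern* — the subset of kept modes it does not hit —
and each pattern is scored by the configured fitness function; the fitness
of the individual is the fitness of its fittest pattern.  Evolution uses
fitness-proportionate selection, elitism (guaranteeing a non-decreasing
maximum fitness), three standard crossovers, a mutation operator flipping
round(ρ·r_m) positions (ρ = number of modes with desirable characteristics),
and pattern-based individual generation that resamples bits in proportion
to how often each mode survived in previously discovered patterns.

Evaluations are cached by individual, so the cut-set solver runs once per
distinct keep/kill partition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .cmcs import (
    CutSet,
    InfeasibleTargetError,
    InterventionProblem,
    default_forbidden,
    solve_intervention,
)
from .efm import EFMSet
from .objectives import FitnessSpec, mode_metrics, pattern_fitness

__all__ = [
    "Individual",
    "Pattern",
    "GAConfig",
    "GAResult",
    "EvaluationCache",
    "good_mode_mask",
    "initialize_population",
    "evaluate",
    "select_parent",
    "crossover",
    "mutate",
    "pattern_weights",
    "generate_pattern_based",
    "pattern_fitness_of_group",
    "run_ga",
]

logger = logging.getLogger(__name__)

_FITNESS_TOL = 1e-12


@dataclass(frozen=True)
class Individual:
    """Keep/kill partition: bit j = 1 keeps EFM j, 0 targets it."""

    bits: tuple[int, ...]

    def ones(self) -> list[int]:
        return [j for j, b in enumerate(self.bits) if b]

    def __len__(self) -> int:
        return len(self.bits)


@dataclass
class Pattern:
    """A survivor pattern with its fitness and minimal-cardinality cut sets."""

    bits: tuple[int, ...]
    fitness: float
    cutsets: list[CutSet]

    @property
    def survivors(self) -> frozenset[int]:
        return frozenset(j for j, b in enumerate(self.bits) if b)


@dataclass
class GAConfig:
    """GA control parameters (key names follow the standard parameter table).

    t: generation budget; p: population size; r_m: mutation rate (the flip
    count per individual is round(ρ·r_m)); cross: crossover kind; elit:
    elite fraction (ceil(elit·p) individuals carried over unchanged);
    new_S: fraction of p regenerated from the pattern archive each
    generation; t_stop: stagnation window; min_1s: minimum fraction of the
    good modes present in each initial individual; w_k: survivor fraction
    defining k(S); threads: accepted for config compatibility (evaluation
    is deterministic, so any schedule equals serial execution).
    """

    t: int = 100
    p: int = 50
    r_m: float = 0.00025
    cross: str = "1point"
    elit: float = 0.025
    new_S: float = 0.1
    t_stop: int = 15
    min_1s: float = 0.9
    w_k: float = 0.03
    threads: int = 1
    seed: int | None = None
    max_cut_cardinality: int = 8
    good_mode_rule: str = "yield>0"

    def __post_init__(self):
        if not (0 <= self.r_m < 1):
            raise ValueError("r_m must satisfy 0 <= r_m < 1")
        for name in ("elit", "new_S", "min_1s", "w_k"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.t < 1 or self.t_stop < 1:
            raise ValueError("t and t_stop must be >= 1")
        if self.p < 2:
            raise ValueError("population size p must be >= 2")
        if self.cross not in ("1point", "2point", "uniform"):
            raise ValueError("cross must be one of 1point|2point|uniform")
        if self.max_cut_cardinality < 1:
            raise ValueError("max_cut_cardinality must be >= 1")
        if self.threads < 1:
            raise ValueError("threads must be >= 1")


@dataclass
class GAResult:
    """Best patterns found, their cut sets, and the fitness trajectory."""

    best_fitness: float
    best_patterns: list[Pattern]
    fitness_trajectory: list[tuple[float, float]]  # per-generation (max, mean)
    generations_run: int
    cache_hits: int
    evaluations: int


class EvaluationCache:
    """Per-run lookup tables: individual → result, plus the pattern archive.

    The archive records every (pattern, fitness) once per distinct evaluated
    individual — cache hits return stored results without re-accumulating
    archive weight, so identical individuals cannot inflate the survival
    counts that drive pattern-based generation.
    """

    def __init__(self):
        self.results: dict[tuple[int, ...], tuple[float, list[tuple[frozenset[int], float]]]] = {}
        self.archive: list[tuple[frozenset[int], float]] = []
        self.registry: dict[frozenset[int], tuple[float, list[CutSet]]] = {}
        self.hits = 0

    @property
    def evaluations(self) -> int:
        return len(self.results)

    def record_pattern(self, pattern: frozenset[int], fitness: float, cuts: list[CutSet]):
        self.archive.append((pattern, fitness))
        prev = self.registry.get(pattern)
        if prev is None or fitness > prev[0] + _FITNESS_TOL:
            self.registry[pattern] = (fitness, list(cuts))
        elif abs(fitness - prev[0]) <= _FITNESS_TOL:
            known = {c.reactions for c in prev[1]}
            merged = prev[1] + [c for c in cuts if c.reactions not in known]
            self.registry[pattern] = (prev[0], merged)


def good_mode_mask(efms: EFMSet, spec: FitnessSpec, rule: str = "yield>0") -> tuple[int, ...]:
    """Mark the ρ modes with desirable characteristics.

    Only marked modes are eligible to be kept during initialisation, and ρ
    scales the mutation flip count.  Rules: ``yield>0`` (producers, the
    default), ``efficiency>0`` (growth-coupled producers), ``all``.
    """
    if rule == "all":
        return tuple([1] * efms.n)
    mask = []
    for mode in efms.modes:
        metrics = mode_metrics(mode, spec)
        if rule == "yield>0":
            mask.append(1 if metrics.yield_product > 0 else 0)
        elif rule == "efficiency>0":
            mask.append(1 if metrics.efficiency > 0 else 0)
        else:
            raise ValueError(f"unknown good-mode rule {rule!r}")
    if sum(mask) == 0:
        raise ValueError(
            f"good-mode rule {rule!r} marks no mode; the GA cannot seed a desired set"
        )
    return tuple(mask)


def initialize_population(
    config: GAConfig, mask: Sequence[int], rng: np.random.Generator
) -> list[Individual]:
    """p random individuals confined to the good-mode mask.

    Each individual keeps between ceil(min_1s·ρ) and ρ of the ρ good modes,
    chosen uniformly; every mask-0 position stays 0.
    """
    good = [j for j, b in enumerate(mask) if b]
    rho = len(good)
    if rho < 1:
        raise ValueError("good-mode mask is empty")
    lo = math.ceil(config.min_1s * rho)
    pop = []
    for _ in range(config.p):
        count = int(rng.integers(lo, rho + 1)) if lo < rho else rho
        keep = rng.choice(good, size=count, replace=False) if count else []
        bits = [0] * len(mask)
        for j in keep:
            bits[int(j)] = 1
        pop.append(Individual(tuple(bits)))
    return pop


def pattern_fitness_of_group(
    pattern: frozenset[int],
    cuts: Sequence[CutSet],
    efms: EFMSet,
    spec: FitnessSpec,
) -> tuple[float, list[CutSet]]:
    """Fitness of one survivor pattern, scored at its minimal cut cardinality.

    Returns the fitness and the minimal-cardinality cut sets of the group.
    """
    min_card = min(c.cardinality for c in cuts)
    min_cuts = sorted(
        (c for c in cuts if c.cardinality == min_card), key=lambda c: c.sorted()
    )
    metrics = [mode_metrics(efms.modes[i], spec) for i in sorted(pattern)]
    fit = pattern_fitness(metrics, min_card, len(pattern), spec)
    return fit, min_cuts


def evaluate(
    individual: Individual,
    efms: EFMSet,
    spec: FitnessSpec,
    config: GAConfig,
    cache: EvaluationCache,
    forbidden: frozenset[int] | None = None,
) -> tuple[float, list[tuple[frozenset[int], float]]]:
    """Solve the individual's intervention problem and score its patterns.

    Returns (individual fitness, [(pattern, fitness), ...]).  Infeasible
    individuals — no cut set within the cardinality budget, an empty keep
    set, or a target mode that only forbidden reactions could hit — score
    fitness 0 with no patterns; this is an outcome, not an error.
    """
    key = individual.bits
    if key in cache.results:
        cache.hits += 1
        return cache.results[key]
    if forbidden is None:
        forbidden = default_forbidden(efms.network)
    supports = efms.supports()
    keep = individual.ones()
    result: tuple[float, list[tuple[frozenset[int], float]]]
    if not keep:
        result = (0.0, [])
    else:
        kill = [i for i in range(efms.n) if not individual.bits[i]]
        problem = InterventionProblem(
            targets=[supports[i] for i in kill],
            desired=[supports[i] for i in keep],
            keep_min=math.ceil(config.w_k * len(keep)),
        )
        try:
            solutions = solve_intervention(
                problem, config.max_cut_cardinality, forbidden=forbidden
            )
        except InfeasibleTargetError:
            solutions = []
        groups: dict[frozenset[int], list[CutSet]] = {}
        for cut, _surv in solutions:
            pattern = frozenset(
                i for i in keep if not (cut.reactions & supports[i])
            )
            if pattern:
                groups.setdefault(pattern, []).append(cut)
        scored = []
        for pattern, cuts in groups.items():
            fit, min_cuts = pattern_fitness_of_group(pattern, cuts, efms, spec)
            scored.append((pattern, fit))
            cache.record_pattern(pattern, fit, min_cuts)
        best = max((f for _, f in scored), default=0.0)
        result = (best, scored)
    cache.results[key] = result
    return result


def select_parent(
    population: Sequence[Individual],
    fitnesses: Sequence[float],
    rng: np.random.Generator,
) -> Individual:
    """Fitness-proportionate (roulette) selection; uniform when all zero."""
    if not population:
        raise ValueError("cannot select from an empty population")
    total = float(sum(fitnesses))
    if total <= 0:
        idx = int(rng.integers(0, len(population)))
    else:
        probs = np.asarray(fitnesses, dtype=float) / total
        idx = int(rng.choice(len(population), p=probs))
    return population[idx]


def crossover(
    parent1: Individual,
    parent2: Individual,
    kind: str,
    rng: np.random.Generator,
) -> tuple[Individual, Individual]:
    """One of the three standard crossovers; per position the offspring
    multiset {S3_j, S4_j} equals the parent multiset {S1_j, S2_j}."""
    s1, s2 = parent1.bits, parent2.bits
    if len(s1) != len(s2):
        raise ValueError("parents must have equal length")
    n = len(s1)
    if kind == "1point":
        r_c = int(rng.integers(1, n))  # 1 <= r_c < n
        c1 = s1[:r_c] + s2[r_c:]
        c2 = s2[:r_c] + s1[r_c:]
    elif kind == "2point":
        r_c1 = int(rng.integers(1, n - 1))
        r_c2 = int(rng.integers(r_c1 + 1, n))
        c1 = s1[:r_c1] + s2[r_c1:r_c2] + s1[r_c2:]
        c2 = s2[:r_c1] + s1[r_c1:r_c2] + s2[r_c2:]
    elif kind == "uniform":
        r_u = rng.random(n)
        c1 = tuple(s1[j] if r_u[j] < 0.5 else s2[j] for j in range(n))
        c2 = tuple(s2[j] if r_u[j] < 0.5 else s1[j] for j in range(n))
    else:
        raise ValueError(f"unknown crossover kind {kind!r}")
    return Individual(tuple(c1)), Individual(tuple(c2))


def mutate(
    individual: Individual,
    r_m: float,
    rho: int,
    rng: np.random.Generator,
) -> Individual:
    """Flip round(ρ·r_m) distinct positions drawn uniformly over all n bits.

    Round-half-up, so r_m = 0 is the identity and ρ·r_m = 2.5 flips 3 bits.
    """
    n = len(individual.bits)
    flips = int(math.floor(rho * r_m + 0.5))
    if flips <= 0:
        return individual
    flips = min(flips, n)
    positions = rng.choice(n, size=flips, replace=False)
    bits = list(individual.bits)
    for j in positions:
        bits[int(j)] ^= 1
    return Individual(tuple(bits))


def pattern_weights(
    archive: Sequence[tuple[frozenset[int], float]], n: int
) -> np.ndarray:
    """w_t^i: how often EFM i survived across all archived patterns."""
    w = np.zeros(n, dtype=np.int64)
    for pattern, _fit in archive:
        for i in pattern:
            w[i] += 1
    return w


def generate_pattern_based(
    weights: np.ndarray, count: int, rng: np.random.Generator
) -> list[Individual]:
    """New individuals biased toward historically surviving EFMs.

    A random-sized random subset of the EFMs with nonzero weight forms the
    candidate pool; candidate i is kept iff a uniform draw
    r_i ∈ [0, max w) does not exceed w_i.  Non-candidates stay 0.
    """
    nonzero = np.nonzero(weights)[0]
    if len(nonzero) == 0:
        raise ValueError("pattern-based generation requires a nonzero weight")
    max_w = float(weights.max())
    n = len(weights)
    out = []
    for _ in range(count):
        pool_size = int(rng.integers(1, len(nonzero) + 1))
        pool = rng.choice(nonzero, size=pool_size, replace=False)
        bits = [0] * n
        for i in pool:
            r_i = rng.uniform(0.0, max_w)
            if weights[int(i)] >= r_i:
                bits[int(i)] = 1
        out.append(Individual(tuple(bits)))
    return out


def run_ga(
    efms: EFMSet,
    spec: FitnessSpec,
    config: GAConfig,
    forbidden: frozenset[int] | None = None,
) -> GAResult:
    """Evolve keep/kill partitions until the generation budget or stagnation.

    Per generation: carry over the top ceil(elit·p) individuals unchanged,
    add round(new_S·p) pattern-based individuals (once the archive is
    non-empty), and fill the remainder with mutated crossover offspring of
    roulette-selected parents.  Stops after t generations or when the
    maximum fitness is unchanged for t_stop consecutive generations.

    The result lists every pattern attaining the final maximum fitness,
    each with all of its minimal-cardinality cut sets.
    """
    rng = np.random.default_rng(config.seed)
    if forbidden is None:
        forbidden = default_forbidden(efms.network)
    mask = good_mode_mask(efms, spec, config.good_mode_rule)
    rho = sum(mask)
    cache = EvaluationCache()

    population = initialize_population(config, mask, rng)
    fitnesses = [
        evaluate(ind, efms, spec, config, cache, forbidden)[0] for ind in population
    ]
    trajectory: list[tuple[float, float]] = [
        (max(fitnesses), float(np.mean(fitnesses)))
    ]
    best_so_far = trajectory[0][0]
    stagnant = 0
    generations = 1
    n_elite = math.ceil(config.elit * config.p)
    n_pattern = round(config.new_S * config.p)

    while generations < config.t and stagnant < config.t_stop:
        order = sorted(
            range(len(population)),
            key=lambda i: (-fitnesses[i], population[i].bits),
        )
        new_pop: list[Individual] = [population[i] for i in order[:n_elite]]
        if cache.archive and n_pattern:
            weights = pattern_weights(cache.archive, efms.n)
            if weights.any():
                new_pop.extend(
                    generate_pattern_based(weights, min(n_pattern, config.p - len(new_pop)), rng)
                )
        while len(new_pop) < config.p:
            p1 = select_parent(population, fitnesses, rng)
            p2 = select_parent(population, fitnesses, rng)
            c1, c2 = crossover(p1, p2, config.cross, rng)
            new_pop.append(mutate(c1, config.r_m, rho, rng))
            if len(new_pop) < config.p:
                new_pop.append(mutate(c2, config.r_m, rho, rng))
        population = new_pop[: config.p]
        fitnesses = [
            evaluate(ind, efms, spec, config, cache, forbidden)[0]
            for ind in population
        ]
        generations += 1
        gen_max = max(fitnesses)
        trajectory.append((gen_max, float(np.mean(fitnesses))))
        if gen_max <= 0:
            logger.warning(
                "generation %d has no feasible individual; continuing", generations
            )
        if gen_max > best_so_far + _FITNESS_TOL:
            best_so_far = gen_max
            stagnant = 0
        else:
            stagnant += 1

    best_patterns: list[Pattern] = []
    if best_so_far > 0:
        for pattern, (fit, cuts) in cache.registry.items():
            if abs(fit - best_so_far) <= 1e-9:
                bits = tuple(1 if i in pattern else 0 for i in range(efms.n))
                best_patterns.append(Pattern(bits=bits, fitness=fit, cutsets=cuts))
        best_patterns.sort(key=lambda p: p.bits, reverse=True)
    return GAResult(
        best_fitness=best_so_far,
        best_patterns=best_patterns,
        fitness_trajectory=trajectory,
        generations_run=generations,
        cache_hits=cache.hits,
        evaluations=cache.evaluations,
    )
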