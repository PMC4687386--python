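"""GA operators, caching, evolution loop and optimality on a small toy."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gamcs import FitnessSpec, GAConfig, good_mode_mask, run_ga
from gamcs.ga import (
    EvaluationCache,
    Individual,
    crossover,
    evaluate,
    generate_pattern_based,
    initialize_population,
    mutate,
    pattern_weights,
    select_parent,
)
from gamcs.oracle import exhaustive_best_fitness
from gamcs.synthetic import Branch, ToySpec, make_cell_factory
from gamcs import enumerate_efms


class FixedRng:
    """Deterministic stand-in feeding preset draws to the operators."""

    def __init__(self, ints=(), floats=()):
        self._ints = list(ints)
        self._floats = list(floats)

    def integers(self, low, high):
        return self._ints.pop(0)

    def random(self, n=None):
        if n is None:
            return self._floats.pop(0)
        return np.array([self._floats.pop(0) for _ in range(n)])


def toy_config(**kw):
    defaults = dict(t=50, p=30, r_m=0.4, elit=0.1, new_S=0.1, t_stop=50,
                    min_1s=0.9, w_k=0.03, seed=0, max_cut_cardinality=8)
    defaults.update(kw)
    return GAConfig(**defaults)


# ---------------------------------------------------------------------------
# good-mode mask and initialization
# ---------------------------------------------------------------------------

def test_good_mode_mask_marks_producers(factory, factory_efms, factory_spec_f1):
    mask = good_mode_mask(factory_efms, factory_spec_f1)
    assert sum(mask) == 5  # the five product-forming branches
    for bit, row in zip(mask, factory_efms.modes):
        spec = factory_spec_f1
        from gamcs import mode_metrics
        assert bit == (1 if mode_metrics(row, spec).yield_product > 0 else 0)


def test_good_mode_mask_rules(factory, factory_efms, factory_spec_f1):
    assert sum(good_mode_mask(factory_efms, factory_spec_f1, "all")) == factory_efms.n
    assert sum(good_mode_mask(factory_efms, factory_spec_f1, "efficiency>0")) == 2


def test_good_mode_mask_empty_rule_is_an_error():
    net, _ = make_cell_factory(ToySpec(branches=(
        Branch("product", 1, product_coef=2), Branch("byproduct", 1))))
    efms = enumerate_efms(net)
    spec = FitnessSpec(objective="F1", network=net, total_modes=efms.n)
    with pytest.raises(ValueError, match="marks no mode"):
        good_mode_mask(efms, spec, "efficiency>0")


def test_initial_population_confined_to_mask():
    mask = (1, 0, 1, 1, 0, 1, 1, 1, 1, 1, 1, 0)  # rho = 9
    config = toy_config(p=50, min_1s=0.9)
    rng = np.random.default_rng(7)
    pop = initialize_population(config, mask, rng)
    assert len(pop) == 50
    lo = math.ceil(0.9 * 9)
    for ind in pop:
        assert all(b == 0 for b, m in zip(ind.bits, mask) if not m)
        assert lo <= sum(ind.bits) <= 9


def test_min_1s_one_forces_the_mask():
    mask = (1, 0, 1, 1)
    pop = initialize_population(toy_config(p=5, min_1s=1.0), mask,
                                np.random.default_rng(0))
    assert all(ind.bits == mask for ind in pop)


# ---------------------------------------------------------------------------
# crossover / mutation algebra
# ---------------------------------------------------------------------------

def test_1point_crossover_formula():
    s1, s2 = Individual((1, 1, 0, 0)), Individual((0, 0, 1, 1))
    c1, c2 = crossover(s1, s2, "1point", FixedRng(ints=[2]))
    assert c1.bits == (1, 1, 1, 1)
    assert c2.bits == (0, 0, 0, 0)


def test_2point_crossover_formula():
    s1, s2 = Individual((1,) * 6), Individual((0,) * 6)
    c1, c2 = crossover(s1, s2, "2point", FixedRng(ints=[2, 4]))
    assert c1.bits == (1, 1, 0, 0, 1, 1)
    assert c2.bits == (0, 0, 1, 1, 0, 0)


def test_uniform_crossover_boundary():
    s1, s2 = Individual((1, 0, 1, 0)), Individual((0, 1, 0, 1))
    c1, c2 = crossover(s1, s2, "uniform", FixedRng(floats=[0.1] * 4))
    assert c1.bits == s1.bits and c2.bits == s2.bits


@settings(max_examples=80, deadline=None, derandomize=True)
@given(st.integers(2, 40), st.integers(0, 2 ** 31 - 1),
       st.sampled_from(["1point", "2point", "uniform"]))
def test_crossover_conserves_positionwise_multisets(n, seed, kind):
    if kind == "2point" and n < 3:
        n = 3
    rng = np.random.default_rng(seed)
    s1 = Individual(tuple(int(b) for b in rng.integers(0, 2, n)))
    s2 = Individual(tuple(int(b) for b in rng.integers(0, 2, n)))
    c1, c2 = crossover(s1, s2, kind, np.random.default_rng(seed + 1))
    for j in range(n):
        assert sorted((c1.bits[j], c2.bits[j])) == sorted((s1.bits[j], s2.bits[j]))


def test_mutation_off_is_identity():
    ind = Individual((1, 0, 1, 1, 0))
    assert mutate(ind, 0.0, rho=10_000, rng=np.random.default_rng(0)) is ind


@pytest.mark.parametrize("rho, r_m, expected", [
    (10_000, 0.00025, 3),   # 2.5 rounds half-up; within the 2-4 band
    (8_000, 0.00025, 2),
    (16_000, 0.00025, 4),
    (5, 0.3, 2),            # toy scale: 1.5 -> 2
])
def test_mutation_flip_count_is_round_rho_rm(rho, r_m, expected):
    n = 40
    ind = Individual((0,) * n)
    out = mutate(ind, r_m, rho, np.random.default_rng(1))
    assert sum(a != b for a, b in zip(ind.bits, out.bits)) == expected


def test_single_flip_example():
    out = mutate(Individual((1, 1, 0, 0)), r_m=0.25, rho=4,
                 rng=FixedRngChoice([1]))
    assert out.bits == (1, 0, 0, 0)


class FixedRngChoice:
    def __init__(self, positions):
        self._positions = positions

    def choice(self, n, size, replace):
        return np.array(self._positions[:size])


# ---------------------------------------------------------------------------
# selection and pattern-based generation
# ---------------------------------------------------------------------------

def test_roulette_frequencies_match_fitness_ratio():
    pop = [Individual((1, 0)), Individual((0, 1))]
    rng = np.random.default_rng(3)
    draws = sum(
        select_parent(pop, [3.0, 1.0], rng) is pop[0] for _ in range(10_000)
    )
    p = 0.75
    sigma = math.sqrt(p * (1 - p) * 10_000)
    assert abs(draws - p * 10_000) < 3 * sigma


def test_roulette_degenerate_cases():
    pop = [Individual((1,)), Individual((0,))]
    rng = np.random.default_rng(0)
    assert all(
        select_parent(pop, [0.0, 2.0], rng) is pop[1] for _ in range(50)
    )
    with pytest.raises(ValueError, match="empty"):
        select_parent([], [], rng)


def test_pattern_weights_examples():
    archive = [(frozenset({0, 2}), 1.0), (frozenset({2}), 0.5)]
    assert pattern_weights(archive, 4).tolist() == [1, 0, 2, 0]
    assert pattern_weights([], 4).tolist() == [0, 0, 0, 0]
    thrice = [(frozenset({1}), 1.0)] * 3
    assert pattern_weights(thrice, 2).tolist() == [0, 3]


def test_pattern_based_zero_weight_bits_never_set():
    weights = np.array([5, 0, 1])
    rng = np.random.default_rng(5)
    for ind in generate_pattern_based(weights, 200, rng):
        assert ind.bits[1] == 0


def test_pattern_based_inclusion_frequency_tracks_weight():
    weights = np.array([5, 0, 1])
    rng = np.random.default_rng(11)
    in_pool = np.zeros(3)
    included = np.zeros(3)
    for ind in generate_pattern_based(weights, 10_000, rng):
        # candidacy is not observable from outside; bit 0 (max weight) is
        # always kept when drawn, so its inclusion marks pool membership
        for i in (0, 2):
            if ind.bits[i]:
                included[i] += 1
    # P(in pool) = E[pool_size]/|nonzero| = 0.75 for two nonzero weights
    n = 10_000
    for i, p_keep in ((0, 1.0), (2, 1 / 5)):
        p = 0.75 * p_keep
        sigma = math.sqrt(p * (1 - p) * n)
        assert abs(included[i] - p * n) < 3 * sigma


def test_pattern_based_requires_nonzero_weights():
    with pytest.raises(ValueError, match="nonzero"):
        generate_pattern_based(np.zeros(3), 1, np.random.default_rng(0))


# ---------------------------------------------------------------------------
# evaluation and caching
# ---------------------------------------------------------------------------

def test_evaluate_pattern_is_subset_of_individual(factory, factory_efms,
                                                  factory_spec_f1):
    cache = EvaluationCache()
    ind = Individual((1, 1, 0, 1, 0, 0, 0, 0))
    fitness, patterns = evaluate(ind, factory_efms, factory_spec_f1,
                                 toy_config(), cache)
    assert fitness > 0 and patterns
    keep = set(ind.ones())
    for pattern, fit in patterns:
        assert pattern <= keep
        assert fit <= fitness


def test_evaluate_cache_hit_skips_solver(factory_efms, factory_spec_f1):
    cache = EvaluationCache()
    cfg = toy_config()
    ind = Individual((1, 1, 0, 0, 0, 0, 0, 0))
    first = evaluate(ind, factory_efms, factory_spec_f1, cfg, cache)
    archive_size = len(cache.archive)
    second = evaluate(ind, factory_efms, factory_spec_f1, cfg, cache)
    assert first == second
    assert cache.hits == 1
    assert cache.evaluations == 1
    assert len(cache.archive) == archive_size  # no weight inflation


def test_evaluate_infeasible_scores_zero(factory_efms, factory_spec_f1):
    cache = EvaluationCache()
    # a cardinality budget of 1 cannot hit seven target modes
    cfg = toy_config(max_cut_cardinality=1)
    fitness, patterns = evaluate(Individual((1,) + (0,) * 7), factory_efms,
                                 factory_spec_f1, cfg, cache)
    assert fitness == 0.0 and patterns == []


def test_evaluate_empty_keep_set_scores_zero(factory_efms, factory_spec_f1):
    cache = EvaluationCache()
    fitness, patterns = evaluate(Individual((0,) * 8), factory_efms,
                                 factory_spec_f1, toy_config(), cache)
    assert fitness == 0.0 and patterns == []


# ---------------------------------------------------------------------------
# the evolution loop
# ---------------------------------------------------------------------------

def test_config_validation():
    for bad in (dict(r_m=1.0), dict(elit=1.5), dict(p=1), dict(cross="3point"),
                dict(t_stop=0), dict(w_k=-0.1)):
        with pytest.raises(ValueError):
            toy_config(**bad)


def test_elitism_keeps_max_fitness_non_decreasing(factory_efms, factory_spec_f1):
    for seed in range(3):
        result = run_ga(factory_efms, factory_spec_f1,
                        toy_config(seed=seed, t=15))
        maxes = [mx for mx, _ in result.fitness_trajectory]
        assert all(a <= b + 1e-12 for a, b in zip(maxes, maxes[1:]))


def test_stagnation_stops_the_run(factory_efms, factory_spec_f1):
    result = run_ga(factory_efms, factory_spec_f1,
                    toy_config(t=50, t_stop=3, r_m=0.0, new_S=0.0, min_1s=1.0))
    # min_1s=1 and no mutation: every individual equals the mask, fitness is
    # constant from generation 1, so the run stops after 3 stagnant rounds
    assert result.generations_run == 4
    assert result.generations_run <= 50


def test_same_seed_reproduces_run(factory_efms, factory_spec_f1):
    a = run_ga(factory_efms, factory_spec_f1, toy_config(seed=9, t=10))
    b = run_ga(factory_efms, factory_spec_f1, toy_config(seed=9, t=10))
    assert a.best_fitness == b.best_fitness
    assert a.fitness_trajectory == b.fitness_trajectory
    assert [p.bits for p in a.best_patterns] == [p.bits for p in b.best_patterns]


def test_result_cut_sets_revalidate(factory, factory_efms, factory_spec_f1):
    net, _ = factory
    result = run_ga(factory_efms, factory_spec_f1, toy_config(seed=2))
    assert result.best_patterns
    supports = factory_efms.supports()
    for pattern in result.best_patterns:
        alive = pattern.survivors
        for cut in pattern.cutsets:
            # survivors of the cut are exactly the pattern
            untouched = {i for i in range(factory_efms.n)
                         if not (cut.reactions & supports[i])}
            assert alive <= untouched
            # every non-surviving mode the originating problem targeted is hit
            for i in range(factory_efms.n):
                if i not in untouched:
                    assert cut.reactions & supports[i]


def test_ga_reaches_exhaustive_optimum_quickly(factory_efms, factory_spec_f1):
    best, _ = exhaustive_best_fitness(
        factory_efms, factory_spec_f1, w_k=0.03, max_cut_cardinality=8
    )
    result = run_ga(factory_efms, factory_spec_f1, toy_config(seed=0))
    assert result.best_fitness <= best + 1e-9
    assert result.best_fitness == pytest.approx(best, abs=1e-9)
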