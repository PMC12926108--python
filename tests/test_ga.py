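"""GA operators, the evolution loop, elitism monotonicity and the
exhaustive-enumeration oracle."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaos2fs import GAParams, run_ga
from gaos2fs.ga import (
    bit_flip_mutation,
    elitist_replacement,
    fitness,
    init_population,
    roulette_select,
    single_point_crossover,
)


def sparsity_evaluator(X, y):
    """Cheap deterministic stand-in for a classifier: error falls with the
    match between selected columns and a planted pair (columns 0 and 1)."""
    if X.shape[1] == 0:
        return 0.5
    return 0.5 / (1 + X.shape[1])


class TestInitPopulation:
    def test_p0_extremes(self):
        assert init_population(5, 8, 1.0, seed=0).all()
        assert not init_population(5, 8, 0.0, seed=0).any()

    def test_mean_bit_value_near_p0(self):
        pop = init_population(200, 100, 0.5, seed=1)
        se = np.sqrt(0.25 / pop.size)
        assert abs(pop.mean() - 0.5) < 3 * se

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            init_population(1, 5, 0.5, seed=0)
        with pytest.raises(ValueError):
            init_population(5, 0, 0.5, seed=0)


class TestFitness:
    def test_all_ones_zero_error_gives_beta(self):
        X = np.ones((10, 4))
        f = fitness(np.ones(4, dtype=int), X, np.zeros(10), lambda X_, y_: 0.0,
                    alpha=1.0, beta=0.25)
        assert f == pytest.approx(0.25)

    def test_beta_zero_gives_pure_error(self):
        X = np.ones((10, 4))
        f = fitness(np.ones(4, dtype=int), X, np.zeros(10), lambda X_, y_: 0.0,
                    alpha=1.0, beta=0.0)
        assert f == pytest.approx(0.0)

    def test_single_perfect_feature_toy(self, separable_toy):
        """1 of 10 features selected, zero error, beta=0.1 -> 0.1/10."""
        from gaos2fs.fitness import ClassifierSpec, EvalProtocol, classification_error

        X, y = separable_toy
        rng = np.random.default_rng(0)
        X10 = np.column_stack([X[:, 0]] + [rng.standard_normal(len(y)) for _ in range(9)])
        bits = np.zeros(10, dtype=int)
        bits[0] = 1
        ev = lambda Xs, ys: classification_error(Xs, ys, ClassifierSpec("knn3"),
                                                 EvalProtocol(seed=1))
        f = fitness(bits, X10, y, ev, alpha=1.0, beta=0.1)
        assert f == pytest.approx(0.01)


class TestRoulette:
    def test_single_individual(self):
        rng = np.random.default_rng(0)
        assert all(roulette_select([0.3], 1e-6, rng) == 0 for _ in range(10))

    def test_two_point_probability(self):
        """fitness (0, 1), iota=0.01 -> P(first) = 100/100.9901 ~ 0.99020."""
        rng = np.random.default_rng(5)
        draws = np.array([roulette_select([0.0, 1.0], 0.01, rng) for _ in range(20000)])
        p_first = np.mean(draws == 0)
        expect = 100.0 / (100.0 + 1.0 / 1.01)
        se = np.sqrt(expect * (1 - expect) / draws.size)
        assert abs(p_first - expect) < 3.5 * se

    def test_empirical_frequencies_match_weights(self):
        f = np.array([0.1, 0.4, 0.9, 0.05])
        w = 1.0 / (f + 1e-6)
        p = w / w.sum()
        rng = np.random.default_rng(9)
        draws = np.bincount(
            [roulette_select(f, 1e-6, rng) for _ in range(10000)], minlength=4
        ) / 10000
        se = np.sqrt(p * (1 - p) / 10000)
        assert np.all(np.abs(draws - p) < 3.5 * se + 1e-9)

    def test_invalid_iota(self):
        with pytest.raises(ValueError):
            roulette_select([0.1], 0.0, np.random.default_rng(0))


class TestCrossover:
    def test_identical_parents_fixed_point(self):
        rng = np.random.default_rng(0)
        b = np.array([1, 0, 1, 1])
        c1, c2 = single_point_crossover(b, b.copy(), 1.0, rng)
        np.testing.assert_array_equal(c1, b)
        np.testing.assert_array_equal(c2, b)

    def test_forced_cut_position(self):
        """With n=3 and p_c=1, cut c=1 swaps the two-bit tails."""
        bp, bq = np.array([1, 1, 1]), np.array([0, 0, 0])
        # find an rng state that draws c == 1
        for seed in range(50):
            rng = np.random.default_rng(seed)
            state = rng.bit_generator.state
            if rng.random() < 1.0 and rng.integers(1, 3) == 1:
                rng.bit_generator.state = state
                c1, c2 = single_point_crossover(bp, bq, 1.0, rng)
                np.testing.assert_array_equal(c1, [1, 0, 0])
                np.testing.assert_array_equal(c2, [0, 1, 1])
                return
        pytest.fail("no seed produced cut position 1")

    def test_pc_zero_copies(self):
        rng = np.random.default_rng(0)
        bp, bq = np.array([1, 0, 1]), np.array([0, 1, 0])
        c1, c2 = single_point_crossover(bp, bq, 0.0, rng)
        np.testing.assert_array_equal(c1, bp)
        np.testing.assert_array_equal(c2, bq)

    def test_length_one_degenerates_to_copy(self):
        rng = np.random.default_rng(0)
        c1, c2 = single_point_crossover(np.array([1]), np.array([0]), 1.0, rng)
        assert (c1[0], c2[0]) == (1, 0)


class TestMutation:
    def test_pm_extremes(self):
        rng = np.random.default_rng(0)
        b = np.array([1, 0, 1, 0])
        np.testing.assert_array_equal(bit_flip_mutation(b, 0.0, rng), b)
        np.testing.assert_array_equal(bit_flip_mutation(b, 1.0, rng), 1 - b)

    def test_mean_flip_count(self):
        rng = np.random.default_rng(1)
        n, p_m, trials = 1000, 0.05, 1000
        b = np.zeros(n, dtype=int)
        flips = [bit_flip_mutation(b, p_m, rng).sum() for _ in range(trials)]
        se = np.sqrt(n * p_m * (1 - p_m) / trials)
        assert abs(np.mean(flips) - n * p_m) < 3 * se


class TestElitism:
    def test_worst_replaced_when_all_offspring_worse(self):
        off = np.array([[1, 0], [0, 1], [1, 1]], dtype=np.int8)
        fits = np.array([0.5, 0.6, 0.7])
        best = np.array([0, 0], dtype=np.int8)
        pop, f = elitist_replacement(off, fits, best, 0.1)
        assert f.min() == pytest.approx(0.1)
        np.testing.assert_array_equal(pop[2], best)

    def test_tie_breaks_to_lowest_index(self):
        off = np.array([[1, 0], [0, 1], [1, 1]], dtype=np.int8)
        fits = np.array([0.7, 0.2, 0.7])  # two equal-worst at 0 and 2
        best = np.array([0, 0], dtype=np.int8)
        pop, f = elitist_replacement(off, fits, best, 0.1)
        np.testing.assert_array_equal(pop[0], best)
        np.testing.assert_array_equal(pop[2], off[2])


class TestRunGa:
    def test_tmax_zero_returns_initial_best(self):
        X = np.random.default_rng(0).standard_normal((20, 6))
        y = np.array([0, 1] * 10)
        params = GAParams(population_size=10, max_iterations=0, seed=3)
        res = run_ga(X, y, params, sparsity_evaluator)
        assert len(res.convergence_curve) == 1
        assert res.best_fitness == res.convergence_curve[0]

    @pytest.mark.parametrize("seed", range(10))
    def test_curve_non_increasing(self, seed):
        X = np.random.default_rng(seed).standard_normal((20, 12))
        y = np.array([0, 1] * 10)
        params = GAParams(population_size=12, max_iterations=25, seed=seed)
        res = run_ga(X, y, params, sparsity_evaluator)
        assert np.all(np.diff(res.convergence_curve) <= 1e-15)

    def test_evaluations_bounded_per_generation(self):
        X = np.random.default_rng(0).standard_normal((20, 10))
        y = np.array([0, 1] * 10)
        N, T = 14, 30
        params = GAParams(population_size=N, max_iterations=T, seed=1)
        res = run_ga(X, y, params, sparsity_evaluator)
        assert res.n_evaluations <= N * (T + 1)

    def test_evaluation_order_invariance(self):
        """Fitness is a pure function of the bit pattern: re-evaluating the
        winner standalone reproduces its recorded fitness."""
        rng = np.random.default_rng(4)
        X = rng.standard_normal((30, 8))
        y = np.array([0, 1] * 15)
        params = GAParams(population_size=10, max_iterations=15, seed=2)
        res = run_ga(X, y, params, sparsity_evaluator)
        standalone = fitness(res.best_bits, X, y, sparsity_evaluator,
                             params.alpha, params.beta)
        assert standalone == pytest.approx(res.best_fitness, abs=0.0)

    def test_finds_global_minimum_on_small_enumerable_task(self):
        """n=8 task: GA best equals exhaustive minimum for most seeds."""
        rng = np.random.default_rng(7)
        y = np.array([0, 1] * 20)
        X = np.column_stack([
            y + 0.05 * rng.standard_normal(40),
            -y + 0.05 * rng.standard_normal(40),
        ] + [rng.standard_normal(40) for _ in range(6)])

        from gaos2fs.fitness import ClassifierSpec, EvalProtocol, classification_error

        spec, proto = ClassifierSpec("knn3"), EvalProtocol(seed=0)
        ev = lambda Xs, ys: classification_error(Xs, ys, spec, proto)
        best = min(
            fitness(np.array(bits), X, y, ev, 1.0, 0.05)
            for bits in itertools.product([0, 1], repeat=8)
        )
        hits = 0
        n_runs = 5
        for seed in range(n_runs):
            params = GAParams(population_size=30, max_iterations=40, beta=0.05, seed=seed)
            res = run_ga(X, y, params, ev)
            hits += res.best_fitness <= best + 1e-12
        assert hits >= n_runs - 1

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            GAParams(population_size=1)
        with pytest.raises(ValueError):
            GAParams(max_iterations=-1)


@settings(max_examples=30, deadline=None)
@given(
    bits=st.lists(st.integers(0, 1), min_size=2, max_size=16),
    seed=st.integers(0, 1000),
    p_m=st.floats(0.0, 1.0),
)
def test_operators_preserve_chromosome_validity(bits, seed, p_m):
    """Bits stay binary and length is preserved under mutation and crossover."""
    rng = np.random.default_rng(seed)
    b = np.array(bits, dtype=np.int8)
    mutated = bit_flip_mutation(b, p_m, rng)
    assert mutated.shape == b.shape
    assert set(np.unique(mutated)) <= {0, 1}
    other = bit_flip_mutation(b, 0.5, rng)
    c1, c2 = single_point_crossover(b, other, 0.8, rng)
    for child in (c1, c2):
        assert child.shape == b.shape
        assert set(np.unique(child)) <= {0, 1}
    # crossover conserves the multiset of bits position-wise across children
    np.testing.assert_array_equal(np.sort(np.stack([c1, c2]), axis=0),
                                  np.sort(np.stack([b, other]), axis=0))
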