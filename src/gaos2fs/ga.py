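"""Genetic-algorithm wrapper selection over binary feature-inclusion vectors.

Chromosomes are binary vectors b of length n (bit j = 1 selects feature j).
The objective being minimised is

    J(b) = alpha * eps(X restricted to b, y) + beta * ||b||_0 / n

where eps is the wrapped classifier's validation error.  One generation is:
roulette selection with weights 1/(f + iota) (lower error -> higher weight),
single-point crossover with probability p_c, independent bit-flip mutation
with probability p_m per gene, then elitism: the best chromosome seen so far
replaces the worst offspring, which makes the best-fitness curve
monotonically non-increasing.

Fitness depends only on the bit pattern, so evaluations are order-independent
and are served from a cache when a pattern recurs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GAParams",
    "GAResult",
    "init_population",
    "fitness",
    "roulette_select",
    "single_point_crossover",
    "bit_flip_mutation",
    "elitist_replacement",
    "run_ga",
]


@dataclass
class GAParams:
    """GA hyper-parameters.

    ``mutation_strength`` is accepted and recorded for interface completeness
    but plays no role: the bit-flip operator is parameterised by
    ``mutation_prob`` alone.
    """

    population_size: int = 30
    max_iterations: int = 100
    crossover_prob: float = 0.8
    mutation_prob: float = 0.05
    init_prob: float = 0.5
    selection_floor: float = 1e-6
    alpha: float = 1.0
    beta: float = 0.01
    mutation_strength: float = 0.01  # recorded, unused
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")
        for name in ("crossover_prob", "mutation_prob", "init_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.selection_floor <= 0:
            raise ValueError("selection_floor must be > 0")
        if self.alpha < 0 or self.beta < 0 or self.alpha + self.beta == 0:
            raise ValueError("need alpha >= 0, beta >= 0 and alpha + beta > 0")


@dataclass
class GAResult:
    """Outcome of one GA run."""

    best_bits: np.ndarray
    best_fitness: float
    convergence_curve: np.ndarray
    n_evaluations: int

    @property
    def selected_indices(self) -> list[int]:
        return [int(j) for j in np.flatnonzero(self.best_bits)]

    @property
    def n_selected(self) -> int:
        return int(self.best_bits.sum())


def init_population(N: int, n: int, p0: float, seed) -> np.ndarray:
    """N chromosomes of length n, each bit an independent Bernoulli(p0) draw."""
    if N < 2:
        raise ValueError("population size must be >= 2")
    if n < 1:
        raise ValueError("chromosome length must be >= 1")
    rng = np.random.default_rng(seed)
    return (rng.random((N, n)) < p0).astype(np.int8)


def fitness(bits, X, y, evaluator, alpha: float = 1.0, beta: float = 0.01) -> float:
    """alpha * classification error of the selected columns + beta * |b|_0 / n.

    ``evaluator(X_sub, y)`` must return an error in [0, 1]; it receives an
    ``M x 0`` matrix for the all-zero chromosome, for which it is expected to
    return the majority-class error (the empty set must not look perfect).
    """
    bits = np.asarray(bits)
    X = np.asarray(X)
    if bits.shape[0] != X.shape[1]:
        raise ValueError("chromosome length must equal the number of columns")
    sel = np.flatnonzero(bits)
    eps = float(evaluator(X[:, sel], y))
    return alpha * eps + beta * sel.size / bits.shape[0]


def roulette_select(fitnesses, iota: float, rng: np.random.Generator) -> int:
    """Roulette-wheel draw with weights 1/(f + iota); returns a population index.

    Implements k = min{i : P_i >= r} with r uniform on (0, 1), where P is the
    cumulative distribution of the normalised weights.
    """
    f = np.asarray(fitnesses, dtype=float)
    if f.ndim != 1 or f.size < 1:
        raise ValueError("fitnesses must be a non-empty vector")
    if iota <= 0:
        raise ValueError("iota must be > 0")
    w = 1.0 / (f + iota)
    cum = np.cumsum(w / w.sum())
    r = rng.random()
    return int(np.searchsorted(cum, r, side="left"))


def single_point_crossover(bp, bq, p_c: float, rng: np.random.Generator):
    """With probability p_c swap tails after a cut c ~ U{1, ..., n-1}.

    Otherwise (and always when n == 1, where no interior cut exists) the
    offspring are exact copies of the parents.
    """
    bp = np.asarray(bp)
    bq = np.asarray(bq)
    if bp.shape != bq.shape:
        raise ValueError("parents must have equal length")
    n = bp.shape[0]
    if n >= 2 and rng.random() < p_c:
        c = int(rng.integers(1, n))  # cut position in {1, ..., n-1}
        child_p = np.concatenate([bp[:c], bq[c:]])
        child_q = np.concatenate([bq[:c], bp[c:]])
        return child_p, child_q
    return bp.copy(), bq.copy()


def bit_flip_mutation(bits, p_m: float, rng: np.random.Generator) -> np.ndarray:
    """Flip each bit independently with probability p_m."""
    bits = np.asarray(bits)
    flip = rng.random(bits.shape) < p_m
    return np.where(flip, 1 - bits, bits).astype(bits.dtype)


def elitist_replacement(offspring: np.ndarray, off_fitness: np.ndarray,
                        best_bits: np.ndarray, best_fitness: float):
    """Replace the worst offspring (max fitness; ties -> lowest index) by the elite.

    Returns the population and fitness vector after replacement; the
    population's minimum fitness is then <= best_fitness.
    """
    off_fitness = np.asarray(off_fitness, dtype=float)
    worst = int(np.argmax(off_fitness))  # argmax returns the lowest tied index
    offspring = offspring.copy()
    off_fitness = off_fitness.copy()
    offspring[worst] = best_bits
    off_fitness[worst] = best_fitness
    return offspring, off_fitness


def run_ga(X, y, params: GAParams | None = None, evaluator=None) -> GAResult:
    """Evolve feature-inclusion chromosomes over the columns of X.

    The loop: initialise (Bernoulli p0) -> evaluate -> repeat T_max times
    {select mating pool by roulette, cross consecutive pairs, mutate,
    evaluate, update best, elitist replacement}.  The convergence curve holds
    the best fitness after each generation (index 0 = initial population) and
    is non-increasing by construction.

    Fitness values are cached per bit pattern, so the number of evaluator
    calls per generation is at most the population size.
    """
    if params is None:
        params = GAParams()
    if evaluator is None:
        raise ValueError("an evaluator callable is required")
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be an M x n matrix with n >= 1")
    n = X.shape[1]
    N = params.population_size
    rng = np.random.default_rng(params.seed)

    cache: dict[bytes, float] = {}
    n_evals = 0

    def evaluate(bits: np.ndarray) -> float:
        nonlocal n_evals
        key = bits.tobytes()
        if key not in cache:
            cache[key] = fitness(bits, X, y, evaluator, params.alpha, params.beta)
            n_evals += 1
        return cache[key]

    pop = init_population(N, n, params.init_prob, rng)
    fits = np.array([evaluate(b) for b in pop])
    best_i = int(np.argmin(fits))
    best_bits = pop[best_i].copy()
    best_fit = float(fits[best_i])
    curve = [best_fit]

    for _ in range(params.max_iterations):
        # mating pool: N roulette draws
        pool = np.array([roulette_select(fits, params.selection_floor, rng) for _ in range(N)])
        parents = pop[pool]
        # consecutive pairs crossed; odd N -> last individual passes through
        offspring = np.empty_like(parents)
        for i in range(0, N - 1, 2):
            offspring[i], offspring[i + 1] = single_point_crossover(
                parents[i], parents[i + 1], params.crossover_prob, rng
            )
        if N % 2 == 1:
            offspring[N - 1] = parents[N - 1].copy()
        for i in range(N):
            offspring[i] = bit_flip_mutation(offspring[i], params.mutation_prob, rng)
        off_fits = np.array([evaluate(b) for b in offspring])
        i_min = int(np.argmin(off_fits))
        if off_fits[i_min] < best_fit:
            best_fit = float(off_fits[i_min])
            best_bits = offspring[i_min].copy()
        pop, fits = elitist_replacement(offspring, off_fits, best_bits, best_fit)
        curve.append(best_fit)

    return GAResult(
        best_bits=best_bits,
        best_fitness=best_fit,
        convergence_curve=np.asarray(curve),
        n_evaluations=n_evals,
    )
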