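"""Genetic-algorithm wrapper feature selection.

A population of feature subsets ("chromosomes", capped at Nmax features) is
ranked by the resubstitution mean squared error of a least-squares linear
classifier on the design set.  Each generation the best 10 survive as
parents, the rest are regenerated by random crossover of the parents, and
per-gene mutation at 1% is applied to everyone except the current best
individual (elitism).  An elimination tournament runs several independent
GAs and seeds a final GA from the winners' parent pools, reducing the risk
of premature stalling.

Fitness is evaluated on design data only; the interface never receives test
rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .classifiers import RIDGE, one_hot


@dataclass(frozen=True)
class Chromosome:
    """An ordered, duplicate-free set of feature column indices plus its
    cached fitness (design-set LSLC MSE; lower is better)."""

    features: tuple[int, ...]
    fitness: float

    def __post_init__(self) -> None:
        if len(set(self.features)) != len(self.features):
            raise ValueError("duplicate feature indices in chromosome")


@dataclass
class GAConfig:
    nmax: int
    population_size: int = 100
    n_parents: int = 10
    mutation_rate: float = 0.01
    generations: int = 100
    branches: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.population_size > self.n_parents >= 1:
            raise ValueError("need population_size > n_parents >= 1")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")


class LslcFitness:
    """Design-set LSLC mean squared error for arbitrary feature subsets.

    The full-feature Gram matrix and cross-moments are computed once, so
    each subset evaluation solves only an (|S|+1)-dimensional normal
    system.  The value equals ``LeastSquaresClassifier.design_mse_`` fitted
    on the same columns."""

    def __init__(self, X: np.ndarray, y: np.ndarray, ridge: float = RIDGE):
        X = np.asarray(X, dtype=float)
        n, d = X.shape
        Xa = np.hstack([X, np.ones((n, 1))])
        classes = np.unique(y)
        Y = one_hot(np.asarray(y), classes)
        self.G = Xa.T @ Xa
        self.C = Xa.T @ Y
        self.ysq = float(np.sum(Y ** 2))
        self.n, self.d, self.m = n, d, len(classes)
        self.ridge = ridge
        self._cache: dict[frozenset, float] = {}

    def __call__(self, features: tuple[int, ...]) -> float:
        key = frozenset(features)
        if key in self._cache:
            return self._cache[key]
        cols = list(features) + [self.d]  # intercept column last
        ix = np.ix_(cols, cols)
        G = self.G[ix]
        C = self.C[cols]
        try:
            W = np.linalg.solve(G + self.ridge * np.eye(len(cols)), C)
        except np.linalg.LinAlgError:
            W = np.linalg.lstsq(G, C, rcond=None)[0]
        sse = self.ysq - 2.0 * float(np.sum(W * C)) + float(np.sum(W * (G @ W)))
        mse = max(sse, 0.0) / (self.n * self.m)
        self._cache[key] = mse
        return mse


def _random_chromosome(rng: np.random.Generator, n_features: int,
                       nmax: int) -> set[int]:
    size = int(rng.integers(1, nmax + 1))
    return set(rng.choice(n_features, size=size, replace=False).tolist())


def _mutate_one(rng: np.random.Generator, genes: set[int],
                n_features: int) -> set[int]:
    """Replace one random gene with a random feature not in the set."""
    genes = set(genes)
    if not genes or len(genes) >= n_features:
        return genes
    out = int(rng.choice(sorted(genes)))
    candidates = np.setdiff1d(np.arange(n_features), sorted(genes))
    genes.remove(out)
    genes.add(int(rng.choice(candidates)))
    return genes


def _dedup(rng: np.random.Generator, population: list[set[int]],
           n_features: int) -> None:
    """Perturb later duplicates until all chromosomes are distinct."""
    seen: set[frozenset] = set()
    for i, genes in enumerate(population):
        guard = 0
        while frozenset(genes) in seen and guard < 100:
            genes = _mutate_one(rng, genes, n_features)
            guard += 1
        population[i] = genes
        seen.add(frozenset(genes))


def _cap(rng: np.random.Generator, genes: set[int], nmax: int) -> set[int]:
    genes = set(genes)
    while len(genes) > nmax:
        genes.remove(int(rng.choice(sorted(genes))))
    return genes


def _crossover(rng: np.random.Generator, a: set[int], b: set[int]) -> set[int]:
    """Child keeps each feature of the parents' union with probability 1/2;
    an empty draw falls back to one random feature of the union."""
    union = sorted(a | b)
    keep = np.asarray(union)[rng.random(len(union)) < 0.5]
    if len(keep) == 0:
        keep = rng.choice(union, size=1)
    return set(int(i) for i in keep)


def _mutate(rng: np.random.Generator, genes: set[int], n_features: int,
            rate: float) -> set[int]:
    genes = set(genes)
    for g in sorted(genes):
        if rng.random() < rate and len(genes) < n_features:
            candidates = np.setdiff1d(np.arange(n_features), sorted(genes))
            genes.remove(g)
            genes.add(int(rng.choice(candidates)))
    return genes


def evolve(X: np.ndarray, y: np.ndarray, config: GAConfig,
           rng: np.random.Generator | None = None,
           fitness=None,
           initial_population: list[set[int]] | None = None,
           history: list[float] | None = None,
           parents_out: list[set[int]] | None = None) -> Chromosome:
    """Run one GA and return the best chromosome found.

    ``fitness`` defaults to the design-set LSLC MSE; ``history``, if given,
    receives the best fitness after each generation (non-increasing, by
    elitism).
    """
    X = np.asarray(X, dtype=float)
    n_features = X.shape[1]
    nmax = config.nmax
    if nmax > n_features:
        warnings.warn("Nmax exceeds the registry size; clamping")
        nmax = n_features
    rng = np.random.default_rng(config.seed) if rng is None else rng
    fit = LslcFitness(X, y) if fitness is None else fitness

    if initial_population is None:
        population = [_random_chromosome(rng, n_features, nmax)
                      for _ in range(config.population_size)]
    else:
        population = [set(c) for c in initial_population]
        while len(population) < config.population_size:
            population.append(_random_chromosome(rng, n_features, nmax))

    best: Chromosome | None = None
    for _ in range(config.generations):
        _dedup(rng, population, n_features)
        population = [_cap(rng, g, nmax) for g in population]
        scored = sorted(
            (Chromosome(tuple(sorted(g)), fit(tuple(sorted(g))))
             for g in population),
            key=lambda c: c.fitness)
        if best is None or scored[0].fitness < best.fitness:
            best = scored[0]
        if history is not None:
            history.append(best.fitness)
        parents = [set(c.features) for c in scored[: config.n_parents]]
        children = []
        for _ in range(config.population_size - config.n_parents):
            i, j = rng.choice(config.n_parents, size=2, replace=False)
            children.append(_crossover(rng, parents[i], parents[j]))
        population = parents + children
        # elitism: the best individual is exempt from mutation
        population = [population[0]] + [
            _mutate(rng, g, n_features, config.mutation_rate)
            for g in population[1:]]
    # final ranking of the last population
    _dedup(rng, population, n_features)
    population = [_cap(rng, g, nmax) for g in population]
    final = sorted((Chromosome(tuple(sorted(g)), fit(tuple(sorted(g))))
                    for g in population), key=lambda c: c.fitness)
    if final[0].fitness < best.fitness:
        best = final[0]
    if parents_out is not None:
        parents_out.extend(set(c.features) for c in final[: config.n_parents])
    return best


def tournament(X: np.ndarray, y: np.ndarray, config: GAConfig,
               fitness=None) -> Chromosome:
    """Elimination tournament: run ``config.branches`` independent GAs from
    distinct seeds, then a final GA whose initial population is seeded from
    the branch winners' parent sets and their random crossovers."""
    if config.branches < 2:
        warnings.warn("tournament with < 2 branches degenerates to evolve()")
        return evolve(X, y, config, fitness=fitness)
    X = np.asarray(X, dtype=float)
    fit = LslcFitness(X, y) if fitness is None else fitness
    root = np.random.default_rng(config.seed)
    pool: list[set[int]] = []
    for _ in range(config.branches):
        rng = np.random.default_rng(int(root.integers(0, 2 ** 31 - 1)))
        parents: list[set[int]] = []
        evolve(X, y, config, rng=rng, fitness=fit, parents_out=parents)
        pool.extend(parents)
    final_rng = np.random.default_rng(int(root.integers(0, 2 ** 31 - 1)))
    # the winners' parent sets enter the final population directly (so the
    # tournament never loses the best branch), the rest are their crossovers
    init = [set(g) for g in pool[: config.population_size]]
    while len(init) < config.population_size:
        i, j = final_rng.choice(len(pool), size=2, replace=len(pool) < 2)
        init.append(_crossover(final_rng, pool[i], pool[j]))
    return evolve(X, y, config, rng=final_rng, fitness=fit,
                  initial_population=init)
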