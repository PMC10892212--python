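"""Genetic-algorithm search over descriptor subsets, with an exhaustive oracle.

Chromosomes are sorted index sets of size between ``subset_size_min`` and
``subset_size_max``; the fitness of a subset is its leave-one-out Q2 on the
training rows.  Selection is seeded binary tournament, crossover samples a
child from the union of two parents, mutation swaps one member for a random
non-member, and elitism carries the best chromosomes over unchanged — so
the best fitness never decreases across generations.  Fitness values are
cached per subset, and the same seed, configuration and data always yield
the same result.  For small pools :func:`exhaustive_search` enumerates
every subset and provides the exact global ranking.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .datasets import DescriptorDataset
from .mlr import ModelFit, fit_ols
from .validation import q2_loo

EXHAUSTIVE_BUDGET = 10**6


@dataclass
class GAConfig:
    subset_size_min: int = 4
    subset_size_max: int = 6
    population_size: int = 100
    generations: int = 200
    crossover_rate: float = 0.9
    mutation_rate: float = 0.1
    elitism: int = 2
    seed: int = 0

    def validate(self, pool: int) -> None:
        if not 1 <= self.subset_size_min <= self.subset_size_max:
            raise ValueError("need 1 <= subset_size_min <= subset_size_max")
        if self.subset_size_max >= pool:
            raise ValueError(
                f"subset_size_max={self.subset_size_max} must be smaller than "
                f"the descriptor pool ({pool})"
            )
        for name in ("crossover_rate", "mutation_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.population_size < 2 or self.generations < 1:
            raise ValueError("population_size >= 2 and generations >= 1 required")
        if not 0 <= self.elitism <= self.population_size:
            raise ValueError("elitism must lie in [0, population_size]")


@dataclass
class RankedSubset:
    descriptor_names: list[str]
    fitness: float  # Q2_LOO
    fit: ModelFit


@dataclass
class GAResult:
    """Ranked distinct subsets (fitness descending) and per-generation log."""

    ranked: list[RankedSubset]
    generations_log: list[float] = field(default_factory=list)  # best fitness
    n_evaluated: int = 0

    @property
    def best(self) -> RankedSubset:
        return self.ranked[0]


class _FitnessCache:
    def __init__(self, ds: DescriptorDataset, y: np.ndarray):
        self.ds = ds
        self.y = np.asarray(y, dtype=float)
        self.cache: dict[tuple[int, ...], tuple[float, float]] = {}

    def __call__(self, subset: tuple[int, ...]) -> float:
        if subset not in self.cache:
            sub = self.ds.X[:, list(subset)]
            names = [self.ds.descriptor_names[j] for j in subset]
            tmp = DescriptorDataset(
                compound_ids=list(self.ds.compound_ids),
                descriptor_names=names,
                X=sub,
            )
            try:
                q2, _ = q2_loo(tmp, self.y)
                r2 = fit_ols(tmp, self.y).stats.r2
            except np.linalg.LinAlgError:
                q2, r2 = -np.inf, -np.inf
            self.cache[subset] = (q2, r2)
        return self.cache[subset][0]

    def r2(self, subset: tuple[int, ...]) -> float:
        self(subset)
        return self.cache[subset][1]


def _rank(cache: _FitnessCache, subsets, top: int) -> list[RankedSubset]:
    # ties: higher R2 first, then lexicographic subset order
    ordered = sorted(subsets, key=lambda s: (-cache(s), -cache.r2(s), s))
    out = []
    for s in ordered[:top]:
        names = [cache.ds.descriptor_names[j] for j in s]
        sub = DescriptorDataset(
            compound_ids=list(cache.ds.compound_ids),
            descriptor_names=names,
            X=cache.ds.X[:, list(s)],
        )
        out.append(RankedSubset(names, cache(s), fit_ols(sub, cache.y)))
    return out


def exhaustive_search(
    ds: DescriptorDataset, y: np.ndarray | None = None, size: int = 5, top: int = 10
) -> GAResult:
    """Evaluate every descriptor subset of the given size; exact ranking.

    Refuses combinatorial budgets above 10^6 subsets.
    """
    if y is None:
        y = ds.y
    pool = ds.n_descriptors
    count = math.comb(pool, size)
    if count > EXHAUSTIVE_BUDGET:
        raise ValueError(
            f"C({pool},{size}) = {count} exceeds the exhaustive budget; use ga_search"
        )
    cache = _FitnessCache(ds, y)
    subsets = list(itertools.combinations(range(pool), size))
    for s in subsets:
        cache(s)
    ranked = _rank(cache, subsets, top)
    return GAResult(ranked=ranked, generations_log=[], n_evaluated=len(subsets))


def _random_subset(rng, pool: int, cfg: GAConfig) -> tuple[int, ...]:
    size = int(rng.integers(cfg.subset_size_min, cfg.subset_size_max + 1))
    return tuple(sorted(rng.choice(pool, size=size, replace=False).tolist()))


def _mutate(rng, subset: tuple[int, ...], pool: int) -> tuple[int, ...]:
    subset = list(subset)
    outside = [j for j in range(pool) if j not in subset]
    if not outside:
        return tuple(subset)
    i = int(rng.integers(len(subset)))
    subset[i] = outside[int(rng.integers(len(outside)))]
    return tuple(sorted(subset))


def _crossover(rng, a: tuple[int, ...], b: tuple[int, ...], cfg: GAConfig) -> tuple[int, ...]:
    union = sorted(set(a) | set(b))
    size = len(a) if rng.random() < 0.5 else len(b)
    size = min(max(size, cfg.subset_size_min), min(cfg.subset_size_max, len(union)))
    child = rng.choice(len(union), size=size, replace=False)
    return tuple(sorted(union[i] for i in child))


def ga_search(
    ds: DescriptorDataset, y: np.ndarray | None = None, config: GAConfig | None = None
) -> GAResult:
    """Evolve descriptor subsets maximizing Q2_LOO on the training rows.

    Returns the top distinct subsets ever evaluated (at least 10 where the
    pool allows), the best-fitness trajectory per generation, and the number
    of unique subsets evaluated.
    """
    if y is None:
        y = ds.y
    cfg = config or GAConfig()
    pool = ds.n_descriptors
    if pool < cfg.subset_size_min:
        raise ValueError(
            f"descriptor pool ({pool}) smaller than subset_size_min "
            f"({cfg.subset_size_min})"
        )
    if pool == cfg.subset_size_min == cfg.subset_size_max:
        # only one candidate subset exists
        cache = _FitnessCache(ds, y)
        s = tuple(range(pool))
        cache(s)
        return GAResult(ranked=_rank(cache, [s], 1), generations_log=[cache(s)], n_evaluated=1)
    cfg.validate(pool)
    rng = np.random.default_rng(cfg.seed)
    cache = _FitnessCache(ds, y)

    population = []
    seen = set()
    while len(population) < cfg.population_size:
        s = _random_subset(rng, pool, cfg)
        if s in seen:
            s = _mutate(rng, s, pool)
        seen.add(s)
        population.append(s)

    log = []
    for _ in range(cfg.generations):
        fits = np.array([cache(s) for s in population])
        order = np.argsort(-fits, kind="stable")
        elite = [population[i] for i in order[: cfg.elitism]]
        nxt = list(elite)
        while len(nxt) < cfg.population_size:
            # binary tournament selection
            def pick():
                i, j = rng.integers(len(population)), rng.integers(len(population))
                return population[i] if fits[i] >= fits[j] else population[j]

            a, b = pick(), pick()
            child = _crossover(rng, a, b, cfg) if rng.random() < cfg.crossover_rate else a
            if rng.random() < cfg.mutation_rate:
                child = _mutate(rng, child, pool)
            if child in set(nxt):  # duplicate repair by resampling
                child = _mutate(rng, child, pool)
            nxt.append(child)
        population = nxt
        log.append(max(cache(s) for s in population))

    ranked = _rank(cache, list(cache.cache.keys()), max(10, cfg.elitism))
    return GAResult(ranked=ranked, generations_log=log, n_evaluated=len(cache.cache))
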