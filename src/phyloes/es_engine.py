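"""The (mu+lambda) evolution-strategy search for balanced minimum evolution.

Each individual is a topology held both as a step-wise code and as a
decoded tree; its fitness is the balanced tree length.  A generation
creates one offspring per current member by *tree generation* — component
``j`` of the child code is sampled uniformly from the multiset of component
``j`` across all parents — refines every offspring with BNNI + BSPR,
truncation-selects the best ``mu`` of parents plus offspring, and applies
the anti-stagnation individual-replacement rule.  The population size
follows a halving schedule (64 for the first 5 generations, 32 up to 25,
16 afterwards by default).  The loop stops on convergence (all individuals
identical), on the generation cap, or when the best-to-worst length spread
falls below ``tol``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from . import bme
from .encoding import TreeCode, all_codes, decode, encode, random_code
from .errors import ConfigError
from .local_search import SearchCounters, rearrange_tree
from .tree_core import Phylogeny

#: default halving schedule: (size, first generation at which it no longer
#: applies); the last entry is open-ended.
DEFAULT_SCHEDULE: Tuple[Tuple[int, Optional[int]], ...] = (
    (64, 5), (32, 25), (16, None))


@dataclass(frozen=True)
class ESConfig:
    """Tunable parameters of the search.

    ``schedule`` is a sequence of ``(size, until)`` pairs: the population
    has ``size`` members for generations ``g < until``; the final pair must
    have ``until=None`` (open-ended).  ``mu`` and ``lambda`` both equal the
    scheduled size of the current generation.
    """

    maxiter: int = 1000
    tol: float = 1e-12
    schedule: Tuple[Tuple[int, Optional[int]], ...] = DEFAULT_SCHEDULE
    seed: int = 0

    def __post_init__(self):
        if self.maxiter < 1:
            raise ConfigError(f"maxiter must be >= 1, got {self.maxiter}")
        if self.tol < 0:
            raise ConfigError(f"tol must be >= 0, got {self.tol}")
        sched = tuple((int(s), None if u is None else int(u))
                      for s, u in self.schedule)
        if not sched or sched[-1][1] is not None:
            raise ConfigError("schedule must end with an open-ended entry")
        sizes = [s for s, _ in sched]
        if any(s <= 0 for s in sizes):
            raise ConfigError("population sizes must be positive")
        if any(a < b for a, b in zip(sizes, sizes[1:])):
            raise ConfigError("population sizes must be non-increasing")
        bounds = [u for _, u in sched[:-1]]
        if any(b <= 0 for b in bounds) or any(
                a >= b for a, b in zip(bounds, bounds[1:])):
            raise ConfigError("schedule thresholds must be increasing")
        object.__setattr__(self, "schedule", sched)

    def size_at(self, g: int) -> int:
        """Scheduled population size at generation ``g`` (0-based)."""
        for size, until in self.schedule:
            if until is None or g < until:
                return size
        raise AssertionError("open-ended schedule entry missing")


@dataclass(frozen=True)
class Individual:
    """A candidate solution: code, decoded tree, and balanced length."""

    code: TreeCode
    tree: Phylogeny
    length: float


@dataclass
class GenerationRecord:
    g: int
    pop_size: int
    best_length: float
    worst_length: float
    offspring: int
    trees_total: int
    nni_total: int
    spr_total: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class RunStats:
    """Per-generation log plus the final outcome of one run."""

    algorithm: str
    n_taxa: int
    seed: int
    generations: List[GenerationRecord] = field(default_factory=list)
    stop_reason: str = ""
    best_length: float = float("inf")
    best_code: Optional[TreeCode] = None
    trees_generated: int = 0
    nni_iterations: int = 0
    spr_iterations: int = 0

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "n_taxa": self.n_taxa,
            "seed": self.seed,
            "generations": [g.to_dict() for g in self.generations],
            "final": {
                "stop_reason": self.stop_reason,
                "best_length": self.best_length,
                "best_code": list(self.best_code.h) if self.best_code else [],
                "trees_generated": self.trees_generated,
                "nni_iterations": self.nni_iterations,
                "spr_iterations": self.spr_iterations,
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


# ---------------------------------------------------------------------------
# ES operators
# ---------------------------------------------------------------------------


def generate_tree(population: Sequence[Individual],
                  rng: np.random.Generator) -> TreeCode:
    """Recombination: component ``j`` of the child is drawn uniformly from
    the multiset of component-``j`` values across all parents (components
    independent).  Always yields a valid code since every parent component
    is in range."""
    if not population:
        raise ConfigError("cannot generate a tree from an empty population")
    codes = [ind.code for ind in population]
    n = codes[0].n
    k = len(codes)
    L = len(codes[0].h)
    picks = rng.integers(0, k, size=L)
    return TreeCode(n, tuple(codes[int(p)].h[j] for j, p in enumerate(picks)))


def truncation_select(pool: Sequence[Individual], mu: int) -> List[Individual]:
    """The ``mu`` smallest-length individuals; ties broken by stable order
    (parents before offspring, then insertion order)."""
    if mu <= 0:
        raise ConfigError(f"mu must be positive, got {mu}")
    if len(pool) < mu:
        raise ConfigError(f"pool of {len(pool)} cannot fill mu={mu}")
    return sorted(pool, key=lambda ind: ind.length)[:mu]


def individual_replacement(population: Sequence[Individual]
                           ) -> List[Individual]:
    """Anti-stagnation rule: if the worst length occurs at least twice and
    some individual is strictly better, replace one duplicate of the worst
    (the last, in population order) with a copy of the best individual whose
    length is strictly below the worst; otherwise return the population
    unchanged."""
    pop = list(population)
    if not pop:
        return pop
    worst = max(ind.length for ind in pop)
    worst_idx = [i for i, ind in enumerate(pop) if ind.length == worst]
    better = [ind for ind in pop if ind.length < worst]
    if len(worst_idx) < 2 or not better:
        return pop
    second_worst = max(better, key=lambda ind: ind.length)
    pop[worst_idx[-1]] = Individual(second_worst.code, second_worst.tree,
                                    second_worst.length)
    return pop


# ---------------------------------------------------------------------------
# main loops
# ---------------------------------------------------------------------------


def _make_individual(code: TreeCode, d: np.ndarray,
                     counters: SearchCounters) -> Individual:
    tree = rearrange_tree(decode(code), d, counters)
    return Individual(encode(tree), tree, bme.bme_length(d, tree))


def _all_identical(population: Sequence[Individual]) -> bool:
    first = population[0].code
    return all(ind.code == first for ind in population[1:])


def _exhaustive_best(d: np.ndarray, n: int) -> Individual:
    best = None
    for code in all_codes(n):
        tree = decode(code)
        length = bme.bme_length(d, tree)
        if best is None or length < best.length:
            best = Individual(code, tree, length)
    return best


def run_phyloes(d, config: Optional[ESConfig] = None
                ) -> Tuple[Phylogeny, RunStats]:
    """Run the full evolution-strategy search on a distance matrix.

    Returns the best tree ever observed and the complete run statistics.
    Identical (matrix, config) pairs give identical results.  For ``n <= 4``
    the tiny code space (1 or 3 topologies) is enumerated directly.
    """
    config = config or ESConfig()
    dm = bme.as_array(d)
    n = dm.shape[0]
    stats = RunStats(algorithm="phyloes", n_taxa=n, seed=config.seed)
    if n <= 4:
        best = _exhaustive_best(dm, n)
        count = 1 if n == 3 else 3
        stats.generations.append(GenerationRecord(
            0, count, best.length, best.length, 0, count, 0, 0))
        stats.stop_reason = "convergence"
        stats.best_length = best.length
        stats.best_code = best.code
        stats.trees_generated = count
        return best.tree, stats

    ss = np.random.SeedSequence(config.seed)
    rng_init, rng_recomb = (np.random.default_rng(s) for s in ss.spawn(2))
    counters = SearchCounters()

    lam = config.size_at(0)
    population = [_make_individual(random_code(n, rng_init), dm, counters)
                  for _ in range(lam)]
    population = sorted(population, key=lambda ind: ind.length)
    trees = lam

    def record(g: int, offspring: int) -> None:
        stats.generations.append(GenerationRecord(
            g, len(population), population[0].length, population[-1].length,
            offspring, trees, counters.nni_iterations,
            counters.spr_iterations))

    best_ever = population[0]
    record(0, 0)
    g = 0
    while (not _all_identical(population) and g < config.maxiter
           and population[-1].length - population[0].length > config.tol):
        offspring = [
            _make_individual(generate_tree(population, rng_recomb), dm,
                             counters)
            for _ in range(len(population))
        ]
        trees += len(offspring)
        pool = list(population) + offspring
        mu = config.size_at(g + 1)
        population = truncation_select(pool, mu)
        population = sorted(individual_replacement(population),
                            key=lambda ind: ind.length)
        if population[0].length < best_ever.length:
            best_ever = population[0]
        g += 1
        record(g, len(offspring))

    if _all_identical(population):
        stats.stop_reason = "convergence"
    elif population[-1].length - population[0].length <= config.tol:
        stats.stop_reason = "tolerance"
    else:
        stats.stop_reason = "maxiter"
    stats.best_length = best_ever.length
    stats.best_code = best_ever.code
    stats.trees_generated = trees
    stats.nni_iterations = counters.nni_iterations
    stats.spr_iterations = counters.spr_iterations
    return best_ever.tree, stats


def run_ri(d, budget: int, seed: int = 0) -> Tuple[Phylogeny, RunStats]:
    """Random-initialization baseline: ``budget`` independent local searches
    from uniform random topologies; used with the tree budget of a matched
    run of the evolution strategy."""
    if budget < 1:
        raise ConfigError(f"budget must be >= 1, got {budget}")
    dm = bme.as_array(d)
    n = dm.shape[0]
    stats = RunStats(algorithm="ri", n_taxa=n, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    counters = SearchCounters()
    best: Optional[Individual] = None
    for _ in range(budget):
        ind = _make_individual(random_code(n, rng), dm, counters)
        if best is None or ind.length < best.length:
            best = ind
    stats.stop_reason = "budget"
    stats.best_length = best.length
    stats.best_code = best.code
    stats.trees_generated = budget
    stats.nni_iterations = counters.nni_iterations
    stats.spr_iterations = counters.spr_iterations
    stats.generations.append(GenerationRecord(
        0, budget, best.length, best.length, 0, budget,
        counters.nni_iterations, counters.spr_iterations))
    return best.tree, stats


def matched_budget_comparison(d, seeds: Sequence[int],
                              config: Optional[ESConfig] = None) -> dict:
    """Desk-scale ES-vs-RI harness: for each seed, run the evolution
    strategy, count its generated trees, and give the random-initialization
    baseline the same budget.  Returns per-seed lengths, budgets, and the
    RF distance between the two best trees, plus summary means."""
    from .tree_core import rf_distance

    config = config or ESConfig()
    rows = []
    for seed in seeds:
        cfg = ESConfig(maxiter=config.maxiter, tol=config.tol,
                       schedule=config.schedule, seed=int(seed))
        es_tree, es_stats = run_phyloes(d, cfg)
        ri_tree, ri_stats = run_ri(d, es_stats.trees_generated, int(seed))
        rows.append({
            "seed": int(seed),
            "trees": es_stats.trees_generated,
            "es_length": es_stats.best_length,
            "ri_length": ri_stats.best_length,
            "rf_es_vs_ri": rf_distance(es_tree, ri_tree),
            "es_nni": es_stats.nni_iterations,
            "es_spr": es_stats.spr_iterations,
            "ri_nni": ri_stats.nni_iterations,
            "ri_spr": ri_stats.spr_iterations,
        })
    return {
        "runs": rows,
        "es_mean_length": float(np.mean([r["es_length"] for r in rows])),
        "ri_mean_length": float(np.mean([r["ri_length"] for r in rows])),
        "mean_rf": float(np.mean([r["rf_es_vs_ri"] for r in rows])),
    }
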