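"""Truncation-selection evolutionary simulation with lineage tracing.

Two protocols act on a constant population of 1000 genotypes founded by
uniform random networks:

* Evo50 -- each generation the top 500 by fitness are preserved and each
  preserved genotype parents one mutated copy (one rewiring move); run for
  150 generations.
* Evo90 -- the top 900 are preserved, 100 parents are drawn uniformly (with
  replacement) from the preserved set and each parents one mutated copy; run
  for 200 generations.

After the final generation the ancestor chain of the fittest individual is
traced back to its founder, giving one lineage per run; comparative
statistics against the multicanonical reference ensemble are computed over
many independent lineages.  A fitness cap (used for the neutral steady-state
protocol) truncates every fitness at the cap, making selection among capped
individuals neutral.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from grnevo.model import (
    DEFAULT_MAX_ITER,
    DEFAULT_TOL,
    ModelParams,
    RegulatoryNetwork,
    fitness as network_fitness,
    random_network,
    rewire_move,
)

__all__ = [
    "EvolutionConfig",
    "Individual",
    "LineageRecord",
    "CappedRunResult",
    "evolve_generation",
    "run_evolution",
    "run_lineage_ensemble",
    "collect_lineage_band",
    "run_capped_evolution",
]

_MODE_KEEP = {"evo50": 500, "evo90": 900}


@dataclass(frozen=True)
class EvolutionConfig:
    """Protocol parameters for one evolutionary run.

    ``generations`` defaults to the protocol value for the mode (150 for
    Evo50, 200 for Evo90).  ``fitness_cap``, when set, truncates every
    computed fitness at the cap.
    """

    params: ModelParams = field(default_factory=ModelParams)
    population_size: int = 1000
    mode: str = "evo50"
    generations: int = -1
    fitness_cap: Optional[float] = None
    snapshot_every: Optional[int] = None
    tol: float = DEFAULT_TOL
    max_iter: int = DEFAULT_MAX_ITER

    def __post_init__(self) -> None:
        mode = self.mode.lower()
        if mode not in _MODE_KEEP:
            raise ValueError("mode must be 'evo50' or 'evo90'")
        object.__setattr__(self, "mode", mode)
        if self.population_size % 10 != 0 or self.population_size < 10:
            raise ValueError("population_size must be a positive multiple of 10")
        if self.generations == -1:
            object.__setattr__(
                self, "generations", 150 if mode == "evo50" else 200
            )
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if self.fitness_cap is not None and not (0 < self.fitness_cap <= 1):
            raise ValueError("fitness_cap must be in (0, 1]")

    @property
    def n_keep(self) -> int:
        """Preserved individuals per generation (500 or 900 per 1000)."""
        return self.population_size * _MODE_KEEP[self.mode] // 1000


@dataclass
class Individual:
    """A population member: genotype, cached (possibly capped) fitness, and
    the index of its parent in the previous generation (-1 for founders)."""

    network: RegulatoryNetwork
    fitness: float
    parent_index: int = -1


@dataclass
class LineageRecord:
    """The ancestor chain of the final top individual, founder first.

    ``entries`` has one (generation, network, fitness) triple per generation
    including generation 0; consecutive genotypes differ by at most one
    rewiring move (exactly zero moves across generations where the ancestor
    was preserved).  ``mean_fitness``/``max_fitness`` summarize the whole
    population per generation.
    """

    entries: list[tuple[int, RegulatoryNetwork, float]]
    mean_fitness: np.ndarray
    max_fitness: np.ndarray

    def fitnesses(self) -> np.ndarray:
        return np.array([f for _, _, f in self.entries])

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class CappedRunResult:
    """Outcome of a fitness-capped (neutral steady-state) Evo90 run."""

    snapshots: list[tuple[int, list[Individual]]]
    first_all_capped_generation: Optional[int]
    final_population: list[Individual]


def _eval_fitness(
    net: RegulatoryNetwork, config: EvolutionConfig
) -> float:
    f = network_fitness(net, tol=config.tol, max_iter=config.max_iter)
    if config.fitness_cap is not None and f > config.fitness_cap:
        return config.fitness_cap
    return f


def _rank(population: list[Individual]) -> np.ndarray:
    """Indices sorted by descending fitness; ties broken by position
    (stable), so ranking is deterministic."""
    f = np.array([ind.fitness for ind in population])
    return np.argsort(-f, kind="stable")


def evolve_generation(
    population: list[Individual],
    config: EvolutionConfig,
    rng: np.random.Generator,
    mutate: Callable[[RegulatoryNetwork, np.random.Generator], RegulatoryNetwork]
    | None = rewire_move,
) -> list[Individual]:
    """One generation of truncation selection; returns the new population.

    Preserved individuals keep their genotype and cached fitness; offspring
    get one application of ``mutate`` (``None`` disables mutation, for
    testing) and a fresh fitness evaluation.  ``parent_index`` points into
    the *input* population: preserved individuals point at themselves.
    """
    if len(population) != config.population_size:
        raise ValueError(
            f"population size {len(population)} != {config.population_size}"
        )
    order = _rank(population)
    keep = order[: config.n_keep]
    nxt = [
        Individual(population[i].network, population[i].fitness, int(i))
        for i in keep
    ]
    n_children = config.population_size - config.n_keep
    if config.mode == "evo50":
        parent_ids = keep
    else:  # evo90: uniform with replacement from the preserved set
        parent_ids = keep[rng.integers(0, config.n_keep, size=n_children)]
    for i in parent_ids:
        net = population[i].network
        if mutate is not None:
            child_net = mutate(net, rng)
            child_fit = _eval_fitness(child_net, config)
        else:
            child_net, child_fit = net, population[i].fitness
        nxt.append(Individual(child_net, child_fit, int(i)))
    return nxt


def _founding_population(
    config: EvolutionConfig, rng: np.random.Generator
) -> list[Individual]:
    pop = []
    for _ in range(config.population_size):
        net = random_network(config.params, rng)
        pop.append(Individual(net, _eval_fitness(net, config)))
    return pop


def run_evolution(
    config: EvolutionConfig, rng: np.random.Generator
) -> LineageRecord:
    """Run one replicate and trace the lineage of the final top individual."""
    pop = _founding_population(config, rng)
    history = [pop]
    for _ in range(config.generations):
        pop = evolve_generation(pop, config, rng)
        history.append(pop)

    fit = np.array([ind.fitness for ind in pop])
    idx = int(np.argmax(fit))
    chain: list[tuple[int, RegulatoryNetwork, float]] = []
    for g in range(config.generations, -1, -1):
        ind = history[g][idx]
        chain.append((g, ind.network, ind.fitness))
        idx = ind.parent_index
    chain.reverse()
    means = np.array([np.mean([i.fitness for i in p]) for p in history])
    maxes = np.array([max(i.fitness for i in p) for p in history])
    return LineageRecord(entries=chain, mean_fitness=means, max_fitness=maxes)


def run_lineage_ensemble(
    config: EvolutionConfig,
    n_replicates: int,
    seed_sequence: np.random.SeedSequence,
) -> list[LineageRecord]:
    """Independent replicates of :func:`run_evolution`, one child seed each."""
    return [
        run_evolution(config, np.random.default_rng(child))
        for child in seed_sequence.spawn(n_replicates)
    ]


def collect_lineage_band(
    lineages: list[LineageRecord], f_lo: float, f_hi: float
) -> list[tuple[RegulatoryNetwork, float]]:
    """All lineage genotypes with fitness in [f_lo, f_hi], across lineages."""
    return [
        (net, f)
        for lineage in lineages
        for _, net, f in lineage.entries
        if f_lo <= f <= f_hi
    ]


def run_capped_evolution(
    config: EvolutionConfig, rng: np.random.Generator
) -> CappedRunResult:
    """Fitness-capped long run collecting snapshots of capped individuals.

    Every ``snapshot_every`` generations all individuals sitting exactly at
    the cap are recorded.  Also reports the first generation at which every
    preserved individual reaches the cap, after which evolution is neutral
    among the preserved set.
    """
    if config.fitness_cap is None:
        raise ValueError("run_capped_evolution requires a fitness cap")
    every = config.snapshot_every or 2000
    cap = config.fitness_cap
    pop = _founding_population(config, rng)
    snapshots: list[tuple[int, list[Individual]]] = []
    first_capped: Optional[int] = None
    for g in range(1, config.generations + 1):
        pop = evolve_generation(pop, config, rng)
        if first_capped is None:
            kept = _rank(pop)[: config.n_keep]
            if all(pop[i].fitness >= cap for i in kept):
                first_capped = g
        if g % every == 0:
            snapshots.append(
                (g, [ind for ind in pop if ind.fitness >= cap])
            )
    return CappedRunResult(
        snapshots=snapshots,
        first_all_capped_generation=first_capped,
        final_population=pop,
    )
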