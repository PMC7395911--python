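"""Policy optimization: replicated parameter sweeps and a genetic algorithm.

Both searches minimize the mean Quality Score over replicated simulation
runs.  The search space is the five-dimensional policy vector: the
priority-criteria percentage (0..100 in steps of 5) and the four per-ESI
waiting thresholds, each on a 60-second grid within its clinical bounds
(ESI 2: 900-3,600 s, ESI 3: 1,800-5,400 s, ESI 4: 3,600-9,600 s,
ESI 5: 7,200-14,400 s).

Fitness evaluations use common random numbers: replicate *r* of every
candidate shares the same simulation seed, so candidates are compared on
identical arrival streams and the fitness surface is deterministic given the
sweep/GA seed.  The GA is integer-coded on the gene grids with tournament
selection, single-point crossover, per-gene uniform-resample mutation, and
elitism (so the best fitness never regresses across generations).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from itertools import product
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import engine, kpi
from .policy import DEFAULT_THRESHOLD_BOUNDS, PolicyParams
from .population import ArrivalConfig, ConfigError

__all__ = [
    "GeneSpec",
    "Chromosome",
    "GAConfig",
    "SweepSpec",
    "BaseScenario",
    "default_gene_specs",
    "sweep",
    "evaluate_fitness",
    "ga_run",
    "brute_force_grid",
]


@dataclass(frozen=True)
class GeneSpec:
    """One integer gene on a bounded regular grid."""

    name: str
    lower: int
    upper: int
    step: int

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ConfigError(f"gene {self.name!r}: step must be > 0")
        if self.lower > self.upper:
            raise ConfigError(f"gene {self.name!r}: lower must be <= upper")

    def grid(self) -> list[int]:
        return list(range(self.lower, self.upper + 1, self.step))

    def contains(self, value: int) -> bool:
        return (
            self.lower <= value <= self.upper
            and (value - self.lower) % self.step == 0
        )

    def sample(self, rng: random.Random) -> int:
        n = (self.upper - self.lower) // self.step
        return self.lower + self.step * rng.randint(0, n)


def default_gene_specs(levels: Sequence[int] = (2, 3, 4, 5)) -> tuple[GeneSpec, ...]:
    """The five-dimensional policy space: priority-criteria + per-ESI thresholds."""
    specs = [GeneSpec("priority_criteria", 0, 100, 5)]
    for level in levels:
        lo, hi = DEFAULT_THRESHOLD_BOUNDS[level]
        specs.append(GeneSpec(f"threshold_esi{level}", lo, hi, 60))
    return tuple(specs)


@dataclass(frozen=True)
class Chromosome:
    """A candidate policy: one integer per gene, each on its grid."""

    genes: tuple[int, ...]
    specs: tuple[GeneSpec, ...]

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.specs):
            raise ConfigError("gene count does not match the gene specs")
        for g, s in zip(self.genes, self.specs):
            if not s.contains(g):
                raise ConfigError(
                    f"gene {s.name!r}={g} off its grid [{s.lower}, {s.upper}] step {s.step}"
                )

    def as_dict(self) -> dict[str, int]:
        return {s.name: g for g, s in zip(self.genes, self.specs)}

    def to_policy(self, base: PolicyParams) -> PolicyParams:
        """Apply the genes onto a base policy."""
        values = self.as_dict()
        thresholds = dict(base.thresholds)
        pc = base.priority_criteria
        for name, v in values.items():
            if name == "priority_criteria":
                pc = int(v)
            elif name.startswith("threshold_esi"):
                thresholds[int(name.removeprefix("threshold_esi"))] = float(v)
            else:
                raise ConfigError(f"gene {name!r} does not map to a policy parameter")
        return replace(base, priority_criteria=pc, thresholds=thresholds)


@dataclass
class GAConfig:
    """Genetic-algorithm hyperparameters."""

    population_size: int = 50
    crossover_rate: float = 0.7
    mutation_rate: float = 0.3
    generations: int = 30
    elitism: int = 1
    tournament_size: int = 2
    replicates: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ConfigError("population_size must be >= 2")
        if not 0 <= self.crossover_rate <= 1:
            raise ConfigError("crossover_rate must lie in [0, 1]")
        if not 0 <= self.mutation_rate <= 1:
            raise ConfigError("mutation_rate must lie in [0, 1]")
        if self.generations < 1:
            raise ConfigError("generations must be >= 1")
        if self.elitism < 0 or self.elitism >= self.population_size:
            raise ConfigError("elitism must lie in [0, population_size)")
        if self.tournament_size < 1:
            raise ConfigError("tournament_size must be >= 1")


@dataclass
class BaseScenario:
    """The fixed simulation scenario a sweep or GA evaluates policies on."""

    graph: object
    arrival_cfg: ArrivalConfig
    staffing: dict[str, int]
    policy: PolicyParams
    sim_cfg: engine.SimConfig
    qs_mode: str = "per_level"


@dataclass
class SweepSpec:
    """A replicated full-factorial sweep over one or more gene grids."""

    grids: tuple[GeneSpec, ...]
    base: BaseScenario
    replicates: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.grids:
            raise ConfigError("sweep needs at least one gene grid")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")


def _replicate_seed(seed: int, r: int) -> int:
    """Common-random-numbers seed for replicate r (shared across candidates)."""
    return int(np.random.SeedSequence([seed, r]).generate_state(1)[0] % (2**31))


def _run_qs(base: BaseScenario, policy: PolicyParams, run_seed: int) -> float:
    sim_cfg = replace(base.sim_cfg, seed=run_seed)
    result = engine.run(base.graph, base.arrival_cfg, base.staffing, policy, sim_cfg)
    return kpi.quality_score(result, policy.thresholds, mode=base.qs_mode)


def make_simulation_fitness(
    base: BaseScenario, specs: tuple[GeneSpec, ...], replicates: int, seed: int
) -> Callable[[tuple[int, ...]], float]:
    """Fitness callable mapping gene tuples to mean QS over replicates."""

    def fitness(genes: tuple[int, ...]) -> float:
        chrom = Chromosome(tuple(int(g) for g in genes), specs)
        policy = chrom.to_policy(base.policy)
        scores = [
            _run_qs(base, policy, _replicate_seed(seed, r)) for r in range(replicates)
        ]
        return float(np.mean(scores))

    return fitness


def evaluate_fitness(
    chrom: Chromosome, base: BaseScenario, replicates: int, seed: int
) -> float:
    """Mean quality score of a chromosome over common-random-number replicates."""
    fitness = make_simulation_fitness(base, chrom.specs, replicates, seed)
    return fitness(chrom.genes)


def sweep(spec: SweepSpec) -> pd.DataFrame:
    """Run every grid cell ``replicates`` times; return the long-form table.

    Columns: one per swept gene, then ``replicate``, ``seed``, ``qs`` and the
    per-cell ``mean_qs``.  Replicate *r* shares its seed across cells (common
    random numbers), so re-running with the same spec reproduces the table.
    """
    names = [g.name for g in spec.grids]
    rows = []
    for cell in product(*(g.grid() for g in spec.grids)):
        chrom = Chromosome(tuple(cell), spec.grids)
        policy = chrom.to_policy(spec.base.policy)
        for r in range(spec.replicates):
            run_seed = _replicate_seed(spec.seed, r)
            qs = _run_qs(spec.base, policy, run_seed)
            rows.append((*cell, r, run_seed, qs))
    df = pd.DataFrame(rows, columns=[*names, "replicate", "seed", "qs"])
    df["mean_qs"] = df.groupby(names)["qs"].transform("mean")
    return df.sort_values([*names, "replicate"]).reset_index(drop=True)


def brute_force_grid(
    grid: Sequence[int] | GeneSpec, fitness: Callable[[int], float]
) -> tuple[int, float]:
    """Exhaustive 1-D minimization; ties break toward the smaller value."""
    values = grid.grid() if isinstance(grid, GeneSpec) else list(grid)
    if not values:
        raise ConfigError("brute_force_grid requires a nonempty grid")
    best_x, best_f = None, None
    for x in values:
        f = fitness(x)
        if best_f is None or f < best_f:
            best_x, best_f = x, f
    return best_x, float(best_f)


def _tournament(
    pop: list[tuple[int, ...]],
    fits: dict[tuple[int, ...], float],
    k: int,
    rng: random.Random,
) -> tuple[int, ...]:
    contenders = [pop[rng.randrange(len(pop))] for _ in range(k)]
    return min(contenders, key=lambda g: fits[g])


def _crossover(
    a: tuple[int, ...], b: tuple[int, ...], rng: random.Random
) -> tuple[tuple[int, ...], tuple[int, ...]]:
    n = len(a)
    if n < 2:
        return a, b
    cut = rng.randint(1, n - 1)
    return a[:cut] + b[cut:], b[:cut] + a[cut:]


def _mutate(
    genes: tuple[int, ...],
    specs: tuple[GeneSpec, ...],
    rate: float,
    rng: random.Random,
) -> tuple[int, ...]:
    return tuple(
        s.sample(rng) if rng.random() < rate else g for g, s in zip(genes, specs)
    )


def ga_run(
    ga_cfg: GAConfig,
    specs: tuple[GeneSpec, ...],
    fitness: Callable[[tuple[int, ...]], float],
) -> tuple[Chromosome, float, pd.DataFrame]:
    """Minimize ``fitness`` over the gene grids with a generational GA.

    Returns the best chromosome, its fitness, and a per-generation history
    (``generation``, ``best``, ``mean``, ``worst``).  With elitism >= 1 the
    best column is monotone non-increasing.  Fitness values are memoized, so
    a deterministic (e.g. common-random-numbers) fitness is evaluated once
    per distinct chromosome.
    """
    rng = random.Random(ga_cfg.seed)
    cache: dict[tuple[int, ...], float] = {}

    def fit(genes: tuple[int, ...]) -> float:
        if genes not in cache:
            cache[genes] = float(fitness(genes))
        return cache[genes]

    pop = [tuple(s.sample(rng) for s in specs) for _ in range(ga_cfg.population_size)]
    history = []
    for gen in range(ga_cfg.generations):
        values = [fit(g) for g in pop]
        order = sorted(range(len(pop)), key=lambda i: (values[i], pop[i]))
        history.append(
            (gen, values[order[0]], float(np.mean(values)), float(np.max(values)))
        )
        if gen == ga_cfg.generations - 1:
            break
        elites = [pop[i] for i in order[: ga_cfg.elitism]]
        nxt = list(elites)
        while len(nxt) < ga_cfg.population_size:
            p1 = _tournament(pop, cache, ga_cfg.tournament_size, rng)
            p2 = _tournament(pop, cache, ga_cfg.tournament_size, rng)
            if rng.random() < ga_cfg.crossover_rate:
                c1, c2 = _crossover(p1, p2, rng)
            else:
                c1, c2 = p1, p2
            for child in (c1, c2):
                child = _mutate(child, specs, ga_cfg.mutation_rate, rng)
                nxt.append(child)
                if len(nxt) >= ga_cfg.population_size:
                    break
        pop = nxt
    values = [fit(g) for g in pop]
    best_i = min(range(len(pop)), key=lambda i: (values[i], pop[i]))
    best = Chromosome(pop[best_i], specs)
    hist = pd.DataFrame(history, columns=["generation", "best", "mean", "worst"])
    return best, float(values[best_i]), hist
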