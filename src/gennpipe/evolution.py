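"""Island-model genetic algorithm over codon genomes.

The total population is split into demes (islands) that evolve
independently — tournament selection, single-point crossover at codon
boundaries, per-codon uniform mutation, elitism — and periodically
exchange their best individual around a ring, the best replacing the
receiving deme's worst.  Fitness is the balanced accuracy of the decoded
network on the training partition; individuals whose genome fails to
decode receive fitness 0, which selects strongly for functionality.

Every deme owns an independent RNG stream derived from ``(seed,
deme_id)``, so results are identical whether demes are stepped serially
or in parallel, and deme 0's trajectory does not change when more demes
are added.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from joblib import Parallel, delayed

from ._fastmap import decode_default
from .data_io import OmicsDataset
from .grammar import (
    Genome,
    Grammar,
    build_default_grammar,
    derive_expression,
    random_functional_genome,
)
from .model import NetworkModel, _eval_node_matrix, evaluate_matrix, parse_expression_string

__all__ = [
    "EvolutionConfig",
    "Individual",
    "Deme",
    "LogEntry",
    "SearchResult",
    "TrainingContext",
    "migration_interval",
    "initialize_demes",
    "step_generation",
    "migrate",
    "run_search",
]


@dataclass(frozen=True)
class EvolutionConfig:
    """Search hyper-parameters.

    The defaults are desk-scale; ``cluster_scale()`` gives a
    full-scale cluster setting (50 demes x 5,000, 300 generations, 15 migrations,
    crossover 0.9, per-codon mutation 0.01).
    """

    n_demes: int = 2
    population_per_deme: int = 500
    n_generations: int = 50
    n_migrations: int = 5
    p_crossover: float = 0.9
    p_mutation: float = 0.01
    max_wraps: int = 2
    max_init_depth: int = 8
    tournament_size: int = 2
    elitism: int = 1
    seed: int = 0
    max_genome_length: int = 500

    def __post_init__(self) -> None:
        for name in (
            "n_demes",
            "population_per_deme",
            "n_generations",
            "max_wraps",
            "max_init_depth",
            "tournament_size",
            "elitism",
            "max_genome_length",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_migrations < 0:
            raise ValueError("n_migrations must be >= 0")
        if self.n_migrations > self.n_generations:
            raise ValueError("n_migrations cannot exceed n_generations")
        for name in ("p_crossover", "p_mutation"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if self.elitism > self.population_per_deme:
            raise ValueError("elitism cannot exceed the deme population")

    @classmethod
    def cluster_scale(cls, seed: int = 0) -> "EvolutionConfig":
        return cls(
            n_demes=50,
            population_per_deme=5000,
            n_generations=300,
            n_migrations=15,
            p_crossover=0.9,
            p_mutation=0.01,
            seed=seed,
        )


@dataclass(frozen=True)
class Individual:
    """A genome with its decoded expression and training fitness."""

    genome: Genome
    expression: str | None  # None when decoding exhausted the wrap budget
    fitness: float

    @property
    def valid(self) -> bool:
        return self.expression is not None

    @property
    def model(self) -> NetworkModel | None:
        if self.expression is None:
            return None
        return parse_expression_string(self.expression)


@dataclass
class Deme:
    individuals: list[Individual]
    deme_id: int
    rng: np.random.Generator


@dataclass(frozen=True)
class LogEntry:
    """Best individual of one deme at one generation (always valid)."""

    generation: int
    deme_id: int
    fitness: float
    expression: str

    @property
    def model(self) -> NetworkModel:
        return parse_expression_string(self.expression)

    @property
    def size(self) -> int:
        return self.model.size


@dataclass
class SearchResult:
    best: Individual
    log: list[LogEntry]


@dataclass
class TrainingContext:
    """Training matrix, labels, and grammar bundled for fitness evaluation.

    Fitness values are memoised by expression string: distinct genomes
    frequently decode to the same network.
    """

    X: np.ndarray
    y: np.ndarray
    grammar: Grammar
    cache: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.ascontiguousarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y shapes disagree")
        self._pos = self.y == 1
        self._neg = ~self._pos
        self._n_pos = int(self._pos.sum())
        self._n_neg = int(self._neg.sum())
        if self._n_pos == 0 or self._n_neg == 0:
            raise ValueError("training data must contain both classes")
        # the specialised decoder applies only to the stock grammar
        self._is_default_grammar = self.grammar.rules == build_default_grammar().rules

    @classmethod
    def from_dataset(cls, dataset: OmicsDataset, grammar: Grammar) -> "TrainingContext":
        return cls(X=dataset.values, y=dataset.labels, grammar=grammar)

    @property
    def n_variables(self) -> int:
        return self.X.shape[1]

    def fitness_of(self, expression: str) -> float:
        cached = self.cache.get(expression)
        if cached is not None:
            return cached
        model = parse_expression_string(expression)
        pred = evaluate_matrix(model, self.X) >= 0.0
        sens = np.count_nonzero(pred & self._pos) / self._n_pos
        spec = np.count_nonzero(~pred & self._neg) / self._n_neg
        fitness = 0.5 * (sens + spec)
        self.cache[expression] = fitness
        return fitness

    def _fitness_of_root(self, expression: str, root) -> float:
        cached = self.cache.get(expression)
        if cached is not None:
            return cached
        with np.errstate(over="ignore", invalid="ignore"):
            out = _eval_node_matrix(root, self.X, None)
        pred = out >= 0.0
        sens = np.count_nonzero(pred & self._pos) / self._n_pos
        spec = np.count_nonzero(~pred & self._neg) / self._n_neg
        fitness = 0.5 * (sens + spec)
        self.cache[expression] = fitness
        return fitness

    def evaluate_genome(self, genome: Genome, config: EvolutionConfig) -> Individual:
        return self.evaluate_codons(genome.codons, config)

    def evaluate_codons(self, codons: tuple[int, ...], config: EvolutionConfig) -> Individual:
        genome = Genome._from_trusted(codons)
        if self._is_default_grammar:
            expression, root, _ = decode_default(codons, self.n_variables, config.max_wraps)
            if expression is None:
                return Individual(genome, None, 0.0)
            if expression in self.cache:
                return Individual(genome, expression, self.cache[expression])
            return Individual(genome, expression, self._fitness_of_root(expression, root))
        expression, _, _ = derive_expression(
            codons, self.grammar, self.n_variables, config.max_wraps
        )
        if expression is None:
            return Individual(genome, None, 0.0)
        return Individual(genome, expression, self.fitness_of(expression))


def migration_interval(n_generations: int, n_migrations: int) -> Optional[int]:
    """Generations between migrations: floor(G/M), clamped to >= 1.

    ``n_migrations = 0`` disables migration (returns None).  Migration
    fires at generations that are positive multiples of the interval.
    """
    if n_migrations == 0:
        return None
    return max(1, n_generations // n_migrations)


def _deme_rng(seed: int, deme_id: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(deme_id,)))


def initialize_demes(
    config: EvolutionConfig, grammar: Grammar, n_variables: int
) -> list[Deme]:
    """Fresh demes of functional genomes; every individual decodes validly.

    Individuals start unevaluated (fitness NaN) until a training context
    scores them.
    """
    demes = []
    for deme_id in range(config.n_demes):
        rng = _deme_rng(config.seed, deme_id)
        individuals = [
            Individual(
                random_functional_genome(grammar, n_variables, config.max_init_depth, rng),
                expression=None,
                fitness=float("nan"),
            )
            for _ in range(config.population_per_deme)
        ]
        demes.append(Deme(individuals=individuals, deme_id=deme_id, rng=rng))
    return demes


def _evaluate_deme(deme: Deme, ctx: TrainingContext, config: EvolutionConfig) -> Deme:
    deme.individuals = [ctx.evaluate_genome(ind.genome, config) for ind in deme.individuals]
    return deme


def _crossover(
    g1: tuple[int, ...], g2: tuple[int, ...], cut_draws: np.ndarray, cap: int
) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Single-point crossover at codon boundaries, cuts drawn per parent."""
    c1 = 1 + int(cut_draws[0] * (len(g1) - 1)) if len(g1) > 1 else 1
    c2 = 1 + int(cut_draws[1] * (len(g2) - 1)) if len(g2) > 1 else 1
    child1 = g1[:c1] + g2[c2:]
    child2 = g2[:c2] + g1[c1:]
    return child1[:cap] or (g1[0],), child2[:cap] or (g2[0],)


def _mutate(codons: tuple[int, ...], rng: np.random.Generator, p: float) -> tuple[int, ...]:
    """Per-codon uniform resampling at rate p.

    Drawing the mutation count Binomial(L, p) and then a uniform subset
    of positions is the same process as an independent coin per codon,
    and skips the common no-mutation case cheaply.
    """
    if p <= 0.0:
        return codons
    L = len(codons)
    k = int(rng.binomial(L, p))
    if k == 0:
        return codons
    if k == 1:
        pos = (int(rng.integers(L)),)
    else:
        pos = rng.choice(L, size=min(k, L), replace=False)
    out = list(codons)
    values = rng.integers(0, 256, size=len(pos))
    for i, v in zip(pos, values):
        out[int(i)] = int(v)
    return tuple(out)


def step_generation(deme: Deme, ctx: TrainingContext, config: EvolutionConfig) -> Deme:
    """One generation: elitism, tournament selection, crossover, mutation.

    Mutates ``deme`` in place (its RNG advances) and returns it.
    """
    pop = config.population_per_deme
    individuals = deme.individuals
    fitness = np.asarray([ind.fitness for ind in individuals])
    order = sorted(range(pop), key=lambda i: -fitness[i])  # stable on ties
    next_gen: list[Individual] = [individuals[i] for i in order[: config.elitism]]

    n_offspring = pop - config.elitism
    n_pairs = (n_offspring + 1) // 2
    rng = deme.rng
    if n_pairs > 0:
        contestants = rng.integers(0, pop, size=(n_pairs, 2, config.tournament_size))
        # batched tournaments: first max wins, as in a sequential scan
        winner_slot = np.argmax(fitness[contestants], axis=2)
        parents = np.take_along_axis(contestants, winner_slot[:, :, None], axis=2)[:, :, 0]
        do_cross = rng.random(n_pairs) < config.p_crossover
        cut_draws = rng.random((n_pairs, 2))
        for k in range(n_pairs):
            p1 = individuals[parents[k, 0]].genome.codons
            p2 = individuals[parents[k, 1]].genome.codons
            if do_cross[k]:
                g1, g2 = _crossover(p1, p2, cut_draws[k], config.max_genome_length)
            else:
                g1, g2 = p1, p2
            for g in (g1, g2):
                if len(next_gen) >= pop:
                    break
                g = _mutate(g, rng, config.p_mutation)
                next_gen.append(ctx.evaluate_codons(g, config))
    deme.individuals = next_gen
    return deme


def _best_index(individuals: list[Individual]) -> int:
    return max(range(len(individuals)), key=lambda i: individuals[i].fitness)


def _worst_index(individuals: list[Individual]) -> int:
    return min(range(len(individuals)), key=lambda i: individuals[i].fitness)


def migrate(demes: list[Deme], config: EvolutionConfig) -> list[Deme]:
    """Ring migration: deme i's best replaces deme (i+1)'s worst, simultaneously."""
    n = len(demes)
    if n < 2:
        return demes
    bests = [deme.individuals[_best_index(deme.individuals)] for deme in demes]
    for i, deme in enumerate(demes):
        incoming = bests[(i - 1) % n]
        deme.individuals[_worst_index(deme.individuals)] = incoming
    return demes


def _run_deme_chunk(
    deme: Deme,
    ctx: TrainingContext,
    config: EvolutionConfig,
    first_generation: int,
    n_generations: int,
) -> tuple[Deme, list[LogEntry], Individual]:
    """Advance one deme by ``n_generations`` and log its per-generation best."""
    entries: list[LogEntry] = []
    best_seen = deme.individuals[_best_index(deme.individuals)]
    for g in range(n_generations):
        step_generation(deme, ctx, config)
        best = deme.individuals[_best_index(deme.individuals)]
        if best.fitness > best_seen.fitness:
            best_seen = best
        if best.valid:
            entries.append(
                LogEntry(first_generation + g, deme.deme_id, best.fitness, best.expression)
            )
    return deme, entries, best_seen


def run_search(
    training,
    grammar: Grammar | None = None,
    config: EvolutionConfig | None = None,
    n_jobs: int = 1,
) -> SearchResult:
    """Full search: initialise, evolve with periodic ring migration, return
    the best individual ever observed plus the per-generation per-deme log.

    ``training`` is an :class:`OmicsDataset` or a prebuilt
    :class:`TrainingContext`.  ``n_jobs > 1`` steps demes in parallel
    between migration points; results are identical to the serial run.
    """
    if config is None:
        raise ValueError("an EvolutionConfig is required")
    if isinstance(training, TrainingContext):
        ctx = training
    else:
        if grammar is None:
            raise ValueError("a grammar is required with a dataset input")
        ctx = TrainingContext.from_dataset(training, grammar)

    demes = initialize_demes(config, ctx.grammar, ctx.n_variables)
    for deme in demes:
        _evaluate_deme(deme, ctx, config)

    interval = migration_interval(config.n_generations, config.n_migrations)
    best = max(
        (deme.individuals[_best_index(deme.individuals)] for deme in demes),
        key=lambda ind: ind.fitness,
    )
    log: list[LogEntry] = []

    generation = 1
    while generation <= config.n_generations:
        if interval is None:
            chunk = config.n_generations - generation + 1
        else:
            chunk = min(interval - (generation - 1) % interval, config.n_generations - generation + 1)
        if n_jobs != 1 and len(demes) > 1:
            results = Parallel(n_jobs=n_jobs)(
                delayed(_run_deme_chunk)(deme, ctx, config, generation, chunk)
                for deme in demes
            )
        else:
            results = [_run_deme_chunk(deme, ctx, config, generation, chunk) for deme in demes]
        demes = [r[0] for r in results]
        chunk_entries = [r[1] for r in results]
        for g in range(chunk):
            for entries in chunk_entries:
                if g < len(entries):
                    log.append(entries[g])
        for _, _, chunk_best in results:
            if chunk_best.fitness > best.fitness:
                best = chunk_best
        generation += chunk
        if interval is not None and (generation - 1) % interval == 0 and generation <= config.n_generations:
            migrate(demes, config)
    return SearchResult(best=best, log=log)
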