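from dataclasses import replace

import numpy as np
import pytest

from gennpipe.evolution import (
    Deme,
    EvolutionConfig,
    TrainingContext,
    initialize_demes,
    migrate,
    migration_interval,
    run_search,
    step_generation,
)
from gennpipe.synth import PlantedEffect, SimulationConfig, generate

TINY = EvolutionConfig(
    n_demes=2, population_per_deme=40, n_generations=10, n_migrations=2, seed=0
)


def threshold_dataset(n=500, p=20, seed=0):
    """Labels are exactly 1{V1 > 0}: the easiest learnable rule."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    y = (X[:, 0] > 0).astype(np.int8)
    from gennpipe.data_io import OmicsDataset

    return OmicsDataset(
        layer="toy",
        sample_ids=tuple(f"s{i}" for i in range(n)),
        feature_names=tuple(f"f{j}" for j in range(p)),
        values=X,
        labels=y,
    )


def noise_dataset(n=120, p=8, seed=1):
    (ds,), _ = generate(
        SimulationConfig(n_samples=n, layers=(("noise", p),), effects=(), seed=seed)
    )
    return ds


class TestMigrationInterval:
    def test_cluster_scale_interval(self):
        # 300 generations with 15 migrations -> every 20 generations
        assert migration_interval(300, 15) == 20

    def test_single_migration_at_end(self):
        assert migration_interval(20, 1) == 20

    def test_interval_clamped_to_every_generation(self):
        assert migration_interval(10, 20) == 1

    def test_zero_migrations_disables(self):
        assert migration_interval(10, 0) is None


class TestInitialization:
    def test_all_initial_individuals_valid(self, grammar):
        demes = initialize_demes(TINY, grammar, n_variables=8)
        ctx = TrainingContext.from_dataset(noise_dataset(), grammar)
        for deme in demes:
            for ind in deme.individuals:
                assert ctx.evaluate_genome(ind.genome, TINY).valid

    def test_seed_reproducible(self, grammar):
        a = initialize_demes(TINY, grammar, 8)
        b = initialize_demes(TINY, grammar, 8)
        for da, db in zip(a, b):
            assert [i.genome.codons for i in da.individuals] == [
                i.genome.codons for i in db.individuals
            ]

    def test_deme_streams_independent_of_deme_count(self, grammar):
        few = initialize_demes(TINY, grammar, 8)
        many = initialize_demes(replace(TINY, n_demes=4), grammar, 8)
        assert [i.genome.codons for i in few[0].individuals] == [
            i.genome.codons for i in many[0].individuals
        ]


class TestStepGeneration:
    def test_no_variation_is_a_fixed_point(self, grammar):
        config = replace(
            TINY, p_crossover=0.0, p_mutation=0.0, elitism=TINY.population_per_deme
        )
        ctx = TrainingContext.from_dataset(noise_dataset(), grammar)
        demes = initialize_demes(config, grammar, ctx.n_variables)
        deme = demes[0]
        deme.individuals = [ctx.evaluate_genome(i.genome, config) for i in deme.individuals]
        before = sorted(i.genome.codons for i in deme.individuals)
        step_generation(deme, ctx, config)
        after = sorted(i.genome.codons for i in deme.individuals)
        assert before == after

    def test_population_size_constant(self, grammar):
        ctx = TrainingContext.from_dataset(noise_dataset(), grammar)
        demes = initialize_demes(TINY, grammar, ctx.n_variables)
        deme = demes[0]
        deme.individuals = [ctx.evaluate_genome(i.genome, TINY) for i in deme.individuals]
        for _ in range(3):
            step_generation(deme, ctx, TINY)
            assert len(deme.individuals) == TINY.population_per_deme

    def test_full_mutation_changes_offspring(self, grammar):
        config = replace(TINY, p_mutation=1.0, elitism=1)
        ctx = TrainingContext.from_dataset(noise_dataset(), grammar)
        deme = initialize_demes(config, grammar, ctx.n_variables)[0]
        deme.individuals = [ctx.evaluate_genome(i.genome, config) for i in deme.individuals]
        parents = {i.genome.codons for i in deme.individuals}
        step_generation(deme, ctx, config)
        changed = [i for i in deme.individuals[1:] if i.genome.codons not in parents]
        assert len(changed) >= len(deme.individuals) - 5


class TestMigrate:
    def _deme_with_fitness(self, grammar, ctx, deme_id, fitnesses):
        deme = initialize_demes(replace(TINY, n_demes=deme_id + 1), grammar, 8)[deme_id]
        deme.individuals = [ctx.evaluate_genome(i.genome, TINY) for i in deme.individuals]
        inds = []
        for ind, f in zip(deme.individuals, fitnesses):
            inds.append(replace(ind, fitness=f))
        deme.individuals = inds
        return deme

    def test_ring_of_two_exchanges_bests(self, grammar):
        ctx = TrainingContext.from_dataset(noise_dataset(), grammar)
        d0 = self._deme_with_fitness(grammar, ctx, 0, np.linspace(0.1, 0.8, 40))
        d1 = self._deme_with_fitness(grammar, ctx, 1, np.linspace(0.2, 0.9, 40))
        best0 = max(d0.individuals, key=lambda i: i.fitness)
        best1 = max(d1.individuals, key=lambda i: i.fitness)
        migrate([d0, d1], TINY)
        assert best1 in d0.individuals and best0 in d1.individuals
        assert len(d0.individuals) == len(d1.individuals) == 40

    def test_global_best_never_decreases(self, grammar):
        ctx = TrainingContext.from_dataset(noise_dataset(), grammar)
        d0 = self._deme_with_fitness(grammar, ctx, 0, np.linspace(0.1, 0.8, 40))
        d1 = self._deme_with_fitness(grammar, ctx, 1, np.linspace(0.2, 0.9, 40))
        before = max(i.fitness for d in (d0, d1) for i in d.individuals)
        migrate([d0, d1], TINY)
        after = max(i.fitness for d in (d0, d1) for i in d.individuals)
        assert after >= before

    def test_single_deme_noop(self, grammar):
        ctx = TrainingContext.from_dataset(noise_dataset(), grammar)
        deme = self._deme_with_fitness(grammar, ctx, 0, np.linspace(0.1, 0.8, 40))
        genomes = [i.genome.codons for i in deme.individuals]
        migrate([deme], TINY)
        assert [i.genome.codons for i in deme.individuals] == genomes


class TestRunSearch:
    def test_requires_both_classes(self, grammar):
        ds = noise_dataset()
        bad = ds.subset_samples(np.nonzero(ds.labels == 1)[0])
        with pytest.raises(ValueError):
            run_search(bad, grammar, TINY)

    def test_seed_stable(self, grammar):
        ds = noise_dataset()
        r1 = run_search(ds, grammar, TINY)
        r2 = run_search(ds, grammar, TINY)
        assert r1.best.expression == r2.best.expression
        assert [(e.generation, e.deme_id, e.fitness, e.expression) for e in r1.log] == [
            (e.generation, e.deme_id, e.fitness, e.expression) for e in r2.log
        ]

    def test_best_is_running_maximum(self, grammar):
        result = run_search(noise_dataset(), grammar, TINY)
        assert result.best.fitness >= max(e.fitness for e in result.log)

    def test_log_covers_every_generation_and_deme(self, grammar):
        result = run_search(noise_dataset(), grammar, TINY)
        assert {(e.generation, e.deme_id) for e in result.log} == {
            (g, d) for g in range(1, 11) for d in range(2)
        }

    def test_per_deme_best_fitness_monotone_under_elitism(self, grammar):
        result = run_search(noise_dataset(n=200), grammar, replace(TINY, n_generations=10))
        for deme_id in range(TINY.n_demes):
            series = [e.fitness for e in result.log if e.deme_id == deme_id]
            assert all(b >= a - 1e-12 for a, b in zip(series, series[1:]))

    def test_recovers_single_threshold_variable(self, grammar):
        config = EvolutionConfig(
            n_demes=2, population_per_deme=200, n_generations=30, n_migrations=3
        )
        hits = 0
        for seed in range(10):
            ds = threshold_dataset(seed=seed)
            result = run_search(ds, grammar, replace(config, seed=seed))
            has_v1 = any(ref.position == 0 for ref in result.best.model.variables)
            if has_v1 and result.best.fitness >= 0.95:
                hits += 1
        assert hits >= 9
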