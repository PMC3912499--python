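from dataclasses import replace

import numpy as np
import pytest

from gennpipe.evolution import EvolutionConfig, LogEntry, run_search
from gennpipe.filtering import (
    apply_threshold,
    collect_intermediate_models,
    filter_training_fold,
    select_filter_threshold,
    variable_frequency,
)
from gennpipe.synth import PlantedEffect, SimulationConfig, generate


def entries(expressions):
    return [LogEntry(g, 0, 0.5, e) for g, e in enumerate(expressions)]


FEATURES = tuple(f"f{i}" for i in range(6))


class TestCollect:
    def test_counts_generation_deme_pairs(self, grammar):
        config = EvolutionConfig(
            n_demes=3, population_per_deme=30, n_generations=4, n_migrations=1, seed=1
        )
        (ds,), _ = generate(
            SimulationConfig(n_samples=80, layers=(("L", 6),), effects=(), seed=0)
        )
        result = run_search(ds, grammar, config)
        models = collect_intermediate_models(result.log)
        assert len(models) == 3 * 4

    def test_empty_log(self):
        assert collect_intermediate_models([]) == []


class TestFrequency:
    def test_fraction_of_models(self):
        log = entries(
            [
                "PADD(1.0*V1,1.0*V2)",
                "PADD(1.0*V1,1.0*V3)",
                "PADD(1.0*V1,1.0*V1)",
                "PADD(1.0*V2,1.0*V4)",
            ]
        )
        table = variable_frequency(collect_intermediate_models(log), FEATURES)
        freq = dict(zip(table.table["variable"], table.table["frequency"]))
        assert freq["f0"] == 0.75  # V1 in 3 of 4 models
        assert freq["f1"] == 0.5
        assert freq["f4"] == 0.0

    def test_repeats_within_model_count_once(self):
        log = entries(["PMULT(1.0*V2,2.0*V2)"])
        table = variable_frequency(collect_intermediate_models(log), FEATURES)
        freq = dict(zip(table.table["variable"], table.table["frequency"]))
        assert freq["f1"] == 1.0

    def test_unseen_variables_get_worst_ranks(self):
        log = entries(["PADD(1.0*V1,1.0*V2)"])
        table = variable_frequency(collect_intermediate_models(log), FEATURES)
        ranked = list(table.table["variable"])
        assert set(ranked[:2]) == {"f0", "f1"}
        assert table.table["rank"].tolist() == [1, 2, 3, 4, 5, 6]

    def test_ties_keep_input_order(self):
        log = entries(["PADD(1.0*V3,1.0*V5)"])
        table = variable_frequency(collect_intermediate_models(log), FEATURES)
        zero_ranked = [v for v, f in zip(table.table["variable"], table.table["frequency"]) if f == 0]
        assert zero_ranked == ["f0", "f1", "f3", "f5"]

    def test_no_models_rejected(self):
        with pytest.raises(ValueError):
            variable_frequency([], FEATURES)


class TestThreshold:
    def make_table(self, p):
        log = entries(["PADD(1.0*V1,1.0*V2)"])
        return variable_frequency(
            collect_intermediate_models(log), tuple(f"x{i}" for i in range(p))
        )

    @pytest.mark.parametrize("p,fraction,expected", [(20, 0.10, 2), (54, 0.50, 27), (10, 1.0, 10)])
    def test_ceil_retention_counts(self, p, fraction, expected):
        assert len(apply_threshold(self.make_table(p), fraction)) == expected

    def test_tiny_fraction_keeps_at_least_one(self):
        assert len(apply_threshold(self.make_table(30), 0.001)) == 1

    def test_monotone_containment(self):
        table = self.make_table(40)
        previous = set()
        for fraction in (0.05, 0.1, 0.3, 0.5, 0.8, 1.0):
            retained = set(apply_threshold(table, fraction))
            assert previous <= retained
            previous = retained

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            apply_threshold(self.make_table(10), 0.0)


class TestFilterTrainingFold:
    def test_planted_variable_retained(self, grammar):
        (ds,), _ = generate(
            SimulationConfig(
                n_samples=300,
                layers=(("L", 40),),
                effects=(PlantedEffect("main", (("L", 7),)),),
                seed=2,
            )
        )
        config = EvolutionConfig(
            n_demes=4, population_per_deme=200, n_generations=10, n_migrations=2, seed=5
        )
        retained = filter_training_fold(ds, grammar, config, fraction=0.25)
        assert "L_f0007" in retained
        assert len(retained) == 10
        # original column order preserved
        assert retained == [n for n in ds.feature_names if n in set(retained)]

    def test_fraction_one_skips_search(self, grammar):
        (ds,), _ = generate(
            SimulationConfig(n_samples=100, layers=(("L", 8),), effects=(), seed=0)
        )
        config = EvolutionConfig(
            n_demes=1, population_per_deme=10, n_generations=1, n_migrations=0, seed=0
        )
        assert filter_training_fold(ds, grammar, config, fraction=1.0) == list(ds.feature_names)


class TestSelectFilterThreshold:
    def test_single_candidate(self, grammar):
        (ds,), _ = generate(
            SimulationConfig(n_samples=120, layers=(("L", 10),), effects=(), seed=1)
        )
        config = EvolutionConfig(
            n_demes=2, population_per_deme=40, n_generations=4, n_migrations=1, seed=0
        )
        best, scores = select_filter_threshold(ds, grammar, [0.5], config, k=3)
        assert best == 0.5 and set(scores) == {0.5}

    def test_noise_reduction_wins_on_noisy_data(self, grammar):
        """With one planted effect among 199 noise features and a modest
        search budget, the strict filter should beat no filtering in most
        seeded trials (noise removal is the point of the stage)."""
        wins = 0
        trials = 6
        for seed in range(trials):
            config = SimulationConfig(
                n_samples=300,
                layers=(("L", 200),),
                effects=(PlantedEffect("main", (("L", 0),)),),
                seed=seed,
            )
            (ds,), _ = generate(config)
            eval_config = EvolutionConfig(
                n_demes=2, population_per_deme=100, n_generations=10, n_migrations=2, seed=seed
            )
            filter_config = EvolutionConfig(
                n_demes=4, population_per_deme=200, n_generations=8, n_migrations=2, seed=seed
            )
            best, scores = select_filter_threshold(
                ds, grammar, [0.1, 1.0], eval_config, filter_config=filter_config, k=3
            )
            if scores[0.1] > scores[1.0]:
                wins += 1
        assert wins >= 5
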