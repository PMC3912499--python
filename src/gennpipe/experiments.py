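"""Reference synthetic experiments at desk scale.

These functions fix the study conditions used by the test suite and the
acceptance script: sample sizes, planted-effect penetrances, and search
budgets small enough for a single CPU.  The full-scale setting
(50 demes x 5,000 over 300 generations) is cluster work; the budgets
here are the package's own reduced configuration, chosen so that the
search reliably recovers the planted structure while a complete
experiment stays in the minutes range.

Three experiments:

* **main effect** — one layer, one planted threshold effect (penetrances
  0.9/0.1) among 99 noise features: the frequency filter should rank the
  planted variable in the top decile, and modelling on the filtered data
  should approach the 0.9 oracle ceiling.
* **cross-layer xor** — two layers, one xor pair spanning them, each
  member marginally null: single-layer models stay near chance while a
  direct meta-dimensional search over both layers recovers the pair.
* **null calibration** — labels independent of all features: the full
  filter -> model -> integrate pipeline must stay near 0.5 test balanced
  accuracy (no optimism leaking through the per-fold protocol).
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np

from .cv import CvResult, derive_seed, run_cv, split_folds
from .evolution import EvolutionConfig, run_search
from .filtering import collect_intermediate_models, variable_frequency
from .grammar import build_default_grammar
from .integration import pool_best_variables, pool_layers, run_integration
from .model import VariableRef
from .synth import PlantedEffect, SimulationConfig, generate

__all__ = [
    "MAIN_FILTER_CONFIG",
    "MAIN_MODEL_CONFIG",
    "main_effect_simulation",
    "main_effect_filter_rank",
    "main_effect_cv",
    "xor_simulation",
    "xor_integration_experiment",
    "null_pipeline_experiment",
]

# --- main-effect study conditions -----------------------------------------
MAIN_FILTER_CONFIG = EvolutionConfig(
    n_demes=10, population_per_deme=500, n_generations=20, n_migrations=4
)
MAIN_MODEL_CONFIG = EvolutionConfig(
    n_demes=2, population_per_deme=500, n_generations=50, n_migrations=5
)
MAIN_FRACTION = 0.10

# --- cross-layer xor study conditions -------------------------------------
XOR_SINGLE_CONFIG = EvolutionConfig(
    n_demes=2, population_per_deme=250, n_generations=25, n_migrations=3
)
# Wide, shallow-initialised, mutation-heavy search for the integrated run:
# an xor pair with marginally null members is found by broadly sampling
# variable pairs into multiplicative nodes, not by hill-climbing, so the
# budget goes into population width and codon churn rather than depth.
XOR_MODEL_CONFIG = EvolutionConfig(
    n_demes=4,
    population_per_deme=4000,
    n_generations=12,
    n_migrations=3,
    max_init_depth=5,
    p_mutation=0.05,
)

# --- null-calibration study conditions ------------------------------------
NULL_FILTER_CONFIG = EvolutionConfig(
    n_demes=4, population_per_deme=200, n_generations=8, n_migrations=2
)
NULL_MODEL_CONFIG = EvolutionConfig(
    n_demes=2, population_per_deme=150, n_generations=15, n_migrations=2
)
NULL_FRACTION = 0.20


def main_effect_simulation(seed: int) -> SimulationConfig:
    return SimulationConfig(
        n_samples=500,
        layers=(("omics1", 100),),
        effects=(PlantedEffect("main", (("omics1", 0),)),),
        seed=seed,
    )


def main_effect_filter_rank(seed: int, n_jobs: int = 1) -> tuple[int, int]:
    """Rank of the planted variable in the filter's frequency table.

    Returns (rank, total variables); the top decile means rank <= 10 of
    100 here.
    """
    (dataset,), effects = generate(main_effect_simulation(seed))
    grammar = build_default_grammar()
    config = dc_replace(MAIN_FILTER_CONFIG, seed=derive_seed(seed, 11))
    result = run_search(dataset, grammar, config, n_jobs=n_jobs)
    table = variable_frequency(
        collect_intermediate_models(result.log), dataset.feature_names, dataset.layer
    )
    planted = dataset.feature_names[effects[0].variables[0][1]]
    rank = int(table.table.loc[table.table["variable"] == planted, "rank"].iloc[0])
    return rank, dataset.n_features


def main_effect_cv(seed: int, n_jobs: int = 1) -> CvResult:
    """Filter (top 10%, per training fold) then model, 5-fold CV."""
    (dataset,), _ = generate(main_effect_simulation(seed))
    grammar = build_default_grammar()
    return run_cv(
        dataset,
        grammar,
        dc_replace(MAIN_MODEL_CONFIG, seed=derive_seed(seed, 12)),
        k=5,
        filter_config=dc_replace(MAIN_FILTER_CONFIG, seed=derive_seed(seed, 13)),
        filter_fraction=MAIN_FRACTION,
        n_jobs=n_jobs,
    )


def xor_simulation(seed: int) -> SimulationConfig:
    return SimulationConfig(
        n_samples=500,
        layers=(("layerA", 100), ("layerB", 100)),
        effects=(PlantedEffect("xor_pair", (("layerA", 0), ("layerB", 0))),),
        seed=seed,
    )


@dataclass
class XorIntegrationOutcome:
    single_layer_means: dict[str, float]
    integrated_mean: float
    gain_over_best_single: float
    folds_with_both_planted: int
    comparisons: dict[str, float]  # layer -> two-sided Wilcoxon p


def xor_integration_experiment(seed: int, n_jobs: int = 1) -> XorIntegrationOutcome:
    """Single-layer models vs a direct cross-layer search on both layers.

    Variables of a cross-layer xor pair carry no marginal signal, so they
    can survive neither single-layer best-model selection nor a frequency
    filter; the integrated run therefore searches the full two-layer pool
    with the wide sampling-oriented configuration above.
    """
    datasets, effects = generate(xor_simulation(seed))
    grammar = build_default_grammar()
    by_layer = {ds.layer: ds for ds in datasets}
    folds = split_folds(
        datasets[0].sample_ids, datasets[0].labels, k=5, seed=derive_seed(seed, 21)
    )
    single: dict[str, CvResult] = {}
    for i, (layer, ds) in enumerate(by_layer.items()):
        single[layer] = run_cv(
            ds,
            grammar,
            dc_replace(XOR_SINGLE_CONFIG, seed=derive_seed(seed, 22, i)),
            folds=folds,
            n_jobs=n_jobs,
        )
    pooled = pool_layers(by_layer)
    integration = run_integration(
        pooled,
        grammar,
        dc_replace(XOR_MODEL_CONFIG, seed=derive_seed(seed, 23)),
        single_layer_results=single,
        folds=folds,
        n_jobs=n_jobs,
    )
    planted = {
        VariableRef(layer, by_layer[layer].feature_names[idx])
        for layer, idx in effects[0].variables
    }
    folds_with_both = sum(
        1 for fr in integration.cv.per_fold if planted <= fr.model.variables
    )
    single_means = {layer: cv.mean_test_accuracy for layer, cv in single.items()}
    integrated_mean = integration.cv.mean_test_accuracy
    return XorIntegrationOutcome(
        single_layer_means=single_means,
        integrated_mean=integrated_mean,
        gain_over_best_single=integrated_mean - max(single_means.values()),
        folds_with_both_planted=folds_with_both,
        comparisons=integration.comparisons,
    )


def null_simulation(seed: int) -> SimulationConfig:
    return SimulationConfig(
        n_samples=300,
        layers=(("nullA", 50), ("nullB", 50)),
        effects=(),
        seed=seed,
    )


def null_pipeline_experiment(seed: int, n_jobs: int = 1) -> float:
    """Full filter -> model -> integrate pipeline on label-independent data.

    Returns the mean held-out balanced accuracy over all runs (two
    single-layer runs and the integration of their pooled best-model
    variables); an unbiased pipeline sits near 0.5.
    """
    datasets, _ = generate(null_simulation(seed))
    grammar = build_default_grammar()
    by_layer = {ds.layer: ds for ds in datasets}
    folds = split_folds(
        datasets[0].sample_ids, datasets[0].labels, k=5, seed=derive_seed(seed, 31)
    )
    accuracies: list[float] = []
    single: dict[str, CvResult] = {}
    for i, (layer, ds) in enumerate(by_layer.items()):
        cv = run_cv(
            ds,
            grammar,
            dc_replace(NULL_MODEL_CONFIG, seed=derive_seed(seed, 32, i)),
            folds=folds,
            filter_config=dc_replace(NULL_FILTER_CONFIG, seed=derive_seed(seed, 33, i)),
            filter_fraction=NULL_FRACTION,
            n_jobs=n_jobs,
        )
        single[layer] = cv
        accuracies.extend(cv.test_accuracies)
    pooled = pool_best_variables(
        {layer: cv.selected_model for layer, cv in single.items()}, by_layer
    )
    integration = run_integration(
        pooled,
        grammar,
        dc_replace(NULL_MODEL_CONFIG, seed=derive_seed(seed, 34)),
        single_layer_results=single,
        folds=folds,
        n_jobs=n_jobs,
    )
    accuracies.extend(integration.cv.test_accuracies)
    return float(np.mean(accuracies))
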