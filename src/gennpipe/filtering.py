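"""Frequency-based noise filtering.

A short, wide search is run first; every per-generation per-deme best
network is an "intermediate model", and each variable's frequency is the
fraction of intermediate models containing it.  Variables are ranked by
frequency and the top fraction (e.g. 10/30/50%) of the layer's variables
is retained — variables that evolution keeps reaching for are likely
signal, and the search downstream performs better once the noise is
gone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace
from typing import Sequence

import pandas as pd

from .data_io import OmicsDataset
from .evolution import EvolutionConfig, LogEntry, run_search
from .grammar import Grammar
from .model import NetworkModel

__all__ = [
    "FrequencyTable",
    "collect_intermediate_models",
    "variable_frequency",
    "apply_threshold",
    "filter_training_fold",
    "select_filter_threshold",
    "DEFAULT_FILTER_CONFIG",
]

#: short, wide search used by the filtering stage (deme count and
#: per-deme population for the filter run are configurable; these are the
#: desk-scale defaults)
DEFAULT_FILTER_CONFIG = EvolutionConfig(
    n_demes=10,
    population_per_deme=500,
    n_generations=20,
    n_migrations=4,
)


@dataclass
class FrequencyTable:
    """Per-variable appearance frequencies over the intermediate models.

    ``table`` has columns variable, layer, frequency, rank, sorted by
    descending frequency; ties keep the variables' input-file order.
    """

    table: pd.DataFrame
    n_models: int

    def to_tsv(self, path, retained: set[str] | None = None) -> None:
        out = self.table.copy()
        if retained is not None:
            out["retained"] = out["variable"].isin(retained).astype(int)
        out.to_csv(path, sep="\t", index=False)


def collect_intermediate_models(log: Sequence[LogEntry]) -> list[NetworkModel]:
    """The best model of every (generation, deme) pair in a search log."""
    cache: dict[str, NetworkModel] = {}
    models = []
    for entry in log:
        model = cache.get(entry.expression)
        if model is None:
            model = cache[entry.expression] = entry.model
        models.append(model)
    return models


def _resolve_names(model: NetworkModel, feature_names: Sequence[str]) -> set[str]:
    names = set()
    for ref in model.variables:
        if ref.is_positional:
            names.add(feature_names[ref.position])
        else:
            names.add(ref.feature_id)
    return names


def variable_frequency(
    models: Sequence[NetworkModel],
    feature_names: Sequence[str],
    layer: str | None = None,
) -> FrequencyTable:
    """Fraction of intermediate models containing each variable.

    Variables never appearing get frequency 0 and the worst ranks;
    multiple occurrences within one model count once.
    """
    if len(models) == 0:
        raise ValueError("no intermediate models to count")
    counts = {name: 0 for name in feature_names}
    for model in models:
        for name in _resolve_names(model, feature_names):
            counts[name] += 1
    rows = pd.DataFrame(
        {
            "variable": list(feature_names),
            "layer": layer or "",
            "frequency": [counts[n] / len(models) for n in feature_names],
        }
    )
    rows = rows.sort_values("frequency", ascending=False, kind="stable").reset_index(drop=True)
    rows["rank"] = range(1, len(rows) + 1)
    return FrequencyTable(table=rows, n_models=len(models))


def apply_threshold(table: FrequencyTable, fraction: float) -> list[str]:
    """Retain the ceil(fraction * p) top-ranked variables (>= 1 for any
    positive fraction); boundary ties follow the table's stable order."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    p = len(table.table)
    n_keep = math.ceil(fraction * p)
    return table.table["variable"].head(n_keep).tolist()


def filter_training_fold(
    train_dataset: OmicsDataset,
    grammar: Grammar,
    config: EvolutionConfig,
    fraction: float,
    n_jobs: int = 1,
) -> list[str]:
    """Run the filter search on one training fold; returns the retained
    feature names in the layer's original column order."""
    if fraction >= 1.0:  # filter disabled: everything is retained
        return list(train_dataset.feature_names)
    result = run_search(train_dataset, grammar, config, n_jobs=n_jobs)
    table = variable_frequency(
        collect_intermediate_models(result.log),
        train_dataset.feature_names,
        layer=train_dataset.layer,
    )
    retained = set(apply_threshold(table, fraction))
    return [name for name in train_dataset.feature_names if name in retained]


def select_filter_threshold(
    dataset: OmicsDataset,
    grammar: Grammar,
    candidate_fractions: Sequence[float],
    eval_config: EvolutionConfig,
    filter_config: EvolutionConfig | None = None,
    k: int = 5,
    n_jobs: int = 1,
) -> tuple[float, dict[float, float]]:
    """Pick the retention fraction whose filtered dataset cross-validates
    best (highest mean test balanced accuracy; ties keep the first
    candidate).  Returns (best fraction, fraction -> mean accuracy)."""
    from .cv import run_cv, split_folds  # local import avoids a cycle

    if not candidate_fractions:
        raise ValueError("need at least one candidate fraction")
    if filter_config is None:
        filter_config = dc_replace(DEFAULT_FILTER_CONFIG, seed=eval_config.seed)
    folds = split_folds(dataset.sample_ids, dataset.labels, k, eval_config.seed)
    scores: dict[float, float] = {}
    for fraction in candidate_fractions:
        result = run_cv(
            dataset,
            grammar,
            eval_config,
            k=k,
            folds=folds,
            filter_config=filter_config,
            filter_fraction=fraction,
            n_jobs=n_jobs,
        )
        scores[fraction] = result.mean_test_accuracy
    best = max(candidate_fractions, key=lambda f: scores[f])
    return best, scores
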