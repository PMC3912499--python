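"""Meta-dimensional integration across omics layers.

The variables of each layer's best model are pooled into one combined
dataset — columns copied unchanged from their source layers and tagged
``layer::feature`` — and the search runs again on the pool to find a
model that may mix layers.  The integrated model is compared against
each single-layer model with an exact Wilcoxon signed-rank test over the
paired per-fold test accuracies, which requires every run to share one
fold assignment.

Pooling only the selected best model per layer follows the classical
protocol, but interactions whose members carry no marginal signal never
enter any single-layer best model; ``pool_layers`` therefore also offers
the full union of (filtered) layer features for a direct cross-layer
search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cv import CvResult, FoldAssignment, run_cv
from .data_io import OmicsDataset
from .evolution import EvolutionConfig
from .grammar import Grammar
from .metrics import wilcoxon_signed_rank_exact
from .model import NetworkModel, VariableRef

__all__ = [
    "IntegrationResult",
    "pool_best_variables",
    "pool_fold_best_variables",
    "pool_layers",
    "run_integration",
]

POOLED_LAYER_NAME = "integrated"


@dataclass
class IntegrationResult:
    final_model: NetworkModel
    cv: CvResult
    comparisons: dict[str, float]  # single layer name -> Wilcoxon p-value

    @property
    def fold_accuracies(self) -> list[float]:
        return self.cv.test_accuracies

    @property
    def consistency(self) -> dict[VariableRef, int]:
        return self.cv.consistency


def _qualified(ref: VariableRef) -> str:
    if ref.layer is None:
        raise ValueError(f"variable {ref} is not bound to a layer")
    return f"{ref.layer}::{ref.feature_id}"


def _build_pool(
    columns: list[tuple[str, np.ndarray]], template: OmicsDataset
) -> OmicsDataset:
    names = [name for name, _ in columns]
    values = np.column_stack([col for _, col in columns])
    return OmicsDataset(
        layer=POOLED_LAYER_NAME,
        sample_ids=template.sample_ids,
        feature_names=tuple(names),
        values=values,
        labels=template.labels,
    )


def _pool_variable_sets(
    variable_sets: dict[str, set[VariableRef]], datasets: dict[str, OmicsDataset]
) -> OmicsDataset:
    template = next(iter(datasets.values()))
    sample_ids = template.sample_ids
    for layer, ds in datasets.items():
        if ds.sample_ids != sample_ids:
            raise ValueError(f"layer {layer!r} is not sample-aligned with the others")
    columns: list[tuple[str, np.ndarray]] = []
    seen: set[str] = set()
    for layer, ds in datasets.items():
        position = {name: i for i, name in enumerate(ds.feature_names)}
        refs = sorted(variable_sets.get(layer, set()), key=lambda r: position.get(r.feature_id, -1))
        for ref in refs:
            if ref.feature_id not in position:
                raise KeyError(
                    f"best-model variable {ref.feature_id!r} missing from layer {layer!r}"
                )
            name = _qualified(ref)
            if name in seen:
                continue
            seen.add(name)
            columns.append((name, ds.values[:, position[ref.feature_id]]))
    if not columns:
        raise ValueError("no variables to pool")
    return _build_pool(columns, template)


def pool_best_variables(
    best_models: dict[str, NetworkModel], datasets: dict[str, OmicsDataset]
) -> OmicsDataset:
    """Union of each layer's selected best-model variables, layer-qualified."""
    variable_sets = {
        layer: set(model.variables) for layer, model in best_models.items()
    }
    return _pool_variable_sets(variable_sets, datasets)


def pool_fold_best_variables(
    cv_results: dict[str, CvResult], datasets: dict[str, OmicsDataset]
) -> OmicsDataset:
    """Wider pool: the union over every fold's best model, per layer."""
    variable_sets: dict[str, set[VariableRef]] = {}
    for layer, cv in cv_results.items():
        refs: set[VariableRef] = set()
        for fr in cv.per_fold:
            refs |= cv_result_layer_vars(fr.model, layer)
        variable_sets[layer] = refs
    return _pool_variable_sets(variable_sets, datasets)


def cv_result_layer_vars(model: NetworkModel, layer: str) -> set[VariableRef]:
    return {ref for ref in model.variables if ref.layer == layer}


def pool_layers(datasets: dict[str, OmicsDataset]) -> OmicsDataset:
    """All features of all layers in one matrix (layer-qualified names)."""
    template = next(iter(datasets.values()))
    for layer, ds in datasets.items():
        if ds.sample_ids != template.sample_ids:
            raise ValueError(f"layer {layer!r} is not sample-aligned with the others")
    columns = [
        (f"{ds.layer}::{name}", ds.values[:, j])
        for ds in datasets.values()
        for j, name in enumerate(ds.feature_names)
    ]
    return _build_pool(columns, template)


def run_integration(
    pooled: OmicsDataset,
    grammar: Grammar,
    config: EvolutionConfig,
    single_layer_results: dict[str, CvResult] | None = None,
    k: int = 5,
    folds: FoldAssignment | None = None,
    filter_config: EvolutionConfig | None = None,
    filter_fraction: float | None = None,
    n_jobs: int = 1,
) -> IntegrationResult:
    """Cross-validate the search on the pooled dataset and compare it with
    each single-layer model (two-sided exact Wilcoxon on paired fold
    accuracies; pass the shared ``folds`` for the pairing to be valid)."""
    if pooled.n_features == 0:
        raise ValueError("pooled dataset has no features")
    cv = run_cv(
        pooled,
        grammar,
        config,
        k=k,
        folds=folds,
        filter_config=filter_config,
        filter_fraction=filter_fraction,
        n_jobs=n_jobs,
    )
    comparisons: dict[str, float] = {}
    if single_layer_results:
        for layer, layer_cv in single_layer_results.items():
            comparisons[layer] = wilcoxon_signed_rank_exact(
                cv.test_accuracies, layer_cv.test_accuracies, sides="two"
            )
    return IntegrationResult(final_model=cv.selected_model, cv=cv, comparisons=comparisons)
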