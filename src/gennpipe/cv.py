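"""Stratified 5-fold cross-validation, best-model selection, consistency.

Each fold trains a search on the other k-1 folds and scores the winning
network on the held-out fold.  The "best model" of a run is the model
identified the most across folds, where model identity is equality of
variable sets (exact tree equality would almost never repeat); variable
consistency reports, per variable, how many folds' best models contain
it.  Feature standardisation and (optionally) the frequency filter are
re-fit inside each training fold, so held-out samples never influence
the search.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .data_io import OmicsDataset, standardize_features
from .evolution import EvolutionConfig, run_search
from .grammar import Grammar
from .metrics import balanced_accuracy_from_labels
from .model import NetworkModel, VariableRef, bind_variables, predict_matrix

__all__ = [
    "FoldAssignment",
    "FoldResult",
    "CvResult",
    "split_folds",
    "run_cv",
    "select_best_model",
    "variable_consistency",
    "derive_seed",
]


def derive_seed(seed: int, *key: int) -> int:
    """A stable child seed (< 2^31) for a keyed sub-computation."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class FoldAssignment:
    fold_of_sample: dict[str, int]
    k: int

    def test_index(self, fold: int, sample_ids: Sequence[str]) -> np.ndarray:
        return np.asarray([i for i, s in enumerate(sample_ids) if self.fold_of_sample[s] == fold])

    def train_index(self, fold: int, sample_ids: Sequence[str]) -> np.ndarray:
        return np.asarray([i for i, s in enumerate(sample_ids) if self.fold_of_sample[s] != fold])


def split_folds(sample_ids: Sequence[str], labels, k: int, seed: int) -> FoldAssignment:
    """Stratified, seed-reproducible assignment; fold sizes differ by <= 1."""
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = np.asarray(labels)
    for cls in (0, 1):
        if int((labels == cls).sum()) < k:
            raise ValueError(f"class {cls} has fewer than k={k} samples")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of_sample: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(len(labels)), labels)):
        for i in test_idx:
            fold_of_sample[sample_ids[i]] = fold
    return FoldAssignment(fold_of_sample=fold_of_sample, k=k)


@dataclass(frozen=True)
class FoldResult:
    model: NetworkModel  # bound to dataset feature names
    train_accuracy: float
    test_accuracy: float
    search_log_size: int = 0


@dataclass
class CvResult:
    per_fold: list[FoldResult]
    selected_model: NetworkModel
    consistency: dict[VariableRef, int]
    folds: FoldAssignment

    @property
    def mean_test_accuracy(self) -> float:
        return float(np.mean([f.test_accuracy for f in self.per_fold]))

    @property
    def test_accuracies(self) -> list[float]:
        return [f.test_accuracy for f in self.per_fold]


def run_cv(
    dataset: OmicsDataset,
    grammar: Grammar,
    config: EvolutionConfig,
    k: int = 5,
    folds: FoldAssignment | None = None,
    filter_config: EvolutionConfig | None = None,
    filter_fraction: float | None = None,
    n_jobs: int = 1,
) -> CvResult:
    """The per-layer protocol: (filter,) search, and test each fold's best.

    When ``filter_config`` and ``filter_fraction`` are given, the
    frequency filter runs inside each training fold before the modelling
    search, so retained features never depend on held-out samples.
    """
    from .filtering import filter_training_fold  # local import avoids a cycle

    if folds is None:
        folds = split_folds(dataset.sample_ids, dataset.labels, k, config.seed)
    per_fold: list[FoldResult] = []
    for fold in range(folds.k):
        tr = folds.train_index(fold, dataset.sample_ids)
        te = folds.test_index(fold, dataset.sample_ids)
        standardized = standardize_features(dataset, train_index=tr)
        fold_ds = standardized
        if filter_config is not None and filter_fraction is not None:
            retained = filter_training_fold(
                standardized.subset_samples(tr),
                grammar,
                dc_replace(filter_config, seed=derive_seed(config.seed, fold, 1)),
                filter_fraction,
                n_jobs=n_jobs,
            )
            fold_ds = standardized.select_features(retained)
        train_ds = fold_ds.subset_samples(tr)
        fold_config = dc_replace(config, seed=derive_seed(config.seed, fold, 0))
        result = run_search(train_ds, grammar, fold_config, n_jobs=n_jobs)
        best = result.best
        model = best.model
        test_ds = fold_ds.subset_samples(te)
        test_pred = predict_matrix(model, test_ds.values)
        test_accuracy = balanced_accuracy_from_labels(test_ds.labels, test_pred)
        bound = bind_variables(model, fold_ds.feature_refs)
        per_fold.append(
            FoldResult(
                model=bound,
                train_accuracy=best.fitness,
                test_accuracy=test_accuracy,
                search_log_size=len(result.log),
            )
        )
    return CvResult(
        per_fold=per_fold,
        selected_model=select_best_model(per_fold),
        consistency=variable_consistency([f.model for f in per_fold]),
        folds=folds,
    )


def select_best_model(per_fold: list[FoldResult]) -> NetworkModel:
    """The model identified the most across folds (identity = variable set).

    Frequency ties break by higher mean test accuracy, then smaller model
    size; the representative of the winning group is its highest-test-
    accuracy member.
    """
    if not per_fold:
        raise ValueError("need at least one fold result")
    groups: dict[frozenset, list[FoldResult]] = {}
    group_order: dict[frozenset, int] = {}
    for i, fr in enumerate(per_fold):
        key = fr.model.variables
        groups.setdefault(key, []).append(fr)
        group_order.setdefault(key, i)

    def group_rank(key: frozenset):
        members = groups[key]
        return (
            -len(members),
            -float(np.mean([m.test_accuracy for m in members])),
            min(m.model.size for m in members),
            group_order[key],  # deterministic final tie-break
        )

    winner = min(groups, key=group_rank)
    representative = max(groups[winner], key=lambda m: m.test_accuracy)
    return representative.model


def variable_consistency(models: Sequence[NetworkModel]) -> dict[VariableRef, int]:
    """How many fold-best models contain each variable (support only)."""
    counts: dict[VariableRef, int] = {}
    for model in models:
        for ref in model.variables:
            counts[ref] = counts.get(ref, 0) + 1
    return counts
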