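"""Reading, aligning, and standardizing omics matrices.

The on-disk dialect is tab-delimited text: first column is the sample id,
an optional ``class`` column carries the binary outcome (``0``/``1`` or
``short``/``long``, short-term survival coded 1), and every other column
is one numeric feature.  Missing cells use the token ``NA`` and are
imputed with the feature median.  Layers are aligned on the intersection
of their sample ids before any analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .model import VariableRef

__all__ = [
    "OmicsDataset",
    "DataFormatError",
    "read_dataset",
    "write_dataset",
    "align_samples",
    "standardize_features",
]

MISSING_TOKEN = "NA"
LABEL_COLUMN = "class"
_LABEL_MAP = {"0": 0, "1": 1, "long": 0, "short": 1}


class DataFormatError(ValueError):
    """Malformed input matrix (duplicate ids, bad labels, non-numeric cells)."""


@dataclass(frozen=True)
class OmicsDataset:
    """One genomic layer: a labelled samples x features matrix."""

    layer: str
    sample_ids: tuple[str, ...]
    feature_names: tuple[str, ...]
    values: np.ndarray  # (n_samples, n_features) float64
    labels: np.ndarray  # (n_samples,) int8 in {0, 1}

    def __post_init__(self) -> None:
        n, p = self.values.shape
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise DataFormatError("sample ids / labels do not match the matrix rows")
        if len(self.feature_names) != p:
            raise DataFormatError("feature names do not match the matrix columns")
        if len(set(self.sample_ids)) != n:
            raise DataFormatError("duplicate sample ids")
        if len(set(self.feature_names)) != p:
            raise DataFormatError("duplicate feature names within a layer")
        if not np.isfinite(self.values).all():
            raise DataFormatError("non-finite feature values after imputation")
        if not np.isin(self.labels, (0, 1)).all():
            raise DataFormatError("labels must be 0/1")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def feature_refs(self) -> list[VariableRef]:
        refs = []
        for name in self.feature_names:
            if "::" in name:  # pooled feature already tagged with its origin
                layer, _, feature = name.partition("::")
                refs.append(VariableRef(layer, feature))
            else:
                refs.append(VariableRef(self.layer, name))
        return refs

    def subset_samples(self, index) -> "OmicsDataset":
        index = np.asarray(index)
        return replace(
            self,
            sample_ids=tuple(np.asarray(self.sample_ids, dtype=object)[index]),
            values=self.values[index],
            labels=self.labels[index],
        )

    def select_features(self, names) -> "OmicsDataset":
        position = {name: i for i, name in enumerate(self.feature_names)}
        try:
            cols = [position[n] for n in names]
        except KeyError as exc:
            raise KeyError(f"feature {exc.args[0]!r} not in layer {self.layer!r}") from None
        return replace(
            self,
            feature_names=tuple(names),
            values=self.values[:, cols],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=list(self.sample_ids), columns=list(self.feature_names))
        df.insert(0, LABEL_COLUMN, self.labels)
        df.index.name = "sample"
        return df


def _parse_labels(raw: pd.Series, path) -> np.ndarray:
    labels = np.empty(raw.size, dtype=np.int8)
    for i, value in enumerate(raw.astype(str).str.strip().str.lower()):
        if value not in _LABEL_MAP:
            raise DataFormatError(
                f"{path}: row {raw.index[i]!r}: label {value!r} not in 0/1/short/long"
            )
        labels[i] = _LABEL_MAP[value]
    return labels


def read_dataset(
    path,
    layer: str,
    label_column: str = LABEL_COLUMN,
    labels_path=None,
) -> OmicsDataset:
    """Parse one tab-delimited layer matrix; labels inline or in a side file.

    A separate label file has two tab-separated columns (sample id, label)
    with a header row.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise DataFormatError(f"{path}: duplicate sample id {dup!r}")
    if labels_path is not None:
        lab = pd.read_csv(labels_path, sep="\t", dtype=str, index_col=0)
        missing = [s for s in df.index if s not in lab.index]
        if missing:
            raise DataFormatError(f"{labels_path}: no label for sample {missing[0]!r}")
        labels = _parse_labels(lab.iloc[:, 0].loc[df.index], labels_path)
    elif label_column in df.columns:
        labels = _parse_labels(df[label_column], path)
        df = df.drop(columns=[label_column])
    else:
        raise DataFormatError(f"{path}: no {label_column!r} column and no label file")

    values = np.empty(df.shape, dtype=np.float64)
    for j, col in enumerate(df.columns):
        cells = df[col].astype(str).str.strip()
        missing_mask = (cells == MISSING_TOKEN) | (cells == "") | (cells == "nan")
        try:
            numeric = pd.to_numeric(cells.where(~missing_mask, other=np.nan))
        except (ValueError, TypeError):
            bad = cells[~missing_mask & cells.apply(lambda v: not _is_number(v))]
            row = bad.index[0] if len(bad) else "?"
            raise DataFormatError(
                f"{path}: non-numeric cell at row {row!r}, column {col!r}"
            ) from None
        column = numeric.to_numpy(dtype=np.float64)
        if np.isnan(column).any():
            median = np.nanmedian(column)
            if np.isnan(median):
                raise DataFormatError(f"{path}: column {col!r} is entirely missing")
            column = np.where(np.isnan(column), median, column)
        values[:, j] = column
    return OmicsDataset(
        layer=layer,
        sample_ids=tuple(str(s) for s in df.index),
        feature_names=tuple(str(c) for c in df.columns),
        values=values,
        labels=labels,
    )


def _is_number(value: str) -> bool:
    try:
        float(value)
        return True
    except ValueError:
        return False


def write_dataset(dataset: OmicsDataset, path) -> None:
    dataset.to_frame().to_csv(path, sep="\t")


def align_samples(datasets: list[OmicsDataset]) -> list[OmicsDataset]:
    """Restrict all layers to their common samples, in one canonical order.

    The canonical order is the first layer's order restricted to the
    intersection.  Labels must agree across layers; idempotent.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    common = set(datasets[0].sample_ids)
    for ds in datasets[1:]:
        common &= set(ds.sample_ids)
    if not common:
        raise DataFormatError("no samples shared by all layers")
    order = [s for s in datasets[0].sample_ids if s in common]
    aligned = []
    for ds in datasets:
        position = {s: i for i, s in enumerate(ds.sample_ids)}
        idx = np.asarray([position[s] for s in order])
        aligned.append(ds.subset_samples(idx))
    reference = aligned[0].labels
    for ds in aligned[1:]:
        disagree = np.nonzero(ds.labels != reference)[0]
        if disagree.size:
            s = order[disagree[0]]
            raise DataFormatError(f"conflicting labels for sample {s!r} across layers")
    return aligned


def standardize_features(dataset: OmicsDataset, train_index=None) -> OmicsDataset:
    """Z-score each feature (sample s.d., ddof=1); zero variance maps to zeros.

    When ``train_index`` is given, the statistics come from those rows
    only and are applied to the whole matrix — the fold-aware form that
    keeps held-out samples out of the scaling.
    """
    X = dataset.values
    ref = X if train_index is None else X[np.asarray(train_index)]
    mean = ref.mean(axis=0)
    sd = ref.std(axis=0, ddof=1) if ref.shape[0] > 1 else np.zeros(X.shape[1])
    out = np.zeros_like(X)
    nonzero = sd > 0
    out[:, nonzero] = (X[:, nonzero] - mean[nonzero]) / sd[nonzero]
    return replace(dataset, values=out)
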