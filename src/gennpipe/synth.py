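"""Synthetic multi-layer datasets with planted effects.

Each layer is an independent standard-normal samples x features matrix
sharing one sample set.  A latent binary risk state is computed per
sample from the planted effects — a *main* effect is the indicator
``x > 0`` of its variable, an *xor_pair* is the exclusive-or of two such
indicators (same or different layers) — and the class label is drawn
Bernoulli(penetrance_high) when any effect's risk state is on, else
Bernoulli(penetrance_low).  Thresholding continuous features at zero
keeps the signal expressible both as a threshold rule and as a small
arithmetic network (for an xor pair, the sign of the product of the two
variables), while leaving each xor member with no marginal association —
the epistasis-style structure the search is meant to recover.

Defaults are the desk-scale study conditions used throughout: penetrances
(0.9, 0.1), four layers of 100 features, 500 samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import OmicsDataset

__all__ = [
    "PlantedEffect",
    "SimulationConfig",
    "generate",
    "bayes_accuracy",
]

DEFAULT_PENETRANCE_HIGH = 0.9
DEFAULT_PENETRANCE_LOW = 0.1


@dataclass(frozen=True)
class PlantedEffect:
    """A main effect (one variable) or an xor pair (two variables)."""

    kind: str  # "main" | "xor_pair"
    variables: tuple[tuple[str, int], ...]  # (layer name, feature index)
    penetrance_high: float = DEFAULT_PENETRANCE_HIGH
    penetrance_low: float = DEFAULT_PENETRANCE_LOW

    def __post_init__(self) -> None:
        if self.kind not in {"main", "xor_pair"}:
            raise ValueError(f"unknown effect kind {self.kind!r}")
        expected = 1 if self.kind == "main" else 2
        if len(self.variables) != expected:
            raise ValueError(f"{self.kind} effect takes {expected} variable(s)")
        if self.kind == "xor_pair" and self.variables[0] == self.variables[1]:
            raise ValueError("xor_pair needs two distinct variables")
        if not 0.0 <= self.penetrance_low < self.penetrance_high <= 1.0:
            raise ValueError("need 0 <= penetrance_low < penetrance_high <= 1")


@dataclass(frozen=True)
class SimulationConfig:
    n_samples: int = 500
    layers: tuple[tuple[str, int], ...] = (
        ("layer1", 100),
        ("layer2", 100),
        ("layer3", 100),
        ("layer4", 100),
    )
    effects: tuple[PlantedEffect, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 20:
            raise ValueError("n_samples must be >= 20")
        sizes = dict(self.layers)
        if len(sizes) != len(self.layers):
            raise ValueError("duplicate layer names")
        for effect in self.effects:
            for layer, index in effect.variables:
                if layer not in sizes:
                    raise ValueError(f"effect references unknown layer {layer!r}")
                if not 0 <= index < sizes[layer]:
                    raise ValueError(f"effect index {index} outside layer {layer!r}")


def _risk_states(config: SimulationConfig, features: dict[str, np.ndarray]) -> np.ndarray:
    """Per-sample indicator that at least one planted effect is on."""
    state = np.zeros(config.n_samples, dtype=bool)
    for effect in config.effects:
        if effect.kind == "main":
            layer, idx = effect.variables[0]
            on = features[layer][:, idx] > 0.0
        else:
            (la, ia), (lb, ib) = effect.variables
            on = (features[la][:, ia] > 0.0) ^ (features[lb][:, ib] > 0.0)
        state |= on
    return state


def generate(config: SimulationConfig) -> tuple[list[OmicsDataset], tuple[PlantedEffect, ...]]:
    """Draw the layers and labels; returns the datasets and the ground truth."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    features = {
        name: rng.standard_normal((config.n_samples, p)) for name, p in config.layers
    }
    if config.effects:
        penetrances = {(e.penetrance_high, e.penetrance_low) for e in config.effects}
        if len(penetrances) > 1:
            raise ValueError("all effects must share one penetrance pair")
        state = _risk_states(config, features)
        high = config.effects[0].penetrance_high
        low = config.effects[0].penetrance_low
        prob = np.where(state, high, low)
    else:
        prob = np.full(config.n_samples, 0.5)
    labels = (rng.random(config.n_samples) < prob).astype(np.int8)
    sample_ids = tuple(f"S{i:05d}" for i in range(config.n_samples))
    datasets = [
        OmicsDataset(
            layer=name,
            sample_ids=sample_ids,
            feature_names=tuple(f"{name}_f{j:04d}" for j in range(p)),
            values=features[name],
            labels=labels,
        )
        for name, p in config.layers
    ]
    return datasets, config.effects


def bayes_accuracy(config: SimulationConfig) -> float:
    """Balanced accuracy of the oracle that predicts class 1 on risk state 1.

    Supported for single-effect configurations, where the risk state is on
    for exactly half the feature space (threshold-at-zero symmetry):
    sensitivity = ph / (ph + pl) and specificity = (1-pl) / ((1-pl) + (1-ph)),
    which reduces to ph (= (ph + 1 - pl) / 2) whenever ph + pl = 1.
    """
    if len(config.effects) != 1:
        raise ValueError("bayes_accuracy supports single-effect configurations only")
    high = config.effects[0].penetrance_high
    low = config.effects[0].penetrance_low
    p1 = 0.5 * (high + low)  # prevalence with P(risk state) = 1/2
    if p1 in (0.0, 1.0):
        raise ValueError("degenerate penetrances give a one-class outcome")
    sensitivity = 0.5 * high / p1
    specificity = 0.5 * (1.0 - low) / (1.0 - p1)
    return 0.5 * (sensitivity + specificity)


def planted_feature_names(
    effects: tuple[PlantedEffect, ...], datasets: list[OmicsDataset]
) -> list[tuple[str, str]]:
    """(layer, feature name) of every planted variable, for reporting."""
    by_layer = {ds.layer: ds for ds in datasets}
    out = []
    for effect in effects:
        for layer, idx in effect.variables:
            out.append((layer, by_layer[layer].feature_names[idx]))
    return out
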