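"""Evolved neural-network models: weighted activation-node trees.

A model is a tree of activation nodes (PADD, PSUB, PMULT, PDIV) whose
inputs are (weight, child) pairs; leaves reference input variables.  The
tree is the phenotype decoded from a codon genome by the grammar engine,
and it classifies a sample by thresholding its raw arithmetic output at
zero.  There is no squashing function and no gradient step: weights and
topology are fixed at decode time and optimised only by the evolutionary
search.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Union

import numpy as np

__all__ = [
    "OPERATORS",
    "VariableRef",
    "NetworkNode",
    "NetworkModel",
    "MissingVariableError",
    "ExpressionParseError",
    "protected_divide",
    "evaluate",
    "evaluate_matrix",
    "predict",
    "predict_matrix",
    "to_expression_string",
    "parse_expression_string",
]

OPERATORS = ("PADD", "PSUB", "PMULT", "PDIV")

#: |denominator| below this triggers the protected-division fallback.
DIVISION_EPS = 1e-10
#: value substituted for a protected division or a non-finite intermediate
PROTECTION_VALUE = 1.0


class MissingVariableError(KeyError):
    """A model variable is absent from the supplied feature map."""

    def __init__(self, ref: "VariableRef"):
        super().__init__(str(ref))
        self.ref = ref

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"feature {self.ref} not present in the feature map"


class ExpressionParseError(ValueError):
    """Malformed expression text; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class VariableRef:
    """Reference to one input variable, optionally tagged with its omics layer.

    Unbound (positional) references use ``layer=None`` and a feature id of
    the form ``"V<k>"`` (1-based), as produced by the grammar mapper; they
    are re-bound to dataset feature names before reporting.
    """

    layer: str | None
    feature_id: str

    @property
    def is_positional(self) -> bool:
        return self.layer is None and re.fullmatch(r"V[1-9][0-9]*", self.feature_id) is not None

    @property
    def position(self) -> int:
        """0-based column index for a positional reference."""
        if not self.is_positional:
            raise ValueError(f"{self} is not a positional reference")
        return int(self.feature_id[1:]) - 1

    def __str__(self) -> str:
        if self.layer is None:
            return self.feature_id
        return f"{self.layer}::{self.feature_id}"


Child = Union["NetworkNode", VariableRef]


@dataclass(frozen=True)
class NetworkNode:
    """One activation node: an operator over 2-3 weighted inputs."""

    operator: str
    inputs: tuple[tuple[float, Child], ...]

    def __post_init__(self) -> None:
        if self.operator not in OPERATORS:
            raise ValueError(f"unknown operator {self.operator!r}")
        if not 2 <= len(self.inputs) <= 3:
            raise ValueError("a node takes 2 or 3 weighted inputs")
        for w, _ in self.inputs:
            if not np.isfinite(w):
                raise ValueError("weights must be finite")


@dataclass(frozen=True)
class NetworkModel:
    """A complete network: root node plus derived variable set and size."""

    root: NetworkNode
    variables: frozenset[VariableRef] = field(compare=False)
    size: int = field(compare=False)

    @classmethod
    def from_root(cls, root: NetworkNode) -> "NetworkModel":
        variables: set[VariableRef] = set()
        size = 0
        for item in _walk(root):
            if isinstance(item, VariableRef):
                variables.add(item)
            else:
                size += 1
        return cls(root=root, variables=frozenset(variables), size=size)

    @property
    def depth(self) -> int:
        return _depth(self.root)


def _walk(node: Child) -> Iterator[Child]:
    yield node
    if isinstance(node, NetworkNode):
        for _, child in node.inputs:
            yield from _walk(child)


def _depth(node: Child) -> int:
    if isinstance(node, VariableRef):
        return 0
    return 1 + max(_depth(child) for _, child in node.inputs)


def protected_divide(numerator: float, denominator: float) -> float:
    """Total division: near-zero denominators (and overflow) yield 1.0."""
    if abs(denominator) < DIVISION_EPS:
        return PROTECTION_VALUE
    out = numerator / denominator
    if not np.isfinite(out):
        return PROTECTION_VALUE
    return float(out)


def _guard(value: float) -> float:
    return float(value) if np.isfinite(value) else PROTECTION_VALUE


def _lookup(features: Mapping, ref: VariableRef) -> float:
    if ref in features:
        value = features[ref]
    elif ref.feature_id in features:
        value = features[ref.feature_id]
    else:
        raise MissingVariableError(ref)
    value = float(value)
    if not np.isfinite(value):
        raise ValueError(f"feature {ref} has a non-finite value")
    return value


def _eval_node(node: Child, features: Mapping) -> float:
    if isinstance(node, VariableRef):
        return _lookup(features, node)
    terms = [w * _eval_node(child, features) for w, child in node.inputs]
    terms = [_guard(t) for t in terms]
    op = node.operator
    if op == "PADD":
        out = sum(terms)
    elif op == "PSUB":
        out = terms[0]
        for t in terms[1:]:
            out -= t
    elif op == "PMULT":
        out = terms[0]
        for t in terms[1:]:
            out = _guard(out * t)
    else:  # PDIV, left fold
        out = terms[0]
        for t in terms[1:]:
            out = protected_divide(out, t)
    return _guard(out)


def evaluate(model: NetworkModel, features: Mapping) -> float:
    """Evaluate the network on one sample's feature map; always finite."""
    return _eval_node(model.root, features)


def predict(model: NetworkModel, features: Mapping) -> int:
    """Binary class: 1 when the raw network output is >= 0, else 0."""
    return 1 if evaluate(model, features) >= 0.0 else 0


def _column_of(ref: VariableRef, columns) -> int:
    if columns is None:
        return ref.position
    if ref in columns:
        return columns[ref]
    if ref.feature_id in columns:
        return columns[ref.feature_id]
    raise MissingVariableError(ref)


def _eval_node_matrix(node: Child, X: np.ndarray, columns) -> np.ndarray:
    if isinstance(node, VariableRef):
        return X[:, _column_of(node, columns)]
    terms = [w * _eval_node_matrix(child, X, columns) for w, child in node.inputs]
    op = node.operator
    if op == "PADD":
        out = terms[0] + terms[1]
        for t in terms[2:]:
            out = out + t
    elif op == "PSUB":
        out = terms[0] - terms[1]
        for t in terms[2:]:
            out = out - t
    elif op == "PMULT":
        out = terms[0] * terms[1]
        for t in terms[2:]:
            out = out * t
    else:  # PDIV
        out = terms[0]
        for t in terms[1:]:
            small = np.abs(t) < DIVISION_EPS
            with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
                out = np.where(small, PROTECTION_VALUE, out / np.where(small, 1.0, t))
    bad = ~np.isfinite(out)
    if bad.any():
        out = np.where(bad, PROTECTION_VALUE, out)
    return out


def evaluate_matrix(model: NetworkModel, X: np.ndarray, columns=None) -> np.ndarray:
    """Vectorised evaluation over a samples x features matrix.

    ``columns`` maps variable references (or feature ids) to column
    indices; when omitted, positional references ``V<k>`` address column
    ``k-1`` directly.
    """
    with np.errstate(over="ignore", invalid="ignore"):
        out = _eval_node_matrix(model.root, np.asarray(X, dtype=np.float64), columns)
    return np.asarray(out, dtype=np.float64)


def predict_matrix(model: NetworkModel, X: np.ndarray, columns=None) -> np.ndarray:
    return (evaluate_matrix(model, X, columns) >= 0.0).astype(np.int8)


def _format_weight(w: float) -> str:
    s = f"{w:.10g}"
    if "." not in s and "e" not in s and "E" not in s:
        s += ".0"
    return s


def _node_to_string(node: Child) -> str:
    if isinstance(node, VariableRef):
        return str(node)
    args = ",".join(f"{_format_weight(w)}*{_node_to_string(child)}" for w, child in node.inputs)
    return f"{node.operator}({args})"


def to_expression_string(model: NetworkModel) -> str:
    """Canonical text form ``OP(w*arg,w*arg[,w*arg])``; inner weights explicit."""
    return _node_to_string(model.root)


# punctuation, then numbers, then general names (layers/features/operators)
_TOKEN_RE = re.compile(r"\s*(\(|\)|,|\*|[-+]?[0-9]+\.?[0-9]*(?:[eE][-+]?[0-9]+)?|[^\s(),*]+)")


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def error(self, message: str) -> ExpressionParseError:
        return ExpressionParseError(message, self.pos)

    def peek(self) -> str | None:
        m = _TOKEN_RE.match(self.text, self.pos)
        return m.group(1) if m else None

    def take(self) -> str:
        m = _TOKEN_RE.match(self.text, self.pos)
        if not m:
            raise self.error("unexpected end of input")
        self.pos = m.end()
        return m.group(1)

    def expect(self, token: str) -> None:
        got = self.take()
        if got != token:
            raise self.error(f"expected {token!r}, found {got!r}")

    def parse_node(self) -> NetworkNode:
        op = self.take()
        if op not in OPERATORS:
            raise self.error(f"expected an operator, found {op!r}")
        self.expect("(")
        inputs = [self.parse_weighted_input()]
        while self.peek() == ",":
            self.take()
            inputs.append(self.parse_weighted_input())
        self.expect(")")
        if not 2 <= len(inputs) <= 3:
            raise self.error(f"{op} takes 2 or 3 inputs, found {len(inputs)}")
        return NetworkNode(op, tuple(inputs))

    def parse_weighted_input(self) -> tuple[float, Child]:
        tok = self.take()
        try:
            weight = float(tok)
        except ValueError:
            raise self.error(f"expected a weight, found {tok!r}") from None
        self.expect("*")
        if self.peek() in OPERATORS:
            return weight, self.parse_node()
        return weight, self.parse_variable()

    def parse_variable(self) -> VariableRef:
        tok = self.take()
        if tok in {"(", ")", ",", "*"}:
            raise self.error(f"expected a variable name, found {tok!r}")
        if "::" in tok:
            layer, _, feature = tok.partition("::")
            return VariableRef(layer, feature)
        return VariableRef(None, tok)


def parse_expression_string(text: str) -> NetworkModel:
    """Parse the canonical expression form back into a model (round trip)."""
    parser = _Parser(text)
    root = parser.parse_node()
    if parser.pos != len(text.rstrip()):
        raise parser.error("trailing characters after expression")
    return NetworkModel.from_root(root)


def bind_variables(model: NetworkModel, refs: "list[VariableRef]") -> NetworkModel:
    """Replace positional references V<k> by the k-th entry of ``refs``."""

    def rebind(node: Child) -> Child:
        if isinstance(node, VariableRef):
            return refs[node.position] if node.is_positional else node
        return NetworkNode(node.operator, tuple((w, rebind(c)) for w, c in node.inputs))

    return NetworkModel.from_root(rebind(model.root))
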