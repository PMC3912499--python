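"""Specialised decoder for the default network grammar.

Decodes codons by direct recursive descent in the exact codon order of
the generic leftmost derivation, producing the expression string and the
node tree in one pass.  Only valid for the stock grammar; the engine
falls back to the generic decoder for user-supplied grammars.  Tests
assert codon-for-codon equivalence with the generic path.
"""

from __future__ import annotations

from .model import NetworkNode, VariableRef, OPERATORS

__all__ = ["decode_default"]

# weight lookup tables: sign, leading digit, decimal digit
_WSTR = [
    [[f"{'-' if s else ''}{a}.{b}" for b in range(10)] for a in range(10)]
    for s in (0, 1)
]
_WVAL = [[[float(_WSTR[s][a][b]) for b in range(10)] for a in range(10)] for s in (0, 1)]

_REFS: list[VariableRef] = []
_REF_STR: list[str] = []


def _ref(index: int) -> VariableRef:
    while len(_REFS) <= index:
        _REFS.append(VariableRef(None, f"V{len(_REFS) + 1}"))
        _REF_STR.append(f"V{len(_REF_STR) + 1}")
    return _REFS[index]


def _node(operator: str, inputs: tuple) -> NetworkNode:
    # trusted construction: operators and arities are grammar-guaranteed
    node = object.__new__(NetworkNode)
    object.__setattr__(node, "operator", operator)
    object.__setattr__(node, "inputs", inputs)
    return node


class _Exhausted(Exception):
    pass


def decode_default(
    codons: tuple[int, ...], n_variables: int, max_wraps: int = 2
) -> tuple[str | None, NetworkNode | None, int]:
    """Returns (expression, root, codons_used); (None, None, used) when the
    wrap budget runs out."""
    L = len(codons)
    limit = L * (max_wraps + 1)
    state = [0]  # consumed count, shared across the recursion

    def take() -> int:
        i = state[0]
        if i >= limit:
            raise _Exhausted
        state[0] = i + 1
        return codons[i] if i < L else codons[i % L]

    parts: list[str] = []

    def winput():
        alt = take() & 1
        sign = take() & 1
        a = take() % 10
        b = take() % 10
        parts.append(_WSTR[sign][a][b])
        parts.append("*")
        if alt == 0:
            if n_variables > 1:
                idx = take() % n_variables
            else:
                idx = 0
            ref = _ref(idx)
            parts.append(_REF_STR[idx])
            return _WVAL[sign][a][b], ref
        return _WVAL[sign][a][b], node()

    def node() -> NetworkNode:
        arity = 2 + (take() & 1)
        op = OPERATORS[take() & 3]
        parts.append(op)
        parts.append("(")
        first = winput()
        if arity == 2:
            parts.append(",")
            inputs = (first, winput())
        else:
            parts.append(",")
            second = winput()
            parts.append(",")
            inputs = (first, second, winput())
        parts.append(")")
        return _node(op, inputs)

    try:
        root = node()
    except _Exhausted:
        return None, None, state[0]
    return "".join(parts), root, state[0]
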