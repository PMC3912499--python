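"""Naive recursive reference decoder, independent of the package's mapper.

Parses the BNF text on its own and expands the derivation recursively;
used only as an oracle to cross-check the production decoders.
"""

from __future__ import annotations


def parse_bnf(text: str) -> dict[str, list[list[str]]]:
    rules: dict[str, list[list[str]]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        lhs, rhs = line.split("::=")
        rules[lhs.strip()] = [alt.split() for alt in rhs.split("|")]
    return rules


class _OutOfCodons(Exception):
    pass


def reference_decode(
    codons: tuple[int, ...],
    bnf_text: str,
    start: str,
    n_variables: int,
    max_wraps: int = 2,
) -> str | None:
    rules = parse_bnf(bnf_text)
    reads = {"i": 0}
    total = len(codons) * (max_wraps + 1)

    def next_codon() -> int:
        if reads["i"] >= total:
            raise _OutOfCodons
        value = codons[reads["i"] % len(codons)]
        reads["i"] += 1
        return value

    def expand(symbol: str) -> str:
        if symbol == "<var>":
            if n_variables > 1:
                index = next_codon() % n_variables
            else:
                index = 0
            return f"V{index + 1}"
        if symbol not in rules:
            return symbol
        alternatives = rules[symbol]
        if len(alternatives) == 1:
            chosen = alternatives[0]
        else:
            chosen = alternatives[next_codon() % len(alternatives)]
        return "".join(expand(child) for child in chosen)

    try:
        return expand(start)
    except _OutOfCodons:
        return None
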