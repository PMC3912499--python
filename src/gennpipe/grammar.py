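"""BNF grammar and genotype-to-phenotype mapping for grammatical evolution.

A genome is a sequence of 8-bit codons.  Decoding performs a leftmost
derivation from the grammar's start symbol: each rule with two or more
alternatives consumes one codon and picks alternative ``codon mod k``;
single-alternative rules consume nothing.  When the genome runs out the
read head wraps to the start, at most ``max_wraps`` times; an individual
whose derivation is still unfinished after that is invalid.

The default grammar derives weighted activation-node networks over the
operators PADD/PSUB/PMULT/PDIV with node arity 2 or 3 and decimal weights
in -9.9..9.9 (step 0.1).  The special non-terminal ``<var>`` expands to an
input variable ``V1..Vp`` where ``p`` is fixed at mapping time; with 8-bit
codons, a single mapping can address at most 256 variables, which is ample
after the filtering stage at the problem sizes this package targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

from .model import NetworkModel, parse_expression_string

__all__ = [
    "Grammar",
    "Genome",
    "MappingResult",
    "GrammarError",
    "VAR_SYMBOL",
    "DEFAULT_GRAMMAR_BNF",
    "build_default_grammar",
    "grammar_from_bnf",
    "grammar_to_bnf",
    "choose_production",
    "derive_expression",
    "map_genome",
    "random_functional_genome",
]

#: special non-terminal: expands to one of V1..Vp, p set at mapping time
VAR_SYMBOL = "<var>"

DEFAULT_GRAMMAR_BNF = """\
<start> ::= <node>
<node> ::= <op> ( <winput> , <winput> ) | <op> ( <winput> , <winput> , <winput> )
<op> ::= PADD | PSUB | PMULT | PDIV
<winput> ::= <const> * <var> | <const> * <node>
<const> ::= <digit> . <digit> | - <digit> . <digit>
<digit> ::= 0 | 1 | 2 | 3 | 4 | 5 | 6 | 7 | 8 | 9
"""


class GrammarError(ValueError):
    """An ill-formed grammar: undefined symbols or inescapable recursion."""


def _is_nonterminal(symbol: str) -> bool:
    return symbol.startswith("<") and symbol.endswith(">")


@dataclass(frozen=True)
class Grammar:
    """Ordered production rules; alternatives are indexed 0..k-1."""

    rules: dict[str, tuple[tuple[str, ...], ...]]
    start_symbol: str = "<start>"

    def __post_init__(self) -> None:
        if self.start_symbol not in self.rules:
            raise GrammarError(f"start symbol {self.start_symbol} has no rule")
        for name, alternatives in self.rules.items():
            if not alternatives:
                raise GrammarError(f"non-terminal {name} has no alternatives")
            for alt in alternatives:
                for sym in alt:
                    if _is_nonterminal(sym) and sym != VAR_SYMBOL and sym not in self.rules:
                        raise GrammarError(f"undefined non-terminal {sym} in rule {name}")
        self.min_depths  # raises if some non-terminal cannot terminate

    @cached_property
    def min_depths(self) -> dict[str, int]:
        """Minimum derivation-tree height per non-terminal (terminals: 0).

        Computed as a fixpoint; a non-terminal that never converges is
        inescapably recursive and rejected.
        """
        depths: dict[str, float] = {name: float("inf") for name in self.rules}
        depths[VAR_SYMBOL] = 1.0
        for _ in range(len(self.rules) + 2):
            changed = False
            for name, alternatives in self.rules.items():
                best = depths[name]
                for alt in alternatives:
                    d = 1 + max(
                        (depths.get(s, float("inf")) for s in alt if _is_nonterminal(s)),
                        default=0,
                    )
                    best = min(best, d)
                if best < depths[name]:
                    depths[name] = best
                    changed = True
            if not changed:
                break
        bad = [name for name, d in depths.items() if not np.isfinite(d)]
        if bad:
            raise GrammarError(f"inescapably recursive non-terminals: {bad}")
        return {name: int(d) for name, d in depths.items()}

    @cached_property
    def _compiled(self) -> dict[str, tuple[int, tuple[tuple[str, ...], ...]]]:
        """Per-rule (alternative count, alternatives with symbols reversed);
        reversed symbol order feeds the decoder's stack directly."""
        return {
            name: (len(alts), tuple(tuple(reversed(alt)) for alt in alts))
            for name, alts in self.rules.items()
        }

    @cached_property
    def alt_min_depths(self) -> dict[str, tuple[int, ...]]:
        """Minimum derivation height of each alternative of each rule."""
        depths = self.min_depths
        out: dict[str, tuple[int, ...]] = {}
        for name, alternatives in self.rules.items():
            out[name] = tuple(
                1 + max((depths[s] for s in alt if _is_nonterminal(s)), default=0)
                for alt in alternatives
            )
        return out


def grammar_from_bnf(text: str, start_symbol: str | None = None) -> Grammar:
    """Parse a plain-text BNF: one rule per line, ``::=`` and ``|`` separators.

    Symbols are whitespace-separated; ``<...>`` marks non-terminals.
    """
    rules: dict[str, tuple[tuple[str, ...], ...]] = {}
    first = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "::=" not in line:
            raise GrammarError(f"line {lineno}: missing '::='")
        lhs, _, rhs = line.partition("::=")
        name = lhs.strip()
        if not _is_nonterminal(name):
            raise GrammarError(f"line {lineno}: left-hand side {name!r} is not <...>")
        if name in rules:
            raise GrammarError(f"line {lineno}: duplicate rule {name}")
        alternatives = tuple(
            tuple(alt.split()) for alt in rhs.split("|") if alt.split()
        )
        if not alternatives:
            raise GrammarError(f"line {lineno}: rule {name} has no alternatives")
        rules[name] = alternatives
        if first is None:
            first = name
    if not rules:
        raise GrammarError("empty grammar")
    return Grammar(rules=rules, start_symbol=start_symbol or first)


def grammar_to_bnf(grammar: Grammar) -> str:
    lines = []
    for name, alternatives in grammar.rules.items():
        alts = " | ".join(" ".join(alt) for alt in alternatives)
        lines.append(f"{name} ::= {alts}")
    return "\n".join(lines) + "\n"


def build_default_grammar() -> Grammar:
    """The fixed network grammar (structurally identical on every call)."""
    return grammar_from_bnf(DEFAULT_GRAMMAR_BNF)


@dataclass(frozen=True)
class Genome:
    """Heritable material: a non-empty sequence of integer codons in [0, 255]."""

    codons: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.codons) == 0:
            raise ValueError("a genome needs at least one codon")
        for c in self.codons:
            if not 0 <= c <= 255:
                raise ValueError(f"codon {c} outside [0, 255]")

    def __len__(self) -> int:
        return len(self.codons)

    @classmethod
    def _from_trusted(cls, codons: tuple[int, ...]) -> "Genome":
        """Skip validation for codons produced by internal operators."""
        genome = object.__new__(cls)
        object.__setattr__(genome, "codons", codons)
        return genome


@dataclass(frozen=True)
class MappingResult:
    """Outcome of decoding one genome; failure is a value, not an exception."""

    model: NetworkModel | None
    valid: bool
    codons_used: int
    wraps_used: int
    expression: str | None = None


def choose_production(codon: int, n_alternatives: int) -> int:
    """The standard grammatical-evolution modulo rule."""
    if n_alternatives < 1:
        raise ValueError("n_alternatives must be >= 1")
    if not 0 <= codon <= 255:
        raise ValueError(f"codon {codon} outside [0, 255]")
    return codon % n_alternatives


def derive_expression(
    codons: tuple[int, ...],
    grammar: Grammar,
    n_variables: int,
    max_wraps: int = 2,
) -> tuple[str | None, int, int]:
    """Leftmost derivation to a terminal string.

    Returns ``(expression, codons_used, wraps_used)``; the expression is
    ``None`` when the wrap budget is exhausted before the derivation
    finishes.  Termination is guaranteed: grammar validation rejects
    non-terminals that cannot reach a finite string, so every unbounded
    expansion path consumes codons and hits the wrap limit.
    """
    if n_variables < 1:
        raise ValueError("n_variables must be >= 1")
    L = len(codons)
    limit = L * (max_wraps + 1)
    consumed = 0
    compiled = grammar._compiled
    var_symbol = VAR_SYMBOL
    stack = [grammar.start_symbol]
    out: list[str] = []

    def wraps(used: int) -> int:
        return 0 if used <= L else (used - 1) // L

    while stack:
        sym = stack.pop()
        rule = compiled.get(sym)
        if rule is None:
            if sym != var_symbol:
                if sym.startswith("<") and sym.endswith(">"):
                    raise GrammarError(f"undefined non-terminal {sym}")
                out.append(sym)
                continue
            if n_variables > 1:
                if consumed >= limit:
                    return None, consumed, wraps(consumed)
                idx = codons[consumed] if consumed < L else codons[consumed % L]
                idx %= n_variables
                consumed += 1
            else:
                idx = 0
            out.append(f"V{idx + 1}")
            continue
        k, alternatives = rule
        if k > 1:
            if consumed >= limit:
                return None, consumed, wraps(consumed)
            choice = (codons[consumed] if consumed < L else codons[consumed % L]) % k
            consumed += 1
        else:
            choice = 0
        stack.extend(alternatives[choice])
    return "".join(out), consumed, wraps(consumed)


def map_genome(
    genome: Genome,
    grammar: Grammar,
    n_variables: int,
    max_wraps: int = 2,
) -> MappingResult:
    """Decode a genome into a network model; a pure function of its inputs."""
    expression, consumed, wraps_used = derive_expression(
        genome.codons, grammar, n_variables, max_wraps
    )
    if expression is None:
        return MappingResult(None, False, consumed, wraps_used)
    model = parse_expression_string(expression)
    return MappingResult(model, True, consumed, wraps_used, expression=expression)


def _encode_choice(choice: int, n_alternatives: int, rng: np.random.Generator) -> int:
    """A uniformly random codon c in [0,255] with c mod n == choice."""
    span = (255 - choice) // n_alternatives + 1
    return choice + n_alternatives * int(rng.integers(span))


def random_functional_genome(
    grammar: Grammar,
    n_variables: int,
    max_depth: int,
    rng: np.random.Generator,
) -> Genome:
    """Grow a random finite derivation tree and emit codons reproducing it.

    Alternatives whose minimum derivation height exceeds the remaining
    depth budget are excluded (falling back to the shallowest alternative
    when none fits), so the genome always decodes to a valid network with
    zero wraps.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    alt_depths = grammar.alt_min_depths
    codons: list[int] = []
    # stack of (symbol, remaining depth); reversed push keeps leftmost order,
    # matching the codon order the mapper consumes
    stack: list[tuple[str, int]] = [(grammar.start_symbol, max_depth)]
    while stack:
        sym, depth_left = stack.pop()
        if not _is_nonterminal(sym):
            continue
        if sym == VAR_SYMBOL:
            k = min(n_variables, 256)
            idx = int(rng.integers(k))
            if n_variables > 1:
                codons.append(_encode_choice(idx, n_variables, rng) if n_variables <= 256 else idx)
            continue
        depths = alt_depths[sym]
        eligible = [i for i, d in enumerate(depths) if d <= depth_left]
        if not eligible:
            eligible = [int(np.argmin(depths))]
        choice = eligible[int(rng.integers(len(eligible)))]
        k = len(depths)
        if k > 1:
            codons.append(_encode_choice(choice, k, rng))
        for child in reversed(grammar.rules[sym][choice]):
            stack.append((child, depth_left - 1))
    if not codons:
        codons = [0]  # grammar with no choices: any codon decodes it
    return Genome(tuple(codons))
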