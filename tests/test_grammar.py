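import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gennpipe.grammar import (
    DEFAULT_GRAMMAR_BNF,
    Genome,
    GrammarError,
    build_default_grammar,
    choose_production,
    derive_expression,
    grammar_from_bnf,
    grammar_to_bnf,
    map_genome,
    random_functional_genome,
)
from gennpipe._fastmap import decode_default
from gennpipe.model import to_expression_string

from reference_decoder import reference_decode


def random_genomes(n, rng, grammar, n_variables=15, p_grown=0.5):
    """Mix of purely random codon strings and grown functional genomes."""
    out = []
    for _ in range(n):
        if rng.random() < p_grown:
            out.append(random_functional_genome(grammar, n_variables, 7, rng).codons)
        else:
            length = int(rng.integers(1, 60))
            out.append(tuple(int(c) for c in rng.integers(0, 256, size=length)))
    return out


class TestChooseProduction:
    @pytest.mark.parametrize(
        "codon,n,expected", [(7, 4, 3), (0, 3, 0), (255, 2, 1), (10, 1, 0)]
    )
    def test_modulo_rule(self, codon, n, expected):
        assert choose_production(codon, n) == expected

    def test_rejects_zero_alternatives(self):
        with pytest.raises(ValueError):
            choose_production(5, 0)


class TestDefaultGrammar:
    def test_construction_is_deterministic(self):
        a, b = build_default_grammar(), build_default_grammar()
        assert a.rules == b.rules and a.start_symbol == b.start_symbol

    def test_all_operators_reachable(self, grammar):
        ops = {alt[0] for alt in grammar.rules["<op>"]}
        assert ops == {"PADD", "PSUB", "PMULT", "PDIV"}

    def test_first_alternatives_terminate(self, grammar):
        # choosing alternative 0 everywhere must yield a finite network
        result = map_genome(Genome((0,) * 12), grammar, n_variables=3)
        assert result.valid
        assert result.expression == "PADD(0.0*V1,0.0*V1)"

    def test_bnf_round_trip(self, grammar):
        again = grammar_from_bnf(grammar_to_bnf(grammar))
        assert again.rules == grammar.rules

    def test_rejects_undefined_nonterminal(self):
        with pytest.raises(GrammarError):
            grammar_from_bnf("<start> ::= <missing>")

    def test_rejects_inescapable_recursion(self):
        with pytest.raises(GrammarError):
            grammar_from_bnf("<start> ::= x <start>")


class TestMapping:
    def test_hand_traced_codons(self, grammar):
        # 2-input node, PADD, weight 1.0, V1, weight 1.0, V2
        codons = (
            0,  # <node>: 2-input alternative
            0,  # <op>: PADD
            0,  # <winput>: constant * variable
            0,  # <const>: unsigned
            1,  # leading digit 1
            0,  # decimal digit 0
            0,  # <var>: V1
            0, 0, 1, 0,  # second weighted input, weight 1.0
            1,  # <var>: V2
        )
        result = map_genome(Genome(codons), grammar, n_variables=5)
        assert result.valid
        assert result.expression == "PADD(1.0*V1,1.0*V2)"
        assert result.codons_used == len(codons)

    def test_mapping_is_pure(self, grammar, rng):
        for codons in random_genomes(50, rng, grammar):
            a = map_genome(Genome(codons), grammar, 15)
            b = map_genome(Genome(codons), grammar, 15)
            assert a.expression == b.expression and a.valid == b.valid

    def test_wrap_exhaustion_is_invalid(self, grammar):
        # codon 1 always picks the recursive weighted-input alternative
        result = map_genome(Genome((1,)), grammar, n_variables=3, max_wraps=2)
        assert not result.valid
        assert result.model is None
        assert result.wraps_used == 2

    def test_codon_neutrality(self, grammar, rng):
        for _ in range(50):
            genome = random_functional_genome(grammar, 8, 6, rng)
            base = map_genome(genome, grammar, 8)
            extra = tuple(int(c) for c in rng.integers(0, 256, size=7))
            appended = map_genome(Genome(genome.codons + extra), grammar, 8)
            assert base.expression == appended.expression

    def test_specialised_decoder_matches_generic(self, grammar, rng):
        for codons in random_genomes(300, rng, grammar):
            generic, used_g, _ = derive_expression(codons, grammar, 15)
            fast, root, used_f = decode_default(codons, 15)
            assert generic == fast
            assert used_g == used_f

    def test_matches_naive_reference_decoder(self, grammar, rng):
        for codons in random_genomes(300, rng, grammar):
            expected = reference_decode(codons, DEFAULT_GRAMMAR_BNF, "<start>", 15)
            got, _, _ = derive_expression(codons, grammar, 15)
            assert got == expected


class TestRandomFunctionalGenome:
    def test_always_maps_valid_with_zero_wraps(self, grammar, rng):
        for _ in range(200):
            genome = random_functional_genome(grammar, 12, 6, rng)
            result = map_genome(genome, grammar, 12)
            assert result.valid
            assert result.wraps_used == 0
            assert result.codons_used == len(genome)

    def test_depth_bound(self, grammar, rng):
        for max_depth in (5, 8, 11):
            for _ in range(40):
                genome = random_functional_genome(grammar, 12, max_depth, rng)
                model = map_genome(genome, grammar, 12).model
                assert model.depth <= max_depth

    def test_seed_reproducible(self, grammar):
        g1 = random_functional_genome(grammar, 9, 7, np.random.default_rng(7))
        g2 = random_functional_genome(grammar, 9, 7, np.random.default_rng(7))
        assert g1.codons == g2.codons


class TestGenomeValidation:
    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            Genome(())

    @given(st.integers())
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_codon_range_enforced(self, codon):
        if 0 <= codon <= 255:
            assert Genome((codon,)).codons == (codon,)
        else:
            with pytest.raises(ValueError):
                Genome((codon,))


def test_mapped_expression_equals_model_serialisation(grammar, rng):
    for _ in range(60):
        genome = random_functional_genome(grammar, 10, 7, rng)
        result = map_genome(genome, grammar, 10)
        assert to_expression_string(result.model) == result.expression
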