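"""Query parsing and answering: the granularity-bridging suite, Nothing
queries, filters, monotonicity and serialization invariance."""

import pytest

import sbmlkb.names as N
from conftest import SCOPES
from sbmlkb.convert import convert_corpus, rep_iri, proc_iri
from sbmlkb.owl.model import And, Named, Only, Or, Some
from sbmlkb.owl.serialize import (
    read_functional,
    read_rdfxml,
    write_functional,
    write_rdfxml,
)
from sbmlkb.query import (
    AmbiguousLabelError,
    CapabilityError,
    QuerySyntaxError,
    UnknownNameError,
    _RefNamed,
    answer_query,
    expression_depth,
    parse_query,
)
from sbmlkb.reasoner.tableau import TableauReasoner

SUGAR_Q = "represents some (has-function some (realized-by only (has-participant some sugar)))"
CELL_CYCLE_Q = "represents some (has-part some (has-function some (realized-by only 'cell cycle')))"
GRANULARITY_Q = (
    "represents some (has-function some (realized-by only "
    "(realizes some 'catalytic activity' and has-participant some "
    "(sugar and part-of some 'Endocrine pancreas'))))"
)
MODEL_SUGAR_Q = (
    "model-of some (has-part some (has-function some "
    "(realized-by only (has-participant some sugar))))"
)


class TestParser:
    def test_nested_restriction_depth(self):
        q = parse_query(CELL_CYCLE_Q)
        assert expression_depth(q.expression) == 5

    def test_nothing_is_bottom(self):
        from sbmlkb.owl.model import NOTHING

        assert parse_query("Nothing").expression == NOTHING

    def test_precedence_and_binds_tighter_than_or(self):
        q = parse_query("'cell cycle' and sugar or mutagen")
        assert isinstance(q.expression, Or)
        assert isinstance(q.expression.operands[0], And)

    def test_unmatched_parenthesis_reports_position(self):
        text = "part-of some ("
        with pytest.raises(QuerySyntaxError) as err:
            parse_query(text)
        assert err.value.position >= text.index("(")

    def test_trailing_garbage_is_error(self):
        with pytest.raises(QuerySyntaxError):
            parse_query("sugar )")

    def test_quoted_label_with_escape(self):
        q = parse_query(r"'it\'s a label'")
        assert isinstance(q.expression, _RefNamed)
        assert q.expression.ref.token == "it's a label"

    def test_unknown_filter_rejected(self):
        with pytest.raises(ValueError):
            parse_query("sugar", result_filter="species_only")


class TestNameResolution:
    def test_unknown_class_listed_verbatim(self, converted, reasoners):
        with pytest.raises(UnknownNameError, match="no such class"):
            answer_query(
                converted["F1"].ontology,
                parse_query("represents some 'no such class'"),
                reasoner=reasoners["F1"],
            )

    def test_ambiguous_label_is_error(self, converted, reasoners):
        # 'GTP' labels both the ChEBI class and the in-silico species class
        with pytest.raises(AmbiguousLabelError):
            answer_query(
                converted["F1"].ontology,
                parse_query("represents some GTP"),
                reasoner=reasoners["F1"],
            )

    def test_curie_disambiguates(self, converted, reasoners):
        result = answer_query(
            converted["F1"].ontology,
            parse_query("represents some CHEBI:15996"),
            reasoner=reasoners["F1"],
        )
        e_gtp, _ = rep_iri("GTP", SCOPES["F1"])
        assert result.iris == {e_gtp}


class TestF6QuerySuite:
    """Answer sets hand-enumerated from the fixture's construction: PFK and
    GPI consume sugar species (D-fructose 6-phosphate, alpha-D-glucose
    6-phosphate); the oxygen-binding and cell-cycle reactions do not."""

    def _labels(self, converted, reasoners, text, result_filter):
        result = answer_query(
            converted["F6"].ontology,
            parse_query(text, result_filter),
            reasoner=reasoners["F6"],
        )
        return {m["label"] for m in result.matches}

    def test_sugar_participation(self, converted, reasoners):
        assert self._labels(converted, reasoners, SUGAR_Q, "model_entities_only") == {
            "PFK", "GPI",
        }

    def test_cell_cycle_retrieves_the_model(self, converted, reasoners):
        assert self._labels(
            converted, reasoners, CELL_CYCLE_Q, "model_entities_only"
        ) == {"F6_pancreas"}

    def test_granularity_bridging_via_fma_part_of_chain(self, converted, reasoners):
        """The query is phrased at the endocrine-pancreas level; the model is
        annotated only at the islet-beta-cell level.  The part-of chain in
        the mini-FMA bridges the granularity gap."""
        assert self._labels(
            converted, reasoners, GRANULARITY_Q, "model_entities_only"
        ) == {"PFK", "GPI"}

    def test_model_level_filter(self, converted, reasoners):
        assert self._labels(converted, reasoners, MODEL_SUGAR_Q, "models_only") == {
            "F6_pancreas",
        }


class TestNothing:
    def test_empty_on_coherent_kbs(self, converted, reasoners):
        for fid in ("F1", "F6"):
            result = answer_query(
                converted[fid].ontology, parse_query("Nothing"),
                reasoner=reasoners[fid],
            )
            assert result.matches == []

    def test_exact_set_on_spindle_model(self, converted, reasoners):
        """Manual DL argument: Rep(SPN) ⊑ PhysicalObject ⊓ spindle-assembly
        (⊑ Process), disjoint, hence ⊥; every other emitted class reaches
        Rep(SPN) through an existential (represents / has-part / part-of /
        has-input), so the whole world of the model collapses: all 15
        emitted classes."""
        scope = SCOPES["F2"]
        expected = set()
        for ent in ("F2_spindle", "cell", "GTP", "DRG", "DRG_GTP", "SPN",
                    "GTP_binding_with_DRG"):
            expected |= set(rep_iri(ent, scope))
        expected.add(proc_iri("GTP_binding_with_DRG", scope))
        result = answer_query(
            converted["F2"].ontology, parse_query("Nothing"),
            reasoner=reasoners["F2"],
        )
        assert result.iris == expected


def test_corpus_growth_never_shrinks_answers(fixture_files, onts, roots):
    """Monotonicity of classical entailment: adding an annotated model to the
    corpus can only grow every query's answer set."""
    small = convert_corpus([fixture_files["F6"]], onts, roots)
    large = convert_corpus([fixture_files["F6"], fixture_files["F1"]], onts, roots)
    r_small = TableauReasoner(small.ontology)
    r_large = TableauReasoner(large.ontology)
    for text in (SUGAR_Q, CELL_CYCLE_Q, "represents some CHEBI:15996"):
        q = parse_query(text, "model_entities_only")
        before = answer_query(small.ontology, q, reasoner=r_small).iris
        after = answer_query(large.ontology, q, reasoner=r_large).iris
        assert before <= after


def test_answers_invariant_across_serializations(converted):
    """RDF/XML and functional-syntax round-trips preserve every answer set."""
    kb = converted["F6"].ontology
    via_ofn = read_functional(write_functional(kb))
    via_rdf = read_rdfxml(write_rdfxml(kb))
    q = parse_query(SUGAR_Q, "model_entities_only")
    reference = answer_query(kb, q).iris
    assert answer_query(via_ofn, q).iris == reference
    assert answer_query(via_rdf, q).iris == reference


def test_el_kb_rejects_non_el_expressions(converted_el):
    kb = converted_el["F6"].ontology
    with pytest.raises(CapabilityError, match="OWL EL"):
        answer_query(kb, parse_query(SUGAR_Q))
    with pytest.raises(CapabilityError):
        answer_query(kb, parse_query("sugar or mutagen"))
    # EL-expressible queries still work
    result = answer_query(kb, parse_query("part-of some 'Endocrine pancreas'"))
    assert result.matches


def test_full_and_el_agree_on_el_queries_outside_realized_by(
    converted, converted_el
):
    """The EL reduction strengthens realized-by axioms (only→some), so
    agreement is asserted for EL queries that do not traverse realized-by."""
    full_kb = converted["F6"].ontology
    el_kb = converted_el["F6"].ontology
    r_full = TableauReasoner(full_kb)
    r_el = TableauReasoner(el_kb)
    for text in (
        "represents some (has-function some 'catalytic activity')",
        "part-of some 'Endocrine pancreas'",
        "has-participant some sugar",
        "represents some (part-of some (has-part some sugar))",
    ):
        q = parse_query(text)
        assert answer_query(full_kb, q, reasoner=r_full).iris == \
            answer_query(el_kb, q, reasoner=r_el).iris, text
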