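"""The conversion rules: class pairs, annotation interpretation, structural
axioms, entity conservation, provenance, corpus assembly and EL reduction."""

import pytest

import sbmlkb.names as N
from conftest import SCOPES, SHAPES
from sbmlkb.convert import (
    RULES,
    convert_corpus,
    convert_model,
    el_profile_violations,
    interpret_annotation,
    proc_iri,
    rep_iri,
    to_el_profile,
    PATO_CONCENTRATION,
)
from sbmlkb.owl.model import Named, Only, Or, Some, SubClassOf
from sbmlkb.owl.serialize import axiom_to_functional
from sbmlkb.registry import Category
from sbmlkb.reasoner.el import ELClassifier
from sbmlkb.reasoner.tableau import TableauReasoner
from sbmlkb.sbml import EntityRef, QualifiedAnnotation, parse_sbml
from sbmlkb.upper import build_upper_ontology


def _ann(qualifier, curie):
    prefix, local = curie.split(":")
    return QualifiedAnnotation(
        qualifier=qualifier,
        target=EntityRef(prefix=prefix, local_id=local, source_uri=f"urn:test:{curie}"),
    )


class TestRepIri:
    def test_pair_is_distinct_and_deterministic(self):
        e1, r1 = rep_iri("GTP", "F1_gtp_binding")
        e2, r2 = rep_iri("GTP", "F1_gtp_binding")
        assert (e1, r1) == (e2, r2)
        assert len({e1, r1}) == 2

    def test_same_entity_in_two_models_gets_four_iris(self):
        iris = set(rep_iri("GTP", "modelA")) | set(rep_iri("GTP", "modelB"))
        assert len(iris) == 4

    def test_insilico_class_is_under_matching_sbml_class(self, converted, reasoners):
        e_gtp, _ = rep_iri("GTP", SCOPES["F1"])
        assert reasoners["F1"].is_subsumed_by(Named(e_gtp), Named(N.SBML_SPECIES))


class TestInterpretAnnotation:
    def test_species_physical_object_is_strict_named_class(self):
        expr = interpret_annotation(
            "species", _ann("is", "CHEBI:15996"), Category.PHYSICAL_OBJECT
        )
        assert expr == Named(N.obo_iri("CHEBI", "15996"))

    def test_species_strict_even_for_process_category(self):
        expr = interpret_annotation(
            "species", _ann("isVersionOf", "GO:0051225"), Category.PROCESS
        )
        assert expr == Named(N.obo_iri("GO", "0051225"))

    def test_reaction_process_is_function_realized_by_only(self):
        expr = interpret_annotation(
            "reaction", _ann("isVersionOf", "GO:0005525"), Category.PROCESS
        )
        assert expr == Some(
            N.HAS_FUNCTION, Only(N.REALIZED_BY, Named(N.obo_iri("GO", "0005525")))
        )

    def test_model_process_is_haspart_function_realized_by_only(self):
        target = Named(N.obo_iri("GO", "0005525"))
        expr = interpret_annotation(
            "model", _ann("isVersionOf", "GO:0005525"), Category.PROCESS
        )
        assert expr == Some(
            N.HAS_PART, Some(N.HAS_FUNCTION, Only(N.REALIZED_BY, target))
        )

    def test_model_unknown_category_is_disjunction_of_three_readings(self):
        expr = interpret_annotation(
            "model", _ann("is", "XX:1"), Category.UNKNOWN
        )
        assert isinstance(expr, Or) and len(expr.operands) == 3

    def test_haspart_wraps_the_isversionof_reading(self):
        target = Named(N.obo_iri("CHEBI", "15996"))
        expr = interpret_annotation(
            "species", _ann("hasPart", "CHEBI:15996"), Category.PHYSICAL_OBJECT
        )
        assert expr == Some(N.HAS_PART, target)
        expr = interpret_annotation(
            "model", _ann("isPartOf", "CHEBI:15996"), Category.PHYSICAL_OBJECT
        )
        assert expr == Some(N.PART_OF, Some(N.HAS_PART, target))

    def test_unsupported_qualifier_rejected(self):
        with pytest.raises(ValueError):
            interpret_annotation("species", _ann("encodes", "GO:0005623"),
                                 Category.PHYSICAL_OBJECT)


class TestConvertModel:
    def test_f1_axioms_present(self, converted):
        kb = converted["F1"].ontology
        scope = SCOPES["F1"]
        axioms = {axiom_to_functional(a) for a in kb.axioms}
        _, rep_gtp = rep_iri("GTP", scope)
        _, rep_cell = rep_iri("cell", scope)
        _, rep_m = rep_iri(scope, scope)
        strict = SubClassOf(Named(rep_gtp), Named(N.obo_iri("CHEBI", "15996")))
        part = SubClassOf(Named(rep_gtp), Some(N.PART_OF, Named(rep_cell)))
        container = SubClassOf(Named(rep_m), Some(N.HAS_PART, Named(rep_cell)))
        quality = SubClassOf(Named(rep_gtp),
                             Some(N.HAS_QUALITY, Named(PATO_CONCENTRATION)))
        for ax in (strict, part, container, quality):
            assert axiom_to_functional(ax) in axioms

    def test_reaction_gets_named_process_class(self, converted, reasoners):
        scope = SCOPES["F1"]
        _, rep_r = rep_iri("GTP_binding_with_DRG", scope)
        proc = proc_iri("GTP_binding_with_DRG", scope)
        r = reasoners["F1"]
        assert r.is_subsumed_by(
            Named(rep_r), Some(N.HAS_FUNCTION, Only(N.REALIZED_BY, Named(proc)))
        )
        assert r.is_subsumed_by(Named(proc), Named(N.PROCESS))

    @pytest.mark.parametrize("fid", sorted(SHAPES))
    def test_entity_conservation(self, converted, fid):
        """#named classes emitted = 2*(models+compartments+species) + 3*reactions."""
        c, s, r = SHAPES[fid]
        expected = 2 * (1 + c + s) + 3 * r
        assert converted[fid].manifest.emitted_class_count() == expected

    @pytest.mark.parametrize("fid", sorted(SHAPES))
    def test_every_axiom_has_exactly_one_documented_rule(self, converted, fid):
        manifest = converted[fid].manifest
        assert manifest.records, "conversion emitted no axioms"
        for record in manifest.records:
            assert record.rule in RULES
        # one provenance record per emitted axiom
        assert len({id(r.axiom) for r in manifest.records}) == len(manifest.records)

    def test_closed_role_vocabulary(self, converted):
        """Every relation in an emitted axiom is declared in the upper ontology."""
        declared = set(build_upper_ontology().properties)
        for res in converted.values():
            assert res.ontology.signature_roles() <= declared

    def test_annotation_free_model_is_coherent(self, onts, roots):
        """Without annotations only structural and category axioms fire, and
        the knowledge base stays coherent."""
        from test_sbml_reader import MINIMAL

        res = convert_model(parse_sbml(MINIMAL), onts, roots)
        rules = {r.rule for r in res.manifest.records}
        assert not any(rule.startswith("annotation.") for rule in rules)
        assert TableauReasoner(res.ontology).is_coherent()

    def test_violation_free_annotation_removal_keeps_coherence(
        self, parsed, onts, roots
    ):
        """Deleting the offending annotation from the spindle model restores a
        coherent knowledge base (removing axioms cannot add entailments)."""
        import copy

        pm = copy.deepcopy(parsed["F2"])
        for sp in pm.species:
            if sp.id == "SPN":
                sp.annotations = []
        res = convert_model(pm, onts, roots)
        assert TableauReasoner(res.ontology).is_coherent()

    def test_unresolved_annotation_is_logged_skip(self, onts, roots):
        from sbmlkb.sbml import parse_sbml as _p

        doc = """<?xml version="1.0"?>
        <sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
        <model id="m1"><listOfCompartments>
          <compartment id="c1" metaid="mc" size="1">
            <annotation><rdf:RDF
              xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
              xmlns:bqbiol="http://biomodels.net/biology-qualifiers/">
              <rdf:Description rdf:about="#mc"><bqbiol:is><rdf:Bag>
                <rdf:li rdf:resource="http://example.org/unknown/42"/>
              </rdf:Bag></bqbiol:is></rdf:Description>
            </rdf:RDF></annotation>
          </compartment>
        </listOfCompartments></model></sbml>"""
        res = convert_model(_p(doc), onts, roots)
        assert len(res.manifest.skipped) == 1
        assert res.manifest.skipped[0].reason == "unresolved URI"
        # the entity is still converted structurally
        assert res.manifest.emitted_class_count() == 4


class TestConvertCorpus:
    def test_combined_class_count_is_sum_of_parts(self, fixture_files, onts, roots):
        single1 = convert_model(parse_sbml(fixture_files["F1"]), onts, roots)
        single6 = convert_model(parse_sbml(fixture_files["F6"]), onts, roots)
        corpus = convert_corpus(
            [fixture_files["F1"], fixture_files["F6"]], onts, roots
        )
        assert corpus.manifest.emitted_class_count() == (
            single1.manifest.emitted_class_count()
            + single6.manifest.emitted_class_count()
        )

    def test_empty_corpus_is_upper_plus_reference_only(self, onts, roots):
        corpus = convert_corpus([], onts, roots)
        assert corpus.manifest.emitted_class_count() == 0
        assert set(onts.classes) <= corpus.ontology.classes

    def test_duplicate_file_gets_distinct_scope(self, fixture_files, onts, roots):
        corpus = convert_corpus(
            [fixture_files["F1"], fixture_files["F1"]], onts, roots
        )
        scopes = {info.scope for info in corpus.manifest.classes.values()}
        assert scopes == {"F1_gtp_binding", "F1_gtp_binding-2"}
        assert corpus.manifest.emitted_class_count() == 26
        assert TableauReasoner(corpus.ontology).is_coherent()

    def test_file_failure_is_isolated(self, fixture_files, onts, roots, tmp_path):
        bad = tmp_path / "broken.xml"
        bad.write_text("<sbml this is not xml")
        corpus = convert_corpus([bad, fixture_files["F1"]], onts, roots)
        assert str(bad) in corpus.manifest.failures
        assert corpus.manifest.emitted_class_count() == 13


class TestELReduction:
    def test_realized_by_only_rewritten_to_some(self, converted):
        el = to_el_profile(converted["F1"].ontology)
        scope = SCOPES["F1"]
        proc = proc_iri("GTP_binding_with_DRG", scope)
        _, rep_r = rep_iri("GTP_binding_with_DRG", scope)
        wanted = SubClassOf(
            Named(rep_r), Some(N.HAS_FUNCTION, Some(N.REALIZED_BY, Named(proc)))
        )
        texts = {axiom_to_functional(a) for a in el.axioms}
        assert axiom_to_functional(wanted) in texts

    def test_el_output_passes_conformance_scan(self, converted_el):
        for res in converted_el.values():
            scan = el_profile_violations(res.ontology)
            assert all(count == 0 for count in scan.values()), scan

    def test_el_output_classified_by_el_reasoner(self, converted_el):
        """The saturation-based EL classifier accepts the EL output without
        unsupported-construct failures and classifies it."""
        classifier = ELClassifier(converted_el["F6"].ontology)
        assert classifier.unsatisfiable_named_classes() == []

    def test_el_mode_manifest_keeps_rewritten_axioms(self, converted_el):
        manifest = converted_el["F6"].manifest
        assert manifest.mode == "el"
        for record in manifest.records:
            assert "ObjectAllValuesFrom" not in axiom_to_functional(record.axiom)
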