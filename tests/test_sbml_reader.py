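"""SBML parsing and MIRIAM annotation normalization."""

import pytest

from sbmlkb.sbml import (
    SBMLParseError,
    SBMLStructureError,
    normalize_annotation_uri,
    parse_sbml,
)

SBML_NS = "http://www.sbml.org/sbml/level2/version4"


def _doc(body: str) -> str:
    return f'<?xml version="1.0"?><sbml xmlns="{SBML_NS}" level="2" version="4">{body}</sbml>'


MINIMAL = _doc(
    """<model id="m1">
      <listOfCompartments><compartment id="c1" size="1"/></listOfCompartments>
      <listOfSpecies><species id="s1" compartment="c1" initialAmount="1"/></listOfSpecies>
      <listOfReactions><reaction id="r1">
        <listOfReactants><speciesReference species="s1"/></listOfReactants>
      </reaction></listOfReactions>
    </model>"""
)


class TestNormalizeAnnotationUri:
    @pytest.mark.parametrize(
        "uri,prefix,local",
        [
            ("http://identifiers.org/obo.go/GO:0005623", "GO", "0005623"),
            ("urn:miriam:obo.chebi:CHEBI%3A15996", "CHEBI", "15996"),
            ("urn:miriam:obo.go:GO%3A0051225", "GO", "0051225"),
            ("http://identifiers.org/chebi/CHEBI:17665", "CHEBI", "17665"),
            ("https://identifiers.org/fma/FMA:70586", "FMA", "70586"),
        ],
    )
    def test_recognized_dialects(self, uri, prefix, local):
        ref = normalize_annotation_uri(uri)
        assert ref.resolved
        assert (ref.prefix, ref.local_id) == (prefix, local)
        assert ref.source_uri == uri

    @pytest.mark.parametrize(
        "uri",
        [
            "http://example.org/unknown/42",
            "urn:miriam:pubmed:12345678" + "x:",  # malformed trailing segment
            "not a uri at all",
            "",
        ],
    )
    def test_unrecognized_uris_are_unresolved_not_errors(self, uri):
        ref = normalize_annotation_uri(uri)
        assert not ref.resolved
        assert ref.curie is None


class TestParseSbml:
    def test_worked_example_structure(self, parsed):
        """One compartment 'cell'; species GTP/DRG/DRG_GTP; one reaction with
        reactants {GTP, DRG} and product DRG_GTP."""
        pm = parsed["F1"]
        assert pm.model_id == "F1_gtp_binding"
        assert [c.id for c in pm.compartments] == ["cell"]
        assert [s.id for s in pm.species] == ["GTP", "DRG", "DRG_GTP"]
        (rx,) = pm.reactions
        assert rx.name == "GTP binding with DRG"
        assert sorted(rx.reactants) == ["DRG", "GTP"]
        assert rx.products == ["DRG_GTP"]
        assert all(s.compartment_id == "cell" for s in pm.species)
        assert all(s.has_initial_concentration for s in pm.species)

    def test_annotation_count_conservation(self, parsed):
        """Each biology-qualifier RDF target yields exactly one annotation."""
        counts = {fid: len(pm.biology_annotations()) for fid, pm in parsed.items()}
        assert counts == {
            "F1": 3, "F2": 4, "F3": 4, "F4": 4, "F4fix": 4, "F5": 5, "F6": 8,
        }

    def test_annotation_free_model_has_empty_annotation_lists(self):
        pm = parse_sbml(MINIMAL)
        assert pm.biology_annotations() == []
        assert pm.annotations == [] and pm.compartments[0].annotations == []
        assert pm.species[0].has_initial_amount
        assert not pm.species[0].has_initial_concentration

    def test_missing_compartment_is_structural_error(self):
        doc = MINIMAL.replace('compartment="c1"', 'compartment="nowhere"')
        with pytest.raises(SBMLStructureError, match="nowhere"):
            parse_sbml(doc)

    def test_dangling_reaction_participant_is_structural_error(self):
        doc = MINIMAL.replace('species="s1"/></listOfReactants>',
                              'species="ghost"/></listOfReactants>')
        with pytest.raises(SBMLStructureError, match="ghost"):
            parse_sbml(doc)

    def test_duplicate_identifier_is_structural_error(self):
        doc = MINIMAL.replace('<species id="s1" compartment="c1" initialAmount="1"/>',
                              '<species id="s1" compartment="c1" initialAmount="1"/>'
                              '<species id="s1" compartment="c1" initialAmount="1"/>')
        with pytest.raises(SBMLStructureError, match="duplicate"):
            parse_sbml(doc)

    def test_malformed_xml_is_parse_error(self):
        with pytest.raises(SBMLParseError):
            parse_sbml("<sbml><model></sbml>")

    def test_non_sbml_root_is_parse_error(self):
        with pytest.raises(SBMLParseError, match="not an SBML element"):
            parse_sbml('<?xml version="1.0"?><notes><model id="m"/></notes>')

    def test_model_qualifiers_are_preserved_but_ignored(self):
        rdf = """<annotation>
          <rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
                   xmlns:bqbiol="http://biomodels.net/biology-qualifiers/"
                   xmlns:bqmodel="http://biomodels.net/model-qualifiers/">
            <rdf:Description rdf:about="#meta_s1">
              <bqbiol:is><rdf:Bag>
                <rdf:li rdf:resource="urn:miriam:obo.chebi:CHEBI%3A15996"/>
              </rdf:Bag></bqbiol:is>
              <bqmodel:is><rdf:Bag>
                <rdf:li rdf:resource="http://identifiers.org/pubmed/123"/>
              </rdf:Bag></bqmodel:is>
              <bqbiol:encodes><rdf:Bag>
                <rdf:li rdf:resource="urn:miriam:obo.go:GO%3A0005623"/>
              </rdf:Bag></bqbiol:encodes>
            </rdf:Description>
          </rdf:RDF>
        </annotation>"""
        doc = MINIMAL.replace(
            '<species id="s1" compartment="c1" initialAmount="1"/>',
            f'<species id="s1" compartment="c1" initialAmount="1" metaid="meta_s1">{rdf}</species>',
        )
        pm = parse_sbml(doc)
        anns = pm.species[0].annotations
        assert len(anns) == 3
        active = [a for a in anns if not a.ignored]
        assert len(active) == 1 and active[0].qualifier == "is"
        ignored = sorted(a.qualifier for a in anns if a.ignored)
        assert ignored == ["encodes", "is"]  # bqbiol:encodes and bqmodel:is

    def test_rdf_bag_with_multiple_targets_is_flattened(self):
        rdf = """<annotation>
          <rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
                   xmlns:bqbiol="http://biomodels.net/biology-qualifiers/">
            <rdf:Description rdf:about="#meta_s1">
              <bqbiol:isVersionOf><rdf:Bag>
                <rdf:li rdf:resource="urn:miriam:obo.chebi:CHEBI%3A15996"/>
                <rdf:li rdf:resource="urn:miriam:obo.chebi:CHEBI%3A16646"/>
              </rdf:Bag></bqbiol:isVersionOf>
            </rdf:Description>
          </rdf:RDF>
        </annotation>"""
        doc = MINIMAL.replace(
            '<species id="s1" compartment="c1" initialAmount="1"/>',
            f'<species id="s1" compartment="c1" initialAmount="1" metaid="meta_s1">{rdf}</species>',
        )
        pm = parse_sbml(doc)
        assert [a.target.curie for a in pm.species[0].annotations] == [
            "CHEBI:15996",
            "CHEBI:16646",
        ]

    def test_parsing_is_read_only(self, fixture_files):
        before = fixture_files["F1"].read_bytes()
        parse_sbml(fixture_files["F1"])
        parse_sbml(fixture_files["F1"])
        assert fixture_files["F1"].read_bytes() == before
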