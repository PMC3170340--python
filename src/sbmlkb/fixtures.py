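"""Miniature reference ontologies and synthetic SBML scenario models.

Everything the pipeline needs to run end-to-end without downloads: small OBO
subsets of GO, ChEBI, FMA, PATO and the Cell Ontology, six annotated SBML
models exercising the conversion and verification scenarios (a clean
two-reactant binding model, a species annotated with a process, a reaction
annotated with a cellular component, a misannotated ATPase substrate, species
used as temporal stages, and a pancreatic beta-cell model for granularity
queries), a registry file and the ATPase constraint file.

Identifiers policy: classes whose identifiers are fixed in the literature
(e.g. GO:0005623 cell, CHEBI:15996 GTP) keep them verbatim; all scaffold
classes carry identifiers in the reserved synthetic ``FIX:`` namespace so no
real-looking identifier is fabricated.  All generated files are synthetic
miniatures for testing, not excerpts of the real ontologies.

Generation is deterministic: two runs with the same seed produce
byte-identical files (the scenario content is fixed; the seed is recorded in
the registry for provenance).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from lxml import etree

FIXTURE_IDS = {
    "F1": "gtp_binding_demo",
    "F2": "species_process_violation",
    "F3": "reaction_object_violation",
    "F4": "atpase_misannotation",
    "F4fix": "atpase_corrected",
    "F5": "temporal_stage_species",
    "F6": "granularity_query_model",
}

# Reserved synthetic-namespace scaffold ids
BP_ROOT = "FIX:0000100"
MF_ROOT = "FIX:0000101"
CC_ROOT = "FIX:0000102"
NUCLEUS = "FIX:0000103"
RENT_COMPLEX = "FIX:0000104"
CELL_CYCLE = "FIX:0000105"
G1_PHASE, G2_PHASE, S_PHASE, M_PHASE = (
    "FIX:0000106", "FIX:0000107", "FIX:0000108", "FIX:0000109",
)
CATALYTIC_ACTIVITY = "FIX:0000110"
PFK_ACTIVITY = "FIX:0000111"
GPI_ACTIVITY = "FIX:0000112"
OXYGEN_BINDING = "FIX:0000113"
CHEMICAL_ROOT = "FIX:0000200"
F6P = "FIX:0000201"
WATER = "FIX:0000202"
ATP = "FIX:0000203"
ADP = "FIX:0000204"
PHOSPHATE = "FIX:0000205"
DIOXYGEN = "FIX:0000207"
ANATOMY_ROOT = "FIX:0000300"
ENDOCRINE_PANCREAS = "FIX:0000301"
PANCREATIC_ISLET = "FIX:0000302"
CELL_ROOT_CL = "FIX:0000500"

_MINI_ONTOLOGIES = {
    # file stem -> (curie, label, is_a list, part_of list)
    "mini_go": [
        (BP_ROOT, "biological_process", [], []),
        (MF_ROOT, "molecular_function", [], []),
        (CC_ROOT, "cellular_component", [], []),
        ("GO:0005623", "cell", [CC_ROOT], []),
        (NUCLEUS, "nucleus", [CC_ROOT], []),
        (RENT_COMPLEX, "RENT complex", [CC_ROOT], []),
        ("GO:0005525", "GTP binding", [BP_ROOT], []),
        ("GO:0051225", "spindle assembly", [BP_ROOT], []),
        (CELL_CYCLE, "cell cycle", [BP_ROOT], []),
        (G1_PHASE, "G1 phase", [BP_ROOT], [CELL_CYCLE]),
        (G2_PHASE, "G2 phase", [BP_ROOT], [CELL_CYCLE]),
        (S_PHASE, "S phase", [BP_ROOT], [CELL_CYCLE]),
        (M_PHASE, "M phase", [BP_ROOT], [CELL_CYCLE]),
        (CATALYTIC_ACTIVITY, "catalytic activity", [MF_ROOT], []),
        ("GO:0008233", "peptidase activity", [CATALYTIC_ACTIVITY], []),
        ("GO:0004002", "ATPase activity", [CATALYTIC_ACTIVITY], []),
        (PFK_ACTIVITY, "6-phosphofructokinase activity", [CATALYTIC_ACTIVITY], []),
        (GPI_ACTIVITY, "glucose-6-phosphate isomerase activity", [CATALYTIC_ACTIVITY], []),
        (OXYGEN_BINDING, "oxygen binding", [MF_ROOT], []),
    ],
    "mini_chebi": [
        (CHEMICAL_ROOT, "chemical entity", [], []),
        ("CHEBI:16646", "sugar", [CHEMICAL_ROOT], []),
        ("CHEBI:17665", "alpha-D-glucose 6-phosphate", ["CHEBI:16646"], []),
        (F6P, "D-fructose 6-phosphate", ["CHEBI:16646"], []),
        ("CHEBI:25435", "mutagen", [CHEMICAL_ROOT], []),
        ("CHEBI:35470", "central nervous system drug", [CHEMICAL_ROOT], []),
        ("CHEBI:15996", "GTP", [CHEMICAL_ROOT], []),
        (WATER, "water", [CHEMICAL_ROOT], []),
        (ATP, "ATP", [CHEMICAL_ROOT], []),
        (ADP, "ADP", [CHEMICAL_ROOT], []),
        (PHOSPHATE, "phosphate", [CHEMICAL_ROOT], []),
        (DIOXYGEN, "dioxygen", [CHEMICAL_ROOT], []),
    ],
    "mini_fma": [
        (ANATOMY_ROOT, "anatomical structure", [], []),
        ("FMA:71132", "Gastrointestinal system", [ANATOMY_ROOT], []),
        (ENDOCRINE_PANCREAS, "Endocrine pancreas", [ANATOMY_ROOT], []),
        (PANCREATIC_ISLET, "Pancreatic islet", [ANATOMY_ROOT], [ENDOCRINE_PANCREAS]),
        ("FMA:70586", "Type B cell of pancreatic islet", [ANATOMY_ROOT], [PANCREATIC_ISLET]),
    ],
    "mini_pato": [
        ("FIX:0000400", "quality", [], []),
        ("PATO:0000033", "Concentration", ["FIX:0000400"], []),
        ("PATO:0002193", "Charge", ["FIX:0000400"], []),
        ("PATO:0000125", "Mass", ["FIX:0000400"], []),
    ],
    "mini_cl": [
        (CELL_ROOT_CL, "native cell", [], []),
        ("FIX:0000501", "epithelial cell", [CELL_ROOT_CL], []),
    ],
}

_ROOTS = {
    BP_ROOT: "process",
    MF_ROOT: "function",
    CC_ROOT: "physical_object",
    CHEMICAL_ROOT: "physical_object",
    ANATOMY_ROOT: "physical_object",
    "FIX:0000400": "quality",
    CELL_ROOT_CL: "physical_object",
}

_REGISTRY_TEMPLATE = """\
# Reference-ontology registry for the packaged miniature subsets.
# seed: {seed}
ontologies:
{onts}
roots:
{roots}
"""

_ATPASE_CONSTRAINTS = """\
# Constraint axioms for the ATPase scenario: the GO definition of
# ATPase activity, stated on the realizing process (has-input/has-output
# relate processes to their participating physical objects), plus the
# disjointness of water, ATP and alpha-D-glucose 6-phosphate missing
# from ChEBI.
disjoint:
  - ["water", "ATP", "'alpha-D-glucose 6-phosphate'"]
definitions:
  "GO:0004002": "'catalytic activity'"
rules:
  - sub: "realizes some 'ATPase activity'"
    sup: >-
      has-input some water and has-input some ATP
      and (has-input only (water or ATP))
      and has-output some ADP and has-output some phosphate
"""


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureSpec:
    fixture_id: str
    outdir: Path
    seed: int = 0

    @property
    def name(self) -> str:
        return FIXTURE_IDS[self.fixture_id]


def _obo_text(terms) -> str:
    lines = ["format-version: 1.2", "ontology: sbmlkb-mini-fixture", ""]
    for curie, label, is_a, part_of in terms:
        lines.append("[Term]")
        lines.append(f"id: {curie}")
        lines.append(f"name: {label}")
        for parent in is_a:
            lines.append(f"is_a: {parent}")
        for whole in part_of:
            lines.append(f"relationship: part_of {whole}")
        lines.append("")
    return "\n".join(lines)


def generate_mini_ontologies(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the miniature reference ontologies, registry and constraint file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for stem, terms in _MINI_ONTOLOGIES.items():
        path = outdir / f"{stem}.obo"
        path.write_text(_obo_text(terms))
        written[stem] = path
    onts = "\n".join(
        f'  - file: {stem}.obo\n    format: obo' for stem in sorted(_MINI_ONTOLOGIES)
    )
    roots = "\n".join(f'  "{curie}": {cat}' for curie, cat in sorted(_ROOTS.items()))
    registry = outdir / "registry.yaml"
    registry.write_text(_REGISTRY_TEMPLATE.format(seed=seed, onts=onts, roots=roots))
    written["registry"] = registry
    constraints = outdir / "atpase_constraints.yaml"
    constraints.write_text(_ATPASE_CONSTRAINTS)
    written["constraints"] = constraints
    return written


# ---------------------------------------------------------------------------
# SBML scenario models

SBML_NS = "http://www.sbml.org/sbml/level2/version4"
RDF = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
BQBIOL = "http://biomodels.net/biology-qualifiers/"


def _uri_for(curie: str) -> str:
    prefix, local = curie.split(":", 1)
    if prefix == "CHEBI":
        # exercise the MIRIAM URN dialect with percent-encoded colon
        return f"urn:miriam:obo.chebi:CHEBI%3A{local}"
    if prefix == "GO":
        return f"http://identifiers.org/obo.go/GO:{local}"
    return f"http://identifiers.org/{prefix.lower()}/{curie}"


def _annotate(element, metaid: str, annotations: list[tuple[str, str]]) -> None:
    if not annotations:
        return
    element.set("metaid", metaid)
    ann = etree.SubElement(element, f"{{{SBML_NS}}}annotation")
    rdf = etree.SubElement(
        ann, f"{{{RDF}}}RDF", nsmap={"rdf": RDF, "bqbiol": BQBIOL}
    )
    desc = etree.SubElement(rdf, f"{{{RDF}}}Description")
    desc.set(f"{{{RDF}}}about", f"#{metaid}")
    for qualifier, curie in annotations:
        qual = etree.SubElement(desc, f"{{{BQBIOL}}}{qualifier}")
        bag = etree.SubElement(qual, f"{{{RDF}}}Bag")
        li = etree.SubElement(bag, f"{{{RDF}}}li")
        li.set(f"{{{RDF}}}resource", _uri_for(curie))


def _sbml_document(
    model_id: str,
    model_name: str,
    compartments,  # (id, [(qualifier, curie)])
    species,  # (id, compartment, initial_attr, value, [(qualifier, curie)])
    reactions,  # (id, name, reactants, products, modifiers, [(qualifier, curie)])
    model_annotations=(),
) -> bytes:
    root = etree.Element(f"{{{SBML_NS}}}sbml", nsmap={None: SBML_NS})
    root.set("level", "2")
    root.set("version", "4")
    model = etree.SubElement(root, f"{{{SBML_NS}}}model")
    model.set("id", model_id)
    model.set("name", model_name)
    _annotate(model, f"meta_{model_id}", list(model_annotations))
    loc = etree.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    for cid, anns in compartments:
        comp = etree.SubElement(loc, f"{{{SBML_NS}}}compartment")
        comp.set("id", cid)
        comp.set("size", "1")
        _annotate(comp, f"meta_{cid}", anns)
    los = etree.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    for sid, cid, attr, value, anns in species:
        sp = etree.SubElement(los, f"{{{SBML_NS}}}species")
        sp.set("id", sid)
        sp.set("compartment", cid)
        sp.set(attr, value)
        _annotate(sp, f"meta_{sid}", anns)
    lor = etree.SubElement(model, f"{{{SBML_NS}}}listOfReactions")
    for rid, rname, reactants, products, modifiers, anns in reactions:
        rx = etree.SubElement(lor, f"{{{SBML_NS}}}reaction")
        rx.set("id", rid)
        if rname:
            rx.set("name", rname)
        rx.set("reversible", "false")
        _annotate(rx, f"meta_{rid}", anns)
        if reactants:
            lst = etree.SubElement(rx, f"{{{SBML_NS}}}listOfReactants")
            for sid in reactants:
                etree.SubElement(lst, f"{{{SBML_NS}}}speciesReference").set("species", sid)
        if products:
            lst = etree.SubElement(rx, f"{{{SBML_NS}}}listOfProducts")
            for sid in products:
                etree.SubElement(lst, f"{{{SBML_NS}}}speciesReference").set("species", sid)
        if modifiers:
            lst = etree.SubElement(rx, f"{{{SBML_NS}}}listOfModifiers")
            for sid in modifiers:
                etree.SubElement(
                    lst, f"{{{SBML_NS}}}modifierSpeciesReference"
                ).set("species", sid)
    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def _gtp_binding_entities(extra_species=(), extra_reactions=()):
    species = [
        ("GTP", "cell", "initialConcentration", "0.1", [("is", "CHEBI:15996")]),
        ("DRG", "cell", "initialConcentration", "0.1", []),
        ("DRG_GTP", "cell", "initialConcentration", "0", []),
    ] + list(extra_species)
    reactions = [
        (
            "GTP_binding_with_DRG",
            "GTP binding with DRG",
            ["GTP", "DRG"],
            ["DRG_GTP"],
            [],
            [("isVersionOf", "GO:0005525")],
        )
    ] + list(extra_reactions)
    return [("cell", [("is", "GO:0005623")])], species, reactions


def _build_fixture(fixture_id: str) -> bytes:
    if fixture_id == "F1":
        comps, species, reactions = _gtp_binding_entities()
        return _sbml_document("F1_gtp_binding", "GTP binding worked example", comps, species, reactions)
    if fixture_id == "F2":
        comps, species, reactions = _gtp_binding_entities(
            extra_species=[
                ("SPN", "cell", "initialConcentration", "0",
                 [("isVersionOf", "GO:0051225")])
            ]
        )
        return _sbml_document(
            "F2_spindle", "Species annotated with spindle assembly",
            comps, species, reactions,
        )
    if fixture_id == "F3":
        comps, species, reactions = _gtp_binding_entities(
            extra_reactions=[
                ("assoc_RENT", "Assoc with NET1P to form RENTP",
                 ["DRG_GTP"], [], [], [("isVersionOf", RENT_COMPLEX)])
            ]
        )
        return _sbml_document(
            "F3_rent", "Reaction annotated with a cellular component",
            comps, species, reactions,
        )
    if fixture_id in ("F4", "F4fix"):
        atp_annotation = ATP if fixture_id == "F4fix" else "CHEBI:17665"
        return _sbml_document(
            "F4_glycolysis",
            "Anaerobic glycolysis (ATPase scenario)",
            [("cytosol", [("is", "GO:0005623")])],
            [
                ("ATP_sp", "cytosol", "initialConcentration", "1",
                 [("is", atp_annotation)]),
                ("ADP_sp", "cytosol", "initialConcentration", "0", [("is", ADP)]),
            ],
            [
                ("ATPase", "ATPase", ["ATP_sp"], ["ADP_sp"], [],
                 [("isVersionOf", "GO:0004002")])
            ],
        )
    if fixture_id == "F5":
        return _sbml_document(
            "F5_cellcycle",
            "Species used as temporal stages",
            [("nucleus", [("is", NUCLEUS)])],
            [
                ("G1", "nucleus", "initialAmount", "1", [("is", G1_PHASE)]),
                ("G2", "nucleus", "initialAmount", "0", [("is", G2_PHASE)]),
                ("S", "nucleus", "initialAmount", "0", [("is", S_PHASE)]),
                ("M", "nucleus", "initialAmount", "0", [("is", M_PHASE)]),
            ],
            [("advance_G1_S", "G1 to S", ["G1"], ["S"], [], [])],
        )
    if fixture_id == "F6":
        return _sbml_document(
            "F6_pancreas",
            "Beta-cell glycolysis for granularity queries",
            [("beta_cell", [("is", "FMA:70586")])],
            [
                ("F6P", "beta_cell", "initialConcentration", "0.2", [("is", F6P)]),
                ("G6P", "beta_cell", "initialConcentration", "0.2",
                 [("is", "CHEBI:17665")]),
                ("O2", "beta_cell", "initialConcentration", "0.1", [("is", DIOXYGEN)]),
                ("FDP", "beta_cell", "initialConcentration", "0", []),
            ],
            [
                ("PFK", "phosphofructokinase", ["F6P"], ["FDP"], [],
                 [("isVersionOf", PFK_ACTIVITY)]),
                ("GPI", "glucose-6-phosphate isomerase", ["G6P"], ["F6P"], [],
                 [("isVersionOf", GPI_ACTIVITY)]),
                ("OXB", "oxygen binding", ["O2"], [], [],
                 [("isVersionOf", OXYGEN_BINDING)]),
                ("CDC", "cell cycle progression", [], ["FDP"], [],
                 [("isVersionOf", CELL_CYCLE)]),
            ],
        )
    raise FixtureError(f"unknown fixture id {fixture_id!r}")


def generate_fixture_models(spec: FixtureSpec) -> Path:
    """Write the SBML file for one scenario fixture; returns its path."""
    if spec.fixture_id not in FIXTURE_IDS:
        raise FixtureError(
            f"unknown fixture id {spec.fixture_id!r}; known: {sorted(FIXTURE_IDS)}"
        )
    spec.outdir.mkdir(parents=True, exist_ok=True)
    path = Path(spec.outdir) / f"{spec.fixture_id}_{spec.name}.xml"
    path.write_bytes(_build_fixture(spec.fixture_id))
    return path


def generate_all(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Mini ontologies, registry, constraints and all scenario models."""
    outdir = Path(outdir)
    written = generate_mini_ontologies(outdir, seed=seed)
    for fid in FIXTURE_IDS:
        written[fid] = generate_fixture_models(FixtureSpec(fid, outdir, seed))
    return written
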