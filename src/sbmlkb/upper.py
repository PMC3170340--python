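"""The upper-level model ontology.

A small top taxonomy that integrates the in-silico side (model entities:
models, model components, and their SBML-specific subclasses) with the in-vivo
side (biological entities: physical objects, processes, functions, qualities),
together with the object properties that link the two sides and structure each
of them.  Sibling classes on each level of distinction are pairwise disjoint,
which is what turns a category-mixing annotation into an unsatisfiable class
under reasoning.
"""

from __future__ import annotations

from . import names as N
from .owl.model import And, Named, Only, Ontology, PropertySpec, Some

UPPER_ONTOLOGY_IRI = "https://w3id.org/sbmlkb/upper"
UPPER_VERSION = "1.0.0"

#: Upper classes, IRI -> label
UPPER_CLASSES = {
    N.MODEL_ENTITY: "Model entity",
    N.MODEL: "Model",
    N.MODEL_COMPONENT: "Model component",
    N.SBML_MODEL: "sbml:Model",
    N.SBML_SPECIES: "sbml:Species",
    N.SBML_COMPARTMENT: "sbml:Compartment",
    N.SBML_REACTION: "sbml:Reaction",
    N.BIOLOGICAL_ENTITY: "Biological entity",
    N.PHYSICAL_OBJECT: "Physical object",
    N.PROCESS: "Process",
    N.FUNCTION: "Function",
    N.QUALITY: "Quality",
}

_SUBCLASS_EDGES = [
    (N.MODEL, N.MODEL_ENTITY),
    (N.MODEL_COMPONENT, N.MODEL_ENTITY),
    (N.SBML_MODEL, N.MODEL),
    (N.SBML_SPECIES, N.MODEL_COMPONENT),
    (N.SBML_COMPARTMENT, N.MODEL_COMPONENT),
    (N.SBML_REACTION, N.MODEL_COMPONENT),
    (N.PHYSICAL_OBJECT, N.BIOLOGICAL_ENTITY),
    (N.PROCESS, N.BIOLOGICAL_ENTITY),
    (N.FUNCTION, N.BIOLOGICAL_ENTITY),
    (N.QUALITY, N.BIOLOGICAL_ENTITY),
]

# Sibling groups declared pairwise disjoint ("on each level of distinction").
_DISJOINT_GROUPS = [
    (N.MODEL_ENTITY, N.BIOLOGICAL_ENTITY),
    (N.MODEL, N.MODEL_COMPONENT),
    (N.SBML_SPECIES, N.SBML_COMPARTMENT, N.SBML_REACTION),
    (N.PHYSICAL_OBJECT, N.PROCESS, N.FUNCTION, N.QUALITY),
]


def relation_specs() -> list[PropertySpec]:
    """The relation table of the model ontology.

    Each relation carries domain, range and (where defined) an inverse;
    input-of/output-of/modifier-of are sub-relations of participates-in (and
    their inverses sub-relations of has-participant).  quality-of is
    functional: a quality is always the quality of exactly one individual.
    represents and model-of have no inverse.  part-of/has-part are transitive,
    which is what lets queries bridge levels of granularity along partonomy
    chains of anatomical ontologies.
    """

    def p(iri, label, domain=None, range=None, inverse=None, parents=(),
          transitive=False, functional=False):
        return PropertySpec(iri=iri, label=label, domain=domain, range=range,
                            inverse=inverse, parents=tuple(parents),
                            transitive=transitive, functional=functional)

    return [
        p(N.PART_OF, "part-of", inverse=N.HAS_PART, transitive=True),
        p(N.HAS_PART, "has-part", inverse=N.PART_OF, transitive=True),
        p(N.PARTICIPATES_IN, "participates-in", domain=N.BIOLOGICAL_ENTITY,
          range=N.PROCESS, inverse=N.HAS_PARTICIPANT),
        p(N.HAS_PARTICIPANT, "has-participant", domain=N.PROCESS,
          range=N.BIOLOGICAL_ENTITY, inverse=N.PARTICIPATES_IN),
        p(N.FUNCTION_OF, "function-of", domain=N.FUNCTION,
          range=N.PHYSICAL_OBJECT, inverse=N.HAS_FUNCTION),
        p(N.HAS_FUNCTION, "has-function", domain=N.PHYSICAL_OBJECT,
          range=N.FUNCTION, inverse=N.FUNCTION_OF),
        p(N.REALIZES, "realizes", domain=N.PROCESS, range=N.FUNCTION,
          inverse=N.REALIZED_BY),
        p(N.REALIZED_BY, "realized-by", domain=N.FUNCTION, range=N.PROCESS,
          inverse=N.REALIZES),
        p(N.OCCURS_IN, "occurs-in", domain=N.PROCESS, range=N.PHYSICAL_OBJECT,
          inverse=N.HAS_PROCESS_OCCURING),
        p(N.HAS_PROCESS_OCCURING, "has-process-occuring",
          domain=N.PHYSICAL_OBJECT, range=N.PROCESS, inverse=N.OCCURS_IN),
        p(N.QUALITY_OF, "quality-of", domain=N.QUALITY,
          range=N.BIOLOGICAL_ENTITY, inverse=N.HAS_QUALITY, functional=True),
        p(N.HAS_QUALITY, "has-quality", domain=N.BIOLOGICAL_ENTITY,
          range=N.QUALITY, inverse=N.QUALITY_OF),
        p(N.INPUT_OF, "input-of", domain=N.PHYSICAL_OBJECT, range=N.PROCESS,
          inverse=N.HAS_INPUT, parents=[N.PARTICIPATES_IN]),
        p(N.HAS_INPUT, "has-input", domain=N.PROCESS, range=N.PHYSICAL_OBJECT,
          inverse=N.INPUT_OF, parents=[N.HAS_PARTICIPANT]),
        p(N.OUTPUT_OF, "output-of", domain=N.PHYSICAL_OBJECT, range=N.PROCESS,
          inverse=N.HAS_OUTPUT, parents=[N.PARTICIPATES_IN]),
        p(N.HAS_OUTPUT, "has-output", domain=N.PROCESS,
          range=N.PHYSICAL_OBJECT, inverse=N.OUTPUT_OF,
          parents=[N.HAS_PARTICIPANT]),
        p(N.MODIFIER_OF, "modifier-of", domain=N.PHYSICAL_OBJECT,
          range=N.PROCESS, inverse=N.HAS_MODIFIER,
          parents=[N.PARTICIPATES_IN]),
        p(N.HAS_MODIFIER, "has-modifier", domain=N.PROCESS,
          range=N.PHYSICAL_OBJECT, inverse=N.MODIFIER_OF,
          parents=[N.HAS_PARTICIPANT]),
        p(N.REPRESENTS, "represents", domain=N.MODEL_ENTITY,
          range=N.PHYSICAL_OBJECT),
        p(N.MODEL_OF, "model-of", domain=N.MODEL, range=N.PHYSICAL_OBJECT),
    ]


def build_upper_ontology(el_safe: bool = False) -> Ontology:
    """Construct the upper-level model ontology.

    With ``el_safe=True`` the two universal part-of constraints (physical
    objects have only physical objects as parts; processes only processes),
    inverse-property axioms and the functionality of quality-of are omitted,
    since OWL EL supports none of them; the omissions are recorded in the
    ontology's annotations.
    """
    ont = Ontology(UPPER_ONTOLOGY_IRI)
    ont.annotations.append(f"upper-level model ontology, version {UPPER_VERSION}")
    for iri, label in UPPER_CLASSES.items():
        ont.declare_class(iri, label)
    for sub, sup in _SUBCLASS_EDGES:
        ont.subclass(Named(sub), Named(sup))
    for group in _DISJOINT_GROUPS:
        ont.disjoint(*(Named(c) for c in group))
    for spec in relation_specs():
        if el_safe:
            spec.inverse = None
            spec.functional = False
        ont.declare_property(spec)
    # Model components must be part of a model.
    ont.subclass(Named(N.MODEL_COMPONENT), Some(N.PART_OF, Named(N.MODEL)))
    if el_safe:
        ont.annotations.append(
            "EL profile: universal part-of constraints on PhysicalObject and "
            "Process, inverse-property axioms and the functionality of "
            "quality-of are omitted (unsupported in OWL EL)"
        )
    else:
        # Physical objects have only physical objects as parts; processes
        # have only processes as parts.
        ont.subclass(Named(N.PHYSICAL_OBJECT),
                     Only(N.HAS_PART, Named(N.PHYSICAL_OBJECT)))
        ont.subclass(Named(N.PROCESS), Only(N.HAS_PART, Named(N.PROCESS)))
    return ont


#: Category token -> upper class a reference-ontology root is asserted under.
CATEGORY_TO_UPPER = {
    "physical_object": N.PHYSICAL_OBJECT,
    "process": N.PROCESS,
    "function": N.FUNCTION,
    "quality": N.QUALITY,
}


class ConfigurationError(ValueError):
    pass


def attach_reference_roots(upper: Ontology, mapping: dict[str, str]) -> Ontology:
    """Assert each reference-ontology root class under its upper class.

    ``mapping`` maps a root class IRI to either a category token
    (``physical_object``/``process``/``function``/``quality``) or the upper
    class IRI itself.  Returns a new, augmented ontology.
    """
    out = upper.copy()
    for root_iri, target in sorted(mapping.items()):
        upper_iri = CATEGORY_TO_UPPER.get(target, target)
        if upper_iri not in (N.PHYSICAL_OBJECT, N.PROCESS, N.FUNCTION, N.QUALITY):
            raise ConfigurationError(
                f"root {root_iri} mapped to unknown upper class {target!r}"
            )
        out.declare_class(root_iri)
        out.subclass(Named(root_iri), Named(upper_iri))
    return out
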