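"""Stable IRIs for the upper-level model ontology and OBO-style references."""

from __future__ import annotations

UPPER = "https://w3id.org/sbmlkb/upper#"
MODEL_NS = "https://w3id.org/sbmlkb/model/"
OBO = "http://purl.obolibrary.org/obo/"

# Upper-level classes: the in-silico side …
MODEL_ENTITY = UPPER + "ModelEntity"
MODEL = UPPER + "Model"
MODEL_COMPONENT = UPPER + "ModelComponent"
SBML_MODEL = UPPER + "SBMLModel"
SBML_SPECIES = UPPER + "SBMLSpecies"
SBML_COMPARTMENT = UPPER + "SBMLCompartment"
SBML_REACTION = UPPER + "SBMLReaction"
# … and the in-vivo side.
BIOLOGICAL_ENTITY = UPPER + "BiologicalEntity"
PHYSICAL_OBJECT = UPPER + "PhysicalObject"
PROCESS = UPPER + "Process"
FUNCTION = UPPER + "Function"
QUALITY = UPPER + "Quality"

# Relations
PART_OF = UPPER + "part-of"
HAS_PART = UPPER + "has-part"
PARTICIPATES_IN = UPPER + "participates-in"
HAS_PARTICIPANT = UPPER + "has-participant"
FUNCTION_OF = UPPER + "function-of"
HAS_FUNCTION = UPPER + "has-function"
REALIZES = UPPER + "realizes"
REALIZED_BY = UPPER + "realized-by"
OCCURS_IN = UPPER + "occurs-in"
HAS_PROCESS_OCCURING = UPPER + "has-process-occuring"
QUALITY_OF = UPPER + "quality-of"
HAS_QUALITY = UPPER + "has-quality"
INPUT_OF = UPPER + "input-of"
HAS_INPUT = UPPER + "has-input"
OUTPUT_OF = UPPER + "output-of"
HAS_OUTPUT = UPPER + "has-output"
MODIFIER_OF = UPPER + "modifier-of"
HAS_MODIFIER = UPPER + "has-modifier"
REPRESENTS = UPPER + "represents"
MODEL_OF = UPPER + "model-of"


def obo_iri(prefix: str, local_id: str) -> str:
    """OBO Foundry style IRI for a CURIE, e.g. ``GO:0005623``."""
    return f"{OBO}{prefix}_{local_id}"


def curie_to_iri(curie: str) -> str:
    prefix, local = curie.split(":", 1)
    return obo_iri(prefix, local)


def iri_to_curie(iri: str) -> str | None:
    if iri.startswith(OBO):
        local = iri[len(OBO):]
        if "_" in local:
            prefix, ident = local.split("_", 1)
            return f"{prefix}:{ident}"
    return None


def model_scope_ns(scope: str) -> str:
    return f"{MODEL_NS}{scope}#"
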