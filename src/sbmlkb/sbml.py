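"""SBML parsing and MIRIAM annotation extraction.

Reads SBML Level 2/3 documents with lxml and extracts, for the model and each
compartment, species and reaction, the structural links (species→compartment,
reaction→participants), the initial-value flags, and the normalized MIRIAM
annotations carried in the RDF block of each element.

Only the five BioModels.net *biology* qualifiers — is, isVersionOf,
hasVersion, isPartOf, hasPart — are consumed; other biology qualifiers and
all model qualifiers (bqmodel) are preserved but marked ignored.
"""

from __future__ import annotations

import logging
import urllib.parse
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from lxml import etree

log = logging.getLogger(__name__)

SBML_NS_PREFIXES = ("http://www.sbml.org/sbml/",)
RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
BQBIOL_NS = "http://biomodels.net/biology-qualifiers/"
BQMODEL_NS = "http://biomodels.net/model-qualifiers/"

BIOLOGY_QUALIFIERS = ("is", "isVersionOf", "hasVersion", "isPartOf", "hasPart")


class SBMLParseError(ValueError):
    """Malformed XML or a non-SBML document root."""


class SBMLStructureError(ValueError):
    """Dangling internal reference or duplicate identifier."""


@dataclass(frozen=True)
class EntityRef:
    """A reference to one reference-ontology class, e.g. (GO, 0005623)."""

    prefix: Optional[str]
    local_id: Optional[str]
    source_uri: str

    @property
    def resolved(self) -> bool:
        return self.prefix is not None

    @property
    def curie(self) -> Optional[str]:
        if not self.resolved:
            return None
        return f"{self.prefix}:{self.local_id}"


@dataclass(frozen=True)
class QualifiedAnnotation:
    qualifier: str  # one of BIOLOGY_QUALIFIERS, or marked ignored
    target: EntityRef
    ignored: bool = False  # non-biology or unsupported qualifier


@dataclass
class Compartment:
    id: str
    name: str = ""
    annotations: list[QualifiedAnnotation] = field(default_factory=list)


@dataclass
class Species:
    id: str
    compartment_id: str
    name: str = ""
    has_initial_concentration: bool = False
    has_initial_amount: bool = False
    has_initial_charge: bool = False
    annotations: list[QualifiedAnnotation] = field(default_factory=list)


@dataclass
class Reaction:
    id: str
    name: str = ""
    reactants: list[str] = field(default_factory=list)
    products: list[str] = field(default_factory=list)
    modifiers: list[str] = field(default_factory=list)
    annotations: list[QualifiedAnnotation] = field(default_factory=list)


@dataclass
class ParsedModel:
    model_id: str
    name: str = ""
    annotations: list[QualifiedAnnotation] = field(default_factory=list)
    compartments: list[Compartment] = field(default_factory=list)
    species: list[Species] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    n_parameters: int = 0  # parsed for reporting; never converted
    has_kinetic_laws: bool = False

    def biology_annotations(self) -> list[tuple[str, str, QualifiedAnnotation]]:
        """(entity kind, entity id, annotation) for all active annotations."""
        out = []
        for ann in self.annotations:
            out.append(("model", self.model_id, ann))
        for c in self.compartments:
            out.extend(("compartment", c.id, a) for a in c.annotations)
        for s in self.species:
            out.extend(("species", s.id, a) for a in s.annotations)
        for r in self.reactions:
            out.extend(("reaction", r.id, a) for a in r.annotations)
        return [(k, i, a) for (k, i, a) in out if not a.ignored]


def normalize_annotation_uri(uri: str) -> EntityRef:
    """Map a MIRIAM URN or identifiers.org URL to an ontology-class reference.

    Recognizes ``urn:miriam:…`` (with percent-encoded colon in the local id)
    and ``http(s)://identifiers.org/…`` dialects; anything else yields an
    unresolved reference.  Total: never raises.
    """
    uri = uri.strip()
    candidate: Optional[str] = None
    if uri.lower().startswith("urn:miriam:"):
        candidate = urllib.parse.unquote(uri.rsplit(":", 1)[-1])
    else:
        parsed = urllib.parse.urlparse(uri)
        if parsed.netloc.lower() in ("identifiers.org", "www.identifiers.org"):
            candidate = urllib.parse.unquote(parsed.path.rstrip("/").rsplit("/", 1)[-1])
    if candidate and ":" in candidate:
        prefix, local = candidate.split(":", 1)
        if prefix and local:
            return EntityRef(prefix=prefix.upper(), local_id=local, source_uri=uri)
    return EntityRef(prefix=None, local_id=None, source_uri=uri)


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _namespace(tag: str) -> str:
    return tag.split("}", 1)[0][1:] if tag.startswith("{") else ""


def _extract_annotations(element: etree._Element) -> list[QualifiedAnnotation]:
    """All qualified annotations in the element's MIRIAM RDF block.

    RDF Bags with several targets under one qualifier are flattened into one
    :class:`QualifiedAnnotation` per target.
    """
    annotations: list[QualifiedAnnotation] = []
    for ann in element:
        if _localname(ann.tag) != "annotation":
            continue
        for desc in ann.iter(f"{{{RDF_NS}}}Description"):
            for qual_el in desc:
                ns = _namespace(qual_el.tag)
                qualifier = _localname(qual_el.tag)
                if ns not in (BQBIOL_NS, BQMODEL_NS):
                    continue
                ignored = ns == BQMODEL_NS or qualifier not in BIOLOGY_QUALIFIERS
                if ignored:
                    log.info("ignoring qualifier %s (%s)", qualifier,
                             "model qualifier" if ns == BQMODEL_NS else "unsupported")
                resources = [
                    li.get(f"{{{RDF_NS}}}resource")
                    for li in qual_el.iter(f"{{{RDF_NS}}}li")
                ]
                for uri in resources:
                    if uri is None:
                        continue
                    annotations.append(
                        QualifiedAnnotation(
                            qualifier=qualifier,
                            target=normalize_annotation_uri(uri),
                            ignored=ignored,
                        )
                    )
    return annotations


def parse_sbml(document: Union[str, Path, bytes]) -> ParsedModel:
    """Parse an SBML Level 2/3 document into a :class:`ParsedModel`.

    ``document`` may be a path or raw XML content.  Raises
    :class:`SBMLParseError` for malformed/non-SBML input and
    :class:`SBMLStructureError` for dangling references or duplicate ids.
    """
    try:
        if isinstance(document, bytes):
            root = etree.fromstring(document)
        elif isinstance(document, Path) or (
            isinstance(document, str) and "<" not in document
        ):
            root = etree.parse(str(document)).getroot()
        else:
            root = etree.fromstring(document.encode())
    except (etree.XMLSyntaxError, OSError) as exc:
        raise SBMLParseError(f"cannot parse SBML document: {exc}") from exc

    if _localname(root.tag) != "sbml" or not _namespace(root.tag).startswith(
        SBML_NS_PREFIXES
    ):
        raise SBMLParseError(
            f"document root is <{_localname(root.tag)}>, not an SBML element"
        )

    model_el = next((el for el in root if _localname(el.tag) == "model"), None)
    if model_el is None:
        raise SBMLParseError("SBML document contains no <model> element")

    pm = ParsedModel(
        model_id=model_el.get("id", "model"),
        name=model_el.get("name", ""),
        annotations=_extract_annotations(model_el),
    )

    def children_of(list_name: str, item_name: str):
        for lst in model_el:
            if _localname(lst.tag) == list_name:
                for item in lst:
                    if _localname(item.tag) == item_name:
                        yield item

    for el in children_of("listOfCompartments", "compartment"):
        pm.compartments.append(
            Compartment(
                id=el.get("id", ""),
                name=el.get("name", ""),
                annotations=_extract_annotations(el),
            )
        )
    for el in children_of("listOfSpecies", "species"):
        pm.species.append(
            Species(
                id=el.get("id", ""),
                compartment_id=el.get("compartment", ""),
                name=el.get("name", ""),
                has_initial_concentration=el.get("initialConcentration") is not None,
                has_initial_amount=el.get("initialAmount") is not None,
                has_initial_charge=el.get("charge") is not None,
                annotations=_extract_annotations(el),
            )
        )
    for el in children_of("listOfReactions", "reaction"):
        reaction = Reaction(
            id=el.get("id", ""),
            name=el.get("name", ""),
            annotations=_extract_annotations(el),
        )
        for part in el:
            part_name = _localname(part.tag)
            refs = [
                ref.get("species")
                for ref in part
                if _localname(ref.tag) in ("speciesReference", "modifierSpeciesReference")
            ]
            if part_name == "listOfReactants":
                reaction.reactants.extend(r for r in refs if r)
            elif part_name == "listOfProducts":
                reaction.products.extend(r for r in refs if r)
            elif part_name == "listOfModifiers":
                reaction.modifiers.extend(r for r in refs if r)
            elif part_name == "kineticLaw":
                pm.has_kinetic_laws = True
        pm.reactions.append(reaction)
    pm.n_parameters = sum(1 for _ in children_of("listOfParameters", "parameter"))

    _validate_structure(pm)
    return pm


def _validate_structure(pm: ParsedModel) -> None:
    ids = [pm.model_id]
    ids += [c.id for c in pm.compartments]
    ids += [s.id for s in pm.species]
    ids += [r.id for r in pm.reactions]
    seen: set[str] = set()
    for ident in ids:
        if ident in seen:
            raise SBMLStructureError(f"duplicate identifier {ident!r} in model")
        seen.add(ident)
    compartment_ids = {c.id for c in pm.compartments}
    species_ids = {s.id for s in pm.species}
    for s in pm.species:
        if s.compartment_id not in compartment_ids:
            raise SBMLStructureError(
                f"species {s.id!r} references missing compartment {s.compartment_id!r}"
            )
    for r in pm.reactions:
        for sid in r.reactants + r.products + r.modifiers:
            if sid not in species_ids:
                raise SBMLStructureError(
                    f"reaction {r.id!r} references missing species {sid!r}"
                )
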