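"""Reference-ontology loading, resolution and categorization.

Loads OBO flat files (via obonet) or OWL documents (RDF/XML or functional
syntax) into an immutable lookup structure, and categorizes every class as
physical object / process / function / quality according to which mapped
upper-level root it descends from along the transitive is_a hierarchy.
part_of relationships are retained separately (they become existential
part-of axioms in the knowledge base, never categorization evidence).
"""

from __future__ import annotations

import enum
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import obonet
import yaml

from . import names as N
from .owl.model import Named, Some, SubClassOf
from .owl.serialize import read_functional, read_rdfxml
from .sbml import EntityRef


class Category(enum.Enum):
    PHYSICAL_OBJECT = "physical_object"
    PROCESS = "process"
    FUNCTION = "function"
    QUALITY = "quality"
    UNKNOWN = "unknown"


class OntologyLoadError(ValueError):
    pass


class DuplicateClassError(OntologyLoadError):
    pass


class ResolutionError(KeyError):
    pass


class CategoryConflictError(ValueError):
    """A class descends from two disjoint upper roots: a data error."""


@dataclass(frozen=True)
class ClassRecord:
    iri: str
    curie: Optional[str]
    label: str
    parents: tuple[str, ...]  # is_a, as IRIs
    part_of: tuple[str, ...]  # as IRIs
    source: str  # provenance file name


@dataclass(frozen=True)
class Provenance:
    file: str
    format: str
    sha256: str


@dataclass
class LoadedOntologySet:
    """Class and relation tables for a set of reference ontologies.

    Treated as immutable after loading; ``merge`` returns a new set and
    rejects duplicate class ids across files.
    """

    classes: dict[str, ClassRecord] = field(default_factory=dict)
    provenance: list[Provenance] = field(default_factory=list)

    def merge(self, other: "LoadedOntologySet") -> "LoadedOntologySet":
        merged = LoadedOntologySet(dict(self.classes), list(self.provenance))
        for iri, rec in other.classes.items():
            if iri in merged.classes:
                raise DuplicateClassError(
                    f"class {rec.curie or iri} defined in both "
                    f"{merged.classes[iri].source} and {rec.source}"
                )
            merged.classes[iri] = rec
        merged.provenance.extend(other.provenance)
        return merged

    def resolve(self, ref: EntityRef) -> str:
        if not ref.resolved:
            raise ResolutionError(f"unresolved annotation URI {ref.source_uri!r}")
        iri = N.obo_iri(ref.prefix, ref.local_id)
        if iri not in self.classes:
            raise ResolutionError(f"{ref.curie} not found in loaded ontologies")
        return iri

    def by_curie(self, curie: str) -> Optional[ClassRecord]:
        return self.classes.get(N.curie_to_iri(curie))

    def by_label(self, label: str) -> list[ClassRecord]:
        return sorted(
            (rec for rec in self.classes.values() if rec.label == label),
            key=lambda rec: rec.iri,
        )

    def ancestors(self, iri: str) -> set[str]:
        """Transitive is_a ancestors of ``iri`` (excluding itself)."""
        out: set[str] = set()
        frontier = list(self.classes[iri].parents) if iri in self.classes else []
        while frontier:
            parent = frontier.pop()
            if parent not in out:
                out.add(parent)
                if parent in self.classes:
                    frontier.extend(self.classes[parent].parents)
        return out

    def axioms(self) -> list[SubClassOf]:
        """is_a and part_of links as subclass axioms for the knowledge base."""
        out = []
        for iri in sorted(self.classes):
            rec = self.classes[iri]
            for parent in rec.parents:
                out.append(SubClassOf(Named(iri), Named(parent)))
            for whole in rec.part_of:
                out.append(SubClassOf(Named(iri), Some(N.PART_OF, Named(whole))))
        return out

    def labels(self) -> dict[str, str]:
        return {iri: rec.label for iri, rec in self.classes.items() if rec.label}


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _curie_iri(token: str) -> str:
    if token.startswith("http://") or token.startswith("https://"):
        return token
    return N.curie_to_iri(token)


def load_reference_ontology(path: str | Path, format: Optional[str] = None) -> LoadedOntologySet:
    """Load one reference ontology file (``obo``, ``owl`` RDF/XML or ``ofn``)."""
    path = Path(path)
    if format is None:
        format = {".obo": "obo", ".owl": "owl", ".ofn": "ofn"}.get(path.suffix, "obo")
    if format == "obo":
        classes = _load_obo(path)
    elif format in ("owl", "rdfxml"):
        classes = _load_owl(read_rdfxml(path.read_text()), path.name)
    elif format in ("ofn", "functional"):
        classes = _load_owl(read_functional(path.read_text()), path.name)
    else:
        raise OntologyLoadError(f"unknown ontology format {format!r}")
    return LoadedOntologySet(
        classes=classes,
        provenance=[Provenance(file=path.name, format=format, sha256=_checksum(path))],
    )


def _load_obo(path: Path) -> dict[str, ClassRecord]:
    try:
        graph = obonet.read_obo(str(path))
    except Exception as exc:  # obonet raises a mix of ValueError/KeyError
        raise OntologyLoadError(f"cannot parse OBO file {path}: {exc}") from exc
    classes: dict[str, ClassRecord] = {}
    for node, data in graph.nodes(data=True):
        iri = _curie_iri(node)
        is_a = tuple(sorted(_curie_iri(p) for p in data.get("is_a", [])))
        part_of = []
        for rel in data.get("relationship", []):
            rel_type, _, target = rel.partition(" ")
            if rel_type == "part_of" and target:
                part_of.append(_curie_iri(target.strip()))
        classes[iri] = ClassRecord(
            iri=iri,
            curie=node if ":" in node else None,
            label=data.get("name", ""),
            parents=is_a,
            part_of=tuple(sorted(part_of)),
            source=path.name,
        )
    return classes


def _load_owl(ont, source: str) -> dict[str, ClassRecord]:
    parents: dict[str, set[str]] = {}
    part_of: dict[str, set[str]] = {}
    for ax in ont.axioms:
        if not isinstance(ax, SubClassOf) or not isinstance(ax.sub, Named):
            continue
        if isinstance(ax.sup, Named):
            parents.setdefault(ax.sub.iri, set()).add(ax.sup.iri)
        elif (
            isinstance(ax.sup, Some)
            and ax.sup.role.endswith(("part-of", "part_of", "BFO_0000050"))
            and isinstance(ax.sup.filler, Named)
        ):
            part_of.setdefault(ax.sub.iri, set()).add(ax.sup.filler.iri)
    classes = {}
    for iri in sorted(ont.classes):
        classes[iri] = ClassRecord(
            iri=iri,
            curie=N.iri_to_curie(iri),
            label=ont.labels.get(iri, ""),
            parents=tuple(sorted(parents.get(iri, ()))),
            part_of=tuple(sorted(part_of.get(iri, ()))),
            source=source,
        )
    return classes


# ---------------------------------------------------------------------------
# Registry files and categorization

#: RootMapping: reference-root IRI -> category token
RootMapping = dict


def load_registry(path: str | Path) -> tuple[LoadedOntologySet, dict[str, str]]:
    """Load a YAML registry mapping ontology files and category roots.

    Format::

        ontologies:
          - file: mini_go.obo
            format: obo
        roots:
          "FIX:0000100": process
          "FIX:0000101": function
    """
    path = Path(path)
    config = yaml.safe_load(path.read_text())
    onts = LoadedOntologySet()
    for entry in config.get("ontologies", []):
        file_path = path.parent / entry["file"]
        onts = onts.merge(load_reference_ontology(file_path, entry.get("format")))
    roots = {
        _curie_iri(str(root)): str(category)
        for root, category in config.get("roots", {}).items()
    }
    return onts, roots


def categorize_class(
    ref: EntityRef | str, onts: LoadedOntologySet, roots: dict[str, str]
) -> Category:
    """Category of the mapped upper root the class descends from (is_a only).

    Deterministic for a fixed ontology set.  A class under two different
    mapped roots would contradict the upper-level disjointness axioms and is
    reported as a data error.
    """
    if isinstance(ref, EntityRef):
        iri = onts.resolve(ref)
    else:
        iri = ref if ref.startswith("http") else N.curie_to_iri(ref)
        if iri not in onts.classes:
            raise ResolutionError(f"{ref} not found in loaded ontologies")
    lineage = {iri} | onts.ancestors(iri)
    categories = sorted({roots[a] for a in lineage if a in roots})
    if not categories:
        return Category.UNKNOWN
    if len(categories) > 1:
        raise CategoryConflictError(
            f"{iri} descends from roots of disjoint categories {categories}"
        )
    return Category(categories[0])
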