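"""Lightweight OWL class-expression and axiom model.

The knowledge bases emitted by this package live in a small fragment of OWL DL:
named classes, intersections, unions, existential ("some") and universal
("only") restrictions, subclass and disjointness axioms, and object-property
axioms (hierarchy, domain, range, inverse, transitivity, functionality).
Everything downstream — serialization, the tableau and EL reasoners, the query
engine — operates on these structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Union

OWL_THING = "http://www.w3.org/2002/07/owl#Thing"
OWL_NOTHING = "http://www.w3.org/2002/07/owl#Nothing"


# ---------------------------------------------------------------------------
# Class expressions


@dataclass(frozen=True)
class Named:
    iri: str

    def __repr__(self) -> str:  # compact, stable
        return f"<{self.iri}>"


@dataclass(frozen=True)
class Not:
    """Complement; appears only in reasoner-internal NNF and negated queries."""

    operand: "ClassExpression"


@dataclass(frozen=True)
class And:
    operands: tuple["ClassExpression", ...]

    def __init__(self, operands: Iterable["ClassExpression"]):
        object.__setattr__(self, "operands", tuple(operands))


@dataclass(frozen=True)
class Or:
    operands: tuple["ClassExpression", ...]

    def __init__(self, operands: Iterable["ClassExpression"]):
        object.__setattr__(self, "operands", tuple(operands))


@dataclass(frozen=True)
class Some:
    role: str
    filler: "ClassExpression"


@dataclass(frozen=True)
class Only:
    role: str
    filler: "ClassExpression"


ClassExpression = Union[Named, Not, And, Or, Some, Only]

THING = Named(OWL_THING)
NOTHING = Named(OWL_NOTHING)


def walk(expr: ClassExpression) -> Iterator[ClassExpression]:
    """Yield ``expr`` and every sub-expression."""
    yield expr
    if isinstance(expr, (And, Or)):
        for op in expr.operands:
            yield from walk(op)
    elif isinstance(expr, (Some, Only)):
        yield from walk(expr.filler)
    elif isinstance(expr, Not):
        yield from walk(expr.operand)


def named_classes_in(expr: ClassExpression) -> set[str]:
    return {e.iri for e in walk(expr) if isinstance(e, Named)}


def roles_in(expr: ClassExpression) -> set[str]:
    return {e.role for e in walk(expr) if isinstance(e, (Some, Only))}


def nnf(expr: ClassExpression, negate: bool = False) -> ClassExpression:
    """Negation normal form: complements pushed onto named classes."""
    if isinstance(expr, Named):
        return Not(expr) if negate else expr
    if isinstance(expr, Not):
        return nnf(expr.operand, not negate)
    if isinstance(expr, And):
        ops = tuple(nnf(o, negate) for o in expr.operands)
        return Or(ops) if negate else And(ops)
    if isinstance(expr, Or):
        ops = tuple(nnf(o, negate) for o in expr.operands)
        return And(ops) if negate else Or(ops)
    if isinstance(expr, Some):
        f = nnf(expr.filler, negate)
        return Only(expr.role, f) if negate else Some(expr.role, f)
    if isinstance(expr, Only):
        f = nnf(expr.filler, negate)
        return Some(expr.role, f) if negate else Only(expr.role, f)
    raise TypeError(f"not a class expression: {expr!r}")


# ---------------------------------------------------------------------------
# Axioms


@dataclass(frozen=True)
class SubClassOf:
    sub: ClassExpression
    sup: ClassExpression


@dataclass(frozen=True)
class DisjointClasses:
    operands: tuple[ClassExpression, ...]

    def __init__(self, operands: Iterable[ClassExpression]):
        object.__setattr__(self, "operands", tuple(operands))


Axiom = Union[SubClassOf, DisjointClasses]


@dataclass
class PropertySpec:
    """One object property with its declared axioms."""

    iri: str
    label: str
    domain: Optional[str] = None  # named class IRI
    range: Optional[str] = None
    inverse: Optional[str] = None  # property IRI
    parents: tuple[str, ...] = ()  # super-property IRIs
    transitive: bool = False
    functional: bool = False


# ---------------------------------------------------------------------------
# Ontology container


class Ontology:
    """An axiom set with class/property declarations, labels and annotations.

    This is the ``GeneratedOntology`` of the pipeline: the upper ontology,
    reference-ontology imports and converter output all accumulate here.
    """

    def __init__(self, iri: str = "https://w3id.org/sbmlkb/kb"):
        self.iri = iri
        self.classes: set[str] = set()
        self.labels: dict[str, str] = {}
        self.axioms: list[Axiom] = []
        self.properties: dict[str, PropertySpec] = {}
        # ontology-level annotations, e.g. profile notes and dropped axioms
        self.annotations: list[str] = []

    # -- construction -------------------------------------------------------

    def declare_class(self, iri: str, label: Optional[str] = None) -> Named:
        self.classes.add(iri)
        if label is not None:
            self.labels[iri] = label
        return Named(iri)

    def declare_property(self, spec: PropertySpec) -> None:
        self.properties[spec.iri] = spec

    def add(self, axiom: Axiom) -> None:
        self.axioms.append(axiom)

    def subclass(self, sub: ClassExpression, sup: ClassExpression) -> SubClassOf:
        ax = SubClassOf(sub, sup)
        self.axioms.append(ax)
        return ax

    def disjoint(self, *members: ClassExpression) -> DisjointClasses:
        ax = DisjointClasses(members)
        self.axioms.append(ax)
        return ax

    # -- interrogation ------------------------------------------------------

    def label_of(self, iri: str) -> str:
        return self.labels.get(iri, iri)

    def by_label(self, label: str) -> list[str]:
        """All class IRIs carrying ``label`` (case-sensitive)."""
        return sorted(iri for iri, lab in self.labels.items() if lab == label)

    def signature_roles(self) -> set[str]:
        roles: set[str] = set()
        for ax in self.axioms:
            if isinstance(ax, SubClassOf):
                roles |= roles_in(ax.sub) | roles_in(ax.sup)
            else:
                for m in ax.operands:
                    roles |= roles_in(m)
        return roles

    def copy(self) -> "Ontology":
        other = Ontology(self.iri)
        other.classes = set(self.classes)
        other.labels = dict(self.labels)
        other.axioms = list(self.axioms)
        other.properties = {k: replace(v) for k, v in self.properties.items()}
        other.annotations = list(self.annotations)
        return other

    def merge(self, other: "Ontology") -> None:
        self.classes |= other.classes
        self.labels.update(other.labels)
        self.axioms.extend(other.axioms)
        for iri, spec in other.properties.items():
            self.properties.setdefault(iri, replace(spec))
        self.annotations.extend(a for a in other.annotations if a not in self.annotations)

    def __len__(self) -> int:
        return len(self.axioms)
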