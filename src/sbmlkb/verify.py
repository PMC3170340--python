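"""Consistency verification of converted models.

Classifies the knowledge base with the tableau reasoner, detects
unsatisfiable named classes, traces them through the conversion manifest to
the SBML entities and annotations they came from, and assigns each offending
annotation a violation kind:

* ``category_mixing`` — the annotation's class category (by entailment under
  the upper-level roots) conflicts with what the entity kind is asserted to
  represent (species and compartments represent physical objects; reactions
  represent function bearers);
* ``language_feature_misuse`` — the category-mixing pattern on several
  sibling species annotated with process classes (species used to encode
  temporal stages rather than molecular pools);
* ``biological_impossibility`` — the class becomes unsatisfiable only after
  user-supplied constraint axioms are added;
* ``unclassified`` — anything else.

Unsatisfiability propagates along existential axioms (a model's world that
has an impossible part is itself impossible), so the raw unsatisfiable-class
list is usually much longer than the offender list; the offender list is the
diagnosis, the raw list the ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from . import names as N
from .convert import Manifest
from .owl.model import DisjointClasses, Named, Ontology, Some, SubClassOf
from .query import LabelResolver, _Parser, resolve_expression
from .reasoner.tableau import TableauReasoner


class ConstraintConfigurationError(ValueError):
    pass


@dataclass
class ConstraintAxiomSet:
    """Disjointness groups, named-class definitions and general rules.

    Classes and relations are referred to by label or CURIE and resolved
    against the knowledge base when the constraints are applied.
    """

    disjoint_groups: list[list[str]] = field(default_factory=list)
    definitions: dict[str, str] = field(default_factory=dict)
    rules: list[tuple[str, str]] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "ConstraintAxiomSet":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            disjoint_groups=[[str(x) for x in grp] for grp in data.get("disjoint", [])],
            definitions={str(k): str(v) for k, v in (data.get("definitions") or {}).items()},
            rules=[(str(r["sub"]), str(r["sup"])) for r in data.get("rules", [])],
        )

    def is_empty(self) -> bool:
        return not (self.disjoint_groups or self.definitions or self.rules)


def _parse_constraint_expr(text: str, resolver: LabelResolver):
    try:
        raw = _Parser(text).parse()
        return resolve_expression(raw, resolver)
    except ValueError as exc:
        raise ConstraintConfigurationError(
            f"cannot resolve constraint expression {text!r}: {exc}"
        ) from exc


def add_constraint_axioms(kb: Ontology, constraints: ConstraintAxiomSet) -> Ontology:
    """Merge constraint axioms into a copy of the knowledge base."""
    out = kb.copy()
    resolver = LabelResolver(out)
    for group in constraints.disjoint_groups:
        members = [_parse_constraint_expr(token, resolver) for token in group]
        out.add(DisjointClasses(members))
    for target, expr_text in sorted(constraints.definitions.items()):
        target_expr = _parse_constraint_expr(target, resolver)
        if not isinstance(target_expr, Named):
            raise ConstraintConfigurationError(
                f"definition target {target!r} must be a named class"
            )
        out.add(SubClassOf(target_expr, _parse_constraint_expr(expr_text, resolver)))
    for sub_text, sup_text in constraints.rules:
        out.add(
            SubClassOf(
                _parse_constraint_expr(sub_text, resolver),
                _parse_constraint_expr(sup_text, resolver),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Report


@dataclass
class UnsatisfiableClass:
    iri: str
    scope: str  # source model scope ("" for import-level classes)
    entity: str
    role: str  # insilico | rep | proc

    def to_json(self) -> dict:
        return self.__dict__.copy()


@dataclass
class OffendingAnnotation:
    scope: str
    entity: str
    kind: str  # entity kind
    qualifier: str
    target: str  # CURIE
    violation: str  # category_mixing | language_feature_misuse | biological_impossibility | unclassified
    note: str = ""

    def to_json(self) -> dict:
        return self.__dict__.copy()


@dataclass
class VerificationReport:
    coherent: bool
    unsatisfiable_classes: list[UnsatisfiableClass]
    offending_annotations: list[OffendingAnnotation]
    import_unsatisfiable: list[str]
    statistics: dict
    incomplete: bool = False

    def to_json(self) -> dict:
        return {
            "coherent": self.coherent,
            "unsatisfiable_classes": [u.to_json() for u in self.unsatisfiable_classes],
            "offending_annotations": [o.to_json() for o in self.offending_annotations],
            "import_unsatisfiable": self.import_unsatisfiable,
            "statistics": self.statistics,
            "incomplete": self.incomplete,
        }

    def write(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=2, sort_keys=True))

    def to_text(self) -> str:
        lines = [
            f"knowledge base is {'coherent' if self.coherent else 'INCOHERENT'}",
            f"unsatisfiable classes: {len(self.unsatisfiable_classes)}",
        ]
        for u in self.unsatisfiable_classes:
            lines.append(f"  {u.iri}  (model {u.scope}, entity {u.entity}, {u.role})")
        if self.offending_annotations:
            lines.append("offending annotations:")
            for o in self.offending_annotations:
                note = f"  [{o.note}]" if o.note else ""
                lines.append(
                    f"  {o.scope}/{o.entity} ({o.kind}) {o.qualifier} {o.target}: "
                    f"{o.violation}{note}"
                )
        if self.import_unsatisfiable:
            lines.append(
                f"unsatisfiable imported classes: {len(self.import_unsatisfiable)}"
            )
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Classification and tracing


def _target_category(reasoner: TableauReasoner, target_iri: str) -> Optional[str]:
    for cat, upper in (
        ("process", N.PROCESS),
        ("function", N.FUNCTION),
        ("quality", N.QUALITY),
        ("physical_object", N.PHYSICAL_OBJECT),
    ):
        if reasoner.is_subsumed_by(Named(target_iri), Named(upper)):
            return cat
    return None


_CONFLICTS = {
    "species": {"process", "function", "quality"},
    "compartment": {"process", "function", "quality"},
    "reaction": {"physical_object", "quality"},
    "model": set(),
}


def classify_and_report(
    kb: Ontology,
    manifest: Manifest,
    constraints: Optional[ConstraintAxiomSet] = None,
) -> VerificationReport:
    """Check satisfiability of every named class and trace the failures.

    When constraints are supplied, classes unsatisfiable only in the
    constrained knowledge base are assigned the ``biological_impossibility``
    kind, and the annotations of the offending entity and of its participant
    species are listed as candidate causes.
    """
    emitted = set(manifest.classes)
    base_reasoner = TableauReasoner(kb)
    base_unsat = set(base_reasoner.unsatisfiable_named_classes(emitted))
    if constraints is not None and not constraints.is_empty():
        final_kb = add_constraint_axioms(kb, constraints)
        final_reasoner = TableauReasoner(final_kb)
        final_unsat = set(final_reasoner.unsatisfiable_named_classes(emitted))
    else:
        final_kb, final_reasoner, final_unsat = kb, base_reasoner, base_unsat
    constraint_only = final_unsat - base_unsat

    import_unsat = final_reasoner.unsatisfiable_named_classes(
        set(kb.classes) - emitted
    )

    unsat_records = [
        UnsatisfiableClass(
            iri=iri,
            scope=manifest.classes[iri].scope,
            entity=manifest.classes[iri].entity,
            role=manifest.classes[iri].role,
        )
        for iri in sorted(final_unsat)
    ]

    # entities whose own emitted classes are unsatisfiable
    unsat_entities = {(u.scope, u.entity) for u in unsat_records}
    constraint_entities = {
        (manifest.classes[iri].scope, manifest.classes[iri].entity)
        for iri in constraint_only
    }

    # temporal-stage pattern: >= 2 species in one model annotated with
    # process classes
    process_species: dict[str, set[str]] = {}
    annotation_records = [
        r for r in manifest.records if r.qualifier and r.target
    ]
    categories = {
        r.target: _target_category(final_reasoner, N.curie_to_iri(r.target))
        for r in annotation_records
    }
    for r in annotation_records:
        if r.kind == "species" and categories[r.target] == "process":
            process_species.setdefault(r.scope, set()).add(r.entity)

    offences: list[OffendingAnnotation] = []
    seen = set()

    def offend(record, violation: str, note: str = "") -> None:
        key = (record.scope, record.entity, record.qualifier, record.target, violation)
        if key in seen:
            return
        seen.add(key)
        offences.append(
            OffendingAnnotation(
                scope=record.scope,
                entity=record.entity,
                kind=record.kind,
                qualifier=record.qualifier,
                target=record.target,
                violation=violation,
                note=note,
            )
        )

    participant_of: dict[tuple[str, str], set[tuple[str, str]]] = {}
    for r in manifest.records:
        if r.rule == "reaction.participants":
            filler = r.axiom.sup.filler  # Some(role, Named(rep-class))
            info = manifest.classes.get(filler.iri)
            if info:
                participant_of.setdefault((r.scope, r.entity), set()).add(
                    (info.scope, info.entity)
                )

    for r in annotation_records:
        if (r.scope, r.entity) not in unsat_entities:
            continue
        category = categories[r.target]
        if (r.scope, r.entity) in constraint_entities:
            offend(r, "biological_impossibility",
                   "unsatisfiable only under the constraint axioms")
            for participant in sorted(participant_of.get((r.scope, r.entity), ())):
                for pr in annotation_records:
                    if (pr.scope, pr.entity) == participant:
                        offend(pr, "biological_impossibility",
                               f"participant of {r.entity}")
        elif category in _CONFLICTS.get(r.kind, set()):
            if (
                r.kind == "species"
                and category == "process"
                and len(process_species.get(r.scope, ())) >= 2
            ):
                offend(r, "language_feature_misuse",
                       "process-annotated sibling species: a temporal-stage "
                       "encoding, not a molecular pool")
            else:
                offend(r, "category_mixing")
        elif (r.scope, r.entity) in {
            (u.scope, u.entity) for u in unsat_records
        } and category is None:
            offend(r, "unclassified", "annotation class has no category")

    coherent = not unsat_records and not import_unsat
    stats = {
        "checked_classes": len(emitted),
        "unsatisfiable": len(unsat_records),
        "unsatisfiable_before_constraints": len(base_unsat),
        "unsatisfiable_only_with_constraints": len(constraint_only),
        "offending_annotations": len(offences),
        "skipped_annotations": len(manifest.skipped),
    }
    return VerificationReport(
        coherent=coherent,
        unsatisfiable_classes=unsat_records,
        offending_annotations=sorted(
            offences, key=lambda o: (o.scope, o.entity, o.qualifier, o.target)
        ),
        import_unsatisfiable=import_unsat,
        statistics=stats,
    )
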