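"""SBML-to-OWL conversion.

For every SBML entity E (model, compartment, species, reaction) two named
classes are emitted: the in-silico class E (a subclass of the matching
sbml:* upper class) and the in-vivo class Rep(E) it represents, linked by
``E SubClassOf represents some Rep(E)``.  Annotation-derived axioms restrict
Rep(E) according to the qualifier (is/isVersionOf/hasVersion strict or
wrapped, isPartOf/hasPart partonomic) and the category of the annotated
reference class (physical object / function / process).  Each reaction
additionally receives a named auxiliary process class Proc(R) gathering its
process annotations and participant axioms, attached to Rep(R) through
``has-function some (realized-by only Proc(R))`` — a named filler is what
makes a biologically impossible process detectable as an unsatisfiable named
class.

Every emitted axiom carries a provenance record (model, entity, rule tag,
qualifier/target where applicable) in the conversion manifest; the rule tags
are documented in :data:`RULES`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from . import names as N
from .owl.model import (
    And,
    ClassExpression,
    Named,
    Only,
    Ontology,
    Or,
    Some,
    SubClassOf,
    walk,
)
from .owl.serialize import axiom_to_functional
from .registry import Category, LoadedOntologySet, ResolutionError, categorize_class
from .sbml import ParsedModel, QualifiedAnnotation, parse_sbml
from .upper import build_upper_ontology, attach_reference_roots

log = logging.getLogger(__name__)

PATO_CONCENTRATION = N.obo_iri("PATO", "0000033")  # Concentration
PATO_CHARGE = N.obo_iri("PATO", "2193".zfill(7))  # Charge, PATO:0002193
PATO_MASS = N.obo_iri("PATO", "0000125")  # Mass

#: Rule tags attached to every emitted axiom: the conversion rule or
#: documented design decision the axiom instantiates.
RULES = {
    "typing": "E is an instance class of the matching sbml:* upper class",
    "represents": "E SubClassOf represents some Rep(E)",
    "model-of": "models additionally link to their world via model-of",
    "category": "Rep(M)/Rep(C)/Rep(S) are physical objects",
    "proc-category": "the auxiliary reaction process class is a Process",
    "structure.part-of": "contained entity: Rep(child) part-of some Rep(parent)",
    "structure.has-part": "container side: Rep(parent) has-part some Rep(child)",
    "structure.insilico": "in-silico containment: E(child) part-of some E(model)",
    "annotation.model.object": "model + physical-object class: has-part some O",
    "annotation.model.function": "model + function class: has-part some (has-function some F)",
    "annotation.model.process": "model + process class: has-part some (has-function some (realized-by only P))",
    "annotation.model.disjunctive": "model + uncategorized class: disjunction of the three readings",
    "annotation.compartment.strict": "compartment annotation asserted as the named class",
    "annotation.species.strict": "species annotation asserted as the named class",
    "annotation.reaction.function": "reaction + function class: has-function some F",
    "annotation.reaction.process": "reaction + process class gathered into Proc(R)",
    "annotation.reaction.fallback": "reaction + other category: has-function some C (strict)",
    "annotation.part-of": "isPartOf: Rep(E) part-of some the isVersionOf interpretation",
    "annotation.has-part": "hasPart: Rep(E) has-part some the isVersionOf interpretation",
    "quality.concentration": "initial concentration: has-quality some Concentration",
    "quality.charge": "initial charge: has-quality some Charge",
    "quality.amount": "initial amount: has-quality some Mass",
    "reaction.function-link": "Rep(R) has-function some (realized-by only Proc(R))",
    "reaction.realizes": "Proc(R) realizes the reaction's annotated functions",
    "reaction.participants": "reactants/products/modifiers: has-input/-output/-modifier some Rep(S)",
}


@dataclass
class AxiomRecord:
    axiom: SubClassOf
    scope: str
    entity: str
    kind: str  # model | compartment | species | reaction
    rule: str
    qualifier: Optional[str] = None
    target: Optional[str] = None

    def to_json(self) -> dict:
        out = {
            "axiom": axiom_to_functional(self.axiom),
            "scope": self.scope,
            "entity": self.entity,
            "kind": self.kind,
            "rule": self.rule,
        }
        if self.qualifier:
            out["qualifier"] = self.qualifier
        if self.target:
            out["target"] = self.target
        return out


@dataclass
class SkippedAnnotation:
    scope: str
    entity: str
    kind: str
    qualifier: str
    uri: str
    reason: str

    def to_json(self) -> dict:
        return self.__dict__.copy()


@dataclass
class ClassInfo:
    iri: str
    scope: str
    entity: str
    kind: str
    role: str  # insilico | rep | proc


@dataclass
class Manifest:
    """Audit trail of a conversion: classes, axioms, skips, statistics."""

    mode: str = "full"
    records: list[AxiomRecord] = field(default_factory=list)
    skipped: list[SkippedAnnotation] = field(default_factory=list)
    classes: dict[str, ClassInfo] = field(default_factory=dict)
    stats: dict[str, dict] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)

    def emitted_class_count(self, scope: Optional[str] = None) -> int:
        return sum(
            1 for info in self.classes.values() if scope is None or info.scope == scope
        )

    def entity_of(self, iri: str) -> Optional[ClassInfo]:
        return self.classes.get(iri)

    def to_json(self) -> dict:
        return {
            "mode": self.mode,
            "axioms": [r.to_json() for r in self.records],
            "skipped_annotations": [s.to_json() for s in self.skipped],
            "classes": {
                iri: {
                    "scope": c.scope,
                    "entity": c.entity,
                    "kind": c.kind,
                    "role": c.role,
                }
                for iri, c in sorted(self.classes.items())
            },
            "statistics": self.stats,
            "failures": self.failures,
        }

    def write(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=2, sort_keys=True))


@dataclass
class ConversionResult:
    ontology: Ontology
    manifest: Manifest


# ---------------------------------------------------------------------------
# IRIs


def rep_iri(entity_id: str, model_scope: str) -> tuple[str, str]:
    """Deterministic (in-silico, Rep) class IRI pair, scoped by model id."""
    ns = N.model_scope_ns(model_scope)
    return ns + entity_id, ns + "Rep_" + entity_id


def proc_iri(reaction_id: str, model_scope: str) -> str:
    return N.model_scope_ns(model_scope) + "Proc_" + reaction_id


# ---------------------------------------------------------------------------
# Annotation interpretation (the conversion rules)

_STRICT_KINDS = ("compartment", "species")
_VERSION_QUALIFIERS = ("is", "isVersionOf", "hasVersion")


def _intrinsic(entity_kind: str, target: Named, category: Category) -> ClassExpression:
    """The is/isVersionOf/hasVersion reading of an annotation target."""
    if entity_kind in _STRICT_KINDS:
        # strict assertion regardless of category: mixed categories must
        # surface as unsatisfiable classes, not be explained away
        return target
    if entity_kind == "model":
        if category is Category.PHYSICAL_OBJECT:
            return Some(N.HAS_PART, target)
        if category is Category.FUNCTION:
            return Some(N.HAS_PART, Some(N.HAS_FUNCTION, target))
        if category is Category.PROCESS:
            return Some(N.HAS_PART, Some(N.HAS_FUNCTION, Only(N.REALIZED_BY, target)))
        # uncategorized: disjunctive interpretation over the three readings
        return Or(
            (
                Some(N.HAS_PART, target),
                Some(N.HAS_PART, Some(N.HAS_FUNCTION, target)),
                Some(N.HAS_PART, Some(N.HAS_FUNCTION, Only(N.REALIZED_BY, target))),
            )
        )
    if entity_kind == "reaction":
        if category is Category.PROCESS:
            return Some(N.HAS_FUNCTION, Only(N.REALIZED_BY, target))
        # functions, and the strict fallback for any other category: the
        # has-function range (Function, disjoint with PhysicalObject) is what
        # flags reactions annotated with physical-object classes
        return Some(N.HAS_FUNCTION, target)
    raise ValueError(f"unknown entity kind {entity_kind!r}")


def interpret_annotation(
    entity_kind: str, ann: QualifiedAnnotation, category: Category
) -> ClassExpression:
    """The superclass contribution of one qualified annotation to Rep(E)."""
    if ann.qualifier not in ("is", "isVersionOf", "hasVersion", "isPartOf", "hasPart"):
        raise ValueError(f"unsupported qualifier {ann.qualifier!r}")
    target = Named(N.obo_iri(ann.target.prefix, ann.target.local_id))
    if ann.qualifier in _VERSION_QUALIFIERS:
        return _intrinsic(entity_kind, target, category)
    interp = _intrinsic(entity_kind, target, category)
    role = N.PART_OF if ann.qualifier == "isPartOf" else N.HAS_PART
    return Some(role, interp)


def _model_annotation_rule(category: Category) -> str:
    return {
        Category.PHYSICAL_OBJECT: "annotation.model.object",
        Category.FUNCTION: "annotation.model.function",
        Category.PROCESS: "annotation.model.process",
    }.get(category, "annotation.model.disjunctive")


# ---------------------------------------------------------------------------
# Model conversion


class _Emitter:
    def __init__(self, ont: Ontology, manifest: Manifest, scope: str):
        self.ont = ont
        self.manifest = manifest
        self.scope = scope

    def declare(self, iri: str, label: str, entity: str, kind: str, role: str) -> Named:
        self.ont.declare_class(iri, label)
        self.manifest.classes[iri] = ClassInfo(
            iri=iri, scope=self.scope, entity=entity, kind=kind, role=role
        )
        return Named(iri)

    def emit(
        self,
        sub: Named,
        sup: ClassExpression,
        rule: str,
        entity: str,
        kind: str,
        qualifier: Optional[str] = None,
        target: Optional[str] = None,
    ) -> None:
        assert rule in RULES, f"undocumented rule tag {rule}"
        ax = SubClassOf(sub, sup)
        self.ont.add(ax)
        self.manifest.records.append(
            AxiomRecord(
                axiom=ax,
                scope=self.scope,
                entity=entity,
                kind=kind,
                rule=rule,
                qualifier=qualifier,
                target=target,
            )
        )


def base_ontology(
    onts: LoadedOntologySet, roots: dict[str, str], mode: str = "full"
) -> Ontology:
    """Upper ontology + reference-ontology imports, ready for model axioms."""
    ont = attach_reference_roots(build_upper_ontology(el_safe=mode == "el"), roots)
    ont.iri = "https://w3id.org/sbmlkb/kb"
    for iri, rec in onts.classes.items():
        ont.declare_class(iri, rec.label or None)
    for ax in onts.axioms():
        ont.add(ax)
    return ont


def _convert_into(
    emitter: _Emitter,
    pm: ParsedModel,
    onts: LoadedOntologySet,
    roots: dict[str, str],
    mode: str,
) -> None:
    scope = emitter.scope
    manifest = emitter.manifest
    e_m_iri, rep_m_iri = rep_iri(pm.model_id, scope)
    e_m = emitter.declare(e_m_iri, pm.model_id, pm.model_id, "model", "insilico")
    rep_m = emitter.declare(
        rep_m_iri, f"Rep({pm.model_id})", pm.model_id, "model", "rep"
    )
    emitter.emit(e_m, Named(N.SBML_MODEL), "typing", pm.model_id, "model")
    emitter.emit(e_m, Some(N.REPRESENTS, rep_m), "represents", pm.model_id, "model")
    emitter.emit(e_m, Some(N.MODEL_OF, rep_m), "model-of", pm.model_id, "model")
    emitter.emit(rep_m, Named(N.PHYSICAL_OBJECT), "category", pm.model_id, "model")

    def annotate(kind: str, entity_id: str, rep: Named, anns, proc: Optional[Named]):
        for ann in anns:
            if ann.ignored:
                continue
            if not ann.target.resolved:
                manifest.skipped.append(
                    SkippedAnnotation(scope, entity_id, kind, ann.qualifier,
                                      ann.target.source_uri, "unresolved URI")
                )
                log.warning("%s/%s: skipping unresolved %s", scope, entity_id,
                            ann.target.source_uri)
                continue
            try:
                target_iri = onts.resolve(ann.target)
                category = categorize_class(ann.target, onts, roots)
            except ResolutionError:
                manifest.skipped.append(
                    SkippedAnnotation(scope, entity_id, kind, ann.qualifier,
                                      ann.target.source_uri,
                                      "class not in loaded ontologies")
                )
                log.warning("%s/%s: %s not in loaded ontologies", scope,
                            entity_id, ann.target.curie)
                continue
            target = Named(target_iri)
            curie = ann.target.curie
            if ann.qualifier in _VERSION_QUALIFIERS:
                if kind == "model":
                    rule = _model_annotation_rule(category)
                    if rule == "annotation.model.disjunctive" and mode == "el":
                        manifest.skipped.append(
                            SkippedAnnotation(scope, entity_id, kind,
                                              ann.qualifier, ann.target.source_uri,
                                              "disjunctive interpretation not EL-expressible")
                        )
                        continue
                    emitter.emit(rep, interpret_annotation(kind, ann, category),
                                 rule, entity_id, kind, ann.qualifier, curie)
                elif kind in _STRICT_KINDS:
                    emitter.emit(rep, target, f"annotation.{kind}.strict",
                                 entity_id, kind, ann.qualifier, curie)
                else:  # reaction
                    if category is Category.PROCESS:
                        emitter.emit(proc, target, "annotation.reaction.process",
                                     entity_id, kind, ann.qualifier, curie)
                    else:
                        rule = ("annotation.reaction.function"
                                if category is Category.FUNCTION
                                else "annotation.reaction.fallback")
                        emitter.emit(rep, Some(N.HAS_FUNCTION, target), rule,
                                     entity_id, kind, ann.qualifier, curie)
                        if category is Category.FUNCTION:
                            emitter.emit(proc, Some(N.REALIZES, target),
                                         "reaction.realizes", entity_id, kind,
                                         ann.qualifier, curie)
            else:  # isPartOf / hasPart
                rule = ("annotation.part-of" if ann.qualifier == "isPartOf"
                        else "annotation.has-part")
                emitter.emit(rep, interpret_annotation(kind, ann, category),
                             rule, entity_id, kind, ann.qualifier, curie)

    annotate("model", pm.model_id, rep_m, pm.annotations, None)

    rep_of: dict[str, Named] = {}
    for comp in pm.compartments:
        e_iri, r_iri = rep_iri(comp.id, scope)
        e_c = emitter.declare(e_iri, comp.id, comp.id, "compartment", "insilico")
        rep_c = emitter.declare(r_iri, f"Rep({comp.id})", comp.id, "compartment", "rep")
        rep_of[comp.id] = rep_c
        emitter.emit(e_c, Named(N.SBML_COMPARTMENT), "typing", comp.id, "compartment")
        emitter.emit(e_c, Some(N.REPRESENTS, rep_c), "represents", comp.id, "compartment")
        emitter.emit(e_c, Some(N.PART_OF, e_m), "structure.insilico", comp.id, "compartment")
        emitter.emit(rep_c, Named(N.PHYSICAL_OBJECT), "category", comp.id, "compartment")
        emitter.emit(rep_c, Some(N.PART_OF, rep_m), "structure.part-of", comp.id, "compartment")
        emitter.emit(rep_m, Some(N.HAS_PART, rep_c), "structure.has-part", comp.id, "compartment")
        annotate("compartment", comp.id, rep_c, comp.annotations, None)

    for sp in pm.species:
        e_iri, r_iri = rep_iri(sp.id, scope)
        e_s = emitter.declare(e_iri, sp.id, sp.id, "species", "insilico")
        rep_s = emitter.declare(r_iri, f"Rep({sp.id})", sp.id, "species", "rep")
        rep_of[sp.id] = rep_s
        e_c, _ = rep_iri(sp.compartment_id, scope)
        rep_c = rep_of[sp.compartment_id]
        emitter.emit(e_s, Named(N.SBML_SPECIES), "typing", sp.id, "species")
        emitter.emit(e_s, Some(N.REPRESENTS, rep_s), "represents", sp.id, "species")
        emitter.emit(e_s, Some(N.PART_OF, Named(e_c)), "structure.insilico", sp.id, "species")
        emitter.emit(rep_s, Named(N.PHYSICAL_OBJECT), "category", sp.id, "species")
        emitter.emit(rep_s, Some(N.PART_OF, rep_c), "structure.part-of", sp.id, "species")
        emitter.emit(rep_c, Some(N.HAS_PART, rep_s), "structure.has-part", sp.id, "species")
        if sp.has_initial_concentration:
            emitter.emit(rep_s, Some(N.HAS_QUALITY, Named(PATO_CONCENTRATION)),
                         "quality.concentration", sp.id, "species")
        if sp.has_initial_charge:
            emitter.emit(rep_s, Some(N.HAS_QUALITY, Named(PATO_CHARGE)),
                         "quality.charge", sp.id, "species")
        if sp.has_initial_amount:
            emitter.emit(rep_s, Some(N.HAS_QUALITY, Named(PATO_MASS)),
                         "quality.amount", sp.id, "species")
        annotate("species", sp.id, rep_s, sp.annotations, None)

    for rx in pm.reactions:
        e_iri, r_iri = rep_iri(rx.id, scope)
        p_iri = proc_iri(rx.id, scope)
        e_r = emitter.declare(e_iri, rx.id, rx.id, "reaction", "insilico")
        rep_r = emitter.declare(r_iri, f"Rep({rx.id})", rx.id, "reaction", "rep")
        proc_r = emitter.declare(p_iri, f"Proc({rx.id})", rx.id, "reaction", "proc")
        emitter.emit(e_r, Named(N.SBML_REACTION), "typing", rx.id, "reaction")
        emitter.emit(e_r, Some(N.REPRESENTS, rep_r), "represents", rx.id, "reaction")
        emitter.emit(e_r, Some(N.PART_OF, e_m), "structure.insilico", rx.id, "reaction")
        emitter.emit(rep_r, Some(N.PART_OF, rep_m), "structure.part-of", rx.id, "reaction")
        emitter.emit(rep_m, Some(N.HAS_PART, rep_r), "structure.has-part", rx.id, "reaction")
        emitter.emit(proc_r, Named(N.PROCESS), "proc-category", rx.id, "reaction")
        emitter.emit(rep_r, Some(N.HAS_FUNCTION, Only(N.REALIZED_BY, proc_r)),
                     "reaction.function-link", rx.id, "reaction")
        for sid in rx.reactants:
            emitter.emit(proc_r, Some(N.HAS_INPUT, rep_of[sid]),
                         "reaction.participants", rx.id, "reaction")
        for sid in rx.products:
            emitter.emit(proc_r, Some(N.HAS_OUTPUT, rep_of[sid]),
                         "reaction.participants", rx.id, "reaction")
        for sid in rx.modifiers:
            emitter.emit(proc_r, Some(N.HAS_MODIFIER, rep_of[sid]),
                         "reaction.participants", rx.id, "reaction")
        annotate("reaction", rx.id, rep_r, rx.annotations, proc_r)

    manifest.stats[scope] = {
        "model_id": pm.model_id,
        "compartments": len(pm.compartments),
        "species": len(pm.species),
        "reactions": len(pm.reactions),
        "parameters": pm.n_parameters,
        "emitted_classes": manifest.emitted_class_count(scope),
        "emitted_axioms": sum(1 for r in manifest.records if r.scope == scope),
    }


def convert_model(
    pm: ParsedModel,
    onts: LoadedOntologySet,
    roots: dict[str, str],
    mode: str = "full",
    scope: Optional[str] = None,
) -> ConversionResult:
    """Convert one parsed model into a knowledge base with manifest."""
    if mode not in ("full", "el"):
        raise ValueError(f"unknown mode {mode!r}")
    scope = scope or pm.model_id
    ont = base_ontology(onts, roots, mode)
    manifest = Manifest(mode=mode)
    emitter = _Emitter(ont, manifest, scope)
    _convert_into(emitter, pm, onts, roots, mode)
    if mode == "el":
        ont = _rewrite_el(ont, manifest)
    _canonicalize(ont)
    return ConversionResult(ont, manifest)


def convert_corpus(
    files: Sequence[Union[str, Path, ParsedModel]],
    onts: LoadedOntologySet,
    roots: dict[str, str],
    mode: str = "full",
) -> ConversionResult:
    """Convert a corpus of SBML files into one combined knowledge base.

    Per-model IRI scopes prevent collisions (a duplicated model id receives a
    numbered scope).  A file-level failure is isolated: the corpus build
    continues and the failure is recorded in the manifest.
    """
    ont = base_ontology(onts, roots, mode)
    manifest = Manifest(mode=mode)
    used_scopes: set[str] = set()
    for item in files:
        source = str(item) if not isinstance(item, ParsedModel) else item.model_id
        try:
            pm = item if isinstance(item, ParsedModel) else parse_sbml(Path(item))
        except Exception as exc:
            manifest.failures[source] = str(exc)
            log.error("skipping %s: %s", source, exc)
            continue
        scope = pm.model_id
        counter = 1
        while scope in used_scopes:
            counter += 1
            scope = f"{pm.model_id}-{counter}"
        used_scopes.add(scope)
        _convert_into(_Emitter(ont, manifest, scope), pm, onts, roots, mode)
    if mode == "el":
        ont = _rewrite_el(ont, manifest)
    _canonicalize(ont)
    return ConversionResult(ont, manifest)


# ---------------------------------------------------------------------------
# OWL EL reduction


def _only_to_some(expr: ClassExpression) -> ClassExpression:
    if isinstance(expr, Named):
        return expr
    if isinstance(expr, And):
        return And(_only_to_some(o) for o in expr.operands)
    if isinstance(expr, Or):
        return Or(_only_to_some(o) for o in expr.operands)
    if isinstance(expr, Some):
        return Some(expr.role, _only_to_some(expr.filler))
    if isinstance(expr, Only):
        return Some(expr.role, _only_to_some(expr.filler))
    raise TypeError(f"unexpected expression {expr!r}")


def _contains(expr: ClassExpression, kind) -> bool:
    return any(isinstance(e, kind) for e in walk(expr))


def to_el_profile(kb: Ontology) -> Ontology:
    """Rewrite a full-mode knowledge base into the OWL EL profile.

    Universal restrictions over realized-by become existential restrictions;
    the upper ontology's universal part-of constraints are dropped (universal
    quantification is unsupported in EL, and weakening them to existentials
    would assert parts that need not exist); union-bearing axioms (the
    disjunctive model reading) are dropped; inverse-property axioms and
    property functionality are removed.  Everything dropped is recorded in
    the output ontology's annotations.
    """
    out = kb.copy()
    return _rewrite_el(out, None)


def _rewrite_el(ont: Ontology, manifest: Optional[Manifest]) -> Ontology:
    dropped_universal = 0
    dropped_union = 0
    new_axioms = []
    keep_records = []
    record_by_axiom: dict[int, AxiomRecord] = {}
    if manifest:
        for rec in manifest.records:
            record_by_axiom[id(rec.axiom)] = rec
    for ax in ont.axioms:
        if isinstance(ax, SubClassOf):
            # upper-ontology universal constraints: drop
            if isinstance(ax.sup, Only) and isinstance(ax.sub, Named) and ax.sub.iri in (
                N.PHYSICAL_OBJECT,
                N.PROCESS,
            ):
                dropped_universal += 1
                continue
            if _contains(ax.sub, Or) or _contains(ax.sup, Or):
                dropped_union += 1
                continue
            new_ax = SubClassOf(_only_to_some(ax.sub), _only_to_some(ax.sup))
            new_axioms.append(new_ax)
            if manifest and id(ax) in record_by_axiom:
                rec = record_by_axiom[id(ax)]
                rec.axiom = new_ax
                keep_records.append(rec)
        else:
            new_axioms.append(ax)
    ont.axioms = new_axioms
    if manifest:
        manifest.records = keep_records
    for spec in ont.properties.values():
        spec.inverse = None
        spec.functional = False
    ont.annotations.append(
        "profile: OWL EL (universal restrictions on realized-by rewritten to "
        f"existentials; {dropped_universal} universal part-of constraint(s) and "
        f"{dropped_union} union-bearing axiom(s) dropped; inverse and "
        "functional property axioms removed)"
    )
    return ont


def el_profile_violations(ont: Ontology) -> dict[str, int]:
    """Syntactic OWL EL conformance scan of an axiom set."""
    universal = union = 0
    for ax in ont.axioms:
        exprs = (
            [ax.sub, ax.sup] if isinstance(ax, SubClassOf) else list(ax.operands)
        )
        for expr in exprs:
            universal += sum(1 for e in walk(expr) if isinstance(e, Only))
            union += sum(1 for e in walk(expr) if isinstance(e, Or))
    inverse = sum(1 for s in ont.properties.values() if s.inverse)
    functional = sum(1 for s in ont.properties.values() if s.functional)
    return {
        "universal_restrictions": universal,
        "unions": union,
        "inverse_property_axioms": inverse,
        "functional_property_axioms": functional,
    }


def _canonicalize(ont: Ontology) -> None:
    """Sort axioms canonically so serialized output is byte-stable."""
    ont.axioms.sort(key=axiom_to_functional)
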