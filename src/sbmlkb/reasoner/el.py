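"""A polynomial-time classifier for the OWL EL fragment of the knowledge base.

EL-mode knowledge bases contain only named classes, intersections and
existential restrictions on axiom right-hand sides, plus class disjointness,
role hierarchy, transitivity and domain/range axioms.  For that Horn fragment
a completion ("saturation") procedure decides subsumption and class
satisfiability without search: each context (a named class, or an existential
successor intersected with the applicable role ranges) accumulates its derived
subsumers and existential links until a fixpoint is reached.

This classifier is deliberately independent of the tableau calculus in
:mod:`sbmlkb.reasoner.tableau`; the two are cross-checked in the test suite.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Optional

from ..owl.model import (
    And,
    ClassExpression,
    DisjointClasses,
    Named,
    Only,
    Ontology,
    Or,
    OWL_NOTHING,
    OWL_THING,
    Some,
    SubClassOf,
)

_BOT = OWL_NOTHING

Context = frozenset[str]  # the core: named classes the context is built from


class NotInProfileError(ValueError):
    """Raised when the input ontology leaves the supported EL fragment."""


class ELClassifier:
    def __init__(self, ontology: Ontology):
        self.ontology = ontology
        # name -> superclass items (Named | Some with named filler marker)
        self.tbox: dict[str, list[ClassExpression]] = {}
        self.disjoint: set[frozenset[str]] = set()
        self._role_sup: dict[str, frozenset[str]] = {}
        self._transitive: set[str] = set()
        self._domain: dict[str, str] = {}
        self._range: dict[str, str] = {}
        self._synth = itertools.count()
        self._filler_name: dict[ClassExpression, str] = {}
        self._load(ontology)
        self.S: dict[Context, set[str]] = {}
        self.R: dict[Context, set[tuple[str, Context]]] = {}
        self._saturate()

    # -- normalization ------------------------------------------------------

    def _name_for(self, expr: ClassExpression) -> str:
        """A synthetic name standing for a complex (conjunction) filler."""
        if isinstance(expr, Named):
            return expr.iri
        if expr in self._filler_name:
            return self._filler_name[expr]
        name = f"urn:sbmlkb:el-aux:{next(self._synth)}"
        self._filler_name[expr] = name
        self._normalize_into(name, expr)
        return name

    def _normalize_into(self, name: str, expr: ClassExpression) -> None:
        items = self.tbox.setdefault(name, [])
        if isinstance(expr, Named):
            if expr.iri != OWL_THING:
                items.append(expr)
        elif isinstance(expr, And):
            for op in expr.operands:
                self._normalize_into(name, op)
        elif isinstance(expr, Some):
            items.append(Some(expr.role, Named(self._name_for(expr.filler))))
        elif isinstance(expr, (Or, Only)):
            raise NotInProfileError(
                f"axiom for {name} uses a non-EL constructor: {type(expr).__name__}"
            )
        else:
            raise NotInProfileError(f"unsupported expression {expr!r}")

    def _load(self, ont: Ontology) -> None:
        for ax in ont.axioms:
            if isinstance(ax, SubClassOf):
                if not isinstance(ax.sub, Named):
                    raise NotInProfileError(
                        "general inclusions with complex left sides are outside "
                        "the supported EL fragment"
                    )
                self._normalize_into(ax.sub.iri, ax.sup)
            elif isinstance(ax, DisjointClasses):
                names = []
                for op in ax.operands:
                    if not isinstance(op, Named):
                        raise NotInProfileError("disjointness over complex classes")
                    names.append(op.iri)
                for i, a in enumerate(names):
                    for b in names[i + 1:]:
                        self.disjoint.add(frozenset((a, b)))
        for spec in ont.properties.values():
            if spec.transitive:
                self._transitive.add(spec.iri)
            if spec.domain:
                self._domain[spec.iri] = spec.domain
            if spec.range:
                self._range[spec.iri] = spec.range
        parents = {iri: set(spec.parents) for iri, spec in ont.properties.items()}
        for iri in list(parents):
            closure = {iri}
            frontier = set(parents.get(iri, ()))
            while frontier:
                r = frontier.pop()
                if r not in closure:
                    closure.add(r)
                    frontier |= set(parents.get(r, ()))
            self._role_sup[iri] = frozenset(closure)

    def sup_roles(self, role: str) -> frozenset[str]:
        return self._role_sup.get(role, frozenset({role}))

    # -- saturation ---------------------------------------------------------

    def _context(self, core: Iterable[str]) -> Context:
        ctx = frozenset(core)
        if ctx not in self.S:
            self.S[ctx] = set(ctx)
            self.R[ctx] = set()
        return ctx

    def _successor_core(self, role: str, filler: str) -> Context:
        core = {filler}
        for s in self.sup_roles(role):
            rng = self._range.get(s)
            if rng:
                core.add(rng)
        return self._context(core)

    def _saturate(self) -> None:
        for iri in sorted(set(self.ontology.classes) | set(self.tbox)):
            if iri != OWL_THING:
                self._context([iri])
        changed = True
        while changed:
            changed = False
            for ctx in list(self.S):
                subsumers = self.S[ctx]
                for name in list(subsumers):
                    for item in self.tbox.get(name, ()):
                        if isinstance(item, Named):
                            if item.iri not in subsumers:
                                subsumers.add(item.iri)
                                changed = True
                        else:  # Some with named filler
                            succ = self._successor_core(item.role, item.filler.iri)
                            edge = (item.role, succ)
                            if edge not in self.R[ctx]:
                                self.R[ctx].add(edge)
                                changed = True
                for pair in self.disjoint:
                    if pair <= subsumers and _BOT not in subsumers:
                        subsumers.add(_BOT)
                        changed = True
                for role, succ in list(self.R[ctx]):
                    for s in self.sup_roles(role):
                        dom = self._domain.get(s)
                        if dom and dom not in subsumers:
                            subsumers.add(dom)
                            changed = True
                    if _BOT in self.S[succ] and _BOT not in subsumers:
                        subsumers.add(_BOT)
                        changed = True
                    # transitivity: compose chains through any transitive role
                    for role2, succ2 in list(self.R[succ]):
                        for t in self._transitive:
                            if (
                                t in self.sup_roles(role)
                                and t in self.sup_roles(role2)
                                and (t, succ2) not in self.R[ctx]
                            ):
                                self.R[ctx].add((t, succ2))
                                changed = True

    # -- queries ------------------------------------------------------------

    def _holds(
        self, ctx: Context, query: ClassExpression, seen: set
    ) -> bool:
        if _BOT in self.S[ctx]:
            return True
        if isinstance(query, Named):
            return query.iri == OWL_THING or query.iri in self.S[ctx]
        if isinstance(query, And):
            return all(self._holds(ctx, op, seen) for op in query.operands)
        if isinstance(query, Some):
            key = (ctx, query)
            if key in seen:
                return False
            seen = seen | {key}
            for role, succ in self.R[ctx]:
                if query.role in self.sup_roles(role) and self._holds(
                    succ, query.filler, seen
                ):
                    return True
            return False
        raise NotInProfileError(f"non-EL query constructor: {type(query).__name__}")

    def is_subsumed_by(self, sub: str, query: ClassExpression) -> bool:
        ctx = self._context([sub])
        self._saturate()
        return self._holds(ctx, query, set())

    def is_satisfiable(self, iri: str) -> bool:
        ctx = self._context([iri])
        self._saturate()
        return _BOT not in self.S[ctx]

    def unsatisfiable_named_classes(
        self, candidates: Optional[Iterable[str]] = None
    ) -> list[str]:
        iris = sorted(candidates) if candidates is not None else sorted(self.ontology.classes)
        return [
            iri
            for iri in iris
            if iri not in (OWL_THING, OWL_NOTHING) and not self.is_satisfiable(iri)
        ]

    def subclasses_of(
        self,
        expr: ClassExpression,
        candidates: Optional[Iterable[str]] = None,
    ) -> set[str]:
        iris = set(candidates) if candidates is not None else set(self.ontology.classes)
        iris -= {OWL_THING, OWL_NOTHING}
        if isinstance(expr, Named) and expr.iri == OWL_NOTHING:
            return set(self.unsatisfiable_named_classes(iris))
        return {
            iri
            for iri in iris
            if self.is_satisfiable(iri) and self.is_subsumed_by(iri, expr)
        }
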