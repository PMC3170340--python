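"""A tableau-based description-logic reasoner.

Decides class satisfiability and subsumption for the fragment the converter
emits and the query language exposes: ALCH with transitive roles (role
hierarchy, domain/range axioms, class disjointness, intersections, unions,
existential and universal restrictions), with general concept inclusions
admitted for constraint axioms.  Inverse-role semantics and number
restrictions are not part of the calculus: no emitted axiom and no packaged
query requires them (inverses are declared in the ontology metadata only).

The calculus is the standard one: a completion graph is expanded by
deterministic rules (conjunction, lazy unfolding of named classes, universal
restrictions with the transitivity propagation rule, domain/range firing on
edge creation), disjunctions branch with backtracking, existentials generate
fresh successors guarded by subset blocking (sound and complete for this
fragment, which has no inverse roles).
"""

from __future__ import annotations

from typing import Iterable, Optional

from ..owl.model import (
    And,
    ClassExpression,
    DisjointClasses,
    Named,
    Not,
    NOTHING,
    Only,
    Ontology,
    Or,
    OWL_NOTHING,
    OWL_THING,
    Some,
    SubClassOf,
    THING,
    nnf,
)
from ..owl.serialize import expr_to_functional


def _sort_key(expr: ClassExpression) -> str:
    return expr_to_functional(expr)


class _State:
    """One completion graph; copied when a disjunction branches."""

    __slots__ = ("labels", "out_edges", "parent", "done_some", "queue", "next_id")

    def __init__(self) -> None:
        self.labels: dict[int, set[ClassExpression]] = {0: set()}
        self.out_edges: dict[int, list[tuple[str, int]]] = {0: []}
        self.parent: dict[int, int] = {}
        self.done_some: set[tuple[int, ClassExpression]] = set()
        self.queue: list[tuple[int, ClassExpression]] = []
        self.next_id = 1

    def copy(self) -> "_State":
        st = _State.__new__(_State)
        st.labels = {n: set(l) for n, l in self.labels.items()}
        st.out_edges = {n: list(e) for n, e in self.out_edges.items()}
        st.parent = dict(self.parent)
        st.done_some = set(self.done_some)
        st.queue = list(self.queue)
        st.next_id = self.next_id
        return st


class TableauReasoner:
    def __init__(self, ontology: Ontology):
        self.ontology = ontology
        self.unfold: dict[str, list[ClassExpression]] = {}
        self.gcis: list[ClassExpression] = []
        self._role_sup: dict[str, frozenset[str]] = {}
        self._transitive: set[str] = set()
        self._domain: dict[str, str] = {}
        self._range: dict[str, str] = {}
        self._sat_cache: dict[ClassExpression, bool] = {}
        self._load(ontology)

    # -- preprocessing ------------------------------------------------------

    def _load(self, ont: Ontology) -> None:
        for ax in ont.axioms:
            if isinstance(ax, SubClassOf):
                if isinstance(ax.sub, Named):
                    if ax.sub.iri == OWL_THING:
                        self.gcis.append(nnf(ax.sup))
                    else:
                        self.unfold.setdefault(ax.sub.iri, []).append(nnf(ax.sup))
                else:
                    # general inclusion: internalized as (not sub) or sup
                    self.gcis.append(
                        Or((nnf(ax.sub, negate=True), nnf(ax.sup)))
                    )
            elif isinstance(ax, DisjointClasses):
                ops = list(ax.operands)
                for i, a in enumerate(ops):
                    for b in ops[i + 1:]:
                        if isinstance(a, Named) and isinstance(b, Named):
                            self.unfold.setdefault(a.iri, []).append(Not(b))
                            self.unfold.setdefault(b.iri, []).append(Not(a))
                        else:
                            self.gcis.append(
                                Or((nnf(a, negate=True), nnf(b, negate=True)))
                            )
        for spec in ont.properties.values():
            if spec.transitive:
                self._transitive.add(spec.iri)
            if spec.domain:
                self._domain[spec.iri] = spec.domain
            if spec.range:
                self._range[spec.iri] = spec.range
        # reflexive-transitive closure of the role hierarchy
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

    # -- calculus -----------------------------------------------------------

    def _add(self, st: _State, node: int, expr: ClassExpression) -> bool:
        """Add ``expr`` to a node label and queue it; True if changed."""
        if expr == THING:
            return False
        label = st.labels[node]
        if expr in label:
            return False
        label.add(expr)
        st.queue.append((node, expr))
        return True

    def _new_node(self, st: _State, x: int, role: str, filler: ClassExpression) -> None:
        y = st.next_id
        st.next_id += 1
        st.labels[y] = set()
        st.out_edges[y] = []
        st.parent[y] = x
        st.out_edges[x].append((role, y))
        self._add(st, y, filler)
        sups = self.sup_roles(role)
        for s in sups:
            dom = self._domain.get(s)
            if dom:
                self._add(st, x, Named(dom))
            rng = self._range.get(s)
            if rng:
                self._add(st, y, Named(rng))
        for gci in self.gcis:
            self._add(st, y, gci)
        # universal restrictions already on x apply to the new edge
        for expr in list(st.labels[x]):
            if isinstance(expr, Only) and expr.role in sups:
                self._propagate_only(st, expr, role, y, sups)

    def _propagate_only(
        self, st: _State, only: Only, edge_role: str, y: int, sups: frozenset[str]
    ) -> None:
        self._add(st, y, only.filler)
        for t in self._transitive:
            if t in sups and only.role in self.sup_roles(t):
                self._add(st, y, Only(t, only.filler))

    def _is_clash(self, st: _State, node: int, expr: ClassExpression) -> bool:
        label = st.labels[node]
        if expr == NOTHING or expr == Not(THING):
            return True
        if isinstance(expr, Named):
            return Not(expr) in label
        if isinstance(expr, Not):
            return expr.operand in label
        return False

    def _blocked(self, st: _State, node: int) -> bool:
        label = st.labels[node]
        anc = st.parent.get(node)
        while anc is not None:
            if label <= st.labels[anc]:
                return True
            anc = st.parent.get(anc)
        return False

    def _drain(self, st: _State) -> bool:
        """Apply non-branching rules until the queue empties; False on clash."""
        while st.queue:
            node, expr = st.queue.pop()
            if self._is_clash(st, node, expr):
                return False
            if isinstance(expr, And):
                for op in expr.operands:
                    self._add(st, node, op)
            elif isinstance(expr, Named):
                for sup in self.unfold.get(expr.iri, ()):
                    self._add(st, node, sup)
            elif isinstance(expr, Only):
                for role, y in list(st.out_edges[node]):
                    sups = self.sup_roles(role)
                    if expr.role in sups:
                        self._propagate_only(st, expr, role, y, sups)
            # Not / Or / Some are handled at addition or in the outer loop
        return True

    def _expand(self, st: _State) -> bool:
        while True:
            if not self._drain(st):
                return False
            # branch on the first unsatisfied disjunction (stable order)
            branch = None
            for node in sorted(st.labels):
                ors = [
                    e
                    for e in st.labels[node]
                    if isinstance(e, Or)
                    and not any(d in st.labels[node] for d in e.operands)
                ]
                if ors:
                    branch = (node, min(ors, key=_sort_key))
                    break
            if branch is not None:
                node, disj = branch
                for op in sorted(disj.operands, key=_sort_key):
                    sub = st.copy()
                    self._add(sub, node, op)
                    if self._expand(sub):
                        return True
                return False
            # generate a successor for the first pending existential
            generated = False
            for node in sorted(st.labels):
                somes = [
                    e
                    for e in st.labels[node]
                    if isinstance(e, Some) and (node, e) not in st.done_some
                ]
                if somes and not self._blocked(st, node):
                    some = min(somes, key=_sort_key)
                    st.done_some.add((node, some))
                    self._new_node(st, node, some.role, some.filler)
                    generated = True
                    break
            if not generated:
                return True

    # -- public API ---------------------------------------------------------

    def is_satisfiable(self, expr: ClassExpression) -> bool:
        expr = nnf(expr)
        if expr in self._sat_cache:
            return self._sat_cache[expr]
        if expr == NOTHING:
            return False
        st = _State()
        self._add(st, 0, expr)
        for gci in self.gcis:
            self._add(st, 0, gci)
        result = self._expand(st)
        self._sat_cache[expr] = result
        return result

    def is_subsumed_by(self, sub: ClassExpression, sup: ClassExpression) -> bool:
        """Entailment ``sub SubClassOf sup``."""
        if sup == THING:
            return True
        return not self.is_satisfiable(And((sub, nnf(sup, negate=True))))

    def unsatisfiable_named_classes(
        self, candidates: Optional[Iterable[str]] = None
    ) -> list[str]:
        iris = sorted(candidates) if candidates is not None else sorted(self.ontology.classes)
        return [
            iri
            for iri in iris
            if iri not in (OWL_THING, OWL_NOTHING)
            and not self.is_satisfiable(Named(iri))
        ]

    def is_coherent(self, candidates: Optional[Iterable[str]] = None) -> bool:
        return not self.unsatisfiable_named_classes(candidates)

    def subclasses_of(
        self,
        expr: ClassExpression,
        candidates: Optional[Iterable[str]] = None,
    ) -> set[str]:
        """Satisfiable named classes entailed to be subclasses of ``expr``.

        Unsatisfiable classes are excluded (they are vacuous subclasses of
        everything); they are retrieved by querying Nothing instead.
        """
        iris = set(candidates) if candidates is not None else set(self.ontology.classes)
        iris -= {OWL_THING, OWL_NOTHING}
        if expr == NOTHING:
            return set(self.unsatisfiable_named_classes(iris))
        return {
            iri
            for iri in iris
            if self.is_satisfiable(Named(iri))
            and self.is_subsumed_by(Named(iri), expr)
        }
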