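"""Serialization of :class:`~sbmlkb.owl.model.Ontology`.

Two standard OWL syntaxes are supported, each with a writer and a reader so a
knowledge base can round-trip losslessly:

* OWL functional-style syntax (``.ofn``)
* RDF/XML (``.owl``), via rdflib

Axioms are sorted canonically before writing so output is byte-stable.
"""

from __future__ import annotations

import re
from typing import Iterable

from rdflib import BNode, Graph, Literal, Namespace, RDF, RDFS, OWL, URIRef
from rdflib.collection import Collection

from .model import (
    And,
    Axiom,
    ClassExpression,
    DisjointClasses,
    Named,
    Not,
    Only,
    Ontology,
    Or,
    PropertySpec,
    Some,
    SubClassOf,
)

# ---------------------------------------------------------------------------
# Functional-style syntax


def expr_to_functional(expr: ClassExpression) -> str:
    if isinstance(expr, Named):
        return f"<{expr.iri}>"
    if isinstance(expr, Not):
        return f"ObjectComplementOf({expr_to_functional(expr.operand)})"
    if isinstance(expr, And):
        inner = " ".join(expr_to_functional(o) for o in expr.operands)
        return f"ObjectIntersectionOf({inner})"
    if isinstance(expr, Or):
        inner = " ".join(expr_to_functional(o) for o in expr.operands)
        return f"ObjectUnionOf({inner})"
    if isinstance(expr, Some):
        return f"ObjectSomeValuesFrom(<{expr.role}> {expr_to_functional(expr.filler)})"
    if isinstance(expr, Only):
        return f"ObjectAllValuesFrom(<{expr.role}> {expr_to_functional(expr.filler)})"
    raise TypeError(f"not a class expression: {expr!r}")


def axiom_to_functional(ax: Axiom) -> str:
    if isinstance(ax, SubClassOf):
        return f"SubClassOf({expr_to_functional(ax.sub)} {expr_to_functional(ax.sup)})"
    if isinstance(ax, DisjointClasses):
        inner = " ".join(expr_to_functional(o) for o in ax.operands)
        return f"DisjointClasses({inner})"
    raise TypeError(f"not an axiom: {ax!r}")


def _escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"')


def write_functional(ont: Ontology) -> str:
    lines = [f"Ontology(<{ont.iri}>"]
    for note in ont.annotations:
        lines.append(f'Annotation(rdfs:comment "{_escape(note)}")')
    for iri in sorted(ont.classes):
        lines.append(f"Declaration(Class(<{iri}>))")
    for iri in sorted(ont.properties):
        lines.append(f"Declaration(ObjectProperty(<{iri}>))")
    for iri, spec in sorted(ont.properties.items()):
        for parent in sorted(spec.parents):
            lines.append(f"SubObjectPropertyOf(<{iri}> <{parent}>)")
        if spec.inverse and spec.iri < spec.inverse:
            lines.append(f"InverseObjectProperties(<{iri}> <{spec.inverse}>)")
        if spec.domain:
            lines.append(f"ObjectPropertyDomain(<{iri}> <{spec.domain}>)")
        if spec.range:
            lines.append(f"ObjectPropertyRange(<{iri}> <{spec.range}>)")
        if spec.transitive:
            lines.append(f"TransitiveObjectProperty(<{iri}>)")
        if spec.functional:
            lines.append(f"FunctionalObjectProperty(<{iri}>)")
        if spec.label:
            lines.append(
                f'AnnotationAssertion(rdfs:label <{iri}> "{_escape(spec.label)}")'
            )
    for ax in sorted((axiom_to_functional(a) for a in ont.axioms)):
        lines.append(ax)
    for iri in sorted(ont.labels):
        lines.append(
            f'AnnotationAssertion(rdfs:label <{iri}> "{_escape(ont.labels[iri])}")'
        )
    lines.append(")")
    return "\n".join(lines) + "\n"


_TOKEN_RE = re.compile(r"<[^>]*>|\"(?:[^\"\\]|\\.)*\"|[A-Za-z][A-Za-z:]*|\(|\)")


def _tokenize(text: str) -> list[str]:
    return _TOKEN_RE.findall(text)


class _FunctionalParser:
    def __init__(self, tokens: list[str]):
        self.toks = tokens
        self.pos = 0

    def peek(self) -> str:
        return self.toks[self.pos]

    def next(self) -> str:
        tok = self.toks[self.pos]
        self.pos += 1
        return tok

    def expect(self, tok: str) -> None:
        got = self.next()
        if got != tok:
            raise ValueError(f"expected {tok!r}, got {got!r}")

    def iri(self) -> str:
        tok = self.next()
        if not tok.startswith("<"):
            raise ValueError(f"expected IRI, got {tok!r}")
        return tok[1:-1]

    def expr(self) -> ClassExpression:
        tok = self.next()
        if tok.startswith("<"):
            return Named(tok[1:-1])
        self.expect("(")
        if tok == "ObjectIntersectionOf":
            ops = self._expr_list()
            return And(ops)
        if tok == "ObjectUnionOf":
            ops = self._expr_list()
            return Or(ops)
        if tok == "ObjectComplementOf":
            inner = self.expr()
            self.expect(")")
            return Not(inner)
        if tok == "ObjectSomeValuesFrom":
            role = self.iri()
            filler = self.expr()
            self.expect(")")
            return Some(role, filler)
        if tok == "ObjectAllValuesFrom":
            role = self.iri()
            filler = self.expr()
            self.expect(")")
            return Only(role, filler)
        raise ValueError(f"unsupported expression constructor {tok!r}")

    def _expr_list(self) -> list[ClassExpression]:
        ops = []
        while self.peek() != ")":
            ops.append(self.expr())
        self.next()
        return ops


def read_functional(text: str) -> Ontology:
    toks = _tokenize(text)
    p = _FunctionalParser(toks)
    p.expect("Ontology")
    p.expect("(")
    ont = Ontology(p.iri())
    specs: dict[str, PropertySpec] = {}

    def spec(iri: str) -> PropertySpec:
        return specs.setdefault(iri, PropertySpec(iri=iri, label=""))

    while p.peek() != ")":
        kw = p.next()
        p.expect("(")
        if kw == "Annotation":
            p.next()  # annotation property
            ont.annotations.append(p.next()[1:-1].replace('\\"', '"').replace("\\\\", "\\"))
            p.expect(")")
        elif kw == "Declaration":
            kind = p.next()
            p.expect("(")
            iri = p.iri()
            p.expect(")")
            p.expect(")")
            if kind == "Class":
                ont.classes.add(iri)
            else:
                spec(iri)
        elif kw == "SubObjectPropertyOf":
            sub, sup = p.iri(), p.iri()
            p.expect(")")
            s = spec(sub)
            s.parents = tuple(sorted(set(s.parents) | {sup}))
        elif kw == "InverseObjectProperties":
            a, b = p.iri(), p.iri()
            p.expect(")")
            spec(a).inverse = b
            spec(b).inverse = a
        elif kw == "ObjectPropertyDomain":
            a = p.iri()
            spec(a).domain = p.iri()
            p.expect(")")
        elif kw == "ObjectPropertyRange":
            a = p.iri()
            spec(a).range = p.iri()
            p.expect(")")
        elif kw == "TransitiveObjectProperty":
            spec(p.iri()).transitive = True
            p.expect(")")
        elif kw == "FunctionalObjectProperty":
            spec(p.iri()).functional = True
            p.expect(")")
        elif kw == "AnnotationAssertion":
            p.next()  # rdfs:label
            iri = p.iri()
            literal = p.next()[1:-1].replace('\\"', '"').replace("\\\\", "\\")
            p.expect(")")
            if iri in specs:
                specs[iri].label = literal
            else:
                ont.labels[iri] = literal
        elif kw == "SubClassOf":
            sub = p.expr()
            sup = p.expr()
            p.expect(")")
            ont.add(SubClassOf(sub, sup))
        elif kw == "DisjointClasses":
            ops = p._expr_list()
            ont.add(DisjointClasses(ops))
        else:
            raise ValueError(f"unsupported axiom constructor {kw!r}")
    ont.properties = specs
    return ont


# ---------------------------------------------------------------------------
# RDF/XML via rdflib


def _expr_to_rdf(g: Graph, expr: ClassExpression):
    if isinstance(expr, Named):
        return URIRef(expr.iri)
    node = BNode()
    if isinstance(expr, (And, Or)):
        g.add((node, RDF.type, OWL.Class))
        items = [_expr_to_rdf(g, o) for o in expr.operands]
        lst = BNode()
        Collection(g, lst, items)
        pred = OWL.intersectionOf if isinstance(expr, And) else OWL.unionOf
        g.add((node, pred, lst))
    elif isinstance(expr, Not):
        g.add((node, RDF.type, OWL.Class))
        g.add((node, OWL.complementOf, _expr_to_rdf(g, expr.operand)))
    elif isinstance(expr, (Some, Only)):
        g.add((node, RDF.type, OWL.Restriction))
        g.add((node, OWL.onProperty, URIRef(expr.role)))
        pred = OWL.someValuesFrom if isinstance(expr, Some) else OWL.allValuesFrom
        g.add((node, pred, _expr_to_rdf(g, expr.filler)))
    else:
        raise TypeError(f"not a class expression: {expr!r}")
    return node


def write_rdfxml(ont: Ontology) -> str:
    g = Graph()
    g.bind("owl", OWL)
    onode = URIRef(ont.iri)
    g.add((onode, RDF.type, OWL.Ontology))
    for note in ont.annotations:
        g.add((onode, RDFS.comment, Literal(note)))
    for iri in sorted(ont.classes):
        g.add((URIRef(iri), RDF.type, OWL.Class))
    for iri, label in sorted(ont.labels.items()):
        g.add((URIRef(iri), RDFS.label, Literal(label)))
    for iri, spec in sorted(ont.properties.items()):
        node = URIRef(iri)
        g.add((node, RDF.type, OWL.ObjectProperty))
        if spec.label:
            g.add((node, RDFS.label, Literal(spec.label)))
        for parent in spec.parents:
            g.add((node, RDFS.subPropertyOf, URIRef(parent)))
        if spec.inverse and spec.iri < spec.inverse:
            g.add((node, OWL.inverseOf, URIRef(spec.inverse)))
        if spec.domain:
            g.add((node, RDFS.domain, URIRef(spec.domain)))
        if spec.range:
            g.add((node, RDFS.range, URIRef(spec.range)))
        if spec.transitive:
            g.add((node, RDF.type, OWL.TransitiveProperty))
        if spec.functional:
            g.add((node, RDF.type, OWL.FunctionalProperty))
    for ax in ont.axioms:
        if isinstance(ax, SubClassOf):
            g.add((_expr_to_rdf(g, ax.sub), RDFS.subClassOf, _expr_to_rdf(g, ax.sup)))
        elif isinstance(ax, DisjointClasses):
            node = BNode()
            g.add((node, RDF.type, OWL.AllDisjointClasses))
            lst = BNode()
            Collection(g, lst, [_expr_to_rdf(g, o) for o in ax.operands])
            g.add((node, OWL.members, lst))
    return g.serialize(format="xml")


def _expr_from_rdf(g: Graph, node) -> ClassExpression:
    if isinstance(node, URIRef):
        return Named(str(node))
    lst = g.value(node, OWL.intersectionOf)
    if lst is not None:
        return And(_expr_from_rdf(g, m) for m in Collection(g, lst))
    lst = g.value(node, OWL.unionOf)
    if lst is not None:
        return Or(_expr_from_rdf(g, m) for m in Collection(g, lst))
    comp = g.value(node, OWL.complementOf)
    if comp is not None:
        return Not(_expr_from_rdf(g, comp))
    prop = g.value(node, OWL.onProperty)
    if prop is not None:
        some = g.value(node, OWL.someValuesFrom)
        if some is not None:
            return Some(str(prop), _expr_from_rdf(g, some))
        only = g.value(node, OWL.allValuesFrom)
        if only is not None:
            return Only(str(prop), _expr_from_rdf(g, only))
    raise ValueError(f"unrecognized class-expression node {node!r}")


def read_rdfxml(text: str) -> Ontology:
    g = Graph()
    g.parse(data=text, format="xml")
    onode = g.value(None, RDF.type, OWL.Ontology)
    ont = Ontology(str(onode) if onode is not None else "https://w3id.org/sbmlkb/kb")
    if onode is not None:
        for note in g.objects(onode, RDFS.comment):
            ont.annotations.append(str(note))
    prop_iris = {str(s) for s in g.subjects(RDF.type, OWL.ObjectProperty)}
    for s in g.subjects(RDF.type, OWL.Class):
        if isinstance(s, URIRef):
            ont.classes.add(str(s))
    for s, o in g.subject_objects(RDFS.label):
        if str(s) in prop_iris:
            continue
        if isinstance(s, URIRef):
            ont.labels[str(s)] = str(o)
    for iri in sorted(prop_iris):
        node = URIRef(iri)
        spec = PropertySpec(iri=iri, label=str(g.value(node, RDFS.label) or ""))
        spec.parents = tuple(sorted(str(p) for p in g.objects(node, RDFS.subPropertyOf)))
        dom = g.value(node, RDFS.domain)
        rng = g.value(node, RDFS.range)
        spec.domain = str(dom) if dom is not None else None
        spec.range = str(rng) if rng is not None else None
        spec.transitive = (node, RDF.type, OWL.TransitiveProperty) in g
        spec.functional = (node, RDF.type, OWL.FunctionalProperty) in g
        ont.properties[iri] = spec
    for s, o in g.subject_objects(OWL.inverseOf):
        a, b = str(s), str(o)
        if a in ont.properties:
            ont.properties[a].inverse = b
        if b in ont.properties:
            ont.properties[b].inverse = a
    for s, o in g.subject_objects(RDFS.subClassOf):
        ont.add(SubClassOf(_expr_from_rdf(g, s), _expr_from_rdf(g, o)))
    for s in g.subjects(RDF.type, OWL.AllDisjointClasses):
        lst = g.value(s, OWL.members)
        if lst is not None:
            ont.add(DisjointClasses(_expr_from_rdf(g, m) for m in Collection(g, lst)))
    for s, o in g.subject_objects(OWL.disjointWith):
        ont.add(DisjointClasses([_expr_from_rdf(g, s), _expr_from_rdf(g, o)]))
    return ont
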