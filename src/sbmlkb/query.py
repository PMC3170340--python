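"""Class-expression queries over a classified knowledge base.

Queries are written in a Manchester-like syntax — named classes by quoted
label or CURIE, ``and``, ``or``, ``some``, ``only``, ``Nothing``,
parentheses — and answered as the set of satisfiable named classes entailed
to be subclasses of the expression (``Nothing`` returns the unsatisfiable
classes instead).  Results can be filtered to models or model entities.
The whole formalization is class-level, so answers are classes, never
individuals.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from . import names as N
from .owl.model import (
    And,
    ClassExpression,
    Named,
    NOTHING,
    Only,
    Ontology,
    Or,
    Some,
    THING,
    walk,
)
from .reasoner.tableau import TableauReasoner


class QuerySyntaxError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class UnknownNameError(ValueError):
    def __init__(self, names: list[str]):
        super().__init__(f"unknown class or relation name(s): {', '.join(names)}")
        self.names = names


class AmbiguousLabelError(ValueError):
    pass


class CapabilityError(ValueError):
    """Raised for non-EL expressions against an EL-profile knowledge base."""


@dataclass(frozen=True)
class _Ref:
    """An unresolved name in a parsed expression (label, CURIE or IRI)."""

    token: str
    quoted: bool
    position: int


@dataclass
class Query:
    expression: ClassExpression
    result_filter: str = "all"  # all | models_only | model_entities_only
    text: str = ""


@dataclass
class QueryResult:
    matches: list[dict]  # {"iri": ..., "label": ...}
    query: str
    result_filter: str
    kb: str
    reasoner: str

    @property
    def iris(self) -> set[str]:
        return {m["iri"] for m in self.matches}

    def to_json(self) -> dict:
        return {
            "query": self.query,
            "filter": self.result_filter,
            "kb": self.kb,
            "reasoner": self.reasoner,
            "n_results": len(self.matches),
            "results": self.matches,
        }

    def to_tsv(self) -> str:
        lines = ["iri\tlabel"]
        lines += [f"{m['iri']}\t{m['label']}" for m in self.matches]
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Parsing

_TOKEN = re.compile(
    r"\s*(?:(?P<quoted>'(?:[^'\\]|\\.)*')|(?P<iri><[^>]*>)|"
    r"(?P<name>[A-Za-z_][A-Za-z0-9_:.\-]*)|(?P<lpar>\()|(?P<rpar>\)))"
)

_KEYWORDS = {"and", "or", "some", "only"}


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            if text[pos:].strip():
                raise QuerySyntaxError(
                    f"unexpected character {text[pos:].strip()[0]!r}", pos
                )
            break
        pos = m.end()
        for kind in ("quoted", "iri", "name", "lpar", "rpar"):
            value = m.group(kind)
            if value is not None:
                tokens.append((kind, value, m.start()))
                break
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.pos = 0

    def _peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def _next(self):
        tok = self._peek()
        if tok is None:
            raise QuerySyntaxError("unexpected end of query", len(self.text))
        self.pos += 1
        return tok

    def parse(self) -> ClassExpression:
        expr = self._or()
        if self._peek() is not None:
            kind, value, position = self._peek()
            raise QuerySyntaxError(f"unexpected token {value!r}", position)
        return expr

    def _or(self) -> ClassExpression:
        operands = [self._and()]
        while self._is_keyword("or"):
            self._next()
            operands.append(self._and())
        return operands[0] if len(operands) == 1 else Or(operands)

    def _and(self) -> ClassExpression:
        operands = [self._unit()]
        while self._is_keyword("and"):
            self._next()
            operands.append(self._unit())
        return operands[0] if len(operands) == 1 else And(operands)

    def _is_keyword(self, word: str) -> bool:
        tok = self._peek()
        return tok is not None and tok[0] == "name" and tok[1] == word

    def _unit(self) -> ClassExpression:
        tok = self._peek()
        if tok is None:
            raise QuerySyntaxError("unexpected end of query", len(self.text))
        kind, value, position = tok
        if kind == "lpar":
            self._next()
            expr = self._or()
            closing = self._peek()
            if closing is None or closing[0] != "rpar":
                raise QuerySyntaxError("unmatched parenthesis", position)
            self._next()
            return expr
        if kind == "rpar":
            raise QuerySyntaxError("unexpected ')'", position)
        self._next()
        if kind == "name" and value in _KEYWORDS:
            raise QuerySyntaxError(f"unexpected keyword {value!r}", position)
        # a restriction if followed by some/only, otherwise a class name
        follow = self._peek()
        if follow is not None and follow[0] == "name" and follow[1] in ("some", "only"):
            _, quantifier, _ = self._next()
            filler = self._unit()
            role = _Ref(_strip(kind, value), kind == "quoted", position)
            ctor = Some if quantifier == "some" else Only
            return ctor(role, filler)  # type: ignore[arg-type]
        if kind == "name" and value == "Nothing":
            return NOTHING
        if kind == "name" and value == "Thing":
            return THING
        return _RefNamed(_Ref(_strip(kind, value), kind == "quoted", position))


def _strip(kind: str, value: str) -> str:
    if kind == "quoted":
        return value[1:-1].replace("\\'", "'")
    if kind == "iri":
        return value[1:-1]
    return value


@dataclass(frozen=True)
class _RefNamed:
    """A class position holding an unresolved reference."""

    ref: _Ref


def parse_query(text: str, result_filter: str = "all") -> Query:
    """Parse a class-expression query; names remain unresolved until answered."""
    if result_filter not in ("all", "models_only", "model_entities_only"):
        raise ValueError(f"unknown result filter {result_filter!r}")
    expr = _Parser(text).parse()
    return Query(expression=expr, result_filter=result_filter, text=text)


def expression_depth(expr) -> int:
    if isinstance(expr, (_RefNamed, Named)):
        return 1
    if isinstance(expr, (And, Or)):
        return 1 + max(expression_depth(o) for o in expr.operands)
    if isinstance(expr, (Some, Only)):
        return 1 + expression_depth(expr.filler)
    return 1


# ---------------------------------------------------------------------------
# Name resolution

_CURIE = re.compile(r"^[A-Za-z][A-Za-z0-9]*:\S+$")


class LabelResolver:
    """Resolves labels, CURIEs and IRIs against a knowledge base.

    Labels resolve case-sensitively; an ambiguous label is an error, CURIEs
    are accepted everywhere as the unambiguous spelling.
    """

    def __init__(self, kb: Ontology):
        self.kb = kb
        self.class_labels: dict[str, list[str]] = {}
        for iri, label in kb.labels.items():
            self.class_labels.setdefault(label, []).append(iri)
        self.role_names: dict[str, str] = {}
        for iri, spec in kb.properties.items():
            if spec.label:
                self.role_names.setdefault(spec.label, iri)
            self.role_names.setdefault(iri.rsplit("#", 1)[-1], iri)

    def resolve_class(self, ref: _Ref) -> Optional[str]:
        token = ref.token
        if token.startswith("http://") or token.startswith("https://"):
            return token if token in self.kb.classes else None
        if not ref.quoted and _CURIE.match(token):
            iri = N.curie_to_iri(token)
            if iri in self.kb.classes:
                return iri
        iris = self.class_labels.get(token, [])
        if len(iris) > 1:
            raise AmbiguousLabelError(
                f"label {token!r} is ambiguous: {sorted(iris)}"
            )
        return iris[0] if iris else None

    def resolve_role(self, ref: _Ref) -> Optional[str]:
        token = ref.token
        if token.startswith("http"):
            return token if token in self.kb.properties else None
        return self.role_names.get(token)


def resolve_expression(expr, resolver: LabelResolver) -> ClassExpression:
    unknown: list[str] = []

    def rec(node):
        if isinstance(node, _RefNamed):
            iri = resolver.resolve_class(node.ref)
            if iri is None:
                unknown.append(node.ref.token)
                return NOTHING
            return Named(iri)
        if isinstance(node, Named):
            return node
        if isinstance(node, And):
            return And(rec(o) for o in node.operands)
        if isinstance(node, Or):
            return Or(rec(o) for o in node.operands)
        if isinstance(node, (Some, Only)):
            role = node.role
            if isinstance(role, _Ref):
                role_iri = resolver.resolve_role(role)
                if role_iri is None:
                    unknown.append(role.token)
                    role_iri = role.token
            else:
                role_iri = role
            ctor = Some if isinstance(node, Some) else Only
            return ctor(role_iri, rec(node.filler))
        raise TypeError(f"unexpected node {node!r}")

    resolved = rec(expr)
    if unknown:
        raise UnknownNameError(sorted(set(unknown)))
    return resolved


# ---------------------------------------------------------------------------
# Answering


def _is_el_kb(kb: Ontology) -> bool:
    return any(a.startswith("profile: OWL EL") for a in kb.annotations)


def answer_query(
    kb: Ontology,
    query: Query,
    reasoner: Optional[TableauReasoner] = None,
    candidates: Optional[set[str]] = None,
) -> QueryResult:
    """Entailed named subclasses of the query expression, filtered.

    ``Nothing`` returns all unsatisfiable named classes.  Against an
    EL-profile knowledge base, expressions using ``only`` or ``or`` raise a
    :class:`CapabilityError` (OWL EL supports neither construct, so such
    queries cannot be answered faithfully there).
    """
    resolver = LabelResolver(kb)
    expr = resolve_expression(query.expression, resolver)
    if _is_el_kb(kb) and any(isinstance(e, (Only, Or)) for e in walk(expr)):
        raise CapabilityError(
            "the knowledge base was reduced to the OWL EL profile, which "
            "supports neither universal quantification ('only') nor unions "
            "('or'); re-convert in full mode to answer this query"
        )
    reasoner = reasoner or TableauReasoner(kb)
    answer_iris = reasoner.subclasses_of(expr, candidates)
    if query.result_filter == "models_only":
        answer_iris = {
            i for i in answer_iris
            if reasoner.is_subsumed_by(Named(i), Named(N.MODEL))
        }
    elif query.result_filter == "model_entities_only":
        answer_iris = {
            i for i in answer_iris
            if reasoner.is_subsumed_by(Named(i), Named(N.MODEL_ENTITY))
        }
    matches = [
        {"iri": iri, "label": kb.label_of(iri)} for iri in sorted(answer_iris)
    ]
    return QueryResult(
        matches=matches,
        query=query.text,
        result_filter=query.result_filter,
        kb=kb.iri,
        reasoner=type(reasoner).__name__,
    )
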