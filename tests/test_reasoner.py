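"""The description-logic reasoners.

Unit tests exercise the tableau calculus on hand-built ontologies (one per
rule family); a seeded property test generates random Horn-EL terminologies
and cross-checks the tableau calculus against the independent saturation
classifier on every pairwise subsumption and every satisfiability verdict.
"""

import pytest
from hypothesis import given, settings, strategies as st

from sbmlkb.owl.model import (
    And,
    DisjointClasses,
    Named,
    NOTHING,
    Only,
    Ontology,
    Or,
    PropertySpec,
    Some,
    SubClassOf,
)
from sbmlkb.reasoner.el import ELClassifier, NotInProfileError
from sbmlkb.reasoner.tableau import TableauReasoner


def _ont(axioms=(), props=(), classes=()):
    ont = Ontology("urn:test:ont")
    for c in classes:
        ont.declare_class(c)
    for spec in props:
        ont.declare_property(spec)
    for ax in axioms:
        ont.add(ax)
    return ont


A, B, C, D = Named("urn:A"), Named("urn:B"), Named("urn:C"), Named("urn:D")
r, s, t = "urn:r", "urn:s", "urn:t"


def test_disjoint_conjunction_is_unsatisfiable():
    ont = _ont([DisjointClasses([A, B])], classes=["urn:A", "urn:B"])
    reasoner = TableauReasoner(ont)
    assert reasoner.is_satisfiable(A)
    assert not reasoner.is_satisfiable(And([A, B]))


def test_role_hierarchy_lifts_existentials():
    ont = _ont(
        [SubClassOf(A, Some(r, B))],
        props=[PropertySpec(r, "r", parents=(s,)), PropertySpec(s, "s")],
        classes=["urn:A", "urn:B"],
    )
    reasoner = TableauReasoner(ont)
    assert reasoner.is_subsumed_by(A, Some(s, B))
    assert not reasoner.is_subsumed_by(A, Some(t, B))


def test_transitive_role_collapses_chains():
    ont = _ont(
        [SubClassOf(A, Some(r, B)), SubClassOf(B, Some(r, C))],
        props=[PropertySpec(r, "r", transitive=True)],
        classes=["urn:A", "urn:B", "urn:C"],
    )
    reasoner = TableauReasoner(ont)
    assert reasoner.is_subsumed_by(A, Some(r, C))


def test_nontransitive_role_does_not_collapse_chains():
    ont = _ont(
        [SubClassOf(A, Some(r, B)), SubClassOf(B, Some(r, C))],
        props=[PropertySpec(r, "r")],
        classes=["urn:A", "urn:B", "urn:C"],
    )
    assert not TableauReasoner(ont).is_subsumed_by(A, Some(r, C))


def test_universal_restriction_monotone_over_filler():
    ont = _ont(
        [SubClassOf(A, Only(r, B)), SubClassOf(B, C)],
        props=[PropertySpec(r, "r")],
        classes=["urn:A", "urn:B", "urn:C"],
    )
    reasoner = TableauReasoner(ont)
    assert reasoner.is_subsumed_by(A, Only(r, C))
    assert not reasoner.is_subsumed_by(A, Only(r, D))


def test_universal_and_existential_clash():
    ont = _ont(
        [SubClassOf(A, And([Some(r, B), Only(r, C)])), DisjointClasses([B, C])],
        props=[PropertySpec(r, "r")],
        classes=["urn:A", "urn:B", "urn:C"],
    )
    assert not TableauReasoner(ont).is_satisfiable(A)


def test_range_axiom_propagates_to_successors():
    ont = _ont(
        [SubClassOf(A, Some(r, B)), SubClassOf(B, C), DisjointClasses([C, D])],
        props=[PropertySpec(r, "r", range="urn:D")],
        classes=["urn:A", "urn:B", "urn:C", "urn:D"],
    )
    reasoner = TableauReasoner(ont)
    # successor must satisfy B ⊓ range(r) = B ⊓ D, but B ⊑ C and C,D disjoint
    assert not reasoner.is_satisfiable(A)


def test_domain_axiom_applies_to_source():
    ont = _ont(
        [SubClassOf(A, Some(r, B))],
        props=[PropertySpec(r, "r", domain="urn:C")],
        classes=["urn:A", "urn:B", "urn:C"],
    )
    assert TableauReasoner(ont).is_subsumed_by(A, C)


def test_general_inclusion_with_complex_left_side():
    gci = SubClassOf(Some(r, A), B)
    ont = _ont(
        [SubClassOf(C, Some(r, A)), gci],
        props=[PropertySpec(r, "r")],
        classes=["urn:A", "urn:B", "urn:C"],
    )
    assert TableauReasoner(ont).is_subsumed_by(C, B)


def test_disjunction_branches():
    ont = _ont(
        [SubClassOf(A, Or([B, C])), SubClassOf(B, NOTHING)],
        classes=["urn:A", "urn:B", "urn:C"],
    )
    reasoner = TableauReasoner(ont)
    assert reasoner.is_satisfiable(A)  # the C branch survives
    assert reasoner.is_subsumed_by(A, C)
    ont2 = _ont(
        [SubClassOf(A, Or([B, C])), SubClassOf(B, NOTHING), SubClassOf(C, NOTHING)],
        classes=["urn:A", "urn:B", "urn:C"],
    )
    assert not TableauReasoner(ont2).is_satisfiable(A)


def test_cyclic_terminology_terminates_by_blocking():
    ont = _ont(
        [SubClassOf(A, Some(r, A))],
        props=[PropertySpec(r, "r", transitive=True)],
        classes=["urn:A"],
    )
    assert TableauReasoner(ont).is_satisfiable(A)


def test_el_classifier_rejects_non_el_input():
    ont = _ont([SubClassOf(A, Only(r, B))], props=[PropertySpec(r, "r")],
               classes=["urn:A", "urn:B"])
    with pytest.raises(NotInProfileError):
        ELClassifier(ont)


# ---------------------------------------------------------------------------
# Property test: tableau vs saturation on random Horn-EL terminologies

_CLASSES = [f"urn:c{i}" for i in range(5)]
_ROLES = [r, s]


@st.composite
def _el_ontologies(draw):
    props = [
        PropertySpec(r, "r", parents=(s,), transitive=draw(st.booleans())),
        PropertySpec(s, "s", transitive=draw(st.booleans())),
    ]
    n_axioms = draw(st.integers(min_value=1, max_value=8))
    axioms = []
    names = st.sampled_from(_CLASSES)
    for _ in range(n_axioms):
        sub = Named(draw(names))
        kind = draw(st.integers(min_value=0, max_value=2))
        if kind == 0:
            sup = Named(draw(names))
        elif kind == 1:
            sup = Some(draw(st.sampled_from(_ROLES)), Named(draw(names)))
        else:
            sup = And([Named(draw(names)),
                       Some(draw(st.sampled_from(_ROLES)), Named(draw(names)))])
        axioms.append(SubClassOf(sub, sup))
    if draw(st.booleans()):
        a_iri, b_iri = draw(
            st.lists(st.sampled_from(_CLASSES), min_size=2, max_size=2, unique=True)
        )
        axioms.append(DisjointClasses([Named(a_iri), Named(b_iri)]))
    return _ont(axioms, props=props, classes=_CLASSES)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(_el_ontologies())
def test_tableau_and_el_saturation_agree_on_horn_el(ont):
    """Two independent calculi, one fragment: every satisfiability verdict
    and every pairwise named subsumption must coincide."""
    tableau = TableauReasoner(ont)
    saturation = ELClassifier(ont)
    for a_iri in _CLASSES:
        assert tableau.is_satisfiable(Named(a_iri)) == saturation.is_satisfiable(a_iri)
        for b_iri in _CLASSES:
            assert tableau.is_subsumed_by(Named(a_iri), Named(b_iri)) == \
                saturation.is_subsumed_by(a_iri, Named(b_iri)), (a_iri, b_iri)
        for role in _ROLES:
            for b_iri in _CLASSES:
                query = Some(role, Named(b_iri))
                assert tableau.is_subsumed_by(Named(a_iri), query) == \
                    saturation.is_subsumed_by(a_iri, query), (a_iri, role, b_iri)
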