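"""Shared fixtures: generated miniature ontologies, scenario models and
their converted knowledge bases (built once per session)."""

from __future__ import annotations

import pytest

from sbmlkb.convert import convert_model
from sbmlkb.fixtures import generate_all
from sbmlkb.registry import load_registry
from sbmlkb.reasoner.tableau import TableauReasoner
from sbmlkb.sbml import parse_sbml
from sbmlkb.verify import ConstraintAxiomSet

#: fixture id -> SBML model id (the IRI scope of its emitted classes)
SCOPES = {
    "F1": "F1_gtp_binding",
    "F2": "F2_spindle",
    "F3": "F3_rent",
    "F4": "F4_glycolysis",
    "F4fix": "F4_glycolysis",
    "F5": "F5_cellcycle",
    "F6": "F6_pancreas",
}

#: fixture id -> (compartments, species, reactions)
SHAPES = {
    "F1": (1, 3, 1),
    "F2": (1, 4, 1),
    "F3": (1, 3, 2),
    "F4": (1, 2, 1),
    "F4fix": (1, 2, 1),
    "F5": (1, 4, 1),
    "F6": (1, 4, 4),
}


@pytest.fixture(scope="session")
def fixture_files(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixtures")
    return generate_all(outdir, seed=7)


@pytest.fixture(scope="session")
def registry(fixture_files):
    return load_registry(fixture_files["registry"])


@pytest.fixture(scope="session")
def onts(registry):
    return registry[0]


@pytest.fixture(scope="session")
def roots(registry):
    return registry[1]


@pytest.fixture(scope="session")
def constraints(fixture_files):
    return ConstraintAxiomSet.from_yaml(fixture_files["constraints"])


@pytest.fixture(scope="session")
def parsed(fixture_files):
    return {fid: parse_sbml(fixture_files[fid]) for fid in SCOPES}


@pytest.fixture(scope="session")
def converted(parsed, onts, roots):
    """Full-mode conversion of every scenario model."""
    return {fid: convert_model(pm, onts, roots, mode="full") for fid, pm in parsed.items()}


@pytest.fixture(scope="session")
def converted_el(parsed, onts, roots):
    """EL-mode conversion of the fixtures the EL tests exercise."""
    return {
        fid: convert_model(parsed[fid], onts, roots, mode="el")
        for fid in ("F2", "F6")
    }


@pytest.fixture(scope="session")
def reasoners(converted):
    return {fid: TableauReasoner(res.ontology) for fid, res in converted.items()}
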