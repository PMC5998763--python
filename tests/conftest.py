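import sys
from pathlib import Path

import dataclasses

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from metmatch.data_io import (
    AssociationNetwork,
    Compound,
    NodeKind,
    ProteinRecord,
    Role,
)
from metmatch.synthetic_fixtures import PRESETS, generate_fixture


@pytest.fixture(scope="session")
def tiny_bundle():
    return generate_fixture(dataclasses.replace(PRESETS["tiny"], rng_seed=11))


@pytest.fixture
def small_network():
    """G1 -> {P1, P2}, G2 -> P2, G1 <-> G2; P3 isolated via G3."""
    nodes = {
        "G1": NodeKind.GENE,
        "G2": NodeKind.GENE,
        "G3": NodeKind.GENE,
        "P1": NodeKind.PHENOTYPE,
        "P2": NodeKind.PHENOTYPE,
        "P3": NodeKind.PHENOTYPE,
    }
    edges = [
        ("G1", "P1", 1.0),
        ("G1", "P2", 1.0),
        ("G2", "P2", 1.0),
        ("G1", "G2", 1.0),
        ("G2", "G1", 1.0),
        ("G3", "P3", 1.0),
    ]
    return AssociationNetwork(nodes=nodes, edges=edges)


@pytest.fixture
def small_proteome():
    return {
        "G1": ProteinRecord("G1", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"),
        "G2": ProteinRecord("G2", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVA"),
        "G3": ProteinRecord("G3", "HEAGAWGHEEWWNDYKLPQRST"),
    }


@pytest.fixture
def compound_pair():
    a = Compound(id="A", role=Role.DRUG, smiles="CCO", targets=frozenset({"G1"}))
    b = Compound(id="B", role=Role.METABOLITE, smiles="OCC", targets=frozenset({"G2"}))
    return a, b
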