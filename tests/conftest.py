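import numpy as np
import pytest

import plantclock as pc
from plantclock.network import (GeneSpec, NetworkDefinition, ParameterSet,
                                RegulatoryEdge)


@pytest.fixture(scope="session")
def canonical_network():
    return pc.load_network()


@pytest.fixture(scope="session")
def reference_params():
    return pc.load_reference_parameters()


@pytest.fixture(scope="session")
def toy_network():
    """A three-gene repressilator (A -| B -| C -| A) with nuclear-only
    proteins — small enough for fast integration in unit tests."""
    genes = (GeneSpec("A"), GeneSpec("B"), GeneSpec("C"))
    edges = (RegulatoryEdge("A", "B", h=2), RegulatoryEdge("B", "C", h=2),
             RegulatoryEdge("C", "A", h=2))
    net = NetworkDefinition(name="toy-repressilator", genes=genes, edges=edges)
    net.validate()
    return net


@pytest.fixture(scope="session")
def toy_params(toy_network):
    p = {}
    for g in "ABC":
        p.update({f"v_{g}": 5.0, f"dm_{g}": 0.5, f"p_{g}": 1.0, f"dp_{g}": 0.3})
    p.update({"K_A_B": 0.5, "K_B_C": 0.5, "K_C_A": 0.5})
    return ParameterSet(p)


@pytest.fixture(scope="session")
def wt_simulation(canonical_network, reference_params):
    """Shared wild-type LD->LL simulation at the reference parameters."""
    from plantclock.light import parse_protocol
    from plantclock.simulate import simulate

    cm = pc.CompiledModel(canonical_network)
    return simulate(cm.bind(reference_params),
                    protocol=parse_protocol("ld:8+ll:7"), dt_out=0.25)
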