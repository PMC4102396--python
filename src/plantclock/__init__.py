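"""plantclock: a repression-centred ODE model of the Arabidopsis circadian
clock, with light-protocol simulation, mutant genotypes, rhythm metrics, a
two-part time-course cost function and parallel-tempering ensemble fitting."""

from importlib import resources

from .network import (
    ConfigurationError,
    GeneSpec,
    RegulatoryEdge,
    NetworkDefinition,
    ParameterSet,
    Genotype,
    Modification,
    CompiledModel,
    build_rhs,
    ec_activity,
)
from .light import LightProtocol, Segment, parse_protocol

__all__ = [
    "ConfigurationError", "GeneSpec", "RegulatoryEdge", "NetworkDefinition",
    "ParameterSet", "Genotype", "Modification", "CompiledModel", "build_rhs",
    "ec_activity", "LightProtocol", "Segment", "parse_protocol",
    "load_network", "load_reference_parameters", "ClockModel",
]

__version__ = "0.1.0"


def load_network(name: str = "arabidopsis_clock") -> NetworkDefinition:
    """Load a packaged network definition by name."""
    ref = resources.files("plantclock") / "networks" / f"{name}.yaml"
    with resources.as_file(ref) as path:
        return NetworkDefinition.from_yaml(path)


def load_reference_parameters(name: str = "reference_params") -> ParameterSet:
    """Load the packaged reference (calibrated) parameter set."""
    ref = resources.files("plantclock") / "networks" / f"{name}.csv"
    with resources.as_file(ref) as path:
        return ParameterSet.from_csv(path)


def __getattr__(attr):
    if attr == "ClockModel":
        from .model import ClockModel
        return ClockModel
    raise AttributeError(attr)
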