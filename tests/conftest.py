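import numpy as np
import pytest

from mycoloop.model import (CompartmentSpec, ConstraintSpec, EqualitySpec,
                            FlowSpec, ModelConfig, compile_problem)
from mycoloop.synth import fixture_problem


def make_model(name, comp_tags, flow_ids, equalities=(), constraints=()):
    """Small helper to declare toy models tersely in tests."""
    comps = [CompartmentSpec(id=c, kind=("nonliving" if t == "pool" else "living"),
                             tags=frozenset() if t == "pool" else frozenset({t}))
             for c, t in comp_tags]
    return ModelConfig(
        name=name, compartments=comps,
        flows=[FlowSpec.from_id(f) for f in flow_ids],
        equalities=[EqualitySpec(*e) for e in equalities],
        constraints=[ConstraintSpec(*c) for c in constraints])


@pytest.fixture(scope="session")
def pavin():
    """Compiled spring-bloom problem plus its packaged mean-flow vector."""
    return fixture_problem("pavin_spring_bloom")


@pytest.fixture(scope="session")
def aydat():
    return fixture_problem("aydat_autumn_bloom")


@pytest.fixture(scope="session")
def pavin_net(pavin):
    from mycoloop.network import to_flow_network
    problem, flows = pavin
    return to_flow_network(flows, problem)


@pytest.fixture(scope="session")
def aydat_net(aydat):
    from mycoloop.network import to_flow_network
    problem, flows = aydat
    return to_flow_network(flows, problem)


@pytest.fixture
def passthrough():
    """Minimal one-compartment model: import z, dissipation z."""
    return make_model("passthrough", [("a", "autotroph")], ["gpp-a", "a-res"])


@pytest.fixture
def chain():
    """import -> a -> b -> export, every flow equal at steady state."""
    return make_model(
        "chain", [("a", "autotroph"), ("b", "heterotroph")],
        ["gpp-a", "a-b", "b-los"])
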