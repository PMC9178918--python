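import numpy as np
import pytest

from quasi2d import fixtures as fx
from quasi2d.energy import CGParams
from quasi2d.stack import DockingParams, build_protofilament


@pytest.fixture(scope="session")
def insulin_like():
    return fx.make_insulin_like(seed=1)


@pytest.fixture(scope="session")
def fc3_conformer():
    return fx.make_planar_conformer("FC3")


@pytest.fixture(scope="session")
def fc1_conformer():
    return fx.make_planar_conformer("FC1")


@pytest.fixture(scope="session")
def docking_params():
    return DockingParams(shape_k=12.0, temperature=0.0)


@pytest.fixture(scope="session")
def cg_params():
    return CGParams()


@pytest.fixture(scope="session")
def fc3_stack4(fc3_conformer, docking_params, cg_params):
    """A 4-layer docked FC3 protofilament, shared across tests."""
    return build_protofilament(fc3_conformer, 4, docking_params, cg_params, seed=11)


def small_chain_molecule(n=6, phi=-120.0, psi=130.0):
    return fx.make_chain([(phi, psi)] * n)
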