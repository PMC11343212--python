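import numpy as np
import pytest

from actinmech.lattice import (
    LatticeParams,
    MechanicalParams,
    build_canonical_lattice,
    derive_topology,
)


@pytest.fixture(scope="session")
def canonical100():
    config = build_canonical_lattice(LatticeParams(n_subunits=100))
    topo = derive_topology(config)
    return config, topo


@pytest.fixture(scope="session")
def canonical40():
    config = build_canonical_lattice(LatticeParams(n_subunits=40))
    topo = derive_topology(config)
    return config, topo


@pytest.fixture()
def mech():
    return MechanicalParams(k_l=300.0, k_theta=100.0, k_phi=150.0)


@pytest.fixture()
def perturbed40(canonical40):
    config, topo = canonical40
    rng = np.random.default_rng(7)
    return config.positions + rng.normal(0.0, 0.05, config.positions.shape), topo
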