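import numpy as np
import pytest

from fibronet import (DomainSpec, ModelParams, apply_prestress,
                      build_voronoi_network, compute_boundary_forces,
                      equilibrate, hexagonal_network, poisson_disk_sample)
from fibronet.experiments import generate_prestressed_network


@pytest.fixture
def params():
    return ModelParams()


@pytest.fixture
def hex_net():
    """Prestressed honeycomb in exact equilibrium under its reaction forces."""
    net = hexagonal_network(2)
    apply_prestress(net, 1.0)
    compute_boundary_forces(net)
    return net


@pytest.fixture(scope="session")
def small_domain():
    return DomainSpec(side=8.0, radius=1.0, seed=42)


@pytest.fixture(scope="session")
def _voronoi_net_master(small_domain):
    return generate_prestressed_network(small_domain, ModelParams())


@pytest.fixture
def voronoi_net(_voronoi_net_master):
    """Small (~100 springs) prestressed Voronoi network, fresh copy per test."""
    return _voronoi_net_master.copy()
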