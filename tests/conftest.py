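import numpy as np
import pytest

from lipidmc.forcefield import EnergyModel
from lipidmc.io import FixtureSpec, generate_fixture
from lipidmc.model import (
    build_dppc_topology,
    build_monomer_start,
    load_forcefield,
    load_move_plan,
)
from lipidmc.sampler import RunConfig, run_mc


@pytest.fixture(scope="session")
def dppc_ff():
    return load_forcefield()


@pytest.fixture(scope="session")
def dppc_topology():
    return build_dppc_topology()


@pytest.fixture(scope="session")
def monomer_conf(dppc_topology, dppc_ff):
    return build_monomer_start(dppc_topology, dppc_ff)


@pytest.fixture(scope="session")
def dppc_plan(dppc_topology):
    return load_move_plan(None, dppc_topology)


@pytest.fixture()
def monomer_model(dppc_topology, dppc_ff):
    return EnergyModel(dppc_topology, dppc_ff)


@pytest.fixture(scope="session")
def relaxed_monomer(dppc_topology, dppc_ff, monomer_conf, dppc_plan):
    """Monomer state after a short relaxation run (shared across tests)."""
    model = EnergyModel(dppc_topology, dppc_ff)
    rc = RunConfig(n_cycles=300, save_every=300, seed=101)
    traj = run_mc(monomer_conf, dppc_topology, dppc_plan, rc, energy_model=model)
    conf = traj.frame_configuration(traj.n_frames - 1)
    return conf, model


@pytest.fixture()
def chain4():
    return generate_fixture(FixtureSpec(kind="linear_chain", n_atoms=4))


@pytest.fixture()
def chain5():
    return generate_fixture(FixtureSpec(kind="linear_chain", n_atoms=5))


def dihedral(coords, i, j, k, l):
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return np.degrees(np.arctan2(np.dot(m1, n2), np.dot(n1, n2)))
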