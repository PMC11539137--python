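"""Shared fixtures: hand-built micro-networks and generated study trees."""

import numpy as np
import pytest

import lungdep as ld
from lungdep.network import AirwayNetwork, attach_default_acini


def build_network(parent, generation, length, radius, proximal, distal,
                  lobe, frc_l=3.3, e_total=6.82):
    """Construct a network from plain lists, attaching default acini to
    every terminal airway."""
    parent = np.asarray(parent, dtype=np.int64)
    n = parent.size
    child_count = np.zeros(n, dtype=int)
    for p in parent:
        if p >= 0:
            child_count[p] += 1
    acinus_index = np.full(n, -1, dtype=np.int64)
    term = np.flatnonzero(child_count == 0)
    acinus_index[term] = np.arange(term.size)
    net = AirwayNetwork(
        ids=np.arange(n, dtype=np.int64), parent_index=parent,
        generation=np.asarray(generation, dtype=np.int64),
        length=np.asarray(length, dtype=float),
        radius=np.asarray(radius, dtype=float),
        proximal=np.asarray(proximal, dtype=float),
        distal=np.asarray(distal, dtype=float),
        lobe=np.asarray(lobe, dtype=object),
        acinus_index=acinus_index, frc=frc_l * 1e-3)
    attach_default_acini(net, e_total)
    return net


@pytest.fixture
def two_branch_factory():
    """Trachea feeding two identical parallel terminal daughters; one may
    be constricted by ``sigma``."""

    def make(sigma=0.0, e_total=6.82, frc_l=3.3):
        return build_network(
            parent=[-1, 0, 0], generation=[1, 2, 2],
            length=[0.05, 0.02, 0.02],
            radius=[0.004, 0.002, 0.002 * (1.0 - sigma)],
            proximal=[[0, 0, 0], [0, 0, -0.05], [0, 0, -0.05]],
            distal=[[0, 0, -0.05], [0.01, 0, -0.065], [-0.01, 0, -0.065]],
            lobe=["TR", "RU", "LU"], e_total=e_total, frc_l=frc_l)

    return make


@pytest.fixture
def single_compartment_net():
    """A trachea of negligible volume feeding one acinus (the ideal
    well-mixed single-compartment lung)."""
    return build_network(
        parent=[-1], generation=[1], length=[1e-3], radius=[1e-3],
        proximal=[[0, 0, 0]], distal=[[0, 0, -1e-3]], lobe=["TR"])


@pytest.fixture(scope="session")
def small_net():
    return ld.make_fixture("asymmetric_small", seed=3)


@pytest.fixture(scope="session")
def small_vent(small_net):
    return ld.assemble_and_solve(small_net)


@pytest.fixture(scope="session")
def symmetric_net():
    return ld.make_fixture("symmetric_small", seed=0)


@pytest.fixture(scope="session")
def medium_net():
    return ld.make_fixture("asymmetric_medium", seed=1)


@pytest.fixture(scope="session")
def medium_vent(medium_net):
    return ld.assemble_and_solve(medium_net)


@pytest.fixture(scope="session")
def small_deposition(small_net, small_vent):
    return ld.run_breath(small_net, small_vent)
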