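import numpy as np
import pytest

import disctraj as dt
from disctraj.model import AtomRecord, Frame, Topology, Trajectory


@pytest.fixture(scope="session")
def nanodisc():
    return dt.build_nanodisc(seed=7)


@pytest.fixture(scope="session")
def probe():
    return dt.build_probe_protein(seed=7)


@pytest.fixture(scope="session")
def binding(nanodisc, probe):
    """A moderate scripted binding run shared by the per-module tests."""
    return dt.generate_binding_trajectory(nanodisc, probe, n_frames=300,
                                          seed=11)


def make_topology(spec):
    """Build a topology from (name, element, resname, resid, chain, segment)
    tuples."""
    return Topology(
        AtomRecord(i, *row) for i, row in enumerate(spec)
    )


@pytest.fixture
def tiny_protein_lipid():
    """One ARG residue plus a DOPS carboxylate and a DOPC phosphate group,
    with controllable coordinates (all atoms start far apart)."""
    spec = [
        ("N", "N", "ARG", 2163, "P", "protein"),
        ("CA", "C", "ARG", 2163, "P", "protein"),
        ("C", "C", "ARG", 2163, "P", "protein"),
        ("O", "O", "ARG", 2163, "P", "protein"),
        ("NH1", "N", "ARG", 2163, "P", "protein"),
        ("O13A", "O", "DOPS", 1, "L", "lipid"),
        ("O13B", "O", "DOPS", 1, "L", "lipid"),
        ("C13", "C", "DOPS", 1, "L", "lipid"),
        ("P", "P", "DOPC", 2, "L", "lipid"),
        ("O11", "O", "DOPC", 2, "L", "lipid"),
    ]
    topo = make_topology(spec)
    coords = np.array([
        [0.0, 0.0, 40.0], [1.5, 0.0, 40.0], [3.0, 0.0, 40.0],
        [4.5, 0.0, 40.0], [6.0, 0.0, 40.0],
        [0.0, 0.0, 0.0], [1.3, 0.0, 0.0], [0.6, 1.0, 0.0],
        [20.0, 0.0, 0.0], [21.3, 0.0, 0.0],
    ])
    return topo, coords


def frames_to_traj(topo, coords_list, box=None):
    return Trajectory(topo, [Frame(np.asarray(c), box=box)
                             for c in coords_list])
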