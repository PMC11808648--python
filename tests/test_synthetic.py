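"""Synthetic nanodisc/probe generator: composition, determinism,
self-hosting through the readers, and planted-truth plumbing."""

import dataclasses
import os

import numpy as np
import pytest

import disctraj as dt
from disctraj.model import ConfigurationError, Trajectory
from disctraj.moieties import assign_lipid_moieties
from disctraj.selection import select
from disctraj.synthetic import ContactSpec, PlantedTruth


def test_default_composition_is_80_20():
    topo, frame = dt.build_nanodisc()
    resids = {}
    for i in np.flatnonzero(topo.segment_classes == "lipid"):
        resids[int(topo.residue_ids[i])] = topo.residue_names[i]
    names = list(resids.values())
    assert len(names) == 160  # 64 + 16 per leaflet, two leaflets
    assert names.count("DOPS") / len(names) == pytest.approx(0.20)
    assert frame.n_atoms == topo.n_atoms


def test_leaflets_are_mirrored():
    topo, frame = dt.build_nanodisc(n_dopc_per_leaflet=8, n_dops_per_leaflet=2)
    lipid = np.flatnonzero(topo.segment_classes == "lipid")
    z = frame.coordinates[lipid, 2]
    assert (z > 0).sum() == (z < 0).sum()


def test_no_dops_means_no_carboxylate():
    topo, _ = dt.build_nanodisc(n_dopc_per_leaflet=10, n_dops_per_leaflet=0)
    moi = assign_lipid_moieties(topo)
    assert len(moi.lipid_indices("carboxylate")) == 0


def test_scaffold_ring_carries_anchor_residues():
    topo, frame = dt.build_nanodisc()
    for rid, resname in ((32, "MET"), (93, "GLU"), (158, "GLU")):
        i = topo.alpha_carbon(rid, "S")
        assert topo.residue_names[i] == resname
        assert topo.segment_classes[i] == "scaffold"
        assert frame.coordinates[i, 2] == 0.0


def test_invalid_parameters_rejected():
    with pytest.raises(ConfigurationError):
        dt.build_nanodisc(area_per_lipid=0.0)
    with pytest.raises(ConfigurationError):
        dt.build_nanodisc(n_dopc_per_leaflet=0, n_dops_per_leaflet=0)
    with pytest.raises(ConfigurationError):
        PlantedTruth(contacts=[ContactSpec(2093, "PHE", "CG", "chain_carbon",
                                           "DOPC", "hydrophobic", 1.5)])
    nano = dt.build_nanodisc(n_dopc_per_leaflet=6, n_dops_per_leaflet=2)
    probe = dt.build_probe_protein()
    with pytest.raises(ConfigurationError):
        dt.generate_binding_trajectory(nano, probe, n_frames=5)


def test_probe_selections(probe):
    topo, frame = probe
    guanidino = select(topo, "resname ARG and name NH1 NH2 NE")
    n_arg = len({int(topo.residue_ids[i]) for i in
                 np.flatnonzero(topo.residue_names == "ARG")})
    assert len(guanidino) == 3 * n_arg
    for rid in set(int(r) for r in topo.residue_ids):
        bb = [i for i in topo.atoms_of_residue(rid)
              if topo.names[i] in ("N", "CA", "C", "O")]
        assert len(bb) == 4
    # residue ids stay within the C-domain numbering
    assert topo.residue_ids.min() >= 2021 and topo.residue_ids.max() <= 2332


def test_generator_determinism_is_byte_identical(tmp_path):
    nano = dt.build_nanodisc(seed=5)
    probe = dt.build_probe_protein(seed=5)
    paths = []
    for rep in ("a", "b"):
        traj, truth = dt.generate_binding_trajectory(nano, probe,
                                                     n_frames=40, seed=5)
        p = tmp_path / f"{rep}.pdb"
        dt.write_trajectory(traj[:5], str(p))
        truth.to_json(str(tmp_path / f"{rep}.json"))
        paths.append(p)
    assert paths[0].read_bytes() == paths[1].read_bytes()
    assert (tmp_path / "a.json").read_bytes() == (tmp_path / "b.json").read_bytes()


def test_generated_trajectory_parses_through_readers(tmp_path, binding):
    traj, truth = binding
    p = tmp_path / "sub.pdb"
    dt.write_trajectory(traj[:3], str(p))
    back = dt.read_trajectory(str(p))
    assert back.n_frames == 3
    assert back.topology.n_atoms == traj.topology.n_atoms
    assert list(back.topology.names) == list(traj.topology.names)
    assert list(back.topology.segment_classes) == \
        list(traj.topology.segment_classes)
    np.testing.assert_allclose(back.frames[2].coordinates,
                               traj.frames[2].coordinates, atol=1e-3)


def test_topology_invariants(binding):
    traj, _ = binding
    topo = traj.topology
    for chain in set(topo.chain_ids):
        ids = topo.residue_ids[topo.chain_ids == chain]
        assert np.all(np.diff(ids) >= 0)  # monotone within chain
    for frame in traj.frames[:5]:
        assert np.all(np.isfinite(frame.coordinates))
        assert frame.n_atoms == topo.n_atoms


def test_truth_json_round_trip(tmp_path, binding):
    _, truth = binding
    p = tmp_path / "truth.json"
    truth.to_json(str(p))
    back = PlantedTruth.from_json(str(p))
    assert back == truth


def test_noiseless_binary_occupancies():
    """With zero jitter and occupancies in {0, 1}, recovery is exact."""
    nano = dt.build_nanodisc(n_dopc_per_leaflet=16, n_dops_per_leaflet=4, seed=2)
    probe = dt.build_probe_protein(seed=2)
    truth = PlantedTruth(contacts=[
        ContactSpec(2093, "PHE", "CG", "chain_carbon", "DOPC", "hydrophobic", 1.0),
        ContactSpec(2200, "PHE", "CG", "chain_carbon", "DOPS", "hydrophobic", 0.0),
        ContactSpec(2163, "ARG", "NH1", "carboxylate", "DOPS", "hydrophilic", 1.0),
    ])
    traj, truth = dt.generate_binding_trajectory(nano, probe, n_frames=60,
                                                 truth=truth, noise_sigma=0.0,
                                                 seed=2)
    from disctraj.contacts import contact_timeseries
    from disctraj.moieties import assign_protein_classes
    topo = traj.topology
    moi = assign_lipid_moieties(topo).merge(assign_protein_classes(topo))
    settled = traj[truth.settled_start:]
    hb = contact_timeseries(settled, [2093, 2200], moi, 4.0, mode="hydrophobic")
    assert hb.occupancy_of(2093, "chain_carbon/DOPC") == 1.0
    assert hb.occupancy_of(2200, "chain_carbon/DOPS") == 0.0
    hp = contact_timeseries(settled, [2163], moi, 4.0, mode="hydrophilic")
    assert hp.occupancy_of(2163, "carboxylate/DOPS") == 1.0


def test_params_table_covers_every_atom(tmp_path, binding):
    traj, _ = binding
    p = tmp_path / "params.tsv"
    dt.write_params_table(traj.topology, str(p))
    params = dt.NonbondedParams(traj.topology, dt.load_params_table(str(p)))
    params.require(np.arange(traj.topology.n_atoms))  # must not raise


def test_frame_times_follow_save_stride(binding):
    traj, _ = binding
    assert traj.frames[0].time == 0.0
    assert traj.frames[3].time == pytest.approx(3 * 240.0)
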