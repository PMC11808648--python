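"""Cutoff Coulomb + Lennard-Jones pair sums: closed forms, oracle
equivalence, additivity, invariances and frame selection."""

import numpy as np
import pandas as pd
import pytest

import disctraj as dt
from disctraj.energetics import (CLASH_FLOOR, COULOMB_CONSTANT,
                                 NonbondedParams, energy_series,
                                 export_lowest_energy_frame, nonbonded_energy)
from disctraj.model import ClashError, Frame, MissingParameterError

from conftest import frames_to_traj, make_topology


def make_params(topo, rows, cutoff=12.0):
    return NonbondedParams(topo, pd.DataFrame(rows), cutoff=cutoff)


def pair_system(d, q1=1.0, q2=1.0, sigma=3.5, eps=0.0):
    topo = make_topology([("Q1", "C", "ION", 1, "A", "ion"),
                          ("Q2", "C", "ION", 2, "A", "ion")])
    params = make_params(topo, [
        dict(residue_name="ION", atom_name="Q1", charge_e=q1, sigma_A=sigma,
             epsilon_kJmol=eps),
        dict(residue_name="ION", atom_name="Q2", charge_e=q2, sigma_A=sigma,
             epsilon_kJmol=eps),
    ])
    frame = Frame(np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]]))
    return frame, params


def test_coulomb_closed_form():
    frame, params = pair_system(10.0)
    e = nonbonded_energy(frame, [0], [1], params)
    assert e.coulomb == pytest.approx(COULOMB_CONSTANT / 10.0, abs=1e-9)
    assert e.coulomb == pytest.approx(138.94, abs=0.01)
    assert e.lj == 0.0


def test_lj_root_and_minimum():
    frame, params = pair_system(3.5, q1=0.0, q2=0.0, sigma=3.5, eps=0.5)
    assert nonbonded_energy(frame, [0], [1], params).lj == pytest.approx(0.0, abs=1e-12)
    d_min = 2.0 ** (1.0 / 6.0) * 3.5
    frame2, _ = pair_system(d_min)
    assert nonbonded_energy(frame2, [0], [1], params).lj == \
        pytest.approx(-0.5, abs=1e-12)


def test_beyond_cutoff_is_zero():
    frame, params = pair_system(12.5)
    e = nonbonded_energy(frame, [0], [1], params)
    assert e.total == 0.0


def test_matches_brute_force_pair_sum():
    rng = np.random.default_rng(0)
    n = 30
    topo = make_topology([(f"A{i}", "C", "MOL", 1 + i // 15, "A", "ion")
                          for i in range(n)])
    rows = [dict(residue_name=f"MOL", atom_name=f"A{i}",
                 charge_e=float(rng.uniform(-1, 1)),
                 sigma_A=float(rng.uniform(2.5, 3.8)),
                 epsilon_kJmol=float(rng.uniform(0.1, 0.9)))
            for i in range(n)]
    rows = [dict(r, residue_name="MOL") for r in rows]
    params = make_params(topo, rows)
    coords = rng.uniform(0, 12, (n, 3))
    frame = Frame(coords)
    a, b = np.arange(15), np.arange(15, 30)
    got = nonbonded_energy(frame, a, b, params)
    e_ref = 0.0
    for i in a:
        for j in b:
            d = np.linalg.norm(coords[i] - coords[j])
            if d < 12.0:
                e_ref += COULOMB_CONSTANT * params.charge[i] * params.charge[j] / d
                sij = 0.5 * (params.sigma[i] + params.sigma[j])
                eij = np.sqrt(params.epsilon[i] * params.epsilon[j])
                e_ref += 4 * eij * ((sij / d) ** 12 - (sij / d) ** 6)
    assert got.total == pytest.approx(e_ref, rel=1e-8)


def test_symmetry_and_rigid_motion_invariance():
    rng = np.random.default_rng(1)
    n = 20
    topo = make_topology([(f"A{i}", "C", "MOL", 1, "A", "ion")
                          for i in range(n)])
    params = make_params(topo, [
        dict(residue_name="MOL", atom_name=f"A{i}", charge_e=0.2,
             sigma_A=3.0, epsilon_kJmol=0.3) for i in range(n)])
    coords = rng.uniform(0, 8, (n, 3))
    a, b = np.arange(10), np.arange(10, 20)
    e_ab = nonbonded_energy(Frame(coords), a, b, params)
    e_ba = nonbonded_energy(Frame(coords), b, a, params)
    assert e_ab.total == pytest.approx(e_ba.total, rel=1e-12)
    th = 1.1
    rot = np.array([[np.cos(th), -np.sin(th), 0],
                    [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
    moved = Frame(coords @ rot.T + np.array([7.0, -3.0, 2.0]))
    assert nonbonded_energy(moved, a, b, params).total == \
        pytest.approx(e_ab.total, rel=1e-9)


def test_opposite_charges_monotone_attraction():
    energies = []
    for d in (8.0, 6.0, 4.0, 2.0, 1.0):
        frame, params = pair_system(d, q1=1.0, q2=-1.0)
        energies.append(nonbonded_energy(frame, [0], [1], params).total)
    assert all(b < a for a, b in zip(energies, energies[1:]))


def test_clash_floor():
    frame, params = pair_system(CLASH_FLOOR / 2)
    with pytest.raises(ClashError):
        nonbonded_energy(frame, [0], [1], params)


def test_missing_parameter_names_atom():
    topo = make_topology([("Q1", "C", "ION", 1, "A", "ion"),
                          ("ZZ", "C", "ION", 2, "A", "ion")])
    params = make_params(topo, [dict(residue_name="ION", atom_name="Q1",
                                     charge_e=0.0, sigma_A=3.0,
                                     epsilon_kJmol=0.1)])
    with pytest.raises(MissingParameterError, match="ZZ"):
        nonbonded_energy(Frame(np.zeros((2, 3)) + [[0, 0, 0], [5, 0, 0]]),
                         [0], [1], params)


def _lipid_pair_system():
    topo = make_topology([
        ("Q1", "N", "PRT", 2100, "P", "protein"),
        ("C21", "C", "DOPC", 1, "L", "lipid"),
        ("C21", "C", "DOPS", 2, "L", "lipid"),
    ])
    rows = [dict(residue_name=r, atom_name=n, charge_e=q, sigma_A=3.0,
                 epsilon_kJmol=0.3)
            for r, n, q in (("PRT", "Q1", 0.5), ("DOPC", "C21", -0.2),
                            ("DOPS", "C21", -0.4))]
    return topo, make_params(topo, rows)


def test_species_additivity_is_exact():
    topo, params = _lipid_pair_system()
    coords = np.array([[0.0, 0.0, 0.0], [4.0, 0.0, 0.0], [0.0, 5.0, 0.0]])
    frame = Frame(coords)
    e_all = nonbonded_energy(frame, [0], [1, 2], params)
    e_pc = nonbonded_energy(frame, [0], [1], params)
    e_ps = nonbonded_energy(frame, [0], [2], params)
    assert e_all.total == pytest.approx(e_pc.total + e_ps.total, rel=1e-12)
    traj = frames_to_traj(topo, [coords])
    series = energy_series(traj, [0], params)
    assert series.total["e_total"][0] == pytest.approx(e_all.total, rel=1e-12)
    assert set(series.per_species) == {"DOPC", "DOPS"}


def test_never_in_range_gives_zero_series_and_first_frame_argmin():
    topo, params = _lipid_pair_system()
    far = np.array([[0.0, 0.0, 100.0], [4.0, 0.0, 0.0], [0.0, 5.0, 0.0]])
    traj = frames_to_traj(topo, [far] * 4)
    series = energy_series(traj, [0], params)
    assert np.all(series.total["e_total"] == 0.0)
    assert series.argmin_frame == 0  # tie broken to the earliest frame


def test_argmin_and_lowest_frame_export(tmp_path):
    topo, params = _lipid_pair_system()
    # opposite charges: closer protein atom -> lower energy
    frames = [np.array([[0.0, 0.0, z], [4.0, 0.0, 0.0], [0.0, 5.0, 0.0]])
              for z in (6.0, 3.0, 8.0)]
    traj = frames_to_traj(topo, frames)
    series = energy_series(traj, [0], params)
    assert series.argmin_frame == 1
    path = tmp_path / "lowest.pdb"
    k = export_lowest_energy_frame(traj, series, str(path))
    assert k == 1
    _, frame = dt.read_structure(str(path))
    np.testing.assert_allclose(frame.coordinates, frames[1], atol=1e-3)


def test_binding_trajectory_argmin_after_insertion(binding):
    """Energy reaches its minimum only after the loops have inserted."""
    import os
    import tempfile
    traj, truth = binding
    topo = traj.topology
    with tempfile.TemporaryDirectory() as tmp:
        pp = os.path.join(tmp, "params.tsv")
        dt.write_params_table(topo, pp)
        params = NonbondedParams(topo, dt.load_params_table(pp))
    prot = np.flatnonzero(topo.segment_classes == "protein")
    series = energy_series(traj, prot, params)
    assert series.argmin_frame >= truth.insertion_frame
    settled = series.total["e_total"][truth.settled_start:]
    approach = series.total["e_total"][:truth.insertion_frame // 2]
    assert settled.mean() < approach.mean()
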