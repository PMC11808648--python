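"""Contact counting: strict-cutoff semantics, brute-force equivalence,
occupancy definition and its invariances."""

import numpy as np
import pytest

from disctraj.contacts import (InvalidGroupsError, average_replicates,
                               contact_timeseries, count_contacts)
from disctraj.model import Frame
from disctraj.moieties import assign_lipid_moieties, assign_protein_classes

from conftest import frames_to_traj, make_topology


def two_atom_frame(d, box=None):
    return Frame(np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]]), box=box)


def test_strict_cutoff_boundary():
    assert count_contacts(two_atom_frame(3.9), [0], [1], 4.0) == 1
    assert count_contacts(two_atom_frame(4.0), [0], [1], 4.0) == 0


def test_empty_group_counts_zero():
    assert count_contacts(two_atom_frame(1.0), [0], [], 4.0) == 0


def test_overlapping_groups_rejected():
    with pytest.raises(InvalidGroupsError):
        count_contacts(two_atom_frame(1.0), [0, 1], [1], 4.0)


def test_symmetry():
    rng = np.random.default_rng(5)
    frame = Frame(rng.uniform(0, 15, (40, 3)))
    a, b = np.arange(20), np.arange(20, 40)
    assert count_contacts(frame, a, b, 4.0) == count_contacts(frame, b, a, 4.0)


def brute_force_count(ca, cb, cutoff, box=None):
    diff = ca[:, None, :] - cb[None, :, :]
    if box is not None:
        diff -= box * np.round(diff / box)
    d = np.sqrt((diff ** 2).sum(axis=2))
    return int((d < cutoff).sum())


@pytest.mark.parametrize("use_box", [False, True])
def test_tree_count_equals_brute_force(use_box):
    """Accelerated pair search equals the all-pairs oracle on 30 random
    systems (the larger 100-system sweep runs in the acceptance suite)."""
    rng = np.random.default_rng(42)
    for _ in range(30):
        n = int(rng.integers(50, 300))
        box = np.array([20.0, 22.0, 25.0]) if use_box else None
        coords = rng.uniform(0, 20, (n, 3))
        split = int(rng.integers(5, n - 5))
        frame = Frame(coords, box=box)
        got = count_contacts(frame, np.arange(split), np.arange(split, n), 4.0)
        want = brute_force_count(coords[:split], coords[split:], 4.0, box)
        assert got == want


def test_rigid_translation_invariance():
    rng = np.random.default_rng(1)
    coords = rng.uniform(0, 15, (60, 3))
    a, b = np.arange(30), np.arange(30, 60)
    box = np.array([30.0, 30.0, 30.0])
    base = count_contacts(Frame(coords, box=box), a, b, 4.0)
    shift = np.array([45.3, -12.2, 7.7])
    assert count_contacts(Frame(coords + shift, box=box), a, b, 4.0) == base
    assert count_contacts(Frame(coords + shift), a, b, 4.0) == \
        count_contacts(Frame(coords), a, b, 4.0)


@pytest.fixture
def tiny_traj(tiny_protein_lipid):
    """Four frames: NH1 touches the DOPS carboxylate in frames 0 and 2
    (per-frame counts 1, 0, 2, 0 against carboxylate oxygens)."""
    topo, base = tiny_protein_lipid
    f0 = base.copy(); f0[4] = [0.0, 0.0, 3.0]        # NH1 3.0 A from O13A
    f1 = base.copy()                                  # far
    f2 = base.copy(); f2[4] = [0.6, 0.0, 0.9]         # close to both oxygens
    f3 = base.copy()
    return topo, frames_to_traj(topo, [f0, f1, f2, f3])


def test_occupancy_is_frame_indicator(tiny_traj):
    topo, traj = tiny_traj
    moi = assign_lipid_moieties(topo).merge(assign_protein_classes(topo))
    mat = contact_timeseries(traj, [2163], moi, 4.0, mode="hydrophilic")
    col = mat.moieties.index("carboxylate/DOPS")
    assert list(mat.counts[:, 0, col] >= 1) == [True, False, True, False]
    assert mat.occupancy[0, col] == pytest.approx(0.5)


def test_occupancy_invariant_under_frame_reordering(tiny_traj):
    topo, traj = tiny_traj
    moi = assign_lipid_moieties(topo).merge(assign_protein_classes(topo))
    mat = contact_timeseries(traj, [2163], moi, 4.0, mode="hydrophilic")
    reordered = frames_to_traj(topo, [traj.frames[i].coordinates
                                      for i in (3, 0, 1, 2)])
    mat2 = contact_timeseries(reordered, [2163], moi, 4.0, mode="hydrophilic")
    np.testing.assert_allclose(mat.occupancy, mat2.occupancy)


def test_occupancy_monotone_in_cutoff(tiny_traj):
    topo, traj = tiny_traj
    moi = assign_lipid_moieties(topo).merge(assign_protein_classes(topo))
    occ = [contact_timeseries(traj, [2163], moi, c, mode="hydrophilic").occupancy
           for c in (2.0, 4.0, 8.0)]
    assert np.all(occ[0] <= occ[1]) and np.all(occ[1] <= occ[2])


def test_static_trajectory_occupancy_is_zero_or_one(tiny_traj):
    topo, traj = tiny_traj
    static = frames_to_traj(topo, [traj.frames[0].coordinates] * 10)
    moi = assign_lipid_moieties(topo).merge(assign_protein_classes(topo))
    mat = contact_timeseries(static, [2163], moi, 4.0, mode="hydrophilic")
    assert set(np.unique(mat.occupancy)) <= {0.0, 1.0}


def test_hydrophobic_mode_ignores_polar_residues(tiny_traj):
    topo, traj = tiny_traj
    moi = assign_lipid_moieties(topo).merge(assign_protein_classes(topo))
    mat = contact_timeseries(traj, [2163], moi, 4.0, mode="hydrophobic")
    # ARG is not in the hydrophobic set: all-zero rows
    assert mat.occupancy.sum() == 0


def test_average_replicates(tiny_traj):
    topo, traj = tiny_traj
    moi = assign_lipid_moieties(topo).merge(assign_protein_classes(topo))
    m1 = contact_timeseries(traj, [2163], moi, 4.0, mode="hydrophilic")
    static = frames_to_traj(topo, [traj.frames[0].coordinates] * 4)
    m2 = contact_timeseries(static, [2163], moi, 4.0, mode="hydrophilic")
    avg = average_replicates([m1, m2])
    np.testing.assert_allclose(avg.occupancy, (m1.occupancy + m2.occupancy) / 2)
    single = average_replicates([m1])
    np.testing.assert_allclose(single.occupancy, m1.occupancy)
    m3 = contact_timeseries(traj, [2163, 1], moi, 4.0, mode="hydrophilic")
    with pytest.raises(Exception):
        average_replicates([m1, m3])


def test_planted_occupancy_recovered(binding):
    """Bernoulli-planted contacts come back within binomial error."""
    traj, truth = binding
    settled = traj[truth.settled_start:]
    topo = traj.topology
    moi = assign_lipid_moieties(topo).merge(assign_protein_classes(topo))
    resids = sorted({s.residue_id for s in truth.contacts})
    n = settled.n_frames
    for mode in ("hydrophilic", "hydrophobic"):
        mat = contact_timeseries(settled, resids, moi, 4.0, mode=mode)
        for s in truth.contacts:
            if s.channel != mode:
                continue
            occ = mat.occupancy_of(s.residue_id, s.moiety_label)
            tol = 3 * np.sqrt(s.occupancy * (1 - s.occupancy) / n) + 1e-9
            assert abs(occ - s.occupancy) <= tol, (s.residue_id, s.moiety_label)
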