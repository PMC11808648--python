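"""Kabsch superposition, RMSD series and per-residue RMSF."""

import numpy as np
import pytest

from disctraj.metrics import (rmsd, rmsd_series, rmsf_atoms, rmsf_per_residue,
                              superpose)
from disctraj.model import DegenerateGeometryError, Frame

from conftest import frames_to_traj, make_topology


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def quaternion_rmsd(mobile, reference):
    """Independent oracle: Horn's closed-form quaternion superposition."""
    x = mobile - mobile.mean(axis=0)
    y = reference - reference.mean(axis=0)
    S = x.T @ y
    K = np.array([
        [S[0, 0] + S[1, 1] + S[2, 2], S[1, 2] - S[2, 1],
         S[2, 0] - S[0, 2], S[0, 1] - S[1, 0]],
        [S[1, 2] - S[2, 1], S[0, 0] - S[1, 1] - S[2, 2],
         S[0, 1] + S[1, 0], S[0, 2] + S[2, 0]],
        [S[2, 0] - S[0, 2], S[0, 1] + S[1, 0],
         -S[0, 0] + S[1, 1] - S[2, 2], S[1, 2] + S[2, 1]],
        [S[0, 1] - S[1, 0], S[0, 2] + S[2, 0],
         S[1, 2] + S[2, 1], -S[0, 0] - S[1, 1] + S[2, 2]],
    ])
    lam = np.linalg.eigvalsh(K)[-1]
    n = mobile.shape[0]
    msd = max(((x ** 2).sum() + (y ** 2).sum() - 2 * lam) / n, 0.0)
    return np.sqrt(msd)


def test_exact_recovery_of_rigid_motion():
    rng = np.random.default_rng(0)
    ref = rng.normal(0, 5, (25, 3))
    th = np.radians(37.0)
    rot = np.array([[np.cos(th), -np.sin(th), 0],
                    [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
    mobile = ref @ rot.T + np.array([5.0, -2.0, 1.0])
    fit = superpose(mobile, ref)
    assert fit.rmsd < 1e-6
    np.testing.assert_allclose(fit.apply(mobile), ref, atol=1e-9)
    assert np.linalg.det(fit.rotation) == pytest.approx(1.0, abs=1e-8)


def test_identity_fit():
    rng = np.random.default_rng(1)
    pts = rng.normal(0, 3, (10, 3))
    fit = superpose(pts, pts)
    np.testing.assert_allclose(fit.rotation, np.eye(3), atol=1e-9)
    np.testing.assert_allclose(fit.translation, 0.0, atol=1e-9)
    assert fit.rmsd < 1e-9


def test_agrees_with_quaternion_oracle():
    rng = np.random.default_rng(7)
    for _ in range(20):
        ref = rng.normal(0, 4, (10, 3))
        mobile = ref @ random_rotation(rng).T + rng.normal(0, 10, 3)
        mobile[0] += rng.normal(0, 1.0, 3)  # perturb one atom
        assert superpose(mobile, ref).rmsd == pytest.approx(
            quaternion_rmsd(mobile, ref), abs=1e-6)


def test_degenerate_inputs_rejected():
    with pytest.raises(DegenerateGeometryError):
        superpose(np.zeros((2, 3)), np.zeros((2, 3)))
    same = np.tile([[1.0, 2.0, 3.0]], (5, 1))
    with pytest.raises(DegenerateGeometryError):
        superpose(same, same)


def _topo(n):
    return make_topology([("CA", "C", "ALA", i + 1, "A", "protein")
                          for i in range(n)])


def test_rmsd_series_of_rigid_motions_is_zero():
    rng = np.random.default_rng(3)
    ref = rng.normal(0, 5, (20, 3))
    frames = [ref @ random_rotation(rng).T + rng.normal(0, 20, 3)
              for _ in range(8)]
    traj = frames_to_traj(_topo(20), frames)
    rs = rmsd_series(traj, Frame(ref), np.arange(20), fit=True)
    assert np.all(rs.values < 1e-6)


def test_no_fit_rmsd_equals_displacement():
    rng = np.random.default_rng(4)
    ref = rng.normal(0, 5, (15, 3))
    shift = np.array([3.0, 4.0, 0.0])  # norm 5
    traj = frames_to_traj(_topo(15), [ref + shift])
    rs = rmsd_series(traj, Frame(ref), np.arange(15), fit=False)
    assert rs.values[0] == pytest.approx(5.0, abs=1e-12)


def test_gaussian_jitter_mean_rmsd():
    """Isotropic jitter sigma per axis gives expected RMSD sigma*sqrt(3)."""
    rng = np.random.default_rng(5)
    ref = rng.normal(0, 10, (300, 3))
    sigma = 0.5
    frames = [ref + rng.normal(0, sigma, ref.shape) for _ in range(60)]
    traj = frames_to_traj(_topo(300), frames)
    rs = rmsd_series(traj, Frame(ref), np.arange(300), fit=False)
    assert rs.mean == pytest.approx(sigma * np.sqrt(3), rel=0.03)


def test_no_fit_rmsd_triangle_inequality():
    rng = np.random.default_rng(6)
    a, b, c = (rng.normal(0, 5, (12, 3)) for _ in range(3))
    assert rmsd(a, c) <= rmsd(a, b) + rmsd(b, c) + 1e-12


def test_static_trajectory_rmsf_is_zero():
    ref = np.random.default_rng(7).normal(0, 5, (10, 3))
    traj = frames_to_traj(_topo(10), [ref] * 5)
    assert np.all(rmsf_atoms(traj, np.arange(10), fit=False) < 1e-12)


def test_alternating_atom_rmsf_definition():
    base = np.zeros((4, 3))
    base[:, 0] = [0.0, 5.0, 10.0, 15.0]
    frames = []
    for k in range(40):
        f = base.copy()
        f[2, 0] += 1.0 if k % 2 == 0 else -1.0
        frames.append(f)
    traj = frames_to_traj(_topo(4), frames)
    vals = rmsf_atoms(traj, np.arange(4), fit=False)
    assert vals[2] == pytest.approx(1.0, abs=1e-12)
    assert np.all(vals[[0, 1, 3]] < 1e-12)


def test_single_frame_rmsf_rejected():
    traj = frames_to_traj(_topo(4), [np.zeros((4, 3))])
    with pytest.raises(DegenerateGeometryError):
        rmsf_atoms(traj, np.arange(4))


def test_two_mobility_classes_recovered():
    """Planted per-atom fluctuation scales come back within 10%."""
    rng = np.random.default_rng(8)
    n_half, T = 40, 400
    ref = rng.normal(0, 20, (2 * n_half, 3))
    sig = np.concatenate([np.full(n_half, 0.3), np.full(n_half, 1.0)])
    frames = [ref + rng.normal(0, 1.0, ref.shape) * sig[:, None]
              for _ in range(T)]
    traj = frames_to_traj(_topo(2 * n_half), frames)
    vals = rmsf_atoms(traj, np.arange(2 * n_half), fit=False)
    expected = sig * np.sqrt(3)
    assert vals[:n_half].mean() == pytest.approx(expected[0], rel=0.10)
    assert vals[n_half:].mean() == pytest.approx(expected[-1], rel=0.10)


def test_rmsf_invariant_under_per_frame_rigid_motion():
    rng = np.random.default_rng(9)
    ref = rng.normal(0, 8, (30, 3))
    jit = [ref + rng.normal(0, 0.4, ref.shape) for _ in range(25)]
    base = rmsf_atoms(frames_to_traj(_topo(30), jit), np.arange(30), fit=True)
    moved = [f @ random_rotation(rng).T + rng.normal(0, 30, 3) for f in jit]
    got = rmsf_atoms(frames_to_traj(_topo(30), moved), np.arange(30), fit=True)
    np.testing.assert_allclose(got, base, atol=1e-8)


def test_rmsf_per_residue_averages_backbone():
    topo = make_topology(
        [("N", "N", "GLY", 1, "A", "protein"),
         ("CA", "C", "GLY", 1, "A", "protein"),
         ("N", "N", "GLY", 2, "A", "protein"),
         ("CA", "C", "GLY", 2, "A", "protein")]
    )
    rng = np.random.default_rng(10)
    ref = np.array([[0, 0, 0], [1.5, 0, 0], [30, 0, 0], [31.5, 0, 0.0]])
    sig = np.array([0.2, 0.2, 0.8, 0.8])
    frames = [ref + rng.normal(0, 1, ref.shape) * sig[:, None]
              for _ in range(300)]
    traj = frames_to_traj(topo, frames)
    table = rmsf_per_residue(traj, np.arange(4), fit=False)
    assert list(table["residue_id"]) == [1, 2]
    assert table["rmsf"][1] > 2.5 * table["rmsf"][0]


def test_domain_tether_reduces_fluctuation(nanodisc, probe):
    """A probe whose second domain wobbles independently with a wide angular
    spread shows larger backbone RMSD than the tightly coupled default —
    the qualitative stabilization signature."""
    import dataclasses
    import disctraj as dt
    from disctraj.selection import select

    tight, truth_t = dt.generate_binding_trajectory(
        nanodisc, probe, n_frames=120, seed=21)
    loose_truth = dt.PlantedTruth(tilt={"C1": (68.0, 8.0), "C2": (69.0, 30.0)})
    loose, truth_l = dt.generate_binding_trajectory(
        nanodisc, probe, n_frames=120, truth=loose_truth, seed=21)
    topo = tight.topology
    sel = select(topo, "resid 2171-2332 and backbone")
    s = truth_t.settled_start
    r_tight = rmsd_series(tight[s:], 0, sel, fit=False)
    r_loose = rmsd_series(loose[s:], 0, sel, fit=False)
    assert r_loose.mean > r_tight.mean
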