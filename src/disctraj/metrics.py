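"""Least-squares superposition (Kabsch), RMSD time series, per-residue RMSF.

Backbone means N, CA, C, O.  No mass weighting.  RMSF is computed about the
time-average structure after one fit–average iteration, the common
convention for fluctuation profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .model import DegenerateGeometryError, EmptySelectionError, Frame, Trajectory


@dataclass
class FitResult:
    """Optimal proper rotation/translation and the minimized RMSD (Å).

    Apply as ``rotated = mobile @ rotation.T + translation``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: Optional[np.ndarray] = None,
) -> FitResult:
    """Kabsch fit of mobile onto reference (equal-length coordinate sets).

    The proper-rotation constraint (det = +1) is enforced by flipping the
    smallest singular direction when needed.
    """
    mobile = np.asarray(mobile, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise DegenerateGeometryError("coordinate sets must both be (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateGeometryError("superposition needs at least 3 atoms")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=np.float64)
        w = w / w.sum()
    mu_m = (w[:, None] * mobile).sum(axis=0)
    mu_r = (w[:, None] * reference).sum(axis=0)
    x = mobile - mu_m
    y = reference - mu_r
    h = (w[:, None] * x).T @ y
    if np.linalg.matrix_rank(h) < 2:
        raise DegenerateGeometryError("rank-deficient covariance (degenerate fit)")
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rot = vt.T @ flip @ u.T
    t = mu_r - rot @ mu_m
    fitted = mobile @ rot.T + t
    rmsd = float(np.sqrt((w * ((fitted - reference) ** 2).sum(axis=1)).sum()))
    return FitResult(rotation=rot, translation=t, rmsd=rmsd)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (no-fit) RMSD between paired coordinate sets."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    return float(np.sqrt(((a - b) ** 2).sum(axis=1).mean()))


@dataclass
class RMSDSeries:
    values: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return float(self.values.std(ddof=1)) if self.values.size > 1 else 0.0


def rmsd_series(
    traj: Trajectory,
    reference: Union[Frame, int],
    selection: Sequence[int],
    fit: bool = True,
) -> RMSDSeries:
    """RMSD of each frame to a reference over the selection.

    With ``fit`` each frame is first superposed onto the reference over the
    same selection; without it the raw displacement RMSD is reported.
    """
    sel = np.asarray(selection, dtype=np.int64)
    if sel.size == 0:
        raise EmptySelectionError("empty selection for RMSD")
    ref = traj.frames[reference] if isinstance(reference, int) else reference
    ref_xyz = ref.coordinates[sel]
    values = np.empty(traj.n_frames)
    for k, frame in enumerate(traj.frames):
        xyz = frame.coordinates[sel]
        if fit:
            values[k] = superpose(xyz, ref_xyz).rmsd
        else:
            values[k] = rmsd(xyz, ref_xyz)
    return RMSDSeries(values=values)


def rmsf_atoms(
    traj: Trajectory,
    selection: Sequence[int],
    fit: bool = True,
) -> np.ndarray:
    """Atomic RMSF about the time-average structure.

    With ``fit``, frames are superposed onto frame 0, averaged, re-fit to
    that average, and the final fluctuation is taken about the re-averaged
    structure (one fit–average iteration).
    """
    sel = np.asarray(selection, dtype=np.int64)
    if sel.size == 0:
        raise EmptySelectionError("empty selection for RMSF")
    if traj.n_frames < 2:
        raise DegenerateGeometryError("RMSF requires at least 2 frames")
    coords = np.stack([f.coordinates[sel] for f in traj.frames])
    if fit:
        ref = coords[0]
        for k in range(coords.shape[0]):
            coords[k] = superpose(coords[k], ref).apply(coords[k])
        mean1 = coords.mean(axis=0)
        for k in range(coords.shape[0]):
            coords[k] = superpose(coords[k], mean1).apply(coords[k])
    mean = coords.mean(axis=0)
    return np.sqrt(((coords - mean) ** 2).sum(axis=2).mean(axis=0))


def rmsf_per_residue(
    traj: Trajectory,
    selection: Sequence[int],
    fit: bool = True,
) -> pd.DataFrame:
    """Residue RMSF = unweighted mean of its selected (backbone) atoms."""
    sel = np.asarray(selection, dtype=np.int64)
    atomic = rmsf_atoms(traj, sel, fit=fit)
    topo = traj.topology
    rows = []
    seen = {}
    for pos, i in enumerate(sel):
        i = int(i)
        key = (topo.chain_ids[i], int(topo.residue_ids[i]))
        if key not in seen:
            seen[key] = dict(residue_id=key[1],
                             residue_name=topo.residue_names[i], vals=[])
            rows.append(seen[key])
        seen[key]["vals"].append(atomic[pos])
    return pd.DataFrame(
        [dict(residue_id=r["residue_id"], residue_name=r["residue_name"],
              rmsf=float(np.mean(r["vals"]))) for r in rows]
    )
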