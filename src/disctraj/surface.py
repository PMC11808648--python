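"""Shrake–Rupley solvent-accessible surface area and ΔSASA upon binding.

For each surface atom, quasi-uniform test points (a deterministic golden-
spiral set) are placed on the sphere of radius (r_vdw + probe); the
accessible fraction — points not strictly inside any other occluder's
expanded sphere — times the sphere area is the atomic SASA.  A residue's
SASA is the plain sum over its atoms.

ΔSASA per residue is mean(unbound) − mean(bound) over trajectory frames,
so positive values mean burial upon membrane binding.  The bound-state
occluder set includes the lipids (that occlusion is what makes membrane
burial visible); the unbound set is protein-only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .model import (
    ConfigurationError,
    Frame,
    MissingParameterError,
    Topology,
    TopologyMismatchError,
    Trajectory,
)

DEFAULT_PROBE_RADIUS = 1.4  # Å, water probe
DEFAULT_N_POINTS = 960

#: van der Waals radii (Å) by element.
DEFAULT_RADII: Dict[str, float] = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.20,
}


def golden_spiral_points(n: int) -> np.ndarray:
    """n deterministic quasi-uniform unit vectors (Fibonacci sphere)."""
    k = np.arange(n)
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _atom_radii(topology: Topology, indices: np.ndarray, radii: Dict[str, float]):
    out = np.empty(indices.size)
    for k, i in enumerate(indices):
        el = topology.elements[int(i)]
        if el not in radii:
            raise MissingParameterError(
                f"no vdW radius for element {el!r} (atom {int(i)}, "
                f"name {topology.names[int(i)]!r})"
            )
        out[k] = radii[el]
    return out


def sasa_atoms(
    topology: Topology,
    frame: Frame,
    surface: Sequence[int],
    occluders: Optional[Sequence[int]] = None,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    radii: Optional[Dict[str, float]] = None,
) -> np.ndarray:
    """Per-atom SASA (Ų) of the surface atoms against the occluder set."""
    if n_points < 32:
        raise ConfigurationError("n_points must be at least 32")
    radii = DEFAULT_RADII if radii is None else radii
    surface = np.asarray(surface, dtype=np.int64)
    occluders = surface if occluders is None else np.asarray(occluders, dtype=np.int64)
    r_surf = _atom_radii(topology, surface, radii) + probe_radius
    r_occ = _atom_radii(topology, occluders, radii) + probe_radius
    c_surf = frame.coordinates[surface]
    c_occ = frame.coordinates[occluders]
    sphere = golden_spiral_points(n_points)
    tree = cKDTree(c_occ)
    r_occ_max = r_occ.max() if r_occ.size else 0.0
    out = np.empty(surface.size)
    for k in range(surface.size):
        nb = tree.query_ball_point(c_surf[k], r_surf[k] + r_occ_max)
        nb = [j for j in nb if occluders[j] != surface[k]]
        pts = c_surf[k] + r_surf[k] * sphere
        if nb:
            diff = pts[:, None, :] - c_occ[nb][None, :, :]
            inside = (diff ** 2).sum(axis=2) < (r_occ[nb] ** 2)[None, :]
            accessible = ~inside.any(axis=1)
            frac = accessible.mean()
        else:
            frac = 1.0
        out[k] = frac * 4.0 * np.pi * r_surf[k] ** 2
    return out


@dataclass
class SASAProfile:
    """Per-residue SASA: frame series plus the mean profile."""

    residue_ids: list
    residue_names: list
    per_frame: np.ndarray  # (n_frames, n_residues)
    probe_radius: float
    n_points: int

    @property
    def mean(self) -> np.ndarray:
        return self.per_frame.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        if self.per_frame.shape[0] < 2:
            return np.zeros(self.per_frame.shape[1])
        return self.per_frame.std(axis=0, ddof=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(residue_id=self.residue_ids, residue_name=self.residue_names,
                 sasa_mean=self.mean, sasa_sd=self.sd)
        )


def _residue_groups(topology: Topology, surface: np.ndarray):
    """Ordered (residue_id, residue_name, positions-within-surface) groups."""
    order: list = []
    groups: dict = {}
    for pos, i in enumerate(surface):
        i = int(i)
        key = (topology.chain_ids[i], int(topology.residue_ids[i]))
        if key not in groups:
            groups[key] = []
            order.append((key, topology.residue_names[i]))
        groups[key].append(pos)
    return [(key[1], name, np.array(groups[key])) for key, name in order]


def sasa_per_residue(
    topology: Topology,
    frame: Frame,
    surface: Sequence[int],
    occluders: Optional[Sequence[int]] = None,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    radii: Optional[Dict[str, float]] = None,
) -> pd.DataFrame:
    """Single-frame per-residue SASA table."""
    surface = np.asarray(surface, dtype=np.int64)
    atom_sasa = sasa_atoms(topology, frame, surface, occluders,
                           probe_radius, n_points, radii)
    rows = [
        dict(residue_id=rid, residue_name=rname, sasa=atom_sasa[pos].sum())
        for rid, rname, pos in _residue_groups(topology, surface)
    ]
    return pd.DataFrame(rows)


def sasa_trajectory(
    traj: Trajectory,
    surface: Sequence[int],
    occluders: Optional[Sequence[int]] = None,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    radii: Optional[Dict[str, float]] = None,
    stride: int = 1,
) -> SASAProfile:
    """Per-residue SASA over (optionally strided) trajectory frames."""
    surface = np.asarray(surface, dtype=np.int64)
    groups = _residue_groups(traj.topology, surface)
    frames = traj.frames[::stride]
    per_frame = np.empty((len(frames), len(groups)))
    for f, frame in enumerate(frames):
        atom_sasa = sasa_atoms(traj.topology, frame, surface, occluders,
                               probe_radius, n_points, radii)
        for g, (_, _, pos) in enumerate(groups):
            per_frame[f, g] = atom_sasa[pos].sum()
    return SASAProfile(
        residue_ids=[g[0] for g in groups],
        residue_names=[g[1] for g in groups],
        per_frame=per_frame,
        probe_radius=probe_radius,
        n_points=n_points,
    )


def delta_sasa(
    bound: Trajectory,
    unbound: Trajectory,
    surface_bound: Sequence[int],
    surface_unbound: Sequence[int],
    occluders_bound: Optional[Sequence[int]] = None,
    occluders_unbound: Optional[Sequence[int]] = None,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    radii: Optional[Dict[str, float]] = None,
    stride: int = 1,
) -> pd.DataFrame:
    """Per-residue ΔSASA = mean SASA(unbound) − mean SASA(bound).

    Positive values indicate burial upon membrane binding.  The two
    trajectories must expose the same surface residues.
    """
    prof_b = sasa_trajectory(bound, surface_bound, occluders_bound,
                             probe_radius, n_points, radii, stride)
    prof_u = sasa_trajectory(unbound, surface_unbound, occluders_unbound,
                             probe_radius, n_points, radii, stride)
    if prof_b.residue_ids != prof_u.residue_ids:
        raise TopologyMismatchError(
            "bound and unbound surface residue sets differ"
        )
    return pd.DataFrame(
        dict(
            residue_id=prof_b.residue_ids,
            residue_name=prof_b.residue_names,
            sasa_bound=prof_b.mean,
            sasa_unbound=prof_u.mean,
            delta_sasa=prof_u.mean - prof_b.mean,
        )
    )
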