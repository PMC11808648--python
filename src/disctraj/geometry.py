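"""Membrane-plane construction and the signed tilt-angle statistic.

The membrane plane is spanned by three anchor points (alpha carbons of
scaffold residues, e.g. M32/E93/E158 of a nanodisc scaffold ring); its
normal is the normalized cross product of the two in-plane vectors.  The
tilt of a protein axis (alpha-carbon pair) is ``90° − angle(normal, axis)``,
a signed value in [−90°, 90°]: +90° means the axis is parallel to the
normal, 0° means it lies in the membrane plane.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .model import DegenerateGeometryError, Frame, Trajectory

_COLLINEAR_TOL = 1e-6


def membrane_normal(frame: Frame, p1: int, p2: int, p3: int) -> np.ndarray:
    """Unit normal of the plane through three anchor atoms.

    The sign follows the right-hand rule on (p2−p1) × (p3−p1); callers that
    need an absolute orientation disambiguate it separately.
    """
    c = frame.coordinates
    v12 = c[p2] - c[p1]
    v13 = c[p3] - c[p1]
    n = np.cross(v12, v13)
    norm = np.linalg.norm(n)
    if norm < _COLLINEAR_TOL:
        raise DegenerateGeometryError(
            "membrane anchor points are collinear (cross-product norm "
            f"{norm:.2e})"
        )
    return n / norm


def tilt_angle(
    frame: Frame,
    anchors: Sequence[int],
    axis_pair: Sequence[int],
    normal_sign: float = 1.0,
) -> float:
    """Signed tilt (degrees) of the axis (first → second atom) vs the plane."""
    n = membrane_normal(frame, *anchors) * normal_sign
    c = frame.coordinates
    p = c[axis_pair[1]] - c[axis_pair[0]]
    norm = np.linalg.norm(p)
    if norm < _COLLINEAR_TOL:
        raise DegenerateGeometryError("zero-length protein axis vector")
    cosang = np.clip(np.dot(n, p / norm), -1.0, 1.0)
    return 90.0 - np.degrees(np.arccos(cosang))


@dataclass
class TiltSeries:
    """Per-frame tilt angles with summary statistics (sample sd, n−1)."""

    angles: np.ndarray
    anchor_atoms: Tuple[int, int, int]
    axis_pair: Tuple[int, int]

    @property
    def mean(self) -> float:
        return float(np.mean(self.angles))

    @property
    def sd(self) -> float:
        return float(np.std(self.angles, ddof=1)) if self.angles.size > 1 else 0.0

    @property
    def n(self) -> int:
        return int(self.angles.size)

    def summary(self) -> dict:
        return {"mean_deg": self.mean, "sd_deg": self.sd, "n": self.n}


def tilt_series(
    traj: Trajectory,
    anchors: Sequence[int],
    axis_pair: Sequence[int],
    membrane_selection: Optional[Sequence[int]] = None,
    protein_selection: Optional[Sequence[int]] = None,
) -> TiltSeries:
    """Tilt angle of a protein axis over a trajectory.

    The anchor-order ambiguity of the normal's sign is resolved at frame 0
    by requiring a positive component along the membrane-centroid →
    protein-centroid direction, when both selections are given; the
    resulting sign flip is then applied to every frame.
    """
    sign = 1.0
    if membrane_selection is not None and protein_selection is not None:
        f0 = traj.frames[0]
        n0 = membrane_normal(f0, *anchors)
        d = (f0.coordinates[np.asarray(protein_selection)].mean(axis=0)
             - f0.coordinates[np.asarray(membrane_selection)].mean(axis=0))
        if np.dot(n0, d) < 0:
            sign = -1.0
    angles = np.empty(traj.n_frames)
    for k, frame in enumerate(traj.frames):
        try:
            angles[k] = tilt_angle(frame, anchors, axis_pair, normal_sign=sign)
        except DegenerateGeometryError as e:
            raise DegenerateGeometryError(f"frame {k}: {e}") from e
    return TiltSeries(angles=angles, anchor_atoms=tuple(int(a) for a in anchors),
                      axis_pair=(int(axis_pair[0]), int(axis_pair[1])))
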