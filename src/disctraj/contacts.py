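"""Hard-cutoff contact counting and per-residue × moiety occupancy maps.

A contact between two atom groups is formed when any inter-group atom pair
is strictly closer than the cutoff (default 4 Å).  The per-frame count is
the number of such pairs; the occupancy of a (residue, moiety) cell is the
fraction of frames with at least one contact — "percent of the simulation"
in the usual reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from ._neighbors import pairs_within
from .model import ConfigurationError, DiscTrajError, Frame, Topology, Trajectory
from .moieties import (
    HYDROPHILIC_LIPID_CLASSES,
    HYDROPHOBIC_LIPID_CLASSES,
    MoietyAssignment,
)

DEFAULT_CONTACT_CUTOFF = 4.0  # Å, strict "<"

CONTACT_MODES = ("hydrophilic", "hydrophobic", "all")


class InvalidGroupsError(DiscTrajError):
    pass


def count_contacts(
    frame: Frame,
    group_a: Sequence[int],
    group_b: Sequence[int],
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    pbc: bool = True,
) -> int:
    """Number of atom pairs (a, b) with d(a, b) < cutoff (strict).

    Symmetric in the two groups, which must be disjoint.  Minimum-image
    distances are used when the frame has a box and ``pbc`` is True.
    """
    a = np.asarray(group_a, dtype=np.int64)
    b = np.asarray(group_b, dtype=np.int64)
    if np.intersect1d(a, b).size:
        raise InvalidGroupsError("contact groups must be disjoint")
    if a.size == 0 or b.size == 0:
        return 0
    box = frame.box if pbc else None
    i, j, d = pairs_within(frame.coordinates[a], frame.coordinates[b], cutoff, box)
    return int(d.size)


@dataclass
class ContactMatrix:
    """Per-frame contact counts and frame-fraction occupancy.

    ``counts`` has shape (n_frames, n_residues, n_moieties); moiety labels
    are lipid-type split, e.g. ``"phosphate/DOPS"``.  Replicate averages
    carry occupancy only (``counts`` is None).
    """

    residues: List[int]
    residue_names: List[str]
    moieties: List[str]
    occupancy: np.ndarray
    counts: Optional[np.ndarray] = None
    cutoff: float = DEFAULT_CONTACT_CUTOFF
    mode: str = "all"
    n_frames: int = 0

    def occupancy_of(self, residue_id: int, moiety: str) -> float:
        return float(
            self.occupancy[self.residues.index(residue_id), self.moieties.index(moiety)]
        )

    def union_occupancy(self, residue_id: int, moieties: Sequence[str]) -> float:
        """Fraction of frames where the residue contacts ANY listed moiety.

        Needs per-frame counts (not available on replicate averages).
        """
        if self.counts is None:
            raise ConfigurationError("union occupancy requires per-frame counts")
        r = self.residues.index(residue_id)
        cols = [self.moieties.index(m) for m in moieties]
        return float((self.counts[:, r, cols].sum(axis=1) >= 1).mean())

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for ri, (rid, rname) in enumerate(zip(self.residues, self.residue_names)):
            for mi, moi in enumerate(self.moieties):
                cls, _, lip = moi.partition("/")
                rows.append(
                    dict(residue_id=rid, residue_name=rname, moiety=cls,
                         lipid=lip, occupancy=self.occupancy[ri, mi])
                )
        return pd.DataFrame(rows)

    def to_wide(self) -> pd.DataFrame:
        return pd.DataFrame(self.occupancy, index=self.residues,
                            columns=self.moieties)


def _residue_probe_atoms(topology, residue_id, moieties, mode):
    """Residue-side probe atoms for one residue under a contact mode."""
    idx = topology.atoms_of_residue(residue_id)
    keep = []
    for i in idx:
        cls = moieties.protein_class.get(int(i), "none")
        if mode == "hydrophilic" and cls == "hydrophilic_probe":
            keep.append(int(i))
        elif mode == "hydrophobic" and cls == "hydrophobic_probe":
            keep.append(int(i))
        elif mode == "all" and cls != "none":
            keep.append(int(i))
    return np.array(keep, dtype=np.int64)


def _lipid_groups(moieties: MoietyAssignment, mode: str):
    if mode == "hydrophilic":
        classes = HYDROPHILIC_LIPID_CLASSES
    elif mode == "hydrophobic":
        classes = HYDROPHOBIC_LIPID_CLASSES
    else:
        classes = HYDROPHILIC_LIPID_CLASSES + HYDROPHOBIC_LIPID_CLASSES
    groups = []
    resnames = sorted(set(moieties.lipid_resname.values()))
    for cls in classes:
        for rn in resnames:
            idx = moieties.lipid_indices(cls, rn)
            if idx.size:
                groups.append((f"{cls}/{rn}", idx))
    return groups


def contact_timeseries(
    traj: Trajectory,
    residue_ids: Sequence[int],
    moiety_assignment: MoietyAssignment,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    mode: str = "all",
    pbc: bool = True,
) -> ContactMatrix:
    """Per-residue × (moiety class, lipid type) contact counts and occupancy.

    Residue-side atoms follow the mode: N/O atoms (hydrophilic), carbons of
    hydrophobic residues (hydrophobic), or both (all).  Residues without
    probe atoms under the mode simply yield all-zero rows.
    """
    if mode not in CONTACT_MODES:
        raise ConfigurationError(f"unknown contact mode {mode!r}")
    topo = traj.topology
    residue_ids = list(residue_ids)
    probe_atoms = {
        rid: _residue_probe_atoms(topo, rid, moiety_assignment, mode)
        for rid in residue_ids
    }
    groups = _lipid_groups(moiety_assignment, mode)
    moiety_labels = [g[0] for g in groups]

    # Stack all probe atoms once; map each to its residue row.
    all_probe = np.concatenate([v for v in probe_atoms.values() if v.size]) \
        if any(v.size for v in probe_atoms.values()) else np.empty(0, dtype=np.int64)
    probe_row = np.concatenate(
        [np.full(probe_atoms[rid].size, ri, dtype=np.int64)
         for ri, rid in enumerate(residue_ids)]
    ) if all_probe.size else np.empty(0, dtype=np.int64)
    all_lipid = np.concatenate([g[1] for g in groups]) if groups else np.empty(0, dtype=np.int64)
    lipid_col = np.concatenate(
        [np.full(g[1].size, gi, dtype=np.int64) for gi, g in enumerate(groups)]
    ) if groups else np.empty(0, dtype=np.int64)

    counts = np.zeros((traj.n_frames, len(residue_ids), len(groups)), dtype=np.int64)
    if all_probe.size and all_lipid.size:
        for f, frame in enumerate(traj.frames):
            box = frame.box if pbc else None
            i, j, _ = pairs_within(
                frame.coordinates[all_probe], frame.coordinates[all_lipid],
                cutoff, box,
            )
            if i.size:
                np.add.at(counts[f], (probe_row[i], lipid_col[j]), 1)

    occupancy = (counts >= 1).mean(axis=0)
    resid_names = []
    for rid in residue_ids:
        idx = topo.atoms_of_residue(rid)
        resid_names.append(topo.residue_names[idx[0]] if idx.size else "UNK")
    return ContactMatrix(
        residues=residue_ids,
        residue_names=resid_names,
        moieties=moiety_labels,
        occupancy=occupancy,
        counts=counts,
        cutoff=cutoff,
        mode=mode,
        n_frames=traj.n_frames,
    )


def average_replicates(matrices: Sequence[ContactMatrix]) -> ContactMatrix:
    """Arithmetic mean of occupancies across replicates (counts dropped)."""
    if not matrices:
        raise ConfigurationError("no matrices to average")
    first = matrices[0]
    for m in matrices[1:]:
        if m.residues != first.residues or m.moieties != first.moieties:
            raise ConfigurationError("replicate matrices have mismatched axes")
    occ = np.mean([m.occupancy for m in matrices], axis=0)
    return ContactMatrix(
        residues=list(first.residues),
        residue_names=list(first.residue_names),
        moieties=list(first.moieties),
        occupancy=occ,
        counts=None,
        cutoff=first.cutoff,
        mode=first.mode,
        n_frames=sum(m.n_frames for m in matrices),
    )
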