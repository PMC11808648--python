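"""Cutoff nonbonded (Coulomb + Lennard-Jones) protein–lipid energies.

This is a documented short-range surrogate: a plain-truncation pair sum
with Lorentz–Berthelot combining, no long-range or reciprocal-space terms
and no bonded contributions.  Its role is comparative — per-frame energy
series, species decomposition and lowest-energy-frame selection — not the
reproduction of full force-field energies.  Every output records the
cutoff so reports are self-describing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as _io
from ._neighbors import pairs_within
from .contacts import InvalidGroupsError
from .model import (
    ClashError,
    ConfigurationError,
    Frame,
    MissingParameterError,
    Topology,
    Trajectory,
)

#: Coulomb constant, kJ·mol⁻¹·Å·e⁻².
COULOMB_CONSTANT = 1389.35458
DEFAULT_ENERGY_CUTOFF = 12.0  # Å
CLASH_FLOOR = 0.1  # Å; guards the 1/d singularity


def load_params_table(path: str) -> pd.DataFrame:
    """Read a nonbonded parameter TSV:
    residue_name, atom_name, charge_e, sigma_A, epsilon_kJmol."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"residue_name", "atom_name", "charge_e", "sigma_A",
                "epsilon_kJmol"}
    if not required.issubset(df.columns):
        raise ConfigurationError(
            f"parameter table must have columns {sorted(required)}"
        )
    return df


class NonbondedParams:
    """Per-atom charge/σ/ε arrays resolved for one topology.

    Lookup is exact on (residue_name, atom_name); an analyzed atom without
    a row raises :class:`MissingParameterError` naming it.
    """

    def __init__(self, topology: Topology, table: pd.DataFrame,
                 cutoff: float = DEFAULT_ENERGY_CUTOFF):
        if cutoff <= 0:
            raise ConfigurationError("energy cutoff must be positive")
        lookup: Dict[Tuple[str, str], Tuple[float, float, float]] = {}
        for row in table.itertuples(index=False):
            if row.epsilon_kJmol < 0 or row.sigma_A <= 0:
                raise ConfigurationError(
                    f"bad LJ parameters for {row.residue_name}/{row.atom_name}"
                )
            lookup[(row.residue_name, row.atom_name)] = (
                float(row.charge_e), float(row.sigma_A), float(row.epsilon_kJmol)
            )
        n = topology.n_atoms
        self.charge = np.full(n, np.nan)
        self.sigma = np.full(n, np.nan)
        self.epsilon = np.full(n, np.nan)
        self._resolved = np.zeros(n, dtype=bool)
        for i in range(n):
            key = (topology.residue_names[i], topology.names[i])
            if key in lookup:
                self.charge[i], self.sigma[i], self.epsilon[i] = lookup[key]
                self._resolved[i] = True
        self.cutoff = cutoff
        self._topology = topology

    def require(self, indices: np.ndarray) -> None:
        missing = indices[~self._resolved[indices]]
        if missing.size:
            i = int(missing[0])
            t = self._topology
            raise MissingParameterError(
                f"no nonbonded parameters for atom {i} "
                f"({t.residue_names[i]} {int(t.residue_ids[i])} {t.names[i]})"
            )


@dataclass
class EnergyTerms:
    coulomb: float
    lj: float

    @property
    def total(self) -> float:
        return self.coulomb + self.lj


def nonbonded_energy(
    frame: Frame,
    group_a: Sequence[int],
    group_b: Sequence[int],
    params: NonbondedParams,
    pbc: bool = True,
) -> EnergyTerms:
    """Pairwise Coulomb + LJ sum over inter-group pairs with d < cutoff.

    σ_ij is the arithmetic and ε_ij the geometric combination
    (Lorentz–Berthelot); plain truncation, no long-range correction.
    """
    a = np.asarray(group_a, dtype=np.int64)
    b = np.asarray(group_b, dtype=np.int64)
    if np.intersect1d(a, b).size:
        raise InvalidGroupsError("energy groups must be disjoint")
    params.require(a)
    params.require(b)
    if a.size == 0 or b.size == 0:
        return EnergyTerms(0.0, 0.0)
    box = frame.box if pbc else None
    i, j, d = pairs_within(frame.coordinates[a], frame.coordinates[b],
                           params.cutoff, box)
    if d.size == 0:
        return EnergyTerms(0.0, 0.0)
    if np.any(d < CLASH_FLOOR):
        k = int(np.argmin(d))
        raise ClashError(
            f"atoms {int(a[i[k]])} and {int(b[j[k]])} are {d[k]:.3f} Å apart "
            f"(below the {CLASH_FLOOR} Å clash floor)"
        )
    qa, qb = params.charge[a[i]], params.charge[b[j]]
    e_coul = float(np.sum(COULOMB_CONSTANT * qa * qb / d))
    sig = 0.5 * (params.sigma[a[i]] + params.sigma[b[j]])
    eps = np.sqrt(params.epsilon[a[i]] * params.epsilon[b[j]])
    sr6 = (sig / d) ** 6
    e_lj = float(np.sum(4.0 * eps * (sr6 ** 2 - sr6)))
    return EnergyTerms(e_coul, e_lj)


@dataclass
class EnergySeries:
    """Per-frame energies per lipid species plus the combined total.

    ``per_species`` maps species name (e.g. "DOPC") → DataFrame with
    columns frame, e_coulomb, e_lj, e_total.  ``argmin_frame`` is the first
    frame minimizing the combined total (ties → earliest).
    """

    per_species: Dict[str, pd.DataFrame]
    total: pd.DataFrame
    cutoff: float

    @property
    def argmin_frame(self) -> int:
        return int(self.total["e_total"].idxmin())

    @property
    def mean(self) -> float:
        return float(self.total["e_total"].mean())

    @property
    def sd(self) -> float:
        v = self.total["e_total"]
        return float(v.std(ddof=1)) if len(v) > 1 else 0.0


def energy_series(
    traj: Trajectory,
    protein_selection: Sequence[int],
    params: NonbondedParams,
    lipid_species: Optional[Sequence[str]] = None,
    pbc: bool = True,
) -> EnergySeries:
    """Protein–lipid energy per frame, split by lipid residue name."""
    topo = traj.topology
    prot = np.asarray(protein_selection, dtype=np.int64)
    if lipid_species is None:
        lipid_mask = topo.segment_classes == "lipid"
        lipid_species = sorted(set(topo.residue_names[lipid_mask]))
    groups = {
        sp: np.flatnonzero((topo.residue_names == sp)
                           & (topo.segment_classes == "lipid"))
        for sp in lipid_species
    }
    rows = {sp: [] for sp in groups}
    for f, frame in enumerate(traj.frames):
        for sp, idx in groups.items():
            e = nonbonded_energy(frame, prot, idx, params, pbc=pbc)
            rows[sp].append(dict(frame=f, e_coulomb=e.coulomb, e_lj=e.lj,
                                 e_total=e.total))
    per_species = {sp: pd.DataFrame(r) for sp, r in rows.items()}
    total = pd.DataFrame(dict(frame=range(traj.n_frames)))
    for col in ("e_coulomb", "e_lj", "e_total"):
        total[col] = sum(df[col] for df in per_species.values())
    return EnergySeries(per_species=per_species, total=total,
                        cutoff=params.cutoff)


def export_lowest_energy_frame(
    traj: Trajectory,
    series: EnergySeries,
    path: str,
    format: Optional[str] = None,
) -> int:
    """Write the argmin-total-energy frame; returns its index."""
    if len(series.total) != traj.n_frames:
        raise ConfigurationError("energy series length does not match trajectory")
    k = series.argmin_frame
    _io.write_structure(traj.topology, traj.frames[k], path, format=format)
    return k
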