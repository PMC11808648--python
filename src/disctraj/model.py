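"""Core structure/trajectory data model.

Coordinates are Ångström everywhere; residue numbering is carried verbatim
from the input (author numbering, e.g. C1 = 2021–2170, C2 = 2171–2332), so
residue identifiers used in the literature map directly onto selections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

SEGMENT_CLASSES = ("protein", "lipid", "scaffold", "solvent", "ion")

#: Standard amino-acid residue names (three-letter, plus CHARMM histidine
#: tautomer names) recognised as protein.
AMINO_ACIDS = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR
    TRP TYR VAL HSD HSE HSP MSE""".split()
)

LIPID_RESNAMES = frozenset({"DOPC", "DOPS"})
WATER_RESNAMES = frozenset({"TIP3", "TIP3P", "HOH", "WAT", "SOL", "SPC"})
ION_RESNAMES = frozenset({"SOD", "CLA", "POT", "MG", "CAL", "NA", "CL", "K"})

#: Default chain identifiers treated as the nanodisc scaffold ring (the
#: membrane-plane anchor residues M32/E93/E158 live on this chain).
DEFAULT_SCAFFOLD_CHAINS = ("S",)


class DiscTrajError(Exception):
    """Base class for all package errors."""


class ParseError(DiscTrajError):
    """A structure/trajectory file failed to parse.

    Carries the 1-based line number of the offending record.
    """

    def __init__(self, message: str, line_number: Optional[int] = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class EmptyInputError(DiscTrajError):
    pass


class TopologyMismatchError(DiscTrajError):
    pass


class SelectionSyntaxError(DiscTrajError):
    """Selection expression failed to parse; carries character position."""

    def __init__(self, message: str, position: int):
        self.position = position
        super().__init__(f"position {position}: {message}")


class EmptySelectionError(DiscTrajError):
    pass


class ConfigurationError(DiscTrajError):
    pass


class DegenerateGeometryError(DiscTrajError):
    pass


class MissingParameterError(DiscTrajError):
    pass


class FormatOverflowError(DiscTrajError):
    pass


class ClashError(DiscTrajError):
    pass


class UnsupportedLipidError(DiscTrajError):
    pass


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the topology (0-based contiguous ``index``)."""

    index: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain_id: str
    segment_class: str


def guess_element(atom_name: str, residue_name: str = "") -> str:
    """Infer an element symbol from an atom name (CHARMM/PDB dialects)."""
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    two = stripped[:2].upper()
    if two in {"CL", "NA", "MG", "BR", "FE", "ZN", "CA"} and residue_name.upper() in ION_RESNAMES:
        return two.capitalize()
    return stripped[0].upper()


def infer_segment_class(
    residue_name: str,
    chain_id: str,
    scaffold_chains: Sequence[str] = DEFAULT_SCAFFOLD_CHAINS,
) -> str:
    rn = residue_name.upper()
    if rn in LIPID_RESNAMES:
        return "lipid"
    if rn in WATER_RESNAMES:
        return "solvent"
    if rn in ION_RESNAMES:
        return "ion"
    if rn in AMINO_ACIDS:
        if chain_id in scaffold_chains:
            return "scaffold"
        return "protein"
    return "solvent"


class Topology:
    """An ordered collection of :class:`AtomRecord` with array views.

    Parallel numpy arrays (``names``, ``residue_ids`` ...) back the fast
    paths used by selections and the analysis modules.
    """

    def __init__(self, records: Iterable[AtomRecord]):
        records = list(records)
        if not records:
            raise EmptyInputError("topology contains zero atoms")
        for i, rec in enumerate(records):
            if rec.index != i:
                raise TopologyMismatchError(
                    f"atom indices must be contiguous from 0; got {rec.index} at slot {i}"
                )
            if rec.segment_class not in SEGMENT_CLASSES:
                raise ConfigurationError(
                    f"unknown segment_class {rec.segment_class!r} on atom {i}"
                )
        self._records = tuple(records)
        self.names = np.array([r.name for r in records], dtype=object)
        self.elements = np.array([r.element for r in records], dtype=object)
        self.residue_names = np.array([r.residue_name for r in records], dtype=object)
        self.residue_ids = np.array([r.residue_id for r in records], dtype=np.int64)
        self.chain_ids = np.array([r.chain_id for r in records], dtype=object)
        self.segment_classes = np.array([r.segment_class for r in records], dtype=object)

    @property
    def n_atoms(self) -> int:
        return len(self._records)

    def __len__(self) -> int:
        return self.n_atoms

    def __iter__(self):
        return iter(self._records)

    def __getitem__(self, i: int) -> AtomRecord:
        return self._records[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, Topology):
            return NotImplemented
        return self._records == other._records

    def subset(self, indices: Sequence[int]) -> "Topology":
        """New topology of the given atoms, re-indexed contiguously."""
        idx = np.asarray(indices, dtype=np.int64)
        recs = []
        for new_i, old_i in enumerate(idx):
            r = self._records[int(old_i)]
            recs.append(
                AtomRecord(new_i, r.name, r.element, r.residue_name, r.residue_id,
                           r.chain_id, r.segment_class)
            )
        return Topology(recs)

    def residue_key(self) -> np.ndarray:
        """Per-atom residue key ``(chain_id, residue_id)`` as object array."""
        return np.array(
            [(r.chain_id, r.residue_id) for r in self._records], dtype=object
        )

    def atoms_of_residue(self, residue_id: int, chain_id: Optional[str] = None) -> np.ndarray:
        mask = self.residue_ids == residue_id
        if chain_id is not None:
            mask &= self.chain_ids == chain_id
        return np.flatnonzero(mask)

    def alpha_carbon(self, residue_id: int, chain_id: Optional[str] = None) -> int:
        """Atom index of a residue's CA (anchor/axis construction helper)."""
        idx = self.atoms_of_residue(residue_id, chain_id)
        for i in idx:
            if self.names[i] == "CA":
                return int(i)
        raise EmptySelectionError(
            f"no CA atom in residue {residue_id}"
            + (f" chain {chain_id}" if chain_id else "")
        )


@dataclass
class Frame:
    """One coordinate frame (Å). ``box`` is optional orthorhombic lengths."""

    coordinates: np.ndarray
    box: Optional[np.ndarray] = None
    time: Optional[float] = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ConfigurationError("coordinates must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ConfigurationError("non-finite coordinates")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=np.float64).reshape(3)

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]

    def copy(self) -> "Frame":
        return Frame(self.coordinates.copy(),
                     None if self.box is None else self.box.copy(),
                     self.time)


@dataclass
class Trajectory:
    """Ordered frames sharing one topology."""

    topology: Topology
    frames: list = field(default_factory=list)

    def __post_init__(self):
        if not self.frames:
            raise EmptyInputError("trajectory must contain at least one frame")
        n = self.topology.n_atoms
        for k, f in enumerate(self.frames):
            if f.n_atoms != n:
                raise TopologyMismatchError(
                    f"frame {k} has {f.n_atoms} atoms, topology has {n}"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, k):
        if isinstance(k, slice):
            return Trajectory(self.topology, [f for f in self.frames[k]])
        return self.frames[k]

    def coordinates_array(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) stacked coordinates."""
        return np.stack([f.coordinates for f in self.frames])

    def subset(self, indices: Sequence[int]) -> "Trajectory":
        """Restrict to a fixed atom set across all frames.

        Used e.g. to carve an unbound (protein-only) trajectory out of a
        bound protein+nanodisc one for ΔSASA.
        """
        idx = np.asarray(indices, dtype=np.int64)
        topo = self.topology.subset(idx)
        frames = [Frame(f.coordinates[idx], f.box, f.time) for f in self.frames]
        return Trajectory(topo, frames)
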