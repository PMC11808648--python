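"""Classification of lipid atoms into headgroup/tail moiety classes and of
protein atoms into hydrophilic/hydrophobic contact-probe classes.

The seven lipid classes resolve a contact map by chemistry rather than by
whole lipid: acyl-chain carbons, headgroup (choline/serine) carbons, ester
oxygens, the amine nitrogen, the phosphate group (P plus its four bonded
oxygens) and — for phosphatidylserine only — the serine carboxylate.
Hydrogens classify as ``other`` and are excluded from default contact
counting, matching heavy-atom group indexing.

The name→class table is a packaged TSV in the CHARMM36 atom-name dialect
(DOPC/DOPS); pass a custom table for other dialects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fnmatch import fnmatchcase
from importlib import resources
from typing import Dict, List, Optional, Tuple

import numpy as np

from .model import EmptySelectionError, Topology, UnsupportedLipidError

LIPID_MOIETY_CLASSES = (
    "chain_carbon",
    "headgroup_carbon",
    "ester_oxygen",
    "amine_nitrogen",
    "phosphate",
    "carboxylate",
    "other",
)

#: Lipid-side classes probed by hydrophilic (N/O) protein atoms.
HYDROPHILIC_LIPID_CLASSES = ("ester_oxygen", "amine_nitrogen", "phosphate",
                             "carboxylate")
#: Lipid-side classes probed by carbons of hydrophobic residues.
HYDROPHOBIC_LIPID_CLASSES = ("chain_carbon", "headgroup_carbon")

#: Default hydrophobic residue set (configurable; the membrane-inserting
#: β-hairpin residues PHE/MET/LEU all fall in it).
DEFAULT_HYDROPHOBIC_RESIDUES = frozenset(
    {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO"}
)

PROTEIN_PROBE_CLASSES = ("hydrophilic_probe", "hydrophobic_probe", "none")


def load_moiety_table(path: Optional[str] = None) -> List[Tuple[str, str, str]]:
    """Ordered (residue_name, atom_name_glob, class) rows; first match wins."""
    if path is None:
        text = (resources.files("disctraj") / "data" / "moieties_charmm36.tsv").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise UnsupportedLipidError(f"bad moiety-table row: {line!r}")
        resname, glob, cls = (p.strip() for p in parts)
        if cls not in LIPID_MOIETY_CLASSES:
            raise UnsupportedLipidError(f"unknown moiety class {cls!r}")
        rows.append((resname, glob, cls))
    return rows


@dataclass
class MoietyAssignment:
    """Atom-index → class maps for the lipid and protein sides."""

    lipid_class: Dict[int, str] = field(default_factory=dict)
    lipid_resname: Dict[int, str] = field(default_factory=dict)
    protein_class: Dict[int, str] = field(default_factory=dict)

    def lipid_indices(self, moiety: str, resname: Optional[str] = None) -> np.ndarray:
        idx = [
            i for i, c in self.lipid_class.items()
            if c == moiety and (resname is None or self.lipid_resname[i] == resname)
        ]
        return np.array(sorted(idx), dtype=np.int64)

    def protein_indices(self, probe: str) -> np.ndarray:
        return np.array(
            sorted(i for i, c in self.protein_class.items() if c == probe),
            dtype=np.int64,
        )

    def merge(self, other: "MoietyAssignment") -> "MoietyAssignment":
        out = MoietyAssignment(dict(self.lipid_class), dict(self.lipid_resname),
                               dict(self.protein_class))
        out.lipid_class.update(other.lipid_class)
        out.lipid_resname.update(other.lipid_resname)
        out.protein_class.update(other.protein_class)
        return out


def _classify_atom(rows, resname: str, name: str) -> Optional[str]:
    for row_res, glob, cls in rows:
        if row_res == resname and fnmatchcase(name, glob):
            return cls
    return None


def assign_lipid_moieties(
    topology: Topology,
    dialect: str = "charmm36",
    table_path: Optional[str] = None,
) -> MoietyAssignment:
    """Classify every lipid atom by (residue_name, atom_name) table lookup.

    Raises :class:`UnsupportedLipidError` for a lipid residue name absent
    from the table or a heavy atom with no matching row.
    """
    if dialect != "charmm36":
        raise UnsupportedLipidError(f"unsupported lipid dialect {dialect!r}")
    rows = load_moiety_table(table_path)
    known_resnames = {r for r, _, _ in rows}
    out = MoietyAssignment()
    lipid_idx = np.flatnonzero(topology.segment_classes == "lipid")
    for i in lipid_idx:
        i = int(i)
        resname = topology.residue_names[i]
        if resname not in known_resnames:
            raise UnsupportedLipidError(
                f"lipid residue {resname!r} (atom {i}) not in moiety table"
            )
        cls = _classify_atom(rows, resname, topology.names[i])
        if cls is None:
            if topology.elements[i] == "H":
                cls = "other"
            else:
                raise UnsupportedLipidError(
                    f"no moiety class for {resname} atom {topology.names[i]!r}"
                )
        out.lipid_class[i] = cls
        out.lipid_resname[i] = resname
    return out


def assign_protein_classes(
    topology: Topology,
    hydrophobic_residues=DEFAULT_HYDROPHOBIC_RESIDUES,
    include_scaffold: bool = False,
) -> MoietyAssignment:
    """Probe classes: every protein N/O → hydrophilic_probe; every C of a
    hydrophobic residue → hydrophobic_probe; everything else → none."""
    classes = ("protein", "scaffold") if include_scaffold else ("protein",)
    prot_idx = np.flatnonzero(np.isin(topology.segment_classes, classes))
    if prot_idx.size == 0:
        raise EmptySelectionError("no protein atoms in topology")
    out = MoietyAssignment()
    for i in prot_idx:
        i = int(i)
        el = topology.elements[i]
        if el in ("N", "O"):
            out.protein_class[i] = "hydrophilic_probe"
        elif el == "C" and topology.residue_names[i] in hydrophobic_residues:
            out.protein_class[i] = "hydrophobic_probe"
        else:
            out.protein_class[i] = "none"
    return out
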