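"""Seeded generator of a toy nanodisc + two-domain probe protein and a
scripted membrane-binding trajectory with planted ground truth.

The generator is kinematic, not physical: rigid bodies are posed so that
every analysis stage has an exact, known answer.  Defaults emulate the
study conditions the analyses were designed for — an 80:20 DOPC:DOPS
bilayer patch (64 + 16 lipids per leaflet, ~70 Ų per lipid), a CA-only
scaffold ring carrying the three membrane-plane anchor residues (32, 93,
158), and a probe with two discoidin-like mini-domains whose β-hairpin
loops insert hydrophobic side chains, settle at a planted tilt
(N(68°, 8°) / N(69°, 9°)), make per-residue contacts with planted
Bernoulli occupancies, and hold one arginine guanidino nitrogen at a
planted distance (N(2.70 Å, 0.10 Å)) from a DOPS carboxylate oxygen.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import (
    AtomRecord,
    ConfigurationError,
    Frame,
    Topology,
    Trajectory,
    guess_element,
)
from .moieties import assign_lipid_moieties

DEFAULT_AREA_PER_LIPID = 70.0  # Ų; per-leaflet area 5606 Ų / 80 lipids
_HEAD_Z = 23.5  # phosphate plane, half the 47 Å bilayer height
_BASE_HEIGHT = 37.0  # z of the probe's loop alpha carbons when docked
_APPROACH_OFFSET = 20.0
_AWAY_MIN = 6.0  # planted "no contact" clearance, Å

# -------------------------------------------------------------- lipids
# Reduced CHARMM36-named heavy-atom templates (x, y, z offsets in Å for
# the upper leaflet; the lower leaflet mirrors z).  Every applicable
# moiety class has at least one atom.

_DOPC_TEMPLATE = [
    ("N", 0.0, 0.0, 26.0), ("C13", 0.8, 0.8, 26.5), ("C14", -0.8, 0.8, 26.5),
    ("C12", 0.0, -0.9, 25.2), ("C11", 0.0, -1.2, 24.3),
    ("P", 0.0, 0.0, 23.5),
    ("O11", 1.2, 0.6, 23.9), ("O12", -1.2, 0.6, 23.9),
    ("O13", 0.7, -1.0, 22.8), ("O14", -0.7, -1.0, 22.8),
    ("C1", 0.0, 0.8, 21.8), ("C2", 0.6, 0.0, 21.0), ("C3", -0.6, 0.0, 21.0),
    ("O21", 1.5, 0.4, 20.2), ("O31", -1.5, 0.4, 20.2),
    ("C21", 1.5, 0.0, 19.2), ("C31", -1.5, 0.0, 19.2),
    ("C22", 1.5, 0.3, 17.6), ("C32", -1.5, 0.3, 17.6),
    ("C23", 1.5, -0.3, 16.0), ("C33", -1.5, -0.3, 16.0),
    ("C24", 1.5, 0.2, 14.4), ("C34", -1.5, 0.2, 14.4),
]

_DOPS_TEMPLATE = [
    ("N", 0.0, 0.3, 26.2), ("C12", 0.0, -0.6, 25.6),
    ("C13", 0.6, 0.4, 26.9), ("O13A", 1.4, 1.1, 27.3), ("O13B", 0.2, -0.2, 27.9),
    ("C11", 0.0, -1.2, 24.4),
    ("P", 0.0, 0.0, 23.5),
    ("O11", 1.2, 0.6, 23.9), ("O12", -1.2, 0.6, 23.9),
    ("O13", 0.7, -1.0, 22.8), ("O14", -0.7, -1.0, 22.8),
    ("C1", 0.0, 0.8, 21.8), ("C2", 0.6, 0.0, 21.0), ("C3", -0.6, 0.0, 21.0),
    ("O21", 1.5, 0.4, 20.2), ("O31", -1.5, 0.4, 20.2),
    ("C21", 1.5, 0.0, 19.2), ("C31", -1.5, 0.0, 19.2),
    ("C22", 1.5, 0.3, 17.6), ("C32", -1.5, 0.3, 17.6),
    ("C23", 1.5, -0.3, 16.0), ("C33", -1.5, -0.3, 16.0),
    ("C24", 1.5, 0.2, 14.4), ("C34", -1.5, 0.2, 14.4),
]


def build_nanodisc(
    n_dopc_per_leaflet: int = 64,
    n_dops_per_leaflet: int = 16,
    area_per_lipid: float = DEFAULT_AREA_PER_LIPID,
    seed: int = 0,
    n_scaffold: int = 160,
) -> Tuple[Topology, Frame]:
    """Two-leaflet DOPC/DOPS patch on a jittered lattice with a CA-only
    scaffold ring (chain S; anchor residues 32/93/158 are MET/GLU/GLU).

    DOPS sites are placed by a seeded shuffle; both leaflets use the same
    composition.  Lipids are chain L; residue ids run 1..2·n per leaflet
    order (upper then lower).
    """
    if area_per_lipid <= 0:
        raise ConfigurationError("area_per_lipid must be positive")
    n_lip = n_dopc_per_leaflet + n_dops_per_leaflet
    if n_lip <= 0:
        raise ConfigurationError("need at least one lipid per leaflet")
    rng = np.random.default_rng(seed)
    spacing = math.sqrt(area_per_lipid)
    n_side = math.ceil(math.sqrt(n_lip))
    grid = []
    for i in range(n_side + 1):
        for j in range(n_side + 1):
            x = (i - n_side / 2) * spacing
            y = (j - n_side / 2) * spacing
            grid.append((x * x + y * y, x, y))
    grid.sort()
    sites = [(x, y) for _, x, y in grid[:n_lip]]

    records: List[AtomRecord] = []
    coords: List[Tuple[float, float, float]] = []
    atom_i = 0
    resid = 0
    for leaflet_sign in (+1.0, -1.0):
        species = ["DOPC"] * n_dopc_per_leaflet + ["DOPS"] * n_dops_per_leaflet
        rng.shuffle(species)
        jitter = rng.uniform(-0.3, 0.3, size=(n_lip, 2))
        for k, ((sx, sy), resname) in enumerate(zip(sites, species)):
            resid += 1
            template = _DOPC_TEMPLATE if resname == "DOPC" else _DOPS_TEMPLATE
            for name, dx, dy, dz in template:
                records.append(
                    AtomRecord(atom_i, name, guess_element(name, resname),
                               resname, resid, "L", "lipid")
                )
                coords.append((sx + jitter[k, 0] + dx, sy + jitter[k, 1] + dy,
                               leaflet_sign * dz))
                atom_i += 1

    ring_radius = max(math.hypot(x, y) for x, y in sites) + 5.0
    for s in range(1, n_scaffold + 1):
        theta = 2.0 * math.pi * (s - 1) / n_scaffold
        resname = "MET" if s == 32 else ("GLU" if s in (93, 158) else "ALA")
        records.append(
            AtomRecord(atom_i, "CA", "C", resname, s, "S", "scaffold")
        )
        coords.append((ring_radius * math.cos(theta),
                       ring_radius * math.sin(theta), 0.0))
        atom_i += 1

    half_l = ring_radius + 15.0
    box = np.array([2 * half_l, 2 * half_l, 160.0])
    return Topology(records), Frame(np.array(coords), box=box)


# -------------------------------------------------------------- probe

_BACKBONE_OFFSETS = [("N", -0.9, 0.6, 0.8), ("C", 1.0, 0.5, -0.6),
                     ("O", 1.3, 1.55, -0.8)]

_SIDECHAIN_OFFSETS = {
    "CB": (0.4, -0.4, -1.4), "CG": (0.8, -0.8, -2.4), "OG": (0.3, -0.5, -1.5),
    "NZ": (0.5, -0.5, -2.6), "NE2": (0.6, -0.6, -2.2), "ND1": (0.6, -0.6, -2.0),
    "NE": (0.0, 0.0, -1.5), "NH1": (0.45, -0.45, -2.6),
    "NH2": (-0.45, 0.45, -2.6),
}

# (resid, resname, domain, CA position, side-chain atom names).  The C1-like
# domain sits at y = −8, the C2-like at y = +8; both axis vectors (loop CA →
# top CA) are vertical in the template, z 0 → 25.
_PROBE_RESIDUES = [
    (2058, "SER", "C1", (1.5, -8.0, 8.0), ("OG",)),
    (2091, "GLN", "C1", (-1.5, -8.0, 5.0), ("NE2",)),
    (2092, "LYS", "C1", (1.8, -8.0, 3.5), ("NZ",)),
    (2093, "PHE", "C1", (0.0, -8.0, 0.0), ("CB", "CG")),
    (2100, "GLY", "C1", (-2.0, -6.5, 10.0), ()),
    (2110, "GLY", "C1", (2.0, -6.5, 12.5), ()),
    (2120, "GLY", "C1", (-2.0, -9.5, 15.0), ()),
    (2130, "GLY", "C1", (2.0, -9.5, 17.5), ()),
    (2136, "GLY", "C1", (0.0, -6.0, 20.0), ()),
    (2145, "ILE", "C1", (0.0, -8.0, 25.0), ("CB",)),
    (2159, "ARG", "C1", (-2.5, -8.0, 6.5), ("NE", "NH1", "NH2")),
    (2163, "ARG", "C1", (2.5, -8.0, 1.8), ("NE", "NH1", "NH2")),
    (2196, "PHE", "C2", (-2.0, 9.0, 2.0), ("CB", "CG")),
    (2199, "MET", "C2", (-2.0, 7.0, 1.0), ("CB", "CG")),
    (2200, "PHE", "C2", (0.0, 8.0, 0.0), ("CB", "CG")),
    (2215, "ARG", "C2", (2.5, 8.0, 5.0), ("NE", "NH1", "NH2")),
    (2230, "GLY", "C2", (-2.0, 6.5, 10.0), ()),
    (2240, "GLY", "C2", (2.0, 6.5, 13.0), ()),
    (2249, "LYS", "C2", (-2.5, 8.0, 4.0), ("NZ",)),
    (2251, "LEU", "C2", (2.0, 7.0, 1.0), ("CB", "CG")),
    (2252, "LEU", "C2", (2.0, 9.0, 1.0), ("CB", "CG")),
    (2290, "PHE", "C2", (0.0, 6.0, 17.0), ("CB",)),
    (2299, "PRO", "C2", (0.0, 8.0, 25.0), ("CB",)),
    (2315, "HIS", "C2", (-2.5, 8.0, 7.0), ("ND1",)),
    (2316, "GLN", "C2", (2.5, 8.0, 8.0), ("NE2",)),
    (2320, "ARG", "C2", (2.5, 8.0, 2.0), ("NE", "NH1", "NH2")),
]

#: Axis residue pairs (loop CA → top CA) per domain.
AXIS_RESIDUES = {"C1": (2093, 2145), "C2": (2200, 2299)}
ANCHOR_RESIDUES = (32, 93, 158)


def build_probe_protein(seed: int = 0) -> Tuple[Topology, Frame]:
    """Two rigid mini-domains (backbone N/CA/C/O plus minimal side chains).

    Residue numbering lies in the 2021–2332 C-domain range so literature
    selections apply directly; the hydrophobic β-hairpin loop residues,
    the arginines and the lysines carry the side-chain atoms the contact
    analyses probe.  Deterministic for any seed (the template is fixed).
    """
    records: List[AtomRecord] = []
    coords: List[Tuple[float, float, float]] = []
    atom_i = 0
    for resid, resname, _domain, ca, side in _PROBE_RESIDUES:
        ca = np.asarray(ca)
        atoms = [("N",) + tuple(ca + _BACKBONE_OFFSETS[0][1:]),
                 ("CA",) + tuple(ca)]
        atoms.append(("C",) + tuple(ca + _BACKBONE_OFFSETS[1][1:]))
        atoms.append(("O",) + tuple(ca + _BACKBONE_OFFSETS[2][1:]))
        for name in side:
            atoms.append((name,) + tuple(ca + np.asarray(_SIDECHAIN_OFFSETS[name])))
        for name, x, y, z in atoms:
            records.append(
                AtomRecord(atom_i, name, guess_element(name, resname),
                           resname, resid, "P", "protein")
            )
            coords.append((x, y, z))
            atom_i += 1
    return Topology(records), Frame(np.array(coords))


# -------------------------------------------------------------- truth

@dataclass
class ContactSpec:
    """One planted (residue, moiety) contact channel."""

    residue_id: int
    residue_name: str
    atom_name: str
    moiety_class: str
    lipid_resname: str
    channel: str  # hydrophilic | hydrophobic
    occupancy: float
    rdf_well: bool = False

    @property
    def moiety_label(self) -> str:
        return f"{self.moiety_class}/{self.lipid_resname}"


def default_contact_plan() -> List[ContactSpec]:
    """Planted occupancies reflecting the study conditions: β-hairpin
    hydrophobic residues in near-constant chain contact (0.98–0.985),
    the key arginines on the DOPS carboxylate ~50% of the time, other
    polar/basic residues on phosphate >50%."""
    C = ContactSpec
    return [
        C(2093, "PHE", "CG", "chain_carbon", "DOPC", "hydrophobic", 0.985),
        C(2199, "MET", "CG", "chain_carbon", "DOPC", "hydrophobic", 0.98),
        C(2200, "PHE", "CG", "chain_carbon", "DOPS", "hydrophobic", 0.98),
        C(2251, "LEU", "CG", "chain_carbon", "DOPC", "hydrophobic", 0.98),
        C(2252, "LEU", "CG", "chain_carbon", "DOPS", "hydrophobic", 0.98),
        C(2196, "PHE", "CG", "chain_carbon", "DOPC", "hydrophobic", 0.30),
        C(2058, "SER", "OG", "phosphate", "DOPC", "hydrophilic", 0.60),
        C(2091, "GLN", "NE2", "phosphate", "DOPC", "hydrophilic", 0.55),
        C(2092, "LYS", "NZ", "phosphate", "DOPC", "hydrophilic", 0.70),
        C(2159, "ARG", "NH1", "carboxylate", "DOPS", "hydrophilic", 0.50),
        C(2163, "ARG", "NH1", "carboxylate", "DOPS", "hydrophilic", 0.50),
        C(2215, "ARG", "NH1", "phosphate", "DOPS", "hydrophilic", 0.55),
        C(2249, "LYS", "NZ", "phosphate", "DOPC", "hydrophilic", 0.60),
        C(2315, "HIS", "ND1", "phosphate", "DOPC", "hydrophilic", 0.55),
        C(2316, "GLN", "NE2", "phosphate", "DOPC", "hydrophilic", 0.50),
        C(2320, "ARG", "NH1", "carboxylate", "DOPS", "hydrophilic", 0.50,
          rdf_well=True),
    ]


@dataclass
class PlantedTruth:
    """Ground truth serialized alongside every generated dataset."""

    contacts: List[ContactSpec] = field(default_factory=default_contact_plan)
    tilt: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {"C1": (68.0, 8.0), "C2": (69.0, 9.0)}
    )
    axis_residues: Dict[str, Tuple[int, int]] = field(
        default_factory=lambda: dict(AXIS_RESIDUES)
    )
    anchor_residues: Tuple[int, int, int] = ANCHOR_RESIDUES
    rdf_r0: float = 2.70
    rdf_spread: float = 0.10
    rdf_residue: int = 2320
    buried_residues: Tuple[int, ...] = (2093, 2199, 2200, 2251, 2252)
    control_residues: Tuple[int, ...] = (2100, 2110, 2120, 2130, 2230, 2240)
    insertion_frame: int = 0
    settled_start: int = 0
    seed: int = 0

    def __post_init__(self):
        for spec in self.contacts:
            if not 0.0 <= spec.occupancy <= 1.0:
                raise ConfigurationError(
                    f"planted occupancy {spec.occupancy} for residue "
                    f"{spec.residue_id} outside [0, 1]"
                )
        if self.rdf_r0 <= 2.0:
            raise ConfigurationError("rdf_r0 must exceed 2 Å")

    def to_json(self, path: str) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=list)

    @classmethod
    def from_json(cls, path: str) -> "PlantedTruth":
        with open(path) as fh:
            payload = json.load(fh)
        payload["contacts"] = [ContactSpec(**c) for c in payload["contacts"]]
        payload["tilt"] = {k: tuple(v) for k, v in payload["tilt"].items()}
        payload["axis_residues"] = {k: tuple(v) for k, v in
                                    payload["axis_residues"].items()}
        for key in ("anchor_residues", "buried_residues", "control_residues"):
            payload[key] = tuple(payload[key])
        return cls(**payload)


# ------------------------------------------------------- trajectory

def _rot_y(angle_rad: float) -> np.ndarray:
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _merge(nanodisc, probe):
    topo_l, frame_l = nanodisc
    topo_p, frame_p = probe
    records = list(topo_l)
    off = topo_l.n_atoms
    for r in topo_p:
        records.append(AtomRecord(off + r.index, r.name, r.element,
                                  r.residue_name, r.residue_id, r.chain_id,
                                  r.segment_class))
    topo = Topology(records)
    return topo, frame_l, frame_p, off


def generate_binding_trajectory(
    nanodisc: Tuple[Topology, Frame],
    probe: Tuple[Topology, Frame],
    n_frames: int = 1000,
    truth: Optional[PlantedTruth] = None,
    noise_sigma: float = 0.1,
    seed: int = 0,
    time_stride_ps: float = 240.0,
) -> Tuple[Trajectory, PlantedTruth]:
    """Scripted binding: rigid approach, loop insertion of each domain in
    turn, then a settled phase at the planted tilt with per-frame Gaussian
    angular noise, Bernoulli contact placement and the planted
    guanidino–carboxylate distance distribution.  All randomness derives
    from ``seed``; isotropic coordinate jitter is added last.
    """
    if n_frames < 10:
        raise ConfigurationError("n_frames must be at least 10")
    if truth is None:
        truth = PlantedTruth()
    truth = dataclasses.replace(truth, seed=seed)
    rng = np.random.default_rng(seed)

    topo, frame_l, frame_p, off = _merge(nanodisc, probe)
    n_l = frame_l.n_atoms
    lipid_coords = frame_l.coordinates
    box = frame_l.box

    # phase boundaries
    n_app = max(1, int(round(0.15 * n_frames)))
    n_ins = max(1, int(round(0.10 * n_frames)))
    settled_start = n_app + 2 * n_ins
    truth = dataclasses.replace(truth, insertion_frame=settled_start,
                                settled_start=settled_start)

    # probe template placed at docking height, centered over the patch
    base = frame_p.coordinates.copy()
    base[:, 2] += _BASE_HEIGHT
    pivot = np.array([0.0, 0.0, _BASE_HEIGHT])

    ptopo = probe[0]
    domain_of = {}
    for resid, _rn, dom, _ca, _side in _PROBE_RESIDUES:
        domain_of[resid] = dom
    c2_atoms = np.array([i for i in range(ptopo.n_atoms)
                         if domain_of.get(int(ptopo.residue_ids[i])) == "C2"])

    def atom_in_probe(resid: int, name: str) -> int:
        idx = ptopo.atoms_of_residue(resid)
        for i in idx:
            if ptopo.names[i] == name:
                return int(i)
        raise ConfigurationError(f"probe has no atom {name} in residue {resid}")

    # settled reference pose (mean tilt, no noise) for partner selection
    alpha_mean = math.radians(90.0 - truth.tilt["C1"][0])
    ref_pose = (base - pivot) @ _rot_y(alpha_mean).T + pivot

    moieties = assign_lipid_moieties(topo)
    upper = lipid_coords[:, 2] > 0

    # For every planted contact pick a partner lipid atom near the residue
    # and a fixed upward-pointing approach direction that maximizes the
    # clearance of the placed atom from all other lipid atoms, so planted
    # geometries never overlap the rest of the headgroup.  Deterministic:
    # computed once from the static lipid coordinates.
    from .surface import golden_spiral_points
    cand_dirs = golden_spiral_points(400)
    cand_dirs = cand_dirs[cand_dirs[:, 2] > 0.25]

    partners: Dict[int, int] = {}  # spec list position -> lipid atom index
    directions: Dict[int, np.ndarray] = {}
    contact_atom: Dict[int, int] = {}  # -> probe-local atom index
    guanidino: Dict[int, Tuple[int, int]] = {}  # -> (NE, NH2) probe-local
    for s_i, spec in enumerate(truth.contacts):
        cand = moieties.lipid_indices(spec.moiety_class, spec.lipid_resname)
        cand = cand[upper[cand]]
        if cand.size == 0:
            raise ConfigurationError(
                f"no upper-leaflet {spec.moiety_label} atoms for planting"
            )
        ca_local = atom_in_probe(spec.residue_id, "CA")
        d = np.linalg.norm(lipid_coords[cand] - ref_pose[ca_local], axis=1)
        partner = int(cand[int(np.argmin(d))])
        partners[s_i] = partner
        contact_atom[s_i] = atom_in_probe(spec.residue_id, spec.atom_name)
        if spec.residue_name == "ARG":
            guanidino[s_i] = (atom_in_probe(spec.residue_id, "NE"),
                              atom_in_probe(spec.residue_id, "NH2"))

        others = np.delete(np.arange(n_l), partner)
        near = others[np.linalg.norm(lipid_coords[others]
                                     - lipid_coords[partner], axis=1) < 10.0]
        placed = lipid_coords[partner] + 3.25 * cand_dirs  # (n_dir, 3)
        if near.size:
            diff = placed[:, None, :] - lipid_coords[near][None, :, :]
            clearance = np.sqrt((diff ** 2).sum(axis=2)).min(axis=1)
        else:
            clearance = np.full(len(cand_dirs), np.inf)
        if spec.rdf_well:
            # keep every other carboxylate oxygen well outside the planted
            # well so the g(r) maximum stays at r0
            cls = moieties.lipid_indices(spec.moiety_class, spec.lipid_resname)
            oxy = np.array([k for k in cls
                            if k != partner and topo.elements[k] == "O"])
            at_r0 = lipid_coords[partner] + truth.rdf_r0 * cand_dirs
            diff = at_r0[:, None, :] - lipid_coords[oxy][None, :, :]
            d_oxy = np.sqrt((diff ** 2).sum(axis=2)).min(axis=1)
            ok = d_oxy >= truth.rdf_r0 + 0.8
            clearance = np.where(ok, clearance, -np.inf)
        directions[s_i] = cand_dirs[int(np.argmax(clearance))]

    buried_specs = {
        s_i for s_i, spec in enumerate(truth.contacts)
        if spec.residue_id in truth.buried_residues
    }

    sd_extra = math.sqrt(max(truth.tilt["C2"][1] ** 2
                             - truth.tilt["C1"][1] ** 2, 0.0))
    mean_extra = truth.tilt["C2"][0] - truth.tilt["C1"][0]

    frames = []
    for f in range(n_frames):
        coords = np.empty((topo.n_atoms, 3))
        coords[:n_l] = lipid_coords

        if f < n_app:
            frac = 1.0 - f / n_app
            pose = base + np.array([0.0, 0.0, _APPROACH_OFFSET * frac])
        else:
            pose = base.copy()

        settled = f >= settled_start
        if settled:
            theta1 = rng.normal(truth.tilt["C1"][0], truth.tilt["C1"][1])
            alpha = math.radians(90.0 - theta1)
            pose = (pose - pivot) @ _rot_y(alpha).T + pivot
            # independent wobble of the second domain about its loop pivot
            delta = rng.normal(mean_extra, sd_extra) if sd_extra > 0 else mean_extra
            pivot2 = pose[atom_in_probe(AXIS_RESIDUES["C2"][0], "CA")]
            rot2 = _rot_y(math.radians(-delta))
            pose[c2_atoms] = (pose[c2_atoms] - pivot2) @ rot2.T + pivot2

        coords[n_l:] = pose

        # planted contacts (settled) and insertion ramps
        if settled:
            for s_i, spec in enumerate(truth.contacts):
                target = lipid_coords[partners[s_i]]
                direction = directions[s_i]
                a = off + contact_atom[s_i]
                if rng.random() < spec.occupancy:
                    if spec.rdf_well:
                        dist = max(rng.normal(truth.rdf_r0, truth.rdf_spread), 2.2)
                    else:
                        dist = rng.uniform(3.0, 3.45)
                    coords[a] = target + direction * dist
                    if s_i in guanidino:
                        # trailing guanidino nitrogens ride the same ray with
                        # randomized extensions so only the planted atom
                        # contributes a sharp g(r) peak
                        ne, nh2 = guanidino[s_i]
                        perp = np.cross(direction, [0.0, 0.0, 1.0])
                        pn = np.linalg.norm(perp)
                        perp = perp / pn if pn > 1e-9 else np.array([1.0, 0, 0])
                        u1 = rng.uniform(0.9, 2.4)
                        u2 = rng.uniform(0.8, 2.2)
                        coords[off + ne] = target + direction * (dist + u1) + perp * 0.4
                        coords[off + nh2] = target + direction * (dist + u2) - perp * 0.7
                # else: side chain stays retracted at its template position,
                # ≥ _AWAY_MIN Å above every lipid atom by construction
        elif f >= n_app:
            # ramp the buried loops in along their cleared rays, first
            # domain first
            phase2 = f >= n_app + n_ins
            frac = ((f - n_app - n_ins) / n_ins) if phase2 else ((f - n_app) / n_ins)
            for s_i in sorted(buried_specs):
                spec = truth.contacts[s_i]
                dom = domain_of[spec.residue_id]
                if dom == "C1" and not phase2:
                    ramp = frac
                elif dom == "C1":
                    ramp = 1.0
                elif dom == "C2" and phase2:
                    ramp = frac
                else:
                    continue
                target = lipid_coords[partners[s_i]]
                a = off + contact_atom[s_i]
                dist = 12.0 + ramp * (3.2 - 12.0)
                coords[a] = target + directions[s_i] * dist

        if noise_sigma > 0:
            coords = coords + rng.normal(0.0, noise_sigma, size=coords.shape)

        frames.append(Frame(coords, box=None if box is None else box.copy(),
                            time=f * time_stride_ps))

    return Trajectory(topo, frames), truth


def write_params_table(topology: Topology, path: str) -> None:
    """Emit a nonbonded parameter TSV covering every (residue, atom) pair.

    Element-based charges/σ/ε with special rows for the DOPS carboxylate
    oxygens and the arginine guanidino nitrogens, so that the planted
    salt-bridge contacts are strongly attractive.
    """
    by_element = {
        "C": (0.0, 2.8, 0.35), "N": (0.35, 2.9, 0.50), "O": (-0.40, 2.8, 0.50),
        "P": (0.80, 3.4, 0.60), "S": (0.0, 3.2, 0.50), "H": (0.10, 1.0, 0.05),
    }
    special = {
        ("DOPS", "O13A"): (-0.55, 2.8, 0.50),
        ("DOPS", "O13B"): (-0.55, 2.8, 0.50),
        ("ARG", "NH1"): (0.45, 2.9, 0.50),
        ("ARG", "NH2"): (0.45, 2.9, 0.50),
        ("ARG", "NE"): (0.45, 2.9, 0.50),
    }
    seen = set()
    rows = []
    for i in range(topology.n_atoms):
        key = (topology.residue_names[i], topology.names[i])
        if key in seen:
            continue
        seen.add(key)
        if key in special:
            q, sig, eps = special[key]
        else:
            el = topology.elements[i]
            if el not in by_element:
                raise ConfigurationError(f"no default parameters for element {el}")
            q, sig, eps = by_element[el]
        rows.append(dict(residue_name=key[0], atom_name=key[1], charge_e=q,
                         sigma_A=sig, epsilon_kJmol=eps))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def paper_like_dataset(
    seed: int = 0,
    n_frames: int = 1000,
    replicates: int = 2,
    noise_sigma: float = 0.1,
):
    """Default study-condition dataset: the 64+16 lipid nanodisc, the
    two-domain probe, and replicate scripted binding trajectories.

    Returns ``(trajectories, truths)`` lists of length ``replicates``
    (replicate k uses seed ``seed + k``).
    """
    nanodisc = build_nanodisc(seed=seed)
    probe = build_probe_protein(seed=seed)
    trajs, truths = [], []
    for k in range(replicates):
        traj, truth = generate_binding_trajectory(
            nanodisc, probe, n_frames=n_frames, noise_sigma=noise_sigma,
            seed=seed + k,
        )
        trajs.append(traj)
        truths.append(truth)
    return trajs, truths
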