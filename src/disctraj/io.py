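"""Readers and writers for PDB (multi-model), GRO and XYZ files.

Multi-model PDB (fixed-column v3.3, MODEL/ENDMDL frame delimiters) is the
trajectory lingua franca so that fixtures stay text-diffable.  GRO files are
converted nm↔Å on read/write; GRO carries no chain identifier, so chain_id
is empty there and scaffold classification must rely on configuration.
"""

from __future__ import annotations

import os
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .model import (
    AtomRecord,
    EmptyInputError,
    FormatOverflowError,
    Frame,
    ParseError,
    Topology,
    TopologyMismatchError,
    Trajectory,
    DEFAULT_SCAFFOLD_CHAINS,
    guess_element,
    infer_segment_class,
)

_FORMATS = ("pdb", "gro", "xyz")


def _infer_format(path: str, format: Optional[str]) -> str:
    if format is not None:
        fmt = format.lower()
    else:
        fmt = os.path.splitext(path)[1].lstrip(".").lower()
    if fmt not in _FORMATS:
        raise ParseError(f"unknown structure format {fmt!r} for {path}")
    return fmt


# ---------------------------------------------------------------- PDB

def _parse_pdb(path: str, scaffold_chains) -> Tuple[Topology, List[Frame]]:
    records: List[AtomRecord] = []
    frames: List[Frame] = []
    coords: List[Tuple[float, float, float]] = []
    box = None
    first_model_done = False
    atom_i = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "CRYST1":
                try:
                    box = np.array([float(line[6:15]), float(line[15:24]),
                                    float(line[24:33])])
                except ValueError as e:
                    raise ParseError(f"bad CRYST1 record: {e}", ln)
            elif rec in ("ATOM  ", "HETATM"):
                if len(line.rstrip("\n")) < 54:
                    raise ParseError("truncated ATOM/HETATM record", ln)
                try:
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                    resid = int(line[22:26])
                except ValueError as e:
                    raise ParseError(f"malformed ATOM/HETATM fields: {e}", ln)
                coords.append((x, y, z))
                if not first_model_done:
                    name = line[12:16].strip()
                    resname = line[17:21].strip()
                    chain = line[21].strip()
                    element = line[76:78].strip() if len(line) >= 78 else ""
                    if not element:
                        element = guess_element(name, resname)
                    records.append(
                        AtomRecord(
                            index=atom_i,
                            name=name,
                            element=element,
                            residue_name=resname,
                            residue_id=resid,
                            chain_id=chain,
                            segment_class=infer_segment_class(resname, chain,
                                                              scaffold_chains),
                        )
                    )
                    atom_i += 1
            elif rec.startswith("ENDMDL") or rec.startswith("END   ") or line.strip() == "END":
                if coords:
                    frames.append(Frame(np.array(coords), box=box))
                    coords = []
                    first_model_done = True
    if coords:
        frames.append(Frame(np.array(coords), box=box))
    if not records:
        raise EmptyInputError(f"{path}: no atoms found")
    n = len(records)
    for k, f in enumerate(frames):
        if f.n_atoms != n:
            raise TopologyMismatchError(
                f"{path}: model {k + 1} has {f.n_atoms} atoms, expected {n}"
            )
    return Topology(records), frames


def _format_pdb_atom(i: int, rec: AtomRecord, xyz: np.ndarray) -> str:
    if np.any(np.abs(xyz) > 9999.999):
        raise FormatOverflowError(
            f"coordinate {xyz} of atom {rec.name} exceeds PDB fixed columns"
        )
    name = rec.name
    # PDB convention: 1–3 char names start in column 14
    name_field = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    resname = f"{rec.residue_name:<4s}"[:4]
    return (
        f"ATOM  {min(i + 1, 99999):5d} {name_field} "[:17].ljust(17)
        + f"{resname}"
        + f"{(rec.chain_id or ' ')[:1]}"
        + f"{rec.residue_id:4d}    "
        + f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        + "  1.00  0.00          "
        + f"{rec.element:>2s}"
    )


def _write_pdb(topology: Topology, frames: Sequence[Frame], path: str) -> None:
    multi = len(frames) > 1
    with open(path, "w") as fh:
        box = frames[0].box
        if box is not None:
            fh.write(
                f"CRYST1{box[0]:9.3f}{box[1]:9.3f}{box[2]:9.3f}"
                "  90.00  90.00  90.00 P 1           1\n"
            )
        for m, frame in enumerate(frames, start=1):
            if multi:
                fh.write(f"MODEL     {m:4d}\n")
            for i, rec in enumerate(topology):
                fh.write(_format_pdb_atom(i, rec, frame.coordinates[i]) + "\n")
            fh.write("ENDMDL\n" if multi else "END\n")
        if multi:
            fh.write("END\n")


# ---------------------------------------------------------------- GRO

def _parse_gro(path: str, scaffold_chains) -> Tuple[Topology, List[Frame]]:
    records: List[AtomRecord] = []
    frames: List[Frame] = []
    with open(path) as fh:
        lines = fh.readlines()
    pos = 0
    first = True
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        if pos + 1 >= len(lines):
            raise ParseError("unexpected end of GRO file", pos + 1)
        try:
            natoms = int(lines[pos + 1])
        except ValueError:
            raise ParseError("expected atom count", pos + 2)
        if natoms == 0:
            raise EmptyInputError(f"{path}: zero atoms")
        if pos + 2 + natoms >= len(lines) + 1 and pos + 2 + natoms > len(lines):
            raise ParseError("truncated GRO frame", len(lines))
        coords = np.empty((natoms, 3))
        for a in range(natoms):
            ln = pos + 2 + a
            line = lines[ln]
            if len(line.rstrip("\n")) < 44:
                raise ParseError("truncated GRO atom record", ln + 1)
            try:
                coords[a] = (
                    float(line[20:28]) * 10.0,
                    float(line[28:36]) * 10.0,
                    float(line[36:44]) * 10.0,
                )
            except ValueError as e:
                raise ParseError(f"malformed GRO coordinates: {e}", ln + 1)
            if first:
                resid = int(line[0:5])
                resname = line[5:10].strip()
                name = line[10:15].strip()
                records.append(
                    AtomRecord(
                        index=a,
                        name=name,
                        element=guess_element(name, resname),
                        residue_name=resname,
                        residue_id=resid,
                        chain_id="",
                        segment_class=infer_segment_class(resname, "",
                                                          scaffold_chains),
                    )
                )
        box_line = pos + 2 + natoms
        box = None
        if box_line < len(lines):
            parts = lines[box_line].split()
            if len(parts) >= 3:
                box = np.array([float(v) * 10.0 for v in parts[:3]])
                if np.all(box == 0):
                    box = None
        frames.append(Frame(coords, box=box))
        first = False
        pos = box_line + 1
    if not records:
        raise EmptyInputError(f"{path}: no atoms found")
    n = len(records)
    for k, f in enumerate(frames):
        if f.n_atoms != n:
            raise TopologyMismatchError(
                f"{path}: frame {k} has {f.n_atoms} atoms, expected {n}"
            )
    return Topology(records), frames


def _write_gro(topology: Topology, frames: Sequence[Frame], path: str) -> None:
    with open(path, "w") as fh:
        for frame in frames:
            t = 0.0 if frame.time is None else frame.time
            fh.write(f"generated by disctraj, t= {t:.3f} ps\n")
            fh.write(f"{topology.n_atoms:5d}\n")
            for i, rec in enumerate(topology):
                x, y, z = frame.coordinates[i] / 10.0  # Å → nm
                if np.any(np.abs(frame.coordinates[i] / 10.0) > 9999.999):
                    raise FormatOverflowError("coordinate exceeds GRO columns")
                fh.write(
                    f"{rec.residue_id % 100000:5d}{rec.residue_name:<5s}"
                    f"{rec.name:>5s}{(i + 1) % 100000:5d}"
                    f"{x:8.3f}{y:8.3f}{z:8.3f}\n"
                )
            if frame.box is not None:
                b = frame.box / 10.0
                fh.write(f"{b[0]:10.5f}{b[1]:10.5f}{b[2]:10.5f}\n")
            else:
                fh.write(f"{0.0:10.5f}{0.0:10.5f}{0.0:10.5f}\n")


# ---------------------------------------------------------------- XYZ

def _parse_xyz(path: str, scaffold_chains) -> Tuple[Topology, List[Frame]]:
    records: List[AtomRecord] = []
    frames: List[Frame] = []
    with open(path) as fh:
        lines = fh.readlines()
    pos = 0
    first = True
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            natoms = int(lines[pos].split()[0])
        except (ValueError, IndexError):
            raise ParseError("expected atom count", pos + 1)
        if natoms == 0:
            raise EmptyInputError(f"{path}: zero atoms")
        coords = np.empty((natoms, 3))
        for a in range(natoms):
            ln = pos + 2 + a
            if ln >= len(lines):
                raise ParseError("truncated XYZ frame", len(lines))
            parts = lines[ln].split()
            if len(parts) < 4:
                raise ParseError("truncated XYZ atom record", ln + 1)
            try:
                coords[a] = [float(v) for v in parts[1:4]]
            except ValueError as e:
                raise ParseError(f"malformed XYZ coordinates: {e}", ln + 1)
            if first:
                sym = parts[0]
                records.append(
                    AtomRecord(a, sym, sym.capitalize(), "UNK", 1, "",
                               "solvent")
                )
        frames.append(Frame(coords))
        first = False
        pos = pos + 2 + natoms
    if not records:
        raise EmptyInputError(f"{path}: no atoms found")
    return Topology(records), frames


# ---------------------------------------------------------------- API

def read_structure(
    path: str,
    format: Optional[str] = None,
    scaffold_chains: Sequence[str] = DEFAULT_SCAFFOLD_CHAINS,
) -> Tuple[Topology, Frame]:
    """Read a structure file; multi-model input returns the first model."""
    fmt = _infer_format(path, format)
    topo, frames = _PARSERS[fmt](path, scaffold_chains)
    return topo, frames[0]


def read_trajectory(
    paths,
    format: Optional[str] = None,
    scaffold_chains: Sequence[str] = DEFAULT_SCAFFOLD_CHAINS,
) -> Trajectory:
    """Read one or more files sharing a topology; frames concatenate in path order."""
    if isinstance(paths, (str, os.PathLike)):
        paths = [paths]
    topology = None
    all_frames: List[Frame] = []
    for p in paths:
        fmt = _infer_format(str(p), format)
        topo, frames = _PARSERS[fmt](str(p), scaffold_chains)
        if topology is None:
            topology = topo
        elif topo.n_atoms != topology.n_atoms:
            raise TopologyMismatchError(
                f"{p}: {topo.n_atoms} atoms, expected {topology.n_atoms}"
            )
        all_frames.extend(frames)
    return Trajectory(topology, all_frames)


def write_structure(topology: Topology, frame: Frame, path: str,
                    format: Optional[str] = None) -> None:
    fmt = _infer_format(path, format)
    if fmt == "xyz":
        with open(path, "w") as fh:
            fh.write(f"{topology.n_atoms}\nwritten by disctraj\n")
            for i, rec in enumerate(topology):
                x, y, z = frame.coordinates[i]
                fh.write(f"{rec.element:<3s} {x:12.5f} {y:12.5f} {z:12.5f}\n")
        return
    _WRITERS[fmt](topology, [frame], path)


def write_trajectory(trajectory: Trajectory, path: str,
                     format: Optional[str] = None) -> None:
    fmt = _infer_format(path, format)
    if fmt == "xyz":
        with open(path, "w") as fh:
            for frame in trajectory.frames:
                fh.write(f"{trajectory.topology.n_atoms}\nframe\n")
                for i, rec in enumerate(trajectory.topology):
                    x, y, z = frame.coordinates[i]
                    fh.write(f"{rec.element:<3s} {x:12.5f} {y:12.5f} {z:12.5f}\n")
        return
    _WRITERS[fmt](trajectory.topology, trajectory.frames, path)


_PARSERS = {"pdb": _parse_pdb, "gro": _parse_gro, "xyz": _parse_xyz}
_WRITERS = {"pdb": _write_pdb, "gro": _write_gro}
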