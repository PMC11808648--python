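"""Configuration-driven orchestration of the full analysis battery.

One declarative config (YAML/JSON or a :class:`RunConfig`) drives, per
replicate trajectory and averaged: contact occupancy matrices
(hydrophilic/hydrophobic/all), tilt series per domain, SASA/ΔSASA,
RMSF/RMSD, RDF→PMF with the minimum, and the energy series with the
lowest-energy frame exported.  Every default left open by convention
(probe radius, bins, backbone atoms, cutoffs) is echoed into the manifest
so outputs are self-describing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .contacts import average_replicates, contact_timeseries
from .energetics import (NonbondedParams, energy_series,
                         export_lowest_energy_frame, load_params_table)
from .geometry import tilt_series
from .io import read_trajectory
from .metrics import rmsd_series, rmsf_per_residue
from .model import ConfigurationError, Trajectory
from .moieties import assign_lipid_moieties, assign_protein_classes
from .rdf import pmf_from_rdf, rdf
from .selection import select

logger = logging.getLogger("disctraj")


@dataclass
class RunConfig:
    trajectories: List[str]
    output_dir: str
    protein_selection: str = "protein"
    domains: Dict[str, str] = field(default_factory=dict)  # name -> selection
    anchor_residues: Tuple[int, int, int] = (32, 93, 158)
    anchor_chain: str = "S"
    axes: Dict[str, Tuple[Tuple[int, str], Tuple[int, str]]] = field(default_factory=dict)
    contact_cutoff: float = 4.0
    contact_modes: Tuple[str, ...] = ("hydrophilic", "hydrophobic", "all")
    sasa_probe_radius: float = 1.4
    sasa_n_points: int = 960
    sasa_stride: int = 20
    rdf_reference: Optional[str] = None
    rdf_target: str = "resname DOPS and name O13A O13B"
    rdf_r_max: float = 15.0
    rdf_bin_width: float = 0.05
    rdf_normalization: str = "tail_unit"
    temperature: float = 310.0
    energy_params: Optional[str] = None
    energy_cutoff: float = 12.0
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if not self.trajectories:
            raise ConfigurationError("no trajectories configured")
        if self.contact_cutoff <= 0:
            raise ConfigurationError("contact cutoff must be positive")
        if self.energy_cutoff <= 0:
            raise ConfigurationError("energy cutoff must be positive")
        if self.temperature <= 0:
            raise ConfigurationError("temperature must be positive")
        if self.sasa_n_points < 32:
            raise ConfigurationError("sasa_n_points must be at least 32")
        if len(self.anchor_residues) != 3:
            raise ConfigurationError("exactly three anchor residues required")

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**payload)
        if cfg.axes:
            cfg.axes = {k: tuple((int(r), str(a)) for r, a in v)
                        for k, v in cfg.axes.items()}
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _atom_by_name(topology, residue_id: int, name: str, chain=None) -> int:
    idx = topology.atoms_of_residue(residue_id, chain)
    for i in idx:
        if topology.names[i] == name:
            return int(i)
    raise ConfigurationError(f"no atom {name} in residue {residue_id}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every analysis stage; returns the manifest dictionary."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "stages": {},
    }

    trajs: List[Trajectory] = []
    for path in config.trajectories:
        trajs.append(read_trajectory(path))
    n_reps = len(trajs)
    topo = trajs[0].topology

    def stage(name):
        def deco(fn):
            t0 = time.time()
            try:
                fn()
            except Exception as e:
                raise ConfigurationError(f"stage {name!r} failed: {e}") from e
            dt = time.time() - t0
            manifest["stages"][name] = {"wall_time_s": round(dt, 3)}
            logger.info("stage %s done in %.2fs", name, dt)
        return deco

    prot_idx = select(topo, config.protein_selection)
    domains = config.domains or {"protein": config.protein_selection}
    moi = assign_lipid_moieties(topo).merge(assign_protein_classes(topo))

    # ---- contacts
    @stage("contacts")
    def _contacts():
        resids = sorted(set(int(r) for r in topo.residue_ids[prot_idx]))
        for mode in config.contact_modes:
            mats = [contact_timeseries(t, resids, moi, config.contact_cutoff,
                                       mode=mode) for t in trajs]
            for k, m in enumerate(mats):
                m.to_tidy().to_csv(
                    os.path.join(out, f"contacts_{mode}_rep{k}.csv"), index=False)
            avg = average_replicates(mats) if n_reps > 1 else mats[0]
            avg.to_tidy().to_csv(
                os.path.join(out, f"contacts_{mode}_avg.csv"), index=False)
            avg.to_wide().to_csv(
                os.path.join(out, f"contacts_{mode}_avg_wide.csv"))

    # ---- tilt
    @stage("tilt")
    def _tilt():
        anchors = [topo.alpha_carbon(r, config.anchor_chain)
                   for r in config.anchor_residues]
        lipid_idx = np.flatnonzero(topo.segment_classes == "lipid")
        summaries = {}
        for dom, ((r1, a1), (r2, a2)) in (config.axes or {}).items():
            axis = (_atom_by_name(topo, r1, a1), _atom_by_name(topo, r2, a2))
            per_rep = []
            for k, t in enumerate(trajs):
                ts = tilt_series(t, anchors, axis,
                                 membrane_selection=lipid_idx,
                                 protein_selection=prot_idx)
                times = [f.time if f.time is not None else i
                         for i, f in enumerate(t.frames)]
                pd.DataFrame(dict(frame=range(t.n_frames), time_ps=times,
                                  angle_deg=ts.angles)).to_csv(
                    os.path.join(out, f"tilt_{dom}_rep{k}.csv"), index=False)
                per_rep.append(ts.summary())
            summaries[dom] = {
                "replicates": per_rep,
                "mean_deg": float(np.mean([s["mean_deg"] for s in per_rep])),
                "sd_deg": float(np.mean([s["sd_deg"] for s in per_rep])),
            }
        with open(os.path.join(out, "tilt_summary.json"), "w") as fh:
            json.dump(summaries, fh, indent=2)

    # ---- SASA / ΔSASA
    @stage("sasa")
    def _sasa():
        from .surface import delta_sasa, sasa_trajectory
        lipid_idx = np.flatnonzero(topo.segment_classes == "lipid")
        occl_bound = np.concatenate([prot_idx, lipid_idx])
        tables = []
        for k, t in enumerate(trajs):
            unbound = t.subset(prot_idx)
            table = delta_sasa(
                t, unbound,
                surface_bound=prot_idx,
                surface_unbound=np.arange(unbound.topology.n_atoms),
                occluders_bound=occl_bound,
                occluders_unbound=None,
                probe_radius=config.sasa_probe_radius,
                n_points=config.sasa_n_points,
                stride=config.sasa_stride,
            )
            table.to_csv(os.path.join(out, f"delta_sasa_rep{k}.csv"), index=False)
            tables.append(table.set_index("residue_id"))
        if n_reps > 1:
            avg = tables[0].copy()
            for col in ("sasa_bound", "sasa_unbound", "delta_sasa"):
                avg[col] = np.mean([tb[col] for tb in tables], axis=0)
            avg.reset_index().to_csv(os.path.join(out, "delta_sasa_avg.csv"),
                                     index=False)

    # ---- RMSF / RMSD
    @stage("structure_metrics")
    def _metrics():
        for dom, expr in domains.items():
            sel = select(topo, f"({expr}) and backbone")
            if sel.size == 0:
                continue
            for k, t in enumerate(trajs):
                rmsf = rmsf_per_residue(t, sel, fit=True)
                rmsf.to_csv(os.path.join(out, f"rmsf_{dom}_rep{k}.csv"),
                            index=False)
                rs = rmsd_series(t, 0, sel, fit=True)
                pd.DataFrame(dict(frame=range(t.n_frames),
                                  rmsd=rs.values)).to_csv(
                    os.path.join(out, f"rmsd_{dom}_rep{k}.csv"), index=False)
                with open(os.path.join(out, f"rmsd_{dom}_rep{k}.json"), "w") as fh:
                    json.dump({"mean": rs.mean, "sd": rs.sd, "n": t.n_frames}, fh)

    # ---- RDF / PMF
    @stage("rdf_pmf")
    def _rdf():
        if config.rdf_reference is None:
            return
        ref = select(topo, config.rdf_reference)
        tgt = select(topo, config.rdf_target)
        results = {}
        for k, t in enumerate(trajs):
            prof = rdf(t, ref, tgt, r_max=config.rdf_r_max,
                       bin_width=config.rdf_bin_width,
                       normalization=config.rdf_normalization)
            pmf = pmf_from_rdf(prof, temperature=config.temperature)
            df = prof.to_frame()
            df["pmf_kJmol"] = pmf.pmf
            df.to_csv(os.path.join(out, f"rdf_pmf_rep{k}.csv"), index=False)
            results[f"rep{k}"] = {
                "minimum_depth_kJmol": pmf.minimum[0],
                "minimum_location_A": pmf.minimum[1],
                "normalization": prof.normalization,
                "temperature_K": config.temperature,
                "note": "depth is an effective/qualitative estimate; it "
                        "depends on the normalization mode",
            }
        with open(os.path.join(out, "pmf_summary.json"), "w") as fh:
            json.dump(results, fh, indent=2)

    # ---- energetics
    @stage("energetics")
    def _energy():
        if config.energy_params is None:
            return
        table = load_params_table(config.energy_params)
        params = NonbondedParams(topo, table, cutoff=config.energy_cutoff)
        for k, t in enumerate(trajs):
            series = energy_series(t, prot_idx, params)
            series.total.to_csv(os.path.join(out, f"energy_rep{k}.csv"),
                                index=False)
            for sp, df in series.per_species.items():
                df.to_csv(os.path.join(out, f"energy_{sp}_rep{k}.csv"),
                          index=False)
            argmin = export_lowest_energy_frame(
                t, series, os.path.join(out, f"lowest_energy_rep{k}.pdb"))
            with open(os.path.join(out, f"energy_rep{k}.json"), "w") as fh:
                json.dump({"mean": series.mean, "sd": series.sd,
                           "argmin_frame": argmin,
                           "cutoff_A": config.energy_cutoff,
                           "model": "cutoff Coulomb+LJ surrogate (no PME, "
                                    "no bonded terms)"}, fh)

    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def render_report(output_dir: str) -> str:
    """Assemble a human-readable markdown summary from a pipeline output
    directory; missing tables are listed as absent, non-fatally."""
    sections = []
    sections.append("# disctraj analysis report\n")
    manifest_path = os.path.join(output_dir, "manifest.json")
    if os.path.exists(manifest_path):
        with open(manifest_path) as fh:
            manifest = json.load(fh)
        sections.append(f"config hash: `{manifest.get('config_hash', '?')}`\n")
    else:
        sections.append("*warning: no manifest found*\n")

    def add_csv(title, name, n=12):
        path = os.path.join(output_dir, name)
        if not os.path.exists(path):
            sections.append(f"## {title}\n\n*absent: {name}*\n")
            return
        df = pd.read_csv(path)
        sections.append(f"## {title}\n\n{df.head(n).to_string(index=False)}\n")

    add_csv("Contact occupancy (hydrophilic, averaged)", "contacts_hydrophilic_avg.csv")
    add_csv("Contact occupancy (hydrophobic, averaged)", "contacts_hydrophobic_avg.csv")
    add_csv("ΔSASA per residue", "delta_sasa_rep0.csv")
    add_csv("Backbone RMSF", "rmsf_protein_rep0.csv")

    for name in ("tilt_summary.json", "pmf_summary.json"):
        path = os.path.join(output_dir, name)
        if os.path.exists(path):
            with open(path) as fh:
                sections.append(f"## {name}\n\n```json\n"
                                f"{json.dumps(json.load(fh), indent=2)}\n```\n")
        else:
            sections.append(f"## {name}\n\n*absent*\n")

    report = "\n".join(sections)
    with open(os.path.join(output_dir, "report.md"), "w") as fh:
        fh.write(report)
    return report
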