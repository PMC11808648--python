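# disctraj

Analysis of how a peripheral membrane-binding protein engages a lipid
nanodisc in molecular-dynamics trajectories.  The package was built around
the blood-coagulation FVIII problem — its discoidin-like C1/C2 domains
(residues 2021–2170 and 2171–2332) docking onto an 80:20 DOPC:DOPS
nanodisc — but every analysis takes generic structures, selections and
parameters.

For structural biologists and simulators who need, from a trajectory:

- **Moiety-resolved contact maps** — per-residue occupancy against seven
  chemically defined lipid atom groups (acyl-chain carbons, headgroup
  carbons, ester oxygens, amine nitrogen, phosphate, DOPS carboxylate),
  with a contact defined as any atom pair at distance *d* < 4 Å (strict)
  and occupancy = fraction of frames with ≥ 1 contact.
- **Membrane tilt angles** — plane from three anchor Cα atoms; signed
  tilt of a protein axis **p̂** versus the unit normal **n̂**:
  θ = 90° − arccos(n̂ · p̂) ∈ [−90°, 90°].
- **SASA and ΔSASA** — Shrake–Rupley with a deterministic golden-spiral
  point set; burial upon binding as ΔSASA = ⟨SASA⟩(no membrane occluders)
  − ⟨SASA⟩(with membrane occluders) per residue.
- **RMSD/RMSF** — Kabsch superposition, backbone (N, CA, C, O) RMSD
  series and per-residue RMSF about the mean structure.
- **RDF → PMF** — g(r) between named groups (e.g. arginine guanidino
  nitrogens vs DOPS carboxylate oxygens) and PMF(r) = −RT ln g(r) at
  310 K, with minimum depth/location reporting.  Depths are effective /
  qualitative numbers for a finite nanodisc; locations are robust.
- **Interaction energies** — a documented short-range surrogate:
  Coulomb + Lennard-Jones pair sums inside a 12 Å cutoff
  (Lorentz–Berthelot combining, no long-range terms), split by lipid
  species, with lowest-energy-frame export.
- **A seeded synthetic generator** — a kinematic nanodisc + two-domain
  probe whose trajectory has planted ground truth (contact occupancies,
  tilt distribution, an arginine–carboxylate distance well, buried
  residues), so the whole pipeline is testable end to end without any
  external data.

## Worked example

```python
import numpy as np
import disctraj as dt

nanodisc = dt.build_nanodisc(seed=0)            # 64 DOPC + 16 DOPS per leaflet
probe = dt.build_probe_protein(seed=0)
traj, truth = dt.generate_binding_trajectory(nanodisc, probe,
                                             n_frames=600, seed=0)
topo = traj.topology
settled = traj[truth.settled_start:]

anchors = [topo.alpha_carbon(r, "S") for r in truth.anchor_residues]
lipids = np.flatnonzero(topo.segment_classes == "lipid")
protein = np.flatnonzero(topo.segment_classes == "protein")
for dom, (r1, r2) in truth.axis_residues.items():
    axis = (topo.alpha_carbon(r1, "P"), topo.alpha_carbon(r2, "P"))
    ts = dt.tilt_series(settled, anchors, axis, membrane_selection=lipids,
                        protein_selection=protein)
    print(dom, f"{ts.mean:.1f} +/- {ts.sd:.1f} deg")
```

prints

```
C1 67.9 +/- 7.8 deg
C2 68.8 +/- 8.9 deg
```

i.e. the settled-phase tilt statistics recover the generator's planted
N(68°, 8°) and N(69°, 9°) within sampling error.  The scripts in
`examples/` walk through each capability the same way (contact maps, ΔSASA
burial, the PMF well, the energy drop upon insertion, the full pipeline).

A thin CLI mirrors the library: `disctraj generate | contacts | tilt |
sasa | rmsf | rmsd | rdf | energy | run | report` (see `disctraj --help`);
`run` executes the whole battery from one YAML config and writes CSV/JSON
tables, a manifest that echoes every default, and exported PDB frames.

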