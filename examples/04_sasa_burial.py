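"""Solvent burial upon membrane binding: per-residue delta-SASA.

SASA is Shrake-Rupley (probe 1.4 A, 960 deterministic sphere points).
delta-SASA = mean SASA without the lipids as occluders minus mean SASA
with them; positive values mean the residue is buried against the membrane.
"""

import numpy as np

import disctraj as dt

nanodisc = dt.build_nanodisc(seed=0)
probe = dt.build_probe_protein(seed=0)
traj, truth = dt.generate_binding_trajectory(nanodisc, probe,
                                             n_frames=300, seed=0)
topo = traj.topology
settled = traj[truth.settled_start:]

protein = np.flatnonzero(topo.segment_classes == "protein")
lipids = np.flatnonzero(topo.segment_classes == "lipid")
unbound = settled.subset(protein)  # same poses, no membrane

table = dt.delta_sasa(
    settled, unbound,
    surface_bound=protein, surface_unbound=np.arange(len(protein)),
    occluders_bound=np.concatenate([protein, lipids]),
    occluders_unbound=None, stride=20,
).set_index("residue_id")

print("residue  dSASA (A^2)   planted role")
for rid in sorted(set(int(r) for r in topo.residue_ids[protein])):
    role = ("buried loop" if rid in truth.buried_residues else
            "control" if rid in truth.control_residues else "")
    print(f"{topo.residue_names[topo.atoms_of_residue(rid, 'P')[0]]}{rid}"
          f"  {table.loc[rid, 'delta_sasa']:8.2f}   {role}")
# Buried beta-hairpin residues lose > 10 A^2 of accessible surface; the
# solvent-facing controls stay near zero.
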