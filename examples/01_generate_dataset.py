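"""Build the synthetic nanodisc-binding dataset and look at its ground truth.

The generator poses rigid bodies: an 80:20 DOPC:DOPS bilayer patch with a
scaffold ring, and a two-domain probe protein that approaches, inserts its
hydrophobic loops and settles at a planted tilt.  Everything downstream is
measured against the PlantedTruth it returns.
"""

import disctraj as dt

nanodisc = dt.build_nanodisc(seed=0)           # 64 DOPC + 16 DOPS per leaflet
probe = dt.build_probe_protein(seed=0)
traj, truth = dt.generate_binding_trajectory(nanodisc, probe,
                                             n_frames=200, seed=0)

print(f"system: {traj.topology.n_atoms} atoms, {traj.n_frames} frames")
print(f"settled phase starts at frame {truth.settled_start}")
print(f"planted tilt: C1 {truth.tilt['C1']} deg, C2 {truth.tilt['C2']} deg")
print(f"planted guanidino-carboxylate well: {truth.rdf_r0} +/- "
      f"{truth.rdf_spread} A on residue {truth.rdf_residue}")
print("planted contacts (residue, moiety, occupancy):")
for s in truth.contacts[:6]:
    print(f"  {s.residue_name}{s.residue_id:5d}  {s.moiety_label:22s} "
          f"{s.occupancy:.2f}")
# The occupancies are the fractions of settled frames in which each residue
# touches (< 4 A) the named lipid moiety; analyses must recover them.
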