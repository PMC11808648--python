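# Methods

## Scope and data model

The package analyzes trajectories of a peripheral membrane protein binding
a lipid nanodisc.  Internally everything is Å; GRO files (nm) are converted
on read/write.  Residue numbering is carried verbatim from the input
(author numbering, e.g. C1 = 2021–2170, C2 = 2171–2332), so literature
residue names map directly onto selections.  Atoms carry a segment class
(protein / lipid / scaffold / solvent / ion) inferred from residue names,
with the scaffold identified by chain id (default chain `S`; GRO has no
chain column, so scaffold classification there relies on configuration).
Multi-model PDB (fixed-column v3.3, MODEL/ENDMDL) is the trajectory
interchange format so fixtures stay text-diffable; occupancy/B-factor are
ignored on read and written as 1.00/0.00.

## Contacts

A contact between two atom groups is formed when the inter-atom distance is
**strictly** below the cutoff (default 4 Å); a tie at exactly the cutoff is
no contact.  The per-frame count is the number of such pairs; the occupancy
of a (residue, moiety) cell is the fraction of frames with count ≥ 1.  The
hard step indicator was chosen over a smooth switching function because the
step is the stated definition; "percent of the simulation" is read as the
frame indicator rather than a count-weighted average.  Hydrogens are
excluded by default (heavy-atom group indexing).  Pair search uses a k-d
tree with strict re-filtering; with a box present, distances follow the
minimum-image convention (the search requires cutoff < box/2).  Since a
nanodisc is finite in-plane, results must be insensitive to turning PBC on
or off — asserted in the tests.

Lipid atoms are classified into seven moiety classes (chain carbon,
headgroup carbon, ester oxygen, amine nitrogen, phosphate, carboxylate,
other) by an ordered, editable TSV keyed on (residue name, atom-name glob)
in the CHARMM36 dialect for DOPC/DOPS.  Choices the boxes-not-atom-lists
figure convention leaves open are made explicit in the table: the phosphate
class is P plus its four bonded oxygens (phosphate-ester oxygens stay in
phosphate, not ester), the ester class is the four carbonyl/linking
oxygens, and glycerol carbons count as headgroup carbons.  The carboxylate
class is nonempty only for DOPS.  Protein probe classes: every protein N/O
is a hydrophilic probe; every carbon of a residue in the hydrophobic set
(default ALA, VAL, LEU, ILE, MET, PHE, TRP, PRO — configurable, since the
full class is conventional) is a hydrophobic probe.  Hydrophilic contacts
pair the N/O probes with {ester O, amine N, phosphate, carboxylate};
hydrophobic contacts pair the carbons with {chain, headgroup carbons};
occupancy cells are split by lipid species.  Because it is not obvious
whether a published per-residue heat map merges the two channels, the tool
reports both channels separately plus their union.

Replicate averaging is the arithmetic mean of occupancies over replicates
(per-frame counts are dropped).

## Tilt geometry

The membrane plane is defined by three anchor alpha carbons (for the
nanodisc scaffold ring: residues 32, 93, 158); the normal is the normalized
cross product (p2−p1) × (p3−p1), with a degenerate-plane error below a
cross-norm of 1e−6.  The protein axis is the vector between two alpha
carbons (first → second).  Tilt = 90° − arccos(n̂·p̂), signed, in
[−90°, 90°]; the sign is kept rather than folded to |θ| because wide
distributions straddling the plane are meaningful.  The cross-product sign
depends on anchor order, so the series constructor disambiguates it at
frame 0 by requiring a positive component along the membrane-centroid →
protein-centroid vector, and applies that fixed flip to all frames.
Summary sd is the sample standard deviation (n−1).  Anchors are always
explicit in configuration — nothing guesses which residues represent the
membrane surface.

## SASA and ΔSASA

Shrake–Rupley: for each surface atom, n quasi-uniform points (a
deterministic golden-spiral/Fibonacci set, default 960) on the sphere of
radius r_vdw + probe (probe default 1.4 Å); points strictly inside any
other occluder's expanded sphere are buried; SASA = accessible fraction ×
4π(r_vdw+probe)².  Per-residue SASA is the plain sum over the residue's
atoms (no normalization by maximum accessibility).  Radii by element
(Å): C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, H 1.20 — an editable table;
a missing element raises an error naming the atom.  The fixed point set
makes results deterministic and exactly translation-invariant; under
rotation they agree only to the discretization error (well below 1% of
total area at 960 points, tighter at 3840), which is the accuracy
granularity of the method.

ΔSASA_i = ⟨SASA_i⟩(unbound) − ⟨SASA_i⟩(bound) per residue, positive =
burial upon membrane binding.  Bound-state occluders are protein + lipids —
lipid occlusion is what makes membrane burial visible — and unbound is
protein-only.  The unbound reference can be a separate trajectory or the
same frames restricted to the protein atoms (`Trajectory.subset`); the
tests use the latter, which isolates the lipid-occlusion signal exactly.

## Superposition, RMSD, RMSF

Kabsch least-squares superposition via SVD with the proper-rotation
constraint (det = +1), optional weights, no mass weighting anywhere.
Backbone means N, CA, C, O.  RMSD series superpose each frame onto the
reference over the analyzed selection (a no-fit mode reports raw
displacement RMSD).  RMSF uses the common one-iteration convention: fit all
frames to frame 0, average, re-fit to the average, then take per-atom
fluctuations about the re-averaged structure; a residue's RMSF is the
unweighted mean over its backbone atoms.  The independent oracle in the
tests is a quaternion (Horn) closed-form fit.

## RDF and PMF

g(r) is a uniform histogram of all reference–target distances over frames
(bins of width Δr up to r_max; defaults 0.02 Å and 15 Å), normalized in
one of two modes: `box_density` divides by N_ref·N_frames·4πr²Δr·ρ with
ρ = N_target/V_box (the conventional bulk g(r); requires a box), and
`tail_unit` rescales so the mean of g over the last 10% of bins is 1.  For
a finite nanodisc in water the "bulk density" is ambiguous, so both modes
ship and every report records which produced it; the two differ by a
constant factor, hence PMF *depths* differ by a constant offset (they are
labeled effective/qualitative) while the minimum *location* is identical —
asserted in tests.  PMF(r) = −RT ln g(r) with
R = 8.314462618×10⁻³ kJ·mol⁻¹·K⁻¹, default T = 310 K; bins with g = 0 are
undefined (NaN).  The minimum is the global minimum over defined bins,
ties broken toward smaller r.  For the arginine–phosphatidylserine use
case the reference group is the guanidino nitrogens NE/NH1/NH2 and the
target the DOPS carboxylate oxygens O13A/O13B.  When locating a planted
well of spread σ, the analysis bin width is chosen on the order of σ
(0.1 Å in the shipped preset): much finer bins make the histogram argmax
wander among near-equal-count neighbors.

## Interaction energies

The energy module is a deliberate short-range surrogate, not a force-field
reimplementation: E = Σ_pairs<cutoff k_e q_i q_j / d + 4ε_ij[(σ_ij/d)¹² −
(σ_ij/d)⁶] with σ_ij arithmetic and ε_ij geometric (Lorentz–Berthelot),
k_e = 1389.35458 kJ·mol⁻¹·Å·e⁻², plain truncation at 12 Å, no PME/
reciprocal-space, switching, or bonded terms.  Absolute magnitudes are
therefore not comparable to full simulation-package energies; the module's
outputs say so and record the cutoff.  Its comparative roles — per-frame
series split by lipid species, mean ± sd, and argmin (lowest-energy) frame
selection with ties to the earliest frame — are well defined.  Parameters
come from a per-(residue, atom) TSV; a 0.1 Å clash floor guards the 1/d
singularity.

## Synthetic generator

The generator is kinematic — posed rigid bodies, not dynamics — because its
purpose is exact planted truth for the analyses.  Defaults are the study
conditions: 64 DOPC + 16 DOPS per leaflet (20% DOPS) on a jittered lattice
at 70 Ų per lipid (per-leaflet area 5606 Ų / 80 lipids), leaflet
headgroups at ±23.5 Å (47 Å bilayer height), reduced CHARMM36-named
heavy-atom lipid templates covering every moiety class, a CA-only scaffold
ring (160 residues; anchors MET32/GLU93/GLU158) and a ~100 Å-class disc.
The probe has two rigid mini-domains with per-residue backbone and minimal
side chains, numbered within 2021–2332 so literature selections work;
axis pairs are (2093→2145) and (2200→2299).

The trajectory script has four phases: rigid approach (15% of frames),
loop insertion of each domain in turn (10% each, first domain first), and
a settled phase.  Settled frames draw a global tilt θ ~ N(68°, 8°) applied
about the loop pivot, plus an independent wobble of the second domain that
makes its axis N(69°, 9°).  Each planted (residue, moiety) contact is a
per-frame Bernoulli draw of its occupancy: on success the designated
side-chain atom is placed 3.0–3.45 Å from a fixed partner lipid atom along
a pre-computed, clearance-maximizing direction (so planted geometries never
overlap the rest of the headgroup); otherwise it retracts to its template
position ≥ 6 Å above every lipid atom.  One arginine's guanidino nitrogen
draws its distance to a DOPS carboxylate oxygen from N(2.70 Å, 0.10 Å)
(the planted PMF well); the trailing NE/NH2 ride the same ray with
randomized extensions so only the planted atom forms a sharp g(r) peak.
Planted occupancies echo reported behavior: β-hairpin hydrophobic residues
0.98–0.985, the key arginines on the carboxylate 0.50, other polar/basic
residues 0.5–0.7.  Isotropic coordinate jitter (default σ = 0.1 Å) is added
last; all randomness derives from one seed and identical inputs are
byte-identical.  Frame times use a 240 ps stride.

What the generator does **not** emulate: water and ions, membrane
undulations and curvature, lipid diffusion, force-field realism, side-chain
covalent geometry (planted side chains stretch to their partners), or
genuine binding kinetics.  Passing tests therefore demonstrate that the
analysis code measures what it claims on data with known answers — not that
any biological conclusion holds on real trajectories.

## Problem sizes and numerical choices

The shipped preset uses 2 replicates × 1000 frames (~4000 atoms), with
SASA sub-sampled (stride ~20–26 frames) since mean surface areas converge
quickly; tests use the same machinery at smaller frame counts.  Recovery
tolerances are statistical: 3σ binomial for occupancies, standard errors
for tilt, one histogram bin for the PMF-well location.  Tie rules
throughout prefer the earliest frame / smallest r.  Degenerate inputs
(collinear anchors, zero axes, rank-deficient covariance, empty groups,
overlapping groups, missing parameters or radii) raise typed errors rather
than producing numbers.

## Known limitations

- The PDB/GRO writers support orthorhombic boxes only.
- The energy surrogate's absolute values are incomparable to
  Ewald/PME-based potentials; only relative/argmin use is supported.
- The moiety table covers DOPC/DOPS; other lipids need a user table.
- Binary trajectory formats (XTC/DCD) are out of scope; convert to
  multi-model PDB/GRO upstream.
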