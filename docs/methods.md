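# Methods

`quasi2d` models the amyloidogenic self-assembly of small
disulfide-constrained two-chain proteins (insulin is the motivating
case) through a three-stage, fully coarse-grained protocol: (1)
planarize the folded monomer into a quasi-2D layer, (2) classify the
layer's discrete 2D topology and (3) stack layers of one topology class
in-register into protofilament models that are then relaxed and
measured.  This note documents the model, its parameters, the synthetic
test structures, and the design decisions taken where the protocol left
genuine freedom.

## Coarse-grained representation

Each residue is reduced to five beads: backbone N, CA, C, O plus one
side-chain centroid bead (`SC`); for cysteines the `SC` bead carries the
sulfur position and element S, so the disulfide anchors used by the
twist measurement are explicit atoms.  Disulfide bonds are first-class
annotations; together with the backbone successions they define the
residue-level covalent graph from which the central topological loop is
extracted.

## Potential energy

Units are Å, fs, Da, kcal/mol.  Harmonic terms use the convention
`E = k (x − x0)²`.

| term | form | default | why |
|---|---|---|---|
| bonds | harmonic, ideal lengths (N–CA 1.458, CA–C 1.525, C–N 1.329, C–O 1.231, CA–SC 2.4 Å) | k = 100 | peptide geometry |
| angles | harmonic on N–CA–C (111°), CA–C–N (116.2°), C–N–CA (121.7°) | k = 20 kcal/mol/rad² | backbone stiffness; dihedrals stay free |
| disulfide | harmonic S–S, r0 = 2.04 Å | k = 200 | covalent-scale stiffness, so the bond never opens thermally (length stays within ~7% at 400 K) |
| excluded volume | WCA-style repulsion below per-pair σ (CA 4.0, SC 3.0, optional backbone 2.3 Å) | ε = 1 | self-avoidance; ≥ 0 by construction |
| attraction | flat-bottom Lennard-Jones tail, depth ε, minimum at 5.5 Å, switched off smoothly between 7 and 9 Å | ε = 0.3 | generic inter-residue cohesion standing in for vdW + hydrogen bonding; without it stacked layers would have no reason to cohere |
| surface field | attractive or repulsive part of a 12-6 potential split at r_min = 5 Å, per bead–atom pair | ε per schedule | the planarization drive |

The surface's attractive branch is the tail clamped at its minimum
value for r < r_min (so the energy is ≤ 0 everywhere and equals ε at
r_min); the repulsive branch is the mirror-image split (≥ 0, zero
beyond r_min).  Nonbonded pairs act between CA/SC beads of residues at
least two apart in sequence (or on different chains), excluding
disulfide-bonded side-chain pairs.  Forces are analytic throughout and
are validated against central finite differences at 1e-4 relative
tolerance in the test suite.

## Dynamics

BAOAB Langevin integration, timestep 10 fs, all bead masses 110 Da.
The friction coefficient is rescaled to the CG timescale; the default
0.05 fs⁻¹ gives strongly overdamped motion, and protocol stages that
must *progress* (planarization, docking descents, the stability probe)
use 0.01–0.002 fs⁻¹, which accelerates conformational exploration
several-fold without affecting the sampled ensemble.  The seed controls
only the noise stream; a run is bit-reproducible given (structure,
parameters, seed).  A zero-temperature run is a damped descent and is
used wherever a deterministic local relaxation is wanted (fixture
settling, docking close-out).  Severely overlapped inputs are handled
with an optional per-bead force cap during settles.

## Planarization

The monomer is placed a few Å above a rectangular grid of fixed dummy
beads (625 beads on 125 × 125 Å at full scale) and run at 400 K while
the attractive well deepens stepwise (−0.5, −1, −3, −6, −9 kcal/mol).
Six starting orientations (stepwise 90° rotations) are used.  Monitors
(radius of gyration, z of the centre of mass, maximal z, slab
thickness) are recorded per frame.  Flatness QC requires thickness
≤ 8 Å (two bead layers), per-residue thickness spread ≤ 2 Å, and no
crossing between projected backbone/disulfide segments that share no
residue.  Desk-scale presets replace the published 10 ns per epsilon
step with a configurable step count; at a few thousand steps per stage
the monomer flattens to a 4–6 Å slab, but residual projected crossings
("bumps") remain in most runs, so the desk-scale QC acceptance rate is
low — matching the protocol's behaviour qualitatively (only ~1/6 of
full-scale runs were acceptable) but not its acceptance statistics,
which are force-field-dependent and out of scope.  Accepted conformers
are relaxed between two parallel repulsive plates 15 Å apart and scored
by the fraction of non-terminal residues with (Φ, Ψ) in a generous
extended basin (Φ ∈ [−180°, −45°], Ψ ∈ [45°, 180°] ∪ [−180°, −150°]).

## Topology classification

The central loop is the cycle through both chains' mid-sections closed
by two interchain disulfides (largest enclosed residue count when more
than two exist).  Loop and termini are projected onto the conformer's
best-fit plane; a free terminal segment is "inside" iff its terminal
residue's projected CA falls inside the loop polygon by the even–odd
rule.  A terminal projecting within 0.5 Å of the polygon boundary is an
explicit ambiguity error, never a guess.  The classifier is invariant
under rigid motion, mirroring and uniform scaling, and is checked
against an independent winding-number oracle on random star-shaped
polygons.  For the insulin architecture the six named classes map to
inward termini as FC1:(A-N), FC2:(A-N, A-C), FC3:(none), FC4:(A-C),
FC5:(A-N, B-N), FC6:(A-C, B-N); the remaining ten conceivable patterns
are "unnamed".

## In-register docking

A pristine copy of the building block is rigidly aligned onto the top
layer, offset 10 Å along the layer normal, and pulled down by
flat-bottom harmonic restraints between corresponding CA beads (zero
force below the release distance of 5 Å; the flat bottom actually sits
0.2 Å inside the release so thermal jitter cannot stall the final
closure).  The docking layer is held quasi-rigid by a full CA
distance-matrix cage plus φ/ψ dihedral restraints, and its side-chain
beads are pinned to their local backbone frame (distance restraints to
N, C and the two neighbouring CAs — the neighbour springs break the
mirror degeneracy of a bead held by in-residue distances alone).  The
base stack is frozen.  Docking is athermal by default (a steered
descent), closing in two phases: approach, then a zero-temperature
close-out with boosted pulls that drives every pair below the release
distance.  Residual rigid in-plane drift is removed by an explicit 2D
superposition onto the in-register target — this is the defining bias
of the assembly mode, so it is applied as a rigid correction rather
than left to the soft restraints.  After a short settle the pulls are
released.  Typical products: every interface CA pair below 5 Å, mean
4.6–4.8 Å, in-register offset 0, |twist| below 0.05°/layer, internal CA
distances preserved to a few percent, topology class conserved in every
layer.

## Stack relaxation and the stability probe

`relax_stack` runs unconstrained Langevin dynamics and reports two
observables per frame: the Fig-4-style core CA RMSD of the whole
assembly versus its start (includes collective bending and inter-layer
shear) and the mean per-layer core RMSD with each layer superposed
separately (conformational integrity of the monomers).  Dissociation
(any interface mean CA distance beyond 8 Å) is flagged, not fatal.

The single-versus-multi-layer stability ordering is probed at low
friction (fast effective timescale) so that conformational degradation
of an unsupported layer becomes observable within a desk-scale run;
the per-layer core RMSD is the observable compared, because the
whole-assembly RMSD of a coarse-grained stack is dominated by soft
collective modes that say nothing about monomer integrity.

## Measurements

- **Twist**: each anchor pair (default: sulfur beads of A7/A20 and of
  B7/B19) spans a vector across its layer; per interface the rotation
  of that vector to the next layer's is measured about the local
  stacking axis (mean layer normal oriented along growth), averaged
  over pairs and interfaces with a circular mean (robust at ±180°).
  Negative = left-handed.  The constructed-stack oracle recovers
  prescribed twists to better than 0.01°.
- **Pitch**: (360/|twist|) · rise, reported in nm; zero twist is
  reported as unbounded, never as a number.  The default rise of
  4.95 Å/layer is the standard axial spacing of flat β-like layers and
  is consistent with all three (twist, pitch) pairs it was back-derived
  from; a measured rise always overrides it when a model is supplied.
- **Core RMSD**: optimal-superposition CA RMSD over the
  disulfide-bounded core (central-loop residues; 27 for insulin).
- **β content**: residue counts as β iff (Φ, Ψ) is in the extended
  basin *and* its CA has a CA neighbour within 5.5 Å in an adjacent
  layer; for single layers the cross-layer half is vacuous and the
  result is flagged dihedral-only.  This is a deliberate simplification
  of H-bond-based secondary-structure assignment: it is bounded and
  cheap.  One consequence: identical stacked layers score equally at
  every stack size, so the layer-count trend of β content is flat
  (non-decreasing as equality) rather than strictly increasing — the
  growth seen with hydrogen-bond-based assignment over MD ensembles is
  a stability effect this model does not reproduce.
- **Bounding box**: width/height (two largest extents) of the
  minimum-volume oriented box of the selected beads, in two regimes
  (all atoms / central-loop only).  The minimum-volume box is used
  instead of bare principal axes because it is orientation-independent
  even for degenerate inertia tensors.
- **Contact maps**: residue CA contact frequency below 8 Å,
  intra-layer and inter-layer reported separately.
- **Cavities**: 1 Å grid; a voxel is free if a 1.4 Å probe centred
  there clears every bead (bead radius 2 Å); free voxels 6-connected to
  the box boundary are bulk, the rest are cavities; wall atoms are
  beads within contact distance of cavity voxels.
- **Cavity waters**: distinct waters within 2.5 Å of any wall atom,
  divided by the layer count.  Because the shell criterion undercounts
  in wide channels, waters are also counted directly inside the cavity
  voxels and the larger of the two counts is used per cavity.
  `hydrate_cavity` packs water probes greedily on cavity voxels at
  ≥ 3.5 Å separation, which makes grid-greedy packing reproduce bulk water number density
  (~1 molecule / 30 Å3).

## Synthetic structures

The generators exist to give every pipeline stage a controlled input:

- **Insulin-like monomer**: chains of 21 + 30 residues, disulfides
  A6–A11, A7–B7, A20–B19.  The fold is a deterministic self-avoiding
  compact arrangement (quasi-Newton minimisation of virtual bonds,
  disulfide tethers, soft excluded volume and a spherical wall from a
  seeded random walk, then a force-capped T = 0 settle).  It reproduces
  insulin's covalent topology and compactness (Rg < 12 Å, no bead
  clash under 2 Å), not its secondary structure.
- **Planar conformers of prescribed class**: an explicit 2D layout.
  The central loop is drawn as two chain baselines 6.8 Å apart closed
  by the interchain disulfide chords; the A6–A11 disulfide forces a
  real detour ("pentagon") between A7 and A11, drawn outside the loop
  when the A N-terminus occupies the interior and dipping inward
  otherwise — the same bump the planarization protocol produces around
  these cysteines.  Interior termini run along the midline; the B-chain
  lens deepens only when the B N-terminus needs interior room,
  otherwise both chains hug their baselines so that an all-outside
  conformer shows interchain contacts along the chains' full lengths.
  CA beads alternate ±0.85 Å out of plane (the β pleat; deeper where a
  segment's in-plane spacing is compressed, keeping the CA–CA virtual
  bond at 3.8 Å), and backbone N/C/O beads are placed by rigidly
  fitting an ideal β-strand template onto each CA triplet, which makes
  straight runs score as extended dihedrals.  Interior terminal
  residues carry no SC bead (there is no room between the loop walls);
  a B-chain C-terminus inside the loop is refused as unrealizable for
  this architecture.
- **Dihedral probes**: ideal β-strand (−120°, 130°) and α-helix
  (−57°, −47°) chains built from exact internal coordinates.
- **Twisted stacks**: rigid helical constructions (layer k rotated by
  k·twist and translated k·rise) that serve as exact oracles for the
  twist/pitch measurements.

What passing tests on these fixtures do **not** show: the real
abundances of topology classes, force-field-accurate twists for real
insulin, or any all-atom/solvent effect — those require the published
force fields and μs-scale simulations and are explicitly out of scope.

## Numerical choices and limitations

- Nonbonded evaluation uses a Verlet-style active-pair list with a 2 Å
  skin refreshed every 20 steps; energies are identical to the full
  pair sum within the skin guarantee.
- Problem sizes used by the shipped tests and the acceptance script:
  monomers of 51 residues, stacks of 2–4 layers (30 for constructed
  twist oracles), planarization stages of 60–700 steps in unit tests.
  These are the package's desk-scale defaults; the `paper` preset
  carries the published protocol values instead.
- The CG model has no electrostatics and no solvation term; stability
  orderings are meaningful, absolute stabilities are not.
- Planar-conformer construction is specific to the two-chain,
  three-disulfide architecture; classification and analysis are
  generic.
- The twist sign convention at exactly ±180° reports +180°.
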