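# quasi2d

Amyloid protofilament models for disulfide-constrained proteins, built
from planarized ("quasi-2D") monomer conformers.

## The problem

Simulating the transition of a folded globular protein into an amyloid
fibril directly is out of reach: diffusion is slow, the free-energy
landscape is rugged, and orderly self-assembly does not happen on
simulated timescales.  For proteins whose topology is pinned by multiple
disulfide bonds — insulin, with two chains cross-linked by three
disulfides, is the canonical case — a different route is possible.  A
monomer squashed flat into an essentially two-dimensional layer can be
stacked in-register with identical copies of itself, saturating
inter-layer contacts the way a parallel β-sheet does.  Because the
disulfides survive the squashing, each flat conformer falls into one of
a small set of *discrete 2D topology classes*, defined by which
N-/C-terminal segments end up inside versus outside the *central
topological loop* (the cycle formed by the mid-sections of both chains
plus the two interchain disulfides).  For four free termini there are
2⁴ = 16 conceivable classes; six are realized by planarization and carry
the names FC1…FC6.  Stacking conformers of one class gives a distinct
fibril polymorph, and the class is conserved through assembly.

`quasi2d` implements this whole pipeline at coarse-grained resolution,
for structural bioinformaticians who want to enumerate and compare
plausible protofilament architectures without μs-scale all-atom MD:

1. **planarize** — Langevin dynamics at 400 K over a plane of attractive
   dummy beads whose Lennard-Jones well deepens stepwise
   (ε = −0.5 … −9 kcal/mol), from six starting orientations, with
   flatness quality control and relaxation between repulsive plates;
2. **classify** — extract the central loop from the covalent graph,
   project onto the best-fit plane, and read off the in/out flag of each
   free terminus (even–odd rule, with an explicit ambiguity error near
   the polygon boundary);
3. **stack** — biased in-register docking: a copy of the flat conformer
   is placed 10 Å above the stack and pulled down by flat-bottom
   harmonic CA–CA restraints released below 5 Å, while its internal
   structure is caged (rigid docking) and the base stack is frozen;
4. **analyze** — helical twist from disulfide-sulfur anchor dihedrals
   (negative = left-handed), pitch = (360/|twist|)·rise, core CA RMSD
   between the interchain disulfides, β-sheet content, bounding boxes,
   contact maps, grid-based cavity detection and cavity-water counts.

Everything needed for testing is generated in-repo: an idealized
insulin-like monomer (chains of 21 + 30 residues, disulfides A6–A11,
A7–B7, A20–B19), flat conformers of any realizable class, ideal
β/α dihedral probes, and rigid helical stacks of known twist that serve
as exact oracles.  See `docs/methods.md` for the model and its
parameters.

## Worked example

```python
from quasi2d import (
    make_planar_conformer, build_protofilament, DockingParams, CGParams,
    classify, analyze, make_twisted_stack, twist, pitch,
)

# a flat insulin-like conformer with all four termini outside the loop
conf = make_planar_conformer("FC3")
print(classify(conf).label, conf.qc_pass, round(conf.thickness, 1))
# FC3 True 3.1         <- class, flatness QC, slab thickness in Å

# dock four copies in register
model = build_protofilament(conf, 4, DockingParams(shape_k=12.0, temperature=0.0),
                            CGParams(), seed=11)
d = model.interface_ca_distances(0)
print(round(d.mean(), 2), round(d.max(), 2), round(model.rise(), 2))
# 4.73 4.93 4.77       <- every CA pair docked below the 5 Å release;
#                         rise ≈ the β-sheet inter-strand spacing

report = analyze(model)
print(round(report.twist_deg, 3), round(report.beta_fraction, 3))
# -0.004 0.887         <- quasi-translational stack, β-rich layers

# a 30-layer left-handed filament of known geometry, re-measured
long_model = make_twisted_stack(conf, 30, twist_deg=-0.9, rise_ang=4.95)
t = twist(long_model)
print(round(t, 3), round(pitch(t, long_model.rise()), 1))
# -0.9 198.0           <- 0.9°/layer at 4.95 Å rise -> 198 nm pitch
```

The same stages are available from a shell:

```sh
quasi2d fixtures --style insulin --seed 1 -o monomer.pdb
quasi2d planarize --input monomer.pdb --runs-per-orientation 2 --seed 0 -o out/
quasi2d classify --input out/conformer_o0_r0.pdb
quasi2d stack --input flat.pdb --layers 4 --seed 0 -o stack.pdb
quasi2d analyze --input stack.pdb
quasi2d run --input monomer.pdb --seed 0 -o pipeline_out/
```

Structures are PDB (one MODEL record per protofilament layer), tables
TSV, reports JSON.

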