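"""Biased in-register docking of planar conformers into protofilaments.

A copy of the top layer is placed ~10 Å above the stack along the layer
normal and pulled down by flat-bottom harmonic restraints between
corresponding CA beads (zero force below the release distance, mirroring
per-pair constraint removal on contact).  The docking layer's internal
structure is caged by a CA distance-matrix restraint (rigid docking) and
by dihedral restraints holding phi/psi near their starting values; the
base stack is held fixed.  Repetition yields an in-register parallel
stack of any desired length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._geometry import best_fit_plane, dihedrals, kabsch_rmsd, kabsch_superpose
from .structure import Molecule
from .energy import CGParams, CGSystem, Restraints, langevin_run
from . import topology as topo
from .planarize import phi_psi


class DockingError(RuntimeError):
    """Docking failed to bring all interface CA pairs below release."""


@dataclass
class DockingParams:
    """Parameters of one biased docking round."""

    initial_offset: float = 10.0  # Å above the monomer plane
    release_distance: float = 5.0  # Å, per-pair constraint removal
    pull_k: float = 2.0  # kcal/mol/Å²
    pull_depth: float = 0.2  # Å the pull flat-bottom sits inside release
    shape_k: float = 5.0  # kcal/mol/Å², CA distance-matrix cage
    dihedral_k: float = 5.0  # kcal/mol/rad², phi/psi holds
    base_fixed: bool = True
    temperature: float = 50.0  # K during docking
    max_steps: int = 8000
    settle_steps: int = 250

    def __post_init__(self):
        if self.release_distance >= self.initial_offset:
            raise ValueError("release_distance must be smaller than initial_offset")


@dataclass
class ProtofilamentModel:
    """Ordered stack of identical layers along a stacking axis.

    The residue-wise correspondence between consecutive layers is the
    identity (in-register stacking).
    """

    layers: list
    stacking_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    water_coords: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))

    def __post_init__(self):
        self.stacking_axis = np.asarray(self.stacking_axis, dtype=float)
        n = np.linalg.norm(self.stacking_axis)
        if n > 0:
            self.stacking_axis = self.stacking_axis / n

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def correspondence(self) -> list:
        return self.layers[0].residue_keys()

    @property
    def disulfides(self):
        return self.layers[0].disulfides

    def copy(self) -> "ProtofilamentModel":
        return ProtofilamentModel(
            [m.copy() for m in self.layers],
            self.stacking_axis.copy(),
            self.water_coords.copy(),
        )

    def layer_centroids(self) -> np.ndarray:
        return np.array([m.ca_coords().mean(axis=0) for m in self.layers])

    def interface_ca_distances(self, k: int) -> np.ndarray:
        """Per-residue CA distances across interface k / k+1."""
        a = self.layers[k].ca_coords()
        b = self.layers[k + 1].ca_coords()
        return np.linalg.norm(a - b, axis=1)

    def rise(self) -> float:
        """Mean axial translation per layer (Å)."""
        cents = self.layer_centroids()
        diffs = np.diff(cents, axis=0)
        axis = diffs.mean(axis=0)
        axis = axis / np.linalg.norm(axis)
        return float((diffs @ axis).mean())


def in_register_offset(model: ProtofilamentModel, k: int = 0, max_shift: int = 3) -> int:
    """Residue-index shift minimising the mean interface CA distance.

    Zero for a true in-register stack.
    """
    top = model.layers[k]
    new = model.layers[k + 1]
    best = (np.inf, 0)
    for shift in range(-max_shift, max_shift + 1):
        dists = []
        for chain in top.chains:
            resids = [int(r) for r in top.chain_resids(chain)]
            for r in resids:
                r2 = r + shift
                if new.has_atom(chain, r2, "CA"):
                    a = top.coords[top.atom_index(chain, r, "CA")]
                    b = new.coords[new.atom_index(chain, r2, "CA")]
                    dists.append(np.linalg.norm(a - b))
        if dists:
            m = float(np.mean(dists))
            if m < best[0]:
                best = (m, shift)
    return best[1]


def _stack_normal(model: ProtofilamentModel) -> np.ndarray:
    """Docking direction: best-fit-plane normal of the top layer, signed
    away from the previous layer (or as computed for a single layer)."""
    top = model.layers[-1]
    _, normal = best_fit_plane(top.ca_coords())
    if model.n_layers >= 2:
        grow = top.ca_coords().mean(axis=0) - model.layers[-2].ca_coords().mean(axis=0)
        if np.dot(normal, grow) < 0:
            normal = -normal
    return normal


def dock_layer(
    model: ProtofilamentModel,
    params: DockingParams,
    cg: CGParams,
    seed: int = 0,
    template: Molecule | None = None,
) -> ProtofilamentModel:
    """Dock one more monomer copy onto the stack.

    The docked copy is a pristine *template* (default: the current top
    layer) rigidly aligned onto the top layer and offset along the layer
    normal, so deformation does not accumulate over many rounds.  The
    base layers are untouched when ``base_fixed``.  Raises
    :class:`DockingError` with a closest-approach diagnostic if any
    corresponding CA pair fails to come below the release distance
    within ``max_steps``.
    """
    model = model.copy()
    top = model.layers[-1]
    normal = _stack_normal(model)
    if template is None:
        new = top.copy()
    else:
        moved, rot, _ = kabsch_superpose(template.ca_coords(), top.ca_coords())
        new = template.copy()
        center = template.ca_coords().mean(axis=0)
        new.coords = (new.coords - center) @ rot.T + top.ca_coords().mean(axis=0)
    new = new.transformed(translation=params.initial_offset * normal)

    k_new = model.n_layers
    segs = model.layers + [new]
    interacting = [(k_new, k_new), (k_new, k_new - 1)]
    if k_new >= 2:
        interacting.append((k_new, k_new - 2))
    cg_dock = replace(cg, temperature=params.temperature)
    system = CGSystem(segs, cg_dock, interacting_segments=interacting)
    off = system.offsets[k_new]
    off_top = system.offsets[k_new - 1]

    rst = Restraints()
    ca_local = top.ca_indices()
    for i in ca_local:
        rst.add_pair(
            off_top + i, off + i,
            params.release_distance - params.pull_depth, params.pull_k,
            flat_bottom=True,
        )
    n_pulls = len(ca_local)
    # rigid-docking cage: full internal CA distance matrix of the new layer
    ca_xyz = new.ca_coords()
    for a in range(len(ca_local)):
        for b in range(a + 1, len(ca_local)):
            r0 = float(np.linalg.norm(ca_xyz[a] - ca_xyz[b]))
            rst.add_pair(off + ca_local[a], off + ca_local[b], r0, params.shape_k)
    # pin side-chain beads to their local backbone frame (they carry the
    # twist anchors, so they must ride rigidly with the layer); the
    # neighbouring-CA springs break the mirror degeneracy of a bead held
    # by in-residue distances alone
    for c, r in new.residue_keys():
        if not new.has_atom(c, r, "SC"):
            continue
        i_sc = new.atom_index(c, r, "SC")
        others = [(c, r, "N"), (c, r, "C"), (c, r - 1, "CA"), (c, r + 1, "CA")]
        for key in others:
            if new.has_atom(*key):
                i_o = new.atom_index(*key)
                r0 = float(np.linalg.norm(new.coords[i_sc] - new.coords[i_o]))
                rst.add_pair(off + i_sc, off + i_o, r0, params.shape_k)
    # hold the new layer's backbone dihedrals near their starting values
    for quad, target in _phi_psi_quads(new):
        rst.add_dihedral(tuple(off + q for q in quad), target, params.dihedral_k)

    x = np.concatenate([m.coords for m in segs])
    fixed = np.zeros(len(x), dtype=bool)
    if params.base_fixed:
        fixed[:off] = True

    pull_i = np.array(rst.pair_i[:n_pulls])
    pull_j = np.array(rst.pair_j[:n_pulls])

    def interface_dists(coords):
        return np.linalg.norm(coords[pull_i] - coords[pull_j], axis=1)

    # Phase 1: thermal approach until the interface is nearly closed.
    chunk = 250
    steps_done = 0
    sub = 0
    cold = replace(cg_dock, temperature=0.0)
    while steps_done < params.max_steps:
        x, _ = langevin_run(
            system, [], cg_dock, chunk, seed=int((seed * 7919 + sub) % (2**31 - 1)),
            restraints=rst, fixed_mask=fixed, coords=x, stride=chunk,
        )
        steps_done += chunk
        sub += 1
        if interface_dists(x).mean() < params.release_distance + 0.3:
            break
    # Phase 2: zero-temperature close-out with boosted pulls, light
    # friction and periodic in-plane re-registration, driving every
    # remaining pair below the release distance.
    cold = replace(cold, friction=0.02)
    rst.pair_k[:n_pulls] = [4.0 * params.pull_k] * n_pulls
    for it in range(30):
        x[off:] = _reregister_in_plane(x[off:], x[pull_i], x[pull_j], normal)
        if np.all(interface_dists(x) < params.release_distance):
            break
        if it == 15:
            # a stubborn last pair: deepen the pull bottom slightly
            rst.pair_r0[:n_pulls] = [
                params.release_distance - params.pull_depth - 0.2
            ] * n_pulls
        x, _ = langevin_run(
            system, [], cold, chunk, seed=0,
            restraints=rst, fixed_mask=fixed, coords=x, stride=chunk,
        )
        steps_done += chunk
    if not np.all(interface_dists(x) < params.release_distance):
        d = interface_dists(x)
        raise DockingError(
            f"interface not closed after {steps_done} steps; "
            f"closest approach max pair distance {d.max():.2f} Å "
            f"({int((d < params.release_distance).sum())}/{len(d)} pairs satisfied)"
        )
    # contact reached: remove residual rigid in-plane drift (the
    # in-register bias), settle with the contact pulls still engaged,
    # then release them (each pair is below the release distance).
    x[off:] = _reregister_in_plane(x[off:], x[pull_i], x[pull_j], normal)
    x, _ = langevin_run(
        system, [], cold, params.settle_steps, seed=0,
        restraints=rst, fixed_mask=fixed, coords=x, stride=params.settle_steps,
    )
    x[off:] = _reregister_in_plane(x[off:], x[pull_i], x[pull_j], normal)
    rst.remove_pairs([True] * n_pulls + [False] * (len(rst.pair_i) - n_pulls))
    if not np.all(interface_dists(x) < params.release_distance):
        raise DockingError("interface re-opened during settle")
    new_out = new.copy()
    new_out.coords = x[off:]
    model.layers.append(new_out)
    cents = model.layer_centroids()
    model.stacking_axis = (cents[-1] - cents[0]) / np.linalg.norm(cents[-1] - cents[0])
    return model


def _reregister_in_plane(new_all, base_ca, new_ca, normal):
    """Rigidly remove in-plane drift of the docked layer.

    The optimal in-plane rotation + translation mapping the new layer's
    CA beads onto the in-register positions above the base layer is
    applied to every bead; axial coordinates are untouched.
    """
    n = normal / np.linalg.norm(normal)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, n)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - np.dot(ref, n) * n
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    basis = np.vstack([e1, e2])
    p = new_ca @ basis.T
    q = base_ca @ basis.T
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    pp, qq = p - pc, q - qc
    theta = np.arctan2(
        float((pp[:, 0] * qq[:, 1] - pp[:, 1] * qq[:, 0]).sum()),
        float((pp * qq).sum()),
    )
    from ._geometry import rotation_about_axis

    rot = rotation_about_axis(n, theta)
    pivot = new_ca.mean(axis=0)
    moved = (new_all - pivot) @ rot.T + pivot
    # in-plane translation correcting the centroid offset
    moved_ca_c = ((new_ca - pivot) @ rot.T + pivot) @ basis.T
    shift2d = qc - moved_ca_c.mean(axis=0)
    return moved + shift2d[0] * e1 + shift2d[1] * e2


def _phi_psi_quads(mol: Molecule):
    """(atom quad, current angle) for each defined phi and psi."""
    quads = []
    for chain in mol.chains:
        resids = [int(r) for r in mol.chain_resids(chain)]
        for n, r in enumerate(resids):
            if n > 0 and resids[n - 1] == r - 1:
                quad = (
                    mol.atom_index(chain, r - 1, "C"),
                    mol.atom_index(chain, r, "N"),
                    mol.atom_index(chain, r, "CA"),
                    mol.atom_index(chain, r, "C"),
                )
                quads.append(quad)
            if n + 1 < len(resids) and resids[n + 1] == r + 1:
                quad = (
                    mol.atom_index(chain, r, "N"),
                    mol.atom_index(chain, r, "CA"),
                    mol.atom_index(chain, r, "C"),
                    mol.atom_index(chain, r + 1, "N"),
                )
                quads.append(quad)
    c = mol.coords
    return [
        (q, float(dihedrals(c[q[0]][None], c[q[1]][None], c[q[2]][None], c[q[3]][None])[0]))
        for q in quads
    ]


def build_protofilament(
    conformer_or_molecule,
    n_layers: int,
    params: DockingParams | None = None,
    cg: CGParams | None = None,
    seed: int = 0,
) -> ProtofilamentModel:
    """Assemble an n-layer in-register protofilament by repeated docking."""
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    params = params or DockingParams()
    cg = cg or CGParams()
    mol = getattr(conformer_or_molecule, "molecule", conformer_or_molecule)
    model = ProtofilamentModel([mol.copy()])
    for k in range(1, n_layers):
        try:
            model = dock_layer(model, params, cg, seed=seed + k, template=mol)
        except DockingError as err:
            raise DockingError(f"interface {k - 1}->{k}: {err}") from err
    return model


def relax_stack(
    model: ProtofilamentModel,
    cg: CGParams,
    n_steps: int = 1000,
    seed: int = 0,
    stride: int = 100,
    core_only: bool = True,
    dissociation_cutoff: float = 8.0,
):
    """Unconstrained CG Langevin relaxation of a whole stack.

    Returns ``(relaxed model, report)`` where the report tracks the
    core-region CA RMSD versus the starting structure over time and
    flags dissociation (any interface mean CA distance beyond the
    cutoff).  Dissociation is reported, not fatal.
    """
    model = model.copy()
    system = CGSystem(model.layers, cg)
    x0 = np.concatenate([m.coords for m in model.layers])
    core_idx = _core_ca_indices(model, system, core_only)
    layer_core = [
        _core_ca_indices(ProtofilamentModel([mol]), CGSystem(mol, cg), core_only)
        + system.offsets[k]
        for k, mol in enumerate(model.layers)
    ]
    x, traj = langevin_run(
        system, [], cg, n_steps, seed=seed, coords=x0, stride=stride,
    )
    rows = []
    for frame, t in zip(traj.frames, traj.times):
        rows.append(
            {
                "time_fs": t,
                # Whole-stack core RMSD: includes collective bending and
                # inter-layer shear of the assembly.
                "core_rmsd": kabsch_rmsd(frame[core_idx], x0[core_idx]),
                # Conformational integrity of the monomers themselves:
                # each layer superposed separately, mean over layers.
                "core_rmsd_per_layer": float(
                    np.mean([kabsch_rmsd(frame[idx], x0[idx]) for idx in layer_core])
                ),
            }
        )
    for k, mol in enumerate(model.layers):
        lo, hi = system.offsets[k], system.offsets[k + 1]
        mol.coords = x[lo:hi]
    dissociated = []
    for k in range(model.n_layers - 1):
        if model.interface_ca_distances(k).mean() > dissociation_cutoff:
            dissociated.append(k)
    report = pd.DataFrame(rows)
    report.attrs["dissociated_interfaces"] = dissociated
    return model, report


def _core_ca_indices(model: ProtofilamentModel, system: CGSystem, core_only: bool) -> np.ndarray:
    """Global CA indices of the disulfide-bounded core (all layers)."""
    keys = None
    if core_only:
        try:
            loop = topo.find_central_loop(model.layers[0])
            keys = set(loop.residues)
        except topo.NoCentralLoopError:
            keys = None
    idx = []
    for k, mol in enumerate(model.layers):
        off = system.offsets[k]
        for c, r in mol.residue_keys():
            if keys is None or (c, r) in keys:
                idx.append(off + mol.atom_index(c, r, "CA"))
    return np.array(idx, dtype=int)
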