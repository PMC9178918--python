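"""Planarization protocol: squash a folded monomer into a quasi-2D layer.

A monomer is placed above an attractive dummy-bead surface and run at
high temperature under a stepwise-deepening Lennard-Jones well depth,
which unfolds and eventually flattens it.  Each run is monitored by the
radius of gyration, the z coordinate of the centre of mass and the slab
thickness.  Flat products are quality-controlled (minimal and uniform
thickness, no overlapping projected backbone/disulfide segments),
physically relaxed between two purely repulsive plates, and scored by
the fraction of backbone dihedrals compatible with extended (β-region)
structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from ._geometry import best_fit_plane, dihedral, radius_of_gyration, rotation_about_axis
from .structure import Molecule
from .energy import (
    REPULSIVE,
    CGParams,
    CGSystem,
    Schedule,
    SurfaceField,
    build_surface,
    langevin_run,
    minimize_structure,
)
from . import topology as topo

logger = logging.getLogger(__name__)

# Flatness acceptance thresholds (Å): two CG bead layers of thickness,
# and an upper bound on the spread of per-residue normal extents.
THICKNESS_MAX = 8.0
UNIFORMITY_MAX = 2.0

# Extended (β) Ramachandran region: generous basin.
PHI_RANGE = (-180.0, -45.0)
PSI_RANGES = ((45.0, 180.0), (-180.0, -150.0))


def orientation_set() -> list[np.ndarray]:
    """Six starting orientations: stepwise 90° rotations about X and Y.

    These present each face of the monomer's bounding cube to the
    surface (identity, ±90° about X, ±90° about Y, 180° about X).
    """
    rx = lambda a: rotation_about_axis([1.0, 0, 0], np.radians(a))
    ry = lambda a: rotation_about_axis([0, 1.0, 0], np.radians(a))
    return [np.eye(3), rx(90), rx(-90), ry(90), ry(-90), rx(180)]


@dataclass
class QCReport:
    passed: bool
    thickness: float
    uniformity: float
    crossings: list

    @property
    def n_crossings(self) -> int:
        return len(self.crossings)


@dataclass
class PlanarConformer:
    """A flattened molecule with its best-fit plane and flatness metrics."""

    molecule: Molecule
    plane: tuple  # (point, normal)
    thickness: float
    thickness_uniformity: float
    rg: float
    qc_pass: bool
    qc_report: QCReport | None = None

    @classmethod
    def from_molecule(cls, molecule: Molecule, run_qc: bool = True) -> "PlanarConformer":
        plane = best_fit_plane(molecule.coords)
        t, u = _thickness_metrics(molecule, plane)
        conf = cls(
            molecule=molecule,
            plane=plane,
            thickness=t,
            thickness_uniformity=u,
            rg=radius_of_gyration(molecule.coords),
            qc_pass=False,
        )
        if run_qc:
            report = flatness_qc(conf)
            conf.qc_report = report
            conf.qc_pass = report.passed
        return conf


def _thickness_metrics(molecule: Molecule, plane) -> tuple[float, float]:
    point, normal = plane
    t = (molecule.coords - point) @ normal
    thickness = float(t.max() - t.min())
    extents = []
    for c, r in molecule.residue_keys():
        mask = (molecule.chain_ids == c) & (molecule.res_ids == r)
        tr = t[mask]
        extents.append(tr.max() - tr.min())
    return thickness, float(np.std(extents))


def _segments_2d(molecule: Molecule, plane):
    """Projected backbone and disulfide segments for the crossing check.

    Returns a list of ``(p2d, q2d, res_a, res_b)``; backbone segments join
    consecutive CA beads, disulfide segments join the SC (sulfur) beads of
    the bonded cysteines.
    """
    _, axes = topo._projection_axes(molecule, plane)
    segs = []
    for chain in molecule.chains:
        resids = [int(r) for r in molecule.chain_resids(chain)]
        for r1, r2 in zip(resids[:-1], resids[1:]):
            if r2 != r1 + 1:
                continue
            p = molecule.coords[molecule.atom_index(chain, r1, "CA")] @ axes.T
            q = molecule.coords[molecule.atom_index(chain, r2, "CA")] @ axes.T
            segs.append((p, q, (chain, r1), (chain, r2)))
    for (c1, r1), (c2, r2) in molecule.disulfides:
        name1 = "SC" if molecule.has_atom(c1, r1, "SC") else "CA"
        name2 = "SC" if molecule.has_atom(c2, r2, "SC") else "CA"
        p = molecule.coords[molecule.atom_index(c1, r1, name1)] @ axes.T
        q = molecule.coords[molecule.atom_index(c2, r2, name2)] @ axes.T
        segs.append((p, q, (c1, r1), (c2, r2)))
    return segs


def _proper_cross(p1, q1, p2, q2) -> bool:
    def orient(a, b, c):
        v = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        return 0 if abs(v) < 1e-12 else (1 if v > 0 else -1)

    o1 = orient(p1, q1, p2)
    o2 = orient(p1, q1, q2)
    o3 = orient(p2, q2, p1)
    o4 = orient(p2, q2, q1)
    return o1 != o2 and o3 != o4 and 0 not in (o1, o2, o3, o4)


def flatness_qc(
    conformer: PlanarConformer,
    thickness_max: float = THICKNESS_MAX,
    uniformity_max: float = UNIFORMITY_MAX,
) -> QCReport:
    """Flatness acceptance test for a planarized conformer.

    Fails when the slab is too thick, non-uniform, or when any two
    projected backbone/disulfide segments that share no residue cross
    each other (the lingering "bump" of a terminus folded over the
    loop).  The verdict is invariant under rigid-body motion.
    """
    mol = conformer.molecule
    plane = conformer.plane
    thickness, uniformity = _thickness_metrics(mol, plane)
    segs = _segments_2d(mol, plane)
    crossings = []
    for i in range(len(segs)):
        p1, q1, a1, b1 = segs[i]
        for j in range(i + 1, len(segs)):
            p2, q2, a2, b2 = segs[j]
            if {a1, b1} & {a2, b2}:
                continue
            if _proper_cross(p1, q1, p2, q2):
                crossings.append(((a1, b1), (a2, b2)))
    passed = thickness <= thickness_max and uniformity <= uniformity_max and not crossings
    return QCReport(passed=passed, thickness=thickness, uniformity=uniformity, crossings=crossings)


# --------------------------------------------------------------------------
# Dihedral analysis


def phi_psi(molecule: Molecule) -> dict:
    """Backbone (phi, psi) per residue key; None where undefined."""
    out = {}
    for chain in molecule.chains:
        resids = [int(r) for r in molecule.chain_resids(chain)]
        for n, r in enumerate(resids):
            if not all(molecule.has_atom(chain, r, x) for x in ("N", "CA", "C")):
                out[(chain, r)] = (None, None)
                continue
            c = molecule.coords
            idx = molecule.atom_index
            phi = psi = None
            if n > 0 and resids[n - 1] == r - 1 and molecule.has_atom(chain, r - 1, "C"):
                phi = dihedral(
                    c[idx(chain, r - 1, "C")], c[idx(chain, r, "N")],
                    c[idx(chain, r, "CA")], c[idx(chain, r, "C")],
                )
            if n + 1 < len(resids) and resids[n + 1] == r + 1 and molecule.has_atom(chain, r + 1, "N"):
                psi = dihedral(
                    c[idx(chain, r, "N")], c[idx(chain, r, "CA")],
                    c[idx(chain, r, "C")], c[idx(chain, r + 1, "N")],
                )
            out[(chain, r)] = (phi, psi)
    return out


def is_extended(phi: float, psi: float) -> bool:
    if phi is None or psi is None:
        return False
    if not (PHI_RANGE[0] <= phi <= PHI_RANGE[1]):
        return False
    return any(lo <= psi <= hi for lo, hi in PSI_RANGES)


def extended_score(conformer) -> float:
    """Fraction of non-terminal residues in the extended (β) region.

    Terminal residues (undefined phi or psi) are excluded from both the
    numerator and denominator.
    """
    mol = getattr(conformer, "molecule", conformer)
    if mol.n_residues < 3:
        raise ValueError("need at least 3 residues to score dihedrals")
    angles = phi_psi(mol)
    scored = [(p, s) for p, s in angles.values() if p is not None and s is not None]
    if not scored:
        raise ValueError("no scorable (non-terminal) residues")
    n_ext = sum(1 for p, s in scored if is_extended(p, s))
    return n_ext / len(scored)


# --------------------------------------------------------------------------
# The squashing protocol


def _derive_seed(seed: int, k: int) -> int:
    return int((seed * 1000003 + 97 * k + 17) % (2**31 - 1))


def planarize(
    molecule: Molecule,
    orientation: np.ndarray,
    field: SurfaceField,
    schedule: Schedule,
    params: CGParams,
    seed: int,
    stride: int = 50,
    start_height: float = 4.0,
):
    """Squash one oriented monomer onto the attractive surface.

    Runs one Langevin stage per schedule epsilon, recording the Fig-style
    monitors (time, Rg, z of centre of mass, max z, slab thickness) each
    *stride* steps.  Returns ``(monitors: DataFrame, PlanarConformer)``;
    a QC failure is reported in the conformer, not raised.
    """
    mol = molecule.transformed(rotation=orientation)
    # centre laterally over the grid, drop to start_height above the plane
    shift = -mol.coords.mean(axis=0)
    shift[2] = field.plane_offset + start_height - mol.coords[:, 2].min()
    mol = mol.transformed(translation=shift)
    system = CGSystem(mol, params)
    x = mol.coords.copy()
    rows = []
    t_offset = 0.0
    for k, eps in enumerate(schedule.epsilon_steps):
        fld = field.with_epsilon(eps)
        x, traj = langevin_run(
            system, [fld], params, schedule.steps_per_stage,
            seed=_derive_seed(seed, k), coords=x, stride=stride,
        )
        for frame, t in zip(traj.frames, traj.times):
            rows.append(
                {
                    "time_fs": t_offset + t,
                    "epsilon": eps,
                    "rg": radius_of_gyration(frame),
                    "z_com": float(frame[:, 2].mean() - field.plane_offset),
                    "z_max": float(frame[:, 2].max() - field.plane_offset),
                    "thickness": float(frame[:, 2].max() - frame[:, 2].min()),
                }
            )
        t_offset += schedule.steps_per_stage * params.timestep
    final = mol.copy()
    final.coords = x
    conformer = PlanarConformer.from_molecule(final)
    return pd.DataFrame(rows), conformer


def relax_between_plates(
    conformer: PlanarConformer,
    params: CGParams,
    gap: float = 15.0,
    n_steps: int = 1000,
    seed: int = 0,
    plate_epsilon: float = 1.0,
    settle_steps: int = 100,
):
    """Relax a flat conformer between two parallel repulsive plates.

    The conformer is first rotated into its plane frame; two
    repulsive-only surfaces *gap* Å apart then cage it while a short
    thermal run followed by a bounded quasi-Newton settle relieves
    internal strain.  The settle is deliberately shallow (*settle_steps*
    L-BFGS iterations): the stiff bonded terms converge within tens of
    iterations, while running the cohesive tail to convergence would
    slowly curl the layer up and destroy its planarity.  The topology
    class must survive; a class change raises ``ValueError``.
    """
    # tight edge tolerance: the guard needs a consistent before/after
    # comparison, not the user-facing ambiguity margin
    before = topo.classify(conformer, edge_tolerance=0.05)
    mol = _to_plane_frame(conformer.molecule)
    span = float(np.abs(mol.coords[:, :2]).max()) * 2 + 30.0
    n_side = max(2, int(span // 5) + 1)
    plates = [
        build_surface(span, span, n_side, plane_offset=-gap / 2, epsilon=plate_epsilon, mode=REPULSIVE),
        build_surface(span, span, n_side, plane_offset=+gap / 2, epsilon=plate_epsilon, mode=REPULSIVE),
    ]
    system = CGSystem(mol, params)
    x = mol.coords.copy()
    if params.temperature > 0 and n_steps > 0:
        x, _ = langevin_run(system, plates, params, n_steps, seed=_derive_seed(seed, 101), coords=x)
    # bounded quasi-Newton settle (strain relief, not full collapse)
    x = minimize_structure(system, x, plates, maxiter=settle_steps)
    out = mol.copy()
    out.coords = x
    relaxed = PlanarConformer.from_molecule(out)
    after = topo.classify(relaxed, edge_tolerance=0.05)
    if after.flags != before.flags:
        raise ValueError(
            f"topology class changed during plate relaxation: {before.flags} -> {after.flags}"
        )
    return relaxed


def _to_plane_frame(molecule: Molecule) -> Molecule:
    """Rigidly move a molecule so its best-fit plane is z = 0."""
    point, normal = best_fit_plane(molecule.coords)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(normal, z)
    s = np.linalg.norm(v)
    if s < 1e-12:
        rot = np.eye(3)
    else:
        c = float(np.dot(normal, z))
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    out = molecule.copy()
    out.coords = (out.coords - point) @ rot.T
    if len(out.water_coords):
        out.water_coords = (out.water_coords - point) @ rot.T
    return out


# --------------------------------------------------------------------------
# Campaign bookkeeping


@dataclass
class CampaignResult:
    runs: pd.DataFrame
    conformers: list  # PlanarConformer per run (same order as runs rows)

    def abundance_table(self) -> pd.DataFrame:
        ok = self.runs[self.runs.qc_pass & (self.runs.label != "")]
        counts = ok.groupby("label").size().rename("count").reset_index()
        total = counts["count"].sum()
        counts["percent"] = 100.0 * counts["count"] / max(total, 1)
        return counts.sort_values("percent", ascending=False).reset_index(drop=True)

    def success_rates(self) -> pd.DataFrame:
        g = self.runs.groupby("orientation").agg(
            n_runs=("qc_pass", "size"), n_success=("qc_pass", "sum")
        )
        g["success_rate"] = g.n_success / g.n_runs
        return g.reset_index()


def run_campaign(
    molecule: Molecule,
    field: SurfaceField,
    schedule: Schedule,
    params: CGParams,
    n_runs_per_orientation: int = 2,
    seed: int = 0,
) -> CampaignResult:
    """Planarize from all six orientations, n runs each, and tabulate.

    Every run gets a derived, logged sub-seed; per-run QC verdicts and
    class labels feed the abundance table (percentages over qc-passing,
    classifiable conformers sum to 100).
    """
    rows = []
    conformers = []
    for o_idx, rot in enumerate(orientation_set()):
        for run_idx in range(n_runs_per_orientation):
            run_seed = _derive_seed(seed, 1000 * o_idx + run_idx + 1)
            monitors, conf = planarize(molecule, rot, field, schedule, params, seed=run_seed)
            label = ""
            flags = None
            if conf.qc_pass:
                try:
                    tc = topo.classify(conf)
                    flags = tc.flags
                    label = tc.label
                except (topo.NoCentralLoopError, topo.AmbiguousClassificationError) as err:
                    logger.warning("run (%d, %d): %s", o_idx, run_idx, err)
            rows.append(
                {
                    "orientation": o_idx,
                    "run": run_idx,
                    "seed": run_seed,
                    "qc_pass": bool(conf.qc_pass),
                    "thickness": conf.thickness,
                    "uniformity": conf.thickness_uniformity,
                    "rg": conf.rg,
                    "flags": "" if flags is None else "/".join(flags),
                    "label": label,
                }
            )
            conformers.append(conf)
    return CampaignResult(runs=pd.DataFrame(rows), conformers=conformers)


def select_best(conformers, labels) -> dict:
    """Per-class argmax of extended score; ties broken by run order.

    Returns ``{label: (index, conformer)}`` over qc-passing conformers.
    """
    best: dict = {}
    for i, (conf, label) in enumerate(zip(conformers, labels)):
        if not conf.qc_pass or not label:
            continue
        score = extended_score(conf)
        cur = best.get(label)
        if cur is None or score > cur[0]:
            best[label] = (score, i, conf)
    return {lbl: (i, conf) for lbl, (s, i, conf) in best.items()}
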