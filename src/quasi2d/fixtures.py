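"""In-repo synthetic test structures.

Everything the pipeline consumes can be generated here from a seed: an
idealized insulin-like two-chain monomer (21 + 30 residues, disulfides
A6-A11, A7-B7, A20-B19, compact fold), pre-planarized conformers of a
prescribed 2D topology class, ideal β-strand / α-helix dihedral probes,
and rigid helical stacks of known twist and rise that serve as exact
oracles for the fibril twist measurement.

The insulin-like fixture reproduces insulin's covalent topology, not its
biology: the fold is a self-avoiding compact arrangement produced by
deterministic minimisation, with native-like CA-CA virtual bonds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from ._geometry import (
    best_fit_plane,
    build_backbone_from_dihedrals,
    kabsch_superpose,
    rotation_about_axis,
)
from .structure import Molecule
from .energy import CGParams, langevin_run
from .planarize import PlanarConformer
from .stack import ProtofilamentModel
from . import topology as topo

# Insulin-like covalent topology: chain lengths and disulfides.
INSULIN_CHAIN_LENGTHS = (21, 30)
INSULIN_DISULFIDES = (
    (("A", 6), ("A", 11)),
    (("A", 7), ("B", 7)),
    (("A", 20), ("B", 19)),
)
_CYS = {("A", 6), ("A", 7), ("A", 11), ("A", 20), ("B", 7), ("B", 19)}

SC_OFFSET = 2.4  # Å, CA->side-chain-centroid bead distance


@dataclass
class FixtureSpec:
    """Declarative description of a synthetic molecule to generate."""

    chain_lengths: tuple = INSULIN_CHAIN_LENGTHS
    disulfides: tuple = INSULIN_DISULFIDES
    seed: int = 0
    style: str = "native_like"  # native_like | planar | beta_strand | alpha_helix
    topology_class: str = "FC3"  # for style == "planar"

    def build(self):
        """Generate the structure this spec describes."""
        if self.style == "native_like":
            return make_insulin_like(self.seed)
        if self.style == "planar":
            return make_planar_conformer(self.topology_class, jitter_seed=self.seed)
        if self.style == "beta_strand":
            return make_beta_strand(sum(self.chain_lengths))
        if self.style == "alpha_helix":
            return make_alpha_helix(sum(self.chain_lengths))
        raise ValueError(f"unknown style {self.style!r}")


class UnrealizableClassError(ValueError):
    """The requested planar topology class cannot be constructed."""


# --------------------------------------------------------------------------
# Backbone helpers


def _beta_template():
    return build_backbone_from_dihedrals([(-120.0, 130.0)] * 5)


def _backbone_from_ca_path(ca: np.ndarray) -> np.ndarray:
    """Fit ideal β-strand backbone fragments onto a CA trace.

    For each residue the five-residue β template is rigidly superposed on
    the local CA triplet; where the trace is straight with ~3.8 Å spacing
    the resulting dihedrals are exactly extended.
    """
    tpl = _beta_template()
    n = len(ca)
    out = np.zeros((n, 4, 3))
    if n == 1:
        out[0] = tpl[2] - tpl[2, 1] + ca[0]
        return out
    if n == 2:
        d = ca[1] - ca[0]
        tpl_d = tpl[3, 1] - tpl[2, 1]
        moved, rot, tr = kabsch_superpose(
            np.array([tpl[2, 1], tpl[3, 1]]), np.array([ca[0], ca[1]])
        )
        for i, t in enumerate((2, 3)):
            out[i] = (tpl[t] - np.array([tpl[2, 1], tpl[3, 1]]).mean(axis=0)) @ rot.T + np.array(
                [ca[0], ca[1]]
            ).mean(axis=0)
        return out
    for i in range(n):
        c = min(max(i, 1), n - 2)
        tpl_cas = np.array([tpl[1, 1], tpl[2, 1], tpl[3, 1]])
        path_cas = ca[c - 1 : c + 2]
        _, rot, _ = kabsch_superpose(tpl_cas, path_cas)
        t_res = 2 + (i - c)  # template residue mapped to i (in {1, 2, 3})
        mapped = (tpl[t_res] - tpl_cas.mean(axis=0)) @ rot.T + path_cas.mean(axis=0)
        # pin the mapped CA exactly onto the trace
        out[i] = mapped + (ca[i] - mapped[1])
    return out


def _assemble(chains, disulfides, sc_dirs) -> Molecule:
    """Build a Molecule from per-chain CA paths and SC direction rules.

    ``chains`` maps chain id -> (n, 3) CA array; ``sc_dirs`` maps
    (chain, resid) -> unit 3-vector or None (no SC bead).
    """
    names, els, coords, chs, rids, rnames = [], [], [], [], [], []
    for chain, ca in chains.items():
        bb = _backbone_from_ca_path(np.asarray(ca, dtype=float))
        for i in range(len(ca)):
            rid = i + 1
            is_cys = (chain, rid) in _CYS or any(
                (chain, rid) in b for b in disulfides
            )
            rname = "CYS" if is_cys else "ALA"
            for j, nm in enumerate(("N", "CA", "C", "O")):
                names.append(nm)
                els.append(nm[0])
                coords.append(bb[i, j])
                chs.append(chain)
                rids.append(rid)
                rnames.append(rname)
            d = sc_dirs.get((chain, rid))
            if d is not None:
                names.append("SC")
                els.append("S" if is_cys else "C")
                coords.append(np.asarray(ca[i]) + SC_OFFSET * np.asarray(d, dtype=float))
                chs.append(chain)
                rids.append(rid)
                rnames.append(rname)
    return Molecule(names, els, coords, chs, rids, rnames, disulfides=disulfides)


def make_chain(phi_psi, chain: str = "A", res_name: str = "ALA") -> Molecule:
    """Single chain with prescribed backbone (phi, psi) per residue.

    SC beads point along the N/C bisector away from the backbone (the
    natural alternating β arrangement).
    """
    bb = build_backbone_from_dihedrals(list(phi_psi))
    names, els, coords, chs, rids, rnames = [], [], [], [], [], []
    for i in range(len(bb)):
        for j, nm in enumerate(("N", "CA", "C", "O")):
            names.append(nm)
            els.append(nm[0])
            coords.append(bb[i, j])
            chs.append(chain)
            rids.append(i + 1)
            rnames.append(res_name)
        d = -((bb[i, 0] - bb[i, 1]) + (bb[i, 2] - bb[i, 1]))
        d = d / np.linalg.norm(d)
        names.append("SC")
        els.append("C")
        coords.append(bb[i, 1] + SC_OFFSET * d)
        chs.append(chain)
        rids.append(i + 1)
        rnames.append(res_name)
    return Molecule(names, els, coords, chs, rids, rnames)


def make_beta_strand(n_res: int = 10) -> Molecule:
    """Ideal extended strand probe (phi = -120°, psi = +130°)."""
    return make_chain([(-120.0, 130.0)] * n_res)


def make_alpha_helix(n_res: int = 10) -> Molecule:
    """Ideal α-helix probe (phi = -57°, psi = -47°)."""
    return make_chain([(-57.0, -47.0)] * n_res)


# --------------------------------------------------------------------------
# Compact insulin-like monomer


def make_insulin_like(seed: int = 1) -> Molecule:
    """Idealized compact two-chain disulfide-constrained monomer.

    Chains of 21 and 30 residues with disulfides A6-A11, A7-B7, A20-B19;
    a deterministic self-avoiding compact CA fold (Rg < 12 Å) is found by
    quasi-Newton minimisation of virtual bonds, disulfide tethers, soft
    excluded volume and a spherical confinement wall, then decorated with
    backbone and side-chain beads and briefly settled at T = 0.
    """
    rng = np.random.default_rng(seed)
    n_a, n_b = INSULIN_CHAIN_LENGTHS
    n = n_a + n_b
    bonds = [(i, i + 1) for i in range(n_a - 1)] + [
        (n_a + i, n_a + i + 1) for i in range(n_b - 1)
    ]
    ss_pairs = []
    for (c1, r1), (c2, r2) in INSULIN_DISULFIDES:
        i = (r1 - 1) if c1 == "A" else n_a + r1 - 1
        j = (r2 - 1) if c2 == "A" else n_a + r2 - 1
        ss_pairs.append((i, j))
    chain_of = np.array([0] * n_a + [1] * n_b)
    nb_pairs = [
        (i, j)
        for i in range(n)
        for j in range(i + 2, n)
        if not (chain_of[i] == chain_of[j] and j - i < 2)
    ]
    nb_i = np.array([p[0] for p in nb_pairs])
    nb_j = np.array([p[1] for p in nb_pairs])
    b_i = np.array([p[0] for p in bonds])
    b_j = np.array([p[1] for p in bonds])
    s_i = np.array([p[0] for p in ss_pairs])
    s_j = np.array([p[1] for p in ss_pairs])

    def objective(flat):
        x = flat.reshape(n, 3)
        g = np.zeros_like(x)

        def spring(i_arr, j_arr, r0, k, only_below=None):
            nonlocal g
            d = x[i_arr] - x[j_arr]
            r = np.linalg.norm(d, axis=1)
            dr = r - r0
            if only_below is not None:
                dr = np.where(r < only_below, dr, 0.0)
            e = k * np.sum(dr**2)
            fm = (2.0 * k * dr / np.maximum(r, 1e-9))[:, None] * d
            np.add.at(g, i_arr, fm)
            np.add.at(g, j_arr, -fm)
            return e

        e = spring(b_i, b_j, 3.8, 10.0)
        e += spring(s_i, s_j, 6.84, 10.0)
        e += spring(nb_i, nb_j, 4.5, 5.0, only_below=4.5)
        rad = np.linalg.norm(x, axis=1)
        over = np.maximum(rad - 8.5, 0.0)
        e += 5.0 * np.sum(over**2)
        g += (10.0 * over / np.maximum(rad, 1e-9))[:, None] * x
        return e, g.ravel()

    # random-walk start inside the confinement sphere
    x0 = np.zeros((n, 3))
    pos = rng.normal(0, 2.0, 3)
    for i in range(n):
        if i == n_a:
            pos = rng.normal(0, 2.0, 3)
        step = rng.normal(0, 1.0, 3)
        step = 3.8 * step / np.linalg.norm(step)
        cand = pos + step
        if np.linalg.norm(cand) > 8.0:
            cand = pos - step
        pos = cand
        x0[i] = pos
    res = minimize(objective, x0.ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-8})
    ca = res.x.reshape(n, 3)

    chains = {"A": ca[:n_a], "B": ca[n_a:]}
    centroid = ca.mean(axis=0)
    sc_dirs = {}
    ss_partner = {}
    for (c1, r1), (c2, r2) in INSULIN_DISULFIDES:
        ss_partner[(c1, r1)] = (c2, r2)
        ss_partner[(c2, r2)] = (c1, r1)
    for chain, arr in chains.items():
        for i in range(len(arr)):
            key = (chain, i + 1)
            if key in ss_partner:
                pc, pr = ss_partner[key]
                target = chains[pc][pr - 1]
                d = target - arr[i]
            else:
                d = arr[i] - centroid
            nrm = np.linalg.norm(d)
            sc_dirs[key] = d / nrm if nrm > 1e-9 else np.array([0.0, 0.0, 1.0])
    mol = _assemble(chains, INSULIN_DISULFIDES, sc_dirs)
    return _settle(mol)


def _settle(mol: Molecule, steps: int = 300) -> Molecule:
    """Deterministic T = 0 descent resolving residual bead overlaps."""
    params = CGParams(
        temperature=0.0, attr_epsilon=0.0, sigma_ca=2.8, sigma_sc=2.4,
        ev_all_beads=True, sigma_backbone=2.3, ss_k=1e-6, friction=0.2,
        timestep=4.0, max_force=30.0,
    )
    x, _ = langevin_run(mol, [], params, steps, seed=0, stride=steps)
    out = mol.copy()
    out.coords = x
    return out


# --------------------------------------------------------------------------
# Planar conformers of prescribed topology class


def _resample_arc(xs, ys, n_pts):
    """Resample a planar curve to n_pts points equally spaced by arc length."""
    pts = np.column_stack([xs, ys])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    t = np.linspace(0.0, s[-1], n_pts)
    return np.column_stack([np.interp(t, s, xs), np.interp(t, s, ys)])


def _arc_between(p0, p1, n_pts, arc_len, side: float, lobes: int = 1):
    """n_pts points from p0 to p1 along a bulged arc of given length.

    The bulge (perpendicular, on the *side* of the chord given by the
    sign) has ``lobes`` humps; its amplitude is found by bisection so
    the curve length matches.  More lobes keep the curve closer to the
    chord for the same arc length.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    chord = p1 - p0
    d = np.linalg.norm(chord)
    u = chord / d
    perp = np.array([-u[1], u[0]]) * np.sign(side)
    t = np.linspace(0.0, 1.0, 400)

    def curve(amp):
        if lobes == 1:
            bump = amp * np.sin(np.pi * t)
        else:
            bump = amp * np.sin(lobes * np.pi * t) ** 2
        return p0 + np.outer(t, chord) + np.outer(bump, perp)

    def length(amp):
        pts = curve(amp)
        return np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()

    lo, hi = 0.0, max(arc_len, d)
    if arc_len <= d + 1e-9:
        amp = 0.0
    else:
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if length(mid) < arc_len:
                lo = mid
            else:
                hi = mid
        amp = 0.5 * (lo + hi)
    pts = curve(amp)
    return _resample_arc(pts[:, 0], pts[:, 1], n_pts)


def _circle_intersect(c1, r1, c2, r2, pick_upper: bool):
    """One of the two intersection points of two circles in the plane."""
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    d = np.linalg.norm(c2 - c1)
    a = (r1**2 - r2**2 + d**2) / (2 * d)
    h = np.sqrt(max(r1**2 - a**2, 0.0))
    u = (c2 - c1) / d
    perp = np.array([-u[1], u[0]])
    p_up = c1 + a * u + h * perp
    p_dn = c1 + a * u - h * perp
    if (p_up[1] >= p_dn[1]) == pick_upper:
        return p_up
    return p_dn


def make_planar_conformer(topology_class, jitter_seed: int = 0) -> PlanarConformer:
    """Construct a flat insulin-like conformer of the requested class.

    ``topology_class`` is an FC label ("FC1".."FC6") or a 4-tuple of
    in/out flags in terminus order (A-N, A-C, B-N, B-C).  The B-chain
    C-terminus cannot be placed inside the loop (its entry is never
    realized by planarization of this architecture) and requesting it
    raises :class:`UnrealizableClassError`.  The returned conformer
    passes flatness QC and classifies as requested.
    """
    if isinstance(topology_class, str):
        if topology_class not in topo.FC_CATALOG:
            raise UnrealizableClassError(f"unknown class label {topology_class!r}")
        flags = topo.FC_CATALOG[topology_class]
    else:
        flags = tuple(topology_class)
    if len(flags) != 4 or any(f not in (topo.IN, topo.OUT) for f in flags):
        raise ValueError("flags must be a 4-tuple of 'in'/'out'")
    an_in, ac_in, bn_in, bc_in = (f == topo.IN for f in flags)
    if bc_in:
        raise UnrealizableClassError(
            "B-chain C-terminus inside the central loop is not realizable "
            "for this architecture"
        )

    L = 40.0
    h_end = 3.4
    step = 3.35  # axial CA spacing of a pleated beta strand

    ca_a = np.zeros((21, 2))
    ca_b = np.zeros((30, 2))

    # A-chain core.  The A6-A11 disulfide forces a real detour between A7
    # and A11 (a closed mini-loop); it bulges outward when the A-chain
    # N-terminus occupies the loop interior and dips inward otherwise.
    a7 = np.array([0.0, h_end])
    if an_in:
        pentagon = [(0.3, 6.9), (2.4, 9.6), (5.8, 10.3), (8.0, 7.6)]
    else:
        pentagon = [(3.2, 1.4), (6.7, 1.2), (9.9, 2.5), (9.0, 5.8)]
    ca_a[6] = a7
    ca_a[7:11] = np.array(pentagon)  # A8..A11
    a11 = ca_a[10]
    a20 = np.array([L, h_end])
    # run A11..A20 bowing gently toward the midline (flat conformers pack
    # the two chains side by side); with the outward pentagon the chord
    # is long enough that the bow vanishes
    ca_a[10:20] = _arc_between(a11, a20, 10, 9 * 3.5, side=-1.0)

    # B-chain core: a deep in-plane lens only when the B-chain N-terminus
    # must fit inside the loop; otherwise straight along the baseline so
    # the two chains run in parallel contact
    b7 = np.array([0.0, -h_end])
    b19 = np.array([L, -h_end])
    if bn_in:
        ca_b[6:19] = _arc_between(b7, b19, 13, 12 * 3.55, side=-1.0)
    else:
        ca_b[6:19] = _arc_between(b7, b19, 13, 0.0, side=-1.0)

    # A6 closes the A6-A11 disulfide: intersection of the bond circle
    # around A7 and the disulfide-reach circle around A11
    ca_a[5] = _circle_intersect(a7, 3.7, a11, 6.84, pick_upper=not an_in)
    a6 = ca_a[5]
    # remaining A-chain N-terminal residues A1..A5
    if an_in:
        start = np.array([7.0, 1.6])
        for k in range(5):
            ca_a[4 - k] = start + np.array([step * k, 0.0])
    else:
        u = np.array([-0.42, 0.91])
        u = u / np.linalg.norm(u)
        for k in range(1, 6):
            ca_a[5 - k] = a6 + step * k * u
    # A-chain C-terminus A21 (attached at A20)
    ca_a[20] = np.array([L - 2.4, 0.9]) if ac_in else a20 + np.array([2.4, 2.7])
    # B-chain N-terminal segment B1..B6; sits deeper in the loop when the
    # A-chain detour dips inward (A-N outside), to keep clear of it
    if bn_in:
        y_bn = -1.6 if an_in else -2.6
        ca_b[5] = np.array([3.3, y_bn])
        for k in range(1, 6):
            ca_b[5 - k] = ca_b[5] + np.array([step * k, 0.0])
    else:
        b6 = np.array([-1.5, -6.7])
        u = np.array([-0.42, -0.91])
        u = u / np.linalg.norm(u)
        ca_b[5] = b6
        for k in range(1, 6):
            ca_b[5 - k] = b6 + step * k * u
    # B-chain C-terminal segment B20..B30, always outside
    u = np.array([0.94, -0.34])
    u = u / np.linalg.norm(u)
    for k in range(1, 12):
        ca_b[18 + k] = b19 + step * k * u

    rng = np.random.default_rng(jitter_seed)
    ca_a = ca_a + rng.normal(0, 0.03, ca_a.shape)
    ca_b = ca_b + rng.normal(0, 0.03, ca_b.shape)
    # pleat: alternate CA beads out of plane, as in a beta sheet; where a
    # segment's in-plane spacing is compressed, the pleat deepens so the
    # CA-CA virtual bond stays at its native length
    ca_ca = 3.804

    def _pleat_for(seg_2d):
        s = np.linalg.norm(np.diff(seg_2d, axis=0), axis=1).mean()
        return float(np.sqrt(max(ca_ca**2 - s**2, 0.25)) / 2.0)

    za = 0.85 * np.ones(21)
    zb = 0.85 * np.ones(30)
    za[10:20] = _pleat_for(ca_a[10:20])
    zb[6:19] = _pleat_for(ca_b[6:19])
    za *= (-1.0) ** np.arange(1, 22)
    zb *= (-1.0) ** np.arange(1, 31)
    ca3_a = np.column_stack([ca_a, za])
    ca3_b = np.column_stack([ca_b, zb])
    chains = {"A": ca3_a, "B": ca3_b}

    sc_dirs = _planar_sc_rules(chains, an_in, ac_in, bn_in)
    mol = _assemble(chains, INSULIN_DISULFIDES, sc_dirs)
    mol = _settle(mol, steps=200)
    conf = PlanarConformer.from_molecule(mol)
    got = topo.classify(conf)
    if got.flags != flags:
        raise RuntimeError(
            f"constructed conformer classified as {got.flags}, requested {flags}"
        )
    if not conf.qc_pass:
        raise RuntimeError("constructed planar conformer failed flatness QC")
    return conf


def _planar_sc_rules(chains, an_in, ac_in, bn_in):
    """SC bead directions for the planar layout.

    Disulfide cysteines point at their partner's CA (so the S-S bond is
    geometrically closed), core rows point away from the loop interior,
    exterior termini point outward; interior terminal residues carry no
    SC bead (no room between the loop walls).
    """
    ss_partner = {}
    for (c1, r1), (c2, r2) in INSULIN_DISULFIDES:
        ss_partner[(c1, r1)] = (c2, r2)
        ss_partner[(c2, r2)] = (c1, r1)
    loop_centroid = np.concatenate([chains["A"][6:20], chains["B"][6:19]]).mean(axis=0)
    dirs = {}
    for chain, arr in chains.items():
        n = len(arr)
        for i in range(n):
            key = (chain, i + 1)
            rid = i + 1
            if key in ss_partner:
                pc, pr = ss_partner[key]
                d = chains[pc][pr - 1] - arr[i]
                d[2] = 0.0
                dirs[key] = d / np.linalg.norm(d)
                continue
            if chain == "A" and 7 <= rid <= 20:
                dirs[key] = np.array([0.0, 1.0, 0.0])
            elif chain == "B" and 7 <= rid <= 19:
                # outward normal of the lens curve
                prv = arr[max(i - 1, 0)]
                nxt = arr[min(i + 1, n - 1)]
                t = (nxt - prv)[:2]
                nrm = np.array([-t[1], t[0]])
                if np.dot(nrm, (arr[i] - loop_centroid)[:2]) < 0:
                    nrm = -nrm
                dirs[key] = np.append(nrm / np.linalg.norm(nrm), 0.0)
            elif chain == "A" and rid <= 5:
                dirs[key] = None if an_in else np.array([-0.91, -0.42, 0.0])
            elif chain == "A" and rid == 21:
                dirs[key] = None if ac_in else np.array([0.55, 0.83, 0.0])
            elif chain == "B" and rid <= 6:
                dirs[key] = None if bn_in else np.array([-0.91, 0.42, 0.0])
            else:  # B-chain C-terminal tail
                dirs[key] = np.array([-0.34, -0.94, 0.0])
    return {k: v for k, v in dirs.items()}


# --------------------------------------------------------------------------
# Constructed helical stacks (twist oracles)


def make_twisted_stack(layer, n_layers: int, twist_deg: float, rise_ang: float) -> ProtofilamentModel:
    """Rigid helical stack: layer k is layer 0 rotated by k·twist about
    the stacking axis and translated by k·rise along it.

    The construction is the exact oracle for the twist measurement.
    """
    if n_layers < 2:
        raise ValueError("a stack needs at least 2 layers")
    if rise_ang <= 0:
        raise ValueError("rise must be positive")
    mol = getattr(layer, "molecule", layer)
    _, normal = best_fit_plane(mol.ca_coords())
    center = mol.ca_coords().mean(axis=0)
    layers = []
    for k in range(n_layers):
        rot = rotation_about_axis(normal, np.radians(k * twist_deg))
        m = mol.copy()
        m.coords = (m.coords - center) @ rot.T + center + k * rise_ang * normal
        layers.append(m)
    return ProtofilamentModel(layers, stacking_axis=normal)
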