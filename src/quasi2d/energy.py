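"""Coarse-grained potential and Langevin dynamics engine.

The model is deliberately minimal: harmonic bonds and angles hold the
five-bead residue geometry, a repulsive excluded-volume term plus a weak
flat-bottom attraction act between residue beads (CA and SC), disulfide
bonds are harmonic springs between the sulfur-carrying SC beads, and a
planar field of fixed dummy beads provides the uniaxial squashing force
used during planarization.  The field interaction is the attractive or
the repulsive part of a Lennard-Jones potential split at its minimum
(Weeks-Chandler-Andersen style): the attractive branch is clamped at
epsilon below r_min, the repulsive branch is zero beyond r_min.

Units: Å, fs, Da, kcal/mol, Kelvin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .structure import Molecule

KB = 0.0019872041  # kcal/mol/K
ACC_CONV = 4.184e-4  # (kcal/mol/Å) / Da -> Å/fs²

ATTRACTIVE = "attractive_only"
REPULSIVE = "repulsive_only"

# Ideal coarse-grained bond lengths (Å) by (name, name) pair.
BOND_LENGTHS = {
    ("N", "CA"): 1.458,
    ("CA", "C"): 1.525,
    ("C", "O"): 1.231,
    ("C", "N"): 1.329,  # inter-residue peptide bond
    ("CA", "SC"): 2.4,
}
# Ideal backbone angles (degrees) for (N,CA,C), (CA,C,N+1), (C,N+1,CA+1).
ANGLE_THETA0 = {"N-CA-C": 111.0, "CA-C-N": 116.2, "C-N-CA": 121.7}


class DivergenceError(RuntimeError):
    """Raised when dynamics coordinates blow up (|x| > 1e4 Å)."""


@dataclass
class SurfaceField:
    """A planar grid of fixed dummy beads interacting with every atom.

    ``epsilon`` is the current well depth in kcal/mol (negative in
    attractive mode); ``mode`` selects the attractive or repulsive branch
    of the Lennard-Jones split at ``r_min``.
    """

    bead_positions: np.ndarray
    r_min: float = 5.0
    epsilon: float = -1.0
    mode: str = ATTRACTIVE
    plane_offset: float = 0.0
    cutoff: float = 12.0

    def __post_init__(self):
        self.bead_positions = np.asarray(self.bead_positions, dtype=float).reshape(-1, 3)
        if self.mode not in (ATTRACTIVE, REPULSIVE):
            raise ValueError(f"unknown surface mode {self.mode!r}")
        if self.mode == ATTRACTIVE and self.epsilon > 0:
            raise ValueError("epsilon must be <= 0 in attractive mode")

    def with_epsilon(self, epsilon: float) -> "SurfaceField":
        return replace(self, epsilon=epsilon)


@dataclass
class Schedule:
    """Stepwise-deepening epsilon schedule for the planarization field."""

    epsilon_steps: tuple = (-0.5, -1.0, -3.0, -6.0, -9.0)
    steps_per_stage: int = 2000

    def __post_init__(self):
        eps = tuple(self.epsilon_steps)
        if any(b > a for a, b in zip(eps[:-1], eps[1:])):
            raise ValueError("epsilon schedule must deepen monotonically")
        self.epsilon_steps = eps


@dataclass
class CGParams:
    """Force-field constants and integrator settings.

    Harmonic terms use the ``E = k (x - x0)**2`` convention (no 1/2).
    """

    bond_k: float = 100.0  # kcal/mol/Å²
    angle_k: float = 20.0  # kcal/mol/rad²
    ev_epsilon: float = 1.0  # kcal/mol, excluded-volume strength
    sigma_ca: float = 4.0  # Å, CA bead excluded-volume diameter
    sigma_sc: float = 3.0  # Å, SC bead excluded-volume diameter
    attr_epsilon: float = 0.3  # kcal/mol, inter-residue cohesion depth
    attr_rmin: float = 5.5  # Å
    cutoff: float = 9.0  # Å, nonbonded cutoff (attraction)
    switch_start: float = 7.0  # Å, switching onset for the attraction tail
    ss_k: float = 200.0  # kcal/mol/Å², disulfide spring (covalent stiffness)
    ss_r0: float = 2.04  # Å, S-S bond length
    ev_all_beads: bool = False  # include N/C/O beads in excluded volume
    sigma_backbone: float = 2.3  # Å, backbone bead diameter when included
    max_force: float | None = None  # kcal/mol/Å per-bead cap (descent stability)
    temperature: float = 400.0  # K
    friction: float = 0.05  # 1/fs
    timestep: float = 10.0  # fs
    mass: float = 110.0  # Da, all beads

    def __post_init__(self):
        if min(self.bond_k, self.angle_k, self.ss_k) <= 0:
            raise ValueError("force constants must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")


@dataclass
class Restraints:
    """Auxiliary restraint terms added on top of the base potential."""

    pair_i: list = field(default_factory=list)
    pair_j: list = field(default_factory=list)
    pair_r0: list = field(default_factory=list)
    pair_k: list = field(default_factory=list)
    pair_flat: list = field(default_factory=list)
    dihe_quads: list = field(default_factory=list)
    dihe_target: list = field(default_factory=list)
    dihe_k: list = field(default_factory=list)
    tether_i: list = field(default_factory=list)
    tether_xyz: list = field(default_factory=list)
    tether_k: list = field(default_factory=list)

    def add_pair(self, i, j, r0, k, flat_bottom=False):
        """Harmonic pair distance restraint; flat-bottom variants exert no
        force below r0 (used for docking pulls and shape cages)."""
        self.pair_i.append(int(i))
        self.pair_j.append(int(j))
        self.pair_r0.append(float(r0))
        self.pair_k.append(float(k))
        self.pair_flat.append(bool(flat_bottom))

    def add_dihedral(self, quad, target_deg, k):
        self.dihe_quads.append(tuple(int(q) for q in quad))
        self.dihe_target.append(float(target_deg))
        self.dihe_k.append(float(k))

    def add_tether(self, i, xyz, k):
        self.tether_i.append(int(i))
        self.tether_xyz.append(np.asarray(xyz, dtype=float))
        self.tether_k.append(float(k))

    def remove_pairs(self, mask):
        """Drop pair restraints where *mask* is True (released pulls)."""
        keep = [not m for m in mask]
        for name in ("pair_i", "pair_j", "pair_r0", "pair_k", "pair_flat"):
            setattr(self, name, [v for v, kp in zip(getattr(self, name), keep) if kp])


def build_surface(
    extent_x: float,
    extent_y: float,
    n_per_side: int,
    plane_offset: float = 0.0,
    r_min: float = 5.0,
    epsilon: float = -1.0,
    mode: str = ATTRACTIVE,
) -> SurfaceField:
    """Rectangular grid of ``n_per_side**2`` fixed dummy beads.

    Beads are evenly spaced with the outer rows on the rectangle boundary
    (spacing ``extent / (n_per_side - 1)``), centred on the origin, at
    ``z = plane_offset``.
    """
    if extent_x <= 0 or extent_y <= 0:
        raise ValueError("extents must be positive")
    if n_per_side < 2:
        raise ValueError("need at least 2 beads per side")
    xs = np.linspace(-extent_x / 2.0, extent_x / 2.0, n_per_side)
    ys = np.linspace(-extent_y / 2.0, extent_y / 2.0, n_per_side)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pos = np.column_stack([gx.ravel(), gy.ravel(), np.full(gx.size, float(plane_offset))])
    return SurfaceField(pos, r_min=r_min, epsilon=epsilon, mode=mode)


# --------------------------------------------------------------------------
# System assembly


class CGSystem:
    """Precomputed force-field topology for one or more stacked segments.

    Segments are molecules sharing one coordinate array (concatenated in
    order); bonded terms never cross segment boundaries, nonbonded terms
    act between CA/SC beads of residue pairs that are non-local in the
    covalent structure.  ``interacting_segments`` optionally restricts
    which segment pairs contribute nonbonded terms (used to keep docking
    against tall stacks cheap).
    """

    def __init__(self, segments, params: CGParams, interacting_segments=None):
        if isinstance(segments, Molecule):
            segments = [segments]
        self.segments = list(segments)
        self.params = params
        self.offsets = np.cumsum([0] + [m.n_atoms for m in self.segments])
        self.n_atoms = int(self.offsets[-1])
        self._build_bonded()
        self._build_nonbonded(interacting_segments)

    # -- topology ----------------------------------------------------------

    def _build_bonded(self):
        bi, bj, br0 = [], [], []
        ai, aj, ak, at0 = [], [], [], []
        si, sj = [], []
        for seg_idx, mol in enumerate(self.segments):
            off = self.offsets[seg_idx]

            def idx(c, r, n):
                return off + mol.atom_index(c, r, n)

            for chain in mol.chains:
                resids = [int(r) for r in mol.chain_resids(chain)]
                for r in resids:
                    for a, b in (("N", "CA"), ("CA", "C"), ("C", "O"), ("CA", "SC")):
                        if mol.has_atom(chain, r, a) and mol.has_atom(chain, r, b):
                            bi.append(idx(chain, r, a))
                            bj.append(idx(chain, r, b))
                            br0.append(BOND_LENGTHS[(a, b)])
                for r1, r2 in zip(resids[:-1], resids[1:]):
                    if r2 != r1 + 1:
                        continue
                    if mol.has_atom(chain, r1, "C") and mol.has_atom(chain, r2, "N"):
                        bi.append(idx(chain, r1, "C"))
                        bj.append(idx(chain, r2, "N"))
                        br0.append(BOND_LENGTHS[("C", "N")])
                    # backbone angles spanning the peptide bond
                    if all(
                        mol.has_atom(chain, r, n)
                        for r, n in ((r1, "CA"), (r1, "C"), (r2, "N"), (r2, "CA"))
                    ):
                        ai.append(idx(chain, r1, "CA"))
                        aj.append(idx(chain, r1, "C"))
                        ak.append(idx(chain, r2, "N"))
                        at0.append(ANGLE_THETA0["CA-C-N"])
                        ai.append(idx(chain, r1, "C"))
                        aj.append(idx(chain, r2, "N"))
                        ak.append(idx(chain, r2, "CA"))
                        at0.append(ANGLE_THETA0["C-N-CA"])
                for r in resids:
                    if all(mol.has_atom(chain, r, n) for n in ("N", "CA", "C")):
                        ai.append(idx(chain, r, "N"))
                        aj.append(idx(chain, r, "CA"))
                        ak.append(idx(chain, r, "C"))
                        at0.append(ANGLE_THETA0["N-CA-C"])
            for (c1, r1), (c2, r2) in mol.disulfides:
                if mol.has_atom(c1, r1, "SC") and mol.has_atom(c2, r2, "SC"):
                    si.append(idx(c1, r1, "SC"))
                    sj.append(idx(c2, r2, "SC"))
        self.bond_i = np.array(bi, dtype=int)
        self.bond_j = np.array(bj, dtype=int)
        self.bond_r0 = np.array(br0, dtype=float)
        self.ang_i = np.array(ai, dtype=int)
        self.ang_j = np.array(aj, dtype=int)
        self.ang_k = np.array(ak, dtype=int)
        self.ang_t0 = np.radians(np.array(at0, dtype=float))
        self.ss_i = np.array(si, dtype=int)
        self.ss_j = np.array(sj, dtype=int)

    def _build_nonbonded(self, interacting_segments):
        p = self.params
        # Per-segment CA/SC bead tables: (global index, residue ordinal, sigma)
        seg_beads = []
        res_offset = 0
        for seg_idx, mol in enumerate(self.segments):
            off = self.offsets[seg_idx]
            keys = mol.residue_keys()
            ordinal = {key: res_offset + n for n, key in enumerate(keys)}
            chain_ord = {c: n for n, c in enumerate(mol.chains)}
            rows = []
            ss_pairs = set()
            for b in mol.disulfides:
                ss_pairs.add((ordinal[b[0]], ordinal[b[1]]))
                ss_pairs.add((ordinal[b[1]], ordinal[b[0]]))
            for i in range(mol.n_atoms):
                name = mol.names[i]
                if name == "CA":
                    sig = p.sigma_ca
                elif name == "SC":
                    sig = p.sigma_sc
                elif p.ev_all_beads and name in ("N", "C", "O"):
                    sig = p.sigma_backbone
                else:
                    continue
                key = (str(mol.chain_ids[i]), int(mol.res_ids[i]))
                rows.append(
                    (off + i, ordinal[key], chain_ord[key[0]], sig, name == "SC")
                )
            seg_beads.append((rows, ss_pairs))
            res_offset += len(keys)

        pi, pj, sig = [], [], []
        n_seg = len(self.segments)
        if interacting_segments is None:
            pairs = [(a, b) for a in range(n_seg) for b in range(a, n_seg)]
        else:
            pairs = [tuple(sorted(t)) for t in interacting_segments]
        for sa, sb in pairs:
            rows_a, ss_a = seg_beads[sa]
            rows_b, _ = seg_beads[sb]
            same = sa == sb
            for x, row_a in enumerate(rows_a):
                ia, orda, ca, siga, sca = row_a
                start = x + 1 if same else 0
                for row_b in rows_b[start:]:
                    ib, ordb, cb, sigb, scb = row_b
                    if same:
                        if ca == cb and abs(orda - ordb) < 2:
                            continue
                        if orda == ordb:
                            continue
                        if sca and scb and (orda, ordb) in ss_a:
                            continue
                    pi.append(ia)
                    pj.append(ib)
                    sig.append(0.5 * (siga + sigb))
        self.nb_i = np.array(pi, dtype=int)
        self.nb_j = np.array(pj, dtype=int)
        self.nb_sigma = np.array(sig, dtype=float)

    # -- energy / forces ---------------------------------------------------

    def neighbor_subset(self, coords, skin: float = 2.0) -> np.ndarray:
        """Indices of nonbonded pairs within cutoff + skin (Verlet list)."""
        reach = max(self.params.cutoff, self.nb_sigma.max() if len(self.nb_sigma) else 0.0) + skin
        d = coords[self.nb_i] - coords[self.nb_j]
        return np.flatnonzero((d**2).sum(axis=1) < reach**2)

    def energy_forces(self, coords, fields=(), restraints=None, nb_subset=None):
        """Potential energy breakdown and per-atom forces.

        Returns ``(breakdown: dict, forces: (n,3) array)``; the breakdown
        keys sum to the total potential energy.  ``nb_subset`` optionally
        restricts the nonbonded terms to a precomputed neighbour list.
        """
        p = self.params
        f = np.zeros_like(coords)
        br = {}

        # bonds (includes disulfides separately)
        def _springs(i_arr, j_arr, r0, k):
            if len(i_arr) == 0:
                return 0.0
            d = coords[i_arr] - coords[j_arr]
            r = np.linalg.norm(d, axis=1)
            dr = r - r0
            e = float(k * np.sum(dr**2))
            fmag = (-2.0 * k * dr / np.maximum(r, 1e-12))[:, None] * d
            np.add.at(f, i_arr, fmag)
            np.add.at(f, j_arr, -fmag)
            return e

        br["bond"] = _springs(self.bond_i, self.bond_j, self.bond_r0, p.bond_k)
        br["disulfide"] = _springs(self.ss_i, self.ss_j, p.ss_r0, p.ss_k)
        br["angle"] = self._angle_term(coords, f)
        br["excluded_volume"], br["attraction"] = self._nonbonded(coords, f, nb_subset)
        br["surface"] = 0.0
        for fld in fields if isinstance(fields, (list, tuple)) else [fields]:
            if fld is not None:
                br["surface"] += surface_energy_forces(coords, fld, f)
        if restraints is not None:
            br["restraint"] = self._restraint_term(coords, f, restraints)
        return br, f

    def _angle_term(self, coords, f):
        if len(self.ang_i) == 0:
            return 0.0
        k = self.params.angle_k
        a = coords[self.ang_i]
        b = coords[self.ang_j]
        c = coords[self.ang_k]
        u = a - b
        v = c - b
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        cos_t = np.clip((u * v).sum(axis=1) / (nu * nv), -1 + 1e-10, 1 - 1e-10)
        theta = np.arccos(cos_t)
        dt = theta - self.ang_t0
        e = float(k * np.sum(dt**2))
        # dE/dtheta = 2k dt; gradient of theta wrt endpoints
        sin_t = np.sqrt(1.0 - cos_t**2)
        coef = 2.0 * k * dt / sin_t
        du = (v / (nu * nv)[:, None]) - (cos_t / nu**2)[:, None] * u
        dv = (u / (nu * nv)[:, None]) - (cos_t / nv**2)[:, None] * v
        fa = coef[:, None] * du
        fc = coef[:, None] * dv
        np.add.at(f, self.ang_i, fa)
        np.add.at(f, self.ang_k, fc)
        np.add.at(f, self.ang_j, -(fa + fc))
        return e

    def _nonbonded(self, coords, f, nb_subset=None):
        if len(self.nb_i) == 0:
            return 0.0, 0.0
        p = self.params
        if nb_subset is None:
            nb_i, nb_j, nb_sigma = self.nb_i, self.nb_j, self.nb_sigma
        else:
            nb_i = self.nb_i[nb_subset]
            nb_j = self.nb_j[nb_subset]
            nb_sigma = self.nb_sigma[nb_subset]
        d = coords[nb_i] - coords[nb_j]
        r2 = (d**2).sum(axis=1)
        r = np.sqrt(r2)

        # excluded volume: WCA-style repulsion below per-pair sigma
        e_ev = 0.0
        mask = r < nb_sigma
        if mask.any():
            rr = r[mask]
            ss = nb_sigma[mask]
            x6 = (ss / rr) ** 6
            e_terms = p.ev_epsilon * (x6**2 - 2.0 * x6 + 1.0)
            e_ev = float(e_terms.sum())
            dEdr = p.ev_epsilon * (-12.0 * x6**2 + 12.0 * x6) / rr
            fmag = (-dEdr / rr)[:, None] * d[mask]
            np.add.at(f, nb_i[mask], fmag)
            np.add.at(f, nb_j[mask], -fmag)

        # flat-bottom attraction with a smooth switch-off before the cutoff
        e_at = 0.0
        eps = p.attr_epsilon
        if eps > 0:
            rmin, rc, rs = p.attr_rmin, p.cutoff, p.switch_start
            inside = r < rmin
            e_at += -eps * float(np.count_nonzero(inside))
            tail = (~inside) & (r < rc)
            if tail.any():
                rr = r[tail]
                x6 = (rmin / rr) ** 6
                lj = eps * (x6**2 - 2.0 * x6)
                dlj = eps * (-12.0 * x6**2 + 12.0 * x6) / rr
                t = np.clip((rr - rs) / max(rc - rs, 1e-9), 0.0, 1.0)
                s = 1.0 - (10.0 * t**3 - 15.0 * t**4 + 6.0 * t**5)
                ds = -(30.0 * t**2 - 60.0 * t**3 + 30.0 * t**4) / max(rc - rs, 1e-9)
                e_at += float((lj * s).sum())
                dEdr = dlj * s + lj * ds
                fmag = (-dEdr / rr)[:, None] * d[tail]
                np.add.at(f, nb_i[tail], fmag)
                np.add.at(f, nb_j[tail], -fmag)
        return e_ev, e_at

    def _restraint_term(self, coords, f, rst: Restraints):
        e = 0.0
        if rst.pair_i:
            i_arr = np.asarray(rst.pair_i)
            j_arr = np.asarray(rst.pair_j)
            r0 = np.asarray(rst.pair_r0)
            kk = np.asarray(rst.pair_k)
            flat = np.asarray(rst.pair_flat)
            d = coords[i_arr] - coords[j_arr]
            r = np.linalg.norm(d, axis=1)
            dr = r - r0
            active = np.where(flat, dr > 0, True)
            dr = np.where(active, dr, 0.0)
            e += float((kk * dr**2).sum())
            fmag = (-2.0 * kk * dr / np.maximum(r, 1e-12))[:, None] * d
            np.add.at(f, i_arr, fmag)
            np.add.at(f, j_arr, -fmag)
        if rst.tether_i:
            i_arr = np.asarray(rst.tether_i)
            xyz = np.asarray(rst.tether_xyz)
            kk = np.asarray(rst.tether_k)
            d = coords[i_arr] - xyz
            e += float((kk * (d**2).sum(axis=1)).sum())
            f[i_arr] += -2.0 * kk[:, None] * d
        if rst.dihe_quads:
            from ._geometry import dihedrals

            quads = np.asarray(rst.dihe_quads)
            target = np.asarray(rst.dihe_target)
            kk = np.asarray(rst.dihe_k)
            pi_, pj_, pk_, pl_ = (coords[quads[:, n]] for n in range(4))
            cur = dihedrals(pi_, pj_, pk_, pl_)
            delta = np.radians((cur - target + 180.0) % 360.0 - 180.0)
            e += float((kk * delta**2).sum())
            # analytic torsion gradient (standard n1/n2 formulation)
            b1 = pj_ - pi_
            b2 = pk_ - pj_
            b3 = pl_ - pk_
            n1 = np.cross(b1, b2)
            n2 = np.cross(b2, b3)
            n1sq = (n1**2).sum(axis=1)
            n2sq = (n2**2).sum(axis=1)
            b2len = np.linalg.norm(b2, axis=1)
            ok = (n1sq > 1e-12) & (n2sq > 1e-12)
            dphi_di = np.zeros_like(b1)
            dphi_dl = np.zeros_like(b1)
            dphi_di[ok] = -(b2len[ok] / n1sq[ok])[:, None] * n1[ok]
            dphi_dl[ok] = (b2len[ok] / n2sq[ok])[:, None] * n2[ok]
            s12 = ((b1 * b2).sum(axis=1) / np.maximum(b2len**2, 1e-12))[:, None]
            s32 = ((b3 * b2).sum(axis=1) / np.maximum(b2len**2, 1e-12))[:, None]
            dphi_dj = -(1.0 + s12) * dphi_di + s32 * dphi_dl
            dphi_dk = s12 * dphi_di - (1.0 + s32) * dphi_dl
            dEdphi = (2.0 * kk * delta)[:, None]
            np.add.at(f, quads[:, 0], -dEdphi * dphi_di)
            np.add.at(f, quads[:, 1], -dEdphi * dphi_dj)
            np.add.at(f, quads[:, 2], -dEdphi * dphi_dk)
            np.add.at(f, quads[:, 3], -dEdphi * dphi_dl)
        return e


def surface_energy_forces(coords, fld: SurfaceField, f=None) -> float:
    """Surface interaction energy (and accumulated forces, if *f* given).

    Attractive mode: ``eps * ((rmin/r)^12 - 2 (rmin/r)^6)`` for
    ``r >= rmin``, clamped at ``eps`` below; repulsive mode is the
    mirror-image split (zero beyond rmin).  Summed over all bead-atom
    pairs within the field cutoff.
    """
    pos = fld.bead_positions
    d = coords[:, None, :] - pos[None, :, :]
    r = np.sqrt((d**2).sum(axis=2))
    eps = fld.epsilon
    rmin = fld.r_min
    e = 0.0
    if fld.mode == ATTRACTIVE:
        inside = r < rmin
        e += eps * float(np.count_nonzero(inside))
        tail = (~inside) & (r < fld.cutoff)
        if tail.any():
            mag = abs(eps)
            rr = r[tail]
            x6 = (rmin / rr) ** 6
            e += float((mag * (x6**2 - 2.0 * x6)).sum())
            if f is not None:
                dEdr = mag * (-12.0 * x6**2 + 12.0 * x6) / rr
                fmag = np.zeros_like(r)
                fmag[tail] = -dEdr / rr
                f += (fmag[:, :, None] * d).sum(axis=1)
    else:
        mask = r < rmin
        if mask.any():
            rr = r[mask]
            x6 = (rmin / rr) ** 6
            mag = abs(eps)
            e += float((mag * (x6**2 - 2.0 * x6 + 1.0)).sum())
            if f is not None:
                dEdr = mag * (-12.0 * x6**2 + 12.0 * x6) / rr
                fmag = np.zeros_like(r)
                fmag[mask] = -dEdr / rr
                f += (fmag[:, :, None] * d).sum(axis=1)
    return e


def surface_energy(molecule: Molecule, fld: SurfaceField) -> float:
    """Surface interaction energy of a molecule in kcal/mol."""
    return surface_energy_forces(molecule.coords, fld, None)


def total_energy(molecule, fld=None, params: CGParams | None = None, restraints=None):
    """Total CG potential energy with a per-term breakdown.

    Returns ``(total, breakdown)``; the breakdown values sum to the
    total to floating-point accuracy.
    """
    params = params or CGParams()
    system = CGSystem(molecule, params)
    fields = [] if fld is None else [fld]
    br, _ = system.energy_forces(molecule.coords, fields, restraints)
    return sum(br.values()), br


def minimize_structure(
    system: "CGSystem",
    coords: np.ndarray,
    fields=(),
    restraints: Restraints | None = None,
    fixed_mask=None,
    maxiter: int = 500,
) -> np.ndarray:
    """Quasi-Newton (L-BFGS) relaxation to a local potential minimum.

    Deterministic; used wherever a converged settle matters (plate
    relaxation, fixture clean-up).  Fixed atoms are pinned.
    """
    from scipy.optimize import minimize as _sp_minimize

    x0 = coords.copy()
    shape = x0.shape

    def fun(flat):
        x = flat.reshape(shape)
        if fixed_mask is not None:
            x = x.copy()
            x[fixed_mask] = x0[fixed_mask]
        br, f = system.energy_forces(x, fields, restraints)
        g = -f
        if fixed_mask is not None:
            g[fixed_mask] = 0.0
        return sum(br.values()), g.ravel()

    res = _sp_minimize(
        fun, x0.ravel(), jac=True, method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-6},
    )
    out = res.x.reshape(shape)
    if fixed_mask is not None:
        out[fixed_mask] = x0[fixed_mask]
    return out


@dataclass
class Trajectory:
    """Recorded frames of a Langevin run."""

    frames: np.ndarray  # (n_frames, n_atoms, 3)
    times: np.ndarray  # fs
    energies: list  # per-frame breakdown dicts

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def langevin_run(
    system_or_molecule,
    fields,
    params: CGParams,
    n_steps: int,
    seed: int,
    restraints: Restraints | None = None,
    fixed_mask=None,
    stride: int = 50,
    coords: np.ndarray | None = None,
    release_rule=None,
) -> tuple[np.ndarray, Trajectory]:
    """BAOAB Langevin dynamics; the seed controls only the noise stream.

    ``release_rule``, if given, is called every 25 steps with the current
    coordinates and the restraints object and may drop satisfied pull
    restraints (the stacker's per-pair release).  Returns the final
    coordinates and the recorded trajectory.
    """
    if isinstance(system_or_molecule, Molecule):
        system = CGSystem(system_or_molecule, params)
        x = system_or_molecule.coords.copy() if coords is None else coords.copy()
    else:
        system = system_or_molecule
        if coords is None:
            raise ValueError("coords required when passing a CGSystem")
        x = coords.copy()
    rng = np.random.default_rng(seed)
    dt = params.timestep
    gamma = params.friction
    m = params.mass
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(max(KB * params.temperature * ACC_CONV / m, 0.0) * (1.0 - c1**2))
    v = np.zeros_like(x)
    if fixed_mask is None:
        fixed_mask = np.zeros(len(x), dtype=bool)
    mobile = ~fixed_mask
    frames, times, energies = [], [], []

    def _clip(forces):
        if params.max_force is not None:
            norms = np.linalg.norm(forces, axis=1)
            over = norms > params.max_force
            if over.any():
                forces[over] *= (params.max_force / norms[over])[:, None]
        return forces

    nb_subset = system.neighbor_subset(x)
    br, f = system.energy_forces(x, fields, restraints, nb_subset)
    f = _clip(f)
    for step in range(n_steps):
        v[mobile] += 0.5 * dt * f[mobile] * ACC_CONV / m
        x[mobile] += 0.5 * dt * v[mobile]
        noise = rng.standard_normal(x.shape)
        v[mobile] = c1 * v[mobile] + c2 * noise[mobile]
        x[mobile] += 0.5 * dt * v[mobile]
        if release_rule is not None and (step + 1) % 25 == 0:
            release_rule(x, restraints)
        if (step + 1) % 20 == 0:
            nb_subset = system.neighbor_subset(x)
        br, f = system.energy_forces(x, fields, restraints, nb_subset)
        f = _clip(f)
        v[mobile] += 0.5 * dt * f[mobile] * ACC_CONV / m
        if (step + 1) % stride == 0 or step == n_steps - 1:
            if np.max(np.abs(x)) > 1e4 or not np.all(np.isfinite(x)):
                raise DivergenceError(f"coordinates diverged at step {step + 1}")
            frames.append(x.copy())
            times.append((step + 1) * dt)
            energies.append(dict(br))
    if np.max(np.abs(x)) > 1e4 or not np.all(np.isfinite(x)):
        raise DivergenceError("coordinates diverged")
    traj = Trajectory(np.array(frames), np.array(times), energies)
    return x, traj
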