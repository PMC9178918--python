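"""Discrete quasi-2D topology taxonomy of planarized conformers.

A two-chain molecule whose chains are cross-linked by (at least) two
interchain disulfide bonds contains a *central topological loop*: the
closed cycle formed by the mid-sections of both chains plus the two
interchain disulfides.  After planarization, each free terminal segment
either lies inside or outside the projected loop polygon; the resulting
in/out bit pattern is the conformer's discrete 2D topology class.  For
an insulin-like molecule with four free termini there are 2**4 = 16
conceivable classes, of which six (FC1...FC6, ordered by decreasing
abundance in the planarization ensemble) carry canonical names.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import networkx as nx

from ._geometry import best_fit_plane
from .structure import Molecule, covalent_graph

IN = "in"
OUT = "out"

#: Canonical class catalog: label -> in/out flags in terminus order
#: (A-N, A-C, B-N, B-C) for a two-chain insulin-like molecule.
FC_CATALOG: dict[str, tuple[str, str, str, str]] = {
    "FC1": (IN, OUT, OUT, OUT),
    "FC2": (IN, IN, OUT, OUT),
    "FC3": (OUT, OUT, OUT, OUT),
    "FC4": (OUT, IN, OUT, OUT),
    "FC5": (IN, OUT, IN, OUT),
    "FC6": (OUT, IN, IN, OUT),
}

#: Inward-directed termini per named class (derived from the catalog).
FC_INWARD: dict[str, tuple[str, ...]] = {
    label: tuple(
        t for t, fl in zip(("A-N", "A-C", "B-N", "B-C"), flags) if fl == IN
    )
    for label, flags in FC_CATALOG.items()
}


class NoCentralLoopError(ValueError):
    """Molecule has fewer than two interchain disulfides."""


class AmbiguousClassificationError(ValueError):
    """A terminal residue projects onto the loop boundary within tolerance."""


@dataclass
class CentralLoop:
    """The closed residue cycle defining the in/out reference polygon."""

    residues: list  # ordered (chain, resid) cycle
    disulfides: list  # the two closing interchain disulfide bonds

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def polygon(self, molecule: Molecule, plane=None) -> np.ndarray:
        """Projected CA polygon (n, 2) of the cycle residues, in order."""
        _, axes = _projection_axes(molecule, plane)
        pts = np.array(
            [molecule.coords[molecule.atom_index(c, r, "CA")] for c, r in self.residues]
        )
        return pts @ axes.T


@dataclass
class TopologyClass:
    """In/out flag per free terminal segment, plus the FC label if named."""

    termini: tuple  # e.g. ("A-N", "A-C", "B-N", "B-C")
    flags: tuple  # matching tuple of "in"/"out"

    @property
    def label(self) -> str:
        return name_class(self)

    def inside(self) -> tuple:
        return tuple(t for t, fl in zip(self.termini, self.flags) if fl == IN)


# --------------------------------------------------------------------------


def find_central_loop(molecule: Molecule) -> CentralLoop:
    """Locate the central topological loop of a two-chain molecule.

    The loop is the cycle running through both chains' mid-sections and
    closed by two interchain disulfides; when more than two interchain
    disulfides exist, the candidate cycle enclosing the most residues is
    chosen.
    """
    inter = molecule.interchain_disulfides()
    if len(inter) < 2:
        raise NoCentralLoopError(
            f"need >= 2 interchain disulfides to form a central loop, found {len(inter)}"
        )
    best = None
    for b1, b2 in itertools.combinations(inter, 2):
        chains1 = frozenset(end[0] for end in b1)
        chains2 = frozenset(end[0] for end in b2)
        if chains1 != chains2 or len(chains1) != 2:
            continue
        ca, cb = sorted(chains1)
        a1 = next(r for c, r in b1 if c == ca)
        a2 = next(r for c, r in b2 if c == ca)
        bb1 = next(r for c, r in b1 if c == cb)
        bb2 = next(r for c, r in b2 if c == cb)
        if a1 == a2 or bb1 == bb2:
            continue
        n = abs(a2 - a1) + 1 + abs(bb2 - bb1) + 1
        key = (n, -min(a1, a2))
        if best is None or key > best[0]:
            best = (key, (ca, a1, a2, cb, bb1, bb2, b1, b2))
    if best is None:
        raise NoCentralLoopError("no cycle through two chains could be closed")
    ca, a1, a2, cb, bb1, bb2, b1, b2 = best[1]
    step_a = 1 if a2 >= a1 else -1
    step_b = 1 if bb1 >= bb2 else -1
    # traverse chain A from bond-1 end to bond-2 end, cross to chain B via
    # bond 2, walk back to bond-1's B end, and close through bond 1
    cycle = [(ca, r) for r in range(a1, a2 + step_a, step_a)]
    cycle += [(cb, r) for r in range(bb2, bb1 + step_b, step_b)]
    return CentralLoop(residues=cycle, disulfides=[b1, b2])


def _projection_axes(molecule: Molecule, plane=None):
    """Orthonormal in-plane axes (2, 3) of the conformer's best-fit plane."""
    if plane is None:
        _, normal = best_fit_plane(molecule.ca_coords())
    else:
        _, normal = plane
        normal = np.asarray(normal, dtype=float)
        normal = normal / np.linalg.norm(normal)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, normal)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - np.dot(ref, normal) * normal
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    return normal, np.vstack([e1, e2])


def point_in_polygon(point: np.ndarray, polygon: np.ndarray) -> bool:
    """Even-odd (ray casting) point-in-polygon test in 2D."""
    x, y = float(point[0]), float(point[1])
    px = polygon[:, 0]
    py = polygon[:, 1]
    qx = np.roll(px, -1)
    qy = np.roll(py, -1)
    crosses = ((py > y) != (qy > y)) & (
        x < px + (y - py) * (qx - px) / np.where(qy == py, np.inf, qy - py)
    )
    return bool(np.count_nonzero(crosses) % 2 == 1)


def distance_to_polygon(point: np.ndarray, polygon: np.ndarray) -> float:
    """Minimum distance from a 2D point to the polygon boundary."""
    p = np.asarray(point, dtype=float)
    a = polygon
    b = np.roll(polygon, -1, axis=0)
    ab = b - a
    denom = np.maximum((ab**2).sum(axis=1), 1e-300)
    t = np.clip(((p - a) * ab).sum(axis=1) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return float(np.sqrt(((proj - p) ** 2).sum(axis=1)).min())


def free_terminal_segments(molecule: Molecule, loop: CentralLoop):
    """Free terminal segments as (name, [residue keys]) in canonical order.

    Order is chain file order, N-segment then C-segment; chain letters in
    names follow file order (first chain = "A").
    """
    loop_set = set(loop.residues)
    out = []
    for chain_label, chain in zip("ABCDEFGH", molecule.chains):
        resids = [int(r) for r in molecule.chain_resids(chain)]
        in_loop = [r for c, r in loop.residues if c == chain]
        if not in_loop:
            continue
        lo, hi = min(in_loop), max(in_loop)
        n_seg = [(chain, r) for r in resids if r < lo]
        c_seg = [(chain, r) for r in resids if r > hi]
        if n_seg:
            out.append((f"{chain_label}-N", n_seg))
        if c_seg:
            out.append((f"{chain_label}-C", c_seg))
    return out


EDGE_TOLERANCE = 0.5  # Å in projection


def classify(conformer, edge_tolerance: float = EDGE_TOLERANCE) -> TopologyClass:
    """Assign the discrete 2D topology class of a planarized conformer.

    Accepts a :class:`~quasi2d.planarize.PlanarConformer` or a bare
    :class:`Molecule`.  Each free terminal segment is flagged "in" if its
    terminal residue's projected CA lies inside the projected central
    loop polygon (even-odd rule).  The result is invariant under rigid
    motion, mirroring and uniform scaling; a terminal residue landing
    within *edge_tolerance* of the polygon boundary raises
    :class:`AmbiguousClassificationError` rather than guessing.
    """
    molecule = getattr(conformer, "molecule", conformer)
    plane = getattr(conformer, "plane", None)
    loop = find_central_loop(molecule)
    _, axes = _projection_axes(molecule, plane)
    polygon = np.array(
        [molecule.coords[molecule.atom_index(c, r, "CA")] for c, r in loop.residues]
    ) @ axes.T
    termini, flags = [], []
    for name, seg in free_terminal_segments(molecule, loop):
        # terminal residue = the chain end (first residue of an N-segment,
        # last residue of a C-segment)
        key = seg[0] if name.endswith("-N") else seg[-1]
        pt = molecule.coords[molecule.atom_index(key[0], key[1], "CA")] @ axes.T
        if distance_to_polygon(pt, polygon) < edge_tolerance:
            raise AmbiguousClassificationError(
                f"terminal residue {key} projects within {edge_tolerance} Å of the loop boundary"
            )
        termini.append(name)
        flags.append(IN if point_in_polygon(pt, polygon) else OUT)
    return TopologyClass(termini=tuple(termini), flags=tuple(flags))


def enumerate_classes(n_free_termini: int) -> list[tuple]:
    """All conceivable in/out flag patterns for n free termini (2**n)."""
    if n_free_termini < 0:
        raise ValueError("n_free_termini must be >= 0")
    return list(itertools.product((IN, OUT), repeat=n_free_termini))


def name_class(topology_class: TopologyClass | tuple) -> str:
    """Map a 4-terminus flag pattern to its FC label, or "unnamed"."""
    flags = tuple(getattr(topology_class, "flags", topology_class))
    if len(flags) != 4:
        raise ValueError(f"expected 4 terminus flags, got {len(flags)}")
    for label, pattern in FC_CATALOG.items():
        if flags == pattern:
            return label
    return "unnamed"


def marginal_inside_percentage(abundances: dict[str, float], terminus: str) -> float:
    """Summed abundance of classes placing *terminus* inside the loop.

    ``abundances`` maps FC labels to ensemble percentages; e.g. the
    A-chain N-terminus marginal over {FC1: 68, FC2: 16, FC5: 2} is 86.
    """
    total = 0.0
    for label, pct in abundances.items():
        if label in FC_INWARD and terminus in FC_INWARD[label]:
            total += pct
    return total
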