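"""Structure representation, covalent connectivity and PDB I/O.

The central object is :class:`Molecule`: a coarse-grained protein built
from up to five beads per residue (backbone N, CA, C, O plus one
side-chain centroid bead named ``SC``; for cysteines the ``SC`` bead
carries the sulfur position and element ``S``).  Disulfide bonds are
first-class annotations because the covalent (residue-level) graph they
induce defines the topological machinery of the rest of the pipeline.

PDB files are parsed and rendered with biotite; SSBOND records and
multi-MODEL layer handling are managed here.  Multi-layer protofilament
models are serialised as one MODEL record per layer, in stacking order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import networkx as nx
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

logger = logging.getLogger(__name__)

BACKBONE_BEADS = ("N", "CA", "C", "O")
SIDECHAIN_BEAD = "SC"
WATER_RESNAME = "HOH"

# 62 usable one-character PDB chain identifiers.
_CHAIN_ID_SPACE = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)


@dataclass(frozen=True)
class Atom:
    """A single coarse-grained bead."""

    name: str
    element: str
    coords: np.ndarray
    chain_id: str
    residue_index: int
    residue_name: str
    is_water: bool = False


DisulfideBond = tuple[tuple[str, int], tuple[str, int]]


def _normalize_bond(bond) -> DisulfideBond:
    (c1, r1), (c2, r2) = bond
    a, b = sorted([(str(c1), int(r1)), (str(c2), int(r2))])
    return (a, b)


class Molecule:
    """A coarse-grained molecule: parallel per-atom arrays plus disulfides.

    Parameters
    ----------
    names, elements, coords, chain_ids, res_ids, res_names
        Parallel per-atom annotation arrays.  ``res_ids`` are 1-based per
        chain.
    disulfides
        Pairs of ``(chain_id, residue_index)`` tuples; both partners must
        be cysteine residues present in the molecule.
    water_coords
        Optional ``(n, 3)`` array of water oxygen positions, kept separate
        from the protein beads.
    """

    def __init__(
        self,
        names,
        elements,
        coords,
        chain_ids,
        res_ids,
        res_names,
        disulfides=(),
        water_coords=None,
    ):
        self.names = np.asarray(names, dtype="U4")
        self.elements = np.asarray(elements, dtype="U2")
        self.coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        self.chain_ids = np.asarray(chain_ids, dtype="U4")
        self.res_ids = np.asarray(res_ids, dtype=int)
        self.res_names = np.asarray(res_names, dtype="U4")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if np.any(self.res_ids < 1):
            raise ValueError("residue indices must be 1-based")
        self.water_coords = (
            np.empty((0, 3)) if water_coords is None else np.asarray(water_coords, dtype=float).reshape(-1, 3)
        )
        self.disulfides: list[DisulfideBond] = sorted(
            {_normalize_bond(b) for b in disulfides}
        )
        self._index: dict[tuple[str, int, str], int] = {
            (c, int(r), n): i
            for i, (c, r, n) in enumerate(zip(self.chain_ids, self.res_ids, self.names))
        }
        for (c1, r1), (c2, r2) in self.disulfides:
            for c, r in ((c1, r1), (c2, r2)):
                if (c, r, "CA") not in self._index:
                    raise ValueError(f"disulfide endpoint {(c, r)} not in molecule")

    # ------------------------------------------------------------------ views

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(str(c))
        return list(seen)

    def chain_resids(self, chain: str) -> np.ndarray:
        return np.unique(self.res_ids[self.chain_ids == chain])

    def residue_keys(self) -> list[tuple[str, int]]:
        """Ordered (chain, residue_index) keys, chain file order then index."""
        return [(c, int(r)) for c in self.chains for r in self.chain_resids(c)]

    @property
    def n_residues(self) -> int:
        return len(self.residue_keys())

    def atom_index(self, chain: str, res_id: int, name: str) -> int:
        return self._index[(chain, int(res_id), name)]

    def has_atom(self, chain: str, res_id: int, name: str) -> bool:
        return (chain, int(res_id), name) in self._index

    def bead_indices(self, names=("CA",)) -> np.ndarray:
        return np.flatnonzero(np.isin(self.names, names))

    def ca_indices(self) -> np.ndarray:
        """CA bead indices in residue order."""
        return np.array([self.atom_index(c, r, "CA") for c, r in self.residue_keys()])

    def ca_coords(self) -> np.ndarray:
        return self.coords[self.ca_indices()]

    def atom(self, i: int) -> Atom:
        return Atom(
            name=str(self.names[i]),
            element=str(self.elements[i]),
            coords=self.coords[i].copy(),
            chain_id=str(self.chain_ids[i]),
            residue_index=int(self.res_ids[i]),
            residue_name=str(self.res_names[i]),
        )

    # ------------------------------------------------------------- operations

    def copy(self) -> "Molecule":
        return Molecule(
            self.names.copy(),
            self.elements.copy(),
            self.coords.copy(),
            self.chain_ids.copy(),
            self.res_ids.copy(),
            self.res_names.copy(),
            list(self.disulfides),
            self.water_coords.copy(),
        )

    def transformed(self, rotation=None, translation=None) -> "Molecule":
        out = self.copy()
        if rotation is not None:
            center = out.coords.mean(axis=0)
            out.coords = (out.coords - center) @ np.asarray(rotation).T + center
            if len(out.water_coords):
                out.water_coords = (out.water_coords - center) @ np.asarray(rotation).T + center
        if translation is not None:
            out.coords = out.coords + np.asarray(translation)
            if len(out.water_coords):
                out.water_coords = out.water_coords + np.asarray(translation)
        return out

    def interchain_disulfides(self) -> list[DisulfideBond]:
        return [b for b in self.disulfides if b[0][0] != b[1][0]]


# ------------------------------------------------------------------ graph


def covalent_graph(molecule: Molecule) -> nx.Graph:
    """Residue-level covalent graph: backbone successions plus disulfides.

    Nodes are ``(chain_id, residue_index)``; consecutive residue indices
    within a chain are joined, plus one edge per disulfide bond (edge
    attribute ``kind`` is ``"backbone"`` or ``"disulfide"``).
    """
    g = nx.Graph()
    for chain in molecule.chains:
        resids = molecule.chain_resids(chain)
        for r in resids:
            g.add_node((chain, int(r)))
        for r1, r2 in zip(resids[:-1], resids[1:]):
            if r2 == r1 + 1:
                g.add_edge((chain, int(r1)), (chain, int(r2)), kind="backbone")
    for b in molecule.disulfides:
        g.add_edge(b[0], b[1], kind="disulfide")
    return g


# ------------------------------------------------------------------ PDB I/O

SS_DETECT_CUTOFF = 2.5  # Å, S-S distance for geometric disulfide detection


def _detect_disulfides_geometric(mol: Molecule) -> list[DisulfideBond]:
    s_idx = np.flatnonzero(mol.elements == "S")
    bonds = []
    for i in range(len(s_idx)):
        for j in range(i + 1, len(s_idx)):
            a, b = s_idx[i], s_idx[j]
            same_res = (
                mol.chain_ids[a] == mol.chain_ids[b] and mol.res_ids[a] == mol.res_ids[b]
            )
            if same_res:
                continue
            d = np.linalg.norm(mol.coords[a] - mol.coords[b])
            if d < SS_DETECT_CUTOFF:
                bonds.append(
                    (
                        (str(mol.chain_ids[a]), int(mol.res_ids[a])),
                        (str(mol.chain_ids[b]), int(mol.res_ids[b])),
                    )
                )
    return bonds


def _parse_ssbond_lines(lines) -> list[DisulfideBond]:
    bonds = []
    for line in lines:
        if line.startswith("SSBOND"):
            c1 = line[15].strip()
            r1 = int(line[17:21])
            c2 = line[29].strip()
            r2 = int(line[31:35])
            bonds.append(((c1, r1), (c2, r2)))
    return bonds


def _molecule_from_atom_array(arr, ssbonds) -> Molecule:
    is_water = arr.res_name == WATER_RESNAME
    prot = arr[~is_water]
    wat = arr[is_water]
    # Drop residues that lack a CA bead.
    keep = np.ones(prot.array_length(), dtype=bool)
    keys = list(zip(prot.chain_id, prot.res_id))
    has_ca = set(
        (c, r) for c, r, n in zip(prot.chain_id, prot.res_id, prot.atom_name) if n == "CA"
    )
    for i, key in enumerate(keys):
        if key not in has_ca:
            keep[i] = False
    dropped = {k for k, ok in zip(keys, keep) if not ok}
    if dropped:
        logger.warning("rejecting %d residue(s) without CA bead: %s", len(dropped), sorted(dropped))
        prot = prot[keep]
    if prot.array_length() == 0:
        raise ValueError("no protein residues with CA beads in file")
    mol = Molecule(
        prot.atom_name,
        prot.element,
        prot.coord,
        prot.chain_id,
        prot.res_id,
        prot.res_name,
        water_coords=wat.coord if wat.array_length() else None,
    )
    bonds = [
        b
        for b in (_normalize_bond(x) for x in ssbonds)
        if mol.has_atom(*b[0], "CA") and mol.has_atom(*b[1], "CA")
    ]
    if not bonds:
        bonds = _detect_disulfides_geometric(mol)
    mol.disulfides = sorted({_normalize_bond(b) for b in bonds})
    return mol


def read_pdb(path) -> Molecule:
    """Read a single-model PDB file into a :class:`Molecule`.

    Disulfides are taken from SSBOND records when present, else detected
    geometrically (S–S distance below 2.5 Å).  Waters (residue name HOH)
    are flagged and retained separately from the protein beads.
    """
    pdb = PDBFile.read(str(path))
    arr = pdb.get_structure(model=1)
    if arr.array_length() == 0:
        raise ValueError(f"no atoms in {path}")
    ssbonds = _parse_ssbond_lines(pdb.lines)
    return _molecule_from_atom_array(arr, ssbonds)


def read_layers(path) -> tuple[list[Molecule], np.ndarray]:
    """Read a multi-MODEL protofilament PDB: one layer per MODEL record.

    Returns the ordered layer list plus all water coordinates found in
    any model (waters are stored globally, not per layer).
    """
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    ssbonds = _parse_ssbond_lines(pdb.lines)
    layers = []
    waters = []
    for m in range(1, n_models + 1):
        arr = pdb.get_structure(model=m)
        mol = _molecule_from_atom_array(arr, ssbonds)
        if len(mol.water_coords):
            waters.append(mol.water_coords)
            mol.water_coords = np.empty((0, 3))
        layers.append(mol)
    all_waters = np.concatenate(waters) if waters else np.empty((0, 3))
    return layers, all_waters


def _to_atom_array(mol: Molecule) -> bst.AtomArray:
    n = mol.n_atoms
    arr = bst.AtomArray(n)
    arr.coord = np.round(mol.coords, 3)
    arr.atom_name = mol.names
    arr.element = mol.elements
    arr.chain_id = mol.chain_ids
    arr.res_id = mol.res_ids
    arr.res_name = mol.res_names
    arr.hetero = np.zeros(n, dtype=bool)
    return arr


def _water_atom_array(coords: np.ndarray, chain_id: str = "w") -> bst.AtomArray:
    n = len(coords)
    arr = bst.AtomArray(n)
    arr.coord = np.round(coords, 3)
    arr.atom_name = np.full(n, "O", dtype="U4")
    arr.element = np.full(n, "O", dtype="U2")
    arr.chain_id = np.full(n, chain_id, dtype="U4")
    arr.res_id = np.arange(1, n + 1)
    arr.res_name = np.full(n, WATER_RESNAME, dtype="U4")
    arr.hetero = np.ones(n, dtype=bool)
    return arr


def _ssbond_lines(disulfides) -> list[str]:
    lines = []
    for i, ((c1, r1), (c2, r2)) in enumerate(disulfides, start=1):
        lines.append(
            f"SSBOND {i:3d} CYS {c1:1s} {r1:4d}    CYS {c2:1s} {r2:4d}"
            + " " * 37
        )
    return lines


def _atom_lines(arr: bst.AtomArray) -> list[str]:
    f = PDBFile()
    f.set_structure(arr)
    return [ln for ln in f.lines if ln.startswith(("ATOM", "HETATM"))]


def write_pdb(obj, path) -> None:
    """Write a :class:`Molecule` or a layered model to a PDB file.

    Layered objects (anything exposing an ordered ``layers`` attribute of
    molecules) are written as one MODEL record per layer, in stacking
    order; waters go into the final model.  Round-tripping preserves
    coordinates to 0.001 Å (PDB fixed-width precision) and topology
    exactly.
    """
    layers = list(obj.layers) if hasattr(obj, "layers") else [obj]
    waters = getattr(obj, "water_coords", np.empty((0, 3)))
    for mol in layers:
        if len(mol.chains) > len(_CHAIN_ID_SPACE):
            raise ValueError("more than 62 chains cannot be written to PDB")
    lines: list[str] = []
    lines.extend(_ssbond_lines(layers[0].disulfides))
    multi = len(layers) > 1
    for k, mol in enumerate(layers, start=1):
        if multi:
            lines.append(f"MODEL     {k:4d}")
        lines.extend(_atom_lines(_to_atom_array(mol)))
        if k == len(layers) and len(waters):
            lines.extend(_atom_lines(_water_atom_array(np.asarray(waters))))
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    with open(str(path), "w") as fh:
        fh.write("\n".join(lines) + "\n")
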