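"""Low-level geometric primitives shared by all pipeline stages.

Everything here operates on bare numpy arrays; structural semantics
(chains, residues, bonds) live in :mod:`quasi2d.structure`.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "best_fit_plane",
    "dihedral",
    "dihedrals",
    "kabsch_rmsd",
    "kabsch_superpose",
    "radius_of_gyration",
    "rotation_about_axis",
    "signed_angle_about_axis",
    "build_backbone_from_dihedrals",
]


def radius_of_gyration(coords: np.ndarray) -> float:
    """Mass-free radius of gyration of a point set, in the units of *coords*."""
    c = coords - coords.mean(axis=0)
    return float(np.sqrt((c**2).sum(axis=1).mean()))


def best_fit_plane(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through a point cloud.

    Returns ``(point, normal)`` where *point* is the centroid and *normal*
    the unit eigenvector of the smallest principal component.  The normal's
    sign is fixed so that its largest-magnitude component is positive,
    making the result deterministic.
    """
    coords = np.asarray(coords, dtype=float)
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid, full_matrices=False)
    normal = vt[-1]
    k = int(np.argmax(np.abs(normal)))
    if normal[k] < 0:
        normal = -normal
    return centroid, normal


def rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about *axis* (Rodrigues)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(angle_rad) * k + (1.0 - np.cos(angle_rad)) * (k @ k)


def signed_angle_about_axis(u: np.ndarray, v: np.ndarray, axis: np.ndarray) -> float:
    """Signed angle (degrees) from *u* to *v* in the plane orthogonal to *axis*.

    Positive values correspond to a right-handed (counter-clockwise when
    looking down the axis toward the origin) rotation.
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    up = u - np.dot(u, axis) * axis
    vp = v - np.dot(v, axis) * axis
    x = float(np.dot(up, vp))
    y = float(np.dot(axis, np.cross(up, vp)))
    return float(np.degrees(np.arctan2(y, x)))


def dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle (degrees, in (-180, 180]) defined by four points."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = float(np.dot(v, w))
    y = float(np.dot(np.cross(b1, v), w))
    return float(np.degrees(np.arctan2(y, x)))


def dihedrals(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> np.ndarray:
    """Vectorised torsion angles for stacked quadruples of points (degrees)."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - (b0 * b1n).sum(axis=-1, keepdims=True) * b1n
    w = b2 - (b2 * b1n).sum(axis=-1, keepdims=True) * b1n
    x = (v * w).sum(axis=-1)
    y = (np.cross(b1n, v) * w).sum(axis=-1)
    return np.degrees(np.arctan2(y, x))


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal rigid superposition of *mobile* onto *reference*.

    Returns ``(transformed, rotation, translation)`` such that
    ``transformed = (mobile - mobile_centroid) @ rotation.T + ref_centroid``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    h = (mobile - cm).T @ (reference - cr)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    transformed = (mobile - cm) @ rot.T + cr
    return transformed, rot, cr - cm @ rot.T


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD between point sets after optimal rigid superposition."""
    moved, _, _ = kabsch_superpose(a, b)
    return float(np.sqrt(((moved - b) ** 2).sum(axis=1).mean()))


# Ideal backbone internal coordinates (Å / degrees) used by the chain builder.
_B_N_CA = 1.458
_B_CA_C = 1.525
_B_C_N = 1.329
_B_C_O = 1.231
_A_N_CA_C = 111.0
_A_CA_C_N = 116.2
_A_C_N_CA = 121.7
_A_CA_C_O = 120.8


def _place(a, b, c, bond, angle_deg, torsion_deg):
    """NeRF placement: next atom at given internal coordinates from a-b-c."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(torsion),
            bond * np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_backbone_from_dihedrals(phi_psi: list[tuple[float, float]], omega: float = 180.0) -> np.ndarray:
    """Build an ideal-geometry N/CA/C/O backbone from (phi, psi) pairs.

    Returns an array of shape ``(n_res, 4, 3)`` with atoms ordered
    N, CA, C, O per residue.  The first residue's phi and the last
    residue's psi are required by the signature but do not influence
    the trace.
    """
    n_res = len(phi_psi)
    if n_res < 1:
        raise ValueError("need at least one residue")
    out = np.zeros((n_res, 4, 3))
    # Seed the first residue in a canonical pose.
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.radians(180.0 - _A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0]) * -1.0
    c0 = _place(np.array([0.0, 1.0, 0.0]), n0, ca0, _B_CA_C, _A_N_CA_C, 0.0)
    out[0, 0], out[0, 1], out[0, 2] = n0, ca0, c0
    for i in range(1, n_res):
        psi_prev = phi_psi[i - 1][1]
        phi_i = phi_psi[i][0]
        n_i = _place(out[i - 1, 0], out[i - 1, 1], out[i - 1, 2], _B_C_N, _A_CA_C_N, psi_prev)
        ca_i = _place(out[i - 1, 1], out[i - 1, 2], n_i, _B_N_CA, _A_C_N_CA, omega)
        c_i = _place(out[i - 1, 2], n_i, ca_i, _B_CA_C, _A_N_CA_C, phi_i)
        out[i, 0], out[i, 1], out[i, 2] = n_i, ca_i, c_i
    # Carbonyl oxygens: anti to the following N (trans peptide), or in the
    # N(i)-CA(i)-C(i) plane for the final residue.
    for i in range(n_res):
        psi_i = phi_psi[i][1] if i + 1 < n_res else 180.0
        out[i, 3] = _place(out[i, 0], out[i, 1], out[i, 2], _B_C_O, _A_CA_C_O, psi_i + 180.0)
    return out
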