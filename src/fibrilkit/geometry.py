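"""Internal-coordinate geometry engine.

Vector routines for measuring and setting torsion angles, NeRF-style atom
placement, and the solve for a translationally periodic β-strand repeat.
All distances are in nanometres, all angles in degrees unless noted.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

DEG = np.pi / 180.0

# Ideal backbone covalent geometry (Engh/Huber-style averages).
BOND = {
    "n_ca": 0.1458,
    "ca_c": 0.1525,
    "c_n": 0.1329,
    "c_o": 0.1231,
    "ca_cb": 0.1530,
}
ANGLE = {
    "n_ca_c": 111.0,
    "ca_c_n": 116.2,
    "c_n_ca": 121.7,
    "ca_c_o": 120.8,
}


def _cross3(a, b):
    # np.cross carries large overhead for single 3-vectors
    return np.array([a[1] * b[2] - a[2] * b[1],
                     a[2] * b[0] - a[0] * b[2],
                     a[0] * b[1] - a[1] * b[0]])


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Position of atom d from the three preceding atoms a-b-c.

    d is placed at distance ``bond`` from c, with angle b-c-d and torsion
    a-b-c-d as requested (natural extension reference frame construction).
    """
    angle = angle_deg * DEG
    dihedral = dihedral_deg * DEG
    bc = c - b
    bc = bc / math.sqrt(bc @ bc)
    n = _cross3(b - a, bc)
    nn = math.sqrt(n @ n)
    if nn < 1e-12:
        raise ValueError("collinear reference atoms; frame undefined")
    n = n / nn
    m = _cross3(n, bc)
    sa = math.sin(angle)
    return (c - bond * math.cos(angle) * bc
            + bond * math.cos(dihedral) * sa * m
            + bond * math.sin(dihedral) * sa * n)


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Torsion angle p0-p1-p2-p3 in degrees, wrapped to (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    nb1 = np.linalg.norm(b1)
    if nb1 < 1e-12:
        raise ValueError("degenerate dihedral: central atoms coincide")
    b1n = b1 / nb1
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    if np.linalg.norm(v) < 1e-10 or np.linalg.norm(w) < 1e-10:
        raise ValueError("degenerate dihedral: collinear atoms")
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def wrap_angle(a):
    """Wrap angle(s) in degrees to the interval (-180, 180]."""
    a = np.asarray(a, dtype=float)
    wrapped = -((-a + 180.0) % 360.0 - 180.0)
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    if wrapped.ndim == 0:
        return float(wrapped)
    return wrapped


def backbone_chain(phi_psi_omega, n_res: int | None = None):
    """Build N/CA/C backbone positions by sequential NeRF placement.

    ``phi_psi_omega`` is either a single (phi, psi, omega) applied to every
    residue, or a sequence of per-residue triples.  The torsions are honoured
    exactly for interior residues (phi of residue 0 and psi/omega of the last
    residue are not defined by the chain).  Returns an (n_res, 3, 3) array of
    N, CA, C coordinates.
    """
    tors = np.asarray(phi_psi_omega, dtype=float)
    if tors.ndim == 1:
        if n_res is None:
            raise ValueError("n_res required with uniform torsions")
        tors = np.tile(tors, (n_res, 1))
    n_res = len(tors)
    out = np.zeros((n_res, 3, 3))
    n0 = np.zeros(3)
    ca0 = np.array([BOND["n_ca"], 0.0, 0.0])
    ang = ANGLE["n_ca_c"] * DEG
    c0 = ca0 + BOND["ca_c"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    out[0] = [n0, ca0, c0]
    for i in range(1, n_res):
        psi_prev = tors[i - 1, 1]
        omega = tors[i - 1, 2]
        phi = tors[i, 0]
        n_i = place_atom(out[i - 1, 0], out[i - 1, 1], out[i - 1, 2],
                         BOND["c_n"], ANGLE["ca_c_n"], psi_prev)
        ca_i = place_atom(out[i - 1, 1], out[i - 1, 2], n_i,
                          BOND["n_ca"], ANGLE["c_n_ca"], omega)
        c_i = place_atom(out[i - 1, 2], n_i, ca_i,
                         BOND["ca_c"], ANGLE["n_ca_c"], phi)
        out[i] = [n_i, ca_i, c_i]
    return out


def extend_backbone(prev_n, prev_ca, prev_c, psi_prev: float,
                    torsions) -> np.ndarray:
    """Continue a backbone by NeRF from an existing residue.

    ``torsions`` is a sequence of (phi, psi, omega) for the new residues;
    ``psi_prev`` is the ψ of the seed residue (it fixes the placement of
    the first new amide nitrogen).  Returns (n_new, 3, 3) N/CA/C positions.
    """
    torsions = np.asarray(torsions, dtype=float)
    out = np.zeros((len(torsions), 3, 3))
    pn, pca, pc = (np.asarray(p, dtype=float) for p in (prev_n, prev_ca,
                                                        prev_c))
    psi = psi_prev
    for i, (phi, psi_i, omega) in enumerate(torsions):
        n_i = place_atom(pn, pca, pc, BOND["c_n"], ANGLE["ca_c_n"], psi)
        ca_i = place_atom(pca, pc, n_i, BOND["n_ca"], ANGLE["c_n_ca"], omega)
        c_i = place_atom(pc, n_i, ca_i, BOND["ca_c"], ANGLE["n_ca_c"], phi)
        out[i] = [n_i, ca_i, c_i]
        pn, pca, pc = n_i, ca_i, c_i
        psi = psi_i
    return out


def carbonyl_oxygen(n, ca, c, psi_deg: float) -> np.ndarray:
    """Backbone carbonyl O, anti to the following amide nitrogen."""
    return place_atom(n, ca, c, BOND["c_o"], ANGLE["ca_c_o"], psi_deg + 180.0)


def cbeta_position(n, ca, c) -> np.ndarray:
    """Ideal CB for an L-amino acid from its backbone frame.

    Placed with the standard L-configuration improper torsion
    C-N-CA-CB ≈ −122.6° and angle N-CA-CB ≈ 110.5°.
    """
    return place_atom(c, n, ca, BOND["ca_cb"], 110.5, -122.6)


def _residue_frame(n, ca, c):
    origin = ca
    x = c - n
    x = x / np.linalg.norm(x)
    t = c - ca
    z = np.cross(x, t)
    z = z / np.linalg.norm(z)
    y = np.cross(z, x)
    return origin, np.stack([x, y, z], axis=1)


def repeat_rotation_vector(phi: float, psi: float, omega: float) -> np.ndarray:
    """Rotation vector (deg) of the two-residue repeat transform.

    Zero means the repeat is a pure translation, i.e. the per-residue screw
    is an exact two-fold (2₁) operation.
    """
    bb = backbone_chain((phi, psi, omega), 3)
    o0, f0 = _residue_frame(*bb[0])
    o2, f2 = _residue_frame(*bb[2])
    rot = f2 @ f0.T
    return Rotation.from_matrix(rot).as_rotvec(degrees=True)


def solve_periodic_strand(phi0: float = -140.0, psi0: float = 135.0,
                          omega0: float = 180.0):
    """Solve (phi, psi, omega) near the ideal antiparallel-β point so that the
    two-residue repeat of a uniform strand is an exact translation.

    Returns ((phi, psi, omega), rise_per_residue_nm).
    """
    sol = least_squares(
        lambda p: repeat_rotation_vector(*p),
        [phi0, psi0, omega0],
        bounds=([phi0 - 20, psi0 - 20, omega0 - 8], [phi0 + 20, psi0 + 20, omega0 + 8]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    if np.linalg.norm(sol.fun) > 1e-6:
        raise RuntimeError("periodic-strand solve did not converge")
    phi, psi, omega = sol.x
    bb = backbone_chain((phi, psi, omega), 3)
    rise = np.linalg.norm(bb[2, 1] - bb[0, 1]) / 2.0
    return (float(phi), float(psi), float(omega)), float(rise)


def rotation_y180(points: np.ndarray, x0: float, z0: float) -> np.ndarray:
    """180° rotation about the y-parallel axis through (x0, ·, z0)."""
    points = np.asarray(points, dtype=float)
    out = points.copy()
    out[..., 0] = 2.0 * x0 - points[..., 0]
    out[..., 2] = 2.0 * z0 - points[..., 2]
    return out
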