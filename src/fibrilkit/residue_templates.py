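"""Ideal side-chain templates for non-glutamine residues.

Gln side chains are placed by internal coordinates with explicit χ control
(see :mod:`fibrilkit.core_builder`); every other residue type takes its
heavy-atom side chain from the chemical component dictionary templates
bundled with biotite, rigidly superimposed on the target backbone frame
(N, CA, C).  This gives chemically sensible ideal rotamers without a
hand-written library for all twenty residue types.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

_BACKBONE = ("N", "CA", "C", "O", "OXT")


def _frame_basis(n, ca, c):
    x = c - n
    x = x / np.sqrt(x @ x)
    t = c - ca
    z = np.array([x[1] * t[2] - x[2] * t[1],
                  x[2] * t[0] - x[0] * t[2],
                  x[0] * t[1] - x[1] * t[0]])
    z = z / np.sqrt(z @ z)
    y = np.array([z[1] * x[2] - z[2] * x[1],
                  z[2] * x[0] - z[0] * x[2],
                  z[0] * x[1] - z[1] * x[0]])
    return np.stack([x, y, z])


@lru_cache(maxsize=None)
def _template(res_name: str):
    import biotite.structure.info as struc_info

    arr = struc_info.residue(res_name)
    if arr is None:
        raise KeyError(f"no ideal template for residue {res_name!r}")
    heavy = arr[arr.element != "H"]
    names = list(heavy.atom_name)
    coords = heavy.coord / 10.0  # Angstrom -> nm
    idx = {n: i for i, n in enumerate(names)}
    for required in ("N", "CA", "C"):
        if required not in idx:
            raise KeyError(f"template {res_name!r} lacks backbone atom {required}")
    basis = _frame_basis(coords[idx["N"]], coords[idx["CA"]], coords[idx["C"]])
    origin = coords[idx["CA"]]
    side_names = tuple(n for n in names if n not in _BACKBONE)
    local = np.stack([(basis @ (coords[idx[n]] - origin))
                      for n in side_names]) if side_names else np.empty((0, 3))
    return side_names, local


def sidechain_from_template(res_name: str, backbone: dict) -> dict:
    """Side-chain heavy atoms (incl. CB) aligned to the backbone frame.

    ``backbone`` must provide N, CA and C positions (nm); the template's
    side chain is carried rigidly in the local N/CA/C frame.  Returns a
    dict of atom name -> position for all non-backbone heavy atoms.
    """
    side_names, local = _template(res_name)
    if not side_names:
        return {}
    basis = _frame_basis(np.asarray(backbone["N"], dtype=float),
                         np.asarray(backbone["CA"], dtype=float),
                         np.asarray(backbone["C"], dtype=float))
    origin = np.asarray(backbone["CA"], dtype=float)
    world = local @ basis + origin
    return dict(zip(side_names, world))


def set_chi2(atoms: dict, chi2_deg: float) -> dict:
    """Rotate a side chain beyond CG about CB-CG so χ2 hits ``chi2_deg``."""
    from .geometry import dihedral_angle

    delta_atom = next((d for d in ("CD", "CD1", "SD", "OD1", "ND1")
                       if d in atoms), None)
    if delta_atom is None or "CG" not in atoms or "CB" not in atoms:
        return atoms
    current = dihedral_angle(atoms["CA"], atoms["CB"], atoms["CG"],
                             atoms[delta_atom])
    delta = np.radians(chi2_deg - current)
    axis = atoms["CG"] - atoms["CB"]
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    rot = (np.eye(3) + np.sin(delta) * k + (1 - np.cos(delta)) * (k @ k))
    pivot = atoms["CG"]
    keep = {"N", "CA", "C", "O", "CB", "CG", "OXT"}
    for name, pos in atoms.items():
        if name not in keep:
            atoms[name] = rot @ (pos - pivot) + pivot
    return atoms


def set_chi1(atoms: dict, chi1_deg: float) -> dict:
    """Rotate a residue's side chain about CA-CB so χ1 hits ``chi1_deg``.

    ``atoms`` must contain N, CA, CB and CG (or CG1/OG/SG as the gamma
    atom); all atoms beyond CB are rotated rigidly.  Returns the dict with
    updated positions.
    """
    from .geometry import dihedral_angle

    gamma = next((g for g in ("CG", "CG1", "OG", "OG1", "SG")
                  if g in atoms), None)
    if gamma is None or "CB" not in atoms:
        return atoms
    current = dihedral_angle(atoms["N"], atoms["CA"], atoms["CB"],
                             atoms[gamma])
    delta = np.radians(chi1_deg - current)
    axis = atoms["CB"] - atoms["CA"]
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    rot = (np.eye(3) + np.sin(delta) * k
           + (1 - np.cos(delta)) * (k @ k))
    pivot = atoms["CB"]
    keep = {"N", "CA", "C", "O", "CB", "OXT"}
    for name, pos in atoms.items():
        if name not in keep:
            atoms[name] = rot @ (pos - pivot) + pivot
    return atoms
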