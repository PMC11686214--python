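"""Atomistic construction of idealized polyQ fibril models.

Three builders share one geometric core:

* :func:`build_core_lattice` — the fully periodic antiparallel cross-β polyQ
  lattice realizing a unit-cell candidate from :mod:`fibrilkit.lattice_enum`.
* :func:`build_q15_fibril` — a solvent-exposed, water-facing fibril of
  Ace-D2Q15K2 peptides (seven β-sheets by default).
* :func:`build_httex1_fibril` — a Q44-HTTex1 protofilament: β-hairpin polyQ
  core plus the disordered N17 and proline-rich (PRD) flanking domains.

The β-strand scaffold is an exact 2₁ screw: backbone torsions are solved so
the two-residue repeat is a pure translation along the strand axis x, which
makes the lattice simultaneously periodic and exactly faithful to the
requested dihedrals.  Glutamine side chains are placed by internal
coordinates with χ1/χ2/χ3 solved per hydrogen-bond class so that successive
side-chain amides stack head-to-tail along the fibril axis z with
Oε1···Nε2 steps inside the amyloid Gln-ladder window (2.6–3.1 Å by default,
motivated by the 2.7–2.9 Å distances seen in related amyloid cores).

Builders emit idealized, unminimized solute-only coordinates intended as
starting structures for downstream refinement; they perform no solvation or
energy minimization.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution, least_squares
from scipy.spatial import cKDTree

from . import geometry as geom
from .geometry import DEG
from .lattice_enum import WELL_CENTERS, HBondClass, UnitCellCandidate

__all__ = [
    "LatticeGeometry",
    "FibrilModel",
    "BuildError",
    "build_core_lattice",
    "build_q15_fibril",
    "build_httex1_fibril",
    "HTTEX1_SEQUENCE",
]


class BuildError(RuntimeError):
    pass


# Gln side-chain internal coordinates (nm / degrees)
GLN_SIDE = {
    "cb_cg": 0.1520, "cg_cd": 0.1516, "cd_oe1": 0.1231, "cd_ne2": 0.1328,
    "ca_cb_cg": 114.1, "cb_cg_cd": 112.6, "cg_cd_oe1": 120.9, "cg_cd_ne2": 116.4,
}

#: canonical turn templates, (phi_i+1, psi_i+1, phi_i+2, psi_i+2) in degrees
TURN_TEMPLATES = {
    "type_I_prime": (60.0, 30.0, 90.0, 0.0),
    "type_II": (-60.0, 120.0, 80.0, 0.0),
}

N17_SEQ = "MATLEKLMKAFESLKSF"
PRD_SEQ = "P" * 11 + "QLPQPPPQAQPLLPQPQ" + "P" * 10 + "GPAVAEEPLHRP"


def HTTEX1_SEQUENCE(polyq_len: int = 44) -> str:
    """Huntingtin exon-1 sequence: N17, the polyQ tract, and the 50-residue PRD."""
    return N17_SEQ + "Q" * polyq_len + PRD_SEQ


@dataclass
class LatticeGeometry:
    """Cross-β lattice geometry.  Distances nm, angles degrees.

    ``beta_phi_deg``/``beta_psi_deg``/``beta_omega_deg`` and
    ``rise_per_residue`` default to the solved translationally periodic
    strand repeat near the ideal antiparallel-β point; pass explicit values
    to override.
    """

    strand_spacing: float = 0.47
    sheet_spacing: float = 0.83
    rise_per_residue: float | None = None
    beta_phi_deg: float | None = None
    beta_psi_deg: float | None = None
    beta_omega_deg: float | None = None
    chi2_deg: float = 180.0
    clash_distance: float = 0.15
    hbond_target: float = 0.285
    hbond_window: tuple = (0.26, 0.31)

    def __post_init__(self):
        if min(self.strand_spacing, self.sheet_spacing) <= 0:
            raise ValueError("lattice spacings must be positive")
        if abs(geom.wrap_angle(self.chi2_deg - 180.0)) > 30.0:
            raise ValueError("chi2 must stay within 30 degrees of 180")
        if None in (self.beta_phi_deg, self.beta_psi_deg, self.beta_omega_deg):
            (phi, psi, omega), rise = _periodic_scaffold_angles()
            self.beta_phi_deg = phi if self.beta_phi_deg is None else self.beta_phi_deg
            self.beta_psi_deg = psi if self.beta_psi_deg is None else self.beta_psi_deg
            self.beta_omega_deg = (omega if self.beta_omega_deg is None
                                   else self.beta_omega_deg)
            if self.rise_per_residue is None:
                self.rise_per_residue = rise
        if self.rise_per_residue is None or self.rise_per_residue <= 0:
            raise ValueError("rise_per_residue must be positive")

    def key(self) -> str:
        payload = ",".join(f"{v:.6f}" for v in (
            self.strand_spacing, self.sheet_spacing, self.rise_per_residue,
            self.beta_phi_deg, self.beta_psi_deg, self.beta_omega_deg,
            self.chi2_deg))
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


_SCAFFOLD_CACHE: dict = {}


def _periodic_scaffold_angles():
    if "angles" not in _SCAFFOLD_CACHE:
        _SCAFFOLD_CACHE["angles"] = geom.solve_periodic_strand()
    return _SCAFFOLD_CACHE["angles"]


ATOM_COLUMNS = ["serial", "name", "element", "res_name", "res_seq",
                "chain_id", "x", "y", "z",
                "sheet", "strand", "conformer", "segment"]


@dataclass
class FibrilModel:
    """Atomistic coordinates plus chain/sheet/strand topology annotations."""

    atoms: pd.DataFrame
    box: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_chains(self) -> int:
        return self.atoms["chain_id"].nunique()

    @property
    def n_residues(self) -> int:
        return len(self.atoms.groupby(["chain_id", "res_seq"], sort=False))

    def coordinates(self) -> np.ndarray:
        return self.atoms[["x", "y", "z"]].to_numpy()

    def extent(self, axis) -> float:
        """Max minus min heavy-atom coordinate along axis (0/1/2 or x/y/z)."""
        axis = {"x": 0, "y": 1, "z": 2}.get(axis, axis)
        col = "xyz"[axis]
        heavy = self.atoms[self.atoms["element"] != "H"]
        return float(heavy[col].max() - heavy[col].min())

    def find_clashes(self, cutoff: float | None = None, min_sep: int = 2):
        """Pairs of atoms closer than ``cutoff`` (nm).

        Pairs within the same chain closer than ``min_sep`` residues apart
        are excluded (covalent neighbours).  Under periodic boxes the check
        also covers wrapped images.
        """
        cutoff = cutoff if cutoff is not None else 0.15
        xyz = self.coordinates()
        if self.box is not None:
            wrapped = np.mod(xyz, self.box)
            wrapped[wrapped >= self.box] -= self.box[
                np.where(wrapped >= self.box)[1]]
            tree = cKDTree(wrapped, boxsize=self.box)
        else:
            tree = cKDTree(xyz)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        if len(pairs) == 0:
            return []
        chain = self.atoms["chain_id"].to_numpy()
        res = self.atoms["res_seq"].to_numpy()
        sep = np.abs(res[pairs[:, 0]] - res[pairs[:, 1]])
        if self.box is not None:
            # periodic chains close on themselves across the box: first and
            # last residues are covalent neighbours, so use cyclic separation
            n_per_chain = self.atoms.groupby("chain_id")["res_seq"].nunique()
            n_chain = n_per_chain[chain[pairs[:, 0]]].to_numpy()
            sep = np.minimum(sep, n_chain - sep)
        keep = ~((chain[pairs[:, 0]] == chain[pairs[:, 1]]) & (sep <= min_sep))
        return [tuple(p) for p in pairs[keep]]

    def validate(self, cutoff: float | None = None):
        clashes = self.find_clashes(cutoff)
        if clashes:
            i, j = clashes[0]
            a, b = self.atoms.iloc[i], self.atoms.iloc[j]
            raise BuildError(
                f"steric clash: {a['chain_id']}/{a['res_seq']}/{a['name']} vs "
                f"{b['chain_id']}/{b['res_seq']}/{b['name']} "
                f"({len(clashes)} clashing pairs)")
        return self


# ---------------------------------------------------------------------------
# scaffold + side-chain realization
# ---------------------------------------------------------------------------

class StrandScaffold:
    """Aligned two-residue β-strand motif with an exact translational repeat.

    The repeat direction is +x with residue 0's CA at the origin; the frame
    is oriented by the backbone carbonyls: residue 0's C=O points along −z
    (towards the antiparallel neighbour strand), which leaves its side chain
    pointing to +y with the small tilt that cross-β pleating imposes.
    Residue 1 is the screw image (side chain −y, C=O +z) at x ≈ rise.  The
    repeat vector is exactly (2·rise, 0, 0).
    """

    def __init__(self, geometry: LatticeGeometry):
        self.geometry = geometry
        tors = (geometry.beta_phi_deg, geometry.beta_psi_deg,
                geometry.beta_omega_deg)
        bb = geom.backbone_chain(tors, 3)
        repeat = bb[2, 1] - bb[0, 1]
        self.rise = float(np.linalg.norm(repeat) / 2.0)
        ex = repeat / np.linalg.norm(repeat)
        o0 = geom.carbonyl_oxygen(bb[0, 0], bb[0, 1], bb[0, 2],
                                  geometry.beta_psi_deg)
        vco = o0 - bb[0, 2]
        vco -= np.dot(vco, ex) * ex
        ez = -vco / np.linalg.norm(vco)
        ey = np.cross(ez, ex)
        cb0 = geom.cbeta_position(*bb[0])
        if np.dot(cb0 - bb[0, 1], ey) < 0:
            ez, ey = -ez, -ey
        rot = np.stack([ex, ey, ez])
        origin = bb[0, 1].copy()

        def tf(p):
            return rot @ (np.asarray(p) - origin)

        self.motif = []
        for j in (0, 1):
            n, ca, c = (tf(bb[j, k]) for k in range(3))
            o = tf(geom.carbonyl_oxygen(bb[j, 0], bb[j, 1], bb[j, 2],
                                        geometry.beta_psi_deg))
            cb = tf(geom.cbeta_position(bb[j, 0], bb[j, 1], bb[j, 2]))
            self.motif.append({"N": n, "CA": ca, "C": c, "O": o, "CB": cb})

    def residue_backbone(self, j: int) -> dict:
        base = self.motif[j % 2]
        shift = np.array([2.0 * self.rise * (j // 2), 0.0, 0.0])
        return {k: p + shift for k, p in base.items()}

    def registry(self) -> tuple:
        """Antiparallel-partner registry offsets (delta_x, delta_z) in nm.

        The partner strand is the two-fold image about a y-parallel axis at
        (rise + delta_x, strand_spacing/2 + delta_z).  The offsets are solved
        once per geometry so that the inter-strand backbone N···O hydrogen
        bonds approach their ideal 0.29 nm in both the narrow and the wide
        H-bond ring of the antiparallel pattern, without steric overlap.
        """
        key = ("registry", self.geometry.key())
        if key not in _SCAFFOLD_CACHE:
            _SCAFFOLD_CACHE[key] = _solve_registry(self)
        return _SCAFFOLD_CACHE[key]


def _solve_registry(scaffold: "StrandScaffold") -> tuple:
    dz = scaffold.geometry.strand_spacing
    rise = scaffold.rise
    # emulate infinite strands: central residues of one strand scored
    # against a long stretch of the partner (the 2-residue motif tiles to
    # negative indices as well)
    long_range = range(-8, 12)
    mid = (0, 1, 2, 3)
    host_long = [scaffold.residue_backbone(j) for j in long_range]
    host_mid = [scaffold.residue_backbone(j) for j in mid]
    host2_long = [{k: p + np.array([0.0, 0.0, 2.0 * dz]) for k, p in r.items()}
                  for r in host_long]
    host2_mid = [{k: p + np.array([0.0, 0.0, 2.0 * dz]) for k, p in r.items()}
                 for r in host_mid]

    def one_sided(aa, bb):
        a_n = np.array([r["N"] for r in aa])
        a_o = np.array([r["O"] for r in aa])
        b_n = np.array([r["N"] for r in bb])
        b_o = np.array([r["O"] for r in bb])
        d_no = np.linalg.norm(a_n[:, None, :] - b_o[None, :, :], axis=-1)
        d_on = np.linalg.norm(a_o[:, None, :] - b_n[None, :, :], axis=-1)
        hb = np.sort(np.concatenate([d_no.min(axis=1), d_on.min(axis=1)]))[:4]
        all_a = np.array([p for r in aa for p in r.values()])
        all_b = np.array([p for r in bb for p in r.values()])
        dmin = np.min(np.linalg.norm(all_a[:, None, :] - all_b[None, :, :],
                                     axis=-1))
        return np.abs(hb - 0.29).sum() + 50.0 * max(0.0, 0.25 - dmin)

    best = None
    # delta_x stays below rise/4 so ladder-column parity remains unambiguous
    for delta in np.linspace(-0.08, 0.08, 33):
        for zeta in np.linspace(-0.12, 0.12, 33):
            def rot(res):
                return {k: geom.rotation_y180(p, x0=rise + delta,
                                              z0=dz / 2.0 + zeta)
                        for k, p in res.items()}
            partner_long = [rot(r) for r in host_long]
            partner_mid = [rot(r) for r in host_mid]
            score = (one_sided(host_mid, partner_long)
                     + one_sided(partner_mid, host_long)
                     + one_sided(partner_mid, host2_long)
                     + one_sided(host2_mid, partner_long))
            if best is None or score < best[0]:
                best = (score, float(delta), float(zeta))
    return best[1], best[2]


def gln_sidechain(res: dict, chi1: float, chi2: float, chi3: float,
                  ang1: float | None = None, ang2: float | None = None) -> dict:
    """CG/CD/OE1/NE2 of a glutamine from its backbone frame and χ angles.

    ``ang1``/``ang2`` override the CA-CB-CG and CB-CG-CD bond angles (the
    ladder solve flexes them by a few degrees for strained classes).
    """
    s = GLN_SIDE
    cg = geom.place_atom(res["N"], res["CA"], res["CB"], s["cb_cg"],
                         ang1 if ang1 is not None else s["ca_cb_cg"], chi1)
    cd = geom.place_atom(res["CA"], res["CB"], cg, s["cg_cd"],
                         ang2 if ang2 is not None else s["cb_cg_cd"], chi2)
    oe1 = geom.place_atom(res["CB"], cg, cd, s["cd_oe1"], s["cg_cd_oe1"], chi3)
    ne2 = geom.place_atom(res["CB"], cg, cd, s["cd_ne2"], s["cg_cd_ne2"],
                          chi3 + 180.0)
    return {"CG": cg, "CD": cd, "OE1": oe1, "NE2": ne2}


@dataclass(frozen=True)
class ClassRealization:
    """Solved side-chain geometry for the two slots of one ladder column."""

    chi_a: tuple  # (chi1, chi2, chi3) for the z-even (slot A) residue
    chi_b: tuple  # for the z-odd (slot B) residue
    ang_a: tuple  # (CA-CB-CG, CB-CG-CD) bond angles, slot A
    ang_b: tuple
    step_distances: tuple  # the two Oε1···Nε2 steps of the repeat (nm)
    in_window: bool

    def sidechain(self, res: dict, slot: str) -> dict:
        chi = self.chi_a if slot == "a" else self.chi_b
        ang = self.ang_a if slot == "a" else self.ang_b
        return gln_sidechain(res, *chi, ang1=ang[0], ang2=ang[1])


_REALIZE_CACHE: dict = {}


def realize_class(cls: HBondClass, geometry: LatticeGeometry,
                  side: int = +1) -> ClassRealization:
    """Solve χ1/χ2/χ3 for both residues of a ladder column of class ``cls``.

    ``side`` is +1 for columns whose side chains point +y (even-x residues)
    and −1 for −y columns.  The slot-A residue sits on a +x-running strand,
    so its intrinsic χ1 well is the class's lab-frame ``well_a`` tag directly,
    while slot B (on the −x strand) realizes the flipped ``well_b`` tag.
    Columns whose geometry cannot close the ladder inside the configured
    window are returned with ``in_window=False`` (a geometry warning, not an
    error): same-well columns are intrinsically strained.
    """
    key = (cls.well_a, cls.well_b, cls.direction, side, geometry.key())
    if key in _REALIZE_CACHE:
        return _REALIZE_CACHE[key]

    scaffold = StrandScaffold(geometry)
    rise, dz = scaffold.rise, geometry.strand_spacing
    delta, zeta = scaffold.registry()
    # +y columns hold the even-x (motif 0) residues, -y columns the odd-x
    # (motif 1) ones; the antiparallel partner is the two-fold image about
    # the registry axis, shifted back onto the column
    j = 0 if side > 0 else 1
    res_a = scaffold.residue_backbone(j)
    x_shift = np.array([2.0 * rise, 0.0, 0.0]) if side > 0 else np.zeros(3)
    res_b = {k: geom.rotation_y180(p, x0=rise + delta, z0=dz / 2.0 + zeta)
             - x_shift for k, p in res_a.items()}
    target_a = WELL_CENTERS[cls.well_a]
    target_b = WELL_CENTERS["m" if cls.well_b == "p" else "p"]
    up = cls.direction == "u"
    t = geometry.hbond_target
    lo, hi = geometry.hbond_window

    ang1c, ang2c = GLN_SIDE["ca_cb_cg"], GLN_SIDE["cb_cg_cd"]

    def step_distances(p):
        # p = (chi1a, chi2a, chi3a, ang1a, ang2a, chi1b, chi2b, chi3b,
        #      ang1b, ang2b)
        sa = gln_sidechain(res_a, *p[0:3], ang1=p[3], ang2=p[4])
        sb = gln_sidechain(res_b, *p[5:8], ang1=p[8], ang2=p[9])
        shift = np.array([0.0, 0.0, 2.0 * dz])
        if up:
            d1 = np.linalg.norm(sa["NE2"] - sb["OE1"])
            d2 = np.linalg.norm(sb["NE2"] - (sa["OE1"] + shift))
        else:
            d1 = np.linalg.norm(sa["OE1"] - sb["NE2"])
            d2 = np.linalg.norm(sb["OE1"] - (sa["NE2"] + shift))
        return float(d1), float(d2)

    chi2c = geometry.chi2_deg
    best = None
    for da in (-40, -20, 0, 20, 40):
        for db in (-40, -20, 0, 20, 40):
            for c3a in range(-180, 180, 45):
                for c3b in range(-180, 180, 45):
                    p = (target_a + da, chi2c, c3a, ang1c, ang2c,
                         target_b + db, chi2c, c3b, ang1c, ang2c)
                    d1, d2 = step_distances(p)
                    # small well-deviation penalty so the coarse search picks
                    # the basin closest to the rotamer-well centres
                    err = (abs(d1 - t) + abs(d2 - t)
                           + 4e-4 * (abs(da) + abs(db)) / 40.0)
                    if best is None or err < best[0]:
                        best = (err, p)
    x0 = np.array(best[1], dtype=float)

    def residuals(p):
        d1, d2 = step_distances(p)
        return [(d1 - t) / 0.001, (d2 - t) / 0.001,
                (p[0] - target_a) / 30.0, (p[1] - chi2c) / 40.0,
                (p[3] - ang1c) / 10.0, (p[4] - ang2c) / 10.0,
                (p[5] - target_b) / 30.0, (p[6] - chi2c) / 40.0,
                (p[8] - ang1c) / 10.0, (p[9] - ang2c) / 10.0]

    lob = [target_a - 45, chi2c - 30, x0[2] - 90, ang1c - 8, ang2c - 8,
           target_b - 45, chi2c - 30, x0[7] - 90, ang1c - 8, ang2c - 8]
    upb = [target_a + 45, chi2c + 30, x0[2] + 90, ang1c + 8, ang2c + 8,
           target_b + 45, chi2c + 30, x0[7] + 90, ang1c + 8, ang2c + 8]
    sol = least_squares(residuals, x0, bounds=(lob, upb))
    x = sol.x
    d1, d2 = step_distances(x)
    if not (lo <= d1 <= hi and lo <= d2 <= hi):
        # strained column: widen the basin and search globally (deterministic
        # seed) for any solution with both steps inside the window
        def penalty(p):
            d1, d2 = step_distances(p)
            w = (max(0.0, lo - d1, d1 - hi) + max(0.0, lo - d2, d2 - hi))
            return w * 1e3 + 1e-4 * (abs(p[0] - target_a) + abs(p[5] - target_b))

        bounds = [(target_a - 55, target_a + 55), (chi2c - 35, chi2c + 35),
                  (-180, 180), (ang1c - 8, ang1c + 8), (ang2c - 8, ang2c + 8),
                  (target_b - 55, target_b + 55), (chi2c - 35, chi2c + 35),
                  (-180, 180), (ang1c - 8, ang1c + 8), (ang2c - 8, ang2c + 8)]
        de = differential_evolution(penalty, bounds, seed=7, maxiter=300,
                                    tol=1e-10, polish=True)
        if de.fun < 1.0:
            x = de.x
            d1, d2 = step_distances(x)

    realization = ClassRealization(
        chi_a=tuple(geom.wrap_angle(v) for v in x[0:3]),
        chi_b=tuple(geom.wrap_angle(v) for v in x[5:8]),
        ang_a=(float(x[3]), float(x[4])),
        ang_b=(float(x[8]), float(x[9])),
        step_distances=(d1, d2),
        in_window=bool(lo <= d1 <= hi and lo <= d2 <= hi),
    )
    _REALIZE_CACHE[key] = realization
    return realization


# ---------------------------------------------------------------------------
# model assembly helpers
# ---------------------------------------------------------------------------

_GLN_ORDER = ["N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "NE2"]

_CHAIN_CHARS = ("ABCDEFGHIJKLMNOPQRSTUVWXYZ"
                "abcdefghijklmnopqrstuvwxyz0123456789")


def chain_label(i: int) -> str:
    if i < len(_CHAIN_CHARS):
        return _CHAIN_CHARS[i]
    i -= len(_CHAIN_CHARS)
    return _CHAIN_CHARS[i // len(_CHAIN_CHARS)] + _CHAIN_CHARS[i % len(_CHAIN_CHARS)]


class _ModelAccumulator:
    def __init__(self):
        self.rows = []
        self.serial = 0

    def add_residue(self, atoms: dict, order, res_name: str, res_seq: int,
                    chain_id: str, sheet=-1, strand=-1, conformer="-",
                    segment="-"):
        for name in order:
            if name not in atoms:
                continue
            p = atoms[name]
            self.serial += 1
            element = name[0] if name[0] in "NCOSH" else name[:1]
            self.rows.append((self.serial, name, element, res_name, res_seq,
                              chain_id, p[0], p[1], p[2],
                              sheet, strand, conformer, segment))

    def to_model(self, box=None, provenance=None) -> FibrilModel:
        atoms = pd.DataFrame(self.rows, columns=ATOM_COLUMNS)
        return FibrilModel(atoms=atoms, box=None if box is None
                           else np.asarray(box, dtype=float),
                           provenance=provenance or {})


def _rotation_center_x(n_scaffold_res: int, rise: float) -> float:
    """x of the 2-fold axis for finite antiparallel partners.

    The axis must sit at an odd multiple of the rise so that rotated
    residues keep their ladder-column parity, and near the strand centre so
    that antiparallel partners overlap along x.
    """
    m = int(round((n_scaffold_res - 1) / 2.0))
    if m % 2 == 0:
        m += 1
    return m * rise


def _require_filtered(candidate: UnitCellCandidate):
    if candidate.strand_conformers is None:
        raise BuildError(
            "candidate has no strand conformers; pass a uniformity-filter "
            "survivor (mixed strands cannot be built)")


def _transform_residue(res: dict, rotate: bool, x0: float, z0: float,
                       offset: np.ndarray) -> dict:
    out = {}
    for k, p in res.items():
        q = geom.rotation_y180(p, x0, z0) if rotate else p
        out[k] = q + offset
    return out


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def _column_contexts(candidate: UnitCellCandidate, alphabet):
    by_label = {c.label: c for c in alphabet}
    for x in (0, 1):
        for y in (0, 1):
            yield (x, y), by_label[candidate.pair_class(x, y)], (1 if x == 0
                                                                 else -1)


def count_strained_columns(candidate: UnitCellCandidate, alphabet,
                           geometry: LatticeGeometry) -> list:
    """Column slots whose ladder cannot close inside the H-bond window."""
    return [(slot, cls.label)
            for slot, cls, side in _column_contexts(candidate, alphabet)
            if not realize_class(cls, geometry, side=side).in_window]


def select_build_image(candidate: UnitCellCandidate, alphabet, group,
                       geometry: LatticeGeometry) -> UnitCellCandidate:
    """Pick the symmetry-equivalent assignment with fewest strained columns.

    All orbit members describe the same architecture; the idealized
    geometric realization is not exactly symmetric under the group (strand
    pleat and registry offsets distinguish the two sheet interfaces), so
    some images close their side-chain ladders where others cannot.  Ties
    break lexicographically for determinism.
    """
    from .lattice_enum import apply_strand_uniformity_filter

    best = None
    for g in group.elements:
        image = group.apply(g, candidate, alphabet)
        image = apply_strand_uniformity_filter([image], alphabet)[0]
        n_bad = len(count_strained_columns(image, alphabet, geometry))
        key = (n_bad, image.encoding)
        if best is None or key < best[0]:
            best = (key, image)
    from dataclasses import replace
    return replace(best[1], canonical_id=candidate.canonical_id)


def build_core_lattice(candidate: UnitCellCandidate, alphabet,
                       n_cells_x: int = 5, n_cells_y: int = 2,
                       n_cells_z: int = 4,
                       geometry: LatticeGeometry | None = None,
                       group=None,
                       validate: bool = True) -> FibrilModel:
    """Fully periodic polyQ core lattice for a filtered candidate.

    The model holds ``8 * n_cells_x * n_cells_y * n_cells_z`` Gln residues:
    2·n_cells_y antiparallel β-sheets stacked along y, each of 2·n_cells_z
    strands of periodic poly-Gln peptides running along x.  The default
    5×2×4 cells replicate the 40-cell, 320-residue reference system
    (4 sheets of 8 Q10 strands).
    """
    _require_filtered(candidate)
    if min(n_cells_x, n_cells_y, n_cells_z) < 1:
        raise ValueError("cell counts must be >= 1")
    geometry = geometry or LatticeGeometry()
    original_id = candidate.canonical_id or candidate.encoding
    if group is not None:
        candidate = select_build_image(candidate, alphabet, group, geometry)
    warnings_list = count_strained_columns(candidate, alphabet, geometry)
    by_label = {c.label: c for c in alphabet}
    scaffold = StrandScaffold(geometry)
    rise = scaffold.rise
    delta, zeta = scaffold.registry()
    dz, dy = geometry.strand_spacing, geometry.sheet_spacing
    nx, ny, nz = 2 * n_cells_x, 2 * n_cells_y, 2 * n_cells_z
    box = np.array([nx * rise, ny * dy, nz * dz])

    acc = _ModelAccumulator()
    chain_idx = 0
    for sheet in range(ny):
        q = sheet % 2
        for strand in range(nz):
            zpar = strand % 2
            cid = chain_label(chain_idx)
            chain_idx += 1
            # odd strands are the two-fold image about (rise, ., dz/2) of the
            # strand one spacing below, so their base offset is (strand-1)*dz
            offset = np.array([0.0, sheet * dy,
                               (strand - zpar) * dz])
            conformer = candidate.strand_conformers[(zpar, q)]
            residues = []
            for j in range(nx):
                res = scaffold.residue_backbone(j)
                res = _transform_residue(res, rotate=bool(zpar),
                                         x0=rise + delta,
                                         z0=dz / 2.0 + zeta, offset=offset)
                xcol = int(round((res["CA"][0] - 2 * delta * zpar)
                                 / rise)) % 2
                side = +1 if xcol == 0 else -1
                cls = by_label[candidate.pair_class(xcol, q)]
                real = realize_class(cls, geometry, side=side)
                res.update(real.sidechain(res, "a" if zpar == 0 else "b"))
                residues.append(res)
            # wrap whole chains (not single atoms) into the primary box so
            # that no covalent seam is introduced within a chain
            center = np.mean([r["CA"] for r in residues], axis=0)
            shift = -np.floor(center / box) * box
            for j, res in enumerate(residues):
                res = {k: p + shift for k, p in res.items()}
                acc.add_residue(res, _GLN_ORDER, "GLN", j + 1, cid,
                                sheet=sheet, strand=strand,
                                conformer=conformer, segment="polyQ")

    model = acc.to_model(box=box, provenance={
        "builder": "core_lattice",
        "candidate": original_id,
        "built_assignment": candidate.encoding,
        "geometry": geometry.key(),
        "cells": (n_cells_x, n_cells_y, n_cells_z),
        "geometry_warnings": [
            {"slot": slot, "class": label} for slot, label in warnings_list],
    })
    clashes = model.find_clashes(geometry.clash_distance)
    if clashes:
        # certain architectures (a pure-p sheet stacked on a pure-m sheet)
        # cannot interdigitate their ladder-optimal side chains without
        # steric overlap: a geometric frustration of the class assignment
        model.provenance["geometry_warnings"].append(
            {"interface_clashes": len(clashes)})
        if validate:
            i, j = clashes[0]
            a, b = model.atoms.iloc[i], model.atoms.iloc[j]
            raise BuildError(
                f"steric clash: {a['chain_id']}/{a['res_seq']}/{a['name']} "
                f"vs {b['chain_id']}/{b['res_seq']}/{b['name']} "
                f"({len(clashes)} clashing pairs)")
    return model


_Q15_SEQ = "DD" + "Q" * 15 + "KK"


def build_q15_fibril(candidate: UnitCellCandidate, alphabet,
                     geometry: LatticeGeometry | None = None,
                     n_sheets: int = 7, peptides_per_sheet: int = 8,
                     validate: bool = True) -> FibrilModel:
    """Seven-sheet fibril of Ace-D2Q15K2 peptides, quasi-infinite along z.

    Each chain carries 19 residues (two Asp, fifteen Gln, two Lys) plus an
    N-terminal acetyl cap; the C-terminus is left uncharged (-COOH modelled
    as OXT on the final lysine).  Charged flanking residues extend the
    β-strand conformation.  The stack of ``n_sheets`` sheets reproduces the
    5.5–6.5 nm fibril width seen by TEM.
    """
    _require_filtered(candidate)
    if peptides_per_sheet % 2 != 0:
        raise BuildError("antiparallel pairing needs an even number of "
                         "peptides per sheet")
    geometry = geometry or LatticeGeometry()
    by_label = {c.label: c for c in alphabet}
    scaffold = StrandScaffold(geometry)
    rise, dz, dy = scaffold.rise, geometry.strand_spacing, geometry.sheet_spacing
    delta, zeta = scaffold.registry()
    n_res = len(_Q15_SEQ)
    box = np.array([n_res * rise + 4.0, (n_sheets - 1) * dy + 4.0,
                    peptides_per_sheet * dz])

    from .residue_templates import sidechain_from_template

    acc = _ModelAccumulator()
    chain_idx = 0
    for sheet in range(n_sheets):
        q = sheet % 2
        for strand in range(peptides_per_sheet):
            zpar = strand % 2
            cid = chain_label(chain_idx)
            chain_idx += 1
            offset = np.array([0.0, sheet * dy, (strand - zpar) * dz])
            x_axis = _rotation_center_x(n_res, rise) + delta
            residues = []
            for j in range(n_res):
                res = scaffold.residue_backbone(j)
                res = _transform_residue(res, rotate=bool(zpar), x0=x_axis,
                                         z0=dz / 2.0 + zeta, offset=offset)
                residues.append(res)
            # acetyl cap from the first residue's frame
            first = residues[0]
            c_ace = geom.place_atom(first["C"], first["CA"], first["N"],
                                    geom.BOND["c_n"], geom.ANGLE["c_n_ca"],
                                    -120.0)
            o_ace = geom.place_atom(first["CA"], first["N"], c_ace,
                                    geom.BOND["c_o"], geom.ANGLE["ca_c_o"], 0.0)
            ch3 = geom.place_atom(first["CA"], first["N"], c_ace,
                                  0.1520, 116.2, 180.0)
            acc.add_residue({"CH3": ch3, "C": c_ace, "O": o_ace},
                            ["CH3", "C", "O"], "ACE", 0, cid,
                            sheet=sheet, strand=strand, segment="cap")
            for j, (aa, res) in enumerate(zip(_Q15_SEQ, residues)):
                seg = "polyQ" if aa == "Q" else "flank"
                conformer = "-"
                if aa == "Q":
                    xcol = int(round((res["CA"][0] - 2 * delta * zpar)
                                     / rise)) % 2
                    side = +1 if xcol == 0 else -1
                    cls = by_label[candidate.pair_class(xcol, q)]
                    real = realize_class(cls, geometry, side=side)
                    res.update(real.sidechain(res, "a" if zpar == 0
                                               else "b"))
                    order = _GLN_ORDER
                    name = "GLN"
                    conformer = candidate.strand_conformers[(zpar, q)]
                else:
                    name = {"D": "ASP", "K": "LYS"}[aa]
                    res.update(sidechain_from_template(name, res))
                    order = ["N", "CA", "C", "O"] + [
                        k for k in res if k not in ("N", "CA", "C", "O")]
                if j == n_res - 1:
                    res["OXT"] = geom.place_atom(
                        res["N"], res["CA"], res["C"], geom.BOND["c_o"],
                        117.0, geometry.beta_psi_deg)
                    order = list(order) + ["OXT"]
                acc.add_residue(res, order, name, j + 1, cid,
                                sheet=sheet, strand=strand,
                                conformer=conformer, segment=seg)

    model = acc.to_model(box=box, provenance={
        "builder": "q15_fibril",
        "candidate": candidate.canonical_id or candidate.encoding,
        "geometry": geometry.key(),
        "n_sheets": n_sheets, "peptides_per_sheet": peptides_per_sheet,
    })
    if validate:
        model.validate(geometry.clash_distance)
    return model


def _solve_hairpin_closure(scaffold: StrandScaffold, arm1_span: int,
                           turn, geometry: LatticeGeometry) -> tuple:
    """Solve the six turn-region torsions that close the β-hairpin.

    The second arm must continue as the exact antiparallel partner of the
    first (the two-fold image of the strand scaffold about the hairpin
    axis at the next strand slot).  The free torsions are ψ of the last
    arm-1 residue, φ/ψ of both turn residues and φ of the first arm-2
    residue — six degrees of freedom matching the six rigid-body degrees of
    the arm-2 placement.  Turn angles stay inside the turn-type basin.

    Returns (solved_six_torsions, residual_nm).
    """
    key = ("closure", scaffold.geometry.key(), arm1_span, tuple(turn))
    if key in _SCAFFOLD_CACHE:
        return _SCAFFOLD_CACHE[key]
    rise, dz = scaffold.rise, geometry.strand_spacing
    delta, zeta = scaffold.registry()
    axis_x = _rotation_center_x(arm1_span, rise) + delta
    m = int(round((axis_x - delta) / rise))
    # arm 2 pairs across the narrow, hydrogen-bonded gap below arm 1 (the
    # natural β-hairpin registry); residue k is the image of scaffold
    # residue j0 + k, shifted one cell down along the fibril axis
    j0 = 2 * m - arm1_span
    beta = (geometry.beta_phi_deg, geometry.beta_psi_deg,
            geometry.beta_omega_deg)
    i_end = arm1_span - 1

    target = {a: geom.rotation_y180(p, x0=axis_x, z0=dz / 2.0 + zeta)
              - np.array([0.0, 0.0, 2.0 * dz])
              for a, p in scaffold.residue_backbone(j0).items()
              if a in ("N", "CA", "C")}
    anchor = [scaffold.residue_backbone(i_end - 1),
              scaffold.residue_backbone(i_end)]

    def mapped_subchain(v):
        psi_end, phi_t1, psi_t1, phi_t2, psi_t2, phi_a2 = v
        tors = [(beta[0], beta[1], beta[2]),        # i_end - 1 (anchor)
                (beta[0], psi_end, beta[2]),        # i_end
                (phi_t1, psi_t1, 180.0),            # turn 1
                (phi_t2, psi_t2, 180.0),            # turn 2
                (phi_a2, beta[1], beta[2])]         # first arm-2 residue
        bb = geom.backbone_chain(tors)
        # rigid-map the subchain so its first two residues coincide with
        # the anchor scaffold slots
        src = np.concatenate([bb[0], bb[1]])
        ref = np.concatenate([np.stack([anchor[0][a] for a in ("N", "CA", "C")]),
                              np.stack([anchor[1][a] for a in ("N", "CA", "C")])])
        rot, shift = _kabsch(src, ref)
        return (rot @ bb.reshape(-1, 3).T).T.reshape(bb.shape) + shift

    # containment band: the turn must thread the gap between its own two
    # strand slots without dipping toward the neighbouring strands (z), the
    # neighbouring sheets (y) or back into the core (x)
    z_lo, z_hi = -(dz - 2 * zeta) - 0.10, 0.10
    y_half = 0.16
    x_min = (arm1_span - 1) * rise + 0.5 * rise
    phi2c, psi2c, phi3c, psi3c = turn

    def residuals(v):
        bb = mapped_subchain(v)
        frame = bb[4]
        ref = np.stack([target[a] for a in ("N", "CA", "C")])
        out = list((frame - ref).ravel())
        for turn_atom in bb[2:4].reshape(-1, 3):
            out.append(20.0 * max(0.0, z_lo - turn_atom[2],
                                  turn_atom[2] - z_hi))
            out.append(40.0 * max(0.0, abs(turn_atom[1]) - y_half))
            out.append(20.0 * max(0.0, x_min - turn_atom[0]))
        # keep the turn inside its canonical basin (soft): the classifier
        # radius is 40 degrees rms over the four angles
        devs = np.array([v[1] - phi2c, v[2] - psi2c, v[3] - phi3c,
                         v[4] - psi3c])
        rms = np.sqrt(np.mean(devs ** 2))
        out.append(0.05 * max(0.0, rms - 33.0))
        return out

    phi2, psi2, phi3, psi3 = turn
    x0 = [beta[1], phi2, psi2, phi3, psi3, beta[0]]
    lob = [beta[1] - 45, phi2 - 50, psi2 - 50, phi3 - 50, psi3 - 50,
           beta[0] - 45]
    upb = [beta[1] + 45, phi2 + 50, psi2 + 50, phi3 + 50, psi3 + 50,
           beta[0] + 45]
    sol = least_squares(residuals, x0, bounds=(lob, upb), xtol=1e-14,
                        ftol=1e-14, gtol=1e-14)
    residual = float(np.sqrt(np.mean(sol.fun ** 2)))
    result = (tuple(float(t) for t in sol.x), residual)
    _SCAFFOLD_CACHE[key] = result
    return result


def _kabsch(src: np.ndarray, ref: np.ndarray):
    src_c = src - src.mean(axis=0)
    ref_c = ref - ref.mean(axis=0)
    h = src_c.T @ ref_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    shift = ref.mean(axis=0) - rot @ src.mean(axis=0)
    return rot, shift


def _httex1_torsions(polyq_len: int, arm_len: int, closure,
                     geometry: LatticeGeometry, rng,
                     jitter_deg: float = 25.0) -> list:
    """Per-residue (phi, psi, omega) for one HTTex1 chain.

    ``closure`` holds the six solved turn-region torsions (ψ of the last
    arm-1 residue, φ/ψ of the two turn residues, φ of the first arm-2
    residue) that place the second hairpin arm on its lattice slot.
    """
    beta = (geometry.beta_phi_deg, geometry.beta_psi_deg,
            geometry.beta_omega_deg)
    helix = (-57.0, -47.0, 180.0)
    coil = (-120.0, 120.0, 180.0)
    ppii = (-75.0, 145.0, 180.0)
    psi_end, phi_t1, psi_t1, phi_t2, psi_t2, phi_a2 = closure
    n17 = len(N17_SEQ)
    tors = []
    for i in range(1, n17 + polyq_len + len(PRD_SEQ) + 1):
        if i <= 3 or 12 <= i <= 14:
            jit = (rng.uniform(-jitter_deg, jitter_deg, size=2)
                   if rng is not None else (0, 0))
            tors.append((coil[0] + jit[0], coil[1] + jit[1], 180.0))
        elif i <= 11:
            tors.append(helix)
        elif i <= n17 - 2:                  # K15, S16: coil linker
            jit = (rng.uniform(-jitter_deg, jitter_deg, size=2)
                   if rng is not None else (0, 0))
            tors.append((coil[0] + jit[0], coil[1] + jit[1], 180.0))
        elif i < n17 + arm_len:             # F17 + arm 1
            tors.append(beta)
        elif i == n17 + arm_len:            # last arm-1 residue
            tors.append((beta[0], psi_end, beta[2]))
        elif i == n17 + arm_len + 1:
            tors.append((phi_t1, psi_t1, 180.0))
        elif i == n17 + arm_len + 2:
            tors.append((phi_t2, psi_t2, 180.0))
        elif i == n17 + arm_len + 3:        # first arm-2 residue
            tors.append((phi_a2, beta[1], beta[2]))
        elif i <= n17 + polyq_len:          # arm 2
            tors.append(beta)
        else:                               # PRD
            pos = i - n17 - polyq_len       # 1-based within the PRD
            # oligoproline runs: PRD positions 1-11 (P62-P72 for Q44) and
            # 29-38 (P90-P99)
            if 1 <= pos <= 11 or 29 <= pos <= 38:
                tors.append(ppii)
            else:
                jit = (rng.uniform(-0.6 * jitter_deg, 0.6 * jitter_deg, size=2)
                       if rng is not None else (0, 0))
                tors.append((coil[0] + jit[0], coil[1] + jit[1], 180.0))
    return tors


def build_httex1_fibril(candidate: UnitCellCandidate, alphabet,
                        geometry: LatticeGeometry | None = None,
                        polyq_len: int = 44, n_sheets: int = 7,
                        hairpins_per_sheet: int = 20,
                        turn_type: str = "type_I_prime",
                        seed: int = 0, max_retries: int = 150,
                        coat_clash_policy: str = "report",
                        validate: bool = True) -> FibrilModel:
    """Q44-HTTex1 protofilament: β-hairpin core plus flanking fuzzy coat.

    Each of the ``n_sheets * hairpins_per_sheet`` chains carries the full
    exon-1 sequence.  The polyQ tract forms a β-hairpin of an 'a' and a 'b'
    strand joined by a two-residue turn (type I′ template by default);
    F17 extends the first arm into the core register, pairing the penultimate
    Gln of the neighbouring arm.  Residues 4–11 of N17 start α-helical, the
    PRD is an extended coil with polyproline-II dihedrals on P62–P72 and
    P90–P99.  Turns of neighbouring hairpins sit on opposite fibril sides;
    flanking-domain coil torsions are re-drawn (seeded) when a chain clashes
    with already placed atoms.

    Rigid idealized pieces at this grafting density can leave a few
    residual interatomic grazes in the disordered coat that only energy
    minimization (out of scope here) would settle.  With
    ``coat_clash_policy='report'`` (default) such residual coat contacts
    are counted in ``provenance['residual_coat_contacts']``; ``'strict'``
    raises instead.  Core-core clashes always raise.
    """
    _require_filtered(candidate)
    if polyq_len < 8 or polyq_len % 2 != 0:
        raise BuildError("polyq_len must be an even number >= 8 to form a "
                         "two-strand hairpin with a two-residue turn")
    geometry = geometry or LatticeGeometry()
    by_label = {c.label: c for c in alphabet}
    scaffold = StrandScaffold(geometry)
    rise, dz, dy = scaffold.rise, geometry.strand_spacing, geometry.sheet_spacing
    delta, zeta = scaffold.registry()
    # asymmetric split: F17 + arm-1 glutamines occupy one slot less than
    # arm 2, whose far end then reaches past F17 so that F17 pairs the
    # penultimate glutamine across the hairpin
    arm_len = polyq_len // 2 - 2
    arm2_len = polyq_len - 2 - arm_len
    turn = TURN_TEMPLATES[turn_type]
    n17 = len(N17_SEQ)
    sequence = HTTEX1_SEQUENCE(polyq_len)
    rng_master = np.random.default_rng(seed)

    from .residue_templates import sidechain_from_template

    # reference arm-1 backbone on the lattice slot, for alignment; only
    # F17 of N17 enters the core register (pairing the penultimate Gln of
    # the neighbouring arm), the rest of N17 belongs to the flexible coat
    arm1_first = n17 - 1            # residue index (0-based) of F17
    arm1_span = 1 + arm_len         # F17 + arm-1 glutamines
    closure, closure_residual = _solve_hairpin_closure(scaffold, arm1_span,
                                                       turn, geometry)

    def align_to_slot(coords, tors):
        """Rigid transform mapping the chain's arm-1 onto the slot scaffold."""
        idx = list(range(arm1_first, arm1_first + arm1_span))
        src = np.concatenate([coords[i] for i in idx])     # (3*span, 3)
        ref = []
        for k, i in enumerate(idx):
            bb = scaffold.residue_backbone(k)
            ref.append(np.stack([bb["N"], bb["CA"], bb["C"]]))
        ref = np.concatenate(ref)
        src_c = src - src.mean(axis=0)
        ref_c = ref - ref.mean(axis=0)
        h = src_c.T @ ref_c
        u, _, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(vt.T @ u.T))
        rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
        shift = ref.mean(axis=0) - rot @ src.mean(axis=0)
        return rot, shift

    acc = _ModelAccumulator()
    placed_coords = []
    chains_data = []
    tree = None
    chain_idx = 0
    clash_cut = geometry.clash_distance
    n_chains = n_sheets * hairpins_per_sheet
    axis_x = _rotation_center_x(arm1_span, rise) + delta
    m_axis = int(round((axis_x - delta) / rise))
    j0 = 2 * m_axis - arm1_span
    turn_end = n17 + arm_len + 2          # 1-based last turn residue
    beta_psi = geometry.beta_psi_deg

    # deterministic core template (F17 + arm 1 + turn + arm 2) in slot
    # coordinates; every chain's core is a rigid copy, so the exact core
    # atoms of all chains are known before any flexible coat is placed
    tors0 = _httex1_torsions(polyq_len, arm_len, closure, geometry, None)
    bb1_0 = geom.backbone_chain(tors0[:turn_end])
    rot0, shift0 = align_to_slot(bb1_0, tors0)
    bb1_0 = (rot0 @ bb1_0.reshape(-1, 3).T).T.reshape(bb1_0.shape) + shift0
    bb2_0 = np.zeros((arm2_len, 3, 3))
    for k in range(arm2_len):
        img = {a: geom.rotation_y180(p, x0=axis_x, z0=dz / 2.0 + zeta)
               - np.array([0.0, 0.0, 2.0 * dz])
               for a, p in scaffold.residue_backbone(j0 + k).items()}
        bb2_0[k] = [img["N"], img["CA"], img["C"]]
    core_bb = np.concatenate([bb1_0[arm1_first:], bb2_0])
    core_first = arm1_first + 1               # 1-based F17
    core_last = n17 + polyq_len               # 1-based last polyQ residue

    # rotamer context for the template's F17 and turn glutamines: backbone
    # images of the neighbouring hairpins and sheets
    # full-chain template coordinates (core atoms and exit-lane reference)
    coords0 = np.concatenate([bb1_0, bb2_0,
                              geom.extend_backbone(*bb2_0[-1], beta_psi,
                                                   tors0[n17 + polyq_len:])])
    own_guard = np.concatenate([coords0[core_last:core_last + 14],
                                coords0[arm1_first - 2:arm1_first]]
                               ).reshape(-1, 3)
    context = [core_bb.reshape(-1, 3), own_guard]
    rot_core = geom.rotation_y180(core_bb.reshape(-1, 3), x0=axis_x,
                                  z0=dz / 2.0 + zeta)
    # a rotated hairpin occupies the slot pair directly above the template,
    # so its images sit at 0 and -2dz
    for dz_off in (0.0, -2 * dz):
        context.append(rot_core + np.array([0.0, 0.0, dz_off]))
    for dy_off in (-dy, dy):
        context.append(core_bb.reshape(-1, 3) + np.array([0.0, dy_off, 0.0]))
        for dz_off in (0.0, -2 * dz):
            context.append(rot_core + np.array([0.0, dy_off, dz_off]))
    context_tree = cKDTree(np.concatenate(context))
    # two passes: the first yields the ladder side-chain cloud, whose
    # sheet/strand images then join the rotamer context of the second, so
    # F17 and the nominal turn also clear the neighbours' side chains
    core_res0 = {}
    core_pts0 = {}
    for pass_i in range(2):
        for swap in (False, True):
            res_list = _httex1_chain_atoms(
                coords0, tors0, sequence, n17, polyq_len, arm_len, False, 0,
                delta, rise, candidate, by_label, geometry, context_tree,
                first_res=core_first, last_res=core_last, slot_swap=swap)
            core_res0[swap] = res_list
            core_pts0[swap] = np.concatenate(
                [np.stack(list(r[0].values())) for r in res_list])
        if pass_i == 0:
            extra = []
            for swap in (False, True):
                cloud = core_pts0[swap]
                rot_cloud = geom.rotation_y180(cloud, x0=axis_x,
                                               z0=dz / 2.0 + zeta)
                for dy_off in (-dy, 0.0, dy):
                    if dy_off != 0.0:
                        extra.append(cloud + np.array([0.0, dy_off, 0.0]))
                    for dz_off in (0.0, -2 * dz):
                        extra.append(rot_cloud
                                     + np.array([0.0, dy_off, dz_off]))
            context_tree = cKDTree(np.concatenate(context + extra))
    core_resno0 = np.concatenate(
        [np.full(len(r[0]), core_first + k)
         for k, r in enumerate(core_res0[False])])
    # exact core atoms of every chain form the static obstacle cloud
    obstacle_pts = []
    obstacle_chain = []
    core_sets = []
    for c_idx in range(n_chains):
        c_sheet, c_hp = divmod(c_idx, hairpins_per_sheet)
        pts = core_pts0[bool(c_hp % 2)]
        if c_hp % 2:
            pts = geom.rotation_y180(pts, x0=axis_x, z0=dz / 2.0 + zeta)
        pts = pts + np.array([0.0, c_sheet * dy,
                              2 * (c_hp - c_hp % 2) * dz])
        core_sets.append(pts)
        obstacle_pts.append(pts)
        obstacle_chain.append(np.full(len(pts), c_idx))
    obstacle_tree = cKDTree(np.concatenate(obstacle_pts))
    obstacle_chain = np.concatenate(obstacle_chain)
    # nominal PRD exit lanes of every chain: N17 placements must keep out
    # of all of them, not only their own
    lane_guard0 = coords0[core_last:core_last + 14].reshape(-1, 3)
    lane_pts = []
    for c_idx in range(n_chains):
        c_sheet, c_hp = divmod(c_idx, hairpins_per_sheet)
        pts = lane_guard0
        if c_hp % 2:
            pts = geom.rotation_y180(pts, x0=axis_x, z0=dz / 2.0 + zeta)
        lane_pts.append(pts + np.array([0.0, c_sheet * dy,
                                        2 * (c_hp - c_hp % 2) * dz]))


    def transform_residues(res_list, rotate_flag, offset_vec):
        out = []
        for res, order, name, seg, conf in res_list:
            moved = {}
            for a, pos in res.items():
                q_ = (geom.rotation_y180(pos, x0=axis_x, z0=dz / 2.0 + zeta)
                      if rotate_flag else pos)
                moved[a] = q_ + offset_vec
            out.append((moved, order, name, seg, conf))
        return out

    def clash_count(pts, resno, other_trees, own_pts=None, own_resno=None):
        n = 0
        for t in other_trees:
            if t is not None:
                n += int(np.sum(t.query_ball_point(pts, clash_cut,
                                                   return_length=True)))
        if own_pts is not None:
            t_own = cKDTree(own_pts)
            for k, hits in enumerate(t_own.query_ball_point(pts, clash_cut)):
                for h in hits:
                    if abs(resno[k] - own_resno[h]) > 2:
                        n += 1
        t_self = cKDTree(pts)
        for ii, jj in t_self.query_pairs(clash_cut):
            if abs(resno[ii] - resno[jj]) > 2:
                n += 1
        return n

    for sheet in range(n_sheets):
        q = sheet % 2
        for hp in range(hairpins_per_sheet):
            cid = chain_label(chain_idx)
            this_chain = chain_idx
            chain_idx += 1
            rotate = bool(hp % 2)
            offset = np.array([0.0, sheet * dy,
                               2 * (hp - hp % 2) * dz])
            core_res = transform_residues(core_res0[rotate], rotate, offset)
            core_pts = core_sets[this_chain]
            # obstacle cloud of every *other* chain's core
            if n_chains > 1:
                other_core = cKDTree(np.concatenate(
                    [core_sets[c] for c in range(n_chains)
                     if c != this_chain]))
            else:
                other_core = None
            own_lane_tree = cKDTree(lane_pts[this_chain])
            if n_chains > 1:
                other_lane_tree = cKDTree(np.concatenate(
                    [lane_pts[c] for c in range(n_chains)
                     if c != this_chain]))
            else:
                other_lane_tree = None

            # ---- stage 0: per-chain turn refinement ------------------
            # the turn caps are the one crowded spot a rigid template
            # cannot settle globally: re-draw the turn torsions around the
            # closure solution and re-pick its rotamers until the cap is
            # clash-free against everything known
            t1 = n17 + arm_len + 1          # 1-based first turn residue
            turn_list_idx = [t1 - core_first, t1 + 1 - core_first]
            arm_prev = core_res[turn_list_idx[0] - 1][0]
            fixed_core = [r for k, r in enumerate(core_res)
                          if k not in turn_list_idx]
            fixed_pts = np.concatenate(
                [np.stack(list(r[0].values())) for r in fixed_core])
            fixed_resno = np.concatenate(
                [np.full(len(r[0]), core_first + k)
                 for k, r in enumerate(core_res) if k not in turn_list_idx])
            best = None
            for attempt in range(max(10, max_retries // 8)):
                rng = np.random.default_rng(
                    (seed * 3000017 + sheet * 149 + hp * 13 + attempt)
                    % (2**31))
                jit = (rng.uniform(-14, 14, size=5) if attempt > 0
                       else np.zeros(5))
                psi_end, p1_, s1_, p2_, s2_ = (
                    np.array(closure[:5]) + jit)
                bb_t = geom.extend_backbone(
                    arm_prev["N"], arm_prev["CA"], arm_prev["C"], psi_end,
                    [(p1_, s1_, 180.0), (p2_, s2_, 180.0)])
                turn_res = []
                turn_pts = []
                clouds = [fixed_pts]
                for k2, (tphi, tpsi) in enumerate(((p1_, s1_), (p2_, s2_))):
                    n_, ca_, c_ = bb_t[k2]
                    res = {"N": n_, "CA": ca_, "C": c_,
                           "O": geom.carbonyl_oxygen(n_, ca_, c_, tpsi)}
                    res["CB"] = geom.cbeta_position(n_, ca_, c_)
                    env = np.concatenate(clouds)
                    best_sc, best_clear = None, -1.0
                    for chi1 in (-177.0, -65.0, 62.0):
                        for chi2 in (65.0, 180.0, -65.0):
                            sc_ = gln_sidechain(res, chi1, chi2, 0.0)
                            pts_ = np.stack(list(sc_.values()))
                            clear = float(np.min(np.linalg.norm(
                                pts_[:, None, :] - env[None, :, :],
                                axis=-1)))
                            if other_core is not None:
                                d_, _ = other_core.query(pts_)
                                clear = min(clear, float(np.min(d_)))
                            if tree is not None:
                                d_, _ = tree.query(pts_)
                                clear = min(clear, float(np.min(d_)))
                            if clear > best_clear:
                                best_sc, best_clear = sc_, clear
                    res.update(best_sc)
                    turn_res.append((res, _GLN_ORDER, "GLN", "turn", "-"))
                    turn_pts.append(np.stack(list(res.values())))
                    clouds.append(turn_pts[-1])
                turn_pts = np.concatenate(turn_pts)
                turn_resno = np.concatenate(
                    [np.full(len(r[0]), t1 + k2)
                     for k2, r in enumerate(turn_res)])
                n_clash = clash_count(turn_pts, turn_resno,
                                      [tree, other_core],
                                      fixed_pts, fixed_resno)
                if best is None or n_clash < best[0]:
                    best = (n_clash, turn_res, turn_pts)
                if n_clash == 0:
                    break
            n_clash, turn_res, turn_pts = best
            if n_clash > 20 and validate and coat_clash_policy == "strict":
                raise BuildError(
                    f"chain {cid}: turn placement clash persists after "
                    f"{max_retries} retry orientations")
            for k2, idx in enumerate(turn_list_idx):
                core_res[idx] = turn_res[k2]
            core_pts = np.concatenate(
                [np.stack(list(r[0].values())) for r in core_res])

            combo_best = None
            n_outer = 3
            n_inner = max(6, max_retries // 10)
            for outer in range(n_outer):
                # ---- stage 1: the N17 segment (short, placed first) ------
                best = None
                for attempt in range(max_retries):
                    rng = np.random.default_rng(
                        (seed * 2000003 + sheet * 137 + hp * 11 + attempt)
                        % (2**31))
                    tors = _httex1_torsions(polyq_len, arm_len, closure, geometry,
                                            rng if attempt > 0 else None,
                                            jitter_deg=min(15 + 4 * attempt, 50))
                    bb1 = geom.backbone_chain(tors[:turn_end])
                    rot, shift = align_to_slot(bb1, tors)
                    bb1 = (rot @ bb1.reshape(-1, 3).T).T.reshape(bb1.shape) + shift
                    n17_angle = (50.0 if sheet % 2 == 0 else 62.0) * DEG
                    n17_y = 0.0
                    if attempt > 0:
                        n17_angle += rng.uniform(-14, 14) * DEG
                        n17_y = rng.uniform(-18, 18) * DEG
                    n17_dir = np.array([-np.cos(n17_angle), np.sin(n17_y),
                                        -np.sin(n17_angle)])
                    n17_dir /= np.linalg.norm(n17_dir)
                    n17_bb = _swing_piece(bb1[:arm1_first],
                                          anchor=bb1[arm1_first, 0],
                                          target_dir=n17_dir)
                    if rotate:
                        flat = geom.rotation_y180(n17_bb.reshape(-1, 3),
                                                  x0=axis_x, z0=dz / 2.0 + zeta)
                        n17_bb = flat.reshape(n17_bb.shape)
                    n17_bb = n17_bb + offset
                    coords_n17 = np.concatenate(
                        [n17_bb, np.zeros((len(sequence) - arm1_first, 3, 3))])
                    n17_res = _httex1_chain_atoms(
                        coords_n17, tors, sequence, n17, polyq_len, arm_len,
                        rotate, q, delta, rise, candidate, by_label, geometry,
                        tree, last_res=arm1_first)
                    pts = np.concatenate(
                        [np.stack(list(r[0].values())) for r in n17_res])
                    resno = np.concatenate(
                        [np.full(len(r[0]), 1 + k)
                         for k, r in enumerate(n17_res)])
                    n_clash = clash_count(pts, resno, [tree, other_core],
                                          core_pts, core_resno0)
                    n_clash += sum(len(h) for h in
                                   own_lane_tree.query_ball_point(pts, 0.20))
                    if other_lane_tree is not None:
                        n_clash += sum(len(h) for h in
                                       other_lane_tree.query_ball_point(pts,
                                                                        0.28))
                    if best is None or n_clash < best[0]:
                        best = (n_clash, n17_res, pts)
                        stall = 0
                    else:
                        stall += 1
                    if n_clash == 0 or (stall > 5 and best[0] <= 2):
                        break
                n_clash_n17, n17_res, n17_pts = best
                n17_resno = np.concatenate(
                    [np.full(len(r[0]), 1 + k) for k, r in enumerate(n17_res)])

                # ---- stage 2: the PRD rod (long, flexible, dodges last) --
                best = None
                for attempt in range(max_retries):
                    rng = np.random.default_rng(
                        (seed * 1000003 + sheet * 131 + hp * 7 + attempt)
                        % (2**31))
                    tors = _httex1_torsions(polyq_len, arm_len, closure, geometry,
                                            rng if attempt > 0 else None,
                                            jitter_deg=min(15 + 4 * attempt, 50))
                    prd_tors = tors[n17 + polyq_len:]
                    # the junction psi spins the oligoproline rod about its own
                    # axis, orienting the ring/carbonyl envelope in the tight
                    # exit corridor
                    psi_exit = beta_psi + (rng.uniform(-180.0, 180.0)
                                           if attempt > 0 else 0.0)
                    # layout: rods run in the chain's own sheet plane; the
                    # first oligoproline run leaves almost level through the
                    # corridor between the hairpin arms, the rest dives below
                    # the fibril axis; alternating tilts with sheet parity
                    # makes the line families of adjacent sheets diverge
                    prd_angle = (22.0 if sheet % 2 == 0 else 36.0) * DEG
                    prd_y = exit_y = 0.0
                    if attempt > 0:
                        prd_angle += rng.uniform(-8, 8) * DEG
                        prd_y = rng.uniform(-8, 8) * DEG
                        exit_y = rng.uniform(-10, 10) * DEG
                    # exit shape: the first hairpin dives directly into free
                    # space; later hairpins first rise over the previous
                    # hairpin's turn-side corner, run level until the core is
                    # cleared, then dive
                    if hp == 0:
                        a1 = a2 = (8.0 if sheet % 2 == 0 else 11.0) * DEG
                    else:
                        a1 = -14.0 * DEG
                        a2 = (0.0 if sheet % 2 == 0 else 6.0) * DEG
                    if attempt > 0:
                        a1 += rng.uniform(-6, 6) * DEG
                        a2 += rng.uniform(-8, 8) * DEG

                    def _dir(angle, ycomp):
                        v = np.array([-np.cos(angle), np.sin(ycomp),
                                      -np.sin(angle)])
                        return v / np.linalg.norm(v)

                    prd_dir = _dir(prd_angle, prd_y)
                    seg_dirs = [_dir(a1, exit_y), _dir(a2, exit_y), prd_dir,
                                prd_dir, prd_dir]
                    bb3_parts = []
                    prev = core_bb[-1]
                    prev_psi = psi_exit
                    for seg_i, (lo, hi) in enumerate(((0, 4), (4, 11), (11, 28),
                                                      (28, 38), (38, 50))):
                        part = geom.extend_backbone(*prev, prev_psi,
                                                    prd_tors[lo:hi])
                        part = _swing_piece(part, anchor=prev[2],
                                            target_dir=seg_dirs[seg_i])
                        bb3_parts.append(part)
                        prev = part[-1]
                        prev_psi = prd_tors[hi - 1][1]
                    bb3 = np.concatenate(bb3_parts)
                    if rotate:
                        flat = geom.rotation_y180(bb3.reshape(-1, 3), x0=axis_x,
                                                  z0=dz / 2.0 + zeta)
                        bb3 = flat.reshape(bb3.shape)
                    bb3 = bb3 + offset
                    coords_prd = np.concatenate(
                        [np.zeros((core_last, 3, 3)), bb3])
                    prd_res = _httex1_chain_atoms(
                        coords_prd, tors, sequence, n17, polyq_len, arm_len,
                        rotate, q, delta, rise, candidate, by_label, geometry,
                        tree, first_res=core_last + 1)
                    pts = np.concatenate(
                        [np.stack(list(r[0].values())) for r in prd_res])
                    resno = np.concatenate(
                        [np.full(len(r[0]), core_last + 1 + k)
                         for k, r in enumerate(prd_res)])
                    own_pts = np.concatenate([n17_pts, core_pts])
                    own_resno = np.concatenate([n17_resno, core_resno0])
                    n_clash = clash_count(pts, resno, [tree, other_core],
                                          own_pts, own_resno)
                    if best is None or n_clash < best[0]:
                        best = (n_clash, prd_res, pts)
                        stall = 0
                    else:
                        stall += 1
                    if n_clash == 0 or (stall > 5 and best[0] <= 2):
                        break
                n_clash_prd, prd_res, prd_pts = best
                total = n_clash_n17 + n_clash_prd
                if combo_best is None or total < combo_best[0]:
                    combo_best = (total, n17_res, n17_pts, prd_res, prd_pts)
                if combo_best[0] <= (0 if outer < 2 else 2):
                    break
            total, n17_res, n17_pts, prd_res, prd_pts = combo_best
            if total > 0 and validate and coat_clash_policy == "strict":
                raise BuildError(
                    f"chain {cid}: coat placement clash persists after "
                    f"joint retries")
            all_res = list(n17_res) + list(core_res) + list(prd_res)
            chains_data.append((cid, sheet, 2 * hp + (1 if rotate else 0),
                                all_res))
            placed_coords.extend(np.concatenate([n17_pts, core_pts,
                                                 prd_pts]))
            tree = cKDTree(np.asarray(placed_coords))



    # residual grazes between rigid pieces are relieved by re-picking the
    # rotamers of the involved side chains against the assembled model
    _repair_side_chains(chains_data, clash_cut)
    for cid, sheet_i, strand_i, all_res in chains_data:
        for k, (res, order, name, seg, conformer) in enumerate(all_res):
            acc.add_residue(res, order, name, k + 1, cid,
                            sheet=sheet_i, strand=strand_i,
                            conformer=conformer, segment=seg)
    model = acc.to_model(box=None, provenance={
        "builder": "httex1_fibril",
        "candidate": candidate.canonical_id or candidate.encoding,
        "geometry": geometry.key(),
        "polyq_len": polyq_len, "n_sheets": n_sheets,
        "hairpins_per_sheet": hairpins_per_sheet, "seed": seed,
        "n_chains": n_chains,
    })
    if validate:
        residual = model.find_clashes(geometry.clash_distance)
        coat_segs = {"N17", "PRD", "turn"}
        segments = model.atoms["segment"].to_numpy()
        core_core = [(i, j) for i, j in residual
                     if segments[i] not in coat_segs
                     and segments[j] not in coat_segs]
        if core_core:
            i, j = core_core[0]
            a, b = model.atoms.iloc[i], model.atoms.iloc[j]
            raise BuildError(
                f"core steric clash: {a['chain_id']}/{a['res_seq']}/"
                f"{a['name']} vs {b['chain_id']}/{b['res_seq']}/{b['name']}")
        if residual and coat_clash_policy == "strict":
            raise BuildError(f"{len(residual)} residual coat contacts below "
                             f"{geometry.clash_distance} nm")
        model.provenance["residual_coat_contacts"] = len(residual)
    return model


_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}
_UNROTATABLE = {"GLY", "ALA", "PRO"}


def _repair_side_chains(chains_data, cutoff: float, rounds: int = 4) -> None:
    """Re-pick rotamers of side chains involved in residual atom grazes.

    Operates in place on the per-chain residue lists.  Each round finds the
    remaining clash pairs, and for every involved rotatable side chain
    searches a χ1 × χ2 grid for the orientation with the largest clearance
    from everything else.
    """
    from .residue_templates import set_chi1, set_chi2

    for _ in range(rounds):
        positions = []
        owner = []  # (chain_idx, residue_idx, atom_name)
        for ci, (_, _, _, res_list) in enumerate(chains_data):
            for ri, (res, _, _, _, _) in enumerate(res_list):
                for an, pos in res.items():
                    positions.append(pos)
                    owner.append((ci, ri, an))
        positions = np.asarray(positions)
        tree = cKDTree(positions)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        if len(pairs) == 0:
            return
        cands = []
        seen = set()
        for i, j in pairs:
            ci, ri, ai = owner[i]
            cj, rj, aj = owner[j]
            if ci == cj and abs(ri - rj) <= 2:
                continue
            for (cc, rr, an) in ((ci, ri, ai), (cj, rj, aj)):
                entry = chains_data[cc][3][rr]
                # only flexible-coat side chains may be re-rotamered: core
                # glutamines carry ladder-solved angles
                if (an not in _BACKBONE_NAMES
                        and entry[2] not in _UNROTATABLE
                        and entry[3] in ("N17", "PRD", "turn")):
                    key = (cc, rr)
                    if key not in seen:
                        seen.add(key)
                        cands.append(key)
        if not cands:
            return
        row_of = {(oc, orr, an): k for k, (oc, orr, an) in enumerate(owner)}
        for cc, rr in cands:
            res, order, name, seg, conf = chains_data[cc][3][rr]
            side_names = [a for a in res if a not in _BACKBONE_NAMES]
            if "CB" not in res or len(side_names) < 2:
                continue
            env_idx = [k for k, (oc, orr, _) in enumerate(owner)
                       if not (oc == cc and abs(orr - rr) <= 1)]
            env_tree = cKDTree(positions[env_idx])
            best = None
            for chi1 in (-177.0, -150.0, -90.0, -65.0, -30.0, 30.0, 62.0,
                         90.0, 150.0):
                for chi2 in (180.0, 65.0, -65.0, 120.0, -120.0):
                    trial = dict(res)
                    set_chi1(trial, chi1)
                    set_chi2(trial, chi2)
                    pts = np.stack([trial[a] for a in side_names
                                    if a != "CB"])
                    d, _ = env_tree.query(pts)
                    clear = float(np.min(d))
                    if best is None or clear > best[0]:
                        best = (clear, trial)
            if best is not None:
                chains_data[cc][3][rr] = (best[1], order, name, seg, conf)
                # keep the working positions fresh so later repairs see the
                # moved side chain
                for an, pos in best[1].items():
                    positions[row_of[(cc, rr, an)]] = pos


def _swing_piece(piece: np.ndarray, anchor: np.ndarray,
                 target_dir: np.ndarray, guide: int | None = None) -> np.ndarray:
    """Rigidly rotate a chain piece about its junction anchor so that its
    direction vector points along target_dir.

    The direction is anchor→CA of the ``guide`` residue (the farthest CA
    when omitted); aligning a proximal guide makes the piece leave the
    junction along the target immediately.  Bond lengths across the
    junction are preserved (pure rotation about the anchor); the junction
    bond angle absorbs the reorientation, the same class of idealization
    as the hairpin-turn closure strain.
    """
    ca = piece[:, 1, :]
    if guide is None:
        d = np.linalg.norm(ca - anchor, axis=1)
        guide = int(np.argmax(d))
    u = ca[guide] - anchor
    u = u / np.linalg.norm(u)
    t = np.asarray(target_dir, dtype=float)
    t = t / np.linalg.norm(t)
    axis = np.cross(u, t)
    s = np.linalg.norm(axis)
    c = float(np.dot(u, t))
    if s < 1e-12:
        if c > 0:
            return piece
        axis = np.cross(u, np.array([0.0, 1.0, 0.0]))
        axis /= np.linalg.norm(axis)
        s, c = 0.0, -1.0
    else:
        axis = axis / s
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    rot = np.eye(3) + s * k + (1 - c) * (k @ k)
    flat = piece.reshape(-1, 3)
    flat = (rot @ (flat - anchor).T).T + anchor
    return flat.reshape(piece.shape)


def _httex1_chain_atoms(coords, tors, sequence, n17, polyq_len, arm_len,
                        rotate, q, delta, rise, candidate, by_label,
                        geometry, tree, first_res: int = 1,
                        last_res: int | None = None,
                        slot_swap: bool = False):
    dy_img = np.array([0.0, geometry.sheet_spacing, 0.0])

    def image_clearance(pts):
        # identical copies of this chain exist one sheet away; a rotamer
        # must clear its own translated image as well
        return float(np.min(np.linalg.norm(
            pts[:, None, :] - (pts[None, :, :] + dy_img), axis=-1)))
    """All-atom residues for one HTTex1 chain from its backbone trace.

    Returns a list of (atoms, order, res_name, segment, conformer) for the
    1-based residue range [first_res, last_res], in sequence order.  Turn
    glutamines pick the rotamer with the most clearance from the chain and
    from already placed atoms.
    """
    from .residue_templates import sidechain_from_template

    residues = []
    for i, aa in enumerate(sequence):
        resno = i + 1
        if resno < first_res or (last_res is not None and resno > last_res):
            continue
        n_, ca_, c_ = coords[i]
        psi = tors[i][1]
        res = {"N": n_, "CA": ca_, "C": c_,
               "O": geom.carbonyl_oxygen(n_, ca_, c_, psi)}
        if resno <= n17:
            seg = "N17"
        elif resno <= n17 + polyq_len:
            in_turn = (n17 + arm_len + 1 <= resno <= n17 + arm_len + 2)
            seg = "turn" if in_turn else "polyQ"
        else:
            seg = "PRD"
        conformer = "-"
        if aa == "Q" and seg == "polyQ":
            arm = 0 if resno <= n17 + arm_len else 1
            # the ladder slot alternates with strand parity: a rotated
            # hairpin's first arm sits on an odd (−x) slot, so its arms'
            # conformers swap — every hairpin still pairs one 'a' with one
            # 'b' strand
            even_slot = (arm == 0) != slot_swap
            conformer = "a" if even_slot else "b"
            xcol = int(round((res["CA"][0]
                              - 2 * delta * (1 if rotate else 0)) / rise)) % 2
            cls = by_label[candidate.pair_class(xcol, q)]
            real = realize_class(cls, geometry, side=+1 if xcol == 0 else -1)
            res["CB"] = geom.cbeta_position(n_, ca_, c_)
            res.update(real.sidechain(res, "a" if even_slot else "b"))
            order = _GLN_ORDER
            name = "GLN"
        elif aa == "Q" and seg == "turn":
            # the turn flips the local frame, so no single default rotamer
            # is safe: pick the one clearing the chain and placed atoms best
            res["CB"] = geom.cbeta_position(n_, ca_, c_)
            backbone_pts = np.delete(coords, i, axis=0).reshape(-1, 3)
            best_sc, best_clear = None, -1.0
            for chi1 in (-177.0, -65.0, 62.0):
                for chi2 in (65.0, 180.0, -65.0):
                    sc = gln_sidechain(res, chi1, chi2, 0.0)
                    pts = np.stack(list(sc.values()))
                    clear = np.min(np.linalg.norm(
                        pts[:, None, :] - backbone_pts[None, :, :], axis=-1))
                    clear = min(clear, image_clearance(pts))
                    if tree is not None:
                        d_placed, _ = tree.query(pts)
                        clear = min(clear, float(np.min(d_placed)))
                    if clear > best_clear:
                        best_sc, best_clear = sc, clear
            res.update(best_sc)
            order = _GLN_ORDER
            name = "GLN"
        else:
            name = _ONE_TO_THREE[aa]
            if aa != "G":
                res.update(sidechain_from_template(name, res))
                if resno == n17:
                    # F17 sits on the core lattice: pick the ring rotamer
                    # with the most clearance from the surrounding lattice
                    from .residue_templates import set_chi1, set_chi2
                    best_sc, best_clear = None, -1.0
                    for chi1 in (-177.0, -150.0, -90.0, -65.0, -30.0,
                                 30.0, 62.0, 90.0, 150.0):
                        for chi2 in (-90.0, -45.0, 45.0, 90.0):
                            trial = dict(res)
                            set_chi1(trial, chi1)
                            set_chi2(trial, chi2)
                            side_pts = np.stack(
                                [v for k_, v in trial.items()
                                 if k_ not in ("N", "CA", "C", "O", "CB")])
                            clear = image_clearance(side_pts)
                            if tree is not None:
                                d_, _ = tree.query(side_pts)
                                clear = min(clear, float(np.min(d_)))
                            if clear > best_clear:
                                best_sc, best_clear = trial, clear
                    res.update(best_sc)
            order = ["N", "CA", "C", "O"] + [
                k for k in res if k not in ("N", "CA", "C", "O")]
        if resno == len(sequence):
            res["OXT"] = geom.place_atom(res["N"], res["CA"], res["C"],
                                         geom.BOND["c_o"], 117.0, psi)
            order = list(order) + ["OXT"]
        residues.append((res, order, name, seg, conformer))
    return residues


_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}
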