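"""Conformer and hydrogen-bond analyses of fibril models and trajectories.

Covers dihedral extraction from coordinates, glutamine rotamer
classification (pt20°, mt-30°, pm0° nomenclature), ssNMR window compliance,
side-chain amide ladder detection, β-turn typing, and secondary-structure
occupancy of flanking-domain ensembles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core_builder import FibrilModel
from .geometry import dihedral_angle, wrap_angle
from .stability import DihedralTrajectory, circular_distance

__all__ = [
    "RotamerClass",
    "SSNMRWindows",
    "LadderReport",
    "default_rotamer_classes",
    "default_ssnmr_windows",
    "extract_dihedrals",
    "classify_rotamers",
    "check_ssnmr_windows",
    "detect_hbond_ladders",
    "classify_turn",
    "secondary_structure_occupancy",
]


@dataclass(frozen=True)
class RotamerClass:
    """A named (χ1, χ2, χ3) rotamer well with per-dihedral half-widths.

    A ``None`` window leaves that dihedral unconstrained; χ3 is
    unconstrained by default because the amide orientation in ladder
    geometries is set by the hydrogen-bond network, not the rotamer well.
    """

    name: str
    chi1_center: float
    chi2_center: float
    chi3_center: float
    window_chi1: float | None = 45.0
    window_chi2: float | None = 45.0
    window_chi3: float | None = None

    def contains(self, chi1, chi2, chi3) -> bool:
        for value, center, window in (
                (chi1, self.chi1_center, self.window_chi1),
                (chi2, self.chi2_center, self.window_chi2),
                (chi3, self.chi3_center, self.window_chi3)):
            if window is not None and circular_distance(value, center) > window:
                return False
        return True

    def distance(self, chi1, chi2, chi3) -> float:
        parts = []
        for value, center, window in (
                (chi1, self.chi1_center, self.window_chi1),
                (chi2, self.chi2_center, self.window_chi2),
                (chi3, self.chi3_center, self.window_chi3)):
            if window is not None:
                parts.append(circular_distance(value, center) / window)
        return float(np.sqrt(np.mean(np.square(parts)))) if parts else np.inf


def default_rotamer_classes() -> list:
    """The glutamine rotamers of the standard nomenclature used here."""
    return [
        RotamerClass("pt20", 62.0, 180.0, 20.0),
        RotamerClass("mt-30", -65.0, 180.0, -30.0),
        RotamerClass("pm0", 62.0, -65.0, 0.0),
    ]


def _verify_exclusive(classes) -> None:
    for i, a in enumerate(classes):
        for b in classes[i + 1:]:
            separable = False
            for ca, cb, wa, wb in (
                    (a.chi1_center, b.chi1_center, a.window_chi1, b.window_chi1),
                    (a.chi2_center, b.chi2_center, a.window_chi2, b.window_chi2),
                    (a.chi3_center, b.chi3_center, a.window_chi3, b.window_chi3)):
                if wa is None or wb is None:
                    continue
                if circular_distance(ca, cb) > wa + wb:
                    separable = True
                    break
            if not separable:
                raise ValueError(
                    f"rotamer classes {a.name!r} and {b.name!r} overlap for "
                    "the configured windows")


@dataclass(frozen=True)
class SSNMRWindows:
    """Per-conformer allowed intervals for χ1, χ2 and ψ.

    ``windows[conformer][dihedral] = (center, half_width)`` in degrees.
    The defaults are deliberately wide estimates of the graphically
    published constraints.
    """

    windows: dict

    def __post_init__(self):
        for conf, per_dih in self.windows.items():
            for dih, (center, half) in per_dih.items():
                if half <= 0:
                    raise ValueError(f"empty window for {conf}/{dih}")
            if "chi2" in per_dih:
                center, half = per_dih["chi2"]
                if circular_distance(center, 180.0) > half:
                    raise ValueError("chi2 window must contain 180 degrees")

    def contains(self, conformer: str, dihedral: str, value) -> np.ndarray:
        center, half = self.windows[conformer][dihedral]
        return circular_distance(value, center) <= half


def default_ssnmr_windows() -> SSNMRWindows:
    return SSNMRWindows(windows={
        "a": {"chi1": (62.0, 50.0), "chi2": (180.0, 50.0),
              "psi": (135.0, 45.0)},
        "b": {"chi1": (-65.0, 50.0), "chi2": (180.0, 50.0),
              "psi": (135.0, 45.0)},
    })


# ---------------------------------------------------------------------------
# dihedral extraction
# ---------------------------------------------------------------------------

_CHI_ATOMS = {
    "chi1": ("N", "CA", "CB", "CG"),
    "chi2": ("CA", "CB", "CG", "CD"),
    "chi3_oe1": ("CB", "CG", "CD", "OE1"),
    "chi3_ne2": ("CB", "CG", "CD", "NE2"),
}


def extract_dihedrals(model: FibrilModel,
                      chi3_reference: str = "OE1") -> DihedralTrajectory:
    """Single-frame dihedral extraction from a structural model.

    χ1/χ2/χ3 are measured for residues with a complete glutamine-like side
    chain (CB, CG, CD, OE1, NE2); χ3 uses the OE1 branch by convention
    (``chi3_reference='NE2'`` selects the amide-nitrogen convention).
    φ/ψ need the neighbouring residues' C/N within the same chain; terminal
    residues and residues with missing atoms yield NaN and are counted in
    the skip report.
    """
    if chi3_reference not in ("OE1", "NE2"):
        raise ValueError("chi3_reference must be 'OE1' or 'NE2'")
    atoms = model.atoms
    keep = atoms["res_name"] != "ACE"
    grouped = atoms[keep].groupby(["chain_id", "res_seq"], sort=False)
    residues = []
    coords = []
    for (chain, resid), grp in grouped:
        pos = {row["name"]: np.array([row.x, row.y, row.z])
               for _, row in grp.iterrows()}
        first = grp.iloc[0]
        residues.append((chain, resid, first["segment"], first["conformer"],
                         first["res_name"]))
        coords.append(pos)
    meta = pd.DataFrame(residues, columns=["chain", "resid", "segment",
                                           "conformer", "res_name"])
    n = len(meta)
    series = {k: np.full(n, np.nan)
              for k in ("chi1", "chi2", "chi3", "phi", "psi")}
    skipped = 0
    chain_arr = meta["chain"].to_numpy()
    resid_arr = meta["resid"].to_numpy()
    for i, pos in enumerate(coords):
        if meta["res_name"].iloc[i] == "GLN":
            chi_atoms = ("N", "CA", "CB", "CG", "CD", "OE1", "NE2")
            if all(a in pos for a in chi_atoms):
                series["chi1"][i] = dihedral_angle(*(pos[a] for a in
                                                     _CHI_ATOMS["chi1"]))
                series["chi2"][i] = dihedral_angle(*(pos[a] for a in
                                                     _CHI_ATOMS["chi2"]))
                key = "chi3_oe1" if chi3_reference == "OE1" else "chi3_ne2"
                series["chi3"][i] = dihedral_angle(*(pos[a] for a in
                                                     _CHI_ATOMS[key]))
            else:
                skipped += 1
                warnings.warn(f"incomplete Gln side chain at "
                              f"{chain_arr[i]}/{resid_arr[i]}; skipped")
        prev_i, next_i = i - 1, i + 1
        has_prev = (prev_i >= 0 and chain_arr[prev_i] == chain_arr[i]
                    and resid_arr[prev_i] == resid_arr[i] - 1)
        has_next = (next_i < n and chain_arr[next_i] == chain_arr[i]
                    and resid_arr[next_i] == resid_arr[i] + 1)
        bb = all(a in pos for a in ("N", "CA", "C"))
        if bb and has_prev and "C" in coords[prev_i]:
            series["phi"][i] = dihedral_angle(coords[prev_i]["C"], pos["N"],
                                              pos["CA"], pos["C"])
        if bb and has_next and "N" in coords[next_i]:
            series["psi"][i] = dihedral_angle(pos["N"], pos["CA"], pos["C"],
                                              coords[next_i]["N"])
    traj = DihedralTrajectory(
        times=np.array([0.0]),
        residues=meta[["chain", "resid", "segment"]].assign(
            conformer=meta["conformer"]),
        angles={k: v[None, :] for k, v in series.items()},
        label=model.provenance.get("builder"),
    )
    traj.skipped_residues = skipped
    return traj


# ---------------------------------------------------------------------------
# rotamer classification and ssNMR windows
# ---------------------------------------------------------------------------

def classify_rotamers(traj: DihedralTrajectory,
                      classes=None) -> pd.DataFrame:
    """Nearest-class-within-window rotamer labels per residue per frame.

    Residues outside every configured window (or lacking χ angles) label
    ``other``.  Returns a DataFrame indexed like ``traj.residues`` with one
    column per frame.
    """
    classes = classes if classes is not None else default_rotamer_classes()
    _verify_exclusive(classes)
    n_f, n_r = traj.n_frames, traj.n_residues
    labels = np.full((n_f, n_r), "other", dtype=object)
    chi1, chi2, chi3 = (traj.angles[k] for k in ("chi1", "chi2", "chi3"))
    for f in range(n_f):
        for r in range(n_r):
            c1, c2, c3 = chi1[f, r], chi2[f, r], chi3[f, r]
            if np.isnan(c1) or np.isnan(c2) or np.isnan(c3):
                continue
            candidates = [(cls.distance(c1, c2, c3), cls.name)
                          for cls in classes if cls.contains(c1, c2, c3)]
            if candidates:
                labels[f, r] = min(candidates)[1]
    out = traj.residues.copy()
    for f in range(n_f):
        out[f"frame_{f}"] = labels[f]
    return out


def check_ssnmr_windows(traj: DihedralTrajectory,
                        windows: SSNMRWindows | None = None) -> pd.DataFrame:
    """Fraction of frames inside the ssNMR window, per residue per dihedral.

    Requires a per-residue conformer assignment ('a'/'b') in
    ``traj.residues['conformer']``; other residues are skipped.  A
    compliance below 1 is reported, never raised — partial excursions
    outside the (approximate) windows are an observation, not an error.
    """
    windows = windows or default_ssnmr_windows()
    rows = []
    conformers = traj.residues.get("conformer")
    if conformers is None:
        raise ValueError("trajectory carries no conformer assignment")
    for r in range(traj.n_residues):
        conf = conformers.iloc[r]
        if conf not in windows.windows:
            continue
        for dih in windows.windows[conf]:
            if dih not in traj.angles:
                raise ValueError(f"no {dih} series for windows check")
            values = traj.angles[dih][:, r]
            ok = ~np.isnan(values)
            if not ok.any():
                continue
            inside = windows.contains(conf, dih, values[ok])
            rows.append({
                "chain": traj.residues["chain"].iloc[r],
                "resid": traj.residues["resid"].iloc[r],
                "conformer": conf,
                "dihedral": dih,
                "compliance": float(np.mean(inside)),
                "mean_angle": float(np.degrees(np.angle(
                    np.mean(np.exp(1j * np.radians(values[ok])))))),
            })
    report = pd.DataFrame(rows)
    if len(report):
        mean_ok = []
        for _, row in report.iterrows():
            mean_ok.append(bool(windows.contains(
                row["conformer"], row["dihedral"], row["mean_angle"])))
        report["mean_in_window"] = mean_ok
    return report


# ---------------------------------------------------------------------------
# side-chain H-bond ladders
# ---------------------------------------------------------------------------

@dataclass
class LadderReport:
    """Side-chain amide ladder columns and their step statistics."""

    ladders: list  # dicts: sheet, column, members, distances, direction
    continuity_fraction: float
    cutoff_nm: float

    @property
    def n_steps(self) -> int:
        return sum(len(l["distances"]) for l in self.ladders)


def detect_hbond_ladders(model: FibrilModel, cutoff_nm: float = 0.32,
                         rise_nm: float | None = None) -> LadderReport:
    """Group Gln side-chain amides into z-columns and score their H-bonds.

    The heavy-atom criterion (Oε1···Nε2 distance at or below ``cutoff_nm``,
    minimum over the two donor orientations) is used; models built without
    hydrogens carry no donor angle.  Steps between consecutive column
    members along z (cyclically closed under a periodic box) count as
    present when bonded; the continuity fraction is present/possible over
    all columns.
    """
    atoms = model.atoms
    gln = atoms[atoms["res_name"] == "GLN"]
    need = {"CA", "CB", "NE2", "OE1"}
    rows = {}
    for (chain, resid), grp in gln.groupby(["chain_id", "res_seq"],
                                           sort=False):
        pos = {row["name"]: np.array([row.x, row.y, row.z])
               for _, row in grp.iterrows() if row["name"] in need}
        if len(pos) < 4:
            continue
        first = grp.iloc[0]
        rows[(chain, resid)] = (pos, int(first["sheet"]))
    if not rows:
        return LadderReport(ladders=[], continuity_fraction=float("nan"),
                            cutoff_nm=cutoff_nm)
    if rise_nm is None:
        # median x-step between consecutive residues of one chain
        diffs = []
        for chain, grp in gln[gln["name"] == "CA"].groupby("chain_id"):
            xs = grp.sort_values("res_seq")["x"].to_numpy()
            diffs.extend(np.abs(np.diff(xs)))
        rise_nm = float(np.median(diffs)) if diffs else 0.347
    box = model.box

    def minimage(u, v):
        d = u - v
        if box is not None:
            d = d - box * np.round(d / box)
        return np.linalg.norm(d)

    columns = {}
    for key, (pos, sheet) in rows.items():
        x = pos["CA"][0]
        if box is not None:
            ncol = max(1, int(round(box[0] / rise_nm)))
            col = int(round(x / rise_nm)) % ncol
        else:
            col = int(round(x / rise_nm))
        side = 1 if (pos["CB"] - pos["CA"])[1] >= 0 else -1
        columns.setdefault((sheet, col, side), []).append((key, pos))

    ladders = []
    present_total = 0
    possible_total = 0
    for (sheet, col, side), members in sorted(columns.items()):
        members.sort(key=lambda kv: kv[1]["CA"][2])
        n = len(members)
        if n < 2:
            continue
        pairs = list(zip(members, members[1:]))
        if box is not None and n > 2:
            pairs.append((members[-1], members[0]))  # periodic closure
        distances = []
        directions = []
        for (ka, pa), (kb, pb) in pairs:
            d_up = minimage(pa["NE2"], pb["OE1"])
            d_dn = minimage(pa["OE1"], pb["NE2"])
            d = min(d_up, d_dn)
            distances.append(float(d))
            directions.append("+z" if d_up <= d_dn else "-z")
        bonded = [d <= cutoff_nm for d in distances]
        present_total += sum(bonded)
        possible_total += len(distances)
        ladders.append({
            "sheet": sheet, "column": col, "side": side,
            "members": [k for k, _ in members],
            "distances": distances,
            "bonded": bonded,
            "direction": max(set(directions), key=directions.count),
        })
    frac = present_total / possible_total if possible_total else float("nan")
    return LadderReport(ladders=ladders, continuity_fraction=frac,
                        cutoff_nm=cutoff_nm)


# ---------------------------------------------------------------------------
# turns and secondary structure
# ---------------------------------------------------------------------------

TURN_CENTERS = {
    "type_I_prime": (60.0, 30.0, 90.0, 0.0),
    "type_II": (-60.0, 120.0, 80.0, 0.0),
}


def classify_turn(phi2: float, psi2: float, phi3: float, psi3: float,
                  radius_deg: float = 40.0) -> str:
    """Type the two-residue β-turn closest to the supplied (φ, ψ) pairs.

    Distance to each canonical template is the root-mean-square circular
    deviation over the four angles; beyond ``radius_deg`` the turn is
    ``other``.
    """
    best = ("other", np.inf)
    for name, center in TURN_CENTERS.items():
        devs = [circular_distance(v, c)
                for v, c in zip((phi2, psi2, phi3, psi3), center)]
        rms = float(np.sqrt(np.mean(np.square(devs))))
        if rms < best[1]:
            best = (name, rms)
    return best[0] if best[1] <= radius_deg else "other"


#: φ/ψ regions for the dihedral-based secondary-structure rule (degrees)
SS_REGIONS = {
    "helix": {"phi": (-100.0, -30.0), "psi": (-80.0, -5.0)},
    "strand": {"phi": (-180.0, -90.0), "psi_either": ((90.0, 180.0),
                                                      (-180.0, -150.0))},
}


def _assign_ss(phi, psi):
    if np.isnan(phi) or np.isnan(psi):
        return "coil"
    h = SS_REGIONS["helix"]
    if h["phi"][0] <= phi <= h["phi"][1] and h["psi"][0] <= psi <= h["psi"][1]:
        return "helix"
    s = SS_REGIONS["strand"]
    if s["phi"][0] <= phi <= s["phi"][1] and any(
            lo <= psi <= hi for lo, hi in s["psi_either"]):
        return "strand"
    return "coil"


def secondary_structure_occupancy(ensemble, segment: str = "N17"):
    """Per-residue helix/strand/coil occupancy of a chain ensemble.

    ``ensemble`` is a DihedralTrajectory or a list of them (one per chain
    or simulation replica); occupancy is the fraction of all chain×frame
    observations assigned to each state by the φ/ψ-region rule (the mode is
    recorded in the result's ``attrs``).  Residues are keyed by their
    residue number within the segment.
    """
    if isinstance(ensemble, DihedralTrajectory):
        ensemble = [ensemble]
    counts = {}
    for traj in ensemble:
        mask = traj.residues["segment"] == segment
        if not mask.any():
            raise ValueError(f"segment {segment!r} absent from ensemble")
        idx = np.where(mask.to_numpy())[0]
        for r in idx:
            resid = int(traj.residues["resid"].iloc[r])
            for f in range(traj.n_frames):
                state = _assign_ss(traj.angles["phi"][f, r],
                                   traj.angles["psi"][f, r])
                key = counts.setdefault(resid, {"helix": 0, "strand": 0,
                                                "coil": 0})
                key[state] += 1
    records = []
    for resid in sorted(counts):
        total = sum(counts[resid].values())
        records.append({"resid": resid,
                        **{k: v / total for k, v in counts[resid].items()}})
    out = pd.DataFrame(records).set_index("resid")
    out.attrs["mode"] = "phi_psi_regions"
    out.attrs["segment"] = segment
    return out
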