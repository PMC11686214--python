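"""Dihedral-retention stability statistic and the staged elimination protocol.

The stability of a core candidate during a simulation is scored from its
side-chain χ1 and χ3 dihedral trajectories:

    S(t) = (N1(t) + N3(t)) / (2 N)

where N is the number of polyQ residues and N_i(t) counts residues whose
χ_i at time t lies within a circular window (default 90°) of its reference
value in the starting structure.  Candidates are screened at a schedule of
checkpoints (default 5, 100, 200 and 1000 ns) and survive a checkpoint only
while S stays strictly above the threshold (default 0.9).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import wrap_angle

__all__ = [
    "DihedralTrajectory",
    "StabilityReport",
    "circular_distance",
    "compute_stability",
    "evaluate_checkpoints",
    "read_dihedral_table",
    "write_dihedral_table",
]

ANGLE_NAMES = ("chi1", "chi2", "chi3", "phi", "psi")


@dataclass
class DihedralTrajectory:
    """Per-frame, per-residue dihedral series in degrees.

    ``angles`` maps an angle name to an (n_frames, n_residues) array wrapped
    to (−180, 180]; ``reference`` maps the name to the per-residue reference
    values (by convention the initial, energy-minimised structure — the
    first frame when nothing else is supplied).
    """

    times: np.ndarray  # ns, strictly increasing
    residues: pd.DataFrame  # columns: chain, resid, segment
    angles: dict
    reference: dict | None = None
    label: str | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        for name, arr in self.angles.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (len(self.times), len(self.residues)):
                raise ValueError(f"angle series {name!r} has shape {arr.shape}")
            self.angles[name] = wrap_angle(arr)
        if self.reference is None:
            self.reference = {name: arr[0].copy()
                              for name, arr in self.angles.items()}
        else:
            self.reference = {k: wrap_angle(np.asarray(v, dtype=float))
                              for k, v in self.reference.items()}

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_residues(self) -> int:
        return len(self.residues)


@dataclass
class StabilityReport:
    """S(t) series plus the checkpoint ledger for one candidate."""

    times: np.ndarray
    S: np.ndarray
    N: int
    N1: np.ndarray
    N3: np.ndarray
    label: str | None = None
    checkpoints: list = field(default_factory=list)  # (t_ns, S, passed)
    eliminated_at_ns: float | None = None

    @property
    def survived(self) -> bool:
        return self.eliminated_at_ns is None and all(
            ok for (_, _, ok) in self.checkpoints)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "N": self.N,
            "times_ns": self.times.tolist(),
            "S": self.S.tolist(),
            "checkpoints": [
                {"t_ns": t, "S": s, "passed": bool(ok)}
                for (t, s, ok) in self.checkpoints],
            "eliminated_at_ns": self.eliminated_at_ns,
        }


def circular_distance(a_deg, b_deg):
    """Shortest angular distance in degrees, in [0, 180]."""
    a = np.asarray(a_deg, dtype=float)
    b = np.asarray(b_deg, dtype=float)
    d = np.abs(a - b) % 360.0
    d = np.where(d > 180.0, 360.0 - d, d)
    if d.ndim == 0:
        return float(d)
    return d


def compute_stability(traj: DihedralTrajectory,
                      window_deg: float = 90.0) -> StabilityReport:
    """Per-frame S(t) from χ1/χ3 retention against the reference angles.

    A residue is retained for χ_i when its circular distance to the
    reference is strictly below ``window_deg``.  Only χ1 and χ3 enter S;
    χ2, φ and ψ are carried in the trajectory for conformer analysis but do
    not contribute.
    """
    if not 0.0 < window_deg <= 180.0:
        raise ValueError("window_deg must lie in (0, 180]")
    for name in ("chi1", "chi3"):
        if name not in traj.angles:
            raise ValueError(f"trajectory lacks {name} series")
        missing = np.isnan(traj.angles[name])
        if missing.any():
            res = traj.residues.iloc[int(np.argmax(missing.any(axis=0)))]
            raise ValueError(
                f"missing {name} for residue {res['chain']}/{res['resid']}")
        if name not in traj.reference:
            raise ValueError(f"reference lacks {name}")
    n = traj.n_residues
    n1 = (circular_distance(traj.angles["chi1"],
                            traj.reference["chi1"][None, :])
          < window_deg).sum(axis=1)
    n3 = (circular_distance(traj.angles["chi3"],
                            traj.reference["chi3"][None, :])
          < window_deg).sum(axis=1)
    s = (n1 + n3) / (2.0 * n)
    return StabilityReport(times=traj.times.copy(), S=s, N=n,
                           N1=n1, N3=n3, label=traj.label)


def evaluate_checkpoints(report: StabilityReport,
                         schedule_ns=(5.0, 100.0, 200.0, 1000.0),
                         threshold: float = 0.9) -> StabilityReport:
    """Apply the staged elimination protocol to a stability report.

    At each checkpoint the S value of the nearest frame at or before the
    checkpoint time is compared strictly against the threshold (S must be
    above it).  A checkpoint beyond the trajectory end is marked
    unevaluated (failed), never silently passed.  The first failed
    checkpoint records the elimination time.
    """
    report.checkpoints = []
    report.eliminated_at_ns = None
    for t_ns in schedule_ns:
        idx = np.searchsorted(report.times, t_ns, side="right") - 1
        if idx < 0 or report.times[-1] < t_ns:
            report.checkpoints.append((float(t_ns), float("nan"), False))
            if report.eliminated_at_ns is None:
                report.eliminated_at_ns = float(t_ns)
            continue
        s = float(report.S[idx])
        ok = s > threshold
        report.checkpoints.append((float(t_ns), s, ok))
        if not ok and report.eliminated_at_ns is None:
            report.eliminated_at_ns = float(t_ns)
    return report


def select_survivors(reports, schedule_ns=(5.0, 100.0, 200.0, 1000.0),
                     threshold: float = 0.9) -> list:
    """Candidate labels passing every checkpoint, in input (catalog) order."""
    out = []
    for rep in reports:
        evaluate_checkpoints(rep, schedule_ns, threshold)
        if rep.survived:
            out.append(rep.label)
    return out


def write_dihedral_table(traj: DihedralTrajectory, path) -> None:
    """Long-format tab-delimited dump: one row per frame × residue."""
    frames = np.repeat(np.arange(traj.n_frames), traj.n_residues)
    rows = {
        "time_ns": np.repeat(traj.times, traj.n_residues),
        "chain": np.tile(traj.residues["chain"].to_numpy(), traj.n_frames),
        "resid": np.tile(traj.residues["resid"].to_numpy(), traj.n_frames),
        "segment": np.tile(traj.residues["segment"].to_numpy(), traj.n_frames),
    }
    for name, arr in traj.angles.items():
        rows[name] = arr.reshape(-1)
    ref = pd.DataFrame({
        "time_ns": -1.0,
        "chain": traj.residues["chain"],
        "resid": traj.residues["resid"],
        "segment": traj.residues["segment"],
        **{name: traj.reference.get(name, np.full(traj.n_residues, np.nan))
           for name in traj.angles},
    })
    table = pd.concat([ref, pd.DataFrame(rows)], ignore_index=True)
    table.to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_dihedral_table(path, label: str | None = None) -> DihedralTrajectory:
    """Read a table written by :func:`write_dihedral_table`.

    Rows with ``time_ns == -1`` hold the reference angles.
    """
    table = pd.read_csv(path, sep="\t")
    ref_rows = table[table["time_ns"] < 0]
    data = table[table["time_ns"] >= 0]
    times = np.sort(data["time_ns"].unique())
    residues = (data[["chain", "resid", "segment"]]
                .drop_duplicates().reset_index(drop=True))
    n_f, n_r = len(times), len(residues)
    angle_cols = [c for c in ANGLE_NAMES if c in table.columns]
    data = data.sort_values(["time_ns", "chain", "resid"], kind="stable")
    angles = {c: data[c].to_numpy().reshape(n_f, n_r) for c in angle_cols}
    reference = None
    if len(ref_rows):
        ref_rows = ref_rows.sort_values(["chain", "resid"], kind="stable")
        reference = {c: ref_rows[c].to_numpy() for c in angle_cols}
    return DihedralTrajectory(times=times, residues=residues, angles=angles,
                              reference=reference,
                              label=label or str(Path(path).stem))
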