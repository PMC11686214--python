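"""Synthetic dihedral trajectories and ensembles with known ground truth.

Microsecond simulations are not reproducible at desk scale, so every
pipeline stage is exercised against generated data whose statistical
structure mimics the relevant observables: stable candidates hold S ≈ 1
with small wrapped-Gaussian fluctuations about the reference angles,
unstable candidates flip side chains into far rotamer wells with
exponential waiting times, and flanking-domain ensembles mix helical and
coil members at a known fraction.  All generators are bitwise reproducible
for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import wrap_angle
from .stability import ANGLE_NAMES, DihedralTrajectory

__all__ = [
    "TrajectorySpec",
    "generate_trajectory",
    "generate_candidate_cohort",
    "generate_n17_mixture",
]

MODES = ("stable", "decay", "flip_fraction", "uniform")


@dataclass
class TrajectorySpec:
    """Parameters of one synthetic dihedral trajectory.

    ``fluctuation_deg`` is the wrapped-Gaussian width about the reference;
    in decay mode residues flip χ1/χ3 into far wells (jumps of 120–180°)
    with exponential waiting times of mean ``decay_time_ns``; in
    flip_fraction mode exactly ⌊f·n⌋ residues flip χ1 at t=0 while χ3 is
    retained; uniform mode draws all angles i.i.d. uniform.
    """

    mode: str = "stable"
    n_residues: int = 320
    n_frames: int = 101
    dt_ns: float = 10.0
    fluctuation_deg: float = 10.0
    flip_fraction: float = 0.0
    decay_time_ns: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown trajectory mode {self.mode!r}")
        if self.fluctuation_deg < 0:
            raise ValueError("fluctuation_deg must be >= 0")
        if not 0.0 <= self.flip_fraction <= 1.0:
            raise ValueError("flip_fraction must lie in [0, 1]")


def _default_reference(n_residues: int, rng) -> dict:
    ref = {}
    wells = np.where(rng.random(n_residues) < 0.5, 62.0, -65.0)
    ref["chi1"] = wells
    ref["chi2"] = np.full(n_residues, 180.0)
    ref["chi3"] = np.where(wells > 0, 20.0, -30.0)
    ref["phi"] = np.full(n_residues, -139.0)
    ref["psi"] = np.full(n_residues, 136.0)
    return {k: wrap_angle(v) for k, v in ref.items()}


def generate_trajectory(spec: TrajectorySpec,
                        reference: dict | None = None,
                        label: str | None = None) -> DihedralTrajectory:
    """Synthesize a dihedral trajectory from its parameters (seeded, reproducible)."""
    rng = np.random.default_rng(spec.seed)
    n_f, n_r = spec.n_frames, spec.n_residues
    times = np.arange(n_f, dtype=float) * spec.dt_ns
    if reference is None:
        reference = _default_reference(n_r, rng)
    angles = {}
    if spec.mode == "uniform":
        for name in ANGLE_NAMES:
            angles[name] = rng.uniform(-180.0, 180.0, size=(n_f, n_r))
    else:
        for name in ANGLE_NAMES:
            base = np.tile(reference[name], (n_f, 1))
            noise = rng.normal(0.0, spec.fluctuation_deg, size=(n_f, n_r))
            angles[name] = base + noise
        if spec.mode == "flip_fraction":
            n_flip = int(np.floor(spec.flip_fraction * n_r))
            flip_idx = rng.permutation(n_r)[:n_flip]
            jump = rng.uniform(120.0, 180.0, size=n_flip)
            jump *= rng.choice([-1.0, 1.0], size=n_flip)
            angles["chi1"][:, flip_idx] += jump[None, :]
        elif spec.mode == "decay":
            for name in ("chi1", "chi3"):
                wait = rng.exponential(spec.decay_time_ns, size=n_r)
                flipped = times[:, None] >= wait[None, :]
                jump = rng.uniform(120.0, 180.0, size=n_r)
                jump *= rng.choice([-1.0, 1.0], size=n_r)
                angles[name] = angles[name] + flipped * jump[None, :]
    angles = {k: wrap_angle(v) for k, v in angles.items()}
    residues = pd.DataFrame({
        "chain": np.repeat("A", n_r),
        "resid": np.arange(1, n_r + 1),
        "segment": np.repeat("polyQ", n_r),
    })
    return DihedralTrajectory(times=times, residues=residues, angles=angles,
                              reference=dict(reference), label=label)


def generate_candidate_cohort(n_stable: int = 2, n_total: int = 30,
                              seed: int = 0, n_residues: int = 320,
                              n_frames: int = 101, dt_ns: float = 10.0,
                              fluctuation_deg: float = 10.0) -> list:
    """A labelled cohort mirroring the screening experiment's structure.

    ``n_stable`` trajectories hold their reference rotamers; the rest decay
    with waiting times drawn short enough that S drops below 0.9 well
    before the final checkpoint.  Returns (label, trajectory, is_stable)
    tuples; ground-truth stability is encoded in the label list order.
    """
    if n_stable > n_total:
        raise ValueError("n_stable cannot exceed n_total")
    rng = np.random.default_rng(seed)
    stable_ids = set(rng.permutation(n_total)[:n_stable])
    cohort = []
    t_final = (n_frames - 1) * dt_ns
    for i in range(n_total):
        is_stable = i in stable_ids
        spec = TrajectorySpec(
            mode="stable" if is_stable else "decay",
            n_residues=n_residues, n_frames=n_frames, dt_ns=dt_ns,
            fluctuation_deg=fluctuation_deg,
            # mean waiting time well inside the run so the late checkpoints
            # catch every decaying candidate
            decay_time_ns=max(dt_ns, 0.05 * t_final),
            seed=int(rng.integers(2**31)),
        )
        label = f"cand{i:02d}"
        cohort.append((label, generate_trajectory(spec, label=label),
                       is_stable))
    return cohort


def generate_n17_mixture(helix_fraction: float = 0.5,
                         residues_window=(4, 11), n_chains: int = 140,
                         n17_len: int = 17, seed: int = 0,
                         fluctuation_deg: float = 8.0):
    """Per-chain φ/ψ ensembles of the N17 segment with known helicity.

    Each chain is helical over ``residues_window`` (inclusive, 1-based)
    with probability ``helix_fraction`` and coil otherwise; returns
    (trajectories, ground_truth_helical) where the trajectory list holds one
    single-frame DihedralTrajectory per chain.
    """
    if not 0.0 <= helix_fraction <= 1.0:
        raise ValueError("helix_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    lo, hi = residues_window
    helix = (-57.0, -47.0)
    coil = (-120.0, 120.0)
    chains = []
    truth = []
    for c in range(n_chains):
        helical = bool(rng.random() < helix_fraction)
        truth.append(helical)
        phi = np.full(n17_len, coil[0])
        psi = np.full(n17_len, coil[1])
        if helical:
            phi[lo - 1:hi] = helix[0]
            psi[lo - 1:hi] = helix[1]
        phi = phi + rng.normal(0, fluctuation_deg, n17_len)
        psi = psi + rng.normal(0, fluctuation_deg, n17_len)
        residues = pd.DataFrame({
            "chain": np.repeat(f"c{c}", n17_len),
            "resid": np.arange(1, n17_len + 1),
            "segment": np.repeat("N17", n17_len),
        })
        chains.append(DihedralTrajectory(
            times=np.array([0.0]),
            residues=residues,
            angles={"phi": phi[None, :], "psi": psi[None, :]},
            label=f"chain{c}",
        ))
    return chains, truth
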