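"""The dihedral-retention statistic S(t) and the elimination protocol."""

import numpy as np
import pandas as pd
import pytest

from fibrilkit.stability import (DihedralTrajectory, circular_distance,
                                 compute_stability, evaluate_checkpoints,
                                 read_dihedral_table, select_survivors,
                                 write_dihedral_table)
from fibrilkit.synthetic_data import TrajectorySpec, generate_trajectory


def _make_traj(chi1, chi3, times=None, reference=None):
    chi1 = np.asarray(chi1, dtype=float)
    n_f, n_r = chi1.shape
    residues = pd.DataFrame({"chain": ["A"] * n_r,
                             "resid": np.arange(1, n_r + 1),
                             "segment": ["polyQ"] * n_r})
    angles = {"chi1": chi1, "chi3": np.asarray(chi3, dtype=float),
              "chi2": np.full((n_f, n_r), 180.0),
              "phi": np.full((n_f, n_r), -139.0),
              "psi": np.full((n_f, n_r), 136.0)}
    return DihedralTrajectory(
        times=times if times is not None else np.arange(n_f, dtype=float),
        residues=residues, angles=angles, reference=reference)


@pytest.mark.parametrize("a,b,expected", [
    (170.0, -170.0, 20.0),
    (37.0, 37.0, 0.0),
    (0.0, 180.0, 180.0),
    (-90.0, 90.0, 180.0),
])
def test_circular_distance(a, b, expected):
    assert circular_distance(a, b) == pytest.approx(expected)


def test_identical_frame_scores_one():
    base = np.full((3, 10), 62.0)
    rep = compute_stability(_make_traj(base, base - 82.0))
    assert np.allclose(rep.S, 1.0)


def test_all_chi1_flipped_scores_half():
    n = 20
    ref1 = np.full(n, 62.0)
    ref3 = np.full(n, 20.0)
    chi1 = np.vstack([ref1, ref1 + 180.0])
    chi3 = np.vstack([ref3, ref3])
    rep = compute_stability(_make_traj(chi1, chi3))
    assert rep.S[0] == pytest.approx(1.0)
    assert rep.S[1] == pytest.approx(0.5)
    assert rep.N1[1] == 0 and rep.N3[1] == n


def test_uniform_angles_average_half():
    """Each angle retains with probability 1/2: binomial mean 0.5."""
    spec = TrajectorySpec(mode="uniform", n_residues=320, n_frames=200,
                          seed=3)
    rep = compute_stability(generate_trajectory(spec))
    n_draws = 2 * 320 * 200
    se = np.sqrt(0.25 / n_draws)
    assert abs(rep.S.mean() - 0.5) < 3 * se


def test_global_rotation_invariance(rng):
    chi1 = rng.uniform(-180, 180, size=(5, 40))
    chi3 = rng.uniform(-180, 180, size=(5, 40))
    ref = {"chi1": chi1[0].copy(), "chi3": chi3[0].copy()}
    s0 = compute_stability(_make_traj(chi1, chi3, reference=dict(
        ref, chi2=np.zeros(40), phi=np.zeros(40), psi=np.zeros(40)))).S
    offset = 77.0
    s1 = compute_stability(_make_traj(chi1 + offset, chi3 + offset,
                                      reference={
                                          "chi1": ref["chi1"] + offset,
                                          "chi3": ref["chi3"] + offset})).S
    assert np.allclose(s0, s1)


def test_wider_window_never_scores_lower(rng):
    chi1 = rng.uniform(-180, 180, size=(8, 60))
    chi3 = rng.uniform(-180, 180, size=(8, 60))
    traj = _make_traj(chi1, chi3)
    s90 = compute_stability(traj, window_deg=90.0).S
    s60 = compute_stability(traj, window_deg=60.0).S
    assert np.all(s90 >= s60)


def test_missing_chi3_is_an_error():
    traj = _make_traj(np.zeros((2, 4)), np.zeros((2, 4)))
    traj.angles["chi3"][1, 2] = np.nan
    with pytest.raises(ValueError, match="chi3"):
        compute_stability(traj)


def test_constant_trajectory_survives_all_checkpoints():
    base = np.full((101, 16), -65.0)
    traj = _make_traj(base, base, times=np.arange(101) * 10.0)
    rep = evaluate_checkpoints(compute_stability(traj))
    assert rep.survived
    assert [t for t, _, ok in rep.checkpoints if ok] == [5, 100, 200, 1000]


def test_dip_at_100ns_is_eliminated_there():
    n = 100
    chi1 = np.tile(np.full(n, 62.0), (101, 1))
    chi3 = chi1.copy()
    times = np.arange(101) * 10.0
    # at 100 ns, 60% of chi1 and all chi3 drift out: S = 0.7... make S=0.85:
    # flip 30% of chi1 and 30% of chi3 from frame 10 on
    chi1[10:, :30] += 180.0
    chi3[10:, :30] += 180.0
    rep = evaluate_checkpoints(compute_stability(_make_traj(chi1, chi3,
                                                            times=times)))
    assert not rep.survived
    assert rep.eliminated_at_ns == 100.0
    ledger = {t: ok for t, _, ok in rep.checkpoints}
    assert ledger[5.0] and not ledger[100.0]


def test_checkpoint_beyond_trajectory_end_not_silently_passed():
    base = np.full((6, 8), 10.0)
    traj = _make_traj(base, base, times=np.arange(6) * 10.0)  # ends at 50 ns
    rep = evaluate_checkpoints(compute_stability(traj))
    ledger = {t: (s, ok) for t, s, ok in rep.checkpoints}
    assert ledger[5.0][1]
    assert not ledger[100.0][1] and np.isnan(ledger[100.0][0])
    assert not rep.survived


def test_raising_threshold_never_adds_survivors():
    specs = [TrajectorySpec(mode="decay", n_residues=64, n_frames=51,
                            dt_ns=20.0, decay_time_ns=80.0, seed=s)
             for s in range(12)]
    reports = [compute_stability(generate_trajectory(sp, label=str(i)))
               for i, sp in enumerate(specs)]
    lo = set(select_survivors(reports, threshold=0.5))
    hi = set(select_survivors(reports, threshold=0.9))
    assert hi <= lo


def test_dihedral_table_round_trip(tmp_path):
    spec = TrajectorySpec(mode="stable", n_residues=12, n_frames=5, seed=9)
    traj = generate_trajectory(spec)
    path = tmp_path / "angles.tsv"
    write_dihedral_table(traj, path)
    loaded = read_dihedral_table(path)
    assert loaded.n_frames == traj.n_frames
    assert loaded.n_residues == traj.n_residues
    for name in traj.angles:
        assert np.allclose(loaded.angles[name], traj.angles[name], atol=1e-3)
        assert np.allclose(loaded.reference[name], traj.reference[name],
                           atol=1e-3)
    s0 = compute_stability(traj).S
    s1 = compute_stability(loaded).S
    assert np.allclose(s0, s1)


# hypothesis property checks (derandomized by the fixed seeds above)
try:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.floats(-720, 720), st.floats(-720, 720))
    @settings(max_examples=200, deadline=None)
    def test_circular_distance_properties(a, b):
        d = circular_distance(a, b)
        assert 0.0 <= d <= 180.0
        assert d == pytest.approx(circular_distance(b, a))
        assert circular_distance(a + 360.0, b) == pytest.approx(d, abs=1e-6)

    @given(st.floats(-1e6, 1e6))
    @settings(max_examples=200, deadline=None)
    def test_wrap_angle_idempotent_and_in_range(a):
        from fibrilkit.geometry import wrap_angle

        w = wrap_angle(a)
        assert -180.0 < w <= 180.0
        assert wrap_angle(w) == pytest.approx(w)
except ImportError:  # pragma: no cover - hypothesis is a test-only extra
    pass
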