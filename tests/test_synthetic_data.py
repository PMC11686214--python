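"""Generators with known ground truth, and their analytic recovery."""

import numpy as np
import pytest

from fibrilkit.stability import compute_stability, evaluate_checkpoints
from fibrilkit.synthetic_data import (TrajectorySpec, generate_candidate_cohort,
                                      generate_n17_mixture,
                                      generate_trajectory)


def test_fixed_seed_is_bitwise_reproducible():
    spec = TrajectorySpec(mode="decay", n_residues=30, n_frames=20, seed=42)
    a = generate_trajectory(spec)
    b = generate_trajectory(spec)
    for name in a.angles:
        assert np.array_equal(a.angles[name], b.angles[name])


def test_different_seeds_differ():
    a = generate_trajectory(TrajectorySpec(seed=1, n_residues=20, n_frames=5))
    b = generate_trajectory(TrajectorySpec(seed=2, n_residues=20, n_frames=5))
    assert not np.array_equal(a.angles["chi1"], b.angles["chi1"])


def test_stable_mode_holds_near_one():
    spec = TrajectorySpec(mode="stable", n_residues=320, n_frames=50,
                          fluctuation_deg=10.0, seed=5)
    rep = compute_stability(generate_trajectory(spec))
    # P(|N(0, 10 deg)| >= 90 deg) is ~1e-19: retention is essentially certain
    assert np.all(rep.S > 0.99)


@pytest.mark.parametrize("f", [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8,
                               0.9, 1.0])
def test_flip_fraction_recovers_one_minus_half_f(f):
    n = 320
    spec = TrajectorySpec(mode="flip_fraction", flip_fraction=f,
                          n_residues=n, n_frames=4, fluctuation_deg=0.0,
                          seed=11)
    rep = compute_stability(generate_trajectory(spec))
    expected = 1.0 - np.floor(f * n) / n / 2.0
    assert np.allclose(rep.S, expected)


def test_invalid_mode_rejected():
    with pytest.raises(ValueError):
        TrajectorySpec(mode="wiggle")


def test_cohort_checkpoints_recover_planted_stable_candidates():
    cohort = generate_candidate_cohort(n_stable=2, n_total=30, seed=1)
    truth = {label for label, _, stable in cohort if stable}
    survivors = set()
    for label, traj, _ in cohort:
        rep = evaluate_checkpoints(compute_stability(traj))
        if rep.survived:
            survivors.add(label)
    assert survivors == truth
    assert len(truth) == 2


@pytest.mark.parametrize("n_stable,n_total", [(0, 5), (5, 5)])
def test_cohort_edge_cases(n_stable, n_total):
    cohort = generate_candidate_cohort(n_stable=n_stable, n_total=n_total,
                                       seed=3)
    survivors = [label for label, traj, _ in cohort
                 if evaluate_checkpoints(compute_stability(traj)).survived]
    assert len(survivors) == n_stable


def test_n17_mixture_recovers_helix_fraction():
    from fibrilkit.conformer_analysis import secondary_structure_occupancy

    chains, truth = generate_n17_mixture(helix_fraction=0.5, n_chains=140,
                                         seed=2)
    occ = secondary_structure_occupancy(chains, segment="N17")
    window = occ.loc[4:11, "helix"]
    se = np.sqrt(0.25 / 140)
    assert np.all(np.abs(window - np.mean(truth)) <= 3 * se + 0.05)
    assert abs(window.mean() - 0.5) <= 3 * se


@pytest.mark.parametrize("frac,expected", [(1.0, 1.0), (0.0, 0.0)])
def test_n17_mixture_extremes(frac, expected):
    from fibrilkit.conformer_analysis import secondary_structure_occupancy

    chains, _ = generate_n17_mixture(helix_fraction=frac, n_chains=30,
                                     seed=4, fluctuation_deg=5.0)
    occ = secondary_structure_occupancy(chains, segment="N17")
    assert np.allclose(occ.loc[5:10, "helix"], expected)
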