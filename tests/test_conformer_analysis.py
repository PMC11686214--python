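"""Dihedral extraction, rotamers, ssNMR windows, ladders, turns and SS."""

import numpy as np
import pandas as pd
import pytest

from fibrilkit import conformer_analysis as ca
from fibrilkit.geometry import dihedral_angle
from fibrilkit.stability import DihedralTrajectory


def _single_frame(chi1, chi2, chi3, conformer=None, segment="polyQ"):
    n = len(chi1)
    residues = pd.DataFrame({
        "chain": ["A"] * n, "resid": np.arange(1, n + 1),
        "segment": [segment] * n,
        "conformer": conformer if conformer is not None else ["-"] * n})
    angles = {"chi1": np.asarray([chi1], float),
              "chi2": np.asarray([chi2], float),
              "chi3": np.asarray([chi3], float),
              "phi": np.full((1, n), -139.0),
              "psi": np.full((1, n), 136.0)}
    return DihedralTrajectory(times=np.array([0.0]), residues=residues,
                              angles=angles)


def _textbook_dihedral(p0, p1, p2, p3):
    # independent construction via the two plane normals
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    return -np.degrees(np.arctan2(np.dot(m1, n2), np.dot(n1, n2)))


def test_dihedral_agrees_with_textbook_oracle(rng):
    """Torsions match an independent plane-normal construction to 1e-6 deg."""
    quads = rng.normal(size=(1000, 4, 3))
    for quad in quads:
        mine = dihedral_angle(*quad)
        exp = _textbook_dihedral(*quad)
        diff = abs((mine - exp + 180.0) % 360.0 - 180.0)
        assert diff < 1e-6


def test_dihedral_agrees_with_mdanalysis(rng):
    """Cross-check against MDAnalysis (float32 internals, coarser bound)."""
    from MDAnalysis.lib.distances import calc_dihedrals

    quads = rng.normal(size=(300, 4, 3))
    expected = np.degrees(calc_dihedrals(quads[:, 0], quads[:, 1],
                                         quads[:, 2], quads[:, 3]))
    for quad, exp in zip(quads, expected):
        mine = dihedral_angle(*quad)
        diff = abs((mine - exp + 180.0) % 360.0 - 180.0)
        assert diff < 1e-3


def test_degenerate_dihedral_raises():
    p = np.zeros(3)
    with pytest.raises(ValueError):
        dihedral_angle(p, p + [1, 0, 0], p + [2, 0, 0], p + [3, 0, 0])


def test_rotamer_center_hits():
    traj = _single_frame([62.0, -65.0, 62.0], [180.0, 180.0, -65.0],
                         [20.0, -30.0, 0.0])
    labels = ca.classify_rotamers(traj)["frame_0"].tolist()
    assert labels == ["pt20", "mt-30", "pm0"]


def test_far_outside_all_windows_is_other():
    traj = _single_frame([180.0], [62.0], [0.0])
    assert ca.classify_rotamers(traj)["frame_0"].tolist() == ["other"]


def test_overlapping_classes_rejected():
    bad = [ca.RotamerClass("a", 60.0, 180.0, 0.0, 90.0, 90.0, None),
           ca.RotamerClass("b", 70.0, 170.0, 0.0, 90.0, 90.0, None)]
    with pytest.raises(ValueError):
        ca.classify_rotamers(_single_frame([0.0], [0.0], [0.0]), bad)


def test_core_lattice_strands_label_pt20_and_mt30(core_lattice):
    """Built conformer-a strands classify as pt20, conformer-b as mt-30."""
    traj = ca.extract_dihedrals(core_lattice)
    labels = ca.classify_rotamers(traj)
    table = pd.crosstab(labels["conformer"], labels["frame_0"])
    assert table.loc["a", "pt20"] == 160 and table.loc["b", "mt-30"] == 160
    assert table.get("other", pd.Series(0, table.index)).sum() == 0


def test_surface_mode_chi2_perturbation_labels_pm0(rng):
    chi2 = rng.normal(-65.0, 8.0, size=30)
    traj = _single_frame(np.full(30, 62.0), chi2, np.zeros(30))
    labels = ca.classify_rotamers(traj)["frame_0"]
    assert (labels == "pm0").all()


def test_ssnmr_windows_full_compliance_inside():
    n = 16
    conf = ["a", "b"] * (n // 2)
    chi1 = [62.0 if c == "a" else -65.0 for c in conf]
    traj = _single_frame(chi1, [178.0] * n, [20.0] * n, conformer=conf)
    report = ca.check_ssnmr_windows(traj)
    assert np.allclose(report["compliance"], 1.0)
    assert report["mean_in_window"].all()


def test_ssnmr_broadened_chi1_reports_partial_compliance(rng):
    n = 200
    chi1 = rng.normal(62.0, 60.0, size=(5, n))
    residues = pd.DataFrame({"chain": ["A"] * n,
                             "resid": np.arange(1, n + 1),
                             "segment": ["polyQ"] * n,
                             "conformer": ["a"] * n})
    traj = DihedralTrajectory(
        times=np.arange(5.0), residues=residues,
        angles={"chi1": chi1, "chi2": np.full((5, n), 180.0),
                "chi3": np.full((5, n), 20.0), "phi": np.full((5, n), -139.0),
                "psi": np.full((5, n), 135.0)})
    report = ca.check_ssnmr_windows(traj)
    chi1_rows = report[report["dihedral"] == "chi1"]
    assert 0.0 < chi1_rows["compliance"].mean() < 1.0


def test_ladder_continuity_one_on_ideal_build(core_lattice):
    report = ca.detect_hbond_ladders(core_lattice)
    assert report.continuity_fraction == pytest.approx(1.0)
    steps = [d for l in report.ladders for d in l["distances"]]
    assert min(steps) >= 0.26 and max(steps) <= 0.31


def test_deleting_a_strand_reduces_continuity(core_lattice):
    atoms = core_lattice.atoms
    keep = ~((atoms["sheet"] == 0) & (atoms["strand"] == 3))
    from fibrilkit.core_builder import FibrilModel

    pruned = FibrilModel(atoms=atoms[keep].reset_index(drop=True),
                         box=core_lattice.box,
                         provenance=dict(core_lattice.provenance))
    full = ca.detect_hbond_ladders(core_lattice)
    part = ca.detect_hbond_ladders(pruned)
    assert part.continuity_fraction < full.continuity_fraction


@pytest.mark.parametrize("angles,expected", [
    ((60.0, 30.0, 90.0, 0.0), "type_I_prime"),
    ((-60.0, 120.0, 80.0, 0.0), "type_II"),
    ((178.0, -175.0, 170.0, 165.0), "other"),
])
def test_turn_classification(angles, expected):
    assert ca.classify_turn(*angles) == expected


def test_turn_radius_boundary():
    assert ca.classify_turn(60.0, 30.0, 90.0, 41.0) == "type_I_prime"
    assert ca.classify_turn(60.0 + 80, 30.0 + 80, 90.0 + 80, 80.0,
                            radius_deg=40.0) == "other"


def _phi_psi_ensemble(phi, psi, n=10, segment="N17"):
    residues = pd.DataFrame({"chain": ["A"] * n,
                             "resid": np.arange(1, n + 1),
                             "segment": [segment] * n})
    return DihedralTrajectory(
        times=np.array([0.0]), residues=residues,
        angles={"phi": np.full((1, n), phi), "psi": np.full((1, n), psi)})


def test_ideal_helix_occupancy_one():
    occ = ca.secondary_structure_occupancy(_phi_psi_ensemble(-57.0, -47.0))
    assert np.allclose(occ["helix"], 1.0)
    assert occ.attrs["mode"] == "phi_psi_regions"


def test_ideal_strand_occupancy_one():
    occ = ca.secondary_structure_occupancy(_phi_psi_ensemble(-139.0, 135.0))
    assert np.allclose(occ["strand"], 1.0)


def test_occupancies_sum_to_one(rng):
    n = 25
    residues = pd.DataFrame({"chain": ["A"] * n,
                             "resid": np.arange(1, n + 1),
                             "segment": ["N17"] * n})
    traj = DihedralTrajectory(
        times=np.arange(8.0), residues=residues,
        angles={"phi": rng.uniform(-180, 180, (8, n)),
                "psi": rng.uniform(-180, 180, (8, n))})
    occ = ca.secondary_structure_occupancy(traj)
    assert np.allclose(occ[["helix", "strand", "coil"]].sum(axis=1), 1.0)


def test_missing_segment_raises():
    with pytest.raises(ValueError):
        ca.secondary_structure_occupancy(_phi_psi_ensemble(-57, -47),
                                         segment="PRD")
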