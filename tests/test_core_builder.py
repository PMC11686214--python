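"""Idealized builders: lattices, peptide fibrils, HTTex1 protofilaments."""

import numpy as np
import pandas as pd
import pytest

from fibrilkit import conformer_analysis as ca
from fibrilkit.core_builder import (BuildError, LatticeGeometry,
                                    build_core_lattice, build_httex1_fibril,
                                    build_q15_fibril, realize_class)


def test_single_cell_has_eight_residues(m_candidate, alphabet):
    model = build_core_lattice(m_candidate, alphabet, 1, 1, 1)
    assert model.n_residues == 8
    assert model.n_chains == 4          # 4 strands of 2 residues
    per_chain = model.atoms.groupby("chain_id")["res_seq"].nunique()
    assert (per_chain == 2).all()


def test_reference_lattice_has_320_glutamines(core_lattice):
    gln = core_lattice.atoms[core_lattice.atoms["res_name"] == "GLN"]
    assert gln.groupby(["chain_id", "res_seq"]).ngroups == 320


def test_atom_count_scales_linearly(m_candidate, alphabet):
    base = build_core_lattice(m_candidate, alphabet, 1, 1, 1).n_atoms
    assert build_core_lattice(m_candidate, alphabet, 2, 1, 1).n_atoms == 2 * base
    assert build_core_lattice(m_candidate, alphabet, 1, 1, 2).n_atoms == 2 * base


def test_unfiltered_candidate_rejected(alphabet):
    from fibrilkit.lattice_enum import UnitCellCandidate

    cand = UnitCellCandidate(("ppu", "pmu", "ppu", "ppu"))
    with pytest.raises(BuildError, match="uniformity"):
        build_core_lattice(cand, alphabet, 1, 1, 1)


def test_dihedral_round_trip_within_one_degree(core_lattice, geometry,
                                               m_candidate, alphabet):
    """Measured φ/ψ/χ of built residues match the requested values."""
    traj = ca.extract_dihedrals(core_lattice)
    res = traj.residues
    built = core_lattice.provenance["built_assignment"].split("|")
    by_label = {c.label: c for c in alphabet}

    phi = traj.angles["phi"][0]
    psi = traj.angles["psi"][0]
    interior = ~np.isnan(phi) & ~np.isnan(psi)
    assert interior.sum() > 200
    assert np.allclose(phi[interior], geometry.beta_phi_deg, atol=1.0)
    assert np.allclose(psi[interior], geometry.beta_psi_deg, atol=1.0)

    # χ angles per residue against the class realization that placed them
    atoms = core_lattice.atoms
    ca_rows = atoms[atoms["name"] == "CA"].reset_index(drop=True)
    rise = geometry.rise_per_residue
    checked = 0
    for i in range(traj.n_residues):
        row = ca_rows.iloc[i]
        strand = int(row["strand"])
        sheet = int(row["sheet"])
        zpar = strand % 2
        xcol = int(round(row["x"] / rise)) % 2
        cls = by_label[built[{(0, 0): 0, (1, 0): 1, (0, 1): 2,
                              (1, 1): 3}[(xcol, sheet % 2)]]]
        real = realize_class(cls, geometry, side=+1 if xcol == 0 else -1)
        expect = real.chi_a if zpar == 0 else real.chi_b
        for k, name in enumerate(("chi1", "chi2", "chi3")):
            measured = traj.angles[name][0, i]
            diff = abs((measured - expect[k] + 180.0) % 360.0 - 180.0)
            assert diff < 1.0, (i, name, measured, expect[k])
        checked += 1
    assert checked == 320


def test_lattice_is_clash_free(core_lattice, geometry):
    assert core_lattice.find_clashes(geometry.clash_distance) == []


def test_antiparallel_backbone_hbond_partners_alternate(core_lattice):
    """Backbone N···O partners of a strand lie in both neighbouring strands."""
    atoms = core_lattice.atoms
    sheet0 = atoms[atoms["sheet"] == 1]
    n_atoms = sheet0[sheet0["name"] == "N"]
    o_atoms = sheet0[sheet0["name"] == "O"]
    from scipy.spatial import cKDTree

    tree = cKDTree(o_atoms[["x", "y", "z"]].to_numpy())
    strand_of_o = o_atoms["strand"].to_numpy()
    partners = {}
    for _, row in n_atoms.iterrows():
        dists, idx = tree.query([row.x, row.y, row.z], k=6)
        for d, j in zip(dists, idx):
            if d < 0.35 and strand_of_o[j] != row["strand"]:
                partners.setdefault(int(row["strand"]),
                                    set()).add(int(strand_of_o[j]))
                break
    interior = [s for s in partners if 0 < s < 7]
    assert interior
    for s in interior:
        assert partners[s] <= {s - 1, s + 1}
        assert len(partners[s]) == 2


def test_invalid_geometry_rejected():
    with pytest.raises(ValueError):
        LatticeGeometry(strand_spacing=-1.0)
    with pytest.raises(ValueError):
        LatticeGeometry(chi2_deg=90.0)


def test_q15_has_56_chains_of_19_residues(m_candidate, alphabet):
    model = build_q15_fibril(m_candidate, alphabet)
    assert model.n_chains == 56
    protein = model.atoms[model.atoms["res_name"] != "ACE"]
    per_chain = protein.groupby("chain_id")["res_seq"].nunique()
    assert (per_chain == 19).all()
    # acetyl cap present on every chain, C-terminus carries OXT
    caps = model.atoms[model.atoms["res_name"] == "ACE"]
    assert caps.groupby("chain_id").ngroups == 56
    assert (model.atoms["name"] == "OXT").sum() == 56


def test_q15_width_matches_tem_range(m_candidate, alphabet):
    model = build_q15_fibril(m_candidate, alphabet)
    assert 5.5 <= model.extent("y") <= 6.5


def test_q15_single_sheet_is_flat(m_candidate, alphabet, geometry):
    model = build_q15_fibril(m_candidate, alphabet, n_sheets=1)
    assert model.extent("y") < 2 * geometry.sheet_spacing


def test_q15_odd_peptides_rejected(m_candidate, alphabet):
    with pytest.raises(BuildError, match="even"):
        build_q15_fibril(m_candidate, alphabet, peptides_per_sheet=7)


@pytest.fixture(scope="module")
def small_httex1(m_candidate, alphabet):
    return build_httex1_fibril(m_candidate, alphabet, n_sheets=2,
                               hairpins_per_sheet=3, seed=1)


def test_httex1_chain_count_and_length(small_httex1):
    assert small_httex1.n_chains == 6
    per_chain = small_httex1.atoms.groupby("chain_id")["res_seq"].nunique()
    assert (per_chain == 111).all()


def test_httex1_segments_cover_sequence(small_httex1):
    atoms = small_httex1.atoms
    seg_of = atoms.groupby(["chain_id", "res_seq"])["segment"].first()
    one = seg_of.loc["A"]
    assert (one.loc[1:16] == "N17").all()
    assert one.loc[17] == "N17"
    assert (one.loc[18:37] == "polyQ").all()
    assert (one.loc[38:39] == "turn").all()
    assert (one.loc[40:61] == "polyQ").all()
    assert (one.loc[62:111] == "PRD").all()


def test_httex1_turns_type_i_prime(small_httex1):
    traj = ca.extract_dihedrals(small_httex1)
    res = traj.residues
    for chain in res["chain"].unique():
        mask = (res["chain"] == chain) & (res["segment"] == "turn")
        idx = np.where(mask.to_numpy())[0]
        assert len(idx) == 2
        t = ca.classify_turn(traj.angles["phi"][0, idx[0]],
                             traj.angles["psi"][0, idx[0]],
                             traj.angles["phi"][0, idx[1]],
                             traj.angles["psi"][0, idx[1]])
        assert t == "type_I_prime"


def test_httex1_hairpin_arms_pair_a_with_b(small_httex1):
    conf = small_httex1.atoms.groupby(["chain_id", "res_seq"])[
        "conformer"].first()
    for chain in small_httex1.atoms["chain_id"].unique():
        arm1 = set(conf.loc[chain].loc[18:37])
        arm2 = set(conf.loc[chain].loc[40:61])
        assert arm1 != arm2
        assert arm1 | arm2 == {"a", "b"}


def test_httex1_n17_helix_initialized(small_httex1):
    traj = ca.extract_dihedrals(small_httex1)
    res = traj.residues
    helix_idx = np.where(((res["segment"] == "N17")
                          & res["resid"].between(5, 11)).to_numpy())[0]
    phi = traj.angles["phi"][0, helix_idx]
    psi = traj.angles["psi"][0, helix_idx]
    assert np.allclose(phi, -57.0, atol=2.0)
    assert np.allclose(psi, -47.0, atol=2.0)


def test_httex1_oligoprolines_are_ppii(small_httex1):
    traj = ca.extract_dihedrals(small_httex1)
    res = traj.residues
    # interior residues of the first oligoproline run (P62-P72 for Q44)
    # interior residues away from the junction and the piecewise-swing
    # boundaries of the rod
    ppii_idx = np.where((res["segment"] == "PRD").to_numpy()
                        & res["resid"].between(68, 71).to_numpy())[0]
    phi = traj.angles["phi"][0, ppii_idx]
    psi = traj.angles["psi"][0, ppii_idx]
    assert np.allclose(phi, -75.0, atol=2.0)
    assert np.allclose(psi, 145.0, atol=2.0)


def test_httex1_f17_in_core_register(small_httex1, geometry):
    """F17 extends arm 1 on the lattice; the second arm's far end reaches
    past it, so its closest cross-strand register is the last/penultimate
    glutamine."""
    atoms = small_httex1.atoms
    a = atoms[(atoms["chain_id"] == "A") & (atoms["name"] == "CA")]
    f17 = a[a["res_seq"] == 17][["x", "y", "z"]].to_numpy()[0]
    arm2 = a[a["res_seq"].between(40, 61)]
    d = np.linalg.norm(arm2[["x", "y", "z"]].to_numpy() - f17, axis=1)
    nearest = int(arm2["res_seq"].to_numpy()[np.argmin(d)])
    assert nearest in (60, 61)
    assert d.min() < 0.8
    # and its nearest backbone amide partner is the penultimate glutamine
    ch = atoms[atoms["chain_id"] == "A"]
    f17_n = ch[(ch["res_seq"] == 17)
               & (ch["name"] == "N")][["x", "y", "z"]].to_numpy()[0]
    o_arm2 = ch[ch["res_seq"].between(40, 61) & (ch["name"] == "O")]
    d_no = np.linalg.norm(o_arm2[["x", "y", "z"]].to_numpy() - f17_n, axis=1)
    assert int(o_arm2["res_seq"].to_numpy()[np.argmin(d_no)]) == 60


def test_httex1_odd_polyq_rejected(m_candidate, alphabet):
    with pytest.raises(BuildError, match="even"):
        build_httex1_fibril(m_candidate, alphabet, polyq_len=15)


def test_httex1_seeds_differ(m_candidate, alphabet, small_httex1):
    other = build_httex1_fibril(m_candidate, alphabet, n_sheets=2,
                                hairpins_per_sheet=3, seed=2)
    # core backbone identical, coats (re-drawn jitters) differ somewhere
    a = small_httex1.atoms
    b = other.atoms
    bb = ("N", "CA", "C")
    sel_a = a[(a["segment"] == "polyQ") & a["name"].isin(bb)]
    sel_b = b[(b["segment"] == "polyQ") & b["name"].isin(bb)]
    assert np.allclose(sel_a[["x", "y", "z"]].to_numpy(),
                       sel_b[["x", "y", "z"]].to_numpy())
    coat_a = a[a["segment"] == "PRD"][["x", "y", "z"]].to_numpy()
    coat_b = b[b["segment"] == "PRD"][["x", "y", "z"]].to_numpy()
    assert not np.allclose(coat_a, coat_b)
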