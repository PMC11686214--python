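"""Unit-cell enumeration, symmetry reduction and the uniformity filter."""

import itertools

import pytest

from fibrilkit import lattice_enum as le


@pytest.mark.parametrize("n_classes,expected", [(1, 1), (2, 16), (3, 81)])
def test_raw_count_is_fourth_power_of_alphabet(alphabet, n_classes, expected):
    cands = le.enumerate_raw_candidates(alphabet[:n_classes])
    assert len(cands) == expected
    # lexicographic ordering in alphabet order
    order = {c.label: i for i, c in enumerate(alphabet[:n_classes])}
    keys = [tuple(order[l] for l in c.pair_assignment) for c in cands]
    assert keys == sorted(keys)


def test_eight_class_alphabet_gives_4096(raw_candidates):
    assert len(raw_candidates) == 4096


def test_empty_alphabet_rejected():
    with pytest.raises(le.ConfigurationError):
        le.enumerate_raw_candidates([])


def test_identity_group_canonical_id_is_own_encoding(alphabet):
    identity = le.SymmetryGroup([le.GroupElement("e", (0, 1, 2, 3))])
    cand = le.UnitCellCandidate(("ppu", "pmd", "mmu", "mpd"))
    assert le.canonicalize(cand, identity, alphabet) == cand.encoding


def test_group_is_closed_and_order_16(group):
    assert len(group) == 16


def test_non_bijective_generator_rejected():
    with pytest.raises(le.ConfigurationError):
        le.GroupElement("bad", (0, 0, 1, 2))


def test_orbit_partition_matches_breadth_first_oracle(raw_candidates, group,
                                                      alphabet):
    """Canonical ids define the same partition as brute-force orbit search."""
    # oracle: BFS from each unseen candidate, applying every group element
    encoding_index = {c.encoding: i for i, c in enumerate(raw_candidates)}
    oracle_label = [-1] * len(raw_candidates)
    n_orbits = 0
    for start, cand in enumerate(raw_candidates):
        if oracle_label[start] >= 0:
            continue
        frontier = [cand]
        oracle_label[start] = n_orbits
        while frontier:
            cur = frontier.pop()
            for g in group.elements:
                img = group.apply(g, cur, alphabet)
                j = encoding_index[img.encoding]
                if oracle_label[j] < 0:
                    oracle_label[j] = n_orbits
                    frontier.append(img)
        n_orbits += 1
    canon = [le.canonicalize(c, group, alphabet) for c in raw_candidates]
    # same partition: two candidates share an oracle orbit iff same canonical id
    pair_of = {}
    for lab, cid in zip(oracle_label, canon):
        assert pair_of.setdefault(lab, cid) == cid
    assert len(set(canon)) == n_orbits


def test_unique_count_at_most_1280(unique_catalog):
    assert len(unique_catalog) <= 1280


def test_canonicalization_is_group_congruence(raw_candidates, group, alphabet,
                                              rng):
    sample = rng.choice(len(raw_candidates), size=100, replace=False)
    for i in sample:
        cand = raw_candidates[i]
        cid = le.canonicalize(cand, group, alphabet)
        for g in group.elements:
            assert le.canonicalize(group.apply(g, cand, alphabet),
                                   group, alphabet) == cid


def test_uniformity_filter_keeps_exactly_30(survivors):
    assert len(survivors) == 30


def test_survivors_have_conformer_tags(survivors):
    for cand in survivors:
        assert set(cand.strand_conformers) == {(0, 0), (1, 0), (0, 1), (1, 1)}
        assert set(cand.strand_conformers.values()) <= {"a", "b"}


def test_mixed_strand_candidate_rejected(alphabet):
    # sheet 0 mixes wells across x: pair (0,0) is pp, pair (1,0) is pm
    cand = le.UnitCellCandidate(("ppu", "pmu", "ppu", "ppu"))
    assert le.apply_strand_uniformity_filter([cand], alphabet) == []


def test_filter_is_idempotent(survivors, alphabet):
    again = le.apply_strand_uniformity_filter(survivors, alphabet)
    assert [c.encoding for c in again] == [c.encoding for c in survivors]


def test_filter_commutes_with_symmetry(raw_candidates, group, alphabet, rng):
    """Uniformity is a symmetry-invariant property of the orbit."""
    sample = rng.choice(len(raw_candidates), size=200, replace=False)
    for i in sample:
        cand = raw_candidates[i]
        uniform = bool(le.apply_strand_uniformity_filter([cand], alphabet))
        for g in group.elements:
            img = group.apply(g, cand, alphabet)
            assert bool(le.apply_strand_uniformity_filter([img],
                                                          alphabet)) == uniform


def test_catalog_round_trip(survivors, tmp_path):
    path = tmp_path / "catalog.tsv"
    le.export_catalog(survivors, path)
    loaded = le.read_catalog(path)
    assert len(loaded) == len(survivors)
    for a, b in zip(survivors, loaded):
        assert a.pair_assignment == b.pair_assignment
        assert a.canonical_id == b.canonical_id
        assert a.strand_conformers == b.strand_conformers


def test_empty_catalog_round_trip(tmp_path):
    path = tmp_path / "empty.tsv"
    le.export_catalog([], path)
    assert le.read_catalog(path) == []


def test_yaml_alphabet_and_group_round_trip(tmp_path, alphabet, group,
                                            raw_candidates):
    import yaml

    alpha_path = tmp_path / "alphabet.yaml"
    alpha_path.write_text(yaml.safe_dump({"alphabet": [
        {"label": c.label, "well_a": c.well_a, "well_b": c.well_b,
         "direction": c.direction,
         "representative_chi1_deg": c.representative_chi1_deg,
         "representative_chi3_deg": c.representative_chi3_deg}
        for c in alphabet]}))
    loaded = le.load_alphabet(alpha_path)
    assert loaded == alphabet

    slots = le.PAIR_SLOTS
    group_path = tmp_path / "group.yaml"
    group_path.write_text(yaml.safe_dump({"generators": [
        {"name": g.name,
         "pair_perm": {f"{x}{y}": "".join(map(str, slots[g.pair_perm[i]]))
                       for i, (x, y) in enumerate(slots)},
         "swap_pair": g.swap_pair,
         "flip_orientation": g.flip_orientation,
         "flip_direction": g.flip_direction}
        for g in group.generators]}))
    loaded_group = le.load_group(group_path)
    assert len(loaded_group) == len(group)
    cand = raw_candidates[1234]
    assert (le.canonicalize(cand, loaded_group, alphabet)
            == le.canonicalize(cand, group, alphabet))
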