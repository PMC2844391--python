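"""Spherical neighborhood membership and its content statistics."""

import numpy as np
import pytest

from catres.neighborhood import (
    AA_ORDER,
    aa_composition,
    atomic_density,
    build_neighborhood,
    charge_features,
    load_physchem_groups,
    physchem_distribution,
    water_count,
)
from catres.structure_model import parse_pdb, representative_point

from conftest import make_pdb, simple_residue


def _structure_with_targets(points, aas=None, waters=(), hets=()):
    aas = aas or ["A"] * len(points)
    return parse_pdb(make_pdb(
        residues=[simple_residue(aa, "A", i + 1, p) for i, (aa, p) in enumerate(zip(aas, points))],
        waters=waters,
        hets=hets,
    ))


def test_boundary_is_inclusive_at_radius():
    s = _structure_with_targets([(0, 0, 0), (7.99, 0, 0), (8.01, 0, 0)])
    nbh = build_neighborhood(s, s.residues[0], radius=8.0)
    members = {r.seq_number for r in nbh.member_residues}
    assert members == {1, 2}


def test_isolated_target_contains_itself_only():
    s = _structure_with_targets([(0, 0, 0), (30, 30, 30)])
    nbh = build_neighborhood(s, s.residues[0], radius=8.0)
    assert nbh.member_residues == [s.residues[0]]
    assert water_count(nbh) == 0
    assert not nbh.hets_in
    # the target's own atoms are inside its sphere
    assert atomic_density(nbh) == len(s.residues[0].atoms)


def test_target_not_in_structure_raises(one_protein):
    other = _structure_with_targets([(0, 0, 0)])
    with pytest.raises(ValueError, match="does not belong"):
        build_neighborhood(one_protein.structure, other.residues[0])


def test_membership_matches_brute_force_scan(one_protein):
    """Neighborhood content equals an all-pairs numpy distance scan."""
    s = one_protein.structure
    rep = {r.key: representative_point(r) for r in s.residues}
    all_atoms = np.array(
        [a.coord for r in s.residues for a in r.atoms]
        + [a.coord for h in s.hets for a in h.atoms]
    )
    for target in s.residues[::7]:
        nbh = build_neighborhood(s, target, radius=8.0)
        c = rep[target.key]
        expected_members = {
            r.key for r in s.residues if np.linalg.norm(rep[r.key] - c) <= 8.0
        }
        assert {r.key for r in nbh.member_residues} == expected_members
        assert water_count(nbh) == sum(
            np.linalg.norm(w.oxygen_coord - c) <= 8.0 for w in s.waters
        )
        assert len(nbh.hets_in) == sum(
            np.linalg.norm(h.centroid - c) <= 8.0 for h in s.hets
        )
        assert atomic_density(nbh) == int(
            np.sum(np.linalg.norm(all_atoms - c, axis=1) <= 8.0)
        )


def test_membership_symmetry(one_protein):
    s = one_protein.structure
    rep = {r.key: representative_point(r) for r in s.residues}
    for a in s.residues[::11]:
        nbh_a = build_neighborhood(s, a, radius=8.0)
        for b in nbh_a.member_residues:
            nbh_b = build_neighborhood(s, b, radius=8.0)
            assert any(r.key == a.key for r in nbh_b.member_residues)
    del rep


def test_counts_monotone_in_radius(one_protein):
    s = one_protein.structure
    target = s.residues[0]
    prev = None
    for radius in (4.0, 6.0, 8.0, 12.0):
        nbh = build_neighborhood(s, target, radius)
        counts = (len(nbh.member_residues), water_count(nbh),
                  atomic_density(nbh), len(nbh.hets_in))
        if prev is not None:
            assert all(c >= p for c, p in zip(counts, prev))
        prev = counts


def test_physchem_single_group_and_normalization():
    s = _structure_with_targets([(0, 0, 0), (3, 0, 0), (0, 3, 0)], aas=["I", "V", "L"])
    nbh = build_neighborhood(s, s.residues[0])
    dist = physchem_distribution(nbh)
    # I, V, L are all high-hydrophobicity
    np.testing.assert_allclose(dist[:3], [0, 0, 1])
    for i in range(4):
        np.testing.assert_allclose(dist[3 * i: 3 * i + 3].sum(), 1.0)


def test_physchem_matches_hand_tally():
    aas = ["R", "G", "C", "D", "H", "W"]
    pts = [(0, 0, 0), (2, 0, 0), (0, 2, 0), (0, 0, 2), (2, 2, 0), (2, 0, 2)]
    s = _structure_with_targets(pts, aas=aas)
    nbh = build_neighborhood(s, s.residues[0])
    dist = physchem_distribution(nbh)
    groups = load_physchem_groups()
    expected = []
    for prop in ("hydrophobicity", "polarity", "polarizability", "vdw_volume"):
        for grp in ("low", "medium", "high"):
            expected.append(sum(aa in groups[prop][grp] for aa in aas) / len(aas))
    np.testing.assert_allclose(dist, expected)


def test_aa_composition_fractions_and_sum():
    s = _structure_with_targets(
        [(0, 0, 0), (2, 0, 0), (0, 2, 0), (0, 0, 2)], aas=["A", "A", "G", "G"])
    nbh = build_neighborhood(s, s.residues[0])
    comp = aa_composition(nbh)
    assert comp[AA_ORDER.index("A")] == 0.5
    assert comp[AA_ORDER.index("G")] == 0.5
    np.testing.assert_allclose(comp.sum(), 1.0)


def test_aa_composition_matches_counting_oracle(one_protein):
    s = one_protein.structure
    target = s.residues[3]
    nbh = build_neighborhood(s, target)
    comp = aa_composition(nbh)
    aas = [r.aa for r in nbh.member_residues]
    for i, aa in enumerate(AA_ORDER):
        np.testing.assert_allclose(comp[i], aas.count(aa) / len(aas))


@pytest.mark.parametrize(
    "aas,expected",
    [(["R", "K", "D"], (2, 1, 3)), (["A", "G", "S"], (0, 0, 0))],
)
def test_charge_features(aas, expected):
    pts = [(0, 0, 0), (2, 0, 0), (0, 2, 0)]
    s = _structure_with_targets(pts, aas=aas)
    nbh = build_neighborhood(s, s.residues[0])
    assert charge_features(nbh) == expected


def test_water_count_by_distance():
    s = _structure_with_targets(
        [(0, 0, 0)], aas=["A"], waters=[(3, 0, 0), (0, 7, 0), (0, 0, 9)])
    nbh = build_neighborhood(s, s.residues[0], radius=8.0)
    assert water_count(nbh) == 2


def test_stats_invariant_under_rigid_motion(one_protein):
    """Rotating and translating the whole structure leaves every
    neighborhood statistic unchanged."""
    s = one_protein.structure
    target = s.residues[0]
    nbh = build_neighborhood(s, target)
    before = (
        physchem_distribution(nbh), aa_composition(nbh), charge_features(nbh),
        water_count(nbh), atomic_density(nbh),
    )

    rng = np.random.default_rng(3)
    R, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    t = np.array([11.0, -4.0, 2.5])
    moved = parse_pdb(one_protein.pdb_text, pdb_id="MOVED")
    for res in moved.residues:
        for a in res.atoms:
            a.coord = R @ a.coord + t
    for h in moved.hets:
        for a in h.atoms:
            a.coord = R @ a.coord + t
    for w in moved.waters:
        w.oxygen_coord = R @ w.oxygen_coord + t

    nbh2 = build_neighborhood(moved, moved.residues[0])
    after = (
        physchem_distribution(nbh2), aa_composition(nbh2), charge_features(nbh2),
        water_count(nbh2), atomic_density(nbh2),
    )
    for b, a in zip(before, after):
        np.testing.assert_allclose(a, b, atol=1e-9)


def test_exclude_target_flag_for_ablation():
    s = _structure_with_targets([(0, 0, 0), (2, 0, 0)], aas=["R", "D"])
    nbh = build_neighborhood(s, s.residues[0])
    assert charge_features(nbh, include_target=True) == (1, 1, 2)
    assert charge_features(nbh, include_target=False) == (0, 1, 1)
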