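"""Heterogen classification, disulphide/cofactor flags, distance histograms."""

import numpy as np
import pandas as pd
import pytest

from catres.ligand_features import (
    HET_CLASSES,
    classify_heterogen,
    cofactor_bond_flag,
    disulphide_flag,
    het_distance_histogram,
    heterogen_counts,
    load_heterogen_table,
)
from catres.neighborhood import build_neighborhood
from catres.structure_model import parse_pdb, representative_point

from conftest import make_pdb, simple_residue


def test_shipped_table_class_sizes():
    table = load_heterogen_table()
    sizes = table.class_sizes()
    assert sizes == {"catalytic": 63, "non_catalytic": 11, "uncertain": 7}
    assert sum(sizes.values()) == 81


@pytest.mark.parametrize(
    "code,cls",
    [("ZN", "catalytic"), ("CL", "non_catalytic"), ("PO4", "uncertain"),
     ("HEM", "catalytic"), ("MAN", "non_catalytic"), ("GOL", "uncertain")],
)
def test_classify_heterogen_examples(code, cls):
    assert classify_heterogen(code) == cls


def test_classify_unknown_code_defaults_to_uncertain():
    assert classify_heterogen("QQQ") == "uncertain"


def test_classify_water_raises():
    with pytest.raises(ValueError, match="water"):
        classify_heterogen("HOH")


def test_heterogen_counts_by_centroid():
    text = make_pdb(
        residues=[simple_residue("A", "A", 1, (0, 0, 0))],
        hets=[("ZN", 501, [("ZN", "ZN", (4, 0, 0))]),
              ("CL", 502, [("CL", "CL", (0, 5, 0))]),
              ("MG", 503, [("MG", "MG", (20, 0, 0))])],
    )
    s = parse_pdb(text)
    nbh = build_neighborhood(s, s.residues[0], radius=8.0)
    assert heterogen_counts(nbh) == (1, 1, 0)

    empty = parse_pdb(make_pdb(residues=[simple_residue("A", "A", 1, (0, 0, 0))]))
    nbh = build_neighborhood(empty, empty.residues[0])
    assert heterogen_counts(nbh) == (0, 0, 0)


def test_heterogen_counts_match_brute_force(small_ensemble):
    _, ens = small_ensemble
    table = load_heterogen_table()
    for fp in ens.values():
        s = fp.structure
        for target in s.residues[::13]:
            c = representative_point(target)
            expected = [0, 0, 0]
            for h in s.hets:
                if np.linalg.norm(h.centroid - c) <= 8.0:
                    expected[HET_CLASSES.index(table[h.code])] += 1
            nbh = build_neighborhood(s, target, radius=8.0)
            assert heterogen_counts(nbh, table) == tuple(expected)


def test_disulphide_by_geometry_is_symmetric():
    # SG-SG at 2.05 A: canonical bridge, flagged on both partners
    text = make_pdb(residues=[simple_residue("C", "A", 1, (0, 0, 0)),
                              simple_residue("C", "A", 2, (2.05, 0, 0))])
    s = parse_pdb(text)
    assert disulphide_flag(s.residues[0], s) == 1
    assert disulphide_flag(s.residues[1], s) == 1


def test_disulphide_negative_cases():
    # 4 A apart and no SSBOND record: no bridge
    text = make_pdb(residues=[simple_residue("C", "A", 1, (0, 0, 0)),
                              simple_residue("C", "A", 2, (4, 0, 0))])
    s = parse_pdb(text)
    assert disulphide_flag(s.residues[0], s) == 0
    # non-cysteine never flagged
    text = make_pdb(residues=[simple_residue("A", "A", 1, (0, 0, 0))])
    s = parse_pdb(text)
    assert disulphide_flag(s.residues[0], s) == 0


def test_disulphide_from_ssbond_record_despite_distance():
    text = make_pdb(
        residues=[simple_residue("C", "A", 1, (0, 0, 0)),
                  simple_residue("C", "A", 2, (4, 0, 0))],
        ssbonds=[(("A", 1), ("A", 2))],
    )
    s = parse_pdb(text)
    assert disulphide_flag(s.residues[0], s) == 1


def test_disulphide_cysteine_without_sg_warns():
    text = make_pdb(residues=[("C", "A", 1, [("N", (1, 0, 0), 10.0),
                                             ("CA", (0, 0, 0), 10.0),
                                             ("CB", (0, 1, 0), 10.0)])])
    s = parse_pdb(text)
    with pytest.warns(UserWarning, match="without SG"):
        assert disulphide_flag(s.residues[0], s) == 0


@pytest.mark.parametrize("het_x,expected", [(2.6, 1), (4.0, 0)])
def test_cofactor_bond_flag_threshold(het_x, expected):
    # side-chain atom at origin; MG at het_x along x: bond iff <= 3 A
    text = make_pdb(
        residues=[simple_residue("A", "A", 1, (0, 0, 0))],
        hets=[("MG", 501, [("MG", "MG", (het_x, 0, 0.0))])],
    )
    s = parse_pdb(text)
    assert cofactor_bond_flag(s.residues[0], s) == expected


def test_cofactor_bond_matches_min_distance_oracle(small_ensemble):
    _, ens = small_ensemble
    fp = next(iter(ens.values()))
    s = fp.structure
    for res in s.residues[::9]:
        res_coords = np.array([a.coord for a in res.atoms])
        dmin = np.inf
        for h in s.hets:
            for a in h.atoms:
                dmin = min(dmin, np.linalg.norm(res_coords - a.coord, axis=1).min())
        assert cofactor_bond_flag(res, s) == int(dmin <= 3.0)


def _label_row(pdb_id, chain, number, label):
    return {"id": 0, "label": label, "protein_PDB_Id": pdb_id,
            "residue": "A", "chain": chain, "number": number}


def test_het_distance_histogram_single_pair():
    text = make_pdb(
        residues=[simple_residue("A", "A", 1, (6, 0, 0))],
        hets=[("ZN", 501, [("ZN", "ZN", (0, 0, 0))])],
    )
    s = parse_pdb(text, pdb_id="P1")
    labels = pd.DataFrame([_label_row("P1", "A", 1, 1)])
    counts, edges = het_distance_histogram({"P1": s}, labels, "ZN", bin_width=2.0)
    # distance exactly 6 -> bin [6, 8)
    assert counts[3] == 1 and counts.sum() == 1
    assert edges[3] == 6.0


def test_het_distance_histogram_empty_cases():
    text = make_pdb(
        residues=[simple_residue("A", "A", 1, (6, 0, 0))],
        hets=[("ZN", 501, [("ZN", "ZN", (0, 0, 0))])],
    )
    s = parse_pdb(text, pdb_id="P1")
    no_pos = pd.DataFrame([_label_row("P1", "A", 1, -1)])
    counts, _ = het_distance_histogram({"P1": s}, no_pos, "ZN")
    assert counts.size == 0
    labels = pd.DataFrame([_label_row("P1", "A", 1, 1)])
    counts, _ = het_distance_histogram({"P1": s}, labels, "FAD")
    assert counts.size == 0


def test_het_distance_histogram_matches_direct_tally(small_ensemble):
    """Planted ensemble: histogram equals a direct double-loop tally."""
    _, ens = small_ensemble
    structures = {fp.pdb_id: fp.structure for fp in ens.values()}
    labels = pd.concat([fp.labels for fp in ens.values()], ignore_index=True)
    counts, edges = het_distance_histogram(structures, labels, "ZN", bin_width=1.0)
    distances = []
    for fp in ens.values():
        cat = [representative_point(r) for r, row in zip(
            fp.structure.residues, fp.labels.itertuples()) if row.label == 1]
        for h in fp.structure.hets:
            if h.code == "ZN":
                distances.extend(np.linalg.norm(h.centroid - p) for p in cat)
    expected, _ = np.histogram(distances, bins=edges)
    np.testing.assert_array_equal(counts, expected)
    # catalytic-class het planted at 4 A from the site center: all distances small
    assert max(distances) < 15.0
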