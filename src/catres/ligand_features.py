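"""Ligand-aware residue features and heterogen classification.

Heterogens (non-water HETATM groups: metal ions, cofactors, substrate
analogues, buffer components) carry strong but ambiguous signal about active
sites: cofactors cluster near catalytic residues while crystallization
additives do not.  The shipped class table assigns each heterogen code seen
in the feature-engineering enzyme set to one of three groups -- catalytic,
non-catalytic or uncertain -- based on literature roles and the distribution
of heterogen-to-catalytic-residue distances.

Features computed here: a disulphide-bonded-cysteine flag, per-class counts
of heterogens in the structural neighborhood, and a flag for a direct
residue-cofactor bond (heavy-atom distance at most 3 A).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np

from catres.neighborhood import StructuralNeighborhood
from catres.structure_model import (
    WATER_CODES,
    ProteinStructure,
    Residue,
    representative_point,
)

__all__ = [
    "HET_CLASSES",
    "HeterogenClassTable",
    "load_heterogen_table",
    "classify_heterogen",
    "heterogen_counts",
    "disulphide_flag",
    "cofactor_bond_flag",
    "het_distance_histogram",
    "SS_BOND_THRESHOLD",
    "COFACTOR_BOND_THRESHOLD",
]

HET_CLASSES = ("catalytic", "non_catalytic", "uncertain")

#: geometric SG-SG cutoff for a disulphide bridge (canonical bond ~2.05 A)
SS_BOND_THRESHOLD = 2.5

#: heavy-atom distance threshold for a residue-cofactor bond
COFACTOR_BOND_THRESHOLD = 3.0

#: nucleotide codes excluded from heterogen processing when they appear as
#: polymer chains (DNA/RNA)
NUCLEIC_CODES = frozenset({"DA", "DC", "DG", "DT", "DU", "A", "C", "G", "U", "T"})


@dataclass
class HeterogenClassTable:
    mapping: dict[str, str]
    default_class: str = "uncertain"

    def __post_init__(self) -> None:
        bad = {c for c in self.mapping.values() if c not in HET_CLASSES}
        if bad:
            raise ValueError(f"unknown heterogen classes: {bad}")
        if self.default_class not in HET_CLASSES:
            raise ValueError(f"unknown default class: {self.default_class}")

    def __getitem__(self, code: str) -> str:
        return self.mapping.get(code.upper(), self.default_class)

    def class_sizes(self) -> dict[str, int]:
        sizes = dict.fromkeys(HET_CLASSES, 0)
        for cls in self.mapping.values():
            sizes[cls] += 1
        return sizes


def load_heterogen_table(path=None, default_class: str = "uncertain") -> HeterogenClassTable:
    """Load a heterogen class table (CSV: code,class).

    With no path, returns the shipped default table of 81 codes
    (63 catalytic, 11 non-catalytic, 7 uncertain).
    """
    if path is None:
        text = resources.files("catres.data").joinpath("heterogen_classes.csv").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    mapping: dict[str, str] = {}
    for row in csv.DictReader(text.splitlines()):
        code = row["code"].strip().upper()
        if code in mapping:
            raise ValueError(f"duplicate heterogen code {code}")
        mapping[code] = row["class"].strip()
    return HeterogenClassTable(mapping, default_class=default_class)


_DEFAULT_TABLE = load_heterogen_table()


def classify_heterogen(code: str, table: HeterogenClassTable | None = None) -> str:
    """Class of a non-water heterogen code; unlisted codes fall back to the
    table's default class."""
    if code.upper() in WATER_CODES:
        raise ValueError(f"{code} is water, not a heterogen")
    if table is None:
        table = _DEFAULT_TABLE
    return table[code]


def heterogen_counts(
    nbh: StructuralNeighborhood, table: HeterogenClassTable | None = None
) -> tuple[int, int, int]:
    """(catalytic, non-catalytic, uncertain) heterogen counts in the sphere.

    Membership is by heterogen centroid, matching the neighborhood build;
    nucleic-acid monomers are skipped.
    """
    if table is None:
        table = _DEFAULT_TABLE
    counts = dict.fromkeys(HET_CLASSES, 0)
    for het in nbh.hets_in:
        if het.code.upper() in NUCLEIC_CODES:
            continue
        counts[table[het.code]] += 1
    return counts["catalytic"], counts["non_catalytic"], counts["uncertain"]


def disulphide_flag(residue: Residue, structure: ProteinStructure) -> int:
    """1 iff the residue is a disulphide-bonded cysteine.

    A cysteine qualifies if it appears in an SSBOND record or if its SG atom
    lies within the geometric bridge cutoff of another cysteine's SG.
    """
    if residue.aa != "C":
        return 0
    if residue.key in {k for pair in structure.ssbonds for k in pair}:
        return 1
    sg = residue.atom("SG")
    if sg is None:
        warnings.warn(f"{residue!r}: cysteine without SG atom")
        return 0
    for other in structure.residues:
        if other is residue or other.aa != "C":
            continue
        other_sg = other.atom("SG")
        if other_sg is None:
            continue
        if np.linalg.norm(sg.coord - other_sg.coord) <= SS_BOND_THRESHOLD:
            return 1
    return 0


def cofactor_bond_flag(
    residue: Residue,
    structure: ProteinStructure,
    threshold: float = COFACTOR_BOND_THRESHOLD,
) -> int:
    """1 iff any heavy atom of the residue is within ``threshold`` of any
    heterogen heavy atom."""
    res_coords = np.array([a.coord for a in residue.atoms if not a.is_hydrogen])
    if res_coords.size == 0:
        return 0
    for het in structure.hets:
        if het.code.upper() in NUCLEIC_CODES:
            continue
        het_coords = np.array([a.coord for a in het.atoms if not a.is_hydrogen])
        if het_coords.size == 0:
            continue
        d = np.linalg.norm(res_coords[:, None, :] - het_coords[None, :, :], axis=2)
        if d.min() <= threshold:
            return 1
    return 0


def het_distance_histogram(
    structures: dict[str, ProteinStructure],
    labels,
    het_code: str,
    bin_width: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of heterogen-centroid to catalytic-residue distances.

    ``labels`` is the label table (as returned by
    :func:`catres.pipeline.read_labels`): rows with label +1 mark the
    catalytic residues of each structure.  Returns (counts, bin_edges); bins
    are [0, w), [w, 2w), ...  Absent het codes give an empty histogram.
    """
    het_code = het_code.upper()
    distances: list[float] = []
    for pdb_id, structure in structures.items():
        sub = labels[(labels["protein_PDB_Id"] == pdb_id) & (labels["label"] == 1)]
        cat_points = []
        for _, row in sub.iterrows():
            try:
                res = structure.residue_by_key(str(row["chain"]), int(row["number"]))
            except KeyError:
                continue
            cat_points.append(representative_point(res))
        if not cat_points:
            continue
        for het in structure.hets:
            if het.code.upper() != het_code:
                continue
            for p in cat_points:
                distances.append(float(np.linalg.norm(het.centroid - p)))
    if not distances:
        return np.array([], dtype=int), np.array([0.0])
    n_bins = int(np.floor(max(distances) / bin_width)) + 1
    edges = np.arange(0, (n_bins + 1) * bin_width, bin_width)
    counts, _ = np.histogram(distances, bins=edges)
    return counts, edges
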