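"""Spherical structural neighborhood of a residue and its content statistics.

A residue is represented by its side-chain centroid; its structural
neighborhood is everything inside a sphere of fixed radius (default 8 A, the
maximum residue-water interaction distance) centered on that point: other
residues (by their own representative points), water molecules (by oxygen),
heterogen groups (by centroid) and individual non-water atoms.

The statistics computed here are, for the member residues: three-bin
distributions of hydrophobicity, polarity, polarizability and van der Waals
volume; the 20-way amino-acid composition; counts of positively / negatively
charged residues; plus the water count and atomic density of the sphere and
the target's normalized B-factor.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from catres.structure_model import (
    HetGroup,
    ProteinStructure,
    Residue,
    WaterMolecule,
    normalized_bfactor,
    representative_point,
)

__all__ = [
    "AA_ORDER",
    "POSITIVE_AAS",
    "NEGATIVE_AAS",
    "StructuralNeighborhood",
    "NeighborhoodStats",
    "build_neighborhood",
    "physchem_distribution",
    "aa_composition",
    "charge_features",
    "water_count",
    "atomic_density",
    "neighborhood_stats",
    "load_physchem_groups",
    "PHYSCHEM_PROPERTIES",
]

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
POSITIVE_AAS = frozenset("RKH")
NEGATIVE_AAS = frozenset("DE")

PHYSCHEM_PROPERTIES = ("hydrophobicity", "polarity", "polarizability", "vdw_volume")
_GROUP_ORDER = ("low", "medium", "high")


def load_physchem_groups(path=None) -> dict[str, dict[str, str]]:
    """Amino-acid three-group tables per physico-chemical property.

    Shipped as an auditable CSV (property, group, residues); an alternative
    table file may be supplied to swap the grouping.
    """
    if path is None:
        source = resources.files("catres.data").joinpath("physchem_groups.csv")
        text = source.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    tables: dict[str, dict[str, str]] = {}
    for row in csv.DictReader(text.splitlines()):
        tables.setdefault(row["property"], {})[row["group"]] = row["residues"]
    for prop, groups in tables.items():
        covered = "".join(sorted("".join(groups.values())))
        if covered != AA_ORDER:
            raise ValueError(f"group table for {prop} does not partition the 20 amino acids")
    return tables


_DEFAULT_GROUPS = load_physchem_groups()


@dataclass
class StructuralNeighborhood:
    target: Residue
    radius: float
    member_residues: list[Residue]
    waters_in: list[WaterMolecule]
    hets_in: list[HetGroup]
    atoms_in: int
    center: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not any(r is self.target for r in self.member_residues):
            raise ValueError("target must belong to its own neighborhood")


@dataclass
class NeighborhoodStats:
    physchem_bins: np.ndarray  # 12 values, (property, low/medium/high)
    aa_freqs: np.ndarray  # 20 values, AA_ORDER
    n_pos: int
    n_neg: int
    n_charged_sum: int
    water_count: int
    atomic_density: int
    bfactor_z: float


def build_neighborhood(
    structure: ProteinStructure,
    target: Residue,
    radius: float = 8.0,
) -> StructuralNeighborhood:
    """All structure content within ``radius`` of the target's representative
    point (inclusive boundary, Euclidean metric).

    The target residue itself is always a member (it lies in the sphere);
    statistics functions take an ``include_target`` flag for ablation.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not any(r is target for r in structure.residues):
        raise ValueError("target residue does not belong to the structure")

    center = representative_point(target)

    rep_points = np.array([representative_point(r) for r in structure.residues])
    tree = cKDTree(rep_points)
    idx = sorted(tree.query_ball_point(center, radius))
    kept = [structure.residues[i] for i in idx]

    waters_in = [
        w for w in structure.waters
        if np.linalg.norm(w.oxygen_coord - center) <= radius
    ]
    hets_in = [
        h for h in structure.hets
        if np.linalg.norm(h.centroid - center) <= radius
    ]

    atom_coords = [a.coord for r in structure.residues for a in r.atoms]
    atom_coords += [a.coord for h in structure.hets for a in h.atoms]
    atom_coords = np.array(atom_coords)
    d = np.linalg.norm(atom_coords - center, axis=1)
    atoms_in = int(np.sum(d <= radius))

    return StructuralNeighborhood(
        target=target,
        radius=radius,
        member_residues=kept,
        waters_in=waters_in,
        hets_in=hets_in,
        atoms_in=atoms_in,
        center=center,
    )


def _stat_residues(nbh: StructuralNeighborhood, include_target: bool) -> list[Residue]:
    if include_target:
        return nbh.member_residues
    return [r for r in nbh.member_residues if r is not nbh.target]


def physchem_distribution(
    nbh: StructuralNeighborhood,
    groups: dict[str, dict[str, str]] | None = None,
    include_target: bool = True,
) -> np.ndarray:
    """Twelve scalars: low/medium/high fraction for each of hydrophobicity,
    polarity, polarizability and van der Waals volume over member residues.

    Unknown ('X') residues are excluded from both numerator and denominator;
    an empty neighborhood yields all zeros.
    """
    if groups is None:
        groups = _DEFAULT_GROUPS
    aas = [r.aa for r in _stat_residues(nbh, include_target) if r.aa != "X"]
    out = np.zeros(12)
    if not aas:
        return out
    n = len(aas)
    for i, prop in enumerate(PHYSCHEM_PROPERTIES):
        for j, grp in enumerate(_GROUP_ORDER):
            members = groups[prop][grp]
            out[3 * i + j] = sum(aa in members for aa in aas) / n
    return out


def aa_composition(nbh: StructuralNeighborhood, include_target: bool = True) -> np.ndarray:
    """Relative frequency of each of the 20 amino acids among member residues."""
    aas = [r.aa for r in _stat_residues(nbh, include_target) if r.aa != "X"]
    out = np.zeros(20)
    if not aas:
        return out
    for aa in aas:
        out[AA_ORDER.index(aa)] += 1
    return out / len(aas)


def charge_features(nbh: StructuralNeighborhood, include_target: bool = True) -> tuple[int, int, int]:
    """(positively charged, negatively charged, total charged) residue counts."""
    aas = [r.aa for r in _stat_residues(nbh, include_target)]
    n_pos = sum(aa in POSITIVE_AAS for aa in aas)
    n_neg = sum(aa in NEGATIVE_AAS for aa in aas)
    return n_pos, n_neg, n_pos + n_neg


def water_count(nbh: StructuralNeighborhood) -> int:
    return len(nbh.waters_in)


def atomic_density(nbh: StructuralNeighborhood) -> int:
    """Total number of atoms in the sphere (protein + heterogen, waters
    counted separately by :func:`water_count`)."""
    return nbh.atoms_in


def neighborhood_stats(
    nbh: StructuralNeighborhood,
    structure: ProteinStructure,
    groups: dict[str, dict[str, str]] | None = None,
) -> NeighborhoodStats:
    n_pos, n_neg, n_sum = charge_features(nbh)
    return NeighborhoodStats(
        physchem_bins=physchem_distribution(nbh, groups),
        aa_freqs=aa_composition(nbh),
        n_pos=n_pos,
        n_neg=n_neg,
        n_charged_sum=n_sum,
        water_count=water_count(nbh),
        atomic_density=atomic_density(nbh),
        bfactor_z=normalized_bfactor(nbh.target, structure),
    )
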