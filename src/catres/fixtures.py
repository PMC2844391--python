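"""Synthetic enzyme-like fixtures with planted active sites.

The generator emulates the data layout the predictor consumes: PDB structure
files, per-residue conservation profiles and binary catalytic labels.  Each
synthetic protein has a compact active site -- a handful of catalytic
residues whose representative points all fit inside one neighborhood sphere,
with a catalytic-class heterogen (a ZN ion by default) and a few ordered
waters placed next to it -- surrounded by a dispersed shell of background
residues.  Non-catalytic heterogens are kept far (> 15 A) from the site,
mirroring the distance separation observed between cofactors and
crystallization additives.  Catalytic positions receive strongly conserved
profiles; background positions noisy near-uniform ones.

Geometry is deliberately minimal: each residue has four backbone atoms and a
single side-chain pseudo-atom placed at the intended representative point,
which is sufficient for every feature the package computes.  All randomness
flows through one seeded generator, so outputs are byte-stable per seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from catres.sequence_features import ConservationProfile, write_profile_tsv
from catres.structure_model import PROTEIN_3TO1, ProteinStructure, parse_pdb

__all__ = [
    "FixtureSpec",
    "FixtureProtein",
    "generate_structure",
    "generate_profile",
    "generate_ensemble",
]

PROTEIN_1TO3 = {v: k for k, v in PROTEIN_3TO1.items()}

#: residues with high catalytic propensity, used for planted sites
CATALYTIC_AAS = "HDECK"

#: multi-atom heterogen codes get a 4-atom tetrahedral placeholder geometry
SINGLE_ATOM_HETS = frozenset({
    "ZN", "MG", "MN", "FE", "FE2", "CU1", "NA", "K", "CL", "CA", "NI", "ZN3",
})


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for the synthetic ensemble.

    Defaults: 20 proteins of 120 residues with 3 catalytic residues each
    (imbalance 1:39), a ZN ion 4 A from the site center, a chloride placed
    far away, four ordered waters at the site, and conservation strength 0.9.
    """

    n_proteins: int = 20
    residues_per_protein: int = 120
    n_catalytic: int = 3
    active_site_radius: float = 8.0
    het_plan: tuple[tuple[str, float], ...] = (("ZN", 4.0),)
    noncat_het_codes: tuple[str, ...] = ("CL",)
    n_waters_near_site: int = 4
    background_spread: float = 40.0
    conservation_strength: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_proteins, self.residues_per_protein, self.n_catalytic) < 0:
            raise ValueError("counts must be non-negative")
        if self.active_site_radius > 8.0:
            raise ValueError("active site must fit inside one 8 A neighborhood")
        if not 0 < self.conservation_strength <= 1:
            raise ValueError("conservation strength must be in (0, 1]")


@dataclass
class FixtureProtein:
    pdb_id: str
    pdb_text: str
    labels: pd.DataFrame
    structure: ProteinStructure
    profile: ConservationProfile | None = None
    profile_tsv: str = ""


def _unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _sample_points(
    rng: np.random.Generator,
    n: int,
    r_min: float,
    r_max: float,
    min_sep: float,
    existing: list[np.ndarray],
    max_tries: int = 20000,
) -> list[np.ndarray]:
    """Points with radial distance in [r_min, r_max] from the origin and
    pairwise separation >= min_sep from each other and ``existing``."""
    points: list[np.ndarray] = []
    tries = 0
    while len(points) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"infeasible geometry: cannot place {n} points with "
                f"separation {min_sep} in shell [{r_min}, {r_max}]"
            )
        p = _unit(rng) * rng.uniform(r_min, r_max)
        if all(np.linalg.norm(p - q) >= min_sep for q in points + existing):
            points.append(p)
    return points


def _pdb_line(record: str, serial: int, name: str, resname: str, chain: str,
              resseq: int, coord: np.ndarray, occ: float, b: float, element: str) -> str:
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"{record:<6s}{serial:5d} {name_field:<4s} {resname:>3s} {chain:1s}"
        f"{resseq:4d}    {coord[0]:8.3f}{coord[1]:8.3f}{coord[2]:8.3f}"
        f"{occ:6.2f}{b:6.2f}          {element:>2s}"
    )


def _residue_lines(serial: int, aa: str, resseq: int, rep_point: np.ndarray,
                   bfactor: float, rng: np.random.Generator) -> tuple[list[str], int]:
    resname = PROTEIN_1TO3[aa]
    lines = []
    if aa == "G":
        ca = rep_point
    else:
        ca = rep_point + _unit(rng) * 1.5
    n = ca + np.array([1.33, 0.44, 0.0])
    c = ca + np.array([-1.21, 0.57, 0.0])
    o = c + np.array([-0.32, 1.18, 0.0])
    for name, element, coord in (("N", "N", n), ("CA", "C", ca), ("C", "C", c), ("O", "O", o)):
        lines.append(_pdb_line("ATOM", serial, name, resname, "A", resseq, coord, 1.0, bfactor, element))
        serial += 1
    if aa != "G":
        side_name, side_elem = ("SG", "S") if aa == "C" else ("CB", "C")
        lines.append(_pdb_line("ATOM", serial, side_name, resname, "A", resseq,
                               rep_point, 1.0, bfactor, side_elem))
        serial += 1
    return lines, serial


def _het_lines(serial: int, code: str, resseq: int, centroid: np.ndarray,
               rng: np.random.Generator) -> tuple[list[str], int]:
    lines = []
    if code in SINGLE_ATOM_HETS:
        element = code[:2] if code[:2].isalpha() else code[0]
        lines.append(_pdb_line("HETATM", serial, code[:3], code, "A", resseq,
                               centroid, 1.0, 20.0, element[:2]))
        serial += 1
    else:
        # four placeholder atoms with zero-mean offsets so the centroid is exact
        offsets = np.array([
            [1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]
        ]) * 0.8
        for i, off in enumerate(offsets):
            lines.append(_pdb_line("HETATM", serial, f"C{i + 1}", code, "A", resseq,
                                   centroid + off, 1.0, 20.0, "C"))
            serial += 1
    return lines, serial


def generate_structure(
    spec: FixtureSpec, protein_index: int = 0, id_offset: int = 0
) -> FixtureProtein:
    """One synthetic protein: PDB text plus its label table.

    ``protein_index`` selects the protein within the ensemble (and its
    sub-seed); ``id_offset`` is the first value of the running example id in
    the label table.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, protein_index]))
    pdb_id = f"S{protein_index:03d}"

    n_back = spec.residues_per_protein - spec.n_catalytic
    if n_back < 0:
        raise ValueError("more catalytic residues than residues per protein")

    # catalytic representative points: pairwise distances <= active_site_radius
    cat_points = _sample_points(
        rng, spec.n_catalytic, 0.0, spec.active_site_radius / 2.0, 3.0, []
    )
    # background shell starts beyond the neighborhood radius of the site
    back_points = _sample_points(
        rng, n_back, 12.0, spec.background_spread, 2.8, cat_points
    )

    cat_aas = [CATALYTIC_AAS[int(rng.integers(len(CATALYTIC_AAS)))] for _ in cat_points]
    back_aas = ["ACDEFGHIKLMNPQRSTVWY"[int(rng.integers(20))] for _ in back_points]

    lines = [f"HEADER    SYNTHETIC ENZYME FIXTURE                        {pdb_id}"]
    serial = 1
    resseq = 0
    rows = []
    eid = id_offset
    order = []  # (aa, rep_point, bfactor, label)
    for aa, p in zip(cat_aas, cat_points):
        order.append((aa, p, max(1.0, rng.normal(15.0, 2.0)), 1))
    for aa, p in zip(back_aas, back_points):
        order.append((aa, p, max(1.0, rng.normal(30.0, 5.0)), -1))

    for aa, p, b, label in order:
        resseq += 1
        res_lines, serial = _residue_lines(serial, aa, resseq, p, b, rng)
        lines.extend(res_lines)
        rows.append({
            "id": eid, "label": label, "protein_PDB_Id": pdb_id,
            "residue": aa, "chain": "A", "number": resseq,
        })
        eid += 1

    het_seq = resseq + 100
    for code, dist in spec.het_plan:
        het_seq += 1
        centroid = _unit(rng) * dist
        het, serial = _het_lines(serial, code.upper(), het_seq, centroid, rng)
        lines.extend(het)
    for code in spec.noncat_het_codes:
        het_seq += 1
        centroid = _unit(rng) * rng.uniform(18.0, 25.0)
        het, serial = _het_lines(serial, code.upper(), het_seq, centroid, rng)
        lines.extend(het)

    wat_seq = het_seq + 100
    for _ in range(spec.n_waters_near_site):
        wat_seq += 1
        coord = _unit(rng) * rng.uniform(3.0, 7.0)
        lines.append(_pdb_line("HETATM", serial, "O", "HOH", "A", wat_seq, coord, 1.0, 30.0, "O"))
        serial += 1
    for _ in range(spec.residues_per_protein // 20):
        wat_seq += 1
        coord = _unit(rng) * rng.uniform(20.0, 30.0)
        lines.append(_pdb_line("HETATM", serial, "O", "HOH", "A", wat_seq, coord, 1.0, 30.0, "O"))
        serial += 1

    lines.append("END")
    pdb_text = "\n".join(lines) + "\n"
    labels = pd.DataFrame(rows, columns=["id", "label", "protein_PDB_Id", "residue", "chain", "number"])
    structure = parse_pdb(pdb_text, pdb_id=pdb_id)
    return FixtureProtein(pdb_id=pdb_id, pdb_text=pdb_text, labels=labels, structure=structure)


def generate_profile(
    structure: ProteinStructure,
    labels: pd.DataFrame,
    conservation_strength: float = 0.9,
    rng: np.random.Generator | None = None,
) -> ConservationProfile:
    """Conservation profile aligned with ``structure.residues``.

    Catalytic positions put ``conservation_strength`` of the mass on the true
    residue (remainder uniform) and get a high effective observation count;
    background positions are noisy near-uniform with few observations.
    """
    from catres.sequence_features import AA_ORDER

    if rng is None:
        rng = np.random.default_rng(0)
    positive = {
        (str(r["chain"]), int(r["number"]))
        for _, r in labels.iterrows() if int(r["label"]) == 1
    }
    probs, n_obs = [], []
    for res in structure.residues:
        if (res.chain, res.seq_number) in positive:
            row = np.full(20, (1.0 - conservation_strength) / 19.0)
            row[AA_ORDER.index(res.aa)] = conservation_strength
            n_obs.append(200.0)
        else:
            row = rng.dirichlet(np.full(20, 5.0))
            n_obs.append(float(rng.uniform(2.0, 8.0)))
        probs.append(row)
    return ConservationProfile(np.array(probs), np.array(n_obs))


def generate_ensemble(spec: FixtureSpec) -> dict[str, FixtureProtein]:
    """The full synthetic study: ``spec.n_proteins`` proteins with labels and
    profiles, keyed by synthetic PDB id."""
    proteins: dict[str, FixtureProtein] = {}
    eid = 0
    for i in range(spec.n_proteins):
        fp = generate_structure(spec, protein_index=i, id_offset=eid)
        eid += len(fp.labels)
        prof_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, i, 1]))
        fp.profile = generate_profile(
            fp.structure, fp.labels, spec.conservation_strength, rng=prof_rng
        )
        fp.profile_tsv = write_profile_tsv(fp.profile)
        proteins[fp.pdb_id] = fp
    return proteins


def ensemble_labels(proteins: dict[str, FixtureProtein]) -> pd.DataFrame:
    """Concatenated label table across the ensemble (Additional-file schema)."""
    return pd.concat([fp.labels for fp in proteins.values()], ignore_index=True)
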