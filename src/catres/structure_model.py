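"""Typed protein-structure model and residue-level geometric primitives.

Parses PDB files (ATOM/HETATM/SSBOND; first model only) into a small typed
model tailored to residue-level feature extraction: protein residues, water
molecules, and heterogen groups (ions, cofactors, substrates) are kept as
distinct populations because downstream features treat them differently.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

__all__ = [
    "Atom",
    "Residue",
    "HetGroup",
    "WaterMolecule",
    "ProteinStructure",
    "PDBParseError",
    "parse_pdb",
    "representative_point",
    "normalized_bfactor",
    "residue_bfactor_zscores",
]

WATER_CODES = frozenset({"HOH", "WAT", "DOD"})

#: Backbone heavy atoms excluded from the side-chain centroid.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

PROTEIN_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: Modified residues recorded as HETATM inside a chain that are mapped back
#: to a standard amino acid.  Overridable via ``parse_pdb(modified_residues=...)``.
DEFAULT_MODIFIED_RESIDUES = {"MSE": "M"}


class PDBParseError(ValueError):
    """Raised when a PDB record cannot be interpreted."""


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray
    bfactor: float
    occupancy: float
    is_hetatm: bool = False

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinate must be a finite 3-vector")
        if self.bfactor < 0:
            warnings.warn(f"atom {self.name}: negative B-factor {self.bfactor}")

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class Residue:
    aa: str
    chain: str
    seq_number: int
    insertion_code: str = ""
    atoms: list[Atom] = field(default_factory=list)
    name3: str = ""

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.seq_number, self.insertion_code)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Residue({self.aa} {self.chain}{self.seq_number}{self.insertion_code})"


@dataclass
class HetGroup:
    code: str
    atoms: list[Atom]
    chain: str = ""
    seq_number: int = 0

    @property
    def centroid(self) -> np.ndarray:
        return np.mean([a.coord for a in self.atoms], axis=0)


@dataclass
class WaterMolecule:
    oxygen_coord: np.ndarray

    def __post_init__(self) -> None:
        self.oxygen_coord = np.asarray(self.oxygen_coord, dtype=float)


@dataclass
class ProteinStructure:
    pdb_id: str
    residues: list[Residue]
    waters: list[WaterMolecule]
    hets: list[HetGroup]
    ssbonds: list[tuple[tuple[str, int, str], tuple[str, int, str]]] = field(
        default_factory=list
    )

    def residue_by_key(self, chain: str, seq_number: int, insertion_code: str = "") -> Residue:
        for r in self.residues:
            if r.key == (chain, seq_number, insertion_code):
                return r
        raise KeyError(f"no residue {chain}/{seq_number}{insertion_code} in {self.pdb_id}")

    @property
    def n_atom_records(self) -> int:
        """Total atoms retained after altLoc pruning (protein + het + water)."""
        n = sum(len(r.atoms) for r in self.residues)
        n += sum(len(h.atoms) for h in self.hets)
        n += len(self.waters)
        return n


def _parse_ssbonds(pdb_text: str) -> list[tuple[tuple[str, int, str], tuple[str, int, str]]]:
    bonds = []
    for line in pdb_text.splitlines():
        if not line.startswith("SSBOND"):
            continue
        try:
            a = (line[15:16].strip(), int(line[17:21]), line[21:22].strip())
            b = (line[29:30].strip(), int(line[31:35]), line[35:36].strip())
        except (ValueError, IndexError) as exc:
            raise PDBParseError(f"malformed SSBOND record: {line!r}") from exc
        bonds.append((a, b))
    return bonds


def parse_pdb(
    pdb_text: str | io.TextIOBase,
    pdb_id: str = "XXXX",
    modified_residues: dict[str, str] | None = None,
) -> ProteinStructure:
    """Parse PDB-format text into a :class:`ProteinStructure`.

    Only the first model of multi-model (NMR) entries is read.  Alternate
    conformers are pruned to the highest-occupancy one.  HETATM groups named
    HOH/WAT/DOD become :class:`WaterMolecule`; modified residues with a known
    standard-residue mapping (MSE by default) are folded back into the chain;
    every other HETATM group becomes a :class:`HetGroup`.

    Raises :class:`PDBParseError` (naming the offending line where the
    underlying parser reports one) on malformed coordinate fields.
    """
    if modified_residues is None:
        modified_residues = DEFAULT_MODIFIED_RESIDUES
    if hasattr(pdb_text, "read"):
        pdb_text = pdb_text.read()

    handle = io.StringIO(pdb_text)
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        bio_structure = parser.get_structure(pdb_id, handle)
    except PDBConstructionException as exc:
        raise PDBParseError(str(exc)) from exc

    models = list(bio_structure)
    if not models:
        raise PDBParseError("no ATOM records found")
    model = models[0]

    residues: list[Residue] = []
    waters: list[WaterMolecule] = []
    hets: list[HetGroup] = []
    seen_keys: set[tuple[str, int, str]] = set()

    for chain in model:
        chain_id = chain.id.strip() or "A"
        for bio_res in chain:
            hetflag, seq_number, icode = bio_res.id
            icode = icode.strip()
            resname = bio_res.get_resname().strip()
            # default iteration yields the selected (highest-occupancy) altloc
            atoms = [
                Atom(
                    name=a.get_name(),
                    element=(a.element or "").strip().upper(),
                    coord=a.get_coord(),
                    bfactor=float(a.get_bfactor() or 0.0),
                    occupancy=float(a.get_occupancy() if a.get_occupancy() is not None else 1.0),
                    is_hetatm=hetflag != " ",
                )
                for a in bio_res
            ]
            if not atoms:
                continue
            if hetflag == "W" or resname in WATER_CODES:
                oxy = next((a for a in atoms if a.element == "O"), atoms[0])
                waters.append(WaterMolecule(oxy.coord))
                continue
            if hetflag != " " and resname not in modified_residues:
                hets.append(HetGroup(resname, atoms, chain=chain_id, seq_number=seq_number))
                continue
            aa = PROTEIN_3TO1.get(resname) or modified_residues.get(resname)
            if aa is None:
                warnings.warn(f"unknown residue code {resname!r}; keeping as aa='X'")
                aa = "X"
            key = (chain_id, seq_number, icode)
            if key in seen_keys:
                raise PDBParseError(f"duplicate residue key {key}")
            seen_keys.add(key)
            residues.append(
                Residue(aa=aa, chain=chain_id, seq_number=seq_number,
                        insertion_code=icode, atoms=atoms, name3=resname)
            )

    if not residues:
        raise PDBParseError("no protein residues parsed")

    return ProteinStructure(
        pdb_id=pdb_id,
        residues=residues,
        waters=waters,
        hets=hets,
        ssbonds=_parse_ssbonds(pdb_text),
    )


def representative_point(residue: Residue) -> np.ndarray:
    """The residue's single 3D representative point.

    Centroid of side-chain heavy atoms (everything but N, CA, C, O, OXT and
    hydrogens); for glycine, the C-alpha coordinate.  A truncated non-glycine
    residue with no side-chain heavy atoms falls back to C-alpha.
    """
    if residue.aa == "G":
        ca = residue.atom("CA")
        if ca is None:
            raise ValueError(f"{residue!r}: glycine without CA atom")
        return ca.coord
    side = [
        a.coord
        for a in residue.atoms
        if a.name not in BACKBONE_ATOMS and not a.is_hydrogen
    ]
    if side:
        return np.mean(side, axis=0)
    ca = residue.atom("CA")
    if ca is None:
        raise ValueError(f"{residue!r}: no side-chain heavy atoms and no CA")
    warnings.warn(f"{residue!r}: no side-chain heavy atoms; using CA")
    return ca.coord


def _mean_bfactor(residue: Residue) -> float:
    return float(np.mean([a.bfactor for a in residue.atoms]))


def residue_bfactor_zscores(structure: ProteinStructure) -> dict[tuple[str, int, str], float]:
    """Per-residue mean B-factor, z-scored over the whole protein.

    Population statistics; a degenerate (constant) distribution maps to 0.
    """
    means = np.array([_mean_bfactor(r) for r in structure.residues])
    mu = means.mean()
    sigma = means.std()  # population std
    if sigma == 0:
        z = np.zeros_like(means)
    else:
        z = (means - mu) / sigma
    return {r.key: float(v) for r, v in zip(structure.residues, z)}


def normalized_bfactor(residue: Residue, structure: ProteinStructure) -> float:
    """Flexibility of one residue relative to the rest of its protein."""
    return residue_bfactor_zscores(structure)[residue.key]
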