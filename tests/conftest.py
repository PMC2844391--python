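"""Shared test fixtures: hand-built PDB snippets and a small synthetic ensemble."""

import numpy as np
import pytest

from catres import fixtures

AA_1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "M": "MET", "F": "PHE", "P": "PRO", "S": "SER",
    "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL", "K": "LYS",
}


def atom_line(record, serial, name, resname, chain, resseq, xyz,
              occ=1.0, b=20.0, element=None, altloc=" "):
    """Format one fixed-width ATOM/HETATM record (independent of the
    package's own PDB writer)."""
    if element is None:
        element = name[0]
    name_field = f" {name:<3s}" if len(name) < 4 else name
    x, y, z = xyz
    return (
        f"{record:<6s}{serial:5d} {name_field:<4s}{altloc}{resname:>3s} {chain}"
        f"{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
        f"          {element:>2s}"
    )


def make_pdb(residues=(), waters=(), hets=(), ssbonds=(), extra_lines=()):
    """Build PDB text.

    residues: (aa_one_letter, chain, resseq, [(atom_name, xyz, b), ...])
    waters:   xyz tuples
    hets:     (code, resseq, [(atom_name, element, xyz)])
    ssbonds:  ((chain, resseq), (chain, resseq))
    """
    lines = list(extra_lines)
    for (ca, cb) in ssbonds:
        lines.append(
            f"SSBOND   1 CYS {ca[0]} {ca[1]:4d}    CYS {cb[0]} {cb[1]:4d}"
        )
    serial = 1
    for aa, chain, resseq, atoms in residues:
        for entry in atoms:
            name, xyz, b = entry if len(entry) == 3 else (*entry, 20.0)
            lines.append(atom_line("ATOM", serial, name, AA_1TO3.get(aa, aa),
                                   chain, resseq, xyz, b=b))
            serial += 1
    for code, resseq, atoms in hets:
        for name, element, xyz in atoms:
            lines.append(atom_line("HETATM", serial, name, code, "A", resseq,
                                   xyz, element=element))
            serial += 1
    for i, xyz in enumerate(waters):
        lines.append(atom_line("HETATM", serial, "O", "HOH", "A", 900 + i, xyz))
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def simple_residue(aa, chain, resseq, rep_point, b=20.0):
    """Backbone + one side-chain atom at the representative point
    (CA at the point for glycine)."""
    p = np.asarray(rep_point, dtype=float)
    if aa == "G":
        return (aa, chain, resseq, [
            ("N", p + (1.3, 0.5, 0), b), ("CA", p, b),
            ("C", p + (-1.3, 0.5, 0), b), ("O", p + (-1.6, 1.7, 0), b)])
    ca = p + (0, 0, 1.5)
    side = "SG" if aa == "C" else "CB"
    return (aa, chain, resseq, [
        ("N", ca + (1.3, 0.5, 0), b), ("CA", ca, b),
        ("C", ca + (-1.3, 0.5, 0), b), ("O", ca + (-1.6, 1.7, 0), b),
        (side, p, b)])


@pytest.fixture(scope="session")
def small_ensemble():
    """4 proteins x 60 residues with planted sites; reused across tests."""
    spec = fixtures.FixtureSpec(n_proteins=4, residues_per_protein=60, seed=7)
    return spec, fixtures.generate_ensemble(spec)


@pytest.fixture(scope="session")
def one_protein(small_ensemble):
    _, ens = small_ensemble
    return next(iter(ens.values()))
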