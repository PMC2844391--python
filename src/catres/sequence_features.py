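"""Sequence-derived residue features: identity/class one-hots and
conservation-profile encodings.

Conservation profiles are per-position 20-way amino-acid distributions from a
multiple alignment (e.g. a two-iteration PSI-Blast search).  Each position is
enriched with two summary values: the Shannon entropy of the distribution
(bits) and a pseudocount reliability weight n / (n + beta), where n is the
effective number of observations at the position.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AA_ORDER",
    "CHARGED",
    "POLAR",
    "HYDROPHOBIC",
    "AA_CLASS",
    "CLASS_ORDER",
    "ConservationProfile",
    "encode_aa_name",
    "encode_aa_class",
    "read_profile",
    "read_fasta",
    "profile_entropy",
    "profile_weight",
    "window_profile",
    "write_profile_tsv",
]

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

# three-way physico-chemical partition of the amino acids
CHARGED = frozenset("HRKED")
POLAR = frozenset("QTSNCYW")
HYDROPHOBIC = frozenset("GFLMAIPV")
CLASS_ORDER = ("charged", "polar", "hydrophobic")
AA_CLASS = {aa: "charged" for aa in CHARGED}
AA_CLASS.update({aa: "polar" for aa in POLAR})
AA_CLASS.update({aa: "hydrophobic" for aa in HYDROPHOBIC})

#: column order of PSI-Blast ASCII PSSM files
PSSM_AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
_PSSM_TO_ALPHA = [PSSM_AA_ORDER.index(aa) for aa in AA_ORDER]

TSV_HEADER = "#catres-profile v1"

DEFAULT_BETA = 10.0


def encode_aa_name(aa: str) -> np.ndarray:
    """20-bit one-hot of the amino acid (alphabetical one-letter order);
    'X' maps to the all-zero vector."""
    vec = np.zeros(20)
    if aa == "X":
        return vec
    idx = AA_ORDER.find(aa)
    if idx < 0:
        raise ValueError(f"not an amino-acid code: {aa!r}")
    vec[idx] = 1.0
    return vec


def encode_aa_class(aa: str) -> np.ndarray:
    """3-bit one-hot over (charged, polar, hydrophobic); 'X' -> all zeros."""
    vec = np.zeros(3)
    if aa == "X":
        return vec
    cls = AA_CLASS.get(aa)
    if cls is None:
        raise ValueError(f"not an amino-acid code: {aa!r}")
    vec[CLASS_ORDER.index(cls)] = 1.0
    return vec


@dataclass
class ConservationProfile:
    """Per-position amino-acid distribution with effective observation counts.

    ``probs`` is (L, 20) in alphabetical amino-acid order, rows summing to 1;
    ``n_obs`` is the per-position effective number of observed sequences.
    """

    probs: np.ndarray
    n_obs: np.ndarray
    beta: float = DEFAULT_BETA

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.n_obs = np.asarray(self.n_obs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 20:
            raise ValueError("profile must be (L, 20)")
        if np.any(self.probs < 0):
            raise ValueError("profile probabilities must be non-negative")
        sums = self.probs.sum(axis=1)
        if not np.allclose(sums[sums > 0], 1.0, atol=1e-9):
            raise ValueError("profile rows must sum to 1")

    def __len__(self) -> int:
        return self.probs.shape[0]

    def entropy(self, i: int) -> float:
        return profile_entropy(self.probs[i])

    def weight(self, i: int) -> float:
        return profile_weight(self.n_obs[i], self.beta)

    def position_features(self, i: int) -> np.ndarray:
        """22 values: the 20 probabilities plus entropy and weight."""
        return np.concatenate([self.probs[i], [self.entropy(i), self.weight(i)]])


def profile_entropy(probs: np.ndarray) -> float:
    """Shannon entropy in bits, with 0 * log 0 := 0."""
    p = np.asarray(probs, dtype=float)
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def profile_weight(n_obs: float, beta: float = DEFAULT_BETA) -> float:
    """Pseudocount reliability weight n / (n + beta), in [0, 1]."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    return float(n_obs / (n_obs + beta))


def _read_tsv_profile(lines: list[str], beta: float) -> ConservationProfile:
    rows, n_obs = [], []
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) not in (20, 21):
            raise ValueError(
                f"profile TSV row must have 20 probability columns "
                f"(+ optional n_obs), got {len(fields)}"
            )
        vals = [float(x) for x in fields[:20]]
        rows.append(vals)
        n_obs.append(float(fields[20]) if len(fields) == 21 else 0.0)
    probs = np.array(rows)
    probs = probs / probs.sum(axis=1, keepdims=True)
    return ConservationProfile(probs, np.array(n_obs), beta=beta)


def _read_pssm_profile(lines: list[str], beta: float) -> ConservationProfile:
    """PSI-Blast ASCII PSSM: per row 20 log-odds then 20 percentages then the
    per-position information content and relative pseudocount weight.

    The percentage block is converted to probabilities; the trailing relative
    weight column (when present) is used as the effective observation count.
    """
    rows, n_obs = [], []
    for line in lines:
        fields = line.split()
        if len(fields) < 42 or not fields[0].isdigit():
            continue
        pct = np.array([float(x) for x in fields[22:42]])
        total = pct.sum()
        if not (99.0 <= total <= 101.0):
            if total <= 0:
                raise ValueError(f"PSSM percentages sum to {total} at position {fields[0]}")
            warnings.warn(
                f"PSSM row {fields[0]}: percentages sum to {total:.1f}, renormalizing"
            )
        probs = pct / total
        rows.append(probs[_PSSM_TO_ALPHA])
        n_obs.append(float(fields[43]) if len(fields) > 43 else 0.0)
    if not rows:
        raise ValueError("no PSSM matrix rows found")
    return ConservationProfile(np.array(rows), np.array(n_obs), beta=beta)


def read_profile(source, beta: float = DEFAULT_BETA) -> ConservationProfile:
    """Read a conservation profile from a PSI-Blast ASCII PSSM or the
    package's tab-separated dialect (header line ``#catres-profile v1``)."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    lines = text.splitlines()
    if lines and lines[0].strip() == TSV_HEADER:
        return _read_tsv_profile(lines[1:], beta)
    return _read_pssm_profile(lines, beta)


def write_profile_tsv(profile: ConservationProfile, handle: io.TextIOBase | None = None) -> str:
    buf = io.StringIO()
    buf.write(TSV_HEADER + "\n")
    for p, n in zip(profile.probs, profile.n_obs):
        buf.write("\t".join(f"{x:.6f}" for x in p) + f"\t{n:.3f}\n")
    text = buf.getvalue()
    if handle is not None:
        handle.write(text)
    return text


def window_profile(profile: ConservationProfile, i: int, w: int = 0) -> np.ndarray:
    """Concatenated (probs, entropy, weight) of positions i-w .. i+w.

    Positions beyond the sequence ends are zero-padded, so the output length
    is always (2w + 1) * 22.
    """
    if w < 0:
        raise ValueError("w must be >= 0")
    parts = []
    for j in range(i - w, i + w + 1):
        if 0 <= j < len(profile):
            parts.append(profile.position_features(j))
        else:
            parts.append(np.zeros(22))
    return np.concatenate(parts)


def read_fasta(source) -> dict[str, str]:
    """Minimal FASTA reader for sequence/structure cross-checks."""
    from Bio import SeqIO

    if hasattr(source, "read"):
        handle = source
    else:
        handle = open(source)
    try:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(handle, "fasta")}
    finally:
        if handle is not source:
            handle.close()
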