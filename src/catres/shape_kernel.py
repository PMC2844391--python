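"""Decomposition kernel on labeled planar shapes from residue neighborhoods.

Each residue neighborhood is reduced to a cloud of side-chain centroids
labeled with the residue class -- charged (Ch), hydrophobic (Hy) or polar
(Po) -- and decomposed into planar shapes with two (segments) or three
(triangles) vertices.  In the default configuration one vertex is the target
residue itself (carrying a distinguished label) and the remaining vertices
are residues whose evolutionary class is conserved: the summed profile mass
of one class exceeds 0.5.  Vertices are connected when closer than 5 A.

Shapes are canonicalized (labels sorted, edge lengths discretized into
fixed-width bins and sorted) and counted; the kernel between two residues is
the dot product of their shape-count vectors, which makes it positive
semidefinite by construction.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from catres.neighborhood import StructuralNeighborhood
from catres.sequence_features import AA_ORDER, AA_CLASS, ConservationProfile
from catres.structure_model import ProteinStructure, Residue, representative_point

__all__ = [
    "CLASS_LABELS",
    "ShapeOptions",
    "Shape",
    "ShapeSet",
    "residue_class_label",
    "class_conserved",
    "conserved_class",
    "extract_shapes",
    "kernel",
    "gram_matrix",
]

#: short class labels used on shape vertices
CLASS_LABELS = {"charged": "Ch", "hydrophobic": "Hy", "polar": "Po"}

_CLASS_MEMBERS = {
    "Ch": [i for i, aa in enumerate(AA_ORDER) if AA_CLASS[aa] == "charged"],
    "Hy": [i for i, aa in enumerate(AA_ORDER) if AA_CLASS[aa] == "hydrophobic"],
    "Po": [i for i, aa in enumerate(AA_ORDER) if AA_CLASS[aa] == "polar"],
}

CONSERVATION_THRESHOLD = 0.5
CONNECTIVITY_THRESHOLD = 5.0


@dataclass(frozen=True)
class ShapeOptions:
    require_target_vertex: bool = True
    connected_only: bool = True
    conserved_only: bool = True
    bin_width: float = 1.0
    connectivity: float = CONNECTIVITY_THRESHOLD
    conservation_threshold: float = CONSERVATION_THRESHOLD


@dataclass(frozen=True)
class Shape:
    """Canonical labeled planar shape.

    ``labels`` are the sorted non-target vertex labels; ``target_label`` is
    the distinguished label of the anchoring vertex (None when shapes are not
    target-anchored); ``edge_bins`` are the sorted discretized edge lengths
    (1 for a segment, 3 for a triangle).
    """

    kind: str  # "segment" | "triangle"
    target_label: str | None
    labels: tuple[str, ...]
    edge_bins: tuple[int, ...]

    def __post_init__(self) -> None:
        n_edges = {"segment": 1, "triangle": 3}[self.kind]
        if len(self.edge_bins) != n_edges:
            raise ValueError(f"{self.kind} needs {n_edges} edge bins")


@dataclass
class ShapeSet:
    counts: Counter = field(default_factory=Counter)
    options: ShapeOptions = field(default_factory=ShapeOptions)

    def add(self, shape: Shape) -> None:
        self.counts[shape] += 1

    def total(self) -> int:
        return sum(self.counts.values())

    def to_text(self) -> str:
        lines = []
        for shape, n in sorted(
            self.counts.items(),
            key=lambda kv: (kv[0].kind, kv[0].target_label or "", kv[0].labels, kv[0].edge_bins),
        ):
            lines.append(
                f"{shape.kind}\t{shape.target_label or '-'}\t"
                f"{','.join(shape.labels)}\t{','.join(map(str, shape.edge_bins))}\t{n}"
            )
        return "\n".join(lines) + ("\n" if lines else "")

    @classmethod
    def from_text(cls, text: str, options: ShapeOptions | None = None) -> "ShapeSet":
        ss = cls(options=options or ShapeOptions())
        for line in text.splitlines():
            if not line.strip():
                continue
            kind, tgt, labels, bins, n = line.split("\t")
            shape = Shape(
                kind=kind,
                target_label=None if tgt == "-" else tgt,
                labels=tuple(labels.split(",")) if labels else (),
                edge_bins=tuple(int(b) for b in bins.split(",")),
            )
            ss.counts[shape] += int(n)
        return ss


def residue_class_label(aa: str) -> str | None:
    cls = AA_CLASS.get(aa)
    return CLASS_LABELS[cls] if cls else None


def class_conserved(
    probs_row: np.ndarray, label: str, threshold: float = CONSERVATION_THRESHOLD
) -> bool:
    """Is the position conserved over the given class (Ch/Hy/Po)?

    True iff the summed profile mass of the class's amino acids exceeds the
    threshold.
    """
    return float(np.sum(np.asarray(probs_row)[_CLASS_MEMBERS[label]])) > threshold


def conserved_class(
    probs_row: np.ndarray, threshold: float = CONSERVATION_THRESHOLD
) -> str | None:
    """The class a position is conserved over, or None.

    At most one class can exceed a threshold >= 0.5.
    """
    for label in ("Ch", "Hy", "Po"):
        if class_conserved(probs_row, label, threshold):
            return label
    return None


def _edge_bin(d: float, bin_width: float) -> int:
    return int(np.floor(d / bin_width))


def extract_shapes(
    structure: ProteinStructure,
    nbh: StructuralNeighborhood,
    profile: ConservationProfile,
    options: ShapeOptions = ShapeOptions(),
) -> ShapeSet:
    """Enumerate and canonicalize the labeled shapes of a neighborhood.

    Profile row ``i`` corresponds to ``structure.residues[i]``.  With the
    default options, segments are (target, v) and triangles (target, v, w)
    where v, w are class-conserved member residues; with ``connected_only``
    every vertex pair of a shape must be closer than the connectivity cutoff.
    """
    index_of = {r.key: i for i, r in enumerate(structure.residues)}
    shapes = ShapeSet(options=options)

    def vertex_label(res: Residue) -> str | None:
        i = index_of[res.key]
        if options.conserved_only:
            return conserved_class(profile.probs[i], options.conservation_threshold)
        return residue_class_label(res.aa)

    others = []
    for res in nbh.member_residues:
        if res is nbh.target:
            continue
        label = vertex_label(res)
        if label is not None:
            others.append((res, label, representative_point(res)))

    def connected(*points: np.ndarray) -> bool:
        if not options.connected_only:
            return True
        return all(
            np.linalg.norm(p - q) < options.connectivity
            for p, q in combinations(points, 2)
        )

    if options.require_target_vertex:
        t_label = residue_class_label(nbh.target.aa) or "X"
        t_point = nbh.center
        for (res, label, point) in others:
            if not connected(t_point, point):
                continue
            shapes.add(Shape(
                kind="segment",
                target_label=t_label,
                labels=(label,),
                edge_bins=(_edge_bin(np.linalg.norm(t_point - point), options.bin_width),),
            ))
        for (r1, l1, p1), (r2, l2, p2) in combinations(others, 2):
            if not connected(t_point, p1, p2):
                continue
            bins = tuple(sorted(
                _edge_bin(np.linalg.norm(a - b), options.bin_width)
                for a, b in ((t_point, p1), (t_point, p2), (p1, p2))
            ))
            shapes.add(Shape(
                kind="triangle",
                target_label=t_label,
                labels=tuple(sorted((l1, l2))),
                edge_bins=bins,
            ))
    else:
        # un-anchored variant: the target is an ordinary vertex
        t_label = vertex_label(nbh.target)
        vertices = list(others)
        if t_label is not None:
            vertices.append((nbh.target, t_label, nbh.center))
        for (r1, l1, p1), (r2, l2, p2) in combinations(vertices, 2):
            if not connected(p1, p2):
                continue
            shapes.add(Shape(
                kind="segment",
                target_label=None,
                labels=tuple(sorted((l1, l2))),
                edge_bins=(_edge_bin(np.linalg.norm(p1 - p2), options.bin_width),),
            ))
        for (r1, l1, p1), (r2, l2, p2), (r3, l3, p3) in combinations(vertices, 3):
            if not connected(p1, p2, p3):
                continue
            bins = tuple(sorted(
                _edge_bin(np.linalg.norm(a - b), options.bin_width)
                for a, b in ((p1, p2), (p1, p3), (p2, p3))
            ))
            shapes.add(Shape(
                kind="triangle",
                target_label=None,
                labels=tuple(sorted((l1, l2, l3))),
                edge_bins=bins,
            ))
    return shapes


def kernel(a: ShapeSet, b: ShapeSet) -> float:
    """Shared-shape similarity: sum over shapes of count_a * count_b."""
    if a.options != b.options:
        raise ValueError("shape sets were extracted with different options")
    if len(b.counts) < len(a.counts):
        a, b = b, a
    return float(sum(n * b.counts.get(s, 0) for s, n in a.counts.items()))


def gram_matrix(
    shape_sets: list[ShapeSet],
    base: np.ndarray | None = None,
    lam: float = 0.0,
) -> np.ndarray:
    """Gram matrix of the shape kernel, optionally combined with a base
    kernel as K_base + lam * K_shape."""
    if lam < 0:
        raise ValueError("kernel combination weight must be >= 0")
    n = len(shape_sets)
    K = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            K[i, j] = K[j, i] = kernel(shape_sets[i], shape_sets[j])
    if base is not None:
        base = np.asarray(base, dtype=float)
        if base.shape != K.shape:
            raise ValueError("base kernel shape mismatch")
        return base + lam * K
    return K
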