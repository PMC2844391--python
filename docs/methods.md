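# Methods

## Problem and model

`catres` predicts catalytic residues in enzymes: the binary classification,
per residue of a solved structure, of whether the residue takes a direct
chemical part in catalysis (nucleophile, proton donor/acceptor).  Positive
annotations of this kind are scarce — of order one catalytic residue per
hundred — so the problem is dominated by class imbalance, and point metrics
(F1, MCC) must be complemented by threshold-free ones (areas under averaged
ROC and recall/precision curves).

The model is a soft-margin linear SVM over named residue feature blocks:

- **Sequence blocks.** `1D1` one-hot residue identity (20 bits, alphabetical
  one-letter order); `1D2` one-hot residue class over the partition charged =
  {H,R,K,E,D}, polar = {Q,T,S,N,C,Y,W}, hydrophobic = {G,F,L,M,A,I,P,V};
  `1D3` the per-position conservation profile (20 probabilities from a
  multiple alignment, e.g. two-iteration PSI-Blast) enriched with its Shannon
  entropy in bits and a pseudocount reliability weight n/(n+β).  An optional
  window concatenates the profile features of the w positions on each side of
  the target, zero-padded at the termini.
- **Structural-neighborhood blocks.** A residue is represented by the
  centroid of its side-chain heavy atoms (Cα for glycine); its neighborhood
  is everything within 8 Å of that point — the maximum residue–water
  interaction distance, chosen because ordered water participates in
  catalysis (hydrolases).  From the member residues: `3D1` three-bin
  low/medium/high distributions of hydrophobicity, polarity, polarizability
  and van der Waals volume (the standard three-group composition tables,
  shipped as an editable CSV); `3D2` 20-way amino-acid composition; `3D3`
  counts of positive (R,K,H) and negative (D,E) residues and their sum;
  `3D4` water molecules in the sphere (by oxygen); `3D5` atomic density (all
  protein and heterogen atoms in the sphere; waters counted separately);
  `3D6` the residue's mean atomic B-factor as a population z-score over the
  protein's per-residue means, removing crystal-to-crystal scale.
- **Ligand blocks.** `3D7` a disulphide-bonded-cysteine flag (SSBOND record,
  or SG–SG ≤ 2.5 Å); `3D8` counts of catalytic / non-catalytic / uncertain
  heterogens (by centroid) in the sphere, using the shipped 81-code class
  table (63/11/7); `3D9` a direct residue–cofactor bond flag (any heavy-atom
  pair ≤ 3 Å).
- **Shape kernel (optional).** Neighborhoods can also be compared by a
  decomposition kernel on labeled planar shapes: segments and triangles
  anchored at the target residue whose other vertices are residues whose
  class (Ch/Hy/Po) is evolutionarily conserved — summed profile mass of the
  class > 0.5 — with vertices connected below 5 Å.  Shapes are canonicalized
  by sorting labels and 1 Å-binned edge lengths; the kernel is the dot
  product of shape counts, hence positive semidefinite by construction.  In
  the pipeline this enters as an explicit count map whose linear kernel
  equals the decomposition kernel.

## Training and evaluation protocol

Features are min–max scaled to [−1, +1] per training split (the only linear
map onto that range); values outside the training range at test time are
clipped.  Missing numeric values are imputed with the training mean before
scaling, binary/categorical ones with the training mode; all statistics come
from the current fold's training residues only, never its test residues.

Cross-validation is stratified at the protein level: proteins are shuffled by
the run seed and dealt round-robin into k folds (default 10), so all residues
of a protein share a fold and no homology-free information leaks across the
split.  The SVM keeps c = 1 and tunes only the cost factor j — the weight on
margin errors of positive examples — over the grid {1, 2, 5, 10, 20, 50,
100, 200} by an inner 5-fold protein-stratified CV inside each training
split, maximizing mean inner F1 with ties broken toward the smallest j.
Hard labels use threshold 0; ROC and RP evaluation uses raw margins.

Per-protein ROC and RP curves are vertically averaged on a fixed grid (step
0.01): TPR is linearly interpolated at each grid FPR; precision at each grid
recall is the best precision attainable at an operating point with recall at
least that value.  Areas are trapezoidal on the averaged curve.  Proteins
lacking either class are excluded from averaging (their curves are
undefined) with a warning.  Paired comparisons between settings use a
two-sided exact Wilcoxon signed-rank test on per-fold F1 at α = 0.05, with
zero differences dropped.

## Synthetic study conditions

The fixture generator emulates the data layout the predictor consumes
without any downloads.  Defaults, which are also the conditions of the
acceptance computation: 20 proteins × 120 residues, 3 catalytic residues per
protein whose representative points fit inside one 8 Å sphere, a ZN ion
(catalytic class) 4 Å from the site center, a chloride (non-catalytic class)
beyond 15 Å — mirroring the observed distance separation between cofactors
and crystallization additives — four ordered waters at the site, background
residues dispersed in a 12–40 Å shell, catalytic positions conserved with
strength 0.9 (mass on the true residue, remainder uniform; high effective
observation count), background positions noisy near-uniform.  Residues carry
minimal atom sets (four backbone atoms plus one side-chain pseudo-atom at
the representative point; SG for cysteine), which is sufficient for every
feature above but is not rotamerically or sequentially realistic.

The planted separation is deliberately strong: every feature family (ligand
counts, water count, profile entropy/weight, B-factor, composition) points
at the site, so the full pipeline should recover the positives essentially
perfectly, and both the sequence-only and the full feature set saturate
under these conditions.  Passing therefore demonstrates the correctness of
the machinery (geometry, normalization hygiene, stratification, tuning,
evaluation), not the attainable accuracy on real enzymes, where conservation
is noisy, sites are not geometrically isolated, and many structures are
solved in apo form.

## Numerical choices and edge cases

- Boundary of the neighborhood sphere is inclusive (d ≤ r); ties are
  measure-zero on real coordinates.  The target residue is counted in its
  own neighborhood statistics (a flag excludes it for ablation).
- altLoc conformers: highest occupancy kept, first-in-file on ties; only the
  first model of multi-model entries is read.
- B-factor z-score uses population variance; a constant distribution maps to
  0.  Unknown residue codes become 'X' (excluded from composition and
  physchem numerators and denominators; all-zero one-hots).
- Profile entropy uses base 2 with 0·log 0 = 0; β = 10 in the reliability
  weight (any fixed β only rescales a linear-model feature monotonely).
- Shape edge bins are floor(d/1 Å); binned counting keeps kernel evaluation
  exact and PSD at the cost of coarse geometry matching.
- Zero denominators in precision/recall/F1/MCC map the metric to 0.
- LinearSVC (hinge loss, liblinear) with a fixed random_state makes the full
  protocol deterministic for a given seed and configuration.

## Known limitations

Sequence realism and full side-chain geometry are out of scope for the
generator; solvent accessibility, cleft geometry and other third-party
attribute sets are supported only through external per-residue tables;
mmCIF input, hydrogen placement and biological-assembly expansion are not
implemented; binding-site prediction for apo structures is not attempted.
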