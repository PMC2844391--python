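"""Feature assembly, normalization, protein-stratified CV and the SVM.

The learning protocol: residues are represented by named feature blocks
(sequence identity/class/profile blocks 1D1-1D3 and structural blocks
3D1-3D9, optionally an explicit shape-count map and external attribute
tables), scaled per training split to [-1, +1], and classified by a linear
soft-margin SVM with regularization c fixed to 1 and the cost factor j --
the multiplier on the loss of positive examples -- tuned by an inner
cross-validation that maximizes F1.  All cross-validation is stratified at
the protein level: every residue of a protein lands in the same fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import LinearSVC

from catres import ligand_features, neighborhood, sequence_features, shape_kernel
from catres.evaluation import Confusion, metrics
from catres.sequence_features import AA_ORDER, CLASS_ORDER, ConservationProfile
from catres.structure_model import ProteinStructure, residue_bfactor_zscores

__all__ = [
    "LABEL_COLUMNS",
    "imbalance_ratio",
    "audit_labels",
    "ProteinData",
    "FeatureSetSpec",
    "read_labels",
    "assemble",
    "NormalizationStats",
    "fit_normalizer",
    "apply_normalizer",
    "CVPlan",
    "make_folds",
    "SVMConfig",
    "LinearModel",
    "train",
    "predict",
    "tune_cost_factor",
    "cross_validate",
    "CVResult",
    "weight_report",
    "write_svmlight",
]

LABEL_COLUMNS = ["id", "label", "protein_PDB_Id", "residue", "chain", "number"]

CORE_BLOCKS = ("1D1", "1D2", "1D3",
               "3D1", "3D2", "3D3", "3D4", "3D5", "3D6", "3D7", "3D8", "3D9")

DEFAULT_J_GRID = (1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0, 200.0)


def read_labels(source) -> pd.DataFrame:
    """Read the per-residue label CSV
    (id,label,protein_PDB_Id,residue,chain,number; label in {+1,-1})."""
    df = pd.read_csv(source)
    missing = set(LABEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"label table missing columns: {sorted(missing)}")
    bad = set(df["label"].unique()) - {1, -1}
    if bad:
        raise ValueError(f"labels must be +1/-1, found {bad}")
    return df[LABEL_COLUMNS]


def imbalance_ratio(n_positive: int, n_total: int) -> str:
    """Positive-to-negative class ratio as the conventional '1:N' string."""
    if not 0 < n_positive <= n_total:
        raise ValueError("need 0 < n_positive <= n_total")
    return f"1:{round((n_total - n_positive) / n_positive)}"


def audit_labels(labels: pd.DataFrame) -> dict[str, int]:
    """Row, positive and distinct-protein counts of a label table."""
    return {
        "n_rows": int(len(labels)),
        "n_positive": int((labels["label"] == 1).sum()),
        "n_proteins": int(labels["protein_PDB_Id"].nunique()),
    }


@dataclass
class ProteinData:
    """Everything known about one protein: structure, aligned conservation
    profile (row i of the profile corresponds to the i-th parsed residue) and
    its label rows."""

    structure: ProteinStructure
    profile: ConservationProfile | None = None
    labels: pd.DataFrame | None = None

    def label_of(self, chain: str, number: int) -> int:
        if self.labels is None:
            return 0
        hit = self.labels[
            (self.labels["chain"].astype(str) == chain) & (self.labels["number"] == number)
        ]
        return int(hit["label"].iloc[0]) if len(hit) else 0


@dataclass(frozen=True)
class FeatureSetSpec:
    """Ordered list of feature blocks.

    Valid block names: 1D1, 1D2, 1D3, 3D1..3D9, shape-kernel, and
    external:<table-name>.  Window width applies to the 1D3 profile block.
    """

    blocks: tuple[str, ...]
    window: int = 0

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("feature set needs at least one block")
        for b in self.blocks:
            if b not in CORE_BLOCKS and b != "shape-kernel" and not b.startswith("external:"):
                raise ValueError(f"unknown feature block {b!r}")
        if self.window < 0:
            raise ValueError("window must be >= 0")

    def block_size(self, block: str) -> int | None:
        """Documented width of a core block (None for data-dependent blocks)."""
        sizes = {"1D1": 20, "1D2": 3, "1D3": 22 * (2 * self.window + 1),
                 "3D1": 12, "3D2": 20, "3D3": 3, "3D4": 1, "3D5": 1, "3D6": 1,
                 "3D7": 1, "3D8": 3, "3D9": 1}
        return sizes.get(block)


def _profile_block_names(window: int) -> list[str]:
    names = []
    for off in range(-window, window + 1):
        prefix = "prof" if window == 0 else f"prof[{off:+d}]"
        names += [f"{prefix}_p{aa}" for aa in AA_ORDER]
        names += [f"{prefix}_entropy", f"{prefix}_weight"]
    return names


def _core_block(
    block: str,
    protein: ProteinData,
    res_index: int,
    nbh,
    zscores,
    window: int,
    het_table,
) -> dict[str, float]:
    structure = protein.structure
    res = structure.residues[res_index]
    if block == "1D1":
        vec = sequence_features.encode_aa_name(res.aa)
        return {f"aa_is_{aa}": v for aa, v in zip(AA_ORDER, vec)}
    if block == "1D2":
        vec = sequence_features.encode_aa_class(res.aa)
        return {f"class_{c}": v for c, v in zip(CLASS_ORDER, vec)}
    if block == "1D3":
        if protein.profile is None:
            return {n: np.nan for n in _profile_block_names(window)}
        vec = sequence_features.window_profile(protein.profile, res_index, window)
        return dict(zip(_profile_block_names(window), vec))
    if block == "3D1":
        vec = neighborhood.physchem_distribution(nbh)
        names = [
            f"phys_{p}_{g}"
            for p in neighborhood.PHYSCHEM_PROPERTIES
            for g in ("low", "medium", "high")
        ]
        return dict(zip(names, vec))
    if block == "3D2":
        vec = neighborhood.aa_composition(nbh)
        return {f"comp_{aa}": v for aa, v in zip(AA_ORDER, vec)}
    if block == "3D3":
        n_pos, n_neg, n_sum = neighborhood.charge_features(nbh)
        return {"n_pos": n_pos, "n_neg": n_neg, "n_charged": n_sum}
    if block == "3D4":
        return {"water_count": neighborhood.water_count(nbh)}
    if block == "3D5":
        return {"atomic_density": neighborhood.atomic_density(nbh)}
    if block == "3D6":
        return {"bfactor_z": zscores[res.key]}
    if block == "3D7":
        return {"ss_bond": ligand_features.disulphide_flag(res, structure)}
    if block == "3D8":
        n_cat, n_non, n_unc = ligand_features.heterogen_counts(nbh, het_table)
        return {"het_catalytic": n_cat, "het_noncatalytic": n_non, "het_uncertain": n_unc}
    if block == "3D9":
        return {"cofactor_bond": ligand_features.cofactor_bond_flag(res, structure)}
    raise AssertionError(block)


def assemble(
    proteins: dict[str, ProteinData],
    spec: FeatureSetSpec,
    radius: float = 8.0,
    het_table=None,
    external_tables: dict[str, pd.DataFrame] | None = None,
    shape_options: shape_kernel.ShapeOptions | None = None,
) -> pd.DataFrame:
    """Assemble the residue feature table for a dataset.

    Returns a DataFrame indexed by (protein, chain, number) with one column
    per feature (blocks in spec order, documented within-block order) plus a
    trailing ``label`` column (+1/-1, or 0 when unlabeled).  Values missing
    from external tables become NaN and are later imputed by the normalizer.
    The ``shape-kernel`` block is the explicit count map of canonical shapes
    over the whole dataset, whose linear kernel equals the decomposition
    kernel.
    """
    external_tables = external_tables or {}
    rows: list[dict[str, float]] = []
    index: list[tuple[str, str, int]] = []
    labels: list[int] = []
    shape_sets: list[shape_kernel.ShapeSet] = []
    column_order: list[str] | None = None

    for pdb_id, protein in proteins.items():
        structure = protein.structure
        zscores = residue_bfactor_zscores(structure)
        for i, res in enumerate(structure.residues):
            nbh = neighborhood.build_neighborhood(structure, res, radius)
            row: dict[str, float] = {}
            for block in spec.blocks:
                if block in CORE_BLOCKS:
                    row.update(_core_block(block, protein, i, nbh, zscores,
                                           spec.window, het_table))
                elif block == "shape-kernel":
                    if protein.profile is None:
                        raise ValueError("shape-kernel block requires profiles")
                    shape_sets.append(shape_kernel.extract_shapes(
                        structure, nbh, protein.profile,
                        shape_options or shape_kernel.ShapeOptions(),
                    ))
                else:
                    name = block.split(":", 1)[1]
                    if name not in external_tables:
                        raise ValueError(f"external table {name!r} not provided")
                    table = external_tables[name]
                    key = (pdb_id, res.chain, res.seq_number)
                    if key in table.index:
                        vals = table.loc[key]
                    else:
                        warnings.warn(f"residue {key} absent from external table {name!r}")
                        vals = pd.Series(np.nan, index=table.columns)
                    row.update({f"ext_{name}_{c}": vals[c] for c in table.columns})
            if column_order is None:
                column_order = list(row.keys())
            rows.append(row)
            index.append((pdb_id, res.chain, res.seq_number))
            labels.append(protein.label_of(res.chain, res.seq_number))

    df = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(
        index, names=["protein", "chain", "number"]))
    if column_order:
        df = df[column_order]

    if shape_sets:
        vocab = sorted(
            {s for ss in shape_sets for s in ss.counts},
            key=lambda s: (s.kind, s.target_label or "", s.labels, s.edge_bins),
        )
        shape_cols = np.zeros((len(shape_sets), len(vocab)))
        for r, ss in enumerate(shape_sets):
            for c, s in enumerate(vocab):
                shape_cols[r, c] = ss.counts.get(s, 0)
        names = [
            f"shape_{s.kind}_{s.target_label or '-'}_{'.'.join(s.labels)}_"
            f"{'.'.join(map(str, s.edge_bins))}"
            for s in vocab
        ]
        df = pd.concat([df, pd.DataFrame(shape_cols, index=df.index, columns=names)], axis=1)

    df["label"] = labels
    return df


# --------------------------------------------------------------------------
# normalization


@dataclass
class NormalizationStats:
    """Per-feature scaling/imputation statistics from one training split.

    Numeric features: (min, max, mean); categorical (observed values all in
    {0, 1}): mode.  Imputation happens before scaling; scaled outputs are
    clipped to [-1, 1]; constant features map to 0.
    """

    numeric: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    categorical: dict[str, float] = field(default_factory=dict)
    dropped: tuple[str, ...] = ()


def fit_normalizer(table: pd.DataFrame) -> NormalizationStats:
    if not len(table):
        raise ValueError("cannot fit normalizer on an empty table")
    X = table.drop(columns=["label"], errors="ignore")
    stats = NormalizationStats()
    dropped = []
    for col in X.columns:
        obs = X[col].dropna()
        if obs.empty:
            warnings.warn(f"feature {col!r} has no observed values; dropped")
            dropped.append(col)
            continue
        if set(np.unique(obs)) <= {0.0, 1.0}:
            stats.categorical[col] = float(obs.mode().iloc[0])
        else:
            stats.numeric[col] = (float(obs.min()), float(obs.max()), float(obs.mean()))
    stats.dropped = tuple(dropped)
    return stats


def apply_normalizer(stats: NormalizationStats, table: pd.DataFrame) -> pd.DataFrame:
    """Impute then min-max scale every feature to [-1, +1] (clipped)."""
    out = {}
    for col, (lo, hi, mean) in stats.numeric.items():
        v = table[col].fillna(mean).to_numpy(dtype=float)
        if hi == lo:
            out[col] = np.zeros(len(v))
        else:
            out[col] = np.clip(2.0 * (v - lo) / (hi - lo) - 1.0, -1.0, 1.0)
    for col, mode in stats.categorical.items():
        v = table[col].fillna(mode).to_numpy(dtype=float)
        out[col] = np.clip(2.0 * v - 1.0, -1.0, 1.0)
    cols = [c for c in table.columns if c in out]
    df = pd.DataFrame({c: out[c] for c in cols}, index=table.index)
    if "label" in table.columns:
        df["label"] = table["label"]
    return df


# --------------------------------------------------------------------------
# cross-validation plan


@dataclass
class CVPlan:
    k: int
    seed: int
    fold_of: dict[str, int]

    def proteins_in_fold(self, fold: int) -> list[str]:
        return [p for p, f in self.fold_of.items() if f == fold]


def make_folds(proteins, k: int = 10, seed: int = 0) -> CVPlan:
    """Deal shuffled proteins round-robin into k folds (protein-stratified:
    every residue of a protein shares its protein's fold)."""
    proteins = list(proteins)
    if k < 2:
        raise ValueError("need at least 2 folds")
    if len(proteins) < k:
        raise ValueError(f"{len(proteins)} proteins cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    order = [proteins[i] for i in rng.permutation(len(proteins))]
    return CVPlan(k=k, seed=seed, fold_of={p: i % k for i, p in enumerate(order)})


# --------------------------------------------------------------------------
# SVM


@dataclass(frozen=True)
class SVMConfig:
    c: float = 1.0
    j_grid: tuple[float, ...] = DEFAULT_J_GRID
    inner_k: int = 5
    seed: int = 0
    max_iter: int = 100000

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("c must be positive")
        if not self.j_grid or any(j <= 0 for j in self.j_grid):
            raise ValueError("cost-factor grid must be non-empty and positive")


@dataclass
class LinearModel:
    feature_names: list[str]
    weights: np.ndarray
    bias: float
    c: float
    j: float

    def decision(self, X: np.ndarray) -> np.ndarray:
        return X @ self.weights + self.bias


def _split_xy(table: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    if "label" not in table.columns:
        raise ValueError("table has no label column")
    return table.drop(columns=["label"]), table["label"].to_numpy(dtype=int)


def train(table: pd.DataFrame, config: SVMConfig, j: float = 1.0) -> LinearModel:
    """Fit the class-weighted linear soft-margin SVM (hinge loss, c fixed by
    config, error on positives weighted j-fold)."""
    X, y = _split_xy(table)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    clf = LinearSVC(
        C=config.c,
        loss="hinge",
        class_weight={1: j, -1: 1.0},
        max_iter=config.max_iter,
        random_state=config.seed,
        tol=1e-5,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # liblinear convergence chatter
        clf.fit(X.to_numpy(dtype=float), y)
    return LinearModel(
        feature_names=list(X.columns),
        weights=clf.coef_.ravel().copy(),
        bias=float(clf.intercept_[0]),
        c=config.c,
        j=j,
    )


def predict(model: LinearModel, table: pd.DataFrame) -> pd.DataFrame:
    """Scores and hard labels (threshold 0) for a normalized table."""
    X = table.drop(columns=["label"], errors="ignore")
    if list(X.columns) != model.feature_names:
        X = X[model.feature_names]
    scores = model.decision(X.to_numpy(dtype=float))
    out = pd.DataFrame({"score": scores}, index=table.index)
    out["pred"] = np.where(scores > 0, 1, -1)
    if "label" in table.columns:
        out["label"] = table["label"]
    return out


def tune_cost_factor(
    table: pd.DataFrame,
    config: SVMConfig,
    groups: np.ndarray | None = None,
) -> float:
    """Pick the cost factor maximizing mean inner-CV F1 (ties: smallest j).

    ``groups`` defaults to the ``protein`` index level; the inner CV is
    stratified on it like the outer one.
    """
    if groups is None:
        groups = table.index.get_level_values("protein").to_numpy()
    groups = np.asarray(groups)
    uniq = pd.unique(groups)
    k = min(config.inner_k, len(uniq))
    if k < 2:
        raise ValueError("inner CV needs at least 2 groups")
    plan = make_folds(uniq, k=k, seed=config.seed)
    fold_ids = np.array([plan.fold_of[g] for g in groups])

    best_j, best_f1 = None, -1.0
    for j in sorted(config.j_grid):
        f1s = []
        for fold in range(k):
            train_tab = table[fold_ids != fold]
            test_tab = table[fold_ids == fold]
            stats = fit_normalizer(train_tab)
            model = train(apply_normalizer(stats, train_tab), config, j=j)
            pred = predict(model, apply_normalizer(stats, test_tab))
            f1s.append(metrics(Confusion.from_labels(pred["label"], pred["pred"]))["f1"])
        mean_f1 = float(np.mean(f1s))
        if mean_f1 > best_f1:
            best_j, best_f1 = j, mean_f1
    return float(best_j)


@dataclass
class CVResult:
    plan: CVPlan
    fold_metrics: pd.DataFrame  # fold, j, precision, recall, fpr, f1, mcc
    scores: pd.DataFrame  # per-residue score/pred/label/fold
    fold_stats: dict[int, NormalizationStats]
    models: dict[int, LinearModel]

    def summary(self) -> dict[str, float]:
        s = {}
        for m in ("precision", "recall", "fpr", "f1", "mcc"):
            s[f"{m}_mean"] = float(self.fold_metrics[m].mean())
            s[f"{m}_sd"] = float(self.fold_metrics[m].std(ddof=1))
        return s

    def per_protein_scores(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        out = {}
        for protein, sub in self.scores.groupby(level="protein"):
            out[protein] = (sub["label"].to_numpy(), sub["score"].to_numpy())
        return out


def cross_validate(
    table: pd.DataFrame,
    config: SVMConfig | None = None,
    k: int = 10,
    seed: int = 0,
    tune: bool = True,
) -> CVResult:
    """The full protocol: k-fold protein-stratified CV, with per-fold
    normalization fitted on the training split and the cost factor tuned by
    inner CV inside each training split."""
    config = config or SVMConfig(seed=seed)
    proteins = list(pd.unique(table.index.get_level_values("protein")))
    plan = make_folds(proteins, k=k, seed=seed)
    group = table.index.get_level_values("protein").to_numpy()
    fold_ids = np.array([plan.fold_of[g] for g in group])

    rows, score_frames = [], []
    fold_stats: dict[int, NormalizationStats] = {}
    models: dict[int, LinearModel] = {}
    for fold in range(k):
        train_tab = table[fold_ids != fold]
        test_tab = table[fold_ids == fold]
        j = tune_cost_factor(train_tab, config) if tune else 1.0
        stats = fit_normalizer(train_tab)
        model = train(apply_normalizer(stats, train_tab), config, j=j)
        pred = predict(model, apply_normalizer(stats, test_tab))
        pred["fold"] = fold
        score_frames.append(pred)
        m = metrics(Confusion.from_labels(pred["label"], pred["pred"]))
        rows.append({"fold": fold, "j": j, **m})
        fold_stats[fold] = stats
        models[fold] = model

    return CVResult(
        plan=plan,
        fold_metrics=pd.DataFrame(rows),
        scores=pd.concat(score_frames),
        fold_stats=fold_stats,
        models=models,
    )


def weight_report(model: LinearModel) -> pd.DataFrame:
    """Features ranked by |weight| (signed weights retained): the SVM's most
    discriminant features come first."""
    df = pd.DataFrame({"feature": model.feature_names, "weight": model.weights})
    df["abs_weight"] = df["weight"].abs()
    df = df.sort_values("abs_weight", ascending=False, kind="stable")
    return df.drop(columns="abs_weight").reset_index(drop=True)


def write_svmlight(table: pd.DataFrame, path) -> None:
    """Write the feature table in SVMlight sparse format (label idx:val ...)."""
    from sklearn.datasets import dump_svmlight_file

    X, y = _split_xy(table)
    dump_svmlight_file(X.to_numpy(dtype=float), y, str(path), zero_based=False)
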