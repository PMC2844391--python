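"""Performance measures for residue-level classification.

Point metrics (precision, recall, false-positive rate, F1, Matthews
correlation) are computed from a confusion table.  Threshold-free evaluation
uses per-protein ROC and recall/precision curves that are vertically averaged
across proteins on a fixed grid before measuring the area -- appropriate when
the unit of prediction is a protein and class skew varies between proteins.
Statistical comparison between two cross-validated settings uses a paired
two-sided Wilcoxon signed-rank test on per-fold F1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon
from sklearn.metrics import precision_recall_curve, roc_curve

__all__ = [
    "Confusion",
    "metrics",
    "AveragedCurve",
    "averaged_roc",
    "averaged_rp",
    "wilcoxon_f1",
]


@dataclass(frozen=True)
class Confusion:
    t_pos: int
    t_neg: int
    f_pos: int
    f_neg: int

    def __post_init__(self) -> None:
        if min(self.t_pos, self.t_neg, self.f_pos, self.f_neg) < 0:
            raise ValueError("confusion counts must be non-negative")

    @classmethod
    def from_labels(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "Confusion":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(
            t_pos=int(np.sum((y_true > 0) & (y_pred > 0))),
            t_neg=int(np.sum((y_true <= 0) & (y_pred <= 0))),
            f_pos=int(np.sum((y_true <= 0) & (y_pred > 0))),
            f_neg=int(np.sum((y_true > 0) & (y_pred <= 0))),
        )


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def metrics(c: Confusion) -> dict[str, float]:
    """precision, recall, fpr, f1 and mcc; zero denominators map to 0."""
    tp, tn, fp, fn = c.t_pos, c.t_neg, c.f_pos, c.f_neg
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    fpr = _safe_div(fp, fp + tn)
    f1 = _safe_div(2 * precision * recall, precision + recall)
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe_div(tp * tn - fp * fn, mcc_den)
    return {"precision": precision, "recall": recall, "fpr": fpr, "f1": f1, "mcc": mcc}


@dataclass
class AveragedCurve:
    grid: np.ndarray  # FPR (ROC) or recall (RP), increasing in [0, 1]
    mean_ordinate: np.ndarray  # averaged TPR or precision
    n_proteins: int

    @property
    def area(self) -> float:
        return float(np.trapezoid(self.mean_ordinate, self.grid))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "grid": self.grid,
            "mean": self.mean_ordinate,
            "n_proteins": self.n_proteins,
        })


def _eligible(scored: dict[str, tuple[np.ndarray, np.ndarray]]):
    out = {}
    for protein, (y, s) in scored.items():
        y = np.asarray(y)
        s = np.asarray(s, dtype=float)
        if np.any(y > 0) and np.any(y <= 0):
            out[protein] = (y, s)
        else:
            warnings.warn(f"{protein}: single-class protein excluded from curve averaging")
    if not out:
        raise ValueError("no protein with both classes; cannot average curves")
    return out


def averaged_roc(
    scored: dict[str, tuple[np.ndarray, np.ndarray]], grid_step: float = 0.01
) -> AveragedCurve:
    """Vertically averaged ROC over proteins.

    ``scored`` maps protein id to (labels, scores).  Each per-protein ROC is
    interpolated onto a fixed FPR grid and TPRs are averaged pointwise;
    proteins lacking either class are excluded.
    """
    scored = _eligible(scored)
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    tprs = []
    for y, s in scored.values():
        fpr, tpr, _ = roc_curve(y > 0, s)
        tprs.append(np.interp(grid, fpr, tpr))
    return AveragedCurve(grid, np.mean(tprs, axis=0), len(scored))


def _rp_step(recall_grid: np.ndarray, recall: np.ndarray, precision: np.ndarray) -> np.ndarray:
    """Precision at each grid recall: the best precision attainable at an
    operating point with recall >= r (rightmost/interpolated precision)."""
    order = np.argsort(recall, kind="stable")
    recall = recall[order]
    precision = precision[order]
    # suffix max: best precision among all points to the right of each recall
    best_right = np.maximum.accumulate(precision[::-1])[::-1]
    idx = np.searchsorted(recall, recall_grid, side="left")
    out = np.empty_like(recall_grid)
    for i, j in enumerate(idx):
        out[i] = best_right[j] if j < len(recall) else 0.0
    return out


def averaged_rp(
    scored: dict[str, tuple[np.ndarray, np.ndarray]], grid_step: float = 0.01
) -> AveragedCurve:
    """Vertically averaged recall/precision curve over proteins."""
    scored = _eligible(scored)
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    precs = []
    for y, s in scored.values():
        precision, recall, _ = precision_recall_curve(y > 0, s)
        # drop the artificial (recall=0, precision=1) terminator added by sklearn
        precs.append(_rp_step(grid, recall[:-1], precision[:-1]))
    return AveragedCurve(grid, np.mean(precs, axis=0), len(scored))


def wilcoxon_f1(
    fold_f1_a, fold_f1_b, alpha: float = 0.05
) -> dict[str, float | bool]:
    """Two-sided paired Wilcoxon signed-rank test on per-fold F1 values.

    Zero differences are dropped (standard treatment); all-zero differences
    give p = 1.  Uses the exact null distribution where available.
    """
    a = np.asarray(fold_f1_a, dtype=float)
    b = np.asarray(fold_f1_b, dtype=float)
    if a.shape != b.shape or a.size < 5:
        raise ValueError("paired samples of equal length >= 5 required")
    if np.all(a == b):
        return {"p_value": 1.0, "significant": False}
    res = wilcoxon(a, b, zero_method="wilcox", alternative="two-sided", method="exact")
    p = float(res.pvalue)
    return {"p_value": p, "significant": p < alpha}
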