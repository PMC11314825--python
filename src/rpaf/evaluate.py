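"""Binary classification metrics, ROC/AUC, and group feature comparison.

Accuracy, precision, recall, and F1 are computed from the confusion counts
in exact rational arithmetic; AUC uses the rank (Mann-Whitney) formulation
with tie correction, equivalent to the trapezoidal area under the ROC
curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from rpaf.ecg import ParameterError

__all__ = [
    "ConfusionCounts",
    "EvalMetrics",
    "confusion",
    "metrics",
    "roc_auc",
    "compare_groups",
]


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ParameterError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


@dataclass
class EvalMetrics:
    """Scalar summary of one evaluation.

    ``undefined`` lists metrics whose denominator was zero (reported as 0).
    """

    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float | None = None
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        d = {"accuracy": self.accuracy, "precision": self.precision,
             "recall": self.recall, "f1": self.f1}
        if self.auc is not None:
            d["auc"] = self.auc
        return d


def _check_labels(y: np.ndarray, name: str) -> np.ndarray:
    y = np.asarray(y)
    if not np.isin(y, (0, 1)).all():
        raise ParameterError(f"{name} must contain only 0/1 labels")
    return y.astype(int)


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Tally TP/TN/FP/FN with class 1 as positive (pre-AF)."""
    y_true = _check_labels(y_true, "y_true")
    y_pred = _check_labels(y_pred, "y_pred")
    if y_true.shape != y_pred.shape:
        raise ParameterError("label sequences differ in length")
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def metrics(c: ConfusionCounts) -> EvalMetrics:
    """Accuracy, precision, recall, F1 from confusion counts.

    Zero-denominator cases are reported as 0 and flagged in ``undefined``.
    """
    if c.total == 0:
        raise ParameterError("empty confusion counts")
    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    acc = (c.tp + c.tn) / c.total
    prec = ratio(c.tp, c.tp + c.fp, "precision")
    rec = ratio(c.tp, c.tp + c.fn, "recall")
    f1 = ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, "f1")
    return EvalMetrics(accuracy=acc, precision=prec, recall=rec, f1=f1,
                       undefined=tuple(undefined))


def roc_auc(scores, y_true) -> tuple[float, np.ndarray]:
    """AUC (rank formulation, ties count one half) and ROC curve points.

    Returns ``(auc, curve)`` where ``curve`` is an (k, 2) array of
    (false-positive rate, true-positive rate) points from (0,0) to (1,1).
    """
    y = _check_labels(y_true, "y_true")
    s = np.asarray(scores, dtype=np.float64)
    if s.shape != y.shape:
        raise ParameterError("scores and labels differ in length")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ParameterError("both classes must be present for ROC analysis")
    ranks = stats.rankdata(s)  # average ranks handle ties
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    order = np.argsort(-s, kind="stable")
    ys = y[order]
    ss = s[order]
    tps = np.cumsum(ys)
    fps = np.cumsum(1 - ys)
    keep = np.r_[np.flatnonzero(np.diff(ss) != 0), ss.size - 1]
    curve = np.column_stack([
        np.r_[0.0, fps[keep] / n_neg],
        np.r_[0.0, tps[keep] / n_pos],
    ])
    return float(auc), curve


def compare_groups(
    features: pd.DataFrame, groups, test: str = "welch"
) -> pd.DataFrame:
    """Per-feature group mean +- SD and a two-sided two-sample test.

    ``test`` is ``'welch'`` (unequal-variance t-test) or ``'mwu'``
    (Mann-Whitney U). Returns one row per feature column with means, sample
    SDs and the p-value, groups keyed by their label value.
    """
    g = np.asarray(groups)
    labels = np.unique(g)
    if labels.size != 2:
        raise ParameterError(f"need exactly 2 groups, got {labels.size}")
    if min((g == v).sum() for v in labels) < 2:
        raise ParameterError("need >= 2 samples per group")
    if test not in ("welch", "mwu"):
        raise ParameterError("test must be 'welch' or 'mwu'")
    rows = []
    for col in features.columns:
        x = features[col].to_numpy(dtype=np.float64)
        a, b = x[g == labels[0]], x[g == labels[1]]
        if a.var() == 0.0 and b.var() == 0.0:
            # degenerate constant groups: identical -> 1, different -> 0
            p = 1.0 if a.mean() == b.mean() else 0.0
        elif test == "welch":
            p = stats.ttest_ind(a, b, equal_var=False).pvalue
        else:
            p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        rows.append({
            "feature": col,
            f"mean_{labels[0]}": a.mean(), f"sd_{labels[0]}": a.std(ddof=1),
            f"mean_{labels[1]}": b.mean(), f"sd_{labels[1]}": b.std(ddof=1),
            "p_value": float(p),
        })
    return pd.DataFrame(rows).set_index("feature")
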