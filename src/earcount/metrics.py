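"""Classification and count-agreement statistics.

Two families of evaluation metrics:

* multiclass classification quality from a confusion matrix — per-class
  precision P_i = TP_i / (TP_i + FP_i), recall R_i = TP_i / (TP_i + FN_i),
  per-class F1 (harmonic mean), the macro F1 (unweighted mean of per-class
  F1) and the micro F1 (harmonic mean of pooled precision/recall; for
  single-label data this equals plain accuracy);

* agreement between manual and predicted per-image ear counts —
  R^2 = 1 - SS_res / SS_tot evaluated against the *predictions* (so it can
  be negative for a poor predictor; it is not a squared correlation),
  RMSE = sqrt(mean (m_i - c_i)^2) in ears, RRMSE = RMSE / mean(m) * 100 in
  percent, bias = mean(m_i - c_i) in ears, plus the least-squares
  slope/intercept of predicted on manual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = [
    "ClassMetrics",
    "CountEvaluation",
    "confusion_from_labels",
    "precision_recall",
    "f1_scores",
    "micro_f1",
    "class_metrics",
    "count_agreement",
    "round_percent",
]


def round_percent(fraction: float, decimals: int = 2) -> float:
    """Fraction in [0, 1] -> percentage rounded half-up to ``decimals``."""
    q = Decimal(10) ** -decimals
    return float(
        Decimal(repr(float(fraction) * 100.0)).quantize(q, rounding=ROUND_HALF_UP)
    )


def _check_cm(cm: np.ndarray) -> np.ndarray:
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError(f"confusion matrix must be square, got shape {cm.shape}")
    if (cm < 0).any():
        raise ValueError("confusion matrix entries must be nonnegative")
    return cm.astype(np.float64)


def confusion_from_labels(true, pred, n_classes: int = 4) -> np.ndarray:
    """Tally an n x n confusion matrix (rows true, cols predicted)."""
    true = np.asarray(true, dtype=np.int64)
    pred = np.asarray(pred, dtype=np.int64)
    if true.shape != pred.shape:
        raise ValueError("true and predicted label lists differ in length")
    if ((true < 0) | (true >= n_classes) | (pred < 0) | (pred >= n_classes)).any():
        raise ValueError(f"labels must lie in 0..{n_classes - 1}")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (true, pred), 1)
    return cm


def precision_recall(cm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-class precision and recall as fractions in [0, 1].

    A class with an empty column (never predicted) or empty row (absent from
    the data) gets precision resp. recall 0, with a warning.
    """
    cm = _check_cm(cm)
    tp = np.diag(cm)
    col = cm.sum(axis=0)
    row = cm.sum(axis=1)
    if (col == 0).any() or (row == 0).any():
        warnings.warn(
            "class with zero TP+FP or TP+FN; its precision/recall is set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, tp / np.where(col == 0, 1, col), 0.0)
        recall = np.where(row > 0, tp / np.where(row == 0, 1, row), 0.0)
    return precision, recall


def f1_scores(
    precision: np.ndarray, recall: np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-class F1 = 2PR/(P+R) (0 where both vanish) and the macro F1."""
    p = np.asarray(precision, dtype=np.float64)
    r = np.asarray(recall, dtype=np.float64)
    if p.shape != r.shape:
        raise ValueError("precision and recall must have the same shape")
    if ((p < 0) | (p > 1) | (r < 0) | (r > 1)).any():
        raise ValueError("precision and recall must be fractions in [0, 1]")
    denom = p + r
    f1 = np.where(denom > 0, 2 * p * r / np.where(denom == 0, 1, denom), 0.0)
    return f1, float(f1.mean())


def micro_f1(cm: np.ndarray) -> tuple[float, float, float]:
    """Micro-averaged (precision, recall, F1) over pooled TP/FP/FN."""
    cm = _check_cm(cm)
    tp = np.diag(cm).sum()
    fp = cm.sum(axis=0).sum() - tp  # = total - trace
    fn = cm.sum(axis=1).sum() - tp
    p_mi = tp / (tp + fp) if tp + fp > 0 else 0.0
    r_mi = tp / (tp + fn) if tp + fn > 0 else 0.0
    f_mi = 2 * p_mi * r_mi / (p_mi + r_mi) if p_mi + r_mi > 0 else 0.0
    return float(p_mi), float(r_mi), float(f_mi)


@dataclass(frozen=True)
class ClassMetrics:
    """All classification metrics, as raw fractions and as 2-decimal
    percentages."""

    precision: tuple[float, ...]
    recall: tuple[float, ...]
    f1: tuple[float, ...]
    macro_f1: float
    micro_precision: float
    micro_recall: float
    micro_f1: float

    def as_percent(self) -> dict[str, object]:
        return {
            "precision": [round_percent(x) for x in self.precision],
            "recall": [round_percent(x) for x in self.recall],
            "f1": [round_percent(x) for x in self.f1],
            "macro_f1": round_percent(self.macro_f1),
            "micro_precision": round_percent(self.micro_precision),
            "micro_recall": round_percent(self.micro_recall),
            "micro_f1": round_percent(self.micro_f1),
        }


def class_metrics(cm: np.ndarray) -> ClassMetrics:
    """Bundle per-class and averaged metrics for one confusion matrix."""
    p, r = precision_recall(cm)
    f1, macro = f1_scores(p, r)
    p_mi, r_mi, f_mi = micro_f1(cm)
    return ClassMetrics(
        precision=tuple(map(float, p)),
        recall=tuple(map(float, r)),
        f1=tuple(map(float, f1)),
        macro_f1=macro,
        micro_precision=p_mi,
        micro_recall=r_mi,
        micro_f1=f_mi,
    )


@dataclass(frozen=True)
class CountEvaluation:
    """Manual-vs-predicted count agreement over a set of images.

    rmse and bias are in ears, rrmse in percent of the manual mean; slope
    and intercept describe the least-squares fit of predicted on manual.
    """

    n: int
    mean_manual: float
    r2: float
    rmse: float
    rrmse: float
    bias: float
    slope: float
    intercept: float


def count_agreement(manual, predicted) -> CountEvaluation:
    """Count-agreement statistics between paired manual/predicted counts."""
    m = np.asarray(manual, dtype=np.float64)
    c = np.asarray(predicted, dtype=np.float64)
    if m.shape != c.shape or m.ndim != 1:
        raise ValueError("manual and predicted must be equal-length 1-D lists")
    if m.size == 0:
        raise ValueError("need at least one image pair")
    mbar = float(m.mean())
    if mbar <= 0:
        raise ValueError("mean manual count must be positive for RRMSE")
    resid = m - c
    ss_res = float((resid**2).sum())
    ss_tot = float(((m - mbar) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    rmse = float(np.sqrt((resid**2).mean()))
    rrmse = rmse / mbar * 100.0
    bias = float(resid.mean())
    if m.size >= 2 and ss_tot > 0:
        slope, intercept = np.polyfit(m, c, 1)
    else:
        slope, intercept = np.nan, np.nan
    return CountEvaluation(
        n=int(m.size),
        mean_manual=mbar,
        r2=float(r2),
        rmse=rmse,
        rrmse=float(rrmse),
        bias=bias,
        slope=float(slope),
        intercept=float(intercept),
    )
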