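"""Overlap metrics, the combined BCE/Dice training loss, and the
statistical comparison harness.

All overlap metrics are defined on pixel-level confusion counts between a
target mask Y and a prediction Y-hat:

    DICE        = 2|Y n Y^| / (|Y| + |Y^|)
    IoU         = |Y n Y^| / |Y u Y^|        (Jaccard; IoU = DICE/(2-DICE))
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    precision   = TP / (TP + FP)             (positive predictive value)

The library returns raw fractions; the reporting layer formats them as
percentages (mean +/- std, two decimals) per timepoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (ParameterError, UndefinedMetricError, UndefinedTestError)
from .frames import BinaryMask, load_mask


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel confusion counts; TP+FP+TN+FN equals the raster size."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ParameterError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _check_shapes(y: BinaryMask, y_hat: BinaryMask) -> None:
    if y.shape != y_hat.shape:
        raise ParameterError(
            f"mask shapes differ: {y.shape} vs {y_hat.shape}")


def confusion(y: BinaryMask, y_hat: BinaryMask) -> ConfusionCounts:
    """Exact integer confusion counts between target y and prediction y_hat."""
    _check_shapes(y, y_hat)
    t = y.as_bool()
    p = y_hat.as_bool()
    return ConfusionCounts(
        tp=int((t & p).sum()), fp=int((~t & p).sum()),
        tn=int((~t & ~p).sum()), fn=int((t & ~p).sum()),
    )


def dice(y: BinaryMask, y_hat: BinaryMask) -> float:
    """Dice similarity coefficient; two empty masks overlap perfectly (1)."""
    _check_shapes(y, y_hat)
    t, p = y.as_bool(), y_hat.as_bool()
    denom = int(t.sum()) + int(p.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((t & p).sum()) / denom


def iou(y: BinaryMask, y_hat: BinaryMask) -> float:
    """Intersection over union (Jaccard); two empty masks give 1."""
    _check_shapes(y, y_hat)
    t, p = y.as_bool(), y_hat.as_bool()
    union = int((t | p).sum())
    if union == 0:
        return 1.0
    return int((t & p).sum()) / union


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN); undefined when the target has no foreground."""
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: TP + FN = 0")
    return c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP); undefined when the target has no background."""
    if c.tn + c.fp == 0:
        raise UndefinedMetricError("specificity undefined: TN + FP = 0")
    return c.tn / (c.tn + c.fp)


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP); undefined when the prediction has no foreground."""
    if c.tp + c.fp == 0:
        raise UndefinedMetricError("precision undefined: TP + FP = 0")
    return c.tp / (c.tp + c.fp)


def bce(y_prob: np.ndarray, y: BinaryMask, eps: float = 1e-7) -> float:
    """Mean per-pixel binary cross-entropy between a probability map and a
    binary target, with probabilities clamped to [eps, 1-eps]."""
    p = np.clip(np.asarray(y_prob, dtype=np.float64), eps, 1.0 - eps)
    t = y.as_bool().astype(np.float64)
    if p.shape != t.shape:
        raise ParameterError("probability map and target shapes differ")
    return float(-(t * np.log(p) + (1 - t) * np.log1p(-p)).mean())


def soft_dice(y_prob: np.ndarray, y: BinaryMask, smooth: float = 1.0) -> float:
    """Differentiable Dice on a probability map:
    (2 sum(T P) + s) / (sum T + sum P + s) with smoothing s."""
    p = np.asarray(y_prob, dtype=np.float64)
    t = y.as_bool().astype(np.float64)
    if p.shape != t.shape:
        raise ParameterError("probability map and target shapes differ")
    return float((2.0 * (t * p).sum() + smooth) / (t.sum() + p.sum() + smooth))


def combined_loss(
    y_prob: np.ndarray,
    y: BinaryMask,
    alpha: float,
    smooth: float = 1.0,
    eps: float = 1e-7,
    dice_term: str = "loss",
) -> float:
    """Weighted segmentation training loss
    ``alpha * BCE + (1 - alpha) * DiceTerm``.

    With ``dice_term="loss"`` (default) the Dice contribution is
    ``1 - softDICE`` so that better overlap lowers the loss; the literal
    variant ``dice_term="similarity"`` uses softDICE itself, in which case
    the quantity is no longer a loss to minimise at alpha < 1.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ParameterError("alpha must lie in [0, 1]")
    if dice_term not in ("loss", "similarity"):
        raise ParameterError("dice_term must be 'loss' or 'similarity'")
    sd = soft_dice(y_prob, y, smooth)
    d = (1.0 - sd) if dice_term == "loss" else sd
    return alpha * bce(y_prob, y, eps) + (1.0 - alpha) * d


# ---------------------------------------------------------------------------
# Statistical comparison harness
# ---------------------------------------------------------------------------

def wilcoxon_matched_pairs(a, b) -> float:
    """Two-sided Wilcoxon matched-pairs signed-rank p-value.

    Zero differences are discarded; the null distribution is exact for
    n <= 25 without ties in the absolute differences, otherwise the normal
    approximation with tie and continuity correction is used.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ParameterError("paired samples must be 1-D and equally long")
    d = a - b
    d = d[d != 0]
    if len(d) == 0:
        raise UndefinedTestError(
            "all paired differences are zero; the signed-rank test is undefined")
    if len(d) < 5:
        raise ParameterError(
            "need at least 5 non-zero differences for a meaningful test")
    has_ties = len(np.unique(np.abs(d))) < len(d)
    if len(d) <= 25 and not has_ties:
        res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                             method="exact")
    else:
        res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                             correction=True, method="approx")
    return float(res.pvalue)


def hochberg_adjust(pvals) -> np.ndarray:
    """Hochberg step-up adjusted p-values, returned in the input order.

    With p-values sorted ascending p_(1) <= ... <= p_(m), the adjusted
    value for p_(k) is min over j >= k of (m - j + 1) * p_(j), clipped to 1;
    adjusted values are monotone and never below the raw values.
    """
    p = np.asarray(pvals, dtype=np.float64)
    if p.ndim != 1 or len(p) == 0:
        raise ParameterError("pvals must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    mult = (m - np.arange(m)) * sorted_p          # (m - j + 1) p_(j), j 1-based
    adj_sorted = np.minimum.accumulate(mult[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


# ---------------------------------------------------------------------------
# Batch evaluation
# ---------------------------------------------------------------------------

_METRIC_COLUMNS = ("dice", "iou", "sensitivity", "specificity", "precision")


@dataclass(frozen=True)
class EvaluationRecord:
    """One row of an evaluation table (metrics as percentages)."""

    frame_id: str
    timepoint: str
    method: str
    dice: float
    iou: float
    sensitivity: float
    specificity: float
    precision: float


def evaluate_pair(y: BinaryMask, y_hat: BinaryMask, frame_id: str,
                  method: str, timepoint: str = "T0") -> EvaluationRecord:
    """Compute the full metric set for one ground-truth/prediction pair,
    expressed as percentages."""
    c = confusion(y, y_hat)
    return EvaluationRecord(
        frame_id=frame_id, timepoint=timepoint, method=method,
        dice=100.0 * dice(y, y_hat), iou=100.0 * iou(y, y_hat),
        sensitivity=100.0 * sensitivity(c),
        specificity=100.0 * specificity(c),
        precision=100.0 * precision(c),
    )


def _timepoint_of(frame_id: str) -> str:
    for tp in ("T0", "T5"):
        if frame_id.endswith(f"_{tp}") or frame_id.endswith(f"-{tp}"):
            return tp
    return "T0"


def evaluate_batch(
    gt_dir: str | Path,
    pred_dir: str | Path,
    method_label: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evaluate every prediction mask against its matching ground truth.

    Both directories hold ``<frame_id>.png`` mask files; frames present in
    only one directory are excluded with a warning.  Returns the per-frame
    record table and a per-timepoint summary with ``mean ± std`` strings
    formatted to two decimals, mirroring how such tables are reported.
    """
    gt_dir, pred_dir = Path(gt_dir), Path(pred_dir)
    gt_ids = {p.stem for p in gt_dir.glob("*.png")}
    pred_ids = {p.stem for p in pred_dir.glob("*.png")}
    common = sorted(gt_ids & pred_ids)
    for missing in sorted((gt_ids ^ pred_ids)):
        warnings.warn(f"frame {missing!r} present in only one directory; "
                      "excluded from evaluation", stacklevel=2)
    records = []
    for fid in common:
        y = load_mask(gt_dir / f"{fid}.png")
        y_hat = load_mask(pred_dir / f"{fid}.png")
        records.append(evaluate_pair(y, y_hat, fid, method_label,
                                     _timepoint_of(fid)))
    table = pd.DataFrame([r.__dict__ for r in records],
                         columns=["frame_id", "timepoint", "method",
                                  *_METRIC_COLUMNS])
    summary = summarize(table)
    return table, summary


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Per-(method, timepoint) summary with 'mean ± std' percentage strings."""
    if table.empty:
        return pd.DataFrame(columns=["method", "timepoint", *_METRIC_COLUMNS])
    rows = []
    for (method, tp), grp in table.groupby(["method", "timepoint"]):
        row = {"method": method, "timepoint": tp}
        for col in _METRIC_COLUMNS:
            mean = grp[col].mean()
            std = grp[col].std(ddof=1) if len(grp) > 1 else 0.0
            row[col] = f"{mean:.2f} ± {std:.2f}"
        rows.append(row)
    return pd.DataFrame(rows)
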