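"""Classification metrics and fold-averaged ROC / precision-recall curves.

Implements the six confusion-matrix metrics (precision, specificity,
accuracy, recall, F1, Matthews correlation) with TRUE as the positive
class, plus two curve summaries:

* :func:`roc_folds` follows the cross-validated ROC construction in which
  the TP/FP/TN/FN counts at each common threshold are averaged across the
  k folds and sensitivity / specificity are computed from the averaged
  counts; the area comes from the trapezoid rule.  Per-fold AUCs are also
  returned for mean +/- sd reporting — the two estimators differ slightly
  and both are surfaced.
* :func:`aupr` sweeps thresholds in descending score order and accumulates
  the non-interpolated (step-wise) area under precision-recall.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion(labels, predictions) -> ConfusionCounts:
    """Count TP/FP/TN/FN with 1 (TRUE) as the positive class."""
    y = np.asarray(labels)
    yhat = np.asarray(predictions)
    if y.shape != yhat.shape:
        raise ValueError("labels and predictions must have equal length")
    for arr in (y, yhat):
        if not np.isin(arr, [0, 1]).all():
            raise ValueError("inputs must be binary (0/1)")
    return ConfusionCounts(
        TP=int(np.sum((y == 1) & (yhat == 1))),
        FP=int(np.sum((y == 0) & (yhat == 1))),
        TN=int(np.sum((y == 0) & (yhat == 0))),
        FN=int(np.sum((y == 1) & (yhat == 0))),
    )


def _ratio(num: float, den: float, flags: list[str], name: str) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def metrics(counts: ConfusionCounts) -> tuple[dict[str, float], list[str]]:
    """PRE, SPE, ACC, REC, F1, MCC from confusion counts.

    A zero-denominator metric is reported as 0 and listed in the returned
    degenerate-flag list instead of raising, so fold aggregation stays
    total while the condition remains visible.
    """
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    if counts.total == 0:
        raise ValueError("all-zero confusion counts")
    flags: list[str] = []
    pre = _ratio(tp, tp + fp, flags, "PRE")
    if fp + tn == 0:
        flags.append("SPE")
        spe = 0.0
    else:
        spe = 1.0 - fp / (fp + tn)
    acc = (tp + tn) / counts.total
    rec = _ratio(tp, tp + fn, flags, "REC")
    f1 = _ratio(2.0 * pre * rec, pre + rec, flags, "F1")
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _ratio(tp * tn - fp * fn, mcc_den, flags, "MCC")
    return (
        {"PRE": pre, "SPE": spe, "ACC": acc, "REC": rec, "F1": f1, "MCC": mcc},
        flags,
    )


def _fold_counts(scores: np.ndarray, labels: np.ndarray, thresholds: np.ndarray):
    """TP, FP arrays over thresholds for one fold (prediction: score >= t)."""
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    cum_tp = np.cumsum(y)
    cum_fp = np.cumsum(1 - y)
    # for each threshold, number of scores >= t
    idx = np.searchsorted(-s, -thresholds, side="right")
    tp = np.where(idx > 0, cum_tp[idx - 1], 0)
    fp = np.where(idx > 0, cum_fp[idx - 1], 0)
    return tp.astype(float), fp.astype(float)


def roc_folds(
    folds: list[tuple[np.ndarray, np.ndarray]],
    n_thresholds: int | None = None,
) -> tuple[pd.DataFrame, float, list[float]]:
    """Fold-averaged ROC curve, its AUC, and per-fold AUCs.

    ``folds`` holds one (scores, labels) pair per CV fold.  Thresholds are
    the union of all observed scores (exact); pass ``n_thresholds`` to
    subsample an evenly spaced grid for very large inputs.
    """
    if len(folds) < 1:
        raise ValueError("need at least one fold")
    clean = []
    for scores, labels in folds:
        s = np.asarray(scores, dtype=float)
        y = np.asarray(labels)
        if len(np.unique(y)) < 2:
            raise ValueError("every fold must contain both classes")
        clean.append((s, y.astype(int)))
    thresholds = np.unique(np.concatenate([s for s, _ in clean]))[::-1]
    if n_thresholds is not None and len(thresholds) > n_thresholds:
        take = np.linspace(0, len(thresholds) - 1, n_thresholds).astype(int)
        thresholds = thresholds[take]
    tp = np.zeros(len(thresholds))
    fp = np.zeros(len(thresholds))
    pos = neg = 0.0
    fold_aucs = []
    for s, y in clean:
        f_tp, f_fp = _fold_counts(s, y, thresholds)
        tp += f_tp
        fp += f_fp
        n_pos = float(y.sum())
        n_neg = float(len(y) - y.sum())
        pos += n_pos
        neg += n_neg
        tpr_f = np.concatenate([[0.0], f_tp / n_pos, [1.0]])
        fpr_f = np.concatenate([[0.0], f_fp / n_neg, [1.0]])
        fold_aucs.append(float(np.trapezoid(tpr_f, fpr_f)))
    tp /= len(clean)
    fp /= len(clean)
    sens = tp / (pos / len(clean))
    fpr = fp / (neg / len(clean))
    sens = np.concatenate([[0.0], sens, [1.0]])
    fpr = np.concatenate([[0.0], fpr, [1.0]])
    auc = float(np.trapezoid(sens, fpr))
    curve = pd.DataFrame(
        {
            "threshold": np.concatenate([[np.inf], thresholds, [-np.inf]]),
            "fpr": fpr,
            "sensitivity": sens,
        }
    )
    return curve, auc, fold_aucs


def aupr(scores, labels) -> float:
    """Non-interpolated area under the precision-recall curve.

    Sweeps distinct scores in descending order; ties move as a block.
    Equals the usual average-precision summary sum_i (R_i - R_{i-1}) P_i.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == len(y):
        raise ValueError("both classes must be present")
    order = np.argsort(-s, kind="stable")
    s = s[order]
    y = y[order]
    cum_tp = np.cumsum(y).astype(float)
    k = np.arange(1, len(y) + 1, dtype=float)
    # keep only the last index of each tied-score block
    last = np.r_[s[1:] != s[:-1], True]
    precision = (cum_tp / k)[last]
    recall = (cum_tp / n_pos)[last]
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_recall) * precision))


def fold_report(
    folds: list[tuple[np.ndarray, np.ndarray]], threshold: float = 0.0
) -> pd.DataFrame:
    """Per-fold metric table (PRE..MCC at ``threshold``, AUC, AUPR) with a
    mean +/- sd summary row appended."""
    rows = []
    _, auc_avg, fold_aucs = roc_folds(folds)
    for i, (scores, labels) in enumerate(folds):
        preds = (np.asarray(scores) > threshold).astype(int)
        m, _ = metrics(confusion(labels, preds))
        m["AUC"] = fold_aucs[i]
        m["AUPR"] = aupr(scores, labels)
        rows.append({"fold": str(i), **m})
    df = pd.DataFrame(rows)
    stat_cols = [c for c in df.columns if c != "fold"]
    mean = df[stat_cols].mean()
    sd = df[stat_cols].std(ddof=1)
    rows.append({"fold": "mean", **mean.to_dict()})
    rows.append({"fold": "sd", **sd.to_dict()})
    out = pd.DataFrame(rows)
    out.attrs["fold_averaged_auc"] = auc_avg
    return out
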