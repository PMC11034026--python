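"""Classification metrics and the cross-validation harness.

The positive class throughout is the prokaryotic virus.  Threshold
metrics follow the standard confusion-matrix definitions

    Sn = TP/(TP+FN)   Sp = TN/(TN+FP)   ACC = (TP+TN)/total
    Precision = TP/(TP+FP)   F1 = 2 * Precision * Recall / (Precision + Recall)

with zero-denominator cases reported as missing (None), never as 0.
Ranking metrics are the ROC area (equal to the Mann-Whitney pair
statistic, ties counted half) and the step-wise, non-interpolated
average precision; both are computed by scikit-learn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

POSITIVE_CLASS = "prokaryotic"

THRESHOLD_METRICS = ("Sn", "Sp", "ACC", "Precision", "F1")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "TN", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"ConfusionCounts.{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Counts with label 1 (or POSITIVE_CLASS) treated as positive."""
    t = np.asarray(y_true)
    p = np.asarray(y_pred)
    if t.dtype.kind in "UO":
        t = (t == POSITIVE_CLASS).astype(int)
    if p.dtype.kind in "UO":
        p = (p == POSITIVE_CLASS).astype(int)
    return ConfusionCounts(
        TP=int(((t == 1) & (p == 1)).sum()),
        FP=int(((t == 0) & (p == 1)).sum()),
        TN=int(((t == 0) & (p == 0)).sum()),
        FN=int(((t == 1) & (p == 0)).sum()),
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def confusion_metrics(counts: ConfusionCounts) -> dict[str, float | None]:
    """Sn, Sp, ACC, Precision and F1 from a confusion matrix.

    Metrics with a zero denominator are returned as None (missing).
    """
    sn = _ratio(counts.TP, counts.TP + counts.FN)
    sp = _ratio(counts.TN, counts.TN + counts.FP)
    acc = _ratio(counts.TP + counts.TN, counts.total)
    prec = _ratio(counts.TP, counts.TP + counts.FP)
    if prec is None or sn is None or (prec + sn) == 0:
        f1 = None
    else:
        f1 = 2 * prec * sn / (prec + sn)
    return {"Sn": sn, "Sp": sp, "ACC": acc, "Precision": prec, "F1": f1}


def _binary_labels(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "UO":
        y = (y == POSITIVE_CLASS).astype(int)
    return y.astype(int)


def roc_auc(labels, scores) -> float:
    """Area under the ROC curve of the positive-class scores.

    Equals the probability that a random positive outscores a random
    negative, ties counted half.  Requires both classes present.
    """
    y = _binary_labels(labels)
    for cls, name in ((1, "positive"), (0, "negative")):
        if not (y == cls).any():
            raise ValueError(f"roc_auc needs at least one {name} example")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def average_precision(labels, scores) -> float:
    """Step-wise (non-interpolated) average precision, ties grouped."""
    y = _binary_labels(labels)
    if not (y == 1).any():
        raise ValueError("average_precision needs at least one positive example")
    if (y == 1).all():
        return 1.0
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


def metrics_from_scores(labels, scores, threshold: float = 0.5) -> dict[str, float | None]:
    """Threshold + ranking metrics for positive-class scores."""
    y = _binary_labels(labels)
    s = np.asarray(scores, dtype=float)
    out = confusion_metrics(confusion_counts(y, (s >= threshold).astype(int)))
    try:
        out["AUC"] = roc_auc(y, s)
    except ValueError:
        out["AUC"] = None
    try:
        out["AP"] = average_precision(y, s)
    except ValueError:
        out["AP"] = None
    return out


@dataclass
class CVResult:
    """Cross-validation output: per-item predictions, per-fold metrics,
    and the mean +/- sd fold summary."""

    predictions: pd.DataFrame
    per_fold: pd.DataFrame
    summary: pd.DataFrame


def summarize_folds(per_fold: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard deviation over folds, per group."""
    value_cols = [c for c in per_fold.columns if c not in ("group", "fold")]
    rows = []
    for group, sub in per_fold.groupby("group", sort=False):
        row = {"group": group}
        for c in value_cols:
            vals = sub[c].dropna().astype(float)
            row[f"{c}_mean"] = vals.mean() if len(vals) else None
            row[f"{c}_sd"] = vals.std(ddof=1) if len(vals) > 1 else None
        rows.append(row)
    return pd.DataFrame(rows)


def cross_validate(dataset, config, kappa: float | None = None,
                   verbose: bool = False):
    """k-fold cross-validation of the classifier on a fragment set.

    For each fold the classifier is trained on the remaining folds and
    evaluated on the held-out fold; metrics are reported per length
    group and pooled ("all"), with mean +/- sd over folds.  Fold
    assignments come from the dataset (genome-level), so no genome
    contributes to both sides of a split.

    Returns an object with ``predictions`` (per-fragment table),
    ``per_fold`` and ``summary`` DataFrames.
    """
    from .cnn import build_model
    from .sgt import encode_batch, stack_weights

    if kappa is None:
        kappa = config.kappa
    folds = sorted(set(int(f) for f in dataset.folds))
    if len(folds) < 2:
        raise ValueError("cross_validate needs >= 2 folds")
    y = _binary_labels(dataset.labels)
    x = stack_weights(encode_batch(dataset.records, kappa=kappa))
    groups = np.asarray(dataset.groups)
    fold_arr = dataset.folds

    pred_rows = []
    for fold in folds:
        test = fold_arr == fold
        train = ~test
        if len(set(y[test])) < 2:
            raise ValueError(f"fold {fold} holds a single class")
        onehot = np.zeros((int(train.sum()), config.n_classes), dtype=np.float32)
        onehot[np.arange(int(train.sum())), 1 - y[train]] = 1.0  # index 0 = positive
        model = build_model(config)
        model.fit(x[train], onehot, verbose=verbose)
        probs = model.predict_proba(x[test])
        for i, idx in enumerate(np.nonzero(test)[0]):
            pred_rows.append({
                "id": dataset.fragments[idx].record.id,
                "group": groups[idx],
                "fold": fold,
                "label": y[idx],
                "score": float(probs[i, 0]),
            })
    predictions = pd.DataFrame(pred_rows)

    fold_metric_rows = []
    for fold in folds:
        sub = predictions[predictions["fold"] == fold]
        for group in list(dict.fromkeys(groups)) + ["all"]:
            gsub = sub if group == "all" else sub[sub["group"] == group]
            if not len(gsub):
                continue
            m = metrics_from_scores(gsub["label"].to_numpy(), gsub["score"].to_numpy())
            fold_metric_rows.append({"group": group, "fold": fold, **m})
    per_fold = pd.DataFrame(fold_metric_rows)
    return CVResult(predictions=predictions, per_fold=per_fold,
                    summary=summarize_folds(per_fold))
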