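"""Evaluation surface: confusion matrices, per-class precision/recall/F1,
accuracy, ROC AUC and partial AUC, and report tables.

AUC uses the probabilistic definition (a uniformly drawn positive
outranks a uniformly drawn negative, ties counting one half), which
equals the trapezoidal area under the tie-aware ROC step curve.  Partial
AUC integrates that curve over FPR in [0, partial_fpr_max] and
normalizes by the interval width.  Multiclass scores are macro-averaged
one-vs-rest.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


class ConfusionMatrix:
    """Square count matrix, rows = true class, columns = predicted class."""

    def __init__(self, counts: np.ndarray, classes: list[str]):
        counts = np.asarray(counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (counts < 0).any():
            raise ValueError("negative counts")
        self.counts = counts.astype(int)
        self.classes = list(classes)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


def confusion(true_labels, predicted_labels, classes=None) -> ConfusionMatrix:
    """Tally counts[i][j] = #{true=i, predicted=j}."""
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label vectors have different lengths")
    if classes is None:
        classes = sorted(set(true_labels) | set(predicted_labels))
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ValueError(f"label outside catalogue: {t!r} / {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, list(classes))


def class_metrics(cm: ConfusionMatrix) -> tuple[pd.DataFrame, float]:
    """One-vs-rest precision/recall/F1 per class plus overall accuracy.

    Zero denominators yield 0 with a warning rather than NaN.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    counts = cm.counts.astype(float)
    tp = np.diag(counts)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    rows = []
    for i, cls in enumerate(cm.classes):
        if tp[i] + fp[i] == 0 or tp[i] + fn[i] == 0:
            warnings.warn(f"zero denominator for class {cls!r}; metric set to 0")
        precision = tp[i] / (tp[i] + fp[i]) if tp[i] + fp[i] else 0.0
        recall = tp[i] / (tp[i] + fn[i]) if tp[i] + fn[i] else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        rows.append({"class": cls, "precision": precision, "recall": recall, "f1": f1})
    accuracy = float(tp.sum() / cm.total)
    return pd.DataFrame(rows).set_index("class"), accuracy


def _roc_curve(scores: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Tie-aware ROC step curve from (0,0) to (1,1)."""
    order = np.argsort(-scores, kind="stable")
    scores = scores[order]
    truth = truth[order]
    distinct = np.r_[np.flatnonzero(np.diff(scores)), scores.size - 1]
    tps = np.cumsum(truth)[distinct]
    fps = np.cumsum(1 - truth)[distinct]
    tpr = np.r_[0.0, tps / tps[-1]] if tps[-1] else np.zeros(distinct.size + 1)
    fpr = np.r_[0.0, fps / fps[-1]] if fps[-1] else np.zeros(distinct.size + 1)
    return fpr, tpr


def roc_auc(scores, truth, partial_fpr_max: float = 0.2) -> tuple[float, float]:
    """AUC and normalized partial AUC over FPR in [0, partial_fpr_max].

    Returns ``(nan, nan)`` with a warning when the truth vector is
    single-class (the ranking problem is undefined).
    """
    scores = np.asarray(scores, float)
    truth = np.asarray(truth).astype(int)
    if not 0 < partial_fpr_max <= 1:
        raise ValueError("partial_fpr_max must lie in (0, 1]")
    if truth.min() == truth.max():
        warnings.warn("single-class truth: AUC undefined")
        return float("nan"), float("nan")
    fpr, tpr = _roc_curve(scores, truth)
    auc = float(np.trapezoid(tpr, fpr))
    # clip the curve at partial_fpr_max, interpolating the crossing point
    tpr_at = np.interp(partial_fpr_max, fpr, tpr)
    keep = fpr <= partial_fpr_max
    fpr_p = np.r_[fpr[keep], partial_fpr_max]
    tpr_p = np.r_[tpr[keep], tpr_at]
    pauc = float(np.trapezoid(tpr_p, fpr_p)) / partial_fpr_max
    return auc, pauc


def macro_ovr_auc(score_matrix, true_labels, classes, partial_fpr_max: float = 0.2
                  ) -> tuple[float, float]:
    """Macro-averaged one-vs-rest AUC / pAUC over the given classes."""
    score_matrix = np.asarray(score_matrix, float)
    true_labels = np.asarray(true_labels)
    aucs, paucs = [], []
    for j, cls in enumerate(classes):
        truth = (true_labels == cls).astype(int)
        if truth.min() == truth.max():
            continue
        a, p = roc_auc(score_matrix[:, j], truth, partial_fpr_max)
        aucs.append(a)
        paucs.append(p)
    if not aucs:
        warnings.warn("no two-class host column: macro AUC undefined")
        return float("nan"), float("nan")
    return float(np.mean(aucs)), float(np.mean(paucs))


def report_tables(results: dict[str, dict[str, float]]) -> pd.DataFrame:
    """Assemble per-configuration metrics into a fixed-column report table.

    ``results`` maps a configuration name (e.g. ``"family-clade"``) to its
    metric dict with keys accuracy / precision / f1 / auc / pauc.
    """
    if not results:
        raise ValueError("no configurations to report")
    columns = ["accuracy", "precision", "f1", "auc", "pauc"]
    frame = pd.DataFrame(
        {name: {c: vals.get(c, float("nan")) for c in columns}
         for name, vals in results.items()}
    ).T[columns]
    frame.index.name = "configuration"
    return frame


def write_report(frame: pd.DataFrame, tsv_path: str, text_path: str | None = None) -> None:
    frame.round(4).to_csv(tsv_path, sep="\t")
    if text_path:
        with open(text_path, "w") as fh:
            fh.write(frame.round(4).to_string())
            fh.write("\n")
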