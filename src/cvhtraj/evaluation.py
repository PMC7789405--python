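"""Metric suite: ROC/AUC (per-class, micro, macro), classification
reports, label correlations, and the exact Bayes-AUROC ceiling for
planted Markov dynamics.

The AUROC here is the pairwise probability definition,
``P(score+ > score-) + 0.5 * P(score+ = score-)`` over all
positive/negative pairs, computed by midrank counting so ties receive
half credit exactly. Micro-averaging flattens the one-vs-rest
(sample, class) indicator/score pairs into one binary problem; the macro
average is the unweighted mean of per-class one-vs-rest AUCs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .categorize import CATEGORIES, ValidationError
from .sequences import SUBMETRIC_ORDER, PatientSequence

logger = logging.getLogger(__name__)


def roc_auc(scores, labels) -> float:
    """AUROC of binary ``labels`` (0/1) under ``scores``; exact half-credit
    tie handling. Raises when only one class is present."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValidationError("scores and labels must be equal-length 1-D arrays")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("AUROC undefined: only one class present")
    return _weighted_auc(pos, np.ones(len(pos)), neg, np.ones(len(neg)))


def _weighted_auc(pos, wpos, neg, wneg) -> float:
    """Weighted pairwise AUC by sweeping the merged unique score grid."""
    grid = np.unique(np.concatenate([pos, neg]))
    p_at = np.zeros(len(grid))
    n_at = np.zeros(len(grid))
    np.add.at(p_at, np.searchsorted(grid, pos), wpos)
    np.add.at(n_at, np.searchsorted(grid, neg), wneg)
    n_below = np.concatenate([[0.0], np.cumsum(n_at)[:-1]])
    num = np.sum(p_at * (n_below + 0.5 * n_at))
    return float(num / (wpos.sum() * wneg.sum()))


def multiclass_auc(proba: np.ndarray, labels, averaging: str = "micro"):
    """One-vs-rest AUROC of a (n, K) score matrix against integer labels.

    ``averaging``: ``"per_class"`` -> dict class -> AUC (NaN when the class
    is absent from ``labels``); ``"macro"`` -> unweighted mean of defined
    per-class AUCs; ``"micro"`` -> AUC over the flattened (sample, class)
    one-vs-rest pairs.
    """
    proba = np.asarray(proba, dtype=float)
    labels = np.asarray(labels)
    if proba.ndim != 2 or len(proba) != len(labels):
        raise ValidationError("proba must be (n, K) aligned with labels")
    k = proba.shape[1]
    onehot = np.zeros_like(proba)
    onehot[np.arange(len(labels)), labels] = 1.0
    if averaging == "micro":
        return roc_auc(proba.ravel(), onehot.ravel())
    per_class = {}
    for c in range(k):
        y = (labels == c).astype(int)
        if y.min() == y.max():
            logger.warning("class %d absent from labels; AUC undefined", c)
            per_class[c] = float("nan")
        else:
            per_class[c] = roc_auc(proba[:, c], y)
    if averaging == "per_class":
        return per_class
    if averaging == "macro":
        vals = [v for v in per_class.values() if not np.isnan(v)]
        return float(np.mean(vals))
    raise ValidationError(f"unknown averaging {averaging!r}")


@dataclass
class EvalReport:
    """Metrics for one prediction design on one test set."""

    per_class_auc: dict
    micro_auc: float
    macro_auc: float
    accuracy: float
    per_class: dict                 # class -> {precision, recall, f1, flagged}
    confusion: np.ndarray
    n_test: int
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"per_class_auc": {str(k): v for k, v in self.per_class_auc.items()},
                "micro_auc": self.micro_auc, "macro_auc": self.macro_auc,
                "accuracy": self.accuracy,
                "per_class": {str(k): v for k, v in self.per_class.items()},
                "confusion": self.confusion.tolist(), "n_test": self.n_test,
                **self.extra}


def classification_report(predictions, labels, n_classes: int = 3,
                          class_names=CATEGORIES) -> dict:
    """Accuracy plus per-class precision/recall/F1 with explicit
    zero-denominator flags (a class the predictor never emits reports
    0.0 precision, flagged)."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape:
        raise ValidationError("predictions and labels must align")
    conf = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in zip(labels, predictions):
        conf[t, p] += 1
    out = {"accuracy": float(np.mean(predictions == labels)), "per_class": {},
           "confusion": conf}
    for c in range(n_classes):
        tp = conf[c, c]
        fp = conf[:, c].sum() - tp
        fn = conf[c, :].sum() - tp
        flagged = False
        if tp + fp == 0 or tp + fn == 0 or tp == 0:
            precision = tp / (tp + fp) if tp + fp else 0.0
            recall = tp / (tp + fn) if tp + fn else 0.0
            flagged = tp + fp == 0 or tp + fn == 0
        else:
            precision = tp / (tp + fp)
            recall = tp / (tp + fn)
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall else 0.0)
        name = class_names[c] if c < len(class_names) else c
        out["per_class"][name] = {"precision": float(precision),
                                  "recall": float(recall), "f1": float(f1),
                                  "flagged": bool(flagged)}
    return out


def evaluate_multiclass(proba: np.ndarray, labels) -> EvalReport:
    """Full report for a 3-class design: per-class/micro/macro AUROC,
    accuracy, precision/recall/F1 and the confusion matrix."""
    rep = classification_report(np.argmax(proba, axis=1), labels,
                                n_classes=proba.shape[1])
    per_class_auc = multiclass_auc(proba, labels, "per_class")
    vals = [v for v in per_class_auc.values() if not np.isnan(v)]
    return EvalReport(per_class_auc=per_class_auc,
                      micro_auc=multiclass_auc(proba, labels, "micro"),
                      macro_auc=float(np.mean(vals)),
                      accuracy=rep["accuracy"], per_class=rep["per_class"],
                      confusion=rep["confusion"], n_test=len(labels))


def latest_label_correlations(sequences: list[PatientSequence]) -> pd.DataFrame:
    """5x5 Pearson correlation matrix of patients' latest ordinal codes.

    Requires all-submetric sequences (each patient labelled on all five).
    Zero-variance submetrics yield NaN rows/columns, reported as such.
    """
    rows = []
    for s in sequences:
        if set(SUBMETRIC_ORDER) - set(s.labels):
            raise ValidationError(
                f"{s.patient_id}: needs labels for all of {SUBMETRIC_ORDER}")
        rows.append([s.labels[sm] for sm in SUBMETRIC_ORDER])
    arr = np.asarray(rows, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(arr, rowvar=False)
    return pd.DataFrame(corr, index=SUBMETRIC_ORDER, columns=SUBMETRIC_ORDER)


def bayes_auroc_oracle(transition_matrix, state_distribution) -> float:
    """Exact micro-AUROC of the optimal predictor under planted first-order
    Markov dynamics.

    The optimal predictor of the next category given the last observed
    state ``s`` is the transition row ``P[s, :]``. Enumerating the nine
    (state, next-state) cells weighted by ``pi(s) * P[s, y]`` gives the
    exact flattened one-vs-rest AUC — no sampling involved.
    """
    m = np.asarray(transition_matrix, dtype=float)
    pi = np.asarray(state_distribution, dtype=float)
    if m.shape != (3, 3) or np.abs(m.sum(axis=1) - 1).max() > 1e-9:
        raise ValidationError("transition matrix must be 3x3 row-stochastic")
    if pi.shape != (3,) or abs(pi.sum() - 1) > 1e-9:
        raise ValidationError("state distribution must be a 3-simplex")
    pos_s, pos_w, neg_s, neg_w = [], [], [], []
    for s in range(3):
        for y in range(3):
            w = pi[s] * m[s, y]
            for c in range(3):  # flattened one-vs-rest channel per class
                score = m[s, c]
                if y == c:
                    pos_s.append(score)
                    pos_w.append(w)
                else:
                    neg_s.append(score)
                    neg_w.append(w)
    return _weighted_auc(np.array(pos_s), np.array(pos_w),
                         np.array(neg_s), np.array(neg_w))


def stationary_distribution(transition_matrix) -> np.ndarray:
    """Left eigenvector of the transition matrix at eigenvalue 1."""
    m = np.asarray(transition_matrix, dtype=float)
    w, v = np.linalg.eig(m.T)
    i = int(np.argmin(np.abs(w - 1)))
    pi = np.real(v[:, i])
    return pi / pi.sum()


def plot_roc(proba: np.ndarray, labels, path, title: str = "",
             class_names=CATEGORIES):
    """One-panel ROC plot with per-class, micro and macro curves and an
    AUC legend; returns the written path."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.metrics import roc_curve

    proba = np.asarray(proba, dtype=float)
    labels = np.asarray(labels)
    if proba.size == 0:
        raise ValidationError("empty curve set")
    fig, ax = plt.subplots(figsize=(5, 4))
    onehot = np.zeros_like(proba)
    onehot[np.arange(len(labels)), labels] = 1
    for c in range(proba.shape[1]):
        y = (labels == c).astype(int)
        if y.min() == y.max():
            continue
        fpr, tpr, _ = roc_curve(y, proba[:, c])
        ax.plot(fpr, tpr, lw=1,
                label=f"{class_names[c]} (AUC={roc_auc(proba[:, c], y):.2f})")
    fpr, tpr, _ = roc_curve(onehot.ravel(), proba.ravel())
    ax.plot(fpr, tpr, "k--", lw=1.5,
            label=f"micro (AUC={multiclass_auc(proba, labels, 'micro'):.2f})")
    ax.plot([0, 1], [0, 1], color="grey", lw=0.5)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
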