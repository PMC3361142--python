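"""Evaluation statistics for comparing similarity measures.

ROC/AUC against a labelled positive/negative pair set (e.g. direct
protein-protein interactions vs. random annotated pairs), confusion-matrix
precision and accuracy at a threshold, and Pearson correlation between
similarity vectors.  Undefined scores (None/NaN sentinels from unannotated
proteins) are removed before any statistic is computed.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn import metrics as _skmetrics

__all__ = [
    "clean_scores",
    "roc_curve",
    "auc",
    "auc_mann_whitney",
    "precision_accuracy",
    "youden_threshold",
    "pearson",
    "random_negative_pairs",
]


def clean_scores(scores: Sequence, labels: Sequence) -> tuple:
    """Drop sentinel (None/NaN) scores and return float arrays."""
    if len(scores) != len(labels):
        raise ValueError("scores and labels differ in length")
    xs, ys = [], []
    for s, lab in zip(scores, labels):
        if s is None or (isinstance(s, float) and math.isnan(s)):
            continue
        xs.append(float(s))
        ys.append(int(lab))
    return np.asarray(xs), np.asarray(ys)


def _require_both_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC analysis needs both positive and negative labels")


def roc_curve(scores: Sequence, labels: Sequence) -> tuple:
    """(fpr, tpr) arrays with thresholds swept over the distinct scores in
    descending order and tied scores grouped."""
    s, y = clean_scores(scores, labels)
    _require_both_classes(y)
    fpr, tpr, _ = _skmetrics.roc_curve(y, s, drop_intermediate=False)
    return fpr, tpr


def auc(scores: Sequence, labels: Sequence) -> float:
    """Trapezoidal area under the ROC curve."""
    fpr, tpr = roc_curve(scores, labels)
    return float(np.trapezoid(tpr, fpr))


def auc_mann_whitney(scores: Sequence, labels: Sequence) -> float:
    """AUC via the tie-corrected Mann-Whitney U statistic.

    Independent of the trapezoidal route; the two must agree to numerical
    precision, which the test suite uses as a cross-check.
    """
    s, y = clean_scores(scores, labels)
    _require_both_classes(y)
    pos = s[y == 1]
    neg = s[y == 0]
    u, _p = stats.mannwhitneyu(pos, neg, alternative="two-sided")
    return float(u / (len(pos) * len(neg)))


def precision_accuracy(
    scores: Sequence, labels: Sequence, threshold: float
) -> tuple:
    """(precision, accuracy) of the classifier ``score >= threshold``.

    Precision is None when nothing is predicted positive.
    """
    s, y = clean_scores(scores, labels)
    pred = s >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    precision = tp / (tp + fp) if (tp + fp) else None
    accuracy = (tp + tn) / len(y)
    return precision, accuracy


def youden_threshold(scores: Sequence, labels: Sequence) -> float:
    """Threshold maximizing Youden's J = tpr - fpr.

    A generic operating-point choice when no threshold is prescribed.
    """
    s, y = clean_scores(scores, labels)
    _require_both_classes(y)
    fpr, tpr, thr = _skmetrics.roc_curve(y, s, drop_intermediate=False)
    return float(thr[int(np.argmax(tpr - fpr))])


def pearson(x: Sequence, y: Sequence) -> float:
    """Sample Pearson correlation after pairwise sentinel removal."""
    if len(x) != len(y):
        raise ValueError("vectors differ in length")
    xs, ys = [], []
    for a, b in zip(x, y):
        bad = any(v is None or (isinstance(v, float) and math.isnan(v)) for v in (a, b))
        if not bad:
            xs.append(float(a))
            ys.append(float(b))
    if len(xs) < 3:
        raise ValueError("need at least 3 defined pairs")
    xs, ys = np.asarray(xs), np.asarray(ys)
    if xs.std() == 0.0 or ys.std() == 0.0:
        raise ValueError("zero-variance vector")
    return float(stats.pearsonr(xs, ys).statistic)


def random_negative_pairs(proteins: Sequence, n_pairs: int, seed: int = 0) -> list:
    """Random annotated-protein pairs as a negative control set,
    size-matched to a positive set by the caller."""
    proteins = sorted(proteins)
    if len(proteins) < 2:
        raise ValueError("need at least two proteins")
    rng = np.random.default_rng(seed)
    pairs = []
    while len(pairs) < n_pairs:
        i, j = rng.choice(len(proteins), size=2, replace=False)
        pairs.append((proteins[int(i)], proteins[int(j)]))
    return pairs
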