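"""Independent brute-force oracles used to cross-check the metrics layer.

Deliberately naive: element counting, an explicit sweep over every distinct
cutoff, and the pairwise-comparison definition of AUROC.  None of them
share code with the implementations they check.
"""

from __future__ import annotations

import math

import numpy as np


def count_confusion(y_true, y_pred) -> tuple[int, int, int, int]:
    """(tp, fp, tn, fn) by explicit element counting."""
    tp = fp = tn = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == 1 and p == 1:
            tp += 1
        elif t == 0 and p == 1:
            fp += 1
        elif t == 0 and p == 0:
            tn += 1
        else:
            fn += 1
    return tp, fp, tn, fn


def metric_from_counts(tp: int, fp: int, tn: int, fn: int, name: str) -> float:
    n = tp + fp + tn + fn

    def div(a, b):
        return a / b if b else 0.0

    if name in ("sensitivity", "recall"):
        return div(tp, tp + fn)
    if name == "specificity":
        return div(tn, tn + fp)
    if name == "precision":
        return div(tp, tp + fp)
    if name == "npv":
        return div(tn, tn + fn)
    if name in ("accuracy", "concordance_relative"):
        return div(tp + tn, n)
    if name == "concordance_count":
        return float(tp + tn)
    if name == "mcc":
        den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        return div(tp * tn - fp * fn, den)
    raise ValueError(name)


def sweep_roc_points(y_true, scores) -> list[tuple[float, float]]:
    """(fpr, tpr) at every distinct cutoff (>= is positive), plus (0, 0)."""
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    pos = int((y == 1).sum())
    neg = int((y == 0).sum())
    points = [(0.0, 0.0)]
    for t in sorted(set(s.tolist()), reverse=True):
        pred = s >= t
        tp = int((pred & (y == 1)).sum())
        fp = int((pred & (y == 0)).sum())
        points.append((fp / neg, tp / pos))
    return points


def sweep_pr_points(y_true, scores) -> list[tuple[float, float]]:
    """(recall, precision) at every distinct cutoff, strictest first."""
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    pos = int((y == 1).sum())
    points = []
    for t in sorted(set(s.tolist()), reverse=True):
        pred = s >= t
        tp = int((pred & (y == 1)).sum())
        fp = int((pred & (y == 0)).sum())
        points.append((tp / pos, tp / (tp + fp)))
    return points


def pairwise_auroc(y_true, scores) -> float:
    """P(pathogenic score > benign score) + ties/2, over all pairs."""
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    s_pos = s[y == 1]
    s_neg = s[y == 0]
    greater = (s_pos[:, None] > s_neg[None, :]).sum()
    ties = (s_pos[:, None] == s_neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (len(s_pos) * len(s_neg)))


def random_instance(rng: np.random.Generator, max_n: int = 200):
    """A random labeled score vector with both classes and frequent ties."""
    n = int(rng.integers(5, max_n + 1))
    y = rng.integers(0, 2, size=n)
    if y.sum() == 0:
        y[0] = 1
    if y.sum() == n:
        y[0] = 0
    if rng.random() < 0.5:
        scores = rng.normal(y * rng.uniform(0, 3), 1.0)
    else:  # heavy ties
        scores = rng.integers(0, 5, size=n).astype(float)
    return y, scores
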