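"""Score interpretation and binary-classification performance measures.

Prioritization methods emit numerical scores; each method's manifest states
a cutoff and which side of it is called pathogenic.  Truth labels are
encoded benign -> 0, pathogenic -> 1, predictions are obtained by
thresholding scores at the cutoff, and the usual binary-classifier
machinery follows: confusion matrices, ratio metrics, Matthews correlation,
ROC / precision-recall curves and the area under the ROC curve.

Conventions fixed here (and relied on throughout the package):

* a score exactly at the cutoff is called pathogenic (``>=`` semantics) —
  the clinically conservative choice, and the same convention anchors the
  ROC threshold sweep, so cutoff metrics always lie on the ROC curve;
* ``direction="lower"`` (smaller score = more deleterious) is implemented
  by negating scores and cutoff and reusing the ``higher`` code path;
* ratio metrics with a zero denominator return 0.0 with a logged warning
  rather than NaN, so reports stay numeric.

AUROC is computed two ways: trapezoidal area over the tie-grouped ROC
curve (:func:`auroc`) and the tie-corrected Mann–Whitney pairwise
probability (:func:`auroc_mann_whitney`).  They are mathematically equal;
the second serves as an independent cross-check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.stats import rankdata

from .errors import DegenerateLabels, UnknownMetric

logger = logging.getLogger(__name__)

Direction = Literal["higher", "lower"]

CLASS_ENCODING = {"benign": 0, "pathogenic": 1}
CLASS_DECODING = {0: "benign", 1: "pathogenic"}

#: Confusion-matrix based metrics (AUROC is curve-based and handled by the
#: report layer alongside these).
METRIC_NAMES = (
    "sensitivity",
    "specificity",
    "precision",
    "recall",
    "npv",
    "accuracy",
    "concordance_count",
    "concordance_relative",
    "mcc",
)

SUMMARY_NAMES = ("confusion_matrix", "roc_curve", "pr_curve")


def encode_classes(classes: Sequence[str]) -> np.ndarray:
    """Encode benign -> 0, pathogenic -> 1, preserving order."""
    return np.asarray([CLASS_ENCODING[c] for c in classes], dtype=np.int64)


def decode_classes(encoded: Sequence[int]) -> list[str]:
    """Inverse of :func:`encode_classes`."""
    return [CLASS_DECODING[int(v)] for v in encoded]


def _orient(scores, cutoff: float | None, direction: Direction):
    """Map scores (and optionally a cutoff) into higher-is-pathogenic space."""
    s = np.asarray(scores, dtype=np.float64)
    if direction not in ("higher", "lower"):
        raise ValueError(f"direction must be 'higher' or 'lower', got {direction!r}")
    if direction == "lower":
        s = -s
        cutoff = None if cutoff is None else -cutoff
    return s, cutoff


def apply_cutoff(
    scores: Sequence[float], cutoff: float, direction: Direction = "higher"
) -> np.ndarray:
    """Threshold scores into predicted classes {0, 1}.

    With ``direction="higher"`` a score >= cutoff is predicted pathogenic
    (1); ``direction="lower"`` mirrors the rule for methods where smaller
    scores mean more deleterious.
    """
    s, cut = _orient(scores, cutoff, direction)
    return (s >= cut).astype(np.int64)


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/TN/FN counts from expected vs. predicted encoded labels."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict[str, int]:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn}

    @classmethod
    def from_dict(cls, d: dict) -> "ConfusionMatrix":
        return cls(tp=int(d["tp"]), fp=int(d["fp"]), tn=int(d["tn"]), fn=int(d["fn"]))


def confusion_matrix(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionMatrix:
    """Count agreement/disagreement between encoded truth and predictions."""
    t = np.asarray(y_true, dtype=np.int64)
    p = np.asarray(y_pred, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    if t.size == 0:
        raise ValueError("cannot build a confusion matrix from zero labels")
    for name, arr in (("y_true", t), ("y_pred", p)):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} contains values outside {{0, 1}}")
    return ConfusionMatrix(
        tp=int(((t == 1) & (p == 1)).sum()),
        fp=int(((t == 0) & (p == 1)).sum()),
        tn=int(((t == 0) & (p == 0)).sum()),
        fn=int(((t == 1) & (p == 0)).sum()),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("metric %s undefined (zero denominator); returning 0.0", name)
        return 0.0
    return num / den


def metric(cm: ConfusionMatrix, which: str) -> float:
    """Compute one named performance metric from a confusion matrix.

    ``concordance_count`` is the absolute number of correctly classified
    variants (tp + tn); ``concordance_relative`` the fraction of correctly
    classified variants, identical to accuracy.  ``recall`` is an alias of
    sensitivity.  Undefined ratios (zero denominator) return 0.0.
    """
    tp, fp, tn, fn = cm.tp, cm.fp, cm.tn, cm.fn
    if which in ("sensitivity", "recall"):
        return _ratio(tp, tp + fn, which)
    if which == "specificity":
        return _ratio(tn, tn + fp, which)
    if which == "precision":
        return _ratio(tp, tp + fp, which)
    if which == "npv":
        return _ratio(tn, tn + fn, which)
    if which in ("accuracy", "concordance_relative"):
        return _ratio(tp + tn, cm.n, which)
    if which == "concordance_count":
        return float(tp + tn)
    if which == "mcc":
        den = float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        if den == 0:
            logger.warning("metric mcc undefined (zero denominator); returning 0.0")
            return 0.0
        return (tp * tn - fp * fn) / np.sqrt(den)
    raise UnknownMetric(f"unsupported metric {which!r}; choose from {METRIC_NAMES}")


# --- threshold sweeps ------------------------------------------------------

def _sweep(y_true, scores, direction: Direction):
    """Shared tie-grouped threshold sweep.

    Returns (thresholds desc in oriented space, cumulative tp, cumulative fp,
    total positives, total negatives).  Thresholds are the distinct score
    values; at threshold t every score >= t is predicted pathogenic.
    """
    y = np.asarray(y_true, dtype=np.int64)
    s, _ = _orient(scores, None, direction)
    if y.shape != s.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {s.shape}")
    if y.size == 0 or not np.isin(y, (0, 1)).all():
        raise ValueError("y_true must be a non-empty vector over {0, 1}")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    # last index of each tie group
    last = np.r_[np.nonzero(np.diff(s_sorted))[0], y.size - 1]
    tps = np.cumsum(y_sorted)[last].astype(np.float64)
    fps = (last + 1) - tps
    return s_sorted[last], tps, fps, float(y.sum()), float(y.size - y.sum())


@dataclass(frozen=True)
class RocCurve:
    """ROC curve: (FPR, TPR) per distinct threshold, anchored at (0,0).

    ``thresholds`` are reported on the original score scale, descending in
    pathogenicity (the leading +inf corresponds to the (0,0) anchor where
    nothing is called pathogenic); for ``direction="lower"`` methods the
    stored thresholds therefore ascend numerically.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    direction: Direction = "higher"

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.fpr, self.tpr])

    def to_dict(self) -> dict:
        # the anchor threshold is +/- infinity; JSON carries it as null
        return {
            "thresholds": [
                float(t) if np.isfinite(t) else None for t in self.thresholds
            ],
            "fpr": [float(v) for v in self.fpr],
            "tpr": [float(v) for v in self.tpr],
            "direction": self.direction,
            "auroc": auroc(self),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RocCurve":
        anchor = np.inf if d.get("direction", "higher") == "higher" else -np.inf
        return cls(
            thresholds=np.asarray(
                [anchor if t is None else t for t in d["thresholds"]],
                dtype=np.float64,
            ),
            fpr=np.asarray(d["fpr"], dtype=np.float64),
            tpr=np.asarray(d["tpr"], dtype=np.float64),
            direction=d.get("direction", "higher"),
        )


def roc_curve(
    y_true: Sequence[int], scores: Sequence[float], direction: Direction = "higher"
) -> RocCurve:
    """Tie-grouped ROC sweep over all distinct cutoffs.

    Requires both classes in ``y_true``; a single-class vector has no
    defined FPR/TPR trade-off and raises :class:`DegenerateLabels`.
    """
    thresholds, tps, fps, pos, neg = _sweep(y_true, scores, direction)
    if pos == 0 or neg == 0:
        raise DegenerateLabels(
            "ROC curve requires both benign and pathogenic truth labels"
        )
    tpr = np.r_[0.0, tps / pos]
    fpr = np.r_[0.0, fps / neg]
    if direction == "lower":
        thresholds = -thresholds
    return RocCurve(
        thresholds=np.r_[np.inf if direction == "higher" else -np.inf, thresholds],
        fpr=fpr,
        tpr=tpr,
        direction=direction,
    )


def auroc(curve: RocCurve) -> float:
    """Trapezoidal area under a ROC curve."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


def auroc_mann_whitney(
    y_true: Sequence[int], scores: Sequence[float], direction: Direction = "higher"
) -> float:
    """AUROC as the tie-corrected pairwise-comparison probability.

    P(random pathogenic variant outscores a random benign one), counting
    ties as half — equal to the trapezoidal area under the tie-grouped ROC
    curve.  Kept as an algorithmically independent cross-check computed
    from rank sums rather than a curve.
    """
    y = np.asarray(y_true, dtype=np.int64)
    s, _ = _orient(scores, None, direction)
    pos = int(y.sum())
    neg = y.size - pos
    if pos == 0 or neg == 0:
        raise DegenerateLabels("AUROC requires both classes in y_true")
    ranks = rankdata(s, method="average")
    rank_sum = float(ranks[y == 1].sum())
    return (rank_sum - pos * (pos + 1) / 2.0) / (pos * neg)


@dataclass(frozen=True)
class PrCurve:
    """Precision-recall pairs per distinct threshold (strictest first)."""

    thresholds: np.ndarray
    recall: np.ndarray
    precision: np.ndarray
    direction: Direction = "higher"

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.recall, self.precision])

    def to_dict(self) -> dict:
        return {
            "thresholds": [float(t) for t in self.thresholds],
            "recall": [float(v) for v in self.recall],
            "precision": [float(v) for v in self.precision],
            "direction": self.direction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PrCurve":
        return cls(
            thresholds=np.asarray(d["thresholds"], dtype=np.float64),
            recall=np.asarray(d["recall"], dtype=np.float64),
            precision=np.asarray(d["precision"], dtype=np.float64),
            direction=d.get("direction", "higher"),
        )


def pr_curve(
    y_true: Sequence[int], scores: Sequence[float], direction: Direction = "higher"
) -> PrCurve:
    """Precision-recall sweep with the same tie grouping as the ROC sweep."""
    thresholds, tps, fps, pos, _neg = _sweep(y_true, scores, direction)
    if pos == 0:
        raise DegenerateLabels("PR curve requires at least one pathogenic label")
    recall = tps / pos
    precision = tps / (tps + fps)
    if direction == "lower":
        thresholds = -thresholds
    return PrCurve(
        thresholds=thresholds, recall=recall, precision=precision,
        direction=direction,
    )
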