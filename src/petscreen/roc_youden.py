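"""Empirical ROC curves, AUC, and Youden-index cut-off selection.

A plasma marker that *falls* with disease (plasma Abeta1-42 is lower in
amyloid-PET-positive subjects) is first oriented into a score that *rises*
with disease — here via the reciprocal transform 1/x, matching the field's
habit of reporting cut-offs in (pg/ml)^-1 — and the empirical ROC curve is
built with the convention "score >= threshold => predicted positive".
Youden's index J = sensitivity + specificity - 1 is maximized over the
observed operating points to select a cut-off, which is reported both on the
score scale and back-transformed onto the original pg/ml scale.

Everything is empirical: no binormal smoothing, no interpolation between
operating points; cut-offs sit at observed score values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "RocCurve",
    "CutoffResult",
    "orient_marker",
    "empirical_roc",
    "auc",
    "youden_cutoff",
]

#: orientation labels recorded on curves and results
RECIPROCAL = "reciprocal"
IDENTITY = "identity"

_DIRECTIONS = {
    "lower_is_positive": RECIPROCAL,
    "higher_is_positive": IDENTITY,
}


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC curve of a score against a binary reference label.

    ``thresholds`` are the distinct score values in descending order, with a
    leading +inf sentinel so the curve starts at (fpr, tpr) = (0, 0); the
    final point is always (1, 1).  ``tpr[i]`` / ``fpr[i]`` are the rates of
    the rule "score >= thresholds[i] => predicted positive".
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    n_pos: int
    n_neg: int
    orientation: str = IDENTITY

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("ROC requires at least one positive and one negative")
        if not (len(self.thresholds) == len(self.tpr) == len(self.fpr)):
            raise ValueError("thresholds, tpr and fpr must be aligned")


@dataclass(frozen=True)
class CutoffResult:
    """Youden-optimal operating point of a ROC curve.

    ``score_cutoff`` is on the (possibly transformed) analysis scale;
    ``marker_cutoff`` is back-transformed onto the original marker scale
    (pg/ml) when the orientation was reciprocal.  ``tie_break`` records the
    rule used to resolve ties in J so alternates are auditable.
    """

    score_cutoff: float
    marker_cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float
    auc: float
    orientation: str = IDENTITY
    tie_break: str = "max J, then max specificity, then min threshold"


def orient_marker(values: Sequence[float], direction: str) -> np.ndarray:
    """Map raw marker values onto a score where higher means more disease-like.

    ``lower_is_positive`` applies the reciprocal transform v -> 1/v (all
    values must be strictly positive); ``higher_is_positive`` is the
    identity.  The transform applied is recorded by the caller via the
    matching orientation label so cut-offs can be back-converted.
    """
    if direction not in _DIRECTIONS:
        raise ValueError(
            f"direction must be one of {sorted(_DIRECTIONS)}, got {direction!r}"
        )
    arr = np.asarray(values, dtype=float)
    if direction == "lower_is_positive":
        bad = np.flatnonzero(arr <= 0)
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"reciprocal orientation requires positive values; "
                f"subject at position {i} has value {arr[i]!r}"
            )
        return 1.0 / arr
    return arr.copy()


def empirical_roc(
    scores: Sequence[float],
    labels: Sequence[bool],
    orientation: str = IDENTITY,
) -> RocCurve:
    """Build the empirical ROC curve of ``scores`` against binary ``labels``.

    Every distinct score value is a threshold; tied scores collapse to a
    single operating point.  Labels must contain both classes.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-d arrays of equal length")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            "labels contain a single class; ROC and AUC are undefined"
        )

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    # indices where a run of tied scores ends
    distinct = np.flatnonzero(np.diff(s_sorted) != 0)
    last_of_run = np.append(distinct, s.size - 1)

    tp_cum = np.cumsum(y_sorted)[last_of_run]
    fp_cum = np.cumsum(~y_sorted)[last_of_run]

    thresholds = np.concatenate(([np.inf], s_sorted[last_of_run]))
    tpr = np.concatenate(([0.0], tp_cum / n_pos))
    fpr = np.concatenate(([0.0], fp_cum / n_neg))
    return RocCurve(
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        n_pos=n_pos,
        n_neg=n_neg,
        orientation=orientation,
    )


def auc(curve: RocCurve) -> float:
    """Trapezoidal area under the empirical ROC curve.

    Equals the rank statistic P(score_pos > score_neg) + 0.5 P(tie) over all
    positive/negative pairs.
    """
    return float(np.trapezoid(curve.tpr, curve.fpr))


def youden_cutoff(curve: RocCurve) -> CutoffResult:
    """Select the threshold maximizing Youden's J = tpr - fpr.

    Ties in J are broken in favour of higher specificity (lower false
    positive rate), then the lower threshold; the rule is recorded on the
    result.  ``marker_cutoff`` is 1/score_cutoff under reciprocal
    orientation, the score itself otherwise.
    """
    j = curve.tpr - curve.fpr
    # lexicographic: max J, then min fpr, then min threshold
    best = 0
    for i in range(1, len(j)):
        if (j[i], -curve.fpr[i], -curve.thresholds[i]) > (
            j[best], -curve.fpr[best], -curve.thresholds[best]
        ):
            best = i
    score_cut = float(curve.thresholds[best])
    if curve.orientation == RECIPROCAL:
        marker_cut = 1.0 / score_cut if np.isfinite(score_cut) else 0.0
    else:
        marker_cut = score_cut
    return CutoffResult(
        score_cutoff=score_cut,
        marker_cutoff=marker_cut,
        sensitivity=float(curve.tpr[best]),
        specificity=float(1.0 - curve.fpr[best]),
        youden_j=float(j[best]),
        auc=auc(curve),
        orientation=curve.orientation,
    )
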