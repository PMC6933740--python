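"""Diagnostic-accuracy arithmetic and confusion-matrix reconstruction.

Two jobs live here.  The forward direction is routine: turn a 2x2 table of
screening outcomes against amyloid-PET status into sensitivity, specificity,
predictive values, accuracy and prevalence.  The inverse direction is the
interesting one: published diagnostic tables usually print rounded metrics
but not the underlying counts, so :func:`reconstruct_confusion` enumerates
every integer 2x2 table compatible with the printed (rounded) metrics and
reports whether the reconstruction is unique.  This lets downstream analyses
recover latent confusion matrices — and detect internally inconsistent
printed values — from a published table alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_EVEN, ROUND_HALF_UP
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "MetricSet",
    "ReconstructionResult",
    "summarize",
    "reconstruct_confusion",
    "pearson_r",
]

#: canonical metric names and the aliases accepted in printed-metric mappings
_METRIC_ALIASES = {
    "sensitivity": "sensitivity",
    "ss": "sensitivity",
    "specificity": "specificity",
    "sp": "specificity",
    "ppv": "ppv",
    "npv": "npv",
    "accuracy": "accuracy",
}


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 table of a binary screen against the PET reference standard."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.total == 0:
            raise ValueError("confusion matrix is empty (total = 0)")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.fp + self.tn

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    """Derived diagnostic metrics; ``None`` marks an undefined (0/0) metric."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    accuracy: float
    prevalence: float

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "accuracy": self.accuracy,
            "prevalence": self.prevalence,
        }


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def summarize(cm: ConfusionMatrix) -> MetricSet:
    """Compute the standard diagnostic metrics for a confusion matrix.

    Metrics with a zero denominator (e.g. PPV when nothing screens positive)
    are reported as ``None`` rather than coerced to a number.
    """
    return MetricSet(
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
        accuracy=(cm.tp + cm.tn) / cm.total,
        prevalence=cm.n_pos / cm.total,
    )


def _rounds_to(value: float, printed: float, decimals: int) -> bool:
    """True if ``value`` rounds to ``printed`` at ``decimals`` places.

    Both half-away-from-zero and half-to-even rounding are accepted, since
    the rounding convention of a published table is generally unknown.
    """
    q = Decimal(1).scaleb(-decimals)
    target = Decimal(repr(printed)).quantize(q, rounding=ROUND_HALF_UP)
    d = Decimal(repr(value))
    return any(
        d.quantize(q, rounding=mode) == target
        for mode in (ROUND_HALF_UP, ROUND_HALF_EVEN)
    )


@dataclass(frozen=True)
class ReconstructionResult:
    """Outcome of inverting rounded printed metrics to integer 2x2 tables.

    ``consistent`` is False when no integer table reproduces the printed
    values; ``nearest`` then lists the closest tables (by maximum absolute
    metric deviation) so the inconsistency can be quantified.
    """

    feasible: tuple
    consistent: bool
    unique: bool
    printed: Mapping[str, float]
    decimals: int
    nearest: tuple = field(default_factory=tuple)

    @property
    def matrix(self) -> ConfusionMatrix:
        """The unique feasible matrix; raises unless exactly one exists."""
        if not self.unique:
            raise ValueError(
                f"reconstruction is not unique ({len(self.feasible)} feasible matrices)"
            )
        return self.feasible[0]

    def report(self) -> dict:
        """JSON-serializable reconstruction report."""
        def row(cm: ConfusionMatrix) -> dict:
            return {
                "tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn,
                "metrics": summarize(cm).as_dict(),
            }

        return {
            "printed": dict(self.printed),
            "decimals": self.decimals,
            "consistent": self.consistent,
            "unique": self.unique,
            "n_feasible": len(self.feasible),
            "feasible": [row(cm) for cm in self.feasible],
            "nearest": [row(cm) for cm in self.nearest],
        }


def _canonical_printed(printed: Mapping[str, float]) -> dict:
    out = {}
    for key, value in printed.items():
        name = _METRIC_ALIASES.get(str(key).lower())
        if name is None:
            raise ValueError(f"unknown metric name {key!r}; expected one of "
                             f"{sorted(set(_METRIC_ALIASES))}")
        out[name] = float(value)
    return out


def reconstruct_confusion(
    n_pos: int,
    n_neg: int,
    printed: Mapping[str, float],
    decimals: int = 3,
) -> ReconstructionResult:
    """Enumerate all 2x2 tables whose metrics round to the printed values.

    Parameters
    ----------
    n_pos, n_neg
        Reference-standard positives and negatives (row totals of the
        latent table), e.g. PET+ and PET- counts.
    printed
        Any subset of {sensitivity, specificity, ppv, npv, accuracy}
        (aliases SS/SP accepted), as printed after rounding.
    decimals
        Number of decimals the source table prints.

    The search is exhaustive over tp in [0, n_pos] x fp in [0, n_neg]
    (sensitivity constrains tp alone and specificity fp alone, so those
    axes are prefiltered before pair-level metrics are checked).
    """
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("n_pos and n_neg must be positive")
    targets = _canonical_printed(printed)
    if not targets:
        raise ValueError("at least one printed metric is required")

    tp_candidates = [
        tp for tp in range(n_pos + 1)
        if "sensitivity" not in targets
        or _rounds_to(tp / n_pos, targets["sensitivity"], decimals)
    ]
    fp_candidates = [
        fp for fp in range(n_neg + 1)
        if "specificity" not in targets
        or _rounds_to((n_neg - fp) / n_neg, targets["specificity"], decimals)
    ]

    feasible = []
    for tp in tp_candidates:
        for fp in fp_candidates:
            cm = ConfusionMatrix(tp=tp, fp=fp, tn=n_neg - fp, fn=n_pos - tp)
            m = summarize(cm).as_dict()
            ok = all(
                m[name] is not None and _rounds_to(m[name], want, decimals)
                for name, want in targets.items()
            )
            if ok:
                feasible.append(cm)

    if feasible:
        return ReconstructionResult(
            feasible=tuple(feasible),
            consistent=True,
            unique=len(feasible) == 1,
            printed=targets,
            decimals=decimals,
        )

    # inconsistent printed metrics: report the nearest tables instead
    best, best_dev = [], np.inf
    for tp in range(n_pos + 1):
        for fp in range(n_neg + 1):
            cm = ConfusionMatrix(tp=tp, fp=fp, tn=n_neg - fp, fn=n_pos - tp)
            m = summarize(cm).as_dict()
            devs = [
                abs(m[name] - want) if m[name] is not None else np.inf
                for name, want in targets.items()
            ]
            dev = max(devs)
            if dev < best_dev - 1e-15:
                best, best_dev = [cm], dev
            elif abs(dev - best_dev) <= 1e-15:
                best.append(cm)
    return ReconstructionResult(
        feasible=(),
        consistent=False,
        unique=False,
        printed=targets,
        decimals=decimals,
        nearest=tuple(best),
    )


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient.

    Requires at least 3 paired observations and non-degenerate variance in
    both arrays.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError(
            "correlation undefined: at least one array has zero variance"
        )
    return float(np.corrcoef(x, y)[0, 1])
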