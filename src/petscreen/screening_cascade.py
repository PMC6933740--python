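"""The five-pathway APOE / plasma Abeta1-42 screening cascade.

Pathways, in increasing order of information used to decide who proceeds to
a confirmatory amyloid-PET scan:

I    scan everyone (no-test baseline; the screen-positive yield is the
     cohort prevalence);
II   scan APOE epsilon-4 carriers only;
III  scan subjects with plasma Abeta1-42 below a single cut-off;
IV   genotype-stratified cut-offs: carriers use the carrier cut-off,
     non-carriers the non-carrier cut-off;
V    as IV, but epsilon-2 carriers without an epsilon-4 allele (e2e2/e2e3)
     are screened out unconditionally.

The published cut-offs are 18.68 pg/ml for carriers and 15.58 pg/ml for
non-carriers; :func:`derive_stratified_cutoffs` re-derives such cut-offs
from a cohort by reciprocal-orientation ROC + Youden's index within each
genotype stratum.  The marker-scale boundary convention is strict: a subject
exactly at the cut-off screens negative ("lower than" the cut-off screens
positive).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .cohort_sim import Cohort, Subject
from .metrics_reconstruct import ConfusionMatrix, MetricSet, summarize
from .roc_youden import CutoffResult, empirical_roc, orient_marker, youden_cutoff

__all__ = [
    "PATHWAYS",
    "PUBLISHED_CUTOFF_E4",
    "PUBLISHED_CUTOFF_NON_E4",
    "PathwayRule",
    "StratifiedCutoffs",
    "paper_rule",
    "classify",
    "derive_stratified_cutoffs",
    "evaluate_pathway",
]

PATHWAYS = ("I", "II", "III", "IV", "V")

#: published plasma Abeta1-42 cut-offs (pg/ml).  The source also prints the
#: reciprocal-scale values 0.054 and 0.064 (pg/ml)^-1, which are not exact
#: reciprocals of these at the printed precision (1/0.064 = 15.625); the
#: marker-scale values are treated as canonical for replay.
PUBLISHED_CUTOFF_E4 = 18.68
PUBLISHED_CUTOFF_NON_E4 = 15.58

_DESCRIPTIONS = {
    "I": "scan everyone (no pre-screen)",
    "II": "scan APOE e4 carriers only",
    "III": "scan if plasma Abeta1-42 < single cut-off",
    "IV": "genotype-stratified Abeta1-42 cut-offs (e4 carrier vs non-carrier)",
    "V": "stratified cut-offs; e2-only (e2e2/e2e3) subjects screened out",
}


@dataclass(frozen=True)
class PathwayRule:
    """Executable form of one screening pathway."""

    pathway_id: str
    cutoff_e4: Optional[float] = None
    cutoff_non_e4: Optional[float] = None
    description: str = ""

    def __post_init__(self) -> None:
        if self.pathway_id not in PATHWAYS:
            raise ValueError(
                f"unknown pathway {self.pathway_id!r}; expected one of {PATHWAYS}"
            )
        needs_non_e4 = self.pathway_id in ("III", "IV", "V")
        needs_e4 = self.pathway_id in ("IV", "V")
        if needs_non_e4 and self.cutoff_non_e4 is None:
            raise ValueError(f"pathway {self.pathway_id} requires cutoff_non_e4")
        if needs_e4 and self.cutoff_e4 is None:
            raise ValueError(f"pathway {self.pathway_id} requires cutoff_e4")
        for name in ("cutoff_e4", "cutoff_non_e4"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")


@dataclass(frozen=True)
class StratifiedCutoffs:
    """Marker-scale cut-offs per APOE e4 stratum, with ROC provenance."""

    cutoff_e4: float
    cutoff_non_e4: float
    result_e4: CutoffResult
    result_non_e4: CutoffResult

    def __post_init__(self) -> None:
        if self.cutoff_e4 <= 0 or self.cutoff_non_e4 <= 0:
            raise ValueError("stratified cut-offs must be positive")

    def rule(self, pathway_id: str = "V") -> PathwayRule:
        """Pathway rule using these derived cut-offs."""
        return make_rule(pathway_id, self.cutoff_e4, self.cutoff_non_e4)


def make_rule(
    pathway_id: str,
    cutoff_e4: Optional[float] = None,
    cutoff_non_e4: Optional[float] = None,
) -> PathwayRule:
    """Build a rule for ``pathway_id`` with the given cut-offs (where used)."""
    if pathway_id not in PATHWAYS:
        raise ValueError(
            f"unknown pathway {pathway_id!r}; expected one of {PATHWAYS}"
        )
    return PathwayRule(
        pathway_id=pathway_id,
        cutoff_e4=cutoff_e4 if pathway_id in ("IV", "V") else None,
        cutoff_non_e4=cutoff_non_e4 if pathway_id in ("III", "IV", "V") else None,
        description=_DESCRIPTIONS[pathway_id],
    )


def paper_rule(pathway_id: str) -> PathwayRule:
    """The rule with the published cut-offs (18.68 / 15.58 pg/ml).

    Pathway III uses the single all-subject cut-off 15.58 pg/ml; IV and V
    use the stratified pair.
    """
    return make_rule(pathway_id, PUBLISHED_CUTOFF_E4, PUBLISHED_CUTOFF_NON_E4)


def classify(subject: Subject, rule: PathwayRule) -> bool:
    """Predicted screen label (True = proceed to PET) for one subject.

    Equality with a cut-off classifies as screen-negative (only values
    strictly *below* the cut-off screen positive).
    """
    pid = rule.pathway_id
    if pid == "I":
        return True
    if pid == "II":
        return subject.e4_carrier
    if subject.abeta42 is None:
        raise ValueError(
            f"subject {subject.subject_id}: abeta42 required for pathway {pid}"
        )
    if pid == "III":
        return subject.abeta42 < rule.cutoff_non_e4
    if pid == "V" and subject.e2_only:
        return False
    # IV, and V for non-e2-only subjects
    cutoff = rule.cutoff_e4 if subject.e4_carrier else rule.cutoff_non_e4
    return subject.abeta42 < cutoff


def _predictions(cohort: Cohort, rule: PathwayRule) -> np.ndarray:
    df = cohort.to_frame()
    pid = rule.pathway_id
    if pid == "I":
        return np.ones(len(df), dtype=bool)
    if pid == "II":
        return df["e4_carrier"].to_numpy(dtype=bool)
    ab42 = df["abeta42"].to_numpy(dtype=float)
    if np.isnan(ab42).any():
        i = int(np.flatnonzero(np.isnan(ab42))[0])
        raise ValueError(
            f"subject {df['subject_id'].iloc[i]}: abeta42 required for pathway {pid}"
        )
    if pid == "III":
        return ab42 < rule.cutoff_non_e4
    e4 = df["e4_carrier"].to_numpy(dtype=bool)
    pred = np.where(e4, ab42 < rule.cutoff_e4, ab42 < rule.cutoff_non_e4)
    if pid == "V":
        pred &= ~df["e2_only"].to_numpy(dtype=bool)
    return pred


def evaluate_pathway(
    cohort: Cohort, rule: PathwayRule
) -> Tuple[ConfusionMatrix, MetricSet]:
    """Apply a pathway to every subject and tally it against PET status."""
    df = cohort.to_frame()
    pred = _predictions(cohort, rule)
    truth = df["pet_positive"].to_numpy(dtype=bool)
    cm = ConfusionMatrix(
        tp=int((pred & truth).sum()),
        fp=int((pred & ~truth).sum()),
        tn=int((~pred & ~truth).sum()),
        fn=int((~pred & truth).sum()),
    )
    return cm, summarize(cm)


def derive_stratified_cutoffs(cohort: Cohort) -> StratifiedCutoffs:
    """Youden cut-offs on reciprocal Abeta1-42 within each e4 stratum.

    Each stratum (epsilon-4 carriers; non-carriers) must contain at least
    one PET+ and one PET- subject, otherwise its ROC curve is undefined.
    """
    df = cohort.to_frame()
    results = {}
    for name, carrier in (("e4_carrier", True), ("non_carrier", False)):
        sub = df[df["e4_carrier"] == carrier]
        labels = sub["pet_positive"].to_numpy(dtype=bool)
        if len(sub) == 0 or labels.all() or not labels.any():
            raise ValueError(
                f"stratum {name!r} lacks both PET classes; "
                "stratified cut-off is undefined"
            )
        scores = orient_marker(
            sub["abeta42"].to_numpy(dtype=float), "lower_is_positive"
        )
        curve = empirical_roc(scores, labels, orientation="reciprocal")
        results[name] = youden_cutoff(curve)
    return StratifiedCutoffs(
        cutoff_e4=results["e4_carrier"].marker_cutoff,
        cutoff_non_e4=results["non_carrier"].marker_cutoff,
        result_e4=results["e4_carrier"],
        result_non_e4=results["non_carrier"],
    )
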