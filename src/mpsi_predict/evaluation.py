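"""Internal validation: sensitivity/specificity per step and overall.

Positive class is Hurler; Hurler-Scheie and Scheie both count as non-H
(the dichotomy that decides between transplantation and enzyme
replacement). Indeterminate predictions and unlabeled records are excluded
from the confusion matrix but reported, never silently dropped; undefined
ratios (empty denominators) stay ``None`` instead of masquerading as 0 or
1 — honesty matters at n = 30.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .cohort import PatientRecord
from .enzyme import ActivityThresholds, ZoneReport, evaluate_zones
from .predictor import INDETERMINATE, Prediction
from .stats import round_half_up_percent

__all__ = ["EvaluationReport", "evaluate", "evaluate_step2_zones"]


@dataclass(frozen=True)
class EvaluationReport:
    """Confusion counts and derived rates for a set of predictions against
    phenotype labels (positive = Hurler)."""

    n_total: int
    n_classifiable: int
    n_indeterminate: int
    n_unlabeled: int
    tp: int
    fp: int
    tn: int
    fn: int
    per_step_attribution: Mapping[str, int] = field(default_factory=dict)

    @property
    def sensitivity(self) -> Optional[float]:
        denom = self.tp + self.fn
        return self.tp / denom if denom else None

    @property
    def specificity(self) -> Optional[float]:
        denom = self.tn + self.fp
        return self.tn / denom if denom else None

    def percent(self, value: Optional[float]) -> Optional[int]:
        return None if value is None else round_half_up_percent(value)

    def summary_lines(self) -> list[str]:
        def fmt(v: Optional[float]) -> str:
            return "undefined" if v is None else f"{self.percent(v)}%"

        lines = [
            f"patients evaluated : {self.n_total}",
            f"classifiable       : {self.n_classifiable}",
            f"indeterminate      : {self.n_indeterminate}",
            f"unlabeled          : {self.n_unlabeled}",
            f"confusion (tp fp tn fn): {self.tp} {self.fp} {self.tn} {self.fn}",
            f"sensitivity        : {fmt(self.sensitivity)}",
            f"specificity        : {fmt(self.specificity)}",
        ]
        if self.per_step_attribution:
            attribution = ", ".join(
                f"{step}={count}" for step, count in self.per_step_attribution.items()
            )
            lines.append(f"decisive steps     : {attribution}")
        return lines


def evaluate(
    cohort: Sequence[PatientRecord],
    predictions: Sequence[Prediction],
    *,
    indeterminate_as_negative: bool = False,
) -> EvaluationReport:
    """Score predictions against the cohort's phenotype labels.

    Every prediction's patient id must exist in the cohort. By default
    indeterminate predictions and predictions for unlabeled records are
    counted but kept out of the confusion matrix — the right accounting for
    the complete algorithm, whose indeterminate verdict is an honest "no
    call". When assessing a one-sided *screening* step in isolation (e.g.
    the genotype rule, which can only rule Hurler in), pass
    ``indeterminate_as_negative=True`` so that an undecided patient counts
    as a negative call: a missed Hurler then shows up as a false negative
    rather than vanishing from the denominator. Invariant to row order.
    """
    by_id = {rec.id: rec for rec in cohort}
    tp = fp = tn = fn = 0
    n_ind = n_unlab = 0
    attribution: dict[str, int] = {}
    for pred in predictions:
        if pred.patient_id not in by_id:
            raise ValueError(f"prediction for unknown patient id {pred.patient_id!r}")
        rec = by_id[pred.patient_id]
        if pred.verdict == INDETERMINATE:
            n_ind += 1
            if not indeterminate_as_negative:
                continue
            if not rec.labeled:
                continue
        else:
            attribution[pred.decisive_step] = attribution.get(pred.decisive_step, 0) + 1
        if not rec.labeled:
            n_unlab += 1
            continue
        truth_h = rec.is_hurler
        called_h = pred.verdict == "H"
        if called_h and truth_h:
            tp += 1
        elif called_h and not truth_h:
            fp += 1
        elif not called_h and not truth_h:
            tn += 1
        else:
            fn += 1
    return EvaluationReport(
        n_total=len(predictions),
        n_classifiable=tp + fp + tn + fn,
        n_indeterminate=n_ind,
        n_unlabeled=n_unlab,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        per_step_attribution=attribution,
    )


def evaluate_step2_zones(
    cohort: Sequence[PatientRecord], thresholds: ActivityThresholds
) -> ZoneReport:
    """Rule-in / rule-out performance of a threshold pair on the labeled,
    activity-bearing subset of the cohort."""
    subset = [r for r in cohort if r.labeled and r.idua_activity is not None]
    if not subset:
        raise ValueError("no labeled records with an activity measurement")
    activities = [r.idua_activity for r in subset]
    labels = [r.is_hurler for r in subset]
    return evaluate_zones(activities, labels, thresholds)
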