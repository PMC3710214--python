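"""The composed three-step severity predictor.

Flow (per patient): genotype rule first — a severe-listed genotype is
final; otherwise residual IDUA activity, when a fibroblast measurement
exists — below the rule-in cut-off is Hurler, above the rule-out cut-off
is non-Hurler; an intermediate activity, or no activity at all, falls to
the clinical tiebreak. A patient no step can decide is *indeterminate*, a
first-class verdict that evaluation reports separately rather than
coercing.

Every prediction carries an audit trace: the ordered list of step
outcomes, including pass-throughs, so a clinician can see which datum was
decisive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .clinical import classify_by_clinical
from .cohort import PatientRecord, SevereMutationList
from .enzyme import ActivityThresholds, DEFAULT_THRESHOLDS, classify_by_activity
from .genotype import classify_by_genotype
from .outcome import StepOutcome, Verdict

__all__ = [
    "Prediction",
    "ALL_STEPS",
    "predict",
    "predict_cohort",
    "predictions_to_json",
    "validate_report",
]

ALL_STEPS = ("genotype", "activity", "clinical")

INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class Prediction:
    """Verdict for one patient: ``H``, ``non-H`` or ``indeterminate``, with
    the step that decided it (``none`` iff indeterminate) and the full
    trace of attempted steps."""

    patient_id: str
    verdict: str  # "H" | "non-H" | "indeterminate"
    decisive_step: str  # "genotype" | "activity" | "clinical" | "none"
    trace: tuple[StepOutcome, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if (self.verdict == INDETERMINATE) != (self.decisive_step == "none"):
            raise ValueError("decisive_step is 'none' iff verdict is indeterminate")


def predict(
    patient: PatientRecord,
    severe: SevereMutationList,
    thresholds: ActivityThresholds = DEFAULT_THRESHOLDS,
    steps: Sequence[str] = ALL_STEPS,
    preterm_uses_clinical: bool = False,
) -> Prediction:
    """Run the algorithm (or the subset named in ``steps``, in canonical
    order) on one patient.

    Missing-data policy: a patient without a fibroblast activity skips the
    activity step; preterm patients pass through the clinical step unless
    ``preterm_uses_clinical`` is set. All gaps resolve to indeterminate.
    """
    unknown = set(steps) - set(ALL_STEPS)
    if unknown:
        raise ValueError(f"unknown steps: {sorted(unknown)}")
    trace: list[StepOutcome] = []

    if "genotype" in steps:
        outcome = classify_by_genotype(patient, severe)
        trace.append(outcome)
        if outcome.decided:
            return Prediction(patient.id, outcome.verdict.value, "genotype", tuple(trace))

    if "activity" in steps:
        if patient.idua_activity is None:
            trace.append(
                StepOutcome(
                    Verdict.PASS_THROUGH,
                    "activity",
                    "no fibroblast activity available",
                )
            )
        else:
            outcome = classify_by_activity(patient.idua_activity, thresholds)
            trace.append(outcome)
            if outcome.decided:
                return Prediction(
                    patient.id, outcome.verdict.value, "activity", tuple(trace)
                )

    if "clinical" in steps:
        preterm = patient.gestational_age.is_preterm and not preterm_uses_clinical
        outcome = classify_by_clinical(patient.findings, preterm=preterm)
        trace.append(outcome)
        if outcome.decided:
            return Prediction(
                patient.id, outcome.verdict.value, "clinical", tuple(trace)
            )

    return Prediction(patient.id, INDETERMINATE, "none", tuple(trace))


def predict_cohort(
    cohort: Sequence[PatientRecord],
    severe: SevereMutationList,
    thresholds: ActivityThresholds = DEFAULT_THRESHOLDS,
    steps: Sequence[str] = ALL_STEPS,
    preterm_uses_clinical: bool = False,
) -> list[Prediction]:
    """One prediction per record, order preserved."""
    return [
        predict(rec, severe, thresholds, steps, preterm_uses_clinical)
        for rec in cohort
    ]


# ---------------------------------------------------------------------------
# JSON report
# ---------------------------------------------------------------------------


def predictions_to_json(predictions: Sequence[Prediction], indent: int = 2) -> str:
    """Serialize predictions as a JSON array matching the shipped schema
    (``data/prediction_report.schema.json``)."""
    payload = [
        {
            "patient_id": p.patient_id,
            "verdict": p.verdict,
            "decisive_step": p.decisive_step,
            "trace": [
                {"step": o.step_name, "verdict": o.verdict.value, "rationale": o.rationale}
                for o in p.trace
            ],
        }
        for p in predictions
    ]
    return json.dumps(payload, indent=indent)


_VERDICTS = {"H", "non-H", INDETERMINATE}
_STEP_VERDICTS = {"H", "non-H", "pass-through"}
_DECISIVE = {"genotype", "activity", "clinical", "none"}


def validate_report(report: object) -> None:
    """Structurally validate a parsed prediction report against the shipped
    schema's constraints; raises ``ValueError`` on the first violation."""
    if not isinstance(report, list):
        raise ValueError("report must be a JSON array")
    for i, entry in enumerate(report):
        if not isinstance(entry, dict):
            raise ValueError(f"entry {i}: not an object")
        for key in ("patient_id", "verdict", "decisive_step", "trace"):
            if key not in entry:
                raise ValueError(f"entry {i}: missing key {key!r}")
        if not isinstance(entry["patient_id"], str) or not entry["patient_id"]:
            raise ValueError(f"entry {i}: patient_id must be a non-empty string")
        if entry["verdict"] not in _VERDICTS:
            raise ValueError(f"entry {i}: bad verdict {entry['verdict']!r}")
        if entry["decisive_step"] not in _DECISIVE:
            raise ValueError(f"entry {i}: bad decisive_step {entry['decisive_step']!r}")
        if (entry["verdict"] == INDETERMINATE) != (entry["decisive_step"] == "none"):
            raise ValueError(f"entry {i}: decisive_step 'none' iff indeterminate")
        if not isinstance(entry["trace"], list):
            raise ValueError(f"entry {i}: trace must be an array")
        for j, step in enumerate(entry["trace"]):
            if not isinstance(step, dict):
                raise ValueError(f"entry {i} trace {j}: not an object")
            if step.get("step") not in ("genotype", "activity", "clinical"):
                raise ValueError(f"entry {i} trace {j}: bad step {step.get('step')!r}")
            if step.get("verdict") not in _STEP_VERDICTS:
                raise ValueError(
                    f"entry {i} trace {j}: bad verdict {step.get('verdict')!r}"
                )
            if not isinstance(step.get("rationale"), str):
                raise ValueError(f"entry {i} trace {j}: rationale must be a string")
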