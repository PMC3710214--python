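"""Step 2 — three-zone classification of residual IDUA activity.

Residual α-L-iduronidase activity in cultured skin fibroblasts
(nmol·mg⁻¹·hr⁻¹) separates phenotypes through a rule-in / rule-out pair of
cut-offs: activity at or below the lower cut-off is only seen in Hurler
patients (call H), activity above the upper cut-off only in attenuated
patients (call non-H), and the gray zone in between is passed to the
clinical step.

Boundary conventions: the lower boundary is inclusive (activity == lower
rules in) and the upper boundary is exclusive upward (only activity
strictly above upper rules out), so the intermediate zone is the half-open
interval (lower, upper].

The packaged default cut-offs are 0.32 and 0.66 nmol·mg⁻¹·hr⁻¹.
:func:`derive_thresholds` re-derives data-driven boundaries from labeled
activities: it reports them at observed data values (the most permissive
lower cut-off with perfect rule-in specificity, and the largest observed
Hurler activity as the tightest upper cut-off with perfect rule-out
sensitivity), not at interpolated midpoints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .outcome import StepOutcome, Verdict

__all__ = [
    "ActivityThresholds",
    "ZoneReport",
    "DEFAULT_THRESHOLDS",
    "classify_by_activity",
    "derive_thresholds",
    "zone_of",
]

STEP_NAME = "activity"

ZONE_HURLER = "hurler"
ZONE_INTERMEDIATE = "intermediate"
ZONE_NON_HURLER = "non-hurler"


@dataclass(frozen=True)
class ActivityThresholds:
    """Rule-in (lower) and rule-out (upper) activity cut-offs in
    nmol·mg⁻¹·hr⁻¹. Requires 0 < lower < upper."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (self.lower > 0 and math.isfinite(self.lower)):
            raise ValueError(f"lower threshold must be positive, got {self.lower}")
        if not (self.upper > self.lower and math.isfinite(self.upper)):
            raise ValueError(
                f"upper threshold must exceed lower ({self.lower}), got {self.upper}"
            )


#: cut-offs packaged with the algorithm
DEFAULT_THRESHOLDS = ActivityThresholds(lower=0.32, upper=0.66)


def zone_of(activity: float, thresholds: ActivityThresholds) -> str:
    """Total zone map: <= lower → Hurler zone; (lower, upper] →
    intermediate; > upper → non-Hurler zone."""
    if not math.isfinite(activity) or activity < 0:
        raise ValueError(f"activity must be finite and >= 0, got {activity}")
    if activity <= thresholds.lower:
        return ZONE_HURLER
    if activity <= thresholds.upper:
        return ZONE_INTERMEDIATE
    return ZONE_NON_HURLER


def classify_by_activity(
    activity: float, thresholds: ActivityThresholds = DEFAULT_THRESHOLDS
) -> StepOutcome:
    """Three-zone verdict for one activity value."""
    zone = zone_of(activity, thresholds)
    if zone == ZONE_HURLER:
        return StepOutcome(
            Verdict.HURLER,
            STEP_NAME,
            f"activity {activity:g} <= rule-in cut-off {thresholds.lower:g}",
        )
    if zone == ZONE_NON_HURLER:
        return StepOutcome(
            Verdict.NON_HURLER,
            STEP_NAME,
            f"activity {activity:g} > rule-out cut-off {thresholds.upper:g}",
        )
    return StepOutcome(
        Verdict.PASS_THROUGH,
        STEP_NAME,
        f"activity {activity:g} in intermediate zone "
        f"({thresholds.lower:g}, {thresholds.upper:g}]",
    )


@dataclass(frozen=True)
class ZoneReport:
    """Performance of a threshold pair on labeled activities.

    Rule-in: call H when activity <= lower. Rule-out: call non-H when
    activity > upper. Sensitivities/specificities are with respect to
    detecting Hurler. When thresholds come from :func:`derive_thresholds`,
    rule-in specificity and rule-out sensitivity are 1 by construction
    (``separable`` flags the degenerate case where no lower boundary
    achieves perfect rule-in specificity).
    """

    thresholds: ActivityThresholds
    rule_in_sensitivity: float
    rule_in_specificity: float
    rule_out_sensitivity: float
    rule_out_specificity: float
    n_intermediate: int
    n_hurler: int
    n_non_hurler: int
    separable: bool = True


def evaluate_zones(
    activities: Sequence[float],
    is_hurler: Sequence[bool],
    thresholds: ActivityThresholds,
    separable: bool = True,
) -> ZoneReport:
    """Measure rule-in / rule-out performance of ``thresholds`` on observed
    labeled points."""
    if len(activities) != len(is_hurler):
        raise ValueError("activities and labels must be paired")
    h = [a for a, lab in zip(activities, is_hurler) if lab]
    non_h = [a for a, lab in zip(activities, is_hurler) if not lab]
    if not h or not non_h:
        raise ValueError("need at least one sample per class")
    n_int = sum(
        1 for a in activities if zone_of(a, thresholds) == ZONE_INTERMEDIATE
    )
    return ZoneReport(
        thresholds=thresholds,
        rule_in_sensitivity=sum(a <= thresholds.lower for a in h) / len(h),
        rule_in_specificity=sum(a > thresholds.lower for a in non_h) / len(non_h),
        rule_out_sensitivity=sum(a <= thresholds.upper for a in h) / len(h),
        rule_out_specificity=sum(a > thresholds.upper for a in non_h) / len(non_h),
        n_intermediate=n_int,
        n_hurler=len(h),
        n_non_hurler=len(non_h),
        separable=separable,
    )


def derive_thresholds(
    activities: Sequence[float], is_hurler: Sequence[bool]
) -> ZoneReport:
    """Derive the rule-in / rule-out cut-off pair from labeled activities.

    lower = the largest observed value v such that every sample with
    activity <= v is Hurler (most permissive cut-off with 100% observed
    rule-in specificity; ties across classes break toward the smaller
    H-zone). upper = the largest observed Hurler activity (tightest cut-off
    with 100% observed rule-out sensitivity under the exclusive-upper
    convention).

    If even the smallest observed value is non-Hurler, no rule-in boundary
    exists: the report carries ``separable=False`` and a width-zero zone
    pinned at the upper boundary.
    """
    if len(activities) != len(is_hurler):
        raise ValueError("activities and labels must be paired")
    h = sorted(a for a, lab in zip(activities, is_hurler) if lab)
    non_h = sorted(a for a, lab in zip(activities, is_hurler) if not lab)
    if not h or not non_h:
        raise ValueError("need at least one sample per class")

    upper = h[-1]
    min_non_h = non_h[0]
    # candidates: observed H values strictly below every non-H value
    # (a tie at the candidate would put a non-H sample in the H zone)
    candidates = [v for v in h if v < min_non_h]
    if not candidates:
        # inverted/overlapping to the point where no pure H zone exists
        thresholds = ActivityThresholds(lower=math.nextafter(upper, 0.0), upper=upper)
        return evaluate_zones(activities, is_hurler, thresholds, separable=False)

    lower = candidates[-1]
    if lower >= upper:
        # perfect separation: every H sample sits below every non-H sample,
        # so the intermediate zone collapses to width zero at max(H)
        upper = math.nextafter(lower, math.inf)
    return evaluate_zones(
        activities, is_hurler, ActivityThresholds(lower=lower, upper=upper)
    )
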