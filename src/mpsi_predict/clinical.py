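"""Step 3 — clinical tiebreak, and the feature screen that selected it.

Two first-month findings discriminate Hurler from attenuated MPS I in the
reference cohort: signs of upper respiratory tract obstruction (excessive
snoring, continuously runny nose, obstructive apneas, feeding difficulty
from nasal obstruction) and inguinal hernia. A patient reaching this step
is called Hurler if either finding is present and non-Hurler only if both
are known absent; an unknown next to an absent finding passes through
(absence of evidence is not evidence of absence).

Children born before 37+0 weeks are special-cased: prematurity itself
causes hernias and respiratory signs, so by default the step refuses to
use their findings and passes them through.

:func:`feature_screen` reproduces the selection procedure: term births
only, unknowns dropped per feature, a 2×2 Hurler × present table per
feature, and a two-sided exact test wherever enough data exists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .cohort import ClinicalFindings, PatientRecord, TriState
from .outcome import StepOutcome, Verdict
from .stats import Contingency2x2, fisher_exact_two_sided

__all__ = ["FeatureScreenRow", "classify_by_clinical", "feature_screen"]

STEP_NAME = "clinical"

DEFAULT_MIN_N = 10


def classify_by_clinical(
    findings: ClinicalFindings, preterm: bool = False
) -> StepOutcome:
    """Tiebreak on the two discriminating findings.

    H if either is present; non-H if both are known absent; pass-through
    otherwise (including every preterm patient, whose findings are deemed
    confounded by prematurity).
    """
    if preterm:
        return StepOutcome(
            Verdict.PASS_THROUGH,
            STEP_NAME,
            "born before 37+0 weeks: findings confounded by prematurity",
        )
    urt = findings.urt_obstruction
    hernia = findings.inguinal_hernia
    present = [
        name
        for name, state in (("urt_obstruction", urt), ("inguinal_hernia", hernia))
        if state is TriState.PRESENT
    ]
    if present:
        return StepOutcome(
            Verdict.HURLER, STEP_NAME, "finding present: " + ", ".join(present)
        )
    if urt is TriState.ABSENT and hernia is TriState.ABSENT:
        return StepOutcome(
            Verdict.NON_HURLER, STEP_NAME, "both discriminating findings absent"
        )
    return StepOutcome(
        Verdict.PASS_THROUGH,
        STEP_NAME,
        "insufficient findings (at least one unknown, none present)",
    )


@dataclass(frozen=True)
class FeatureScreenRow:
    """Per-feature screen result. ``p_value`` is None ("not computed") when
    a margin is empty or fewer than ``min_n`` patients have data."""

    feature: str
    n_available: int
    contingency: Optional[Contingency2x2]
    p_value: Optional[float]


def feature_screen(
    cohort: Sequence[PatientRecord],
    features: Optional[Sequence[str]] = None,
    min_n: int = DEFAULT_MIN_N,
) -> list[FeatureScreenRow]:
    """Screen candidate findings for association with the Hurler phenotype.

    Excludes preterm births, drops unknown cells per feature, tabulates
    Hurler/non-Hurler × present/absent and applies the two-sided exact test
    when ``n_available >= min_n`` and both margins are non-zero. Rows come
    back sorted by p-value, not-computed rows last.
    """
    labeled = [
        r for r in cohort if r.labeled and not r.gestational_age.is_preterm
    ]
    if features is None:
        seen: list[str] = []
        for rec in labeled:
            for name in rec.findings.feature_names():
                if name not in seen:
                    seen.append(name)
        features = seen

    rows = []
    for feature in features:
        counts = {
            (True, TriState.PRESENT): 0,
            (True, TriState.ABSENT): 0,
            (False, TriState.PRESENT): 0,
            (False, TriState.ABSENT): 0,
        }
        for rec in labeled:
            state = rec.findings.get(feature)
            if state is TriState.UNKNOWN:
                continue
            counts[(rec.is_hurler, state)] += 1
        n_avail = sum(counts.values())
        if n_avail == 0:
            rows.append(FeatureScreenRow(feature, 0, None, None))
            continue
        table = Contingency2x2(
            a=counts[(True, TriState.PRESENT)],
            b=counts[(True, TriState.ABSENT)],
            c=counts[(False, TriState.PRESENT)],
            d=counts[(False, TriState.ABSENT)],
        )
        p: Optional[float] = None
        if n_avail >= min_n and 0 not in table.row_margins and 0 not in table.col_margins:
            p = fisher_exact_two_sided(table)
        rows.append(FeatureScreenRow(feature, n_avail, table, p))

    rows.sort(key=lambda r: (r.p_value is None, r.p_value if r.p_value is not None else 0.0))
    return rows
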