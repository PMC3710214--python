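"""Step 1 — genotype rule.

A patient homozygous or compound-heterozygous for mutations on the severe
list is predicted Hurler. The rule is deliberately one-sided: alleles absent
from the list carry no information (novel mutations and mutations of
variable effect must flow to the later steps), so the step never returns a
non-Hurler verdict.
"""

from __future__ import annotations

from .cohort import Genotype, PatientRecord, SevereMutationList
from .outcome import StepOutcome, Verdict

__all__ = ["is_severe_genotype", "classify_by_genotype"]

STEP_NAME = "genotype"


def is_severe_genotype(genotype: Genotype, severe: SevereMutationList) -> bool:
    """True iff *both* alleles are on the severe list; symmetric in allele
    order."""
    return genotype.allele1 in severe and genotype.allele2 in severe


def classify_by_genotype(
    patient: PatientRecord, severe: SevereMutationList
) -> StepOutcome:
    """Hurler if both alleles are severe-listed, otherwise pass-through."""
    a1, a2 = patient.genotype.allele1, patient.genotype.allele2
    if is_severe_genotype(patient.genotype, severe):
        return StepOutcome(
            Verdict.HURLER,
            STEP_NAME,
            f"both alleles severe-listed: {a1.render()} / {a2.render()}",
        )
    unlisted = [a.render() for a in (a1, a2) if a not in severe]
    return StepOutcome(
        Verdict.PASS_THROUGH,
        STEP_NAME,
        "allele(s) not on severe list (non-informative): " + ", ".join(unlisted),
    )
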