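"""Shared verdict vocabulary for the three algorithm steps."""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

__all__ = ["Verdict", "StepOutcome"]


class Verdict(str, Enum):
    HURLER = "H"
    NON_HURLER = "non-H"
    PASS_THROUGH = "pass-through"


@dataclass(frozen=True)
class StepOutcome:
    """Result of one algorithm step. ``PASS_THROUGH`` means the step could
    not decide and the patient flows to the next step."""

    verdict: Verdict
    step_name: str
    rationale: str

    @property
    def decided(self) -> bool:
        return self.verdict is not Verdict.PASS_THROUGH
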