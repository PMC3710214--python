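"""Domain types and file I/O for MPS I patient cohorts.

A cohort is a delimited-text table (comma or tab, auto-detected) with one
row per newborn: an identifier, the clinically assigned phenotype where
known (``H`` = Hurler, ``HS`` = Hurler-Scheie, ``S`` = Scheie, ``X`` =
unknown), gestational age as ``"weeks + days"``, the two *IDUA* alleles in
HGVS-style shorthand, the residual IDUA activity measured in cultured skin
fibroblasts (nmol·mg⁻¹·hr⁻¹, blank or ``X`` when no culture was available)
and tri-state clinical findings coded ``+`` / ``-`` / ``X``.

The package ships two fixtures: a 30-patient reference cohort on which the
prediction algorithm was developed and internally validated, and the list
of 25 *IDUA* mutations reported in the literature to predict a Hurler
phenotype when both alleles carry one of them.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

__all__ = [
    "Allele",
    "Genotype",
    "GestationalAge",
    "TriState",
    "ClinicalFindings",
    "PatientRecord",
    "SevereMutationList",
    "CohortError",
    "MalformedAlleleError",
    "normalize_allele",
    "parse_gestational_age",
    "read_cohort",
    "write_cohort",
    "read_mutation_list",
    "load_reference_cohort",
    "load_severe_mutations",
    "CORE_FEATURES",
    "MISSING",
]

#: literal cell markers that map to "unknown / value absent"
MISSING = ("X", "")

#: the two clinical findings every cohort file must carry
CORE_FEATURES = ("urt_obstruction", "inguinal_hernia")

_REQUIRED_COLUMNS = (
    "patient_id",
    "phenotype",
    "gestational_age",
    "allele1",
    "allele2",
    "idua_activity",
    "urt_obstruction",
    "inguinal_hernia",
)

_PHENOTYPES = ("H", "HS", "S", "unknown")

TERM_DAYS = 259  # 37 weeks + 0 days


class CohortError(ValueError):
    """Raised for malformed cohort or mutation-list input."""


class MalformedAlleleError(CohortError):
    """Raised when an allele string cannot be normalized."""


# ---------------------------------------------------------------------------
# alleles and genotypes
# ---------------------------------------------------------------------------

_PREFIX_RE = re.compile(r"^(p|c)\.", re.IGNORECASE)


@dataclass(frozen=True, order=True)
class Allele:
    """A normalized *IDUA* variant: protein ("p.") or coding ("c.") namespace
    plus an uppercased, whitespace-free token. Tokens are opaque keys matched
    by exact set membership; no HGVS grammar validation is attempted."""

    namespace: str  # "protein" | "coding"
    token: str

    def render(self) -> str:
        prefix = "p." if self.namespace == "protein" else "c."
        return prefix + self.token


def normalize_allele(raw: str) -> Allele:
    """Normalize a raw allele string like ``" p.W402X "`` or ``"c.474-2A > G"``.

    The ``p.``/``c.`` prefix (any case) selects the namespace; the remaining
    token is uppercased and stripped of internal whitespace so comparison is
    case- and spacing-insensitive. ``&gt;`` is treated as ``>``.
    """
    s = raw.strip()
    if not s:
        raise MalformedAlleleError("empty allele string")
    m = _PREFIX_RE.match(s)
    if m is None:
        raise MalformedAlleleError(
            f"allele {raw!r} lacks a 'p.' or 'c.' prefix"
        )
    namespace = "protein" if m.group(1).lower() == "p" else "coding"
    token = s[m.end():]
    token = token.replace("&gt;", ">").replace("&GT;", ">")
    token = re.sub(r"\s+", "", token).upper()
    if not token:
        raise MalformedAlleleError(f"allele {raw!r} has an empty token")
    return Allele(namespace, token)


@dataclass(frozen=True)
class Genotype:
    """An unordered pair of alleles; equality and matching are symmetric
    under allele swap."""

    allele1: Allele
    allele2: Allele

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genotype):
            return NotImplemented
        return {self.allele1, self.allele2} == {other.allele1, other.allele2} and (
            sorted([self.allele1, self.allele2])
            == sorted([other.allele1, other.allele2])
        )

    def __hash__(self) -> int:
        return hash(frozenset((self.allele1, self.allele2))) ^ hash(
            tuple(sorted([self.allele1, self.allele2]))
        )

    def alleles(self) -> tuple[Allele, Allele]:
        return (self.allele1, self.allele2)


# ---------------------------------------------------------------------------
# gestational age
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GestationalAge:
    """Gestational age at birth as completed weeks plus days, or unknown.

    Term is defined as >= 37+0 weeks (259 days). An unknown gestational age
    is *treated* as term downstream (term is the population prior) but keeps
    ``known = False`` so callers can flag the assumption.
    """

    weeks: Optional[int] = None
    days: Optional[int] = None

    def __post_init__(self) -> None:
        if (self.weeks is None) != (self.days is None):
            raise CohortError("weeks and days must both be set or both unset")
        if self.weeks is not None:
            if self.weeks < 20:
                raise CohortError(f"implausible gestational age: {self.weeks} weeks")
            if not 0 <= self.days <= 6:
                raise CohortError(f"days must be 0-6, got {self.days}")

    @property
    def known(self) -> bool:
        return self.weeks is not None

    @property
    def total_days(self) -> Optional[int]:
        if not self.known:
            return None
        return 7 * self.weeks + self.days

    @property
    def is_term(self) -> bool:
        """True for >= 37+0 weeks; unknown ages are assumed term."""
        if not self.known:
            return True
        return self.total_days >= TERM_DAYS

    @property
    def is_preterm(self) -> bool:
        """True only for a *known* gestational age below 37+0 weeks."""
        return self.known and not self.is_term

    def render(self) -> str:
        if not self.known:
            return "X"
        return f"{self.weeks} + {self.days}"


_GA_RE = re.compile(r"^(\d+)\s*\+\s*(\d+)$")


def parse_gestational_age(raw: str) -> GestationalAge:
    """Parse ``"W + D"`` / ``"W+D"``; the missing markers map to unknown."""
    s = raw.strip()
    if s in MISSING:
        return GestationalAge()
    m = _GA_RE.match(s)
    if m is None:
        raise CohortError(f"cannot parse gestational age {raw!r}")
    weeks, days = int(m.group(1)), int(m.group(2))
    if days > 6:
        raise CohortError(f"gestational-age days must be 0-6, got {raw!r}")
    return GestationalAge(weeks, days)


# ---------------------------------------------------------------------------
# clinical findings
# ---------------------------------------------------------------------------


class TriState(Enum):
    """Present / absent / unknown coding of a clinical finding. Unknown is
    distinct from absent in every downstream computation."""

    PRESENT = "+"
    ABSENT = "-"
    UNKNOWN = "X"

    @classmethod
    def from_cell(cls, raw: str) -> "TriState":
        s = raw.strip()
        if s in MISSING:
            return cls.UNKNOWN
        if s == "+":
            return cls.PRESENT
        if s == "-":
            return cls.ABSENT
        raise CohortError(f"tri-state cell must be one of + - X, got {raw!r}")

    def render(self) -> str:
        return self.value


@dataclass(frozen=True)
class ClinicalFindings:
    """First-month clinical findings. The two discriminating features —
    signs of upper respiratory tract obstruction and inguinal hernia — are
    always present; further features live in ``extras``."""

    urt_obstruction: TriState = TriState.UNKNOWN
    inguinal_hernia: TriState = TriState.UNKNOWN
    extras: Mapping[str, TriState] = field(default_factory=dict)

    def get(self, feature: str) -> TriState:
        if feature == "urt_obstruction":
            return self.urt_obstruction
        if feature == "inguinal_hernia":
            return self.inguinal_hernia
        return self.extras.get(feature, TriState.UNKNOWN)

    def feature_names(self) -> tuple[str, ...]:
        return CORE_FEATURES + tuple(self.extras)


# ---------------------------------------------------------------------------
# patient records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatientRecord:
    """One newborn: genotype, optional fibroblast IDUA activity
    (nmol·mg⁻¹·hr⁻¹), tri-state clinical findings, gestational age and, when
    known, the clinically assigned phenotype label."""

    id: str
    phenotype: str  # "H" | "HS" | "S" | "unknown"
    gestational_age: GestationalAge
    genotype: Genotype
    idua_activity: Optional[float] = None
    findings: ClinicalFindings = field(default_factory=ClinicalFindings)

    def __post_init__(self) -> None:
        if self.phenotype not in _PHENOTYPES:
            raise CohortError(
                f"patient {self.id}: unknown phenotype label {self.phenotype!r}"
            )
        if self.idua_activity is not None:
            a = float(self.idua_activity)
            if not (a == a and a >= 0 and a != float("inf")):
                raise CohortError(
                    f"patient {self.id}: activity must be finite and >= 0"
                )

    @property
    def labeled(self) -> bool:
        return self.phenotype != "unknown"

    @property
    def is_hurler(self) -> Optional[bool]:
        """H vs non-H dichotomy (HS and S are both non-H); None if unlabeled."""
        if not self.labeled:
            return None
        return self.phenotype == "H"


# ---------------------------------------------------------------------------
# severe-mutation list
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SevereMutationList:
    """Set of normalized alleles whose homozygous or compound-heterozygous
    combination predicts a Hurler phenotype. Membership is exact on the
    normalized form."""

    alleles: frozenset[Allele]

    @classmethod
    def from_strings(cls, raw: Iterable[str]) -> "SevereMutationList":
        return cls(frozenset(normalize_allele(s) for s in raw))

    def __contains__(self, allele: Allele) -> bool:
        return allele in self.alleles

    def __len__(self) -> int:
        return len(self.alleles)

    def __iter__(self) -> Iterator[Allele]:
        return iter(sorted(self.alleles))

    def without(self, allele: Allele) -> "SevereMutationList":
        return SevereMutationList(self.alleles - {allele})


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def _detect_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def _parse_activity(raw: str, patient_id: str) -> Optional[float]:
    s = raw.strip()
    if s in MISSING:
        return None
    try:
        value = float(s)
    except ValueError as exc:
        raise CohortError(
            f"patient {patient_id}: unparseable activity {raw!r}"
        ) from exc
    if value < 0:
        raise CohortError(f"patient {patient_id}: negative activity {value}")
    return value


def _parse_phenotype(raw: str, patient_id: str) -> str:
    s = raw.strip().upper().replace("/", "")
    if s in MISSING:
        return "unknown"
    if s in ("H", "HS", "S"):
        return s
    raise CohortError(f"patient {patient_id}: unknown phenotype label {raw!r}")


def read_cohort(source: Union[str, Path, io.TextIOBase]) -> list[PatientRecord]:
    """Read a cohort file (see module docstring for the column contract).

    Raises :class:`CohortError` on a duplicate patient id, an unparseable
    activity, an unknown phenotype label or a missing required column.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8", newline="") as fh:
            return read_cohort(fh)

    text = source.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise CohortError("cohort file is empty (no header)")
    delimiter = _detect_delimiter(lines[0])
    reader = csv.DictReader(lines, delimiter=delimiter)
    missing = [c for c in _REQUIRED_COLUMNS if c not in (reader.fieldnames or [])]
    if missing:
        raise CohortError(f"cohort file lacks required columns: {missing}")
    extra_features = [
        c[len("feat_"):]
        for c in reader.fieldnames
        if c.startswith("feat_")
    ]

    records: list[PatientRecord] = []
    seen: set[str] = set()
    for row in reader:
        pid = (row["patient_id"] or "").strip()
        if not pid:
            raise CohortError("row with empty patient_id")
        if pid in seen:
            raise CohortError(f"duplicate patient id {pid!r}")
        seen.add(pid)
        findings = ClinicalFindings(
            urt_obstruction=TriState.from_cell(row["urt_obstruction"] or ""),
            inguinal_hernia=TriState.from_cell(row["inguinal_hernia"] or ""),
            extras={
                name: TriState.from_cell(row[f"feat_{name}"] or "")
                for name in extra_features
            },
        )
        records.append(
            PatientRecord(
                id=pid,
                phenotype=_parse_phenotype(row["phenotype"] or "", pid),
                gestational_age=parse_gestational_age(row["gestational_age"] or ""),
                genotype=Genotype(
                    normalize_allele(row["allele1"]),
                    normalize_allele(row["allele2"]),
                ),
                idua_activity=_parse_activity(row["idua_activity"] or "", pid),
                findings=findings,
            )
        )
    return records


def write_cohort(
    cohort: Sequence[PatientRecord], dest: Union[str, Path, io.TextIOBase]
) -> None:
    """Write a cohort in the canonical comma-delimited format; round-trips
    through :func:`read_cohort` field-by-field."""
    if isinstance(dest, (str, Path)):
        with open(dest, "w", encoding="utf-8", newline="") as fh:
            write_cohort(cohort, fh)
            return

    extra_names: list[str] = []
    for rec in cohort:
        for name in rec.findings.extras:
            if name not in extra_names:
                extra_names.append(name)
    header = list(_REQUIRED_COLUMNS) + [f"feat_{n}" for n in extra_names]
    writer = csv.writer(dest, lineterminator="\n")
    writer.writerow(header)
    for rec in cohort:
        row = [
            rec.id,
            "X" if rec.phenotype == "unknown" else rec.phenotype,
            rec.gestational_age.render(),
            rec.genotype.allele1.render(),
            rec.genotype.allele2.render(),
            "X" if rec.idua_activity is None else f"{rec.idua_activity:g}",
            rec.findings.urt_obstruction.render(),
            rec.findings.inguinal_hernia.render(),
        ]
        row += [rec.findings.get(n).render() for n in extra_names]
        writer.writerow(row)


def read_mutation_list(source: Union[str, Path, io.TextIOBase]) -> SevereMutationList:
    """Read a severe-mutation list: one allele per line, ``#`` comments.

    Malformed alleles are reported with their line number; duplicates are
    deduplicated (set semantics).
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            return read_mutation_list(fh)

    alleles: set[Allele] = set()
    for lineno, line in enumerate(source, start=1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        try:
            alleles.add(normalize_allele(stripped))
        except MalformedAlleleError as exc:
            raise MalformedAlleleError(f"line {lineno}: {exc}") from exc
    return SevereMutationList(frozenset(alleles))


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------


def _data_text(name: str) -> str:
    return resources.files("mpsi_predict.data").joinpath(name).read_text("utf-8")


def load_reference_cohort() -> list[PatientRecord]:
    """The packaged 30-patient development cohort (17 Hurler, 6
    Hurler-Scheie, 7 Scheie; fibroblast IDUA activity available for 18)."""
    return read_cohort(io.StringIO(_data_text("reference_cohort.csv")))


def load_severe_mutations() -> SevereMutationList:
    """The packaged list of 25 literature-reported Hurler-predicting *IDUA*
    mutations."""
    return read_mutation_list(io.StringIO(_data_text("severe_mutations.txt")))
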