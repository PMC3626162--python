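"""Domain model and I/O for the health-financing evidence database.

The database holds one record per study. Each study assesses one or more
health financing mechanisms, and for every mechanism it addresses it carries
a qualitative impact score for each of the five health-system goals. Goals a
study did not look at are stored explicitly as ``not_considered`` — evidence
gaps are first-class data here, not missing data.

Two on-disk dialects are supported: a canonical nested JSON form and a flat
CSV form with one row per (study, mechanism) pair.
"""

from __future__ import annotations

import csv
import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from .errors import (
    EvidenceFormatError,
    IntegrityError,
    NotFoundError,
    ScattarError,
    VocabularyError,
)


class Goal(str, enum.Enum):
    """The five health-system goals a financing policy may pursue."""

    PROMOTE_EQUITY = "promote_equity"
    REDUCE_POVERTY = "reduce_poverty"
    IMPROVE_QUALITY = "improve_quality"
    GENERATE_REVENUE = "generate_revenue"
    INCREASE_USE = "increase_use"


class FinancingMechanism(str, enum.Enum):
    """The seven domestic revenue-raising mechanisms, in fixed sector order.

    User fees are deliberately split into two distinct mechanisms: the
    implementation/increase/maintenance of fees, and their reduction/removal —
    the two policies have opposite evidence profiles.
    """

    EQUITY_FUNDS_DISCOUNT_CARDS = "equity_funds_discount_cards"
    TAX_FUNDED = "tax_funded"
    PRIVATE_HEALTH_INSURANCE = "private_health_insurance"
    USER_FEES_IMPLEMENTATION = "user_fees_implementation"
    USER_FEES_REMOVAL = "user_fees_removal"
    COMMUNITY_BASED_HEALTH_INSURANCE = "community_based_health_insurance"
    NATIONAL_HEALTH_INSURANCE = "national_health_insurance"


class ImpactScore(str, enum.Enum):
    """Qualitative impact assessment of a mechanism on a goal.

    The first five members form an ordered scale from most negative to most
    positive; ``NOT_CONSIDERED`` sits outside that scale and marks a goal the
    study simply did not assess.
    """

    EVIDENCE_AGAINST = "evidence_against"
    SOME_EVIDENCE_AGAINST = "some_evidence_against"
    NO_EVIDENCE_OF_IMPACT = "no_evidence_of_impact"
    SOME_EVIDENCE_FOR = "some_evidence_for"
    EVIDENCE_FOR = "evidence_for"
    NOT_CONSIDERED = "not_considered"


#: The ordered five-point scale (excludes NOT_CONSIDERED).
ORDERED_SCORES: tuple[ImpactScore, ...] = tuple(ImpactScore)[:5]


class StudyType(str, enum.Enum):
    REVIEW = "review"
    EVALUATION = "evaluation"


def _parse_enum(cls, label: str, kind: str):
    try:
        return cls(label)
    except ValueError:
        valid = ", ".join(m.value for m in cls)
        raise VocabularyError(
            f"unknown {kind} label {label!r}; valid labels: {valid}"
        ) from None


@dataclass(frozen=True)
class Citation:
    authors: str
    title: str
    year: int
    journal: str

    def __str__(self) -> str:
        return f"{self.authors} ({self.year}). {self.title}. {self.journal}."


@dataclass
class Study:
    """One study and its per-(mechanism, goal) impact assessments.

    On construction, each addressed mechanism's assessment set is normalised
    so all five goals are present — unstated goals become explicit
    ``NOT_CONSIDERED`` entries.
    """

    study_id: str
    citation: Citation
    study_type: StudyType
    countries: list[str]
    assessments: dict[tuple[FinancingMechanism, Goal], ImpactScore]
    abstract: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.assessments:
            raise IntegrityError(
                f"study {self.study_id!r} has an empty assessment map"
            )
        for mech in self.mechanisms():
            for goal in Goal:
                self.assessments.setdefault((mech, goal), ImpactScore.NOT_CONSIDERED)

    def mechanisms(self) -> tuple[FinancingMechanism, ...]:
        """Mechanisms this study addresses, in fixed sector order."""
        addressed = {mech for mech, _ in self.assessments}
        return tuple(m for m in FinancingMechanism if m in addressed)

    def score(self, mechanism: FinancingMechanism, goal: Goal) -> ImpactScore:
        try:
            return self.assessments[(mechanism, goal)]
        except KeyError:
            raise NotFoundError(
                f"study {self.study_id!r} does not address mechanism "
                f"{mechanism.value!r}"
            ) from None


@dataclass
class EvidenceDB:
    """A collection of studies plus free-text provenance metadata."""

    studies: list[Study]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for s in self.studies:
            if s.study_id in seen:
                raise IntegrityError(f"duplicate study_id {s.study_id!r}")
            seen.add(s.study_id)

    def __len__(self) -> int:
        return len(self.studies)

    def get(self, study_id: str) -> Study:
        for s in self.studies:
            if s.study_id == study_id:
                return s
        raise NotFoundError(f"no study with id {study_id!r}")

    def country_codes(self) -> set[str]:
        out: set[str] = set()
        for s in self.studies:
            out.update(s.countries)
        return out


# ---------------------------------------------------------------------------
# I/O — canonical JSON and flat CSV dialects
# ---------------------------------------------------------------------------

CSV_COLUMNS = [
    "study_id",
    "authors",
    "title",
    "year",
    "journal",
    "study_type",
    "countries",
    "mechanism",
    *[g.value for g in Goal],
]


def _study_to_json(study: Study) -> dict:
    assessments = []
    for mech in study.mechanisms():
        for goal in Goal:
            assessments.append(
                {
                    "mechanism": mech.value,
                    "goal": goal.value,
                    "score": study.assessments[(mech, goal)].value,
                }
            )
    rec: dict = {
        "study_id": study.study_id,
        "citation": {
            "authors": study.citation.authors,
            "title": study.citation.title,
            "year": study.citation.year,
            "journal": study.citation.journal,
        },
        "study_type": study.study_type.value,
        "countries": list(study.countries),
        "assessments": assessments,
    }
    if study.abstract is not None:
        rec["abstract"] = study.abstract
    return rec


def _study_from_json(rec: Mapping, index: int) -> Study:
    try:
        cit = rec["citation"]
        citation = Citation(
            authors=str(cit["authors"]),
            title=str(cit["title"]),
            year=int(cit["year"]),
            journal=str(cit["journal"]),
        )
        study_type = _parse_enum(StudyType, rec["study_type"], "study_type")
        assessments: dict[tuple[FinancingMechanism, Goal], ImpactScore] = {}
        for a in rec["assessments"]:
            mech = _parse_enum(FinancingMechanism, a["mechanism"], "mechanism")
            goal = _parse_enum(Goal, a["goal"], "goal")
            score = _parse_enum(ImpactScore, a["score"], "score")
            assessments[(mech, goal)] = score
        return Study(
            study_id=str(rec["study_id"]),
            citation=citation,
            study_type=study_type,
            countries=[str(c) for c in rec.get("countries", [])],
            assessments=assessments,
            abstract=rec.get("abstract"),
        )
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, ScattarError):
            raise
        raise EvidenceFormatError(
            f"malformed study record #{index}: {exc}"
        ) from exc


def write_evidence(db: EvidenceDB, path: Union[str, Path], format: Optional[str] = None) -> None:
    """Write *db* to *path* as JSON (canonical) or CSV (flat)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "json":
        doc = {
            "provenance": db.provenance,
            "studies": [_study_to_json(s) for s in db.studies],
        }
        path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    elif fmt == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=CSV_COLUMNS)
            writer.writeheader()
            for s in db.studies:
                for mech in s.mechanisms():
                    row = {
                        "study_id": s.study_id,
                        "authors": s.citation.authors,
                        "title": s.citation.title,
                        "year": s.citation.year,
                        "journal": s.citation.journal,
                        "study_type": s.study_type.value,
                        "countries": ";".join(s.countries),
                        "mechanism": mech.value,
                    }
                    for goal in Goal:
                        row[goal.value] = s.assessments[(mech, goal)].value
                    writer.writerow(row)
    else:
        raise ValueError(f"unknown evidence format {fmt!r}")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("json", "csv"):
        return suffix
    raise ValueError(f"cannot infer evidence format from {path.name!r}")


def load_evidence(path: Union[str, Path], format: Optional[str] = None) -> EvidenceDB:
    """Load and validate an evidence database from JSON or CSV.

    Unknown mechanism/goal/score labels raise :class:`VocabularyError`;
    duplicate study ids raise :class:`IntegrityError`; anything unparseable
    raises :class:`EvidenceFormatError` naming the record.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "json":
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise EvidenceFormatError(f"{path}: invalid JSON ({exc})") from exc
        if not isinstance(doc, Mapping) or "studies" not in doc:
            raise EvidenceFormatError(f"{path}: missing top-level 'studies' array")
        studies = [
            _study_from_json(rec, i) for i, rec in enumerate(doc["studies"])
        ]
        return EvidenceDB(studies=studies, provenance=str(doc.get("provenance", "")))
    if fmt == "csv":
        return _load_evidence_csv(path)
    raise ValueError(f"unknown evidence format {fmt!r}")


def _load_evidence_csv(path: Path) -> EvidenceDB:
    by_id: dict[str, dict] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in CSV_COLUMNS if reader.fieldnames is None or c not in reader.fieldnames]
        if missing:
            raise EvidenceFormatError(
                f"{path}: missing columns {', '.join(missing)}"
            )
        for lineno, row in enumerate(reader, start=2):
            sid = row["study_id"]
            if not sid:
                raise EvidenceFormatError(f"{path}: line {lineno}: empty study_id")
            mech = _parse_enum(FinancingMechanism, row["mechanism"], "mechanism")
            try:
                year = int(row["year"])
            except ValueError:
                raise EvidenceFormatError(
                    f"{path}: line {lineno}: non-integer year {row['year']!r}"
                ) from None
            rec = by_id.setdefault(
                sid,
                {
                    "citation": Citation(row["authors"], row["title"], year, row["journal"]),
                    "study_type": _parse_enum(StudyType, row["study_type"], "study_type"),
                    "countries": [c for c in row["countries"].split(";") if c],
                    "assessments": {},
                    "mechs_seen": set(),
                },
            )
            if mech in rec["mechs_seen"]:
                raise IntegrityError(
                    f"{path}: line {lineno}: duplicate row for study {sid!r}, "
                    f"mechanism {mech.value!r}"
                )
            rec["mechs_seen"].add(mech)
            for goal in Goal:
                cell = row[goal.value]
                score = (
                    ImpactScore.NOT_CONSIDERED
                    if cell == ""
                    else _parse_enum(ImpactScore, cell, "score")
                )
                rec["assessments"][(mech, goal)] = score
    studies = [
        Study(
            study_id=sid,
            citation=rec["citation"],
            study_type=rec["study_type"],
            countries=rec["countries"],
            assessments=rec["assessments"],
        )
        for sid, rec in by_id.items()
    ]
    return EvidenceDB(studies=studies, provenance=f"loaded from {path.name}")


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    """Findings from :func:`validate_evidence`; empty means all clear."""

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors and not self.warnings


def validate_evidence(db: EvidenceDB) -> ValidationReport:
    """Check study-level invariants, returning a report rather than raising.

    An evaluation study with no countries is an error (its context match is
    undefined); a review with no countries is only a warning (reviews sit on
    the inner ring regardless).
    """
    report = ValidationReport()
    for s in db.studies:
        if not s.assessments:
            report.errors.append(f"{s.study_id}: empty assessment map")
        if s.study_type is StudyType.EVALUATION and not s.countries:
            report.errors.append(
                f"{s.study_id}: evaluation study with no countries"
            )
        if s.study_type is StudyType.REVIEW and not s.countries:
            report.warnings.append(
                f"{s.study_id}: review with no country list"
            )
        for mech in s.mechanisms():
            missing_goals = [g for g in Goal if (mech, g) not in s.assessments]
            if missing_goals:  # unreachable after normalisation; belt and braces
                report.errors.append(
                    f"{s.study_id}: mechanism {mech.value} missing goals "
                    f"{[g.value for g in missing_goals]}"
                )
    return report


# ---------------------------------------------------------------------------
# Querying and summarising
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudySummary:
    """One table row: a (study, mechanism) pair with all five goal scores."""

    study_id: str
    authors: str
    title: str
    year: int
    journal: str
    study_type: str
    countries: tuple[str, ...]
    mechanism: str
    scores: Mapping[str, str]  # goal value -> score value


SORT_KEYS = (
    "study_id",
    "authors",
    "title",
    "year",
    "journal",
    "study_type",
    "mechanism",
)


def _summaries(study: Study) -> Iterable[StudySummary]:
    for mech in study.mechanisms():
        yield StudySummary(
            study_id=study.study_id,
            authors=study.citation.authors,
            title=study.citation.title,
            year=study.citation.year,
            journal=study.citation.journal,
            study_type=study.study_type.value,
            countries=tuple(study.countries),
            mechanism=mech.value,
            scores={
                g.value: study.assessments[(mech, g)].value for g in Goal
            },
        )


def query_studies(
    db: EvidenceDB,
    text: Optional[str] = None,
    mechanism: Optional[FinancingMechanism] = None,
    goal: Optional[Goal] = None,
    country: Optional[str] = None,
    sort_key: str = "study_id",
    descending: bool = False,
) -> list[StudySummary]:
    """Search and sort the evidence table (one row per study-mechanism pair).

    ``text`` matches case-insensitively against the citation fields, the
    abstract and the study's country codes. The ``goal`` filter keeps rows
    whose study actually assessed that goal for the row's mechanism (i.e. the
    score is not ``not_considered``). Sorting is stable.
    """
    if sort_key not in SORT_KEYS:
        raise ValueError(
            f"unknown sort_key {sort_key!r}; valid keys: {', '.join(SORT_KEYS)}"
        )
    rows: list[StudySummary] = []
    for study in db.studies:
        if text is not None:
            haystack = " ".join(
                [
                    study.citation.authors,
                    study.citation.title,
                    str(study.citation.year),
                    study.citation.journal,
                    study.abstract or "",
                    " ".join(study.countries),
                ]
            ).lower()
            if text.lower() not in haystack:
                continue
        if country is not None and country not in study.countries:
            continue
        for row in _summaries(study):
            if mechanism is not None and row.mechanism != mechanism.value:
                continue
            if goal is not None and row.scores[goal.value] == ImpactScore.NOT_CONSIDERED.value:
                continue
            rows.append(row)
    rows.sort(key=lambda r: getattr(r, sort_key), reverse=descending)
    return rows


@dataclass
class ImpactTally:
    """Score counts for one (mechanism, goal) cell of the evidence base."""

    counts: dict[ImpactScore, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def impact_summary(
    db: EvidenceDB, mechanism: FinancingMechanism, goal: Goal
) -> ImpactTally:
    """Tally scores over studies that address *mechanism*.

    Studies not addressing the mechanism at all are excluded — they are not
    counted as ``not_considered`` for it.
    """
    counts = {score: 0 for score in ImpactScore}
    for study in db.studies:
        key = (mechanism, goal)
        if key in study.assessments:
            counts[study.assessments[key]] += 1
    return ImpactTally(counts=counts)


def study_detail(db: EvidenceDB, study_id: str) -> Study:
    """Return the full record for one study (drill-down page content).

    The returned study carries all five goal scores for every mechanism it
    addresses, with ``not_considered`` entries explicit.
    """
    return db.get(study_id)
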