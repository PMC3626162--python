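"""Shared fixtures: hand-built micro-databases and the paper-shaped fixture.

All fixtures are generated in memory or in tmp_path; nothing is read from
checked-in data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from scattar import (
    Citation,
    EvidenceDB,
    FinancingMechanism,
    Goal,
    ImpactScore,
    IndicatorTable,
    Study,
    StudyType,
    paper_shaped_fixture,
)

CBHI = FinancingMechanism.COMMUNITY_BASED_HEALTH_INSURANCE
NHI = FinancingMechanism.NATIONAL_HEALTH_INSURANCE


def _cit(authors: str, title: str, year: int = 2005) -> Citation:
    return Citation(authors=authors, title=title, year=year, journal="J Health Fin")


@pytest.fixture
def tiny_table() -> IndicatorTable:
    """Three countries with hand-computable context vectors.

    AAA sits at every indicator minimum (profile all zeros), BBB at every
    maximum (all ones) and CCC at every midpoint (all 0.5). Raw values are
    chosen per-dimension so min-max scaling is trivial to verify by hand.
    """
    base = np.arange(1.0, 12.0)  # per-dimension minima 1..11
    return IndicatorTable.from_values(
        {
            "AAA": base.copy(),
            "BBB": base + 2.0,  # per-dimension maxima
            "CCC": base + 1.0,  # midpoints
        }
    )


@pytest.fixture
def small_db() -> EvidenceDB:
    """One review, one exact-match evaluation, one worst-match evaluation.

    All three address community-based health insurance; the evaluation R2
    also addresses national health insurance (a two-mechanism study).
    """
    studies = [
        Study(
            study_id="R1",
            citation=_cit("Okello", "A review of CBHI schemes", 2008),
            study_type=StudyType.REVIEW,
            countries=[],
            assessments={(CBHI, Goal.PROMOTE_EQUITY): ImpactScore.EVIDENCE_FOR},
        ),
        Study(
            study_id="E1",
            citation=_cit("Mensah, Patel", "CBHI uptake in AAA", 2006),
            study_type=StudyType.EVALUATION,
            countries=["AAA"],
            assessments={
                (CBHI, Goal.PROMOTE_EQUITY): ImpactScore.SOME_EVIDENCE_AGAINST,
                (CBHI, Goal.INCREASE_USE): ImpactScore.EVIDENCE_FOR,
            },
            abstract="Household survey of community-based health insurance.",
        ),
        Study(
            study_id="E2",
            citation=_cit("Silva", "Insurance reform outcomes in BBB", 2010),
            study_type=StudyType.EVALUATION,
            countries=["BBB"],
            assessments={
                (CBHI, Goal.PROMOTE_EQUITY): ImpactScore.EVIDENCE_AGAINST,
                (NHI, Goal.GENERATE_REVENUE): ImpactScore.SOME_EVIDENCE_FOR,
            },
        ),
    ]
    return EvidenceDB(studies=studies, provenance="hand-built test fixture")


@pytest.fixture
def defect_db() -> EvidenceDB:
    """Five studies with planted validation defects.

    D3 is an evaluation without countries (error); D4 is a review without
    countries (warning only); the rest are clean.
    """
    mk = lambda sid, st, countries: Study(  # noqa: E731
        study_id=sid,
        citation=_cit("Khan", f"Study {sid}"),
        study_type=st,
        countries=countries,
        assessments={(CBHI, Goal.INCREASE_USE): ImpactScore.SOME_EVIDENCE_FOR},
    )
    return EvidenceDB(
        studies=[
            mk("D1", StudyType.EVALUATION, ["AAA"]),
            mk("D2", StudyType.REVIEW, ["AAA", "BBB"]),
            mk("D3", StudyType.EVALUATION, []),
            mk("D4", StudyType.REVIEW, []),
            mk("D5", StudyType.EVALUATION, ["CCC"]),
        ]
    )


@pytest.fixture(scope="session")
def paper_fixture():
    """The paper-shaped fixture: 30 countries, 88 single-mechanism studies."""
    return paper_shaped_fixture(seed=123)
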