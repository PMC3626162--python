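"""Seeded synthetic fixtures: indicator tables and evidence databases.

Real inputs would be World Bank / UN country indicators and a hand-curated
literature database; neither is redistributable here, so these generators
produce structurally faithful stand-ins. Values are drawn from plausible
low- and middle-income-country ranges — they need only be ordinally
sensible, since no statistical claim depends on them. Everything is
deterministic for a fixed seed.

:func:`paper_shaped_fixture` mirrors the published per-mechanism study
counts (2 equity funds, 2 tax, 4 private insurance, 21 fee implementation,
10 fee removal, 24 CBHI, 25 NHI — 88 assessment pairs in total).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from string import ascii_uppercase
from typing import Mapping

import numpy as np

from .context import INDICATORS, IndicatorTable
from .evidence import (
    Citation,
    EvidenceDB,
    FinancingMechanism,
    Goal,
    ImpactScore,
    ORDERED_SCORES,
    Study,
    StudyType,
)

#: Published per-mechanism study counts.
PAPER_STUDY_COUNTS: dict[FinancingMechanism, int] = {
    FinancingMechanism.EQUITY_FUNDS_DISCOUNT_CARDS: 2,
    FinancingMechanism.TAX_FUNDED: 2,
    FinancingMechanism.PRIVATE_HEALTH_INSURANCE: 4,
    FinancingMechanism.USER_FEES_IMPLEMENTATION: 21,
    FinancingMechanism.USER_FEES_REMOVAL: 10,
    FinancingMechanism.COMMUNITY_BASED_HEALTH_INSURANCE: 24,
    FinancingMechanism.NATIONAL_HEALTH_INSURANCE: 25,
}

#: Plausible per-indicator ranges (low, high, log-uniform?) for synthetic
#: low- and middle-income countries. Ordinally sensible, not calibrated.
PLAUSIBLE_RANGES: dict[str, tuple[float, float, bool]] = {
    "health_expenditure_per_capita_usd": (10.0, 500.0, False),
    "maternal_mortality_ratio": (20.0, 1500.0, False),  # per 100,000 live births
    "under5_mortality_rate": (5.0, 200.0, False),  # per 1,000 live births
    "hiv_prevalence": (0.1, 25.0, False),  # % of adults 15-49
    "malaria_incidence": (0.0, 400.0, False),  # per 1,000 at risk
    "education_index": (0.2, 0.8, False),
    "gdp_usd": (1e9, 1e12, True),
    "life_expectancy_at_birth": (40.0, 80.0, False),  # years
    "urban_population_pct": (10.0, 90.0, False),
    "poverty_125_usd_pct": (0.5, 80.0, False),  # living on < $1.25/day
    "population": (1e5, 1e9, True),
}

_MECH_PHRASES = {
    FinancingMechanism.EQUITY_FUNDS_DISCOUNT_CARDS: "health equity funds",
    FinancingMechanism.TAX_FUNDED: "tax-funded health financing",
    FinancingMechanism.PRIVATE_HEALTH_INSURANCE: "private health insurance",
    FinancingMechanism.USER_FEES_IMPLEMENTATION: "user fee implementation",
    FinancingMechanism.USER_FEES_REMOVAL: "user fee removal",
    FinancingMechanism.COMMUNITY_BASED_HEALTH_INSURANCE: "community-based health insurance",
    FinancingMechanism.NATIONAL_HEALTH_INSURANCE: "national health insurance",
}

_SURNAMES = (
    "Okello", "Mensah", "Nguyen", "Garcia", "Patel", "Abebe", "Silva",
    "Banda", "Rahman", "Diallo", "Khan", "Moyo", "Sari", "Das", "Traore",
)

_JOURNALS = (
    "Health Policy and Planning",
    "Social Science & Medicine",
    "Bulletin of Global Health Economics",
    "International Journal of Health Financing",
    "Tropical Medicine & International Health",
)


@dataclass
class SyntheticConfig:
    """Knobs for fixture generation; defaults mirror the published study mix."""

    n_countries: int = 30
    study_counts: Mapping[FinancingMechanism, int] = field(
        default_factory=lambda: dict(PAPER_STUDY_COUNTS)
    )
    review_fraction: float = 0.2
    countries_per_study: tuple[int, int] = (1, 3)
    goal_coverage_prob: float = 0.6
    score_weights: tuple[float, float, float, float, float] = (
        0.15, 0.2, 0.15, 0.25, 0.25
    )
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_countries < 2:
            raise ValueError("n_countries must be >= 2")
        for p in (self.review_fraction, self.goal_coverage_prob, self.missing_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if any(c < 0 for c in self.study_counts.values()):
            raise ValueError("study counts must be non-negative")
        lo, hi = self.countries_per_study
        if not 1 <= lo <= hi:
            raise ValueError("countries_per_study must be a range with 1 <= lo <= hi")
        w = self.score_weights
        if len(w) != 5 or any(x < 0 for x in w) or sum(w) <= 0:
            raise ValueError("score_weights must be 5 non-negative weights")


def synthetic_country_codes(n: int) -> list[str]:
    """Deterministic fake alpha-3 codes: AAA, AAB, AAC, ..."""
    codes = []
    for letters in product(ascii_uppercase, repeat=3):
        codes.append("".join(letters))
        if len(codes) == n:
            return codes
    raise ValueError("n too large")


def generate_indicator_table(config: SyntheticConfig) -> IndicatorTable:
    """Draw a synthetic country-indicator table.

    Values are uniform within :data:`PLAUSIBLE_RANGES` (log-uniform for GDP
    and population). With ``missing_fraction > 0`` a random subset of cells
    is blanked to exercise the partial-coverage distance path.
    """
    rng = np.random.default_rng([config.seed, 1])
    codes = synthetic_country_codes(config.n_countries)
    values: dict[str, np.ndarray] = {}
    for code in codes:
        vec = np.empty(len(INDICATORS))
        for j, name in enumerate(INDICATORS):
            lo, hi, log = PLAUSIBLE_RANGES[name]
            if log:
                v = 10.0 ** rng.uniform(np.log10(lo), np.log10(hi))
            else:
                v = rng.uniform(lo, hi)
            # Population is stored internally on the log10 scale.
            vec[j] = np.log10(v) if name == "population" else v
        values[code] = vec
    if config.missing_fraction > 0.0:
        for code in codes:
            mask = rng.random(len(INDICATORS)) < config.missing_fraction
            values[code][mask] = np.nan
        # Keep every indicator's bounds well-defined.
        for j in range(len(INDICATORS)):
            if all(np.isnan(values[c][j]) for c in codes):
                lo, hi, log = PLAUSIBLE_RANGES[INDICATORS[j]]
                mid = 10.0 ** ((np.log10(lo) + np.log10(hi)) / 2) if log else (lo + hi) / 2
                values[codes[0]][j] = np.log10(mid) if INDICATORS[j] == "population" else mid
    return IndicatorTable.from_values(values)


def _citation(rng: np.random.Generator, mech: FinancingMechanism,
              study_type: StudyType, countries: list[str], year: int) -> Citation:
    n_auth = int(rng.integers(1, 4))
    picks = rng.choice(len(_SURNAMES), size=n_auth, replace=False)
    authors = ", ".join(_SURNAMES[i] for i in picks)
    phrase = _MECH_PHRASES[mech]
    if study_type is StudyType.REVIEW:
        title = f"A review of {phrase} in low- and middle-income countries"
    else:
        where = " and ".join(countries[:2]) if countries else "selected settings"
        title = f"Impact of {phrase} in {where}"
    journal = _JOURNALS[int(rng.integers(0, len(_JOURNALS)))]
    return Citation(authors=authors, title=title, year=year, journal=journal)


def generate_evidence_db(
    config: SyntheticConfig, table: IndicatorTable
) -> EvidenceDB:
    """Generate an evidence database with exact per-mechanism study counts.

    Each study addresses a single mechanism. Reviews (drawn with probability
    ``review_fraction``) carry no country list; evaluations sample 1-3
    countries from the table. Each (mechanism, goal) pair is assessed with
    probability ``goal_coverage_prob``, drawing from the five-point scale
    with ``score_weights``; otherwise it is recorded as not considered.
    The output always passes :func:`scattar.evidence.validate_evidence`
    with no errors.
    """
    rng = np.random.default_rng([config.seed, 2])
    codes = table.countries()
    weights = np.asarray(config.score_weights, dtype=float)
    weights = weights / weights.sum()
    studies: list[Study] = []
    counter = 0
    for mech in FinancingMechanism:
        for _ in range(config.study_counts.get(mech, 0)):
            counter += 1
            sid = f"S{counter:04d}"
            is_review = rng.random() < config.review_fraction
            study_type = StudyType.REVIEW if is_review else StudyType.EVALUATION
            if is_review:
                countries: list[str] = []
            else:
                lo, hi = config.countries_per_study
                k = int(rng.integers(lo, hi + 1))
                k = min(k, len(codes))
                picks = rng.choice(len(codes), size=k, replace=False)
                countries = [codes[i] for i in sorted(picks)]
            assessments: dict[tuple[FinancingMechanism, Goal], ImpactScore] = {}
            for goal in Goal:
                if rng.random() < config.goal_coverage_prob:
                    idx = int(rng.choice(5, p=weights))
                    assessments[(mech, goal)] = ORDERED_SCORES[idx]
                else:
                    assessments[(mech, goal)] = ImpactScore.NOT_CONSIDERED
            year = int(rng.integers(1995, 2011))
            studies.append(
                Study(
                    study_id=sid,
                    citation=_citation(rng, mech, study_type, countries, year),
                    study_type=study_type,
                    countries=countries,
                    assessments=assessments,
                    abstract=None,
                )
            )
    return EvidenceDB(
        studies=studies,
        provenance=f"synthetic fixture (seed={config.seed})",
    )


def paper_shaped_fixture(seed: int = 0) -> tuple[IndicatorTable, EvidenceDB]:
    """30 synthetic countries plus a database with the published study mix."""
    config = SyntheticConfig(seed=seed)
    table = generate_indicator_table(config)
    db = generate_evidence_db(config, table)
    return table, db
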