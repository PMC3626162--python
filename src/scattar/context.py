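"""Country context matching: indicator normalisation and the 11-D distance.

Each country is described by 11 indicators (health expenditure per capita,
maternal mortality ratio, under-5 mortality, HIV prevalence, malaria
incidence, education index, GDP, life expectancy, urban population share,
extreme-poverty headcount, and population on a log10 scale). Every indicator
value I is rescaled to T(I) = (I - min) / (max - min) in [0, 1], with the
minima and maxima taken over the countries in the loaded table, so a country
becomes a point in the unit 11-cube. Similarity between two countries Y and
Z is the Euclidean distance d_YZ between their points; smaller means better
matched. The distance is a navigation aid, not a validated measure — exact
rankings should not be over-interpreted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .errors import (
    DistanceUndefinedError,
    EvidenceFormatError,
    NotFoundError,
    UnresolvableDistanceError,
)
from .evidence import Study, StudyType

#: The 11 indicator column names, in canonical order. ``population`` is read
#: as a raw headcount and stored as its base-10 logarithm.
INDICATORS: tuple[str, ...] = (
    "health_expenditure_per_capita_usd",
    "maternal_mortality_ratio",
    "under5_mortality_rate",
    "hiv_prevalence",
    "malaria_incidence",
    "education_index",
    "gdp_usd",
    "life_expectancy_at_birth",
    "urban_population_pct",
    "poverty_125_usd_pct",
    "population",
)

N_DIMS = len(INDICATORS)
MAX_DISTANCE = math.sqrt(N_DIMS)


@dataclass
class IndicatorTable:
    """Per-country raw indicator values with per-indicator (min, max) bounds.

    ``values`` maps country code to a float array of length 11 in
    :data:`INDICATORS` order (NaN marks a missing cell; the population entry
    is already log10-transformed). Bounds are computed over the stored rows,
    ignoring missing cells.
    """

    values: dict[str, np.ndarray]
    mins: np.ndarray
    maxs: np.ndarray

    indicators: tuple[str, ...] = INDICATORS

    @classmethod
    def from_values(cls, values: dict[str, np.ndarray]) -> "IndicatorTable":
        """Build a table, recomputing bounds from the given rows."""
        rows = {c: np.asarray(v, dtype=float) for c, v in values.items()}
        for code, row in rows.items():
            if row.shape != (N_DIMS,):
                raise ValueError(
                    f"country {code!r}: expected {N_DIMS} values, got {row.shape}"
                )
        stacked = np.vstack(list(rows.values()))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            mins = np.nanmin(stacked, axis=0)
            maxs = np.nanmax(stacked, axis=0)
        return cls(values=rows, mins=mins, maxs=maxs)

    def __contains__(self, code: str) -> bool:
        return code in self.values

    def __len__(self) -> int:
        return len(self.values)

    def countries(self) -> list[str]:
        return sorted(self.values)

    def to_frame(self) -> pd.DataFrame:
        """Export as a DataFrame in the CSV dialect (population raw again)."""
        df = pd.DataFrame.from_dict(
            {c: v for c, v in self.values.items()}, orient="index", columns=list(INDICATORS)
        )
        df["population"] = 10.0 ** df["population"]
        df.index.name = "country_code"
        return df.sort_index()


def load_indicators(path: Union[str, Path]) -> IndicatorTable:
    """Load the country indicator CSV and compute per-indicator bounds.

    The ``population`` column must hold positive raw headcounts; it is
    replaced by its base-10 logarithm before bounds are computed. Blank cells
    are flagged missing; any other non-numeric cell is a format error naming
    the row and column.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    if "country_code" not in df.columns:
        raise EvidenceFormatError(f"{path}: missing column 'country_code'")
    missing_cols = [c for c in INDICATORS if c not in df.columns]
    if missing_cols:
        raise EvidenceFormatError(
            f"{path}: missing columns {', '.join(missing_cols)}"
        )
    values: dict[str, np.ndarray] = {}
    for _, row in df.iterrows():
        code = row["country_code"]
        vec = np.empty(N_DIMS)
        for j, name in enumerate(INDICATORS):
            cell = row[name]
            if cell is None or (isinstance(cell, float) and math.isnan(cell)) or str(cell).strip() == "":
                vec[j] = np.nan
                continue
            try:
                vec[j] = float(cell)
            except ValueError:
                raise EvidenceFormatError(
                    f"{path}: country {code!r}, column {name!r}: "
                    f"non-numeric value {cell!r}"
                ) from None
        pop = vec[INDICATORS.index("population")]
        if not math.isnan(pop):
            if pop <= 0:
                raise ValueError(
                    f"{path}: country {code!r}: population must be positive, "
                    f"got {pop}"
                )
            vec[INDICATORS.index("population")] = math.log10(pop)
        values[code] = vec
    if not values:
        raise EvidenceFormatError(f"{path}: no country rows")
    return IndicatorTable.from_values(values)


def write_indicators(table: IndicatorTable, path: Union[str, Path]) -> None:
    """Write the table back to the CSV dialect (inverse of load)."""
    table.to_frame().to_csv(path, float_format="%.10g")


def transform_indicator(value: float, lo: float, hi: float) -> float:
    """Min-max scale a raw indicator value onto [0, 1].

    Values outside [lo, hi] clamp to the boundary. A degenerate indicator
    (lo == hi) is uninformative and maps every value to 0.5 so it cannot
    discriminate between countries.
    """
    if lo > hi:
        raise ValueError(f"min {lo} exceeds max {hi}")
    if lo == hi:
        return 0.5
    t = (value - lo) / (hi - lo)
    return min(1.0, max(0.0, t))


@dataclass
class ContextVector:
    """A country's 11 transformed indicator values T(I)_j in [0, 1].

    ``present`` masks the dimensions whose raw value was not missing; absent
    dimensions hold NaN in ``values``.
    """

    values: np.ndarray
    present: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.present = np.asarray(self.present, dtype=bool)
        if self.values.shape != (N_DIMS,) or self.present.shape != (N_DIMS,):
            raise ValueError(f"context vectors have exactly {N_DIMS} dimensions")
        ok = self.values[self.present]
        if ok.size and (ok.min() < 0.0 or ok.max() > 1.0):
            raise ValueError("present T(I) values must lie in [0, 1]")


def country_profile(table: IndicatorTable, country: str) -> ContextVector:
    """Transform one country's row into its unit-cube context vector."""
    try:
        raw = table.values[country]
    except KeyError:
        raise NotFoundError(
            f"country {country!r} not in indicator table "
            f"({len(table)} countries loaded)"
        ) from None
    present = ~np.isnan(raw)
    vals = np.full(N_DIMS, np.nan)
    for j in range(N_DIMS):
        if present[j] and not (math.isnan(table.mins[j]) or math.isnan(table.maxs[j])):
            vals[j] = transform_indicator(raw[j], table.mins[j], table.maxs[j])
        else:
            present[j] = False
    return ContextVector(values=vals, present=present)


@dataclass(frozen=True)
class MatchDistance:
    """A context distance and the number of indicator dimensions it used."""

    value: float
    k_present: int

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("distance cannot be negative")


def context_distance(a: ContextVector, b: ContextVector) -> MatchDistance:
    """Euclidean distance between two context vectors.

    Only dimensions present in both vectors contribute; the sum of squares is
    rescaled by 11/k (k = shared dimensions) so partial-coverage distances
    stay on the same [0, sqrt(11)] scale as full-coverage ones.
    """
    shared = a.present & b.present
    k = int(shared.sum())
    if k == 0:
        raise DistanceUndefinedError(
            "the two profiles share no present indicator dimension"
        )
    diff = a.values[shared] - b.values[shared]
    value = math.sqrt((N_DIMS / k) * float(np.dot(diff, diff)))
    return MatchDistance(value=value, k_present=k)


def rank_matches(
    table: IndicatorTable, country: str, include_self: bool = False
) -> list[tuple[str, MatchDistance]]:
    """All other countries ordered by ascending context distance.

    Ties break alphabetically by country code. With ``include_self`` the
    query country appears first at distance zero.
    """
    ref = country_profile(table, country)
    out: list[tuple[str, MatchDistance]] = []
    for code in table.countries():
        if code == country and not include_self:
            continue
        out.append((code, context_distance(ref, country_profile(table, code))))
    out.sort(key=lambda item: (item[1].value, item[0]))
    return out


def study_distance(
    study: Study, country: str, table: IndicatorTable
) -> MatchDistance:
    """Context distance from a study's countries to the chosen country.

    Multi-country studies take the minimum over their countries — the best
    match determines relevance. Reviews sit on the inner ring by convention
    and return distance zero without consulting the table. Study countries
    absent from the table are skipped with a warning; an evaluation study
    with no resolvable country raises :class:`UnresolvableDistanceError`.
    """
    if study.study_type is StudyType.REVIEW:
        return MatchDistance(value=0.0, k_present=0)
    ref = country_profile(table, country)
    best: MatchDistance | None = None
    for code in study.countries:
        if code not in table:
            warnings.warn(
                f"study {study.study_id!r}: country {code!r} absent from "
                f"indicator table; skipped",
                stacklevel=2,
            )
            continue
        d = context_distance(ref, country_profile(table, code))
        if best is None or d.value < best.value:
            best = d
    if best is None:
        raise UnresolvableDistanceError(
            f"evaluation study {study.study_id!r} has no country resolvable "
            f"in the indicator table (countries={study.countries})"
        )
    return best
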