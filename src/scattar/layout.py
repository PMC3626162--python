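"""Pure geometry engine for scattar plots.

A scattar plot is a hybrid scatter/radar display: an annulus divided into 7
sectors, one per financing mechanism. Every (study, mechanism) assessment
pair becomes one dot. Radius encodes context mismatch (inner ring = exact
country match, outer ring = worst possible match), colour encodes the impact
score for the chosen goal, and shape distinguishes reviews (squares, pinned
to the inner ring) from primary evaluations (circles). Every plot for a
given database shows the same dots: changing the country moves them, changing
the goal recolours them. Grey dots mark studies that addressed the mechanism
but never assessed the goal — the evidence gaps.

This module computes a render-agnostic layout; SVG emission lives in
:mod:`scattar.render`.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from typing import Optional

from .context import MAX_DISTANCE, IndicatorTable, MatchDistance, study_distance
from .errors import LayoutError, NotFoundError
from .evidence import (
    EvidenceDB,
    FinancingMechanism,
    Goal,
    ImpactScore,
    StudyType,
)

TWO_PI = 2.0 * math.pi

#: Fixed sector order, clockwise from 12 o'clock.
SECTOR_ORDER: tuple[FinancingMechanism, ...] = tuple(FinancingMechanism)


class ColorCategory(str, enum.Enum):
    GREEN = "green"
    LIGHT_GREEN = "light_green"
    ORANGE = "orange"
    LIGHT_RED = "light_red"
    RED = "red"
    GREY = "grey"


class DotShape(str, enum.Enum):
    SQUARE = "square"
    CIRCLE = "circle"


_COLOR_OF_SCORE = {
    ImpactScore.EVIDENCE_FOR: ColorCategory.GREEN,
    ImpactScore.SOME_EVIDENCE_FOR: ColorCategory.LIGHT_GREEN,
    ImpactScore.NO_EVIDENCE_OF_IMPACT: ColorCategory.ORANGE,
    ImpactScore.SOME_EVIDENCE_AGAINST: ColorCategory.LIGHT_RED,
    ImpactScore.EVIDENCE_AGAINST: ColorCategory.RED,
    ImpactScore.NOT_CONSIDERED: ColorCategory.GREY,
}


def dot_color(score: ImpactScore) -> ColorCategory:
    """Colour for an impact score: green (for) through red (against), orange
    for definite evidence of no impact, grey for goals not considered."""
    return _COLOR_OF_SCORE[score]


def dot_shape(study_type: StudyType) -> DotShape:
    """Reviews are squares on the inner ring; evaluations are circles."""
    return DotShape.SQUARE if study_type is StudyType.REVIEW else DotShape.CIRCLE


@dataclass(frozen=True)
class GeometryConfig:
    """Shared geometry for a scattar plot, in abstract length units."""

    inner_radius: float = 60.0
    outer_radius: float = 240.0
    sector_gap: float = 0.08  # radians of dead space between sectors
    dot_diameter: float = 9.0
    max_distance: float = MAX_DISTANCE

    def __post_init__(self) -> None:
        if not 0 < self.inner_radius < self.outer_radius:
            raise ValueError("require 0 < inner_radius < outer_radius")
        if not 0 <= self.sector_gap < TWO_PI / len(SECTOR_ORDER):
            raise ValueError("sector_gap must be in [0, 2*pi/7)")
        if self.max_distance <= 0:
            raise ValueError("max_distance must be positive")


def dot_radius(d: MatchDistance, geometry: GeometryConfig) -> float:
    """Normalised radius in [0, 1]: 0 on the inner ring, 1 on the outer.

    Linear in the distance, normalised by the theoretical maximum (sqrt(11)
    by default) so layouts remain comparable across databases.
    """
    if d.value > geometry.max_distance:
        raise ValueError(
            f"distance {d.value} exceeds max_distance {geometry.max_distance}"
        )
    return d.value / geometry.max_distance


@dataclass(frozen=True)
class Dot:
    study_id: str
    mechanism: FinancingMechanism
    shape: DotShape
    radius_norm: float  # 0 = inner ring, 1 = outer ring
    angle: float  # radians clockwise from 12 o'clock
    color: ColorCategory


@dataclass
class ScattarLayout:
    """The computed dot set for one (country, goal) view of a database."""

    country: str
    goal: Goal
    sectors: dict[FinancingMechanism, tuple[float, float]]
    dots: list[Dot]
    geometry: GeometryConfig = field(default_factory=GeometryConfig)

    def sector_counts(self) -> dict[FinancingMechanism, int]:
        counts = {m: 0 for m in SECTOR_ORDER}
        for dot in self.dots:
            counts[dot.mechanism] += 1
        return counts

    def positions(self) -> list[tuple[str, str, float, float]]:
        """(study_id, mechanism, radius, angle) — the goal-independent part."""
        return [
            (d.study_id, d.mechanism.value, d.radius_norm, d.angle)
            for d in self.dots
        ]

    def to_json(self) -> str:
        """Serialise for external renderers: polar plus Cartesian coordinates.

        Cartesian coordinates put the origin at the plot centre with y down
        (screen convention); angle 0 points to 12 o'clock and increases
        clockwise.
        """
        g = self.geometry
        dots = []
        for d in self.dots:
            r = g.inner_radius + d.radius_norm * (g.outer_radius - g.inner_radius)
            dots.append(
                {
                    "study_id": d.study_id,
                    "mechanism": d.mechanism.value,
                    "shape": d.shape.value,
                    "radius_norm": d.radius_norm,
                    "angle": d.angle,
                    "color": d.color.value,
                    "x": r * math.sin(d.angle),
                    "y": -r * math.cos(d.angle),
                }
            )
        doc = {
            "country": self.country,
            "goal": self.goal.value,
            "geometry": {
                "inner_radius": g.inner_radius,
                "outer_radius": g.outer_radius,
                "sector_gap": g.sector_gap,
                "dot_diameter": g.dot_diameter,
                "max_distance": g.max_distance,
            },
            "sectors": {
                m.value: [start, end] for m, (start, end) in self.sectors.items()
            },
            "dots": dots,
        }
        return json.dumps(doc, indent=2, sort_keys=True)


def sector_bounds() -> dict[FinancingMechanism, tuple[float, float]]:
    """Seven equal angular sectors clockwise from 12 o'clock, in fixed order."""
    span = TWO_PI / len(SECTOR_ORDER)
    return {
        mech: (i * span, (i + 1) * span) for i, mech in enumerate(SECTOR_ORDER)
    }


def layout_scattar(
    db: EvidenceDB,
    table: IndicatorTable,
    country: str,
    goal: Goal,
    geometry: Optional[GeometryConfig] = None,
) -> ScattarLayout:
    """Compute the dot layout for one (country, goal) view.

    One dot per (study, mechanism) assessment pair. Radii come from the
    study's context distance to *country* (reviews pinned at zero); colours
    from its score for (mechanism, *goal*). Within each sector dots are
    ordered by (radius, study_id) and placed at deterministic evenly spread
    angles, so identical inputs always produce identical layouts and
    coincident dots get successive angular slots instead of overplotting.
    """
    geometry = geometry or GeometryConfig()
    if country not in table:
        raise NotFoundError(
            f"country {country!r} not in indicator table"
        )
    # Radius is per-study (same in every sector); compute once.
    radii: dict[str, float] = {}
    failures: list[str] = []
    for study in db.studies:
        try:
            radii[study.study_id] = dot_radius(
                study_distance(study, country, table), geometry
            )
        except Exception as exc:
            failures.append(f"{study.study_id}: {exc}")
    if failures:
        raise LayoutError(
            "cannot place studies: " + "; ".join(sorted(failures))
        )

    sectors = sector_bounds()
    per_sector: dict[FinancingMechanism, list[tuple[float, str, DotShape, ColorCategory]]] = {
        m: [] for m in SECTOR_ORDER
    }
    for study in db.studies:
        shape = dot_shape(study.study_type)
        r = 0.0 if shape is DotShape.SQUARE else radii[study.study_id]
        for mech in study.mechanisms():
            color = dot_color(study.assessments[(mech, goal)])
            per_sector[mech].append((r, study.study_id, shape, color))

    dots: list[Dot] = []
    for mech in SECTOR_ORDER:
        entries = sorted(per_sector[mech], key=lambda e: (e[0], e[1]))
        start, end = sectors[mech]
        usable_start = start + geometry.sector_gap / 2.0
        usable = (end - start) - geometry.sector_gap
        n = len(entries)
        for i, (r, sid, shape, color) in enumerate(entries):
            angle = usable_start + usable * (i + 0.5) / n
            dots.append(
                Dot(
                    study_id=sid,
                    mechanism=mech,
                    shape=shape,
                    radius_norm=r,
                    angle=angle,
                    color=color,
                )
            )
    return ScattarLayout(
        country=country, goal=goal, sectors=sectors, dots=dots, geometry=geometry
    )


def layout_thumbnails(
    db: EvidenceDB,
    table: IndicatorTable,
    country: str,
    geometry: Optional[GeometryConfig] = None,
) -> dict[Goal, ScattarLayout]:
    """One layout per goal, sharing identical positions and differing only in
    colour — the thumbnail strip under the main plot."""
    return {
        goal: layout_scattar(db, table, country, goal, geometry) for goal in Goal
    }
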