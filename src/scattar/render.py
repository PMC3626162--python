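"""Deterministic SVG rendering of scattar layouts.

SVG is emitted by direct string assembly with fixed-precision coordinates so
that identical layouts always yield byte-identical documents, and every dot
marker carries a ``data-study-id`` attribute for downstream interactivity
(hover cards, click-through to the study page).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

from .errors import ScattarError
from .evidence import Goal
from .layout import ColorCategory, DotShape, ScattarLayout

DEFAULT_PALETTE: dict[ColorCategory, str] = {
    ColorCategory.GREEN: "#1a9641",
    ColorCategory.LIGHT_GREEN: "#a6d96a",
    ColorCategory.ORANGE: "#fdae61",
    ColorCategory.LIGHT_RED: "#f4a0a0",
    ColorCategory.RED: "#d7191c",
    ColorCategory.GREY: "#b0b0b0",
}

SECTOR_LABELS = {
    "equity_funds_discount_cards": "Equity funds",
    "tax_funded": "Tax funded",
    "private_health_insurance": "Private insurance",
    "user_fees_implementation": "User fees (implement)",
    "user_fees_removal": "User fees (remove)",
    "community_based_health_insurance": "CBHI",
    "national_health_insurance": "NHI",
}

GOAL_LABELS = {
    Goal.PROMOTE_EQUITY: "Promote equity",
    Goal.REDUCE_POVERTY: "Reduce poverty",
    Goal.IMPROVE_QUALITY: "Improve quality",
    Goal.GENERATE_REVENUE: "Generate revenue",
    Goal.INCREASE_USE: "Increase use",
}


@dataclass(frozen=True)
class StyleConfig:
    palette: Mapping[ColorCategory, str] = field(
        default_factory=lambda: dict(DEFAULT_PALETTE)
    )
    canvas: int = 640
    font_family: str = "Helvetica, Arial, sans-serif"
    font_size: float = 12.0
    ring_stroke: str = "#666666"
    ring_stroke_width: float = 1.0
    legend: bool = True

    def __post_init__(self) -> None:
        if set(self.palette) != set(ColorCategory):
            raise ValueError("palette must cover all 6 colour categories")
        if self.canvas <= 0:
            raise ValueError("canvas size must be positive")


def _fmt(x: float) -> str:
    return f"{x:.2f}"


def _polar(cx: float, cy: float, r: float, angle: float) -> tuple[float, float]:
    # Angle measured clockwise from 12 o'clock; SVG y grows downward.
    return cx + r * math.sin(angle), cy - r * math.cos(angle)


def _plot_group(layout: ScattarLayout, style: StyleConfig, scale: float,
                tx: float, ty: float, label: Optional[str] = None,
                with_labels: bool = True) -> list[str]:
    g = layout.geometry
    half = style.canvas / 2.0
    cx = cy = half
    parts = [
        f'<g transform="translate({_fmt(tx)},{_fmt(ty)}) scale({_fmt(scale)})">'
    ]
    ring = (
        f'fill="none" stroke="{style.ring_stroke}" '
        f'stroke-width="{_fmt(style.ring_stroke_width)}"'
    )
    parts.append(f'<circle class="ring inner" cx="{_fmt(cx)}" cy="{_fmt(cy)}" r="{_fmt(g.inner_radius)}" {ring}/>')
    parts.append(f'<circle class="ring outer" cx="{_fmt(cx)}" cy="{_fmt(cy)}" r="{_fmt(g.outer_radius)}" {ring}/>')
    # Sector boundaries and labels.
    for mech, (start, _end) in layout.sectors.items():
        x1, y1 = _polar(cx, cy, g.inner_radius, start)
        x2, y2 = _polar(cx, cy, g.outer_radius, start)
        parts.append(
            f'<line class="sector-boundary" x1="{_fmt(x1)}" y1="{_fmt(y1)}" '
            f'x2="{_fmt(x2)}" y2="{_fmt(y2)}" stroke="{style.ring_stroke}" '
            f'stroke-width="{_fmt(style.ring_stroke_width)}"/>'
        )
    if with_labels:
        for mech, (start, end) in layout.sectors.items():
            mid = (start + end) / 2.0
            lx, ly = _polar(cx, cy, g.outer_radius + 18.0, mid)
            parts.append(
                f'<text class="sector-label" x="{_fmt(lx)}" y="{_fmt(ly)}" '
                f'text-anchor="middle" font-family="{style.font_family}" '
                f'font-size="{_fmt(style.font_size)}">{SECTOR_LABELS[mech.value]}</text>'
            )
    # Dots.
    for d in layout.dots:
        r = g.inner_radius + d.radius_norm * (g.outer_radius - g.inner_radius)
        x, y = _polar(cx, cy, r, d.angle)
        fill = style.palette[d.color]
        common = (
            f'class="dot" data-study-id="{d.study_id}" '
            f'data-mechanism="{d.mechanism.value}" data-color="{d.color.value}" '
            f'fill="{fill}"'
        )
        if d.shape is DotShape.SQUARE:
            side = g.dot_diameter
            parts.append(
                f'<rect {common} x="{_fmt(x - side / 2)}" y="{_fmt(y - side / 2)}" '
                f'width="{_fmt(side)}" height="{_fmt(side)}"/>'
            )
        else:
            parts.append(
                f'<circle {common} cx="{_fmt(x)}" cy="{_fmt(y)}" '
                f'r="{_fmt(g.dot_diameter / 2)}"/>'
            )
    if label is not None:
        parts.append(
            f'<text class="plot-title" x="{_fmt(half)}" y="{_fmt(style.font_size + 2)}" '
            f'text-anchor="middle" font-family="{style.font_family}" '
            f'font-size="{_fmt(style.font_size + 2)}">{label}</text>'
        )
    parts.append("</g>")
    return parts


def _legend_group(style: StyleConfig, tx: float, ty: float) -> list[str]:
    entries = [
        (ColorCategory.GREEN, "Evidence for"),
        (ColorCategory.LIGHT_GREEN, "Some evidence for"),
        (ColorCategory.ORANGE, "No evidence of impact"),
        (ColorCategory.LIGHT_RED, "Some evidence against"),
        (ColorCategory.RED, "Evidence against"),
        (ColorCategory.GREY, "Goal not considered"),
    ]
    parts = [f'<g class="legend" transform="translate({_fmt(tx)},{_fmt(ty)})">']
    for i, (cat, text) in enumerate(entries):
        y = i * (style.font_size + 6)
        parts.append(
            f'<circle cx="6.00" cy="{_fmt(y)}" r="5.00" fill="{style.palette[cat]}"/>'
        )
        parts.append(
            f'<text x="16.00" y="{_fmt(y + style.font_size / 3)}" '
            f'font-family="{style.font_family}" '
            f'font-size="{_fmt(style.font_size)}">{text}</text>'
        )
    parts.append("</g>")
    return parts


def render_svg(layout: ScattarLayout, style: Optional[StyleConfig] = None) -> str:
    """Render one scattar plot as a standalone SVG 1.1 document."""
    style = style or StyleConfig()
    w = style.canvas + (150 if style.legend else 0)
    h = style.canvas
    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{w}" height="{h}" viewBox="0 0 {w} {h}">',
        f'<title>{GOAL_LABELS[layout.goal]} — {layout.country}</title>',
    ]
    parts += _plot_group(
        layout, style, scale=1.0, tx=0.0, ty=0.0,
        label=f"{GOAL_LABELS[layout.goal]} in {layout.country}",
    )
    if style.legend:
        parts += _legend_group(style, tx=style.canvas + 10.0, ty=style.canvas / 3.0)
    parts.append("</svg>")
    return "\n".join(parts) + "\n"


def render_page(
    main: ScattarLayout,
    thumbs: Mapping[Goal, ScattarLayout],
    style: Optional[StyleConfig] = None,
) -> str:
    """Composite page: the main plot with 5 goal thumbnails underneath.

    The thumbnails share the main plot's positions and differ only in colour,
    giving an immediate impression of how the evidence shifts across goals.
    """
    style = style or StyleConfig()
    if set(thumbs) != set(Goal):
        missing = [g.value for g in Goal if g not in thumbs]
        raise ScattarError(
            f"thumbnail set must cover all 5 goals; missing: {', '.join(missing)}"
        )
    thumb_scale = 0.18
    thumb_w = style.canvas * thumb_scale
    w = style.canvas + (150 if style.legend else 0)
    h = style.canvas + thumb_w + 30
    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_fmt(w)}" height="{_fmt(h)}" viewBox="0 0 {_fmt(w)} {_fmt(h)}">',
        f'<title>Evidence summary — {main.country}</title>',
    ]
    parts += _plot_group(
        main, style, scale=1.0, tx=0.0, ty=0.0,
        label=f"{GOAL_LABELS[main.goal]} in {main.country}",
    )
    for i, goal in enumerate(Goal):
        tx = i * (thumb_w + 6.0)
        parts += _plot_group(
            thumbs[goal], style, scale=thumb_scale, tx=tx,
            ty=style.canvas + 10.0, with_labels=False,
        )
        parts.append(
            f'<text class="thumb-label" x="{_fmt(tx + thumb_w / 2)}" '
            f'y="{_fmt(style.canvas + thumb_w + 24.0)}" text-anchor="middle" '
            f'font-family="{style.font_family}" '
            f'font-size="{_fmt(style.font_size - 2)}">{GOAL_LABELS[goal]}</text>'
        )
    if style.legend:
        parts += _legend_group(style, tx=style.canvas + 10.0, ty=style.canvas / 3.0)
    parts.append("</svg>")
    return "\n".join(parts) + "\n"
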