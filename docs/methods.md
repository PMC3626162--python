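# Methods

This note documents the model implemented by `scattar`, the choices made
where the design was genuinely open, and what the synthetic fixtures do and
do not establish about real data.

## Evidence model

A *study* is the unit of evidence. Each study addresses one or more of
seven health financing mechanisms and, for every mechanism it addresses,
carries a qualitative score for each of five health-system goals on the
ordered scale *evidence against* < *some evidence against* < *no evidence
of impact* < *some evidence for* < *evidence for*, plus the out-of-scale
state *not considered*. Two normalisation rules are applied at
construction time and are deliberate modelling choices, not conveniences:

- **Explicit gaps.** If a study addresses a mechanism but a goal's score is
  unstated, the score is materialised as `not_considered`. Gaps in the
  evidence are data: they become the grey dots that show where the
  literature is silent.
- **Mechanisms are the join key.** A study addressing several mechanisms is
  stored once but contributes one table row / one plot dot per mechanism.
  This is why per-mechanism counts can legitimately sum to more than the
  number of studies.

User fees are split into two mechanisms — implementation/increase versus
reduction/removal — because the two policies have opposite evidence
profiles and merging them would cancel signal.

The canonical on-disk form is nested JSON; a flat CSV dialect (one row per
study-mechanism pair, goals as five columns, countries semicolon-joined)
is provided for spreadsheet workflows. Both round-trip losslessly.
Vocabulary is closed: unknown mechanism/goal/score labels are rejected at
load, never coerced.

## Context matching

Countries are identified by ISO 3166-1 alpha-3 codes and described by 11
indicators chosen to be widely available and transparent (see
`scattar.context.INDICATORS`). Population enters on a log₁₀ scale —
raw headcounts would let one indicator dominate the metric by four orders
of magnitude. Each indicator is min-max scaled to [0, 1] with bounds taken
over the countries in the loaded table, and the distance between two
countries is the Euclidean distance between their 11-vectors.

Numerical and degenerate-input choices:

- **Clamping.** A value outside the table's [min, max] (possible when a
  user supplies a country profile from newer data) clamps to the boundary,
  keeping the codomain contract rather than extrapolating.
- **Degenerate indicator** (min = max): every country maps to 0.5 and the
  dimension contributes zero to every distance. An indicator that cannot
  discriminate should not discriminate.
- **Missing values.** A blank indicator cell is flagged absent rather than
  imputed. Distances are computed over the k dimensions present in both
  profiles and rescaled by √(11/k) so partial- and full-coverage distances
  share the [0, √11] scale. Two profiles with no shared dimension have no
  defined distance (an error, not 0 or ∞).
- **No direction handling.** Whether a high value is "good" is irrelevant:
  the distance is symmetric in the sign of differences.
- **Multi-country studies** take the *minimum* distance over their
  countries: a study is as relevant as its best-matching setting. Ties in
  rankings break alphabetically by country code for determinism.
- **Reviews** have distance 0 by convention and their country lists are
  never consulted: synthesised evidence sits on the inner ring.

The functional forms (linear scaling, Euclidean distance) are the standard
reading of the source material, which describes the transformation only as
mapping into [0, 1] and the distance as an 11-dimensional distance between
points; both are isolated behind `transform_indicator` and
`context_distance` so either could be swapped without touching the rest of
the package. The measure was never formally validated and the package
treats it as a visual sorting aid only.

## Layout

A layout is pure geometry, independent of rendering. Seven equal sectors in
a fixed order (equity funds, tax, private insurance, fee implementation,
fee removal, CBHI, NHI), clockwise from 12 o'clock. Radius is the study
distance normalised by the *theoretical* maximum √11 — not the observed
maximum — so layouts are comparable across databases. Squares (reviews) are
pinned at radius 0; circles at radius 0 are studies of exactly the chosen
country.

Angular placement is not described in the source material, so the scheme
here is a convention chosen for reproducibility: within each sector, dots
are ordered by (radius, study id) and placed at evenly spread angles. This
also resolves collisions — dots with identical radius receive successive
angular slots instead of overplotting, so every study remains individually
addressable by a renderer. The consequences are the package's core
invariants, all tested: the dot set and its positions depend only on
(database, country); colours depend only on (database, goal); every plot of
one database has the same number of dots; identical inputs give
byte-identical layouts.

## Rendering

SVG is assembled as text with fixed two-decimal coordinates, giving
byte-identical documents for identical inputs. Every dot marker carries
`data-study-id`, `data-mechanism` and `data-color` attributes — the hooks a
web front-end needs for hover cards and click-through. The default palette
is a five-step diverging green-to-red ramp with grey for unassessed goals;
whether the original display used distinct colours for "some evidence"
grades is unknown, and a five-step ramp was chosen to preserve the full
ordered scale. The composite page mirrors the published tool: one main plot
plus five goal thumbnails that share positions and differ only in colour.

## Synthetic fixtures

Real inputs would be World Bank / UN indicator tables and a hand-curated
study database; neither is redistributable, so seeded generators produce
stand-ins. Indicator values are drawn uniformly (log-uniformly for GDP and
population) from plausible low- and middle-income-country ranges hard-coded
in `scattar.synthetic.PLAUSIBLE_RANGES`; they are ordinally sensible, not
calibrated, and no statistical claim depends on them. The default study mix
is the published one: 2 equity-fund, 2 tax, 4 private-insurance, 21
fee-implementation, 10 fee-removal, 24 CBHI and 25 NHI studies (88
assessment pairs). Each generated study addresses a single mechanism;
multi-mechanism studies are exercised by hand-built fixtures in the tests.
Defaults chosen once where no source value exists: 30 countries (enough for
a non-trivial distance distribution at negligible cost), review fraction
0.2 (reviews are a minority of this literature), goal coverage probability
0.6 (roughly as many assessed as unassessed goal cells, so both coloured
dots and grey gaps appear), 1–3 countries per evaluation, and mildly
optimistic score weights (0.15/0.2/0.15/0.25/0.25 from most negative to
most positive).

What passing tests on these fixtures show: the metric, layout rules,
serialisation and CLI behave correctly for any database with this
structure. What they do not show: anything about the content of the real
literature — the generators emulate the *shape* of the evidence base
(counts, coverage, country spread), not real-world indicator correlations
or actual study findings.

## Problem sizes and limitations

Tests and the acceptance script run the full pipeline on the 30-country,
88-pair fixture and verify the distance metric against a brute-force oracle
on 1,000 random vector pairs — sizes at which everything completes in
seconds while still exercising every code path, including partial-coverage
distances via configurable missingness.

Known limitations: the context measure weights all 11 indicators equally
and was never validated; a review's constituent countries are ignored by
design, which flattens genuinely multi-country syntheses onto the inner
ring; and the evidence model cannot represent mixed financing strategies —
a study of a combined reform must be coded under each mechanism separately.
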