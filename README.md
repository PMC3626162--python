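# scattar

Context-matched navigation of the evidence on health financing policy.

Policy makers in low- and middle-income countries choosing between health
financing mechanisms — user fees, community-based health insurance (CBHI),
national/social health insurance (NHI), private insurance, tax funding,
equity funds — face a literature that is broad, heterogeneous, and hard to
survey. `scattar` implements the engine behind a visual evidence-navigation
tool for exactly this problem. It takes a database of studies, each scored
qualitatively for its reported impact of a financing mechanism on five
health-system goals (promote equity, reduce poverty, improve quality,
generate revenue, increase use), and lays every study out on a **scattar
plot**: a hybrid scatter/radar display whose seven sectors are the financing
mechanisms, whose dot colours encode the reported impact on a chosen goal,
and whose dot radii encode how closely each study's countries match a
user-chosen country.

## The model

**Context matching.** Each country is described by 11 indicators *I₁…I₁₁*
(health expenditure per capita, maternal mortality ratio, under-5 mortality,
HIV prevalence, malaria incidence, education index, GDP, life expectancy,
urban population share, $1.25/day poverty headcount, and log₁₀ population).
Every indicator is min-max normalised over the countries in the table,

&nbsp;&nbsp;&nbsp;&nbsp;*T(I) = (I − I_min) / (I_max − I_min)* ∈ [0, 1],

so a country *Y* becomes a point {*T(I)ⱼ*} in the unit 11-cube. Similarity
between countries *Y* and *Z* is the Euclidean distance

&nbsp;&nbsp;&nbsp;&nbsp;*d_YZ = √Σⱼ (T(I)ⱼ(Y) − T(I)ⱼ(Z))²* ∈ [0, √11],

with a √(11/k) rescaling when only *k* < 11 dimensions are available in
both profiles. A study's distance to the chosen country is the minimum
*d_YZ* over the countries it examined. The distance is a visual sorting
aid, not a validated similarity measure — exact rankings should not be
over-interpreted.

**The plot.** One dot per (study, mechanism) assessment pair, so every plot
of a given database has the same number of dots. Review studies are squares
pinned to the inner ring; primary evaluations are circles whose distance
from the inner ring is *d* / √11 (dots *on* the inner ring study exactly the
chosen country). Colours run green ("evidence for") through orange
("definite evidence of no impact") to red ("evidence against"); grey marks
studies that addressed the mechanism but never assessed the chosen goal —
the evidence gaps. Changing the country moves the dots; changing the goal
only recolours them.

Because neither the original 78-study bibliography nor licensed indicator
data can be redistributed, the package ships seeded synthetic generators
(`scattar.synthetic`) producing structurally faithful stand-ins, including
a fixture with the published per-mechanism study mix
(2 equity funds, 2 tax, 4 private, 21 fee-implementation, 10 fee-removal,
24 CBHI, 25 NHI — 88 assessment pairs).

## Worked example

Generate fixtures, rank context matches, and render a plot:

```sh
$ scattar simulate --seed 42 --out-dir fx
wrote 30 countries and 88 studies to fx

$ scattar match --indicators fx/indicators.csv --country AAA --top 5
country  distance  k_indicators
-------  --------  ------------
AAP      0.6068    11
AAV      0.8295    11
AAR      0.9071    11
AAJ      0.9196    11
AAM      1.0821    11
```

Country `AAP` is the closest context match to `AAA`: its 11-indicator
profile sits 0.6068 away in the unit cube (0 would be an identical profile,
√11 ≈ 3.3166 the worst possible mismatch), using all 11 indicators.

```sh
$ scattar list --evidence fx/evidence.json --mechanism tax_funded --sort year
study_id  authors     year  study_type  countries  mechanism   promote_equity  ...
--------  ----------  ----  ----------  ---------  ----------  --------------
S0003     Das, Silva  1995  evaluation  AAS;AAT    tax_funded  not_considered
S0004     Nguyen      2007  review                 tax_funded  not_considered
```

Both tax-funded studies carry explicit scores for all five goals;
`not_considered` rows are retained deliberately — they become the grey dots
that show where evidence is lacking.

```sh
$ scattar plot --evidence fx/evidence.json --indicators fx/indicators.csv \
    --country AAA --goal promote_equity --output equity_AAA.svg
```

The SVG shows the main plot (88 dots across 7 sectors) with five goal
thumbnails sharing identical positions, and every marker carries a
`data-study-id` attribute so a renderer can attach hover/click behaviour.
`scattar detail --evidence fx/evidence.json S0003` prints any study's full
per-goal score table, and `scattar validate` checks database invariants.

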