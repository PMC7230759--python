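# Methods

`nutriprofile` classifies prepacked foods under ten front-of-package (FOP)
nutrient-profiling schemes, harmonises each scheme's output to a binary
"healthier" verdict, and compares the schemes statistically. This note
documents the models, the configuration data, the synthetic food-supply
generator, and the numerical and design choices a maintainer would want to
audit.

## Scope and data model

The unit of analysis is one prepacked product with a per-100 g nutrient
declaration (energy in kJ, total/saturated fat, total sugars, salt, fibre,
protein, plus optional trans fat, added sugars, fruit/vegetable/nut share,
wholegrain share, calcium, and a sweetener flag) in one of seven leaf
categories: breakfast cereals, pasta, cheese, plain/flavoured/drinkable
yoghurt, and cooking oils. Sodium is derived from salt at the EU labelling
factor of 400 mg/g. All models are applied per 100 g, for drinks as well
(label declarations are per 100 g; density differences are ignored).

Missing optional nutrients default to zero with a logged warning — a
product that does not declare a positive nutrient is assumed to contain
none of it, which is the conservative direction for every scheme. Missing
mandatory nutrients invalidate the row; in permissive reads invalid rows
are dropped with a machine-readable reason, in strict reads the first
violation aborts. Accepted plus rejected rows always cover the input.

## The ten schemes

Four are point-scoring models sharing one skeleton — negative/baseline
points from energy, saturated fat, total sugars and sodium minus
positive/modifying points from fruit/vegetable/nut (FVN) content, fibre and
protein — differing in category structure, tables and cut-offs:

- **Nutri-Score (2017 foods algorithm).** Categories: general food, cheese,
  added fats. Added fats score saturated fat as a percentage of total fat.
  If negative points reach 11 and FVN points are below 5, protein points
  are suppressed — except for cheese, where protein always counts. Letters
  from the shipped boundaries (A ≤ −1, B ≤ 2, C ≤ 10, D ≤ 18, E above).
  Healthier = A or B.
- **Ofcom NPM (2004/05).** Two categories (food/drink); A-points (max 10
  per component) minus C-points (max 5); protein suppressed when A ≥ 11
  unless FVN scores 5. Healthier = permitted for marketing to children:
  score < 4 (foods) or < 1 (drinks).
- **FSANZ NPSC (2016).** Three categories; category 3 (oils/spreads and
  cheese with ≥ 320 mg calcium/100 g) uses an extended saturated-fat table
  (to 30 points) and a cut-off of 28; protein suppressed at baseline ≥ 13
  unless FVN scores 5. Healthier = permitted to carry claims
  (score < 1 / < 4 / < 28).
- **HSR (2016).** Four categories here (food, dairy food, oils, cheese);
  NPSC-style tables with extended fibre/protein tables (to 15 points), and
  a per-category score→star breakpoint map. Healthier = ≥ 3.5 stars.

Six are threshold schemes — conjunctions of per-category limits:

- **UK FSA traffic light (per-100 g, 2007 bands).** Fat green ≤ 3.0 / red
  > 17.5; sat fat 1.5 / 5.0; sugars 5.0 / 22.5; salt 0.3 / 1.5 (g/100 g).
  Healthier = no red light. Applied to every category, including
  single-ingredient cooking oils: any oil with ≥ 90 g fat/100 g is
  necessarily fat-red, so the healthier share of cooking oils is
  structurally 0% under this scheme.
- **Protective Food symbol.** Traffic-light screen (no red) with category
  overrides: dairy requires total fat < 3 g and saturated fat < 1.5 g per
  100 g (strict comparisons, as printed in the scheme's criteria); cooking
  oils qualify when they could carry an authorised nutrition/health claim.
  The claim predicate shipped here — unsaturated fat ≥ 70% of total fat and
  supplying > 20% of energy at 37 kJ/g — is this package's
  operationalisation and is config-replaceable. For a degenerate zero-energy
  declaration the energy-share condition is treated as satisfied when any
  unsaturated fat is present (the share tends to infinity), which keeps
  eligibility monotone in energy.
- **Keyhole, Choices, Finnish Heart, WHO-Europe.** Per-category limit sets
  (see configuration below). Flavoured yoghurt drinks use each scheme's
  fermented-milk-drink category. The WHO-Europe energy rule applies to
  pasta only; its category assignment for dried pasta is ambiguous in the
  source taxonomy, and the shipped 1570 kJ/100 g limit is this package's
  transcription choice.

## Configuration as data

Every numeric table and limit ships as versioned YAML under
`nutriprofile/data/`; the code implements only the scoring/thresholding
skeletons. This keeps the transcriptions auditable and swappable; the test
suite pins each file by SHA-256 so silent drift fails loudly, checks that
threshold lists are strictly increasing with non-decreasing points, and
checks that each symbol scheme references only the nutrients its protocol
uses. Two transcription decisions in the HSR tables deserve note: the dairy
categories are exempt from the 13-point protein-suppression rule (protein
marks dairy content), and cheese shares the extended saturated-fat table
with oils, mirroring the NPSC's treatment of the two as one category. The
fibre point tables default to the AOAC thresholds (EU labels declare AOAC
fibre); an NSP variant is selectable by config. Nutrient values are
compared against thresholds exactly as declared — no rounding is applied
before lookup, since label rounding happens upstream of the dataset.

A known tension in the literature this package implements: published
category results report ~91% of cooking oils at Nutri-Score A/B, which the
2017 added-fats tables cannot produce — at 37 kJ per g of fat, any ≥ 91 g
fat oil scores 10 energy points and lands at grade C or worse. The package
ships the standard public tables and makes no attempt to reverse-engineer
a variant; the reproducible oil results (traffic light 0%, Ofcom 0%,
degenerate kappa 0) are the ones used as acceptance anchors.

## Comparison statistics

- **Proportions.** Per (category, model): n, healthier count, share. No
  aggregation across categories is offered — the five categories are a
  purposive, not representative, sample of a market.
- **Sales weighting.** Healthier sales over total sales; sales units are
  unitless relative weights. Products without recorded sales are excluded
  from both sums and counted in the log. An empty or zero-sales denominator
  is an error, never a silent 0.
- **Cohen's kappa.** Direct formula, κ = (p_o − p_e)/(1 − p_e), with p_e
  from the binary marginals. When both raters are constant p_e = 1 and the
  statistic is 0/0; the package returns 0 with a `degenerate` flag —
  agreement is indistinguishable from chance under zero variation, and this
  matches the reported 0 for oils under the traffic light. Band labels
  follow the printed ranges (0.01–0.20 none-to-slight, …, 0.81–0.99 near
  perfect); κ ≤ 0 and κ = 1.0 fold into the adjacent outer bands and the
  raw value is always reported alongside the label. An independent oracle
  (scikit-learn) verifies the implementation to 1e−12 in tests.
- **Scenario cross-tab.** For a (symbol, rating) pair: A = green rating +
  symbol, B = green only, C = symbol but non-green (the conflicting case),
  D = neither. Only interpretive rating models (Nutri-Score, HSR, traffic
  light) expose a green notion.

## Synthetic supply generator

The real dataset behind the published comparison (a national branded-food
composition survey with retailer sales, N = 1,370) is not deposited, so the
package ships a seeded generator that emulates its structure: per-category
truncated-normal (or uniform) nutrient draws with hard bounds inside the
panel invariants, a wholegrain subpopulation for cereals and pasta, sugar
distributions ordered plain < flavoured across yoghurt subtypes, fat- and
salt-rich cheese, and cooking oils with total fat uniform on [91, 100]
g/100 g, saturated fat truncated-normal on [7, 92] (clipped to total fat)
and energy tied to fat at 37 kJ/g. The shipped spec generates 800 products
(180 cereals, 160 pasta, 190 cheese, 220 yoghurt products, 50 oils) — a
desk-scale market chosen for fast, deterministic runs rather than a match
to any real category sizes.

Sales are log-normal (heavy-tailed, μ = 4, σ = 1.2 on the log scale). A
per-category bias coefficient `b` couples log-sales to a healthiness index
— the negated Ofcom score, standardised within category. The Ofcom score is
used because it is continuous and category-agnostic, avoiding circularity
with any single binary scheme under test; it is negated so the index is
healthiness-oriented and the sign convention is direct: `b < 0` makes
market leaders less healthy, so sales-weighting lowers the healthier share
(the published breakfast-cereals pattern, shipped default b = −0.8), and
`b > 0` raises it (the cheese pattern, b = +0.8). With b = 0 sales are
independent of composition.

What the generator does *not* emulate: brand/retailer structure, real
category sizes and market shares, correlations between nutrients beyond
the constructed ones, label rounding, and missing-data patterns. Tests that
pass on synthetic supplies therefore validate the *machinery* (scoring,
harmonisation, statistics, bias mechanism), not any empirical claim about
a real market.

## Numerical choices and degenerate inputs

- Point lookups use a binary search over the threshold list; an
  independently coded linear scan serves as the oracle in tests.
- Added-fats ratio with zero total fat: ratio points are 0 with a warning.
- Proportions over empty categories and sales weighting over zero total
  sales raise errors rather than returning 0.
- Kappa needs at least two items; mismatched lengths are input errors.
- Determinism: generation is a pure function of the spec + seed (the sales
  stream is derived from the same seed); classification is a pure function
  of panel + config. Identical inputs give byte-identical reports.

## Known limitations

- The symbol-scheme limits and HSR star breakpoints are best-effort
  transcriptions of the public protocol documents; the version tags and
  checksum pins make any correction an explicit, visible config change.
- Per-portion traffic-light overrides, beverage classes beyond the studied
  categories, the full Finnish/Keyhole category taxonomies, and the 2022/23
  Nutri-Score revision are out of scope (the latter could be added as an
  alternative config).
- Whether flavoured yoghurts face added-sugar or total-sugar limits varies
  by scheme and is recorded per scheme in the config files (Choices limits
  added sugars; Finnish Heart limits total sugars for flavoured products).
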